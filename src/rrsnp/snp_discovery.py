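"""Diagnostic SNP selection.

Candidate detection followed by a seven-part audit:

* C1 — the variant allele is unique to a single group (autapomorphy);
* C2 — pooled read depth at the site is at least ``min_depth``;
* C3 — 50 bp of flank on either side, with no indel or ambiguity
  evidence within ``clean_zone`` bp of the site;
* C4 — the minor allele has at least ``min_minor_reads`` reads and at
  least ``min_minor_fraction`` of the A/C/G/T calls;
* C5 — within the focal group the variant allele reaches
  ``min_group_identity`` of the group's calls;
* C6 — the site is outside repeat masks and off mtDNA contigs;
* W  — a position-weighted window score of nearby polymorphisms stays
  below the rejection threshold;
* C7 — at most one locus per contig is kept (highest pooled depth,
  leftmost on ties).

Every criterion's verdict is recorded independently; nothing
short-circuits in the audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConfigurationError, PreconditionError
from .io_formats import MaskSet
from .pileup import ACGT, GroupScheme, PileupColumn, column_group_counts

DEFAULT_WINDOW_WEIGHTS: Tuple[Tuple[int, int, int], ...] = (
    (1, 5, 3),
    (6, 10, 2),
    (11, 20, 1),
)


@dataclass
class FilterParams:
    min_depth: int = 8
    flank_len: int = 50
    clean_zone: int = 20
    min_minor_reads: int = 3
    min_minor_fraction: float = 0.04
    min_group_identity: float = 0.95
    window_radius: int = 20
    window_weights: Tuple[Tuple[int, int, int], ...] = DEFAULT_WINDOW_WEIGHTS
    window_reject_threshold: int = 6
    other_group_tolerance_reads: int = 0
    # a neighboring position counts as polymorphic for the window filter
    # when >= 2 alleles each carry at least this many reads
    window_min_allele_reads: int = 2

    def validate(self) -> None:
        for name in ("min_depth", "flank_len", "clean_zone", "min_minor_reads",
                     "window_radius", "window_reject_threshold",
                     "other_group_tolerance_reads"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        for name in ("min_minor_fraction", "min_group_identity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name}: must be in [0, 1]")
        if self.window_radius > self.flank_len:
            raise ConfigurationError("window_radius: must be <= flank_len")

    def weight_for(self, distance: int) -> int:
        for lo, hi, weight in self.window_weights:
            if lo <= distance <= hi:
                return weight
        return 0


@dataclass
class CandidateSNP:
    contig: str
    pos0: int
    major_allele: str
    minor_allele: str
    pooled_counts: Dict[str, int]
    group_counts: Dict[str, Dict[str, int]]
    focal_group: Optional[str] = None

    @property
    def pooled_depth(self) -> int:
        return sum(n for b, n in self.pooled_counts.items() if b in ACGT)

    @property
    def minor_count(self) -> int:
        return self.pooled_counts.get(self.minor_allele, 0)


@dataclass
class FilterResult:
    candidate: CandidateSNP
    per_criterion: Dict[str, Tuple[bool, str]] = field(default_factory=dict)

    def record(self, criterion: str, passed: bool, reason: str) -> None:
        self.per_criterion[criterion] = (passed, reason)

    @property
    def final(self) -> bool:
        return all(passed for passed, _ in self.per_criterion.values())

    def passed(self, criterion: str) -> bool:
        return self.per_criterion[criterion][0]


@dataclass
class ValidatedLocus:
    locus_id: str
    candidate: CandidateSNP
    left_flank: str
    right_flank: str
    bracket_context: str


# ---------------------------------------------------------------------------
# candidate detection (putative SNPs)
# ---------------------------------------------------------------------------

def detect_candidates(
    columns: Iterable[PileupColumn], scheme: GroupScheme
) -> List[CandidateSNP]:
    """One candidate per column with >= 2 distinct A/C/G/T alleles.

    Major/minor are the two most frequent pooled bases; ties break by
    fixed base order A < C < G < T.
    """
    out: List[CandidateSNP] = []
    for column in columns:
        acgt = column.acgt_counts()
        observed = [b for b in ACGT if acgt.get(b, 0) >= 1]
        if len(observed) < 2:
            continue
        ranked = sorted(observed, key=lambda b: (-acgt[b], b))
        by_group, pooled = column_group_counts(column, scheme)
        out.append(
            CandidateSNP(
                contig=column.contig,
                pos0=column.pos0,
                major_allele=ranked[0],
                minor_allele=ranked[1],
                pooled_counts=pooled,
                group_counts=by_group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# criterion 1 — autapomorphy
# ---------------------------------------------------------------------------

def classify_autapomorphy(
    candidate: CandidateSNP, params: FilterParams, scheme: GroupScheme
) -> Optional[str]:
    """Return the focal group if the minor allele is unique to one group.

    The focal group is the group holding the minor-allele reads; every
    other group may carry at most ``other_group_tolerance_reads`` of the
    allele.  The verdict is stored on the candidate.
    """
    allele = candidate.minor_allele
    counts = {
        group: candidate.group_counts.get(group, {}).get(allele, 0)
        for group in scheme.groups()
    }
    carriers = [g for g, n in counts.items() if n > 0]
    if not carriers:
        candidate.focal_group = None
        return None
    focal = max(sorted(counts), key=lambda g: counts[g])
    others_ok = all(
        n <= params.other_group_tolerance_reads
        for g, n in counts.items()
        if g != focal
    )
    # focal must stand out unambiguously beyond the tolerance
    runner_up = max(
        (n for g, n in counts.items() if g != focal), default=0
    )
    if counts[focal] == 0 or counts[focal] == runner_up or not others_ok:
        candidate.focal_group = None
        return None
    candidate.focal_group = focal
    return focal


# ---------------------------------------------------------------------------
# criteria 2–5
# ---------------------------------------------------------------------------

def filter_candidate(
    candidate: CandidateSNP,
    column_context: Mapping[int, PileupColumn],
    contig_length: int,
    params: FilterParams,
) -> FilterResult:
    """Evaluate depth, flank/clean-zone, minor-allele and group-identity rules.

    Requires a focal group (criterion 1 already applied); all four
    verdicts are recorded independently.
    """
    if candidate.focal_group is None:
        raise PreconditionError(
            f"candidate {candidate.contig}:{candidate.pos0} has no focal group"
        )
    result = FilterResult(candidate=candidate)
    _apply_c2_to_c5(result, column_context, contig_length, params)
    return result


def _apply_c2_to_c5(
    result: FilterResult,
    column_context: Mapping[int, PileupColumn],
    contig_length: int,
    params: FilterParams,
) -> None:
    cand = result.candidate
    column = column_context[cand.pos0]

    depth = column.depth()
    result.record("C2", depth >= params.min_depth,
                  f"pooled depth {depth} vs min {params.min_depth}")

    left_ok = cand.pos0 >= params.flank_len
    right_ok = contig_length - cand.pos0 - 1 >= params.flank_len
    dirty = []
    for pos in range(cand.pos0 - params.clean_zone,
                     cand.pos0 + params.clean_zone + 1):
        col = column_context.get(pos)
        if col is not None and (col.indel_evidence > 0 or col.ambiguous_evidence > 0):
            dirty.append(pos)
    c3 = left_ok and right_ok and not dirty
    reason = (f"flanks {'ok' if left_ok and right_ok else 'short'}; "
              f"{len(dirty)} dirty position(s) within {params.clean_zone} bp")
    result.record("C3", c3, reason)

    minor_n = cand.minor_count
    acgt_depth = cand.pooled_depth
    fraction = minor_n / acgt_depth if acgt_depth else 0.0
    c4 = minor_n >= params.min_minor_reads and fraction >= params.min_minor_fraction
    result.record("C4", c4,
                  f"minor {minor_n} reads, {fraction:.3f} of {acgt_depth}")

    if cand.focal_group is None:
        result.record("C5", False, "no focal group")
        return
    group = cand.group_counts.get(cand.focal_group, {})
    group_depth = sum(n for b, n in group.items() if b in ACGT)
    focal_n = group.get(cand.minor_allele, 0)
    identity = focal_n / group_depth if group_depth else 0.0
    c5 = group_depth > 0 and identity >= params.min_group_identity
    result.record("C5", c5,
                  f"focal identity {identity:.3f} ({focal_n}/{group_depth})")


# ---------------------------------------------------------------------------
# position-weighted window filter
# ---------------------------------------------------------------------------

def window_score(
    candidate: CandidateSNP,
    nearby_polymorphic_positions: Sequence[int],
    params: FilterParams,
) -> Tuple[int, bool]:
    """Score neighboring polymorphisms by distance band; reject at >= threshold.

    ``nearby_polymorphic_positions`` holds distances in bases (positive
    integers up to ``window_radius``).  Returns (score, passed).
    """
    score = 0
    for distance in nearby_polymorphic_positions:
        if distance == 0:
            raise PreconditionError("distance 0 is the SNP itself")
        if distance < 0 or distance > params.window_radius:
            raise PreconditionError(
                f"distance {distance} outside (0, {params.window_radius}]"
            )
        score += params.weight_for(distance)
    return score, score < params.window_reject_threshold


def window_neighbor_distances(
    candidate: CandidateSNP,
    column_context: Mapping[int, PileupColumn],
    params: FilterParams,
) -> List[int]:
    """Distances of polymorphic neighbors within the window radius.

    A neighbor is polymorphic when at least two A/C/G/T alleles each
    carry ``window_min_allele_reads`` reads — unguarded singletons are
    sequencing noise at pyrosequencing error rates.
    """
    distances: List[int] = []
    for pos in range(candidate.pos0 - params.window_radius,
                     candidate.pos0 + params.window_radius + 1):
        if pos == candidate.pos0:
            continue
        column = column_context.get(pos)
        if column is None:
            continue
        counts = column.acgt_counts()
        strong = sum(1 for n in counts.values()
                     if n >= params.window_min_allele_reads)
        if strong >= 2:
            distances.append(abs(pos - candidate.pos0))
    return distances


# ---------------------------------------------------------------------------
# criterion 6 — masks
# ---------------------------------------------------------------------------

def mask_filter(candidate: CandidateSNP, masks: MaskSet) -> bool:
    """True (pass) iff the site is unmasked and off mtDNA contigs."""
    return not masks.contains(candidate.contig, candidate.pos0)


# ---------------------------------------------------------------------------
# criterion 7 — one per contig, flank extraction
# ---------------------------------------------------------------------------

def extract_flanks(
    candidate: CandidateSNP, reference_sequence: str, flank_len: int
) -> Tuple[str, str, str]:
    """Reference flanks around the site plus the bracketed context string."""
    pos = candidate.pos0
    if pos < flank_len or len(reference_sequence) - pos - 1 < flank_len:
        raise PreconditionError(
            f"flank of {flank_len} bp overruns contig at {candidate.contig}:{pos}"
        )
    left = reference_sequence[pos - flank_len:pos]
    right = reference_sequence[pos + 1:pos + 1 + flank_len]
    context = f"{left}[{candidate.major_allele}/{candidate.minor_allele}]{right}"
    return left, right, context


def select_one_per_contig(
    passing: Sequence[FilterResult],
    reference: Mapping[str, str],
    params: FilterParams,
) -> List[ValidatedLocus]:
    """Keep one locus per contig: highest pooled depth, leftmost on ties."""
    best: Dict[str, FilterResult] = {}
    for result in passing:
        cand = result.candidate
        incumbent = best.get(cand.contig)
        if incumbent is None:
            best[cand.contig] = result
            continue
        inc = incumbent.candidate
        if (cand.pooled_depth, -cand.pos0) > (inc.pooled_depth, -inc.pos0):
            best[cand.contig] = result
    loci: List[ValidatedLocus] = []
    for contig in sorted(best):
        cand = best[contig].candidate
        left, right, context = extract_flanks(
            cand, reference[contig], params.flank_len
        )
        loci.append(
            ValidatedLocus(
                locus_id=f"{contig}:{cand.pos0}",
                candidate=cand,
                left_flank=left,
                right_flank=right,
                bracket_context=context,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# pairwise diagnostic counts (Table 2-style matrix)
# ---------------------------------------------------------------------------

def _group_consensus(candidate: CandidateSNP, group: str) -> Optional[str]:
    counts = {b: n for b, n in candidate.group_counts.get(group, {}).items()
              if b in ACGT and n > 0}
    if not counts:
        return None
    return sorted(counts, key=lambda b: (-counts[b], b))[0]


def pairwise_counts(
    candidates: Sequence[CandidateSNP], scheme: GroupScheme
) -> pd.DataFrame:
    """Ordered-pair matrix: entry (A, B) counts candidates focal to A whose
    group-consensus base differs between A and B.  Diagonal is zero."""
    groups = scheme.groups()
    matrix = pd.DataFrame(0, index=groups, columns=groups)
    for cand in candidates:
        focal = cand.focal_group
        if focal is None:
            continue
        focal_base = _group_consensus(cand, focal)
        if focal_base is None:
            continue
        for other in groups:
            if other == focal:
                continue
            other_base = _group_consensus(cand, other)
            if other_base is not None and other_base != focal_base:
                matrix.loc[focal, other] += 1
    return matrix


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    results: List[FilterResult]
    loci: List[ValidatedLocus]
    attrition: Dict[str, int]
    pairwise: pd.DataFrame


def audit_candidate(
    candidate: CandidateSNP,
    column_context: Mapping[int, PileupColumn],
    contig_length: int,
    masks: MaskSet,
    params: FilterParams,
    scheme: GroupScheme,
) -> FilterResult:
    """Full C1–C6 + W audit with no short-circuiting."""
    result = FilterResult(candidate=candidate)
    focal = classify_autapomorphy(candidate, params, scheme)
    result.record("C1", focal is not None,
                  f"focal group {focal}" if focal else "variant not unique to one group")
    _apply_c2_to_c5(result, column_context, contig_length, params)
    result.record("C6", mask_filter(candidate, masks),
                  "outside masks" if mask_filter(candidate, masks)
                  else "in repeat mask or mtDNA contig")
    distances = window_neighbor_distances(candidate, column_context, params)
    score, ok = window_score(candidate, distances, params)
    result.record("W", ok, f"window score {score} "
                           f"(threshold {params.window_reject_threshold})")
    return result


def discover_loci(
    columns_by_contig: Mapping[str, Mapping[int, PileupColumn]],
    reference: Mapping[str, str],
    scheme: GroupScheme,
    masks: MaskSet,
    params: FilterParams,
) -> DiscoveryResult:
    """Run the full selection procedure and report the attrition funnel."""
    params.validate()
    masks = masks.normalized()
    results: List[FilterResult] = []
    for contig in sorted(columns_by_contig):
        context = columns_by_contig[contig]
        ordered = [context[pos] for pos in sorted(context)]
        for cand in detect_candidates(ordered, scheme):
            results.append(
                audit_candidate(cand, context, len(reference[contig]),
                                masks, params, scheme)
            )

    c1 = [r for r in results if r.passed("C1")]
    c2_5 = [r for r in c1 if all(r.passed(c) for c in ("C2", "C3", "C4", "C5"))]
    c6 = [r for r in c2_5 if r.passed("C6")]
    w = [r for r in c6 if r.passed("W")]
    loci = select_one_per_contig(w, reference, params)
    selected = {(l.candidate.contig, l.candidate.pos0) for l in loci}
    for result in results:
        key = (result.candidate.contig, result.candidate.pos0)
        result.record("C7", key in selected,
                      "selected" if key in selected else "not selected for contig")

    attrition = {
        "candidates": len(results),
        "pass_c1": len(c1),
        "pass_c2_c5": len(c2_5),
        "pass_mask": len(c6),
        "pass_window": len(w),
        "one_per_contig": len(loci),
    }
    pairwise = pairwise_counts([r.candidate for r in c2_5], scheme)
    return DiscoveryResult(results=results, loci=loci,
                           attrition=attrition, pairwise=pairwise)


def write_audit_tsv(results: Sequence[FilterResult], path) -> None:
    criteria = ["C1", "C2", "C3", "C4", "C5", "C6", "W", "C7"]
    with open(path, "w") as fh:
        header = ["contig", "pos0", "major", "minor", "focal_group", "depth"]
        header += criteria + ["final"]
        fh.write("\t".join(header) + "\n")
        for result in sorted(results, key=lambda r: (r.candidate.contig,
                                                     r.candidate.pos0)):
            cand = result.candidate
            row = [cand.contig, str(cand.pos0), cand.major_allele,
                   cand.minor_allele, cand.focal_group or ".",
                   str(cand.pooled_depth)]
            for c in criteria:
                if c in result.per_criterion:
                    row.append("PASS" if result.passed(c) else "FAIL")
                else:
                    row.append(".")
            row.append("PASS" if result.final else "FAIL")
            fh.write("\t".join(row) + "\n")
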