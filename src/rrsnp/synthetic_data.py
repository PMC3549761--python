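"""Synthetic reference panels, in-silico genome reduction, and read simulation.

The module builds a multi-contig reference seeded with restriction-site
cassettes so that a controlled minority of the genome survives double
digestion plus size selection, plants three classes of variants
(group-diagnostic, shared, and rare within-group), and simulates
barcoded 454-like single-end reads with substitution and
homopolymer-indel errors.  Every stochastic stage is driven by one
integer seed; the stream order is panel -> reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError
from .io_formats import MaskSet

BASES = "ACGT"
ECORI_SITE = "GAATTC"  # cuts G^AATTC
BFAI_SITE = "CTAG"     # cuts C^TAG
ECORI_CUT_OFFSET = 1
BFAI_CUT_OFFSET = 1
MTDNA_CONTIG = "mtDNA"
MTDNA_LENGTH = 16_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Design of a synthetic lineage panel."""

    n_groups: int = 10
    individuals_per_group: Union[int, Sequence[int]] = 4
    genome_length: int = 2_000_000
    n_contigs: int = 40
    autapomorphic_rate: float = 0.05   # fixed-difference SNPs / kb / group
    shared_poly_rate: float = 0.05    # shared polymorphisms / kb
    within_group_rate: float = 0.05   # rare within-group variants / kb
    repeat_fraction: float = 0.05
    mtdna_contig: bool = True
    seed: int = 0
    group_names: Optional[Sequence[str]] = None
    # cassette geometry controls what fraction of the genome is retainable
    spacer_len_range: Tuple[int, int] = (1500, 4500)
    insert_len_range: Tuple[int, int] = (380, 650)

    def validate(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError("n_groups: must be >= 2")
        for count in self.individuals_counts():
            if count < 1:
                raise ConfigurationError("individuals_per_group: must be >= 1")
        if self.genome_length < self.n_contigs:
            raise ConfigurationError("genome_length: must be >= n_contigs")
        if self.n_contigs < 1:
            raise ConfigurationError("n_contigs: must be >= 1")
        for name in ("autapomorphic_rate", "shared_poly_rate",
                     "within_group_rate", "repeat_fraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.group_names is not None and len(self.group_names) != self.n_groups:
            raise ConfigurationError("group_names: length must equal n_groups")

    def groups(self) -> List[str]:
        if self.group_names is not None:
            return list(self.group_names)
        return [f"grp{i + 1:02d}" for i in range(self.n_groups)]

    def individuals_counts(self) -> List[int]:
        if isinstance(self.individuals_per_group, int):
            return [self.individuals_per_group] * self.n_groups
        counts = list(self.individuals_per_group)
        if len(counts) != self.n_groups:
            raise ConfigurationError(
                "individuals_per_group: list length must equal n_groups"
            )
        return counts


@dataclass
class TruthSNP:
    contig: str
    pos0: int
    focal_group: str  # group label, "shared", or the group of a rare variant
    ref: str
    alt: str
    kind: str  # "autapomorphic" | "shared" | "rare"


@dataclass
class TruthPanel:
    """Reference contigs, per-individual haplotypes, and truth tables.

    Haplotypes are stored sparsely as per-haplotype substitution maps
    (position -> alternate base) over the reference; use
    :meth:`haplotype_sequence` to materialize a full sequence.
    """

    contigs: List[Tuple[str, str]]
    variants: Dict[str, Dict[str, Tuple[Dict[int, str], Dict[int, str]]]]
    truth_snps: List[TruthSNP]
    masks: MaskSet
    group_map: Dict[str, str]

    def contig_seq(self, contig: str) -> str:
        for name, seq in self.contigs:
            if name == contig:
                return seq
        raise KeyError(contig)

    def reference_dict(self) -> Dict[str, str]:
        return dict(self.contigs)

    def individuals(self) -> List[str]:
        return sorted(self.group_map)

    def haplotype_sequence(self, individual: str, contig: str, hap: int) -> str:
        ref = self.contig_seq(contig)
        subs = self.variants[individual][contig][hap]
        if not subs:
            return ref
        chars = list(ref)
        for pos, alt in subs.items():
            chars[pos] = alt
        return "".join(chars)

    def haplotype_slice(
        self, individual: str, contig: str, hap: int, start: int, end: int
    ) -> str:
        ref = self.contig_seq(contig)
        subs = self.variants[individual][contig][hap]
        chunk = list(ref[start:end])
        for pos, alt in subs.items():
            if start <= pos < end:
                chunk[pos - start] = alt
        return "".join(chunk)

    def haplotype_base(self, individual: str, contig: str, hap: int, pos0: int) -> str:
        subs = self.variants[individual][contig][hap]
        if pos0 in subs:
            return subs[pos0]
        return self.contig_seq(contig)[pos0]


@dataclass
class Fragment:
    """A restriction fragment as a 0-based half-open interval."""

    contig: str
    start: int
    end: int
    left_end: str   # "EcoRI" | "BfaI" | "terminus"
    right_end: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigurationError("start/end: require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadSimParams:
    """Parameters of the 454-like read simulator."""

    mean_read_length: float = 379.0
    read_length_sd: float = 40.0
    mean_depth: float = 2.0        # reads per retained fragment per individual
    depth_dispersion: float = 0.3  # 0 disables per-individual yield variation
    sub_error_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    size_min: int = 450
    size_max: int = 600
    require_mixed_ends: bool = True
    min_read_length: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.size_min > self.size_max:
            raise ConfigurationError("size_min: must be <= size_max")
        if self.mean_read_length <= 0:
            raise ConfigurationError("mean_read_length: must be > 0")
        for name in ("sub_error_rate", "homopolymer_indel_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}: must be in [0, 1]")
        if self.mean_depth < 0 or self.depth_dispersion < 0:
            raise ConfigurationError("mean_depth/depth_dispersion: must be >= 0")


@dataclass
class SimulatedRead:
    """One simulated read plus its error-free truth placement."""

    read_id: str
    individual: str
    fastq_sequence: str   # barcode + error-perturbed insert
    contig: str
    start: int            # truth placement of the insert, 0-based
    cigar: str
    insert_sequence: str  # read sequence without the barcode

    @property
    def quality(self) -> str:
        return "I" * len(self.fastq_sequence)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _scrub_sites(seq: str, rng: np.random.Generator) -> str:
    """Disrupt any internal recognition site so cassette inserts stay whole."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for motif in (ECORI_SITE, BFAI_SITE):
            idx = s.find(motif)
            if idx >= 0:
                pos = idx + int(rng.integers(0, len(motif)))
                old = chars[pos]
                choices = [b for b in BASES if b != old]
                chars[pos] = choices[int(rng.integers(0, 3))]
                changed = True
                break
    return "".join(chars)


def _build_contig(rng: np.random.Generator, length: int, cfg: PanelConfig) -> str:
    """Concatenate spacer / EcoRI / insert / BfaI cassettes up to ``length``."""
    parts: List[str] = []
    total = 0
    lo_s, hi_s = cfg.spacer_len_range
    lo_i, hi_i = cfg.insert_len_range
    while total < length:
        spacer = _random_bases(rng, int(rng.integers(lo_s, hi_s + 1)))
        insert = _scrub_sites(_random_bases(rng, int(rng.integers(lo_i, hi_i + 1))), rng)
        cassette = spacer + ECORI_SITE + insert + BFAI_SITE
        parts.append(cassette)
        total += len(cassette)
    return "".join(parts)[:length]


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(config: PanelConfig) -> TruthPanel:
    """Build a deterministic truth panel from a validated configuration.

    Planted autapomorphic SNPs are fixed (both haplotypes) in every
    individual of their focal group and absent elsewhere; shared
    polymorphisms segregate in at least two groups; rare variants sit on
    a single haplotype of a single individual.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = config.groups()
    group_map: Dict[str, str] = {}
    for group, count in zip(groups, config.individuals_counts()):
        for k in range(count):
            group_map[f"{group}_i{k + 1}"] = group

    # contigs: genome_length split evenly, plus an optional mtDNA contig
    base_len = config.genome_length // config.n_contigs
    lengths = [base_len] * config.n_contigs
    lengths[0] += config.genome_length - base_len * config.n_contigs
    contigs: List[Tuple[str, str]] = []
    for i, length in enumerate(lengths):
        contigs.append((f"contig{i + 1:04d}", _build_contig(rng, length, config)))
    nuclear_names = [name for name, _ in contigs]
    if config.mtdna_contig:
        contigs.append((MTDNA_CONTIG, _build_contig(rng, MTDNA_LENGTH, config)))

    variants: Dict[str, Dict[str, Tuple[Dict[int, str], Dict[int, str]]]] = {
        ind: {name: ({}, {}) for name, _ in contigs} for ind in sorted(group_map)
    }
    members: Dict[str, List[str]] = {g: [] for g in groups}
    for ind in sorted(group_map):
        members[group_map[ind]].append(ind)

    contig_lens = {name: len(seq) for name, seq in contigs}
    nuclear_weights = np.array([contig_lens[n] for n in nuclear_names], dtype=float)
    nuclear_weights /= nuclear_weights.sum()
    genome_kb = config.genome_length / 1000.0
    used_positions: set = set()
    truth_snps: List[TruthSNP] = []
    ref_by_name = dict(contigs)

    def draw_site() -> Optional[Tuple[str, int, str, str]]:
        for _ in range(50):
            contig = nuclear_names[int(rng.choice(len(nuclear_names), p=nuclear_weights))]
            pos = int(rng.integers(0, contig_lens[contig]))
            if (contig, pos) in used_positions:
                continue
            ref_base = ref_by_name[contig][pos]
            if ref_base not in BASES:
                continue
            alts = [b for b in BASES if b != ref_base]
            alt = alts[int(rng.integers(0, 3))]
            used_positions.add((contig, pos))
            return contig, pos, ref_base, alt
        return None

    # autapomorphic: fixed in focal group, absent elsewhere
    n_aut = int(round(config.autapomorphic_rate * genome_kb))
    for group in groups:
        for _ in range(n_aut):
            site = draw_site()
            if site is None:
                continue
            contig, pos, ref_base, alt = site
            for ind in members[group]:
                variants[ind][contig][0][pos] = alt
                variants[ind][contig][1][pos] = alt
            truth_snps.append(TruthSNP(contig, pos, group, ref_base, alt, "autapomorphic"))

    # shared polymorphisms: segregate in >= 2 groups
    n_shared = int(round(config.shared_poly_rate * genome_kb))
    for _ in range(n_shared):
        site = draw_site()
        if site is None:
            continue
        contig, pos, ref_base, alt = site
        k = int(rng.integers(2, min(4, config.n_groups) + 1))
        chosen = [groups[i] for i in sorted(rng.choice(config.n_groups, size=k, replace=False))]
        for group in chosen:
            for j, ind in enumerate(members[group]):
                for hap in (0, 1):
                    # first haplotype of the first member is forced alt so the
                    # variant truly segregates in every chosen group
                    if (j == 0 and hap == 0) or rng.random() < 0.5:
                        variants[ind][contig][hap][pos] = alt
        truth_snps.append(TruthSNP(contig, pos, "shared", ref_base, alt, "shared"))

    # rare within-group variants: a single haplotype of one individual
    n_rare = int(round(config.within_group_rate * genome_kb))
    for _ in range(n_rare):
        site = draw_site()
        if site is None:
            continue
        contig, pos, ref_base, alt = site
        group = groups[int(rng.integers(0, config.n_groups))]
        ind = members[group][int(rng.integers(0, len(members[group])))]
        variants[ind][contig][int(rng.integers(0, 2))][pos] = alt
        truth_snps.append(TruthSNP(contig, pos, group, ref_base, alt, "rare"))

    truth_snps.sort(key=lambda s: (s.contig, s.pos0))

    # repeat masks covering ~repeat_fraction of the nuclear genome
    masks = MaskSet()
    target = config.repeat_fraction * config.genome_length
    covered = 0.0
    while covered < target:
        contig = nuclear_names[int(rng.choice(len(nuclear_names), p=nuclear_weights))]
        span = int(rng.integers(500, 3000))
        start = int(rng.integers(0, max(1, contig_lens[contig] - span)))
        masks.intervals.setdefault(contig, []).append((start, start + span))
        covered += span
    if config.mtdna_contig:
        masks.mtdna_contigs.add(MTDNA_CONTIG)
    masks = masks.normalized()

    return TruthPanel(
        contigs=contigs,
        variants=variants,
        truth_snps=truth_snps,
        masks=masks,
        group_map=group_map,
    )


# ---------------------------------------------------------------------------
# in-silico genome reduction
# ---------------------------------------------------------------------------

def digest_genome(sequence: str, contig_id: str) -> List[Fragment]:
    """Double-digest ``sequence`` at EcoRI (G^AATTC) and BfaI (C^TAG) sites.

    Fragments tile the sequence exactly; end labels record the enzyme
    (or ``"terminus"``) that produced each boundary.
    """
    if not sequence:
        return []
    cuts: List[Tuple[int, str]] = []
    for motif, offset, label in (
        (ECORI_SITE, ECORI_CUT_OFFSET, "EcoRI"),
        (BFAI_SITE, BFAI_CUT_OFFSET, "BfaI"),
    ):
        idx = sequence.find(motif)
        while idx >= 0:
            cuts.append((idx + offset, label))
            idx = sequence.find(motif, idx + 1)
    cuts.sort()
    fragments: List[Fragment] = []
    prev_pos, prev_label = 0, "terminus"
    for pos, label in cuts:
        if pos > prev_pos:
            fragments.append(Fragment(contig_id, prev_pos, pos, prev_label, label))
            prev_pos, prev_label = pos, label
        elif pos == prev_pos:
            prev_label = label  # coincident cut: keep the later enzyme label
    if prev_pos < len(sequence):
        fragments.append(
            Fragment(contig_id, prev_pos, len(sequence), prev_label, "terminus")
        )
    return fragments


def size_select(fragments: Sequence[Fragment], params: ReadSimParams) -> List[Fragment]:
    """Retain mixed-end fragments within [size_min, size_max], order preserved."""
    params.validate()
    out: List[Fragment] = []
    for frag in fragments:
        if not params.size_min <= frag.length <= params.size_max:
            continue
        if params.require_mixed_ends:
            if {frag.left_end, frag.right_end} != {"EcoRI", "BfaI"}:
                continue
        out.append(frag)
    return out


def digest_panel(panel: TruthPanel, params: ReadSimParams) -> List[Fragment]:
    """Digest and size-select every contig of the panel reference."""
    retained: List[Fragment] = []
    for name, seq in panel.contigs:
        retained.extend(size_select(digest_genome(seq, name), params))
    return retained


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def default_barcode_map(individuals: Sequence[str], length: int = 10) -> Dict[str, str]:
    """Deterministic fixed-length barcodes, one per individual."""
    barcodes: Dict[str, str] = {}
    for i, ind in enumerate(sorted(individuals)):
        digits = []
        x = i
        for _ in range(length):
            digits.append(BASES[x % 4])
            x //= 4
        barcodes["".join(reversed(digits))] = ind
    return barcodes


def _apply_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, hp_rate: float
) -> Tuple[str, List[Tuple[str, int]]]:
    """Perturb ``seq``; return (read sequence, alignment ops vs the original)."""
    chars = list(seq)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hits:
            options = [b for b in BASES if b != chars[i]]
            chars[i] = options[int(rng.integers(0, 3))]
    if hp_rate <= 0:
        return "".join(chars), [("M", len(chars))]
    out: List[str] = []
    ops: List[Tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    i = 0
    n = len(chars)
    while i < n:
        j = i
        while j < n and chars[j] == chars[i]:
            j += 1
        run = j - i
        if run >= 2 and rng.random() < hp_rate:
            if rng.random() < 0.5:  # +1 insertion at the end of the run
                out.append(chars[i] * (run + 1))
                push("M", run)
                push("I", 1)
            else:  # -1 deletion
                out.append(chars[i] * (run - 1))
                push("M", run - 1)
                push("D", 1)
        else:
            out.append(chars[i] * run)
            push("M", run)
        i = j
    return "".join(out), ops


def _cigar_string(ops: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def simulate_reads(
    panel: TruthPanel,
    fragments: Sequence[Fragment],
    params: ReadSimParams,
    barcode_map: Mapping[str, str],
) -> List[SimulatedRead]:
    """Simulate barcoded single-end reads over the retained fragments.

    Each read starts at one end of a fragment (either end with equal
    probability, always reported in reference orientation), is drawn
    from one of the individual's two haplotypes, and is perturbed by the
    error model.  The returned records carry both the FASTQ sequence
    (barcode-prefixed) and the truth placement with its CIGAR.
    """
    params.validate()
    from .io_formats import BarcodeMap  # validates prefix-freeness

    BarcodeMap(dict(barcode_map))
    barcode_of = {ind: bc for bc, ind in barcode_map.items()}
    missing = [ind for ind in panel.group_map if ind not in barcode_of]
    if missing:
        raise ConfigurationError(f"barcode_map: no barcode for {missing[0]}")

    rng = np.random.default_rng(params.seed)
    reads: List[SimulatedRead] = []
    contig_lens = {name: len(seq) for name, seq in panel.contigs}
    for ind in panel.individuals():
        serial = 0
        if params.depth_dispersion > 0 and params.mean_depth > 0:
            shape = 1.0 / params.depth_dispersion
            effort = float(rng.gamma(shape, params.mean_depth / shape))
        else:
            effort = params.mean_depth
        for frag in fragments:
            count = int(rng.poisson(effort)) if effort > 0 else 0
            for _ in range(count):
                hap = int(rng.integers(0, 2))
                length = int(round(rng.normal(params.mean_read_length,
                                              params.read_length_sd)))
                length = max(params.min_read_length, min(length, frag.length))
                if rng.random() < 0.5:
                    start = frag.start
                else:
                    start = frag.end - length
                end = start + length
                if end > contig_lens[frag.contig]:  # defensive; cannot happen
                    continue
                template = panel.haplotype_slice(ind, frag.contig, hap, start, end)
                seq, ops = _apply_errors(
                    template, rng, params.sub_error_rate,
                    params.homopolymer_indel_rate,
                )
                serial += 1
                reads.append(
                    SimulatedRead(
                        read_id=f"{ind}|{serial}",
                        individual=ind,
                        fastq_sequence=barcode_of[ind] + seq,
                        contig=frag.contig,
                        start=start,
                        cigar=_cigar_string(ops),
                        insert_sequence=seq,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# truth-table export
# ---------------------------------------------------------------------------

def write_truth_snps(truth_snps: Sequence[TruthSNP], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos0\tfocal_group\tref\talt\tkind\n")
        for snp in truth_snps:
            fh.write(f"{snp.contig}\t{snp.pos0}\t{snp.focal_group}\t"
                     f"{snp.ref}\t{snp.alt}\t{snp.kind}\n")


def read_truth_snps(path) -> List[TruthSNP]:
    out: List[TruthSNP] = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("contig")
        for line in fh:
            contig, pos0, focal, ref, alt, kind = line.rstrip("\n").split("\t")
            out.append(TruthSNP(contig, int(pos0), focal, ref, alt, kind))
    return out
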