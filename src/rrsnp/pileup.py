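"""Per-position allele counts stratified by individual and group.

Conventions: deletions contribute indel evidence but no base count at
the deleted positions; insertions attach evidence to the reference
positions flanking the insertion point; non-ACGT calls count toward
depth and ambiguity evidence but never toward any allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

from .errors import ConfigurationError, FormatError
from .io_formats import PlacedRead

ACGT = "ACGT"


@dataclass
class GroupScheme:
    """Grouping of individuals at subspecies or species level."""

    level: str  # "subspecies" | "species"
    group_of: Dict[str, str]

    def __post_init__(self) -> None:
        if self.level not in ("subspecies", "species"):
            raise ConfigurationError("level: must be 'subspecies' or 'species'")
        if len(set(self.group_of.values())) < 2:
            raise ConfigurationError("group_of: need >= 2 groups")

    def groups(self) -> List[str]:
        return sorted(set(self.group_of.values()))

    def pooled_to_species(self, species_of_group: Mapping[str, str]) -> "GroupScheme":
        """Relabel subspecies groups into species-level pools."""
        return GroupScheme(
            level="species",
            group_of={
                ind: species_of_group[grp] for ind, grp in self.group_of.items()
            },
        )


@dataclass
class PileupColumn:
    contig: str
    pos0: int
    counts_by_individual: Dict[str, Dict[str, int]] = field(default_factory=dict)
    indel_evidence: int = 0
    ambiguous_evidence: int = 0

    def add_base(self, individual: str, base: str) -> None:
        per_ind = self.counts_by_individual.setdefault(individual, {})
        per_ind[base] = per_ind.get(base, 0) + 1

    def pooled_counts(self) -> Dict[str, int]:
        pooled: Dict[str, int] = {}
        for per_ind in self.counts_by_individual.values():
            for base, n in per_ind.items():
                pooled[base] = pooled.get(base, 0) + n
        return pooled

    def depth(self) -> int:
        """Total read depth, ambiguous calls included."""
        return sum(n for per in self.counts_by_individual.values()
                   for n in per.values())

    def acgt_counts(self) -> Dict[str, int]:
        return {b: n for b, n in self.pooled_counts().items() if b in ACGT}

    def acgt_depth(self) -> int:
        return sum(self.acgt_counts().values())


def build_pileup(
    placed_reads: Iterable[PlacedRead],
    reference: Mapping[str, str],
    scheme: GroupScheme = None,
) -> Iterator[PileupColumn]:
    """Yield pileup columns ordered by (contig, pos0) for covered positions."""
    columns = build_pileup_dict(placed_reads, reference)
    for contig in sorted(columns):
        for pos in sorted(columns[contig]):
            yield columns[contig][pos]


def build_pileup_dict(
    placed_reads: Iterable[PlacedRead],
    reference: Mapping[str, str],
) -> Dict[str, Dict[int, PileupColumn]]:
    """Materialize the pileup as contig -> pos0 -> column."""
    columns: Dict[str, Dict[int, PileupColumn]] = {}

    def col(contig: str, pos: int) -> PileupColumn:
        per_contig = columns.setdefault(contig, {})
        if pos not in per_contig:
            per_contig[pos] = PileupColumn(contig=contig, pos0=pos)
        return per_contig[pos]

    for read in placed_reads:
        contig_len = len(reference[read.contig])
        if read.start + read.reference_length > contig_len:
            raise FormatError(
                f"read {read.read_id} overhangs contig {read.contig}"
            )
        ref_pos = read.start
        query_pos = 0
        for op, n in read.ops:
            if op in "M=X":
                for k in range(n):
                    base = read.sequence[query_pos + k].upper()
                    c = col(read.contig, ref_pos + k)
                    if base in ACGT:
                        c.add_base(read.individual, base)
                    else:
                        c.add_base(read.individual, "N")
                        c.ambiguous_evidence += 1
                ref_pos += n
                query_pos += n
            elif op == "I":
                if ref_pos > 0:
                    col(read.contig, ref_pos - 1).indel_evidence += 1
                if ref_pos < contig_len:
                    col(read.contig, ref_pos).indel_evidence += 1
                query_pos += n
            elif op in "DN":
                for k in range(n):
                    col(read.contig, ref_pos + k).indel_evidence += 1
                ref_pos += n
            elif op == "S":
                query_pos += n
            elif op in "HP":
                continue
            else:
                raise FormatError(f"read {read.read_id}: unsupported op {op!r}")
    return columns


def column_group_counts(
    column: PileupColumn, scheme: GroupScheme
) -> Tuple[Dict[str, Dict[str, int]], Dict[str, int]]:
    """Sum member-individual counts into per-group and pooled tallies."""
    by_group: Dict[str, Dict[str, int]] = {}
    pooled: Dict[str, int] = {}
    for individual, per_ind in column.counts_by_individual.items():
        if individual not in scheme.group_of:
            raise ConfigurationError(
                f"group_of: individual {individual!r} not in scheme"
            )
        group = scheme.group_of[individual]
        dest = by_group.setdefault(group, {})
        for base, n in per_ind.items():
            dest[base] = dest.get(base, 0) + n
            pooled[base] = pooled.get(base, 0) + n
    return by_group, pooled


def write_pileup_tsv(columns: Iterable[PileupColumn], scheme: GroupScheme, path) -> None:
    """Debug dump: per-group A/C/G/T/N counts plus indel evidence."""
    groups = scheme.groups()
    with open(path, "w") as fh:
        header = ["contig", "pos0"]
        for g in groups:
            header += [f"{g}_{b}" for b in "ACGTN"]
        header += ["indel_evidence", "ambiguous_evidence"]
        fh.write("\t".join(header) + "\n")
        for column in columns:
            by_group, _ = column_group_counts(column, scheme)
            row = [column.contig, str(column.pos0)]
            for g in groups:
                counts = by_group.get(g, {})
                row += [str(counts.get(b, 0)) for b in "ACGTN"]
            row += [str(column.indel_evidence), str(column.ambiguous_evidence)]
            fh.write("\t".join(row) + "\n")
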