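"""Readers/writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  SAM (1-based)
and BED (already 0-based) are converted at the boundary.  Individual
identity travels in SAM read groups (``RG`` tag) with a read-name
fallback of the form ``<individual>|<serial>``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One sequencing read; quality string has the same length as sequence."""

    read_id: str
    sequence: str
    quality: str
    assigned_individual: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )


@dataclass
class BarcodeMap:
    """Mapping barcode string -> individual id.

    Barcodes must be non-empty, mutually prefix-free, and map to unique
    individuals, so that any read matches at most one barcode.
    """

    entries: Dict[str, str]

    def __post_init__(self) -> None:
        barcodes = list(self.entries)
        if not barcodes:
            raise ConfigurationError("entries: barcode map is empty")
        if any(not b for b in barcodes):
            raise ConfigurationError("entries: empty barcode")
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1:]:
                if a.startswith(b) or b.startswith(a):
                    raise ConfigurationError(
                        f"entries: barcode {a!r} and {b!r} are not prefix-free"
                    )
        individuals = list(self.entries.values())
        if len(set(individuals)) != len(individuals):
            raise ConfigurationError("entries: duplicate individual ids")


@dataclass
class MaskSet:
    """Per-contig repeat intervals plus mtDNA contig ids (criterion 6 input)."""

    intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    mtdna_contigs: set = field(default_factory=set)

    def normalized(self) -> "MaskSet":
        """Return a copy with sorted, merged, non-overlapping intervals."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for contig in sorted(self.intervals):
            merged: List[Tuple[int, int]] = []
            for start, end in sorted(self.intervals[contig]):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            out[contig] = merged
        return MaskSet(intervals=out, mtdna_contigs=set(self.mtdna_contigs))

    def contains(self, contig: str, pos0: int) -> bool:
        if contig in self.mtdna_contigs:
            return True
        for start, end in self.intervals.get(contig, ()):
            if start <= pos0 < end:
                return True
        return False

    def total_masked(self) -> int:
        norm = self.normalized()
        return sum(e - s for ivs in norm.intervals.values() for s, e in ivs)


@dataclass
class PlacedRead:
    """A mapped read in 0-based coordinates with its alignment operations."""

    read_id: str
    contig: str
    start: int
    ops: List[Tuple[str, int]]  # (op in MIDNS=X, length)
    sequence: str
    individual: str

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.ops if op in "MDN=X")


# ---------------------------------------------------------------------------
# FASTA / FASTQ / BED
# ---------------------------------------------------------------------------

def write_fasta(contigs: Sequence[Tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def read_fastq(path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            quality="".join(chr(q + 33) for q in quals),
        )


def write_bed(masks: MaskSet, path) -> None:
    """Masks as 4-column BED; the name column tags repeat vs mtDNA rows."""
    norm = masks.normalized()
    with open(path, "w") as fh:
        for contig in sorted(norm.intervals):
            for start, end in norm.intervals[contig]:
                fh.write(f"{contig}\t{start}\t{end}\trepeat\n")
        for contig in sorted(norm.mtdna_contigs):
            fh.write(f"{contig}\t0\t0\tmtDNA\n")


def read_bed(path) -> MaskSet:
    masks = MaskSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with <3 columns: {line!r}")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "repeat"
            if name == "mtDNA":
                masks.mtdna_contigs.add(contig)
            else:
                masks.intervals.setdefault(contig, []).append((start, end))
    return masks.normalized()


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Iterable[ReadRecord], barcodes: BarcodeMap
) -> Tuple[Dict[str, List[ReadRecord]], List[ReadRecord], Dict[str, int]]:
    """Assign reads to individuals by exact barcode prefix match.

    A read is assigned iff its sequence starts with exactly one barcode
    (guaranteed unique because barcodes are prefix-free); the barcode is
    trimmed from assigned reads.  Returns (per-individual reads,
    unassigned reads, per-individual counts including ``"unassigned"``).
    """
    by_individual: Dict[str, List[ReadRecord]] = {
        ind: [] for ind in barcodes.entries.values()
    }
    unassigned: List[ReadRecord] = []
    for read in reads:
        hit = None
        for barcode, individual in barcodes.entries.items():
            if read.sequence.startswith(barcode):
                hit = (barcode, individual)
                break
        if hit is None:
            unassigned.append(read)
            continue
        barcode, individual = hit
        trimmed = ReadRecord(
            read_id=read.read_id,
            sequence=read.sequence[len(barcode):],
            quality=read.quality[len(barcode):],
            assigned_individual=individual,
        )
        by_individual[individual].append(trimmed)
    counts = {ind: len(lst) for ind, lst in by_individual.items()}
    counts["unassigned"] = len(unassigned)
    return by_individual, unassigned, counts


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(
    records: Iterable[Tuple[str, str, int, str, str, str]],
    contigs: Sequence[Tuple[str, str]],
    path,
) -> None:
    """Write plain-text SAM.

    ``records`` yields (read_id, contig, start0, cigar, sequence,
    individual); all reads are written as mapped forward-strand
    alignments with an RG tag carrying the individual id.
    """
    individuals = []
    rows = []
    for read_id, contig, start0, cigar, sequence, individual in records:
        if individual not in individuals:
            individuals.append(individual)
        rows.append((read_id, contig, start0, cigar, sequence, individual))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in contigs:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for ind in individuals:
            fh.write(f"@RG\tID:{ind}\tSM:{ind}\n")
        for read_id, contig, start0, cigar, sequence, individual in rows:
            qual = "I" * len(sequence)
            fh.write(
                f"{read_id}\t0\t{contig}\t{start0 + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{sequence}\t{qual}\tRG:Z:{individual}\n"
            )


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise FormatError(f"malformed CIGAR string: {cigar!r}")
    return ops


def parse_alignments(
    sam_path, reference: Mapping[str, str]
) -> Tuple[List[PlacedRead], int]:
    """Parse a SAM file into placed reads; returns (placed, skipped_unmapped).

    Only mapped records are yielded; coordinates are converted to
    0-based.  The individual id comes from the RG tag, falling back to
    the ``<individual>|<serial>`` read-name convention.
    """
    placed: List[PlacedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                skipped += 1
                continue
            contig = rec.reference_name
            if contig not in reference:
                raise FormatError(
                    f"read {rec.query_name}: contig {contig!r} absent from reference"
                )
            if rec.has_tag("RG"):
                individual = rec.get_tag("RG")
            elif "|" in rec.query_name:
                individual = rec.query_name.split("|", 1)[0]
            else:
                raise FormatError(
                    f"read {rec.query_name}: no RG tag and no '|' in read name"
                )
            ops = [
                ("MIDNSHP=X"[code], length)
                for code, length in (rec.cigartuples or [])
            ]
            placed.append(
                PlacedRead(
                    read_id=rec.query_name,
                    contig=contig,
                    start=rec.reference_start,
                    ops=ops,
                    sequence=rec.query_sequence or "",
                    individual=individual,
                )
            )
    return placed, skipped


# ---------------------------------------------------------------------------
# assay sheet / VCF export
# ---------------------------------------------------------------------------

def write_assay_sheet(
    loci: Sequence["ValidatedLocus"],  # noqa: F821 - defined in snp_discovery
    path,
    maf_by_group: Optional[Mapping[str, Mapping[str, float]]] = None,
    flank_len: int = 50,
) -> int:
    """Write a primer-ready CSV, one row per locus, sorted by (contig, pos0).

    ``maf_by_group`` optionally maps group -> {locus_id: MAF} and adds one
    column per group.  Rows whose flanks are shorter than ``flank_len``
    are refused and logged.  Returns the number of rows written.
    """
    groups = sorted(maf_by_group) if maf_by_group else []
    header = ["locus_id", "contig", "pos0", "focal_group", "bracket_context"]
    header += [f"maf_{g}" for g in groups]
    written = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for locus in sorted(loci, key=lambda l: (l.candidate.contig, l.candidate.pos0)):
            if len(locus.left_flank) < flank_len or len(locus.right_flank) < flank_len:
                logger.warning("assay sheet: flank < %d bp, refusing locus %s",
                               flank_len, locus.locus_id)
                continue
            row = [
                locus.locus_id,
                locus.candidate.contig,
                locus.candidate.pos0,
                locus.candidate.focal_group or "",
                locus.bracket_context,
            ]
            for g in groups:
                row.append(maf_by_group[g].get(locus.locus_id, ""))
            writer.writerow(row)
            written += 1
    return written


def partition_assays(
    loci: Sequence, n_chips: int, chip_size: int = 96
) -> Tuple[List[List], int]:
    """Partition loci onto fixed-capacity genotyping chips.

    Returns (chips, total_capacity) where total_capacity = n_chips *
    chip_size; loci beyond the capacity are dropped.
    """
    capacity = chip_capacity(n_chips, chip_size)
    chips = [
        list(loci[i * chip_size:(i + 1) * chip_size]) for i in range(n_chips)
    ]
    return chips, capacity


def chip_capacity(n_chips: int, chip_size: int = 96) -> int:
    """Total assay capacity of ``n_chips`` arrays of ``chip_size`` wells."""
    if n_chips < 0 or chip_size < 0:
        raise ConfigurationError("n_chips/chip_size: must be non-negative")
    return n_chips * chip_size


def write_vcf(loci: Sequence, path, source: str = "rrsnp") -> None:
    """Minimal VCF v4.2 for validated loci (CHROM/POS/ID/REF/ALT + FOCAL)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=FOCAL,Number=1,Type=String,'
                 'Description="Group diagnosed by the alternate allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for locus in sorted(loci, key=lambda l: (l.candidate.contig, l.candidate.pos0)):
            cand = locus.candidate
            fh.write(
                f"{cand.contig}\t{cand.pos0 + 1}\t{locus.locus_id}\t"
                f"{cand.major_allele}\t{cand.minor_allele}\t.\tPASS\t"
                f"FOCAL={cand.focal_group or '.'}\n"
            )


def read_group_tsv(path) -> Dict[str, str]:
    """Two-column TSV individual -> group."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"group TSV line with <2 columns: {line!r}")
            out[parts[0]] = parts[1]
    return out


def write_group_tsv(group_of: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for individual in sorted(group_of):
            fh.write(f"{individual}\t{group_of[individual]}\n")
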