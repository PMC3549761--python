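import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rrsnp import io_formats, synthetic_data
from rrsnp.pileup import GroupScheme


@pytest.fixture(scope="session")
def small_config():
    """Dense-cassette panel small enough for brute-force checking."""
    return synthetic_data.PanelConfig(
        n_groups=4,
        individuals_per_group=3,
        genome_length=48_000,
        n_contigs=2,
        autapomorphic_rate=0.15,
        shared_poly_rate=0.08,
        within_group_rate=0.08,
        repeat_fraction=0.05,
        mtdna_contig=True,
        seed=11,
        spacer_len_range=(300, 800),
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthetic_data.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_scheme(small_panel):
    return GroupScheme(level="subspecies", group_of=dict(small_panel.group_map))


def simulate_to_files(panel, params, outdir):
    """Write FASTA/SAM/FASTQ/BED for a panel; returns a dict of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fragments = synthetic_data.digest_panel(panel, params)
    barcode_map = synthetic_data.default_barcode_map(panel.individuals())
    reads = synthetic_data.simulate_reads(panel, fragments, params, barcode_map)
    io_formats.write_fasta(panel.contigs, outdir / "reference.fasta")
    io_formats.write_bed(panel.masks, outdir / "masks.bed")
    io_formats.write_fastq(
        (io_formats.ReadRecord(r.read_id, r.fastq_sequence, r.quality)
         for r in reads),
        outdir / "reads.fastq",
    )
    io_formats.write_sam(
        ((r.read_id, r.contig, r.start, r.cigar, r.insert_sequence, r.individual)
         for r in reads),
        panel.contigs,
        outdir / "truth.sam",
    )
    return {
        "reference": outdir / "reference.fasta",
        "masks": outdir / "masks.bed",
        "fastq": outdir / "reads.fastq",
        "sam": outdir / "truth.sam",
        "fragments": fragments,
        "reads": reads,
        "barcodes": barcode_map,
    }
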