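"""Shared fixtures: handcrafted transcripts and the seeded benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from scrscreen.simulate import SENSE_CODONS
from scrscreen.transcripts import CuratedTranscript, TranscriptRecord, curate_transcriptome


def random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n))


def random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_record(
    rng: np.random.Generator,
    utr5: int = 30,
    cds_codons: int = 100,
    stop: str = "TGA",
    isr_codons: int = 30,
    dstop: str = "TAA",
    utr3: int = 60,
    gene_id: str = "gX",
    transcript_id: str = "gX.1",
) -> TranscriptRecord:
    """Assemble a well-formed transcript with known coordinates."""
    seq = (
        random_bases(rng, utr5)
        + "ATG"
        + random_codons(rng, cds_codons - 1)
        + stop
        + random_codons(rng, isr_codons)
        + dstop
        + random_bases(rng, utr3)
    )
    return TranscriptRecord(
        transcript_id=transcript_id,
        gene_id=gene_id,
        sequence=seq,
        cds_start=utr5,
        cds_stop_start=utr5 + 3 * cds_codons,
    )


def build_curated(rng: np.random.Generator, **kwargs) -> CuratedTranscript:
    rec = build_record(rng, **kwargs)
    (cur,) = curate_transcriptome([rec])
    assert cur.passes_curation, cur.curation_flags
    return cur


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def window_transcript(rng):
    """Transcript with cds_start=100, canonical stop at 400, downstream stop at 520."""
    t = build_curated(rng, utr5=100, cds_codons=100, isr_codons=39, utr3=60)
    assert (t.cds_start, t.cds_stop_start, t.isr_end_exclusive) == (100, 400, 520)
    return t


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """The seeded parameter-recovery benchmark, run through the file pipeline.

    100 genes: 20 readthrough (efficiency 0.1-0.8), 10 frameshift decoys,
    5 annotation-collision plants; reads travel through FASTQ, trimming,
    ncRNA depletion and perfect-match alignment.
    """
    from scrscreen.screen import ScreenConfig
    from scrscreen.simulate import benchmark_spec, generate_reads, generate_world, write_reads, write_world
    from scrscreen.transcripts import read_transcript_fasta
    from scrscreen.workflow import run_pipeline_files

    outdir = tmp_path_factory.mktemp("benchmark")
    spec = benchmark_spec(seed=1)
    world = generate_world(spec)
    reads, read_truth = generate_reads(spec, world)
    paths = write_world(world, outdir)
    paths |= write_reads(reads, read_truth, outdir)
    result = run_pipeline_files(
        paths["transcriptome"],
        paths["cds"],
        {"ds1": paths["fastq"]},
        ScreenConfig(),
        ncrna=read_transcript_fasta(paths["ncrna"]),
        proteome=read_transcript_fasta(paths["proteome"]),
    )
    return {"spec": spec, "world": world, "result": result, "paths": paths,
            "n_raw_reads": len(reads)}
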