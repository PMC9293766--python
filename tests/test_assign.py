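"""Region windows, frames, per-region statistics and metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from scrscreen.assign import (
    RegionWindows,
    assign_frame,
    assign_region,
    dataset_qc,
    metagene_profile,
    region_stats,
    stats_frame,
    stats_from_frame,
    region_stats_table,
)
from scrscreen.reads import ALIGNMENT_COLUMNS

from conftest import build_curated


def aln(rows):
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def oracle_assign(pos5, t):
    """Independent restatement of the window rules."""
    if t.cds_start - 12 <= pos5 <= t.cds_stop_start - 22:
        return "CDS"
    if t.cds_stop_start - 12 <= pos5 <= t.isr_end_exclusive - 22:
        return "ISR"
    if t.isr_end_exclusive - 12 <= pos5 <= len(t.sequence) - 1:
        return "UTR"
    return None


class TestWindows:
    @pytest.mark.parametrize(
        "pos5,expected",
        [
            (88, "CDS"),  # cds_start - 12
            (87, None),
            (378, "CDS"),  # cds_stop_start - 22
            (379, None),  # in the 9-position gap
            (388, "ISR"),  # cds_stop_start - 12
            (498, "ISR"),  # downstream stop - 22
            (499, None),
            (508, "UTR"),  # downstream stop - 12
        ],
    )
    def test_window_boundaries(self, window_transcript, pos5, expected):
        assert assign_region(pos5, window_transcript) == expected

    def test_windows_are_disjoint_exhaustively(self, window_transcript):
        t = window_transcript
        w = RegionWindows.for_transcript(t)
        for pos5 in range(len(t.sequence)):
            labels = [
                name
                for name, (lo, hi) in
                (("CDS", w.cds), ("ISR", w.isr), ("UTR", w.utr))
                if lo <= pos5 <= hi
            ]
            assert len(labels) <= 1

    def test_assignment_matches_independent_oracle(self, rng):
        transcripts = [
            build_curated(rng, gene_id=f"g{i}", transcript_id=f"g{i}.1",
                          cds_codons=int(rng.integers(30, 120)),
                          isr_codons=int(rng.integers(16, 60)),
                          utr3=int(rng.integers(45, 200)))
            for i in range(10)
        ]
        for t in transcripts:
            for _ in range(1000):
                pos5 = int(rng.integers(0, len(t.sequence)))
                assert assign_region(pos5, t) == oracle_assign(pos5, t)


class TestFrames:
    def test_frame_relative_to_start_codon(self, window_transcript):
        t = window_transcript
        assert assign_frame(t.cds_start, t) == 0
        assert assign_frame(t.cds_start + 4, t) == 1

    def test_isr_window_lower_bound_is_frame_zero(self, window_transcript):
        # cds_stop_start - cds_start is a codon multiple and 12 % 3 == 0
        t = window_transcript
        assert assign_frame(t.cds_stop_start - 12, t) == 0

    def test_shift_by_three_preserves_frame(self, window_transcript, rng):
        t = window_transcript
        for _ in range(100):
            pos5 = int(rng.integers(0, len(t.sequence) - 3))
            assert assign_frame(pos5, t) == assign_frame(pos5 + 3, t)


class TestRegionStats:
    def test_tiling_reads_give_full_coverage_and_density(self, rng):
        t = build_curated(rng, cds_codons=100, isr_codons=100, utr3=60)
        isr_len = t.isr_length
        assert isr_len == 300
        rows = [
            (f"r{i}", t.transcript_id, t.isr_start + 30 * i, 30, 1) for i in range(10)
        ]
        s = region_stats(aln(rows), t, lengths={30})
        assert s.coverage["ISR"] == 1.0
        assert s.density["ISR"] == pytest.approx(10 / 300)

    def test_stop_spanning_counts_footprints_covering_all_three_stop_nt(self, rng):
        t = build_curated(rng)
        rows = [
            ("r1", t.transcript_id, t.cds_stop_start - 1, 28, 1),  # spans
            ("r2", t.transcript_id, t.cds_stop_start + 1, 28, 1),  # starts inside stop
            ("r3", t.transcript_id, t.cds_stop_start - 26, 28, 1),  # ends 2 nt into stop
        ]
        s = region_stats(aln(rows), t, lengths={28})
        assert s.stop_spanning == 1

    def test_coverage_matches_per_nucleotide_mask_oracle(self, rng):
        t = build_curated(rng, cds_codons=80, isr_codons=40, utr3=120)
        rows = []
        for i in range(300):
            pos5 = int(rng.integers(0, len(t.sequence) - 26))
            rows.append((f"r{i}", t.transcript_id, pos5, 25, 1))
        s = region_stats(aln(rows), t, lengths={25})
        intervals = {
            "CDS": (t.cds_start, t.cds_stop_start),
            "ISR": (t.isr_start, t.isr_end_exclusive),
            "UTR": (t.rest3utr_start, len(t.sequence)),
        }
        for region, (lo, hi) in intervals.items():
            mask = np.zeros(len(t.sequence), dtype=bool)
            for rid, tid, pos5, length, _ in rows:
                if oracle_assign(pos5, t) == region:
                    mask[pos5 : pos5 + length] = True
            assert s.coverage[region] == pytest.approx(mask[lo:hi].mean())

    def test_read_conservation_per_transcript(self, rng):
        t = build_curated(rng)
        rows = [
            (f"r{i}", t.transcript_id, int(rng.integers(0, len(t.sequence) - 26)), 26, 1)
            for i in range(500)
        ]
        s = region_stats(aln(rows), t, lengths={26})
        assert sum(s.n_reads.values()) + s.n_unassigned == s.n_total == 500

    def test_stats_roundtrip_through_table(self, rng):
        t = build_curated(rng)
        rows = [
            (f"r{i}", t.transcript_id, int(rng.integers(0, len(t.sequence) - 26)), 25, 1)
            for i in range(200)
        ]
        stats = region_stats_table(aln(rows), [t], {25})
        back = stats_from_frame(stats_frame(stats))
        s0, s1 = stats[t.transcript_id], back[t.transcript_id]
        assert s0.n_reads == s1.n_reads
        assert s0.stop_spanning == s1.stop_spanning
        np.testing.assert_allclose(
            s0.frame_fractions["CDS"], s1.frame_fractions["CDS"]
        )


class TestMetagene:
    def test_pure_frame_zero_scores_one(self, rng):
        t = build_curated(rng, cds_codons=200)
        rows = [
            (f"r{i}", t.transcript_id, t.cds_start + 3 * i, 25, 1) for i in range(60)
        ]
        _, scores = metagene_profile(aln(rows), [t])
        assert scores[25] == 1.0

    def test_uniform_frames_score_one_third(self, rng):
        t = build_curated(rng, cds_codons=300)
        n = 10_000
        positions = rng.integers(t.cds_start, t.cds_stop_start - 22, size=n)
        rows = [(f"r{i}", t.transcript_id, int(p), 25, 1) for i, p in enumerate(positions)]
        _, scores = metagene_profile(aln(rows), [t])
        assert scores[25] == pytest.approx(1 / 3, abs=0.02)

    def test_simulator_frame_bias_recovered(self):
        from scrscreen.simulate import SimSpec, generate_reads, generate_world, true_alignments
        from scrscreen.transcripts import curate_transcriptome

        spec = SimSpec(seed=9, n_genes=30, n_readthrough=0, ncrna_fraction=0.0,
                       expression_mean=800.0)
        world = generate_world(spec)
        _, read_truth = generate_reads(spec, world)
        alignments = true_alignments(read_truth)
        curated = curate_transcriptome(world.transcripts)
        profile, scores = metagene_profile(alignments, curated)
        # dataset-level modal-frame fraction recovers the 0.80 frame bias
        best = max(scores.values())
        assert best == pytest.approx(0.80, abs=0.02)
        assert dataset_qc(scores, 0.55)
        # profile fractions sum to one within each length
        sums = profile.groupby("length")["fraction"].sum()
        assert np.allclose(sums, 1.0)
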