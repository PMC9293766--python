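"""Four-level screen: thresholds, reference distribution, combination rules."""

import numpy as np
import pandas as pd
import pytest

from scrscreen.assign import RegionStats
from scrscreen.screen import (
    FrameReference,
    ProteomeIndex,
    ScreenConfig,
    build_frame_reference,
    level1_density,
    level2_coverage,
    level3_periodicity,
    level4_annotation_collision,
    run_screen,
    translate_isr,
)

from conftest import build_curated


def make_stats(
    tid="t1",
    n=(1000, 50, 5),
    density=(2.0, 1.0, 0.1),
    coverage=(0.9, 0.8, 0.05),
    frames_cds=(0.8, 0.15, 0.05),
    frames_isr=(0.8, 0.15, 0.05),
    stop_spanning=2,
):
    return RegionStats(
        transcript_id=tid,
        n_reads=dict(zip(("CDS", "ISR", "UTR"), n)),
        density=dict(zip(("CDS", "ISR", "UTR"), density)),
        coverage=dict(zip(("CDS", "ISR", "UTR"), coverage)),
        frame_fractions={
            "CDS": np.array(frames_cds),
            "ISR": np.array(frames_isr),
            "UTR": None,
        },
        stop_spanning=stop_spanning,
        n_unassigned=0,
        n_total=sum(n),
    )


CFG = ScreenConfig()


class TestLevel1:
    def test_ratio_exactly_four_passes(self):
        s = make_stats(density=(3.0, 2.0, 0.5))
        ok, q = level1_density(s, CFG)
        assert ok and q["density_ratio"] == pytest.approx(4.0)

    def test_ratio_below_four_fails(self):
        s = make_stats(density=(3.0, 1.99, 0.5))
        assert not level1_density(s, CFG)[0]

    def test_isr_hotter_than_cds_fails(self):
        s = make_stats(density=(1.5, 2.0, 0.1))
        assert not level1_density(s, CFG)[0]

    def test_empty_isr_fails_regardless_of_utr(self):
        s = make_stats(density=(2.0, 0.0, 0.0))
        assert not level1_density(s, CFG)[0]

    def test_zero_utr_density_counts_as_infinite_ratio(self):
        s = make_stats(density=(2.0, 1.0, 0.0))
        ok, q = level1_density(s, CFG)
        assert ok and np.isinf(q["density_ratio"])


class TestLevel2:
    def test_boundary_pass(self):
        s = make_stats(n=(1000, 30, 5), coverage=(0.9, 0.51, 0.24), stop_spanning=1)
        assert level2_coverage(s, CFG)[0]

    def test_29_reads_fail(self):
        s = make_stats(n=(1000, 29, 5), coverage=(0.9, 0.51, 0.24), stop_spanning=1)
        assert not level2_coverage(s, CFG)[0]

    def test_isr_coverage_exactly_half_fails(self):
        s = make_stats(n=(1000, 30, 5), coverage=(0.9, 0.50, 0.24), stop_spanning=1)
        assert not level2_coverage(s, CFG)[0]

    def test_utr_coverage_exactly_quarter_fails(self):
        s = make_stats(n=(1000, 30, 5), coverage=(0.9, 0.51, 0.25), stop_spanning=1)
        assert not level2_coverage(s, CFG)[0]

    def test_no_stop_spanning_read_fails(self):
        s = make_stats(n=(1000, 30, 5), coverage=(0.9, 0.51, 0.24), stop_spanning=0)
        assert not level2_coverage(s, CFG)[0]


class TestFrameReference:
    def test_two_transcript_mean_and_population_sd(self):
        stats = {
            "a": make_stats("a", frames_cds=(0.8, 0.15, 0.05)),
            "b": make_stats("b", frames_cds=(0.6, 0.25, 0.15)),
        }
        ref = build_frame_reference(stats, CFG)
        np.testing.assert_allclose(ref.mu, (0.7, 0.2, 0.1))
        np.testing.assert_allclose(ref.sigma, (0.1, 0.05, 0.05))

    def test_identical_transcripts_give_zero_sd(self):
        stats = {t: make_stats(t) for t in "abc"}
        ref = build_frame_reference(stats, CFG)
        np.testing.assert_allclose(ref.sigma, 0.0, atol=1e-12)

    def test_shallow_transcripts_are_excluded(self):
        stats = {
            "a": make_stats("a"),
            "b": make_stats("b"),
            "shallow": make_stats("shallow", n=(100, 5, 1), frames_cds=(0.1, 0.1, 0.8)),
        }
        ref = build_frame_reference(stats, CFG)
        assert ref.n_transcripts == 2

    def test_direct_recomputation_on_simulated_stats(self, rng):
        vecs = rng.dirichlet((8, 1.5, 0.5), size=100)
        stats = {
            f"t{i}": make_stats(f"t{i}", frames_cds=tuple(v)) for i, v in enumerate(vecs)
        }
        ref = build_frame_reference(stats, CFG)
        np.testing.assert_allclose(ref.mu, vecs.mean(0))
        np.testing.assert_allclose(ref.sigma, vecs.std(0))

    def test_fewer_than_two_qualifying_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            build_frame_reference({"a": make_stats("a")}, CFG)


class TestLevel3:
    REF = FrameReference(mu=np.array([0.7, 0.2, 0.1]),
                         sigma=np.array([0.05, 0.04, 0.03]), n_transcripts=50)

    def test_within_two_sd_in_one_frame_passes(self):
        assert level3_periodicity(
            np.array([0.68, 0.22, 0.10]), np.array([0.71, 0.19, 0.10]), self.REF, CFG
        )

    def test_uniform_isr_frames_fail(self):
        assert not level3_periodicity(
            np.array([0.33, 0.33, 0.34]), np.array([0.71, 0.19, 0.10]), self.REF, CFG
        )

    def test_no_isr_reads_fail(self):
        assert not level3_periodicity(None, np.array([0.7, 0.2, 0.1]), self.REF, CFG)

    def test_zero_sigma_requires_exact_match(self):
        ref = FrameReference(mu=np.array([0.8, 0.15, 0.05]),
                             sigma=np.zeros(3), n_transcripts=5)
        exact = np.array([0.8, 0.15, 0.05])
        off = np.array([0.8001, 0.1498, 0.0501])  # every frame off the mean
        assert level3_periodicity(exact, exact, ref, CFG)
        assert not level3_periodicity(off, off, ref, CFG)

    def test_cds_requirement_can_be_relaxed(self):
        cfg = ScreenConfig(require_cds_periodicity=False)
        bad_cds = np.array([0.33, 0.33, 0.34])
        good_isr = np.array([0.7, 0.2, 0.1])
        assert level3_periodicity(good_isr, bad_cds, self.REF, cfg)
        assert not level3_periodicity(good_isr, bad_cds, self.REF, CFG)

    def test_frameshifted_isr_rejected_in_most_replicates(self, rng):
        """ISR reads planted in frame +1 fail in >90% of 200 replicates."""
        p = np.array([0.8, 0.15, 0.05])
        conc = 200.0
        ref_vecs = rng.dirichlet(conc * p, size=80)
        ref = FrameReference(ref_vecs.mean(0), ref_vecs.std(0), 80)
        rejected = 0
        n_reps = 200
        for _ in range(n_reps):
            gp = rng.dirichlet(conc * p)
            isr = rng.multinomial(60, gp[[2, 0, 1]]) / 60  # rotated +1, 60 reads
            cds = rng.multinomial(2000, gp) / 2000
            if not level3_periodicity(isr, cds, ref, CFG):
                rejected += 1
        assert rejected / n_reps > 0.90


class TestLevel4:
    def test_planted_peptides_eliminated_exactly(self, rng):
        transcripts = [
            build_curated(rng, gene_id=f"g{i}", transcript_id=f"g{i}.1", isr_codons=20)
            for i in range(20)
        ]
        planted = {t.transcript_id for t in transcripts[:5]}
        proteins = {}
        for i in range(20):
            base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
            if transcripts[i].transcript_id in planted:
                pep = translate_isr(transcripts[i])[:10]
                base = base[:100] + pep + base[100:]
            proteins[f"P{i}"] = base
        index = ProteomeIndex(proteins, window=8)
        eliminated = {
            t.transcript_id
            for t in transcripts
            if not level4_annotation_collision(t, index, CFG)[0]
        }
        assert eliminated == planted

    def test_no_proteome_passes_with_warning(self, rng):
        t = build_curated(rng)
        with pytest.warns(UserWarning, match="level-4"):
            ok, _ = level4_annotation_collision(t, None, CFG)
        assert ok


class TestRunScreen:
    def _world(self, rng, n=12):
        transcripts = [
            build_curated(rng, gene_id=f"g{i}", transcript_id=f"g{i}.1")
            for i in range(n)
        ]
        return transcripts

    def _stats_for(self, transcripts, positive_ids):
        # negatives carry a small alternating frame wobble so the reference
        # SD is positive (an all-identical reference degenerates to
        # exact-equality level-3 tests)
        stats = {}
        for i, t in enumerate(transcripts):
            delta = 0.01 if i % 2 else -0.01
            wobble = (0.8 + delta, 0.15 - delta, 0.05)
            if t.transcript_id in positive_ids:
                stats[t.transcript_id] = make_stats(t.transcript_id)
            else:
                stats[t.transcript_id] = make_stats(
                    t.transcript_id, n=(1000, 2, 1), density=(2.0, 0.05, 0.04),
                    coverage=(0.9, 0.05, 0.02), stop_spanning=1,
                    frames_cds=wobble, frames_isr=wobble,
                )
        return stats

    def test_combine_rule_requires_min_support(self, rng):
        transcripts = self._world(rng)
        pos = {"g0.1"}
        ds1 = self._stats_for(transcripts, pos)
        ds2 = self._stats_for(transcripts, set())  # positive in dataset 1 only
        res_k1 = run_screen({"d1": ds1, "d2": ds2}, transcripts,
                            ScreenConfig(min_support=1), eliminate_ids=set())
        res_k2 = run_screen({"d1": ds1, "d2": ds2}, transcripts,
                            ScreenConfig(min_support=2), eliminate_ids=set())
        assert res_k1.positive_transcripts == ["g0.1"]
        assert res_k2.positive_transcripts == []

    def test_empty_isr_everywhere_yields_zero_positives(self, rng):
        transcripts = self._world(rng)
        stats = self._stats_for(transcripts, set())
        for s in stats.values():
            s.n_reads["ISR"] = 0
            s.density["ISR"] = 0.0
            s.frame_fractions["ISR"] = None
        res = run_screen({"d1": stats}, transcripts, ScreenConfig(), eliminate_ids=set())
        assert res.positive_transcripts == []

    def test_funnel_is_monotone(self, rng):
        transcripts = self._world(rng)
        stats = self._stats_for(transcripts, {"g0.1", "g1.1", "g2.1"})
        res = run_screen({"d1": stats}, transcripts, ScreenConfig(), eliminate_ids=set())
        row = res.funnel.iloc[0]
        assert row.candidates >= row.level1 >= row.level2 >= row.level3 >= row.level4

    def test_raising_thresholds_never_grows_the_positive_set(self, rng):
        transcripts = self._world(rng)
        stats = {}
        for i, t in enumerate(transcripts):
            delta = 0.01 if i % 2 else -0.01
            wobble = (0.8 + delta, 0.15 - delta, 0.05)
            stats[t.transcript_id] = make_stats(
                t.transcript_id,
                n=(1000, 25 + 2 * i, 5),
                density=(2.0, 0.3 + 0.1 * i, 0.1),
                coverage=(0.9, 0.4 + 0.04 * i, 0.10 + 0.01 * i),
                stop_spanning=1,
                frames_cds=wobble, frames_isr=wobble,
            )
        prev = None
        for ratio, min_reads, cov in [(2.0, 20, 0.3), (4.0, 30, 0.5), (6.0, 40, 0.7)]:
            cfg = ScreenConfig(
                density_ratio_min=ratio, isr_min_reads=min_reads, isr_coverage_min=cov
            )
            res = run_screen({"d1": stats}, transcripts, cfg, eliminate_ids=set())
            current = set(res.positive_transcripts)
            if prev is not None:
                assert current <= prev
            prev = current

    def test_gene_call_is_any_transcript(self, rng):
        transcripts = self._world(rng)
        stats = self._stats_for(transcripts, {"g3.1"})
        res = run_screen({"d1": stats}, transcripts, ScreenConfig(), eliminate_ids=set())
        genes = res.gene_calls.set_index("gene_id")["called"]
        assert genes["g3"] and not genes["g0"]

    def test_invalid_config_is_a_startup_error(self, rng):
        transcripts = self._world(rng)
        with pytest.raises(ValueError, match="density_ratio_min"):
            run_screen(
                {"d1": self._stats_for(transcripts, set())},
                transcripts,
                ScreenConfig(density_ratio_min=-1),
            )
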