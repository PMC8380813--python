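import numpy as np
import pandas as pd
import pytest

from nicscall.classify import call_embryo
from nicscall.simulate import (
    EmbryoTruth,
    SimulationConfig,
    TruthEvent,
    MANIFEST_COLUMNS,
    lineage_karyotype,
    sample_copy,
    simulate_cohort,
    simulate_counts,
    simulate_truth,
)


def _cfg(**kw):
    kw.setdefault("seed", 1)
    return SimulationConfig(**kw)


class TestTruth:
    def test_all_euploid_mix(self, small_grid):
        cfg = _cfg(n_embryos=50, category_mix={"euploid": 1.0})
        truths = simulate_truth(cfg, np.random.default_rng(0), small_grid)
        assert all(t.category == "euploid" and not t.events for t in truths)

    def test_all_mac_mix(self, hg19_grid):
        cfg = _cfg(n_embryos=30, category_mix={"mac": 1.0})
        truths = simulate_truth(cfg, np.random.default_rng(0), hg19_grid)
        assert all(t.category == "MAC" for t in truths)
        assert all(len({e.chrom for e in t.events}) >= 5 for t in truths)

    def test_category_proportions_converge(self, hg19_grid):
        cfg = _cfg(n_embryos=2000)
        truths = simulate_truth(cfg, np.random.default_rng(5), hg19_grid)
        counts = pd.Series([t.category for t in truths]).value_counts()
        expect = {
            "euploid": 0.50,
            # aneuploid + segmental + mosaic all land in category "abnormal"
            "abnormal": 0.43,
            "MAC": 0.07,
        }
        n = len(truths)
        for cat, p in expect.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(cat, 0) / n - p) < 3 * se

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(seed=None).validate()

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(category_mix={"euploid": 0.7}).validate()


class TestCounts:
    def test_noiseless_euploid_xy_structure(self, flat_small_grid):
        cfg = _cfg(noise="none")
        truth = EmbryoTruth("E", "XY", (), "euploid", 0.0)
        t = simulate_counts(truth, "whole", flat_small_grid, cfg, np.random.default_rng(0))
        full = flat_small_grid.lengths_bp == 1_000_000
        aut = flat_small_grid.is_autosome & full
        x = (flat_small_grid.chrom == "X") & full
        assert np.ptp(t.counts[aut]) <= 1  # uniform up to rounding
        assert np.allclose(t.counts[x], t.counts[aut].mean() / 2, atol=1)

    def test_noiseless_trisomy_ratio(self, flat_small_grid):
        cfg = _cfg(noise="none")
        truth = EmbryoTruth("E", "XX", (TruthEvent("2", +1),), "abnormal", 0.0)
        t = simulate_counts(truth, "whole", flat_small_grid, cfg, np.random.default_rng(0))
        full = flat_small_grid.lengths_bp == 1_000_000
        c1 = t.counts[(flat_small_grid.chrom == "1") & full].mean()
        c2 = t.counts[(flat_small_grid.chrom == "2") & full].mean()
        assert c2 / c1 == pytest.approx(1.5, abs=0.001)

    def test_pure_maternal_medium_is_euploid_xx(self, flat_small_grid):
        cfg = _cfg(noise="none")
        aneu = EmbryoTruth("A", "XY", (TruthEvent("2", -1),), "abnormal", 1.0)
        xx = EmbryoTruth("N", "XX", (), "euploid", 0.0)
        got = simulate_counts(aneu, "medium", flat_small_grid, cfg, np.random.default_rng(0))
        ref = simulate_counts(xx, "whole", flat_small_grid, cfg, np.random.default_rng(0))
        assert np.array_equal(got.counts, ref.counts)

    def test_same_seed_same_counts(self, small_grid):
        cfg = _cfg()
        truth = EmbryoTruth("E", "XX", (), "euploid", 0.0)
        a = simulate_counts(truth, "TE", small_grid, cfg, np.random.default_rng(9))
        b = simulate_counts(truth, "TE", small_grid, cfg, np.random.default_rng(9))
        assert np.array_equal(a.counts, b.counts)

    def test_unknown_assay_rejected(self, small_grid):
        truth = EmbryoTruth("E", "XX", (), "euploid", 0.0)
        with pytest.raises(ValueError, match="assay"):
            simulate_counts(truth, "icm", small_grid, _cfg(), np.random.default_rng(0))

    def test_mean_structure_matches_copy_ratio(self, flat_small_grid):
        # over many Poisson draws the chr2/chr1 density ratio -> c/2
        cfg = _cfg(noise="poisson")
        truth = EmbryoTruth("E", "XX", (TruthEvent("2", +1),), "abnormal", 0.0)
        rng = np.random.default_rng(2)
        full = flat_small_grid.lengths_bp == 1_000_000
        tot1 = tot2 = 0.0
        for _ in range(50):
            t = simulate_counts(truth, "whole", flat_small_grid, cfg, rng)
            tot1 += t.counts[(flat_small_grid.chrom == "1") & full].mean()
            tot2 += t.counts[(flat_small_grid.chrom == "2") & full].mean()
        assert tot2 / tot1 == pytest.approx(1.5, rel=0.02)


class TestContamination:
    def test_effective_copy_decreases_with_maternal_fraction(self, small_grid):
        cfg = _cfg()
        levels = []
        for f in (0.0, 0.3, 0.6, 0.9):
            truth = EmbryoTruth("E", "XX", (TruthEvent("2", +1),), "abnormal", f)
            c = sample_copy(truth, "medium", small_grid, cfg)
            levels.append(c[small_grid.chrom_index("2")].mean())
        assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_called_mosaic_level_decreases_with_contamination(
        self, flat_small_grid, flat_small_caller
    ):
        cfg = _cfg(noise="none")
        rng = np.random.default_rng(0)
        called = []
        for f in (0.1, 0.4, 0.7):
            truth = EmbryoTruth("E", "XX", (TruthEvent("2", +1),), "abnormal", f)
            t = simulate_counts(truth, "medium", flat_small_grid, cfg, rng)
            ec = call_embryo(flat_small_caller.predict(t), embryo_id="E")
            call = ec.calls["2"]
            called.append(call.level if call.abnormal else 0.0)
        assert called[0] > called[1] > called[2]


class TestCohort:
    def test_empty_cohort(self):
        cohort = simulate_cohort(_cfg(n_embryos=0))
        assert cohort.truths == [] and cohort.tables == {}
        assert list(cohort.manifest.columns) == MANIFEST_COLUMNS
        assert len(cohort.manifest) == 0

    def test_manifest_row_count(self, small_grid):
        cohort = simulate_cohort(_cfg(n_embryos=5), grid=small_grid, n_blanks=2)
        assert len(cohort.manifest) == 3 * 5 + 2
        assert len(cohort.tables) == 17

    def test_cohort_determinism(self, small_grid):
        a = simulate_cohort(_cfg(n_embryos=4), grid=small_grid)
        b = simulate_cohort(_cfg(n_embryos=4), grid=small_grid)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for sid in a.tables:
            assert np.array_equal(a.tables[sid].counts, b.tables[sid].counts)

    def test_qc_failure_rate_leaves_about_nine_of_265_trios_incomplete(self, small_grid):
        cohort = simulate_cohort(_cfg(n_embryos=265), grid=small_grid)
        m = cohort.manifest
        affected = m[m["designated_qc_fail"] == 1]["embryo_id"].nunique()
        assert 2 <= affected <= 20  # E = 9.05, binomial 3-sigma band
        # a designated failure actually trips the CV gate
        sid = m[m["designated_qc_fail"] == 1]["sample_id"].iloc[0]
        from nicscall.cnv import compute_cv

        assert compute_cv(cohort.tables[sid]) >= 0.2

    def test_lineage_karyotypes_recorded(self, small_grid):
        truth = EmbryoTruth(
            "E", "XY", (TruthEvent("2", +1), TruthEvent("16", -1, 0.4, 0.0)), "abnormal", 0.0
        )
        assert lineage_karyotype(truth, "icm") == "[47, XY, +2, -16mos]"
        assert lineage_karyotype(truth, "te") == "[47, XY, +2]"
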