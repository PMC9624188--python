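import numpy as np
import pytest

from gramprod.controls import ControlConfig
from gramprod.errors import LemmaMismatchError
from gramprod.inference import (
    bootstrap_mean_ci,
    bootstrap_mean_cis,
    compare_samples,
    difference_vector,
)
from gramprod.productivity import PerLemmaProfile
from gramprod.synthetic import SyntheticConfig, generate_pair

from conftest import make_sample


class TestDifferenceVector:
    def test_identical_profiles_give_zero_mean(self):
        p = PerLemmaProfile({"a": 2.0, "b": 3.0})
        dv = difference_vector(p, p)
        assert dv.deltas == (0.0, 0.0) and dv.mean == 0.0

    def test_direction_is_profile2_minus_profile1(self):
        # a lemma used with two slots by the child and one by the adult
        # contributes a negative delta
        child = PerLemmaProfile({"mir": 2.0, "com": 1.0})
        adult = PerLemmaProfile({"mir": 1.0, "com": 3.0})
        dv = difference_vector(child, adult)
        assert dict(zip(dv.lemmas, dv.deltas)) == {"mir": -1.0, "com": 2.0}

    def test_arithmetic_and_lexicographic_order(self):
        dv = difference_vector(PerLemmaProfile({"a": 1.0, "b": 1.0}),
                               PerLemmaProfile({"b": 3.0, "a": 2.0}))
        assert dv.lemmas == ("a", "b")
        assert dv.deltas == (1.0, 2.0)
        assert dv.mean == 1.5

    def test_lemma_mismatch_lists_difference(self):
        with pytest.raises(LemmaMismatchError, match="c"):
            difference_vector(PerLemmaProfile({"a": 1.0, "b": 1.0}),
                              PerLemmaProfile({"a": 1.0, "c": 1.0}))


class TestBootstrapCI:
    def test_constant_deltas_degenerate_interval(self):
        for method in ("percentile", "bca"):
            ci = bootstrap_mean_ci(np.array([0.5, 0.5, 0.5]), method=method, seed=0)
            assert ci.low == ci.high == ci.observed_mean == 0.5
            assert ci.degenerate

    def test_zero_corrections_reduce_bca_to_percentile(self):
        rng = np.random.default_rng(12)
        deltas = rng.normal(0.3, 1.0, size=80)
        pct = bootstrap_mean_ci(deltas, "percentile", seed=5, n_replicates=2000)
        bca = bootstrap_mean_ci(deltas, "bca", seed=5, n_replicates=2000,
                                z0_override=0.0, accel_override=0.0)
        assert (bca.low, bca.high) == (pct.low, pct.high)

    def test_symmetric_deltas_methods_nearly_identical(self):
        rng = np.random.default_rng(31)
        deltas = rng.normal(0.0, 1.0, size=500)
        bca, pct = bootstrap_mean_cis(deltas, n_replicates=10_000, seed=8)
        sd = deltas.std(ddof=1)
        assert abs(bca.low - pct.low) < 0.02 * sd
        assert abs(bca.high - pct.high) < 0.02 * sd

    def test_replicate_mean_converges_to_observed(self):
        rng = np.random.default_rng(99)
        deltas = rng.normal(1.0, 2.0, size=120)
        ci = bootstrap_mean_ci(deltas, "percentile", n_replicates=10_000, seed=3)
        # the interval midpoint sits within ~3 bootstrap SEs of the observed mean
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs((ci.low + ci.high) / 2 - deltas.mean()) <= 3 * se / np.sqrt(1)

    def test_wider_level_widens_interval(self):
        rng = np.random.default_rng(4)
        deltas = rng.normal(0.0, 1.0, size=60)
        narrow = bootstrap_mean_ci(deltas, "percentile", level=0.90, seed=1)
        wide = bootstrap_mean_ci(deltas, "percentile", level=0.99, seed=1)
        assert wide.low <= narrow.low and wide.high >= narrow.high

    def test_percentile_endpoints_are_order_statistics(self):
        rng = np.random.default_rng(17)
        deltas = rng.normal(0.0, 1.0, size=40)
        ci = bootstrap_mean_ci(deltas, "percentile", n_replicates=1000, seed=2)
        # regenerate the replicate stream independently
        rng2 = np.random.default_rng(2)
        idx = rng2.integers(0, 40, size=(1000, 40))
        reps = np.sort(deltas[idx].mean(axis=1))
        assert ci.low in reps and ci.high in reps
        assert ci.low == reps[int(np.ceil(0.025 * 1000)) - 1]
        assert ci.high == reps[int(np.ceil(0.975 * 1000)) - 1]

    def test_seed_reproducibility(self):
        deltas = np.arange(20, dtype=float)
        a = bootstrap_mean_ci(deltas, "bca", seed=6)
        b = bootstrap_mean_ci(deltas, "bca", seed=6)
        assert (a.low, a.high) == (b.low, b.high)

    def test_low_never_exceeds_high(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            deltas = rng.exponential(1.0, size=25) - 0.3
            ci = bootstrap_mean_ci(deltas, "bca", n_replicates=500,
                                   seed=int(rng.integers(1 << 30)))
            assert ci.low <= ci.high

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_mean_ci(np.array([1.0]), "bca")
        with pytest.raises(ValueError):
            bootstrap_mean_ci(np.arange(5.0), "bca", level=1.2)
        with pytest.raises(ValueError):
            bootstrap_mean_ci(np.arange(5.0), "bca", n_replicates=10)
        with pytest.raises(ValueError):
            bootstrap_mean_ci(np.arange(5.0), method="studentized")


class TestComparePipeline:
    def test_self_comparison_degenerates_at_zero(self, es_paradigm):
        s = make_sample(["com_o", "com_en", "salt_a", "quer_e"], label="x")
        cfg = ControlConfig(n_subsamples=50, match_size_policy="postfilter_sample1",
                            seed=0)
        rows, dv, (ci_bca, ci_pct) = compare_samples(s, s, es_paradigm, cfg,
                                                     n_bootstrap=200)
        assert all(d == 0.0 for d in dv.deltas)
        for ci in (ci_bca, ci_pct):
            assert ci.degenerate and ci.low == ci.high == 0.0

    def test_row_layout_and_tri_invariance(self, es_paradigm):
        cfg1 = SyntheticConfig(n_lemmas=25, n_tokens=400, concentration=1.0,
                               seed=21, label="child")
        cfg2 = SyntheticConfig(n_lemmas=30, n_tokens=900, concentration=1.0,
                               seed=22, label="adult")
        s1, s2 = generate_pair(cfg1, cfg2, 0.8)
        rows, dv, _ = compare_samples(s1, s2, cfg1.paradigm,
                                      ControlConfig(n_subsamples=100, seed=1),
                                      n_bootstrap=500)
        assert [r.control for r in rows] == ["None", "None", "LH", "LH", "LH and SH"]
        assert [r.label for r in rows] == ["child", "adult", "child", "adult", "adult"]
        lh_adult, sh_adult = rows[3], rows[4]
        assert sh_adult.tri_pct == lh_adult.tri_pct
        # match size defaults to sample 1's unfiltered token count
        assert sh_adult.n_tokens == s1.n_tokens
        # shared lemma sets after LH
        assert rows[2].n_lemmas == rows[3].n_lemmas == len(dv)

    def test_pipeline_deterministic_given_seed(self, es_paradigm):
        cfg1 = SyntheticConfig(n_lemmas=20, n_tokens=300, concentration=1.5, seed=31)
        cfg2 = SyntheticConfig(n_lemmas=20, n_tokens=700, concentration=1.5, seed=32)
        s1, s2 = generate_pair(cfg1, cfg2, 1.0)
        out1 = compare_samples(s1, s2, cfg1.paradigm,
                               ControlConfig(n_subsamples=100, seed=7), n_bootstrap=500)
        out2 = compare_samples(s1, s2, cfg1.paradigm,
                               ControlConfig(n_subsamples=100, seed=7), n_bootstrap=500)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
        assert out1[2][0] == out2[2][0] and out1[2][1] == out2[2][1]
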