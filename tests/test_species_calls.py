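import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosspeak._stats import bh_qvalues, exact_mwu_two_sided, ranksum_pvalues
from crosspeak.errors import ValidationError
from crosspeak.genomic_io import SampleMeta
from crosspeak.species_calls import (
    AnalysisConfig,
    call_depletion,
    call_gain,
    filter_celltype_enriched,
    intersect_calls,
    select_control_peaks,
)
from crosspeak.synthetic_data import GeneratorSpec, gen_counts, gen_peak_pool
from crosspeak.quantify import normalize_density


def _density(rows, samples, lengths=None):
    ids = [f"p{i + 1}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=ids, columns=[s.sample_id for s in samples])
    lens = lengths or {i: 1000 for i in ids}
    return df, pd.Series(lens)


class TestRankSum:
    def test_perfectly_separated_3v2_gives_two_tenths(self):
        # 10 rank configurations, 2 extreme ones -> exact p = 0.2
        assert exact_mwu_two_sided([5, 6, 7], [1, 2]) == pytest.approx(0.2)

    def test_3v3_separated_gives_one_tenth(self):
        assert exact_mwu_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_agrees_with_scipy_exact_on_untied_rows(self, rng):
        from scipy import stats

        x = rng.normal(size=(100, 9))
        mine = ranksum_pvalues(x, 4)
        ref = stats.mannwhitneyu(x[:, :4], x[:, 4:], axis=1, method="exact").pvalue
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_monotone_and_dominates_p(self, pvals):
        p = np.asarray(pvals)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallGain:
    def test_identical_densities_yield_no_labels(self, toy_samples):
        dens, lens = _density([[2.0] * 5] * 4, toy_samples)
        calls = call_gain(dens, toy_samples, "human", ["chimpanzee"], lens,
                          AnalysisConfig())
        assert all(c.label == "none" for c in calls)
        assert all(c.folds["chimpanzee"] == pytest.approx(1.0) for c in calls)

    def test_toy_peak_exact_p(self, toy_samples):
        dens, lens = _density([[5, 6, 7, 1, 2]], toy_samples)
        (call,) = call_gain(dens, toy_samples, "human", ["chimpanzee"], lens,
                            AnalysisConfig())
        assert call.p == pytest.approx(0.2)
        assert call.q >= call.p

    def test_zero_background_fold_is_finite(self, toy_samples):
        dens, lens = _density([[0, 0, 0, 5, 6]], toy_samples)
        cfg = AnalysisConfig(pseudo_density=0.1, presence_floor=0.0)
        (call,) = call_depletion(dens, toy_samples, "human", ["chimpanzee"],
                                 lens, cfg)
        assert np.isfinite(call.folds["chimpanzee"])
        assert call.folds["chimpanzee"] == pytest.approx(5.6 / 0.1)

    def test_gain_and_depletion_are_mirrors(self, rng):
        samples = [SampleMeta(f"H{i}", "human", "NeuN+", 10**7) for i in range(6)] \
            + [SampleMeta(f"C{i}", "chimpanzee", "NeuN+", 10**7) for i in range(6)]
        dens = pd.DataFrame(rng.lognormal(1, 0.3, (300, 12)),
                            index=[f"p{i}" for i in range(300)],
                            columns=[s.sample_id for s in samples])
        dens.iloc[:30, :6] *= 6  # human-high block
        dens.iloc[30:60, 6:] *= 6  # chimp-high block
        lens = pd.Series(1000, index=dens.index)
        cfg = AnalysisConfig(presence_floor=0.0)
        gains_chimp = call_gain(dens, samples, "chimpanzee", ["human"], lens, cfg)
        loss_human = call_depletion(dens, samples, "human", ["chimpanzee"], lens, cfg)
        gain_set = {c.peak_id for c in gains_chimp if c.label == "gain"}
        loss_set = {c.peak_id for c in loss_human if c.label == "loss"}
        assert gain_set == loss_set and loss_set  # non-empty and identical

    def test_each_species_mode_is_stricter(self):
        spec = GeneratorSpec(n_peaks=400, n_gain_peaks=40, rng_seed=3)
        peaks, _ = gen_peak_pool(spec)
        counts, samples, _ = gen_counts(peaks, spec)
        lens = pd.Series({p.id: p.length for p in peaks})
        dens = normalize_density(counts, samples, lens)
        each = call_gain(dens, samples, "human", ["chimpanzee", "macaque"],
                         lens, AnalysisConfig(fold_mode="each_species"))
        pooled = call_gain(dens, samples, "human", ["chimpanzee", "macaque"],
                           lens, AnalysisConfig(fold_mode="pooled_average"))
        each_set = {c.peak_id for c in each if c.label == "gain"}
        pooled_set = {c.peak_id for c in pooled if c.label == "gain"}
        assert each_set <= pooled_set

    def test_short_peaks_never_labeled(self, toy_samples):
        dens, lens = _density([[9, 9, 9, 1, 1]], toy_samples, {"p1": 300})
        calls = call_gain(dens, toy_samples, "human", ["chimpanzee"], lens,
                          AnalysisConfig(min_length=500))
        assert calls[0].label == "none"

    def test_small_group_rejected(self, toy_samples):
        dens, lens = _density([[1, 2, 3, 4, 5]], toy_samples)
        with pytest.raises(ValidationError, match="<2 samples"):
            call_gain(dens, toy_samples, "macaque", ["chimpanzee"], lens,
                      AnalysisConfig())


class TestCellTypeFilter:
    def _cohort(self):
        return (
            [SampleMeta(f"H{i}", "human", "NeuN+", 10**7) for i in range(6)]
            + [SampleMeta(f"N{i}", "human", "NeuN-", 10**7) for i in range(4)]
            + [SampleMeta(f"C{i}", "chimpanzee", "NeuN+", 10**7) for i in range(3)]
        )

    def test_equal_neuronal_and_reference_means_excluded(self):
        samples = self._cohort()
        dens = pd.DataFrame([[8.0] * 6 + [8.0] * 4 + [1.0] * 3],
                            index=["p1"], columns=[s.sample_id for s in samples])
        lens = pd.Series({"p1": 1000})
        calls = call_gain(dens, samples, "human", ["chimpanzee"], lens,
                          AnalysisConfig())
        kept = filter_celltype_enriched(calls, dens, samples, AnalysisConfig())
        assert kept == []

    def test_neuron_restricted_peak_retained(self):
        samples = self._cohort()
        dens = pd.DataFrame(
            [[8.0, 9, 8.5, 9.5, 8.2, 9.1] + [1.0, 1.2, 0.9, 1.1] + [1.0, 1.1, 0.9]],
            index=["p1"], columns=[s.sample_id for s in samples])
        lens = pd.Series({"p1": 1000})
        calls = call_gain(dens, samples, "human", ["chimpanzee"], lens,
                          AnalysisConfig())
        assert calls[0].label == "gain"
        kept = filter_celltype_enriched(calls, dens, samples, AnalysisConfig())
        assert [c.peak_id for c in kept] == ["p1"]

    def test_empty_call_list_passes_through(self):
        samples = self._cohort()
        dens = pd.DataFrame(np.ones((1, 13)), index=["p1"],
                            columns=[s.sample_id for s in samples])
        assert filter_celltype_enriched([], dens, samples, AnalysisConfig()) == []

    def test_missing_reference_cell_type_is_an_error(self, toy_samples):
        dens = pd.DataFrame(np.ones((1, 5)), index=["p1"],
                            columns=[s.sample_id for s in toy_samples])
        calls = call_gain(dens, toy_samples, "human", ["chimpanzee"],
                          pd.Series({"p1": 1000}), AnalysisConfig())
        for c in calls:
            c.label = "gain"
        with pytest.raises(ValidationError, match="NeuN-"):
            filter_celltype_enriched(calls, dens, toy_samples, AnalysisConfig())


class TestIntersectCalls:
    @pytest.mark.parametrize("a,b,n,j", [
        ({"A", "B", "C"}, {"B", "C", "D"}, 2, 0.5),
        ({"A"}, {"B"}, 0, 0.0),
        ({"A", "B"}, {"A", "B"}, 2, 1.0),
    ])
    def test_set_arithmetic(self, a, b, n, j):
        rep = intersect_calls(a, b)
        assert rep["n_intersection"] == n
        assert rep["jaccard"] == pytest.approx(j)


class TestControlPeaks:
    def test_flat_peak_ranked_first_and_k_zero(self, toy_samples):
        dens, lens = _density([[3, 3, 3, 3, 3], [1, 1, 1, 9, 9], [2, 2, 2, 3, 3]],
                              toy_samples)
        cfg = AnalysisConfig()
        picked = select_control_peaks(dens, toy_samples, 1, cfg,
                                      species=("human", "chimpanzee"))
        assert picked == ["p1"]
        assert select_control_peaks(dens, toy_samples, 0, cfg,
                                    species=("human", "chimpanzee")) == []

    def test_matches_full_sort_oracle(self, rng, toy_samples):
        dens = pd.DataFrame(rng.lognormal(0, 1, (200, 5)),
                            index=[f"p{i}" for i in range(200)],
                            columns=[s.sample_id for s in toy_samples])
        cfg = AnalysisConfig()
        picked = select_control_peaks(dens, toy_samples, 25, cfg,
                                      species=("human", "chimpanzee"))
        # oracle: explicit per-peak max |log fold| then full stable sort
        eps = cfg.pseudo_density
        hm = dens[["H1", "H2", "H3"]].mean(axis=1)
        cm = dens[["C1", "C2"]].mean(axis=1)
        score = np.abs(np.log(hm + eps) - np.log(cm + eps))
        expect = list(score.sort_values(kind="stable").index[:25])
        assert picked == expect

    def test_k_exceeding_pool_rejected(self, toy_samples):
        dens, lens = _density([[1, 1, 1, 1, 1]], toy_samples)
        with pytest.raises(ValidationError, match="eligible"):
            select_control_peaks(dens, toy_samples, 5, AnalysisConfig(),
                                 species=("human", "chimpanzee"))
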