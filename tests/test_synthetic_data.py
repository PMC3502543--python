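import numpy as np
import pandas as pd
import pytest

from crosspeak.errors import ValidationError
from crosspeak.evo_footprint import count_hsas
from crosspeak.genomic_io import GenomeLayout
from crosspeak.perm_stats import overlap_categories
from crosspeak.synthetic_data import (
    GeneratorSpec,
    gen_alignment_blocks,
    gen_annotations,
    gen_counts,
    gen_peak_pool,
)


class TestPeakPool:
    def test_empty_pool(self):
        spec = GeneratorSpec(n_peaks=0, n_gain_peaks=0)
        peaks, truth = gen_peak_pool(spec)
        assert peaks == [] and truth.empty

    def test_same_seed_identical_output(self):
        spec = GeneratorSpec(n_peaks=150, n_clustered_pairs=10)
        a, ta = gen_peak_pool(spec, seed=5)
        b, tb = gen_peak_pool(spec, seed=5)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_peaks_respect_layout_and_do_not_overlap(self):
        spec = GeneratorSpec(n_peaks=500)
        peaks, _ = gen_peak_pool(spec, seed=1)
        by_chrom: dict = {}
        for p in peaks:
            assert 0 <= p.start < p.end <= spec.layout.chrom_lengths[p.chrom]
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_clustered_pairs_are_within_distance(self):
        spec = GeneratorSpec(n_peaks=300, n_clustered_pairs=40,
                             cluster_max_dist=400_000)
        peaks, truth = gen_peak_pool(spec, seed=2)
        mids = {p.id: p.midpoint for p in peaks}
        chroms = {p.id: p.chrom for p in peaks}
        for cid, grp in truth[truth.cluster_id >= 0].groupby("cluster_id"):
            a, b = grp.index
            assert chroms[a] == chroms[b]
            assert abs(mids[a] - mids[b]) < 400_000


class TestCounts:
    def test_planted_fold_recovered_in_group_means(self):
        spec = GeneratorSpec(n_peaks=1000, n_gain_peaks=500, gain_fold=4.0,
                             neuron_restricted_fraction=0.0)
        peaks, _ = gen_peak_pool(spec, seed=3)
        counts, samples, truth = gen_counts(peaks, spec, seed=4)
        libs = pd.Series({s.sample_id: s.library_size for s in samples})
        lens = pd.Series({p.id: p.length for p in peaks})
        dens = counts / (libs / 1e6) / (lens / 1e3).values[:, None]
        hcols = [s.sample_id for s in samples
                 if s.species == "human" and s.cell_type == "NeuN+"]
        ccols = [s.sample_id for s in samples if s.species != "human"]
        planted = truth.index[truth.planted_gain]
        ratio = dens.loc[planted, hcols].mean().mean() \
            / dens.loc[planted, ccols].mean().mean()
        assert 3.5 <= ratio <= 4.5

    def test_zero_dispersion_limits_to_poisson(self):
        spec = GeneratorSpec(n_peaks=1, n_gain_peaks=0, dispersion=0.0)
        rng = np.random.default_rng(0)
        from crosspeak.synthetic_data import _nb_draw

        draws = _nb_draw(rng, np.full(10_000, 50.0), 0.0)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.1)

    def test_overdispersion_matches_nb_parameterization(self):
        rng = np.random.default_rng(0)
        from crosspeak.synthetic_data import _nb_draw

        mu, disp = 50.0, 0.2
        draws = _nb_draw(rng, np.full(200_000, mu), disp)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu + disp * mu**2, rel=0.05)

    def test_invalid_library_size_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorSpec(library_size_range=(0, 10))


class TestAnnotations:
    def test_realized_fractions_near_baseline(self):
        spec = GeneratorSpec(n_peaks=5000, n_gain_peaks=0)
        peaks, _ = gen_peak_pool(spec, seed=6)
        target, other, truth = gen_annotations(peaks, spec, seed=7)
        fracs = truth.category.value_counts(normalize=True)
        for cat, expect in spec.annotation_fracs.items():
            assert fracs.get(cat, 0.0) == pytest.approx(expect, abs=0.02)

    def test_overlap_categories_reproduce_truth_exactly(self):
        spec = GeneratorSpec(n_peaks=400, n_gain_peaks=50)
        peaks, _ = gen_peak_pool(spec, seed=8)
        enriched = [p.id for p in peaks[:50]]
        target, other, truth = gen_annotations(peaks, spec, seed=9,
                                               enriched_ids=enriched)
        cats = overlap_categories(peaks, target, other)
        assert cats.as_dict() == truth.category.value_counts().to_dict()

    def test_enriched_subset_hits_planted_fraction(self):
        spec = GeneratorSpec(n_peaks=4000, n_gain_peaks=0,
                             enriched_target_only=0.22)
        peaks, _ = gen_peak_pool(spec, seed=10)
        enriched = [p.id for p in peaks[:2000]]
        _, _, truth = gen_annotations(peaks, spec, seed=11, enriched_ids=enriched)
        frac = (truth.loc[enriched].category == "target_only").mean()
        assert frac == pytest.approx(0.22, abs=0.03)


class TestAlignmentBlocks:
    def test_zero_rates_give_identical_taxa_and_no_hsas(self):
        spec = GeneratorSpec(n_peaks=5, n_gain_peaks=0, sub_rate_human=0,
                             sub_rate_human_background=0, sub_rate_comparison=0,
                             indel_rate_human=0, indel_rate_comparison=0,
                             long_indel_rate_human=0)
        peaks, _ = gen_peak_pool(spec, seed=12)
        blocks, truth = gen_alignment_blocks(peaks, spec, seed=13)
        assert truth.empty
        for b in blocks:
            assert len(set(b.sequences.values())) == 1
            assert count_hsas(b, list(spec.comparison_taxa)) == []

    def test_truth_states_match_recovered_states(self):
        spec = GeneratorSpec(n_peaks=30, n_gain_peaks=0, sub_rate_human=10,
                             sub_rate_human_background=10,
                             sub_rate_comparison=0, indel_rate_human=0,
                             indel_rate_comparison=0, long_indel_rate_human=0,
                             archaic_postsplit=0.5, archaic_missing=0.0)
        peaks, _ = gen_peak_pool(spec, seed=14)
        blocks, truth = gen_alignment_blocks(peaks, spec, seed=15)
        recovered = []
        for b in blocks:
            for h in count_hsas(b, list(spec.comparison_taxa),
                                list(spec.archaic_taxa)):
                recovered.append(h.archaic_states["neanderthal"])
        truth_states = list(truth["state_neanderthal"])
        assert len(recovered) == len(truth_states)
        assert recovered.count("ancestral") == truth_states.count("ancestral")

    def test_same_seed_identical_blocks(self):
        spec = GeneratorSpec(n_peaks=10, n_gain_peaks=0)
        peaks, _ = gen_peak_pool(spec, seed=16)
        a, ta = gen_alignment_blocks(peaks, spec, seed=17)
        b, tb = gen_alignment_blocks(peaks, spec, seed=17)
        assert [x.sequences for x in a] == [x.sequences for x in b]
        pd.testing.assert_frame_equal(ta, tb)
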