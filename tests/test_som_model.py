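"""Somatic forest: window fitting, sliding score, density profile."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualmut.features import build_window_matrix
from dualmut.genome import GenomeModel
from dualmut.intervals import FeatureTrack
from dualmut.simulate import (
    FeatureSpec,
    SyntheticConfig,
    generate_feature_tracks,
    generate_genome,
    generate_somatic_mutations,
)
from dualmut.som_model import (
    ScoredTrack,
    feature_mutation_density_profile,
    fit_som_model,
    sliding_som_score,
)
from dualmut.variants import VariantSet


def somatic(chrom, pos, patient="P0") -> VariantSet:
    return VariantSet.from_arrays(
        [chrom] * len(pos), pos, "somatic", patient_id=[patient] * len(pos)
    )


def planted_world(seed=13, genome_mb=25):
    specs = [
        FeatureSpec("repressed", 0.25, 1_000_000),
        FeatureSpec("active", 0.25, 1_000_000),
        FeatureSpec("noise", 0.2, 500_000),
    ]
    cfg = SyntheticConfig(
        genome_size=genome_mb * 1_000_000,
        n_chromosomes=1,
        feature_specs=specs,
        snp_density=0.0,
        somatic_baseline_density=100.0,
        somatic_multipliers={"repressed": 3.0, "active": 0.3},
        n_patients=10,
        n_disease_variants=0,
        seed=seed,
    )
    g = generate_genome(cfg)
    tr = generate_feature_tracks(g, cfg)
    som = generate_somatic_mutations(g, tr, cfg)
    return cfg, g, tr, som


class TestFit:
    def test_uniform_density_predicts_mean(self, rng):
        g = GenomeModel([("chr1", 25_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        pos = rng.integers(0, 25_000_000, size=25_000)
        wm = build_window_matrix([t], somatic("chr1", pos), g)
        fit = fit_som_model(wm, seed=0, select=False, n_trees=100)
        pred = fit.forest.predict(wm.design())
        # single near-constant predictor: predictions hug the mean density
        assert np.allclose(pred, wm.response.mean(), rtol=0.1)

    def test_same_seed_identical_predictions(self):
        cfg, g, tr, som = planted_world()
        wm = build_window_matrix(tr, som, g)
        p1 = fit_som_model(wm, seed=5, select=False, n_trees=100).forest.predict(wm.design())
        p2 = fit_som_model(wm, seed=5, select=False, n_trees=100).forest.predict(wm.design())
        assert np.array_equal(p1, p2)

    def test_all_zero_response_rejected(self):
        g = GenomeModel([("chr1", 25_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        wm = build_window_matrix([t], VariantSet.empty(), g)
        with pytest.raises(ValueError, match="all-zero"):
            fit_som_model(wm, seed=0)

    def test_too_few_windows_rejected(self):
        g = GenomeModel([("chr1", 5_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        wm = build_window_matrix([t], somatic("chr1", [10, 20]), g)
        with pytest.raises(ValueError, match="windows"):
            fit_som_model(wm, seed=0)

    def test_selection_recovers_planted_features(self):
        cfg, g, tr, som = planted_world()
        wm = build_window_matrix(tr, som, g)
        fit = fit_som_model(wm, seed=1, select=True, n_trees=150, n_repeats=3)
        assert {"repressed", "active"} <= set(fit.selected_features)


class TestSlidingScore:
    def test_constant_features_constant_score(self):
        """Criterion: constant predictors -> every bin equals the single
        window prediction to 1e-6 relative."""
        g = GenomeModel([("chr1", 25_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 25_000_000)])  # covers everything
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 25_000_000, size=25_000)
        wm = build_window_matrix([t], somatic("chr1", pos), g)
        fit = fit_som_model(wm, seed=0, select=False, n_trees=50)
        bins = sliding_som_score(fit, [t], g)["chr1"]
        ref = fit.forest.predict(np.log1p([[1_000_000.0]]))[0]
        assert np.nanmax(np.abs(bins - ref)) <= 1e-6 * ref

    def test_three_mb_toy_matches_enumeration(self):
        """Bin scores equal the brute-force mean over covering windows."""
        cfg, g, tr, som = planted_world(genome_mb=3)
        wm = build_window_matrix(tr, som, g)
        # only 3 training windows: below the fitting floor, so build the
        # forest directly — the oracle checks the sliding averaging, not the fit
        from sklearn.ensemble import RandomForestRegressor
        from dualmut.som_model import SomModelFit

        rf = RandomForestRegressor(n_estimators=50, random_state=0)
        rf.fit(wm.design(), wm.response)
        fit = SomModelFit("toy", wm.feature_names, wm.feature_names, rf, 1, 0.0, 0)
        bins = sliding_som_score(fit, tr, g)["chr1"]

        # enumeration oracle
        length = 3_000_000
        starts = np.arange(0, length - 1_000_000 + 1, 1_000)
        X = []
        for s in starts:
            row = []
            for t in tr:
                iv = t.intervals("chr1")
                inter = np.clip(np.minimum(iv[:, 1], s + 1_000_000) - np.maximum(iv[:, 0], s), 0, None)
                row.append(np.log1p(inter.sum()))
            X.append(row)
        preds = rf.predict(np.array(X))
        for b in [0, 1, 500, 1_500, 2_500, 2_999]:
            lo = max(0, b - 999)
            hi = min(len(starts) - 1, b)
            oracle = preds[lo : hi + 1].mean()
            assert bins[b] == pytest.approx(oracle, rel=1e-12)

    def test_exclusion_propagates_to_bins(self):
        """Bins whose every covering window hits an excluded region are NaN."""
        g = GenomeModel(
            [("chr1", 5_000_000)],
            excluded=FeatureTrack("excl", [("chr1", 2_000_000, 2_100_000)]),
        )
        specs = [FeatureSpec("A", 0.3, 100_000)]
        cfg = SyntheticConfig(
            genome_size=5_000_000, n_chromosomes=1, feature_specs=specs,
            snp_density=0, somatic_baseline_density=100, n_patients=5,
            n_disease_variants=0, seed=2,
        )
        tr = generate_feature_tracks(g, cfg)
        som = generate_somatic_mutations(g, tr, cfg)
        wm = build_window_matrix(tr, som, g)
        from sklearn.ensemble import RandomForestRegressor
        from dualmut.som_model import SomModelFit

        rf = RandomForestRegressor(n_estimators=20, random_state=0)
        rf.fit(wm.design(), wm.response)
        fit = SomModelFit("toy", wm.feature_names, wm.feature_names, rf, 1, 0.0, 0)
        bins = sliding_som_score(fit, tr, g)["chr1"]
        # bin fully surrounded: e.g. bin at 2.05 Mb — all windows overlap exclusion
        assert np.isnan(bins[2_050])
        assert not np.isnan(bins[500])

    def test_catalogue_mismatch_rejected(self):
        cfg, g, tr, som = planted_world()
        wm = build_window_matrix(tr, som, g)
        fit = fit_som_model(wm, seed=0, select=False, n_trees=50)
        with pytest.raises(ValueError, match="missing tracks"):
            sliding_som_score(fit, tr[:1], g)

    def test_per_patient_normalization(self):
        cfg, g, tr, som = planted_world()
        wm = build_window_matrix(tr, som, g)
        fit = fit_som_model(wm, seed=0, select=False, n_trees=50, n_patients=10)
        pooled = sliding_som_score(fit, tr, g)["chr1"]
        per_pat = sliding_som_score(fit, tr, g, per_patient=True)["chr1"]
        assert np.allclose(per_pat, pooled / 10, equal_nan=True)

    def test_monotone_in_planted_multiplier(self):
        """Raising one multiplier (same seed) raises mean score inside it."""
        means = []
        for mult in (1.0, 3.0):
            specs = [FeatureSpec("A", 0.25, 1_000_000), FeatureSpec("B", 0.25, 500_000)]
            cfg = SyntheticConfig(
                genome_size=25_000_000, n_chromosomes=1, feature_specs=specs,
                snp_density=0, somatic_baseline_density=100,
                somatic_multipliers={"A": mult}, n_patients=10,
                n_disease_variants=0, seed=6,
            )
            g = generate_genome(cfg)
            tr = generate_feature_tracks(g, cfg)
            som = generate_somatic_mutations(g, tr, cfg)
            wm = build_window_matrix(tr, som, g)
            fit = fit_som_model(wm, seed=0, select=False, n_trees=100)
            bins = sliding_som_score(fit, tr, g)["chr1"]
            mid = np.arange(len(bins)) * 1_000 + 500
            inside = tr[0].contains("chr1", mid)
            means.append(np.nanmean(bins[inside]))
        assert means[1] > means[0]


class TestDensityProfile:
    def test_whole_genome_feature_is_one(self, rng):
        g = GenomeModel([("chr1", 2_000_000)])
        t = FeatureTrack("all", [("chr1", 0, 2_000_000)])
        som = somatic("chr1", rng.integers(0, 2_000_000, size=1_000))
        prof = feature_mutation_density_profile(som, [t], g)
        assert prof.loc[0, "relative_density"] == pytest.approx(1.0)

    def test_planted_multiplier_direction(self):
        """Repressed-like (x3) features show relative density > 1; active-like
        (x0.3) < 1 — the qualitative profile of tumor mutation densities."""
        cfg, g, tr, som = planted_world()
        prof = feature_mutation_density_profile(som, tr, g).set_index("feature")
        assert prof.loc["repressed", "relative_density"] > 1.2
        assert prof.loc["active", "relative_density"] < 0.8
        # counting oracle for the repressed feature
        n_in = tr[0].contains("chr1", som.positions("chr1")).sum()
        expected = (n_in / tr[0].total_bp()) / (len(som) / g.total_size)
        assert prof.loc["repressed", "relative_density"] == pytest.approx(expected)

    def test_zero_mutation_feature_zero(self, rng):
        g = GenomeModel([("chr1", 2_000_000)])
        t = FeatureTrack("empty_region", [("chr1", 1_900_000, 2_000_000)])
        som = somatic("chr1", rng.integers(0, 1_000_000, size=500))
        prof = feature_mutation_density_profile(som, [t], g)
        assert prof.loc[0, "relative_density"] == 0.0

    def test_zero_length_feature_skipped(self, rng):
        g = GenomeModel([("chr1", 2_000_000)])
        t = FeatureTrack("none", [])
        som = somatic("chr1", [5, 10])
        with pytest.warns(UserWarning, match="zero length"):
            prof = feature_mutation_density_profile(som, [t], g)
        assert len(prof) == 0

    def test_empty_variant_set_rejected(self):
        g = GenomeModel([("chr1", 2_000_000)])
        t = FeatureTrack("A", [("chr1", 0, 1_000)])
        with pytest.raises(ValueError, match="empty"):
            feature_mutation_density_profile(VariantSet.empty(), [t], g)


class TestScoredTrack:
    def test_bins_tile_without_overlap(self, toy_genome):
        st = ScoredTrack.empty(toy_genome)
        assert len(st.df) == 150  # 100 + 50 bins of 1 kb
        assert (st.df["label"] == "unscored").all()

    def test_bin_index_lookup(self, toy_genome):
        st = ScoredTrack.empty(toy_genome)
        idx = st.bin_index(["chr1", "chr2", "chr1"], [1_500, 2_200, 0])
        assert idx.tolist() == [1, 102, 0]
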