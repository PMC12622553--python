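"""Expression preprocessing and PLS inference."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import klsconn as k
from klsconn.exceptions import DegenerateInputError, ValidationError
from klsconn.transcriptomics import _pls1, _standardize


def _probe_rows(probe, gene, values_by_donor, background=4.0):
    rows = []
    for donor, vals in values_by_donor.items():
        for i, v in enumerate(vals):
            rows.append((probe, gene, donor, f"R{i:02d}", v, background))
    return rows


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["probe_id", "gene_symbol", "donor_id", "region_id", "intensity", "background"],
    )


class TestIntensityFilter:
    def test_bright_probes_kept_unchanged(self):
        t = _table(_probe_rows("p1", "g1", {"D1": [7, 8, 9], "D2": [7, 8, 9]}))
        out = k.filter_probes_intensity(t)
        assert len(out) == len(t)

    def test_exact_threshold_kept(self):
        t = _table(_probe_rows("p1", "g1", {"D1": [6.0, 6.0]}, background=4.0))
        assert len(k.filter_probes_intensity(t, factor=1.5)) == 2  # 6.0 == 1.5*4.0

    def test_all_below_removed_partial_kept(self):
        rows = _probe_rows("dim", "g1", {"D1": [5.0, 5.0], "D2": [5.0, 5.0]})
        rows += _probe_rows("half", "g1", {"D1": [5.0, 5.0], "D2": [7.0, 7.0]})
        out = k.filter_probes_intensity(_table(rows))
        assert set(out["probe_id"]) == {"half"}


class TestDifferentialStability:
    def test_single_probe_retained(self):
        t = _table(_probe_rows("only", "g1", {"D1": [1, 2, 3], "D2": [3, 2, 1]}))
        out = k.collapse_probes_differential_stability(t)
        assert set(out["probe_id"]) == {"only"}

    def test_stable_probe_beats_noise(self, probe_table):
        # probe *_p1 replicates one profile across donors (DS = 1); *_p2 is noisy
        ds = k.differential_stability(probe_table)
        stable = ds.set_index("probe_id")["ds"]
        assert stable["geneA_p1"] == pytest.approx(1.0)
        assert stable["geneA_p1"] > stable["geneA_p2"]
        out = k.collapse_probes_differential_stability(probe_table)
        assert set(out["probe_id"]) == {"geneA_p1", "geneB_p1"}

    def test_ds_matches_explicit_pairwise_spearman(self, probe_table):
        from scipy.stats import spearmanr

        sub = probe_table[probe_table["probe_id"] == "geneA_p2"]
        wide = sub.pivot(index="region_id", columns="donor_id", values="intensity")
        pairs = [("D01", "D02"), ("D01", "D03"), ("D02", "D03")]
        expected = np.mean([spearmanr(wide[a], wide[b]).statistic for a, b in pairs])
        ds = k.differential_stability(probe_table).set_index("probe_id")["ds"]
        assert ds["geneA_p2"] == pytest.approx(expected, abs=1e-12)

    def test_exact_tie_breaks_lexicographically(self):
        rows = _probe_rows("pB", "g1", {"D1": [1, 2, 3], "D2": [1, 2, 3]})
        rows += _probe_rows("pA", "g1", {"D1": [3, 2, 1], "D2": [3, 2, 1]})
        out = k.collapse_probes_differential_stability(_table(rows))
        assert set(out["probe_id"]) == {"pA"}

    def test_unmeasurable_gene_dropped_with_warning(self):
        rows = _probe_rows("p1", "gOK", {"D1": [1, 2, 3], "D2": [1, 2, 3]})
        rows += _probe_rows("p2", "gBad", {"D1": [1, 2, 3]})  # single donor
        with pytest.warns(UserWarning, match="gBad"):
            out = k.collapse_probes_differential_stability(_table(rows))
        assert set(out["gene_symbol"]) == {"gOK"}


class TestSRS:
    def test_hand_computed_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
        expected = (s - s.min()) / (s.max() - s.min())
        np.testing.assert_allclose(k.srs_normalize(x), expected, atol=1e-12)

    def test_median_maps_to_sigmoid_center(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        s_med = 1.0 / (1.0 + np.exp(-(3.0 - 3.0) / (iqr / 1.35)))
        assert s_med == 0.5

    def test_monotone_and_bounded(self, rng):
        x = np.sort(rng.normal(0, 1, 50))
        out = k.srs_normalize(x)
        assert (np.diff(out) >= 0).all()
        assert out.min() == 0.0 and out.max() == 1.0

    def test_zero_iqr_degenerate(self):
        with pytest.raises(DegenerateInputError):
            k.srs_normalize(np.array([1.0, 1.0, 1.0, 1.0, 9.0]))

    def test_not_idempotent(self, rng):
        x = rng.normal(0, 1, 30)
        once = k.srs_normalize(x)
        twice = k.srs_normalize(once)
        assert not np.allclose(once, twice)


class TestBuildExpressionMatrix:
    def test_full_pipeline_output(self, probe_table):
        mat = k.build_expression_matrix(probe_table)
        assert mat.attrs["srs_applied"] is True
        assert not mat.isna().to_numpy().any()
        assert (mat.to_numpy() >= 0).all() and (mat.to_numpy() <= 1).all()
        assert set(mat.columns) == {"geneA", "geneB"}


class TestFitPLS:
    def test_single_driver_limit(self):
        # many regions, few genes: incidental correlations (~1/sqrt(R)) from
        # the other genes barely mix into component 1
        rng = np.random.default_rng(1)
        target = rng.standard_normal(1000)
        spec = k.GeneMatrixSpec(n_regions=1000, n_genes=5, seed=1)
        X, _ = k.generate_gene_matrix(spec, target)
        y = X.iloc[:, 2].to_numpy() + rng.normal(0, 1e-3, 1000)
        res = k.fit_pls(X, y)
        assert np.argmax(np.abs(res.gene_weights)) == 2
        assert res.component_r > 0.99

    def test_sign_convention_and_flip_symmetry(self, rng):
        X = rng.standard_normal((40, 20))
        y = rng.standard_normal(40)
        r1 = k.fit_pls(X, y)
        r2 = k.fit_pls(X, -y)
        assert r1.component_r >= 0 and r2.component_r >= 0
        np.testing.assert_allclose(r1.pls1_scores, -r2.pls1_scores, atol=1e-10)
        np.testing.assert_allclose(r1.gene_weights, -r2.gene_weights, atol=1e-10)

    def test_fast_component_matches_sklearn(self, rng):
        """The closed-form first component (normalised X'y) used by the
        permutation engine must match the NIPALS component from sklearn."""
        X = rng.standard_normal((50, 80))
        y = rng.standard_normal(50)
        Xz, yz = _standardize(X), _standardize(y.reshape(-1, 1)).ravel()
        w_fast, t_fast = _pls1(Xz, yz)
        fit = PLSRegression(n_components=1, scale=False).fit(Xz, yz)
        w_sk = fit.x_weights_[:, 0]
        sign = np.sign(w_fast @ w_sk)
        np.testing.assert_allclose(w_fast, sign * w_sk, atol=1e-10)
        np.testing.assert_allclose(t_fast, sign * fit.x_scores_[:, 0], atol=1e-8)

    def test_misaligned_regions_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 4)), index=[f"R{i}" for i in range(10)])
        y = pd.Series(rng.standard_normal(10), index=[f"Q{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            k.fit_pls(X, y)


class TestPermutationTest:
    def test_minimum_attainable_p(self, rng):
        target = rng.standard_normal(60)
        spec = k.GeneMatrixSpec(
            n_regions=60, n_genes=100, n_planted_pos=10, planted_r=0.9, seed=2
        )
        X, _ = k.generate_gene_matrix(spec, target)
        p = k.permutation_test_component(X, target, n_perm=200, seed=0)
        assert p >= 1 / 201
        assert p <= 0.05

    def test_small_n_perm_warns(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="n_perm"):
            k.permutation_test_component(X, y, n_perm=50, seed=0)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        p1 = k.permutation_test_component(X, y, n_perm=300, seed=5)
        p2 = k.permutation_test_component(X, y, n_perm=300, seed=5)
        assert p1 == p2


class TestBootstrapZ:
    def test_planted_genes_exceed_threshold(self, rng):
        target = rng.standard_normal(120)
        spec = k.GeneMatrixSpec(
            n_regions=120, n_genes=200, n_planted_pos=3, n_planted_neg=3,
            planted_r=0.8, seed=3,
        )
        X, _ = k.generate_gene_matrix(spec, target)
        z = k.bootstrap_gene_z(X, target, n_boot=400, seed=3)
        assert (z[:3] > 3).all()
        assert (z[3:6] < -3).all()

    def test_null_z_roughly_standard_normal(self, rng):
        target = rng.standard_normal(150)
        spec = k.GeneMatrixSpec(n_regions=150, n_genes=400, seed=4)
        X, _ = k.generate_gene_matrix(spec, target)
        z = k.bootstrap_gene_z(X, target, n_boot=400, seed=4)
        assert abs(z.mean()) < 0.2
        assert 0.8 < z.std() < 1.25

    def test_stability_when_doubling_boots(self, rng):
        target = rng.standard_normal(100)
        spec = k.GeneMatrixSpec(
            n_regions=100, n_genes=50, n_planted_pos=5, planted_r=0.8, seed=5
        )
        X, _ = k.generate_gene_matrix(spec, target)
        z1 = k.bootstrap_gene_z(X, target, n_boot=500, seed=6)
        z2 = k.bootstrap_gene_z(X, target, n_boot=1000, seed=6)
        big = np.abs(z1) > 2
        assert np.all(np.abs(z2[big] - z1[big]) / np.abs(z1[big]) < 0.10)


class TestGeneSets:
    def test_direct_thresholding(self):
        sets = k.select_gene_sets(np.array([4.0, -5.0, 1.0]), ["g1", "g2", "g3"])
        assert sets.pls_plus == ["g1"] and sets.pls_minus == ["g2"]

    def test_boundary_excluded(self):
        sets = k.select_gene_sets(np.array([3.0, -3.0]), ["a", "b"])
        assert sets.pls_plus == [] and sets.pls_minus == []

    def test_all_subthreshold_empty(self):
        sets = k.select_gene_sets(np.array([1.0, -2.0]), ["a", "b"])
        assert sets.pls_plus == [] and sets.pls_minus == []


class TestGeneMapCorrelation:
    def test_perfect_correlations(self, rng):
        y = rng.standard_normal(20)
        assert k.gene_map_correlation(y, y)[0] == pytest.approx(1.0)
        assert k.gene_map_correlation(-y, y)[0] == pytest.approx(-1.0)

    def test_textbook_formula(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        r, _ = k.gene_map_correlation(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            k.gene_map_correlation(np.ones(10), np.arange(10.0))
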