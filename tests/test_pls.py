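"""NIPALS PLS2 and the enrichment / isolate-database analyses."""

import numpy as np
import pandas as pd
import pytest

from sipriming.plfa import (
    enrichment_matrix,
    plfa_incorporation,
    relative_enrichment,
)
from sipriming.isotope import SubstrateSpec
from sipriming.pls import (
    IsolateDB,
    compare_to_isolates,
    nipals_pls2,
    pls_enrichment_analysis,
)

LC = SubstrateSpec("lignocellulose", atom_fraction_13c=0.97, dose_mgc_per_ml=0.15)


def align_sign(ours, theirs):
    i = np.argmax(np.abs(ours))
    return theirs * np.sign(ours[i] * theirs[i])


class TestNipals:
    def test_rank_one_exact_fit_explains_everything(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=5))
        Y = np.outer(t, rng.normal(size=3))
        m = nipals_pls2(X, Y, n_components=1)
        assert m.explained_y[0] == pytest.approx(100.0, abs=1e-8)

    def test_orthonormal_predictors_pick_first_axis(self):
        # orthonormal zero-mean columns (QR of a centred matrix), so
        # centring inside the fit leaves them untouched
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 4))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        Y = Q[:, [0]].copy()
        m = nipals_pls2(Q, Y, n_components=1)
        w = m.x_weights[:, 0]
        assert abs(w[0]) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(w[1:], 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_pls_implementation(self, seed):
        """Scores/weights/loadings agree with scikit-learn up to sign."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 3))
        m = nipals_pls2(X, Y, n_components=3, tol=1e-14, max_iter=10000)
        sk = PLSRegression(n_components=3, scale=False, tol=1e-14, max_iter=10000).fit(
            X, Y
        )
        for ours, theirs in (
            (m.x_weights, sk.x_weights_),
            (m.x_scores, sk.x_scores_),
            (m.x_loadings, sk.x_loadings_),
            (m.y_loadings, sk.y_loadings_),
        ):
            for a in range(3):
                ref = align_sign(ours[:, a], theirs[:, a])
                assert np.allclose(ours[:, a], ref, atol=1e-6)

    def test_scores_orthogonal_and_full_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 5))
        Y = rng.normal(size=(9, 2))
        m = nipals_pls2(X, Y, n_components=5)
        G = m.x_scores.T @ m.x_scores
        assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8
        Xc = X - X.mean(axis=0)
        recon = m.x_scores @ m.x_loadings.T
        assert np.max(np.abs(Xc - recon)) < 1e-8

    def test_explained_variance_non_decreasing_cumulative(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        Y = X @ rng.normal(size=(6, 3)) + 0.1 * rng.normal(size=(12, 3))
        m = nipals_pls2(X, Y, n_components=4)
        cum = m.cumulative_explained_y
        assert np.all(np.diff(cum) >= -1e-10)
        assert cum[-1] <= 100.0 + 1e-8

    def test_y_column_reordering_permutes_loadings_only(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 3))
        perm = [2, 0, 1]
        m1 = nipals_pls2(X, Y, n_components=2)
        m2 = nipals_pls2(X, Y[:, perm], n_components=2)
        assert np.allclose(m1.x_scores, m2.x_scores, atol=1e-9)
        assert np.allclose(m1.y_loadings[perm, :], m2.y_loadings, atol=1e-9)

    def test_zero_variance_column_error_names_column(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [1.0, 1, 1, 1]})
        Y = pd.DataFrame({"y": [1.0, 2, 1, 2]})
        with pytest.raises(ValueError, match="flat"):
            nipals_pls2(X, Y, n_components=1, scale=True)

    def test_input_validation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="n_components"):
            nipals_pls2(X, Y, n_components=4)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            nipals_pls2(Xn, Y, n_components=1)


def make_matrix(rates_sim):
    incorp = plfa_incorporation(rates_sim.plfa, LC)
    props = relative_enrichment(incorp[incorp.day > 0])
    return enrichment_matrix(props, time_average=True)


class TestEnrichmentPLS:
    def test_constant_profiles_explain_nothing(self):
        matrix = pd.DataFrame(
            {c: [0.5, 0.3, 0.2] for c in ("LC", "LC1D", "LC2D")},
            index=["i15:0", "16:0", "18:1w9"],
        )
        res = pls_enrichment_analysis(matrix, n_components=2)
        assert res.model.explained_y.sum() == pytest.approx(0.0, abs=1e-8)

    def test_known_contrast_loads_opposite_ends_of_axis1(self):
        # PLFA "hi" enriched only in LC2D, "lo" only in LC
        matrix = pd.DataFrame(
            {
                "LC": [0.70, 0.10, 0.20],
                "LC1D": [0.40, 0.40, 0.20],
                "LC2D": [0.10, 0.70, 0.20],
            },
            index=["lo", "hi", "flat"],
        )
        res = pls_enrichment_analysis(matrix, n_components=2)
        v = res.variable_coordinates
        assert v.loc["lo", "axis1"] * v.loc["hi", "axis1"] < 0
        assert abs(v.loc["flat", "axis1"]) < 0.5

    def test_generator_encoded_treatment_geometry(self, rates_sim):
        """Time-averaged profiles order LC vs 2D opposed, 1D between."""
        res = pls_enrichment_analysis(make_matrix(rates_sim), n_components=2)
        s = res.observation_scores["axis1"]
        assert (s["LC"] < s["LC1D"] < s["LC2D"]) or (s["LC"] > s["LC1D"] > s["LC2D"])
        assert res.dropped_plfas == ["15:0", "cy19:0"]  # never enriched

    def test_low_enrichment_filter_applied_before_logit(self, rates_sim):
        res = pls_enrichment_analysis(make_matrix(rates_sim))
        assert set(res.retained_plfas).isdisjoint(res.dropped_plfas)
        assert len(res.model.y_names) == len(res.retained_plfas)


class TestIsolateComparison:
    def test_self_match_attains_max_axis1_correlation(self, rates_sim):
        matrix = make_matrix(rates_sim)
        rng = np.random.default_rng(9)
        profiles = rng.dirichlet(np.ones(len(matrix.index)), size=10).T
        db = pd.DataFrame(
            profiles, index=matrix.index, columns=[f"Genus{i:02d}" for i in range(10)]
        )
        # plant the LC enrichment profile itself as one genus
        self_col = matrix["LC"] / matrix["LC"].sum()
        db["SelfMatch"] = self_col
        model, cors = compare_to_isolates(matrix, IsolateDB(profiles=db), n_components=3)
        best = cors["axis1"].abs().idxmax()
        assert best == "SelfMatch"

    def test_common_plfa_intersection_matches_set_logic(self, rates_sim):
        matrix = make_matrix(rates_sim)
        rng = np.random.default_rng(10)
        names = list(matrix.index[:5]) + ["unknown1", "unknown2"]
        db = pd.DataFrame(
            rng.dirichlet(np.ones(len(names)), size=6).T,
            index=names,
            columns=[f"G{i}" for i in range(6)],
        )
        model, cors = compare_to_isolates(matrix, IsolateDB(profiles=db))
        common = set(matrix.index) & set(names)
        assert model.x_scores.shape[0] == len(common)

    def test_too_few_common_plfas_errors(self, rates_sim):
        matrix = make_matrix(rates_sim)
        db = pd.DataFrame(
            {"G1": [0.5, 0.5], "G2": [0.2, 0.8]}, index=["zzz1", "zzz2"]
        )
        with pytest.raises(ValueError, match="common"):
            compare_to_isolates(matrix, IsolateDB(profiles=db))

    def test_isolate_db_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            IsolateDB(profiles=pd.DataFrame({"G1": [-0.1, 1.1]}, index=["a", "b"]))
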