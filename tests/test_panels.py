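"""Panel models: Begg-Gray decomposition, BIC model averaging, CAR
scores and scalar panel scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla

import triroc as tr
from triroc.panels import (
    BeggGrayBMA,
    CandidateSet,
    CARScorePanel,
    DEFAULT_PSEUDO_RESPONSE,
)


def _make_candidates(rng, n=(60, 40, 60), shift=(0.0, 1.0, 2.0),
                     n_noise=2, forced=()):
    labels = np.repeat(["H", "P", "C"], n)
    signal = np.concatenate(
        [rng.normal(m, 1.0, k) for m, k in zip(shift, n)]
    )
    cols = {"signal": signal}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(size=labels.size)
    return CandidateSet(
        X=pd.DataFrame(cols), y=labels, forced_in=list(forced)
    )


class TestBeggGray:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        cand = _make_candidates(rng, n=(50, 25, 75))
        fit = tr.begg_gray_fit(cand, [])
        assert fit.blocks["P"]["const"] == pytest.approx(
            np.log(25 / 50), abs=1e-6
        )
        assert fit.blocks["C"]["const"] == pytest.approx(
            np.log(75 / 50), abs=1e-6
        )

    def test_duplicated_feature_rejected(self):
        rng = np.random.default_rng(1)
        cand = _make_candidates(rng)
        cand.X["dup"] = cand.X["signal"]
        with pytest.raises(tr.ValidationError, match="rank-deficient"):
            tr.begg_gray_fit(cand, ["signal", "dup"])

    def test_agrees_with_full_multinomial_ml(self):
        """The binary decomposition tracks the full multinomial MLE on a
        single informative feature."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        cand = _make_candidates(rng, n=(350, 300, 350), n_noise=0)
        fit = tr.begg_gray_fit(cand, ["signal"])
        y_codes = pd.Categorical(
            cand.y, categories=["H", "P", "C"]
        ).codes
        X = sm.add_constant(cand.X[["signal"]].to_numpy())
        full = sm.MNLogit(y_codes, X).fit(disp=0)
        # statsmodels params is (k_exog, J-1); column j is class code
        # j+1 vs baseline code 0
        params = np.asarray(full.params)
        for j, cls in enumerate(["P", "C"]):
            ours = fit.blocks[cls]["signal"]
            theirs = params[1, j]
            assert abs(ours - theirs) / abs(theirs) < 0.10

    def test_separation_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        cand = _make_candidates(rng, n=(20, 15, 20), shift=(0, 40, 80),
                                n_noise=0)
        fit = tr.begg_gray_fit(cand, ["signal"])
        assert fit.separation
        assert np.isfinite(fit.bic)


class TestBMA:
    def test_single_candidate_weight_one(self):
        rng = np.random.default_rng(4)
        cand = _make_candidates(rng, n_noise=0, forced=["signal"])
        model = tr.bma_mlogit(cand, max_subset_size=1)
        assert len(model.subsets) == 1
        assert model.weights[0] == pytest.approx(1.0)
        assert model.inclusion_probs["signal"] == pytest.approx(1.0)

    def test_occam_ratio_one_keeps_best_only(self):
        rng = np.random.default_rng(5)
        cand = _make_candidates(rng, n_noise=3)
        model = tr.bma_mlogit(cand, max_subset_size=2, occam_ratio=1.0)
        assert len(model.subsets) == 1

    def test_weights_invariant_to_feature_rescaling(self):
        """BIC of a logistic fit is invariant to affine feature maps,
        hence so are the posterior weights."""
        rng = np.random.default_rng(6)
        cand = _make_candidates(rng, n_noise=2)
        before = tr.bma_mlogit(cand, max_subset_size=2)
        scaled = CandidateSet(
            X=cand.X * np.array([1000.0, 0.01, 5.0]) + 7.0,
            y=cand.y,
            forced_in=[],
        )
        after = tr.bma_mlogit(scaled, max_subset_size=2)
        np.testing.assert_allclose(
            before.weights, after.weights, atol=1e-5
        )

    def test_pure_noise_keeps_forced_in_only(self):
        rng = np.random.default_rng(7)
        labels = np.repeat(["H", "P", "C"], (50, 30, 50))
        ref = np.concatenate(
            [rng.lognormal(m, 0.7, k)
             for m, k in zip((2.0, 2.3, 3.5), (50, 30, 50))]
        )
        X = pd.DataFrame({"ref": ref})
        for j in range(4):
            X[f"noise{j}"] = rng.normal(size=labels.size)
        cand = CandidateSet(X=X, y=labels, forced_in=["ref"])
        model = tr.bma_mlogit(cand, max_subset_size=2)
        assert model.top_model().features == ["ref"]

    def test_signal_recovery_with_forced_reference(self):
        """A pancreatitis-specific metabolite joins the forced-in
        carcinoma-oriented reference in the top model."""
        cfg = tr.CohortConfig(
            n_metabolites=6,
            latent_correlation="identity",
            class_shifts=np.array(
                [[0.0] * 6, [2.0] + [0.0] * 5, [0.0] * 6]
            ),
            missing_rate=0.0,
            include_covariates=False,
            seed=31,
        )
        t = tr.generate_cohort(cfg)
        X = pd.concat(
            [
                t.data[[t.refmarker]].reset_index(drop=True),
                t.data[t.metabolites].reset_index(drop=True),
            ],
            axis=1,
        )
        cand = CandidateSet(
            X=X, y=t.classes.to_numpy(), forced_in=[t.refmarker]
        )
        model = tr.bma_mlogit(cand, max_subset_size=2)
        assert model.inclusion_probs[t.metabolites[0]] > 0.9
        assert set(model.top_model().features) == {
            t.refmarker, t.metabolites[0]
        }

    def test_weights_sum_to_one_and_window_invariant(self):
        rng = np.random.default_rng(8)
        cand = _make_candidates(rng, n_noise=3)
        model = tr.bma_mlogit(cand, max_subset_size=2, occam_ratio=20.0)
        assert model.weights.sum() == pytest.approx(1.0)
        bics = np.array([f.bic for f in model.subsets])
        assert np.all(bics <= bics.min() + 2 * np.log(20.0) + 1e-9)


class TestCAR:
    def test_identity_correlation_equals_marginal(self):
        """With exactly orthonormal features the decorrelation step is
        the identity, so CAR scores equal marginal correlations."""
        rng = np.random.default_rng(9)
        raw = rng.normal(size=(90, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(q, columns=list("abcd"))
        labels = np.array((["H"] * 30) + (["P"] * 30) + (["C"] * 30))
        cand = CandidateSet(X=X, y=labels)
        model = tr.car_fit(cand, k=2)
        y = np.array([DEFAULT_PSEUDO_RESPONSE[c] for c in labels])
        Xs = (X - X.mean()) / X.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        marginal = (Xs.T @ ys) / (len(y) - 1)
        np.testing.assert_allclose(
            model.car_scores.to_numpy(), marginal.to_numpy(), atol=1e-10
        )

    def test_matches_matrix_square_root_oracle(self):
        """Three correlated features against an independent
        scipy.linalg.sqrtm/solve computation."""
        rng = np.random.default_rng(10)
        L = np.array([[1.0, 0, 0], [0.6, 0.8, 0], [-0.4, 0.2, 0.89]])
        X = pd.DataFrame(
            rng.normal(size=(120, 3)) @ L.T, columns=list("abc")
        )
        labels = np.array((["H"] * 40) + (["P"] * 40) + (["C"] * 40))
        cand = CandidateSet(X=X, y=labels)
        model = tr.car_fit(cand, k=3, shrinkage=None)
        Xs = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        y = np.array([DEFAULT_PSEUDO_RESPONSE[c] for c in labels])
        ys = (y - y.mean()) / y.std(ddof=1)
        corr = (Xs.T @ Xs) / (len(y) - 1)
        oracle = sla.solve(
            np.real(sla.sqrtm(corr)), (Xs.T @ ys) / (len(y) - 1)
        )
        np.testing.assert_allclose(
            model.car_scores.to_numpy(), oracle, atol=1e-10
        )

    def test_defaults(self):
        import inspect

        sig = inspect.signature(tr.car_fit)
        assert sig.parameters["k"].default == 2
        assert DEFAULT_PSEUDO_RESPONSE == {"C": 1.0, "H": 0.3, "P": 0.1}

    def test_singular_without_shrinkage_errors(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=90)
        X = pd.DataFrame(
            {
                "a": base,
                "b": base + 1e-10 * rng.normal(size=90),
                "c": rng.normal(size=90),
            }
        )
        labels = np.array((["H"] * 30) + (["P"] * 30) + (["C"] * 30))
        cand = CandidateSet(X=X, y=labels)
        with pytest.raises(tr.ComputationError, match="shrinkage"):
            tr.car_fit(cand, k=2, shrinkage=None)
        model = tr.car_fit(cand, k=2, shrinkage="auto")
        assert model.shrinkage > 0
        assert np.all(np.isfinite(model.car_scores))

    def test_selection_size(self):
        rng = np.random.default_rng(12)
        cand = _make_candidates(rng, n_noise=4)
        model = tr.car_fit(cand, k=3)
        assert len(model.selected) == 3


class TestScoring:
    def test_zero_coefficients_give_constant_scores(self):
        rng = np.random.default_rng(13)
        cand = _make_candidates(rng, n_noise=1)
        model = tr.bma_mlogit(cand, max_subset_size=1)
        model.averaged_coef.loc[:, :] = 0.0
        scores = tr.score_samples(model, cand.X).scores
        assert np.allclose(scores, scores[0])

    def test_monotone_single_feature_model_preserves_vus(self):
        """A single-feature monotone panel scores to the same VUS as
        the raw feature (rank invariance)."""
        rng = np.random.default_rng(14)
        cand = _make_candidates(rng, n_noise=0, forced=["signal"])
        model = tr.bma_mlogit(cand, max_subset_size=1)
        pred = tr.score_samples(model, cand.X)
        raw = tr.OrderedMarkerTriple.from_labels(
            cand.X["signal"].to_numpy(), cand.y
        )
        panel = tr.OrderedMarkerTriple.from_labels(pred.scores, cand.y)
        coef = model.averaged_coef["signal"]
        if (coef >= 0).all() or (coef <= 0).all():
            assert tr.vus_estimate(panel) == pytest.approx(
                tr.vus_estimate(raw) if (coef >= 0).all()
                else 1 - tr.vus_estimate(raw),
                abs=1e-12,
            )

    def test_panel_beats_best_single_feature(self):
        """On a well-separated cohort with complementary signals the
        averaged panel VUS exceeds each single feature's VUS."""
        rng = np.random.default_rng(15)
        n = (60, 40, 60)
        labels = np.repeat(["H", "P", "C"], n)
        # feature A separates C from the rest, feature B separates P
        fa = np.concatenate(
            [rng.normal(m, 1, k) for m, k in zip((0, 0, 2.5), n)]
        )
        fb = np.concatenate(
            [rng.normal(m, 1, k) for m, k in zip((0, 2.5, 0), n)]
        )
        X = pd.DataFrame({"fa": fa, "fb": fb})
        cand = CandidateSet(X=X, y=labels)
        model = tr.bma_mlogit(cand, max_subset_size=2)
        panel_vus = tr.vus_estimate(
            tr.OrderedMarkerTriple.from_labels(
                tr.score_samples(model, X).scores, labels
            )
        )
        single = max(
            tr.vus_estimate(tr.OrderedMarkerTriple.from_labels(f, labels))
            for f in (fa, fb)
        )
        assert panel_vus > single

    def test_unknown_feature_errors(self):
        rng = np.random.default_rng(16)
        cand = _make_candidates(rng, n_noise=0)
        model = tr.bma_mlogit(cand, max_subset_size=1)
        with pytest.raises(tr.ValidationError):
            model.predict_proba(pd.DataFrame({"other": [1.0]}))

    def test_predict_proba_rows_sum_to_one(self):
        rng = np.random.default_rng(17)
        cand = _make_candidates(rng)
        model = tr.bma_mlogit(cand, max_subset_size=2)
        proba = model.predict_proba(cand.X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


class TestSklearnEstimators:
    def test_begg_gray_bma_estimator(self):
        from sklearn.base import clone

        rng = np.random.default_rng(18)
        cand = _make_candidates(rng, n_noise=1)
        est = BeggGrayBMA(max_subset_size=2)
        est_clone = clone(est)
        est_clone.fit(cand.X, cand.y)
        assert hasattr(est_clone, "model_")
        proba = est_clone.predict_proba(cand.X)
        assert proba.shape == (len(cand.X), 3)
        preds = est_clone.predict(cand.X)
        assert set(preds) <= {"H", "P", "C"}
        scores = est_clone.score_samples(cand.X)
        assert scores.shape == (len(cand.X),)
        assert est.get_params()["max_subset_size"] == 2

    def test_car_estimator_in_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(19)
        cand = _make_candidates(rng, n_noise=2)
        pipe = Pipeline(
            [("scale", StandardScaler()), ("car", CARScorePanel(k=2))]
        )
        pipe.fit(cand.X.to_numpy(), cand.y)
        out = pipe.predict(cand.X.to_numpy())
        assert out.shape == (len(cand.X),)
        assert np.all(np.isfinite(out))
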