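"""Multi-marker "meta-marker" panel construction.

Two complementary routes from a candidate feature set (a conventional
reference marker plus metabolite concentrations or their principal
components) to a single scalar panel score per sample:

* **Begg-Gray Bayesian model averaging** — the three-class multinomial
  logit is approximated by two binary logistic regressions of each
  non-baseline class against the baseline class (the Begg-Gray
  decomposition), giving a cheap BIC per candidate feature subset.
  Subsets inside an Occam window are weighted by exp(-BIC/2) and their
  coefficients averaged; posterior inclusion probabilities fall out of
  the same weights.

* **CAR scores** — correlation-adjusted marginal correlations
  ``R_XX^{-1/2} r_Xy`` of the features with a pseudo-metric response
  encoding of the three classes; features are ranked by squared CAR
  score, the top k kept, and an OLS fit on them provides the panel
  score.  Under an identity feature correlation matrix CAR scores equal
  the marginal correlations exactly.

Both are wrapped as scikit-learn estimators (:class:`BeggGrayBMA`,
:class:`CARScorePanel`) so they compose with pipelines and model
selection; the module-level functions are thin over the same code.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CLASS_ORDER = ("H", "P", "C")

#: Pseudo-metric responses of the three clinical groups for the CAR
#: route: carcinoma 1.0, healthy control 0.3, pancreatitis 0.1.
DEFAULT_PSEUDO_RESPONSE = {"C": 1.0, "H": 0.3, "P": 0.1}


# ---------------------------------------------------------------------------
# candidate sets


@dataclass
class CandidateSet:
    """Named feature matrix, three-level labels and forced-in features."""

    X: pd.DataFrame
    y: np.ndarray
    class_order: tuple[str, str, str] = DEFAULT_CLASS_ORDER
    baseline: str | None = None
    forced_in: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValidationError("X and y lengths differ")
        if self.X.isna().any().any():
            raise ValidationError("candidate features contain missing values")
        variances = self.X.var(axis=0)
        dead = list(variances.index[variances == 0])
        if dead:
            raise ValidationError(f"zero-variance features: {dead}")
        observed = set(np.unique(self.y))
        if observed != set(self.class_order):
            raise ValidationError(
                f"labels {sorted(observed)} do not match declared classes "
                f"{self.class_order}"
            )
        if self.baseline is None:
            self.baseline = self.class_order[0]
        if self.baseline not in self.class_order:
            raise ValidationError(f"unknown baseline {self.baseline!r}")
        missing = [f for f in self.forced_in if f not in self.X.columns]
        if missing:
            raise ValidationError(f"forced-in features not in X: {missing}")

    @property
    def nonbaseline(self) -> list[str]:
        return [c for c in self.class_order if c != self.baseline]


# ---------------------------------------------------------------------------
# Begg-Gray binary decomposition


def _fit_binary_logit(
    X: np.ndarray, y01: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """ML binary logistic fit; (coef, deviance, separation_flag).

    Falls back to a lightly ridge-penalised fit when the ML fit fails
    to converge or separates perfectly.
    """
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y01, X).fit(disp=0, maxiter=100, warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", True))
        if converged and np.all(np.abs(res.params) < 50):
            return np.asarray(res.params), float(-2.0 * res.llf), False
    except Exception:  # PerfectSeparationError, LinAlgError, ...
        pass
    clf = LogisticRegression(
        C=10.0, solver="lbfgs", max_iter=1000, fit_intercept=False,
    ).fit(X, y01)
    coef = clf.coef_.ravel()
    eta = X @ coef
    ll = np.sum(y01 * eta - np.log1p(np.exp(np.clip(eta, -500, 500))))
    return coef, float(-2.0 * ll), True


@dataclass
class BeggGrayFit:
    """Two binary-logit coefficient blocks and their summed BIC."""

    features: list[str]
    blocks: dict[str, pd.Series]   # non-baseline class -> coefficients
    deviance: float
    bic: float
    n_used: int
    separation: bool = False


def begg_gray_fit(
    candidates: CandidateSet, subset: list[str]
) -> BeggGrayFit:
    """Fit the Begg-Gray binary decomposition on one feature subset.

    For each non-baseline class the binary logit of that class versus
    the baseline is fitted on the samples of the two classes only; the
    total deviance is the sum of the two binary deviances and
    ``BIC = deviance + n_params * log(n)`` with ``n`` the full sample
    count.  Rank-deficient subsets (e.g. duplicated columns) are
    rejected.
    """
    subset = list(subset)
    unknown = [f for f in subset if f not in candidates.X.columns]
    if unknown:
        raise ValidationError(f"unknown features: {unknown}")
    Xs = candidates.X[subset].to_numpy(float) if subset else np.empty(
        (len(candidates.X), 0)
    )
    design = np.column_stack([np.ones(len(Xs)), Xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(
            f"rank-deficient design for subset {subset}"
        )
    n_total = len(candidates.X)
    blocks: dict[str, pd.Series] = {}
    deviance = 0.0
    separated = False
    names = ["const"] + subset
    for cls in candidates.nonbaseline:
        mask = np.isin(candidates.y, [candidates.baseline, cls])
        y01 = (candidates.y[mask] == cls).astype(float)
        coef, dev, sep = _fit_binary_logit(design[mask], y01)
        if sep:
            separated = True
            logger.warning(
                "begg_gray_fit: separation in %s-vs-%s for subset %s; "
                "ridge fallback used", cls, candidates.baseline, subset,
            )
        blocks[cls] = pd.Series(coef, index=names)
        deviance += dev
    n_params = 2 * (len(subset) + 1)
    bic = deviance + n_params * np.log(n_total)
    return BeggGrayFit(
        features=subset,
        blocks=blocks,
        deviance=deviance,
        bic=float(bic),
        n_used=n_total,
        separation=separated,
    )


# ---------------------------------------------------------------------------
# BIC-weighted model averaging


@dataclass
class AveragedModel:
    """Occam-window subset fits with posterior weights and averages."""

    subsets: list[BeggGrayFit]
    weights: np.ndarray
    averaged_coef: pd.DataFrame      # non-baseline classes x (const+features)
    inclusion_probs: pd.Series
    baseline: str
    class_order: tuple[str, str, str]
    feature_names: list[str]
    occam_ratio: float

    def top_model(self) -> BeggGrayFit:
        return self.subsets[int(np.argmax(self.weights))]

    def _eta(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names
                   if f not in features.columns]
        if missing:
            raise ValidationError(f"features missing columns: {missing}")
        design = np.column_stack(
            [np.ones(len(features)),
             features[self.feature_names].to_numpy(float)]
        )
        return design @ self.averaged_coef.to_numpy(float).T

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Class probabilities (columns in declared class order) from
        the weight-averaged coefficients via the multinomial inverse
        link with the baseline class as reference."""
        eta = self._eta(features)
        nonbase = [c for c in self.class_order if c != self.baseline]
        full = np.zeros((len(features), 3))
        for j, cls in enumerate(nonbase):
            full[:, self.class_order.index(cls)] = eta[:, j]
        full -= full.max(axis=1, keepdims=True)
        expd = np.exp(full)
        return expd / expd.sum(axis=1, keepdims=True)

    def expected_rank(self, features: pd.DataFrame) -> np.ndarray:
        """Scalar panel score: expected ordinal class, ranks (0, 1, 2)
        along the declared class order."""
        proba = self.predict_proba(features)
        return proba @ np.arange(3, dtype=float)


def bma_mlogit(
    candidates: CandidateSet,
    max_subset_size: int = 2,
    occam_ratio: float = 20.0,
) -> AveragedModel:
    """BIC-based Bayesian model averaging over candidate subsets.

    Enumerates every subset that contains the forced-in features, up to
    ``max_subset_size`` features in total; keeps subsets with
    ``BIC <= BIC_min + 2 log(occam_ratio)`` (the Occam window); weights
    them by ``exp(-(BIC - BIC_min)/2)`` renormalised.  Averaged
    coefficients treat a feature absent from a subset as zero.
    """
    if occam_ratio < 1.0:
        raise ValidationError("occam_ratio must be >= 1")
    forced = list(candidates.forced_in)
    free = [c for c in candidates.X.columns if c not in forced]
    max_free = max(0, max_subset_size - len(forced))
    fits: list[BeggGrayFit] = []
    for size in range(0, max_free + 1):
        for combo in itertools.combinations(free, size):
            subset = forced + list(combo)
            try:
                fits.append(begg_gray_fit(candidates, subset))
            except ValidationError as exc:
                logger.info("bma_mlogit: skipping subset %s (%s)",
                            subset, exc)
    if not fits:
        raise ComputationError("no candidate subset could be fitted")
    bics = np.array([f.bic for f in fits])
    best = bics.min()
    window = bics <= best + 2.0 * np.log(occam_ratio)
    kept = [f for f, w in zip(fits, window) if w]
    kept_bics = bics[window]
    logw = -(kept_bics - best) / 2.0
    weights = np.exp(logw)
    weights /= weights.sum()

    names = list(candidates.X.columns)
    cols = ["const"] + names
    nonbase = candidates.nonbaseline
    avg = pd.DataFrame(0.0, index=nonbase, columns=cols)
    incl = pd.Series(0.0, index=names)
    for fit, w in zip(kept, weights):
        for cls in nonbase:
            avg.loc[cls, fit.blocks[cls].index] += w * fit.blocks[cls]
        for f in fit.features:
            incl[f] += w
    return AveragedModel(
        subsets=kept,
        weights=weights,
        averaged_coef=avg,
        inclusion_probs=incl,
        baseline=candidates.baseline,
        class_order=candidates.class_order,
        feature_names=names,
        occam_ratio=occam_ratio,
    )


# ---------------------------------------------------------------------------
# CAR scores


@dataclass
class CARModel:
    """CAR-score ranking and the OLS panel fit on the top-k features."""

    car_scores: pd.Series
    selected: list[str]
    intercept: float
    coef: pd.Series
    pseudo_response: dict[str, float]
    shrinkage: float
    k: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected if f not in features.columns]
        if missing:
            raise ValidationError(f"features missing columns: {missing}")
        return (
            self.intercept
            + features[self.selected].to_numpy(float) @ self.coef.to_numpy()
        )


def _inverse_sqrt_corr(
    corr: np.ndarray, shrinkage: str | float | None
) -> tuple[np.ndarray, float]:
    evals = np.linalg.eigvalsh(corr)
    lmin, lmax = float(evals[0]), float(evals[-1])
    cond_limit = 1e6
    s = 0.0
    if shrinkage is None:
        if lmin <= lmax / cond_limit:
            raise ComputationError(
                "feature correlation matrix is ill-conditioned; rerun "
                "with shrinkage='auto' (shrinks toward the identity)"
            )
    elif shrinkage == "auto":
        if lmin <= lmax / cond_limit:
            # smallest s with cond((1-s) R + s I) <= cond_limit
            t = (cond_limit - 1.0) / (lmax - 1.0 - cond_limit * lmin
                                      + cond_limit)
            t = float(np.clip(t, 0.0, 1.0))
            s = 1.0 - t
    else:
        s = float(shrinkage)
        if not 0.0 <= s < 1.0:
            raise ValidationError("shrinkage must lie in [0, 1)")
    if s > 0:
        corr = (1.0 - s) * corr + s * np.eye(corr.shape[0])
    evals, evecs = np.linalg.eigh(corr)
    evals = np.clip(evals, 1e-12, None)
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return inv_sqrt, s


def car_fit(
    candidates: CandidateSet,
    pseudo_response: dict[str, float] | None = None,
    k: int = 2,
    shrinkage: str | float | None = "auto",
) -> CARModel:
    """CAR-score feature ranking with an OLS panel fit on the top k.

    The class labels are encoded by ``pseudo_response`` (default
    carcinoma 1.0, control 0.3, pancreatitis 0.1 on the declared
    order), CAR scores computed as ``R_XX^{-1/2} r_Xy``, features
    ranked by squared score, and an OLS of the encoded response on the
    selected features fitted for scoring.
    """
    if pseudo_response is None:
        order = candidates.class_order
        pseudo_response = {order[0]: 0.3, order[1]: 0.1, order[2]: 1.0}
    missing = set(np.unique(candidates.y)) - set(pseudo_response)
    if missing:
        raise ValidationError(
            f"pseudo_response lacks classes: {sorted(missing)}"
        )
    if not 1 <= k <= candidates.X.shape[1]:
        raise ValidationError("k must lie in [1, n_features]")
    y = np.array([pseudo_response[c] for c in candidates.y], dtype=float)
    X = candidates.X.to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    n = len(y)
    r_xy = (Xs.T @ ys) / (n - 1)
    corr = (Xs.T @ Xs) / (n - 1)
    inv_sqrt, s = _inverse_sqrt_corr(corr, shrinkage)
    car = pd.Series(inv_sqrt @ r_xy, index=candidates.X.columns)
    selected = list(car.pow(2).sort_values(ascending=False).index[:k])
    design = np.column_stack(
        [np.ones(n), candidates.X[selected].to_numpy(float)]
    )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return CARModel(
        car_scores=car,
        selected=selected,
        intercept=float(beta[0]),
        coef=pd.Series(beta[1:], index=selected),
        pseudo_response=dict(pseudo_response),
        shrinkage=s,
        k=k,
    )


# ---------------------------------------------------------------------------
# scalar panel scores


@dataclass
class PanelPredictor:
    """Per-sample scalar panel scores with their scoring rule."""

    scores: np.ndarray
    scoring_rule: str
    model: object


def score_samples(
    model: AveragedModel | CARModel, features: pd.DataFrame
) -> PanelPredictor:
    """Scalarise a fitted panel model into one marker value per sample.

    Averaged multinomial models score by the expected ordinal class
    (ranks 0, 1, 2 along the declared order) — a monotone summary that
    respects the three-class ordering the VUS needs; CAR models score
    by their fitted linear predictor.
    """
    if isinstance(model, AveragedModel):
        return PanelPredictor(
            scores=model.expected_rank(features),
            scoring_rule="expected_ordinal_class",
            model=model,
        )
    if isinstance(model, CARModel):
        return PanelPredictor(
            scores=model.predict(features),
            scoring_rule="linear_predictor",
            model=model,
        )
    raise ValidationError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# scikit-learn estimator wrappers


class BeggGrayBMA(BaseEstimator, ClassifierMixin):
    """BIC-averaged Begg-Gray multinomial logit panel classifier.

    Parameters
    ----------
    forced_in : list of str, optional
        Features present in every candidate subset (typically the
        conventional reference marker).
    max_subset_size : int, default 2
        Largest subset enumerated, forced-in features included; the
        default matches strongly penalised two-marker panels.
    occam_ratio : float, default 20
        Occam-window ratio; subsets with BIC within ``2 log(ratio)`` of
        the best are averaged.  A ratio of 1 keeps only the best model.
    baseline : str, optional
        Reference class of the binary decompositions (default: the
        lowest-ordered class, i.e. healthy controls).
    class_order : tuple of 3 str
        Declared clinical ordering of the labels.

    Attributes
    ----------
    model_ : AveragedModel
    classes_ : ndarray of the three labels in declared order
    """

    def __init__(
        self,
        forced_in: list[str] | None = None,
        max_subset_size: int = 2,
        occam_ratio: float = 20.0,
        baseline: str | None = None,
        class_order: tuple[str, str, str] = DEFAULT_CLASS_ORDER,
    ):
        self.forced_in = forced_in
        self.max_subset_size = max_subset_size
        self.occam_ratio = occam_ratio
        self.baseline = baseline
        self.class_order = class_order

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        names = getattr(
            self, "feature_names_in_",
            [f"x{j}" for j in range(X.shape[1])],
        )
        return pd.DataFrame(X, columns=list(names))

    def fit(self, X, y):
        frame = self._as_frame(X)
        candidates = CandidateSet(
            X=frame,
            y=np.asarray(y),
            class_order=tuple(self.class_order),
            baseline=self.baseline,
            forced_in=list(self.forced_in or []),
        )
        self.model_ = bma_mlogit(
            candidates,
            max_subset_size=self.max_subset_size,
            occam_ratio=self.occam_ratio,
        )
        self.feature_names_in_ = list(frame.columns)
        self.n_features_in_ = frame.shape[1]
        self.classes_ = np.asarray(self.class_order)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._as_frame(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def score_samples(self, X):
        """Expected-ordinal-class panel score per sample."""
        check_is_fitted(self, "model_")
        return self.model_.expected_rank(self._as_frame(X))


class CARScorePanel(BaseEstimator, RegressorMixin):
    """CAR-score-selected linear panel scorer.

    Encodes the three classes by pseudo-metric responses, ranks
    features by squared CAR score, keeps the top ``k`` and scores
    samples by the OLS linear predictor on those features.

    Attributes
    ----------
    model_ : CARModel
    """

    def __init__(
        self,
        pseudo_response: dict[str, float] | None = None,
        k: int = 2,
        shrinkage: str | float | None = "auto",
        class_order: tuple[str, str, str] = DEFAULT_CLASS_ORDER,
    ):
        self.pseudo_response = pseudo_response
        self.k = k
        self.shrinkage = shrinkage
        self.class_order = class_order

    def fit(self, X, y):
        frame = (
            X if isinstance(X, pd.DataFrame)
            else pd.DataFrame(
                np.asarray(X, float),
                columns=[f"x{j}" for j in range(np.asarray(X).shape[1])],
            )
        )
        candidates = CandidateSet(
            X=frame, y=np.asarray(y), class_order=tuple(self.class_order)
        )
        self.model_ = car_fit(
            candidates,
            pseudo_response=self.pseudo_response,
            k=self.k,
            shrinkage=self.shrinkage,
        )
        self.feature_names_in_ = list(frame.columns)
        self.n_features_in_ = frame.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        frame = (
            X if isinstance(X, pd.DataFrame)
            else pd.DataFrame(
                np.asarray(X, float), columns=self.feature_names_in_
            )
        )
        return self.model_.predict(frame)

    score_samples = predict
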