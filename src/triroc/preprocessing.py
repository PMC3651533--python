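"""Preprocessing: sample exclusion, reference-marker multiple
imputation, Yeo-Johnson normalisation and correlation PCA.

The imputation follows a bootstrap multiple-imputation scheme: several
chains each repeatedly (i) bootstrap-resample the complete cases,
(ii) refit a linear predictive model of the log reference marker on
class membership and metabolite profile, and (iii) draw imputed values
as prediction plus a resampled residual.  Chains run until the
Gelman-Rubin R-hat of every imputed cell drops to the target (default
1.1 across 3 chains) and the final imputation is the across-chain
average, mirroring standard MI practice for a handful of missing
tumour-marker values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import CohortTable
from .errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exclusion


def exclude_nonrandom_missing(
    table: CohortTable, max_missing_features: int = 0
) -> CohortTable:
    """Drop samples whose metabolite missingness exceeds a threshold.

    Samples missing more than ``max_missing_features`` metabolite values
    are treated as non-randomly incomplete (e.g. insufficient sample
    volume) and excluded outright rather than imputed.  Raises if an
    exclusion would leave any class with fewer than 2 samples.
    """
    counts = table.data[table.metabolites].isna().sum(axis=1)
    drop = counts > max_missing_features
    if not drop.any():
        return table.copy()
    kept = table.data.loc[~drop]
    sizes = kept[table.class_column].value_counts()
    for c in table.class_order:
        if int(sizes.get(c, 0)) < 2:
            raise ValidationError(
                f"excluding {int(drop.sum())} samples would leave class "
                f"{c!r} with fewer than 2 samples"
            )
    for sid, cnt in zip(table.data.loc[drop, "sample_id"], counts[drop]):
        logger.info(
            "exclude_nonrandom_missing: dropping %s "
            "(%d missing metabolite values > threshold %d)",
            sid, int(cnt), max_missing_features,
        )
    out = table.copy()
    out.data = kept.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# multiple imputation


@dataclass
class ImputationResult:
    """Completed table plus per-cell convergence diagnostics."""

    table: CohortTable
    n_chains: int
    chain_values: pd.DataFrame   # imputed cells x chains (chain means)
    rhat: pd.Series              # per imputed cell
    iterations_used: int
    converged: bool
    imputed_index: list = field(default_factory=list)


def _gelman_rubin(draws: np.ndarray) -> float:
    """R-hat over ``draws`` of shape (chains, iterations)."""
    m, n = draws.shape
    if n < 2:
        return np.inf
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    b_over_n = chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def impute_reference_marker(
    table: CohortTable,
    n_chains: int = 3,
    rhat_target: float = 1.1,
    max_iterations: int = 2000,
    min_iterations: int = 20,
    seed: int = 0,
) -> ImputationResult:
    """Multiply impute missing reference-marker values.

    Each chain iterates bootstrap refits of an OLS model of
    ``log1p(refmarker)`` on class indicators and standardised
    log-metabolite profiles, drawing imputations as prediction plus a
    resampled residual.  Convergence is declared when the across-chain
    R-hat of every imputed cell (computed from the second half of each
    chain) is at or below ``rhat_target``; the final value is the
    across-chain mean of those draws.  Observed cells are never altered.
    """
    if n_chains < 2:
        raise ValidationError("n_chains must be at least 2")
    ref = table.data[table.refmarker]
    missing = ref.isna()
    if missing.all():
        raise ValidationError("reference marker is entirely missing")
    for c in table.class_order:
        cls_mask = table.classes == c
        if ref[cls_mask].notna().sum() < 1:
            raise ValidationError(
                f"class {c!r} has no observed reference-marker value"
            )
    if not missing.any():
        return ImputationResult(
            table=table.copy(),
            n_chains=n_chains,
            chain_values=pd.DataFrame(
                np.empty((0, n_chains)),
                columns=[f"chain{i}" for i in range(n_chains)],
            ),
            rhat=pd.Series(dtype=float),
            iterations_used=0,
            converged=True,
            imputed_index=[],
        )

    # design: intercept + class dummies + standardised log metabolites
    met = np.log1p(table.data[table.metabolites].to_numpy(float))
    if np.isnan(met).any():
        raise ValidationError(
            "metabolites contain missing values; run exclusion first"
        )
    met = (met - met.mean(axis=0)) / np.where(
        met.std(axis=0) > 0, met.std(axis=0), 1.0
    )
    dummies = pd.get_dummies(table.classes).reindex(
        columns=list(table.class_order)
    ).to_numpy(float)[:, 1:]
    design = np.column_stack([np.ones(len(table)), dummies, met])
    n_obs = int((~missing).sum())
    if design.shape[1] >= n_obs:
        # keep the model identifiable on small complete-case sets:
        # restrict to the metabolites most correlated with the marker
        keep = max(1, n_obs // 3)
        yl_obs = np.log1p(ref[~missing].to_numpy(float))
        cors = np.abs(
            [np.corrcoef(met[~missing.values, j], yl_obs)[0, 1]
             for j in range(met.shape[1])]
        )
        top = np.argsort(-np.nan_to_num(cors))[:keep]
        design = np.column_stack(
            [np.ones(len(table)), dummies, met[:, top]]
        )

    obs_idx = np.where(~missing.to_numpy())[0]
    mis_idx = np.where(missing.to_numpy())[0]
    y_log = np.log1p(np.nan_to_num(ref.to_numpy(float)))
    y_obs = np.log1p(ref.to_numpy(float)[obs_idx])

    rng = np.random.default_rng(seed)
    chain_rngs = [np.random.default_rng(s) for s in rng.integers(
        0, 2**31 - 1, size=n_chains
    )]
    draws: list[list[np.ndarray]] = [[] for _ in range(n_chains)]

    iterations = 0
    converged = False
    rhats = np.full(mis_idx.size, np.inf)
    while iterations < max_iterations:
        iterations += 1
        for c, crng in enumerate(chain_rngs):
            boot = crng.integers(0, obs_idx.size, obs_idx.size)
            Xb = design[obs_idx[boot]]
            yb = y_obs[boot]
            beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
            resid = yb - Xb @ beta
            pred = design[mis_idx] @ beta
            noise = resid[crng.integers(0, resid.size, mis_idx.size)]
            draws[c].append(pred + noise)
        if iterations >= min_iterations and iterations % 10 == 0:
            arr = np.array(
                [np.array(d)[iterations // 2:] for d in draws]
            )  # chains x kept-iters x cells
            rhats = np.array(
                [_gelman_rubin(arr[:, :, k]) for k in range(mis_idx.size)]
            )
            if np.all(rhats <= rhat_target):
                converged = True
                break

    arr = np.array([np.array(d)[iterations // 2:] for d in draws])
    chain_means = arr.mean(axis=1)  # chains x cells
    final_log = chain_means.mean(axis=0)
    if not converged:
        rhats = np.array(
            [_gelman_rubin(arr[:, :, k]) for k in range(mis_idx.size)]
        )
        logger.warning(
            "impute_reference_marker: R-hat target %.3f not reached after "
            "%d iterations (max R-hat %.3f)",
            rhat_target, iterations, float(np.max(rhats)),
        )

    out = table.copy()
    values = out.data[out.refmarker].to_numpy(float)
    values[mis_idx] = np.expm1(final_log)
    out.data[out.refmarker] = values
    cells = [str(out.data["sample_id"].iloc[i]) for i in mis_idx]
    return ImputationResult(
        table=out,
        n_chains=n_chains,
        chain_values=pd.DataFrame(
            chain_means.T,
            index=cells,
            columns=[f"chain{i}" for i in range(n_chains)],
        ),
        rhat=pd.Series(rhats, index=cells),
        iterations_used=iterations,
        converged=converged,
        imputed_index=list(mis_idx),
    )


# ---------------------------------------------------------------------------
# Yeo-Johnson


@dataclass
class TransformSpec:
    """A fitted per-variable Yeo-Johnson transform."""

    lmbda: float
    variable: str | None = None
    loglik: float = np.nan

    def transform(self, values: np.ndarray) -> np.ndarray:
        return stats.yeojohnson(np.asarray(values, dtype=float), self.lmbda)


def yeo_johnson_fit(values: np.ndarray, variable: str | None = None) -> TransformSpec:
    """Maximum-likelihood Yeo-Johnson parameter, bracketed on [-5, 5].

    The transform is strictly increasing for every lambda and reduces to
    the identity at lambda = 1 on non-negative data.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValidationError("need at least 3 finite values")
    if np.ptp(x) == 0:
        raise ValidationError("constant input has no normalising transform")
    res = optimize.minimize_scalar(
        lambda lm: -stats.yeojohnson_llf(lm, x),
        bounds=(-5.0, 5.0),
        method="bounded",
    )
    if not res.success:
        raise ComputationError("Yeo-Johnson likelihood optimisation failed")
    return TransformSpec(
        lmbda=float(res.x), variable=variable, loglik=float(-res.fun)
    )


class YeoJohnsonTransformer(BaseEstimator, TransformerMixin):
    """Column-wise maximum-likelihood Yeo-Johnson normalisation.

    Like :class:`sklearn.preprocessing.PowerTransformer` with
    ``method='yeo-johnson'`` but with the likelihood optimisation
    bracketed on lambda in [-5, 5] and no implicit standardisation.

    Attributes
    ----------
    lambdas_ : ndarray of shape (n_features,)
    specs_ : list of TransformSpec
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.specs_ = [
            yeo_johnson_fit(X[:, j], variable=str(j))
            for j in range(X.shape[1])
        ]
        self.lambdas_ = np.array([s.lmbda for s in self.specs_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "specs_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.column_stack(
            [s.transform(X[:, j]) for j, s in enumerate(self.specs_)]
        )


# ---------------------------------------------------------------------------
# correlation PCA


@dataclass
class PCAResult:
    """Correlation-matrix PCA with eigenvalue-based retention."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame       # variables x all components
    scores: pd.DataFrame         # samples x retained components
    retained_k: int
    cumulative_variance: float
    transform_specs: list[TransformSpec] | None = None


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA of the correlation matrix (variables standardised first).

    Components are retained by the Kaiser rule (eigenvalue > 1) unless
    ``n_components`` overrides it; loading signs are fixed so each
    component's largest-magnitude loading is positive.  Standardisation
    is what makes the eigenvalue > 1 criterion meaningful for variables
    measured on very different concentration scales.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValidationError("need a 2-D array with at least 3 samples")
        if np.isnan(X).any():
            raise ValidationError("PCA input must be complete")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("constant column in PCA input")
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_
        corr = (Z.T @ Z) / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic orientation: largest |loading| entry positive
        flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                             np.arange(evecs.shape[1])])
        flip[flip == 0] = 1.0
        evecs = evecs * flip
        self.eigenvalues_ = evals
        self.loadings_ = evecs
        if self.n_components is not None:
            k = int(self.n_components)
            if not 1 <= k <= evals.size:
                raise ValidationError("n_components out of range")
        else:
            k = max(1, int(np.sum(evals > 1.0)))
        self.retained_k_ = k
        self.cumulative_variance_ = float(evals[:k].sum() / evals.sum())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.loadings_[:, : self.retained_k_]

    def transform_full(self, X):
        """Scores on all components (for reconstruction checks)."""
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.loadings_


def pca_transform(
    table: CohortTable,
    specs: list[TransformSpec] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Yeo-Johnson-transform the metabolites, then correlation PCA.

    ``specs`` may carry pre-fitted per-metabolite transforms; otherwise
    each metabolite's lambda is fitted here.  Retention follows the
    Kaiser eigenvalue > 1 rule unless ``n_components`` is given.
    """
    X = table.data[table.metabolites].to_numpy(float)
    if np.isnan(X).any():
        raise ValidationError(
            "metabolites contain missing values; run exclusion/imputation "
            "first"
        )
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples for PCA")
    if specs is None:
        specs = [
            yeo_johnson_fit(X[:, j], variable=name)
            for j, name in enumerate(table.metabolites)
        ]
    if len(specs) != len(table.metabolites):
        raise ValidationError("one TransformSpec per metabolite required")
    T = np.column_stack(
        [spec.transform(X[:, j]) for j, spec in enumerate(specs)]
    )
    pca = CorrelationPCA(n_components=n_components).fit(T)
    comp_names = [f"PC{i + 1}" for i in range(len(table.metabolites))]
    return PCAResult(
        eigenvalues=pca.eigenvalues_,
        loadings=pd.DataFrame(
            pca.loadings_, index=table.metabolites, columns=comp_names
        ),
        scores=pd.DataFrame(
            pca.transform(T),
            index=table.data["sample_id"],
            columns=comp_names[: pca.retained_k_],
        ),
        retained_k=pca.retained_k_,
        cumulative_variance=pca.cumulative_variance_,
        transform_specs=specs,
    )
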