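"""Nonparametric three-class ROC analysis.

The volume under the ROC surface (VUS) generalises the AUROC to three
ordered classes: it is the probability that a randomly drawn triple of
subjects, one per class, is correctly ordered by the marker,

    VUS = P(X < Y < Z)

for marker values X, Y, Z from the lowest-, middle- and highest-ordered
class.  A perfect marker scores 1; an uninformative one scores 1/6 (the
chance that three exchangeable values land in one particular order).

The empirical estimator is the exact U-statistic over all n1*n2*n3
triples.  Under the default partial tie rule a triple with exactly one
ordering-consistent tie (x = y < z or x < y = z) contributes 1/2 and a
triple tie contributes 1/6, so a constant marker scores exactly the
random-classifier value; under ``strict`` ties contribute nothing.
Confidence intervals come from a class-stratified percentile bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OrderedMarkerTriple:
    """Marker values split by the three ordered classes.

    ``x`` holds the lowest-ordered class (default healthy), ``y`` the
    middle (pancreatitis), ``z`` the highest (carcinoma).  The order is
    a declared clinical input; no automatic re-orientation is done.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    class_order: tuple[str, str, str] = ("H", "P", "C")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if arr.size == 0:
                raise ValidationError(f"class vector {name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"class vector {name!r} contains non-finite values"
                )

    @classmethod
    def from_labels(
        cls,
        values: Sequence[float],
        labels: Sequence[str],
        class_order: Sequence[str] = ("H", "P", "C"),
    ) -> "OrderedMarkerTriple":
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        order = tuple(class_order)
        if len(order) != 3:
            raise ValidationError("class_order must name exactly 3 classes")
        parts = [values[labels == c] for c in order]
        return cls(*parts, class_order=order)

    def sizes(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)


@dataclass
class VUSResult:
    """Point estimate and bootstrap CI of one marker's VUS."""

    vus: float
    ci_low: float
    ci_high: float
    B: int
    ci_level: float
    seed: int
    grid_subdivisions: int = 50_000
    tie_rule: str = "partial"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vus <= 1.0:
            raise ValidationError(f"VUS {self.vus} outside [0, 1]")
        if not self.ci_low <= self.vus <= self.ci_high:
            raise ValidationError("CI must bracket the point estimate")


@dataclass
class ROCSurfaceGrid:
    """Empirical ROC surface over the lattice of threshold pairs.

    Each row is one (c1, c2) pair with c1 <= c2 drawn from the pooled
    unique marker values; ``tcr1``/``tcr2``/``tcr3`` are the true class
    rates of the three ordered classes at those thresholds.
    """

    c1: np.ndarray
    c2: np.ndarray
    tcr1: np.ndarray
    tcr2: np.ndarray
    tcr3: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c1": self.c1,
                "c2": self.c2,
                "tcr1": self.tcr1,
                "tcr2": self.tcr2,
                "tcr3": self.tcr3,
            }
        )


def _vus_numerator(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, tie_rule: str
) -> int:
    """Six times the weighted count of correctly ordered triples.

    Works in integer arithmetic (weights 6, 3, 1 for strict / single-tie
    / triple-tie) so the vectorised sum is bit-exact against a
    brute-force triple loop.
    """
    xs = np.sort(x)
    zs = np.sort(z)
    a = np.searchsorted(xs, y, side="left")        # x strictly below y_j
    ax = np.searchsorted(xs, y, side="right") - a  # x tied with y_j
    lo = np.searchsorted(zs, y, side="left")
    hi = np.searchsorted(zs, y, side="right")
    b = zs.size - hi                               # z strictly above y_j
    bz = hi - lo                                   # z tied with y_j
    if tie_rule == "strict":
        return int(6 * np.sum(a * b, dtype=np.int64))
    total = 6 * np.sum(a * b, dtype=np.int64)
    total += 3 * np.sum(ax * b + a * bz, dtype=np.int64)
    total += np.sum(ax * bz, dtype=np.int64)
    return int(total)


def vus_estimate(
    triple: OrderedMarkerTriple, tie_rule: str = "partial"
) -> float:
    """Empirical VUS of a scalar marker over three ordered classes.

    Exact average of the triple-ordering kernel over all n1*n2*n3
    triples, computed in O(n log n) by sorted rank counting.
    """
    if tie_rule not in ("partial", "strict"):
        raise ValidationError(f"unknown tie_rule {tie_rule!r}")
    n1, n2, n3 = triple.sizes()
    num = _vus_numerator(triple.x, triple.y, triple.z, tie_rule)
    return num / (6.0 * n1 * n2 * n3)


def vus_bootstrap_ci(
    triple: OrderedMarkerTriple,
    B: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    tie_rule: str = "partial",
) -> VUSResult:
    """VUS point estimate with a stratified percentile bootstrap CI.

    Each class is resampled with replacement within itself (so no
    resample can empty a class), the VUS recomputed per resample, and
    the CI taken as the (alpha/2, 1 - alpha/2) empirical percentiles.
    Deterministic given ``seed``.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValidationError("ci_level must lie in (0, 1)")
    if B < 1:
        raise ValidationError("B must be positive")
    if B < 100:
        logger.warning(
            "vus_bootstrap_ci: B=%d is small; percentile CI will be coarse",
            B,
        )
    point = vus_estimate(triple, tie_rule=tie_rule)
    rng = np.random.default_rng(seed)
    n1, n2, n3 = triple.sizes()
    denom = 6.0 * n1 * n2 * n3
    stats = np.empty(B)
    for b in range(B):
        xb = triple.x[rng.integers(0, n1, n1)]
        yb = triple.y[rng.integers(0, n2, n2)]
        zb = triple.z[rng.integers(0, n3, n3)]
        stats[b] = _vus_numerator(xb, yb, zb, tie_rule) / denom
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return VUSResult(
        vus=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        B=B,
        ci_level=ci_level,
        seed=seed,
        tie_rule=tie_rule,
    )


def roc_surface(triple: OrderedMarkerTriple) -> ROCSurfaceGrid:
    """Empirical ROC surface over all threshold pairs c1 <= c2.

    Thresholds run over the pooled unique marker values; a sample is
    called class 1 if its value is <= c1, class 3 if > c2, class 2
    otherwise, giving true class rates

        tcr1 = F1(c1),  tcr2 = F2(c2) - F2(c1),  tcr3 = 1 - F3(c2).
    """
    pooled = np.unique(np.concatenate([triple.x, triple.y, triple.z]))
    m = pooled.size
    ii, jj = np.triu_indices(m)
    c1 = pooled[ii]
    c2 = pooled[jj]
    f1 = np.searchsorted(np.sort(triple.x), pooled, side="right") / triple.x.size
    f2 = np.searchsorted(np.sort(triple.y), pooled, side="right") / triple.y.size
    f3 = np.searchsorted(np.sort(triple.z), pooled, side="right") / triple.z.size
    return ROCSurfaceGrid(
        c1=c1,
        c2=c2,
        tcr1=f1[ii],
        tcr2=f2[jj] - f2[ii],
        tcr3=1.0 - f3[jj],
    )


def surface_volume(triple: OrderedMarkerTriple) -> float:
    """Numerically integrated volume under the empirical ROC surface.

    Integrates tcr2 over the (tcr1, tcr3) unit square along the
    empirical threshold lattice.  For tie-free data this equals the
    triple-counting VUS estimator exactly (up to float rounding), which
    is the classical surface/probability equivalence for three ordered
    classes.
    """
    pooled = np.unique(np.concatenate([triple.x, triple.y, triple.z]))
    f1 = np.searchsorted(np.sort(triple.x), pooled, side="right") / triple.x.size
    f2 = np.searchsorted(np.sort(triple.y), pooled, side="right") / triple.y.size
    f3 = np.searchsorted(np.sort(triple.z), pooled, side="right") / triple.z.size
    d1 = np.diff(np.concatenate([[0.0], f1]))  # class-1 mass at each value
    d3 = np.diff(np.concatenate([[0.0], f3]))  # class-3 mass at each value
    # volume = sum_{i<=j} d1_i * d3_j * (F2_j - F2_i), via suffix sums
    s3 = np.cumsum(d3[::-1])[::-1]
    t3 = np.cumsum((d3 * f2)[::-1])[::-1]
    return float(np.sum(d1 * (t3 - f2 * s3)))


def triple_from_frame(
    frame: pd.DataFrame,
    value_column: str,
    class_column: str = "class",
    class_order: Sequence[str] = ("H", "P", "C"),
) -> OrderedMarkerTriple:
    """Build an :class:`OrderedMarkerTriple` from a (value, class) table."""
    sub = frame[[value_column, class_column]].dropna()
    return OrderedMarkerTriple.from_labels(
        sub[value_column].to_numpy(float),
        sub[class_column].to_numpy(),
        class_order=class_order,
    )
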