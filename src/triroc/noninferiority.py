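"""Bootstrap non-inferiority and superiority testing on delta-VUS.

A candidate panel score is compared with the reference marker on the
same subjects via the paired difference of their VUS values,
``delta = VUS_candidate - VUS_reference``.  A class-stratified paired
bootstrap (both markers evaluated on the identical resample) yields the
(100 - 2*delta_margin)% percentile confidence interval — 90% for the
conventional 5% margin — and the decision rule is the standard
two-step one: non-inferiority when the lower CI bound exceeds
``-delta_margin``; superiority, assessed second, when it exceeds zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .vus import OrderedMarkerTriple, _vus_numerator, vus_estimate

logger = logging.getLogger(__name__)


@dataclass
class DeltaVUSDecision:
    """Outcome of one candidate-vs-reference delta-VUS comparison."""

    delta_hat: float
    ci_low: float
    ci_high: float
    delta_margin: float
    B_outer: int
    B_inner: int
    non_inferior: bool
    superior: bool
    reference_vus: float
    candidate_vus: float
    ci_method: str
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.delta_hat <= self.ci_high:
            raise ValidationError("CI must bracket the delta estimate")
        if self.superior and not self.non_inferior:
            raise ValidationError("superiority implies non-inferiority")


def _verdicts(ci_low: float, delta_margin: float) -> tuple[bool, bool]:
    non_inferior = ci_low > -delta_margin
    superior = ci_low > 0.0
    return non_inferior, superior


def delta_vus_test(
    candidate_scores: Sequence[float],
    reference_scores: Sequence[float],
    classes: Sequence[str],
    class_order: Sequence[str] = ("H", "P", "C"),
    delta: float = 0.05,
    B_outer: int = 1000,
    B_inner: int = 1000,
    ci_method: str = "percentile",
    tie_rule: str = "partial",
    seed: int = 0,
) -> DeltaVUSDecision:
    """Paired bootstrap non-inferiority/superiority test on delta-VUS.

    Parameters
    ----------
    candidate_scores, reference_scores : array-like, same length
        Paired marker values for the identical samples.
    classes : array-like of labels
        Three-level class membership per sample.
    delta : float, default 0.05
        Non-inferiority margin on the VUS scale; the CI level is
        ``100 - 2 * delta * 100`` percent (90% at the default).
    B_outer : int, default 1000
        Outer bootstrap resamples (stratified within class; candidate
        and reference are always evaluated on the same resample).
    B_inner : int, default 1000
        Inner resamples per outer resample; used only in the
        ``studentized`` CI mode to estimate se(delta*).
    ci_method : {"percentile", "studentized"}
        Percentile interval of the outer delta* draws (default), or a
        bootstrap-t interval studentised by the nested inner bootstrap.
    """
    cand = np.asarray(candidate_scores, dtype=float)
    ref = np.asarray(reference_scores, dtype=float)
    labels = np.asarray(classes)
    if cand.shape != ref.shape or cand.shape[0] != labels.shape[0]:
        raise ValidationError(
            "candidate, reference and classes must be paired (same length)"
        )
    if not 0.0 < delta < 0.5:
        raise ValidationError("delta must lie in (0, 0.5)")
    if ci_method not in ("percentile", "studentized"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    order = tuple(class_order)
    idx_by_class = [np.where(labels == c)[0] for c in order]
    for c, idx in zip(order, idx_by_class):
        if idx.size < 2:
            raise ValidationError(f"class {c!r} needs at least 2 samples")

    def paired_delta(indices: list[np.ndarray]) -> float:
        n1, n2, n3 = (ix.size for ix in indices)
        denom = 6.0 * n1 * n2 * n3
        dc = _vus_numerator(
            cand[indices[0]], cand[indices[1]], cand[indices[2]], tie_rule
        )
        dr = _vus_numerator(
            ref[indices[0]], ref[indices[1]], ref[indices[2]], tie_rule
        )
        return (dc - dr) / denom

    delta_hat = paired_delta(idx_by_class)
    cand_vus = vus_estimate(
        OrderedMarkerTriple(
            cand[idx_by_class[0]], cand[idx_by_class[1]],
            cand[idx_by_class[2]], class_order=order,
        ),
        tie_rule=tie_rule,
    )
    ref_vus = cand_vus - delta_hat

    rng = np.random.default_rng(seed)
    deltas = np.empty(B_outer)
    ses = np.empty(B_outer) if ci_method == "studentized" else None
    for b in range(B_outer):
        resample = [
            ix[rng.integers(0, ix.size, ix.size)] for ix in idx_by_class
        ]
        # stratified resampling keeps every class populated by
        # construction; guard anyway against future resampling schemes
        if any(r.size == 0 for r in resample):  # pragma: no cover
            logger.warning("delta_vus_test: degenerate resample redrawn")
            resample = [
                ix[rng.integers(0, ix.size, ix.size)] for ix in idx_by_class
            ]
        deltas[b] = paired_delta(resample)
        if ses is not None:
            inner = np.empty(B_inner)
            for bi in range(B_inner):
                nested = [
                    r[rng.integers(0, r.size, r.size)] for r in resample
                ]
                inner[bi] = paired_delta(nested)
            ses[b] = inner.std(ddof=1)

    if ci_method == "percentile":
        lo, hi = np.quantile(deltas, [delta, 1.0 - delta])
    else:
        se_hat = deltas.std(ddof=1)
        valid = ses > 0
        if se_hat == 0 or valid.sum() < 2:
            # degenerate (e.g. identical markers): fall back to the
            # percentile construction, which is exact here
            lo, hi = np.quantile(deltas, [delta, 1.0 - delta])
        else:
            t_stats = (deltas[valid] - delta_hat) / ses[valid]
            t_lo, t_hi = np.quantile(t_stats, [delta, 1.0 - delta])
            lo = delta_hat - t_hi * se_hat
            hi = delta_hat - t_lo * se_hat
    lo = float(min(lo, delta_hat))
    hi = float(max(hi, delta_hat))
    non_inferior, superior = _verdicts(lo, delta)
    return DeltaVUSDecision(
        delta_hat=float(delta_hat),
        ci_low=lo,
        ci_high=hi,
        delta_margin=delta,
        B_outer=B_outer,
        B_inner=B_inner if ci_method == "studentized" else 0,
        non_inferior=non_inferior,
        superior=superior,
        reference_vus=float(ref_vus),
        candidate_vus=float(cand_vus),
        ci_method=ci_method,
        seed=seed,
    )


def forest_data(
    decisions: Sequence[DeltaVUSDecision],
    labels: Sequence[str],
    reference_label: str = "reference",
) -> pd.DataFrame:
    """Forest-plot-ready table of delta-VUS decisions.

    The first row anchors the reference marker at delta = 0 with
    +/- margin bars; subsequent rows preserve the input order and carry
    both verdicts.
    """
    decisions = list(decisions)
    labels = list(labels)
    if not decisions:
        raise ValidationError("need at least one decision")
    if len(decisions) != len(labels):
        raise ValidationError("one label per decision required")
    margin = decisions[0].delta_margin
    rows = [
        {
            "label": reference_label,
            "delta_hat": 0.0,
            "ci_low": -margin,
            "ci_high": margin,
            "margin_low": -margin,
            "zero": 0.0,
            "reference_vus": decisions[0].reference_vus,
            "non_inferior": True,
            "superior": False,
        }
    ]
    for dec, label in zip(decisions, labels):
        rows.append(
            {
                "label": label,
                "delta_hat": dec.delta_hat,
                "ci_low": dec.ci_low,
                "ci_high": dec.ci_high,
                "margin_low": -dec.delta_margin,
                "zero": 0.0,
                "reference_vus": dec.reference_vus,
                "non_inferior": dec.non_inferior,
                "superior": dec.superior,
            }
        )
    return pd.DataFrame(rows)
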