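"""Scoring a localization trace against a ground-truth area trace.

Errors are decomposed into *transition* periods (epochs surrounding a true
change of area, where the 10-s sampling makes some error unavoidable) and
*nontransition* (dwelling) periods.  With ``T_l = T_t,l + T_nt,l`` for trial
*l* and misclassified seconds ``ê_t,l`` / ``ê_nt,l`` accumulated separately
over the two period types:

    e_t,l  = 100 · ê_t,l  / T_t,l      relative transition error
    e_nt,l = 100 · ê_nt,l / T_nt,l     relative nontransition error
    ē_l    = 100 · ê_t,l  / T_l        transition error relative to the trial
    e_l    = 100 · (ê_t,l + ê_nt,l) / T_l

Dwelling-time agreement between predicted and criterion occupancy is scored
per visit (continuous occupancy bout) with an OLS fit ``y = p1·x + p2``, a
two-way mixed absolute-agreement single-rater ICC, and the regression
goodness-of-fit summary (SSE, R², adjusted R², RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .filtering import LocalizationTrace

DEFAULT_TRANSITION_WINDOW = 1  # epochs flagged on each side of a true change
DWELL_THRESHOLD_S = 100.0


@dataclass
class GroundTruthTrace:
    """Criterion area occupancy per epoch.

    ``moving`` optionally marks in-transit epochs (simulator bookkeeping);
    transition masks for scoring are derived from area changes, not from it.
    """

    area_ids: list[str]
    epoch_s: float = 10.0
    moving: np.ndarray | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.area_ids)

    def visits(self) -> list[tuple[str, int, int]]:
        """Continuous occupancy bouts as (area_id, start_epoch, length)."""
        out: list[tuple[str, int, int]] = []
        for k, a in enumerate(self.area_ids):
            if out and out[-1][0] == a and out[-1][1] + out[-1][2] == k:
                area, start, length = out[-1]
                out[-1] = (area, start, length + 1)
            else:
                out.append((a, k, 1))
        return out


def _predicted_areas(trace: LocalizationTrace | Sequence[str]) -> list[str]:
    if isinstance(trace, LocalizationTrace):
        return trace.smoothed_area_ids()
    return list(trace)


def mark_transitions(
    truth: GroundTruthTrace, window: int = DEFAULT_TRANSITION_WINDOW
) -> np.ndarray:
    """Boolean mask of transition epochs: within ±window of any true change.

    A change at epoch k (``truth[k] != truth[k-1]``) flags epochs
    ``k-window … k+window``, clipped to the trace.
    """
    n = truth.n_epochs
    mask = np.zeros(n, dtype=bool)
    for k in range(1, n):
        if truth.area_ids[k] != truth.area_ids[k - 1]:
            mask[max(0, k - window) : min(n, k + window + 1)] = True
    return mask


@dataclass
class ErrorReport:
    """Transition/nontransition error decomposition for one trial.

    Times in seconds, relative errors in percent; a zero-duration
    denominator leaves the relative quantity NaN (undefined), never 0.
    """

    misclassified_transition_s: float  # ê_t,l
    misclassified_nontransition_s: float  # ê_nt,l
    transition_s: float  # T_t,l
    nontransition_s: float  # T_nt,l

    @property
    def total_s(self) -> float:
        return self.transition_s + self.nontransition_s

    @property
    def transition_error_pct(self) -> float:
        """e_t,l = 100 · ê_t,l / T_t,l"""
        return _ratio_pct(self.misclassified_transition_s, self.transition_s)

    @property
    def nontransition_error_pct(self) -> float:
        """e_nt,l = 100 · ê_nt,l / T_nt,l"""
        return _ratio_pct(self.misclassified_nontransition_s, self.nontransition_s)

    @property
    def transition_error_vs_total_pct(self) -> float:
        """ē_l = 100 · ê_t,l / T_l — transition-caused error over the whole trial."""
        return _ratio_pct(self.misclassified_transition_s, self.total_s)

    @property
    def overall_error_pct(self) -> float:
        """e_l = 100 · (ê_t,l + ê_nt,l) / T_l"""
        return _ratio_pct(
            self.misclassified_transition_s + self.misclassified_nontransition_s,
            self.total_s,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "misclassified_transition_s": self.misclassified_transition_s,
            "misclassified_nontransition_s": self.misclassified_nontransition_s,
            "transition_s": self.transition_s,
            "nontransition_s": self.nontransition_s,
            "total_s": self.total_s,
            "transition_error_pct": self.transition_error_pct,
            "nontransition_error_pct": self.nontransition_error_pct,
            "transition_error_vs_total_pct": self.transition_error_vs_total_pct,
            "overall_error_pct": self.overall_error_pct,
        }


def _ratio_pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def error_report(
    trace: LocalizationTrace | Sequence[str],
    truth: GroundTruthTrace,
    window: int = DEFAULT_TRANSITION_WINDOW,
    min_dwell_s: float | None = None,
) -> ErrorReport:
    """Accumulate misclassified time separately over transition and
    nontransition epochs.

    ``min_dwell_s`` optionally restricts the *nontransition* tally to epochs
    belonging to truth visits longer than the threshold (robustness
    stratification; transition terms are unaffected).
    """
    pred = _predicted_areas(trace)
    if len(pred) != truth.n_epochs:
        raise ValueError(
            f"trace has {len(pred)} epochs but truth has {truth.n_epochs}"
        )
    mask = mark_transitions(truth, window=window)
    mis = np.array([p != t for p, t in zip(pred, truth.area_ids)])
    nt = ~mask
    if min_dwell_s is not None:
        keep = np.zeros(truth.n_epochs, dtype=bool)
        for _, start, length in truth.visits():
            if length * truth.epoch_s > min_dwell_s:
                keep[start : start + length] = True
        nt = nt & keep
    s = truth.epoch_s
    return ErrorReport(
        misclassified_transition_s=float((mis & mask).sum()) * s,
        misclassified_nontransition_s=float((mis & nt).sum()) * s,
        transition_s=float(mask.sum()) * s,
        nontransition_s=float(nt.sum()) * s,
    )


def average_error_reports(reports: Sequence[ErrorReport]) -> dict[str, float]:
    """Trial-averaged relative errors (mean over trials, NaN-skipping)."""
    if not reports:
        raise ValueError("no reports to average")
    keys = (
        "transition_error_pct",
        "nontransition_error_pct",
        "transition_error_vs_total_pct",
        "overall_error_pct",
    )
    out = {}
    for key in keys:
        vals = np.array([getattr(r, key) for r in reports])
        out[key] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    out["misclassified_transition_s"] = float(
        np.mean([r.misclassified_transition_s for r in reports])
    )
    out["misclassified_nontransition_s"] = float(
        np.mean([r.misclassified_nontransition_s for r in reports])
    )
    return out


@dataclass
class AgreementStats:
    """Dwelling-time agreement: OLS fit, ICC, and goodness of fit.

    ``slope``/``intercept`` are the coefficients of ``predicted =
    p1·criterion + p2`` with 95% CIs; ``icc`` is the two-way mixed
    absolute-agreement single-rater ICC; SSE (s²), R², adjusted R² and RMSE
    (s) summarize the regression fit.  Degenerate inputs leave statistics
    NaN.
    """

    n_pairs: int
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    icc: float
    sse: float
    r2: float
    adj_r2: float
    rmse: float

    def as_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "icc": self.icc,
            "sse": self.sse,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
        }
        return d


def dwelling_pairs(
    trace: LocalizationTrace | Sequence[str], truth: GroundTruthTrace
) -> pd.DataFrame:
    """Per-visit (criterion, predicted) dwelling times in seconds.

    Each truth visit contributes one pair: criterion time = visit length,
    predicted time = time the algorithm placed the receiver in that visit's
    area during the visit's span.
    """
    pred = _predicted_areas(trace)
    rows = []
    for area, start, length in truth.visits():
        span = pred[start : start + length]
        rows.append(
            {
                "area_id": area,
                "start_epoch": start,
                "criterion_s": length * truth.epoch_s,
                "predicted_s": sum(p == area for p in span) * truth.epoch_s,
            }
        )
    return pd.DataFrame(rows)


def icc_absolute_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """Two-way mixed absolute-agreement single-rater ICC between two raters.

    McGraw & Wong ICC(A,1): with row (target), column (rater) and error mean
    squares MSR, MSC, MSE from the two-way ANOVA on the n×k rating table,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k/n·(MSC − MSE))

    Perfect agreement (MSE = MSC = 0) gives exactly 1; zero between-target
    variance leaves the coefficient NaN.
    """
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 3:
        return float("nan")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def dwelling_agreement(
    trace: LocalizationTrace | Sequence[str],
    truth: GroundTruthTrace,
    pairs: pd.DataFrame | None = None,
) -> AgreementStats:
    """Agreement statistics over per-visit dwelling-time pairs.

    Requires at least 3 pairs; degenerate variance (all criterion times
    equal) yields NaN fit statistics.
    """
    if pairs is None:
        pairs = dwelling_pairs(trace, truth)
    x = pairs["criterion_s"].to_numpy(float)
    y = pairs["predicted_s"].to_numpy(float)
    n = len(pairs)
    nan = float("nan")
    if n < 3 or np.ptp(x) == 0.0:
        return AgreementStats(
            n_pairs=n, slope=nan, intercept=nan, slope_ci=(nan, nan),
            intercept_ci=(nan, nan), icc=icc_absolute_agreement(x, y),
            sse=nan, r2=nan, adj_r2=nan, rmse=nan,
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    sse = float(fit.ssr)
    rmse = float(np.sqrt(sse / fit.df_resid)) if fit.df_resid > 0 else 0.0
    return AgreementStats(
        n_pairs=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        icc=icc_absolute_agreement(x, y),
        sse=sse,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        rmse=rmse,
    )


def stratified_agreement(
    trace: LocalizationTrace | Sequence[str],
    truth: GroundTruthTrace,
    threshold_s: float = DWELL_THRESHOLD_S,
) -> dict[str, AgreementStats]:
    """Agreement for all visits, visits ≤ threshold, and visits > threshold."""
    pairs = dwelling_pairs(trace, truth)
    return {
        "all": dwelling_agreement(trace, truth, pairs),
        "under_threshold": dwelling_agreement(
            trace, truth, pairs[pairs["criterion_s"] <= threshold_s]
        ),
        "over_threshold": dwelling_agreement(
            trace, truth, pairs[pairs["criterion_s"] > threshold_s]
        ),
    }


def confusion(
    trace: LocalizationTrace | Sequence[str],
    truth: GroundTruthTrace,
    variant: str = "all",
    window: int = DEFAULT_TRANSITION_WINDOW,
    area_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Time-weighted row-normalized confusion matrix (rows = true area).

    ``variant="all"`` scores every epoch; ``"nontransition"`` excludes the
    transition mask.  Rows with no truth time are left as zeros.
    """
    if variant not in ("all", "nontransition"):
        raise ValueError(f"unknown variant {variant!r}")
    pred = _predicted_areas(trace)
    if isinstance(trace, LocalizationTrace) and area_ids is None:
        area_ids = trace.area_ids
    if area_ids is None:
        area_ids = sorted(set(truth.area_ids) | set(pred))
    keep = np.ones(truth.n_epochs, dtype=bool)
    if variant == "nontransition":
        keep = ~mark_transitions(truth, window=window)
    idx = {a: i for i, a in enumerate(area_ids)}
    mat = np.zeros((len(area_ids), len(area_ids)))
    for k in range(truth.n_epochs):
        if keep[k]:
            mat[idx[truth.area_ids[k]], idx[pred[k]]] += 1.0
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, mat / sums, 0.0)
    return pd.DataFrame(norm, index=list(area_ids), columns=list(area_ids))
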