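"""ROC analysis of autoregulation scores between conditions.

The positive class is always the impaired (hypercapnic) condition.
Autoregulation indices live on the bounded 0-9 scale and are thresholded
at the integers (a subject is called impaired when its index falls
*below* the threshold; ties count as non-positive); continuous transfer
function coefficients are thresholded at every observed score midpoint.
The area under the curve (AUC) is the trapezoidal area, which for
midpoint thresholds equals the tie-corrected Mann-Whitney statistic.
AUCs of two methods measured on the same subjects are compared with a
paired bootstrap over subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .preprocessing import DataError, ParameterError

__all__ = [
    "LabeledScores",
    "RocResult",
    "BootstrapComparison",
    "roc_index",
    "roc_continuous",
    "auc_bootstrap_compare",
]


@dataclass
class LabeledScores:
    """Per-subject scores under both conditions (subjects paired)."""

    baseline: np.ndarray
    hypercapnia: np.ndarray
    subjects: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.hypercapnia = np.asarray(self.hypercapnia, dtype=float)
        if self.baseline.size == 0 or self.hypercapnia.size == 0:
            raise DataError("need at least one score per condition")


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str = "below"  # positive when score is below / above the threshold
    name: str = ""

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


def _roc_points(
    baseline: np.ndarray, hypercapnia: np.ndarray, thresholds: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity at each threshold (strict inequality)."""
    b = baseline[:, None]
    h = hypercapnia[:, None]
    if direction == "below":
        sens = (h < thresholds).mean(axis=0)
        spec = (b >= thresholds).mean(axis=0)
    else:
        sens = (h > thresholds).mean(axis=0)
        spec = (b <= thresholds).mean(axis=0)
    return sens, spec


def _trapezoid_auc(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], sens[order]
    # stable sort keeps threshold order within equal-FPR runs; sort TPR too
    tpr = np.sort(tpr)
    return float(np.trapezoid(tpr, fpr))


def roc_index(
    scores: LabeledScores, thresholds: np.ndarray | None = None
) -> RocResult:
    """ROC over a bounded 0-9 index using the integers as thresholds.

    A subject is classified impaired when its index is strictly below
    the threshold. Endpoint thresholds (below the minimum and above the
    maximum score) anchor the curve at (0, 0) and (1, 1).
    """
    if np.any(scores.baseline < 0) or np.any(scores.baseline > 9) or np.any(
        scores.hypercapnia < 0
    ) or np.any(scores.hypercapnia > 9):
        raise ParameterError("index scores must lie in [0, 9]")
    if thresholds is None:
        thresholds = np.arange(0.0, 10.0)
    thresholds = np.concatenate([thresholds, [10.0]])  # (1, 1) endpoint
    sens, spec = _roc_points(scores.baseline, scores.hypercapnia, thresholds, "below")
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=_trapezoid_auc(sens, spec),
        direction="below",
        name=scores.name,
    )


def roc_continuous(scores: LabeledScores, direction: str = "auto") -> RocResult:
    """ROC over a continuous score, thresholds at observed midpoints.

    ``direction`` picks which tail marks impairment: ``"below"`` (e.g.
    phase drops when autoregulation fails), ``"above"``, or ``"auto"``
    which keeps whichever orientation reaches AUC >= 0.5.
    """
    pooled = np.concatenate([scores.baseline, scores.hypercapnia])
    if not np.all(np.isfinite(pooled)):
        raise DataError("scores must be finite")
    uniq = np.unique(pooled)
    if uniq.size < 2:
        warnings.warn("constant scores: AUC is 0.5 by convention", stacklevel=2)
        thr = np.array([uniq[0]])
    else:
        thr = (uniq[:-1] + uniq[1:]) / 2.0
    lo, hi = pooled.min() - 1.0, pooled.max() + 1.0
    thr = np.concatenate([[lo], thr, [hi]])

    def _build(d: str) -> RocResult:
        sens, spec = _roc_points(scores.baseline, scores.hypercapnia, thr, d)
        return RocResult(
            thresholds=thr,
            sensitivity=sens,
            specificity=spec,
            auc=_trapezoid_auc(sens, spec),
            direction=d,
            name=scores.name,
        )

    if direction in ("below", "above"):
        return _build(direction)
    below = _build("below")
    return below if below.auc >= 0.5 else _build("above")


@dataclass
class BootstrapComparison:
    auc_a: float
    auc_b: float
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


def auc_bootstrap_compare(
    a: LabeledScores,
    b: LabeledScores,
    n_boot: int = 5000,
    seed: int | None = None,
    roc_fn=roc_continuous,
) -> BootstrapComparison:
    """Paired bootstrap comparison of two methods' AUCs.

    Methods a and b must score the same subjects in both conditions.
    Each replicate resamples subjects with replacement — the same
    subjects for both methods and both conditions, preserving pairing —
    and recomputes both AUCs. The two-sided p-value follows the
    studentized convention: the observed difference divided by the
    bootstrap SD of the difference, referred to a standard normal.
    """
    if a.baseline.size != b.baseline.size or a.hypercapnia.size != b.hypercapnia.size:
        raise ParameterError("methods must score the same subjects")
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is very small", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_base = a.baseline.size
    n_hyp = a.hypercapnia.size

    def _auc(s: LabeledScores) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return roc_fn(s).auc

    auc_a = _auc(a)
    auc_b = _auc(b)
    observed = auc_a - auc_b

    deltas = np.empty(n_boot)
    for i in range(n_boot):
        ib = rng.integers(0, n_base, n_base)
        ih = rng.integers(0, n_hyp, n_hyp)
        ra = LabeledScores(a.baseline[ib], a.hypercapnia[ih])
        rb = LabeledScores(b.baseline[ib], b.hypercapnia[ih])
        deltas[i] = _auc(ra) - _auc(rb)

    sd = float(deltas.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if observed == 0.0 else 0.0
    else:
        z = observed / sd
        p = float(2.0 * _stats.norm.sf(abs(z)))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return BootstrapComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_boot=n_boot,
    )
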