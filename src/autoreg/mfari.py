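"""Model-free autoregulation index (mfARI).

A CBFV step response, normalized by its pre-step baseline, is summarized
by the best pair of straight lines: an unconstrained *transient* line
covering the first ``delta_tau`` seconds after the pressure step and a
horizontal *steady-state* line (a constant ``K_s``) covering the rest.
The pair minimizing the summed squared errors e_T + e_S over all
candidate transient durations gives three descriptors:

- ``delta_tau`` — duration of the transient (s),
- ``K_s`` — steady-state level relative to baseline (dimensionless),
- ``phi`` — angle (degrees) between the transient line and the pressure
  line; for the idealized sustained step the pressure line is horizontal
  and phi reduces to arctan of the normalized transient slope.

The three descriptors are mapped onto the familiar 0-9 autoregulation
scale by a linear regression calibrated on the ten canonical
second-order templates, so the index needs no parametric model of the
response being scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import DataError, ParameterError
from .tiecks import TiecksTemplate

__all__ = [
    "StepResponse",
    "MfariFit",
    "MfariCalibration",
    "fit_two_lines",
    "calibrate",
    "mfari",
]


@dataclass
class StepResponse:
    """A CBFV trajectory responding to an idealized pressure step.

    ``values`` are dimensionless (already divided by the pre-step
    baseline ``v_base``); ``step_index`` is the sample of step onset.
    """

    values: np.ndarray
    rate: float
    step_index: int
    v_base: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if not 0 <= self.step_index < self.values.size:
            raise ParameterError("step_index outside the series")
        if self.v_base <= 0:
            raise DataError("baseline level must be positive")

    @property
    def post_step(self) -> np.ndarray:
        return self.values[self.step_index :]


@dataclass
class MfariFit:
    """Two-line characterization of a step response."""

    delta_tau: float  # transient duration, s
    K_s: float  # steady-state level, dimensionless
    phi: float  # transient angle vs the BP line, degrees
    fit_error: float  # summed squared residuals e_T + e_S
    slope: float  # transient slope, 1/s (normalized units)
    intercept: float  # transient line value at step onset
    plausible: bool = True
    index: float | None = None


def _line_sse_prefix(t: np.ndarray, y: np.ndarray):
    """Closed-form least-squares line SSE for every prefix y[0..k].

    Returns arrays (sse, slope, intercept) indexed by k, computed from
    running sums; entries for k < 1 are invalid.
    """
    n = np.arange(1.0, t.size + 1)
    st = np.cumsum(t)
    stt = np.cumsum(t * t)
    sy = np.cumsum(y)
    sty = np.cumsum(t * y)
    syy = np.cumsum(y * y)
    denom = n * stt - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sty - st * sy) / denom
        slope = np.where(denom > 1e-30, slope, 0.0)
        intercept = (sy - slope * st) / n
    sse = syy - intercept * sy - slope * sty
    return np.maximum(sse, 0.0), slope, intercept


def _const_sse_suffix(y: np.ndarray):
    """SSE about the mean for every suffix y[k..]; returns (sse, mean)."""
    rev = y[::-1]
    n = np.arange(1.0, y.size + 1)
    s = np.cumsum(rev)
    ss = np.cumsum(rev * rev)
    mean = s / n
    sse = ss - s * s / n
    return np.maximum(sse[::-1], 0.0), mean[::-1]


def fit_two_lines(
    resp: StepResponse,
    min_tau: float = 1.0,
    max_tau: float = 15.0,
    bp_slope: float = 0.0,
    drift_tol: float = 0.1,
) -> MfariFit:
    """Fit the optimal transient-line / steady-line pair to a response.

    Every candidate breakpoint on the sample grid between ``min_tau``
    and ``max_tau`` seconds after the step is evaluated: the transient
    line is the least-squares line through the samples up to the
    breakpoint, the steady line is the mean of the remaining samples,
    and the candidate minimizing the total squared error wins (first
    minimum on ties, i.e. the shorter transient).

    ``bp_slope`` is the slope (1/s, normalized units) of the pressure
    line the angle is measured against; zero for a sustained step.
    A response whose tail still drifts by more than ``drift_tol``
    (normalized units) is flagged non-plausible.
    """
    y = resp.post_step
    if y.size < 10:
        raise DataError("need at least 10 post-step samples")
    t = np.arange(y.size) / resp.rate

    k_min = max(2, int(np.ceil(min_tau * resp.rate)))
    k_max = min(int(np.floor(max_tau * resp.rate)), y.size - 3)
    if k_max < k_min:
        raise DataError("post-step window too short for the breakpoint search")

    sse_t, slopes, intercepts = _line_sse_prefix(t, y)
    sse_s, means = _const_sse_suffix(y)

    ks = np.arange(k_min, k_max + 1)
    total = sse_t[ks] + sse_s[ks + 1]
    best = int(ks[np.argmin(total)])

    slope = float(slopes[best])
    fit = MfariFit(
        delta_tau=best / resp.rate,
        K_s=float(means[best + 1]),
        phi=float(np.degrees(np.arctan(slope) - np.arctan(bp_slope))),
        fit_error=float(total[best - k_min]),
        slope=slope,
        intercept=float(intercepts[best]),
    )

    # no steady state: the tail keeps drifting away from the fitted level
    tail = y[best + 1 :]
    t_tail = t[best + 1 :]
    drift = abs(np.polyfit(t_tail, tail, 1)[0]) * (t_tail[-1] - t_tail[0])
    if drift > drift_tol:
        warnings.warn(
            "response does not settle: steady-state fit is not plausible",
            stacklevel=2,
        )
        fit.plausible = False
    return fit


@dataclass
class MfariCalibration:
    """Linear map from (delta_tau, K_s, phi) to the 0-9 scale."""

    coef: np.ndarray  # (intercept, c_tau, c_Ks, c_phi)
    residuals: np.ndarray  # per-grade in-sample residuals
    fit_kwargs: dict

    def predict(self, fit: MfariFit) -> float:
        x = np.array([1.0, fit.delta_tau, fit.K_s, fit.phi])
        return float(self.coef @ x)


def calibrate(templates: list[TiecksTemplate], **fit_kwargs) -> MfariCalibration:
    """Regress the known grades on two-line descriptors of the templates.

    The ten canonical step responses are characterized with
    :func:`fit_two_lines` and an ordinary least-squares plane through
    their (delta_tau, K_s, phi) triples maps descriptors to grades.
    Coefficients are recomputed here every time — they depend on the
    step geometry and rate of the templates, which must match the
    responses that will be scored.
    """
    rows, grades = [], []
    for tpl in templates:
        resp = StepResponse(
            tpl.response.values, rate=tpl.response.rate, step_index=tpl.step_index
        )
        fit = fit_two_lines(resp, **fit_kwargs)
        rows.append([1.0, fit.delta_tau, fit.K_s, fit.phi])
        grades.append(tpl.params.ari_grade)
    X = np.asarray(rows)
    y = np.asarray(grades)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("rank-deficient calibration design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = X @ coef - y
    return MfariCalibration(coef=coef, residuals=residuals, fit_kwargs=fit_kwargs)


def mfari(resp: StepResponse, cal: MfariCalibration) -> float:
    """Score a step response on the 0-9 scale using a calibration."""
    fit = fit_two_lines(resp, **cal.fit_kwargs)
    return float(np.clip(cal.predict(fit), 0.0, 9.0))
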