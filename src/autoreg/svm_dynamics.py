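"""Nonlinear dynamic models of the pressure-flow relationship via nu-SVR.

Two univariate structures relate normalized BP (input p) to normalized
CBFV (output v), both realized as support vector regression with a
radial-basis kernel:

- NFIR (nonlinear finite impulse response):
      v(t) = F(p(t), p(t-1), ..., p(t-n_p))
- NAR (nonlinear autoregressive with exogenous input):
      v(t) = F(v(t-1), ..., v(t-n_v), p(t), ..., p(t-n_p))

Training is one-step-ahead: NAR regressors use *measured* past CBFV.
Validation is free-run ("model predictive output"): the model predicts a
whole unseen segment, NAR recurrences fed back from its *own* previous
predictions — a much stricter test that exposes models which merely
track the previous sample. Model order and hyper-parameters are chosen
by grid search on validation Pearson correlation, with the recording's
two halves swapped between the training and validation roles, and the
winning model must produce a physiologically plausible response to a
negative pressure step.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import NuSVR

from .mfari import StepResponse
from .preprocessing import (
    DataError,
    ParameterError,
    UniformSignal,
    denormalize01,
    normalize01,
)

__all__ = [
    "DynamicModelSpec",
    "TrainedModel",
    "GridSearchResult",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "build_regressors",
    "train_model",
    "free_run_predict",
    "grid_search",
    "model_step_response",
    "plausibility_filter",
    "pearson_cc",
]

# Hyper-parameter grid bracketing the magnitudes typical of selected
# models on 5-min recordings (C of order 1e3-1e4, nu near 0.5, gamma
# between 0.1 and ~1); fully overridable.
DEFAULT_GRID: dict = {
    "n_p": list(range(1, 9)),
    "n_v": list(range(1, 7)),
    "C": [1.0, 10.0, 100.0, 1000.0, 10000.0],
    "nu": [0.2, 0.4, 0.6, 0.8],
    "gamma": [0.01, 0.05, 0.1, 0.5, 1.0, 5.0],
}

# Coarse grid for cohort-scale runs: spans the useful order range for
# second-order hemodynamics sampled at 2 Hz at a fraction of the cost.
REDUCED_GRID: dict = {
    "n_p": [2, 4],
    "n_v": [1, 2],
    "C": [10.0],
    "nu": [0.5],
    "gamma": [0.1, 1.0],
}


@dataclass(frozen=True)
class DynamicModelSpec:
    """Structure and hyper-parameters of one candidate model."""

    structure: str  # "NFIR" | "NAR"
    n_p: int
    n_v: int = 0
    C: float = 1.0
    nu: float = 0.5
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.structure not in ("NFIR", "NAR"):
            raise ParameterError(f"unknown structure {self.structure!r}")
        if self.structure == "NFIR" and self.n_v:
            raise ParameterError("NFIR models have no output recurrences")
        if self.structure == "NAR" and self.n_v < 1:
            raise ParameterError("NAR models need at least one recurrence")
        if self.n_p < 1:
            raise ParameterError("need at least one pressure lag")
        if self.C <= 0 or self.gamma <= 0 or not 0 < self.nu <= 1:
            raise ParameterError("hyper-parameters out of range")

    @property
    def max_lag(self) -> int:
        return max(self.n_p, self.n_v)


def build_regressors(
    p: np.ndarray, v: np.ndarray, spec: DynamicModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead design matrix and targets.

    Row t (for t >= max(n_p, n_v)) holds, for NAR, the *measured*
    v(t-1)..v(t-n_v) followed by p(t)..p(t-n_p); for NFIR only the
    pressure lags. The target is v(t). Current-sample pressure p(t) is
    part of the regressor in both structures.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise ParameterError("p and v must be 1-D arrays of equal length")
    lag0 = spec.max_lag
    n = p.size
    if n < lag0 + 1:
        raise DataError(f"series of length {n} shorter than max lag + 1 = {lag0 + 1}")
    t = np.arange(lag0, n)
    cols = []
    if spec.structure == "NAR":
        cols += [v[t - j] for j in range(1, spec.n_v + 1)]
    cols += [p[t - j] for j in range(0, spec.n_p + 1)]
    return np.column_stack(cols), v[t]


@dataclass
class TrainedModel:
    """A fitted nu-SVR dynamic model plus everything free-run needs."""

    spec: DynamicModelSpec
    svr: NuSVR
    p_bounds: tuple[float, float]  # training-segment normalization constants
    v_bounds: tuple[float, float]
    p_train_mean: float  # mean of the normalized training pressure
    v_train_mean: float
    segment: str = ""  # which half served as training data
    cc_validation: float | None = None

    # cached kernel pieces for fast sequential prediction
    _sv: np.ndarray = field(init=False, repr=False)
    _dual: np.ndarray = field(init=False, repr=False)
    _b: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._sv = self.svr.support_vectors_
        self._dual = self.svr.dual_coef_.ravel()
        self._b = float(self.svr.intercept_[0])

    def predict_row(self, x: np.ndarray) -> float:
        """RBF decision function for a single regressor vector.

        Identical to ``svr.predict`` but without estimator overhead, so
        the sample-by-sample free-run loop stays fast.
        """
        d = self._sv - x
        k = np.exp(-self.svr._gamma * np.einsum("ij,ij->i", d, d))
        return float(self._dual @ k + self._b)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svr.predict(X)


def train_model(
    design: np.ndarray,
    targets: np.ndarray,
    spec: DynamicModelSpec,
    p_bounds: tuple[float, float] = (0.0, 1.0),
    v_bounds: tuple[float, float] = (0.0, 1.0),
    p_train_mean: float = 0.5,
    v_train_mean: float = 0.5,
    segment: str = "",
) -> TrainedModel:
    """Fit a nu-SVR with RBF kernel on a one-step-ahead design.

    The nu parameter lower-bounds the fraction of support vectors and
    upper-bounds the fraction of margin errors. Fitting is deterministic
    for identical inputs.
    """
    if design.shape[0] < 50:
        raise DataError(f"need at least 50 training rows, got {design.shape[0]}")
    svr = NuSVR(C=spec.C, nu=spec.nu, gamma=spec.gamma, kernel="rbf")
    svr.fit(design, targets)
    if svr.fit_status_ != 0:
        raise RuntimeError(f"nu-SVR solver failed for {spec}")
    return TrainedModel(
        spec=spec,
        svr=svr,
        p_bounds=p_bounds,
        v_bounds=v_bounds,
        p_train_mean=p_train_mean,
        v_train_mean=v_train_mean,
        segment=segment,
    )


def free_run_predict(
    model: TrainedModel,
    p: np.ndarray,
    v_init: np.ndarray | None = None,
    divergence_bounds: tuple[float, float] = (-0.5, 1.5),
) -> tuple[np.ndarray, int, bool]:
    """Predict a whole segment, feeding back NAR recurrences.

    Parameters
    ----------
    p : ndarray
        Pressure segment normalized with the *training* constants.
    v_init : ndarray or None
        The first ``max(n_p, n_v)`` measured output values that seed the
        recurrences; ignored (may be None) for NFIR.

    Returns
    -------
    (vhat, t_start, diverged) : predictions over the full segment length
    (entries before ``t_start`` are the seed values, or the training
    mean for NFIR), the first predicted index, and a flag raised when
    any prediction leaves ``divergence_bounds``.
    """
    p = np.asarray(p, dtype=float)
    spec = model.spec
    lag0 = spec.max_lag
    n = p.size
    if n < lag0 + 1:
        raise DataError("segment shorter than max lag + 1")
    vhat = np.empty(n)

    if spec.structure == "NFIR":
        t = np.arange(lag0, n)
        X = np.column_stack([p[t - j] for j in range(0, spec.n_p + 1)])
        vhat[lag0:] = model.predict(X)
        vhat[:lag0] = model.v_train_mean if v_init is None else v_init[:lag0]
    else:
        if v_init is None or len(v_init) < lag0:
            raise ParameterError(f"NAR free-run needs {lag0} seed output values")
        vhat[:lag0] = np.asarray(v_init, dtype=float)[:lag0]
        row = np.empty(spec.n_v + spec.n_p + 1)
        for t in range(lag0, n):
            for j in range(spec.n_v):
                row[j] = vhat[t - 1 - j]
            for j in range(spec.n_p + 1):
                row[spec.n_v + j] = p[t - j]
            vhat[t] = model.predict_row(row)

    lo, hi = divergence_bounds
    diverged = bool(np.any((vhat[lag0:] < lo) | (vhat[lag0:] > hi)))
    if diverged:
        warnings.warn("free-run prediction left the plausible range", stacklevel=2)
    return vhat, lag0, diverged


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, returning 0 for a constant argument."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def model_step_response(
    model: TrainedModel,
    settle_s: float = 60.0,
    step_amplitude: float = 0.2,
    post_s: float = 20.0,
    rate: float = 2.0,
    p_level: float | None = None,
) -> StepResponse:
    """Drive a trained model with an idealized negative pressure step.

    The normalized pressure input is held at the training-segment mean
    for ``settle_s`` seconds so the model output settles, then dropped
    by ``step_amplitude`` (normalized units) and held. The output is
    mapped back to physical units and divided by its pre-step level
    (V_base, the mean over the last 10 s before the step), yielding the
    dimensionless step response the autoregulation indices consume.
    """
    if p_level is None:
        p_level = model.p_train_mean
    n_pre = int(round(settle_s * rate))
    n_post = int(round(post_s * rate)) + 1
    p = np.concatenate(
        [np.full(n_pre, p_level), np.full(n_post, p_level - step_amplitude)]
    )
    lag0 = model.spec.max_lag
    v_init = np.full(lag0, model.v_train_mean)
    vhat, _, diverged = free_run_predict(model, p, v_init)

    pre_tail = vhat[max(0, n_pre - int(10 * rate)) : n_pre]
    if np.std(pre_tail) > 0.02:
        warnings.warn("pre-step output did not settle", stacklevel=2)
    v_phys = denormalize01(vhat, model.v_bounds)
    v_base = float(np.mean(v_phys[max(0, n_pre - int(10 * rate)) : n_pre]))
    if v_base <= 0:
        raise DataError("non-positive pre-step output level")
    return StepResponse(v_phys / v_base, rate=rate, step_index=n_pre, v_base=v_base)


def plausibility_filter(
    resp: StepResponse,
    bounds: tuple[float, float] = (0.0, 2.0),
    initial_window_s: float = 2.0,
    settle_frac: float = 0.25,
    settle_tol: float = 0.05,
    oscillation_frac: float = 0.5,
    step_sign: int = -1,
) -> bool:
    """Decide whether a model step response is physiologically credible.

    All four rules must hold:

    i.   the response stays within ``bounds`` times baseline;
    ii.  the initial deflection has the sign of the pressure step;
    iii. it settles — the SD of the final ``settle_frac`` of post-step
         samples is below ``settle_tol`` of baseline;
    iv.  after first recovering to the steady level it does not ring
         with peak-to-peak excursion above ``oscillation_frac`` of the
         initial deflection.
    """
    d = resp.values
    if not np.all(np.isfinite(d)):
        return False
    if np.any(d < bounds[0]) or np.any(d > bounds[1]):
        return False

    post = resp.post_step
    n_init = max(1, int(round(initial_window_s * resp.rate)))
    deflection = float(np.mean(post[:n_init]) - 1.0)
    if np.sign(deflection) != np.sign(step_sign):
        return False

    n_tail = max(2, int(round(settle_frac * post.size)))
    steady = float(np.mean(post[-n_tail:]))
    if float(np.std(post[-n_tail:])) >= settle_tol:
        return False

    i_ext = int(np.argmin(post) if step_sign < 0 else np.argmax(post))
    extremum = float(post[i_ext] - 1.0)
    after = post[i_ext:]
    crossed = np.flatnonzero(
        (after - steady) * np.sign(extremum - steady + 1e-12) <= 0
    )
    if crossed.size:
        tail = after[crossed[0] :]
        if float(np.ptp(tail)) > oscillation_frac * abs(extremum):
            return False
    return True


@dataclass
class GridSearchResult:
    """Winning model of a structure search plus its validation evidence."""

    model: TrainedModel
    cc: float
    prediction: np.ndarray  # free-run prediction on the validation segment
    v_validation: np.ndarray  # measured validation output, training-normalized
    t_start: int
    plausible: bool
    step_response: StepResponse | None
    n_candidates: int


def _iter_specs(structure: str, grid: dict):
    n_ps = grid["n_p"]
    n_vs = grid["n_v"] if structure == "NAR" else [0]
    for n_p, n_v, C, nu, gamma in itertools.product(
        n_ps, n_vs, grid["C"], grid["nu"], grid["gamma"]
    ):
        yield DynamicModelSpec(structure, n_p=n_p, n_v=n_v, C=C, nu=nu, gamma=gamma)


def grid_search(
    p: UniformSignal,
    v: UniformSignal,
    structure: str,
    grid: dict | None = None,
    step_kwargs: dict | None = None,
    plausibility_kwargs: dict | None = None,
) -> GridSearchResult:
    """Select the best dynamic model for one recording.

    The recording (2 Hz, physical units) is split into halves; for each
    ordering (train on the first half, validate on the second, then
    swapped) every grid point is trained one-step-ahead and scored by
    the Pearson correlation of its free-run prediction on the held-out
    half. Normalization constants come from the training half only.
    Candidates are then examined in descending correlation order and the
    first whose step response passes :func:`plausibility_filter` wins.
    If none passes, the highest-correlation model is returned with
    ``plausible=False``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if p.rate != v.rate or len(p) != len(v):
        raise ParameterError("BP and CBFV must share rate and length")
    half = len(p) // 2
    segments = {
        "A": (p.values[:half], v.values[:half]),
        "B": (p.values[half:], v.values[half:]),
    }

    candidates = []
    for train_id, val_id in (("A", "B"), ("B", "A")):
        p_tr_raw, v_tr_raw = segments[train_id]
        p_va_raw, v_va_raw = segments[val_id]
        p_tr_sig, p_bounds = normalize01(UniformSignal(p_tr_raw, p.rate))
        v_tr_sig, v_bounds = normalize01(UniformSignal(v_tr_raw, v.rate))
        p_tr, v_tr = p_tr_sig.values, v_tr_sig.values
        p_va = (p_va_raw - p_bounds[0]) / (p_bounds[1] - p_bounds[0])
        v_va = (v_va_raw - v_bounds[0]) / (v_bounds[1] - v_bounds[0])

        for spec in _iter_specs(structure, grid):
            X, y = build_regressors(p_tr, v_tr, spec)
            model = train_model(
                X,
                y,
                spec,
                p_bounds=p_bounds,
                v_bounds=v_bounds,
                p_train_mean=float(p_tr.mean()),
                v_train_mean=float(v_tr.mean()),
                segment=train_id,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vhat, t0, _ = free_run_predict(model, p_va, v_init=v_va[: spec.max_lag])
            cc = pearson_cc(vhat[t0:], v_va[t0:])
            model.cc_validation = cc
            candidates.append((cc, model, vhat, v_va, t0))

    candidates.sort(key=lambda c: c[0], reverse=True)
    step_kwargs = {"rate": p.rate, **(step_kwargs or {})}
    plausibility_kwargs = plausibility_kwargs or {}
    for cc, model, vhat, v_va, t0 in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                resp = model_step_response(model, **step_kwargs)
            except DataError:
                continue
        if plausibility_filter(resp, **plausibility_kwargs):
            return GridSearchResult(
                model, cc, vhat, v_va, t0, True, resp, len(candidates)
            )

    cc, model, vhat, v_va, t0 = candidates[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            resp = model_step_response(model, **step_kwargs)
        except DataError:
            resp = None
    return GridSearchResult(model, cc, vhat, v_va, t0, False, resp, len(candidates))
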