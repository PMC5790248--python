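"""Synthetic paired BP-CBFV cohorts with known autoregulation grades.

Every pipeline stage can be exercised without clinical recordings:
pressure is simulated as band-limited spontaneous variability (power
concentrated in the 0.02-0.2 Hz range where autoregulation operates,
plus a ~0.1 Hz Mayer-wave component), flow velocity follows from the
second-order autoregulation model at a chosen grade, and white
observation noise is added. Impairment (the hypercapnic condition) is
emulated by drawing lower grades and shifting the CBFV operating point
upward, the dominant effects of CO2 on these signals.

The flow generator reuses the same forward model the classic index fits
— deliberate circularity that makes grade-recovery tests exact. For
robustness checks an alternative first-order high-pass generator
(``model="highpass"``) produces responses the fitted templates do not
represent exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

from .preprocessing import ParameterError, UniformSignal
from .tiecks import interpolate_parameters, tiecks_forward

__all__ = [
    "SyntheticSubjectConfig",
    "SyntheticCohortConfig",
    "SyntheticRecording",
    "generate_bp",
    "generate_subject",
    "generate_cohort",
]


@dataclass
class SyntheticSubjectConfig:
    """One simulated 5-minute recording.

    Defaults follow typical resting values in healthy adults: mean BP
    94.5 mmHg, CBFV 57.4 cm/s; spontaneous BP variability of 5 mmHg SD
    concentrated below 0.25 Hz; observation noise as a fraction of the
    CBFV operating point.
    """

    ari_true: float = 5.0
    duration: float = 300.0
    rate: float = 5.0
    bp_mean: float = 94.5
    bp_sd: float = 5.0
    cbfv_base: float = 57.4
    noise_sd: float = 0.05
    seed: int = 0
    model: str = "tiecks"  # or "highpass"
    mayer_amp: float = 0.4  # relative weight of the ~0.1 Hz component

    def __post_init__(self) -> None:
        if self.duration < 60.0:
            raise ParameterError("duration must be at least 60 s")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not 0.0 <= self.ari_true <= 9.0:
            raise ParameterError("ari_true must lie in [0, 9]")


@dataclass
class SyntheticCohortConfig:
    """A paired cohort: every subject recorded in both conditions.

    Grade distributions default to truncated normals matching typical
    healthy (5.9 +/- 1.5) and hypercapnic (2.5 +/- 1.2) index spreads.
    ``cbfv_shift`` raises the hypercapnic CBFV operating point, the
    well-known vasodilatory effect of CO2.
    """

    n: int = 45
    baseline_mean: float = 5.9
    baseline_sd: float = 1.5
    hypercapnia_mean: float = 2.5
    hypercapnia_sd: float = 1.2
    cbfv_shift: float = 8.0
    seed: int = 0
    subject_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("cohort needs at least 2 subjects")


@dataclass
class SyntheticRecording:
    """A generated paired recording plus its ground truth."""

    time: np.ndarray
    bp: UniformSignal
    cbfv: UniformSignal
    beat_times: np.ndarray
    ari_true: float
    config: SyntheticSubjectConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "bp_mmhg": self.bp.values, "cbfv_cm_s": self.cbfv.values}
        )

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df["beat"] = np.isin(
            np.round(self.time, 9), np.round(self.beat_times, 9)
        ).astype(int)
        df.to_csv(path, index=False, float_format="%.6f")


def generate_bp(cfg: SyntheticSubjectConfig, rng: np.random.Generator | None = None) -> UniformSignal:
    """Band-limited spontaneous pressure variability.

    White Gaussian noise band-passed to 0.015-0.25 Hz plus a 0.1 Hz
    Mayer-wave sinusoid, rescaled to ``bp_sd`` and recentred exactly on
    ``bp_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.rate)) + 1
    white = rng.standard_normal(n + 2 * int(cfg.rate * 60))
    sos = _sig.butter(2, [0.015, 0.25], btype="band", fs=cfg.rate, output="sos")
    slow = _sig.sosfilt(sos, white)[-n:]  # discard the filter transient
    t = np.arange(n) / cfg.rate
    mayer = np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    x = slow / slow.std() + cfg.mayer_amp * mayer
    x = (x - x.mean()) / x.std() * cfg.bp_sd + cfg.bp_mean
    return UniformSignal(x, rate=cfg.rate, unit="mmHg")


def _highpass_flow(bp: UniformSignal, grade: float, cbfv_base: float) -> UniformSignal:
    """First-order high-pass surrogate for autoregulated flow.

    The corner frequency rises with grade: better autoregulation rejects
    slower pressure fluctuations. Grade 0 degenerates to the passive
    (all-pass) response.
    """
    dp = (bp.values - bp.values.mean()) / (bp.values.mean() - 12.0)
    if grade <= 0:
        out = dp
    else:
        fc = 0.005 * 2.0 ** (grade / 1.5)  # Hz; ~0.005 -> ~0.32 across grades
        sos = _sig.butter(1, fc, btype="high", fs=bp.rate, output="sos")
        out = _sig.sosfilt(sos, dp)
    return UniformSignal(cbfv_base * (1.0 + out), rate=bp.rate, unit="cm/s")


def generate_subject(
    cfg: SyntheticSubjectConfig, out_path: str | Path | None = None
) -> SyntheticRecording:
    """Simulate one paired BP-CBFV recording at a known grade.

    CBFV is the forward-model response to the simulated pressure at
    ``ari_true`` plus white noise of SD ``noise_sd * cbfv_base``. Beat
    markers are laid down at ~1 s intervals with 5% timing jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    bp = generate_bp(cfg, rng)
    if cfg.model == "tiecks":
        params = interpolate_parameters(cfg.ari_true)
        cbfv = tiecks_forward(bp, params, (cfg.bp_mean, cfg.cbfv_base))
    elif cfg.model == "highpass":
        cbfv = _highpass_flow(bp, cfg.ari_true, cfg.cbfv_base)
    else:
        raise ParameterError(f"unknown forward model {cfg.model!r}")
    noisy = cbfv.values + rng.standard_normal(len(cbfv)) * cfg.noise_sd * cfg.cbfv_base
    cbfv = cbfv.with_values(noisy)

    t = bp.times
    ibis = np.clip(1.0 + 0.05 * rng.standard_normal(int(cfg.duration) + 2), 0.5, 1.8)
    beat_times = np.cumsum(ibis)
    beat_times = beat_times[beat_times < t[-1]]
    # snap markers to the sample grid so they survive a CSV round trip
    beat_times = np.round(beat_times * cfg.rate) / cfg.rate

    rec = SyntheticRecording(
        time=t, bp=bp, cbfv=cbfv, beat_times=beat_times, ari_true=cfg.ari_true, config=cfg
    )
    if out_path is not None:
        rec.write(out_path)
    return rec


def _truncnorm(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (9.0 - mean) / sd
    return _stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    cfg: SyntheticCohortConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Simulate a paired cohort and return its ground-truth manifest.

    Each subject gets one baseline and one hypercapnia recording with
    grades drawn from the configured truncated normals. When ``out_dir``
    is given, recordings are written as CSV files next to a
    ``manifest.csv``/``manifest.json`` mapping file to true grade; the
    manifest also carries a ``recording`` column holding the in-memory
    object when no directory is given.
    """
    rng = np.random.default_rng(cfg.seed)
    grades_b = _truncnorm(cfg.baseline_mean, cfg.baseline_sd, cfg.n, rng)
    grades_h = _truncnorm(cfg.hypercapnia_mean, cfg.hypercapnia_sd, cfg.n, rng)
    seeds = rng.integers(0, 2**31 - 1, size=2 * cfg.n)

    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n):
        for cond, grade, seed in (
            ("baseline", grades_b[i], seeds[2 * i]),
            ("hypercapnia", grades_h[i], seeds[2 * i + 1]),
        ):
            kwargs = dict(cfg.subject_kwargs)
            if cond == "hypercapnia":
                kwargs["cbfv_base"] = kwargs.get("cbfv_base", 57.4) + cfg.cbfv_shift
            scfg = SyntheticSubjectConfig(ari_true=float(grade), seed=int(seed), **kwargs)
            fname = f"subject{i:03d}_{cond}.csv"
            rec = generate_subject(scfg, out_dir / fname if out_dir else None)
            rows.append(
                {
                    "subject": i,
                    "condition": cond,
                    "file": fname,
                    "ari_true": float(grade),
                    "seed": int(seed),
                    "recording": None if out_dir else rec,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.drop(columns="recording").to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(
                {
                    "n": cfg.n,
                    "seed": cfg.seed,
                    "baseline": [cfg.baseline_mean, cfg.baseline_sd],
                    "hypercapnia": [cfg.hypercapnia_mean, cfg.hypercapnia_sd],
                },
                indent=2,
            )
        )
    return manifest
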