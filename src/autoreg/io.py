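"""CSV readers and writers for recordings and per-subject tables.

Recordings are plain CSV with a time column (seconds), BP (mmHg), CBFV
(cm/s) and optionally EtCO2 (mmHg) and a 0/1 beat-marker column.
Columns are resolved by name (a tolerant keyword match) or, failing
that, by position. Per-subject tables — transfer function coefficients,
step responses, and model hyper-parameters, as typically distributed as
supplementary material — arrive in unknown dialects, so the reader
sniffs the delimiter and the orientation (subjects as rows vs columns)
and normalizes everything to subjects-as-rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import DataError, UniformSignal

__all__ = [
    "FormatError",
    "Recording",
    "SupplementaryTable",
    "read_recording",
    "write_recording",
    "read_supplementary",
    "write_supplementary",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as the expected format."""


# keyword fragments used to resolve columns by name (case-insensitive)
_COLUMN_KEYS = {
    "time": ("time", "t_s", "sec"),
    "bp": ("bp", "abp", "pressure", "mmhg_bp"),
    "cbfv": ("cbfv", "fv", "velocity", "flow"),
    "etco2": ("etco2", "co2"),
    "beat": ("beat", "marker", "rpeak"),
}


@dataclass
class Recording:
    """A validated paired recording.

    ``rate`` is the uniform sampling rate in Hz, or ``None`` for
    beat-annotated (irregular) series.
    """

    time: np.ndarray
    bp: np.ndarray
    cbfv: np.ndarray
    etco2: np.ndarray | None = None
    beat_times: np.ndarray | None = None
    rate: float | None = None
    path: str = ""

    def bp_signal(self) -> UniformSignal:
        if self.rate is None:
            raise DataError("recording is not uniformly sampled")
        return UniformSignal(self.bp, rate=self.rate, unit="mmHg", t0=float(self.time[0]))

    def cbfv_signal(self) -> UniformSignal:
        if self.rate is None:
            raise DataError("recording is not uniformly sampled")
        return UniformSignal(self.cbfv, rate=self.rate, unit="cm/s", t0=float(self.time[0]))


def _resolve(columns: list[str], role: str) -> str | None:
    for col in columns:
        low = col.strip().lower()
        if any(key in low for key in _COLUMN_KEYS[role]):
            return col
    return None


def read_recording(
    path: str | Path, columns: dict[str, str] | None = None
) -> Recording:
    """Read and validate a recording CSV.

    ``columns`` may map roles (``time``, ``bp``, ``cbfv``, ``etco2``,
    ``beat``) to explicit column names, overriding name matching. When
    names resolve nothing, the first three columns are taken as time,
    BP, CBFV in that order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least time, BP and CBFV columns")

    columns = columns or {}
    names = list(df.columns)
    resolved = {}
    for role in ("time", "bp", "cbfv", "etco2", "beat"):
        resolved[role] = columns.get(role) or _resolve(names, role)
    if resolved["time"] is None and resolved["bp"] is None and resolved["cbfv"] is None:
        resolved["time"], resolved["bp"], resolved["cbfv"] = names[:3]
    for role in ("time", "bp", "cbfv"):
        if resolved[role] is None or resolved[role] not in names:
            raise FormatError(f"{path}: cannot resolve the {role} column")

    t = df[resolved["time"]].to_numpy(dtype=float)
    bp = df[resolved["bp"]].to_numpy(dtype=float)
    cbfv = df[resolved["cbfv"]].to_numpy(dtype=float)
    for role, arr in (("bp", bp), ("cbfv", cbfv), ("time", t)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise DataError(f"{path}: non-finite {role} value at row {int(bad[0])}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise DataError(f"{path}: time not strictly increasing at row {row}")

    etco2 = None
    if resolved["etco2"] in names:
        etco2 = df[resolved["etco2"]].to_numpy(dtype=float)
    beat_times = None
    if resolved["beat"] in names:
        beat_times = t[df[resolved["beat"]].to_numpy() > 0]

    rate = None
    if dt.size and np.allclose(dt, dt.mean(), rtol=0, atol=1e-6 * dt.mean()):
        rate = 1.0 / float(dt.mean())
    return Recording(
        time=t, bp=bp, cbfv=cbfv, etco2=etco2, beat_times=beat_times, rate=rate,
        path=str(path),
    )


def write_recording(path: str | Path, rec: Recording) -> None:
    data = {"time_s": rec.time, "bp_mmhg": rec.bp, "cbfv_cm_s": rec.cbfv}
    if rec.etco2 is not None:
        data["etco2_mmhg"] = rec.etco2
    if rec.beat_times is not None:
        data["beat"] = np.isin(
            np.round(rec.time, 9), np.round(rec.beat_times, 9)
        ).astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class SupplementaryTable:
    """A normalized per-subject table (always subjects as rows)."""

    kind: str  # tf_coefficients | step_responses | hyper_parameters
    records: pd.DataFrame  # one row per subject
    condition: str = ""  # baseline | hypercapnia | ""
    structure: str = ""  # NFIR | NAR | ""

    def __post_init__(self) -> None:
        if self.kind not in ("tf_coefficients", "step_responses", "hyper_parameters"):
            raise FormatError(f"unknown table kind {self.kind!r}")
        idx = self.records.index
        if idx.has_duplicates:
            raise DataError("subject identifiers must be unique")

    @property
    def responses(self) -> np.ndarray:
        """Step responses as a (subjects, samples) array."""
        if self.kind != "step_responses":
            raise FormatError("not a step-response table")
        return self.records.to_numpy(dtype=float)


def _looks_like_labels(values) -> bool:
    """True when a header/index looks like subject identifiers."""
    try:
        np.asarray(values, dtype=float)
    except (TypeError, ValueError):
        return True
    return False


def read_supplementary(
    path: str | Path,
    kind: str | None = None,
    orientation: str = "auto",
    condition: str = "",
    structure: str = "",
) -> SupplementaryTable:
    """Read a per-subject table of unknown dialect.

    The delimiter is sniffed. ``orientation`` decides whether subjects
    occupy rows or columns; ``"auto"`` keeps labelled axes as subjects
    and otherwise assumes subjects-as-rows unless the table is much
    taller than wide. When the two readings stay genuinely ambiguous,
    an error asks for an explicit ``orientation``. Rows that are
    entirely empty (e.g. subjects for which no model was accepted) are
    dropped rather than treated as an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")

    if kind is None:
        joined = " ".join(str(c).lower() for c in df.columns)
        if "gain" in joined or "phase" in joined:
            kind = "tf_coefficients"
        elif any(k in joined for k in ("c", "nu", "gamma")) and df.shape[1] <= 8:
            kind = "hyper_parameters"
        else:
            kind = "step_responses"

    subj_rows = _looks_like_labels(df.index.to_numpy())
    subj_cols = _looks_like_labels(np.asarray(df.columns))
    if orientation == "auto":
        if subj_rows and not subj_cols:
            orientation = "rows"
        elif subj_cols and not subj_rows:
            orientation = "columns"
        elif df.shape[0] > 3 * df.shape[1]:
            orientation = "columns" if kind == "step_responses" else "rows"
        elif df.shape[1] > 3 * df.shape[0]:
            orientation = "rows"
        elif kind == "step_responses" and subj_rows and subj_cols:
            # labelled on both axes: samples usually outnumber subjects
            orientation = "rows" if df.shape[1] >= df.shape[0] else "columns"
        elif kind in ("tf_coefficients", "hyper_parameters"):
            orientation = "rows"
        else:
            raise FormatError(
                f"{path}: cannot decide table orientation; pass orientation="
                "'rows' or 'columns'"
            )
    if orientation == "columns":
        df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    df = df.dropna(how="all")
    if df.empty:
        raise FormatError(f"{path}: no numeric records")
    if kind == "step_responses" and df.isna().any().any():
        raise DataError(f"{path}: step-response rows differ in length")
    return SupplementaryTable(
        kind=kind, records=df, condition=condition, structure=structure
    )


def write_supplementary(path: str | Path, table: SupplementaryTable) -> None:
    table.records.to_csv(path)
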