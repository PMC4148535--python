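"""CSV / YAML interchange for recordings, angle series and parameter sets.

Column conventions
------------------
* EMG CSV: one header row of channel labels, one column per channel, one
  row per sample; an optional leading ``time_s`` column is ignored on read
  and written on request.
* Angle CSV: ``time_s`` column plus one column per DOF label, degrees.
* Marker CSV: ``time_s`` plus ``<marker>_x, <marker>_y, <marker>_z`` (mm).
* ActivationParams YAML stores only {gamma1, gamma2, d_seconds, A}; the
  derived filter coefficients are always recomputed on load so the
  constraint equations remain the single source of truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activation import ActivationParams
from .preprocess import EmgRecording, JointAngleSeries, MarkerTrajectories

__all__ = [
    "read_emg_csv", "write_emg_csv",
    "read_angles_csv", "write_angles_csv",
    "read_markers_csv", "write_markers_csv",
    "load_params_yaml", "save_params_yaml",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate header column(s) {dup}")
    if any(str(c).startswith("Unnamed") for c in df.columns):
        raise ValueError(f"{path}: missing or incomplete header row")

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    if all(_is_number(str(c)) for c in df.columns):
        raise ValueError(f"{path}: header row looks numeric — missing header?")
    body = df.drop(columns=["time_s"], errors="ignore")
    non_numeric = body.columns[
        [not np.issubdtype(dt, np.number) for dt in body.dtypes]
    ].tolist()
    if non_numeric:
        raise ValueError(f"{path}: non-numeric cells in column(s) {non_numeric}")
    if body.isna().any().any():
        row = int(body.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: ragged/missing value near line {row + 2}")
    return df


def read_emg_csv(path: str | Path, fs: float,
                 expected_labels: list[str] | None = None) -> EmgRecording:
    df = _read_table(path)
    labels = [c for c in df.columns if c != "time_s"]
    if expected_labels is not None and labels != list(expected_labels):
        raise ValueError(
            f"{path}: channel labels {labels} do not match configured "
            f"{list(expected_labels)}"
        )
    return EmgRecording(df[labels].to_numpy().T, fs, labels)


def write_emg_csv(path: str | Path, rec: EmgRecording, time_column: bool = True) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    if time_column:
        df.insert(0, "time_s", np.arange(rec.n_samples) / rec.fs)
    df.to_csv(path, index=False, float_format="%.17g")


def read_angles_csv(path: str | Path, fs: float) -> JointAngleSeries:
    df = _read_table(path)
    labels = [c for c in df.columns if c != "time_s"]
    return JointAngleSeries(df[labels].to_numpy().T, labels, fs)


def write_angles_csv(path: str | Path, angles: JointAngleSeries) -> None:
    df = pd.DataFrame(angles.angles.T, columns=angles.dof_labels)
    df.insert(0, "time_s", np.arange(angles.angles.shape[1]) / angles.fs)
    df.to_csv(path, index=False, float_format="%.17g")


def read_markers_csv(path: str | Path, fs: float) -> MarkerTrajectories:
    df = _read_table(path)
    cols = [c for c in df.columns if c != "time_s"]
    names: list[str] = []
    for c in cols:
        if not c.endswith(("_x", "_y", "_z")):
            raise ValueError(f"{path}: marker column {c!r} lacks _x/_y/_z suffix")
        base = c[:-2]
        if base not in names:
            names.append(base)
    pos = np.stack(
        [df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy() for m in names]
    )
    return MarkerTrajectories(pos, fs, names)


def write_markers_csv(path: str | Path, markers: MarkerTrajectories) -> None:
    data = {"time_s": np.arange(markers.positions.shape[1]) / markers.fs}
    for i, m in enumerate(markers.marker_labels):
        for j, ax in enumerate("xyz"):
            data[f"{m}_{ax}"] = markers.positions[i, :, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def save_params_yaml(path: str | Path, p: ActivationParams) -> None:
    Path(path).write_text(yaml.safe_dump({
        "gamma1": float(p.gamma1), "gamma2": float(p.gamma2),
        "d_seconds": float(p.d), "A": float(p.A),
    }))


def load_params_yaml(path: str | Path) -> ActivationParams:
    raw = yaml.safe_load(Path(path).read_text())
    extra = set(raw) - {"gamma1", "gamma2", "d_seconds", "A"}
    if extra:
        raise ValueError(f"{path}: unknown keys {sorted(extra)}")
    return ActivationParams(raw["gamma1"], raw["gamma2"], raw["d_seconds"], raw["A"])
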