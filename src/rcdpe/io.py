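"""Readers, writers and study configuration.

Canonical formats: WAV for signals (float64 PCM so round trips are
bit-exact), comma-delimited text for tables, and a flat ``key = value``
file for configuration.  Every results directory carries the resolved
configuration and a JSON manifest of the files written, so a run can be
audited or repeated from its own output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthetic import CohortSpec, FatigueSubject
from .types import Signal

__all__ = [
    "StudyConfig",
    "read_signal",
    "write_signal",
    "write_results",
    "save_cohort",
    "load_cohort",
]


def read_signal(path: str | Path, fs_override: float | None = None, label: str = "") -> Signal:
    """Load a signal from WAV or delimited text.

    WAV files carry their own sampling rate (``fs_override`` wins if
    given).  Text files — one value per line, or two columns
    ``time,value`` with an optional header — have no rate, so
    ``fs_override`` is required.
    """
    path = Path(path)
    if not label:
        label = path.stem
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        return Signal(np.asarray(data, dtype=np.float64), fs_override or float(rate), label=label)

    if fs_override is None:
        raise ValueError(f"{path}: text input carries no sampling rate; pass fs_override")
    values = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        parts = line.replace(",", " ").replace(";", " ").replace("\t", " ").split()
        try:
            row = [float(p) for p in parts]
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise ValueError(f"{path}: non-numeric row at line {lineno}: {line!r}") from None
        values.append(row[-1])  # last column = value; first may be time
    if not values:
        raise ValueError(f"{path}: no numeric rows found")
    return Signal(np.array(values), fs_override, label=label)


def write_signal(signal: Signal, path: str | Path) -> Path:
    """Write a signal as float64 WAV (lossless round trip) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(signal.fs)), signal.samples)
    else:
        np.savetxt(path, signal.samples, delimiter=",", header="value", comments="")
    return path


@dataclass
class StudyConfig:
    """Resolved parameters of one fatigue-study run."""

    methods: tuple[str, ...] = ("MPE", "rcMPE", "rcDPE")
    dims: tuple[int, ...] = (3, 4, 5)
    scale_min: int = 1
    scale_max: int = 100
    n_windows: int = 4
    normalized: bool = True
    tie_policy: str = "earlier"
    selection_method: str = "rcDPE"
    selection_d: int = 4
    seed: int = 0
    inputs: tuple[str, ...] = ()
    output_dir: str = "results"

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.dims = tuple(int(d) for d in self.dims)
        self.inputs = tuple(self.inputs)
        if self.scale_min < 1 or self.scale_max < self.scale_min:
            raise ValueError("need 1 <= scale_min <= scale_max")
        for d in self.dims:
            if d < 2:
                raise ValueError("dimensions must be >= 2")

    @property
    def scales(self) -> range:
        return range(self.scale_min, self.scale_max + 1)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, (tuple, list)):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key} = {value}\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        kw: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, value = line.partition("=")
                kw[key.strip()] = value.strip()
        conv = {
            "methods": lambda v: tuple(s for s in v.split(",") if s),
            "dims": lambda v: tuple(int(s) for s in v.split(",") if s),
            "inputs": lambda v: tuple(s for s in v.split(",") if s),
            "scale_min": int,
            "scale_max": int,
            "n_windows": int,
            "selection_d": int,
            "seed": int,
            "normalized": lambda v: v.lower() in ("true", "1", "yes"),
        }
        return cls(**{k: conv.get(k, str)(v) for k, v in kw.items() if k in cls.__dataclass_fields__})


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def write_results(result, out_dir: str | Path, config: StudyConfig | None = None) -> Path:
    """Serialize a FatigueStudyResult: tables, config, JSON manifest.

    Returns the manifest path; the manifest enumerates exactly the files
    written, plus the selected scale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    _write_table(result.profiles, out / "profiles.csv")
    written.append("profiles.csv")
    _write_table(result.deltas.table, out / "deltas.csv")
    written.append("deltas.csv")
    for group, tables in (("deltas", result.anova_deltas), ("windows", result.anova_windows)):
        for name, frame in tables.items():
            fname = f"anova_{group}_{name}.csv"
            _write_table(frame.reset_index(), out / fname)
            written.append(fname)
    if config is not None:
        config.to_file(out / "study_config.cfg")
        written.append("study_config.cfg")

    manifest = {
        "selected_scale": int(result.selected_scale),
        "selection_method": result.selection_method,
        "selection_d": int(result.selection_d),
        "files": sorted(written),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def save_cohort(
    cohort: Sequence[FatigueSubject],
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    fmt: str = "wav",
) -> Path:
    """Write one signal file per subject plus a key-value manifest."""
    if fmt not in ("wav", "csv"):
        raise ValueError("fmt must be 'wav' or 'csv'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    if spec is not None:
        for key, value in asdict(spec).items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            lines.append(f"spec.{key} = {value}")
    for subj in cohort:
        fname = f"{subj.subject_id}.{fmt}"
        write_signal(subj.signal, out / fname)
        bounds = ";".join(f"{a}:{b}" for a, b in subj.window_bounds)
        lines.append(f"subject.{subj.subject_id}.file = {fname}")
        lines.append(f"subject.{subj.subject_id}.fs = {subj.signal.fs:g}")
        lines.append(f"subject.{subj.subject_id}.windows = {bounds}")
    manifest = out / "cohort_manifest.cfg"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_cohort(manifest_path: str | Path) -> list[FatigueSubject]:
    """Re-load a cohort written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    entries: dict[str, dict[str, str]] = {}
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line.startswith("subject."):
            continue
        key, _, value = line.partition("=")
        _, sid, attr = key.strip().split(".", 2)
        entries.setdefault(sid, {})[attr] = value.strip()
    cohort = []
    for sid, attrs in entries.items():
        sig = read_signal(base / attrs["file"], fs_override=float(attrs["fs"]), label=sid)
        bounds = [tuple(int(x) for x in b.split(":")) for b in attrs["windows"].split(";")]
        cohort.append(
            FatigueSubject(subject_id=sid, signal=sig, window_bounds=bounds, seed_entropy=0)
        )
    return cohort
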