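"""EEG recording container and on-disk formats.

A recording is a channels x samples matrix (microvolt), its sampling rate,
10-20 channel labels, 3-D electrode positions (mm, sphere frame) and subject
metadata.  Serialization is a numeric matrix (``.npy`` or ``.csv``) plus a
JSON sidecar; EDF files can be read through mne.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class EEGRecording:
    data: np.ndarray  # (n_channels, n_samples), microvolt
    fs: float
    labels: list[str]
    positions: dict[str, np.ndarray]
    subject_id: str = "unknown"
    group: str = "unknown"  # "R", "NR" or "unknown"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("row count must match number of channel labels")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN/Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[lb] for lb in self.labels], dtype=float)

    def copy_with(self, **kw) -> "EEGRecording":
        if "log" not in kw:
            kw["log"] = list(self.log)
        return replace(self, **kw)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path, fmt: str = "npy") -> Path:
        """Write ``<path>.npy``/``.csv`` and ``<path>.json`` sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "npy":
            mat = path.with_suffix(".npy")
            np.save(mat, self.data)
        elif fmt == "csv":
            mat = path.with_suffix(".csv")
            np.savetxt(mat, self.data, delimiter=",")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        sidecar = {
            "fs": self.fs,
            "labels": self.labels,
            "positions": {k: list(map(float, v)) for k, v in self.positions.items()},
            "subject_id": self.subject_id,
            "group": self.group,
            "log": self.log,
            "matrix": mat.name,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return mat

    @classmethod
    def load(cls, path: str | Path) -> "EEGRecording":
        path = Path(path)
        if path.suffix.lower() == ".edf":
            return cls._load_edf(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        mat = path.parent / sidecar["matrix"]
        if mat.suffix == ".npy":
            data = np.load(mat)
        else:
            data = np.loadtxt(mat, delimiter=",")
        return cls(
            data=data,
            fs=sidecar["fs"],
            labels=list(sidecar["labels"]),
            positions={k: np.array(v) for k, v in sidecar["positions"].items()},
            subject_id=sidecar.get("subject_id", path.stem),
            group=sidecar.get("group", "unknown"),
            log=list(sidecar.get("log", [])),
        )

    @classmethod
    def _load_edf(cls, path: Path) -> "EEGRecording":
        import mne

        from .montage import standard_montage_32

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fwd = standard_montage_32()
        labels = [ch for ch in raw.ch_names]
        positions = {lb: fwd.positions[lb] for lb in labels if lb in fwd.positions}
        return cls(
            data=raw.get_data() * 1e6,  # V -> uV
            fs=float(raw.info["sfreq"]),
            labels=labels,
            positions=positions,
            subject_id=path.stem,
        )
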