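"""Spherical-head electrode montage for the 32-channel 10-20 recording setup.

Electrode coordinates come from the standard 10-20 template montage shipped
with :mod:`mne`, re-centred by a least-squares sphere fit and projected onto a
single sphere (default radius 85 mm).  The coordinate frame is RAS-like:
+x toward the right ear, +y toward the nasion, +z toward the vertex, origin at
the head (sphere) centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Channel set of a 32-channel 10-20 cap (eWave32-style layout).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

DEFAULT_HEAD_RADIUS_MM = 85.0


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere fit; returns the centre (mm)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


@dataclass(frozen=True)
class ForwardModel:
    """Electrode geometry plus the spherical-head assumption.

    Positions are in mm on a sphere of ``head_radius`` centred at the origin.
    The lead field itself (single-sphere analytic dipole projection) lives in
    :mod:`rtmspredict.forward`.
    """

    positions: dict[str, np.ndarray]
    head_radius: float = DEFAULT_HEAD_RADIUS_MM
    labels: tuple[str, ...] = field(default=CHANNELS_32)

    def position_array(self, labels: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.array([self.positions[lb] for lb in labels], dtype=float)

    def subset(self, labels: list[str]) -> "ForwardModel":
        return ForwardModel(
            positions={lb: self.positions[lb] for lb in labels},
            head_radius=self.head_radius,
            labels=tuple(labels),
        )


def standard_montage_32(head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> ForwardModel:
    """Build the 32-channel 10-20 montage on a sphere.

    Returns a deterministic :class:`ForwardModel` whose 32 electrode positions
    (including F3 and AF3, the DLPFC landmarks) all lie on a sphere of
    ``head_radius`` mm centred at the origin.
    """
    # the template name changed upstream; accept either
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            mont = mne.channels.make_standard_montage("standard_1020")
        except ValueError:  # pragma: no cover - newer mne
            mont = mne.channels.make_standard_montage("colin27_1020")
    ch_pos = mont.get_positions()["ch_pos"]
    raw = np.array([ch_pos[lb] for lb in CHANNELS_32]) * 1000.0  # m -> mm
    center = _fit_sphere_center(raw)
    centered = raw - center
    on_sphere = centered * (head_radius / np.linalg.norm(centered, axis=1, keepdims=True))
    positions = {lb: on_sphere[i] for i, lb in enumerate(CHANNELS_32)}
    return ForwardModel(positions=positions, head_radius=head_radius)
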