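"""ICA decomposition and DLPFC region-of-interest component selection.

The stimulation target (left DLPFC) is localized in electrode space as the
midpoint of F3 and AF3, pulled inward to a cortical shell, and surrounded by
a flat cylinder (radius 25 mm, thickness 2.5 mm, axis radial) that plays the
role of the cortical patch of interest.  Components whose equivalent dipole
falls inside that cylinder - with the axial tolerance relaxed in logged 1-mm
steps when the fit scatter demands it - are retained, ordered by the fraction
of scalp-signal variance they explain (their weight, lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .forward import fit_dipole
from .montage import DEFAULT_HEAD_RADIUS_MM
from .recording import EEGRecording

DEFAULT_CORTICAL_SHELL = 0.85  # fraction of head radius
DEFAULT_ROI_RADIUS_MM = 25.0
DEFAULT_ROI_THICKNESS_MM = 2.5


class NoRoiComponentError(RuntimeError):
    """No component dipole falls in the ROI even at maximal axial slack."""


@dataclass(frozen=True)
class ROICylinder:
    """DLPFC region of interest: a thin disk on the cortical shell."""

    center: np.ndarray  # mm
    axis: np.ndarray  # unit vector, radial
    radius: float = DEFAULT_ROI_RADIUS_MM
    half_thickness: float = DEFAULT_ROI_THICKNESS_MM / 2.0

    def contains(self, point: np.ndarray, axial_slack: float = 0.0) -> bool:
        v = np.asarray(point, dtype=float) - self.center
        axial = float(v @ self.axis)
        radial = float(np.linalg.norm(v - axial * self.axis))
        return radial <= self.radius and abs(axial) <= self.half_thickness + axial_slack


def roi_from_montage(
    positions: dict[str, np.ndarray],
    side: str = "left",
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    shell_fraction: float = DEFAULT_CORTICAL_SHELL,
    radius: float = DEFAULT_ROI_RADIUS_MM,
    thickness: float = DEFAULT_ROI_THICKNESS_MM,
) -> ROICylinder:
    """Cylinder ROI centred on the (scalp) midpoint of F3/AF3, projected to
    the cortical shell.  ``side='right'`` mirrors to F4/AF4."""
    pair = ("F3", "AF3") if side == "left" else ("F4", "AF4")
    for lb in pair:
        if lb not in positions:
            raise KeyError(f"missing landmark electrode {lb!r}")
    mid = (np.asarray(positions[pair[0]]) + np.asarray(positions[pair[1]])) / 2.0
    axis = mid / np.linalg.norm(mid)
    center = axis * shell_fraction * head_radius
    return ROICylinder(center=center, axis=axis, radius=radius, half_thickness=thickness / 2.0)


@dataclass
class ComponentSet:
    """ICA result: maps, sources, weights, dipoles and the selected subset."""

    mixing: np.ndarray  # channels x components, unit-norm columns
    unmixing: np.ndarray  # components x channels
    series: np.ndarray  # components x samples (microvolt-scaled)
    lambda_weight: np.ndarray  # variance fraction per component, descending
    fs: float
    labels: list[str]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    dipole_locations: np.ndarray | None = None  # components x 3, mm
    dipole_gof: np.ndarray | None = None
    selected: list[int] = field(default_factory=list)
    selection_slack_mm: float = 0.0
    selection_fallback: int = 0  # components taken from outside the ROI

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def selected_series(self) -> np.ndarray:
        return self.series[self.selected]

    def fit_dipoles(self, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> "ComponentSet":
        pos = np.array([self.positions[lb] for lb in self.labels])
        locs, gofs = [], []
        for i in range(self.n_components):
            f = fit_dipole(self.mixing[:, i], pos, head_radius)
            locs.append(f.location)
            gofs.append(f.gof)
        self.dipole_locations = np.array(locs)
        self.dipole_gof = np.array(gofs)
        return self

    def report(self) -> list[dict]:
        out = []
        for i in range(self.n_components):
            out.append(
                {
                    "component": i,
                    "lambda": float(self.lambda_weight[i]),
                    "dipole_mm": None
                    if self.dipole_locations is None
                    else [float(v) for v in self.dipole_locations[i]],
                    "gof": None if self.dipole_gof is None else float(self.dipole_gof[i]),
                    "selected": i in self.selected,
                }
            )
        return out


def decompose(
    recording: EEGRecording,
    n_components: int | None = None,
    seed: int = 0,
    algorithm: str = "extended-infomax",
    max_iter: int = 200,
) -> ComponentSet:
    """ICA of a preprocessed recording.

    PCA-whitens to ``n_components`` (rank-reduced with a warning if the data
    are rank deficient, e.g. after average referencing) and runs extended
    infomax (default) or FastICA.  Component series are scaled so that each
    unit-norm scalp map times its series reproduces the back-projection in
    microvolt; ``lambda_weight`` is the fraction of total channel variance
    each component explains, and components are ordered by it, descending.
    """
    X = recording.data - recording.data.mean(axis=1, keepdims=True)
    n_ch, n_samp = X.shape
    if n_components is None:
        n_components = min(n_ch, 20)
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed channel count")

    cov = X @ X.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > evals[0] * 1e-10).sum())
    if rank < n_components:
        warnings.warn(
            f"rank-deficient data (rank {rank}); reducing to {rank} components",
            RuntimeWarning,
        )
        n_components = rank
    keep = slice(0, n_components)
    W_white = (evecs[:, keep] / np.sqrt(evals[keep])).T  # k x ch
    Z = W_white @ X

    if algorithm == "extended-infomax":
        from mne.preprocessing import infomax

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                W = infomax(Z.T, extended=True, max_iter=max_iter,
                            rng=np.random.RandomState(seed), verbose="error")
            except TypeError:  # older mne spells the argument random_state
                W = infomax(Z.T, extended=True, max_iter=max_iter,
                            random_state=np.random.RandomState(seed), verbose="error")
        unmixing = W @ W_white
    elif algorithm == "fastica":
        from sklearn.decomposition import FastICA

        # Deflation avoids the symmetric variant's occasional convergence
        # stalls on envelope-modulated rhythms and is faster here.  Two
        # seeded starts guard against spurious fixed points: a solution that
        # leaves sources mixed scores lower total non-Gaussianity.
        best = None
        for attempt, s in enumerate((seed, seed + 101)):
            f = FastICA(whiten=False, random_state=s, max_iter=max_iter,
                        algorithm="deflation")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f.fit(Z.T)
            U = f.components_
            y = U @ Z
            y = y / y.std(axis=1, keepdims=True)
            score = float(np.abs((y**4).mean(axis=1) - 3.0).sum())
            if best is None or score > best[0]:
                best = (score, U)
        unmixing = best[1] @ W_white
    else:
        raise ValueError(f"unknown ICA algorithm {algorithm!r}")

    series = unmixing @ X
    mixing = np.linalg.pinv(unmixing)
    # move scalp-map scale into the series so the series is microvolt-like
    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    mixing = mixing / norms
    series = series * norms[:, None]

    total_var = float((X**2).sum() / n_samp)
    lam = series.var(axis=1) / total_var  # unit-norm maps: back-projected variance
    order = np.argsort(lam)[::-1]
    return ComponentSet(
        mixing=mixing[:, order],
        unmixing=(unmixing * norms[:, None])[order],
        series=series[order],
        lambda_weight=lam[order],
        fs=recording.fs,
        labels=list(recording.labels),
        positions=dict(recording.positions),
    )


def select_dlpfc_components(
    cs: ComponentSet,
    roi: ROICylinder,
    n: int = 3,
    base_axial_slack_mm: float = 10.0,
    max_axial_slack_mm: float = 30.0,
    min_gof: float = 0.0,
    min_lambda: float = 0.0,
) -> ComponentSet:
    """Keep the ``n`` highest-weight components whose dipole sits in the ROI.

    The cylinder's 1.25-mm axial half-thickness is far tighter than
    single-dipole localization scatter, so the axial tolerance starts at
    ``base_axial_slack_mm`` (the localization uncertainty) and is relaxed in
    1-mm steps (final value logged in ``selection_slack_mm``) until ``n``
    components qualify; qualifying components are then ordered by lambda.
    Optional quality gates drop components whose dipole fit is flagged
    (``gof < min_gof``) or whose weight is negligible (``lambda <
    min_lambda``).  Raises :class:`NoRoiComponentError` if none qualify at
    maximal slack.
    """
    if cs.dipole_locations is None:
        cs.fit_dipoles()
    candidates = [
        i
        for i in range(cs.n_components)
        if cs.dipole_gof[i] >= min_gof and cs.lambda_weight[i] >= min_lambda
    ]
    if not candidates:  # all maps flagged: fall back to every component
        candidates = list(range(cs.n_components))
    slack = float(base_axial_slack_mm)
    chosen: list[int] = []
    while slack <= max_axial_slack_mm:
        chosen = [
            i for i in candidates if roi.contains(cs.dipole_locations[i], axial_slack=slack)
        ]
        if len(chosen) >= n:
            break
        slack += 1.0
    if not chosen:
        raise NoRoiComponentError(
            f"no component dipole inside ROI within {max_axial_slack_mm} mm axial slack"
        )
    chosen.sort(key=lambda i: -cs.lambda_weight[i])
    chosen = chosen[:n]
    n_fallback = 0
    if len(chosen) < n:
        # ROI under-populated for this decomposition: fill with the spatially
        # closest remaining components so downstream stages see n series.
        def roi_distance(i: int) -> float:
            v = cs.dipole_locations[i] - roi.center
            axial = float(v @ roi.axis)
            radial = float(np.linalg.norm(v - axial * roi.axis))
            return max(radial - roi.radius, 0.0) + max(abs(axial) - roi.half_thickness, 0.0)

        rest = sorted((i for i in candidates if i not in chosen), key=roi_distance)
        if len(chosen) + len(rest) < n:
            rest += sorted(
                (i for i in range(cs.n_components) if i not in chosen and i not in rest),
                key=roi_distance,
            )
        n_fallback = n - len(chosen)
        chosen = chosen + rest[:n_fallback]
    return replace(
        cs,
        selected=chosen,
        selection_slack_mm=min(slack, max_axial_slack_mm),
        selection_fallback=n_fallback,
    )
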