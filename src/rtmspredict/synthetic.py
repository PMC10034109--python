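"""Synthetic EEG cohort generator with ground-truth group contrasts.

Each subject's scalp EEG is built from dipolar cortical sources projected to
32 channels through the single-sphere forward model, plus sensor noise,
50 Hz line noise and optional high-variance bad channels.  Group differences
(responder R vs non-responder NR) are injected at the *source* level so that
preprocessing, ICA, ROI selection and feature extraction are all on the
causal path:

* an alpha-band (8-12 Hz) DLPFC source, stronger in R,
* a beta-band (12-24 Hz) DLPFC source, stronger in NR,
* a quadratically phase-coupled triplet (6, 10, 16 Hz) DLPFC source whose
  coupling strength and broadband-noise admixture ("complexity") differ by
  group,

consistent with the direction of published pretreatment markers (higher beta
power and lower alpha power in non-responders, complexity differences).

Band-limited sources are amplitude-modulated by a slow positive envelope so
their marginals are super-Gaussian and separable by ICA, as bursty EEG
rhythms are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .components import roi_from_montage
from .forward import sphere_leadfield
from .montage import ForwardModel, standard_montage_32
from .recording import EEGRecording

WAVEFORM_KINDS = ("band_limited_noise", "coupled_triplet", "ar_process")


@dataclass(frozen=True)
class SourceSpec:
    """One dipolar source: where it sits, which way it points, what it emits."""

    dipole_location: np.ndarray  # mm, head frame
    orientation: np.ndarray  # unit vector
    waveform_kind: str
    band: tuple[float, float]
    amplitude: float  # microvolt-equivalent scalp RMS scale
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dipole_location", np.asarray(self.dipole_location, float))
        ori = np.asarray(self.orientation, float)
        n = np.linalg.norm(ori)
        if n == 0:
            raise ValueError("orientation must be nonzero")
        object.__setattr__(self, "orientation", ori / n)
        if self.waveform_kind not in WAVEFORM_KINDS:
            raise ValueError(f"unknown waveform kind {self.waveform_kind!r}")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy lo < hi")

    def to_dict(self) -> dict:
        return {
            "dipole_location": [float(v) for v in self.dipole_location],
            "orientation": [float(v) for v in self.orientation],
            "waveform_kind": self.waveform_kind,
            "band": [float(self.band[0]), float(self.band[1])],
            "amplitude": float(self.amplitude),
            "params": {k: float(v) for k, v in self.params.items()},
        }


#: Default group contrasts: power ratios, per-group quadratic phase-coupling
#: strength, and per-group white-noise admixture of the coupled source.
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "alpha_power_ratio_r_nr": 2.0,
    "beta_power_ratio_nr_r": 2.0,
    "coupling_r": 0.85,
    "coupling_nr": 0.15,
    "complexity_mix_r": 0.15,
    "complexity_mix_nr": 0.55,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_responders: int = 46
    n_nonresponders: int = 42
    duration_s: float = 300.0
    fs: float = 1000.0
    effect_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    line_noise_amp: float = 5.0  # uV per channel at 50 Hz
    sensor_noise_uv: float = 2.0
    n_bad_channels: int = 1
    n_background_sources: int = 5
    roi_source_amp: float = 10.0  # uV scalp RMS of each DLPFC source
    background_amp: float = 8.0
    subject_sigma: float = 0.25  # log-normal sd of per-subject amplitude scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("group sizes must be >= 1")
        if self.duration_s * self.fs < 3000:
            raise ValueError("need at least 3000 samples per recording")

    @classmethod
    def null(cls, **kw) -> "SyntheticCohortConfig":
        """Config with every group contrast switched off."""
        effects = {
            "alpha_power_ratio_r_nr": 1.0,
            "beta_power_ratio_nr_r": 1.0,
            "coupling_r": 0.5,
            "coupling_nr": 0.5,
            "complexity_mix_r": 0.35,
            "complexity_mix_nr": 0.35,
        }
        return cls(effect_map=effects, **kw)


# --------------------------------------------------------------- waveforms
def _smooth_envelope(
    n: int, fs: float, rng: np.random.Generator, cutoff: float = 0.5, sigma: float = 0.5
) -> np.ndarray:
    """Slow positive envelope with unit mean square, for bursty rhythms.

    ``sigma`` sets the modulation depth (log-amplitude SD); 0 gives a flat
    envelope.  The exponential is re-smoothed so its peaks stay slower than
    ``cutoff`` (exp sharpens Gaussian peaks, which would otherwise smear a
    modulated source's spectrum far outside its band).
    """
    if sigma == 0:
        return np.ones(n)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    e = signal.sosfiltfilt(sos, rng.standard_normal(n))
    env = np.exp(sigma * e / max(e.std(), 1e-12))
    env = np.clip(signal.sosfiltfilt(sos, env), 0.05, None)
    return env / np.sqrt(np.mean(env**2))


def generate_source(
    spec: SourceSpec, n_samples: int, fs: float, rng_seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Zero-mean source time series with RMS = ``spec.amplitude``.

    ``coupled_triplet`` emits tones at f1, f2 and f1+f2 whose phases are
    redrawn every block; the sum-frequency phase equals phase(f1)+phase(f2)
    plus a jitter controlled by ``params['coupling']`` (1 = perfectly coupled,
    0 = random), so the squared normalized bispectrum at (f1, f2) approaches
    1 or 0 respectively.
    """
    if n_samples < 3000:
        raise ValueError("need n_samples >= 3000")
    lo, hi = spec.band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {spec.band} outside (0, fs/2)")
    rng = np.random.default_rng(rng_seed)

    if spec.waveform_kind == "band_limited_noise":
        sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        x = x * _smooth_envelope(n_samples, fs, rng)
    elif spec.waveform_kind == "coupled_triplet":
        f1 = spec.params.get("f1", 6.0)
        f2 = spec.params.get("f2", 10.0)
        c = float(np.clip(spec.params.get("coupling", 1.0), 0.0, 1.0))
        block = int(round(spec.params.get("block_s", 4.0) * fs))
        t = np.arange(n_samples) / fs
        x = np.empty(n_samples)
        for start in range(0, n_samples, block):
            stop = min(start + block, n_samples)
            p1, p2 = rng.uniform(0, 2 * np.pi, 2)
            jitter = (1.0 - c) * rng.uniform(-np.pi, np.pi)
            tt = t[start:stop]
            x[start:stop] = (
                np.cos(2 * np.pi * f1 * tt + p1)
                + np.cos(2 * np.pi * f2 * tt + p2)
                + np.cos(2 * np.pi * (f1 + f2) * tt + p1 + p2 + jitter)
            )
        # a common slow envelope (params["env_sigma"] > 0) ties the three
        # tones into one physiological source for ICA; the default of 0 keeps
        # the canonical constant-amplitude phase-coupling test signal
        env_sigma = float(spec.params.get("env_sigma", 0.0))
        if env_sigma > 0:
            x = x * _smooth_envelope(n_samples, fs, rng, cutoff=0.3, sigma=env_sigma)
        mix = float(spec.params.get("noise_mix", 0.0))
        if mix > 0:
            w = rng.standard_normal(n_samples)
            x = np.sqrt(1 - mix) * x / max(x.std(), 1e-12) + np.sqrt(mix) * w / w.std()
    elif spec.waveform_kind == "ar_process":
        r = float(spec.params.get("ar_r", 0.95))
        f0 = float(spec.params.get("ar_f0", 0.5 * (lo + hi)))
        a1 = 2 * r * np.cos(2 * np.pi * f0 / fs)
        a2 = -(r**2)
        innov = rng.laplace(size=n_samples + 500)
        x = signal.lfilter([1.0], [1.0, -a1, -a2], innov)[500:]
    else:  # pragma: no cover - guarded in SourceSpec
        raise ValueError(spec.waveform_kind)

    x = x - x.mean()
    return spec.amplitude * x / max(x.std(), 1e-12)


# ----------------------------------------------------------------- cohort
def _roi_jitter(rng: np.random.Generator, roi, max_radial: float = 10.0) -> np.ndarray:
    """A point inside the ROI cylinder near its centre."""
    u1, u2 = rng.normal(size=2)
    # orthonormal tangential basis
    ref = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(roi.axis, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(roi.axis, t1)
    radial = rng.uniform(0, max_radial)
    ang = rng.uniform(0, 2 * np.pi)
    axial = rng.uniform(-roi.half_thickness, roi.half_thickness)
    return roi.center + radial * (np.cos(ang) * t1 + np.sin(ang) * t2) + axial * roi.axis


def _background_location(
    rng: np.random.Generator, head_radius: float, roi_center: np.ndarray, min_dist: float = 45.0
) -> np.ndarray:
    for _ in range(200):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        p = d * rng.uniform(0.6, 0.88) * head_radius
        if np.linalg.norm(p - roi_center) >= min_dist:
            return p
    return -roi_center  # antipode fallback


def _subject_sources(
    cfg: SyntheticCohortConfig, group: str, roi, rng: np.random.Generator, head_radius: float
) -> list[SourceSpec]:
    e = cfg.effect_map
    a_ratio = e.get("alpha_power_ratio_r_nr", 1.0) ** 0.25
    b_ratio = e.get("beta_power_ratio_nr_r", 1.0) ** 0.25
    alpha_amp = cfg.roi_source_amp * (a_ratio if group == "R" else 1 / a_ratio)
    beta_amp = cfg.roi_source_amp * (1 / b_ratio if group == "R" else b_ratio)
    coupling = e.get("coupling_r" if group == "R" else "coupling_nr", 0.5)
    mix = e.get("complexity_mix_r" if group == "R" else "complexity_mix_nr", 0.35)

    def jitter() -> float:
        return float(np.exp(cfg.subject_sigma * rng.standard_normal()))

    def rand_ori() -> np.ndarray:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    sources = [
        SourceSpec(_roi_jitter(rng, roi), rand_ori(), "band_limited_noise",
                   (8.0, 12.0), alpha_amp * jitter()),
        SourceSpec(_roi_jitter(rng, roi), rand_ori(), "band_limited_noise",
                   (12.0, 24.0), beta_amp * jitter()),
        # triplet tones at 1.8, 3.2 and 5 Hz: the coupling peak lands in the
        # delta-band bispectral features and no tone leaks into the alpha or
        # beta bands whose power ratios are separate effect-map entries
        SourceSpec(_roi_jitter(rng, roi), rand_ori(), "coupled_triplet",
                   (1.0, 8.0), cfg.roi_source_amp * jitter(),
                   params={"f1": 1.8, "f2": 3.2, "coupling": coupling, "noise_mix": mix}),
    ]
    bg_bands = [(8.0, 12.0), (4.0, 8.0), (1.0, 4.0), (12.0, 24.0), (2.0, 30.0)]
    for i in range(cfg.n_background_sources):
        band = bg_bands[i % len(bg_bands)]
        kind = "ar_process" if i % 3 == 2 else "band_limited_noise"
        sources.append(
            SourceSpec(
                _background_location(rng, head_radius, roi.center),
                rand_ori(), kind, band, cfg.background_amp * jitter() * 0.8,
            )
        )
    return sources


def generate_cohort(
    cfg: SyntheticCohortConfig, fwd: ForwardModel | None = None
) -> tuple[list[EEGRecording], dict]:
    """Generate the labelled cohort and its ground-truth record.

    Returns ``(recordings, truth)``; ``truth`` stores, per subject, the
    injected source specs (the first three are the in-ROI DLPFC sources), the
    bad channels, and which feature families carry a group contrast.
    Identical ``cfg`` gives a bit-identical cohort.
    """
    if fwd is None:
        fwd = standard_montage_32()
    roi = roi_from_montage(fwd.positions, head_radius=fwd.head_radius)
    pos = fwd.position_array()
    n_samples = int(round(cfg.duration_s * cfg.fs))
    groups = ["R"] * cfg.n_responders + ["NR"] * cfg.n_nonresponders

    recordings: list[EEGRecording] = []
    truth: dict = {
        "effect_map": dict(cfg.effect_map),
        "roi_center_mm": [float(v) for v in roi.center],
        "contrast_families": sorted(
            k for k, v in cfg.effect_map.items() if "ratio" in k and v != 1.0
        ),
        "subjects": {},
    }
    for idx, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, idx)))
        sid = f"S{idx + 1:03d}"
        sources = _subject_sources(cfg, group, roi, rng, fwd.head_radius)
        X = np.zeros((len(fwd.labels), n_samples))
        for k, spec in enumerate(sources):
            series = generate_source(spec, n_samples, cfg.fs, np.random.SeedSequence((cfg.seed, idx, k)))
            lead = sphere_leadfield(pos, spec.dipole_location, fwd.head_radius) @ spec.orientation
            lead = lead / max(np.sqrt(np.mean(lead**2)), 1e-30)
            X += np.outer(lead, series)
        X += cfg.sensor_noise_uv * rng.standard_normal(X.shape)
        if cfg.line_noise_amp > 0:
            t = np.arange(n_samples) / cfg.fs
            phase = rng.uniform(0, 2 * np.pi)
            amps = cfg.line_noise_amp * rng.uniform(0.5, 1.5, size=len(fwd.labels))
            X += np.outer(amps, np.sin(2 * np.pi * 50.0 * t + phase))
        bad = sorted(rng.choice(len(fwd.labels), size=cfg.n_bad_channels, replace=False).tolist())
        bad_labels = [fwd.labels[b] for b in bad]
        rms = np.median(np.sqrt(np.mean(X**2, axis=1)))
        # band-limit the artifact noise to the EEG band so its 20x amplitude
        # ratio survives resampling and band-pass filtering downstream
        bad_sos = signal.butter(4, [1.0, min(60.0, 0.45 * cfg.fs)], btype="band",
                                fs=cfg.fs, output="sos")
        for b in bad:
            w = signal.sosfiltfilt(bad_sos, rng.standard_normal(n_samples))
            X[b] = 20.0 * rms * w / w.std()

        recordings.append(
            EEGRecording(
                data=X, fs=cfg.fs, labels=list(fwd.labels),
                positions=dict(fwd.positions), subject_id=sid, group=group,
            )
        )
        truth["subjects"][sid] = {
            "group": group,
            "bad_channels": bad_labels,
            "n_roi_sources": 3,
            "sources": [s.to_dict() for s in sources],
        }
    return recordings, truth


def write_cohort(
    out_dir: str | Path, recordings: list[EEGRecording], truth: dict, fmt: str = "npy"
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        rec.save(out / rec.subject_id, fmt=fmt)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
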