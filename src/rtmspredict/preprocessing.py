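"""Cleaning chain from raw recording to analysis-ready signal.

Fixed order: resample to 250 Hz -> 1-60 Hz zero-phase Butterworth ->
bad-channel exclusion (channel-SD z-score rule) -> adaptive 50 Hz line-noise
removal (windowed sinusoidal regression, no notch hole) -> average reference
-> trim to the first 300 s.  Every exclusion is appended to the recording
log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EEGRecording


class InsufficientDataError(ValueError):
    """Recording shorter than the requested analysis duration."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 250.0
    band: tuple[float, float] = (1.0, 60.0)
    bad_channel_k: float = 3.1  # z-score threshold on channel SDs
    line_freq: float = 50.0
    keep_duration_s: float = 300.0
    filter_order: int = 4
    remove_artifact_ics: bool = False  # opt-in automated artifact-IC rule

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1] < self.target_fs / 2):
            raise ValueError("band must lie inside (0, target_fs/2)")
        if self.bad_channel_k <= 0:
            raise ValueError("bad_channel_k must be positive")


def bandpass(rec: EEGRecording, lo: float, hi: float, order: int = 4) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass; removes DC."""
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"band ({lo}, {hi}) violates Nyquist at fs={rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="band", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data, log=rec.log + [f"bandpass {lo}-{hi} Hz order {order}"])


def resample_to(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased polyphase resampling (downsampling only)."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if abs(target_fs - rec.fs) < 1e-9:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(
        data=data, fs=target_fs, log=rec.log + [f"resampled {rec.fs} -> {target_fs} Hz"]
    )


def detect_bad_channels(rec: EEGRecording, k: float = 3.1) -> list[str]:
    """Channels whose SD deviates from the cross-channel mean SD by more than
    ``k`` times the SD of the channel SDs."""
    if rec.n_channels < 3:
        raise ValueError("need at least 3 channels")
    sds = rec.data.std(axis=1)
    spread = sds.std()
    if spread == 0:
        return []
    flag = np.abs(sds - sds.mean()) > k * spread
    return [rec.labels[i] for i in np.flatnonzero(flag)]


def remove_line_noise(
    rec: EEGRecording, line_freq: float = 50.0, window_s: float = 4.0
) -> EEGRecording:
    """Adaptive sinusoidal regression in overlapping windows.

    In each Hann-weighted 4-s window the 50 Hz sine/cosine pair is regressed
    out per channel, tracking amplitude/phase drift without carving a notch
    hole into the neighbouring spectrum.
    """
    if line_freq >= rec.fs / 2:
        raise ValueError("line frequency above Nyquist")
    n = rec.n_samples
    win = int(round(window_s * rec.fs))
    win = min(win, n)
    hop = max(win // 2, 1)
    t = np.arange(n) / rec.fs
    carrier = np.stack([np.sin(2 * np.pi * line_freq * t), np.cos(2 * np.pi * line_freq * t)])
    est = np.zeros_like(rec.data)
    weight = np.zeros(n)
    taper = np.hanning(win) + 1e-3
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        sl = slice(s, s + win)
        C = carrier[:, sl]  # 2 x win
        G = C @ C.T
        coef = np.linalg.solve(G, C @ rec.data[:, sl].T)  # 2 x ch
        est[:, sl] += (coef.T @ C) * taper
        weight[sl] += taper
    est /= weight
    return rec.copy_with(
        data=rec.data - est, log=rec.log + [f"line noise removed at {line_freq} Hz"]
    )


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous cross-channel mean (average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, log=rec.log + ["average reference"])


def remove_artifact_components(
    rec: EEGRecording,
    flagged: list[str] | None = None,
    seed: int = 0,
    map_concentration: float = 0.6,
    high_freq_fraction: float = 0.5,
) -> EEGRecording:
    """Rule-based stand-in for visual artifact-IC screening.

    Drops independent components whose scalp-map energy is concentrated
    (> ``map_concentration``) on a single flagged or peripheral channel, or
    whose spectral power lies mostly (> ``high_freq_fraction``) above 30 Hz,
    then recomposes the data without them.
    """
    from .components import decompose

    cs = decompose(rec, n_components=min(rec.n_channels, 20), seed=seed)
    flagged = set(flagged or [])
    peripheral = {lb for lb in rec.labels if lb[0] in ("F", "T", "O") and lb[-1] in "1278z"}
    drop = []
    freqs, _ = signal.welch(cs.series[0], fs=rec.fs, nperseg=min(1024, rec.n_samples))
    for i in range(cs.n_components):
        m = cs.mixing[:, i] ** 2
        j = int(np.argmax(m))
        conc = m[j] / m.sum()
        if conc > map_concentration and (rec.labels[j] in flagged | peripheral):
            drop.append(i)
            continue
        _, psd = signal.welch(cs.series[i], fs=rec.fs, nperseg=min(1024, rec.n_samples))
        if psd[freqs > 30.0].sum() / psd.sum() > high_freq_fraction:
            drop.append(i)
    if not drop:
        return rec
    keep = [i for i in range(cs.n_components) if i not in drop]
    data = cs.mixing[:, keep] @ cs.series[keep]
    return rec.copy_with(data=data, log=rec.log + [f"dropped artifact ICs {drop}"])


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Full cleaning chain; output is exactly keep_duration_s * target_fs
    samples of average-referenced signal at target_fs, minus bad channels."""
    cfg = cfg or PreprocessConfig()
    if rec.duration_s < cfg.keep_duration_s:
        raise InsufficientDataError(
            f"recording is {rec.duration_s:.1f} s, need {cfg.keep_duration_s} s"
        )
    out = resample_to(rec, cfg.target_fs)
    out = bandpass(out, *cfg.band, order=cfg.filter_order)
    bad = detect_bad_channels(out, cfg.bad_channel_k)
    if bad:
        keep = [i for i, lb in enumerate(out.labels) if lb not in bad]
        out = out.copy_with(
            data=out.data[keep],
            labels=[out.labels[i] for i in keep],
            log=out.log + [f"excluded bad channels {bad} (|z|>{cfg.bad_channel_k} on channel SDs)"],
        )
    out = remove_line_noise(out, cfg.line_freq)
    if cfg.remove_artifact_ics:
        out = remove_artifact_components(out, flagged=bad)
    out = rereference_average(out)
    n_keep = int(round(cfg.keep_duration_s * cfg.target_fs))
    out = out.copy_with(
        data=np.ascontiguousarray(out.data[:, :n_keep]),
        log=out.log + [f"trimmed to first {cfg.keep_duration_s} s"],
    )
    if not np.isfinite(out.data).all():  # pragma: no cover - invariant guard
        raise RuntimeError("preprocessing produced non-finite values")
    return out
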