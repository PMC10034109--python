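"""Spectral, cordance, nonlinear and bispectral features of component series.

Per selected component (three per subject) the feature inventory is:

* absolute Welch band power in delta (1-4), theta (4-8), alpha (8-12) and
  beta (12-24 Hz), from non-overlapping 1-s windows;
* four complexity measures - permutation entropy, Higuchi fractal dimension,
  Lempel-Ziv complexity (median binarization, LZ76 parsing) and correlation
  dimension - each computed on 3000-sample epochs and averaged;
* three bispectral measures per band - the sum of bispectrum diagonal
  elements, the mean bispectral magnitude over the non-redundant triangle,
  and the normalized bispectral entropy;
* theta cordance, computed across the three components treated as sites.

That is 21 named values per component, 63 per subject.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .components import ComponentSet

#: Conventional EEG bands (Hz); beta extends to 24 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 24.0),
}

FAMILIES: dict[str, tuple[str, ...]] = {
    "Non-Linear": ("pe", "hfd", "lzc", "cd"),
    "Power": ("power_",),
    "Bispectrum": ("bisp_",),
    "Cordance": ("cordance_",),
}


@dataclass(frozen=True)
class NonlinearConfig:
    pe_m: int = 4
    pe_tau: int = 1
    hfd_kmax: int = 16
    cd_m_range: tuple[int, ...] = tuple(range(2, 11))
    cd_tau: int | None = None  # None -> first autocorrelation zero crossing
    epoch_len: int = 3000

    def __post_init__(self) -> None:
        if not 3 <= self.pe_m <= 7:
            raise ValueError("pe_m must be in [3, 7]")
        if self.hfd_kmax < 2:
            raise ValueError("hfd_kmax must be >= 2")
        if self.epoch_len < 3000:
            raise ValueError("epoch_len must be >= 3000 samples")


@dataclass(frozen=True)
class BispectrumConfig:
    nfft: int = 256
    segment_len: int = 256
    overlap: float = 0.5


# ---------------------------------------------------------------- spectral
def welch_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], window_s: float = 1.0
) -> float:
    """Band-integrated Welch power from non-overlapping 1-s Hann windows."""
    lo, hi = band
    if not (0 <= lo < hi <= fs / 2):
        raise ValueError(f"band {band} outside [0, fs/2]")
    nper = int(round(window_s * fs))
    if len(x) < nper:
        raise ValueError("series shorter than one Welch window")
    freqs, psd = signal.welch(x, fs=fs, nperseg=nper, noverlap=0, window="hann")
    df = freqs[1] - freqs[0]
    m = (freqs >= lo) & (freqs < hi)
    return float(psd[m].sum() * df)


def band_powers(x: np.ndarray, fs: float, window_s: float = 1.0) -> dict[str, float]:
    return {name: welch_band_power(x, fs, b, window_s) for name, b in BANDS.items()}


# ---------------------------------------------------------------- cordance
@dataclass(frozen=True)
class CordanceResult:
    panorm: pd.DataFrame  # sites x bands, max-normalized absolute power
    prnorm: pd.DataFrame  # sites x bands, max-normalized relative power
    cordance: pd.DataFrame  # sites x bands, in [-1, 1]


def cordance(powers: pd.DataFrame) -> CordanceResult:
    """Cordance from a sites x bands table of absolute band powers.

    Relative power divides each row by its total over bands; both absolute
    and relative powers are then normalized by their per-band maximum across
    sites, and combined as C = (PANORM - 0.5) + (PRNORM - 0.5).
    """
    if powers.shape[0] < 2:
        raise ValueError("cordance needs at least 2 sites")
    if (powers.values < 0).any():
        raise ValueError("band powers must be non-negative")
    col_max = powers.max(axis=0)
    if (col_max == 0).any():
        raise ValueError("undefined cordance: a band has all-zero power")
    rel = powers.div(powers.sum(axis=1), axis=0)
    panorm = powers.div(col_max, axis=1)
    prnorm = rel.div(rel.max(axis=0), axis=1)
    return CordanceResult(panorm=panorm, prnorm=prnorm, cordance=panorm + prnorm - 1.0)


# --------------------------------------------------------------- nonlinear
def permutation_entropy(x: np.ndarray, m: int = 4, tau: int = 1) -> float:
    """Normalized permutation entropy in [0, 1].

    Ordinal patterns of length ``m`` at lag ``tau``; ties are broken by order
    of occurrence (stable argsort).  0 = fully regular, 1 = fully random.
    """
    x = np.asarray(x, dtype=float)
    n_pat = len(x) - (m - 1) * tau
    if n_pat < max(math.factorial(m), 2):
        raise ValueError("fewer ordinal patterns than m! - series too short")
    idx = np.arange(n_pat)[:, None] + np.arange(m)[None, :] * tau
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    base = m ** np.arange(m)
    codes = patterns @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    H = float(-(p * np.log(p)).sum())
    return H / math.log(math.factorial(m))


def higuchi_fd(x: np.ndarray, k_max: int = 16) -> float:
    """Higuchi fractal dimension (slope of ln L(k) vs ln(1/k), k=1..k_max)."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < 2 * k_max:
        raise ValueError("series too short for k_max")
    Lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, N, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (N - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        Lk[k - 1] = np.mean(lengths)
    if np.any(Lk <= 0):
        warnings.warn("constant series has undefined curve length; returning 1.0", RuntimeWarning)
        return 1.0
    k = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(1.0 / k), np.log(Lk), 1)[0]
    return float(slope)


def _lz76_complexity(bits: np.ndarray) -> int:
    """Number of words in the LZ76 exhaustive-history parsing.

    Each word is the shortest extension not reproducible from the extended
    history; substring search runs at C speed on bytes.
    """
    s = np.asarray(bits, dtype=np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return 0
    c, l = 1, 1  # the first symbol is always a word
    while l < n:
        k = 1
        while l + k <= n and s.find(s[l : l + k], 0, l + k - 1) != -1:
            k += 1
        c += 1
        l += k
    return c


def lempel_ziv(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of the median-binarized series."""
    x = np.asarray(x)
    if len(x) < 100:
        raise ValueError("series too short for LZC")
    if x.dtype == bool or set(np.unique(x)).issubset({0, 1}):
        bits = x.astype(np.int8)
    else:
        bits = (x >= np.median(x)).astype(np.int8)
    n = len(bits)
    return _lz76_complexity(bits) / (n / math.log2(n))


class NonConvergentCDError(RuntimeError):
    """The correlation integral shows no usable linear scaling region."""


def _acf_zero_crossing(x: np.ndarray, max_lag: int = 200) -> int:
    x = x - x.mean()
    denom = float(x @ x)
    for lag in range(1, min(max_lag, len(x) - 1)):
        if float(x[:-lag] @ x[lag:]) / denom <= 0:
            return lag
    return max_lag


def correlation_dimension(
    x: np.ndarray,
    m_range: tuple[int, ...] = tuple(range(2, 11)),
    tau: int | None = None,
    n_radii: int = 12,
    max_points: int = 400,
    min_r2: float = 0.5,
) -> float:
    """Grassberger-Procaccia correlation dimension.

    Delay-embeds at lag ``tau`` (default: first autocorrelation zero
    crossing), counts pairs below log-spaced radii with a Theiler window of
    ``tau``, fits the slope of ln C vs ln r over the best-R^2 sliding window,
    and reports the plateau over increasing embedding dimension (the first
    pair of adjacent dimensions whose slopes agree within 0.3; otherwise the
    slope at the largest dimension).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 1000:
        raise ValueError("series too short for correlation dimension")
    if tau is None:
        tau = _acf_zero_crossing(x)
    tau = max(int(tau), 1)
    theiler = tau

    m_range = tuple(sorted(m_range))
    n_vec = len(x) - (m_range[-1] - 1) * tau
    while n_vec < 50 and len(m_range) > 1:
        m_range = m_range[:-1]
        n_vec = len(x) - (m_range[-1] - 1) * tau
    if n_vec < 50:
        raise NonConvergentCDError("series too short to embed at the requested dimensions")
    step = max(n_vec // max_points, 1)
    sel = np.arange(0, n_vec, step)
    iu, ju = np.triu_indices(len(sel), k=1)
    keep = (sel[ju] - sel[iu]) > theiler
    iu, ju = iu[keep], ju[keep]
    # squared distances grown incrementally over embedding dimension
    d2 = np.zeros((len(sel), len(sel)))
    next_j = 0
    slopes = []
    for m in m_range:
        while next_j < m:
            col = x[sel + next_j * tau]
            d2 += (col[:, None] - col[None, :]) ** 2
            next_j += 1
        dist = np.sqrt(d2[iu, ju])
        dist = dist[dist > 0]
        if len(dist) < 100:
            break
        r_lo, r_hi = np.percentile(dist, [5.0, 70.0])
        radii = np.logspace(np.log10(max(r_lo, 1e-12)), np.log10(r_hi), n_radii)
        C = np.array([(dist < r).mean() for r in radii])
        ok = C > 10.0 / len(dist)
        if ok.sum() < 4:
            break
        lr, lC = np.log(radii[ok]), np.log(C[ok])
        best = None
        w = min(6, len(lr))
        for s in range(0, len(lr) - w + 1):
            sl, ic = np.polyfit(lr[s : s + w], lC[s : s + w], 1)
            resid = lC[s : s + w] - (sl * lr[s : s + w] + ic)
            ss_tot = ((lC[s : s + w] - lC[s : s + w].mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / max(ss_tot, 1e-30)
            if best is None or r2 > best[1]:
                best = (sl, r2)
        if best is None or best[1] < min_r2:
            raise NonConvergentCDError(
                f"no linear scaling region at m={m} (best R^2 "
                f"{0.0 if best is None else best[1]:.2f})"
            )
        slopes.append(best[0])
        if len(slopes) >= 2 and abs(slopes[-1] - slopes[-2]) < 0.3:
            return float(0.5 * (slopes[-1] + slopes[-2]))
    if not slopes:
        raise NonConvergentCDError("could not embed the series at any requested dimension")
    return float(slopes[-1])


# -------------------------------------------------------------- bispectrum
@dataclass(frozen=True)
class BispectrumResult:
    bis: np.ndarray  # complex, freqs x freqs
    bis_norm: np.ndarray  # normalized magnitude in [0, 1+eps]
    freqs: np.ndarray
    omega: np.ndarray  # bool mask of the non-redundant triangle
    fs: float


def bispectrum(
    x: np.ndarray,
    fs: float,
    nfft: int = 256,
    segment_len: int = 256,
    overlap: float = 0.5,
) -> BispectrumResult:
    """Direct (FFT-segment-average) bispectrum estimate.

    Bis(f1,f2) = E[X(f1+f2) X*(f1) X*(f2)] over Hann-windowed segments, with
    the power-spectrum normalization whose squared magnitude is 1 for
    perfectly phase-coupled triplets and 0 for independent phases.  Only the
    non-redundant triangle 0 <= f2 <= f1, f1+f2 <= Nyquist is meaningful.
    """
    if nfft < segment_len:
        raise ValueError("nfft must be >= segment_len")
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * segment_len:
        raise ValueError("need at least 4 segments worth of samples")
    hop = max(int(round(segment_len * (1 - overlap))), 1)
    starts = range(0, len(x) - segment_len + 1, hop)
    win = np.hanning(segment_len)
    segs = np.stack([x[s : s + segment_len] for s in starts])
    segs = (segs - segs.mean(axis=1, keepdims=True)) * win
    F = np.fft.rfft(segs, n=nfft, axis=1)  # K x nh
    nh = F.shape[1]
    f_idx = np.arange(nh)
    sum_idx = np.minimum(f_idx[:, None] + f_idx[None, :], nh - 1)
    valid = (f_idx[:, None] + f_idx[None, :]) <= nh - 1

    bis = np.zeros((nh, nh), dtype=complex)
    P = np.zeros(nh)
    chunk = 64
    for s in range(0, len(F), chunk):
        Fc = F[s : s + chunk]
        bis += np.einsum("kab,ka,kb->ab", Fc[:, sum_idx], np.conj(Fc), np.conj(Fc))
        P += (np.abs(Fc) ** 2).sum(axis=0)
    K = len(F)
    bis /= K
    P /= K
    denom = np.sqrt(P[f_idx][:, None] * P[f_idx][None, :] * P[sum_idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        bn = np.abs(bis) / denom
    bn[~np.isfinite(bn)] = 0.0
    bn[~valid] = 0.0
    bis[~valid] = 0.0
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    omega = valid & (f_idx[None, :] <= f_idx[:, None])  # f2 <= f1
    return BispectrumResult(bis=bis, bis_norm=bn, freqs=freqs, omega=omega, fs=fs)


def bispec_features(b: BispectrumResult, band: tuple[float, float]) -> dict[str, float]:
    """Band-restricted bispectral summaries.

    ``mave``: mean |Bis| over the in-band triangle; ``p1``/``p2``: normalized
    bispectral (squared) entropies, divided by log of the region size so both
    lie in [0, 1]; ``diag_sum``: sum of |Bis(f, f)| over in-band f.
    """
    lo, hi = band
    in_band = (b.freqs >= lo) & (b.freqs < hi)
    mask = b.omega & in_band[:, None] & in_band[None, :]
    if not mask.any():
        raise ValueError(f"no bispectrum bins inside band {band}")
    mag = np.abs(b.bis[mask])
    L = mag.size
    total = mag.sum()
    if total <= 0:
        p1 = p2 = 0.0
    else:
        p = mag / total
        q = mag**2 / (mag**2).sum()
        logL = math.log(L) if L > 1 else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = float(-(p[p > 0] * np.log(p[p > 0])).sum() / logL)
            p2 = float(-(q[q > 0] * np.log(q[q > 0])).sum() / logL)
    diag = float(np.abs(np.diag(b.bis))[in_band].sum())
    return {"mave": float(mag.mean()), "p1": p1, "p2": p2, "diag_sum": diag}


# -------------------------------------------------------------- assembly
class FeatureExtractionError(RuntimeError):
    pass


@dataclass
class FeatureTable:
    """Subjects x named features, with responder/non-responder labels."""

    features: pd.DataFrame
    groups: pd.Series  # aligned with features.index, values "R"/"NR"

    def __post_init__(self) -> None:
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        self.groups = self.groups.loc[self.features.index]

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def family_columns(self, family: str) -> list[str]:
        if family == "Combination":
            return list(self.features.columns)
        keys = FAMILIES[family]
        out = []
        for c in self.features.columns:
            suffix = c.split("_", 1)[1] if "_" in c else c  # strip the ICn_ prefix
            if any(suffix.startswith(k) if k.endswith("_") else suffix == k for k in keys):
                out.append(c)
        return out

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.features[columns].copy(), self.groups.copy())

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df["group"] = self.groups
        df.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject")
        groups = df.pop("group")
        return cls(df, groups)


def _epoch_mean(x: np.ndarray, epoch_len: int, fn) -> float:
    n_ep = len(x) // epoch_len
    if n_ep == 0:
        raise ValueError("series shorter than one epoch")
    return float(np.mean([fn(x[i * epoch_len : (i + 1) * epoch_len]) for i in range(n_ep)]))


def extract_features(
    cs: ComponentSet,
    nonlinear: NonlinearConfig | None = None,
    bispec: BispectrumConfig | None = None,
) -> pd.Series:
    """One named feature row for a subject's three selected components."""
    nonlinear = nonlinear or NonlinearConfig()
    bispec = bispec or BispectrumConfig()
    if len(cs.selected) < 1:
        raise FeatureExtractionError("no selected components")
    series = cs.selected_series()
    fs = cs.fs
    values: dict[str, float] = {}
    comp_powers = []
    for ci, x in enumerate(series, start=1):
        name = f"IC{ci}"
        pw = band_powers(x, fs)
        comp_powers.append(pw)
        for bname, p in pw.items():
            values[f"{name}_power_{bname}"] = p
        values[f"{name}_pe"] = _epoch_mean(
            x, nonlinear.epoch_len, lambda e: permutation_entropy(e, nonlinear.pe_m, nonlinear.pe_tau)
        )
        values[f"{name}_hfd"] = _epoch_mean(
            x, nonlinear.epoch_len, lambda e: higuchi_fd(e, nonlinear.hfd_kmax)
        )
        values[f"{name}_lzc"] = _epoch_mean(x, nonlinear.epoch_len, lempel_ziv)
        values[f"{name}_cd"] = _epoch_mean(
            x, nonlinear.epoch_len,
            lambda e: correlation_dimension(e, nonlinear.cd_m_range, nonlinear.cd_tau),
        )
        b = bispectrum(x, fs, bispec.nfft, bispec.segment_len, bispec.overlap)
        for bname, band in BANDS.items():
            f = bispec_features(b, band)
            values[f"{name}_bisp_sl_{bname}"] = f["diag_sum"]
            values[f"{name}_bisp_2m_{bname}"] = f["mave"]
            values[f"{name}_bisp_en_{bname}"] = f["p1"]
    ptab = pd.DataFrame(comp_powers, index=[f"IC{i+1}" for i in range(len(series))])
    cor = cordance(ptab)
    for ci in range(1, len(series) + 1):
        values[f"IC{ci}_cordance_theta"] = float(cor.cordance.loc[f"IC{ci}", "theta"])
    row = pd.Series(values)
    bad = row[~np.isfinite(row)]
    if len(bad):
        raise FeatureExtractionError(f"non-finite features: {list(bad.index)}")
    return row
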