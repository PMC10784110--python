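"""Welch logPSD estimation, band powers, peak detection, and analytic
forecasting of where stimulation-artifact energy lands after undersampling.

The estimator settings are fixed by the recording device's analysis chain:
1024 FFT bins, an 844-sample Blackman–Harris window, 0% overlap, density
scaling, with power reported in dB (10·log10 Pxx). On the 422 Hz output
grid this gives a 0.412 Hz bin spacing and places the 105.5 Hz marker tone
exactly on bin 256.

Artifact taxonomy (for stimulation at f_T sampled at fs):

* SSH — stimulation shaping harmonics: retained harmonics k·f_T below the
  output Nyquist, recorded at their true frequency.
* ASH — aliased shaping harmonics: retained harmonics above Nyquist,
  folded into band by the undersampling ADC. Present even with a
  perfectly linear amplifier.
* IMH — intermodulation harmonics: harmonics beyond the waveform's
  truncation order, regenerated by amplifier nonlinearity and then
  aliased. Their presence indicates gain compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import signal as sps

from .config import ConfigError, StimConfig, WelchConfig
from .device import Recording

__all__ = [
    "LogPSD",
    "BandScheme",
    "STANDARD_BANDS",
    "ADJUSTED_BANDS",
    "ArtifactForecast",
    "PeakResult",
    "welch_logpsd",
    "band_power",
    "band_power_table",
    "find_peaks",
    "alias_frequency",
    "predict_artifacts",
]


@dataclass
class LogPSD:
    """Frequency grid and log-power estimates (dB) with the Welch settings
    that produced them."""

    freqs: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def nearest_bin(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))


@dataclass(frozen=True)
class BandScheme:
    """Named frequency windows (Hz). Bands are half-open [lo, hi) so
    adjacent bands never double-count a bin."""

    name: str
    windows: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for band, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ConfigError(f"band {band!r} has empty window ({lo}, {hi})")


STANDARD_BANDS = BandScheme(
    "standard",
    {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 14), "beta": (14, 30), "gamma": (30, 50)},
)

#: Artifact-avoiding windows: beta stops at 20 Hz and gamma starts at
#: 40 Hz so that the 32 Hz aliased harmonic of 130 Hz stimulation (and the
#: 22–25 Hz device artifacts) fall outside every band, without extending
#: any band past its standard range.
ADJUSTED_BANDS = BandScheme(
    "adjusted",
    {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 14), "beta": (14, 20), "gamma": (40, 50)},
)


@dataclass
class ArtifactForecast:
    """Predicted artifact frequencies (Hz) on the recorded grid."""

    ssh: set[float]
    ash: set[float]
    imh: set[float]

    def all_frequencies(self) -> set[float]:
        return self.ssh | self.ash | self.imh


def welch_logpsd(rec: Recording | np.ndarray, cfg: WelchConfig | None = None, fs: float | None = None) -> LogPSD:
    """Welch log power spectral density of a recording.

    Non-overlapping Blackman–Harris-windowed segments, zero-padded to
    ``nfft``, averaged, density-normalized, then 10·log10. No detrending
    is applied (the hardware high-pass is modeled upstream; the DC bin is
    excluded from all band computations instead).
    """
    cfg = cfg or WelchConfig()
    if isinstance(rec, Recording):
        x, fs = rec.samples, rec.fs
    else:
        x = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    if len(x) < cfg.nperseg:
        raise ValueError(
            f"recording of {len(x)} samples is shorter than one "
            f"{cfg.nperseg}-sample segment"
        )
    win = sps.get_window(cfg.window, cfg.nperseg)
    freqs, pxx = sps.welch(
        x,
        fs=fs,
        window=win,
        nperseg=cfg.nperseg,
        noverlap=0,
        nfft=cfg.nfft,
        detrend=False,
        scaling="density",
    )
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(pxx)
    meta = {"nfft": cfg.nfft, "nperseg": cfg.nperseg, "window": cfg.window, "fs": fs,
            "n_segments": len(x) // cfg.nperseg}
    return LogPSD(freqs, values, meta)


def _band_indices(psd: LogPSD, lo: float, hi: float) -> np.ndarray:
    mask = (psd.freqs >= lo) & (psd.freqs < hi) & (psd.freqs > 0)  # DC excluded
    return np.flatnonzero(mask)


def band_power(psd: LogPSD, scheme: BandScheme, band: str, agg: str = "median") -> float:
    """Aggregate log-power (dB) over one band's bins.

    Bins satisfy ``f_lo <= f < f_hi``; the DC bin is always excluded. The
    aggregator is ``"mean"`` or ``"median"`` over the dB values.
    """
    if band not in scheme.windows:
        raise KeyError(f"band {band!r} not in scheme {scheme.name!r}")
    lo, hi = scheme.windows[band]
    idx = _band_indices(psd, lo, hi)
    if idx.size == 0:
        raise ValueError(f"band {band!r} ({lo}-{hi} Hz) contains no bins on this grid")
    vals = psd.values[idx]
    if agg == "mean":
        return float(np.mean(vals))
    if agg == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregator {agg!r}")


def band_power_table(psd: LogPSD, scheme: BandScheme, agg: str = "median",
                     recording_id: str = "") -> "pd.DataFrame":
    """Band powers for every band of a scheme as a tidy table."""
    import pandas as pd

    rows = [
        {
            "recording_id": recording_id,
            "band": band,
            "scheme": scheme.name,
            "aggregator": agg,
            "power_db": band_power(psd, scheme, band, agg),
        }
        for band in scheme.windows
    ]
    return pd.DataFrame(rows)


@dataclass
class PeakResult:
    found: bool
    prominence_db: float
    freq_hz: float


def find_peaks(
    psd: LogPSD,
    candidates: list[float],
    tol_bins: int = 1,
    prominence_db: float = 6.0,
    neighborhood_hz: float = 2.0,
) -> dict[float, PeakResult]:
    """Test candidate frequencies for a narrowband peak.

    A candidate is found when a local maximum exists within ±``tol_bins``
    of its nearest bin whose prominence — its value minus the median of
    the surrounding ±``neighborhood_hz`` (the candidate window itself
    excluded) — exceeds the threshold. The local-maximum requirement
    rejects the monotone leakage skirt of a nearby stronger tone, which
    is elevated but is a slope, not a peak. The default 6 dB threshold
    sits far below the ≥20 dB excursions the artifact model produces.
    With ``tol_bins=0`` only the exact bin is examined and the
    local-maximum condition is waived.
    """
    out: dict[float, PeakResult] = {}
    nyq = psd.freqs[-1]
    v = psd.values
    for f0 in candidates:
        if not 0 <= f0 <= nyq:
            raise ValueError(f"candidate {f0} Hz outside [0, {nyq}] Hz")
        i0 = psd.nearest_bin(f0)
        lo = max(i0 - tol_bins, 0)
        hi = min(i0 + tol_bins + 1, len(psd.freqs))
        if tol_bins == 0:
            local_maxima = [i0]
        else:
            local_maxima = [
                i for i in range(lo, hi)
                if (i == 0 or v[i] > v[i - 1]) and (i == len(v) - 1 or v[i] > v[i + 1])
            ]
        i_peak = max(local_maxima, key=lambda i: v[i]) if local_maxima else lo + int(np.argmax(v[lo:hi]))
        n_nb = max(1, int(round(neighborhood_hz / psd.bin_width)))
        nb_lo = max(i0 - n_nb, 0)
        nb_hi = min(i0 + n_nb + 1, len(psd.freqs))
        nb_idx = [i for i in range(nb_lo, nb_hi) if not lo <= i < hi]
        background = float(np.median(v[nb_idx])) if nb_idx else float(v[lo:hi].min())
        prom = float(v[i_peak] - background)
        out[f0] = PeakResult(bool(local_maxima) and prom >= prominence_db, prom, float(psd.freqs[i_peak]))
    return out


def alias_frequency(f: float, fs: float) -> float:
    """Fold a frequency into the first Nyquist zone [0, fs/2].

    ``r = f mod fs``; the result is ``r`` if below Nyquist, else
    ``fs - r``. Idempotent. E.g. 390 Hz sampled at 422 Hz appears at
    32 Hz; 910 Hz (7th harmonic of 130 Hz) appears at 66 Hz.
    """
    if f < 0 or fs <= 0:
        raise ValueError("need f >= 0 and fs > 0")
    r = math.fmod(f, fs)
    return r if r <= fs / 2 else fs - r


def predict_artifacts(stim: StimConfig, fs: float, imh_max_order: int = 8) -> ArtifactForecast:
    """Forecast SSH/ASH/IMH frequencies for a stimulation setting and
    output sampling rate.

    Retained harmonics below fs/2 are SSH; retained harmonics above fs/2
    fold to ASH; harmonics between the truncation order and
    ``imh_max_order`` (which exist only if the amplifier regenerates
    them) fold to IMH. For 130 Hz stimulation at 422 Hz with 6 retained
    harmonics: ASH ⊇ {32, 64}, IMH ∋ 66.
    """
    if imh_max_order <= stim.n_harmonics:
        raise ConfigError("imh_max_order must exceed the truncation order")
    nyq = fs / 2
    ssh, ash, imh = set(), set(), set()
    for k in range(1, stim.n_harmonics + 1):
        f = k * stim.f_T
        (ssh if f <= nyq else ash).add(alias_frequency(f, fs) if f > nyq else f)
    for k in range(stim.n_harmonics + 1, imh_max_order + 1):
        imh.add(alias_frequency(k * stim.f_T, fs))
    return ArtifactForecast(ssh=ssh, ash=ash, imh=imh)
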