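"""Brain-layer signal generators of the focused mismatch-compression model.

All sources are generated on a common high-rate grid (default 4220 Hz,
20 s): two neural sources carrying 1/f background (one of them also a
stationary 15 Hz oscillation), the stimulation artifact as a truncated
Fourier series of its base-frequency harmonics, and the device's constant
105.5 Hz over-range-marker (ORM) tone.

All tones start at zero phase. The stimulation harmonics use the cosine
convention (an even-symmetric pulse's Fourier series): each tone's own
power is phase-invariant, but the phase alignment between harmonics
shapes the intermodulation products once the waveform meets the
amplifier nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BrainConfig, ConfigError, StimConfig

__all__ = [
    "SourceSignal",
    "gen_oscillation",
    "gen_pink_noise",
    "gen_stim_artifact",
    "gen_orm",
    "assemble_sources",
    "harmonic_weights",
]


@dataclass
class SourceSignal:
    """A uniformly sampled voltage series with its sampling rate and a
    label identifying which model source it is (x1, x3, stim, orm, ...)."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SourceSignal samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("SourceSignal samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def _time_grid(fs: float, duration: float) -> np.ndarray:
    if fs <= 0 or duration <= 0:
        raise ConfigError("sampling rate and duration must be positive")
    n = round(fs * duration)
    return np.arange(n) / fs


def gen_oscillation(
    f: float, amplitude: float, fs: float, duration: float
) -> SourceSignal:
    """Stationary sinusoidal neural oscillation (zero initial phase).

    Raises ``ConfigError`` if ``f`` is at or above the Nyquist rate.
    """
    t = _time_grid(fs, duration)
    if not 0 < f < fs / 2:
        raise ConfigError(f"oscillation at {f} Hz would alias at fs={fs} Hz")
    if amplitude < 0:
        raise ConfigError("amplitude must be non-negative")
    return SourceSignal(amplitude * np.sin(2 * np.pi * f * t), fs, label="osc")


def gen_pink_noise(strength: float, fs: float, duration: float, seed: int) -> SourceSignal:
    """1/f ("pink") background noise.

    White Gaussian noise is shaped in the frequency domain with an
    amplitude envelope proportional to f^(-1/2) (power proportional to
    1/f), transformed back, and normalized so the realization's RMS equals
    ``strength``. Seeded and fully reproducible.
    """
    if strength < 0:
        raise ConfigError("pink-noise strength must be non-negative")
    t = _time_grid(fs, duration)
    n = len(t)
    if strength == 0:
        return SourceSignal(np.zeros(n), fs, label="pink")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    envelope = np.zeros_like(freqs)
    envelope[1:] = freqs[1:] ** -0.5  # DC dropped: zero-mean output
    shaped = np.fft.irfft(spectrum * envelope, n)
    shaped -= shaped.mean()
    rms = np.sqrt(np.mean(shaped**2))
    return SourceSignal(strength * shaped / rms, fs, label="pink")


def harmonic_weights(stim: StimConfig) -> np.ndarray:
    """Relative amplitudes of harmonics 1..n_harmonics, normalized so the
    fundamental has weight 1.

    ``"inverse_k"`` (default) rolls off as 1/k. ``"pulse"`` uses the
    closed-form Fourier-series magnitudes of a biphasic rectangular
    pulse (phase width ``pulse_width_s``) repeated at f_T:

        |c_k| ∝ sin²(π k f_T τ) / k

    For a 90 µs pulse at 130 Hz these grow near-linearly in k over the
    retained orders — narrow pulses put most energy in high harmonics,
    which drives the soft-clipping amplifier far into saturation at
    clinical voltages.
    """
    k = np.arange(1, stim.n_harmonics + 1, dtype=float)
    if stim.harmonic_decay == "inverse_k":
        w = 1.0 / k
    else:
        tau = stim.pulse_width_s
        w = np.sin(np.pi * k * stim.f_T * tau) ** 2 / k
    return w / w[0]


def gen_stim_artifact(stim: StimConfig, fs: float, duration: float) -> SourceSignal:
    """Stimulation artifact: sum of the retained harmonics of f_T.

    Every retained harmonic must sit below the grid Nyquist; a harmonic at
    or above fs/2 raises ``ConfigError`` rather than being dropped
    silently.
    """
    t = _time_grid(fs, duration)
    top = stim.n_harmonics * stim.f_T
    if top >= fs / 2:
        raise ConfigError(
            f"harmonic {stim.n_harmonics} at {top} Hz is not representable at "
            f"fs={fs} Hz; lower n_harmonics or raise the grid rate"
        )
    if stim.amplitude == 0:
        return SourceSignal(np.zeros(len(t)), fs, label="stim")
    weights = harmonic_weights(stim)
    out = np.zeros(len(t))
    # Zero-phase cosines: the Fourier series of an even-symmetric pulse.
    # Phase coherence between harmonics matters once the waveform meets a
    # nonlinearity — the cosine alignment makes the first regenerated
    # harmonic (truncation order + 1) the dominant intermodulation
    # product, with monotone decay beyond, as a compressed pulse train
    # physically produces.
    for k, w in enumerate(weights, start=1):
        out += w * np.cos(2 * np.pi * k * stim.f_T * t)
    return SourceSignal(stim.amplitude * out, fs, label="stim")


def gen_orm(fs: float, duration: float, amplitude: float, freq: float = 105.5) -> SourceSignal:
    """Constant-amplitude device over-range-marker tone.

    At the device rate (422 Hz, 1024-bin grid) 105.5 Hz is exactly bin
    256, so the tone is bin-centered after the full pipeline.
    """
    t = _time_grid(fs, duration)
    if not 0 < freq < fs / 2:
        raise ConfigError(f"marker tone at {freq} Hz would alias at fs={fs} Hz")
    return SourceSignal(amplitude * np.sin(2 * np.pi * freq * t), fs, label="orm")


def assemble_sources(
    cfg: BrainConfig, stim: StimConfig
) -> tuple[SourceSignal, SourceSignal, SourceSignal, SourceSignal]:
    """Build all brain-layer sources on the shared high-rate grid.

    Returns ``(x1, x3, S, orm)``: x1 = oscillation + 1/f, x3 = independent
    1/f only, S the stimulation artifact, and the ORM tone. The two pink
    components use independent child seeds derived from ``cfg.seed``.
    """
    seed_a, seed_b = (int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(2))
    osc = gen_oscillation(cfg.f_osc, cfg.osc_amplitude, cfg.fs_hi, cfg.duration)
    pink1 = gen_pink_noise(cfg.pink_strength, cfg.fs_hi, cfg.duration, seed_a)
    pink3 = gen_pink_noise(cfg.pink_strength, cfg.fs_hi, cfg.duration, seed_b)
    x1 = SourceSignal(osc.samples + pink1.samples, cfg.fs_hi, label="x1")
    x3 = SourceSignal(pink3.samples.copy(), cfg.fs_hi, label="x3")
    s = gen_stim_artifact(stim, cfg.fs_hi, cfg.duration)
    orm = gen_orm(cfg.fs_hi, cfg.duration, cfg.orm_amplitude, cfg.orm_freq)
    return x1, x3, s, orm
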