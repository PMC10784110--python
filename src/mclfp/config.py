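"""Typed configuration objects for the mismatch-compression (MC) model.

The simulator is layered — brain sources, lead (electrode impedances),
amplifier, ADC — and each layer has its own small config. Defaults follow
the published parameter set of the focused MC model: dimensionless model
units with ``g1 = g2 = 1``, an oscillation amplitude of ``2e-3``, a 1/f
strength of ``1e-3`` and an internal channel impedance ``Z_b = 1e4`` Ω.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates a model invariant."""


@dataclass
class StimConfig:
    """Stimulation waveform: a truncated Fourier series at the base rate.

    Parameters
    ----------
    f_T:
        Therapeutic stimulation base frequency in Hz (130 Hz clinically).
    amplitude:
        Stimulation voltage in model volts; the clinical sweep protocol
        spans 0–8 V. The fundamental (k=1) carries exactly this amplitude.
    n_harmonics:
        Truncation order of the Fourier series. With 6 retained harmonics
        and 422 Hz output sampling the aliased set covers 32 and 64 Hz
        while the 7th harmonic (66 Hz alias) exists only if the amplifier
        nonlinearity regenerates it.
    harmonic_decay:
        Rule mapping harmonic index k to relative amplitude.
        ``"inverse_k"`` (default) rolls off as 1/k, keeping the leaked
        artifact in the mild-compression regime where the regenerated
        harmonics decay beyond the truncation order. ``"pulse"`` uses the
        Fourier magnitudes of a biphasic rectangular pulse of width
        ``pulse_width_s`` (these grow with k for a narrow pulse, driving
        the amplifier into deep saturation at clinical voltages).
    """

    f_T: float = 130.0
    amplitude: float = 6.0
    n_harmonics: int = 6
    harmonic_decay: str = "inverse_k"
    pulse_width_s: float = 90e-6

    def __post_init__(self) -> None:
        if self.f_T <= 0:
            raise ConfigError(f"stimulation frequency must be positive, got {self.f_T}")
        if self.amplitude < 0:
            raise ConfigError(f"stimulation amplitude must be >= 0, got {self.amplitude}")
        if self.n_harmonics < 1:
            raise ConfigError(f"n_harmonics must be >= 1, got {self.n_harmonics}")
        if self.harmonic_decay not in ("pulse", "inverse_k"):
            raise ConfigError(f"unknown harmonic_decay rule {self.harmonic_decay!r}")


@dataclass
class BrainConfig:
    """Brain-layer sources on the high-rate ("tissue") sampling grid.

    ``fs_hi`` is ten times the device output rate: the ADC models the
    recorder's 10-fold undersampling, so a 4220 Hz tissue grid yields a
    422 Hz differential LFP.
    """

    fs_hi: float = 4220.0
    duration: float = 20.0
    f_osc: float = 15.0
    osc_amplitude: float = 2e-3
    pink_strength: float = 1e-3
    orm_freq: float = 105.5
    orm_amplitude: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hi <= 0 or self.duration <= 0:
            raise ConfigError("fs_hi and duration must be positive")
        if not 0 < self.f_osc < self.fs_hi / 2:
            raise ConfigError(
                f"oscillation frequency {self.f_osc} Hz not representable below "
                f"Nyquist {self.fs_hi / 2} Hz"
            )
        if self.osc_amplitude < 0 or self.pink_strength < 0 or self.orm_amplitude < 0:
            raise ConfigError("amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return round(self.fs_hi * self.duration)


@dataclass
class LeadModel:
    """Electrode impedances of the two recording contacts flanking the
    stimulating contact, plus the internal channel impedance Z_b.

    The impedance mismatch ``|Z1 - Z3|`` is the driver of artifact
    leakage: with perfectly matched contacts the stimulation is pure
    common mode and is rejected entirely.
    """

    Z1: float = 1000.0
    Z3: float = 1000.0
    Z_b: float = 1e4

    def __post_init__(self) -> None:
        if self.Z1 < 0 or self.Z3 < 0 or self.Z_b <= 0:
            raise ConfigError("impedances must be non-negative (Z_b positive)")

    def mismatch(self) -> float:
        return abs(self.Z1 - self.Z3)


@dataclass
class AmplifierConfig:
    """Signal-amplifier model: linear, hard clipping, or tanh soft clipping.

    ``g1`` is the pre-nonlinearity gain and ``g2`` the post-nonlinearity
    gain, both normalized to 1 in the published parameter set.
    """

    model: str = "soft_clip"
    g1: float = 1.0
    g2: float = 1.0
    clip_level: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("linear", "hard_clip", "soft_clip"):
            raise ConfigError(f"unknown amplifier model {self.model!r}")
        if self.g1 <= 0 or self.g2 <= 0:
            raise ConfigError("gains must be positive")
        if self.model == "hard_clip" and self.clip_level <= 0:
            raise ConfigError("hard_clip requires clip_level > 0")


@dataclass
class ADCConfig:
    """ADC stage: plain decimation (every n-th sample kept).

    No anti-alias filter is applied by default — undersampling the
    residual stimulation artifact is precisely the mechanism that folds
    its harmonics into the recorded band. ``anti_alias`` enables a
    first-order 100 Hz low-pass applied before decimation, mirroring the
    device's analog hardware filter.
    """

    decimation: int = 10
    anti_alias: bool = False
    anti_alias_cutoff: float = 100.0

    def __post_init__(self) -> None:
        if self.decimation < 1:
            raise ConfigError(f"decimation factor must be >= 1, got {self.decimation}")


@dataclass
class WelchConfig:
    """Welch PSD settings: 1024 FFT bins, 844-sample Blackman–Harris
    window, 0% overlap — an 8440-sample (20 s at 422 Hz) recording splits
    into exactly 10 averaged segments with 422/1024 Hz bin spacing."""

    nfft: int = 1024
    nperseg: int = 844
    window: str = "blackmanharris"
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.nperseg > self.nfft:
            raise ConfigError("window length must not exceed nfft (zero-padding only)")
        if self.overlap != 0:
            raise ConfigError("this estimator is defined with 0% overlap")


_CONFIG_TYPES: dict[str, type] = {
    "brain": BrainConfig,
    "stim": StimConfig,
    "lead": LeadModel,
    "amp": AmplifierConfig,
    "adc": ADCConfig,
    "welch": WelchConfig,
}


def config_to_dict(cfg: Any) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON config file into typed config objects.

    The file holds top-level sections named ``brain``, ``stim``, ``lead``,
    ``amp``, ``adc``, ``welch`` (any subset); field names match the
    dataclass fields. Unknown sections or fields raise ``ConfigError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping at top level")
    out: dict[str, Any] = {}
    for section, values in raw.items():
        if section not in _CONFIG_TYPES:
            raise ConfigError(f"unknown config section {section!r}")
        cls = _CONFIG_TYPES[section]
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(values) - known
        if bad:
            raise ConfigError(f"unknown fields {sorted(bad)} in section {section!r}")
        out[section] = cls(**values)
    return out


def dump_config(configs: dict[str, Any], path: str | Path) -> None:
    """Write typed config objects back to YAML (inverse of load_config)."""
    raw = {name: config_to_dict(cfg) for name, cfg in configs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
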