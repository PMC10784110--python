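"""Quality diagnostics for mismatch compression.

The gain compression ratio (GCr) grades compression severity from the
recording itself by comparing power at an aliased shaping harmonic (ASH,
default 64 Hz — present whenever artifact leaks, even through a perfectly
linear amplifier) against power at an intermodulation harmonic (IMH,
default 66 Hz — created only by amplifier nonlinearity). Sign convention:

    GCr = ASH_dB - IMH_dB

so LARGER values mean LESS compression (the IMH sits at the noise floor).

The over-range marker (ORM) is a constant-amplitude device tone at
105.5 Hz; because its injected amplitude never changes, a drop in its
measured power — or loss of a discernible peak — indicates the amplifier
is compressing or saturating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import ConfigError
from .spectral import LogPSD, find_peaks

__all__ = ["GcrConfig", "OrmTrace", "compute_gcr", "orm_power", "impedance_mismatch"]


@dataclass
class GcrConfig:
    f_ash: float = 64.0
    f_imh: float = 66.0
    bandwidth_bins: int = 1

    def __post_init__(self) -> None:
        if self.f_ash == self.f_imh:
            raise ConfigError("ASH and IMH frequencies must differ")
        if self.bandwidth_bins < 0:
            raise ConfigError("bandwidth_bins must be >= 0")


def _local_max_db(psd: LogPSD, f: float, half_width_bins: int) -> float:
    nyq = psd.freqs[-1]
    if not 0 <= f <= nyq:
        raise ValueError(f"{f} Hz is outside the PSD grid [0, {nyq}] Hz")
    i0 = psd.nearest_bin(f)
    lo = max(i0 - half_width_bins, 0)
    hi = min(i0 + half_width_bins + 1, len(psd.freqs))
    return float(psd.values[lo:hi].max())


def compute_gcr(psd: LogPSD, cfg: GcrConfig | None = None) -> float:
    """Gain compression ratio in dB: ASH power minus IMH power.

    Each power is the maximum dB value within ±``bandwidth_bins`` of the
    target frequency's nearest bin, so a peak sitting one bin off-center
    is still captured. Invariant to any constant dB offset of the PSD.
    """
    cfg = cfg or GcrConfig()
    ash_db = _local_max_db(psd, cfg.f_ash, cfg.bandwidth_bins)
    imh_db = _local_max_db(psd, cfg.f_imh, cfg.bandwidth_bins)
    return ash_db - imh_db


def orm_power(
    psd: LogPSD, orm_freq: float = 105.5, prominence_db: float = 6.0
) -> tuple[float, bool]:
    """Power at the ORM bin and whether the tone is still discernible.

    Returns ``(power_db, discernible)``; saturation is flagged when no
    peak of sufficient prominence remains at the marker frequency.
    """
    if psd.bin_width > 2.0:
        raise ValueError("PSD grid too coarse to resolve the marker tone")
    power_db = float(psd.values[psd.nearest_bin(orm_freq)])
    result = find_peaks(psd, [orm_freq], tol_bins=1, prominence_db=prominence_db)[orm_freq]
    return power_db, result.found


@dataclass
class OrmTrace:
    """ORM power tracked across a series of recordings (e.g. weeks)."""

    entries: list[tuple[str, float, bool]] = field(default_factory=list)

    def add(self, recording_id: str, psd: LogPSD, **kwargs) -> None:
        power, discernible = orm_power(psd, **kwargs)
        self.entries.append((recording_id, power, discernible))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["recording_id", "orm_power_db", "discernible"]
        ).assign(saturation_flag=lambda d: ~d["discernible"])


def impedance_mismatch(z_a: float, z_b: float) -> float:
    """Impedance mismatch: absolute difference of the two electrode
    impedances (Ω)."""
    if z_a < 0 or z_b < 0:
        raise ValueError("impedances must be non-negative")
    return abs(z_a - z_b)
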