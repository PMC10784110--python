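"""Experiment fixtures: voltage sweeps and chronic (weekly) series.

The voltage sweep mirrors the clinical protocol of stepping stimulation
amplitude while recording ∂LFP, run here as a paired design: every
voltage condition reuses the same noise seed so artifact effects are not
confounded with background realizations. The chronic series emulates the
electrode-impedance dynamics observed after implantation — large
week-to-week mismatch changes in an early settling phase, near-stable
after — with mismatch bounded to the observed 0–600 Ω range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import ADCConfig, AmplifierConfig, BrainConfig, ConfigError, LeadModel, StimConfig
from .device import Recording, simulate_recording

__all__ = ["SweepProtocol", "run_sweep", "ChronicSeries", "gen_chronic_series"]


@dataclass
class SweepProtocol:
    """A stimulation-amplitude sweep.

    Default voltages cover 0 V (stim-free reference) and the 2–8 V
    clinical range. Simulated conditions default to 20 s each (the
    simulator's native duration); the clinical protocol's 60 s-with-washout
    timing can be set via ``on_duration``/``washout``.
    """

    voltages: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    on_duration: float = 20.0
    washout: float = 0.0
    brain: BrainConfig = field(default_factory=BrainConfig)
    stim: StimConfig = field(default_factory=StimConfig)
    lead: LeadModel = field(default_factory=LeadModel)
    amp: AmplifierConfig = field(default_factory=AmplifierConfig)
    adc: ADCConfig = field(default_factory=ADCConfig)
    paired_seeds: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.voltages):
            raise ConfigError("voltages must be non-negative")
        if self.on_duration <= 0 or self.washout < 0:
            raise ConfigError("durations must be positive (washout >= 0)")


def run_sweep(protocol: SweepProtocol) -> list[Recording]:
    """One recording per voltage condition.

    With ``paired_seeds`` (default) the brain noise seed is identical
    across voltages; otherwise each condition gets seed + index.
    """
    recordings = []
    for i, v in enumerate(protocol.voltages):
        seed = protocol.brain.seed if protocol.paired_seeds else protocol.brain.seed + i
        brain = dataclasses.replace(protocol.brain, duration=protocol.on_duration, seed=seed)
        stim = dataclasses.replace(protocol.stim, amplitude=v)
        rec = simulate_recording(brain, stim, protocol.lead, protocol.amp, protocol.adc)
        rec.meta["condition_index"] = i
        recordings.append(rec)
    return recordings


@dataclass
class ChronicSeries:
    """Weekly impedance trajectory plus one simulated recording per week."""

    weeks: list[int]
    z1: list[float]
    z3: list[float]
    recordings: list[Recording]

    def mismatches(self) -> np.ndarray:
        return np.abs(np.asarray(self.z1) - np.asarray(self.z3))


def gen_chronic_series(
    weeks: int,
    phase_change_week: int = 10,
    seed: int = 0,
    protocol: SweepProtocol | None = None,
    early_step_ohm: float = 150.0,
    late_step_ohm: float = 20.0,
    mismatch_range_ohm: tuple[float, float] = (0.0, 600.0),
) -> ChronicSeries:
    """Simulate a weekly recording series with two-phase impedance dynamics.

    The mismatch follows a bounded random walk: step std
    ``early_step_ohm`` before ``phase_change_week`` (the variable settling
    phase) and ``late_step_ohm`` after (stable phase), clamped to
    ``mismatch_range_ohm``. One electrode is held fixed and the other
    carries the mismatch. Stimulation settings are fixed across weeks.
    """
    if weeks < 1:
        raise ConfigError("need at least one week")
    if not 0 <= phase_change_week < weeks and weeks > 1:
        raise ConfigError("phase_change_week must fall inside the series")
    protocol = protocol or SweepProtocol()
    rng = np.random.default_rng(seed)
    lo, hi = mismatch_range_ohm
    mismatch = float(rng.uniform(lo, hi))
    z1_base = protocol.lead.Z1
    week_ids, z1s, z3s, recs = [], [], [], []
    for w in range(weeks):
        step = early_step_ohm if w < phase_change_week else late_step_ohm
        if w > 0:
            mismatch = float(np.clip(mismatch + rng.normal(0, step), lo, hi))
        lead = dataclasses.replace(protocol.lead, Z1=z1_base, Z3=z1_base + mismatch)
        brain = dataclasses.replace(protocol.brain, seed=protocol.brain.seed + w)
        rec = simulate_recording(brain, protocol.stim, lead, protocol.amp, protocol.adc)
        rec.meta["week"] = w
        week_ids.append(w)
        z1s.append(lead.Z1)
        z3s.append(lead.Z3)
        recs.append(rec)
    return ChronicSeries(week_ids, z1s, z3s, recs)
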