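"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the library code paths they check:
periodograms are computed with an explicit DFT matrix, band aggregation
with hand-built index sets, and polynomial fits with normal equations on
a centered Vandermonde basis.
"""

from __future__ import annotations

import numpy as np
import pytest

import mclfp as m


@pytest.fixture(scope="session")
def table_lead():
    """1000 Ω mismatch with the published internal impedance."""
    return m.LeadModel(Z1=1000.0, Z3=2000.0, Z_b=1e4)


@pytest.fixture(scope="session")
def default_sim(table_lead):
    """6 V soft-clip simulation at the published parameters, seed 1."""
    return m.simulate_recording(
        m.BrainConfig(seed=1),
        m.StimConfig(amplitude=6.0),
        table_lead,
        m.AmplifierConfig(model="soft_clip"),
        m.ADCConfig(),
    )


@pytest.fixture(scope="session")
def linear_sim(table_lead):
    """Same run with the perfectly linear amplifier."""
    return m.simulate_recording(
        m.BrainConfig(seed=1),
        m.StimConfig(amplitude=6.0),
        table_lead,
        m.AmplifierConfig(model="linear"),
        m.ADCConfig(),
    )


@pytest.fixture(scope="session")
def quiet_sim():
    """No stimulation, linear amplifier: oscillation + 1/f + marker only."""
    return m.simulate_recording(
        m.BrainConfig(seed=1),
        m.StimConfig(amplitude=0.0),
        m.LeadModel(),
        m.AmplifierConfig(model="linear"),
        m.ADCConfig(),
    )


# ----------------------------------------------------------------- oracles


def dft_matrix_periodogram(x: np.ndarray, win: np.ndarray, fs: float, nfft: int) -> np.ndarray:
    """One-sided modified periodogram via an explicit DFT matrix (no FFT)."""
    n = len(win)
    y = np.zeros(nfft, dtype=complex)
    seg = x * win
    k = np.arange(nfft)
    # DFT of the zero-padded windowed segment, summed term by term
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / nfft)
    y = basis @ seg
    n_onesided = nfft // 2 + 1
    pxx = (np.abs(y[:n_onesided]) ** 2) / (fs * np.sum(win**2))
    pxx[1:-1] *= 2.0  # fold negative frequencies (even nfft: keep Nyquist single)
    return pxx


def welch_oracle(x: np.ndarray, fs: float, nperseg: int, nfft: int, win: np.ndarray) -> np.ndarray:
    """Average of per-segment brute-force periodograms, 0% overlap."""
    n_seg = len(x) // nperseg
    psds = [
        dft_matrix_periodogram(x[i * nperseg : (i + 1) * nperseg], win, fs, nfft)
        for i in range(n_seg)
    ]
    return np.mean(psds, axis=0)


def polyfit_normal_equations(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """Least-squares polynomial fit by explicitly solving the normal
    equations on a centered/scaled regressor; returns fitted values on x."""
    t = 2.0 * (x - x.min()) / (x.max() - x.min()) - 1.0
    v = np.vander(t, order + 1, increasing=True)
    coef = np.linalg.solve(v.T @ v, v.T @ y)
    return v @ coef


def band_indices_oracle(freqs: np.ndarray, lo: float, hi: float) -> list[int]:
    return [i for i, f in enumerate(freqs) if lo <= f < hi and f > 0]
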