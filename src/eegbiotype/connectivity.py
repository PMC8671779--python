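"""Inter-trial phase-locking connectivity from complex Morlet wavelets.

Per-trial instantaneous phase is extracted with a continuous wavelet
transform (complex Morlet, centre-frequency parameter ``omega0``, default
6), filtering and phase extraction in a single operation.  The phase-
locking value between channels x and y at time k and scale s is the
modulus of the trial-averaged unit phasor of their phase difference::

    PLV_xy(k, s) = | (1/N_t) * sum_n exp(i * dphi_xy(k, s, n)) |

which is 1 for perfectly synchronised trials and tends to 0 for
independent phases.  Edge effects are removed with the cone of influence
defined by the e-folding time of the wavelet's Gaussian envelope
(Torrence-Compo convention).  Band/window connectivity matrices average
PLV over the COI-valid grid points of a frequency band and analysis
window; no threshold is applied, so entries live in [0, 1] with unit
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .epochs import EpochedRecording, WindowSpec, PRESTIMULUS, RESPONSE

THETA_BAND = (4.0, 8.0)
BROADBAND = (1.0, 70.0)

#: Gaussian-envelope width of the complex Morlet in pywt's
#: bandwidth-centre parameterisation that matches omega0-style Morlets
#: (psi ~ exp(i*omega0*t) * exp(-t^2/2)).
_MORLET_BANDWIDTH = 2.0


@dataclass(frozen=True)
class TimeFrequencyGrid:
    """Time-scale grid of the transform: times (ms), pseudo-frequencies
    (Hz, decreasing with scale), scales, and the COI validity mask."""

    times_ms: np.ndarray
    freqs_hz: np.ndarray
    scales: np.ndarray
    coi_mask: np.ndarray  # (n_freqs, n_times), True where edge-safe
    omega0: float = 6.0

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return np.flatnonzero((self.freqs_hz >= lo) & (self.freqs_hz <= hi))

    def window_indices(self, window: WindowSpec) -> np.ndarray:
        return np.flatnonzero(window.mask(self.times_ms))


def band_frequencies(
    band: tuple[float, float], voices_per_octave: int = 4
) -> np.ndarray:
    """Log-spaced analysis frequencies covering ``band`` at
    ``voices_per_octave`` resolution, returned in decreasing order."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    n = int(np.ceil(np.log2(hi / lo) * voices_per_octave)) + 1
    return np.geomspace(hi, lo, n)


def _wavelet_name(omega0: float) -> str:
    fc = omega0 / (2.0 * np.pi)
    return f"cmor{_MORLET_BANDWIDTH}-{fc:.8f}"


def _coi_efolding_s(freqs_hz: np.ndarray, omega0: float) -> np.ndarray:
    """E-folding time (s) of the Morlet Gaussian envelope at each
    pseudo-frequency: sqrt(2) * s with s the Torrence-Compo scale."""
    s = (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi * freqs_hz)
    return np.sqrt(2.0) * s


def _cwt_coefficients(
    data: np.ndarray, fs: float, freqs_hz: np.ndarray, omega0: float
) -> np.ndarray:
    """Complex CWT coefficients of trials x channels x samples data,
    returned as (trials, channels, n_freqs, n_samples)."""
    wavelet = _wavelet_name(omega0)
    scales = pywt.frequency2scale(wavelet, np.asarray(freqs_hz) / fs)
    n_trials, n_channels, n_samples = data.shape
    out = np.empty(
        (n_trials, n_channels, len(freqs_hz), n_samples), dtype=np.complex64
    )
    for ch in range(n_channels):
        coef, _ = pywt.cwt(
            data[:, ch, :], scales, wavelet, sampling_period=1.0 / fs,
            method="fft", axis=-1,
        )
        # coef: (n_freqs, n_trials, n_samples)
        out[:, ch] = np.moveaxis(coef, 0, 1).astype(np.complex64)
    return out


def cwt_phase(
    recording: EpochedRecording,
    freqs_hz: np.ndarray | None = None,
    band: tuple[float, float] = BROADBAND,
    voices_per_octave: int = 4,
    omega0: float = 6.0,
) -> tuple[np.ndarray, TimeFrequencyGrid]:
    """Per-trial instantaneous phase on a time-frequency grid.

    Returns ``(phase, grid)`` with phase shaped
    (trials, channels, n_freqs, n_samples) in (-pi, pi], and the grid
    carrying pseudo-frequencies and the COI mask.
    """
    fs = recording.sampling_rate
    if freqs_hz is None:
        freqs_hz = band_frequencies(band, voices_per_octave)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0) or np.any(freqs_hz >= fs / 2):
        raise ValueError(
            f"requested frequencies must lie in (0, Nyquist={fs / 2} Hz)"
        )
    coef = _cwt_coefficients(recording.data, fs, freqs_hz, omega0)
    phase = np.angle(coef).astype(np.float32)

    t_ms = recording.time_ms
    coi_ms = _coi_efolding_s(freqs_hz, omega0) * 1000.0
    from_start = t_ms[None, :] - t_ms[0]
    to_end = t_ms[-1] - t_ms[None, :]
    coi_mask = (from_start >= coi_ms[:, None]) & (to_end >= coi_ms[:, None])
    grid = TimeFrequencyGrid(
        times_ms=t_ms.copy(),
        freqs_hz=freqs_hz,
        scales=pywt.frequency2scale(_wavelet_name(omega0), freqs_hz / fs),
        coi_mask=coi_mask,
        omega0=omega0,
    )
    return phase, grid


def trial_power(
    recording: EpochedRecording,
    freqs_hz: np.ndarray | None = None,
    band: tuple[float, float] = BROADBAND,
    voices_per_octave: int = 4,
    omega0: float = 6.0,
) -> tuple[np.ndarray, TimeFrequencyGrid]:
    """Trial-averaged wavelet power (channels, n_freqs, n_samples)."""
    fs = recording.sampling_rate
    if freqs_hz is None:
        freqs_hz = band_frequencies(band, voices_per_octave)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0) or np.any(freqs_hz >= fs / 2):
        raise ValueError(
            f"requested frequencies must lie in (0, Nyquist={fs / 2} Hz)"
        )
    coef = _cwt_coefficients(recording.data, fs, freqs_hz, omega0)
    power = np.mean(np.abs(coef).astype(np.float64) ** 2, axis=0)
    t_ms = recording.time_ms
    coi_ms = _coi_efolding_s(freqs_hz, omega0) * 1000.0
    coi_mask = ((t_ms[None, :] - t_ms[0]) >= coi_ms[:, None]) & (
        (t_ms[-1] - t_ms[None, :]) >= coi_ms[:, None]
    )
    grid = TimeFrequencyGrid(
        times_ms=t_ms.copy(),
        freqs_hz=freqs_hz,
        scales=pywt.frequency2scale(_wavelet_name(omega0), freqs_hz / fs),
        coi_mask=coi_mask,
        omega0=omega0,
    )
    return power, grid


def plv_map(phase: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    """PLV over the whole (freq, time) grid for one channel pair."""
    if phase.ndim != 4:
        raise ValueError("phase must be trials x channels x freqs x times")
    if phase.shape[0] < 2:
        raise ValueError("PLV requires N_t >= 2 trials")
    x, y = pair
    dphi = phase[:, x].astype(np.float64) - phase[:, y].astype(np.float64)
    return np.abs(np.mean(np.exp(1j * dphi), axis=0))


def plv(
    phase: np.ndarray,
    pair: tuple[int, int],
    k: int | None = None,
    s: int | None = None,
) -> np.ndarray | float:
    """PLV for a channel pair, optionally at a single time index ``k`` and
    scale index ``s``."""
    full = plv_map(phase, pair)
    if k is None and s is None:
        return full
    if k is None or s is None:
        raise ValueError("give both k (time) and s (scale) or neither")
    return float(full[s, k])


def connectivity_matrix(
    phase: np.ndarray,
    grid: TimeFrequencyGrid,
    band: tuple[float, float],
    window: WindowSpec,
) -> np.ndarray:
    """Band/window-averaged PLV connectivity matrix.

    PLV is computed per (k, s) grid point and averaged over the points of
    the band x window rectangle that are COI-valid; masked points are
    excluded from the average.  The matrix is symmetric with unit
    diagonal and entries in [0, 1].
    """
    if phase.shape[0] < 2:
        raise ValueError("PLV requires N_t >= 2 trials")
    f_idx = grid.band_indices(band)
    t_idx = grid.window_indices(window)
    if len(f_idx) == 0 or len(t_idx) == 0:
        raise ValueError(
            f"band {band} / window {window.name!r} selects no grid points"
        )
    valid = grid.coi_mask[np.ix_(f_idx, t_idx)]
    if not np.any(valid):
        raise ValueError(
            f"no COI-valid grid points for band {band} in window "
            f"{window.name!r}; use a longer epoch"
        )
    sub = phase[:, :, f_idx][:, :, :, t_idx]  # (n, c, F, T)
    z = np.exp(1j * sub.astype(np.float64))
    n_trials, n_channels = z.shape[:2]
    # Trial-mean phasor for every ordered channel pair at each grid point.
    mean_phasor = np.einsum("naft,nbft->abft", z, np.conj(z)) / n_trials
    plv_grid = np.abs(mean_phasor)  # (c, c, F, T)
    matrix = plv_grid[:, :, valid].mean(axis=-1)
    matrix = 0.5 * (matrix + matrix.T)
    np.fill_diagonal(matrix, 1.0)
    return np.clip(matrix, 0.0, 1.0)


def band_window_matrices(
    recording: EpochedRecording,
    bands: dict[str, tuple[float, float]] | None = None,
    windows: tuple[WindowSpec, ...] = (PRESTIMULUS, RESPONSE),
    voices_per_octave: int = 4,
    omega0: float = 6.0,
) -> dict[str, dict[str, np.ndarray]]:
    """All band x window connectivity matrices from one recording.

    The phase tensor is computed once on a grid spanning the widest band;
    narrower bands select their frequencies from it.  Returns
    ``{band_name: {window_name: matrix}}``.
    """
    if bands is None:
        bands = {"theta": THETA_BAND, "broadband": BROADBAND}
    span = (min(b[0] for b in bands.values()), max(b[1] for b in bands.values()))
    phase, grid = cwt_phase(
        recording, band=span, voices_per_octave=voices_per_octave, omega0=omega0
    )
    out: dict[str, dict[str, np.ndarray]] = {}
    for band_name, band in bands.items():
        out[band_name] = {
            w.name: connectivity_matrix(phase, grid, band, w) for w in windows
        }
    return out
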