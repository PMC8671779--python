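"""Spectral entropy of event-related EEG and its task modulation.

Spectral entropy (SE) is the Shannon entropy of the normalised power
spectrum divided by log of the number of frequency bins, so it lives in
[0, 1]: 1 for a flat spectrum, 0 when all power sits in one bin.  Here the
spectrum per sensor and analysis window is the trial-averaged wavelet
power (event-related regularity), averaged over the COI-valid samples of
the window.  SE modulation is response minus prestimulus; when the
response concentrates power into few frequencies (the usual evoked
dynamics in healthy controls) modulation is negative.

Because per-sensor modulation values are strongly correlated across the
scalp, they are summarised by a single factor (first principal factor of
the sensor correlation matrix) whose subject scores feed group
comparisons; loadings are sign-aligned so all sensors contribute
positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochedRecording, WindowSpec, PRESTIMULUS, RESPONSE
from .connectivity import trial_power, BROADBAND


def spectral_entropy(power: np.ndarray) -> float:
    """Normalised Shannon entropy of a power distribution, in [0, 1]."""
    p = np.asarray(power, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("power must be a 1-d distribution with >= 2 bins")
    if np.any(p < 0):
        raise ValueError("power must be nonnegative")
    total = p.sum()
    if total == 0:
        raise ValueError("power must not be all zero")
    p = p / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(len(p)))


@dataclass
class SEProfile:
    """Per-sensor spectral entropy in both windows plus modulation."""

    se_prestim: np.ndarray
    se_response: np.ndarray
    se_modulation: np.ndarray
    channel_names: list[str]
    subject_id: str = ""


def se_modulation(
    recording: EpochedRecording,
    band: tuple[float, float] = BROADBAND,
    windows: tuple[WindowSpec, WindowSpec] = (PRESTIMULUS, RESPONSE),
    voices_per_octave: int = 4,
    omega0: float = 6.0,
) -> SEProfile:
    """Spectral entropy per sensor in each window and their difference.

    Power at each frequency is the trial-averaged wavelet power, averaged
    over the window's COI-valid samples; frequencies with no valid sample
    in a window are excluded from both windows' spectra so the two
    entropies share a common support.
    """
    power, grid = trial_power(
        recording, band=band, voices_per_octave=voices_per_octave, omega0=omega0
    )
    pre_w, resp_w = windows
    spectra = {}
    supports = {}
    for w in (pre_w, resp_w):
        t_idx = grid.window_indices(w)
        if len(t_idx) == 0:
            raise ValueError(f"window {w.name!r} outside the epoch")
        valid = grid.coi_mask[:, t_idx]  # (F, Tw)
        if not np.any(valid):
            raise ValueError(
                f"no COI-valid samples for window {w.name!r}; "
                "use a longer epoch"
            )
        counts = valid.sum(axis=1)
        sub = power[:, :, t_idx]
        spec = np.where(valid[None], sub, 0.0).sum(axis=2) / np.maximum(counts, 1)
        spectra[w.name] = spec  # (channels, F)
        supports[w.name] = counts > 0
    support = supports[pre_w.name] & supports[resp_w.name]
    if support.sum() < 2:
        raise ValueError("fewer than 2 frequencies COI-valid in both windows")
    se_pre = np.array(
        [spectral_entropy(s[support]) for s in spectra[pre_w.name]]
    )
    se_resp = np.array(
        [spectral_entropy(s[support]) for s in spectra[resp_w.name]]
    )
    return SEProfile(
        se_prestim=se_pre,
        se_response=se_resp,
        se_modulation=se_resp - se_pre,
        channel_names=list(recording.channel_names),
        subject_id=recording.subject_id,
    )


@dataclass
class SEFactorScores:
    """Single-factor summary of per-sensor SE modulation."""

    loadings: pd.Series
    scores: np.ndarray
    variance_explained: float


def se_factor_scores(table: pd.DataFrame) -> SEFactorScores:
    """First principal factor of the sensor correlation matrix.

    ``table`` is subjects x sensors.  Loadings are sign-aligned so the
    sensor consensus is positive; subject scores are standardised to mean
    0, SD 1 over the fitted sample.
    """
    x = np.asarray(table, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 sensors")
    if x.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.asarray(table.columns)[sd == 0]
        raise ValueError(f"zero-variance sensor column(s): {list(bad)}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    lead = eigvec[:, -1]
    if lead.sum() < 0:
        lead = -lead
    loadings = np.sqrt(max(eigval[-1], 0.0)) * lead
    raw_scores = z @ lead
    s_sd = raw_scores.std(ddof=1)
    if s_sd == 0:
        raise ValueError("degenerate factor: zero score variance")
    scores = (raw_scores - raw_scores.mean()) / s_sd
    return SEFactorScores(
        loadings=pd.Series(loadings, index=table.columns),
        scores=scores,
        variance_explained=float(eigval[-1] / len(corr)),
    )
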