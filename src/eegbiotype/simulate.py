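"""Synthetic oddball-EEG cohorts with known ground truth.

The generator emulates the three-condition auditory oddball used in
event-related phase-locking studies: 600 stimuli with probabilities
0.2 (target) / 0.2 (distractor) / 0.6 (standard), inter-stimulus interval
jittered uniformly in 1.16-1.44 s, and epochs cut only around targets
followed by a button press ("attended" targets).

Inter-trial phase coupling is injected through a shared narrowband
component: on trial ``n`` every channel ``c`` carries
``cos(2*pi*f0*t + theta_n + eps_cn(t))`` where ``theta_n`` is a common
random trial phase and ``eps_cn`` is von Mises jitter with concentration
``kappa``.  The phase difference between two channels is then the
difference of two independent von Mises draws, so the expected inter-trial
phase-locking value of any pair is ``(I1(kappa)/I0(kappa))**2`` — an
analytically invertible calibration: to program a pairwise PLV ``rho`` we
solve ``I1(kappa)/I0(kappa) = sqrt(rho)``.

Two latent subject subgroups are built in: a "C1-like" profile (lower
prestimulus coupling, clearly positive task modulation, strong response
power concentration) and a "C2-like" profile (higher prestimulus coupling,
near-zero modulation, weak power concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .epochs import EpochedRecording, TARGET, DISTRACTOR, STANDARD

#: Order of the six clustering features (prestimulus and modulation of
#: path length, connectivity strength and small-world index).
FEATURE_COLUMNS = (
    "pl_prestim",
    "cs_prestim",
    "sw_prestim",
    "pl_modulation",
    "cs_modulation",
    "sw_modulation",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic oddball cohort.

    Defaults follow the task the generator emulates (600 stimuli at
    0.2/0.2/0.6, ISI jitter 1.16-1.44 s, 32 channels, theta carrier).
    ``n_trials_target`` (attended targets retained per subject) defaults to
    150: the true per-subject count after artifact rejection is not
    publicly documented, so this is an explicit, configurable guess.
    The epoch extends to -800 ms so the -300-0 ms prestimulus window stays
    inside the wavelet cone of influence down to 4 Hz.
    """

    n_channels: int = 32
    sampling_rate: float = 500.0
    n_stimuli: int = 600
    n_trials_target: int = 150
    p_target: float = 0.2
    p_distractor: float = 0.2
    p_standard: float = 0.6
    isi_range: tuple[float, float] = (1.16, 1.44)
    epoch_window_ms: tuple[float, float] = (-800.0, 1000.0)
    coupling_prestim: float = 0.30
    coupling_response: float = 0.45
    coupling_sd: float = 0.2
    carrier_band: tuple[float, float] = (4.0, 8.0)
    response_gain: float = 2.0
    noise_sd: float = 0.5
    attend_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_target, self.p_distractor, self.p_standard)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("stimulus probabilities must be >= 0 and sum to 1")
        if not self.isi_range[0] < self.isi_range[1]:
            raise ValueError("isi_range must satisfy min < max")
        for c in (self.coupling_prestim, self.coupling_response):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling targets must lie in [0, 1]")
        if not 0.0 <= self.attend_prob <= 1.0:
            raise ValueError("attend_prob must lie in [0, 1]")


@dataclass(frozen=True)
class GroupParams:
    """Per-subgroup coupling profile.

    ``coupling_prestim`` / ``coupling_response`` are the window-wise
    programmed pairwise PLV targets; ``coupling_sd`` (when set, else the
    config default applies) is the spatial heterogeneity of the coupling
    profile across channels — larger values produce more uneven weight
    matrices, hence longer normalised path length and lower small-world
    index; ``response_gain`` scales carrier amplitude in the response
    window, driving spectral-entropy modulation.
    """

    name: str
    coupling_prestim: float
    coupling_response: float
    response_gain: float = 1.0
    coupling_sd: float | None = None


#: Lower prestimulus coupling, positive task modulation, homogeneous
#: near-small-world topology, marked response power concentration
#: (control-like dynamics).
C1_LIKE = GroupParams("C1-like", coupling_prestim=0.30, coupling_response=0.45,
                      response_gain=2.0, coupling_sd=0.15)
#: Higher prestimulus coupling with near-zero modulation, more
#: heterogeneous topology (longer normalised PL, lower SW) and weak
#: power concentration.
C2_LIKE = GroupParams("C2-like", coupling_prestim=0.45, coupling_response=0.45,
                      response_gain=1.1, coupling_sd=0.35)


@dataclass
class GroundTruth:
    """What the generator actually programmed for one subject."""

    subject_id: str
    group_label: str
    programmed_plv: dict[str, np.ndarray]
    achieved_plv: dict[str, float]
    programmed_features: np.ndarray | None = None


def expected_pair_plv(kappa: float) -> float:
    """Expected pairwise PLV when both channels carry von Mises jitter
    of concentration ``kappa``: ``(I1(kappa)/I0(kappa))**2``."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0.0:
        return 0.0
    return float((i1e(kappa) / i0e(kappa)) ** 2)


def _kappa_for_resultant(r: float) -> float:
    """Concentration whose von Mises mean resultant length is ``r``."""
    if r <= 0.0:
        return 0.0
    if r >= 1.0 - 1e-9:
        return np.inf
    return float(brentq(lambda k: i1e(k) / i0e(k) - r, 1e-9, 1e4))


def kappa_for_plv(rho: float) -> float:
    """Invert the von Mises calibration: concentration giving expected
    pairwise PLV ``rho``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if rho == 0.0:
        return 0.0
    return _kappa_for_resultant(float(np.sqrt(rho)))


def simulate_events(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the oddball stimulus stream.

    Returns a frame with columns ``code`` (target/distractor/standard),
    ``onset_s`` (cumulative, uniform ISI jitter) and ``pressed`` (Bernoulli
    per target with ``attend_prob``; always False otherwise).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codes = rng.choice(
        [TARGET, DISTRACTOR, STANDARD],
        size=config.n_stimuli,
        p=[config.p_target, config.p_distractor, config.p_standard],
    )
    gaps = rng.uniform(*config.isi_range, size=config.n_stimuli)
    onsets = np.cumsum(gaps)
    pressed = (codes == TARGET) & (rng.random(config.n_stimuli) < config.attend_prob)
    return pd.DataFrame({"code": codes, "onset_s": onsets, "pressed": pressed})


def _von_mises(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    if np.isinf(kappa):
        return np.zeros(size)
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, size=size)
    return rng.vonmises(0.0, kappa, size=size)


def _ramp(t_ms: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Smooth 0->1 cosine ramp between ``start`` and ``stop`` (ms)."""
    x = np.clip((t_ms - start) / (stop - start), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def simulate_subject(
    config: SimConfig,
    group_params: GroupParams | None = None,
    seed: int | None = None,
) -> tuple[EpochedRecording, GroundTruth]:
    """Simulate one subject's attended-target epochs.

    Each epoch carries a band-limited carrier (coupled oscillators
    log-spaced over ``carrier_band``, sharing the per-channel jitter)
    whose per-channel trial phase offset transitions smoothly (cosine
    ramp over 0-150 ms) from the prestimulus jitter draw to the response
    draw, so the two analysis windows realise their own programmed
    coupling at every wavelet scale inside the band.  The carrier amplitude rises by
    ``group_params.response_gain`` in the response window, emulating the
    evoked power concentration that drives spectral-entropy modulation.
    Broadband Gaussian noise is added at ``noise_sd``.
    """
    if group_params is None:
        group_params = GroupParams(
            "custom",
            config.coupling_prestim,
            config.coupling_response,
            config.response_gain,
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # Oversample the stimulus stream so enough attended targets exist.
    need = config.n_trials_target
    p_keep = max(config.p_target * config.attend_prob, 1e-6)
    n_stim = max(config.n_stimuli, int(np.ceil(need / p_keep * 1.5)) + 20)
    ev_cfg = SimConfig(**{**config.__dict__, "n_stimuli": n_stim})
    events = simulate_events(ev_cfg, seed=rng.integers(2**31))
    n_trials = min(need, int(events["pressed"].sum()))
    if n_trials < need:
        warnings.warn(
            f"only {n_trials} attended targets available "
            f"(requested {need})", stacklevel=2
        )
    if n_trials == 0:
        raise ValueError("no attended target trials were generated")

    fs = config.sampling_rate
    t0, t1 = config.epoch_window_ms
    n_samples = int(round((t1 - t0) / 1000.0 * fs))
    t_ms = t0 + np.arange(n_samples) / fs * 1000.0

    # Per-channel coupling heterogeneity: a spatial profile multiplies the
    # square-root coupling, so pairwise expected PLV is the outer product
    # of the per-channel resultants (mean over pairs ~= the target) and
    # the resulting matrices carry realistic weight spread.
    n_ch = config.n_channels
    coupling_sd = (
        group_params.coupling_sd
        if group_params.coupling_sd is not None
        else config.coupling_sd
    )
    # Truncate the profile: unbounded weak channels would make inverse-
    # weight path lengths arbitrarily heavy-tailed.
    chan_mult = np.clip(
        1.0 + coupling_sd * rng.standard_normal(n_ch), 0.6, 1.6
    )

    programmed: dict[str, np.ndarray] = {}
    achieved: dict[str, float] = {}
    eps = {}
    off = ~np.eye(n_ch, dtype=bool)
    for wname, rho in (
        ("prestimulus", group_params.coupling_prestim),
        ("response", group_params.coupling_response),
    ):
        a = np.clip(np.sqrt(rho) * chan_mult, 0.0, 1.0)
        kappas = [_kappa_for_resultant(ai) for ai in a]
        eps[wname] = np.column_stack(
            [_von_mises(rng, k, n_trials) for k in kappas]
        )
        pair = np.outer(a, a)
        np.fill_diagonal(pair, 1.0)
        programmed[wname] = pair
        achieved[wname] = float(pair[off].mean())
        if abs(achieved[wname] - rho) > 0.05:
            warnings.warn(
                f"{wname} coupling target {rho} unreachable with this "
                f"channel profile (resultants clip at 1); achieved "
                f"pair-mean expectation {achieved[wname]:.4f}",
                stacklevel=2,
            )
    eps_pre, eps_resp = eps["prestimulus"], eps["response"]

    # Phase offset transitions along the shortest arc during 0-150 ms.
    delta = np.angle(np.exp(1j * (eps_resp - eps_pre)))
    ramp_phase = _ramp(t_ms, 0.0, 150.0)  # (n_samples,)
    offset = eps_pre[:, :, None] + delta[:, :, None] * ramp_phase[None, None, :]

    amp = 1.0 + (group_params.response_gain - 1.0) * (
        _ramp(t_ms, 0.0, 150.0) - _ramp(t_ms, 450.0, 600.0)
    )

    # Shared band-limited component: coupled oscillators spanning the
    # carrier band, all carrying the same per-channel jitter, so every
    # wavelet scale inside the band sees the programmed coupling.
    lo, hi = config.carrier_band
    n_comp = max(int(np.ceil(np.log2(max(hi / lo, 1.0 + 1e-9)) * 4)) + 1, 1)
    comp_freqs = np.geomspace(lo, hi, n_comp)
    comp_amp = 1.0 / np.sqrt(n_comp)
    t_s = t_ms / 1000.0
    carrier = np.zeros((n_trials, config.n_channels, n_samples))
    for f in comp_freqs:
        theta = rng.uniform(-np.pi, np.pi, size=(n_trials, 1, 1))
        carrier += comp_amp * np.cos(
            2.0 * np.pi * f * t_s[None, None, :] + theta + offset
        )
    data = amp[None, None, :] * carrier + config.noise_sd * rng.standard_normal(
        (n_trials, config.n_channels, n_samples)
    )

    subject_id = f"sim-{group_params.name}-{config.seed if seed is None else seed}"
    recording = EpochedRecording(
        data=data,
        sampling_rate=fs,
        channel_names=[f"CH{i + 1:02d}" for i in range(config.n_channels)],
        time_ms=t_ms,
        subject_id=subject_id,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        group_label=group_params.name,
        programmed_plv=programmed,
        achieved_plv=achieved,
    )
    return recording, truth


def two_group_centroids(
    separation: float, spread: float = 1.0, n_features: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric centroid pair offset by ``separation`` within-group SDs
    on every feature."""
    half = 0.5 * separation * spread
    return (-half * np.ones(n_features), half * np.ones(n_features))


def simulate_feature_cohort(
    n_per_group: int,
    centroids: tuple[Sequence[float], Sequence[float]] | None = None,
    spread: float | Sequence[float] = 1.0,
    separation: float | None = None,
    seed: int = 0,
    columns: Sequence[str] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian two-group feature table with recoverable labels.

    Either pass explicit ``centroids`` (two vectors, e.g. published group
    means) with per-feature ``spread`` (published SDs), or a scalar
    ``separation``: the per-feature centroid offset in within-group SD
    units.  Returns (table, labels) with labels in {0, 1}.
    """
    if centroids is None:
        if separation is None:
            raise ValueError("pass either centroids or separation")
        centroids = two_group_centroids(separation, np.mean(np.atleast_1d(spread)),
                                        n_features=len(columns))
    c0, c1 = (np.asarray(c, dtype=float) for c in centroids)
    if c0.shape != c1.shape or c0.ndim != 1:
        raise ValueError("centroids must be two equal-length vectors")
    if len(c0) != len(columns):
        raise ValueError("centroid length must match the feature columns")
    spread = np.broadcast_to(np.asarray(spread, dtype=float), c0.shape)
    rng = np.random.default_rng(seed)
    g0 = c0 + spread * rng.standard_normal((n_per_group, len(c0)))
    g1 = c1 + spread * rng.standard_normal((n_per_group, len(c0)))
    table = pd.DataFrame(np.vstack([g0, g1]), columns=list(columns))
    labels = np.repeat([0, 1], n_per_group)
    return table, labels


def simulate_structural_matrix(
    n_nodes: int,
    mean_weight: float = 0.345,
    cv: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric positive-weight matrix with zero diagonal, standing in for
    an FA-weighted structural connectivity matrix.

    Edge weights are Gamma-distributed with mean ``mean_weight`` and
    coefficient of variation ``cv``.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if mean_weight <= 0:
        raise ValueError("mean_weight must be positive")
    rng = np.random.default_rng(seed)
    shape = 1.0 / cv**2
    scale = mean_weight / shape
    m = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    m[iu] = rng.gamma(shape, scale, size=len(iu[0]))
    return m + m.T
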