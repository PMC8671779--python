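"""Epoched EEG container, portable I/O, epoch selection, and analysis windows.

The container is deliberately minimal: a trials x channels x samples array
in microvolts plus the metadata needed downstream (sampling rate, channel
names, a millisecond time axis anchored at stimulus onset, and per-trial
condition / attended flags).  On disk it is a ``.npy`` array next to a JSON
sidecar, so recordings survive round trips without any vendor format; a
thin BrainVision reader is provided for real acquisitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

TARGET, DISTRACTOR, STANDARD = "target", "distractor", "standard"


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window in milliseconds relative to stimulus onset.

    Windows are half-open ``[start_ms, end_ms)`` when mapped to samples.
    """

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"window {self.name!r}: start_ms ({self.start_ms}) must be "
                f"< end_ms ({self.end_ms})"
            )

    def mask(self, time_ms: np.ndarray) -> np.ndarray:
        """Boolean sample mask for this window on a millisecond time axis."""
        time_ms = np.asarray(time_ms, dtype=float)
        return (time_ms >= self.start_ms) & (time_ms < self.end_ms)


#: Expectation period before stimulus onset.
PRESTIMULUS = WindowSpec("prestimulus", -300.0, 0.0)
#: Window centred on the P3b response.
RESPONSE = WindowSpec("response", 150.0, 450.0)


@dataclass
class EpochedRecording:
    """Per-subject epoched EEG: trials x channels x samples, in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    time_ms: np.ndarray
    trial_codes: np.ndarray = field(default=None)  # type: ignore[assignment]
    trial_attended: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{n_channels} channels"
            )
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.time_ms.shape != (n_samples,):
            raise ValueError("time_ms length must match the sample axis")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if not (self.time_ms[0] <= 0.0 <= self.time_ms[-1]):
            raise ValueError("time_ms must contain stimulus onset (0 ms)")
        if self.trial_codes is None:
            self.trial_codes = np.array([TARGET] * n_trials)
        self.trial_codes = np.asarray(self.trial_codes)
        if self.trial_attended is None:
            self.trial_attended = np.ones(n_trials, dtype=bool)
        self.trial_attended = np.asarray(self.trial_attended, dtype=bool)
        if len(self.trial_codes) != n_trials or len(self.trial_attended) != n_trials:
            raise ValueError("trial flags must match the trial axis")

    @property
    def n_trials(self) -> int:
        """Retained trial count N_t."""
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset_trials(self, index: np.ndarray) -> "EpochedRecording":
        """New recording keeping ``index`` trials, order preserved."""
        return replace(
            self,
            data=self.data[index],
            trial_codes=self.trial_codes[index],
            trial_attended=self.trial_attended[index],
        )


def save_epochs(recording: EpochedRecording, path: str | Path) -> Path:
    """Write the portable epochs container: ``<stem>.npy`` + ``<stem>.json``.

    Returns the sidecar path, which is what :func:`load_epochs` accepts.
    """
    path = Path(path)
    stem = path.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), recording.data)
    sidecar = {
        "subject_id": recording.subject_id,
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.channel_names),
        "time_ms": recording.time_ms.tolist(),
        "trial_codes": recording.trial_codes.tolist(),
        "trial_attended": recording.trial_attended.astype(int).tolist(),
    }
    out = stem.with_suffix(".json")
    out.write_text(json.dumps(sidecar, sort_keys=True))
    return out


def load_epochs(path: str | Path) -> EpochedRecording:
    """Read a portable epochs container (or a BrainVision ``.vhdr`` header).

    Raises a parse error naming the offending field when the sidecar is
    incomplete.
    """
    path = Path(path)
    if path.suffix == ".vhdr":
        return load_brainvision(path)
    stem = path.with_suffix("")
    sidecar_path = stem.with_suffix(".json")
    array_path = stem.with_suffix(".npy")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "channel_names", "time_ms"):
        if key not in meta:
            raise ValueError(f"epochs container {sidecar_path}: missing field {key!r}")
    data = np.load(array_path)
    return EpochedRecording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_names=list(meta["channel_names"]),
        time_ms=np.asarray(meta["time_ms"], dtype=float),
        trial_codes=np.asarray(meta.get("trial_codes")) if "trial_codes" in meta else None,
        trial_attended=(
            np.asarray(meta["trial_attended"], dtype=bool)
            if "trial_attended" in meta
            else None
        ),
        subject_id=str(meta.get("subject_id", "unknown")),
    )


def load_brainvision(
    vhdr_path: str | Path,
    tmin_ms: float = -800.0,
    tmax_ms: float = 1000.0,
) -> EpochedRecording:
    """Epoch a BrainVision recording around its stimulus markers via MNE.

    All stimulus events are epoched and coded ``target``; condition and
    button-press bookkeeping for real sessions is expected to come from the
    acquisition's own event table via :func:`select_attended_targets`.
    """
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    epochs = mne.Epochs(
        raw,
        events,
        tmin=tmin_ms / 1000.0,
        tmax=tmax_ms / 1000.0,
        baseline=None,
        preload=True,
        verbose="error",
    )
    data_uv = epochs.get_data() * 1e6
    time_ms = epochs.times * 1000.0
    return EpochedRecording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(epochs.ch_names),
        time_ms=time_ms,
        subject_id=Path(vhdr_path).stem,
    )


def select_attended_targets(
    recording: EpochedRecording, events=None
) -> EpochedRecording:
    """Keep only target trials followed by a button press.

    ``events`` may supply per-trial ``code`` / ``pressed`` columns (anything
    with those attributes or keys, one row per epoch); otherwise the
    recording's own trial flags are used.
    """
    if events is not None:
        codes = np.asarray(
            events["code"] if not hasattr(events, "code") else events.code
        )
        pressed = np.asarray(
            events["pressed"] if not hasattr(events, "pressed") else events.pressed,
            dtype=bool,
        )
        if len(codes) != recording.n_trials:
            raise ValueError("events must have one row per epoch")
        recording = replace(recording, trial_codes=codes, trial_attended=pressed)
    keep = (recording.trial_codes == TARGET) & recording.trial_attended
    if not np.any(keep):
        raise ValueError("no attended target trials retained")
    return recording.subset_trials(np.flatnonzero(keep))


def reject_artifacts(
    recording: EpochedRecording, amplitude_limit_uv: float = 100.0
) -> tuple[EpochedRecording, list[dict]]:
    """Drop trials whose absolute amplitude exceeds the limit on any channel.

    Returns the cleaned recording and a per-rejected-trial log.  More than
    half the trials rejected raises a warning; zero retained is an error.
    """
    if amplitude_limit_uv <= 0:
        raise ValueError("amplitude_limit_uv must be > 0")
    peak = np.max(np.abs(recording.data), axis=(1, 2))
    channel_peak = np.max(np.abs(recording.data), axis=2)
    keep = peak <= amplitude_limit_uv
    log = []
    for i in np.flatnonzero(~keep):
        ch = int(np.argmax(channel_peak[i]))
        log.append(
            {
                "trial": int(i),
                "reason": "amplitude",
                "peak_uv": float(peak[i]),
                "channel": recording.channel_names[ch],
            }
        )
    if not np.any(keep):
        raise ValueError(
            f"all {recording.n_trials} trials exceed "
            f"{amplitude_limit_uv} uV; nothing retained"
        )
    if np.count_nonzero(~keep) > recording.n_trials / 2:
        warnings.warn(
            f"artifact rejection dropped {np.count_nonzero(~keep)} of "
            f"{recording.n_trials} trials",
            stacklevel=2,
        )
    return recording.subset_trials(np.flatnonzero(keep)), log


def baseline_correct(
    recording: EpochedRecording, window: WindowSpec = PRESTIMULUS
) -> EpochedRecording:
    """Subtract the per-trial, per-channel mean over ``window``."""
    mask = window.mask(recording.time_ms)
    if not np.any(mask):
        raise ValueError(f"baseline window {window.name!r} outside the epoch")
    baseline = recording.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(recording, data=recording.data - baseline)
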