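"""Core data containers and the HDF5 session/fixture format.

All on-disk exchange goes through a single HDF5 container with groups
``/session``, ``/localizer``, ``/truth``, ``/wideband`` and (optionally)
``/classifiers`` and ``/hmm``.  Everything in memory is a plain dataclass
wrapping numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "RecordingSession",
    "LocalizerTrials",
    "GroundTruth",
    "SubjectFixture",
    "save_fixture",
    "load_fixture",
]


@dataclass
class RecordingSession:
    """A multichannel recording: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    bad_mask: np.ndarray | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.n_samples, dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (self.n_samples,):
            raise ValueError(
                f"bad_mask length {self.bad_mask.shape} does not match {self.n_samples} samples"
            )
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RecordingSession":
        return RecordingSession(
            self.data.copy(), self.fs, self.bad_mask.copy(), list(self.channel_names)
        )


@dataclass
class LocalizerTrials:
    """Peri-stimulus trials: ``trials`` is n_trials x channels x samples."""

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (n_trials x channels x samples)")
        if self.labels.shape != (self.trials.shape[0],):
            raise ValueError("labels length must match trial count")
        s = self.n_stimuli
        if self.labels.min() < 0 or self.labels.max() >= s:
            raise ValueError("labels must be contiguous 0..S-1")
        counts = np.bincount(self.labels, minlength=s)
        if np.any(counts < 2):
            raise ValueError("every stimulus must appear at least twice for cross-validation")

    @property
    def n_stimuli(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Peri-stimulus sample times in ms relative to stimulus onset."""
        n = self.trials.shape[2]
        return (np.arange(n) / self.fs + self.t0_offset) * 1000.0

    def sample_at(self, time_ms: float) -> int:
        """Index of the peri-stimulus sample closest to ``time_ms`` (exact required)."""
        times = self.times_ms
        idx = int(np.argmin(np.abs(times - time_ms)))
        if abs(times[idx] - time_ms) > 0.5 / self.fs * 1000.0 + 1e-9:
            raise ValueError(f"time {time_ms} ms does not map to a peri-stimulus sample")
        return idx


@dataclass
class GroundTruth:
    """Planted truth carried alongside synthetic fixtures."""

    state_path: np.ndarray
    replay_times: np.ndarray
    replay_lag_ms: float
    coupled_states: frozenset[int] = field(default_factory=frozenset)
    hf_state: int | None = None

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=int)
        self.replay_times = np.asarray(self.replay_times, dtype=int)
        self.coupled_states = frozenset(int(s) for s in self.coupled_states)
        if self.replay_times.size:
            if np.any(np.diff(self.replay_times) <= 0):
                raise ValueError("replay_times must be strictly increasing")
            if self.replay_times.min() < 0 or self.replay_times.max() >= len(self.state_path):
                raise ValueError("replay_times outside [0, T)")


@dataclass
class SubjectFixture:
    """Everything generated for one virtual subject."""

    session: RecordingSession
    localizer: LocalizerTrials
    truth: GroundTruth
    wideband: RecordingSession | None = None
    patterns: np.ndarray | None = None  # S x P planted stimulus patterns
    sequences: tuple[tuple[int, ...], ...] | None = None


def _write_session(grp: h5py.Group, session: RecordingSession) -> None:
    grp.create_dataset("data", data=session.data)
    grp.create_dataset("fs", data=session.fs)
    grp.create_dataset("bad_mask", data=session.bad_mask)
    grp.create_dataset(
        "channel_names", data=np.array(session.channel_names, dtype=h5py.string_dtype())
    )


def _read_session(grp: h5py.Group) -> RecordingSession:
    return RecordingSession(
        data=grp["data"][...],
        fs=float(grp["fs"][()]),
        bad_mask=grp["bad_mask"][...].astype(bool),
        channel_names=[s.decode() if isinstance(s, bytes) else str(s) for s in grp["channel_names"][...]],
    )


def save_fixture(path: str, fixture: SubjectFixture) -> None:
    with h5py.File(path, "w") as f:
        _write_session(f.create_group("session"), fixture.session)
        loc = f.create_group("localizer")
        loc.create_dataset("trials", data=fixture.localizer.trials)
        loc.create_dataset("labels", data=fixture.localizer.labels)
        loc.create_dataset("fs", data=fixture.localizer.fs)
        loc.create_dataset("t0_offset", data=fixture.localizer.t0_offset)
        tr = f.create_group("truth")
        tr.create_dataset("state_path", data=fixture.truth.state_path)
        tr.create_dataset("replay_times", data=fixture.truth.replay_times)
        tr.create_dataset("replay_lag_ms", data=fixture.truth.replay_lag_ms)
        tr.create_dataset("coupled_states", data=sorted(fixture.truth.coupled_states))
        tr.create_dataset(
            "hf_state", data=-1 if fixture.truth.hf_state is None else fixture.truth.hf_state
        )
        if fixture.wideband is not None:
            _write_session(f.create_group("wideband"), fixture.wideband)
        if fixture.patterns is not None:
            f.create_dataset("patterns", data=fixture.patterns)
        if fixture.sequences is not None:
            f.create_dataset("sequences", data=np.asarray(fixture.sequences, dtype=int))


def load_fixture(path: str) -> SubjectFixture:
    with h5py.File(path, "r") as f:
        session = _read_session(f["session"])
        loc = f["localizer"]
        localizer = LocalizerTrials(
            trials=loc["trials"][...],
            labels=loc["labels"][...],
            fs=float(loc["fs"][()]),
            t0_offset=float(loc["t0_offset"][()]),
        )
        tr = f["truth"]
        hf = int(tr["hf_state"][()])
        truth = GroundTruth(
            state_path=tr["state_path"][...],
            replay_times=tr["replay_times"][...],
            replay_lag_ms=float(tr["replay_lag_ms"][()]),
            coupled_states=frozenset(int(s) for s in tr["coupled_states"][...]),
            hf_state=None if hf < 0 else hf,
        )
        wideband = _read_session(f["wideband"]) if "wideband" in f else None
        patterns = f["patterns"][...] if "patterns" in f else None
        sequences = (
            tuple(tuple(int(x) for x in row) for row in f["sequences"][...])
            if "sequences" in f
            else None
        )
    return SubjectFixture(session, localizer, truth, wideband, patterns, sequences)
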