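"""Core containers for scored sleep sessions.

The hypnogram — one brain-state label per fixed-length epoch — is the
coordinate system every analysis in this package runs on.  States are
``'W'`` (wake), ``'N'`` (NREM sleep) and ``'R'`` (REM sleep), annotated
at 2.5 s resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES = ("W", "N", "R")

DEFAULT_EPOCH_S = 2.5


@dataclass
class Hypnogram:
    """Per-epoch brain-state labels with an optional laser mask.

    Parameters
    ----------
    labels : array of str
        One of ``'W'``, ``'N'``, ``'R'`` per epoch.
    epoch_s : float
        Epoch duration in seconds (default 2.5).
    laser : bool array or None
        True where the laser was on during the epoch.
    """

    labels: np.ndarray
    epoch_s: float = DEFAULT_EPOCH_S
    laser: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        bad = ~np.isin(self.labels, STATES)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown state label {self.labels[idx]!r} at epoch {idx}"
            )
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be positive")
        if self.laser is not None:
            self.laser = np.asarray(self.laser, dtype=bool)
            if self.laser.shape != self.labels.shape:
                raise ValueError("laser mask must match labels in length")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def times(self) -> np.ndarray:
        """Epoch start times in seconds."""
        return np.arange(self.n_epochs) * self.epoch_s

    def set_labels(self, start: int, stop: int, label: str) -> None:
        """Manually re-score epochs ``start:stop`` (curation edit API)."""
        if label not in STATES:
            raise ValueError(f"unknown state label {label!r}")
        self.labels[start:stop] = label

    def state_mask(self, state: str) -> np.ndarray:
        return self.labels == state

    def copy(self) -> "Hypnogram":
        return Hypnogram(
            self.labels.copy(),
            self.epoch_s,
            None if self.laser is None else self.laser.copy(),
        )


@dataclass
class LaserSchedule:
    """Laser stimulation trials: onsets, durations, pulse rate, provenance."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    pulse_hz: float = 20.0
    mode: str = "open"  # "open" or "closed"

    def __post_init__(self) -> None:
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        self.durations_s = np.atleast_1d(np.asarray(self.durations_s, dtype=float))
        if self.onsets_s.shape != self.durations_s.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.mode not in ("open", "closed"):
            raise ValueError("mode must be 'open' or 'closed'")

    @property
    def n_trials(self) -> int:
        return self.onsets_s.size

    def intervals(self) -> np.ndarray:
        """(n_trials, 2) array of [onset, offset) in seconds."""
        return np.column_stack([self.onsets_s, self.onsets_s + self.durations_s])

    def mask(self, n_epochs: int, epoch_s: float = DEFAULT_EPOCH_S) -> np.ndarray:
        """Boolean per-epoch laser mask on the hypnogram grid.

        An epoch counts as laser-on if its start falls inside a trial.
        """
        t = np.arange(n_epochs) * epoch_s
        on = np.zeros(n_epochs, dtype=bool)
        for onset, off in self.intervals():
            on |= (t >= onset) & (t < off)
        return on


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) within a recording of known span."""

    times: np.ndarray
    t_end: float
    t_start: float = 0.0
    unit_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and np.any(np.diff(self.times) < 0):
            import warnings

            warnings.warn("spike times were unsorted; sorting", stacklevel=2)
            self.times = np.sort(self.times)
        if self.times.size and (
            self.times[0] < self.t_start or self.times[-1] > self.t_end
        ):
            raise ValueError("spike times fall outside the recording span")

    @property
    def n_spikes(self) -> int:
        return self.times.size


def laser_overlap_mask(
    starts_s: np.ndarray, ends_s: np.ndarray, schedule: LaserSchedule | None
) -> np.ndarray:
    """True for each [start, end) interval intersecting any laser trial."""
    starts_s = np.asarray(starts_s, dtype=float)
    ends_s = np.asarray(ends_s, dtype=float)
    out = np.zeros(starts_s.shape, dtype=bool)
    if schedule is None:
        return out
    for onset, off in schedule.intervals():
        out |= (starts_s < off) & (ends_s > onset)
    return out
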