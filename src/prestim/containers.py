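"""Shared in-memory containers for epochs and pupil traces.

A session is represented by three aligned objects: a pandas ``DataFrame``
trial table (one row per trial), an :class:`EpochSet` holding the
pre-stimulus sensor time series, and a :class:`PupilTrace` holding the
continuous pupil-diameter recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["EpochSet", "PupilTrace"]


@dataclass
class EpochSet:
    """Pre-stimulus sensor time series, one epoch per trial.

    Parameters
    ----------
    values
        Array of shape ``(n_trials, n_sensors, n_samples)`` in sensor units.
        The time axis spans exactly ``window`` seconds ending at stimulus
        onset (half-open interval ``[onset - window, onset)``).
    sampling_rate
        Sampling rate in Hz.
    window
        Epoch duration in seconds before stimulus onset.
    block
        Experimental block index per trial, shape ``(n_trials,)``.
    onsets
        Stimulus onset time of each trial in seconds from the start of the
        recording.  Used to place epoch samples on the session timeline when
        removing per-block linear trends.
    """

    values: np.ndarray
    sampling_rate: float
    window: float
    block: np.ndarray
    onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"epoch array must be (trials, sensors, samples); got shape {self.values.shape}"
            )
        self.block = np.asarray(self.block)
        if self.block.shape[0] != self.values.shape[0]:
            raise ValueError("block labels must align with trials")
        if self.onsets is not None:
            self.onsets = np.asarray(self.onsets, dtype=float)
            if self.onsets.shape[0] != self.values.shape[0]:
                raise ValueError("onsets must align with trials")
        n_expected = int(round(self.window * self.sampling_rate))
        if self.values.shape[2] != n_expected:
            raise ValueError(
                f"time axis has {self.values.shape[2]} samples but window x rate = {n_expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("epoch values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def sample_times(self, trial: int) -> np.ndarray:
        """Absolute time of each sample of one epoch (seconds)."""
        if self.onsets is None:
            onset = trial * self.window + self.window  # contiguous fallback
        else:
            onset = self.onsets[trial]
        return onset - self.window + np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "EpochSet":
        return replace(self, values=self.values.copy())


@dataclass
class PupilTrace:
    """Continuous pupil-diameter recording with per-trial stimulus onsets.

    ``diameter`` is sampled uniformly at ``sampling_rate`` starting at time
    ``t0``; ``onsets`` gives stimulus onset times on the same clock.
    """

    diameter: np.ndarray
    sampling_rate: float
    onsets: np.ndarray
    stimulus_duration: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.diameter.ndim != 1:
            raise ValueError("pupil trace must be one-dimensional")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.diameter.size) / self.sampling_rate

    @property
    def n_trials(self) -> int:
        return self.onsets.size
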