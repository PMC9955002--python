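"""The basic container: one channel's fixed-rate sample series.

A :class:`SignalSegment` is the unit every stage of the pipeline consumes —
a single EEG channel clipped to the analysis window from seizure onset
(4 s at 400 Hz in the reference configuration), optionally carrying its
seizure-type label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

#: The three seizure types the classifier distinguishes: tonic-clonic,
#: complex partial, and electrographic seizures.
SEIZURE_LABELS = ("TCSZ", "CPSZ", "EGSZ")


@dataclass
class SignalSegment:
    """A single-channel, fixed-rate signal segment.

    Parameters
    ----------
    samples : ndarray
        Real-valued sample series ``x(n)``. Unitless for synthetic data,
        microvolts for clinical EEG.
    sampling_rate_hz : float
        Sampling rate in samples per second; must be positive.
    channel_id : str
        Identifier of the originating channel.
    label : str or None
        One of ``TCSZ``, ``CPSZ``, ``EGSZ`` if known.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_id: str = ""
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")
        if not (self.sampling_rate_hz > 0):
            raise InvalidArgumentError("sampling_rate_hz must be positive")
        if self.label is not None and self.label not in SEIZURE_LABELS:
            raise InvalidArgumentError(
                f"label must be one of {SEIZURE_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate_hz
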