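"""Ion-current trace container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceRecording:
    """A sampled ion-current recording.

    Attributes
    ----------
    current
        Current samples, pA.
    sampling_rate
        Acquisition rate, Hz.
    lowpass_cutoff
        Acquisition low-pass filter cutoff, Hz (``None`` if unknown).
    label
        Sample name carried through to event tables.
    metadata
        Free-form acquisition metadata (voltage, electrolyte, seed, ...).
    """

    current: np.ndarray
    sampling_rate: float
    lowpass_cutoff: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1 or self.current.size < 2:
            raise ValueError("current must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current contains missing or non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.current.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.current.size) / self.sampling_rate
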