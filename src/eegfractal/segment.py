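"""Core container for a single-channel EEG segment."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Nominal sampling rate (Hz) of the Bonn benchmark recordings.
BONN_SAMPLING_RATE = 173.61
#: Nominal segment length of the Bonn benchmark files (23.6 s at 173.61 Hz).
BONN_N_SAMPLES = 4097

MIN_SEGMENT_LENGTH = 64


@dataclass
class EEGSegment:
    """A labelled single-channel EEG segment.

    Parameters
    ----------
    samples
        Amplitude sequence in microvolts.
    sampling_rate
        Sampling frequency in Hz.
    label
        Class tag — one of ``A``–``E`` for Bonn-style corpora, or any
        synthetic analogue.
    source_id
        Identifier of the originating file or generator call.
    """

    samples: np.ndarray
    sampling_rate: float = BONN_SAMPLING_RATE
    label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < MIN_SEGMENT_LENGTH:
            raise ValueError(
                f"segment too short: {self.samples.size} < {MIN_SEGMENT_LENGTH}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.sampling_rate
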