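"""In-memory container for multichannel pulse-wave recordings.

A recording holds a set of equally long, uniformly sampled channels
(typically ``ecg``, ``ppg_r``, ``ppg_ir``, ``fcg``) together with the
sampling rate and free-form provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical channel order of the multimodal finger sensor + ECG lead I
CHANNELS = ("ecg", "ppg_r", "ppg_ir", "fcg")
#: the pulse-wave (non-ECG) channels
PW_CHANNELS = ("ppg_r", "ppg_ir", "fcg")
#: the optical channels, emitted with raw (inverted) polarity
PPG_CHANNELS = ("ppg_r", "ppg_ir")


@dataclass
class MultimodalRecording:
    """Equal-length sampled channels at a common sampling rate.

    Parameters
    ----------
    data : pandas.DataFrame
        One column per channel, one row per sample.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Provenance (seed, generator config, processing log, ...).
    """

    data: pd.DataFrame
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.fs

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    def copy(self) -> "MultimodalRecording":
        return MultimodalRecording(self.data.copy(), self.fs, dict(self.meta))
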