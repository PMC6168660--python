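"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: a continuous recording, a set of
fixed-length epochs, a binarized sequence and a diversity score.  Heavy
lifting (filtering, scoring, statistics) lives in the functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AnnotationError

ANNOTATION_COLUMNS = ["onset_s", "duration_s", "condition", "repetition"]


@dataclass
class RawRecording:
    """Continuous multichannel signal with condition annotations.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
    annotations : DataFrame
        Columns ``onset_s, duration_s, condition, repetition``; one row per
        presentation, 0-based half-open intervals in seconds.
    positions : ndarray or None, shape (n_channels, 3)
        Electrode positions (meters, head frame) if a montage is attached.
    meta : dict
        Provenance (generator design/config, seeds, subject id ...).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    annotations: pd.DataFrame
    positions: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match number of channels")
        if self.annotations is not None:
            missing = set(ANNOTATION_COLUMNS) - set(self.annotations.columns)
            if missing:
                raise AnnotationError(f"annotations missing columns: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "RawRecording":
        return RawRecording(
            data=self.data.copy(),
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            annotations=None if self.annotations is None else self.annotations.copy(),
            positions=None if self.positions is None else self.positions.copy(),
            meta=dict(self.meta),
        )


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch labels and a rejection mask.

    ``labels`` has one row per epoch with columns
    ``subject, condition, repetition, session_order`` where ``session_order``
    is a strict total order of epochs within the subject's session.
    Rejected epochs are retained in ``data`` and flagged in ``rejected``.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    sfreq: float
    epoch_length_s: float
    labels: pd.DataFrame
    ch_names: list[str]
    rejected: np.ndarray = None  # type: ignore[assignment]
    positions: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        n_samp = int(round(self.epoch_length_s * self.sfreq))
        if self.data.shape[2] != n_samp:
            raise ValueError(
                f"epochs have {self.data.shape[2]} samples, expected "
                f"{n_samp} = epoch_length_s * sfreq"
            )
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def kept(self) -> np.ndarray:
        """Indices of epochs that survived rejection."""
        return np.flatnonzero(~self.rejected)

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            epoch_length_s=self.epoch_length_s,
            labels=self.labels.copy(),
            ch_names=list(self.ch_names),
            rejected=self.rejected.copy(),
            positions=None if self.positions is None else self.positions.copy(),
            meta=dict(self.meta),
        )


@dataclass
class BinarySequence:
    """A 0/1 symbol sequence derived from one envelope-thresholded signal."""

    bits: np.ndarray  # uint8, values in {0, 1}
    origin: tuple = ("", "")  # (epoch id, channel id | "concatenated")
    threshold_value: float = float("nan")

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def is_constant(self) -> bool:
        return bool(self.bits.size) and bool(np.all(self.bits == self.bits[0]))


@dataclass
class DiversityScore:
    """Raw and surrogate-normalized Lempel-Ziv word counts for one sequence.

    ``normalized = min(1, raw_count / surrogate_count)``; for constant
    sequences (shuffling is the identity) ``degenerate_flag`` is set.
    """

    raw_count: int
    surrogate_count: float
    normalized: float
    kind: str  # {"LZs_channel", "LZs_mean", "LZc"}
    degenerate_flag: bool = False
    origin: tuple = ("", "")

    def __post_init__(self) -> None:
        if not (0.0 <= self.normalized <= 1.0):
            raise ValueError(f"normalized score {self.normalized} outside [0, 1]")
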