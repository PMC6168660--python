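"""Preprocessing chain: FIR filter bank, downsampling, epoching, rejection,
re-referencing and bad-channel interpolation.

The default filter bank reproduces the study's three filters at 500 Hz: a
1 Hz high-pass (order 1650), a 45-55 Hz notch (order 826) and a 100 Hz
low-pass (order 66).  Filters are linear-phase Hamming-window FIRs applied
in a single pass with the group delay compensated (the kernel is centered),
so the net delay is zero and output length equals input length.  Visual
artifact screening is replaced by explicit amplitude and flatline rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .errors import AnnotationError, ChannelError, LengthError, QualityError
from .types import EpochSet, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "default_filter_bank",
    "fir_filter_bank",
    "resample_half",
    "epoch_segments",
    "reject_epochs_auto",
    "rereference_and_interpolate",
]


@dataclass(frozen=True)
class FilterSpec:
    """One linear-phase FIR filter: kind, corner frequency(ies), tap order."""

    kind: str  # {"highpass", "notch", "lowpass"}
    cutoff_hz: float | tuple[float, float]
    order: int
    window: str = "hamming"

    def design(self, sfreq: float) -> np.ndarray:
        """Impulse response (order + 1 taps).  Orders must be even so the
        kernel is symmetric around an integer delay."""
        if self.order <= 0 or self.order % 2:
            raise ValueError("filter order must be a positive even tap count")
        numtaps = self.order + 1
        if self.kind == "highpass":
            return firwin(numtaps, self.cutoff_hz, window=self.window,
                          pass_zero=False, fs=sfreq)
        if self.kind == "lowpass":
            return firwin(numtaps, self.cutoff_hz, window=self.window,
                          pass_zero=True, fs=sfreq)
        if self.kind == "notch":
            lo, hi = self.cutoff_hz  # type: ignore[misc]
            return firwin(numtaps, [lo, hi], window=self.window,
                          pass_zero=True, fs=sfreq)
        raise ValueError(f"unknown filter kind {self.kind!r}")


def default_filter_bank() -> list[FilterSpec]:
    """The study's filter chain (designed for 500 Hz input)."""
    return [
        FilterSpec("highpass", 1.0, 1650),
        FilterSpec("notch", (45.0, 55.0), 826),
        FilterSpec("lowpass", 100.0, 66),
    ]


def fir_filter_bank(
    recording: RawRecording, specs: list[FilterSpec] | None = None
) -> RawRecording:
    """Apply a cascade of zero-net-delay linear-phase FIR filters.

    Each kernel is applied centered (``mode='same'``), which for a
    symmetric FIR equals a single filtering pass shifted back by order/2
    samples; edges are implicitly zero-padded.
    """
    if specs is None:
        specs = default_filter_bank()
    max_order = max(s.order for s in specs)
    if recording.n_samples <= max_order:
        raise LengthError(
            f"signal ({recording.n_samples} samples) not longer than the "
            f"maximum filter order ({max_order})"
        )
    out = recording.copy()
    for spec in specs:
        taps = spec.design(recording.sfreq)
        out.data = fftconvolve(out.data, taps[None, :], mode="same", axes=1)
    out.meta.setdefault("filters", []).extend(specs)
    return out


def resample_half(recording: RawRecording) -> RawRecording:
    """Downsample by a factor of 2 (decimation; anti-aliasing is expected to
    be guaranteed by a preceding low-pass, as in the default bank).

    Output length is floor(n/2); the rate metadata is halved.  Annotations
    are in seconds and carry over unchanged.
    """
    out = recording.copy()
    n = recording.n_samples
    out.data = recording.data[:, : 2 * (n // 2) : 2].copy()
    out.sfreq = recording.sfreq / 2.0
    return out


def epoch_segments(
    recording: RawRecording,
    epoch_length_s: float = 10.0,
    subject=0,
) -> EpochSet:
    """Tile non-overlapping fixed-length epochs within each presentation.

    Epoching restarts at every presentation onset; remainder samples at the
    end of a presentation are dropped.  Epoch labels carry the condition,
    repetition and a strict session order.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    ann = recording.annotations
    if ann is None or len(ann) == 0:
        raise AnnotationError("recording has no condition annotations")
    n_ep_samples = int(round(epoch_length_s * recording.sfreq))
    epochs, rows = [], []
    order = 0
    for _, pres in ann.sort_values("onset_s").iterrows():
        start = int(round(pres["onset_s"] * recording.sfreq))
        n_avail = int(round(pres["duration_s"] * recording.sfreq))
        n_fit = n_avail // n_ep_samples
        if n_fit == 0:
            logger.warning(
                "presentation of condition %r (%.1f s) shorter than the epoch "
                "length; contributes no epochs",
                pres["condition"], pres["duration_s"],
            )
        for k in range(n_fit):
            lo = start + k * n_ep_samples
            epochs.append(recording.data[:, lo : lo + n_ep_samples])
            rows.append(
                {
                    "subject": subject,
                    "condition": pres["condition"],
                    "repetition": int(pres["repetition"]),
                    "session_order": order,
                }
            )
            order += 1
    data = (
        np.stack(epochs)
        if epochs
        else np.empty((0, recording.n_channels, n_ep_samples))
    )
    return EpochSet(
        data=data,
        sfreq=recording.sfreq,
        epoch_length_s=epoch_length_s,
        labels=pd.DataFrame(
            rows, columns=["subject", "condition", "repetition", "session_order"]
        ),
        ch_names=list(recording.ch_names),
        positions=recording.positions,
        meta=dict(recording.meta),
    )


def reject_epochs_auto(
    epochs: EpochSet,
    amp_threshold_uv: float = 100.0,
    flat_threshold_uv: float = 0.1,
) -> EpochSet:
    """Flag epochs with extreme amplitudes or flat channels.

    An epoch is rejected when any sample exceeds ``amp_threshold_uv`` in
    magnitude or any channel's peak-to-peak range falls below
    ``flat_threshold_uv``.  Rejected epochs are retained with the mask set;
    re-applying the same thresholds is a no-op.
    """
    if amp_threshold_uv <= 0 or flat_threshold_uv <= 0:
        raise ValueError("rejection thresholds must be positive")
    out = epochs.copy()
    if epochs.n_epochs == 0:
        return out
    amp_bad = np.abs(epochs.data).max(axis=(1, 2)) > amp_threshold_uv
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    flat_bad = (ptp < flat_threshold_uv).any(axis=1)
    out.rejected = epochs.rejected | amp_bad | flat_bad
    n_new = int(out.rejected.sum() - epochs.rejected.sum())
    if n_new:
        logger.info("rejected %d epochs (amplitude/flatline rules)", n_new)
    if out.rejected.all():
        logger.warning("all epochs rejected")
    return out


def rereference_and_interpolate(
    epochs: EpochSet,
    bad_channels: list[str] | tuple = (),
    scheme: str = "linked_ears",
    ear_names: tuple[str, str] = ("A1", "A2"),
    n_neighbors: int = 4,
) -> EpochSet:
    """Interpolate bad channels, then re-reference every epoch.

    Bad channels are replaced by the inverse-distance-weighted mean of their
    ``n_neighbors`` nearest good neighbors (requires electrode positions).
    ``scheme='average'`` subtracts the instantaneous mean over channels;
    ``'linked_ears'`` subtracts the mean of the two ear channels.
    """
    names = list(epochs.ch_names)
    bad = list(bad_channels)
    unknown = set(bad) - set(names)
    if unknown:
        raise ChannelError(f"bad channels not in recording: {sorted(unknown)}")
    if len(bad) >= len(names):
        raise ChannelError("bad_channels must be a strict subset of channels")
    if len(bad) > 0.25 * len(names):
        raise QualityError(
            f"{len(bad)} of {len(names)} channels bad (> 25%): data not repairable"
        )
    out = epochs.copy()
    if bad:
        if epochs.positions is None:
            raise ChannelError("interpolation requires electrode positions")
        bad_idx = [names.index(b) for b in bad]
        good_idx = [i for i in range(len(names)) if i not in bad_idx]
        for bi in bad_idx:
            d = np.linalg.norm(
                epochs.positions[good_idx] - epochs.positions[bi], axis=1
            )
            nearest = np.argsort(d)[:n_neighbors]
            idx = np.asarray(good_idx)[nearest]
            w = 1.0 / np.maximum(d[nearest], 1e-12)
            w /= w.sum()
            out.data[:, bi, :] = np.einsum("j,ejs->es", w, out.data[:, idx, :])
    if scheme == "average":
        ref = out.data.mean(axis=1, keepdims=True)
    elif scheme == "linked_ears":
        try:
            ears = [names.index(e) for e in ear_names]
        except ValueError as err:
            raise ChannelError(
                f"linked-ears reference requires channels {ear_names}"
            ) from err
        ref = out.data[:, ears, :].mean(axis=1, keepdims=True)
    else:
        raise ValueError("scheme must be 'average' or 'linked_ears'")
    out.data = out.data - ref
    out.meta["reference"] = scheme
    out.meta["interpolated"] = bad
    return out
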