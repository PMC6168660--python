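"""Signal-diversity scoring: LZs (single channel) and LZc (spatio-temporal).

Per 10-s epoch and channel the signal is standardized (demean, divide by SD,
remove linear trend), its Hilbert envelope is thresholded at the envelope
mean to give a binary sequence, and the number of LZ76 words in that sequence
is the raw diversity.  The raw count is normalized by the count of the same
sequence shuffled in time, so scores lie in [0, 1]: 0 for minimally and 1
for maximally diverse signals.

LZs scores each channel independently (and reports the channel mean); LZc
concatenates all channels' binarized envelopes observation-by-observation
(all channels at time step 1, then all at time step 2, ...) and scores the
single concatenated string, capturing diversity over space and time at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend, hilbert

from ._lz76 import lz76_count_bits
from .errors import DegenerateSignalError, EmptyInputError
from .types import BinarySequence, DiversityScore

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_segment",
    "binarize_hilbert",
    "lz76_count",
    "surrogate_normalize",
    "lzs_epoch",
    "lzc_epoch",
    "LzsResult",
]


def standardize_segment(x: np.ndarray) -> np.ndarray:
    """Demean, divide by the standard deviation, then remove a linear trend.

    The three operations are applied in this order.  Raises
    :class:`DegenerateSignalError` for constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize_segment expects a single channel")
    if x.size < 3:
        raise ValueError("segment too short to standardize (need >= 3 samples)")
    sd = x.std()
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError("constant (zero-variance) segment")
    y = (x - x.mean()) / sd
    return detrend(y, type="linear")


def binarize_hilbert(x: np.ndarray, origin: tuple = ("", "")) -> BinarySequence:
    """Binarize at the mean of the Hilbert envelope.

    The envelope is the magnitude of the analytic signal, computed on the
    full segment without padding or tapering.  Bits are 1 where the envelope
    exceeds its mean; values exactly equal to the mean map to 0.
    """
    x = np.asarray(x, dtype=float)
    env = np.abs(hilbert(x))
    return binarize_envelope(env, origin=origin)


def binarize_envelope(env: np.ndarray, origin: tuple = ("", "")) -> BinarySequence:
    """Threshold an envelope at its mean: bit = 1 iff strictly above.

    Values exactly equal to the mean map to 0 (the documented tie rule;
    a measure-zero event for real signals but decisive for edge cases).
    """
    env = np.asarray(env, dtype=float)
    thr = env.mean()
    bits = (env > thr).astype(np.uint8)
    return BinarySequence(bits=bits, origin=origin, threshold_value=float(thr))


def lz76_count(b) -> int:
    """LZ76 exhaustive-history word count of a binary sequence.

    Accepts a :class:`BinarySequence`, a 0/1 array, or a '0'/'1' string.
    """
    if isinstance(b, BinarySequence):
        bits = b.bits
    elif isinstance(b, str):
        bits = np.frombuffer(b.encode(), dtype=np.uint8) - ord("0")
    else:
        bits = np.asarray(b, dtype=np.uint8)
    if bits.size == 0:
        raise EmptyInputError("empty binary sequence")
    return lz76_count_bits(bits)


def surrogate_normalize(
    raw_count: int,
    b: BinarySequence,
    n_surrogates: int = 1,
    seed: int | np.random.SeedSequence | None = 0,
    kind: str = "LZs_channel",
) -> DiversityScore:
    """Normalize a raw LZ76 count by time-shuffled surrogates of the sequence.

    ``surrogate_count`` is the mean word count over ``n_surrogates`` seeded
    uniform permutations; ``normalized = min(1, raw / surrogate)``.  A
    constant sequence is its own shuffle: the score is flagged degenerate.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if b.is_constant:
        logger.warning("constant binary sequence %s: surrogate equals input", b.origin)
        return DiversityScore(
            raw_count=int(raw_count),
            surrogate_count=float(raw_count),
            normalized=1.0,
            kind=kind,
            degenerate_flag=True,
            origin=b.origin,
        )
    rng = np.random.default_rng(seed)
    counts = [
        lz76_count_bits(rng.permutation(b.bits)) for _ in range(int(n_surrogates))
    ]
    surrogate = float(np.mean(counts))
    normalized = min(1.0, raw_count / surrogate)
    if raw_count > surrogate:
        logger.debug("score capped at 1 for %s (raw %d > surrogate %.2f)",
                     b.origin, raw_count, surrogate)
    return DiversityScore(
        raw_count=int(raw_count),
        surrogate_count=surrogate,
        normalized=float(normalized),
        kind=kind,
        degenerate_flag=False,
        origin=b.origin,
    )


@dataclass
class LzsResult:
    """Per-channel LZs scores plus their arithmetic mean."""

    per_channel: list[DiversityScore]
    channel_mean: float


def _binarize_epoch(epoch: np.ndarray, epoch_id="") -> list[BinarySequence]:
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim == 1:
        epoch = epoch[None, :]
    seqs = []
    for ch, x in enumerate(epoch):
        try:
            z = standardize_segment(x)
        except DegenerateSignalError as err:
            raise DegenerateSignalError(f"channel {ch}: {err}") from err
        seqs.append(binarize_hilbert(z, origin=(epoch_id, ch)))
    return seqs


def lzs_epoch(
    epoch: np.ndarray,
    n_surrogates: int = 1,
    seed: int | None = 0,
    epoch_id="",
) -> LzsResult:
    """Single-channel Lempel-Ziv diversity of every channel in one epoch.

    Each channel runs the full standardize -> binarize -> count -> normalize
    pipeline independently; the channel mean is the mean of the normalized
    per-channel scores.  Surrogate shuffles are seeded per channel, so a
    fixed ``seed`` makes the whole result reproducible.
    """
    seqs = _binarize_epoch(epoch, epoch_id)
    ss = np.random.SeedSequence(seed).spawn(len(seqs))
    scores = []
    for b, child in zip(seqs, ss):
        raw = lz76_count_bits(b.bits)
        scores.append(
            surrogate_normalize(raw, b, n_surrogates, child, kind="LZs_channel")
        )
    mean = float(np.mean([s.normalized for s in scores]))
    return LzsResult(per_channel=scores, channel_mean=mean)


def lzc_epoch(
    epoch: np.ndarray,
    n_surrogates: int = 1,
    seed: int | None = 0,
    epoch_id="",
    surrogate_scope: str = "full",
) -> DiversityScore:
    """Spatio-temporal Lempel-Ziv diversity of one multichannel epoch.

    Channels are binarized exactly as for LZs, then concatenated
    channel-major within each time step (the first ``n_channels`` symbols are
    all channels at time step 1, and so on).  The LZ76 count of the
    concatenated string is normalized against shuffled surrogates.

    ``surrogate_scope='full'`` permutes the whole concatenated string
    (destroying spatial and temporal structure symmetrically);
    ``'within_channel'`` permutes each channel's bits in place before
    re-concatenating, preserving the marginal bit patterns per channel.
    """
    seqs = _binarize_epoch(epoch, epoch_id)
    stacked = np.vstack([b.bits for b in seqs])  # channels x samples
    concat = np.ascontiguousarray(stacked.T.reshape(-1))  # time-major
    b = BinarySequence(bits=concat, origin=(epoch_id, "concatenated"))
    raw = lz76_count_bits(b.bits)
    if surrogate_scope == "full":
        return surrogate_normalize(raw, b, n_surrogates, seed, kind="LZc")
    if surrogate_scope != "within_channel":
        raise ValueError("surrogate_scope must be 'full' or 'within_channel'")
    if b.is_constant:
        return surrogate_normalize(raw, b, n_surrogates, seed, kind="LZc")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(int(n_surrogates)):
        shuffled = np.vstack([rng.permutation(row) for row in stacked])
        counts.append(lz76_count_bits(np.ascontiguousarray(shuffled.T.reshape(-1))))
    surrogate = float(np.mean(counts))
    return DiversityScore(
        raw_count=int(raw),
        surrogate_count=surrogate,
        normalized=float(min(1.0, raw / surrogate)),
        kind="LZc",
        origin=b.origin,
    )
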