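"""Synthetic multichannel EEG sessions with the study's design.

A session is a randomized sequence of presentations: 7 conditions (5 speech
speeds, backward speech, resting-state) x 4 presentations x 90 s each, 64
channels.  Each channel is a linear mixture of unit-variance sources, and
each source is a mixture of 1/f^alpha broadband background and narrowband
(alpha-band by default) filtered noise.  The narrowband fraction is the
diversity dial: narrowband-dominated signals have slowly varying Hilbert
envelopes, hence fewer Lempel-Ziv words after envelope binarization, hence
lower normalized diversity.  Rhythmicity per condition and a linear
time-on-task drift across presentations are therefore controllable, letting
every downstream stage (preprocessing, scoring, statistics) be tested with
known ground truth.

Generation is a pure function of (SessionDesign, GeneratorConfig): the same
seed reproduces the session bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import montage
from .errors import ConfigError, InvalidDesignError, RangeError
from .types import RawRecording

logger = logging.getLogger(__name__)

#: Condition labels of the study: five presentation speeds (% of original),
#: time-reversed speech, and eyes-open rest with no stimulation.
STUDY_CONDITIONS = ["65", "83", "100", "117", "135", "backward", "resting-state"]
SPEED_CONDITIONS = ["65", "83", "100", "117", "135"]
MEANING_CONDITIONS = ["100", "backward", "resting-state"]


@dataclass(frozen=True)
class SessionDesign:
    """Randomized presentation schedule of one recording session."""

    conditions: tuple[str, ...]
    presentations_per_condition: int
    presentation_duration_s: float
    sampling_rate_hz: float
    n_channels: int
    presentation_order: tuple[tuple[str, int], ...]
    seed: int

    @property
    def n_presentations(self) -> int:
        return len(self.presentation_order)

    @property
    def total_duration_s(self) -> float:
        return self.n_presentations * self.presentation_duration_s

    def annotation_table(self) -> pd.DataFrame:
        """One row per presentation: onset/duration in seconds, 0-based
        half-open intervals, in session order."""
        rows = []
        t = 0.0
        for cond, rep in self.presentation_order:
            rows.append(
                {
                    "onset_s": t,
                    "duration_s": self.presentation_duration_s,
                    "condition": cond,
                    "repetition": rep,
                }
            )
            t += self.presentation_duration_s
        return pd.DataFrame(rows)


def build_design(
    conditions: list[str] | None = None,
    presentations_per_condition: int = 4,
    presentation_duration_s: float = 90.0,
    sampling_rate_hz: float = 250.0,
    n_channels: int = 64,
    seed: int = 0,
) -> SessionDesign:
    """Build a randomized session design (defaults reproduce the study).

    Every (condition, repetition) pair appears exactly once; the order is a
    seeded uniform permutation, reproducible from ``seed``.
    """
    if conditions is None:
        conditions = STUDY_CONDITIONS
    conditions = [str(c) for c in conditions]
    if len(conditions) == 0 or len(set(conditions)) != len(conditions):
        raise InvalidDesignError("conditions must be a non-empty list of unique labels")
    if presentations_per_condition <= 0:
        raise InvalidDesignError("presentations_per_condition must be positive")
    if presentation_duration_s <= 0:
        raise InvalidDesignError("presentation_duration_s must be positive")
    if sampling_rate_hz <= 0 or n_channels <= 0:
        raise InvalidDesignError("sampling rate and channel count must be positive")
    pairs = [(c, r) for c in conditions for r in range(presentations_per_condition)]
    rng = np.random.default_rng(seed)
    order = [pairs[i] for i in rng.permutation(len(pairs))]
    return SessionDesign(
        conditions=tuple(conditions),
        presentations_per_condition=int(presentations_per_condition),
        presentation_duration_s=float(presentation_duration_s),
        sampling_rate_hz=float(sampling_rate_hz),
        n_channels=int(n_channels),
        presentation_order=tuple(order),
        seed=int(seed),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic EEG generator.

    ``narrowband_fraction`` maps condition label -> fraction of source
    variance carried by the narrowband oscillation (a scalar applies to all
    conditions).  Higher fractions mean more rhythmic signals and lower
    Lempel-Ziv diversity.  ``drift_slope`` adds ``slope * presentation_index``
    to the fraction, emulating a gradual vigilance change over the session.
    ``channel_mixing`` is an (n_channels x n_sources) matrix with unit-norm
    rows; ``None`` selects the default: one global source shared by all
    channels (variance fraction ``shared_variance``) plus one private source
    per channel.
    """

    spectral_exponent: float = 1.0
    osc_freq_hz: float = 10.0
    osc_bandwidth_hz: float = 2.0
    osc_amplitude: float = 1.0
    narrowband_fraction: float | dict = 0.3
    channel_mixing: np.ndarray | None = None
    shared_variance: float = 0.1
    drift_slope: float = 0.0
    noise_floor: float = 0.02
    amplitude_uv: float = 20.0
    seed: int = 0

    def fraction_for(self, condition: str) -> float:
        if isinstance(self.narrowband_fraction, dict):
            if condition not in self.narrowband_fraction:
                raise ConfigError(f"no narrowband_fraction for condition {condition!r}")
            return float(self.narrowband_fraction[condition])
        return float(self.narrowband_fraction)

    def with_fractions(self, fractions: dict) -> "GeneratorConfig":
        return replace(self, narrowband_fraction=dict(fractions))


def default_mixing(n_channels: int, shared_variance: float = 0.1) -> np.ndarray:
    """One shared source plus one private source per channel, unit-norm rows.

    Pairwise channel correlation equals ``shared_variance``.
    """
    if not 0.0 <= shared_variance < 1.0:
        raise ConfigError("shared_variance must be in [0, 1)")
    w = np.zeros((n_channels, n_channels + 1))
    w[:, 0] = np.sqrt(shared_variance)
    w[np.arange(n_channels), np.arange(n_channels) + 1] = np.sqrt(1.0 - shared_variance)
    return w


def colored_noise(n: int, exponent: float, sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def narrowband_noise(
    n: int, center_hz: float, bandwidth_hz: float, sfreq: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited noise (boxcar in the frequency domain).

    The envelope fluctuates on the ~1/bandwidth timescale, so the signal is
    rhythmic with a slowly varying amplitude.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    mask = (f >= center_hz - bandwidth_hz / 2.0) & (f <= center_hz + bandwidth_hz / 2.0)
    if not mask.any():
        raise ConfigError("narrowband passband contains no FFT bins")
    x = np.fft.irfft(spec * mask, n)
    return x / x.std()


def _validate_mixing(mixing: np.ndarray, n_channels: int) -> np.ndarray:
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[0] != n_channels:
        raise ConfigError(
            f"channel_mixing must have {n_channels} rows, got shape {mixing.shape}"
        )
    norms = np.linalg.norm(mixing, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ConfigError("channel_mixing rows must have unit norm")
    return mixing


def generate_session(design: SessionDesign, cfg: GeneratorConfig) -> RawRecording:
    """Render a full session: mixed 1/f background + narrowband rhythm.

    Per presentation the narrowband fraction is the condition's fraction plus
    ``drift_slope * presentation_index``; a fraction outside [0, 1] raises
    :class:`RangeError`.  Fully deterministic for a fixed (design, cfg).
    """
    mixing = (
        default_mixing(design.n_channels, cfg.shared_variance)
        if cfg.channel_mixing is None
        else _validate_mixing(cfg.channel_mixing, design.n_channels)
    )
    n_sources = mixing.shape[1]
    fs = design.sampling_rate_hz
    n_per = int(round(design.presentation_duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, cfg.seed)))

    fractions = []
    for idx, (cond, _rep) in enumerate(design.presentation_order):
        frac = cfg.fraction_for(cond) + cfg.drift_slope * idx
        if not 0.0 <= frac <= 1.0:
            raise RangeError(
                f"narrowband fraction {frac:.3f} outside [0, 1] at presentation "
                f"{idx} (condition {cond!r})"
            )
        fractions.append(frac)

    segments = []
    for frac in fractions:
        sources = np.empty((n_sources, n_per))
        for j in range(n_sources):
            bg = colored_noise(n_per, cfg.spectral_exponent, fs, rng)
            nb = narrowband_noise(n_per, cfg.osc_freq_hz, cfg.osc_bandwidth_hz, fs, rng)
            src = np.sqrt(1.0 - frac) * bg + np.sqrt(frac) * cfg.osc_amplitude * nb
            sources[j] = src / src.std()
        seg = mixing @ sources
        if cfg.noise_floor > 0.0:
            seg = (
                np.sqrt(1.0 - cfg.noise_floor) * seg
                + np.sqrt(cfg.noise_floor) * rng.standard_normal(seg.shape)
            )
        segments.append(seg)

    data = cfg.amplitude_uv * np.concatenate(segments, axis=1)
    ch_names, positions = montage.default_layout(design.n_channels)
    return RawRecording(
        data=data,
        sfreq=fs,
        ch_names=ch_names,
        annotations=design.annotation_table(),
        positions=positions,
        meta={
            "design": design,
            "cfg": cfg,
            "narrowband_fractions": fractions,
            "seed": design.seed,
            "generator": "diversitrace.synthgen",
        },
    )


def _provenance(recording: RawRecording) -> tuple[SessionDesign, GeneratorConfig]:
    design = recording.meta.get("design")
    cfg = recording.meta.get("cfg")
    if design is None or cfg is None:
        raise ConfigError(
            "recording lacks generator provenance; effects can only be injected "
            "into sessions produced by generate_session"
        )
    return design, cfg


def inject_condition_effects(recording: RawRecording, effect_map: dict) -> RawRecording:
    """Re-render the session with per-condition narrowband-fraction offsets.

    Positive offsets make a condition more rhythmic, hence lower diversity.
    Zero offsets reproduce the input exactly (generation is pure).
    """
    design, cfg = _provenance(recording)
    unknown = set(effect_map) - set(design.conditions)
    if unknown:
        raise ConfigError(f"effect_map references unknown conditions: {sorted(unknown)}")
    fractions = {c: cfg.fraction_for(c) for c in design.conditions}
    for cond, offset in effect_map.items():
        new = fractions[cond] + float(offset)
        if not 0.0 <= new <= 1.0:
            raise RangeError(
                f"offset {offset:+.3f} pushes condition {cond!r} fraction to "
                f"{new:.3f}, outside [0, 1]"
            )
        fractions[cond] = new
    return generate_session(design, cfg.with_fractions(fractions))


def inject_vigilance_drift(recording: RawRecording, drift_slope: float) -> RawRecording:
    """Re-render the session with a linear narrowband-fraction drift.

    The fraction changes by ``drift_slope`` per presentation index; a slope
    of 0 leaves the session stationary.  A drift that exits [0, 1] anywhere
    in the session raises :class:`RangeError`.
    """
    design, cfg = _provenance(recording)
    return generate_session(design, replace(cfg, drift_slope=float(drift_slope)))


def inject_transient(
    recording: RawRecording,
    time_s: float,
    amplitude_uv: float = 500.0,
    width_s: float = 0.2,
    channel: int = 0,
) -> RawRecording:
    """Add a high-amplitude Gaussian transient (artifact) to one channel.

    Used only to exercise automatic epoch rejection; real artifact
    morphologies (blinks, EMG) are not modeled.
    """
    out = recording.copy()
    t = np.arange(out.n_samples) / out.sfreq
    out.data[channel] += amplitude_uv * np.exp(-0.5 * ((t - time_s) / (width_s / 4)) ** 2)
    return out
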