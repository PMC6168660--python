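"""Tests for the preprocessing chain: filters, decimation, epoching,
rejection and re-referencing."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import freqz

from diversitrace.errors import AnnotationError, ChannelError, LengthError, QualityError
from diversitrace.montage import fibonacci_sphere
from diversitrace.preprocess import (
    FilterSpec,
    default_filter_bank,
    epoch_segments,
    fir_filter_bank,
    reject_epochs_auto,
    rereference_and_interpolate,
    resample_half,
)
from diversitrace.synthgen import GeneratorConfig, build_design, generate_session
from diversitrace.types import EpochSet, RawRecording


def _recording_from(data, sfreq=500.0, annotations=None, positions=None):
    n_ch = data.shape[0]
    return RawRecording(
        data=data,
        sfreq=sfreq,
        ch_names=[f"CH{i}" for i in range(n_ch)],
        annotations=annotations,
        positions=positions,
    )


def _bank_response(freq_hz, sfreq=500.0):
    """Designed frequency response of the default cascade at one frequency."""
    h = 1.0 + 0.0j
    for spec in default_filter_bank():
        w, resp = freqz(spec.design(sfreq), worN=[freq_hz], fs=sfreq)
        h *= resp[0]
    return abs(h)


class TestFilterBank:
    @pytest.mark.parametrize("freq,bound", [(0.1, 0.1), (50.0, 0.1)])
    def test_stopband_attenuation(self, freq, bound):
        # power <= 1% means amplitude <= 10%
        assert _bank_response(freq) <= bound

    def test_passband_preserved_at_10hz(self):
        assert _bank_response(10.0) == pytest.approx(1.0, abs=0.05)

    def test_time_domain_passband(self):
        t = np.arange(8000) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        out = fir_filter_bank(_recording_from(x[None, :])).data[0]
        interior = slice(2000, 6000)
        assert np.max(np.abs(out[interior])) == pytest.approx(1.0, abs=0.05)

    def test_output_length_equals_input(self):
        x = np.random.default_rng(0).standard_normal((2, 4000))
        out = fir_filter_bank(_recording_from(x))
        assert out.data.shape == x.shape

    def test_short_signal_rejected(self):
        with pytest.raises(LengthError):
            fir_filter_bank(_recording_from(np.zeros((1, 1000))))

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 4000))
        y = rng.standard_normal((1, 4000))
        lhs = fir_filter_bank(_recording_from(2 * x + 3 * y)).data
        rhs = 2 * fir_filter_bank(_recording_from(x)).data + 3 * fir_filter_bank(
            _recording_from(y)
        ).data
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("lowpass", 30.0, 67).design(500.0)


class TestResample:
    def test_decimation_arithmetic(self):
        rec = _recording_from(np.zeros((1, 5000)), sfreq=500.0)
        out = resample_half(rec)
        assert out.data.shape[1] == 2500
        assert out.sfreq == 250.0

    def test_sinusoid_preserved(self):
        t = np.arange(5000) / 500.0
        rec = _recording_from(np.sin(2 * np.pi * 10 * t)[None, :])
        out = resample_half(rec)
        expected = np.sin(2 * np.pi * 10 * np.arange(2500) / 250.0)
        assert np.allclose(out.data[0], expected, atol=0.02)


class TestEpoching:
    def test_full_study_design_epoch_count(self):
        design = build_design(sampling_rate_hz=250.0, n_channels=2, seed=1)
        rec = generate_session(design, GeneratorConfig(seed=1))
        epochs = epoch_segments(rec, 10.0)
        assert epochs.n_epochs == 252
        assert (epochs.labels.groupby("condition").size() == 36).all()
        orders = epochs.labels["session_order"].to_numpy()
        assert np.array_equal(np.sort(orders), np.arange(252))

    def test_remainder_dropped(self):
        ann = pd.DataFrame(
            [{"onset_s": 0.0, "duration_s": 95.0, "condition": "a", "repetition": 0}]
        )
        rec = _recording_from(np.zeros((1, 95 * 100)), sfreq=100.0, annotations=ann)
        epochs = epoch_segments(rec, 10.0)
        assert epochs.n_epochs == 9  # 5 s discarded

    def test_short_presentation_contributes_nothing(self, caplog):
        ann = pd.DataFrame(
            [
                {"onset_s": 0.0, "duration_s": 4.0, "condition": "a", "repetition": 0},
                {"onset_s": 4.0, "duration_s": 20.0, "condition": "b", "repetition": 0},
            ]
        )
        rec = _recording_from(np.zeros((1, 2400)), sfreq=100.0, annotations=ann)
        with caplog.at_level("WARNING"):
            epochs = epoch_segments(rec, 10.0)
        assert epochs.n_epochs == 2
        assert "shorter than the epoch length" in caplog.text

    def test_missing_annotations(self):
        rec = _recording_from(np.zeros((1, 1000)))
        with pytest.raises(AnnotationError):
            epoch_segments(rec, 10.0)

    def test_sample_conservation_per_presentation(self):
        # kept + discarded remainder = presentation samples
        ann = pd.DataFrame(
            [{"onset_s": 0.0, "duration_s": 37.0, "condition": "a", "repetition": 0}]
        )
        rec = _recording_from(np.zeros((1, 3700)), sfreq=100.0, annotations=ann)
        epochs = epoch_segments(rec, 10.0)
        kept = epochs.n_epochs * 1000
        assert kept + (3700 - kept) == 3700
        assert epochs.n_epochs == 3


def _epochset(data, positions=None, names=None):
    n_ep, n_ch, n_samp = data.shape
    labels = pd.DataFrame(
        {
            "subject": 0,
            "condition": "a",
            "repetition": 0,
            "session_order": np.arange(n_ep),
        }
    )
    return EpochSet(
        data=data,
        sfreq=100.0,
        epoch_length_s=n_samp / 100.0,
        labels=labels,
        ch_names=names or [f"CH{i}" for i in range(n_ch)],
        positions=positions,
    )


class TestRejection:
    def test_clean_epochs_survive(self, rng):
        epochs = _epochset(10 * rng.standard_normal((6, 3, 200)))
        out = reject_epochs_auto(epochs, 100.0, 0.1)
        assert out.rejected.sum() == 0

    def test_planted_transient_rejected(self, rng):
        data = 10 * rng.standard_normal((6, 3, 200))
        data[4, 1, 50] = 500.0
        out = reject_epochs_auto(_epochset(data), 100.0, 0.1)
        assert list(np.flatnonzero(out.rejected)) == [4]

    def test_flatline_rejected(self, rng):
        data = 10 * rng.standard_normal((5, 3, 200))
        data[2, 0, :] = 0.0
        out = reject_epochs_auto(_epochset(data), 100.0, 0.1)
        assert list(np.flatnonzero(out.rejected)) == [2]

    def test_idempotent(self, rng):
        data = 10 * rng.standard_normal((8, 2, 200))
        data[0, 0, 10] = 900.0
        once = reject_epochs_auto(_epochset(data), 100.0, 0.1)
        twice = reject_epochs_auto(once, 100.0, 0.1)
        assert np.array_equal(once.rejected, twice.rejected)


class TestRereference:
    def test_average_reference_zeroes_channel_mean(self, rng):
        epochs = _epochset(rng.standard_normal((4, 6, 200)))
        out = rereference_and_interpolate(epochs, scheme="average")
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_linked_ears_reference(self, rng):
        names = ["F1", "F2", "A1", "A2"]
        epochs = _epochset(rng.standard_normal((3, 4, 200)), names=names)
        out = rereference_and_interpolate(epochs, scheme="linked_ears")
        ears = out.data[:, 2:4, :].mean(axis=1)
        assert np.allclose(ears, 0.0, atol=1e-12)

    def test_missing_ears_error(self, rng):
        epochs = _epochset(rng.standard_normal((2, 3, 200)))
        with pytest.raises(ChannelError):
            rereference_and_interpolate(epochs, scheme="linked_ears")

    def test_interpolation_recovers_common_signal(self, rng):
        common = rng.standard_normal(200)
        data = np.tile(common, (2, 6, 1))
        data[:, 3, :] = 777.0  # corrupt one channel
        epochs = _epochset(data, positions=fibonacci_sphere(6))
        out = rereference_and_interpolate(epochs, bad_channels=["CH3"], scheme="average")
        # after average reference all channels share the same signal => zero
        assert np.allclose(out.data[:, 3, :], out.data[:, 0, :], atol=1e-9)

    def test_too_many_bad_channels(self, rng):
        epochs = _epochset(rng.standard_normal((2, 8, 200)),
                           positions=fibonacci_sphere(8))
        with pytest.raises(QualityError):
            rereference_and_interpolate(
                epochs, bad_channels=["CH0", "CH1", "CH2"], scheme="average"
            )

    def test_bad_channels_strict_subset(self, rng):
        epochs = _epochset(rng.standard_normal((2, 2, 200)))
        with pytest.raises(ChannelError):
            rereference_and_interpolate(
                epochs, bad_channels=["CH0", "CH1"], scheme="average"
            )
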