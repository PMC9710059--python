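"""Preprocessing contracts: filter magnitude response, resampling,
blind segmentation, min-max normalisation and subject-disjoint splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from leadconv.preprocess import (
    DegenerateSegmentError,
    FilterSpec,
    InvalidFilterSpecError,
    MetadataError,
    MissingLeadError,
    SegmentDataset,
    SignalLengthError,
    SplitSpec,
    bandpass_filter,
    blind_segment,
    minmax_normalise,
    preprocess_pipeline,
    resample,
    subject_split,
)
from leadconv.records import EcgRecord


def analytic_attenuation_db(freq, fs, spec=FilterSpec()):
    """Magnitude response of the Butterworth band-pass, doubled in dB for
    the forward-backward (zero-phase) application."""
    b, a = sps.butter(spec.order, [spec.fc_low, spec.fc_high],
                      btype="bandpass", fs=fs)
    _, h = sps.freqz(b, a, worN=[freq], fs=fs)
    return -2 * 20 * np.log10(np.abs(h[0]))


def sinusoid(freq, fs, seconds):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpassFilter:
    def test_passband_sinusoid_preserved(self):
        x = sinusoid(10.0, 1000.0, 5.0)
        y = bandpass_filter(x, 1000.0)
        rms_in = np.sqrt(np.mean(x ** 2))
        rms_out = np.sqrt(np.mean(y ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_subhertz_sinusoid_attenuated(self):
        x = sinusoid(0.1, 1000.0, 30.0)
        y = bandpass_filter(x, 1000.0)
        att_db = -20 * np.log10(np.sqrt(np.mean(y ** 2))
                                / np.sqrt(np.mean(x ** 2)))
        assert att_db >= 20.0

    @pytest.mark.parametrize("freq,seconds", [(0.1, 40.0), (10.0, 5.0),
                                              (80.0, 20.0)])
    def test_attenuation_matches_analytic_response(self, freq, seconds):
        fs = 1000.0
        x = sinusoid(freq, fs, seconds)
        y = bandpass_filter(x, fs)
        # discard edge transients before measuring
        n = len(x) // 10
        measured = -20 * np.log10(
            np.sqrt(np.mean(y[n:-n] ** 2)) / np.sqrt(np.mean(x[n:-n] ** 2)))
        assert measured == pytest.approx(
            analytic_attenuation_db(freq, fs), abs=1.0)

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass_filter(np.zeros(1000), 500.0), 0.0)

    def test_invalid_spec_and_short_signal(self):
        with pytest.raises(InvalidFilterSpecError):
            bandpass_filter(np.ones(100), 60.0)  # 40 Hz >= Nyquist of 60 Hz
        with pytest.raises(SignalLengthError):
            bandpass_filter(np.ones(5), 1000.0)
        with pytest.raises(InvalidFilterSpecError):
            FilterSpec(order=0)
        with pytest.raises(InvalidFilterSpecError):
            FilterSpec(fc_low=50.0, fc_high=10.0)


class TestResample:
    def test_output_length_rule(self):
        y = resample(np.random.default_rng(0).standard_normal(7710),
                     257.0, 1000.0)
        assert len(y) == 30000

    def test_identity_when_rates_match(self):
        x = np.arange(100.0)
        np.testing.assert_array_equal(resample(x, 250.0, 250.0), x)

    def test_sinusoid_resampled_accurately(self):
        x = sinusoid(5.0, 257.0, 10.0)
        y = resample(x, 257.0, 1000.0)
        ref = sinusoid(5.0, 1000.0, len(y) / 1000.0)[:len(y)]
        assert np.corrcoef(y, ref)[0, 1] >= 0.999

    def test_empty_input_rejected(self):
        with pytest.raises(SignalLengthError):
            resample(np.empty(0), 100.0, 200.0)


class TestBlindSegment:
    def _record(self, seconds, fs=1000.0):
        n = int(round(seconds * fs))
        sig = np.arange(n, dtype=float)[:, None] * np.ones((1, 2))
        return EcgRecord(sig, fs, ("I", "II"), "s", "r")

    def test_counts_and_offsets(self):
        groups = blind_segment(self._record(32.4), 5.0)
        assert len(groups) == 6
        assert [g["I"].offset for g in groups] == [0, 5000, 10000,
                                                   15000, 20000, 25000]

    def test_exact_and_short_records(self):
        assert len(blind_segment(self._record(5.0), 5.0)) == 1
        assert blind_segment(self._record(4.9), 5.0) == []

    def test_concatenation_reproduces_cropped_prefix(self):
        record = self._record(12.3)
        groups = blind_segment(record, 5.0)
        joined = np.concatenate([g["II"].samples for g in groups])
        np.testing.assert_array_equal(joined, record.lead("II")[:10000])


class TestMinmaxNormalise:
    def _seg(self, samples):
        from leadconv.preprocess import Segment
        return Segment(np.asarray(samples, float), "I", 100.0, "s", "r", 0)

    @pytest.mark.parametrize("samples,expected", [
        ([0, 5, 10], [-1, 0, 1]),
        ([-2, -2, 2], [-1, -1, 1]),
    ])
    def test_hand_worked_examples(self, samples, expected):
        out = minmax_normalise(self._seg(samples))
        np.testing.assert_allclose(out.samples, expected)
        assert out.normalised

    def test_idempotent_on_full_span_input(self):
        first = minmax_normalise(self._seg([0.0, 0.25, 1.0]))
        again = minmax_normalise(self._seg(first.samples))
        np.testing.assert_allclose(again.samples, first.samples)

    def test_flat_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError, match="flat"):
            minmax_normalise(self._seg([3.0, 3.0, 3.0]))

    def test_double_normalisation_rejected(self):
        with pytest.raises(ValueError, match="already"):
            minmax_normalise(minmax_normalise(self._seg([0.0, 1.0])))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_span_is_exact_for_non_degenerate_input(self, samples):
        if max(samples) == min(samples):
            return
        out = minmax_normalise(self._seg(samples))
        assert out.samples.min() == pytest.approx(-1.0, abs=1e-9)
        assert out.samples.max() == pytest.approx(1.0, abs=1e-9)


def _records_for_subjects(subjects, n_samples=100):
    recs = []
    for i, s in enumerate(subjects):
        sig = np.random.default_rng(i).standard_normal((n_samples, 2))
        recs.append(EcgRecord(sig, 100.0, ("I", "II"), s, f"{s}_r{i}"))
    return recs


class TestSubjectSplit:
    def test_each_subject_in_exactly_one_set(self):
        recs = _records_for_subjects(["A", "B", "C", "D"])
        tr, va, te = subject_split(recs, SplitSpec((0.5, 0.25, 0.25), seed=0))
        sets = [set(r.subject_id for r in part) for part in (tr, va, te)]
        assert sets[0] | sets[1] | sets[2] == {"A", "B", "C", "D"}
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_explicit_test_subjects(self):
        recs = _records_for_subjects(["A", "B", "C", "D"]) * 2
        tr, va, te = subject_split(
            recs, SplitSpec(test_subjects=("A",), seed=0))
        assert {r.subject_id for r in te} == {"A"}
        assert "A" not in {r.subject_id for r in tr + va}

    def test_same_seed_identical_partition(self):
        recs = _records_for_subjects([f"S{i}" for i in range(10)])
        a = subject_split(recs, SplitSpec(seed=42))
        b = subject_split(recs, SplitSpec(seed=42))
        for pa, pb in zip(a, b):
            assert [r.record_id for r in pa] == [r.record_id for r in pb]

    def test_conflicting_subject_metadata_rejected(self):
        r1 = EcgRecord(np.ones((10, 1)), 10.0, ("I",), "A", "rec")
        r2 = EcgRecord(np.ones((10, 1)), 10.0, ("I",), "B", "rec")
        with pytest.raises(MetadataError):
            subject_split([r1, r2], SplitSpec())

    @given(st.integers(0, 10_000), st.integers(3, 12))
    @settings(max_examples=60, deadline=None)
    def test_disjointness_for_random_seeds(self, seed, n_subjects):
        recs = _records_for_subjects([f"S{i}" for i in range(n_subjects)],
                                     n_samples=10)
        tr, va, te = subject_split(recs, SplitSpec(seed=seed))
        sets = [set(r.subject_id for r in part) for part in (tr, va, te)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert len(tr) + len(va) + len(te) == len(recs)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.2, 0.2))


class TestPipeline:
    def test_two_groups_from_ten_second_record(self, small_records):
        ds = preprocess_pipeline(small_records[:1], window_seconds=5.0,
                                 fs_target=250.0)
        assert len(ds) == 2
        assert list(ds.offsets) == [0, 1250]
        assert set(ds.leads) == set(small_records[0].lead_names)

    def test_missing_lead_error_names_lead(self):
        rec = EcgRecord(np.random.default_rng(0).standard_normal((1000, 2)),
                        250.0, ("I", "II"), "s", "r")
        with pytest.raises(MissingLeadError, match="V1"):
            preprocess_pipeline([rec], 2.0, fs_target=250.0,
                                leads=("I", "II", "V1"))

    def test_flat_window_drops_whole_group(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((1000, 2))
        sig[500:, 0] = 2.0  # lead I flat in the second window
        rec = EcgRecord(sig, 250.0, ("I", "II"), "s", "r")
        ds = preprocess_pipeline([rec], 2.0, fs_target=250.0,
                                 leads=("I", "II"))
        assert len(ds) == 1
        assert len(ds.dropped) == 1
        assert ds.dropped[0]["offset"] == 500

    def test_normalisation_span_exact(self, limb_dataset):
        for lead in limb_dataset.leads:
            x = limb_dataset.X[lead]
            np.testing.assert_allclose(x.min(axis=1), -1.0, atol=1e-9)
            np.testing.assert_allclose(x.max(axis=1), 1.0, atol=1e-9)

    def test_pipeline_deterministic(self, small_records):
        a = preprocess_pipeline(small_records[:2], 2.5, fs_target=200.0)
        b = preprocess_pipeline(small_records[:2], 2.5, fs_target=200.0)
        for lead in a.leads:
            np.testing.assert_array_equal(a.X[lead], b.X[lead])

    def test_alignment_preserved_across_leads(self, limb_dataset):
        assert len({len(limb_dataset.X[lead]) for lead in limb_dataset.leads}) == 1
        # same record/offset bookkeeping for every row
        assert len(limb_dataset.subject_ids) == len(limb_dataset)

    def test_normalise_before_filter_still_spans(self, small_records):
        ds = preprocess_pipeline(small_records[:1], 2.5, fs_target=250.0,
                                 leads=("I", "II"),
                                 normalise_before_filter=True)
        for lead in ds.leads:
            np.testing.assert_allclose(ds.X[lead].min(axis=1), -1.0, atol=1e-9)

    def test_save_load_round_trip(self, tmp_path, limb_dataset):
        limb_dataset.save(tmp_path / "ds")
        back = SegmentDataset.load(tmp_path / "ds")
        assert back.manifest_hash() == limb_dataset.manifest_hash()
        for lead in limb_dataset.leads:
            np.testing.assert_array_equal(back.X[lead], limb_dataset.X[lead])
        assert back.subject_ids == limb_dataset.subject_ids
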