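import numpy as np
import pytest

from tvv import ecg_io
from tvv.ecg_io import (AnnotatedEcg, BeatAnnotation, EcgIoError,
                        InsufficientBeatsError, MissingLeadError, StudyKey,
                        baseline_correct, bessel_lowpass, load_annotated_ecg)


def _quantized(ecg: AnnotatedEcg, step: float = 1e-3) -> AnnotatedEcg:
    sig = np.round(ecg.signal / step) / (1.0 / step)
    return AnnotatedEcg(sig, ecg.fs, [BeatAnnotation(b.p_on, b.q_on,
                                                     b.j_point, b.t_end)
                                      for b in ecg.beats], meta=ecg.meta)


@pytest.mark.parametrize("fmt,writer,suffix", [
    ("wfdb", ecg_io.write_wfdb, ""),
    ("aecg", ecg_io.write_aecg, ".xml"),
    ("csv", ecg_io.write_csv, ".csv"),
])
def test_round_trip(tmp_path, clean_ecg, fmt, writer, suffix):
    ecg = _quantized(clean_ecg[0])
    path = tmp_path / ("rec" + suffix)
    writer(ecg, path)
    back = load_annotated_ecg(path, format=fmt)
    np.testing.assert_allclose(back.signal, ecg.signal, atol=1e-9)
    assert len(back.beats) == len(ecg.beats)
    for a, b in zip(back.beats, ecg.beats):
        assert (a.p_on, a.q_on, a.j_point, a.t_end) == \
            (b.p_on, b.q_on, b.j_point, b.t_end)


def test_wfdb_round_trip_bit_identical(tmp_path, clean_ecg):
    ecg = _quantized(clean_ecg[0])
    ecg_io.write_wfdb(ecg, tmp_path / "rec")
    back = load_annotated_ecg(tmp_path / "rec.hea", format="wfdb")
    assert np.array_equal(back.signal, ecg.signal)


def test_aecg_ms_annotation_to_sample_index(tmp_path, clean_ecg):
    # 402 ms at 500 Hz -> sample 201
    ecg = _quantized(clean_ecg[0])
    ecg.beats[0] = BeatAnnotation(10, 50, 150, 201)
    ecg_io.write_aecg(ecg, tmp_path / "rec.xml")
    txt = (tmp_path / "rec.xml").read_text()
    assert 'value="402"' in txt
    back = load_annotated_ecg(tmp_path / "rec.xml", format="aecg")
    assert back.beats[0].t_end == 201


def test_missing_lead_is_fatal_and_named(tmp_path, clean_ecg):
    ecg = _quantized(clean_ecg[0])
    path = tmp_path / "rec.csv"
    ecg_io.write_csv(ecg, path)
    txt = "\n".join(ln for ln in path.read_text().splitlines()
                    if ",V3," not in ln)
    path.write_text(txt)
    with pytest.raises(MissingLeadError, match="V3"):
        load_annotated_ecg(path, format="csv")


def test_missing_annotation_marks_beat_unusable(tmp_path, clean_ecg):
    ecg = _quantized(clean_ecg[0])
    ecg_io.write_csv(ecg, tmp_path / "rec.csv")
    ann = tmp_path / "rec.ann.csv"
    lines = ann.read_text().splitlines()
    parts = lines[1].split(",")
    parts[4] = ""  # drop t_end of the first beat
    lines[1] = ",".join(parts)
    ann.write_text("\n".join(lines) + "\n")
    back = load_annotated_ecg(tmp_path / "rec.csv", format="csv")
    assert sum(not b.is_usable for b in back.beats) == 1
    assert len(back.usable_beats()) == len(ecg.beats) - 1


def test_unparseable_aecg_fatal(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text("<AnnotatedECG><broken")
    with pytest.raises(EcgIoError):
        load_annotated_ecg(p, format="aecg")


def test_resampled_to_500hz(tmp_path, clean_ecg):
    ecg = _quantized(clean_ecg[0])
    slow = AnnotatedEcg(ecg.signal[::2].copy(), 250.0,
                        [BeatAnnotation(b.p_on // 2, b.q_on // 2,
                                        b.j_point // 2, b.t_end // 2)
                         for b in ecg.beats])
    ecg_io.write_wfdb(slow, tmp_path / "slow")
    back = load_annotated_ecg(tmp_path / "slow.hea", format="wfdb")
    assert back.fs == 500.0
    assert back.n_samples == 2 * slow.n_samples
    assert back.beats[0].q_on == 2 * slow.beats[0].q_on


def test_beats_sorted_and_bounds_checked():
    sig = np.zeros((1000, 8))
    beats = [BeatAnnotation(500, 550, 600, 700),
             BeatAnnotation(10, 50, 100, 200),
             BeatAnnotation(900, 950, 990, 1500)]  # t_end out of range
    ecg = AnnotatedEcg(sig, 500.0, beats)
    assert [b.q_on for b in ecg.beats] == [50, 550, 950]
    assert not ecg.beats[-1].is_usable


def test_derived_leads():
    sig = np.zeros((10, 8))
    sig[:, 0] = 1.0  # I
    sig[:, 1] = 3.0  # II
    ecg = AnnotatedEcg(sig, 500.0, [])
    np.testing.assert_allclose(ecg.lead("III"), 2.0)
    np.testing.assert_allclose(ecg.lead("aVR"), -2.0)
    np.testing.assert_allclose(ecg.lead("aVL"), -0.5)
    np.testing.assert_allclose(ecg.lead("aVF"), 2.5)


# -- baseline correction -----------------------------------------------------


def test_baseline_noop_when_pq_zero(flat_ecg):
    out = baseline_correct(flat_ecg)
    np.testing.assert_allclose(out.signal, flat_ecg.signal, atol=1e-12)


def test_baseline_removes_constant_offset(flat_ecg):
    shifted = AnnotatedEcg(flat_ecg.signal + 0.3, flat_ecg.fs,
                           [BeatAnnotation(b.p_on, b.q_on, b.j_point, b.t_end)
                            for b in flat_ecg.beats])
    out = baseline_correct(shifted)
    for b in out.usable_beats():
        lo, hi = b.q_on - 20, b.q_on - 5
        med = np.median(out.signal[lo:hi, 1])
        assert abs(med) < 1e-9


def test_baseline_linear_drift_vs_spline_oracle(flat_ecg):
    fs = flat_ecg.fs
    drift = np.linspace(0.0, 1.0, flat_ecg.n_samples)[:, None]
    drifted = AnnotatedEcg(flat_ecg.signal + drift, fs,
                           [BeatAnnotation(b.p_on, b.q_on, b.j_point, b.t_end)
                            for b in flat_ecg.beats])
    out = baseline_correct(drifted)
    # oracle: explicit natural-cubic-spline subtraction through the PQ nodes
    from scipy.interpolate import CubicSpline
    nodes_t, nodes_v = [], []
    for b in drifted.usable_beats():
        lo, hi = b.q_on - 20, b.q_on - 5
        nodes_t.append(0.5 * (lo + hi - 1))
        nodes_v.append(np.median(drifted.signal[lo:hi, 0]))
    spl = CubicSpline(np.array(nodes_t), np.array(nodes_v), bc_type="natural")
    t = np.clip(np.arange(drifted.n_samples, dtype=float), nodes_t[0],
                nodes_t[-1])
    expected = drifted.signal[:, 0] - spl(t)
    np.testing.assert_allclose(out.signal[:, 0], expected, atol=1e-9)
    for b in out.usable_beats():
        med = np.median(out.signal[b.q_on - 20:b.q_on - 5, 0])
        assert abs(med) < 0.02


def test_baseline_idempotent(clean_ecg):
    once = baseline_correct(clean_ecg[0])
    twice = baseline_correct(once)
    assert np.max(np.abs(twice.signal - once.signal)) < 1e-6


def test_baseline_needs_two_beats():
    sig = np.zeros((1000, 8))
    ecg = AnnotatedEcg(sig, 500.0, [BeatAnnotation(10, 50, 100, 200)])
    with pytest.raises(InsufficientBeatsError, match="insufficient beats"):
        baseline_correct(ecg)


# -- Bessel filter -----------------------------------------------------------


def _sine_ecg(freq, fs=500.0, n=5000):
    t = np.arange(n) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 8))
    return AnnotatedEcg(sig, fs, [])


def _fft_amplitude(x, freq, fs):
    n = len(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(n)))
    f = np.fft.rfftfreq(n, 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


def test_bessel_dc_gain_unity():
    ecg = AnnotatedEcg(np.ones((2000, 8)), 500.0, [])
    out = bessel_lowpass(ecg)
    assert np.max(np.abs(out.signal - 1.0)) < 1e-6


def test_bessel_passband_5hz():
    ecg = _sine_ecg(5.0)
    out = bessel_lowpass(ecg)
    a_in = _fft_amplitude(ecg.signal[:, 0], 5.0, 500.0)
    a_out = _fft_amplitude(out.signal[:, 0], 5.0, 500.0)
    assert abs(a_out / a_in - 1.0) < 0.02


def test_bessel_stopband_100hz():
    # oracle: squared magnitude of the analog 4-pole Bessel response
    from scipy.signal import bessel as bessel_design, freqs
    b, a = bessel_design(4, 2 * np.pi * 36.0, btype="low", analog=True,
                         norm="mag")
    _, h = freqs(b, a, worN=[2 * np.pi * 100.0])
    bound = np.abs(h[0]) ** 2  # bidirectional = squared single-pass
    assert bound < 0.15
    ecg = _sine_ecg(100.0)
    out = bessel_lowpass(ecg)
    a_in = _fft_amplitude(ecg.signal[:, 0], 100.0, 500.0)
    a_out = _fft_amplitude(out.signal[:, 0], 100.0, 500.0)
    assert a_out / a_in < 0.15


def test_bessel_zero_phase():
    rng = np.random.default_rng(5)
    t = np.arange(4000) / 500.0
    x = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 6)) for f in (3, 7, 11))
    ecg = AnnotatedEcg(np.tile(x[:, None], (1, 8)), 500.0, [])
    out = bessel_lowpass(ecg)
    xc = np.correlate(out.signal[500:-500, 0], x[500:-500], mode="full")
    lag = np.argmax(xc) - (len(x) - 1001)
    assert lag == 0


def test_bessel_cutoff_above_nyquist_errors():
    ecg = AnnotatedEcg(np.ones((100, 8)), 500.0, [])
    with pytest.raises(EcgIoError):
        bessel_lowpass(ecg, cutoff_hz=300.0)


def test_studykey_on_load(tmp_path, clean_ecg):
    ecg = _quantized(clean_ecg[0])
    ecg_io.write_wfdb(ecg, tmp_path / "rec")
    key = StudyKey("S1", "drug", 2.5, 1)
    back = load_annotated_ecg(tmp_path / "rec.hea", format="wfdb", meta=key)
    assert back.meta == key
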