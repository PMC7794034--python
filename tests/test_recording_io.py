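"""Recording data model, I/O round-trips, derived pressures, QC masks, binning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from autoregkit import recording_io as rio


# ---------------------------------------------------------------------------
# File round-trips and validation
# ---------------------------------------------------------------------------


def test_write_read_round_trip_is_bit_exact(toy_recording, tmp_path):
    rio.write_recording(toy_recording, tmp_path / "rec")
    back = rio.read_recording(tmp_path / "rec")
    assert back.subject_id == toy_recording.subject_id
    assert back.group == toy_recording.group
    for name, ch in toy_recording.channels.items():
        assert np.array_equal(back.channels[name].t, ch.t)
        assert np.array_equal(back.channels[name].values, ch.values)
    assert len(back.markers) == len(toy_recording.markers)
    m0, m1 = back.markers[0], toy_recording.markers[0]
    assert (m0.t_start, m0.t_end, m0.kind, m0.frequency) == (
        m1.t_start, m1.t_end, m1.kind, m1.frequency,
    )
    assert np.array_equal(back.vitals, toy_recording.vitals)


def test_three_column_toy_file_loads(tmp_path):
    lines = ["time_s\tabp_mmhg\ticp_mmhg"]
    for i in range(10):
        lines.append(f"{i * 0.01}\t{100 + i}\t{8 + 0.1 * i}")
    d = tmp_path / "rec"
    d.mkdir()
    (d / "pressures.tsv").write_text("\n".join(lines))
    (d / "meta.json").write_text('{"subject_id": "x", "group": "fentanyl"}')
    with pytest.warns(UserWarning, match="pressure-only"):
        rec = rio.read_recording(d)
    assert rec.pressure_only
    assert len(rec.channels) == 2
    assert len(rec.channels["abp"].t) == 10


def test_non_monotonic_timestamps_error_names_row(tmp_path):
    d = tmp_path / "rec"
    d.mkdir()
    (d / "pressures.tsv").write_text(
        "time_s\tabp_mmhg\ticp_mmhg\n0.0\t100\t8\n0.01\t101\t8\n0.005\t99\t8\n"
    )
    (d / "meta.json").write_text('{"subject_id": "x", "group": "fentanyl"}')
    with pytest.raises(rio.RecordingError, match="row 2"):
        rio.read_recording(d)


def test_missing_pressures_is_hard_error(tmp_path):
    with pytest.raises(rio.RecordingError, match="pressures"):
        rio.read_recording(tmp_path)


# ---------------------------------------------------------------------------
# Beat pressures and MAP/CPP/dCBF formulas
# ---------------------------------------------------------------------------


def test_beat_pressures_on_sinusoid():
    t = np.arange(0, 10, 0.01)
    abp = 100 + 20 * np.sin(2 * np.pi * 2.0 * t)
    sys_p, dia_p = rio.estimate_beat_pressures(t, abp)
    # the 100 Hz grid does not sample the exact sinusoid extrema
    assert np.allclose(sys_p, 120, atol=0.05)
    assert np.allclose(dia_p, 80, atol=0.05)


def test_beat_pressures_flat_line_warns():
    t = np.arange(0, 4, 0.01)
    with pytest.warns(UserWarning, match="flat-line"):
        sys_p, dia_p = rio.estimate_beat_pressures(t, np.full_like(t, 80.0))
    assert np.array_equal(sys_p, dia_p)


def test_beat_pressures_single_half_sine_beat():
    t = np.arange(0, 2.02, 0.01)
    abp = np.where(t < 0.5, 30 * np.sin(2 * np.pi * t), 0.0)
    sys_p, dia_p = rio.estimate_beat_pressures(t, abp, window_s=2.0)
    assert sys_p[0] == pytest.approx(30.0, abs=0.1)
    assert dia_p[0] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "sys_v,dia_v,expected",
    [(120.0, 60.0, 80.0), (90.0, 90.0, 90.0), (120.0, 80.0, 93.33333333333333)],
)
def test_map_formula(sys_v, dia_v, expected):
    assert rio.compute_map(sys_v, dia_v) == pytest.approx(expected)


def test_map_rejects_inverted_pressures():
    with pytest.raises(rio.RecordingError):
        rio.compute_map(np.array([80.0]), np.array([90.0]))


def test_cpp_elementwise_and_conservation():
    m = np.array([80.0, 90.0])
    i = np.array([40.0, 45.0])
    cpp = rio.compute_cpp(m, i)
    assert np.array_equal(cpp, [40.0, 45.0])
    assert np.array_equal(cpp + i, m)
    with pytest.raises(rio.RecordingError):
        rio.compute_cpp(m, i[:1])


@given(
    st.lists(st.floats(30, 200), min_size=3, max_size=40),
    st.lists(st.floats(0, 60), min_size=3, max_size=40),
)
def test_cpp_plus_icp_reconstructs_map(map_vals, icp_vals):
    n = min(len(map_vals), len(icp_vals))
    m, i = np.array(map_vals[:n]), np.array(icp_vals[:n])
    assert np.allclose(rio.compute_cpp(m, i) + i, m, rtol=1e-12, atol=1e-12)


def test_delta_cbf_arithmetic():
    # baseline samples [1, 3] (mean 2); a later sample of 3 gives dCBF = 0.5
    dcbf = rio.compute_delta_cbf(np.array([1.0, 3.0, 3.0]), np.array([0.0, 40.0, 80.0]))
    assert dcbf[2] == pytest.approx(0.5)
    # identity: flow equal to its baseline mean gives dCBF = 0 everywhere
    assert np.all(rio.compute_delta_cbf(np.full(100, 5.0), np.arange(100.0)) == 0.0)
    # doubling the baseline flow gives dCBF = 1
    doubled = rio.compute_delta_cbf(
        np.concatenate([np.full(70, 1.0), np.full(30, 2.0)]), np.arange(100.0)
    )
    assert doubled[-1] == pytest.approx(1.0)


def test_delta_cbf_rejects_nonpositive_baseline():
    with pytest.raises(rio.RecordingError):
        rio.compute_delta_cbf(np.full(100, -1.0), np.arange(100.0))


# ---------------------------------------------------------------------------
# Quality-control masks
# ---------------------------------------------------------------------------


def test_beta_mask_constant_rejects_nothing():
    assert not rio.beta_quality_mask(np.full(100, 0.5)).any()


def test_beta_mask_median_rule():
    beta = np.full(100, 0.5)
    beta[42] = 0.48  # below median - 0.01
    mask = rio.beta_quality_mask(beta)
    assert mask[42]
    assert mask.sum() == 1


def test_beta_mask_z_rule_catches_spike(rng):
    beta = 0.5 + rng.normal(0, 0.001, 500)
    beta[123] = 0.5 + 10 * 0.001 * 10  # huge positive spike: z-rule only
    mask = rio.beta_quality_mask(beta)
    assert mask[123]
    # brute-force z check: the spike is the only |z| > 0.5 sample far above median
    z = (beta - beta.mean()) / beta.std(ddof=1)
    assert set(np.nonzero(mask)[0]) == set(
        np.nonzero((np.abs(z) > 0.5) | (beta < np.median(beta) - 0.01))[0]
    )


def test_beta_mask_too_few_samples_warns():
    with pytest.warns(UserWarning):
        mask = rio.beta_quality_mask(np.array([0.5, 0.4, 0.3]))
    assert not mask.any()


def test_beta_mask_idempotent(rng):
    beta = 0.5 + rng.normal(0, 0.01, 200)
    m1 = rio.beta_quality_mask(beta)
    m2 = rio.beta_quality_mask(beta)
    assert np.array_equal(m1, m2)


def test_cbf_outlier_mask_threshold_strict(rng):
    vals = rng.normal(size=200)
    vals[7] = 5.0
    mask = rio.cbf_outlier_mask(vals)
    assert mask[7]
    assert not rio.cbf_outlier_mask(np.full(50, 1.0)).any()
    # a bin exactly at |z| = 2 is kept (strict inequality)
    x = np.array([-1.0, 1.0] * 8)
    z = rio.zscores(x)
    assert np.all(np.abs(z) < 2) or not rio.cbf_outlier_mask(x)[np.argmax(np.abs(z))]


# ---------------------------------------------------------------------------
# Alignment and binning
# ---------------------------------------------------------------------------


def test_align_constant_channel_is_constant(toy_recording):
    rec = toy_recording
    rec.channels["icp"] = rio.Channel(rec.channels["icp"].t, np.full(3000, 10.0), "mmHg")
    aligned = rio.align_resample(rec)
    assert np.allclose(aligned.icp, 10.0)
    # overlap ends with the 1 Hz DCS channel at 29 s -> 145 full 0.2-s intervals
    assert len(aligned.t) == 145


def test_align_block_average_matches_brute_force():
    t = np.arange(0, 10, 0.01)
    ramp = np.linspace(0, 1, len(t))
    ch = rio.Channel(t, ramp, "")
    rec_t = rio.Channel(t, np.full_like(t, 10.0), "mmHg")
    rec = rio.RawRecording(
        "s", "fentanyl", {"abp": rio.Channel(t, 100 + 15 * np.sin(2 * np.pi * 2 * t), "mmHg"),
                          "icp": ch}
    )
    aligned = rio.align_resample(rec)
    nbins = len(aligned.t)
    brute = ramp[: nbins * 20].reshape(nbins, 20).mean(axis=1)
    assert np.allclose(aligned.icp, brute, atol=1e-12)
    assert aligned.icp[0] == pytest.approx(ramp[:20].mean())


def test_align_low_overlap_errors():
    t1 = np.arange(0, 10, 0.01)
    t2 = np.arange(9.0, 19.0, 0.01)
    rec = rio.RawRecording(
        "s", "fentanyl",
        {"abp": rio.Channel(t1, 100 + 10 * np.sin(t1 * 12), "mmHg"),
         "icp": rio.Channel(t2, np.full_like(t2, 8.0), "mmHg")},
    )
    with pytest.raises(rio.RecordingError, match="overlap"):
        rio.align_resample(rec)


def test_align_offset_channels_share_grid():
    """Channels starting 2 s apart produce one grid over the overlap."""
    t1 = np.arange(0, 30, 0.01)
    t2 = np.arange(2.0, 32.0, 0.01)
    rec = rio.RawRecording(
        "s", "fentanyl",
        {"abp": rio.Channel(t1, 100 + 15 * np.sin(2 * np.pi * 2 * t1), "mmHg"),
         "icp": rio.Channel(t2, np.full_like(t2, 8.0), "mmHg")},
    )
    aligned = rio.align_resample(rec)
    assert aligned.t[0] >= 2.0
    # overlap [2.0, 29.99] -> 139 full intervals
    assert len(aligned.t) == 139


def _aligned_from(values, rate=5.0, reject=None):
    n = len(values)
    values = np.asarray(values, dtype=float)
    qc = rio.QCMask(beta_reject=np.zeros(n, bool) if reject is None else np.asarray(reject))
    return rio.AlignedSeries(
        rate, np.arange(n) / rate, values.copy(), values.copy(), values.copy(),
        values.copy(), values.copy(), qc,
    )


def test_bin_average_constant_and_partial_bin():
    s = _aligned_from(np.full(75, 7.0))
    b = rio.bin_average(s, 10.0)
    assert len(b.t_center) == 1  # 75 samples at 5 Hz -> one full 50-sample bin
    assert b.means["map"][0] == 7.0
    assert b.n_valid[0] == 50


def test_bin_average_ramp_matches_block_means():
    ramp = np.arange(1.0, 101.0)
    s = _aligned_from(ramp)
    b = rio.bin_average(s, 10.0)
    assert np.allclose(b.means["cpp"], ramp[:100].reshape(2, 50).mean(axis=1))


def test_bin_average_excludes_masked_and_empty_bin_is_nan():
    reject = np.zeros(100, bool)
    reject[:50] = True
    vals = np.arange(100.0)
    s = _aligned_from(vals, reject=reject)
    b = rio.bin_average(s, 10.0)
    assert np.isnan(b.means["dcbf"][0])
    assert b.means["dcbf"][1] == pytest.approx(vals[50:].mean())
    assert b.means["map"][0] == pytest.approx(vals[:50].mean())  # pressures unmasked


def test_bin_average_idempotent_on_bin_means():
    vals = np.sin(np.arange(500) / 7.0)
    b1 = rio.bin_average(_aligned_from(vals), 10.0)
    # re-binning the 10-s means with the same width must not change them
    s2 = _aligned_from(b1.means["map"], rate=0.1)
    b2 = rio.bin_average(s2, 10.0)
    assert np.allclose(b2.means["map"], b1.means["map"])


@given(st.floats(-50, 200), st.integers(2, 10))
def test_block_downsample_constant_invariance(value, factor):
    x = np.full(factor * 7, value)
    out = rio.block_average(x, factor)
    assert np.allclose(out, value)
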