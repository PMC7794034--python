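"""Data model, file I/O and preprocessing for multimodal cerebral-hemodynamics recordings.

A recording bundles arterial blood pressure (ABP) and intracranial pressure
(ICP) waveforms sampled at ~100 Hz, a diffuse-correlation-spectroscopy (DCS)
blood-flow index ``alpha_db`` with its data-quality value ``beta`` at ~1 Hz,
event markers describing induced-oscillation segments, an anesthesia log and
a vitals log.  This module turns that bundle into a uniformly sampled 5 Hz
set of derived channels (MAP, ICP, CPP, fractional CBF change) with
quality-control masks, plus 10-s block averages used by the static and
pseudo-dynamic autoregulation analyses.

All pressures are mmHg and all times are seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Induced-oscillation frequencies of the perturbation protocol (Hz).
PROTOCOL_FREQUENCIES = (0.009, 0.017, 0.025, 0.033, 0.059)

MARKER_KINDS = ("icp_osc", "abp_osc", "baseline")

GROUPS = ("isoflurane", "fentanyl")

#: Physical conversion factor between cmH2O and mmHg.
CMH2O_TO_MMHG = 0.7355

_CHANNEL_UNITS = {"abp": "mmHg", "icp": "mmHg", "alpha_db": "cm^2/s", "beta": ""}


class RecordingError(ValueError):
    """Raised for malformed or inconsistent recording inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Channel:
    t: np.ndarray          # timestamps, s, strictly increasing
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise RecordingError("channel timestamps and values differ in length")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise RecordingError(
                f"timestamps not strictly increasing: first offending row {bad[0] + 1}"
            )

    @property
    def sample_rate(self) -> float:
        if len(self.t) < 2:
            return 0.0
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class EventMarker:
    t_start: float
    t_end: float
    kind: str                       # icp_osc | abp_osc | baseline
    frequency: float = 0.0          # Hz, 0 for baseline segments
    icp_baseline_target: float = 0.0  # mmHg

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise RecordingError(f"marker t_end {self.t_end} <= t_start {self.t_start}")
        if self.kind not in MARKER_KINDS:
            raise RecordingError(f"unknown marker kind {self.kind!r}")
        allowed = (0.0,) + PROTOCOL_FREQUENCIES
        if not any(np.isclose(self.frequency, f, atol=1e-9) for f in allowed):
            raise RecordingError(f"frequency {self.frequency} not in protocol set")


@dataclass
class RawRecording:
    subject_id: str
    group: str                      # isoflurane | fentanyl
    channels: dict[str, Channel]
    markers: list[EventMarker] = field(default_factory=list)
    # rows of (time s, isoflurane %, fentanyl rate ug/kg/hr)
    anesthesia_log: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    # rows of (time s, heart rate bpm, etco2 mmHg)
    vitals: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        if self.group not in GROUPS:
            raise RecordingError(f"unknown group {self.group!r}")
        for name in ("abp", "icp"):
            if name not in self.channels:
                raise RecordingError(f"mandatory channel {name!r} missing")
        self.anesthesia_log = np.asarray(self.anesthesia_log, dtype=float).reshape(-1, 3)
        self.vitals = np.asarray(self.vitals, dtype=float).reshape(-1, 3)

    @property
    def pressure_only(self) -> bool:
        """True when no DCS flow index is available (PRx/phase still computable)."""
        return "alpha_db" not in self.channels


@dataclass
class QCMask:
    """Boolean rejection masks; True marks a rejected sample/bin."""

    beta_reject: np.ndarray                  # per aligned sample
    cbf_outlier: np.ndarray | None = None    # per 10-s bin, filled after binning


@dataclass
class AlignedSeries:
    """Derived channels on one uniform grid (default 5 Hz)."""

    sample_rate: float
    t: np.ndarray
    map: np.ndarray
    icp: np.ndarray
    cpp: np.ndarray
    dcbf: np.ndarray        # fractional CBF change; NaN when pressure-only
    alpha_db: np.ndarray    # raw flow index held to the grid; NaN when absent
    qc: QCMask

    def __post_init__(self):
        n = len(self.t)
        for name in ("map", "icp", "cpp", "dcbf", "alpha_db"):
            if len(getattr(self, name)) != n:
                raise RecordingError("aligned channels differ in length")


@dataclass
class BinnedSeries:
    """Non-overlapping block means (default 10 s) of an AlignedSeries."""

    bin_width: float
    t_center: np.ndarray
    means: dict[str, np.ndarray]   # map, icp, cpp, dcbf, alpha_db
    n_valid: np.ndarray            # unmasked DCS samples per bin
    n_samples: int                 # samples per full bin
    cbf_outlier: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Small numeric helpers
# ---------------------------------------------------------------------------


def zscores(x: np.ndarray) -> np.ndarray:
    """NaN-aware z-scores; a zero-variance series scores 0 everywhere."""
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x) if np.any(np.isfinite(x)) else np.nan
    s = np.nanstd(x, ddof=1) if np.sum(np.isfinite(x)) > 1 else 0.0
    if not np.isfinite(m) or s == 0:
        return np.zeros_like(x)
    return (x - m) / s


def block_average(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean over consecutive non-overlapping blocks; trailing partial dropped."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // factor) * factor
    if n == 0:
        return np.empty(0)
    return x[:n].reshape(-1, factor).mean(axis=1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SEP = {"tsv": "\t", "csv": ","}


def write_recording(rec: RawRecording, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a recording as a directory of delimited-text files plus meta.json."""
    sep = _SEP[dialect]
    ext = dialect
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    abp, icp = rec.channels["abp"], rec.channels["icp"]
    if len(abp.t) != len(icp.t) or not np.array_equal(abp.t, icp.t):
        raise RecordingError("abp and icp must share one time base for writing")
    pd.DataFrame(
        {"time_s": abp.t, "abp_mmhg": abp.values, "icp_mmhg": icp.values}
    ).to_csv(path / f"pressures.{ext}", sep=sep, index=False, float_format="%.17g")

    if not rec.pressure_only:
        a, b = rec.channels["alpha_db"], rec.channels["beta"]
        pd.DataFrame({"time_s": a.t, "alpha_db": a.values, "beta": b.values}).to_csv(
            path / f"dcs.{ext}", sep=sep, index=False, float_format="%.17g"
        )

    pd.DataFrame(
        rec.vitals, columns=["time_s", "heart_rate_bpm", "etco2_mmhg"]
    ).to_csv(path / f"vitals.{ext}", sep=sep, index=False, float_format="%.17g")
    pd.DataFrame(
        rec.anesthesia_log, columns=["time_s", "isoflurane_pct", "fentanyl_ug_kg_hr"]
    ).to_csv(path / f"anesthesia.{ext}", sep=sep, index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {
                "t_start_s": m.t_start,
                "t_end_s": m.t_end,
                "kind": m.kind,
                "freq_hz": m.frequency,
                "icp_target_mmhg": m.icp_baseline_target,
            }
            for m in rec.markers
        ],
        columns=["t_start_s", "t_end_s", "kind", "freq_hz", "icp_target_mmhg"],
    ).to_csv(path / f"events.{ext}", sep=sep, index=False, float_format="%.17g")

    (path / "meta.json").write_text(
        json.dumps({"subject_id": rec.subject_id, "group": rec.group}, indent=1)
    )
    return path


def read_recording(path: str | Path, dialect: str = "tsv") -> RawRecording:
    """Read a recording directory written by :func:`write_recording`.

    A missing pressures file (or its ABP/ICP columns) is a hard error; a
    missing DCS file yields a pressure-only recording.
    """
    sep = _SEP[dialect]
    ext = dialect
    path = Path(path)
    pfile = path / f"pressures.{ext}"
    if not pfile.exists():
        raise RecordingError(f"mandatory pressures file missing: {pfile}")
    press = pd.read_csv(pfile, sep=sep, float_precision="round_trip")
    for col in ("time_s", "abp_mmhg", "icp_mmhg"):
        if col not in press.columns:
            raise RecordingError(f"mandatory column {col!r} missing in {pfile}")

    channels = {
        "abp": Channel(press["time_s"].to_numpy(), press["abp_mmhg"].to_numpy(), "mmHg"),
        "icp": Channel(press["time_s"].to_numpy(), press["icp_mmhg"].to_numpy(), "mmHg"),
    }
    dfile = path / f"dcs.{ext}"
    if dfile.exists():
        dcs = pd.read_csv(dfile, sep=sep, float_precision="round_trip")
        channels["alpha_db"] = Channel(
            dcs["time_s"].to_numpy(), dcs["alpha_db"].to_numpy(), "cm^2/s"
        )
        channels["beta"] = Channel(dcs["time_s"].to_numpy(), dcs["beta"].to_numpy(), "")
    else:
        warnings.warn(f"{path}: no DCS file, recording flagged pressure-only")

    def _table(name, ncol):
        f = path / f"{name}.{ext}"
        if not f.exists():
            return np.empty((0, ncol))
        return pd.read_csv(f, sep=sep, float_precision="round_trip").to_numpy(dtype=float).reshape(-1, ncol)

    markers = []
    efile = path / f"events.{ext}"
    if efile.exists():
        for row in pd.read_csv(efile, sep=sep, float_precision="round_trip").itertuples(index=False):
            markers.append(
                EventMarker(
                    t_start=float(row.t_start_s),
                    t_end=float(row.t_end_s),
                    kind=str(row.kind),
                    frequency=float(row.freq_hz),
                    icp_baseline_target=float(row.icp_target_mmhg),
                )
            )

    meta = json.loads((path / "meta.json").read_text())
    return RawRecording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        channels=channels,
        markers=markers,
        anesthesia_log=_table("anesthesia", 3),
        vitals=_table("vitals", 3),
    )


# ---------------------------------------------------------------------------
# Derived-pressure computation
# ---------------------------------------------------------------------------


def estimate_beat_pressures(
    t: np.ndarray, abp: np.ndarray, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Systolic/diastolic estimates from the ABP waveform.

    Per-window maxima/minima over non-overlapping windows (default 2 s,
    covering at least two cardiac cycles at typical heart rates), held
    constant across each window so the outputs live on the waveform grid.
    """
    t = np.asarray(t, dtype=float)
    abp = np.asarray(abp, dtype=float)
    if t[-1] - t[0] < window_s:
        raise RecordingError("waveform shorter than one beat-estimation window")
    if np.ptp(abp) < 1.0:
        warnings.warn("flat-line ABP waveform: systolic equals diastolic")
    fs = 1.0 / float(np.median(np.diff(t)))
    per = max(int(round(window_s * fs)), 1)
    n = len(abp)
    sys_out = np.empty(n)
    dia_out = np.empty(n)
    for start in range(0, n, per):
        stop = min(start + per, n)
        seg = abp[start:stop]
        sys_out[start:stop] = seg.max()
        dia_out[start:stop] = seg.min()
    return sys_out, dia_out


def compute_map(systolic: np.ndarray, diastolic: np.ndarray) -> np.ndarray:
    """Mean arterial pressure via the clinical 2/3 diastolic + 1/3 systolic rule."""
    systolic = np.asarray(systolic, dtype=float)
    diastolic = np.asarray(diastolic, dtype=float)
    if np.any(systolic < diastolic):
        raise RecordingError("systolic below diastolic")
    return (2.0 / 3.0) * diastolic + (1.0 / 3.0) * systolic


def compute_cpp(map_series: np.ndarray, icp_series: np.ndarray) -> np.ndarray:
    """Cerebral perfusion pressure, CPP = MAP - ICP (not clipped at 0)."""
    map_series = np.asarray(map_series, dtype=float)
    icp_series = np.asarray(icp_series, dtype=float)
    if map_series.shape != icp_series.shape:
        raise RecordingError("MAP and ICP length mismatch")
    return map_series - icp_series


def compute_delta_cbf(
    alpha_db: np.ndarray,
    t: np.ndarray | None = None,
    baseline_window: float = 60.0,
    reject: np.ndarray | None = None,
) -> np.ndarray:
    """Fractional CBF change relative to the start-of-measurement flow index.

    dCBF = (alpha_db - alpha_db0) / alpha_db0 with alpha_db0 the mean over the
    first ``baseline_window`` seconds of unmasked samples.
    """
    alpha_db = np.asarray(alpha_db, dtype=float)
    if t is None:
        t = np.arange(len(alpha_db), dtype=float)
    t = np.asarray(t, dtype=float)
    keep = np.ones(len(alpha_db), bool) if reject is None else ~np.asarray(reject, bool)
    base = keep & (t <= t[0] + baseline_window)
    if t[base].size == 0 or (t[base][-1] - t[0]) < min(baseline_window, t[-1] - t[0]) * 0.5:
        raise RecordingError("baseline window has insufficient unmasked samples")
    alpha0 = float(np.mean(alpha_db[base]))
    if alpha0 <= 0:
        raise RecordingError(f"non-positive baseline flow index {alpha0}")
    return (alpha_db - alpha0) / alpha0


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def beta_quality_mask(
    beta: np.ndarray,
    alpha_db: np.ndarray | None = None,
    z_threshold: float = 0.5,
    median_margin: float = 0.01,
    min_samples: int = 10,
) -> np.ndarray:
    """Laser-instability rejection from the DCS beta value.

    A sample is rejected when |z(beta)| > ``z_threshold`` (z over the whole
    recording) or when beta < median(beta) - ``median_margin``; both rules are
    applied.  The mask applies one-to-one to the co-timed flow-index samples.
    """
    beta = np.asarray(beta, dtype=float)
    if alpha_db is not None and len(alpha_db) != len(beta):
        raise RecordingError("beta and alpha_db must be co-timed")
    if len(beta) < min_samples:
        warnings.warn(f"fewer than {min_samples} beta samples: nothing rejected")
        return np.zeros(len(beta), dtype=bool)
    z = zscores(beta)
    reject = (np.abs(z) > z_threshold) | (beta < np.median(beta) - median_margin)
    return reject


def cbf_outlier_mask(binned_dcbf: np.ndarray, z_threshold: float = 2.0) -> np.ndarray:
    """Reject 10-s CBF bins with |z| strictly above ``z_threshold``."""
    binned_dcbf = np.asarray(binned_dcbf, dtype=float)
    z = zscores(binned_dcbf)
    return np.abs(z) > z_threshold


# ---------------------------------------------------------------------------
# Alignment, resampling, binning
# ---------------------------------------------------------------------------


def _hold_to_grid(t_src, v_src, t_grid):
    """Zero-order hold: value at each grid point is the latest source sample."""
    idx = np.searchsorted(t_src, t_grid, side="right") - 1
    idx = np.clip(idx, 0, len(t_src) - 1)
    return np.asarray(v_src)[idx]


def align_resample(rec: RawRecording, target_rate: float = 5.0) -> AlignedSeries:
    """Put all derived channels (MAP, ICP, CPP, dCBF) on one uniform grid.

    Channels faster than the target rate are block-averaged over each output
    interval (anti-aliasing for the sub-0.06 Hz analysis band); slower
    channels are held constant between samples.  The common origin is the
    latest channel start; channels must overlap for at least half of the
    longest channel span.
    """
    abp, icp = rec.channels["abp"], rec.channels["icp"]
    chans = [abp, icp] + ([rec.channels["alpha_db"]] if not rec.pressure_only else [])
    t0 = max(c.t[0] for c in chans)
    t1 = min(c.t[-1] for c in chans)
    longest = max(c.t[-1] - c.t[0] for c in chans)
    if t1 - t0 < 0.5 * longest:
        raise RecordingError("channels overlap for less than 50% of the recording")

    dt = 1.0 / target_rate
    nbins = int(np.floor((t1 - t0) / dt))
    if nbins < 1:
        raise RecordingError("overlap shorter than one output interval")
    t_grid = t0 + (np.arange(nbins) + 0.5) * dt  # bin centers

    def _downsample(ch: Channel) -> np.ndarray:
        ratio = ch.sample_rate / target_rate
        factor = int(round(ratio))
        if factor >= 1 and abs(ratio - factor) < 1e-6:
            # regular waveform grid: exact non-overlapping block means
            i0 = int(np.searchsorted(ch.t, t0 - 0.5 / ch.sample_rate))
            use = min(nbins, (len(ch.t) - i0) // factor)
            out = np.full(nbins, np.nan)
            out[:use] = ch.values[i0 : i0 + use * factor].reshape(use, factor).mean(axis=1)
            if use < nbins:  # ragged tail: hold the last full block
                out[use:] = out[use - 1]
            return out
        if ch.sample_rate > target_rate:
            # irregular fast channel: mean of the samples in each interval
            sel = (ch.t >= t0) & (ch.t < t0 + nbins * dt)
            ts, vs = ch.t[sel], ch.values[sel]
            idx = np.floor((ts - t0) / dt).astype(int)
            out = np.bincount(idx, weights=vs, minlength=nbins)
            cnt = np.bincount(idx, minlength=nbins)
            with np.errstate(invalid="ignore"):
                out = out / cnt
            if np.any(cnt == 0):
                good = cnt > 0
                out[~good] = _hold_to_grid(t_grid[good], out[good], t_grid[~good])
            return out
        return _hold_to_grid(ch.t, ch.values, t_grid)

    sys_w, dia_w = estimate_beat_pressures(abp.t, abp.values)
    map_native = compute_map(sys_w, dia_w)
    map5 = _downsample(Channel(abp.t, map_native, "mmHg"))
    icp5 = _downsample(icp)
    cpp5 = compute_cpp(map5, icp5)

    if rec.pressure_only:
        nan = np.full(nbins, np.nan)
        qc = QCMask(beta_reject=np.ones(nbins, dtype=bool))
        return AlignedSeries(target_rate, t_grid, map5, icp5, cpp5, nan, nan.copy(), qc)

    alpha = rec.channels["alpha_db"]
    beta = rec.channels["beta"]
    reject_native = beta_quality_mask(beta.values, alpha.values)
    dcbf_native = compute_delta_cbf(
        alpha.values, alpha.t, baseline_window=60.0, reject=reject_native
    )
    alpha5 = _hold_to_grid(alpha.t, alpha.values, t_grid)
    dcbf5 = _hold_to_grid(alpha.t, dcbf_native, t_grid)
    reject5 = _hold_to_grid(alpha.t, reject_native.astype(float), t_grid) > 0.5
    qc = QCMask(beta_reject=reject5)
    return AlignedSeries(target_rate, t_grid, map5, icp5, cpp5, dcbf5, alpha5, qc)


def bin_average(s: AlignedSeries, bin_width: float = 10.0) -> BinnedSeries:
    """Non-overlapping left-aligned block means; trailing partial bin dropped.

    Pressure channels average every sample; DCS-derived channels exclude
    beta-rejected samples, and a bin with no valid DCS sample is NaN.
    """
    per_f = bin_width * s.sample_rate
    per = int(round(per_f))
    if abs(per_f - per) > 1e-9 or per < 1:
        raise RecordingError("bin width must be an integer multiple of the sample interval")
    nbins = len(s.t) // per
    if nbins == 0:
        return BinnedSeries(bin_width, np.empty(0), {}, np.empty(0, int), per)

    cut = nbins * per
    t_center = block_average(s.t[:cut], per)
    means = {name: block_average(getattr(s, name)[:cut], per) for name in ("map", "icp", "cpp")}

    keep = (~s.qc.beta_reject[:cut]).reshape(nbins, per)
    n_valid = keep.sum(axis=1)
    for name in ("dcbf", "alpha_db"):
        v = getattr(s, name)[:cut].reshape(nbins, per)
        with np.errstate(invalid="ignore"):
            m = np.where(n_valid > 0, np.nansum(np.where(keep, v, 0.0), axis=1) / n_valid, np.nan)
        means[name] = m
    return BinnedSeries(bin_width, t_center, means, n_valid, per)


def apply_cbf_outlier_mask(binned: BinnedSeries, z_threshold: float = 2.0) -> BinnedSeries:
    """Attach the 10-s CBF outlier mask and blank rejected bins in dcbf/alpha."""
    mask = cbf_outlier_mask(binned.means["dcbf"], z_threshold)
    binned.cbf_outlier = mask
    for name in ("dcbf", "alpha_db"):
        binned.means[name] = np.where(mask, np.nan, binned.means[name])
    return binned
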