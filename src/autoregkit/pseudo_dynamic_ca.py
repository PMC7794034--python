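"""Pseudo-dynamic cerebral autoregulation: the pressure reactivity index (PRx).

PRx is the Pearson correlation of slow MAP and ICP fluctuations computed in
moving 5-minute windows on 0.1 Hz (10-s mean) series.  Negative PRx means an
intact vasoreactive response (rising pressure -> constriction -> smaller
blood volume -> falling ICP); values at or above about +0.3 mean the
vasculature transmits pressure passively.  Window correlations are averaged
on the Fisher-Z (atanh) scale within 1.2-mmHg-wide CPP groups spanning
0-180 mmHg, giving a CPP-resolved reactivity profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording_io import AlignedSeries, RecordingError, block_average

__all__ = [
    "PRxWindow",
    "PRxProfile",
    "downsample_10s",
    "windowed_prx",
    "fisher_mean",
    "prx_by_cpp",
    "fisher_mean_in_band",
]

#: CPP range and group count of the reactivity profile.
CPP_RANGE = (0.0, 180.0)
N_CPP_GROUPS = 150


@dataclass
class PRxWindow:
    t_center: float
    r: float
    mean_cpp: float
    n_samples: int


@dataclass
class PRxProfile:
    group: str
    edges: np.ndarray          # 151 edges of the 150 half-open CPP intervals
    mean_prx: np.ndarray       # Fisher-Z mean per interval, NaN where empty
    sd: np.ndarray             # SD of window r values (r scale)
    window_count: np.ndarray
    dropped: int = 0           # windows outside [0, 180) mmHg
    windows: list[PRxWindow] = field(default_factory=list, repr=False)


def downsample_10s(s: AlignedSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """0.1 Hz series via non-overlapping 10-s block means of MAP, ICP, CPP.

    Returns (t, map10, icp10, cpp10); the 10-s mean doubles as the smoothing
    of the underlying pressure traces.
    """
    per = int(round(10.0 * s.sample_rate))
    return (
        block_average(s.t, per),
        block_average(s.map, per),
        block_average(s.icp, per),
        block_average(s.cpp, per),
    )


def windowed_prx(
    map10: np.ndarray,
    icp10: np.ndarray,
    cpp10: np.ndarray | None = None,
    t10: np.ndarray | None = None,
    window_s: float = 300.0,
    step_s: float = 60.0,
    sample_interval_s: float = 10.0,
) -> tuple[list[PRxWindow], int]:
    """Moving-window Pearson correlation of 0.1 Hz MAP and ICP.

    Each full window (default 5 min = 30 points, 60 s step) yields one
    correlation and the mean CPP over the same points.  Windows with missing
    samples or zero variance in either channel are skipped; the skip count is
    returned for bookkeeping.
    """
    map10 = np.asarray(map10, dtype=float)
    icp10 = np.asarray(icp10, dtype=float)
    if map10.shape != icp10.shape:
        raise RecordingError("MAP and ICP length mismatch")
    if cpp10 is None:
        cpp10 = map10 - icp10
    if t10 is None:
        t10 = np.arange(len(map10)) * sample_interval_s
    wlen = int(round(window_s / sample_interval_s))
    step = int(round(step_s / sample_interval_s))
    windows: list[PRxWindow] = []
    skipped = 0
    for start in range(0, len(map10) - wlen + 1, step):
        m = map10[start : start + wlen]
        i = icp10[start : start + wlen]
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(i))):
            skipped += 1
            continue
        if np.ptp(m) == 0 or np.ptp(i) == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(m, i)[0, 1])
        windows.append(
            PRxWindow(
                t_center=float(np.mean(t10[start : start + wlen])),
                r=r,
                mean_cpp=float(np.mean(cpp10[start : start + wlen])),
                n_samples=wlen,
            )
        )
    return windows, skipped


def fisher_mean(rs) -> float:
    """Average correlations on the Fisher-Z scale: tanh(mean(atanh(r))).

    Correlations at |r| = 1 (legitimate for noise-free inputs) are clipped to
    1 - 1e-12 before the transform.  An empty input gives NaN.
    """
    rs = np.asarray(list(rs) if not isinstance(rs, np.ndarray) else rs, dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return float("nan")
    if np.any(np.abs(rs) > 1):
        raise RecordingError("correlation outside [-1, 1]")
    clip = 1.0 - 1e-12
    return float(np.tanh(np.mean(np.arctanh(np.clip(rs, -clip, clip)))))


def cpp_group_index(mean_cpp: float, n_groups: int = N_CPP_GROUPS, cpp_range=CPP_RANGE) -> int:
    """Half-open group index floor(cpp / width); -1 when out of range."""
    lo, hi = cpp_range
    width = (hi - lo) / n_groups
    if mean_cpp < lo or mean_cpp >= hi:
        return -1
    return int(np.floor((mean_cpp - lo) / width))


def prx_by_cpp(
    windows: list[PRxWindow],
    group: str,
    n_groups: int = N_CPP_GROUPS,
    cpp_range=CPP_RANGE,
) -> PRxProfile:
    """Sort pooled windows into CPP groups and Fisher-Z average each group.

    Windows whose mean CPP falls outside the range are dropped and counted.
    The group SD is computed on the correlation scale.
    """
    lo, hi = cpp_range
    edges = np.linspace(lo, hi, n_groups + 1)
    rs_per = [[] for _ in range(n_groups)]
    dropped = 0
    for w in windows:
        gi = cpp_group_index(w.mean_cpp, n_groups, cpp_range)
        if gi < 0:
            dropped += 1
        else:
            rs_per[gi].append(w.r)
    mean_prx = np.array([fisher_mean(rs) if rs else np.nan for rs in rs_per])
    sd = np.array([np.std(rs, ddof=1) if len(rs) >= 2 else np.nan for rs in rs_per])
    count = np.array([len(rs) for rs in rs_per])
    return PRxProfile(group, edges, mean_prx, sd, count, dropped, list(windows))


def fisher_mean_in_band(profile: PRxProfile, band: tuple[float, float]) -> float:
    """Fisher-Z mean of all windows in CPP groups fully inside ``band``."""
    lo, hi = band
    rs = []
    for w in profile.windows:
        gi = cpp_group_index(w.mean_cpp, len(profile.mean_prx), (profile.edges[0], profile.edges[-1]))
        if gi < 0:
            continue
        if profile.edges[gi] >= lo and profile.edges[gi + 1] <= hi:
            rs.append(w.r)
    return fisher_mean(rs)
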