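"""Static cerebral autoregulation: Lassen-curve construction and group statistics.

The steady-state relation between cerebral blood flow and cerebral perfusion
pressure (Lassen's curve) is reconstructed per subject by averaging the
quality-controlled 10-s flow-index means within 1-mmHg CPP bins.  Subject
curves are normalized (mean subtracted and mean divided, on the raw
flow-index scale) before group averaging.  A three-segment piecewise-linear
fit with a flat middle segment estimates the lower and upper limits of
autoregulation (LLA/ULA); with intact autoregulation the middle segment is
the plateau, with pressure-passive flow the fit degenerates to a narrow or
sloped middle segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .recording_io import AlignedSeries, BinnedSeries, RecordingError

__all__ = [
    "SubjectCurve",
    "LassenCurve",
    "PlateauFit",
    "lassen_curve_subject",
    "normalize_subject_curve",
    "group_lassen",
    "estimate_plateau",
    "distribution_test",
    "pressure_histograms",
]


@dataclass
class SubjectCurve:
    """Per-subject binned flow values over half-open 1-mmHg CPP bins [k, k+1)."""

    subject_id: str
    bin_left: np.ndarray    # integer left edges, mmHg
    values: np.ndarray      # mean flow index (raw) or normalized dCBF per bin
    n: np.ndarray           # contributing 10-s bins
    normalized: bool = False


@dataclass
class LassenCurve:
    group: str
    bin_left: np.ndarray
    mean_dcbf: np.ndarray
    sd: np.ndarray               # NaN where fewer than 2 subjects contribute
    subjects_per_bin: np.ndarray
    plateau: "PlateauFit | None" = None


@dataclass
class PlateauFit:
    lla: float
    ula: float
    plateau_level: float
    slope_below: float
    slope_above: float
    sse: float

    @property
    def width(self) -> float:
        return self.ula - self.lla

    @property
    def degenerate(self) -> bool:
        """A plateau narrower than 10 mmHg signals a pressure-passive curve."""
        return self.width < 10.0


def lassen_curve_subject(
    binned: BinnedSeries,
    subject_id: str = "",
    value_channel: str = "alpha_db",
    bin_width_mmhg: float = 1.0,
) -> SubjectCurve:
    """Average 10-s flow means within 1-mmHg CPP bins (half-open [k, k+1))."""
    cpp = np.asarray(binned.means["cpp"], dtype=float)
    val = np.asarray(binned.means[value_channel], dtype=float)
    ok = np.isfinite(cpp) & np.isfinite(val)
    if binned.cbf_outlier is not None:
        ok &= ~binned.cbf_outlier
    if not np.any(ok):
        raise RecordingError("no valid 10-s bins for the Lassen curve")
    idx = np.floor(cpp[ok] / bin_width_mmhg).astype(int)
    order = np.argsort(idx, kind="stable")
    uniq, start, counts = np.unique(idx[order], return_index=True, return_counts=True)
    sums = np.add.reduceat(val[ok][order], start)
    return SubjectCurve(
        subject_id=subject_id,
        bin_left=uniq.astype(float) * bin_width_mmhg,
        values=sums / counts,
        n=counts,
    )


def normalize_subject_curve(c: SubjectCurve) -> SubjectCurve:
    """Mean-subtract and mean-divide the curve: v -> (v - m) / m.

    m is the unweighted mean over non-missing bins of the raw flow-index
    values, so the normalized curve always has unweighted mean zero.
    """
    m = float(np.mean(c.values))
    if m == 0:
        raise RecordingError("curve mean is zero; normalization undefined")
    return SubjectCurve(c.subject_id, c.bin_left.copy(), (c.values - m) / m, c.n.copy(), True)


def group_lassen(curves: list[SubjectCurve], group: str) -> LassenCurve:
    """Per-bin unweighted mean and SD across the subjects possessing that bin."""
    if not curves:
        raise RecordingError(f"empty group {group!r}")
    all_bins = np.unique(np.concatenate([c.bin_left for c in curves]))
    stackedv = np.full((len(curves), len(all_bins)), np.nan)
    for i, c in enumerate(curves):
        pos = np.searchsorted(all_bins, c.bin_left)
        stackedv[i, pos] = c.values
    nsub = np.sum(np.isfinite(stackedv), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # bins with < 2 subjects
        mean = np.nanmean(stackedv, axis=0)
        sd = np.where(nsub >= 2, np.nanstd(stackedv, axis=0, ddof=1), np.nan)
    return LassenCurve(group, all_bins, mean, sd, nsub)


def _three_segment_sse(x, y, lla, ula):
    """Least-squares fit of level + rising arms for fixed breakpoints."""
    below = np.minimum(x - lla, 0.0)
    above = np.maximum(x - ula, 0.0)
    cols = [np.ones_like(x), below, above]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    # arms must rise (slopes >= 0); refit with offending arm removed
    drop = [j for j, c in zip((1, 2), coef[1:]) if c < 0]
    if drop:
        keep = [0] + [j for j in (1, 2) if j not in drop]
        coef_k, *_ = np.linalg.lstsq(A[:, keep], y, rcond=None)
        coef = np.zeros(3)
        coef[keep] = coef_k
    resid = y - A @ coef
    return float(resid @ resid), coef


def estimate_plateau(curve: LassenCurve, min_bins: int = 20) -> PlateauFit | None:
    """Continuous three-segment (rising/flat/rising) fit over the bin means.

    Breakpoints are searched on the 1-mmHg bin grid; the inner linear
    parameters are solved exactly for each candidate pair, and the pair with
    the lowest residual wins (ties break toward the narrower plateau).
    Returns None when the fit cannot be formed.
    """
    ok = np.isfinite(curve.mean_dcbf)
    x = curve.bin_left[ok] + 0.5
    y = curve.mean_dcbf[ok]
    if len(x) < min_bins:
        return None
    cand = np.asarray(sorted(set(np.round(x))), dtype=float)
    cand = cand[(cand > x.min()) & (cand < x.max())]
    best = None
    for i, lla in enumerate(cand):
        for ula in cand[i:]:
            sse, coef = _three_segment_sse(x, y, lla, ula)
            key = (sse, ula - lla)
            if best is None or key < best[0]:
                best = (key, lla, ula, coef)
    if best is None:
        return None
    (sse, _), lla, ula, coef = best
    return PlateauFit(float(lla), float(ula), float(coef[0]), float(coef[1]), float(coef[2]), sse)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(np.sum(ranks_a) - n_a * (n_a + 1) / 2.0)


def distribution_test(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney rank-sum test for a difference in medians (two-sided).

    Uses the exact permutation distribution of the U statistic (midranks, so
    ties are handled) when the combined sample is small, and the
    tie-corrected normal approximation with continuity correction otherwise.
    Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise RecordingError("each group needs at least 3 subjects")
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if np.ptp(pooled) == 0:
        return u_obs, 1.0

    if n <= exact_max_n:
        mu = n_a * (n - n_a) / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            hits += abs(u - mu) >= dev - 1e-12
            total += 1
        assert total == comb(n, n_a)
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pressure_histograms(
    series: list[AlignedSeries], channel: str, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Group-pooled sample counts in half-open 1-mmHg bins.

    Returns (edges, counts) with len(edges) = len(counts) + 1.
    """
    if channel not in ("cpp", "map", "icp"):
        raise RecordingError(f"unsupported histogram channel {channel!r}")
    pooled = np.concatenate([getattr(s, channel) for s in series]) if series else np.empty(0)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        return np.array([0.0, bin_width]), np.array([0])
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.floor(pooled.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(pooled, bins=edges)
    return edges, counts
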