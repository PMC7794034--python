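"""Dynamic cerebral autoregulation: ABP-ICP phase lag at induced frequencies.

During an induced oscillation (reservoir-driven ICP or ventilator/PEEP-driven
ABP) both pressure channels are passed through the same narrowband
linear-phase FIR filter centered on the induced frequency, the analytic
signal is formed with the Hilbert transform, and the phase delay is the
circular mean of (ABP phase - ICP phase) over the segment.  With intact
autoregulation, slow ABP oscillations below the autoregulatory cutoff
(~0.03 Hz) drive counter-regulatory blood-volume changes, so ICP moves in
antiphase and the delay sits near 180 degrees; a pressure-passive bed
transmits the oscillation directly and the delay collapses toward 0.

Because the protocol frequencies sit only 0.008 Hz apart, each bandpass must
reject every other protocol frequency; the passband is therefore narrower
than a naive fixed width would suggest, and the filters run to a few
thousand taps at 5 Hz.  The same filter is applied to both channels, so its
group delay cancels exactly in the phase subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .recording_io import PROTOCOL_FREQUENCIES, EventMarker, RecordingError

__all__ = [
    "NarrowbandFilter",
    "PhaseDelay",
    "PhaseLagResult",
    "design_narrowband",
    "analytic_phase",
    "segment_phase_delay",
    "phase_by_frequency",
    "circular_mean_deg",
    "circular_sd_deg",
]


@dataclass
class NarrowbandFilter:
    f0: float
    passband: tuple[float, float]
    transition_width: float
    taps: np.ndarray
    sample_rate: float
    method: str = "parks-mcclellan"

    def __post_init__(self):
        if len(self.taps) % 2 != 1:
            raise RecordingError("narrowband filter must have an odd tap count")

    def gain_at(self, f: float) -> float:
        w = 2 * np.pi * f / self.sample_rate
        n = np.arange(len(self.taps))
        return float(np.abs(np.sum(self.taps * np.exp(-1j * w * n))))


@dataclass
class PhaseDelay:
    """Per-segment phase delay (ABP phase minus ICP phase)."""

    frequency: float
    delay_deg: float            # in (-180, 180]
    abp_magnitude: float        # mmHg, median envelope
    icp_magnitude: float
    reliable: bool = True


@dataclass
class PhaseLagResult:
    modality: str               # icp_osc | abp_osc
    frequency: float
    group: str
    mean_delay_deg: float       # circular mean across subjects
    circ_sd_deg: float
    n_subjects: int
    mean_abp_magnitude: float = float("nan")
    mean_icp_magnitude: float = float("nan")
    subject_delays: list[float] = field(default_factory=list, repr=False)


_FILTER_CACHE: dict[tuple, NarrowbandFilter] = {}


def design_narrowband(
    f0: float,
    sample_rate: float = 5.0,
    protocol: tuple[float, ...] = PROTOCOL_FREQUENCIES,
    stop_atten_db: float = 45.0,
) -> NarrowbandFilter:
    """Equiripple linear-phase bandpass centered on a protocol frequency.

    The passband half-width is min(0.03, f0/2, 0.35*d) and the transition
    width 0.55*d, where d is the distance to the nearest other protocol
    frequency; this guarantees every other protocol frequency and DC fall in
    the stopband (gain <= 0.01) while f0 passes with gain within 1%.
    Parks-McClellan design is attempted first and a Kaiser-window design is
    the fallback when the exchange algorithm fails to converge.
    """
    key = (round(f0, 6), sample_rate, protocol, stop_atten_db)
    if key in _FILTER_CACHE:
        return _FILTER_CACHE[key]
    others = [f for f in protocol if abs(f - f0) > 1e-9]
    if not any(abs(f - f0) < 1e-9 for f in protocol):
        raise RecordingError(f"{f0} Hz is not a protocol frequency")
    d = min(abs(f - f0) for f in others) if others else 0.03
    hw = min(0.03, 0.5 * f0, 0.35 * d)
    tw = 0.55 * d
    flo, fhi = f0 - hw, f0 + hw
    numtaps, beta = signal.kaiserord(stop_atten_db, tw / (sample_rate / 2))
    numtaps |= 1
    taps = None
    method = "parks-mcclellan"
    try:
        taps = signal.remez(
            numtaps,
            [0, flo - tw, flo, fhi, fhi + tw, sample_rate / 2],
            [0, 1, 0],
            fs=sample_rate,
            maxiter=100,
        )
    except Exception:
        taps = None
    filt = None
    if taps is not None:
        filt = NarrowbandFilter(f0, (flo, fhi), tw, taps, sample_rate, method)
        if not _meets_spec(filt, protocol):
            filt = None
    if filt is None:
        taps = signal.firwin(
            numtaps, [flo, fhi], window=("kaiser", beta), pass_zero=False, fs=sample_rate
        )
        filt = NarrowbandFilter(f0, (flo, fhi), tw, taps, sample_rate, "kaiser-window")
        if not _meets_spec(filt, protocol):
            raise RecordingError(
                f"narrowband design failed for f0={f0} Hz at order {numtaps}"
            )
    _FILTER_CACHE[key] = filt
    return filt


def _meets_spec(filt: NarrowbandFilter, protocol) -> bool:
    if not 0.99 <= filt.gain_at(filt.f0) <= 1.01:
        return False
    if filt.gain_at(0.0) > 0.01:
        return False
    return all(filt.gain_at(f) <= 0.01 for f in protocol if abs(f - filt.f0) > 1e-9)


def analytic_phase(
    x: np.ndarray, filt: NarrowbandFilter
) -> tuple[np.ndarray, np.ndarray]:
    """Narrowband-filter a series and extract instantaneous phase and envelope.

    The FIR is applied once, centered (odd, symmetric taps, so the linear
    phase is exactly compensated and the same filter on both channels leaves
    their phase difference untouched).  The analytic signal is built over the
    whole series; phase is unwrapped.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3 * len(filt.taps):
        raise RecordingError(
            f"series of {len(x)} samples shorter than 3 filter lengths "
            f"({3 * len(filt.taps)}); record longer or use a shorter filter"
        )
    y = signal.fftconvolve(x - np.mean(x), filt.taps, mode="same")
    n = len(y)
    nfast = sp_fft.next_fast_len(n)
    analytic = signal.hilbert(y, N=nfast)[:n]
    phase = np.unwrap(np.angle(analytic))
    envelope = np.abs(analytic)
    return phase, envelope


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Map angles in degrees to (-180, 180]."""
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


def circular_mean_deg(angles_deg) -> float:
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        return float("nan")
    v = np.mean(np.exp(1j * a))
    return float(_wrap_deg(np.degrees(np.angle(v))))


def circular_sd_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        return float("nan")
    r = np.abs(np.mean(np.exp(1j * a)))
    r = min(r, 1.0)
    if r == 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def segment_phase_delay(
    t: np.ndarray,
    abp: np.ndarray,
    icp: np.ndarray,
    segment: EventMarker,
    sample_rate: float = 5.0,
    noise_floor_mmhg: float = 0.5,
    filt: NarrowbandFilter | None = None,
) -> PhaseDelay:
    """Phase delay (ABP phase - ICP phase) over one oscillation segment.

    Both full-length channels are filtered identically; the delay is the
    circular mean of the instantaneous phase difference over the segment
    minus one oscillation cycle at each end (filter transients ring).
    Magnitudes are the median analytic envelopes over the same window.  When
    either envelope sits below the noise floor the estimate is flagged
    unreliable.
    """
    f0 = segment.frequency
    if f0 <= 0:
        raise RecordingError("segment has no oscillation frequency")
    if segment.t_end - segment.t_start < 1.0 / f0:
        raise RecordingError("segment shorter than one oscillation period")
    if filt is None:
        filt = design_narrowband(f0, sample_rate)
    ph_a, env_a = analytic_phase(abp, filt)
    ph_i, env_i = analytic_phase(icp, filt)
    cycle = 1.0 / f0
    sel = (t >= segment.t_start + cycle) & (t <= segment.t_end - cycle)
    if not np.any(sel):
        raise RecordingError("segment too short after trimming one cycle per end")
    diff = np.degrees(ph_a[sel] - ph_i[sel])
    delay = circular_mean_deg(diff)
    mag_a = float(np.median(env_a[sel]))
    mag_i = float(np.median(env_i[sel]))
    reliable = mag_a >= noise_floor_mmhg and mag_i >= noise_floor_mmhg
    if not reliable:
        warnings.warn(
            f"oscillation envelope below {noise_floor_mmhg} mmHg at {f0} Hz; "
            "phase delay flagged unreliable"
        )
    return PhaseDelay(f0, delay, mag_a, mag_i, reliable)


def phase_by_frequency(
    subject_results: dict[str, list[PhaseDelay]],
    modality: str,
    group: str,
) -> list[PhaseLagResult]:
    """Group circular mean/SD of per-subject delays, one result per frequency.

    ``subject_results`` maps subject id -> list of per-segment delays for one
    modality.  Repeated segments at the same frequency (different ICP
    baselines) are first circularly averaged within the subject; unreliable
    segments are excluded.
    """
    freqs = sorted(
        {d.frequency for ds in subject_results.values() for d in ds if d.reliable}
    )
    results = []
    for f0 in freqs:
        subj_delays, mags_a, mags_i = [], [], []
        for ds in subject_results.values():
            mine = [d for d in ds if d.frequency == f0 and d.reliable]
            if mine:
                subj_delays.append(circular_mean_deg([d.delay_deg for d in mine]))
                mags_a.append(np.mean([d.abp_magnitude for d in mine]))
                mags_i.append(np.mean([d.icp_magnitude for d in mine]))
        results.append(
            PhaseLagResult(
                modality=modality,
                frequency=f0,
                group=group,
                mean_delay_deg=circular_mean_deg(subj_delays),
                circ_sd_deg=circular_sd_deg(subj_delays),
                n_subjects=len(subj_delays),
                mean_abp_magnitude=float(np.mean(mags_a)),
                mean_icp_magnitude=float(np.mean(mags_i)),
                subject_delays=subj_delays,
            )
        )
    return results
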