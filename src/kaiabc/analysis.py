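"""Period, amplitude, circadian time, phase shift and synchrony extraction.

Operates on recorded trajectories of the ensemble-mean phosphorylation level.
Peaks are detected on a lightly smoothed copy of the series (moving average
over 1 h) to suppress the stochastic step noise of finite ensembles; the
summary statistics are computed from the detected peak/trough times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "OscillationSummary",
    "PRC",
    "period_amplitude",
    "q10",
    "circadian_time_map",
    "phase_shift",
    "sync_index",
]

#: peak at the rhythm's crest is pinned at this circadian time
CT_OF_PEAK = 16.0
#: default smoothing window (h) before peak detection
SMOOTH_WINDOW_H = 1.0
#: minimum peak prominence for a cycle to count
MIN_PROMINENCE = 0.02
#: below this mean peak-to-trough amplitude a series is called non-oscillatory
AMPLITUDE_FLOOR = 0.02


@dataclass
class OscillationSummary:
    """Period/amplitude statistics of one oscillatory time series."""

    oscillatory: bool
    period: float = np.nan        # mean peak-to-peak interval (h)
    period_se: float = np.nan     # standard error of the intervals
    amplitude: float = np.nan     # mean peak-to-following-trough drop
    n_cycles: int = 0
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trough_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "oscillatory": bool(self.oscillatory),
            "period_h": None if np.isnan(self.period) else float(self.period),
            "period_se": None if np.isnan(self.period_se) else float(self.period_se),
            "amplitude": None if np.isnan(self.amplitude) else float(self.amplitude),
            "n_cycles": int(self.n_cycles),
        }


@dataclass
class PRC:
    """Phase-response curve: shift (CT h, advance positive) vs onset CT."""

    ct: np.ndarray
    shift: np.ndarray
    desynchronized: np.ndarray  # True where the perturbed rhythm collapsed
    post_amplitude: Optional[np.ndarray] = None  # ensemble amplitude after onset

    def to_dict(self) -> dict:
        return {
            "ct": self.ct.tolist(),
            "shift_ct_h": [None if not np.isfinite(s) else float(s)
                           for s in self.shift],
            "desynchronized": self.desynchronized.astype(bool).tolist(),
            "post_amplitude": None if self.post_amplitude is None
            else [None if not np.isfinite(a) else float(a)
                  for a in self.post_amplitude],
        }


def _smooth(x: np.ndarray, t: np.ndarray, window_h: float) -> np.ndarray:
    if window_h <= 0 or x.size < 3:
        return x
    dt = float(np.median(np.diff(t)))
    w = max(int(round(window_h / dt)), 1)
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def period_amplitude(t: np.ndarray, x: np.ndarray,
                     min_prominence: float = MIN_PROMINENCE,
                     smooth_window_h: float = SMOOTH_WINDOW_H,
                     amplitude_floor: float = AMPLITUDE_FLOOR,
                     min_peaks: int = 3) -> OscillationSummary:
    """Detect cycles in a time series and summarise period and amplitude.

    Period is the mean inter-peak interval; amplitude the mean drop from a
    peak to the following trough.  The series is flagged non-oscillatory
    when fewer than ``min_peaks`` qualifying peaks are found or the mean
    amplitude falls below ``amplitude_floor``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size != x.size or t.size < 8:
        raise ValueError("trajectory too short for period estimation")
    xs = _smooth(x, t, smooth_window_h)
    peaks, _ = find_peaks(xs, prominence=min_prominence)
    troughs, _ = find_peaks(-xs, prominence=min_prominence)
    if peaks.size < min_peaks:
        return OscillationSummary(oscillatory=False)
    peak_t = t[peaks]
    intervals = np.diff(peak_t)
    period = float(intervals.mean())
    period_se = float(intervals.std(ddof=1) / np.sqrt(intervals.size)) \
        if intervals.size > 1 else np.nan
    # pair each peak with the first following trough
    drops = []
    for pk in peaks:
        later = troughs[troughs > pk]
        if later.size:
            drops.append(xs[pk] - xs[later[0]])
    amplitude = float(np.mean(drops)) if drops else 0.0
    if amplitude < amplitude_floor:
        return OscillationSummary(oscillatory=False, n_cycles=intervals.size,
                                  peak_times=peak_t, trough_times=t[troughs])
    return OscillationSummary(
        oscillatory=True, period=period, period_se=period_se,
        amplitude=amplitude, n_cycles=intervals.size,
        peak_times=peak_t, trough_times=t[troughs],
    )


def q10(period_low: float, period_high: float) -> float:
    """Temperature coefficient period(T0-5)/period(T0+5); 1 = compensated."""
    if not (period_low > 0 and period_high > 0):
        raise ValueError("Q10 requires positive periods at both temperatures")
    return period_low / period_high


def circadian_time_map(peak_times: np.ndarray, period: float):
    """Map incubation time to circadian time (CT).

    Per cycle affine map with the rhythm's peak pinned at CT 16 and the
    cycle normalised to 24 h.  Returns ``(to_ct, to_time)``; ``to_time``
    uses the cycle containing (or nearest to) the requested time.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size == 0 or not period > 0:
        raise ValueError("circadian time map needs an oscillatory trajectory")
    ref = peak_times[0]

    def to_ct(time_h):
        return (CT_OF_PEAK + 24.0 * (np.asarray(time_h) - ref) / period) % 24.0

    def to_time(ct, cycle: int = 0):
        return ref + (np.asarray(ct) - CT_OF_PEAK) / 24.0 * period + cycle * period

    return to_ct, to_time


def _wrap_half(x: np.ndarray, half: float = 12.0) -> np.ndarray:
    """Wrap to the interval (-half, half]."""
    return half - np.mod(half - x, 2.0 * half)


def phase_shift(perturbed_peaks: np.ndarray, reference_peaks: np.ndarray,
                reference_period: float, after: float = 0.0,
                n_cycles: int = 3) -> float:
    """Phase shift of a perturbed rhythm in CT hours, advance positive.

    For each of the first ``n_cycles`` reference peaks after time ``after``
    the nearest perturbed peak is located; the mean (reference - perturbed)
    peak-time difference, converted to CT hours and wrapped to (-12, 12],
    is the shift (a perturbed peak arriving *earlier* is an advance).
    """
    ref = np.asarray(reference_peaks, dtype=float)
    per = np.asarray(perturbed_peaks, dtype=float)
    ref = ref[ref >= after]
    per = per[per >= after]
    if ref.size == 0 or per.size == 0:
        raise ValueError("no post-perturbation peaks to compare")
    shifts = []
    for r in ref[:n_cycles]:
        j = np.argmin(np.abs(per - r))
        shifts.append(_wrap_half((r - per[j]) / reference_period * 24.0))
    return float(_wrap_half(np.mean(shifts)))


def phase_shift_extrapolated(perturbed_peaks: np.ndarray, onset_time: float,
                             onset_ct: float, n_cycles: int = 3,
                             after: Optional[float] = None) -> float:
    """Phase shift of a (possibly sustained) perturbation, advance positive.

    The unperturbed null rhythm is extrapolated forward from the
    perturbation onset: its phase at the onset is ``onset_ct`` (from the
    pre-perturbation circadian-time map) and it advances at the perturbed
    trajectory's own post-perturbation period, so a sustained change of the
    period (e.g. a temperature step) does not masquerade as a phase shift.
    The shift is the mean null-minus-actual peak-time difference over the
    first ``n_cycles`` post-onset peaks, in CT hours wrapped to (-12, 12].
    """
    pk = np.asarray(perturbed_peaks, dtype=float)
    pk = pk[pk > (onset_time if after is None else after)]
    if pk.size < 2:
        raise ValueError("need at least two post-perturbation peaks")
    # integer-cycle pairing offsets are absorbed by the (-12, 12] wrap
    period_to = float(np.mean(np.diff(pk)))
    # first null peak after the onset (peaks sit at CT 16)
    frac = np.mod(CT_OF_PEAK - onset_ct, 24.0) / 24.0
    shifts = []
    for k, t_k in enumerate(pk[:n_cycles]):
        t_null = onset_time + (frac + k) * period_to
        shifts.append(_wrap_half((t_null - t_k) / period_to * 24.0))
    return float(_wrap_half(np.mean(shifts)))


def sync_index(t: np.ndarray, D_mol: np.ndarray,
               D_mean: Optional[np.ndarray] = None,
               **peak_kwargs) -> dict:
    """Ensemble coherence from per-molecule phosphorylation traces.

    Returns the ratio of the ensemble-mean amplitude to the mean
    single-molecule amplitude: ~1 when the population oscillates in phase,
    ~0 when molecules oscillate incoherently (the ensemble mean averages
    out), together with the underlying summaries.
    """
    D_mol = np.atleast_2d(np.asarray(D_mol, dtype=float))
    if D_mol.shape[0] == np.asarray(t).size and D_mol.shape[1] != np.asarray(t).size:
        D_mol = D_mol.T  # accept (time, molecules) layout
    if D_mean is None:
        D_mean = D_mol.mean(axis=0)
    # single-molecule saw-tooth traces are noisy: use a generous prominence
    peak_kwargs.setdefault("min_prominence", 0.05)
    singles = [period_amplitude(t, d, **peak_kwargs) for d in D_mol]
    amp_single = [s.amplitude for s in singles if s.oscillatory]
    ens = period_amplitude(t, np.asarray(D_mean, dtype=float), **peak_kwargs)
    if not amp_single:
        raise ValueError("no oscillatory single-molecule traces")
    mean_single = float(np.mean(amp_single))
    ens_amp = ens.amplitude if ens.oscillatory else 0.0
    return {
        "index": float(ens_amp / mean_single),
        "ensemble_amplitude": float(ens_amp),
        "mean_single_amplitude": mean_single,
        "n_oscillatory_molecules": len(amp_single),
        "ensemble_summary": ens,
        "single_summaries": singles,
    }
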