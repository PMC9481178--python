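"""In-silico experiment protocols: scans, phase-response curves, assays.

Each protocol is a seeded, reproducible procedure built on
:func:`kaiabc.ensemble_sim.simulate`.  Scan points and PRC points are run
with independent child seeds spawned from the master seed, so results do not
depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analysis import (
    OscillationSummary,
    PRC,
    circadian_time_map,
    period_amplitude,
    phase_shift_extrapolated,
    q10,
    sync_index,
)
from .ensemble_sim import AdpPulse, TemperatureStep, simulate
from .model_core import ModelParameters
from .thermo_rules import TemperatureModel

__all__ = [
    "ScanResult",
    "feedback_scaling_scan",
    "temperature_scan",
    "tstep_prc",
    "adp_pulse_prc",
    "atpase_scaling_scan",
    "atpase_activity_assay",
    "desynchronization_assay",
]

#: ensemble amplitude below this fraction of the mean single-molecule
#: amplitude counts as a lost (desynchronized) ensemble rhythm
DESYNC_INDEX_THRESHOLD = 0.10


@dataclass
class ScanResult:
    """Per-point oscillation summaries of a one-parameter scan."""

    variable: str
    values: np.ndarray
    summaries: list
    extra: dict = field(default_factory=dict)

    @property
    def oscillatory(self) -> np.ndarray:
        return np.array([s.oscillatory for s in self.summaries])

    @property
    def periods(self) -> np.ndarray:
        return np.array([s.period for s in self.summaries])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude for s in self.summaries])

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "values": np.asarray(self.values).tolist(),
            "summaries": [s.to_dict() for s in self.summaries],
        }
        d.update(self.extra)
        return d


def _child_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


_FEEDBACK_MODES = {
    "neg": ("d3", "d4"),       # delayed negative feedback + ATPase coupling
    "pos": ("d1", "d2"),       # binding/unbinding positive feedback
    "d3_only": ("d3",),
    "d4_only": ("d4",),
}


def feedback_scaling_scan(params: ModelParameters, mode: str,
                          s_values: Sequence[float], seed: int,
                          duration: float = 240.0, warmup: float = 100.0,
                          thermo: Optional[TemperatureModel] = None) -> ScanResult:
    """Scale selected structure-reaction couplings by s and measure the rhythm.

    ``mode``: ``neg`` scales d3 and d4 together (weaker negative feedback at
    s < 1 lengthens the period and enlarges the amplitude until the rhythm is
    lost, stuck in the X ~ 1 state), ``pos`` scales d1 and d2, and
    ``d3_only``/``d4_only`` scale a single coupling.
    """
    if mode not in _FEEDBACK_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(_FEEDBACK_MODES)}")
    s_values = np.asarray(list(s_values), dtype=float)
    if np.any(s_values <= 0):
        raise ValueError("scaling factors must be positive")
    names = _FEEDBACK_MODES[mode]
    seeds = _child_seeds(seed, len(s_values))
    summaries = []
    for s, sd in zip(s_values, seeds):
        pp = params.replace(**{n: getattr(params, n) * s for n in names})
        traj = simulate(pp, thermo=thermo, duration=duration, warmup=warmup,
                        seed=sd)
        summaries.append(period_amplitude(traj.t, traj.D_mean))
    return ScanResult(variable=f"s({'+'.join(names)})", values=s_values,
                      summaries=summaries)


def temperature_scan(params: ModelParameters, thermo: TemperatureModel,
                     T_values: Sequence[float], seed: int,
                     duration: float = 240.0, warmup: float = 100.0,
                     n_replicates: int = 1) -> ScanResult:
    """Measure period and amplitude across temperatures; Q10 when possible.

    Q10 = period(T0-5)/period(T0+5) is attached when both endpoints are in
    the scan and oscillatory (replicate periods are averaged first).
    """
    T_values = np.asarray(list(T_values), dtype=float)
    seeds = _child_seeds(seed, len(T_values) * n_replicates)
    summaries = []
    periods = {}
    for i, T in enumerate(T_values):
        reps = []
        for r in range(n_replicates):
            traj = simulate(params, thermo=thermo.at(T), duration=duration,
                            warmup=warmup, seed=seeds[i * n_replicates + r])
            reps.append(period_amplitude(traj.t, traj.D_mean))
        osc = [s for s in reps if s.oscillatory]
        if osc:
            mean = OscillationSummary(
                oscillatory=True,
                period=float(np.mean([s.period for s in osc])),
                period_se=float(np.mean([s.period_se for s in osc])
                                / np.sqrt(len(osc))),
                amplitude=float(np.mean([s.amplitude for s in osc])),
                n_cycles=int(np.sum([s.n_cycles for s in osc])),
            )
        else:
            mean = OscillationSummary(oscillatory=False)
        summaries.append(mean)
        periods[float(T)] = mean
    extra = {}
    lo, hi = thermo.T0_celsius - 5.0, thermo.T0_celsius + 5.0
    if lo in periods and hi in periods:
        if periods[lo].oscillatory and periods[hi].oscillatory:
            extra["Q10"] = q10(periods[lo].period, periods[hi].period)
        else:
            extra["Q10"] = None
    return ScanResult(variable="T_celsius", values=T_values,
                      summaries=summaries, extra=extra)


def _prc(params, thermo, make_events, ct_grid, seed, duration, warmup,
         settle_cycles: int = 3) -> PRC:
    """Shared PRC machinery: reference run + one perturbed run per onset CT.

    The reference run fixes the circadian-time map (peak -> CT 16, cycle ->
    24 CT h).  Each onset CT is converted to an incubation time within a
    cycle after ``settle_cycles`` full cycles, the perturbation is applied
    there, and the shift is measured on the first three post-perturbation
    reference peaks.
    """
    ref = simulate(params, thermo=thermo, duration=duration, warmup=warmup,
                   seed=seed)
    ref_sum = period_amplitude(ref.t, ref.D_mean)
    if not ref_sum.oscillatory:
        raise ValueError("reference condition is non-oscillatory")
    to_ct, to_time = circadian_time_map(ref_sum.peak_times, ref_sum.period)

    ct_grid = np.asarray(list(ct_grid), dtype=float)
    shifts = np.full(len(ct_grid), np.nan)
    desync = np.zeros(len(ct_grid), dtype=bool)
    post_amp = np.full(len(ct_grid), np.nan)
    # the perturbed run reuses the reference seed: the two trajectories are
    # then identical up to the perturbation, so the comparison is paired
    for i, ct in enumerate(ct_grid):
        onset = float(to_time(ct, cycle=settle_cycles))
        events, min_tail = make_events(onset)
        pert = simulate(params, thermo=thermo, duration=duration,
                        warmup=warmup, seed=seed, events=events)
        pert_sum = period_amplitude(pert.t, pert.D_mean)
        tail = pert.t >= onset + min_tail
        if tail.sum() >= 8:
            tail_sum = period_amplitude(pert.t[tail], pert.D_mean[tail],
                                        min_peaks=2)
            post_amp[i] = tail_sum.amplitude if tail_sum.oscillatory else 0.0
        if (not pert_sum.oscillatory
                or (pert_sum.peak_times > onset + min_tail).sum() < 2):
            desync[i] = True
            continue
        shifts[i] = phase_shift_extrapolated(
            pert_sum.peak_times, onset, onset_ct=ct,
            after=onset + min_tail)
    return PRC(ct=ct_grid, shift=shifts, desynchronized=desync,
               post_amplitude=post_amp)


def tstep_prc(params: ModelParameters, thermo: TemperatureModel,
              T_from: float, T_to: float, ct_grid: Sequence[float],
              seed: int, duration: float = 260.0,
              warmup: float = 100.0) -> PRC:
    """PRC of a sustained temperature step ``T_from`` -> ``T_to``.

    The run sits at ``T_from`` until the onset CT, then switches to
    ``T_to``; the constant-``T_from`` trajectory (same seed, so identical up
    to the step) is the reference.  Advance is positive.
    """
    thermo_from = thermo.at(T_from)

    def make_events(onset):
        return [TemperatureStep(time_h=onset, T_celsius=T_to)], 6.0

    return _prc(params, thermo_from, make_events, ct_grid, seed,
                duration, warmup)


def adp_pulse_prc(params: ModelParameters,
                  thermo: Optional[TemperatureModel] = None,
                  lifetime_multiplier: float = 4.0,
                  pulse_duration: float = 6.0,
                  ct_grid: Sequence[float] = tuple(range(0, 24, 2)),
                  seed: int = 0, duration: float = 260.0,
                  warmup: float = 100.0) -> PRC:
    """PRC of a transient ADP pulse (ADP lifetime multiplied for 6 h).

    An elevated ADP concentration lengthens the ADP-bound lifetime of the CI
    domains; a pulse near the trough delays the rhythm, near the peak it
    advances it, and near the delay/advance discontinuity it splits the
    population and collapses the ensemble amplitude.
    """
    if lifetime_multiplier <= 0:
        raise ValueError("lifetime multiplier must be positive")

    def make_events(onset):
        return [AdpPulse(time_h=onset, duration_h=pulse_duration,
                         lifetime_multiplier=lifetime_multiplier)], \
            pulse_duration + 4.0

    return _prc(params, thermo, make_events, ct_grid, seed, duration, warmup)


def atpase_scaling_scan(params: ModelParameters, case: str,
                        sa_values: Sequence[float], seed: int,
                        duration: float = 240.0, warmup: float = 100.0,
                        activity_duration: float = 60.0) -> ScanResult:
    """Scale the ATPase rate constants and measure rhythm and activity.

    Case I multiplies both the inverse ADP lifetime and the hydrolysis
    frequency by sa (preserving the product Delta_ADP * f_hyd, to which the
    period is insensitive); case II multiplies the ADP *lifetime* and the
    hydrolysis frequency by sa, breaking the constraint, so the oscillation
    frequency tracks the ATPase activity.  The activity is measured in the
    KaiA/KaiB-free non-oscillatory condition, in released ADP per CI domain
    per day.
    """
    case = case.strip().upper()
    if case not in ("I", "II"):
        raise ValueError("case must be 'I' or 'II'")
    sa_values = np.asarray(list(sa_values), dtype=float)
    if np.any(sa_values <= 0):
        raise ValueError("sa values must be positive")
    seeds = _child_seeds(seed, len(sa_values))
    summaries, activities = [], []
    for sa, sd in zip(sa_values, seeds):
        if case == "I":
            pp = params.replace(inv_dADP0=params.inv_dADP0 * sa,
                                f_hyd=params.f_hyd * sa)
        else:
            pp = params.replace(inv_dADP0=params.inv_dADP0 / sa,
                                f_hyd=params.f_hyd * sa)
        traj = simulate(pp, duration=duration, warmup=warmup, seed=sd)
        summaries.append(period_amplitude(traj.t, traj.D_mean))
        activities.append(atpase_activity_assay(pp, seed=sd + 1,
                                                duration=activity_duration))
    return ScanResult(variable=f"sa(case {case})", values=sa_values,
                      summaries=summaries,
                      extra={"atpase_activity_per_day": activities})


def atpase_activity_assay(params: ModelParameters,
                          thermo: Optional[TemperatureModel] = None,
                          seed: int = 0, duration: float = 60.0,
                          warmup: float = 20.0) -> float:
    """ATPase activity without KaiA and KaiB (released ADP per CI per day).

    With AT = BT = 0 the ensemble settles to the free-KaiC structural fixed
    point and the release rate is the renewal rate of the
    hydrolysis/release cycle, 1/(1/f_hyd + Delta_ADP(X*)) per hour.
    """
    pp = params.replace(AT=0.0, BT=0.0)
    traj = simulate(pp, thermo=thermo, duration=duration, warmup=warmup,
                    seed=seed)
    return float(np.mean(traj.qr) * 24.0)


def desynchronization_assay(params: ModelParameters, hAB_factor: float,
                            temperatures: Sequence[float], seed: int,
                            thermo: Optional[TemperatureModel] = None,
                            duration: float = 240.0, warmup: float = 100.0,
                            n_molecules: int = 20) -> dict:
    """Ensemble vs single-molecule rhythm when KaiA-KaiB affinity is reduced.

    Reducing hAB (modelling a KaiB mutant with low KaiA affinity) removes
    the sequestration coupling: the ensemble rhythm collapses while
    individual hexamers keep oscillating.  Returns, per temperature, the
    synchrony index (ensemble amplitude over mean single-molecule
    amplitude), the single-molecule period statistics, and an
    ``ensemble_lost`` flag (index < 0.1).
    """
    if not (0 < hAB_factor <= 1):
        raise ValueError("hAB_factor must be in (0, 1]")
    pp = params.replace(hAB=params.hAB * hAB_factor)
    thermo = thermo or TemperatureModel()
    seeds = _child_seeds(seed, len(list(temperatures)))
    out = {}
    for T, sd in zip(temperatures, seeds):
        traj = simulate(pp, thermo=thermo.at(T), duration=duration,
                        warmup=warmup, seed=sd, n_molecule_traces=n_molecules)
        res = sync_index(traj.t, traj.D_mol.T, traj.D_mean)
        singles = [s for s in res["single_summaries"] if s.oscillatory]
        out[float(T)] = {
            "sync_index": res["index"],
            "ensemble_amplitude": res["ensemble_amplitude"],
            "mean_single_amplitude": res["mean_single_amplitude"],
            "single_period_mean": float(np.mean([s.period for s in singles]))
            if singles else None,
            "single_period_sd": float(np.std([s.period for s in singles]))
            if len(singles) > 1 else None,
            "n_oscillatory_molecules": len(singles),
            "ensemble_lost": res["index"] < DESYNC_INDEX_THRESHOLD,
        }
    return out
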