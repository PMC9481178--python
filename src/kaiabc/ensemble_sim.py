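"""Ensemble simulation of N KaiC hexamers coupled through KaiA sequestration.

The hexamers interact only through the shared pools of free KaiA dimers and
free KaiB monomers: KaiA absorbed into KaiC-KaiB-KaiA complexes during the
dephosphorylation phase is unavailable to hexamers trying to start their
phosphorylation phase, which entrains the population and produces coherent
ensemble oscillations.

The scheme is hybrid: the binding probabilities and the phosphorylation level
evolve deterministically (mean-field kinetics, explicit Euler at dt = 1e-3 h),
the six CI nucleotide bits per hexamer are simulated stochastically, and the
free KaiA concentration is obtained at every step from the conservation law
by a safeguarded Newton solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    IntegrationError,
    ModelParameters,
    adp_lifetime,
    kaiA_rates,
    kaiB_rates,
    kaiB_ring_step,
    phospho_step,
    structure_drive,
    structure_update,
)
from .thermo_rules import TemperatureModel, effective_parameters

__all__ = [
    "EnsembleState",
    "Trajectory",
    "TemperatureStep",
    "AdpPulse",
    "initial_state",
    "solve_free_kaiA",
    "solve_free_kaiB",
    "simulation_step",
    "simulate",
    "release_rate",
]

#: width of the sliding window for the ADP-release rate (h)
RELEASE_WINDOW_H = 0.2

_KAIB_SITES = np.arange(7.0)  # number of bound KaiB monomers per state


@dataclass
class EnsembleState:
    """State of the N-hexamer ensemble plus the free Kai protein pools."""

    pA: np.ndarray   # (N,)  P(C6A2)
    pB: np.ndarray   # (N,7) P(C6Bi)
    D: np.ndarray    # (N,)  phosphorylation level
    X: np.ndarray    # (N,)  structural order parameter
    q: np.ndarray    # (N,6) ADP(1)/ATP(0) bits
    xA: float        # free KaiA dimer concentration (counts per V)
    xB: float        # free KaiB monomer concentration (counts per V)
    t: float = 0.0   # simulation time (h)

    @property
    def n_hexamers(self) -> int:
        return self.D.shape[0]

    def bound_kaiB(self, V: float = 1.0) -> float:
        """Total KaiC-bound KaiB monomer concentration, (1/V) sum_k sum_i i*pB."""
        return float(np.sum(self.pB * _KAIB_SITES)) / V


@dataclass
class Trajectory:
    """Recorded ensemble observables.

    ``qr`` is the ADP-release rate per CI domain per hour averaged over the
    trailing 0.2 h window; ``D_mol`` optionally holds per-molecule
    phosphorylation traces (one column per traced hexamer).
    """

    t: np.ndarray
    D_mean: np.ndarray
    X_mean: np.ndarray
    q_mean: np.ndarray
    qr: np.ndarray
    xA: np.ndarray
    xB: np.ndarray
    D_mol: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t_h": self.t,
            "D_mean": self.D_mean,
            "X_mean": self.X_mean,
            "q_mean": self.q_mean,
            "qr_per_h": self.qr,
            "xA": self.xA,
            "xB": self.xB,
        })
        if self.D_mol is not None:
            for j in range(self.D_mol.shape[1]):
                df[f"D_mol{j}"] = self.D_mol[:, j]
        return df


@dataclass
class TemperatureStep:
    """Switch the ambient temperature at a given production time (h)."""

    time_h: float
    T_celsius: float


@dataclass
class AdpPulse:
    """Transiently multiply the baseline ADP lifetime (models added ADP)."""

    time_h: float
    duration_h: float
    lifetime_multiplier: float = 4.0


def initial_state(params: ModelParameters, rng: np.random.Generator,
                  T_kelvin: float = None, T0_kelvin: float = None) -> EnsembleState:
    """Randomised initial ensemble.

    All hexamers start KaiB-free with no KaiA bound; phosphorylation levels
    are drawn uniformly in [0, 1] (an artificially synchronised start is
    avoided) and the nucleotide bits are i.i.d. Bernoulli(1/2).  X is set by
    one quasi-equilibrium pass and the free pools by the conservation laws.
    A warm-up run discards the dependence on these choices.
    """
    N = params.N
    pB = np.zeros((N, 7))
    pB[:, 0] = 1.0
    pA = np.zeros(N)
    D = rng.random(N)
    q = (rng.random((N, 6)) < 0.5).astype(np.int8)
    X = np.full(N, 0.5)
    R = structure_drive(pA, pB, D, X, q.mean(axis=1), params)
    if T_kelvin is None:
        T_kelvin = T0_kelvin = 1.0
    X = structure_update(R, T_kelvin, T0_kelvin)
    state = EnsembleState(pA=pA, pB=pB, D=D, X=X, q=q,
                          xA=params.AT / 2.0, xB=params.BT, t=0.0)
    g = _binding_ratio(X, params)
    state.xA, _ = solve_free_kaiA(g, pB[:, 0], 0.0, params, x0=state.xA)
    xg = state.xA * g
    state.pA = pB[:, 0] * xg / (1.0 + xg)
    return state


def _binding_ratio(X, params: ModelParameters):
    hA, fA = kaiA_rates(X, params)
    return hA / np.maximum(fA, 1e-300)


def solve_free_kaiA(g, pB0, bound_kaiB, params: ModelParameters,
                    x0: float = None, rtol: float = 1e-10,
                    max_iter: int = 200):
    """Free KaiA dimer concentration from the conservation law.

    Solves ``xA + (xA/V) sum_k g_k pB0_k / (1 + xA g_k)
    + alpha(xA) * bound_kaiB = AT/2`` for the unique root xA >= 0; the left
    side rises continuously and strictly from 0, so a Newton iteration
    safeguarded by bisection on [0, AT/2] always converges.  Warm-starting
    from the previous step's value typically needs 2-3 iterations.

    Returns ``(xA, residual)``.
    """
    target = params.AT / 2.0
    if target <= 0.0:
        return 0.0, 0.0
    gcb = params.hAB / params.fAB
    Vinv = 1.0 / params.V
    lo, hi = 0.0, target
    x = min(max(x0 if x0 is not None else 0.5 * target, lo), hi)
    tol = rtol * target
    for _ in range(max_iter):
        xg = x * g
        denom = 1.0 + xg
        seq_cii = Vinv * float(np.sum(pB0 * xg / denom))
        dseq_cii = Vinv * float(np.sum(pB0 * g / (denom * denom)))
        xgcb = x * gcb
        alpha = xgcb / (1.0 + xgcb)
        dalpha = gcb / (1.0 + xgcb) ** 2
        fx = x + seq_cii + alpha * bound_kaiB - target
        if abs(fx) <= tol:
            return x, fx
        if fx > 0.0:
            hi = x
        else:
            lo = x
        dfx = 1.0 + dseq_cii + dalpha * bound_kaiB
        x_new = x - fx / dfx
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        x = x_new
    raise IntegrationError("free-KaiA conservation solve did not converge")


def solve_free_kaiB(pB, params: ModelParameters, tol: float = 1e-9):
    """Free KaiB monomer concentration xB = BT - (1/V) sum_k sum_i i*pB[i](k)."""
    bound = float(np.sum(pB * _KAIB_SITES)) / params.V
    xB = params.BT - bound
    if xB < -tol * max(params.BT, 1.0):
        raise IntegrationError(
            f"bound KaiB ({bound:.6g}) exceeds the total BT ({params.BT:.6g})"
        )
    return max(xB, 0.0), bound


def simulation_step(state: EnsembleState, params: ModelParameters,
                    rng: np.random.Generator, beta_ratio: float = 1.0,
                    lifetime_scale: float = 1.0) -> int:
    """Advance the ensemble by one step dt; returns the ADP-release count.

    Update order within the step: (i) stochastic nucleotide bits,
    (ii)+(iii) structure-dependent rates and the Euler update of the KaiB
    occupancies, (iv) conservation solves for the free pools and the
    quasi-equilibrium KaiA-on-CII probability, (v) phosphorylation Euler
    update, (vi) structural field and order parameter (one-step lag in X).

    ``beta_ratio`` is T0/T (absolute); ``lifetime_scale`` multiplies the ADP
    lifetime (ADP-pulse protocols).
    """
    p = params
    dt = p.dt
    X = state.X

    # (i) stochastic ATPase update (hazards from the current structure)
    dADP = lifetime_scale * adp_lifetime(X, p)
    p_hyd = p.f_hyd * dt
    p_rel = dt / dADP
    if p_hyd >= 1.0 or np.any(p_rel >= 1.0):
        raise IntegrationError("ATPase hazard per step >= 1; reduce dt")
    u = rng.random(state.q.shape)
    is_adp = state.q == 1
    hydrolyse = ~is_adp & (u < p_hyd)
    release = is_adp & (u < p_rel[:, None])
    state.q[hydrolyse] = 1
    state.q[release] = 0
    n_release = int(np.count_nonzero(release))

    # (ii)+(iii) rate evaluation and KaiB-ring Euler update
    hB, fB = kaiB_rates(X, p)
    state.pB = kaiB_ring_step(state.pB, state.xB, hB, fB, dt)

    # (iv) conservation solves, then quasi-equilibrium KaiA on the CII
    state.xB, bound_b = solve_free_kaiB(state.pB, p)
    g = _binding_ratio(X, p)
    state.xA, _ = solve_free_kaiA(g, state.pB[:, 0], bound_b, p, x0=state.xA)
    xg = state.xA * g
    state.pA = state.pB[:, 0] * xg / (1.0 + xg)

    # (v) phosphorylation update
    state.D = phospho_step(state.D, state.pA, p, dt)

    # (vi) structural order parameter (R from the pre-update X)
    R = structure_drive(state.pA, state.pB, state.D, X,
                        state.q.mean(axis=1), p)
    state.X = 0.5 * (1.0 + np.tanh(R * beta_ratio))

    state.t += dt
    return n_release


def release_rate(release_counts: np.ndarray, dt: float, n_hexamers: int,
                 window: float = RELEASE_WINDOW_H) -> np.ndarray:
    """Sliding-window ADP-release rate per CI domain per hour.

    ``release_counts[j]`` is the number of release events in step j; the
    rate at step j averages the trailing ``window`` hours (shorter early on).
    """
    if window < dt:
        raise ValueError("window must be at least one time step")
    w = int(round(window / dt))
    c = np.cumsum(np.asarray(release_counts, dtype=float))
    trailing = c.copy()
    if c.size > w:
        trailing[w:] = c[w:] - c[:-w]
    steps = np.minimum(np.arange(1, c.size + 1), w)
    return trailing / (6.0 * n_hexamers * steps * dt)


def _kernel_args(p: ModelParameters):
    return (p.hA0, p.fA0, p.hB0, p.fB0, p.hAB / p.fAB, p.kp, p.kdp,
            p.f_hyd, p.inv_dADP0, p.d0, p.d1, p.d2, p.d3, p.d4,
            p.A_X, p.B_X, p.C_X, p.P0, p.d2_includes_free_state,
            p.AT / 2.0, p.BT, 1.0 / p.V, p.dt)


def simulate(params: ModelParameters,
             thermo: Optional[TemperatureModel] = None,
             duration: float = 480.0,
             warmup: float = 100.0,
             seed: int = 0,
             record_stride: float = 0.1,
             n_molecule_traces: int = 0,
             events: Sequence = (),
             initial: Optional[EnsembleState] = None,
             engine: str = "numba") -> Trajectory:
    """Run the ensemble and record observables.

    The first ``warmup`` hours are integrated but discarded; recorded times
    are production times starting at 0 (the paper-scale production length is
    3276.8 h; scaled-down runs use whatever ``duration`` covers the required
    number of cycles).  Event times (temperature steps, ADP pulses) are in
    production time.  With a fixed ``(params, thermo, seed)`` the trajectory
    is bit-reproducible, and the ``numba`` and ``numpy`` engines follow the
    identical random stream and produce the same trajectory.
    """
    rng = np.random.default_rng(seed)
    thermo = thermo or TemperatureModel()

    state = initial if initial is not None else initial_state(
        params, rng, thermo.T_kelvin, thermo.T0_kelvin)

    dt = params.dt
    n_warm = int(round(warmup / dt))
    n_prod = int(round(duration / dt))
    stride = max(int(round(record_stride / dt)), 1)
    total = n_warm + n_prod
    win_steps = int(round(RELEASE_WINDOW_H / dt))

    # event schedule in production-step indices
    temp_steps = {int(round(ev.time_h / dt)): ev.T_celsius
                  for ev in events if isinstance(ev, TemperatureStep)}
    pulses = [(int(round(ev.time_h / dt)),
               int(round((ev.time_h + ev.duration_h) / dt)),
               ev.lifetime_multiplier)
              for ev in events if isinstance(ev, AdpPulse)]

    # chunk boundaries: records, event switches, start/end
    bset = {0, n_prod}
    bset.update(range(0, n_prod + 1, stride))
    bset.update(i for i in temp_steps if 0 <= i <= n_prod)
    for on, off, _ in pulses:
        bset.update(i for i in (on, off) if 0 <= i <= n_prod)
    boundaries = sorted(bset)

    releases = np.zeros(total, dtype=np.int64)

    n_rec = sum(1 for b in boundaries if b % stride == 0)
    t_out = np.empty(n_rec)
    D_out = np.empty(n_rec)
    X_out = np.empty(n_rec)
    q_out = np.empty(n_rec)
    qr_out = np.empty(n_rec)
    xA_out = np.empty(n_rec)
    xB_out = np.empty(n_rec)
    mol_out = (np.empty((n_rec, n_molecule_traces))
               if n_molecule_traces > 0 else None)

    use_kernel = engine == "numba"
    if use_kernel:
        from ._kernel import run_steps
    max_resid = 0.0
    denom = 6.0 * params.N * win_steps * dt
    isample = 0

    def run_chunk(p_eff, beta_ratio, scale, start, n_steps):
        nonlocal max_resid
        if n_steps <= 0:
            return
        if use_kernel:
            xA, xB, resid = run_steps(
                state.pA, state.pB, state.D, state.X, state.q,
                state.xA, state.xB, n_steps, releases, start,
                *_kernel_args(p_eff), beta_ratio, scale, rng)
            state.xA, state.xB = xA, xB
            max_resid = max(max_resid, resid)
        else:
            for j in range(n_steps):
                releases[start + j] = simulation_step(
                    state, p_eff, rng, beta_ratio, scale)
        state.t = (start + n_steps) * dt

    def record(prod_i):
        nonlocal isample
        abs_i = n_warm + prod_i
        lo = max(abs_i - win_steps, 0)
        window = releases[lo:abs_i]
        t_out[isample] = prod_i * dt
        D_out[isample] = state.D.mean()
        X_out[isample] = state.X.mean()
        q_out[isample] = state.q.mean()
        qr_out[isample] = (window.sum() / denom if abs_i >= win_steps
                           else (window.sum() / (6.0 * params.N * max(abs_i, 1) * dt)))
        xA_out[isample] = state.xA
        xB_out[isample] = state.xB
        if mol_out is not None:
            mol_out[isample] = state.D[:n_molecule_traces]
        isample += 1

    # warm-up (no events, reference thermo condition)
    p_eff = effective_parameters(params, thermo)
    beta_ratio = thermo.T0_kelvin / thermo.T_kelvin
    run_chunk(p_eff, beta_ratio, 1.0, 0, n_warm)

    for bi, b in enumerate(boundaries):
        if b in temp_steps:
            thermo_now = thermo.at(temp_steps[b])
            p_eff = effective_parameters(params, thermo_now)
            beta_ratio = thermo.T0_kelvin / thermo_now.T_kelvin
        if b % stride == 0:
            record(b)
        if bi + 1 < len(boundaries):
            nxt = boundaries[bi + 1]
            scale = 1.0
            for on, off, mult in pulses:
                if on <= b < off:
                    scale = mult
                    break
            run_chunk(p_eff, beta_ratio, scale, n_warm + b, nxt - b)

    traj = Trajectory(
        t=t_out[:isample], D_mean=D_out[:isample], X_mean=X_out[:isample],
        q_mean=q_out[:isample], qr=qr_out[:isample],
        xA=xA_out[:isample], xB=xB_out[:isample],
        D_mol=mol_out[:isample] if mol_out is not None else None,
        meta={
            "N": params.N, "V": params.V, "dt": dt,
            "warmup_h": warmup, "duration_h": duration,
            "record_stride_h": stride * dt,
            "release_window_h": win_steps * dt,
            "seed": seed,
            "T_celsius": thermo.T_celsius,
            "n_molecule_traces": n_molecule_traces,
            "max_kaiA_residual": max_resid,
            "engine": engine,
        },
    )
    return traj
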