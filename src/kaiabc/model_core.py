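"""Single-hexamer state and elementary rate laws of the KaiC reaction-structure model.

Each KaiC hexamer is described by four coarse-grained chemical coordinates --
the KaiA-on-CII binding probability ``pA``, the KaiB-on-CI occupancy
distribution ``pB[0..6]``, the CII phosphorylation level ``D`` and the CI
nucleotide occupancy bits ``q[1..6]`` -- plus a continuous structural order
parameter ``X`` in [0, 1] that interpolates between the dephosphorylation-phase
conformation (X ~ 0) and the phosphorylation-phase conformation (X ~ 1).

The structure is treated as in quasi-equilibrium under an effective field R
built from the chemical state (KaiA binding stabilises X ~ 1, KaiB binding
stabilises X ~ 0, high phosphorylation and ADP-loaded CI domains destabilise
X ~ 1), and every reaction rate in turn depends on X through tanh switching
functions.  This mutual dependence is the multifold feedback loop that makes
individual hexamers oscillate.

All functions are vectorised over a leading ensemble axis; energies are in
units of kB*T0 (T0 the reference temperature), rates in 1/h, concentrations in
counts per simulation volume V.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "IntegrationError",
    "ModelParameters",
    "HexamerState",
    "kaiA_rates",
    "kaiB_rates",
    "kaiA_cii_equilibrium",
    "kaiA_on_kaiB_alpha",
    "kaiB_ring_step",
    "phospho_step",
    "adp_lifetime",
    "atpase_step",
    "structure_drive",
    "structure_update",
]

#: tolerance below which a negative probability produced by an Euler step is
#: treated as roundoff and clipped; larger violations abort the integration.
NEGATIVITY_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when an explicit-Euler step produces an unstable update."""


@dataclass
class ModelParameters:
    """Rate constants and coupling constants of the hexamer model.

    Defaults are the standard parameter set at the reference temperature
    T0 = 30 C.  Rates are in 1/h with concentrations measured in counts per
    simulation volume ``V``; coupling energies ``d0``..``d4`` are in kB*T0.
    """

    # --- binding / unbinding rate constants (1/h) ---
    hA0: float = 5e-1     # KaiA dimer binding to the CII
    fA0: float = 1e3      # KaiA dimer unbinding from the CII
    hB0: float = 5e-5     # KaiB monomer binding to a CI domain
    fB0: float = 2.0      # KaiB monomer unbinding from a CI domain
    hAB: float = 6e-1     # KaiA dimer binding to a KaiC-bound KaiB
    fAB: float = 1e2      # KaiA dimer unbinding from a KaiC-bound KaiB
    # --- P/dP reactions (1/h) ---
    kp: float = 0.18      # phosphorylation
    kdp: float = 0.18     # dephosphorylation
    # --- ATPase reactions in the CI ---
    f_hyd: float = 1.0        # hydrolysis frequency of bound ATP (1/h)
    inv_dADP0: float = 1.0    # inverse baseline lifetime of bound ADP (1/h)
    # --- structural coupling energies (kB*T0) ---
    d0: float = 2.0   # bias setting the average structure
    d1: float = 5.0   # KaiA-on-CII binding stabilises X ~ 1
    d2: float = 5.0   # KaiB-on-CI binding stabilises X ~ 0
    d3: float = 3.0   # phosphorylation level, delayed negative feedback
    d4: float = 2.0   # CI nucleotide state, transition trigger
    # --- structure sensitivities (dimensionless) ---
    A_X: float = 1.0
    B_X: float = 1.0
    C_X: float = 2.0
    P0: float = 0.1   # KaiA-binding sensitivity of the P/dP reactions
    # --- ensemble composition ---
    N: int = 1000         # number of KaiC hexamers
    V: float = 1.0        # simulation volume (V=1 corresponds to N=1000)
    AT: float = field(default=None)  # total KaiA monomers per V (2N/V)
    BT: float = field(default=None)  # total KaiB monomers per V (6N/V)
    CT: float = field(default=None)  # total KaiC monomers per V (6N/V)
    dt: float = 1e-3      # integration step (h)
    #: include the KaiB-free state in the d2 sum (literal reading of the
    #: structural field; equivalent to shifting d0 for free KaiC).
    d2_includes_free_state: bool = False

    def __post_init__(self) -> None:
        if self.AT is None:
            self.AT = 2.0 * self.N / self.V
        if self.BT is None:
            self.BT = 6.0 * self.N / self.V
        if self.CT is None:
            self.CT = 6.0 * self.N / self.V
        self.validate()

    @classmethod
    def standard(cls, N: int = 1000, **overrides) -> "ModelParameters":
        """Standard condition at ensemble size ``N``.

        The volume is scaled as V = N/1000 so that all concentrations
        (counts per V) are independent of N; N=1000 gives V=1.
        """
        overrides.setdefault("V", N / 1000.0)
        return cls(N=N, **overrides)

    def validate(self) -> None:
        rates = {
            "hA0": self.hA0, "fA0": self.fA0, "hB0": self.hB0,
            "fB0": self.fB0, "hAB": self.hAB, "fAB": self.fAB,
            "kp": self.kp, "kdp": self.kdp,
            "f_hyd": self.f_hyd, "inv_dADP0": self.inv_dADP0,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")
        for name in ("A_X", "B_X", "C_X", "P0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.V <= 0:
            raise ValueError("V must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("AT", "BT", "CT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    @property
    def dADP0(self) -> float:
        """Baseline lifetime of the ADP-bound state (h)."""
        return 1.0 / self.inv_dADP0

    @property
    def rate_names(self) -> Tuple[str, ...]:
        """The ten kinetic rate constants of the model."""
        return ("hA0", "fA0", "hB0", "fB0", "hAB", "fAB",
                "kp", "kdp", "f_hyd", "inv_dADP0")


@dataclass
class HexamerState:
    """State of a single KaiC hexamer (convenience container).

    The ensemble simulator stores these fields as stacked arrays; this class
    is the per-molecule view used for unit-level work.
    """

    pA: float                 # P(C6A2): KaiA dimer bound on the CII
    pB: np.ndarray            # P(C6Bi), i=0..6: number of bound KaiB monomers
    D: float                  # phosphorylation level in [0, 1]
    X: float                  # structural order parameter in [0, 1]
    q: np.ndarray             # ADP(1)/ATP(0) occupancy of the six CI domains

    def validate(self, tol: float = 1e-9) -> None:
        pB = np.asarray(self.pB, dtype=float)
        if pB.shape != (7,):
            raise ValueError("pB must have shape (7,)")
        if abs(pB.sum() - 1.0) > 1e-9:
            raise ValueError("sum of pB must equal 1")
        if np.any(pB < -tol):
            raise ValueError("pB components must be >= 0")
        if not (-tol <= self.pA <= pB[0] + tol):
            raise ValueError("pA must lie in [0, pB[0]] (the KaiB-free state)")
        if not (0.0 <= self.D <= 1.0):
            raise ValueError("D must lie in [0, 1]")
        if not (0.0 <= self.X <= 1.0):
            raise ValueError("X must lie in [0, 1]")
        q = np.asarray(self.q)
        if q.shape != (6,) or not np.isin(q, (0, 1)).all():
            raise ValueError("q must be six binary occupancy bits")

    @property
    def q_mean(self) -> float:
        return float(np.mean(self.q))


# ---------------------------------------------------------------------------
# structure-dependent rate laws
# ---------------------------------------------------------------------------

def kaiA_rates(X, params: ModelParameters):
    """KaiA-on-CII binding and unbinding rates hA(X), fA(X).

    Binding is favoured and unbinding suppressed in the X ~ 1 structure:
    hA = hA0 [1 + tanh((2X-1)/A_X)], fA = fA0 [1 - tanh((2X-1)/A_X)].
    """
    t = np.tanh((2.0 * np.asarray(X) - 1.0) / params.A_X)
    return params.hA0 * (1.0 + t), params.fA0 * (1.0 - t)


def kaiB_rates(X, params: ModelParameters):
    """KaiB-on-CI binding and unbinding rates hB(X), fB(X) (favour X ~ 0)."""
    t = np.tanh((2.0 * np.asarray(X) - 1.0) / params.B_X)
    return params.hB0 * (1.0 - t), params.fB0 * (1.0 + t)


def kaiA_cii_equilibrium(xA, X, pB0, params: ModelParameters):
    """Quasi-equilibrium probability pA that the CII binds a KaiA dimer.

    KaiA exchange on the CII is orders of magnitude faster than every other
    reaction, so pA instantaneously partitions the KaiB-free state pB0:
    pA = pB0 * xA*g / (1 + xA*g) with g = hA(X)/fA(X).

    Returns ``(pA, hA, fA)``.
    """
    hA, fA = kaiA_rates(X, params)
    fA = np.maximum(fA, 1e-300)  # X -> 1 exactly cannot occur for finite R
    g = hA / fA
    xg = np.asarray(xA) * g
    return np.asarray(pB0) * xg / (1.0 + xg), hA, fA


def kaiA_on_kaiB_alpha(xA, params: ModelParameters):
    """Probability alpha that any given KaiC-bound KaiB carries a KaiA dimer.

    KaiA-on-KaiB exchange is fast and independent of the KaiC structure, so
    the 2j-mer occupancies factorise binomially over the i bound KaiB
    monomers with per-site probability alpha = xA*g / (1 + xA*g),
    g = hAB/fAB; only alpha is needed downstream.
    """
    xg = np.asarray(xA) * (params.hAB / params.fAB)
    return xg / (1.0 + xg)


def kaiB_ring_step(pB, xB, hB, fB, dt):
    """Explicit-Euler update of the 7-state KaiB occupancy birth-death chain.

    State i (i bound KaiB monomers, 0..6) binds at rate (6-i)*hB*xB and
    unbinds at rate i*fB.  The update is written in flux form so the total
    probability is conserved to machine roundoff.

    ``pB`` has shape (..., 7); ``hB``/``fB`` broadcast against the leading
    axes.  Raises :class:`IntegrationError` on a step-size instability
    (components more negative than the clipping tolerance).
    """
    pB = np.asarray(pB, dtype=float)
    hBxB = np.asarray(hB) * xB
    sites_free = np.arange(6.0, 0.0, -1.0)      # 6-i for i=0..5
    sites_bound = np.arange(1.0, 7.0)           # i for i=1..6
    # forward flux i -> i+1 and backward flux i+1 -> i, for i = 0..5
    J_bind = (hBxB[..., None] * sites_free) * pB[..., :6]
    J_unbind = (np.asarray(fB)[..., None] * sites_bound) * pB[..., 1:]
    net = J_bind - J_unbind
    out = pB.copy()
    out[..., :6] -= dt * net
    out[..., 1:] += dt * net
    if np.any(out < -NEGATIVITY_TOL):
        raise IntegrationError(
            "KaiB ring update produced negative probability "
            f"(min {out.min():.3e}); reduce dt"
        )
    np.clip(out, 0.0, None, out=out)
    return out


def phospho_step(D, pA, params: ModelParameters, dt):
    """Explicit-Euler update of the phosphorylation level.

    dD/dt = kp H+ (1-D) - kdp H- D with H+ = z/(1+z), H- = 1/(1+z) and
    z = pA/P0: KaiA residence on the CII tilts the balance toward
    phosphorylation.  D stays in [0, 1] for dt*max(kp, kdp) < 1.
    """
    z = np.asarray(pA) / params.P0
    Hp = z / (1.0 + z)
    Hm = 1.0 / (1.0 + z)
    return np.asarray(D) + dt * (params.kp * Hp * (1.0 - np.asarray(D))
                                 - params.kdp * Hm * np.asarray(D))


def adp_lifetime(X, params: ModelParameters):
    """Mean lifetime of the ADP-bound CI state, Delta_ADP(X).

    Delta_ADP = Delta_ADP0 [1 - tanh((2X-1)/C_X)]: the X ~ 1 structure
    releases ADP quickly, the X ~ 0 structure holds it.
    """
    return params.dADP0 * (1.0 - np.tanh((2.0 * np.asarray(X) - 1.0) / params.C_X))


def atpase_step(q, X, params: ModelParameters, dt, rng,
                lifetime_scale: float = 1.0, f_hyd: float = None):
    """One stochastic update of the CI nucleotide bits.

    Each ATP-loaded domain (q=0) hydrolyses with probability f_hyd*dt; each
    ADP-loaded domain (q=1) releases its ADP (and instantly rebinds ATP) with
    the memoryless hazard dt/Delta_ADP(X), which realises the prescribed
    fluctuating lifetime with the correct mean while letting the lifetime
    track the structural state during the bound interval.

    ``lifetime_scale`` multiplies Delta_ADP (used for ADP-pulse protocols).
    Returns ``(q_new, n_release)`` with the total number of release events.
    """
    q = np.asarray(q)
    fh = params.f_hyd if f_hyd is None else f_hyd
    dADP = lifetime_scale * adp_lifetime(X, params)
    p_hyd = fh * dt
    p_rel = dt / dADP
    if p_hyd >= 1.0 or np.any(p_rel >= 1.0):
        raise IntegrationError("ATPase hazard per step >= 1; reduce dt")
    u = rng.random(q.shape)
    is_adp = q == 1
    hydrolyse = ~is_adp & (u < p_hyd)
    if np.ndim(p_rel) and q.ndim == p_rel.ndim + 1:
        p_rel = p_rel[..., None]
    release = is_adp & (u < p_rel)
    q_new = np.where(hydrolyse, 1, np.where(release, 0, q)).astype(q.dtype)
    return q_new, int(release.sum())


# ---------------------------------------------------------------------------
# structural order parameter
# ---------------------------------------------------------------------------

def structure_drive(pA, pB, D, X, q_mean, params: ModelParameters):
    """Quasi-equilibrium structural field R (units kB*T0).

    R = d0 + d1*pA - d2*sum_{i>=1} pB[i] - d3*(2D-1) - d4*F with the
    ATPase coupling F = q_mean*X - (1-q_mean)*(1-X); ``X`` is the order
    parameter of the previous step (explicit one-step lag).

    With ``params.d2_includes_free_state`` the d2 sum also counts the
    KaiB-free, KaiA-free state (pB[0]-pA), the literal sum over all complex
    states; for free KaiC that term is a constant offset degenerate with d0,
    which is why the bound-only sum is the default.
    """
    pA = np.asarray(pA)
    pB = np.asarray(pB)
    D = np.asarray(D)
    X = np.asarray(X)
    q_mean = np.asarray(q_mean)
    bound = 1.0 - pB[..., 0]
    if params.d2_includes_free_state:
        bound = bound + (pB[..., 0] - pA)
    F = q_mean * X - (1.0 - q_mean) * (1.0 - X)
    return (params.d0 + params.d1 * pA - params.d2 * bound
            - params.d3 * (2.0 * D - 1.0) - params.d4 * F)


def structure_update(R, T_kelvin: float, T0_kelvin: float):
    """Quasi-equilibrium order parameter X = (1 + tanh(beta*R)) / 2.

    ``R`` is in kB*T0 units, so beta*R = R * T0/T at absolute temperature T.
    """
    return 0.5 * (1.0 + np.tanh(np.asarray(R) * (T0_kelvin / T_kelvin)))
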