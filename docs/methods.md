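# Methods

## The model

`kaiabc` simulates an ensemble of N KaiC hexamers in a well-mixed volume
containing KaiA and KaiB. Each hexamer k carries five coupled descriptors:

* `D(k)` ∈ [0,1] — phosphorylation level of the twelve CII sites (Ser431 and
  Thr432 are lumped; the two sites are not distinguished).
* `X(k)` ∈ [0,1] — structural order parameter of the two-state allosteric
  transition; X ≈ 1 is the phosphorylation-phase conformation, X ≈ 0 the
  dephosphorylation-phase conformation.
* `pA(k)` — probability that the CII ring binds a KaiA dimer (C6A2).
* `pB(k, i)`, i = 0..6 — probability that i KaiB monomers sit on the CI ring.
  KaiA dimers load onto bound KaiB independently with probability
  α = xA·g_CB:A/(1 + xA·g_CB:A), so the full complex distribution over
  C6BiA2j is binomial in j and never needs to be stored.
* `q(i; k)` ∈ {0,1}, i = 1..6 — ADP(1)/ATP(0) occupancy of each CI domain,
  the only microscopically stochastic variables.

The structure is in quasi-equilibrium under an effective field (units kB·T0)

    R = d0 + d1·pA − d2·Σ_{i≥1} pB_i − d3·(2D − 1) − d4·F,
    F = q̄·X − (1 − q̄)·(1 − X),        X = ½(1 + tanh(βR)),

with β·R = R·T0/T because the coupling constants are expressed in kB·T0.
KaiA binding (d1) stabilises X ≈ 1 and KaiB binding (d2) stabilises X ≈ 0
(positive feedback); the slowly accumulating phosphorylation (d3) and the
CI nucleotide state (d4) destabilise the current conformation (delayed
negative feedback and stochastic triggering). All binding/unbinding rates
switch with X through tanh((2X − 1)/A_X)-type factors; the ADP-bound
lifetime Δ_ADP(X) = Δ_ADP0·(1 − tanh((2X − 1)/C_X)) is short in the X ≈ 1
state. Phosphorylation follows
dD/dt = kp·H⁺·(1 − D) − kdp·H⁻·D with H⁺ = z/(1+z), H⁻ = 1/(1+z),
z = pA/P0.

Hexamers interact only through conservation of KaiA and KaiB. Free KaiA
(xA) is obtained every step as the unique root of

    xA + Σ_k pA(k)/V + α(xA)·Σ_k Σ_i i·pB(k,i)/V = AT/2,

solved by Newton iteration safeguarded with bisection on [0, AT/2]
(relative tolerance 1e-10, warm-started from the previous step; the
conservation residual is tracked and stays below 1e-8·AT/2). Free KaiB is
the explicit difference xB = BT − Σ i·pB/V. Sequestration of KaiA into
KaiC–KaiB–KaiA complexes during the dephosphorylation phase starves the
phosphorylating hexamers of KaiA, which is the synchronisation mechanism.

## Integration scheme

Hybrid stochastic–deterministic explicit Euler at dt = 1e-3 h, per step:
(i) stochastic update of the q bits (hydrolysis hazard f_hyd·dt for ATP
domains, release hazard dt/Δ_ADP(X) for ADP domains); (ii) evaluation of the
X-dependent rate constants; (iii) Euler update of the KaiB occupancy chain
(binding (6−i)·hB·xB, unbinding i·fB, written in flux form so Σ pB is
conserved to machine roundoff); (iv) conservation solves and the
quasi-equilibrium pA = pB0·xA·g/(1 + xA·g); (v) phosphorylation update;
(vi) structural field and X with a one-step lag (R is evaluated with the
previous X; at dt = 1e-3 h the lag is far below every other timescale and
iterating X to its fixed point changes nothing detectable). Probabilities
more negative than 1e-9 abort the run; smaller excursions are clipped.

The ADP lifetime prescription (a fluctuating lifetime with mean Δ_ADP) is
realised as the memoryless hazard above: it has the prescribed mean, lets
the lifetime track structural change during the bound interval, and avoids
carrying per-domain alarm clocks. ADP+Pi and ADP states are not
distinguished.

Two engines produce bit-compatible trajectories from the same seed: a
readable vectorised numpy path (`engine="numpy"`) and a fused numba kernel
(`engine="numba"`, default) that advances whole chunks between recording
points; a test asserts they follow the identical random stream.

## Parameters and units

Concentrations are counts per simulation volume V; V = 1 corresponds to
3×10⁻¹⁵ l, so N = 1000 hexamers give 3.3 μM KaiC (monomer basis) with
AT : BT : CT = 1 : 3 : 3 (AT/2 = N KaiA dimers, BT = 6N). When N is reduced
for speed, V scales as N/1000 so all concentrations — and therefore all
deterministic dynamics — are unchanged; only the finite-size fluctuations
grow as 1/√N. Default rates (1/h): hA0 = 0.5, fA0 = 1e3, hB0 = 5e-5,
fB0 = 2, hAB = 0.6, fAB = 1e2, kp = kdp = 0.18, f_hyd = 1, 1/Δ_ADP0 = 1;
couplings (kB·T0): d0 = 2, d1 = d2 = 5, d3 = 3, d4 = 2; sensitivities
A_X = B_X = 1, C_X = 2, P0 = 0.1. The implied dissociation constants are
Kd(CII:KaiA) = 1.1 μM, Kd(CI:KaiB) = 22 μM, Kd(KaiB:KaiA) = 0.09 μM
(`concentration_report`).

The d2 sum runs over the KaiB-bound states i ≥ 1 only. The literal sum over
all complex states would add the KaiB-free term, which for free KaiC is a
constant offset indistinguishable from d0 and which in practice pins the
ensemble in a non-oscillatory low-D state; a switch
(`d2_includes_free_state`) exposes the literal reading.

## Temperature model

Every rate carries the Arrhenius-type factor
s(ΔE; T, T0) = exp(−ΔE/kBT + ΔE/kBT0) relative to T0 = 30 °C. The six
generic rates (hA0, fA0, hAB, fAB, kp, kdp) share ΔE0 (default 10 kB·T0).
Three rules modify the rest:

* **Rule 1** — d3 and d4 are *divided* by s(ΔEf; T, T0) (ΔEf = 7 kB·T0):
  thermal loosening of the CI–CII interface weakens the reaction–structure
  coupling at higher temperature, which lengthens the period and enlarges
  the amplitude, compensating the Arrhenius acceleration. (A published
  table prints this factor as a product, but only division gives weaker
  coupling at higher temperature, and the accompanying text states the
  division.)
* **Rule 2** — hB0 gains the extra factor s(ΔE_gs→fs) (=10 kB·T0) and fB0
  the factor s(ΔE′_fs→gs) (=12 kB·T0): the KaiB fold switch to the
  binding-competent conformation is thermally activated.
* **Rule 3** — f_hyd and 1/Δ_ADP0 are temperature-independent (the measured
  ATPase insensitivity); without Rule 3 they scale with s(ΔE0), and
  mutant-style overrides ΔEa/ΔEb scale them independently.

Presets: Case A = Rules 1+2+3, B = 1+3 (KaiB energies zero), C = 1+2
(ATPase follows ΔE0), D = 2+3 with ΔEf = 0. Q10 is defined as
period(T0−5 °C)/period(T0+5 °C).

## Analysis conventions

Periods and amplitudes come from peak/trough detection (scipy
`find_peaks`, prominence 0.02) on the ensemble-mean phosphorylation level
smoothed by a 1 h moving average; amplitude is the mean peak-to-following-
trough drop, and a series with fewer than three qualifying peaks or
amplitude below 0.02 is non-oscillatory. Circadian time pins the peak at
CT 16 with the cycle normalised to 24 CT hours. Phase shifts are reported
in CT hours, advance positive, wrapped to (−12, 12]. For sustained
perturbations (temperature steps) the null rhythm is extrapolated from the
onset phase at the perturbed trajectory's own post-step period, so a
changed period does not masquerade as a phase shift; for transient
perturbations (ADP pulses) this reduces to comparison against the
unperturbed reference, which shares the random seed so the comparison is
exactly paired. The synchrony index is the ensemble-mean amplitude divided
by the mean single-molecule amplitude; below 0.1 the ensemble rhythm is
called lost.

## Problem sizes

Production analyses in the package's tests and in `scripts/acceptance.py`
use N = 150–400 hexamers with 100 h warm-up and 200–260 h of production
(10–16 cycles), two replicate seeds per temperature point for Q10; these
sizes keep every estimate's standard error well inside the reported
tolerances while completing in minutes on one CPU. Initial conditions are
KaiB-free hexamers with uniformly random phosphorylation levels and
Bernoulli(1/2) nucleotide bits; the warm-up makes the attractor independent
of this choice (verified against a fully synchronised start).

## Known limitations

* With the published parameter tables implemented verbatim, the
  standard-condition ensemble rhythm here has a period of ~15.5 h and a
  D-amplitude of ~0.2. The feedback architecture behaves as described —
  reducing d3·d4 by ~20–25 % moves the system to a ~25 h, large-amplitude
  rhythm, oscillation is lost below s ≈ 0.5 (caught at X ≈ 1), period and
  amplitude fall monotonically with s — but the absolute operating point
  sits closer to the strong-feedback boundary than the published figures
  suggest. Temperature-compensation ratios computed here should therefore
  be read as properties of this parameterisation: the Q10-versus-ΔEf series
  is monotone and spans compensation to overcompensation, but is compressed
  relative to the published range (see the package tests for measured
  values).
* The synthetic ensemble is well mixed, with no hexamer–monomer exchange,
  no explicit KaiB fold-switch kinetics (they enter only through activation
  energies) and no separate Ser/Thr phosphorylation pathways; conclusions
  about real phosphoform ordering or spatial effects are out of reach by
  construction.
* Binding probabilities are mean-field per hexamer (no Gillespie layer), so
  molecule-to-molecule variability in KaiA/KaiB occupancy is
  underestimated; only the ATPase bits are microscopically stochastic.
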