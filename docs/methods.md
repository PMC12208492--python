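# Methods

## The electrodiffusive picture

The package models a single-compartment neuron as two well-mixed ionic
reservoirs (intra- and extracellular) separated by a thin membrane slab.
Inside the slab the electric field is taken uniform (Gauss's law with bulk
electroneutrality on both sides), so the steady-state intramembrane
concentration profile of each permeant ion is the classical constant-field
profile

    c_q(ξ) = c_out + (c_in − c_out) · expm1(−u ξ)/expm1(−u),
    u = z_q F V / RT,   ξ = x/d  (ξ = 0 extracellular, ξ = 1 intracellular).

The harmonic mean of that profile, c̄_q = d / ∫ dx/c_q(x), has the closed
form

    c̄_q = [c_in − c_out e^{−u}] / [1 − e^{−u}] · V / (V − E_q),

and converts a permeability into a conductance density:

    G_q = z_q² F² P_q c̄_q / RT,      I_q = −G_q (V − E_q).

The product −G_q(V − E_q) is *identically* the Goldman–Hodgkin–Katz (GHK)
current, which is the bridge between permeability-based electrodiffusion
and conductance-based circuit models: rectification is nothing but the
voltage- and concentration-dependence of c̄_q.  Membrane-averaged
permeability relates to single channels by P = (N_c/S) · S_c · P_c · p_o
with channel density N_c/S, pore cross-section S_c and open probability
p_o.

Sign convention: all currents are depolarizing-positive (C_m dV/dt = Σ I_q)
throughout the library; channel I-V *tables* can be emitted with the
experimental −i convention in the CLI reporting layer only.

## Channel characterization

A multi-permeant channel is linear exactly when the permeability ratio
counterbalances the concentration gradients (P_q2/P_q1 =
−Δ[q1]/Δ[q2]).  Measured linear-condition slopes therefore invert into
single-channel permeabilities.  The presets calibrate:

* GABA_A (Cl⁻, HCO₃⁻; ratio 0.2): 30 pS slope at [Cl]i/o = 147/145 mM
  (the 2 mM excess is what the HCO₃ gradient 15/25 mM requires),
  giving P_Cl = 7.03e−2, P_HCO3 = 1.41e−2 m/s;
* AMPA (K⁺, Na⁺): 30 pS at the physiological baths, which sit at the
  linearity condition when P_Na/P_K = 0.87, giving P_K = 8.99e−2,
  P_Na = 7.81e−2 m/s;
* the GluR2-lacking AMPA preset adds P_Ca = 2.70 m/s
  ([Ca]o = 2, [Ca]i = 1e−4 mM), which breaks the K/Na counterbalance and
  makes the channel inwardly rectifying;
* the equivalent leak channel uses P_K = 2.55e−1, P_Cl = 5.08e−2,
  P_Na = 1.27e−2 m/s at 1e7 channels/cm².

**Pore cross-section convention.**  Both presets use a 5 Å nominal pore.
The effective electrodiffusive cross-section is taken as S_c = π·d²
(four times the geometric disc area).  This is a calibration convention,
not a geometric claim: it is the unique choice under which the published
30 pS calibrations, the published single-channel permeabilities, and the
published membrane-averaged permeabilities (through P = (N_c/S)·S_c·P_c
with the stated densities of 1e7 leak and 4e6 AMPA channels per cm²) are
all mutually consistent.

Two equivalent conductance/reversal decompositions of the same total
current are provided.  The *apparent* pair builds a composite permeant
[C] = [q1] + (P_q2/P_q1)[q2] (equal unit valences only); its reversal is
voltage-independent and is the channel's true zero-current voltage
(−62.41 mV for the physiological GABA_A preset).  The *latent* pair is the
chord-conductance form g_l = Σ g_q, E_l = Σ g_q E_q / g_l, valid for any
valence mix but voltage-dependent even for perfectly linear channels.

## The neuron models

Seven variants share one parameter set and the reduced Traub–Miles (RTM)
m/h/n kinetics (time in ms, V in mV):

| variant | state | leak | glutamate | voltage-gated |
|---|---|---|---|---|
| cHH    | V,m,h,n          | linear (G_LH, E_LH) | linear | circuit |
| fGNP   | V,m,h,n          | GHK (frozen conc.)  | linear | circuit |
| GNP    | Ko,Nai,Cli,m,h,n | GHK | GHK | circuit |
| vGNP   | Ko,Nai,Cli,m,h,n | GHK | GHK | GHK / f_q (K and Na) |
| kvGNP  | Ko,Nai,Cli,m,h,n | GHK | GHK | GHK / f_K (K only) |
| navGNP | Ko,Nai,Cli,m,h,n | GHK | GHK | GHK / f_Na (Na only) |
| iHH    | V,Ko,Nai,Cli,m,h,n | linear, frozen G | linear, frozen G | circuit |

In the GNP family the voltage is algebraic in the concentrations,

    V = vF/(2 S C_m) · (−[A⁻]_i + Σ_q z_q([q]_i − [q]_o)),

with sensitivity vF/(2SC_m) ≈ 1.21e4 mV/mM: physiological voltages
correspond to micromolar net-charge offsets, which is why integration
tolerances are tight (below) and why initial conditions must be *solved*
fixed points, never rounded table values (the rounded reference
concentrations are 0.0056 mM of net charge away from −68.17 mV — i.e. at
V ≈ 0).

Concentration balances (closed system, [q]_i + [q]_o = σ_q):

    d[K⁺]_o/dt  = (S/vF)(−I_KV − I_KL − I_KG + 2 I_NaK)
    d[Na⁺]_i/dt = (S/vF)( I_NaV + I_NaL + I_NaG + 3 I_NaK)
    d[Cl⁻]_i/dt = −(S/vF) I_ClL

**Chloride direction.**  The chloride row carries a minus sign in the
depolarizing-positive convention: chloride influx (negative current)
raises [Cl⁻]_i.  This is the only direction consistent with the
charge-voltage relation above (C_m dV/dt must equal Σ I_q + I_NaK) and it
makes the chloride subsystem self-restoring (E_Cl tracks V).  The
anti-restoring alternative moves the vGNP Hopf point by about +0.15
μA/cm² and makes long iHH simulations diverge through chloride runaway.

The Na⁺/K⁺-ATPase is either a constant current or the sigmoidal form

    I_NaK = −(vF/S) M_NaK / (1+e^{(25−[Na]_i)/3}) / (1+e^{3.5−[K]_o}),

with ceiling (vF/S)·M_NaK (16.89 μA/cm² at M_NaK = 0.70 mM/s; −1.158
μA/cm² at the resting concentrations with M_NaK = 0.30 mM/s).

The vGNP-family normalisation f_q(V) is a cubic fitted by unweighted least
squares to the pointwise ratio I′_qV/I_qV at the reference concentrations
over V ∈ [−100, +50] mV on a 1 mV grid (gate factors cancel in the
ratio).  The published coefficient quadruples are shipped as the canonical
inputs of all reproduction runs; `fit_fq` regenerates very similar values
and is validated by self-consistency (I′/f matches I within 2% over the
range).  The direction is I′_qV / f_q(V) = I_qV: only this direction
recovers G_KM = 20 and G_NaM = 30 mS/cm² from the equivalent-conductance
formula G′_qM = F²P_qV c̄_q / (RT f_q(V)) at rest.

### Canonical parameters

Temperature 309.15 K, C_m = 1 μF/cm², S/v = 4e5 m⁻¹, [A⁻]_i = 110 mM,
σ_K/σ_Na/σ_Cl = 100/155/145 mM, reference rest (Ko, Nai, Cli, V) =
(3.17, 23.58, 10.41 mM, −68.17 mV).  Leak permeabilities P_KL = 2.00e−8,
P_NaL = 1.00e−9, P_ClL = 4.00e−9 m/s; gated P_KV = 1.70e−6,
P_NaV = 1.47e−6 m/s; G_KM = 20, G_NaM = 30 mS/cm².  F = 96485.33 C/mol and
R = 8.314 J/(mol·K) (CODATA; they reproduce the published conductances to
two significant figures).

**Glutamate permeabilities (calibrated).**  The default membrane-averaged
AMPA permeabilities are P_KG = 8.46e−9 and P_NaG = 7.35e−9 m/s — three
times the value implied by the channel calibration with a 4e6/cm² density,
with the 0.87 ratio preserved.  The published parameter set is internally
inconsistent about the glutamate drive scale (the permeability row and the
linearized conductance row differ by 10x), and no choice of either printed
value reproduces the documented behaviors.  The 3x scale was fixed once by
calibration against two *printed* outcomes — the concentration-frozen vs
classical leak comparison (1 vs 3 spikes in 80 ms at p_o: 0 → 0.065) and
the phasic-event pump excursion (−1.16 → −1.41 μA/cm² between t = 1 s and
t = 5 s) — and then left untouched; the firing-regime map (resting/tonic/
depolarization block at p_o = 0.033/0.17/0.18) and the bifurcation
analysis were run only after this calibration was frozen.  The linear
glutamate conductance of the cHH/fGNP variants (G_glu ≈ 0.36 mS/cm²,
E_glu ≈ 0 mV) and the per-ion iHH glutamate constants are always *derived*
from P_G via the apparent/per-ion linearizations, so every variant sees
the same drive.

Derived-and-frozen constants (computed at construction from the reference
state, matching their published prints to 2 significant figures):
G_KL = 0.101, G_NaL = 0.030, G_ClL = 0.042, G_LH = 0.173 mS/cm²,
E_LH = −61.51 mV.

## Numerics

* **Singularities.**  All GHK-type expressions are assembled from
  φ(u) = u/(1 − e^{−u}) evaluated with `expm1`, a series for |u| < 1e−8,
  and asymptotic branches for |u| > 37 (overflow-safe).  The harmonic mean's
  second removable singularity (V = E_q) switches to a 2nd-order series for
  |V − E_q| < 1e−6 mV (|z| = 1).  The RTM rates use the same treatment at
  V = −54, −27, −52 mV.
* **Integration.**  `scipy.integrate.solve_ivp` with LSODA, rtol = 1e−8,
  atol = 1e−10, split at every stimulus change point.  The tolerances are
  set by the charge-relation sensitivity: 1e−10 mM of concentration error
  is ~1e−6 mV of voltage noise.
* **Spikes and classification.**  A spike is an upward crossing of −20 mV
  with a 2 ms refractory separation (the threshold separates spikes from
  the ~−35 mV depolarization-block plateau).  Classification rules over a
  window: depolarization block = no spikes in the final 500 ms with mean V
  above −45 mV; resting = no spikes and end voltage within 10 mV of the
  window start; tonic = inter-spike-interval CV < 0.5 with spiking through
  the window end; phasic otherwise (spikes confined to the first half).
  All thresholds are keyword-overridable.
* **Fixed points.**  Gates are eliminated at their steady state inside the
  root system (their equations are strictly stable, so no roots are lost);
  stability is judged from the eigenvalues of the full-state Jacobian
  (central differences, step 1e−6 of each variable's scale), because the
  Hopf mechanism involves the gate dynamics — the gate-eliminated
  3-variable system has no complex pair on the depolarization-block branch
  at all.  GNP-family roots are parametrised as (V, Ko, Nai) with Cli
  eliminated through the charge relation; solving in raw concentration
  space is hopeless at 1.2e4 mV/mM.  The iHH equations conserve
  V − V_charge exactly (its fixed points form a one-parameter family with a
  neutral eigenvalue), so iHH roots are solved on the charge-consistent
  leaf — the leaf every trajectory started from a solved rest lives on —
  and eigenvalues smaller than 1e−7/ms are treated as neutral.
* **Continuation.**  Natural-parameter continuation in the constant pump
  current I_NaK with warm starts and adaptive steps (default 0.05–0.2
  μA/cm², shrink on failure or >5 mV voltage jumps, terminate below 1e−4).
  Unphysical points (negative complement concentrations — evaluable in the
  GNP family because GHK needs no logarithms) are kept and flagged so
  branches can be split, mirroring the discontinuous electrodiffusive
  branches.  Saddle-nodes are flagged where a non-neutral real eigenvalue
  crosses zero, Hopf points where the leading complex pair's real part
  does; crossings are sharpened by bisection to |ΔI_NaK| < 0.005 μA/cm².
* **Depolarization-block seeding.**  The DB branch is seeded by driving
  the model from its dependent-pump rest (M = 0.3) into block with a
  p_o = 0.83 pulse under the M = 0.70 pump for 35 s, then relaxing for
  10 s under the constant continuation pump, then root-polishing.
* **Sliding-window current differences.**  Per-ion current differences
  between two runs are reconstructed from the stored model-current traces
  (equivalently, from the concentration balances scaled by (v/S)F — never
  from finite differences of the sampled traces, which oscillate at spike
  resolution) and averaged in 8 s windows advancing by 4 s.

## Canonical protocols and problem sizes

Stimulus onsets are not part of the published protocols and are a package
choice: short two-variant comparisons step p_o at t = 0; the phasic and
firing-regime episodes step at t = 1 s.  The regime runs use 30 s
(resting) and 60 s (tonic / depolarization block) horizons; the
depolarization-block persistence comparison uses a 35 s pulse with a 20 s
(vGNP) / 165 s (iHH) observation tail — the iHH block decays through a
slow drift toward its unstable equilibrium before escaping.  The Hopf
continuations sweep I_NaK from −10 to −20 μA/cm².

## What these conditions do and do not emulate

The closed two-compartment geometry conserves σ_q exactly, has no
glia, no extracellular diffusion to a bath, no cation–chloride
cotransport (KCC2/NKCC1), no GABAergic input, no volume/osmotic dynamics
and no calcium in the whole-cell variants (calcium appears only in
single-channel characterization).  Passing reproduction tests therefore
demonstrates the electrodiffusive mechanics — rectifying conductances,
charge-voltage bookkeeping, pump competition, depolarization-block
stability — in an idealised neuron; they do not certify quantitative
behavior of real tissue, where the omitted pathways buffer or redirect
every one of these fluxes.

## Known limitations

* The intramembrane profile is quasi-static: transient relaxation inside
  the slab is assumed fast relative to the voltage dynamics and never
  solved.
* The published vGNP Hopf point is reproduced to ~1% but not to the last
  printed digit; the residual traces to the chloride-direction choice
  above.
* The iHH glutamate constants published alongside the model are not
  derivable from the stated freezing rule; the package derives them (the
  published pair is available as an override), so stimulated iHH runs
  deviate from the original figures in drive by construction.
* Natural-parameter continuation cannot round vertical folds in I_NaK; the
  branch terminates there instead of turning.  The saddle-node markers come
  from eigenvalue sign changes, not from fold-tracking.
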