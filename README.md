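# gnpneuro

Electrodiffusive (Gauss–Nernst–Planck) modelling of ion channels and
single-neuron dynamics, for computational neurophysiologists who want
channel rectification and ion-concentration dynamics in a model that stays
as cheap as a Hodgkin–Huxley simulation.

## The science

Ion flux through a membrane channel is driven by both the voltage and the
concentration gradient.  Treating the intramembrane electric field as
uniform (Gauss's law with bulk electroneutrality), the steady
intramembrane concentration profile is the constant-field profile, and its
**harmonic mean** c̄_q(V) converts a permeability into a conductance
density:

    G_q = z_q² F² P_q c̄_q / (R T),        I_q = −G_q (V − E_q)

where the right-hand product is *identically* the Goldman–Hodgkin–Katz
current.  Rectification is then just the voltage/concentration dependence
of c̄_q: a channel's nonlinearity lives in its baths as much as in its
pore.  On this foundation the package provides

* **Channel characterization** — the exact linearity condition for
  multi-permeant channels, recovery of single-channel permeabilities from
  measured linear-condition slopes (30 pS presets for GABA_A and AMPA),
  per-ion current decomposition, and the two paired
  conductance/reversal descriptions of a channel: the *apparent* form
  (composite permeant, voltage-independent reversal) and the *latent*
  chord-conductance form (any valences, voltage-dependent);
* **Neuron models** — seven variants over one parameter set (classical HH
  `chh`, concentration-frozen `fgnp`, electrodiffusive `gnp`, GHK-gated
  `vgnp`/`kvgnp`/`navgnp`, and the conductance-based-with-concentrations
  `ihh`), with a closed two-compartment ion budget, an algebraic
  charge-voltage relation V = vF/(2SC_m)(−[A⁻]_i + Σ z_q Δ[q]), and a
  Na⁺/K⁺-ATPase pump (constant or sigmoidal in [Na⁺]_i and [K⁺]_o);
* **Simulation and analysis** — stiff integration, spike detection,
  resting/phasic/tonic/depolarization-block classification, and
  sliding-window current-difference analysis between model variants;
* **Bifurcation analysis** — fixed points, continuation over the pump
  current I_NaK, full-state Jacobian eigenvalues, saddle-node and Hopf
  detection for the stability of the depolarization-block state.

See `docs/methods.md` for the model equations, parameter provenance,
numerical choices and limitations.

## Worked example

```python
from gnpneuro import (
    gabaa_channel, apparent_conductance_reversal, single_channel_current,
    ModelDefinition, PumpSpec, find_fixed_point,
)

# single GABAA channel at physiological baths
ch = gabaa_channel()
print({ion.name: round(P, 4) for ion, P in ch.permeants})
# {'Cl': 0.0703, 'HCO3': 0.0141}        single-channel permeabilities, m/s
print(round(apparent_conductance_reversal(ch, -60.0)[1], 2))
# -62.41                                 true zero-current voltage, mV
for v in (-60.0, 0.0, 60.0):
    print(v, round(single_channel_current(ch, v)[1], 3))
# -60.0 -0.017     +0.0 -0.672    +60.0 -1.853   (pA, depolarizing-positive)
```

The tiny current at −60 mV vs the large one at +60 mV (both ~60 mV from
the −62.4 mV reversal) is the channel's outward rectification: chloride's
harmonic-mean concentration, hence its conductance, grows with
depolarization.

```python
# resting state of the electrodiffusive neuron
defn = ModelDefinition(variant="gnp",
                       pump=PumpSpec(mode="concentration_dependent",
                                     M_NaK_mM_per_s=0.3))
fp = find_fixed_point(defn)
print({k: round(fp.state[k], 3) for k in ("V", "Ko", "Nai", "Cli")})
# {'V': -68.174, 'Ko': 3.166, 'Nai': 23.576, 'Cli': 10.413}
```

The rest sits exactly at the chloride Nernst potential (the only way the
chloride balance closes) with the pump at −1.158 μA/cm², and the
micromolar net-charge offset behind −68 mV illustrates why the package
always *solves* for initial states instead of using rounded tables: the
charge relation amplifies concentrations at ~1.2e4 mV per mM.

A CLI wraps the same library:

```sh
gnpneuro characterize --channel gabaa --vmin -80 --vmax 80 --steps 161 --out gabaa_iv.csv
gnpneuro simulate --model gnp --tmax 5000 --out run.csv
gnpneuro bifurcate --model vgnp --inak-min -20 --inak-max -10 --out diagram.csv
gnpneuro fitfq
gnpneuro fixtures
```

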