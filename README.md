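# chromoswitch

Modelling toolkit for **ideal efficacy photoswitches** — photopharmacology
reagents whose *E*/*Z* photoisomers bind a receptor competitively with
similar affinity but opposing intrinsic efficacy, so that the applied light
wavelength (via the photostationary state, PSS) sets the biological effect
*independently of reagent concentration* ("chromocontrol"). The package is
aimed at photopharmacologists and quantitative pharmacologists who want to
reason about, simulate, or fit wavelength-controlled receptor experiments,
such as azobenzene-xanthine modulators of TRPC4/5 cation channels.

## The model

**Photochemistry.** Two-state E⇆Z kinetics under monochromatic light of
photon flux *I*:

    d f_Z/dt = k_EZ (1 − f_Z) − (k_ZE + k_th) f_Z,
    k_EZ = C ε_E(λ) Φ_EZ I,   k_ZE = C ε_Z(λ) Φ_ZE I,

giving the photostationary Z fraction

    φ_λ = k_EZ / (k_EZ + k_ZE + k_th)
        = ε_E Φ_EZ / (ε_E Φ_EZ + ε_Z Φ_ZE)   (bistable switch, k_th = 0),

which is flux-independent for a bistable switch. Illumination protocols are
propagated piecewise-analytically (exact exponential relaxation per
segment).

**Pharmacology.** Gaddum competitive occupancy of the two isomers at total
concentration *c* and Z fraction *f_Z*:

    ρ_Z = (f_Z c / K_Z) / (1 + f_Z c / K_Z + (1 − f_Z) c / K_E),

combined with per-state efficacies and constitutive tone *b* into a
stimulus S = b ρ_free + max(b + e_Z, 0) ρ_Z + max(b + e_E, 0) ρ_E (negative
efficacy = inverse agonism), transduced operationally:

    E* = (τS)^n / ((τS)^n + 1)      (defaults τ = 10, n = 1).

Above a saturation threshold (total occupancy ≥ 0.83, i.e. c ≥ 5 × the
half-saturation concentration) E* depends only on φ_λ — the wavelength acts
as a rheostat while concentration drops out. Two rival action-spectrum
models are built in and compared by AIC:

* efficacy switch: bioactivity ∝ −log10(φ_λ / (1 − φ_λ)) (c-independent),
* affinity switch: bioactivity ∝ −log10(φ_λ · c) (shifts by log10 2 on
  concentration doubling).

## Worked example

```python
import numpy as np
from chromoswitch import *
from chromoswitch.fit import hill_fit
from chromoswitch.simulate import cycle_stats

spectra = make_calibrated_spectra()          # synthetic E/Z spectra, PSS-anchored
phot = default_photophysics()                # Phi_EZ = 0.30, Phi_ZE = 0.45
pharm = get_preset("trpc4_azpico")           # Z agonist / E inverse agonist

for lam in (360, 385, 410, 440):
    print(f"phi({lam} nm) = {compute_pss(spectra, phot, lam):.3f}")

th = independence_threshold(pharm)
print(f"chromocontrol threshold: {th.c_min*1e9:.0f} nM ({th.multiple} x half-saturation)")

phi365 = compute_pss(spectra, phot, 365.0)
fit = hill_fit(dose_response(pharm, phi365, np.geomspace(12e-12, 1.6e-6, 12)))
print(f"365-nm EC50 = {fit.ec50*1e9:.2f} nM (Hill n = {fit.hill_n:.2f})")

trace = make_cycle_trace(spectra, phot, pharm, c_tot=1e-8, n_cycles=36)
st = cycle_stats(trace)
print(f"36 cycles: amplitude CV = {st.amplitude_cv:.1e}, "
      f"fatigue slope = {st.fatigue_slope:.1e} per cycle")

print(classify_switch(pharm).label)
```

prints

```
phi(360 nm) = 0.950
phi(385 nm) = 0.772
phi(410 nm) = 0.180
phi(440 nm) = 0.020
chromocontrol threshold: 130 nM (5 x half-saturation)
365-nm EC50 = 3.01 nM (Hill n = 1.00)
36 cycles: amplitude CV = 2.4e-05, fatigue slope = -6.4e-07 per cycle
ideal_efficacy
```

Read: the calibrated spectra put the switch at 95% Z under 360 nm (strong
agonism), 77% Z under 385 nm (weak agonism) and 2% Z under 440 nm (off);
above ~130 nM the light colour alone sets the response; the TRPC4 preset
reproduces its nanomolar potency; and deterministic 360/440-nm cycling is
fatigue-free over 36 cycles, classifying the reagent as an ideal efficacy
switch.

A command-line surface mirrors the library:

```sh
chromoswitch pss --lambda 360
chromoswitch synth doseresp --seed 1 --out dr.csv
chromoswitch fit hill --in dr.csv
chromoswitch classify --preset trpc4_azpico
```

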