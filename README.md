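# itcdimer

Thermodynamic analysis of **ligand-bridged receptor dimerization**, built for
the case of a small polysulfonated drug binding the histone-fold heterodimer
of a transcription factor. The package covers the three quantitative arms of
such a study: equilibrium speciation, isothermal titration calorimetry (ITC)
model fitting, and STD-NMR epitope mapping — plus a synthetic-data generator
so the entire pipeline is testable without instrument data.

## The model

The core is the *double-dependent binding site* scheme: two sequential
mass-action equilibria,

```
P + L  ⇌  PL       Kd1 = [P][L]/[PL]
PL + P ⇌  P2L      Kd2 = [PL][P]/[P2L]
```

where the ligand L binds one receptor chain P, and the 1:1 complex presents a
surface that recruits a second chain into a 2:1 sandwich. Because every
sandwich consumes a PL complex, the sandwich population is **bell-shaped** in
the ligand:receptor ratio (hook/prozone effect): equimolar ligand promotes
dimerization, a large ligand excess converts every chain to the 1:1 complex
and dissolves the dimer. Mass balance reduces the coupled system to one
monotone scalar equation in [P], solved by bracketed Brent root-finding.

ITC heats follow the perfusion-cell convention: injection *i* dilutes in-cell
totals by (1 − vᵢ/V₀), and

```
qᵢ = V₀·[ΔH1·(Δ[PL] + Δ[P2L]) + ΔH2·Δ[P2L]] + q_dil .
```

Fitting is multistart nonlinear least squares on normalized heats with the
Kd's in log-space and the enthalpies profiled out linearly (variable
projection), compared against a 1:1 single-site null model by AIC.

STD-NMR build-up curves are fitted per proton as
`std(t) = STDmax·(1 − exp(−k_sat·t))`; epitope maps report either the
0.6 s single-time values or the T1-insensitive initial slopes
`STD0 = STDmax·k_sat`, rescaled so the strongest proton is exactly 100%.

## Worked example

```python
import numpy as np
from itcdimer import (BindingParameters, TitrationProtocol,
                      simulate_thermogram, ThermogramFitter,
                      speciation_profile, uM)

truth = BindingParameters(kd1=2.9e-6, kd2=61.5e-6, dh1=-8000, dh2=8000)
proto = TitrationProtocol.vp_itc_default()       # 250 µM into 20 µM, 56 x 8 µL
tg = simulate_thermogram(proto, truth)

fit = ThermogramFitter(scheme="double_dependent").fit(tg)
print(f"Kd1 = {fit.params_.kd1*1e6:.2f} uM, Kd2 = {fit.params_.kd2*1e6:.2f} uM")

prof = speciation_profile(uM(20), [1, 5, 100], truth)
print(prof[["ratio", "dimer_fraction"]].to_string(index=False))
```

prints

```
Kd1 = 2.90 uM, Kd2 = 61.50 uM
 ratio  dimer_fraction
   1.0        0.109629
   5.0        0.020836
 100.0        0.000948
```

A noise-free thermogram returns the generating constants exactly; the
speciation table shows the hook effect — 11% of receptor chains sit in the
sandwich at a 1:1 ratio, and a 100-fold ligand excess suppresses it a
hundred-fold, the pattern a gel-filtration series of the same mixtures shows
as a vanishing dimer peak.

The same workflow is available from the shell:

```sh
itcdimer simulate --seed 1 --out tg.csv        # + tg.csv.truth sidecar
itcdimer fit tg.csv --scheme both
itcdimer speciate --ratios 1,5,100
itcdimer std-epitope std.csv --reference-time 0.6
```

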