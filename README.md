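# tnfkin

Kinetic and equilibrium analysis of TNF-α trimer↔monomer dynamics and
therapeutic-scavenger binding.

Tumor necrosis factor-alpha (TNF-α) signals as a non-covalent homotrimer of
~17.5 kDa monomers; at sub-nanomolar concentrations the trimer decays into
inactive monomers, and anti-TNF-α biologics (Adalimumab, Infliximab,
Golimumab, Certolizumab, Etanercept and their Fab fragments) differ in how
strongly they stabilize the trimer they bind. `tnfkin` is a tested analysis
pipeline for biosensor experiments that probe these processes — trimer
decay traces, association/dissociation concentration series, solution
titrations and multi-scavenger stabilization panels — together with a
seeded synthetic-data generator that emulates the traces, so the whole
chain is testable without instrument data. It is aimed at biophysicists and
assay scientists doing real-time binding-kinetics work.

## Models

- **Trimer decay** (buffer flow): `y(t) = −A·e^(−k·t) + y0`, first-order
  rate *k* (free trimer: *k* ≈ 1.7 × 10⁻³ s⁻¹, half-life ≈ 7 min).
- **1:1 binding kinetics**: dissociation `y = A·e^(−k_off·t) + y0` fitted
  globally (one shared *k_off* per series); association
  `y = −A·e^(−(c·k_on + k_off)·t) + y0` with the observed rate
  k_obs = c·k_on + k_off and k_off fixed from the dissociation fit;
  K_D = k_off / k_on.
- **Biphasic dissociation** from partially saturated surfaces:
  `y = −A_fast·e^(−k_fast·t) − A_slow·e^(−k_slow·t) + y0`, shared rates,
  per-curve amplitudes — the fast phase is unprotected-trimer decay, the
  slow phase scavenger release.
- **Depletion-corrected solution isotherm** for picomolar affinities, where
  receptor and ligand totals are comparable to K_D:
  `b = ((R_T+L_T+K_D) − √((R_T+L_T+K_D)² − 4·R_T·L_T)) / (2·R_T)` and the
  readout is the free-receptor fraction `y = y0 + A·(1 − b)`.
- **Size interpretation**: switching-speed (dynamic response,
  DR = ∫ F_norm dt) → hydrodynamic diameter via a user calibration, and a
  linear trimer-fraction scale between the measured end states
  (trimer 5.6 nm, monomer 3.9 nm).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a four-concentration (1/2/4/8 nM) association–dissociation series
at the Fab-analyte reference rates with 1 % noise, and fit it globally:

```python
import numpy as np
from tnfkin import synthdata as sd
from tnfkin.fitting import (global_fit_dissociation, global_fit_association,
                            kinetics_report, fit_titration)
from tnfkin.io import kinetics_display_units
from tnfkin.models import Phase

traces = sd.gen_kinetic_series(
    [1e-9, 2e-9, 4e-9, 8e-9], k_on=2.82e6, k_off=8.52e-5,
    noise=sd.NoiseModel(sigma=0.01, seed=1),
)
dissoc = [t for t in traces if t.phase is Phase.DISSOCIATION]
assoc = [t for t in traces if t.phase is Phase.ASSOCIATION]
d = global_fit_dissociation(dissoc)
a = global_fit_association(assoc, d.k_off)
du = kinetics_display_units(kinetics_report(a, d))
print(f"k_on  = {du['k_on_1e6_per_M_s']:.2f} x 1e6 /M/s")
print(f"k_off = {du['k_off_1e-5_per_s']:.2f} x 1e-5 /s")
print(f"K_D   = {du['kd_pM']:.1f} pM")

tab = sd.gen_titration(100e-12, 53.6e-12, np.geomspace(7e-12, 15e-9, 12),
                       noise=sd.NoiseModel(0.01, 1))
print(fit_titration(tab, rt=100e-12, seed=1))
```

prints

```
k_on  = 2.82 x 1e6 /M/s
k_off = 8.51 x 1e-5 /s
K_D   = 30.2 pM
K_D = 52.9 pM [49.3, 56.8]
```

The global fit returns the generating rate constants (k_on in 10⁶ M⁻¹s⁻¹,
k_off in 10⁻⁵ s⁻¹) and the derived affinity K_D = k_off/k_on in pM; the
solution titration at a fixed 100 pM receptor concentration recovers the
generating 53.6 pM affinity within its 95 % bootstrap confidence interval.

The same workflows are available from the shell:

```sh
tnfkin simulate --kind panel --out panel.csv
tnfkin panel panel.csv --out panel_report.json
```

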