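# osteotwin

Agent-based micro-multiphysics simulation of trabecular bone remodeling
under anti-RANKL antibody (denosumab) therapy.

Postmenopausal osteoporosis degrades trabecular bone as falling estrogen
tilts the balance between bone-resorbing osteoclasts and bone-forming
osteoblasts. Denosumab, dosed 60 mg every six months, sequesters RANKL —
the cytokine osteoclasts need to form and survive — and suppresses
resorption. `osteotwin` models this at the cell scale: individual
osteocytes, osteoblasts, osteoclasts, precursors and stem cells live on a
voxel lattice (14 µm), sense their mechanical environment through
micro-finite-element strain energy density S(x), exchange signals through
a RANK–RANKL–OPG reaction–diffusion system extended with the antibody
(RANKL + mAb ⇌ complex, with bolus–decay pharmacokinetics: instantaneous
rise to the interpolated 8000 ng/ml marrow peak, 26-day elimination
half-life), and resorb or deposit tissue that mineralizes over time. A
virtual-trial driver runs each structure as a pair of "digital clones" —
identical baselines, one arm treated, one not — and reads out 3D
histomorphometry (BV/TV, Tb.Th, MS/BS, ES/BS, Oc.N/BS, tissue mineral
content) monthly, with paired t / Bonferroni statistics across the cohort.

The package is aimed at researchers exploring in-silico trial design and
the cell-level mechanisms behind antiresorptive pharmacodynamics. Since no
reference micro-CT images are distributed, a generator synthesizes
trabecular networks with controllable bone volume fraction (spanning the
6.6–17.1 % range of a postmenopausal biopsy cohort), and a combinatorial
selection tool picks biopsy subsets from a database to match target cohort
statistics by minimizing
`Error = Σ_i w_i |set_point_i − value_i| / set_point_i`.

## Worked example

```python
import numpy as np
from osteotwin import (
    StructureSpec, generate_trabecular, compute_bv_tv,
    dose_per_body_weight, peak_concentration_from_dose,
    Schedule, TrialConfig, run_trial,
)

dose, _ = dose_per_body_weight(60.0, 67.0)
peak = peak_concentration_from_dose(dose)
print(f"dose {dose} mg/kg -> marrow peak {peak:.0f} ng/ml")

grid = generate_trabecular(StructureSpec(shape=(32, 32, 32),
                                         target_bv_tv=0.131, seed=7))
print(f"baseline BV/TV {compute_bv_tv(grid):.3f}")

record = run_trial([grid], Schedule(duration=365.0), master_seed=1,
                   config=TrialConfig(relax_steps=3))
arm = record.arms[0]
t, c = arm["treatment"], arm["control"]
print(f"year-1 BV/TV: treatment {t.final_bv_tv:.4f}, control {c.final_bv_tv:.4f}")
print(f"mean osteoclasts: treatment {t.series.n_osteoclast.mean():.1f}, "
      f"control {c.series.n_osteoclast.mean():.1f}")
```

Output:

```
dose 0.9 mg/kg -> marrow peak 8000 ng/ml
baseline BV/TV 0.131
year-1 BV/TV: treatment 0.1319, control 0.1280
mean osteoclasts: treatment 0.3, control 1.8
```

The 60 mg dose at the reference 67.0 kg body weight normalizes to
0.9 mg/kg, which interpolates between measured marrow peaks to
8000 ng/ml. From an identical 13.1 % BV/TV baseline, one simulated year
of dosing suppresses the osteoclast population (0.3 vs 1.8 on average at
this desk scale) and leaves the treated clone gaining bone while its
untreated twin loses it — the divergence that accumulates over a full
10-year schedule (1000 cell steps, 200 mechanics solves, 20 injections).
Both arms are bitwise reproducible from the master seed.

The same workflow is available from the shell:

```bash
osteotwin generate --out cohort/ --n 7 --size 64 --seed 1
osteotwin trial --cohort cohort/cohort.csv --out results/ --seed 1
osteotwin select --db biopsies.csv --k 7 --out shortlist.csv
```

See `docs/methods.md` for the model description, parameter defaults and
their provenance, numerical choices, and known limitations.

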