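# Methods

`osteotwin` is an agent-based, micro-multiphysics model of trabecular bone
remodeling under anti-RANKL antibody (denosumab) therapy. It couples four
layers on a single isotropic voxel lattice (nominally 14 µm): tissue state,
linear-elastic micro-finite-element (micro-FE) mechanics, reaction–diffusion
signaling, and stochastic cell agents. A multiscale scheduler advances the
layers on their own time scales and a virtual-trial driver runs matched
treatment/control pairs from byte-identical initial states ("digital
clones").

## Tissue lattice and morphometry

Each voxel is marrow, osteoid, or mineralized bone and carries a mineral
fraction `m ∈ [0, 1]` of a configurable maximum density (default
1200 mg HA/cm³). Tissue mineral content (TMC) is `Σ m·ρ_max·v_voxel`,
discounted by partial resorption. Surfaces are detected by 6-connectivity
face adjacency to marrow, with area estimated as exposed faces × voxel
area; cut faces at the domain boundary are not counted as remodeling
surface (biopsy-core convention). Trabecular thickness (Tb.Th) uses
largest-inscribed-sphere fitting on the Euclidean distance transform: each
bone voxel's local thickness is the diameter of the largest sphere
containing it that fits in the bone phase, and Tb.Th is the mean over bone
voxels. The distance map is computed with the inscribed radius taken as
`EDT − 0.5` voxels, which makes an n-voxel plate measure exactly n voxels
thick; discrete rim effects bias cylinders low by a sub-voxel band, which
vanishes as the radius grows.

Dynamic indices use a trailing window of 30.4 days (365/12, matching
monthly sampling): MS/BS is the fraction of current surface voxels with at
least one formation event in the window, ES/BS the same for erosion
events, and Oc.N/BS the osteoclast agent count divided by total surface
area — a 3D analogue of the clinical per-perimeter nuclei count. The
mapping between 3D agent counts and 2D histological nuclei counts is not
one-to-one; these indices are internally consistent across arms and
times, not calibrated to 2D histology units.

## Synthetic trabecular structures

No reference micro-CT images ship with the package; structures are
synthesized by thresholding a periodic Gaussian random field smoothed with
`σ = correlation_length / 2` (default correlation length 0.17 mm, which
yields strut widths of a few voxels at 14 µm). The threshold is bisected
on the raw bone fraction, the largest 26-connected component kept, and the
component grown by field-ordered boundary accretion until the bone volume
fraction (BV/TV) matches the target to within ±0.5 percentage points
(in practice to one voxel). Cohorts span BV/TV 6.6–17.1 % evenly — the
range of the postmenopausal biopsy cohort the trial emulates — with donor
ages drawn from N(72, 5.2²) years. Per-structure seeds are spawned from
the master seed with counter-based `SeedSequence` keys, so regeneration is
bitwise reproducible and extending a cohort never reshuffles existing
members.

These structures reproduce the volume fraction, connectivity, and strut
scale of trabecular bone but not its fabric anisotropy, plate/rod mixture
or cortical shell; trial results on them demonstrate mechanism and
direction, not patient-specific magnitudes.

## Micro-FE mechanics

Every bone/osteoid voxel is a trilinear hexahedral element with modulus
`E = E₀·m²` (E₀ = 10 GPa; the density exponent is configurable — the
power-law form is the standard constitutive choice, and no published value
pins the exponent for this model) and Poisson ratio 0.3. Seven canonical load cases
are applied as affine Dirichlet displacements on all domain-boundary
nodes: compression along each axis with lateral expansion `ν·ε` (so a
homogeneous solid reproduces the uniaxial stress state, SED = ½Eε²),
three symmetric shears, and volumetric compression. The system is solved
matrix-free with Jacobi-preconditioned conjugate gradients (numba element
loops); the affine field itself serves as the cold-start guess and
previous solutions as warm starts during a run. Strain energy density is
evaluated from the centroid strain of each element. Floating bone
fragments that do not reach the boundary carry no load and are excluded
with zero SED.

**Load estimation.** The scale factors of the seven unit cases are chosen
to minimize the coefficient of variation of the combined SED over bone at
a fixed physiological mean (default 0.02 MPa; only the qualitative notion
of a physiological mean is established, so the value is configurable). The combined SED per element is an exact quadratic
form in the scale vector built from superposed centroid strains. Because
the three compressions sum to 0.4× the volumetric case, the scale vector
is optimized in the orthogonal complement of that exact null space; the
quartic objective is minimized with a trust-region Newton method (exact
gradient and Hessian) under the mean constraint, restarted from every
sign pattern of the uniform start vector (the landscape is multimodal in
the shear signs), and the result rescaled so the mean SED hits the target
exactly. Whether the homogeneity objective should act on strain magnitude or on
SED is an open modeling choice; SED is used here.

**Homeostatic relaxation.** Before seeding cells, the structure is adapted
to its estimated load at constant mass: each step pairs the highest-SED
surface voxels (bone accreted on a marrow face-neighbor) with an equal
number of lowest-SED surface voxels (removed), so the bone voxel count is
conserved exactly. Pairs are only exchanged while the high candidate
exceeds the low candidate by a 10 % relative margin, which leaves
already-adapted structures (e.g. a plate under axial load) untouched. The
add/remove thresholds are re-derived from the current SED distribution at
every step; the threshold values of the original adaptation algorithm are
not publicly available and are treated as free.

Boundary conditions are displacement-controlled throughout a run (the
scale factors are estimated once at baseline). A consequence is that
global stiffening under treatment raises rather than lowers element SED,
so the stress-shielding feedback on RANKL production is muted compared
with a load-controlled model; the treatment effect in this model is
carried by the pharmacology, which is the dominant mechanism on the
3–10-year horizon.

## Signaling and pharmacokinetics

Marrow voxels carry RANKL, OPG, sclerostin, denosumab and the RANKL–OPG
and RANKL–denosumab complexes in nM; estrogen is a global scalar in pg/ml
(a systemic hormone, not a local field). Denosumab I/O uses ng/ml with a
147 kDa molar mass (IgG2).

**Dosing.** The marrow peak after a 60 mg injection is interpolated
between measured peaks at 0.3 mg/kg (2000 ng/ml) and 1.0 mg/kg
(9000 ng/ml) using the dose rounded to one decimal: 60 mg / 67.0 kg →
0.9 mg/kg → 8000 ng/ml. Each injection *sets* the marrow field to the
peak (the residual from the previous dose, ~62 ng/ml after six months, is
negligible); free denosumab and its RANKL complex then decay with a
26-day half-life. This is a phase-2-only model: subcutaneous absorption
(phase 1) and the fast target-mediated elimination below ~1000 ng/ml
(phase 3) are deliberately out of scope, so the simulated profile is
closest to an intravenous bolus. (Target-mediated consumption of
denosumab by accumulating RANKL does emerge from the mass balance late in
each interval.)

**Binding kinetics and units.** The published rate pair for
RANKL–denosumab is reported as 0.047 M⁻¹s⁻¹ / 0.0005 s⁻¹. Taken literally
this gives K_D ≈ 0.011 M — about nine orders of magnitude weaker than the
antibody's measured picomolar affinity, and weak enough that an 8000 ng/ml
bolus (≈54 nM) would bind essentially no RANKL over a dosing interval,
leaving the drug inert in the model. Read as nM⁻¹s⁻¹ the same numerals
give K_D ≈ 10.6 pM, consistent with the measured affinity and with the
osteoclast suppression the therapy produces. The defaults therefore use
the per-nM reading; both rates are configurable if a different unit
convention is wanted. OPG–RANKL uses weaker decoy kinetics (K_D 10 nM,
configurable; no published value at this model's granularity).

Each binding update advances one reaction pair with the exact closed-form
solution of the mass-action Riccati ODE under the within-step conservation
laws, so it is unconditionally stable, strictly positive, and conserves
total RANKL to machine precision; the two pairs sharing free RANKL are
composed by Strang splitting (denosumab half-step, OPG step, denosumab
half-step).

**Diffusion.** All species diffuse at 1×10⁻¹⁰ m²/s (typical marrow
protein) with zero-flux boundaries at bone and the domain surface. At the
20-minute reaction–diffusion substep the Fourier number is ≈600, far past
the explicit stability limit and deep in the well-mixed regime: the
backward-Euler solution is within O(1/Fo) of the per-component mean. The
integrator therefore uses three regimes — explicit FTCS when stable,
backward-Euler CG at intermediate Fourier numbers, and the exact
infinite-diffusivity limit (mass-conserving per-component averaging) above
Fo = 50. In a trial run the whole 4-hour window is integrated on
per-component scalar concentrations, which is numerically identical to
the per-voxel path in this regime (diffusion is applied before binding in
each substep) and removes the dominant cost.

**Production and clearance.** Osteocytes deposit RANKL and sclerostin
into their nearest marrow voxel in proportion to the unloading stimulus
`max(0, 1 − SED/setpoint)`; osteoblasts deposit OPG. Free RANKL, OPG and
sclerostin clear at 2/day; the RANKL–OPG complex at 0.3/day. Because
clearance is fast on the 3.65-day cell step (λ·dt ≈ 7), production and
clearance are integrated with the exact closed form
`C·e^(−λdt) + (P/λ)(1 − e^(−λdt))` rather than sequential splitting.

**Estrogen.** Declines linearly from 40 pg/ml at baseline to 25 pg/ml at
ten years, constant afterwards ("continuous decay" is read as the simplest
curve through both reported endpoints; an exponential reading would differ
by <1 pg/ml mid-trajectory). Receptor occupancy is the equilibrium
`E/(E + K_d)` with K_d = 32 pg/ml, chosen (no published value) so the
bound-majority/unbound-majority switch flips inside the 40→25 pg/ml
trajectory, at about year 5.3.

## Cell agents

Seven types: osteocytes (in bone), osteoblasts, osteoclasts, osteoclast
precursors and lining cells (one per surface voxel, never co-located),
and MSCs/HSCs (marrow, random-walking one voxel per cell step).

**Seeding.** Osteocytes: Bernoulli per bone voxel at 4800/mm³. Stem
cells: 8000/mm³ combined with equal MSC/HSC probability (the reported
density is read as the combined pool; a per-type reading would double
it). Initial osteoblast/osteoclast counts come from surface-density
targets Ob.N/BS = 2.0 and Oc.N/BS = 0.5 cells/mm² (placeholders — the
reference cohort's values are not published). Half of each population is
placed deterministically at local SED extrema: counting 26-neighborhood
*surface* voxels with strictly lower (N_lo) and strictly higher (N_hi)
SED, osteoblasts go where N_lo ≥ 1.5·N_hi (local maxima) and osteoclasts
where N_hi ≥ 1.5·N_lo, ties counting in neither, ratios rewritten as
products to avoid division by zero. The inequality for osteoblasts as
originally reported points the other way, contradicting the prose
("osteoblasts were seeded at high SED locations") and the accompanying
figure; the prose/figure direction is the default and the as-reported
form is available via `SeedingParams(literal_inequalities=True)`. The
other half seeds uniformly on free surface; precursors take 10 % of the
remainder; lining cells cover the rest.

**Apoptosis.** Per-step death probability `1 − (1 − r)^dt`. Osteoblasts:
0.1 %/day, fourfold when unbound receptors dominate (occupancy ≤ 0.5);
osteocytes the same rule at 0.01 %/day; osteoclasts the mirror image
(fourfold when bound dominate) at a 2 %/day base. The fourfold factor and
the osteoblast base rate are published; the other bases are calibration.

**Differentiation.** MSCs adjacent to quiescent (lining-covered) surface
become osteoblasts at `2×10⁻² /day × occupancy / (1 + sclerostin/1 nM)` —
estrogen promotes, sclerostin damps (the TGF-β intermediate is folded
into the estrogen scaling; no kinetics are published for it). Precursors
activate to osteoclasts at 3×10⁻³/day while local free RANKL exceeds
0.03 nM; osteoclasts starved below that threshold for more than 2 days
revert to precursors. RANK receptor density is not published, hence the
free-RANKL threshold stand-in.

**Remodeling.** Osteoclasts erode their voxel at 0.4 voxel-fractions/day
(≈1.1×10⁻⁶ mm³/day, the scale of a resorption pit over weeks); a fully
eroded voxel becomes marrow and the osteoclast steps to a neighboring
surface voxel. Osteoblasts deposit osteoid into an adjacent marrow voxel
at 0.3 voxel-fractions/day; a filled voxel becomes osteoid at zero
mineral. All osteoid/bone mineral relaxes toward full mineralization with
τ = 365 days, so fresh osteoid follows `ρ_max(1 − e^(−Δt/τ))` — this
produces the concave ("logarithmic-like") early TMC rise — and osteoid is
relabeled bone at 45 % mineral. Osteoblasts enclosed on all six faces
become osteocytes. Lining cells are re-derived each step to cover exactly
the free surface.

**Calibration.** The production, clearance, threshold, differentiation
and remodeling-rate constants above are not published; they were
calibrated as a set so that (i) an untreated structure holds roughly
stable osteoblast (~3–5) and osteoclast (~5–8) populations with free
RANKL about twice the activation threshold, (ii) the untreated arm loses
bone slowly (≈1 %/year relative) as estrogen declines, and (iii) under
dosing, free RANKL is suppressed for most of each interval and recovers
above threshold in its final weeks as the antibody decays — reproducing
the post-injection osteoclast crash and late-interval recovery. The SED
setpoint (0.04 MPa, 2× the physiological mean) leaves osteocytes at
roughly half-maximal signaling reserve at mechanical homeostasis.

## Scheduler and virtual trial

Cell behavior advances in 3.65-day steps; reaction–diffusion runs as
twelve 20-minute substeps spanning a 4-hour window each cell step (the
molecular system equilibrates much faster than cells act; antibody decay
and production/clearance are integrated over the full cell step so the
PK half-life is exact); mechanics re-solve every fifth cell step
(5 × 3.65 = 18.25 days — the step-count reading of the stated "18-day
interval"); morphometry samples monthly (30.4 days) starting at t = 0. A
10-year run is exactly 1000 cell steps, 200 mechanics solves and 20
injections (first dose at baseline). Within a cell step the order is:
injection (if due) → production/clearance → RD window → antibody decay →
differentiation → apoptosis → remodeling → motility → lining
maintenance → mechanics (every fifth step).

The trial driver prepares each biopsy once (load estimation, 10
relaxation steps, cell seeding) and runs both arms from deep copies of
that state; per-biopsy and per-arm RNG streams are split from the master
seed with counter-based keys, so records are bitwise reproducible and
the baseline rows of the two arms are identical. Between-arm statistics
use a two-sided paired t test with Bonferroni correction (`p_adj =
min(1, m·p)`); zero-variance zero-mean differences return p = 1 by
convention. A resorption-rate proxy (daily eroded volume as percent
change from the pre-treatment mean) is exported in place of serum CTX-1,
which is biochemistry outside this model. Monthly morphometry plus the
per-cell-step series are both recorded; end-of-interval (pre-injection)
states can be read directly off the series.

## Cohort selection

Selecting k = 7 of 25 database biopsies scores all C(25,7) = 480,700
combinations with `Error = Σ w_i·|set_point_i − value_i|/set_point_i`
over mean BV/TV (13.1 %, w = 10), mean age (72 y, w = 10), SD age
(5.2 y, w = 1) and SD BV/TV (4.1 %, w = 2), plus a uniformity term with
w = 2 and no set point: it is implemented as the coefficient of variation
of sorted consecutive BV/TV increments (zero for perfectly even spacing),
entering unnormalized since a CV is already dimensionless — the only
reading that gives the published weight meaning without a set point.
Sample SDs use n − 1 (a convention choice). The 50 lowest-error
combinations are shortlisted and the member with mean BV/TV closest to
the set point wins; ties break lexicographically by id. Baseline
back-casting fits an ordinary least-squares line to follow-up
measurements and evaluates it at year 0.

## Problem sizes and limitations

Default demonstration scale is a 64³ grid (0.9 mm cube) at 14 µm voxels;
the test suite exercises the full pipeline on three 64³ clones over three
years and component physics on 24³–32³ grids. At this scale a biopsy
carries ~450 osteocytes and single-digit osteoblast/osteoclast counts, so
per-arm cell-count curves are noisy; directional comparisons pool clones.
Known limitations: displacement-controlled mechanics mute stress
shielding; no treatment-withdrawal scenarios; no 2D histology emulation
or resampling below the native voxel size; sclerostin is carried but no
anti-sclerostin intervention is modeled; marrow cells beyond MSC/HSC are
absent; the synthetic structures lack anatomical fabric. The model's
quantitative outputs reflect its calibration, not an independent
validation data set.
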