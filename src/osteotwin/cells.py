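"""Cell agents: seeding, estrogen-modulated apoptosis, mechanotransduction,
differentiation, resorption, formation and mineralization.

Seven agent types live on the voxel lattice.  Osteocytes sit inside the
bone matrix and translate their local strain energy density into RANKL and
sclerostin production (more signal where loading is reduced).  Osteoblasts,
osteoclasts, osteoclast precursors and lining cells occupy bone-surface
voxels (one cell per voxel — colocalization is not allowed); mesenchymal
and hematopoietic stem cells drift through the marrow.

Estrogen acts through equilibrium receptor occupancy E/(E + Kd): when
unbound receptors outnumber bound ones the apoptosis hazard of osteoblasts
and osteocytes rises fourfold, while osteoclasts show the opposite
response — the cellular basis of postmenopausal bone loss in the model.
Osteoclast formation requires free RANKL above an activation threshold, so
denosumab's RANKL sequestration shuts down precursor activation and
starves existing osteoclasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import (
    BONE,
    EV_ACTIVATE,
    EV_APOPTOSIS,
    EV_ERODE,
    EV_FORM,
    EV_MINERALIZE,
    MARROW,
    OSTEOID,
    EventLog,
    VoxelGrid,
    surface_mask,
)

# agent type codes
OSTEOCYTE = 0
OSTEOBLAST = 1
OSTEOCLAST = 2
OC_PRECURSOR = 3
LINING = 4
MSC = 5
HSC = 6

TYPE_NAMES = {
    OSTEOCYTE: "osteocyte",
    OSTEOBLAST: "osteoblast",
    OSTEOCLAST: "osteoclast",
    OC_PRECURSOR: "oc_precursor",
    LINING: "lining",
    MSC: "msc",
    HSC: "hsc",
}

SURFACE_TYPES = (OSTEOBLAST, OSTEOCLAST, OC_PRECURSOR, LINING)

_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)

_NEIGH26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

@dataclass
class SeedingParams:
    """Initial cell placement densities and criteria.

    ``stem_density`` is the combined MSC+HSC marrow density; each type is
    seeded with equal probability.  Half of the initial osteoblasts and
    osteoclasts (``deterministic_fraction``) are placed by the local-SED
    neighborhood criterion with threshold ``t_seed_ob``/``t_seed_oc``, the
    rest stochastically.  ``ob_n_bs``/``oc_n_bs`` set the initial surface
    densities (not publicly reported for the reference cohort; placeholders).
    """

    stem_density: float = 8000.0  # cells/mm^3, MSC + HSC combined
    osteocyte_density: float = 4800.0  # cells/mm^3 of bone
    t_seed_ob: float = 1.5
    t_seed_oc: float = 1.5
    ob_n_bs: float = 2.0  # cells/mm^2 bone surface
    oc_n_bs: float = 0.5
    deterministic_fraction: float = 0.5
    precursor_fraction: float = 0.1  # of surface left after OB/OC seeding
    literal_inequalities: bool = False  # as-reported inequality direction; see methods note


@dataclass
class RateParams:
    """Cell process rates.

    The apoptosis rates and the fourfold estrogen modulation are measured
    quantities; the production, clearance-coupled and remodeling rates are
    calibration constants chosen so an untreated structure holds its
    baseline cell populations and loses bone slowly as estrogen declines
    (see the methods note).
    """

    ob_apoptosis_per_day: float = 0.001  # 0.1 %/day
    ocy_apoptosis_per_day: float = 1e-4
    oc_apoptosis_per_day: float = 0.02
    apoptosis_fold: float = 4.0
    resorption_rate: float = 0.4  # voxel fraction/day per osteoclast
    osteoid_rate: float = 0.3  # voxel fraction/day per osteoblast
    mineralization_tau: float = 365.0  # days
    osteoid_to_bone_mineral: float = 0.45  # label switch threshold
    rankl_activation_threshold: float = 0.03  # nM free RANKL
    oc_starvation_persistence: float = 2.0  # days below threshold before revert
    precursor_activation_per_day: float = 3e-3
    msc_differentiation_per_day: float = 2e-2
    sed_setpoint: float = 0.04  # MPa, ~2x the physiological mean SED
    estrogen_kd: float = 32.0  # pg/ml
    # production in nM * mm^3 / day per cell, deposited into marrow
    rankl_production_per_osteocyte: float = 6e-4
    scl_production_per_osteocyte: float = 1e-4
    opg_production_per_osteoblast: float = 1e-4
    scl_halfmax: float = 1.0  # nM, sclerostin inhibition of MSC->OB

    def __post_init__(self) -> None:
        if self.apoptosis_fold < 1:
            raise ValueError("apoptosis fold must be >= 1")
        for name in ("ob_apoptosis_per_day", "oc_apoptosis_per_day",
                     "resorption_rate", "osteoid_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ----------------------------------------------------------------------
# Population container
# ----------------------------------------------------------------------

@dataclass
class CellPopulation:
    """Struct-of-arrays agent container."""

    types: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.int64)
    )
    bound_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    age: np.ndarray = field(default_factory=lambda: np.zeros(0))
    starved: np.ndarray = field(default_factory=lambda: np.zeros(0))  # days, OC only

    def __len__(self) -> int:
        return len(self.types)

    def count(self, cell_type: int) -> int:
        return int(np.count_nonzero(self.types == cell_type))

    def positions_of(self, cell_type: int) -> np.ndarray:
        return self.positions[self.types == cell_type]

    def add(self, cell_type: int, positions: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64).reshape(-1, 3)
        n = len(positions)
        self.types = np.concatenate([self.types, np.full(n, cell_type, np.int8)])
        self.positions = np.concatenate([self.positions, positions])
        self.bound_fraction = np.concatenate([self.bound_fraction, np.zeros(n)])
        self.age = np.concatenate([self.age, np.zeros(n)])
        self.starved = np.concatenate([self.starved, np.zeros(n)])

    def remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        self.types = self.types[keep]
        self.positions = self.positions[keep]
        self.bound_fraction = self.bound_fraction[keep]
        self.age = self.age[keep]
        self.starved = self.starved[keep]

    def merged_with(self, other: "CellPopulation") -> "CellPopulation":
        pop = CellPopulation()
        pop.types = np.concatenate([self.types, other.types])
        pop.positions = np.concatenate([self.positions, other.positions])
        pop.bound_fraction = np.concatenate(
            [self.bound_fraction, other.bound_fraction]
        )
        pop.age = np.concatenate([self.age, other.age])
        pop.starved = np.concatenate([self.starved, other.starved])
        return pop

    def validate_positions(self, grid: VoxelGrid) -> None:
        """Assert the tissue-type position invariants."""
        tissue = grid.tissue[tuple(self.positions.T)] if len(self) else np.zeros(0)
        surf = surface_mask(grid)
        for t in (MSC, HSC):
            m = self.types == t
            if np.any(tissue[m] != MARROW):
                raise ValueError(f"{TYPE_NAMES[t]} off marrow")
        m = self.types == OSTEOCYTE
        if np.any(tissue[m] == MARROW):
            raise ValueError("osteocyte off bone")
        for t in SURFACE_TYPES:
            m = self.types == t
            if len(self.positions[m]) and not surf[tuple(self.positions[m].T)].all():
                raise ValueError(f"{TYPE_NAMES[t]} off surface")
        # no two surface cells co-located
        surf_cells = np.isin(self.types, SURFACE_TYPES)
        if surf_cells.any():
            lin = np.ravel_multi_index(tuple(self.positions[surf_cells].T), grid.shape)
            if len(np.unique(lin)) != len(lin):
                raise ValueError("co-located surface cells")

    def to_frame(self, time: float = 0.0):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_days": time,
                "type": [TYPE_NAMES[t] for t in self.types],
                "z": self.positions[:, 0],
                "y": self.positions[:, 1],
                "x": self.positions[:, 2],
            }
        )


# ----------------------------------------------------------------------
# Seeding
# ----------------------------------------------------------------------

def seed_osteocytes(
    grid: VoxelGrid, density: float, rng: np.random.Generator
) -> CellPopulation:
    """Bernoulli seeding of osteocytes in bone voxels at ``density``/mm^3."""
    if density < 0:
        raise ValueError("density must be non-negative")
    p = density * grid.voxel_volume
    if p > 1:
        raise ValueError(
            f"density {density}/mm^3 exceeds one cell per voxel "
            f"({1 / grid.voxel_volume:.0f}/mm^3)"
        )
    pop = CellPopulation()
    if p == 0:
        return pop
    coords = np.argwhere(grid.bone_mask)
    hit = rng.random(len(coords)) < p
    pop.add(OSTEOCYTE, coords[hit])
    return pop


def seed_marrow_cells(
    grid: VoxelGrid, stem_density: float, rng: np.random.Generator
) -> CellPopulation:
    """Uniform MSC + HSC seeding at combined ``stem_density``/mm^3.

    MSC and HSC seeding probabilities are identical, so the expected
    MSC:HSC ratio is 1.
    """
    if stem_density < 0:
        raise ValueError("density must be non-negative")
    p = stem_density * grid.voxel_volume
    if p > 1:
        raise ValueError("stem density exceeds one cell per voxel")
    pop = CellPopulation()
    if p == 0:
        return pop
    coords = np.argwhere(grid.marrow_mask)
    hit = rng.random(len(coords)) < p
    chosen = coords[hit]
    is_msc = rng.random(len(chosen)) < 0.5
    pop.add(MSC, chosen[is_msc])
    pop.add(HSC, chosen[~is_msc])
    return pop


def _neighbor_sed_counts(
    surf_coords: np.ndarray, sed: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """For each surface voxel: counts of 26-neighborhood *surface* voxels
    with strictly lower / strictly higher SED.  Ties count in neither."""
    surf_lin = np.ravel_multi_index(tuple(surf_coords.T), shape)
    is_surf = np.zeros(int(np.prod(shape)), dtype=bool)
    is_surf[surf_lin] = True
    vals = sed[tuple(surf_coords.T)]
    val_of = np.zeros(int(np.prod(shape)))
    val_of[surf_lin] = vals
    n_lo = np.zeros(len(surf_coords), dtype=np.int64)
    n_hi = np.zeros(len(surf_coords), dtype=np.int64)
    for off in _NEIGH26:
        nb = surf_coords + off
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        lin = np.ravel_multi_index(tuple(nb[ok].T), shape)
        valid = is_surf[lin]
        idx = np.flatnonzero(ok)[valid]
        nb_vals = val_of[lin[valid]]
        n_lo[idx] += nb_vals < vals[idx]
        n_hi[idx] += nb_vals > vals[idx]
    return n_lo, n_hi


def seed_surface_cells(
    grid: VoxelGrid,
    sed_field: np.ndarray,
    params: SeedingParams,
    rng: np.random.Generator,
) -> CellPopulation:
    """Seed osteoblasts, osteoclasts, precursors and lining cells on the surface.

    Deterministic halves go to local SED extrema: osteoblasts where
    strictly-lower-SED surface neighbors dominate (``n_lo >= t * n_hi``,
    high-strain sites) and osteoclasts at the mirrored low-strain sites —
    the modeling component.  Stochastic halves are uniform over free
    surface — the remodeling component.  Precursors fill a fraction of the
    remainder; lining cells cover the rest.  One cell per surface voxel.
    """
    from .grid import extract_surface

    surf = extract_surface(grid)
    coords = surf.voxels
    n_surf = len(coords)
    area = surf.total_area
    n_ob = int(round(params.ob_n_bs * area))
    n_oc = int(round(params.oc_n_bs * area))
    if n_ob + n_oc > n_surf:
        raise ValueError("requested osteoblast+osteoclast counts exceed surface")

    vals = sed_field[tuple(coords.T)]
    n_lo, n_hi = _neighbor_sed_counts(coords, sed_field, grid.shape)
    if params.literal_inequalities:
        # the inequality direction as originally reported: ratio n_lo/n_hi
        # below threshold for osteoblasts, above for osteoclasts (product form)
        ob_eligible = (n_lo < params.t_seed_ob * n_hi) & (n_hi > 0)
        oc_eligible = (n_lo > params.t_seed_oc * n_hi) & (n_lo > 0)
    else:
        ob_eligible = (n_lo >= params.t_seed_ob * n_hi) & (n_lo > 0)
        oc_eligible = (n_hi >= params.t_seed_oc * n_lo) & (n_hi > 0)

    taken = np.zeros(n_surf, dtype=bool)
    pop = CellPopulation()

    def det_place(cell_type, n_det, eligible, descending):
        idx = np.flatnonzero(eligible & ~taken)
        order = np.argsort(-vals[idx] if descending else vals[idx], kind="stable")
        chosen = idx[order[:n_det]]
        taken[chosen] = True
        pop.add(cell_type, coords[chosen])

    n_ob_det = int(round(params.deterministic_fraction * n_ob))
    n_oc_det = int(round(params.deterministic_fraction * n_oc))
    det_place(OSTEOBLAST, n_ob_det, ob_eligible, descending=True)
    det_place(OSTEOCLAST, n_oc_det, oc_eligible, descending=False)
    n_ob_det = pop.count(OSTEOBLAST)  # may be fewer than requested
    n_oc_det = pop.count(OSTEOCLAST)

    def stoch_place(cell_type, n_stoch):
        free = np.flatnonzero(~taken)
        chosen = rng.choice(free, size=min(n_stoch, len(free)), replace=False)
        taken[chosen] = True
        pop.add(cell_type, coords[chosen])

    stoch_place(OSTEOBLAST, n_ob - n_ob_det)
    stoch_place(OSTEOCLAST, n_oc - n_oc_det)
    free = np.flatnonzero(~taken)
    n_prec = int(round(params.precursor_fraction * len(free)))
    stoch_place(OC_PRECURSOR, n_prec)
    pop.add(LINING, coords[~taken])
    return pop


def build_population(
    grid: VoxelGrid,
    sed_field: np.ndarray,
    seeding: SeedingParams,
    rng: np.random.Generator,
) -> CellPopulation:
    """Full initial population: osteocytes, marrow stem cells, surface cells."""
    pop = seed_osteocytes(grid, seeding.osteocyte_density, rng)
    pop = pop.merged_with(seed_marrow_cells(grid, seeding.stem_density, rng))
    pop = pop.merged_with(seed_surface_cells(grid, sed_field, seeding, rng))
    return pop


# ----------------------------------------------------------------------
# Estrogen & apoptosis
# ----------------------------------------------------------------------

def estrogen_receptor_update(estrogen_pgml: float, kd_pgml: float) -> float:
    """Equilibrium receptor occupancy E/(E + Kd)."""
    if estrogen_pgml < 0:
        raise ValueError("estrogen must be non-negative")
    if estrogen_pgml == 0:
        return 0.0
    return estrogen_pgml / (estrogen_pgml + kd_pgml)


def apoptosis_rate(
    cell_type: int | np.ndarray,
    bound_fraction: float | np.ndarray,
    rates: RateParams,
):
    """Effective daily apoptosis hazard with the estrogen fourfold rule.

    Osteoblasts and osteocytes: base rate, elevated fourfold when unbound
    receptors dominate (bound <= 0.5).  Osteoclasts: the mirror image —
    elevated when bound receptors dominate.
    """
    ct = np.asarray(cell_type)
    bf = np.asarray(bound_fraction, dtype=float)
    base = np.select(
        [ct == OSTEOBLAST, ct == OSTEOCYTE, ct == OSTEOCLAST],
        [rates.ob_apoptosis_per_day, rates.ocy_apoptosis_per_day,
         rates.oc_apoptosis_per_day],
        default=0.0,
    )
    elevated = (((ct == OSTEOBLAST) | (ct == OSTEOCYTE)) & (bf <= 0.5)) | (
        (ct == OSTEOCLAST) & (bf > 0.5)
    )
    return np.where(elevated, base * rates.apoptosis_fold, base)


def apoptosis_step(
    cell_type: int | np.ndarray,
    bound_fraction: float | np.ndarray,
    rates: RateParams,
    dt: float,
    rng: np.random.Generator,
):
    """Survival draw over ``dt`` days: death probability 1 - (1 - r_eff)**dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    r_eff = apoptosis_rate(cell_type, bound_fraction, rates)
    p_death = 1.0 - (1.0 - r_eff) ** dt
    draws = rng.random(np.shape(p_death) if np.ndim(p_death) else None)
    return draws >= p_death  # True = survives


def osteocyte_mechanotransduction(
    sed_local: float | np.ndarray, setpoint: float
):
    """Relative RANKL/sclerostin production: max(0, 1 - SED/setpoint).

    Fully stimulated osteocytes (SED at or above setpoint) are silent;
    unloaded osteocytes produce at the maximal rate.
    """
    if setpoint <= 0:
        raise ValueError("setpoint must be positive")
    sed = np.asarray(sed_local, dtype=float)
    if np.any(sed < 0):
        raise ValueError("SED must be non-negative")
    out = np.maximum(0.0, 1.0 - sed / setpoint)
    return float(out) if np.ndim(sed_local) == 0 else out


# ----------------------------------------------------------------------
# Differentiation
# ----------------------------------------------------------------------

def _sample_marrow_field(
    field_arr: np.ndarray, positions: np.ndarray, grid: VoxelGrid, fallback: float
) -> np.ndarray:
    """Field value at the first face-adjacent marrow voxel of each position
    (surface cells sit on bone, the signal lives in marrow)."""
    out = np.full(len(positions), fallback)
    marrow = grid.marrow_mask
    shape = np.array(grid.shape)
    found = np.zeros(len(positions), dtype=bool)
    for off in _FACE_OFFSETS:
        nb = positions + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1) & ~found
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        nb_ok = nb[idx]
        in_marrow = marrow[tuple(nb_ok.T)]
        sel = idx[in_marrow]
        out[sel] = field_arr[tuple(nb_ok[in_marrow].T)]
        found[sel] = True
    return out


def differentiation_step(
    pop: CellPopulation,
    fields,
    rates: RateParams,
    dt: float,
    rng: np.random.Generator,
    grid: VoxelGrid,
    events: EventLog | None = None,
    time: float = 0.0,
) -> CellPopulation:
    """MSC -> osteoblast and precursor <-> osteoclast transitions.

    MSCs adjacent to a lining-covered surface voxel differentiate into
    osteoblasts with a probability scaled by estrogen receptor occupancy
    and damped by local sclerostin.  Precursors activate into osteoclasts
    when local free RANKL exceeds the activation threshold; osteoclasts
    starved of RANKL for longer than the persistence time revert to
    precursors.
    """
    occupancy = estrogen_receptor_update(fields.estrogen, rates.estrogen_kd)
    pop.bound_fraction[:] = occupancy

    # --- precursor activation -----------------------------------------
    prec = np.flatnonzero(pop.types == OC_PRECURSOR)
    if len(prec):
        marrow_mean = fields.marrow_mean("rankl")
        local_rankl = _sample_marrow_field(
            fields.rankl, pop.positions[prec], grid, marrow_mean
        )
        p_act = 1.0 - (1.0 - min(rates.precursor_activation_per_day, 1.0)) ** dt
        activate = (local_rankl > rates.rankl_activation_threshold) & (
            rng.random(len(prec)) < p_act
        )
        idx = prec[activate]
        pop.types[idx] = OSTEOCLAST
        pop.starved[idx] = 0.0
        if events is not None and len(idx):
            events.extend(time, pop.positions[idx], EV_ACTIVATE)

    # --- osteoclast starvation ----------------------------------------
    ocs = np.flatnonzero(pop.types == OSTEOCLAST)
    if len(ocs):
        marrow_mean = fields.marrow_mean("rankl")
        local_rankl = _sample_marrow_field(
            fields.rankl, pop.positions[ocs], grid, marrow_mean
        )
        below = local_rankl <= rates.rankl_activation_threshold
        pop.starved[ocs] = np.where(below, pop.starved[ocs] + dt, 0.0)
        revert = pop.starved[ocs] > rates.oc_starvation_persistence
        idx = ocs[revert]
        pop.types[idx] = OC_PRECURSOR
        pop.starved[idx] = 0.0

    # --- MSC -> osteoblast --------------------------------------------
    # only MSCs next to quiescent (lining-covered) surface are eligible;
    # the differentiation probability applies to those
    mscs = np.flatnonzero(pop.types == MSC)
    if len(mscs):
        lining_idx = np.flatnonzero(pop.types == LINING)
        if len(lining_idx):
            lining_map = np.full(int(np.prod(grid.shape)), -1, dtype=np.int64)
            lin_lin = np.ravel_multi_index(
                tuple(pop.positions[lining_idx].T), grid.shape
            )
            lining_map[lin_lin] = lining_idx
            shape = np.array(grid.shape)
            adj_lining = np.full(len(mscs), -1, dtype=np.int64)
            for off in _FACE_OFFSETS:
                nb = pop.positions[mscs] + off
                ok = np.all((nb >= 0) & (nb < shape), axis=1) & (adj_lining < 0)
                idx = np.flatnonzero(ok)
                lin = np.ravel_multi_index(tuple(nb[idx].T), grid.shape)
                hit = lining_map[lin] >= 0
                adj_lining[idx[hit]] = lining_map[lin[hit]]
            eligible = np.flatnonzero(adj_lining >= 0)
            if len(eligible):
                scl = fields.marrow_mean("sclerostin")
                scl_factor = 1.0 / (1.0 + scl / rates.scl_halfmax)
                p = rates.msc_differentiation_per_day * occupancy * scl_factor
                p_diff = 1.0 - (1.0 - min(p, 1.0)) ** dt
                chosen = eligible[rng.random(len(eligible)) < p_diff]
                converted_lining = []
                for ei in chosen:
                    li = int(adj_lining[ei])
                    if li in converted_lining:
                        continue
                    ci = mscs[ei]
                    # MSC becomes an osteoblast at the surface spot the
                    # lining cell vacated
                    pop.types[ci] = OSTEOBLAST
                    pop.positions[ci] = pop.positions[li]
                    pop.starved[ci] = 0.0
                    converted_lining.append(li)
                if converted_lining:
                    mask = np.zeros(len(pop), dtype=bool)
                    mask[np.asarray(converted_lining)] = True
                    pop.remove(mask)
    return pop


# ----------------------------------------------------------------------
# Remodeling
# ----------------------------------------------------------------------

@dataclass
class TissueAux:
    """Per-voxel remodeling progress carried between cell steps."""

    osteoid_frac: np.ndarray
    resorbed_frac: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "TissueAux":
        return cls(np.zeros(shape), np.zeros(shape))


def remodel_step(
    pop: CellPopulation,
    grid: VoxelGrid,
    fields,
    rates: RateParams,
    dt: float,
    rng: np.random.Generator,
    aux: TissueAux | None = None,
    events: EventLog | None = None,
    time: float = 0.0,
) -> tuple[VoxelGrid, EventLog]:
    """One resorption/formation/mineralization update (in place on ``grid``).

    Osteoclasts erode their voxel at ``resorption_rate`` (voxel fractions
    per day); a fully eroded voxel becomes marrow and the osteoclast steps
    to an adjacent surface voxel.  Osteoblasts deposit osteoid into an
    adjacent marrow voxel at ``osteoid_rate``; a filled voxel becomes
    OSTEOID with zero mineral.  All osteoid/bone mineral relaxes toward
    full mineralization with time constant ``mineralization_tau`` (fresh
    osteoid follows max*(1 - exp(-t/tau))).  Osteoblasts buried on all six
    faces become osteocytes.
    """
    if aux is None:
        aux = TissueAux.zeros(grid.shape)
    if events is None:
        events = EventLog()
    shape = np.array(grid.shape)

    bone_like = grid.tissue != MARROW
    pos_all = pop.positions
    if len(pop) and np.any(
        np.isin(pop.types, SURFACE_TYPES) & ~bone_like[tuple(pos_all.T)]
    ):
        raise ValueError("surface agent on a marrow voxel")

    # --- resorption ----------------------------------------------------
    oc_idx = np.flatnonzero(pop.types == OSTEOCLAST)
    emptied = []
    for i in oc_idx:
        v = tuple(pop.positions[i])
        aux.resorbed_frac[v] += rates.resorption_rate * dt
        events.add(time, v, EV_ERODE)
        if aux.resorbed_frac[v] >= 1.0:
            emptied.append((i, v))
    for i, v in emptied:
        grid.tissue[v] = MARROW
        grid.mineral[v] = 0.0
        aux.resorbed_frac[v] = 0.0
        aux.osteoid_frac[v] = 0.0
    # relocate osteoclasts (and any other surface cells) off emptied voxels
    if emptied:
        surf = surface_mask(grid)
        occupied = set(
            np.ravel_multi_index(
                tuple(pop.positions[np.isin(pop.types, SURFACE_TYPES)].T), grid.shape
            ).tolist()
        )
        dead = np.zeros(len(pop), dtype=bool)
        for i, v in emptied:
            placed = False
            neighbors = np.asarray(v) + _NEIGH26
            ok = np.all((neighbors >= 0) & (neighbors < shape), axis=1)
            for nb in neighbors[ok][rng.permutation(int(ok.sum()))]:
                t_nb = tuple(nb)
                lin = int(np.ravel_multi_index(t_nb, grid.shape))
                if surf[t_nb] and lin not in occupied:
                    pop.positions[i] = nb
                    occupied.add(lin)
                    placed = True
                    break
            if not placed:
                dead[i] = True
        if dead.any():
            pop.remove(dead)

    # --- formation -------------------------------------------------------
    ob_idx = np.flatnonzero(pop.types == OSTEOBLAST)
    filled = []
    marrow = grid.marrow_mask
    for i in ob_idx:
        p = pop.positions[i]
        nb = p + _FACE_OFFSETS
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        in_marrow = marrow[tuple(nb.T)]
        targets = nb[in_marrow]
        if len(targets) == 0:
            continue
        tv = tuple(targets[rng.integers(len(targets))])
        aux.osteoid_frac[tv] += rates.osteoid_rate * dt
        events.add(time, tuple(p), EV_FORM)
        if aux.osteoid_frac[tv] >= 1.0:
            filled.append(tv)
    for tv in filled:
        grid.tissue[tv] = OSTEOID
        grid.mineral[tv] = 0.0
        aux.osteoid_frac[tv] = 0.0
        events.add(time, tv, EV_FORM)
        # evict marrow cells from the newly formed voxel
        if len(pop):
            here = np.all(pop.positions == np.asarray(tv), axis=1) & np.isin(
                pop.types, (MSC, HSC)
            )
            if here.any():
                nb = np.asarray(tv) + _FACE_OFFSETS
                ok = np.all((nb >= 0) & (nb < shape), axis=1)
                nb = nb[ok]
                open_marrow = nb[grid.marrow_mask[tuple(nb.T)]]
                if len(open_marrow):
                    pop.positions[here] = open_marrow[0]
                else:
                    pop.remove(here)

    # --- mineralization --------------------------------------------------
    bone_like = grid.tissue != MARROW
    if rates.mineralization_tau > 0:
        factor = np.exp(-dt / rates.mineralization_tau)
        grid.mineral[bone_like] = 1.0 - (1.0 - grid.mineral[bone_like]) * factor
    promote = (grid.tissue == OSTEOID) & (
        grid.mineral >= rates.osteoid_to_bone_mineral
    )
    if promote.any():
        grid.tissue[promote] = BONE
        if events is not None:
            events.extend(time, np.argwhere(promote), EV_MINERALIZE)

    # --- burial: osteoblasts enclosed on all faces become osteocytes -----
    ob_idx = np.flatnonzero(pop.types == OSTEOBLAST)
    if len(ob_idx):
        bone_pad = np.pad(grid.tissue != MARROW, 1, constant_values=True)
        buried = np.ones(len(ob_idx), dtype=bool)
        for off in _FACE_OFFSETS:
            nb = pop.positions[ob_idx] + off + 1  # +1 for padding
            buried &= bone_pad[tuple(nb.T)]
        pop.types[ob_idx[buried]] = OSTEOCYTE
    return grid, events


def maintain_lining(pop: CellPopulation, grid: VoxelGrid) -> CellPopulation:
    """Restore the surface-occupancy invariants after remodeling.

    Surface cells whose voxel lost its marrow exposure are resolved
    (buried osteoblasts become osteocytes, entombed osteoclasts and
    precursors are removed), then lining cells are re-derived to cover
    exactly the free surface.
    """
    surf = surface_mask(grid)
    keep = pop.types != LINING
    pop.remove(~keep)
    surf_cells = np.isin(pop.types, (OSTEOBLAST, OSTEOCLAST, OC_PRECURSOR))
    if surf_cells.any():
        on_surface = surf[tuple(pop.positions[surf_cells].T)]
        idx = np.flatnonzero(surf_cells)[~on_surface]
        if len(idx):
            buried_ob = idx[pop.types[idx] == OSTEOBLAST]
            pop.types[buried_ob] = OSTEOCYTE
            gone = np.zeros(len(pop), dtype=bool)
            gone[idx[pop.types[idx] != OSTEOCYTE]] = True
            if gone.any():
                pop.remove(gone)
    surf_cells = np.isin(pop.types, (OSTEOBLAST, OSTEOCLAST, OC_PRECURSOR))
    occ = np.zeros(grid.shape, dtype=bool)
    if surf_cells.any():
        occ[tuple(pop.positions[surf_cells].T)] = True
    free = surf & ~occ
    pop.add(LINING, np.argwhere(free))
    return pop


def stem_cell_motility(
    pop: CellPopulation, grid: VoxelGrid, rng: np.random.Generator
) -> None:
    """Random walk of marrow cells to a face-adjacent marrow voxel."""
    idx = np.flatnonzero(np.isin(pop.types, (MSC, HSC)))
    if not len(idx):
        return
    steps = _FACE_OFFSETS[rng.integers(6, size=len(idx))]
    nb = pop.positions[idx] + steps
    shape = np.array(grid.shape)
    ok = np.all((nb >= 0) & (nb < shape), axis=1)
    ok[ok] &= grid.marrow_mask[tuple(nb[ok].T)]
    pop.positions[idx[ok]] = nb[ok]
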