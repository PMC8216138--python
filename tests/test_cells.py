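import numpy as np
import pytest
from scipy import stats as sps

from osteotwin.cells import (
    HSC,
    LINING,
    MSC,
    OC_PRECURSOR,
    OSTEOBLAST,
    OSTEOCLAST,
    OSTEOCYTE,
    CellPopulation,
    RateParams,
    SeedingParams,
    TissueAux,
    apoptosis_rate,
    apoptosis_step,
    build_population,
    differentiation_step,
    estrogen_receptor_update,
    osteocyte_mechanotransduction,
    remodel_step,
    seed_marrow_cells,
    seed_osteocytes,
    seed_surface_cells,
)
from osteotwin.grid import BONE, MARROW, OSTEOID, EventLog, VoxelGrid, extract_surface
from osteotwin.pkpd import ConcentrationFields


def _ramp_sed(grid, max_sed=0.04):
    sed = np.zeros(grid.shape)
    sed[:] = np.linspace(0.0, max_sed, grid.shape[2])[None, None, :]
    sed[~grid.bone_mask] = 0.0
    return sed


class TestSeeding:
    def test_osteocyte_density(self, medium_structure, rng):
        pop = seed_osteocytes(medium_structure, 4800.0, rng)
        bone_volume = medium_structure.bone_mask.sum() * medium_structure.voxel_volume
        expected = 4800.0 * bone_volume
        assert abs(len(pop) - expected) <= 3.0 * np.sqrt(expected)
        tissues = medium_structure.tissue[tuple(pop.positions.T)]
        assert np.all(tissues != MARROW)

    def test_zero_density_empty(self, medium_structure, rng):
        assert len(seed_osteocytes(medium_structure, 0.0, rng)) == 0
        assert len(seed_marrow_cells(medium_structure, 0.0, rng)) == 0

    def test_overdense_lattice_rejected(self, medium_structure, rng):
        with pytest.raises(ValueError, match="cell per voxel"):
            seed_osteocytes(medium_structure, 1e9, rng)

    def test_stem_cell_density_and_ratio(self, medium_structure, rng):
        pop = seed_marrow_cells(medium_structure, 8000.0, rng)
        marrow_volume = (
            medium_structure.marrow_mask.sum() * medium_structure.voxel_volume
        )
        expected = 8000.0 * marrow_volume
        assert abs(len(pop) - expected) <= 3.0 * np.sqrt(expected)
        ratio = pop.count(MSC) / pop.count(HSC)
        assert ratio == pytest.approx(1.0, abs=0.08)

    def test_stem_cell_spatial_uniformity(self, small_structure):
        """Chi-square over octants not rejected at alpha=0.01 for >=18/20 seeds."""
        marrow = small_structure.marrow_mask
        mid = np.array(small_structure.shape) // 2
        passes = 0
        for seed in range(20):
            pop = seed_marrow_cells(
                small_structure, 8000.0, np.random.default_rng(seed)
            )
            octant = (
                (pop.positions[:, 0] >= mid[0]).astype(int) * 4
                + (pop.positions[:, 1] >= mid[1]).astype(int) * 2
                + (pop.positions[:, 2] >= mid[2]).astype(int)
            )
            observed = np.bincount(octant, minlength=8)
            # expected proportional to marrow voxels per octant
            oz, oy, ox = np.meshgrid(*[np.arange(s) for s in small_structure.shape],
                                     indexing="ij")
            oct_vox = (
                (oz >= mid[0]).astype(int) * 4
                + (oy >= mid[1]).astype(int) * 2
                + (ox >= mid[2]).astype(int)
            )
            counts = np.bincount(oct_vox[marrow], minlength=8)
            expected = counts / counts.sum() * observed.sum()
            _, p = sps.chisquare(observed, expected)
            passes += p > 0.01
        assert passes >= 18

    def test_uniform_sed_disables_deterministic_seeding(self, small_structure, rng):
        """With uniform SED every neighbor ties, so no site satisfies the
        strict local-extremum criteria; all placements are stochastic."""
        from osteotwin.cells import _neighbor_sed_counts

        sed = np.where(small_structure.bone_mask, 0.02, 0.0)
        surf = extract_surface(small_structure)
        n_lo, n_hi = _neighbor_sed_counts(surf.voxels, sed, small_structure.shape)
        params = SeedingParams()
        assert np.count_nonzero((n_lo >= params.t_seed_ob * n_hi) & (n_lo > 0)) == 0
        assert np.count_nonzero((n_hi >= params.t_seed_oc * n_lo) & (n_hi > 0)) == 0

    def test_ramp_sed_places_cells_at_extremes(self, medium_structure, rng):
        """On a monotone SED ramp, deterministic osteoblasts concentrate in
        the top SED tertile and osteoclasts in the bottom tertile."""
        sed = _ramp_sed(medium_structure)
        params = SeedingParams(
            ob_n_bs=4.0, oc_n_bs=4.0, deterministic_fraction=1.0
        )
        pop = seed_surface_cells(medium_structure, sed, params, rng)
        surf = extract_surface(medium_structure)
        vals = sed[tuple(surf.voxels.T)]
        lo_t, hi_t = np.quantile(vals, [1 / 3, 2 / 3])
        ob_sed = sed[tuple(pop.positions_of(OSTEOBLAST).T)]
        oc_sed = sed[tuple(pop.positions_of(OSTEOCLAST).T)]
        assert np.mean(ob_sed >= hi_t) >= 0.8
        assert np.mean(oc_sed <= lo_t) >= 0.8

    def test_full_surface_coverage_identity(self, small_structure, rng):
        """Every surface voxel carries exactly one agent; lining fills the
        complement of osteoblasts, osteoclasts and precursors."""
        sed = _ramp_sed(small_structure)
        pop = seed_surface_cells(small_structure, sed, SeedingParams(), rng)
        surf = extract_surface(small_structure)
        n = surf.n_voxels
        n_ob = pop.count(OSTEOBLAST)
        n_oc = pop.count(OSTEOCLAST)
        n_prec = pop.count(OC_PRECURSOR)
        assert pop.count(LINING) == n - n_ob - n_oc - n_prec
        lin = np.ravel_multi_index(tuple(pop.positions.T), small_structure.shape)
        assert len(np.unique(lin)) == len(lin)
        surf_lin = np.ravel_multi_index(tuple(surf.voxels.T), small_structure.shape)
        assert set(lin) == set(surf_lin)

    def test_deterministic_stochastic_split(self, medium_structure, rng):
        """About half of the seeded osteoblasts/osteoclasts come from the
        SED criterion."""
        sed = _ramp_sed(medium_structure)
        params = SeedingParams(ob_n_bs=20.0, oc_n_bs=20.0)
        det = seed_surface_cells(
            medium_structure,
            sed,
            SeedingParams(ob_n_bs=20.0, oc_n_bs=20.0, deterministic_fraction=1.0),
            np.random.default_rng(0),
        )
        both = seed_surface_cells(medium_structure, sed, params, np.random.default_rng(0))
        n_total = both.count(OSTEOBLAST)
        # deterministic half = cells placed at eligible ranked sites
        det_available = det.count(OSTEOBLAST)
        expected_det = round(0.5 * n_total)
        assert min(expected_det, det_available) / n_total == pytest.approx(
            0.5, abs=0.05
        )

    def test_requested_counts_exceed_surface(self, small_structure, rng):
        with pytest.raises(ValueError, match="exceed"):
            seed_surface_cells(
                small_structure,
                _ramp_sed(small_structure),
                SeedingParams(ob_n_bs=1e5, oc_n_bs=1e5),
                rng,
            )

    def test_full_population_invariants(self, small_structure, rng):
        pop = build_population(
            small_structure, _ramp_sed(small_structure), SeedingParams(), rng
        )
        pop.validate_positions(small_structure)


class TestEstrogenRules:
    def test_receptor_occupancy(self):
        assert estrogen_receptor_update(32.0, 32.0) == 0.5
        assert estrogen_receptor_update(0.0, 32.0) == 0.0
        # occupancy crosses 0.5 as estrogen decays from 40 to 25 pg/ml
        assert estrogen_receptor_update(40.0, 32.0) > 0.5
        assert estrogen_receptor_update(25.0, 32.0) < 0.5

    def test_osteoblast_hazards(self):
        rates = RateParams()
        assert apoptosis_rate(OSTEOBLAST, 0.9, rates) == pytest.approx(0.001)
        assert apoptosis_rate(OSTEOBLAST, 0.1, rates) == pytest.approx(0.004)

    def test_osteoclast_mirror_rule(self):
        rates = RateParams()
        base = rates.oc_apoptosis_per_day
        assert apoptosis_rate(OSTEOCLAST, 0.9, rates) == pytest.approx(4 * base)
        assert apoptosis_rate(OSTEOCLAST, 0.1, rates) == pytest.approx(base)

    def test_zero_rate_certain_survival(self, rng):
        rates = RateParams(ob_apoptosis_per_day=0.0)
        survives = apoptosis_step(
            np.full(1000, OSTEOBLAST), np.full(1000, 0.1), rates, 1.0, rng
        )
        assert survives.all()

    def test_death_probability_formula(self, rng):
        """Empirical one-day death frequency matches 1 - (1 - r)^dt."""
        rates = RateParams()
        n = 200_000
        survives = apoptosis_step(
            np.full(n, OSTEOBLAST), np.full(n, 0.1), rates, 1.0, rng
        )
        p_emp = 1.0 - survives.mean()
        assert p_emp == pytest.approx(0.004, rel=0.15)


class TestMechanotransduction:
    def test_linear_unloading_response(self):
        assert osteocyte_mechanotransduction(0.02, 0.02) == 0.0
        assert osteocyte_mechanotransduction(0.0, 0.02) == 1.0
        assert osteocyte_mechanotransduction(0.01, 0.02) == 0.5
        assert osteocyte_mechanotransduction(0.05, 0.02) == 0.0

    def test_invalid_setpoint(self):
        with pytest.raises(ValueError):
            osteocyte_mechanotransduction(0.01, 0.0)


class TestDifferentiation:
    def _prep(self, grid, rng, rankl):
        pop = build_population(grid, _ramp_sed(grid), SeedingParams(), rng)
        fields = ConcentrationFields(grid)
        fields.rankl[fields.marrow] = rankl
        return pop, fields

    def test_no_rankl_no_activation(self, small_structure, rng):
        pop, fields = self._prep(small_structure, rng, 0.0)
        n_oc_before = pop.count(OSTEOCLAST)
        rates = RateParams(oc_starvation_persistence=1e9)
        differentiation_step(pop, fields, rates, 3.65, rng, small_structure)
        assert pop.count(OSTEOCLAST) == n_oc_before

    def test_saturating_rankl_activates_all(self, small_structure, rng):
        pop, fields = self._prep(small_structure, rng, 10.0)
        n_prec = pop.count(OC_PRECURSOR)
        rates = RateParams(precursor_activation_per_day=1.0)
        differentiation_step(pop, fields, rates, 3.65, rng, small_structure)
        assert pop.count(OC_PRECURSOR) == 0
        assert pop.count(OSTEOCLAST) >= n_prec

    def test_denosumab_bolus_reduces_activation(self, small_structure):
        """Same seed, with and without bolus: strictly fewer activations."""
        from osteotwin.pkpd import KineticsParams, apply_injection, binding_step

        results = {}
        for label, peak in (("control", 0.0), ("bolus", 8000.0)):
            rng = np.random.default_rng(7)
            pop, fields = self._prep(small_structure, rng, 0.1)
            if peak:
                apply_injection(fields, peak)
                binding_step(fields, KineticsParams(), 20.0 / 1440.0)
            rates = RateParams(precursor_activation_per_day=0.5)
            differentiation_step(pop, fields, rates, 3.65, rng, small_structure)
            results[label] = pop.count(OSTEOCLAST)
        assert results["bolus"] < results["control"]


class TestRemodeling:
    def test_no_agents_no_change(self, small_structure):
        grid = small_structure.copy()
        pop = CellPopulation()
        fields = ConcentrationFields(grid)
        _, events = remodel_step(
            pop, grid, fields, RateParams(), 3.65, np.random.default_rng(0)
        )
        # mineralization may advance mineral, but tissue labels are untouched
        assert np.array_equal(grid.tissue, small_structure.tissue)
        assert sum(k in ("FORM", "ERODE") for k in events.kinds) == 0

    def test_resorption_bookkeeping(self, embedded_cube, rng):
        """A single osteoclast removes resorption_rate * dt voxel fractions."""
        grid = embedded_cube.copy()
        surf = extract_surface(grid)
        pop = CellPopulation()
        pop.add(OSTEOCLAST, surf.voxels[:1])
        rates = RateParams(resorption_rate=0.1, osteoid_rate=0.0,
                           mineralization_tau=0.0)
        aux = TissueAux.zeros(grid.shape)
        fields = ConcentrationFields(grid)
        remodel_step(pop, grid, fields, rates, 3.65, rng, aux=aux)
        assert aux.resorbed_frac.sum() == pytest.approx(0.1 * 3.65)

    def test_full_resorption_erases_voxel(self, embedded_cube, rng):
        grid = embedded_cube.copy()
        surf = extract_surface(grid)
        target = tuple(surf.voxels[0])
        pop = CellPopulation()
        pop.add(OSTEOCLAST, surf.voxels[:1])
        rates = RateParams(resorption_rate=0.5, osteoid_rate=0.0,
                           mineralization_tau=0.0)
        aux = TissueAux.zeros(grid.shape)
        fields = ConcentrationFields(grid)
        for _ in range(2):
            remodel_step(pop, grid, fields, rates, 3.65, rng, aux=aux)
        assert grid.tissue[target] == MARROW
        assert grid.mineral[target] == 0.0

    def test_fresh_osteoid_mineralization_curve(self, rng):
        """density(tau) = max * (1 - 1/e) for newly formed osteoid."""
        t = np.zeros((5, 5, 5), np.uint8)
        t[2, 2, 2] = OSTEOID
        grid = VoxelGrid(t, 0.014, mineral=np.zeros((5, 5, 5)))
        rates = RateParams(mineralization_tau=365.0, osteoid_to_bone_mineral=2.0)
        fields = ConcentrationFields(grid)
        pop = CellPopulation()
        n_steps = 100
        dt = 365.0 / n_steps
        for _ in range(n_steps):
            remodel_step(pop, grid, fields, rates, dt, rng)
        assert grid.mineral[2, 2, 2] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-9)

    def test_buried_osteoblast_becomes_osteocyte(self, rng):
        t = np.full((5, 5, 5), BONE, np.uint8)
        t[2, 2, 2] = BONE  # fully enclosed position
        grid = VoxelGrid(t, 0.014)
        pop = CellPopulation()
        pop.add(OSTEOBLAST, np.array([[2, 2, 2]]))
        fields = ConcentrationFields(grid)
        remodel_step(pop, grid, fields, RateParams(osteoid_rate=0.0), 3.65, rng)
        assert pop.count(OSTEOBLAST) == 0
        assert pop.count(OSTEOCYTE) == 1

    def test_formation_creates_osteoid(self, embedded_cube, rng):
        grid = embedded_cube.copy()
        surf = extract_surface(grid)
        pop = CellPopulation()
        pop.add(OSTEOBLAST, surf.voxels[:1])
        rates = RateParams(osteoid_rate=0.6, resorption_rate=0.0)
        aux = TissueAux.zeros(grid.shape)
        fields = ConcentrationFields(grid)
        n_osteoid_before = np.count_nonzero(grid.tissue == OSTEOID)
        _, events = remodel_step(pop, grid, fields, rates, 3.65, rng, aux=aux)
        assert np.count_nonzero(grid.tissue == OSTEOID) > n_osteoid_before
        assert "FORM" in events.kinds
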