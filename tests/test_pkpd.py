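import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import convolve

from osteotwin.grid import BONE, VoxelGrid
from osteotwin.pkpd import (
    ConcentrationFields,
    KineticsParams,
    apply_injection,
    binding_step,
    decay_step,
    diffusion_step,
    dose_per_body_weight,
    estrogen_level,
    fit_half_life,
    ngml_to_nM,
    nM_to_ngml,
    peak_concentration_from_dose,
)


@pytest.fixture
def marrow_grid():
    """All-marrow 6^3 domain."""
    return VoxelGrid(np.zeros((6, 6, 6), np.uint8), 0.014)


class TestDosing:
    def test_reference_dose_normalization(self):
        rounded, exact = dose_per_body_weight(60.0, 67.0)
        assert rounded == 0.9
        assert exact == pytest.approx(60.0 / 67.0)

    def test_identity_ratio_and_rounding(self):
        assert dose_per_body_weight(67.0, 67.0)[0] == 1.0
        rounded, exact = dose_per_body_weight(30.0, 67.0)
        assert rounded == 0.4
        assert exact == pytest.approx(0.4478, abs=1e-4)

    def test_nonpositive_weight(self):
        with pytest.raises(ValueError):
            dose_per_body_weight(60.0, 0.0)

    def test_peak_interpolation(self):
        assert peak_concentration_from_dose(0.9) == pytest.approx(8000.0)
        assert peak_concentration_from_dose(0.3) == pytest.approx(2000.0)
        assert peak_concentration_from_dose(0.65) == pytest.approx(5500.0)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="outside"):
            peak_concentration_from_dose(1.5)

    def test_unit_conversion(self):
        assert ngml_to_nM(8000.0, 147000.0) == pytest.approx(54.42, abs=0.01)
        assert ngml_to_nM(0.0, 147000.0) == 0.0
        c = 3.7
        assert ngml_to_nM(nM_to_ngml(c, 147000.0), 147000.0) == pytest.approx(
            c, rel=1e-12
        )


class TestInjectionAndDecay:
    def test_bolus_sets_marrow_uniformly(self, embedded_cube):
        fields = ConcentrationFields(embedded_cube)
        apply_injection(fields, 8000.0)
        marrow = embedded_cube.marrow_mask
        expected_nM = ngml_to_nM(8000.0, 147000.0)
        assert np.allclose(fields.denosumab[marrow], expected_nM)
        assert np.all(fields.denosumab[~marrow] == 0.0)

    def test_bolus_sets_not_adds(self, marrow_grid):
        fields = ConcentrationFields(marrow_grid)
        fields.denosumab[:] = ngml_to_nM(100.0, 147000.0)
        apply_injection(fields, 8000.0)
        assert np.allclose(
            fields.denosumab, ngml_to_nM(8000.0, 147000.0)
        )

    def test_zero_peak_noop(self, marrow_grid):
        fields = ConcentrationFields(marrow_grid)
        apply_injection(fields, 0.0)
        assert np.all(fields.denosumab == 0.0)

    def test_half_life_definition(self):
        assert decay_step(8000.0, 26.0, 26.0) == pytest.approx(4000.0)
        assert decay_step(8000.0, 0.0, 26.0) == 8000.0
        assert decay_step(8000.0, 52.0, 26.0) == pytest.approx(2000.0)

    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    def test_decay_composition(self, dt1, dt2):
        """Decaying dt1 then dt2 equals decaying dt1+dt2 in one step."""
        a = decay_step(decay_step(1000.0, dt1, 26.0), dt2, 26.0)
        b = decay_step(1000.0, dt1 + dt2, 26.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_injection_curve_log_linear(self):
        """Between boluses the concentration is log-linear with slope
        -ln2/26 per day."""
        t = np.arange(0.0, 183.0, 1.0)
        conc = decay_step(8000.0, t, 26.0)
        assert np.all(np.diff(conc) < 0)
        half_life, r2 = fit_half_life(t, conc)
        assert half_life == pytest.approx(26.0, abs=1e-9)
        assert r2 > 0.999


class TestEstrogen:
    def test_printed_endpoints(self):
        assert estrogen_level(0.0) == 40.0
        assert estrogen_level(3650.0) == 25.0
        assert estrogen_level(5000.0) == 25.0

    def test_linear_midpoint(self):
        assert estrogen_level(1825.0) == pytest.approx(32.5)

    def test_negative_time(self):
        with pytest.raises(ValueError):
            estrogen_level(-1.0)


class TestBinding:
    def test_frozen_kinetics_noop(self, marrow_grid):
        fields = ConcentrationFields(marrow_grid)
        fields.rankl[:] = 1.0
        fields.denosumab[:] = 1.0
        params = KineticsParams(k_on=0.0, k_off=0.0, k_on_opg=0.0, k_off_opg=0.0)
        binding_step(fields, params, 1.0)
        assert np.all(fields.rankl == 1.0)
        assert np.all(fields.rankl_dmab == 0.0)

    def test_equilibrium_matches_dissociation_constant(self, marrow_grid):
        """Long binding-only integration: [R][D]/[C] -> k_off/k_on."""
        fields = ConcentrationFields(marrow_grid)
        params = KineticsParams()
        fields.rankl[:] = 0.05
        fields.denosumab[:] = 0.03
        for _ in range(200):
            binding_step(fields, params, 20.0 / 1440.0)
        ratio = fields.rankl[0, 0, 0] * fields.denosumab[0, 0, 0] / fields.rankl_dmab[0, 0, 0]
        kd = params.k_off / params.k_on
        assert ratio == pytest.approx(kd, rel=0.01)
        assert kd == pytest.approx(0.010638, abs=1e-6)

    @given(
        st.floats(0.0, 10.0),
        st.floats(0.0, 10.0),
        st.floats(0.0, 5.0),
        st.floats(0.0, 5.0),
    )
    def test_rankl_conservation(self, r0, d0, c0, o0):
        """Free + complexed RANKL is conserved by a pure binding step."""
        grid = VoxelGrid(np.zeros((3, 3, 3), np.uint8), 0.014)
        fields = ConcentrationFields(grid)
        fields.rankl[:] = r0
        fields.denosumab[:] = d0
        fields.rankl_dmab[:] = c0
        fields.opg[:] = o0
        total = fields.total_rankl()
        binding_step(fields, KineticsParams(), 0.01)
        if total > 0:
            assert fields.total_rankl() == pytest.approx(total, rel=1e-9)
        assert fields.rankl.min() >= 0 and fields.denosumab.min() >= 0

    def test_negative_concentration_rejected(self, marrow_grid):
        fields = ConcentrationFields(marrow_grid)
        fields.rankl[:] = -1.0
        with pytest.raises(ValueError, match="negative"):
            binding_step(fields, KineticsParams(), 0.01)

    def test_monotone_dose_response(self, marrow_grid):
        """More denosumab leaves less free RANKL at fixed total RANKL."""
        free = []
        for peak in (500.0, 3000.0, 8000.0):
            fields = ConcentrationFields(marrow_grid)
            fields.rankl[:] = 0.1
            apply_injection(fields, peak)
            for _ in range(12):
                binding_step(fields, KineticsParams(), 20.0 / 1440.0)
            free.append(fields.rankl[0, 0, 0])
        assert free[0] > free[1] > free[2]


class TestDiffusion:
    def test_uniform_field_fixed_point(self, embedded_cube):
        field = np.where(embedded_cube.marrow_mask, 2.5, 0.0)
        out = diffusion_step(field, 1e-7, 1e-4, embedded_cube)
        assert np.allclose(out, field)

    def test_mass_conservation_explicit(self, embedded_cube, rng):
        field = np.zeros(embedded_cube.shape)
        marrow = embedded_cube.marrow_mask
        field[marrow] = rng.random(int(marrow.sum()))
        total = field.sum()
        for _ in range(100):
            field = diffusion_step(field, 1e-7, 1e-4, embedded_cube)
        assert field.sum() == pytest.approx(total, rel=1e-9)
        assert np.all(field[~marrow] == 0.0)

    def test_point_source_greens_function(self):
        """Three explicit steps on an open lattice equal the 3-fold
        convolution of the single-step stencil."""
        grid = VoxelGrid(np.zeros((13, 13, 13), np.uint8), 0.014)
        D, dt = 1e-7, 1e-4
        r = D * dt * 86400.0 / grid.voxel_size**2
        field = np.zeros(grid.shape)
        field[6, 6, 6] = 1.0
        out = field.copy()
        for _ in range(3):
            out = diffusion_step(out, D, dt, grid)
        stencil = np.zeros((3, 3, 3))
        stencil[1, 1, 1] = 1.0 - 6.0 * r
        for dz, dy, dx in [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0)]:
            stencil[1 + dz, 1 + dy, 1 + dx] = r
        oracle = field
        for _ in range(3):
            oracle = convolve(oracle, stencil, mode="same")
        assert np.allclose(out, oracle, atol=1e-15)

    def test_explicit_instability_detected(self, embedded_cube):
        field = np.where(embedded_cube.marrow_mask, 1.0, 0.0)
        with pytest.raises(ValueError, match="smaller dt"):
            diffusion_step(field, 1e-4, 20.0 / 1440.0, embedded_cube, method="explicit")

    def test_well_mixed_limit(self, embedded_cube, rng):
        """At huge Fourier number the field relaxes to the component mean."""
        field = np.zeros(embedded_cube.shape)
        marrow = embedded_cube.marrow_mask
        field[marrow] = rng.random(int(marrow.sum()))
        mean = field[marrow].mean()
        out = diffusion_step(field, 1e-4, 20.0 / 1440.0, embedded_cube)
        assert np.allclose(out[marrow], mean)
        assert out.sum() == pytest.approx(field.sum(), rel=1e-12)

    def test_implicit_conserves_mass(self, embedded_cube, rng):
        field = np.zeros(embedded_cube.shape)
        marrow = embedded_cube.marrow_mask
        field[marrow] = rng.random(int(marrow.sum()))
        out = diffusion_step(field, 1e-7, 0.05, embedded_cube, method="implicit")
        assert out.sum() == pytest.approx(field.sum(), rel=1e-9)
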