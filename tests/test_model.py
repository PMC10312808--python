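import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normgain import model as nm

from .oracles import (
    naive_attention,
    naive_excitatory,
    naive_gaussian_convolve,
    naive_max,
    naive_population,
    naive_suppressive,
)

LOW, HIGH = nm.DEFAULT_CONTRASTS
SIZES = nm.DEFAULT_SIZES_DEG


def grid_for(params, sizes=SIZES, spacing=None):
    stims = [nm.StimulusSpec(extent=params.au(s), contrast=1.0) for s in sizes]
    return nm.default_grid(params, stims, spacing=spacing)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_grid_requires_positive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            nm.SpatialGrid(np.linspace(-5, 5, 64), 0.0)

    def test_grid_requires_symmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            nm.SpatialGrid(np.linspace(0, 10, 64), 10 / 63)

    def test_make_has_at_least_64_samples(self):
        g = nm.SpatialGrid.make(1.0, 0.5)
        assert g.n_space >= 64

    def test_params_require_broader_suppression(self):
        with pytest.raises(ValueError, match="spatially broader"):
            nm.ModelParams(excit_width=5.0, suppress_width=4.0)

    def test_params_reject_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            dataclasses.replace(nm.DEFAULT_PARAMS, sigma=0.0)

    def test_params_reject_sub_unit_attention(self):
        with pytest.raises(ValueError, match="attn_amplitude"):
            dataclasses.replace(nm.DEFAULT_PARAMS, attn_amplitude=0.5)

    def test_stimulus_contrast_bounds(self):
        with pytest.raises(ValueError, match="contrast"):
            nm.StimulusSpec(extent=1.0, contrast=1.2)

    def test_surround_consistency(self):
        with pytest.raises(ValueError, match="outer_extent"):
            nm.StimulusSpec(
                extent=2.0,
                contrast=0.5,
                surround=nm.SurroundSpec(gap=1.0, outer_extent=1.5),
            )

    def test_population_response_rejects_negative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nm.PopulationResponse(np.array([[-0.1, 0.2]]))

    def test_population_response_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            nm.PopulationResponse(np.array([[np.inf, 0.2]]))


# ---------------------------------------------------------------------------
# build_stimulus_drive
# ---------------------------------------------------------------------------

class TestStimulusDrive:
    def test_zero_contrast_gives_zero_drive(self, small_grid):
        stim = nm.StimulusSpec(extent=4.0, contrast=0.0)
        assert not nm.build_stimulus_drive(stim, small_grid).any()

    def test_indicator_definition(self):
        grid = nm.SpatialGrid(0.5 * np.arange(-40, 41, dtype=float), 0.5)
        stim = nm.StimulusSpec(extent=2.0, contrast=0.98, direction="left")
        drive = nm.build_stimulus_drive(stim, grid)
        inside = np.abs(grid.positions) <= 1.0
        assert np.all(drive[inside, 0] == 0.98)
        assert not drive[~inside, 0].any()
        assert not drive[:, 1].any()

    def test_surround_annulus_enumerated(self):
        # center bar half-width 1, gap 1 => ring occupies 2 <= |x| <= 4
        grid = nm.SpatialGrid(0.5 * np.arange(-40, 41, dtype=float), 0.5)
        stim = nm.StimulusSpec(
            extent=2.0,
            contrast=0.5,
            direction="left",
            surround=nm.SurroundSpec(gap=1.0, outer_extent=4.0, direction="left"),
        )
        drive = nm.build_stimulus_drive(stim, grid)
        for i, x in enumerate(grid.positions):
            if abs(x) <= 1.0 or 2.0 <= abs(x) <= 4.0:
                assert drive[i, 0] == 0.5, x
            else:
                assert drive[i, 0] == 0.0, x
        assert not drive[:, 1].any()

    def test_opposite_direction_surround_uses_other_channel(self, small_grid):
        stim = nm.StimulusSpec(
            extent=2.0,
            contrast=0.5,
            direction="left",
            surround=nm.SurroundSpec(gap=1.0, outer_extent=4.0, direction="right"),
        )
        drive = nm.build_stimulus_drive(stim, small_grid)
        assert drive[:, 0].any() and drive[:, 1].any()

    def test_guard_violation_names_margin(self, params):
        grid = nm.SpatialGrid.make(30.0, 0.5, guard_margin=10.0)
        stim = nm.StimulusSpec(extent=45.0, contrast=0.5)
        with pytest.raises(ValueError, match="guard"):
            nm.build_stimulus_drive(stim, grid)


# ---------------------------------------------------------------------------
# drives and response
# ---------------------------------------------------------------------------

class TestDrives:
    def test_excitatory_zero_input(self, params, small_grid):
        out = nm.excitatory_drive(small_grid.zeros(), params, small_grid)
        assert not out.any()

    def test_point_input_peak_closed_form(self, params):
        grid = nm.SpatialGrid.make(40.0, 0.25)
        image = grid.zeros()
        c = 0.7
        image[grid.n_space // 2, 0] = c
        out = nm.excitatory_drive(image, params, grid)
        expected_peak = c * grid.spacing / (params.excit_width * np.sqrt(2 * np.pi))
        assert out[:, 0].max() == pytest.approx(expected_peak, rel=1e-4)

    def test_point_input_matches_direct_summation(self, params, tiny_grid):
        image = tiny_grid.zeros()
        image[4, 0] = 0.7
        out = nm.excitatory_drive(image, params, tiny_grid)
        ref = naive_excitatory(image, params, tiny_grid)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_wider_kernel_halves_peak_conserves_sum(self, params):
        grid = nm.SpatialGrid.make(60.0, 0.25)
        image = grid.zeros()
        image[grid.n_space // 2, 0] = 1.0
        narrow = nm.excitatory_drive(image, params, grid)
        wide = nm.excitatory_drive(
            image, dataclasses.replace(params, excit_width=2 * params.excit_width), grid
        )
        assert wide[:, 0].max() == pytest.approx(narrow[:, 0].max() / 2, rel=1e-3)
        assert wide[:, 0].sum() == pytest.approx(narrow[:, 0].sum(), rel=1e-6)

    def test_conservation_per_channel(self, params):
        rng = np.random.default_rng(0)
        grid = nm.SpatialGrid.make(80.0, 0.5, guard_margin=30.0)
        image = grid.zeros()
        mid = grid.n_space // 2
        image[mid - 20 : mid + 20, 0] = rng.random(40)
        image[mid - 10 : mid + 30, 1] = rng.random(40)
        out = nm.excitatory_drive(image, params, grid)
        np.testing.assert_allclose(
            out.sum(axis=0), image.sum(axis=0), rtol=1e-6
        )

    def test_suppressive_zero(self, params, small_grid):
        assert not nm.suppressive_drive(small_grid.zeros(), params, small_grid).any()

    def test_suppressive_wider_and_lower_than_excitatory(self, params):
        grid = nm.SpatialGrid.make(120.0, 0.5)
        image = grid.zeros()
        image[grid.n_space // 2, 0] = 1.0
        E = nm.excitatory_drive(image, params, grid)
        S = nm.suppressive_drive(image, params, grid)
        assert S[:, 0].max() < E[:, 0].max()
        width_e = (E[:, 0] > E[:, 0].max() / 2).sum()
        width_s = (S[:, 0] > S[:, 0].max() / 2).sum()
        assert width_s > width_e

    def test_suppression_is_untuned(self, params, small_grid):
        one = small_grid.zeros()
        one[40:50, 0] = 0.3
        one[60:70, 1] = 0.3
        both_on_one = small_grid.zeros()
        both_on_one[40:50, 0] = 0.3
        both_on_one[60:70, 0] = 0.3
        S1 = nm.suppressive_drive(one, params, small_grid)
        S2 = nm.suppressive_drive(both_on_one, params, small_grid)
        np.testing.assert_allclose(S1, S2, atol=1e-12)

    def test_attention_identity_when_amplitude_one(self, params, small_grid):
        p = dataclasses.replace(params, attn_amplitude=1.0)
        stim = nm.StimulusSpec(extent=2.0, contrast=0.5)
        np.testing.assert_array_equal(
            nm.attention_field(stim, p, small_grid), 1.0
        )

    def test_attention_peak_at_center(self, params, small_grid):
        stim = nm.StimulusSpec(extent=2.0, contrast=0.5)
        A = nm.attention_field(stim, params, small_grid)
        center = np.argmin(np.abs(small_grid.positions))
        assert A[center, 0] == pytest.approx(params.attn_amplitude)

    def test_narrow_vs_wide_attention_pointwise(self, params, small_grid):
        stim = nm.StimulusSpec(extent=2.0, contrast=0.5)
        narrow = nm.attention_field(
            stim, dataclasses.replace(params, attn_width=3.0), small_grid
        )
        wide = nm.attention_field(
            stim, dataclasses.replace(params, attn_width=7.0), small_grid
        )
        center = np.argmin(np.abs(small_grid.positions))
        assert narrow[center, 0] == pytest.approx(wide[center, 0])
        off = np.abs(small_grid.positions) > 5.0
        assert np.all(narrow[off] < wide[off])

    def test_population_zero_excitation(self, params, tiny_grid):
        Z = tiny_grid.zeros()
        A = np.ones_like(Z)
        R = nm.population_response(Z, Z, A, params)
        assert not R.values.any()

    def test_population_reduces_to_e_over_sigma(self, params, tiny_grid):
        E = tiny_grid.zeros()
        E[3, 0] = 0.4
        A = np.ones_like(E)
        S = np.zeros_like(E)
        R = nm.population_response(E, S, A, params)
        np.testing.assert_allclose(R.values, E / params.sigma)

    def test_population_hand_instance(self, params):
        grid = nm.SpatialGrid(np.arange(-2.0, 3.0), 1.0)
        E = np.abs(np.sin(np.arange(10))).reshape(5, 2)
        S = np.abs(np.cos(np.arange(10))).reshape(5, 2)
        A = 1.0 + np.linspace(0, 1, 10).reshape(5, 2)
        R = nm.population_response(E, S, A, params)
        np.testing.assert_allclose(
            R.values, naive_population(E, S, A, params.sigma), atol=1e-12
        )

    def test_model_response_examples(self, rng):
        assert nm.model_response(nm.PopulationResponse(np.zeros((3, 2)))) == 0.0
        m = np.zeros((4, 2))
        m[2, 1] = 0.7
        assert nm.model_response(nm.PopulationResponse(m)) == 0.7
        random = rng.random((7, 2))
        assert nm.model_response(nm.PopulationResponse(random)) == naive_max(random)


# ---------------------------------------------------------------------------
# threshold prediction
# ---------------------------------------------------------------------------

class TestPrediction:
    def test_inverse_proportionality(self, params):
        t1 = nm.predict_threshold(0.25, params)
        t2 = nm.predict_threshold(0.5, params)
        assert t1 == pytest.approx(2 * t2)

    def test_arithmetic(self):
        p = dataclasses.replace(nm.DEFAULT_PARAMS, scale_k=50.0)
        assert nm.predict_threshold(0.5, p) == pytest.approx(100.0)

    def test_zero_response_raises_or_inf(self, params):
        with pytest.raises(nm.NoResponseError):
            nm.predict_threshold(0.0, params)
        assert nm.predict_threshold(0.0, params, infinite_ok=True) == np.inf

    def test_surround_suppression_at_high_contrast(self, params):
        """Largest high-contrast stimulus needs a longer duration than the smallest."""
        grid = grid_for(params)
        small = nm.predict_stimulus_threshold(
            nm.StimulusSpec(extent=params.au(SIZES[0]), contrast=HIGH), params, grid
        )
        large = nm.predict_stimulus_threshold(
            nm.StimulusSpec(extent=params.au(SIZES[-1]), contrast=HIGH), params, grid
        )
        assert large > small

    def test_condition_grid_shape(self, params):
        table = nm.predict_condition_grid(params)
        assert set(table) == {(s, c) for s in SIZES for c in nm.DEFAULT_CONTRASTS}
        assert all(v > 0 for v in table.values())

    def test_narrow_excitation_helps_small_not_large(self, params):
        narrow = nm.predict_condition_grid(
            dataclasses.replace(params, excit_width=3.0)
        )
        wide = nm.predict_condition_grid(
            dataclasses.replace(params, excit_width=4.5)
        )
        d_small = wide[(SIZES[0], LOW)] - narrow[(SIZES[0], LOW)]
        d_large = wide[(SIZES[-1], LOW)] - narrow[(SIZES[-1], LOW)]
        assert d_small > 0
        assert abs(d_large) < 0.1 * d_small

    def test_narrow_attention_helps_large_more_than_small(self, params):
        narrow = nm.predict_condition_grid(
            dataclasses.replace(params, attn_width=3.0)
        )
        wide = nm.predict_condition_grid(
            dataclasses.replace(params, attn_width=7.0)
        )
        d_small = wide[(SIZES[0], LOW)] - narrow[(SIZES[0], LOW)]
        d_large = wide[(SIZES[-1], LOW)] - narrow[(SIZES[-1], LOW)]
        assert d_large > 0
        assert d_large > d_small

    def test_contrast_never_hurts_at_smallest_size(self, params):
        grid = grid_for(params)
        stim = lambda c: nm.StimulusSpec(extent=params.au(SIZES[0]), contrast=c)
        prev = np.inf
        for c in (0.03, 0.1, 0.3, 0.6, 0.98):
            t = nm.predict_stimulus_threshold(stim(c), params, grid)
            assert t <= prev * (1 + 1e-9)
            prev = t

    def test_grid_convergence_under_refinement(self, params):
        coarse = nm.predict_condition_grid(params)
        fine_grid = grid_for(params, spacing=params.excit_width / 128.0)
        for (size, con), t_coarse in coarse.items():
            t_fine = nm.predict_stimulus_threshold(
                nm.StimulusSpec(extent=params.au(size), contrast=con),
                params,
                fine_grid,
            )
            assert abs(t_fine - t_coarse) / t_coarse < 0.01


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

class TestProperties:
    @settings(max_examples=25, deadline=None)
    @given(
        extent=st.floats(0.5, 10.0),
        contrast=st.floats(0.01, 1.0),
        center=st.floats(-3.0, 3.0),
    )
    def test_response_nonnegative(self, extent, contrast, center):
        params = nm.DEFAULT_PARAMS
        stim = nm.StimulusSpec(extent=extent, contrast=contrast, center=center)
        grid = nm.default_grid(params, [stim], spacing=0.5)
        D = nm.build_stimulus_drive(stim, grid)
        E = nm.excitatory_drive(D, params, grid)
        A = nm.attention_field(stim, params, grid)
        S = nm.suppressive_drive(A * E, params, grid)
        R = nm.population_response(E, S, A, params)
        assert np.all(R.values >= 0)

    def test_all_stages_match_oracle_on_tiny_grid(self, params, tiny_grid, rng):
        image = rng.random((tiny_grid.n_space, 2)) * 0.5
        E = nm.excitatory_drive(image, params, tiny_grid)
        np.testing.assert_allclose(
            E, naive_excitatory(image, params, tiny_grid), atol=1e-9
        )
        S = nm.suppressive_drive(E, params, tiny_grid)
        np.testing.assert_allclose(
            S, naive_suppressive(E, params, tiny_grid), atol=1e-9
        )
        stim = nm.StimulusSpec(extent=2.0, contrast=0.5, center=0.5)
        A = nm.attention_field(stim, params, tiny_grid)
        np.testing.assert_allclose(
            A, naive_attention(0.5, params, tiny_grid), atol=1e-12
        )
        R = nm.population_response(E, S, A, params)
        np.testing.assert_allclose(
            R.values, naive_population(E, S, A, params.sigma), atol=1e-9
        )
        assert nm.model_response(R) == pytest.approx(naive_max(R.values), abs=1e-12)

    def test_convolution_oracle_multiple_widths(self, tiny_grid, rng):
        image = rng.random((tiny_grid.n_space, 2))
        for sd in (0.7, 1.5, 4.0):
            ref = naive_gaussian_convolve(image, sd, tiny_grid.positions, 1.0)
            params = nm.ModelParams(excit_width=sd, suppress_width=sd * 2)
            out = nm.excitatory_drive(image, params, tiny_grid)
            np.testing.assert_allclose(out, ref, atol=1e-9)
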