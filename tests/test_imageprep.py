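"""Illumination correction, median filtering, and round registration."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from oracles import brute_median_filter
from scmst.errors import InsufficientDataError, ValidationError
from scmst.imageprep import (
    FlatField,
    correct_illumination,
    estimate_flatfield,
    median_filter_3d,
    register_rounds,
    translate,
)
from scmst.synth import _quadratic_field


class TestFlatField:
    def test_constant_planes_give_flat_field(self):
        rng = np.random.default_rng(0)
        planes = rng.normal(500, 10, (20, 48, 48))
        ff = estimate_flatfield(planes)
        assert np.abs(ff.flatfield - 1).max() < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_quadratic_field_recovered(self, seed):
        rng = np.random.default_rng(seed)
        field = _quadratic_field((64, 64), 0.3, rng)
        planes = np.abs(rng.normal(100, 20, (20, 64, 64))) * field
        ff = estimate_flatfield(planes)
        est = ff.flatfield / ff.flatfield.mean()
        tru = field / field.mean()
        rms = np.sqrt(np.mean((est - tru) ** 2))
        assert rms < 0.05

    def test_single_plane_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_flatfield(np.ones((1, 16, 16)))

    def test_flatfield_invariants_enforced(self):
        with pytest.raises(ValidationError):
            FlatField(np.full((8, 8), 2.0))          # mean != 1
        with pytest.raises(ValidationError):
            FlatField(np.zeros((8, 8)))              # nonpositive

    def test_simulator_stack_corrected_by_its_own_field(self):
        from scmst.synth import default_config, simulate_section

        cfg = default_config(seed=3, n_rounds=1, channels_per_round=2,
                             gene_panel=["A", "B"], round_shifts=[(0, 0, 0)])
        images, gt = simulate_section(cfg)
        vol = images.stacks[0][0][0]
        ff = FlatField.from_unnormalized(gt.applied_flatfields[(0, 0)])
        corr = correct_illumination(vol, ff)
        # residual shading: column means flat relative to the raw image
        raw_prof = vol.mean(axis=(0, 1))
        corr_prof = corr.mean(axis=(0, 1))
        assert np.std(corr_prof) < 0.5 * np.std(raw_prof)


class TestCorrectIllumination:
    def test_identity_field(self):
        vol = np.random.default_rng(1).uniform(0, 100, (4, 8, 8))
        out = correct_illumination(vol, FlatField(np.ones((8, 8))))
        assert np.array_equal(out, vol)

    def test_division_arithmetic(self):
        field = np.ones((8, 8))
        field[3, 4] = 2.0
        field /= field.mean()
        ff = FlatField(field)
        out = correct_illumination(np.full((2, 8, 8), 100.0), ff)
        assert np.isclose(out[0, 3, 4], 100.0 / field[3, 4])

    def test_nonpositive_field_rejected(self):
        ff = FlatField(np.ones((4, 4)))
        ff.flatfield = ff.flatfield.copy()
        ff.flatfield[0, 0] = -1.0   # corrupt after construction
        with pytest.raises(ValidationError):
            correct_illumination(np.ones((2, 4, 4)), ff)


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = np.full((6, 6, 6), 7.0)
        assert np.array_equal(median_filter_3d(vol), vol)

    def test_isolated_hot_voxel_removed(self):
        vol = np.zeros((7, 7, 7))
        vol[3, 3, 3] = 100.0
        assert median_filter_3d(vol).max() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        vol = np.random.default_rng(seed).uniform(0, 100, (8, 8, 8))
        assert np.array_equal(median_filter_3d(vol), brute_median_filter(vol))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            median_filter_3d(np.zeros((4, 4, 4)), kernel=2)

    def test_idempotent_on_piecewise_constant(self):
        vol = np.zeros((10, 10, 10))
        vol[:, :, 5:] = 50.0   # two half-space regions, larger than kernel
        once = median_filter_3d(vol)
        assert np.array_equal(median_filter_3d(once), once)


class TestRegistration:
    def _structured(self, seed, shape=(20, 48, 48)):
        rng = np.random.default_rng(seed)
        return ndi.gaussian_filter(rng.normal(0, 1, shape), 1.5)

    def test_self_registration_zero_shift_unit_score(self):
        ref = self._structured(0)
        rs = register_rounds(ref, ref, max_shift=5)
        assert rs.shift == (0, 0, 0)
        assert abs(rs.score - 1.0) < 1e-9

    @pytest.mark.parametrize("shift", [(2, -3, 1), (0, 4, -4), (-1, 0, 5)])
    def test_planted_roll_recovered_exactly(self, shift):
        ref = self._structured(1)
        mov = np.roll(ref, shift, axis=(0, 1, 2))
        rs = register_rounds(ref, mov, max_shift=6)
        assert rs.shift == shift

    def test_antisymmetry_of_planted_shifts(self):
        ref = self._structured(2)
        mov = np.roll(ref, (1, -2, 3), axis=(0, 1, 2))
        fwd = register_rounds(ref, mov, max_shift=5)
        rev = register_rounds(mov, ref, max_shift=5)
        assert tuple(-s for s in fwd.shift) == rev.shift

    def test_noise_flagged_low_confidence(self):
        ref = self._structured(3)
        noise = np.random.default_rng(4).normal(0, 1, ref.shape)
        with pytest.warns(UserWarning, match="low-confidence"):
            rs = register_rounds(ref, noise, max_shift=4)
        assert rs.low_confidence
        assert rs.score < 0.2

    def test_excessive_max_shift_rejected(self):
        ref = np.zeros((10, 40, 40))
        with pytest.raises(ValidationError):
            register_rounds(ref, ref, max_shift=5)   # 2*5 >= z dim


class TestTranslate:
    def test_round_trip_preserves_interior(self):
        vol = np.random.default_rng(5).uniform(0, 1, (8, 12, 12))
        shift = (1, -2, 3)
        back = translate(translate(vol, shift), tuple(-s for s in shift))
        sl = tuple(
            slice(abs(s), n - abs(s)) for s, n in zip(shift, vol.shape)
        )
        assert np.array_equal(back[sl], vol[sl])

    def test_fill_value(self):
        vol = np.ones((4, 4, 4))
        out = translate(vol, (1, 0, 0), fill=-7.0)
        assert (out[0] == -7.0).all()
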