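import numpy as np
import pytest

import melanophot as mp
from melanophot.exceptions import DegenerateSystemError, GamutError, ValidationError
from melanophot.metamer import (
    CONE_TAGS,
    STUDY_SUBSET_HM,
    STUDY_SUBSET_LM,
    mixture_spectrum,
    receptor_matrix,
)
from melanophot.observer import ActionSpectra

from conftest import cofactor_inverse_3x3, random_toy_device


def _line_values(wavelength, value=1.0):
    vals = np.zeros(mp.CANONICAL_GRID.size)
    vals[mp.CANONICAL_GRID == wavelength] = value
    return vals


def _toy_observer():
    """Disjoint-line toy observer making the metamer system hand-solvable.

    sc/mc/lc are single lines at 430/550/630 nm; melanopsin sees 430 nm at
    half weight and 480 nm at full weight.
    """
    grid = mp.CANONICAL_GRID
    s_alpha = {
        "sc": _line_values(430.0),
        "mc": _line_values(550.0),
        "lc": _line_values(630.0),
        "rh": _line_values(507.0),
        "mel": _line_values(430.0, 0.5) + _line_values(480.0, 1.0),
    }
    return ActionSpectra(
        wavelengths_nm=grid,
        s_alpha=s_alpha,
        vlambda=_line_values(555.0),
        d65=np.ones(grid.size),
    )


def _toy_device():
    """p1=430 line, p2=mixed 430+480 LED, p3=550 line, p4=630 line."""
    mk = lambda vals, lab: mp.Spectrum(mp.CANONICAL_GRID, vals, label=lab)
    prims = (
        mk(_line_values(430.0), "p430"),
        mk(_line_values(430.0, 0.5) + _line_values(480.0, 0.5), "p430+480"),
        mk(_line_values(550.0), "p550"),
        mk(_line_values(630.0), "p630"),
    )
    return mp.MultiprimaryDevice(prims, ("p430", "p430+480", "p550", "p630"))


class TestReceptorMatrix:
    def test_shape_for_five_led_device(self, device, obs):
        m = receptor_matrix(device, CONE_TAGS, obs)
        assert m.shape == (3, 5)

    def test_single_line_primary_column(self, obs):
        prim = mp.Spectrum(mp.CANONICAL_GRID, _line_values(555.0))
        dev = mp.MultiprimaryDevice((prim,), ("l555",))
        m = receptor_matrix(dev, mp.RECEPTORS, obs)
        expected = [
            mp.alpha_opic_irradiance(prim, t, obs) for t in mp.RECEPTORS
        ]
        assert m[:, 0] == pytest.approx(expected)

    def test_doubling_a_primary_doubles_its_column(self, device, obs):
        doubled = mp.MultiprimaryDevice(
            (mp.scale(device.primaries[0], 2.0),) + device.primaries[1:],
            device.labels,
        )
        m1 = receptor_matrix(device, CONE_TAGS, obs)
        m2 = receptor_matrix(doubled, CONE_TAGS, obs)
        assert m2[:, 0] == pytest.approx(2.0 * m1[:, 0], rel=1e-12)
        assert m2[:, 1:] == pytest.approx(m1[:, 1:], rel=1e-12)

    def test_empty_device_rejected(self):
        with pytest.raises(ValidationError):
            mp.MultiprimaryDevice((), ())


class TestSolveWeights:
    def test_self_consistency_half_drive(self, device, obs):
        m = receptor_matrix(device, CONE_TAGS, obs)[:, [0, 2, 4]]
        target = m @ np.full(3, 0.5)
        w = mp.solve_weights(device, (0, 2, 4), target, obs)
        assert w[[0, 2, 4]] == pytest.approx([0.5, 0.5, 0.5], rel=1e-12)
        assert w[[1, 3]] == pytest.approx([0.0, 0.0])

    def test_zero_target_gives_zero_weights(self, device, obs):
        w = mp.solve_weights(device, (0, 1, 2), np.zeros(3), obs)
        assert not np.any(w)

    def test_matches_explicit_inverse_oracle(self, obs):
        rng = np.random.default_rng(7)
        for _ in range(100):
            dev = random_toy_device(rng)
            m = receptor_matrix(dev, CONE_TAGS, obs)
            if np.linalg.cond(m) > 1e9:
                continue
            w_true = rng.uniform(0.05, 0.95, size=3)
            target = m @ w_true
            w = mp.solve_weights(dev, (0, 1, 2), target, obs)
            w_oracle = cofactor_inverse_3x3(m) @ target
            assert w[:3] == pytest.approx(w_oracle, rel=1e-9, abs=1e-12)

    def test_gamut_error_names_the_primary(self, device, obs):
        m = receptor_matrix(device, CONE_TAGS, obs)[:, [0, 2, 4]]
        target = m @ np.array([1.5, 0.5, 0.5])  # needs >1 drive on 430 nm
        with pytest.raises(GamutError) as exc:
            mp.solve_weights(device, (0, 2, 4), target, obs)
        assert exc.value.primary == "430nm"

    def test_singular_subset_is_degenerate(self, obs):
        prim = mp.gaussian_primary(500.0, 30.0)
        dev = mp.MultiprimaryDevice((prim, prim, prim), ("a", "b", "c"))
        with pytest.raises(DegenerateSystemError):
            mp.solve_weights(dev, (0, 1, 2), np.ones(3), obs)


class TestMetamerPair:
    def test_identical_subsets_zero_contrast(self, device, obs):
        m = receptor_matrix(device, CONE_TAGS, obs)[:, [0, 2, 4]]
        target = m @ np.full(3, 0.4)
        pair = mp.design_metamer_pair(device, (0, 2, 4), (0, 2, 4), target, obs)
        assert pair.contrast_mel == 0.0
        assert pair.cone_residual <= 1e-9

    def test_hand_engineered_200_percent_pair(self):
        """Toy lines give an analytic 200% melanopsin contrast.

        LM subset (p430, p550, p630) at target (0.25, 0.5, 0.5)·k solves to
        weights (0.25, 0.5, 0.5) and melanopic content 0.5·0.25; the HM
        subset replaces p430 with the half-430/half-480 LED, forcing weight
        0.5 and melanopic content 0.5·0.25 + 1.0·0.25 = 3× the LM value.
        """
        toy_obs = _toy_observer()
        dev = _toy_device()
        k = 1000.0  # mW scaling of the α-opic sums, Δλ = 1
        target = np.array([0.25, 0.5, 0.5]) * k
        pair = mp.design_metamer_pair(dev, (0, 2, 3), (1, 2, 3), target,
                                      toy_obs)
        assert pair.weights_lm == pytest.approx([0.25, 0, 0.5, 0.5])
        assert pair.weights_hm == pytest.approx([0, 0.5, 0.5, 0.5])
        assert pair.contrast_mel == pytest.approx(200.0, abs=1e-9)
        assert pair.cone_residual <= 1e-9

    def test_study_subsets_on_gaussian_device(self, device, obs):
        pair = mp.maximize_melanopsin_contrast(device)
        assert pair.cone_residual <= 1e-9
        assert 200.0 <= pair.contrast_mel <= 300.0

    def test_binding_primary_saturates_and_matches_grid_oracle(self, device, obs):
        pair = mp.maximize_melanopsin_contrast(device)
        top = max(pair.weights_lm.max(), pair.weights_hm.max())
        assert top == pytest.approx(1.0, abs=1e-9)
        # 1-D grid-search oracle over the target scale: contrast must be
        # scale-invariant and the feasibility edge must match
        m = receptor_matrix(device, CONE_TAGS, obs)
        d65 = mp.Spectrum(obs.wavelengths_nm, obs.d65)
        direction = np.array(
            [mp.alpha_opic_irradiance(d65, t, obs) for t in CONE_TAGS]
        )
        direction /= np.linalg.norm(direction)
        contrasts, feasible_scales = [], []
        for c in np.linspace(0.01, 2.0, 80):
            try:
                p = mp.design_metamer_pair(
                    device, STUDY_SUBSET_LM, STUDY_SUBSET_HM, c * direction,
                    obs,
                )
            except GamutError:
                continue
            contrasts.append(p.contrast_mel)
            feasible_scales.append(c)
        assert np.ptp(contrasts) < 1e-6  # ratio invariance along the gamut
        assert contrasts[0] == pytest.approx(pair.contrast_mel, rel=1e-9)

    def test_luminance_target_beyond_gamut_raises(self, device):
        with pytest.raises(GamutError):
            mp.maximize_melanopsin_contrast(device, luminance_target=1e9)


class TestContrast:
    @pytest.mark.parametrize(
        "e_hm,e_lm,expected",
        [(20.11, 4.91, 310), (43.51, 11.70, 272),
         (93.27, 27.46, 240), (193.62, 64.17, 202)],
    )
    def test_published_condition_pairs(self, e_hm, e_lm, expected):
        assert round(mp.melanopsin_contrast(e_hm, e_lm)) == expected

    def test_equal_inputs_zero(self):
        assert mp.melanopsin_contrast(5.0, 5.0) == 0.0

    def test_unit_invariance(self):
        k = mp.observer.K_ALPHA_D65["mel"]
        irr = mp.melanopsin_contrast(20.11, 4.91)
        edi = mp.melanopsin_contrast(20.11 / k, 4.91 / k)
        assert irr == pytest.approx(edi, rel=1e-12)

    def test_zero_lm_is_error(self):
        with pytest.raises(ValidationError):
            mp.melanopsin_contrast(1.0, 0.0)
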