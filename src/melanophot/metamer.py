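"""Silent-substitution metamer design for a multiprimary display.

Photoreceptor univariance makes receptor responses linear in the primary
drive weights, so a pair of lights matched for the three cone classes but
differing maximally for melanopsin reduces to linear algebra: for each
condition a 3×3 solve of cone-opic irradiance against a 3-primary subset,
followed by a scan of the common cone target along the device gamut.

The study design this reproduces: a five-LED display (dominant
wavelengths 430/480/500/550/630 nm) driven as two 3-primary subsets —
480/500/630 for the high-melanopic (HM) condition, 430/550/630 for the
low-melanopic (LM) condition — giving cone-matched pairs with a 2–3×
melanopsin contrast.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aopic import AlphaOpicQuantities, alpha_opic_irradiance, full_report
from .exceptions import DegenerateSystemError, GamutError, ValidationError
from .observer import ActionSpectra, default_observer
from .spd import CANONICAL_GRID, Spectrum, add, scale

__all__ = [
    "MultiprimaryDevice",
    "MetamerPair",
    "gaussian_primary",
    "example_device",
    "receptor_matrix",
    "solve_weights",
    "mixture_spectrum",
    "design_metamer_pair",
    "maximize_melanopsin_contrast",
    "melanopsin_contrast",
]

CONE_TAGS = ("sc", "mc", "lc")

#: dominant wavelengths of the study display's five LED types, nm
STUDY_PEAKS_NM = (430.0, 480.0, 500.0, 550.0, 630.0)
#: primary subsets used for the low-/high-melanopic conditions
STUDY_SUBSET_LM = (0, 3, 4)  # 430, 550, 630 nm
STUDY_SUBSET_HM = (1, 2, 4)  # 480, 500, 630 nm


@dataclass(frozen=True)
class MultiprimaryDevice:
    """Primary spectra at full drive; drive range is [0, 1] per primary."""

    primaries: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.primaries) == 0:
            raise ValidationError("device needs at least one primary")
        if len(self.labels) != len(self.primaries):
            raise ValidationError("one label per primary required")

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)


@dataclass(frozen=True)
class MetamerPair:
    """A solved cone-matched LM/HM pair with its achieved quantities."""

    weights_lm: np.ndarray
    weights_hm: np.ndarray
    achieved_lm: AlphaOpicQuantities
    achieved_hm: AlphaOpicQuantities
    contrast_mel: float  # (E_mel,HM - E_mel,LM)/E_mel,LM × 100, %
    cone_residual: float  # max relative cone mismatch over sc, mc, lc
    binding_primary: str | None = None  # gamut-limiting primary, if scanned


def gaussian_primary(peak_nm: float, fwhm_nm: float,
                     peak_value: float = 1.0e-2,
                     grid=CANONICAL_GRID, label: str | None = None) -> Spectrum:
    """Gaussian LED model: peak spectral irradiance at ``peak_nm`` with the
    given full width at half maximum.  Used where measured primary spectra
    are unavailable."""
    if fwhm_nm <= 0 or peak_value < 0:
        raise ValidationError("fwhm and peak value must be positive")
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = peak_value * np.exp(-0.5 * ((np.asarray(grid) - peak_nm) / sigma) ** 2)
    return Spectrum(grid, vals, quantity="irradiance",
                    label=label or f"LED {peak_nm:g} nm")


def example_device(fwhm_nm: float = 25.0,
                   peak_value: float = 1.0e-2) -> MultiprimaryDevice:
    """Five-LED Gaussian model of the study display (430–630 nm peaks)."""
    prims = tuple(
        gaussian_primary(p, fwhm_nm, peak_value) for p in STUDY_PEAKS_NM
    )
    labels = tuple(f"{int(p)}nm" for p in STUDY_PEAKS_NM)
    return MultiprimaryDevice(primaries=prims, labels=labels)


def receptor_matrix(device: MultiprimaryDevice, receptors=CONE_TAGS,
                    observer: ActionSpectra | None = None) -> np.ndarray:
    """Matrix [r, p] of receptor r's α-opic irradiance for primary p at
    full drive; a mixture's responses are ``matrix @ weights``."""
    obs = observer or default_observer()
    return np.array(
        [
            [alpha_opic_irradiance(p, r, obs) for p in device.primaries]
            for r in receptors
        ]
    )


def solve_weights(device: MultiprimaryDevice, subset, target,
                  observer: ActionSpectra | None = None,
                  rtol: float = 1e-9, gamut_slack: float = 1e-12) -> np.ndarray:
    """Drive weights on a 3-primary subset reproducing a cone-opic target.

    Returns a full-length weight vector (zeros off-subset).  Raises
    :class:`DegenerateSystemError` for a singular subset and
    :class:`GamutError` (naming the primary) for weights outside [0, 1].
    """
    subset = tuple(subset)
    target = np.asarray(target, dtype=float)
    if len(subset) != 3 or target.shape != (3,):
        raise ValidationError("need exactly 3 primaries and 3 cone targets")
    if np.any(target < 0):
        raise ValidationError("cone-opic targets must be >= 0")
    obs = observer or default_observer()
    m = receptor_matrix(device, CONE_TAGS, obs)[:, subset]
    if np.linalg.cond(m) > 1e12:
        raise DegenerateSystemError("cone/primary subsystem is singular")
    w_sub = np.linalg.solve(m, target)
    resid = np.abs(m @ w_sub - target)
    denom = np.maximum(np.abs(target), 1e-300)
    if np.any(target > 0) and np.max(resid / denom) > rtol:
        raise DegenerateSystemError("linear solve failed the residual check")
    for i, w in zip(subset, w_sub):
        if w < -gamut_slack or w > 1.0 + gamut_slack:
            raise GamutError(
                f"primary {device.labels[i]} requires drive {w:.6g} "
                "outside [0, 1]",
                primary=device.labels[i],
            )
    weights = np.zeros(device.n_primaries)
    weights[list(subset)] = np.clip(w_sub, 0.0, 1.0)
    return weights


def mixture_spectrum(device: MultiprimaryDevice, weights) -> Spectrum:
    """Weighted sum of the primaries at the given drive fractions."""
    weights = np.asarray(weights, dtype=float)
    mix = scale(device.primaries[0], float(weights[0]))
    for p, w in zip(device.primaries[1:], weights[1:]):
        mix = add(mix, scale(p, float(w)))
    return mix


def _pair_from_weights(device, w_lm, w_hm, obs, binding=None) -> MetamerPair:
    rep_lm = full_report(mixture_spectrum(device, w_lm), observer=obs)
    rep_hm = full_report(mixture_spectrum(device, w_hm), observer=obs)
    resid = 0.0
    for t in CONE_TAGS:
        a, b = rep_lm.e_alpha[t], rep_hm.e_alpha[t]
        if max(abs(a), abs(b)) > 0:
            resid = max(resid, abs(a - b) / max(abs(a), abs(b)))
    contrast = melanopsin_contrast(rep_hm.e_alpha["mel"], rep_lm.e_alpha["mel"])
    return MetamerPair(
        weights_lm=w_lm, weights_hm=w_hm,
        achieved_lm=rep_lm, achieved_hm=rep_hm,
        contrast_mel=contrast, cone_residual=resid, binding_primary=binding,
    )


def design_metamer_pair(device: MultiprimaryDevice, subset_lm, subset_hm,
                        target_cones,
                        observer: ActionSpectra | None = None) -> MetamerPair:
    """Solve both conditions against one cone-opic target (sc, mc, lc)."""
    obs = observer or default_observer()
    w_lm = solve_weights(device, subset_lm, target_cones, obs)
    w_hm = solve_weights(device, subset_hm, target_cones, obs)
    return _pair_from_weights(device, w_lm, w_hm, obs)


def maximize_melanopsin_contrast(
    device: MultiprimaryDevice,
    subset_lm=STUDY_SUBSET_LM,
    subset_hm=STUDY_SUBSET_HM,
    luminance_target: float | None = None,
    cone_direction=None,
    observer: ActionSpectra | None = None,
) -> MetamerPair:
    """Scale the common cone target along the device gamut.

    Melanopsin contrast is invariant to a common rescaling of both
    conditions, so for fixed subsets the contrast is set by the cone-target
    *direction* (default: the cone coordinates of a D65-shaped white, the
    natural chromaticity for a display).  This routine solves both subsets
    for that direction and returns the pair at the largest feasible scale
    — all weights in [0, 1], the binding primary reported — or, when
    ``luminance_target`` (cd·m⁻²-equivalent photopic content of the LM
    mixture in lx here, see note) is given, at that photometric level.
    """
    obs = observer or default_observer()
    if cone_direction is None:
        d65 = Spectrum(obs.wavelengths_nm, obs.d65, quantity="irradiance",
                       label="D65")
        cone_direction = np.array(
            [alpha_opic_irradiance(d65, t, obs) for t in CONE_TAGS]
        )
    cone_direction = np.asarray(cone_direction, dtype=float)
    if np.any(cone_direction < 0) or not np.any(cone_direction > 0):
        raise ValidationError("cone direction must be nonnegative, nonzero")
    unit = cone_direction / np.linalg.norm(cone_direction)

    # weights are linear in the target: solve once at the unit target with
    # the gamut check disabled, then scale to the feasibility boundary
    w_lm = _solve_unbounded(device, subset_lm, unit, obs)
    w_hm = _solve_unbounded(device, subset_hm, unit, obs)
    if np.any(w_lm < -1e-12) or np.any(w_hm < -1e-12):
        raise GamutError("cone direction unreachable with nonnegative drives")
    peak = max(w_lm.max(), w_hm.max())
    if peak <= 0:
        raise DegenerateSystemError("zero target direction")
    c_max = 1.0 / peak

    if luminance_target is not None:
        from .aopic import photopic_illuminance

        level = photopic_illuminance(
            mixture_spectrum(device, w_lm), obs
        )
        if level <= 0:
            raise DegenerateSystemError("LM mixture has zero luminous content")
        c = luminance_target / level
        if c > c_max * (1.0 + 1e-12):
            raise GamutError(
                f"luminance target needs scale {c:.4g} beyond gamut "
                f"limit {c_max:.4g}"
            )
    else:
        c = c_max

    all_w = np.concatenate([w_lm, w_hm])
    binding_idx = int(np.argmax(all_w))
    labels = device.labels + device.labels
    binding = labels[binding_idx % device.n_primaries]
    return _pair_from_weights(
        device, np.clip(c * w_lm, 0, 1), np.clip(c * w_hm, 0, 1), obs,
        binding=binding,
    )


def _solve_unbounded(device, subset, target, obs) -> np.ndarray:
    subset = tuple(subset)
    m = receptor_matrix(device, CONE_TAGS, obs)[:, subset]
    if np.linalg.cond(m) > 1e12:
        raise DegenerateSystemError("cone/primary subsystem is singular")
    w_sub = np.linalg.solve(m, np.asarray(target, dtype=float))
    weights = np.zeros(device.n_primaries)
    weights[list(subset)] = w_sub
    return weights


def melanopsin_contrast(e_hm: float, e_lm: float) -> float:
    """Michelson-free melanopsin contrast (E_HM − E_LM)/E_LM × 100, %.

    Unit-invariant: identical whether both inputs are melanopic
    irradiances (mW·m⁻²) or melanopic EDIs (lx)."""
    if e_lm == 0:
        raise ValidationError("contrast undefined for zero LM input")
    return (e_hm - e_lm) / e_lm * 100.0
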