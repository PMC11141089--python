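"""Retinal dose: conventional and α-opic trolands.

Retinal irradiance cannot be measured directly in behaving observers; the
conventional proxy is the troland, luminance (cd·m⁻²) × pupil area (mm²).
The α-opic generalization used here weights the source's spectral
*radiance* by a photoreceptor sensitivity and multiplies by pupil area:

    Td_α = [α-opic radiance, mW·m⁻²·sr⁻¹] × [pupil area, mm²]

The absolute unit convention of an "α-opic troland" is not standardized;
only relative comparisons (correlations and regressions on log dose) are
used downstream, where the convention cancels.  For a uniform extended
source the radiance may be derived from a corneal irradiance as
L(λ) = E(λ)/Ω with the source's solid angle Ω (a helper computes Ω for a
flat screen from its width, height and viewing distance).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .aopic import photopic_luminance
from .exceptions import UnitError, ValidationError
from .observer import RECEPTORS, ActionSpectra, default_observer
from .spd import Spectrum

__all__ = [
    "RetinalDose",
    "conventional_trolands",
    "alpha_opic_radiance",
    "alpha_opic_trolands",
    "retinal_dose_report",
    "irradiance_to_radiance",
    "screen_solid_angle",
    "log10_dose",
]


def conventional_trolands(luminance_cd_m2: float, area_mm2: float) -> float:
    """Conventional retinal illuminance: luminance × pupil area, Td."""
    if luminance_cd_m2 < 0 or area_mm2 < 0:
        raise ValidationError("luminance and pupil area must be >= 0")
    return luminance_cd_m2 * area_mm2


def irradiance_to_radiance(s: Spectrum, solid_angle_sr: float) -> Spectrum:
    """Corneal irradiance of a uniform extended source -> its radiance."""
    s.require_quantity("irradiance")
    if solid_angle_sr <= 0:
        raise ValidationError("solid angle must be positive")
    return replace(s, values=s.values / solid_angle_sr, quantity="radiance")


def screen_solid_angle(width_m: float, height_m: float,
                       distance_m: float) -> float:
    """Small-angle solid angle of a flat screen: width × height / distance²."""
    if min(width_m, height_m, distance_m) <= 0:
        raise ValidationError("screen dimensions and distance must be positive")
    return width_m * height_m / distance_m**2


def alpha_opic_radiance(s: Spectrum, alpha: str,
                        observer: ActionSpectra | None = None) -> float:
    """α-opic radiance of a radiance spectrum, mW·m⁻²·sr⁻¹."""
    s.require_quantity("radiance")
    obs = observer or default_observer()
    # same kernel as the irradiance case, per steradian
    as_irr = replace(s, quantity="irradiance")
    from .aopic import alpha_opic_irradiance

    return alpha_opic_irradiance(as_irr, alpha, obs)


def alpha_opic_trolands(s: Spectrum, alpha: str, area_mm2: float,
                        solid_angle_sr: float | None = None,
                        observer: ActionSpectra | None = None) -> float:
    """α-opic retinal irradiance: α-opic radiance × pupil area.

    ``s`` is either a radiance spectrum, or a corneal irradiance spectrum
    together with the source solid angle (uniform extended source).
    """
    if area_mm2 < 0:
        raise ValidationError("pupil area must be >= 0")
    if s.quantity == "irradiance":
        if solid_angle_sr is None:
            raise UnitError(
                "irradiance input needs solid_angle_sr to derive radiance"
            )
        s = irradiance_to_radiance(s, solid_angle_sr)
    return alpha_opic_radiance(s, alpha, observer) * area_mm2


@dataclass(frozen=True)
class RetinalDose:
    """Conventional and α-opic trolands for one spectrum + pupil."""

    trolands_conventional: float
    trolands_alpha: dict
    pupil_area_mm2: float
    luminance_cd_m2: float

    def to_dict(self) -> dict:
        out = {
            "trolands_conventional_Td": self.trolands_conventional,
            "pupil_area_mm2": self.pupil_area_mm2,
            "luminance_cd_m2": self.luminance_cd_m2,
        }
        for tag in RECEPTORS:
            out[f"Td_{tag}"] = self.trolands_alpha[tag]
        return out


def retinal_dose_report(s: Spectrum, pupil_diameter_mm: float,
                        solid_angle_sr: float | None = None,
                        observer: ActionSpectra | None = None) -> RetinalDose:
    """Full troland report from a spectrum and a pupil diameter."""
    from .pupil import diameter_to_area

    area = diameter_to_area(pupil_diameter_mm)
    if s.quantity == "irradiance":
        if solid_angle_sr is None:
            raise UnitError(
                "irradiance input needs solid_angle_sr to derive radiance"
            )
        s = irradiance_to_radiance(s, solid_angle_sr)
    obs = observer or default_observer()
    lum = photopic_luminance(s, obs)
    td_alpha = {
        tag: alpha_opic_radiance(s, tag, obs) * area for tag in RECEPTORS
    }
    return RetinalDose(
        trolands_conventional=conventional_trolands(lum, area),
        trolands_alpha=td_alpha,
        pupil_area_mm2=area,
        luminance_cd_m2=lum,
    )


def log10_dose(x) -> float:
    """Base-10 log of a strictly positive dose; nonpositive input is a
    hard error, never silently dropped or offset."""
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError("log10 dose requires strictly positive values")
    out = np.log10(arr)
    return float(out) if out.ndim == 0 else out
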