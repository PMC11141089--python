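"""α-opic photometry: irradiances, illuminance, EDIs and efficacy ratios.

An α-opic irradiance weights a corneal spectral irradiance by one
photoreceptor's sensitivity s\\ :sub:`α`\\ (λ).  The equivalent daylight
illuminance (EDI) re-expresses it as the photopic illuminance of a D65
spectrum producing the same α-opic irradiance:

    EDI_α = E_α / K_α,   K_α = E_α(D65) / illuminance(D65)  (mW·lm⁻¹)

Two bases for K_α are available.  ``basis="published"`` (default for
scalar conversion) uses the standard's printed daylight efficacy
constants, exact to the convention used by screening tools in this field.
``basis="tables"`` derives K_α from the packaged observer tables, which
keeps a full spectral report internally consistent to machine precision
(a D65-shaped input yields EDI_α ≡ illuminance for every α) at the cost
of the reconstruction's few-percent model error in the cone channels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .observer import (
    K_ALPHA_D65,
    KM_LM_PER_W,
    RECEPTORS,
    ActionSpectra,
    default_observer,
)
from .spd import Spectrum, resample

__all__ = [
    "AlphaOpicQuantities",
    "alpha_opic_irradiance",
    "photopic_illuminance",
    "photopic_luminance",
    "d65_efficacy",
    "alpha_opic_edi",
    "full_report",
]


def _on_observer_grid(s: Spectrum, obs: ActionSpectra) -> np.ndarray:
    if (
        s.wavelengths_nm.size == obs.wavelengths_nm.size
        and np.array_equal(s.wavelengths_nm, obs.wavelengths_nm)
    ):
        return s.values
    return resample(s, obs.wavelengths_nm).values


def alpha_opic_irradiance(s: Spectrum, alpha: str,
                          observer: ActionSpectra | None = None) -> float:
    """α-opic irradiance of a corneal irradiance spectrum, mW·m⁻²."""
    if alpha not in RECEPTORS:
        raise ValidationError(f"unknown receptor tag {alpha!r}")
    s.require_quantity("irradiance")
    obs = observer or default_observer()
    vals = _on_observer_grid(s, obs)
    return 1000.0 * obs.step_nm * float(np.sum(vals * obs.s_alpha[alpha]))


def photopic_illuminance(s: Spectrum,
                         observer: ActionSpectra | None = None) -> float:
    """Photopic illuminance of a corneal irradiance spectrum, lx."""
    s.require_quantity("irradiance")
    obs = observer or default_observer()
    vals = _on_observer_grid(s, obs)
    return KM_LM_PER_W * obs.step_nm * float(np.sum(vals * obs.vlambda))


def photopic_luminance(s: Spectrum,
                       observer: ActionSpectra | None = None) -> float:
    """Photopic luminance of a radiance spectrum, cd·m⁻² (same kernel)."""
    s.require_quantity("radiance")
    obs = observer or default_observer()
    vals = _on_observer_grid(s, obs)
    return KM_LM_PER_W * obs.step_nm * float(np.sum(vals * obs.vlambda))


def d65_efficacy(alpha: str, basis: str = "tables",
                 observer: ActionSpectra | None = None) -> float:
    """Daylight efficacy constant K_α in mW·lm⁻¹.

    ``basis="tables"`` computes E_α(D65)/illuminance(D65) from the packaged
    tables (invariant to any rescaling of D65); ``basis="published"``
    returns the standard's printed constant.
    """
    if alpha not in RECEPTORS:
        raise ValidationError(f"unknown receptor tag {alpha!r}")
    if basis == "published":
        return K_ALPHA_D65[alpha]
    if basis != "tables":
        raise ValidationError("basis must be 'tables' or 'published'")
    obs = observer or default_observer()
    num = 1000.0 * float(np.sum(obs.d65 * obs.s_alpha[alpha]))
    den = KM_LM_PER_W * float(np.sum(obs.d65 * obs.vlambda))
    return num / den


def alpha_opic_edi(e_alpha: float, alpha: str, basis: str = "published",
                   observer: ActionSpectra | None = None) -> float:
    """α-opic equivalent daylight (D65) illuminance, lx, of an α-opic
    irradiance in mW·m⁻² (for melanopsin this is the mEDI)."""
    if e_alpha < 0:
        raise ValidationError("α-opic irradiance must be >= 0")
    return e_alpha / d65_efficacy(alpha, basis=basis, observer=observer)


@dataclass(frozen=True)
class AlphaOpicQuantities:
    """The α-opic row set for one spectrum (irradiances in mW·m⁻², lx)."""

    e_alpha: dict
    illuminance: float
    edi_alpha: dict
    der_alpha: dict  # NaN marks the undefined case (zero illuminance)
    label: str = ""

    def to_dict(self) -> dict:
        out = {"label": self.label, "illuminance_lx": self.illuminance}
        for tag in RECEPTORS:
            out[f"E_{tag}_mW_m2"] = self.e_alpha[tag]
            out[f"EDI_{tag}_lx"] = self.edi_alpha[tag]
            out[f"DER_{tag}"] = self.der_alpha[tag]
        return out

    @property
    def medi(self) -> float:
        """Melanopic EDI, lx."""
        return self.edi_alpha["mel"]


def full_report(s: Spectrum, basis: str = "tables",
                observer: ActionSpectra | None = None) -> AlphaOpicQuantities:
    """All five α-opic irradiances, the illuminance, EDIs and DERs.

    The default ``basis="tables"`` keeps the report self-consistent: a
    D65-shaped spectrum yields EDI_α = illuminance and DER_α = 1 exactly.
    """
    obs = observer or default_observer()
    e_alpha = {t: alpha_opic_irradiance(s, t, obs) for t in RECEPTORS}
    illum = photopic_illuminance(s, obs)
    edi = {
        t: alpha_opic_edi(e_alpha[t], t, basis=basis, observer=obs)
        for t in RECEPTORS
    }
    der = {
        t: (edi[t] / illum if illum > 0 else float("nan")) for t in RECEPTORS
    }
    return AlphaOpicQuantities(e_alpha=e_alpha, illuminance=illum,
                               edi_alpha=edi, der_alpha=der, label=s.label)
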