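"""Standard-observer data: α-opic action spectra, V(λ), and D65.

The five retinal sensitivity functions (S-, M-, L-cone-opic, rhodopic,
melanopic), the photopic luminous efficiency function V(λ) and the D65
daylight spectrum are shipped as a packaged 1 nm table on 380–780 nm.

Provenance — reconstruction, not the normative tabulation
---------------------------------------------------------
The packaged file ``data/observer_reconstructed_1nm.csv`` is a *synthetic
reconstruction* built by ``scripts/build_observer_tables.py``: Govardovskii
A1 pigment nomograms with analytic lens/macular filtering for the cones and
melanopsin, and transcribed classic 5 nm (10 nm scotopic) tabulations for
V(λ), V′(λ) and D65, interpolated to 1 nm.  The melanopic curve is
calibrated so its daylight (D65) efficacy equals the published constant
1.3262 mW·lm⁻¹; the other four published efficacy constants then validate
the reconstruction (rhodopic within 0.3 %, M-/L-cone within ~2.5 %,
S-cone within ~11 %).  Spectrally resolved results therefore carry a
few-percent model error; scalar EDI conversions use the published
constants in :data:`K_ALPHA_D65` and are exact to the standard.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .exceptions import ValidationError

#: receptor tags in the package's canonical column order
RECEPTORS = ("sc", "mc", "lc", "rh", "mel")

RECEPTOR_NAMES = {
    "sc": "S-cone-opic",
    "mc": "M-cone-opic",
    "lc": "L-cone-opic",
    "rh": "rhodopic",
    "mel": "melanopic",
}

#: published CIE S 026 α-opic daylight (D65) efficacy constants, mW·lm⁻¹
K_ALPHA_D65 = {
    "sc": 0.8173,
    "mc": 1.4558,
    "lc": 1.6289,
    "rh": 1.4497,
    "mel": 1.3262,
}

#: maximum luminous efficacy of monochromatic 555 nm radiation, lm·W⁻¹
KM_LM_PER_W = 683.0

_DATA_FILE = "observer_reconstructed_1nm.csv"
_DATA_SHA256 = "4f5c39b4b29df1b87424e654f29dd4f42cd180377b1c8f3336a7e168c8b5051a"


@dataclass(frozen=True)
class ActionSpectra:
    """The standard-observer tables on one shared 1 nm grid, peaks = 1."""

    wavelengths_nm: np.ndarray
    s_alpha: dict  # receptor tag -> sensitivity array, max exactly 1
    vlambda: np.ndarray  # photopic luminous efficiency, max 1 at 555 nm
    d65: np.ndarray  # relative spectral power of D65 (100 at 560 nm)

    def __post_init__(self):
        for tag in RECEPTORS:
            s = self.s_alpha[tag]
            if s.shape != self.wavelengths_nm.shape:
                raise ValidationError(f"{tag} not on the shared grid")
            if np.any(s < 0) or not np.isclose(s.max(), 1.0, atol=1e-12):
                raise ValidationError(f"{tag} must be >= 0 with max 1")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])


def _load_table() -> ActionSpectra:
    raw = (resources.files("melanophot") / "data" / _DATA_FILE).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DATA_SHA256:
        raise ValidationError(
            f"observer table checksum mismatch: {digest} != {_DATA_SHA256}"
        )
    data = np.genfromtxt(raw.decode().splitlines(), delimiter=",", names=True)
    grid = data["wavelength_nm"]
    s_alpha = {tag: np.asarray(data[tag], dtype=float) for tag in RECEPTORS}
    # renormalize away any last-digit rounding from the CSV serialization
    for tag in RECEPTORS:
        s_alpha[tag] = s_alpha[tag] / s_alpha[tag].max()
    v = np.asarray(data["vlambda"], dtype=float)
    return ActionSpectra(
        wavelengths_nm=np.asarray(grid, dtype=float),
        s_alpha=s_alpha,
        vlambda=v / v.max(),
        d65=np.asarray(data["d65"], dtype=float),
    )


_cached: ActionSpectra | None = None


def default_observer() -> ActionSpectra:
    """The packaged standard-observer tables (cached singleton)."""
    global _cached
    if _cached is None:
        _cached = _load_table()
    return _cached
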