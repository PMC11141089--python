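"""Spectral power distributions: the container and arithmetic every
photometric operation in this package rests on.

A :class:`Spectrum` is a wavelength-gridded spectral flux: spectral
irradiance (W·m⁻²·nm⁻¹) at the cornea, or spectral radiance
(W·m⁻²·sr⁻¹·nm⁻¹) of an extended source such as a display.  All
downstream α-opic quantities are Δλ-weighted rectangular sums on the
canonical 380–780 nm 1 nm grid, matching tabulated-summation practice for
the standard observer functions.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import SpectrumFormatError, UnitError, ValidationError

#: canonical computational grid, 380–780 nm at 1 nm
CANONICAL_GRID = np.arange(380.0, 781.0)

_QUANTITIES = ("irradiance", "radiance")


@dataclass(frozen=True)
class Spectrum:
    """A nonnegative spectral flux on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing grid within [300, 830] nm, length >= 2.
    values:
        Spectral flux per nm; same length, finite, >= 0.
    quantity:
        ``"irradiance"`` (W·m⁻²·nm⁻¹) or ``"radiance"`` (W·m⁻²·sr⁻¹·nm⁻¹).
    label:
        Free-text description.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    quantity: str = "irradiance"
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size or w.size < 2:
            raise ValidationError(
                "wavelengths and values must be 1-D of equal length >= 2"
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise ValidationError("spectrum contains non-finite entries")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if w[0] < 300.0 or w[-1] > 830.0:
            raise ValidationError("wavelength grid must lie within [300, 830] nm")
        if np.any(v < 0):
            raise ValidationError("spectral values must be >= 0")
        if self.quantity not in _QUANTITIES:
            raise ValidationError(f"quantity must be one of {_QUANTITIES}")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def is_uniform(self) -> bool:
        steps = np.diff(self.wavelengths_nm)
        return bool(np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12))

    @property
    def step_nm(self) -> float:
        if not self.is_uniform:
            raise ValidationError("grid is not uniform; resample first")
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def require_quantity(self, quantity: str) -> "Spectrum":
        if self.quantity != quantity:
            raise UnitError(
                f"operation requires a {quantity} spectrum, got {self.quantity}"
            )
        return self


def read_spd(path, quantity: str = "irradiance", label: str | None = None,
             clip_negative: bool = False) -> Spectrum:
    """Read one spectrum from a two-column delimited text file.

    Comma or whitespace delimited; lines starting with ``#`` are ignored.
    Negative entries are rejected unless ``clip_negative`` (then clipped
    to 0, which mirrors common treatment of spectrometer noise floors).
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    arr = np.array(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise SpectrumFormatError(f"{path}: wavelengths not strictly increasing")
    vals = arr[:, 1]
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    return Spectrum(arr[:, 0], vals, quantity=quantity,
                    label=label if label is not None else str(path))


def read_spd_table(path, quantity: str = "irradiance") -> dict[str, Spectrum]:
    """Read a wide CSV (wavelength column + one named column per spectrum)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    wave = df.iloc[:, 0].to_numpy(dtype=float)
    out = {}
    for col in df.columns[1:]:
        out[col] = Spectrum(wave, df[col].to_numpy(dtype=float),
                            quantity=quantity, label=col)
    return out


def write_spd(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text, lossless to 9+ significant digits."""
    buf = io.StringIO()
    if spectrum.label:
        buf.write(f"# {spectrum.label}\n")
    buf.write(f"# quantity: {spectrum.quantity}\n")
    for w, v in zip(spectrum.wavelengths_nm, spectrum.values):
        buf.write(f"{w:.9g} {v:.17g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def resample(spectrum: Spectrum, grid=CANONICAL_GRID) -> Spectrum:
    """Linear interpolation onto ``grid``; zero outside the source support.

    Out-of-support extrapolation is zero rather than edge-hold: physical
    sources emit nothing where they were not measured.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("target grid is empty")
    if grid.size < 2:
        raise ValidationError("target grid must have length >= 2")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("target grid must be strictly increasing")
    vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values,
                     left=0.0, right=0.0)
    return replace(spectrum, wavelengths_nm=grid, values=vals)


def integrate(spectrum: Spectrum) -> float:
    """Total flux Δλ·Σv (rectangular summation on a uniform grid)."""
    return spectrum.step_nm * float(np.sum(spectrum.values))


def scale(spectrum: Spectrum, factor: float) -> Spectrum:
    """Pointwise nonnegative rescaling."""
    if not np.isfinite(factor) or factor < 0:
        raise ValidationError("scale factor must be finite and >= 0")
    return replace(spectrum, values=spectrum.values * factor)


def add(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise sum of two spectra on identical grids and units."""
    if a.quantity != b.quantity:
        raise UnitError("cannot add spectra with different quantity tags")
    if a.wavelengths_nm.size != b.wavelengths_nm.size or not np.array_equal(
        a.wavelengths_nm, b.wavelengths_nm
    ):
        raise ValidationError("cannot add spectra on different grids")
    return replace(a, values=a.values + b.values,
                   label=f"{a.label}+{b.label}" if a.label or b.label else "")
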