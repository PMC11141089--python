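"""Pupillometry preprocessing: artifact filtering and median binning.

Mirrors the eye-tracker analysis the study used: 3-D model pupil
diameters sampled nominally at 200 Hz are cleaned by excluding samples
with confidence < 0.6 or diameters outside [2, 10] mm (blinks and model
failures), then reduced to one median diameter per test part, and parts
with < 2 % of the expected samples surviving are dropped as poor quality.

Boundary semantics follow the strict inequalities of those rules:
confidence exactly 0.6, diameters exactly 2 or 10 mm, and a valid
fraction of exactly 2 % are all *retained*.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PupilRecording",
    "filter_samples",
    "bin_median",
    "exclude_low_quality",
    "diameter_to_area",
    "relative_increase",
    "MIN_CONFIDENCE",
    "DIAMETER_RANGE_MM",
    "MIN_VALID_FRACTION",
]

MIN_CONFIDENCE = 0.6
DIAMETER_RANGE_MM = (2.0, 10.0)
MIN_VALID_FRACTION = 0.02

#: required sample columns
_COLUMNS = ("t_s", "diameter_mm", "confidence")


@dataclass(frozen=True)
class PupilRecording:
    """Time-ordered pupil samples for one subject/session, with labels.

    ``samples`` columns: ``t_s`` (seconds from session start),
    ``diameter_mm`` (3-D model estimate), ``confidence`` in [0, 1], and
    optionally ``part`` (test-part label; one median is computed per part).
    """

    samples: pd.DataFrame
    subject: str = ""
    session: str = ""
    expected_rate_hz: float = 200.0

    def __post_init__(self):
        df = self.samples
        for col in _COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"samples missing column {col!r}")
        if len(df) and not df["t_s"].is_monotonic_increasing:
            raise ValidationError("timestamps must be nondecreasing")
        if len(df) and (
            df["confidence"].min() < 0 or df["confidence"].max() > 1
        ):
            raise ValidationError("confidence must lie in [0, 1]")
        if self.expected_rate_hz <= 0:
            raise ValidationError("expected_rate_hz must be positive")


def filter_samples(rec: PupilRecording) -> PupilRecording:
    """Retain samples with confidence >= 0.6 and 2 mm <= diameter <= 10 mm.

    Idempotent; an empty result is allowed.
    """
    df = rec.samples
    lo, hi = DIAMETER_RANGE_MM
    keep = (
        (df["confidence"] >= MIN_CONFIDENCE)
        & (df["diameter_mm"] >= lo)
        & (df["diameter_mm"] <= hi)
    )
    return replace(rec, samples=df.loc[keep].reset_index(drop=True))


def bin_median(rec: PupilRecording, bin_minutes: float = 20.0,
               expected_samples: int | None = None) -> pd.DataFrame:
    """Median diameter per test part (or per ``bin_minutes`` time bin).

    ``rec`` should already be filtered.  If a ``part`` column is present
    each labelled part is one analysis unit; otherwise samples are binned
    by time from the recording start.  The even-count median is the mean
    of the two central values (standard definition).

    ``expected_samples`` is the *nominal* per-part denominator for the
    valid-data fraction; it defaults to bin duration × the nominal rate,
    so that storage dropouts count against quality.

    Returns one row per part with columns ``subject, session, part,
    median_diameter_mm, n_valid, n_expected, fraction_valid, excluded,
    reason`` (``excluded`` here marks only empty parts; the 2 % quality
    rule is applied by :func:`exclude_low_quality`).
    """
    if bin_minutes <= 0:
        raise ValidationError("bin_minutes must be positive")
    df = rec.samples
    n_expected = (
        expected_samples
        if expected_samples is not None
        else int(round(bin_minutes * 60.0 * rec.expected_rate_hz))
    )
    if "part" in df.columns and len(df):
        groups = list(df.groupby("part", sort=True))
    elif len(df):
        idx = np.floor(df["t_s"].to_numpy() / (bin_minutes * 60.0)).astype(int)
        groups = [(k, g) for k, g in df.groupby(pd.Series(idx, index=df.index))]
    else:
        groups = []
    rows = []
    for part, g in groups:
        n_valid = int(len(g))
        rows.append(
            {
                "subject": rec.subject,
                "session": rec.session,
                "part": part,
                "median_diameter_mm": (
                    float(g["diameter_mm"].median()) if n_valid else np.nan
                ),
                "n_valid": n_valid,
                "n_expected": n_expected,
                "fraction_valid": n_valid / n_expected if n_expected else 0.0,
                "excluded": n_valid == 0,
                "reason": "" if n_valid else "no valid samples",
            }
        )
    cols = ["subject", "session", "part", "median_diameter_mm", "n_valid",
            "n_expected", "fraction_valid", "excluded", "reason"]
    return pd.DataFrame(rows, columns=cols)


def exclude_low_quality(bins: pd.DataFrame,
                        min_fraction: float = MIN_VALID_FRACTION) -> pd.DataFrame:
    """Flag parts whose valid fraction is strictly below ``min_fraction``.

    Returns a copy with ``excluded``/``reason`` updated; exactly 2 % is
    retained.  Rows already excluded stay excluded.
    """
    out = bins.copy()
    poor = (out["fraction_valid"] < min_fraction) & ~out["excluded"]
    out.loc[poor, "excluded"] = True
    out.loc[poor, "reason"] = (
        f"poor data quality (<{min_fraction:.0%} of available data)"
    )
    return out


def diameter_to_area(diameter_mm: float) -> float:
    """Pupil area π(d/2)² in mm²."""
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("diameter must be positive")
    out = np.pi * (d / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def relative_increase(d_lm: float, d_hm: float) -> float:
    """Relative LM-vs-HM pupil size increase (d_LM − d_HM)/d_HM × 100, %."""
    if np.any(np.asarray(d_hm) == 0):
        raise ValidationError("relative increase undefined for zero HM size")
    out = (np.asarray(d_lm, dtype=float) - d_hm) / d_hm * 100.0
    return float(out) if np.ndim(out) == 0 else out
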