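"""Synthetic study generator: the full 4 × 2 × 18 design with known truth.

No raw recordings are deposited with the study this package reimplements,
so every pipeline stage is exercised against simulated data whose
generating parameters are known exactly:

* the eight light conditions default to the published condition table
  (four luminance groups × low-/high-melanopic arms with their α-opic
  irradiances and mEDIs) — those printed values are *inputs* here;
* steady-state pupil diameter follows a logistic in log melanopic EDI,
  d(E) = d_min + (d_max − d_min) / (1 + (E/E50)^h), which nests the
  log-linear decline the study observed over 3.7–146 lx and saturates
  sanely outside it, plus a per-subject offset and AR(1) sample noise;
  blink events inject low-confidence samples with sub-2 mm diameters,
  exercising both artifact-filter clauses;
* evening melatonin is a logistic baseline rise attenuated by a
  dose-dependent suppression factor s = 1/(1 + (dose/S50)^k), with the
  driving dose selectable as corneal (mEDI) or retinal (melanopic
  trolands) — the mechanism switch behind the corneal-vs-retinal
  predictor comparison;
* all randomness flows from one seed through per-subject-session
  substreams, so a dataset is reproducible bit-exactly.

Pupil traces default to 10 Hz, a decimated export of the nominal 200 Hz
tracker; the valid-fraction bookkeeping uses the configured rate
consistently.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import lfilter

from .doseresponse import MelatoninSeries, melatonin_auc
from .exceptions import ValidationError
from .pupil import (
    PupilRecording,
    bin_median,
    diameter_to_area,
    exclude_low_quality,
    filter_samples,
)
from .retinal import screen_solid_angle

__all__ = [
    "TABLE1_CONDITIONS",
    "PupilModelParams",
    "MelatoninModelParams",
    "SamplingParams",
    "SimConfig",
    "StudyBundle",
    "steady_state_diameter",
    "suppression_factor",
    "simulate_pupil_trace",
    "simulate_melatonin_profile",
    "generate_study",
    "study_pupil_table",
    "study_outcomes",
    "recover_pupil_model",
]

#: the published condition grid: luminance (cd·m⁻²), α-opic irradiances
#: (mW·m⁻²) and melanopic EDI (lx) for the 4 intensity × 2 arm design
TABLE1_CONDITIONS = pd.DataFrame(
    {
        "condition": ["LM 1", "HM 1", "LM 2", "HM 2",
                      "LM 3", "HM 3", "LM 4", "HM 4"],
        "group": [1, 1, 2, 2, 3, 3, 4, 4],
        "arm": ["LM", "HM"] * 4,
        "luminance_cd_m2": [27.43, 27.41, 62.93, 61.39,
                            135.03, 133.0, 283.74, 284.5],
        "E_sc": [6.40, 6.22, 13.87, 13.72, 29.58, 29.71, 60.21, 62.00],
        "E_mc": [11.19, 11.74, 25.52, 25.43, 55.08, 54.79, 116.58, 115.12],
        "E_lc": [13.32, 13.50, 29.95, 30.09, 64.90, 64.78, 138.10, 138.86],
        "E_rh": [6.87, 18.70, 16.47, 40.39, 38.09, 86.81, 87.00, 180.89],
        "E_mel": [4.91, 20.11, 11.70, 43.51, 27.46, 93.27, 64.17, 193.62],
        "medi_lx": [3.70, 15.17, 8.82, 32.81, 20.70, 70.33, 48.39, 146.00],
    }
)

#: 27-inch 16:9 display seen from 60 cm (the study's viewing geometry)
SCREEN_SOLID_ANGLE_SR = screen_solid_angle(0.598, 0.336, 0.60)


@dataclass(frozen=True)
class PupilModelParams:
    """Steady-state pupil model and its noise structure (mm, lx)."""

    d_max_mm: float = 7.0
    d_min_mm: float = 2.2
    e50_lx: float = 25.0
    hill: float = 0.55
    lmhm_offset_mm: float = 0.0  # residual LM/HM offset beyond melanopsin
    subject_sd_mm: float = 0.30  # between-subject diameter offset SD
    noise_sd_mm: float = 0.15  # stationary AR(1) sample noise SD
    ar_coef: float = 0.95
    blink_rate_hz: float = 0.2
    blink_duration_s: float = 0.3
    low_conf_fraction: float = 0.02  # scattered low-confidence samples

    def __post_init__(self):
        if not self.d_min_mm < self.d_max_mm:
            raise ValidationError("d_min must be below d_max")
        for name in ("e50_lx", "hill"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("subject_sd_mm", "noise_sd_mm", "blink_rate_hz",
                     "blink_duration_s", "low_conf_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValidationError("ar_coef must lie in [0, 1)")


@dataclass(frozen=True)
class MelatoninModelParams:
    """Evening melatonin baseline rise and dose-dependent suppression."""

    baseline_peak_pg_ml: float = 25.0
    rise_center_h: float = -2.0  # hours relative to habitual bedtime
    rise_tau_h: float = 0.6
    s50: float = 100.0  # half-suppression dose, units of the driver
    hill_k: float = 1.0
    noise_sd_log: float = 0.15  # multiplicative lognormal sigma
    subject_amp_sd_log: float = 0.30  # per-subject amplitude, lognormal

    def __post_init__(self):
        for name in ("baseline_peak_pg_ml", "rise_tau_h", "s50", "hill_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("noise_sd_log", "subject_amp_sd_log"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SamplingParams:
    """Recording layout: five 20-min test parts, half-hourly melatonin."""

    pupil_rate_hz: float = 10.0  # decimated from the nominal 200 Hz
    nominal_rate_hz: float = 200.0
    n_parts: int = 5
    part_minutes: float = 20.0
    melatonin_start_h: float = -5.0
    melatonin_end_h: float = 0.0
    melatonin_step_h: float = 0.5
    exposure_window: tuple = (-4.0, -0.5)  # 3.5 h ending 30 min pre-bed


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one full synthetic study."""

    conditions: pd.DataFrame = field(
        default_factory=lambda: TABLE1_CONDITIONS.copy()
    )
    n_per_group: int = 18
    pupil: PupilModelParams = field(default_factory=PupilModelParams)
    melatonin: MelatoninModelParams = field(default_factory=MelatoninModelParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    suppression_driver: str = "corneal"  # or "retinal" (melanopic trolands)
    screen_solid_angle_sr: float = SCREEN_SOLID_ANGLE_SR
    seed: int = 0

    def __post_init__(self):
        if self.suppression_driver not in ("corneal", "retinal"):
            raise ValidationError(
                "suppression_driver must be 'corneal' or 'retinal'"
            )
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")


def steady_state_diameter(medi_lx, p: PupilModelParams):
    """Noiseless steady-state pupil diameter at a melanopic EDI, mm."""
    medi = np.asarray(medi_lx, dtype=float)
    if np.any(medi <= 0):
        raise ValidationError("melanopic EDI must be positive")
    out = p.d_min_mm + (p.d_max_mm - p.d_min_mm) / (
        1.0 + (medi / p.e50_lx) ** p.hill
    )
    return float(out) if out.ndim == 0 else out


def suppression_factor(dose, m: MelatoninModelParams):
    """Fraction of the melatonin baseline surviving at a given dose."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValidationError("dose must be >= 0")
    out = 1.0 / (1.0 + (d / m.s50) ** m.hill_k)
    return float(out) if out.ndim == 0 else out


def _baseline_rise(times_h, m: MelatoninModelParams):
    return m.baseline_peak_pg_ml / (
        1.0 + np.exp(-(np.asarray(times_h, dtype=float) - m.rise_center_h)
                     / m.rise_tau_h)
    )


def simulate_pupil_trace(
    medi_lx: float,
    duration_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    params: PupilModelParams | None = None,
    subject_offset_mm: float = 0.0,
    subject: str = "",
    session: str = "",
    n_parts: int = 1,
) -> PupilRecording:
    """One session's pupil trace: steady state + AR(1) noise + blinks.

    With zero noise and zero blink rate the trace is exactly the model
    diameter.  ``n_parts`` splits the duration into equal labelled test
    parts (the analysis unit downstream).
    """
    p = params or PupilModelParams()
    if duration_s <= 0 or rate_hz <= 0:
        raise ValidationError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    mean = steady_state_diameter(medi_lx, p) + subject_offset_mm

    if p.noise_sd_mm > 0 and n > 1:
        innov = rng.normal(
            0.0, p.noise_sd_mm * np.sqrt(1.0 - p.ar_coef**2), size=n
        )
        innov[0] = rng.normal(0.0, p.noise_sd_mm)
        noise = lfilter([1.0], [1.0, -p.ar_coef], innov)
    else:
        noise = np.zeros(n)
    diam = mean + noise
    conf = rng.uniform(0.75, 1.0, size=n)

    # scattered low-confidence samples (tracking glitches)
    if p.low_conf_fraction > 0:
        glitch = rng.random(n) < p.low_conf_fraction
        conf[glitch] = rng.uniform(0.0, 0.59, size=int(glitch.sum()))

    # blink events: low-confidence runs with sub-2 mm diameter excursions
    n_blinks = rng.poisson(p.blink_rate_hz * duration_s)
    blink_len = max(1, int(round(p.blink_duration_s * rate_hz)))
    for start in np.sort(rng.integers(0, max(1, n - blink_len), size=n_blinks)):
        sl = slice(start, start + blink_len)
        m = diam[sl].size
        diam[sl] = rng.uniform(0.3, 1.9, size=m)
        conf[sl] = rng.uniform(0.0, 0.59, size=m)

    np.clip(diam, 0.1, None, out=diam)
    df = pd.DataFrame(
        {"t_s": t, "diameter_mm": diam, "confidence": conf}
    )
    if n_parts > 1:
        df["part"] = np.minimum(
            (t / (duration_s / n_parts)).astype(int), n_parts - 1
        ) + 1
    return PupilRecording(samples=df, subject=subject, session=session,
                         expected_rate_hz=rate_hz)


def simulate_melatonin_profile(
    dose: float,
    rng: np.random.Generator,
    params: MelatoninModelParams | None = None,
    times_h=None,
    subject_amp: float = 1.0,
    subject: str = "",
    session: str = "",
) -> MelatoninSeries:
    """Half-hourly evening melatonin attenuated by the suppression factor."""
    m = params or MelatoninModelParams()
    if dose <= 0:
        raise ValidationError("dose must be positive")
    if times_h is None:
        times_h = np.arange(-5.0, 0.0 + 1e-9, 0.5)
    times_h = np.asarray(times_h, dtype=float)
    conc = _baseline_rise(times_h, m) * suppression_factor(dose, m) * subject_amp
    if m.noise_sd_log > 0:
        conc = conc * rng.lognormal(0.0, m.noise_sd_log, size=conc.size)
    return MelatoninSeries(times_h=times_h, conc_pg_ml=conc,
                           subject=subject, session=session)


@dataclass(frozen=True)
class StudyBundle:
    """One generated study: inputs in pipeline formats plus ground truth."""

    config: SimConfig
    conditions: pd.DataFrame
    assignments: pd.DataFrame  # subject, group, first condition
    pupil_recordings: list
    melatonin_series: list
    ground_truth: pd.DataFrame  # per subject-session latent quantities

    def write(self, outdir) -> None:
        """Write the bundle as the pipeline's plain-text input formats."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.conditions.to_csv(out / "conditions.csv", index=False)
        self.assignments.to_csv(out / "assignments.csv", index=False)
        pupil_frames = []
        for rec in self.pupil_recordings:
            df = rec.samples.copy()
            df.insert(0, "subject", rec.subject)
            df.insert(1, "session", rec.session)
            pupil_frames.append(df)
        pd.concat(pupil_frames, ignore_index=True).rename(
            columns={"t_s": "timestamp_s", "diameter_mm": "diameter_3d_mm"}
        ).to_csv(out / "pupil_samples.csv", index=False)
        mel_rows = []
        for s in self.melatonin_series:
            for t, c in zip(s.times_h, s.conc_pg_ml):
                mel_rows.append(
                    {"subject": s.subject, "session": s.session,
                     "time_h": t, "conc_pg_ml": c}
                )
        pd.DataFrame(mel_rows).to_csv(out / "melatonin.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        (out / "ground_truth_params.json").write_text(
            json.dumps(
                {
                    "pupil": asdict(self.config.pupil),
                    "melatonin": asdict(self.config.melatonin),
                    "suppression_driver": self.config.suppression_driver,
                    "seed": self.config.seed,
                },
                indent=2,
            )
        )


def generate_study(config: SimConfig | None = None) -> StudyBundle:
    """Generate the full counterbalanced study under one seed.

    72 subjects (4 groups × ``n_per_group``) × 2 sessions (LM, HM) →
    144 pupil recordings and melatonin series; per-subject latent effects
    and the generating parameters are returned as ground truth.
    """
    cfg = config or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    cond = cfg.conditions
    groups = sorted(cond["group"].unique())
    subjects = []
    for g in groups:
        for i in range(cfg.n_per_group):
            subjects.append((f"S{g}{i + 1:02d}", g))

    sub_seeds = root.spawn(len(subjects))
    duration_s = cfg.sampling.n_parts * cfg.sampling.part_minutes * 60.0
    times_h = np.arange(
        cfg.sampling.melatonin_start_h,
        cfg.sampling.melatonin_end_h + 1e-9,
        cfg.sampling.melatonin_step_h,
    )

    assignments, recordings, series, truth = [], [], [], []
    for (subject, group), seed in zip(subjects, sub_seeds):
        rng = np.random.default_rng(seed)
        offset = rng.normal(0.0, cfg.pupil.subject_sd_mm)
        amp = rng.lognormal(0.0, cfg.melatonin.subject_amp_sd_log)
        order = ("LM", "HM") if int(subject[2:]) % 2 else ("HM", "LM")
        assignments.append(
            {"subject": subject, "group": group, "first_condition": order[0]}
        )
        for arm in order:
            row = cond[(cond["group"] == group) & (cond["arm"] == arm)].iloc[0]
            medi = float(row["medi_lx"])
            arm_offset = (
                cfg.pupil.lmhm_offset_mm if arm == "LM" else 0.0
            )
            rec = simulate_pupil_trace(
                medi,
                duration_s,
                cfg.sampling.pupil_rate_hz,
                rng,
                cfg.pupil,
                subject_offset_mm=offset + arm_offset,
                subject=subject,
                session=arm,
                n_parts=cfg.sampling.n_parts,
            )
            recordings.append(rec)

            d_true = (
                steady_state_diameter(medi, cfg.pupil) + offset + arm_offset
            )
            area_true = diameter_to_area(max(d_true, 0.5))
            mel_radiance = float(row["E_mel"]) / cfg.screen_solid_angle_sr
            mel_td_true = mel_radiance * area_true
            dose = medi if cfg.suppression_driver == "corneal" else mel_td_true
            series.append(
                simulate_melatonin_profile(
                    dose, rng, cfg.melatonin, times_h=times_h,
                    subject_amp=amp, subject=subject, session=arm,
                )
            )
            truth.append(
                {
                    "subject": subject,
                    "group": group,
                    "session": arm,
                    "medi_lx": medi,
                    "subject_offset_mm": offset,
                    "true_diameter_mm": d_true,
                    "true_mel_td": mel_td_true,
                    "suppression_dose": dose,
                    "suppression_factor": suppression_factor(
                        dose, cfg.melatonin
                    ),
                    "melatonin_amp": amp,
                }
            )

    return StudyBundle(
        config=cfg,
        conditions=cond.copy(),
        assignments=pd.DataFrame(assignments),
        pupil_recordings=recordings,
        melatonin_series=series,
        ground_truth=pd.DataFrame(truth),
    )


def study_pupil_table(bundle: StudyBundle) -> pd.DataFrame:
    """Run the pupil pipeline over a bundle: filter → per-part medians →
    quality exclusion, joined with each session's melanopic EDI."""
    cfg = bundle.config
    frames = []
    for rec in bundle.pupil_recordings:
        bins = bin_median(
            filter_samples(rec),
            bin_minutes=cfg.sampling.part_minutes,
            expected_samples=int(
                round(
                    cfg.sampling.part_minutes * 60.0 *
                    cfg.sampling.pupil_rate_hz
                )
            ),
        )
        frames.append(bins)
    # recordings whose samples are entirely artifact-filtered yield empty
    # frames; drop them before concat to keep stable dtypes
    frames = [f for f in frames if len(f)]
    table = pd.concat(frames, ignore_index=True)
    table["excluded"] = table["excluded"].astype(bool)
    table = exclude_low_quality(table)
    key = bundle.ground_truth[
        ["subject", "session", "group", "medi_lx", "true_mel_td"]
    ]
    return table.merge(key, on=["subject", "session"], how="left")


def study_outcomes(bundle: StudyBundle) -> pd.DataFrame:
    """One row per subject-session: observed pupil median, melanopic
    trolands from the observed pupil, and the melatonin AUC over the
    light-exposure window."""
    cfg = bundle.config
    parts = study_pupil_table(bundle)
    good = parts[~parts["excluded"]]
    per_session = (
        good.groupby(["subject", "session"], as_index=False)
        .agg(
            group=("group", "first"),
            medi_lx=("medi_lx", "first"),
            pupil_median_mm=("median_diameter_mm", "median"),
        )
    )
    e_mel = bundle.conditions.set_index(["group", "arm"])["E_mel"]
    mel_rad = {
        (g, a): e_mel.loc[(g, a)] / cfg.screen_solid_angle_sr
        for g, a in e_mel.index
    }
    per_session["mel_td"] = [
        mel_rad[(int(r.group), r.session)] *
        diameter_to_area(r.pupil_median_mm)
        for r in per_session.itertuples()
    ]
    aucs = {
        (s.subject, s.session): melatonin_auc(s, cfg.sampling.exposure_window)
        for s in bundle.melatonin_series
    }
    per_session["melatonin_auc"] = [
        aucs[(r.subject, r.session)] for r in per_session.itertuples()
    ]
    return per_session


def recover_pupil_model(medi_lx, median_mm,
                        d_max_mm: float | None = None,
                        d_min_mm: float | None = None,
                        p0=(7.5, 2.5, 40.0, 0.8)) -> dict:
    """Fit the steady-state logistic to observed medians (the parameter-
    recovery harness).

    The study's dose range (3.7–146 lx mEDI) reaches neither asymptote,
    so d_max/d_min trade off strongly against E50 in a free fit; pass
    the known asymptotes to recover the identifiable parameters (E50,
    hill).  Returns d_max, d_min, e50, hill estimates."""
    x = np.asarray(medi_lx, dtype=float)
    y = np.asarray(median_mm, dtype=float)

    if d_max_mm is not None and d_min_mm is not None:

        def model2(e, e50, hill):
            return d_min_mm + (d_max_mm - d_min_mm) / (
                1.0 + (e / e50) ** hill
            )

        popt, _ = curve_fit(
            model2, x, y, p0=p0[2:],
            bounds=([1.0, 0.05], [1000.0, 5.0]), maxfev=20000,
        )
        return {"d_max_mm": d_max_mm, "d_min_mm": d_min_mm,
                "e50_lx": popt[0], "hill": popt[1]}

    def model(e, d_max, d_min, e50, hill):
        return d_min + (d_max - d_min) / (1.0 + (e / e50) ** hill)

    popt, _ = curve_fit(
        model, x, y, p0=p0,
        bounds=([3.0, 0.5, 1.0, 0.05], [12.0, 5.0, 1000.0, 5.0]),
        maxfev=20000,
    )
    return {"d_max_mm": popt[0], "d_min_mm": popt[1],
            "e50_lx": popt[2], "hill": popt[3]}
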