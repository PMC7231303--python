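"""Synthetic cohort generator.

Emulates a pediatric overweight/obesity cohort: 4-part daily time-use
compositions closing to 1440 min (logistic-normal around group means, so
behaviours are mutually correlated and strictly positive), a 33-band
awake-time intensity spectrum, anthropometric/demographic covariates, and
hippocampal gray-matter-volume outcomes with configurable planted effects.
Also provides the covariate-derivation formulas (BMI, maturity offset) and
an epoch-series generator so the accelerometry reduction can be exercised
end-to-end.
"""

from __future__ import annotations

import dataclasses
import functools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accel
from .coda import PARTS, TOTAL_MIN, first_pivot_coordinate

GROUPS: tuple[str, ...] = ("overweight", "obesity I", "obesity II-III")
SEXES: tuple[str, ...] = ("male", "female")
EDU_LEVELS: tuple[str, ...] = ("neither", "one", "both")
OUTCOMES: tuple[str, ...] = ("gmv_left_hippocampus", "gmv_right_hippocampus")

# ---------------------------------------------------------------------------
# Default calibration: group-level descriptives (mean, SD) of the reference
# cohort the generator emulates (n=93: 23 / 41 / 29 by weight status).
# ---------------------------------------------------------------------------

DEFAULT_GROUP_PROPORTIONS: tuple[float, ...] = (23 / 93, 41 / 93, 29 / 93)

#: Whole-sample behaviour descriptives (mean, SD) in min/day of the reference
#: cohort (n = 93); used for calibration and descriptive benchmarks.
WHOLE_SAMPLE_BEHAVIOR_MEANS: dict[str, tuple[float, float]] = {
    "sed": (561.39, 60.85),
    "lpa": (275.36, 39.75),
    "mvpa": (54.61, 20.91),
}

_SED_MEAN_SD = {"overweight": (534.25, 71.12), "obesity I": (559.35, 50.59),
                "obesity II-III": (585.78, 57.52)}
_LPA_MEAN_SD = {"overweight": (277.85, 40.42), "obesity I": (273.16, 43.31),
                "obesity II-III": (276.49, 34.83)}
_MVPA_MEAN_SD = {"overweight": (61.76, 26.79), "obesity I": (53.84, 19.66),
                 "obesity II-III": (50.05, 16.0)}


def _default_composition_means() -> dict[str, dict[str, float]]:
    out = {}
    for g in GROUPS:
        sed, lpa, mvpa = _SED_MEAN_SD[g][0], _LPA_MEAN_SD[g][0], _MVPA_MEAN_SD[g][0]
        out[g] = {"sleep": TOTAL_MIN - sed - lpa - mvpa,
                  "sed": sed, "lpa": lpa, "mvpa": mvpa}
    return out


DEFAULT_GROUP_COMPOSITION_MEANS = _default_composition_means()

_AGE = {"overweight": (10.13, 1.08), "obesity I": (10.29, 1.04),
        "obesity II-III": (9.51, 1.14)}
_HEIGHT = {"overweight": (142.16, 8.80), "obesity I": (146.59, 7.78),
           "obesity II-III": (141.84, 7.08)}
_BMI = {"overweight": (22.64, 1.41), "obesity I": (26.26, 2.06),
        "obesity II-III": (30.68, 2.36)}
_TBV = {"overweight": (1210.02, 99.41), "obesity I": (1221.03, 94.93),
        "obesity II-III": (1169.54, 122.50)}
_P_FEMALE = {"overweight": 9 / 23, "obesity I": 15 / 41, "obesity II-III": 13 / 29}
_EDU_PROPS = {"overweight": (0.57, 0.17, 0.26), "obesity I": (0.59, 0.22, 0.19),
              "obesity II-III": (0.90, 0.07, 0.03)}
_GMV_BASE = {
    "gmv_left_hippocampus": {"overweight": 3387.17, "obesity I": 3572.49,
                             "obesity II-III": 3386.71},
    "gmv_right_hippocampus": {"overweight": 3568.46, "obesity I": 3709.9,
                              "obesity II-III": 3463.19},
}

#: Public alias: group-level hippocampal GMV means (mm^3) the synthetic
#: outcome model is anchored to.
REFERENCE_GMV_MEANS = _GMV_BASE

#: Log-ratio scale of (sed, lpa, mvpa) relative to sleep, calibrated so the
#: minute-scale SDs approximate the reference descriptives at dispersion 1.
DEFAULT_ALR_SIGMA: tuple[float, float, float] = (0.155, 0.20, 0.42)

#: Correlation among the additive log-ratios, calibrated so pairwise |r| of
#: SED/LPA/MVPA minutes lands in the 0.3-0.5 range (SED negative with both
#: activity intensities, LPA-MVPA positive).
DEFAULT_ALR_CORR: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.45, 0.0),
    (0.45, 1.0, 0.45),
    (0.0, 0.45, 1.0),
)

DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "sex_female": -60.0,          # mm^3, female vs male
    "phv_offset": 25.0,           # mm^3 per year from peak height velocity
    "edu_one": 15.0,              # vs neither parent with university education
    "edu_both": 30.0,
    "total_brain_volume": 1.2,    # mm^3 per unit
}

#: Within-class spectral decay scale (m*g*): activity time concentrates at
#: the low-acceleration end of each behaviour's intensity range.
DEFAULT_SPECTRUM_SCALE: dict[str, float] = {"sed": 15.0, "lpa": 60.0, "mvpa": 120.0}


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index: weight (kg) divided by squared height (m^2)."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def compute_phv_offset(sex: str, age_years: float, height_cm: float | None = None,
                       seated_height_cm: float | None = None) -> float:
    """Maturity offset (years from peak height velocity), Moore equations.

    Boys: -8.13 + 0.007 x (age x seated height); girls: -7.71 + 0.004 x
    (age x standing height). Applied literally with height in cm.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    if np.any(np.asarray(age_years) < 0):
        raise ValueError("age must be non-negative")
    if sex == "male":
        if seated_height_cm is None:
            raise ValueError("seated height is required for boys")
        if np.any(np.asarray(seated_height_cm) <= 0):
            raise ValueError("seated height must be positive")
        return -8.13 + 0.007 * (np.asarray(age_years) * np.asarray(seated_height_cm))
    if height_cm is None:
        raise ValueError("standing height is required for girls")
    if np.any(np.asarray(height_cm) <= 0):
        raise ValueError("height must be positive")
    return -7.71 + 0.004 * (np.asarray(age_years) * np.asarray(height_cm))


@dataclasses.dataclass
class EffectSpec:
    """Planted behaviour→outcome effects, per weight-status group.

    ``scale='ilr'``: slope applies to the behaviour's first pivot coordinate
    (behaviour relative to the rest). ``scale='absolute'``: slope applies to
    the behaviour's minutes. Effects act on ``outcome`` only and are centered
    at the group's mean composition so group outcome means stay at their base.
    """

    scale: str = "ilr"
    slopes: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    outcome: str = "gmv_right_hippocampus"

    def __post_init__(self) -> None:
        if self.scale not in ("ilr", "absolute"):
            raise ValueError("effect scale must be 'ilr' or 'absolute'")

    @classmethod
    def uniform(cls, scale: str = "ilr",
                outcome: str = "gmv_right_hippocampus", **slopes: float) -> "EffectSpec":
        return cls(scale=scale, outcome=outcome,
                   slopes={g: dict(slopes) for g in GROUPS})

    def slope(self, group: str, behavior: str) -> float:
        return float(self.slopes.get(group, {}).get(behavior, 0.0))


@dataclasses.dataclass
class GeneratorConfig:
    n_participants: int = 93
    group_proportions: Sequence[float] = DEFAULT_GROUP_PROPORTIONS
    group_composition_means: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=_default_composition_means)
    composition_dispersion: float = 1.0
    effect_spec: EffectSpec = dataclasses.field(default_factory=EffectSpec)
    outcome_noise_sd: float = 250.0
    seed: int = 0
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    alr_sigma: Sequence[float] = DEFAULT_ALR_SIGMA
    alr_corr: Sequence[Sequence[float]] = DEFAULT_ALR_CORR
    spectrum_scale: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_SCALE))

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if len(props) != len(GROUPS) or np.any(props < 0) or abs(props.sum() - 1) > 1e-8:
            raise ValueError("group_proportions must be a non-negative "
                             f"{len(GROUPS)}-vector summing to 1")
        if self.composition_dispersion <= 0:
            raise ValueError("composition_dispersion must be positive")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be non-negative")
        for g in GROUPS:
            m = self.group_composition_means[g]
            total = sum(m[p] for p in PARTS)
            if abs(total - TOTAL_MIN) > 1e-6:
                raise ValueError(f"group mean composition for {g!r} sums to "
                                 f"{total}, expected {TOTAL_MIN}")
            if any(m[p] <= 0 for p in PARTS):
                raise ValueError(f"group mean composition for {g!r} has "
                                 "non-positive parts")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effect_spec" in raw and isinstance(raw["effect_spec"], dict):
            raw["effect_spec"] = EffectSpec(**raw["effect_spec"])
        return cls(**raw)


@dataclasses.dataclass
class ParticipantRecord:
    id: str
    sex: str
    age: float
    height: float
    seated_height: float
    weight: float
    bmi: float
    phv_offset: float
    parental_education: str
    weight_status: str
    total_brain_volume: float
    gmv_left_hippocampus: float
    gmv_right_hippocampus: float
    sleep_min: float
    sed_min: float
    lpa_min: float
    mvpa_min: float
    spectrum: np.ndarray

    @property
    def composition(self) -> np.ndarray:
        """Behaviour minutes in canonical part order (sleep, sed, lpa, mvpa)."""
        return np.array([self.sleep_min, self.sed_min, self.lpa_min, self.mvpa_min])

    def __post_init__(self) -> None:
        comp = self.composition
        if np.any(comp <= 0) or abs(comp.sum() - TOTAL_MIN) > 1e-6:
            raise ValueError("composition parts must be positive and sum to 1440")
        if min(self.total_brain_volume, self.gmv_left_hippocampus,
               self.gmv_right_hippocampus) <= 0:
            raise ValueError("volumes must be positive")


# ---------------------------------------------------------------------------
# Composition and spectrum sampling
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _corrected_mu(mean_key: tuple[float, ...], cov_key: tuple[float, ...]) -> np.ndarray:
    """Log-ratio location whose logistic-normal mean hits the target composition.

    The arithmetic mean of a logistic-normal is biased away from the closed
    back-transform of the location (most visibly for the small, high-variance
    MVPA part); a few fixed-seed Monte-Carlo moment-matching iterations remove
    it. Cached: the correction is deterministic in (mean, covariance).
    """
    mean_comp = np.asarray(mean_key)
    cov = np.asarray(cov_key).reshape(3, 3)
    target = mean_comp / mean_comp.sum()
    mu = np.log(mean_comp[1:] / mean_comp[0])
    rng = np.random.default_rng(1_234_567)
    for _ in range(4):
        u = rng.multivariate_normal(mu, cov, size=8000, method="cholesky")
        parts = np.column_stack([np.ones(len(u)), np.exp(u)])
        est = (parts / parts.sum(axis=1, keepdims=True)).mean(axis=0)
        mu = mu + np.log(target[1:] / est[1:]) - np.log(target[0] / est[0])
    mu.setflags(write=False)
    return mu


def _sample_compositions(rng: np.random.Generator, n: int, mean_comp: np.ndarray,
                         config: GeneratorConfig) -> np.ndarray:
    """Logistic-normal draw around a group mean composition (n x 4 minutes)."""
    sigma = np.asarray(config.alr_sigma, dtype=float) * config.composition_dispersion
    corr = np.asarray(config.alr_corr, dtype=float)
    cov = np.outer(sigma, sigma) * corr
    mu = _corrected_mu(tuple(mean_comp), tuple(cov.ravel()))
    u = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    parts = np.column_stack([np.ones(n), np.exp(u)])
    return parts / parts.sum(axis=1, keepdims=True) * TOTAL_MIN


def _class_band_weights(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Per behaviour: fixed 33-vector distributing its minutes over bands.

    Each behaviour's m*g* range is split by the 25-m*g* band grid; weight of
    an overlapping segment is proportional to its width times an exponential
    decay from the class's lower edge.
    """
    ranges = {"sed": (0.0, accel.SED_CUTOFF_MG),
              "lpa": (accel.SED_CUTOFF_MG, accel.MVPA_CUTOFF_MG),
              "mvpa": (accel.MVPA_CUTOFF_MG, 1200.0)}
    weights = {}
    for cls, (lo, hi) in ranges.items():
        scale = float(config.spectrum_scale[cls])
        w = np.zeros(accel.N_BANDS)
        for j, (blo, bhi) in enumerate(accel.band_edges()):
            seg_lo, seg_hi = max(lo, blo), min(hi, bhi if np.isfinite(bhi) else hi)
            if seg_hi <= seg_lo:
                continue
            mid = 0.5 * (seg_lo + seg_hi)
            w[j] = (seg_hi - seg_lo) * np.exp(-(mid - lo) / scale)
        weights[cls] = w / w.sum()
    return weights


def _spectra_from_compositions(comps: np.ndarray,
                               config: GeneratorConfig) -> np.ndarray:
    """Deterministic spectrum: awake minutes of each class spread over bands."""
    w = _class_band_weights(config)
    return (np.outer(comps[:, 1], w["sed"]) + np.outer(comps[:, 2], w["lpa"])
            + np.outer(comps[:, 3], w["mvpa"]))


# ---------------------------------------------------------------------------
# Outcome model
# ---------------------------------------------------------------------------

def _covariate_centers(config: GeneratorConfig, group: str) -> dict[str, float]:
    """Approximate expectations of the covariates under the generator."""
    p_f = _P_FEMALE[group]
    age, height = _AGE[group][0], _HEIGHT[group][0]
    seated = 0.52 * height
    phv = (p_f * compute_phv_offset("female", age, height_cm=height)
           + (1 - p_f) * compute_phv_offset("male", age, seated_height_cm=seated))
    edu = _EDU_PROPS[group]
    return {"sex_female": p_f, "phv_offset": float(phv),
            "edu_one": edu[1], "edu_both": edu[2],
            "total_brain_volume": _TBV[group][0]}


def covariate_predictor(df: pd.DataFrame, config: GeneratorConfig,
                        outcome: str) -> np.ndarray:
    """Deterministic covariate-only part of the outcome linear predictor."""
    eff = config.covariate_effects
    pred = np.zeros(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        g = row["weight_status"]
        c = _covariate_centers(config, g)
        pred[i] = (_GMV_BASE[outcome][g]
                   + eff["sex_female"] * ((row["sex"] == "female") - c["sex_female"])
                   + eff["phv_offset"] * (row["phv_offset"] - c["phv_offset"])
                   + eff["edu_one"] * ((row["parental_education"] == "one") - c["edu_one"])
                   + eff["edu_both"] * ((row["parental_education"] == "both") - c["edu_both"])
                   + eff["total_brain_volume"] * (row["total_brain_volume"]
                                                 - c["total_brain_volume"]))
    return pred


def _behavior_effect(comps: np.ndarray, group: str, mean_comp: np.ndarray,
                     spec: EffectSpec) -> np.ndarray:
    """Planted compositional/absolute effect, centered at the group mean."""
    out = np.zeros(len(comps))
    for bi, b in enumerate(PARTS):
        s = spec.slope(group, b)
        if s == 0.0:
            continue
        if spec.scale == "ilr":
            z = first_pivot_coordinate(comps, b)
            z0 = first_pivot_coordinate(mean_comp, b)
            out += s * (np.atleast_1d(z) - z0)
        else:
            out += s * (comps[:, bi] - mean_comp[bi])
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic cohort from ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    group_idx = rng.choice(len(GROUPS), size=n, p=np.asarray(config.group_proportions))

    records: list[ParticipantRecord] = []
    for i in range(n):
        g = GROUPS[group_idx[i]]
        mean_comp = np.array([config.group_composition_means[g][p] for p in PARTS])
        comp = _sample_compositions(rng, 1, mean_comp, config)[0]
        spectrum = _spectra_from_compositions(comp[None, :], config)[0]

        sex = "female" if rng.random() < _P_FEMALE[g] else "male"
        age = float(np.clip(rng.normal(*_AGE[g]), 8.0, 12.0))
        height = float(rng.normal(*_HEIGHT[g]))
        seated = float(0.52 * height + rng.normal(0.0, 1.5))
        bmi = float(rng.normal(*_BMI[g]))
        weight = bmi * (height / 100.0) ** 2
        phv = float(compute_phv_offset(sex, age, height_cm=height,
                                       seated_height_cm=seated))
        edu = EDU_LEVELS[rng.choice(3, p=np.asarray(_EDU_PROPS[g]))]
        tbv = float(rng.normal(*_TBV[g]))

        centers = _covariate_centers(config, g)
        eff = config.covariate_effects
        cov_term = (eff["sex_female"] * ((sex == "female") - centers["sex_female"])
                    + eff["phv_offset"] * (phv - centers["phv_offset"])
                    + eff["edu_one"] * ((edu == "one") - centers["edu_one"])
                    + eff["edu_both"] * ((edu == "both") - centers["edu_both"])
                    + eff["total_brain_volume"] * (tbv - centers["total_brain_volume"]))

        gmv = {}
        for outcome in OUTCOMES:
            val = _GMV_BASE[outcome][g] + cov_term
            if outcome == config.effect_spec.outcome:
                val += float(_behavior_effect(comp[None, :], g, mean_comp,
                                              config.effect_spec)[0])
            val += rng.normal(0.0, config.outcome_noise_sd)
            gmv[outcome] = float(val)

        records.append(ParticipantRecord(
            id=f"P{i + 1:04d}", sex=sex, age=age, height=height,
            seated_height=seated, weight=weight, bmi=compute_bmi(weight, height),
            phv_offset=phv, parental_education=edu, weight_status=g,
            total_brain_volume=tbv,
            gmv_left_hippocampus=gmv["gmv_left_hippocampus"],
            gmv_right_hippocampus=gmv["gmv_right_hippocampus"],
            sleep_min=comp[0], sed_min=comp[1], lpa_min=comp[2], mvpa_min=comp[3],
            spectrum=spectrum,
        ))
    return records


def cohort_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Participant table, one row per participant (documented column names)."""
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in dataclasses.fields(r)
               if f.name != "spectrum"}
        row.update(dict(zip(accel.band_labels(), r.spectrum)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_participants_csv(records: Sequence[ParticipantRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Epoch-series generation
# ---------------------------------------------------------------------------

def generate_epoch_series(record: ParticipantRecord, n_days: int = 7,
                          epoch_s: int = 5, seed: int | None = None,
                          nonwear: Sequence[tuple[int, int, int]] = (),
                          start: str = "2015-01-05") -> accel.EpochSeries:
    """Simulate an epoch series whose reduction recovers ``record``'s minutes.

    Each day starts with the sleep window; awake epochs carry magnitudes drawn
    inside their class's m*g* range (band chosen by the configured spectral
    profile), so the intensity thresholds recover each behaviour within one
    epoch. ``nonwear`` is a list of (day_index, start_minute, duration_min)
    gaps. ``start`` defaults to a Monday so days 5-6 are the weekend.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if 60 % epoch_s != 0:
        raise ValueError("epoch length must divide 60 s")
    rng = np.random.default_rng(seed)
    per_day = 86400 // epoch_s
    per_min = 60 // epoch_s

    # largest-remainder apportionment keeps every class within one epoch
    minutes = {"sleep": record.sleep_min, "sed": record.sed_min,
               "lpa": record.lpa_min, "mvpa": record.mvpa_min}
    exact = np.array([minutes[b] * per_min for b in PARTS])
    counts = np.floor(exact).astype(int)
    short = per_day - counts.sum()
    for j in np.argsort(-(exact - np.floor(exact)))[:short]:
        counts[j] += 1

    weights = _class_band_weights(GeneratorConfig(n_participants=1))
    edges = accel.band_edges()
    ranges = {"sed": (0.0, accel.SED_CUTOFF_MG),
              "lpa": (accel.SED_CUTOFF_MG, accel.MVPA_CUTOFF_MG),
              "mvpa": (accel.MVPA_CUTOFF_MG + 1e-6, 1200.0)}

    def draw(cls: str, size: int) -> np.ndarray:
        if size == 0:
            return np.empty(0)
        lo, hi = ranges[cls]
        bands = rng.choice(accel.N_BANDS, size=size, p=weights[cls])
        blo = np.array([max(edges[b][0], lo) for b in bands])
        bhi = np.array([min(edges[b][1] if np.isfinite(edges[b][1]) else hi, hi)
                        for b in bands])
        return rng.uniform(blo, bhi)

    day_frames = []
    t0 = pd.Timestamp(start)
    for d in range(n_days):
        n_sleep = counts[0]
        labels = np.concatenate([np.full(counts[1], 1), np.full(counts[2], 2),
                                 np.full(counts[3], 3)])
        rng.shuffle(labels)
        enmo = np.empty(per_day)
        enmo[:n_sleep] = rng.uniform(0.0, 20.0, size=n_sleep)
        awake = np.empty(per_day - n_sleep)
        awake[labels == 1] = draw("sed", int((labels == 1).sum()))
        awake[labels == 2] = draw("lpa", int((labels == 2).sum()))
        awake[labels == 3] = draw("mvpa", int((labels == 3).sum()))
        enmo[n_sleep:] = awake

        df = pd.DataFrame({
            "timestamp": t0 + pd.Timedelta(days=d)
            + pd.to_timedelta(np.arange(per_day) * epoch_s, unit="s"),
            "enmo_mg": enmo,
            "wear": True,
            "sleep": np.arange(per_day) < n_sleep,
        })
        day_frames.append(df)

    data = pd.concat(day_frames, ignore_index=True)
    for day_idx, start_min, dur_min in nonwear:
        lo = day_idx * per_day + start_min * per_min
        hi = lo + dur_min * per_min
        data.loc[lo:hi - 1, "wear"] = False
        data.loc[lo:hi - 1, "enmo_mg"] = 0.0
    return accel.EpochSeries(record.id, data, epoch_s)
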