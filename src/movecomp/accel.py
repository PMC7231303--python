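"""Epoch-level accelerometry reduction.

Turns wrist-acceleration epoch series (ENMO magnitude in milli-gravitational
units, m*g*) into daily and participant-level behaviour minutes plus a
33-band awake-time intensity spectrum. Includes non-wear imputation from the
same clock-time slot on other days, weekday/weekend 5:2 weighting, and the
valid-day filter (>=16 h wear, >=4 valid days incl. >=1 weekend day).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Intensity thresholds for the non-dominant wrist in children, in m*g*.
#: SED < 35; LPA 35-200 (both endpoints included); MVPA > 200.
SED_CUTOFF_MG: float = 35.0
MVPA_CUTOFF_MG: float = 200.0

#: Awake-time intensity spectrum: 33 contiguous 25-m*g* bands; the last band
#: (>=800 m*g*) is open-ended so no epoch is orphaned.
BAND_WIDTH_MG: float = 25.0
N_BANDS: int = 33

#: Validity rules.
MIN_WEAR_HOURS: float = 16.0
MIN_VALID_DAYS: int = 4
MIN_VALID_WEEKEND_DAYS: int = 1

BEHAVIORS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")

EPOCH_CSV_COLUMNS = ("id", "timestamp", "enmo_mg", "wear", "sleep")


def band_edges() -> list[tuple[float, float]]:
    """(low, high) m*g* edges per band; the final high edge is +inf."""
    edges = [(i * BAND_WIDTH_MG, (i + 1) * BAND_WIDTH_MG) for i in range(N_BANDS - 1)]
    edges.append(((N_BANDS - 1) * BAND_WIDTH_MG, np.inf))
    return edges


def band_labels() -> list[str]:
    """Column labels spec_000_025 ... spec_800_plus."""
    labels = [f"spec_{int(lo):03d}_{int(hi):03d}" for lo, hi in band_edges()[:-1]]
    labels.append(f"spec_{int((N_BANDS - 1) * BAND_WIDTH_MG):03d}_plus")
    return labels


@dataclasses.dataclass
class EpochSeries:
    """Ordered epoch series for one participant.

    ``data`` columns: timestamp (datetime64), enmo_mg (float), wear (bool),
    sleep (bool) and, after imputation, imputed (bool).
    """

    participant_id: str
    data: pd.DataFrame
    epoch_s: int

    def __post_init__(self) -> None:
        ts = self.data["timestamp"]
        step = ts.diff().dropna().dt.total_seconds()
        if len(step) and not np.allclose(step, self.epoch_s):
            raise ValueError("timestamps must be strictly increasing with a "
                             f"constant {self.epoch_s}-s epoch length")
        worn = self.data["wear"].to_numpy(dtype=bool)
        if np.any(self.data["enmo_mg"].to_numpy()[worn] < 0):
            raise ValueError("negative acceleration magnitude on worn epochs")

    @property
    def n_days(self) -> int:
        return self.data["timestamp"].dt.normalize().nunique()


def classify(enmo_mg: Sequence[float], sed_cutoff: float = SED_CUTOFF_MG,
             mvpa_cutoff: float = MVPA_CUTOFF_MG) -> np.ndarray:
    """Vectorized intensity classification → codes 0=SED, 1=LPA, 2=MVPA."""
    e = np.asarray(enmo_mg, dtype=float)
    if np.any(e < 0):
        raise ValueError("acceleration magnitude must be non-negative")
    return np.where(e < sed_cutoff, 0, np.where(e <= mvpa_cutoff, 1, 2))


def classify_epoch(enmo_mg: float) -> str:
    """Classify one awake worn epoch as 'SED', 'LPA' or 'MVPA'."""
    return ("SED", "LPA", "MVPA")[int(classify([enmo_mg])[0])]


def spectrum_bins(enmo_mg: Sequence[float]) -> np.ndarray:
    """Vectorized band index floor(enmo/25), capped at the open-ended band 32."""
    e = np.asarray(enmo_mg, dtype=float)
    if np.any(e < 0):
        raise ValueError("acceleration magnitude must be non-negative")
    return np.minimum((e // BAND_WIDTH_MG).astype(int), N_BANDS - 1)


def spectrum_bin(enmo_mg: float) -> int:
    return int(spectrum_bins([enmo_mg])[0])


def impute_nonwear(series: EpochSeries) -> EpochSeries:
    """Fill non-wear epochs with the mean of the same clock-time slot on worn days.

    Wear flags are untouched (imputation replaces values, it does not create
    wear). Slots that are non-wear on every day are flagged unimputable via
    ``imputed=False`` and stay excluded from summaries. Idempotent.
    """
    df = series.data.copy()
    wear = df["wear"].to_numpy(dtype=bool)
    if "imputed" not in df.columns:
        df["imputed"] = False
    if wear.all():
        return EpochSeries(series.participant_id, df, series.epoch_s)
    if series.n_days < 2:
        raise ValueError("non-wear imputation needs at least 2 recorded days")

    slot = (df["timestamp"].dt.hour * 3600 + df["timestamp"].dt.minute * 60
            + df["timestamp"].dt.second)
    slot_mean = df.loc[wear].groupby(slot[wear])["enmo_mg"].mean()
    fill = slot[~wear].map(slot_mean)

    imputable = fill.notna()
    df.loc[fill.index[imputable], "enmo_mg"] = fill[imputable]
    df.loc[fill.index[imputable], "imputed"] = True
    return EpochSeries(series.participant_id, df, series.epoch_s)


@dataclasses.dataclass
class DailySummary:
    date: pd.Timestamp
    is_weekend: bool
    wear_hours: float
    sleep_min: float
    sed_min: float
    lpa_min: float
    mvpa_min: float
    spectrum: np.ndarray  # 33 awake-time minutes per band

    @property
    def is_valid(self) -> bool:
        return self.wear_hours >= MIN_WEAR_HOURS


def summarize_day(day: pd.DataFrame, epoch_s: int) -> DailySummary:
    """Reduce one calendar day of (already imputed) epochs.

    Behaviour minutes count awake epochs that are worn or imputed; sleep
    minutes come from the sleep annotations; wear hours count measured wear
    only. The spectrum covers the same awake classified epochs.
    """
    if day.empty:
        raise ValueError("cannot summarize an empty day")
    min_per_epoch = epoch_s / 60.0
    sleep = day["sleep"].to_numpy(dtype=bool)
    wear = day["wear"].to_numpy(dtype=bool)
    usable = wear | day.get("imputed", pd.Series(False, index=day.index)).to_numpy(dtype=bool)
    awake = ~sleep & usable

    enmo = day["enmo_mg"].to_numpy(dtype=float)[awake]
    codes = classify(enmo)
    counts = np.bincount(codes, minlength=3)
    spectrum = np.bincount(spectrum_bins(enmo), minlength=N_BANDS).astype(float)

    date = day["timestamp"].iloc[0].normalize()
    return DailySummary(
        date=date,
        is_weekend=date.weekday() >= 5,
        wear_hours=wear.sum() * epoch_s / 3600.0,
        sleep_min=sleep.sum() * min_per_epoch,
        sed_min=counts[0] * min_per_epoch,
        lpa_min=counts[1] * min_per_epoch,
        mvpa_min=counts[2] * min_per_epoch,
        spectrum=spectrum * min_per_epoch,
    )


def summarize_days(series: EpochSeries) -> list[DailySummary]:
    return [summarize_day(day, series.epoch_s)
            for _, day in series.data.groupby(series.data["timestamp"].dt.normalize())]


@dataclasses.dataclass
class ParticipantBehaviorSummary:
    participant_id: str
    sleep_min: float
    sed_min: float
    lpa_min: float
    mvpa_min: float
    spectrum: np.ndarray
    n_valid_days: int
    n_valid_weekend_days: int
    valid: bool


def weight_week(daily: Iterable[DailySummary],
                participant_id: str = "") -> ParticipantBehaviorSummary:
    """Combine daily summaries as (weekday mean x 5 + weekend mean x 2) / 7.

    Only valid days (>=16 h measured wear) enter the averages. When one side
    (weekday or weekend) has no valid day the plain mean over valid days is
    used instead; the participant is flagged invalid in that case anyway by
    the >=4 valid days / >=1 weekend day rule.
    """
    valid_days = [d for d in daily if d.is_valid]
    if not valid_days:
        return ParticipantBehaviorSummary(participant_id, np.nan, np.nan, np.nan,
                                          np.nan, np.full(N_BANDS, np.nan), 0, 0, False)

    fields = ("sleep_min", "sed_min", "lpa_min", "mvpa_min")

    def stack(days: list[DailySummary]) -> np.ndarray:
        return np.array([[getattr(d, f) for f in fields] + list(d.spectrum)
                         for d in days])

    weekend = [d for d in valid_days if d.is_weekend]
    weekday = [d for d in valid_days if not d.is_weekend]
    if weekday and weekend:
        combined = (stack(weekday).mean(axis=0) * 5 + stack(weekend).mean(axis=0) * 2) / 7
    else:
        combined = stack(valid_days).mean(axis=0)

    n_weekend = len(weekend)
    return ParticipantBehaviorSummary(
        participant_id=participant_id,
        sleep_min=combined[0], sed_min=combined[1],
        lpa_min=combined[2], mvpa_min=combined[3],
        spectrum=combined[4:],
        n_valid_days=len(valid_days),
        n_valid_weekend_days=n_weekend,
        valid=len(valid_days) >= MIN_VALID_DAYS and n_weekend >= MIN_VALID_WEEKEND_DAYS,
    )


def summarize_participant(series: EpochSeries) -> ParticipantBehaviorSummary:
    """Full reduction: impute non-wear, summarize days, apply 5:2 weighting."""
    imputed = impute_nonwear(series) if not series.data["wear"].all() else series
    return weight_week(summarize_days(imputed), participant_id=series.participant_id)


def summaries_to_frame(summaries: Iterable[ParticipantBehaviorSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"id": s.participant_id, "sleep_min": s.sleep_min, "sed_min": s.sed_min,
               "lpa_min": s.lpa_min, "mvpa_min": s.mvpa_min,
               "n_valid_days": s.n_valid_days,
               "n_valid_weekend_days": s.n_valid_weekend_days, "valid": s.valid}
        row.update(dict(zip(band_labels(), s.spectrum)))
        rows.append(row)
    return pd.DataFrame(rows)


def read_epochs_csv(path) -> list[EpochSeries]:
    """Read a long epoch CSV (id, timestamp ISO-8601, enmo_mg[, wear, sleep])."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "wear" not in df.columns:
        df["wear"] = True
    if "sleep" not in df.columns:
        df["sleep"] = False
    df["wear"] = df["wear"].astype(bool)
    df["sleep"] = df["sleep"].astype(bool)
    out = []
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        step = grp["timestamp"].diff().dropna().dt.total_seconds()
        epoch_s = int(step.iloc[0]) if len(step) else 60
        out.append(EpochSeries(str(pid), grp[["timestamp", "enmo_mg", "wear", "sleep"]],
                               epoch_s))
    return out


def write_epochs_csv(series_list: Iterable[EpochSeries], path) -> None:
    frames = []
    for s in series_list:
        df = s.data[["timestamp", "enmo_mg", "wear", "sleep"]].copy()
        df.insert(0, "id", s.participant_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
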