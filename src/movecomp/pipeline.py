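"""End-to-end orchestration: synthesize → reduce → describe → model.

A configured run generates (or loads) a participant table, optionally pushes
every participant through the epoch-level accelerometry reduction with the
validity filter, and then executes the enabled analyses (absolute-minutes
regression with the moderation screen, compositional regression with
reallocation curves, and the PLS pattern analysis), writing tidy CSVs,
figure analogues and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, accel, coda, plsmv, stdmodels, synthdata

log = logging.getLogger("movecomp")

MODEL_BEHAVIORS = ("sed", "lpa", "mvpa")


def percent_of_day(minutes: float) -> int:
    """Minutes per day as a percent of 1440, rounded to the nearest integer."""
    return int(np.floor(minutes / coda.TOTAL_MIN * 100.0 + 0.5))


def percent_of(value: float, reference: float) -> int:
    """``value`` as an integer-rounded percentage of ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return int(np.floor(value / reference * 100.0 + 0.5))


_TABLE_VARS = [
    ("age", "Age (years)"),
    ("phv_offset", "PHV offset (years)"),
    ("weight", "Weight (kg)"),
    ("height", "Height (cm)"),
    ("bmi", "BMI (kg/m2)"),
    ("total_brain_volume", "Total brain volume"),
    ("gmv_left_hippocampus", "L hippocampus (mm3)"),
    ("gmv_right_hippocampus", "R hippocampus (mm3)"),
    ("sleep_min", "Sleep (min/day)"),
    ("sed_min", "SED (min/day)"),
    ("lpa_min", "LPA (min/day)"),
    ("mvpa_min", "MVPA (min/day)"),
]


def describe_cohort(df: pd.DataFrame,
                    group_col: str = "weight_status") -> pd.DataFrame:
    """Mean (SD) descriptives per group and overall, tidy long format."""
    if df.empty:
        raise ValueError("cannot describe an empty cohort")
    rows = []
    groups = [("all", df)]
    for g in synthdata.GROUPS:
        sub = df[df[group_col] == g]
        if sub.empty:
            warnings.warn(f"group {g!r} is empty and was omitted", stacklevel=2)
            continue
        groups.append((g, sub))
    for gname, sub in groups:
        for col, label in _TABLE_VARS:
            if col not in sub.columns:
                continue
            vals = sub[col].astype(float)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append({"group": gname, "variable": label, "column": col,
                         "mean": float(vals.mean()), "sd": sd, "n": len(vals)})
        rows.append({"group": gname, "variable": "Girls (%)", "column": "sex",
                     "mean": 100.0 * (sub["sex"] == "female").mean(),
                     "sd": np.nan, "n": len(sub)})
        for lev in synthdata.EDU_LEVELS:
            rows.append({"group": gname, "variable": f"Parental university: {lev} (%)",
                         "column": "parental_education",
                         "mean": 100.0 * (sub["parental_education"] == lev).mean(),
                         "sd": np.nan, "n": len(sub)})
    return pd.DataFrame(rows)


def percent_of_day_table(df: pd.DataFrame) -> dict[str, int]:
    """Integer percent of the day per behaviour from cohort mean minutes."""
    out = {b: percent_of_day(float(df[f"{b}_min"].mean()))
           for b in ("sed", "lpa", "mvpa")}
    awake = (df["sed_min"] + df["lpa_min"] + df["mvpa_min"]).mean()
    out["in_bed"] = percent_of_day(coda.TOTAL_MIN - float(awake))
    return out


def behavior_correlations(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (with p) among behaviour minutes and with outcomes."""
    import scipy.stats

    cols = [f"{b}_min" for b in MODEL_BEHAVIORS] + [
        c for c in ("gmv_left_hippocampus", "gmv_right_hippocampus")
        if c in df.columns]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r, p = scipy.stats.pearsonr(df[a], df[b])
            rows.append({"var1": a, "var2": b, "r": float(r), "p_value": float(p),
                         "n": len(df)})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "results/run"
    participants_csv: str | None = None   # load instead of generating
    generator: dict = dataclasses.field(default_factory=dict)
    outcomes: Sequence[str] = ("right_hippocampus", "left_hippocampus")
    analyses: Mapping[str, bool] = dataclasses.field(
        default_factory=lambda: {"absolute": True, "coda": True, "pls": True})
    stratify: bool = True
    simulate_epochs: bool = False
    epoch_seconds: int = 60
    n_days: int = 7
    pls_reps: int = 100
    pls_holdout: float = 0.5
    pls_k_max: int = 3
    max_delta: float = 60.0
    figures: bool = True

    def __post_init__(self) -> None:
        if not any(self.analyses.values()):
            raise ValueError("at least one analysis must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _apply_accelerometry(records, config: RunConfig) -> pd.DataFrame:
    """Replay each participant through epoch simulation + reduction."""
    rows = []
    for i, rec in enumerate(records):
        series = synthdata.generate_epoch_series(
            rec, n_days=config.n_days, epoch_s=config.epoch_seconds,
            seed=config.seed + 100_000 + i)
        summ = accel.summarize_participant(series)
        rows.append(summ)
    meas = accel.summaries_to_frame(rows)
    df = synthdata.cohort_to_frame(records)
    for col in ["sleep_min", "sed_min", "lpa_min", "mvpa_min", "valid",
                "n_valid_days", "n_valid_weekend_days"] + accel.band_labels():
        df[col] = meas[col].to_numpy()
    n0 = len(df)
    df = df[df["valid"]].drop(columns=["valid"]).reset_index(drop=True)
    log.info("validity filter: %d of %d participants retained", len(df), n0)
    if df.empty:
        raise ValueError("all participants failed the validity filter")
    # measured compositions carry epoch-rounding error; re-close to 1440
    comp = df[[f"{p}_min" for p in coda.PARTS]].to_numpy(dtype=float)
    df[[f"{p}_min" for p in coda.PARTS]] = coda.close(comp)
    return df


def _strata(df: pd.DataFrame, stratify: bool):
    yield "all", df
    if stratify:
        for g in synthdata.GROUPS:
            sub = df[df["weight_status"] == g]
            if len(sub) > 0:
                yield g, sub.reset_index(drop=True)


def run(config: RunConfig) -> dict:
    """Execute a full configured analysis run; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    manifest: dict = {"movecomp_version": __version__,
                      "numpy_version": np.__version__,
                      "pandas_version": pd.__version__,
                      "seed": config.seed,
                      "config": dataclasses.asdict(config)}

    if config.participants_csv:
        df = pd.read_csv(config.participants_csv)
        log.info("loaded %d participants from %s", len(df), config.participants_csv)
    else:
        gen_kwargs = dict(config.generator)
        gen_kwargs.setdefault("seed", config.seed)
        gcfg = synthdata.GeneratorConfig(**gen_kwargs)
        records = synthdata.generate_cohort(gcfg)
        log.info("generated %d synthetic participants", len(records))
        if config.simulate_epochs:
            df = _apply_accelerometry(records, config)
        else:
            df = synthdata.cohort_to_frame(records)
    manifest["n_participants"] = int(len(df))

    df.to_csv(out / "participants.csv", index=False)
    describe_cohort(df).to_csv(out / "table1.csv", index=False)
    behavior_correlations(df).to_csv(out / "correlations.csv", index=False)
    manifest["percent_of_day"] = percent_of_day_table(df)

    outcomes = [stdmodels.resolve_outcome(df, o) for o in config.outcomes]

    if config.analyses.get("absolute"):
        abs_rows, mod_rows = [], []
        for outcome in outcomes:
            for b in MODEL_BEHAVIORS:
                res = {"all": stdmodels.fit_absolute(df, b, outcome)}
                mod = stdmodels.test_moderation(df, b, outcome)
                mod_rows.append({"behavior": b, "outcome": outcome,
                                 "p_interaction": mod.p_interaction,
                                 "moderated": mod.moderated})
                if config.stratify:
                    res.update(stdmodels.stratify_and_fit(df, b, outcome))
                abs_rows.append(stdmodels.results_to_frame(res))
        abs_df = pd.concat(abs_rows, ignore_index=True)
        abs_df.to_csv(out / "absolute_models.csv", index=False)
        pd.DataFrame(mod_rows).to_csv(out / "moderation.csv", index=False)
        if config.figures:
            _forest_figure(abs_df, out / "figures" / "absolute_models.png",
                           value="B", title="Absolute-minutes regression")
        log.info("absolute models: %d fits", len(abs_df))

    if config.analyses.get("coda"):
        coda_rows, curve_rows = [], []
        for outcome in outcomes:
            for gname, sub in _strata(df, config.stratify):
                try:
                    gammas = coda.fit_all_gammas(sub, outcome)
                except ValueError as err:
                    log.warning("coda stratum %s skipped: %s", gname, err)
                    continue
                for focal, fit in gammas.items():
                    coda_rows.append({"group": gname, "behavior": focal,
                                      "outcome": outcome, "gamma": fit.gamma,
                                      "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                                      "p_value": fit.p_value, "n": fit.n})
                if outcome == "gmv_right_hippocampus":
                    for receiver in ("lpa", "mvpa"):
                        fit = coda.fit_compositional(sub, receiver, outcome)
                        deltas = np.linspace(-config.max_delta, config.max_delta, 25)
                        curve = coda.substitution_curve(fit, None, "sed",
                                                        receiver, deltas)
                        cdf = curve.to_frame()
                        cdf.insert(0, "outcome", outcome)
                        cdf.insert(0, "group", gname)
                        curve_rows.append(cdf)
        coda_df = pd.DataFrame(coda_rows)
        coda_df.to_csv(out / "coda_models.csv", index=False)
        curves = pd.concat(curve_rows, ignore_index=True)
        curves.to_csv(out / "reallocation_curves.csv", index=False)
        if config.figures:
            _forest_figure(coda_df, out / "figures" / "coda_models.png",
                           value="gamma", title="Compositional models (gamma)")
            _curves_figure(curves, out / "figures" / "reallocation_curves.png")
        log.info("compositional models: %d fits", len(coda_df))

    if config.analyses.get("pls"):
        plan_rows, sr_rows = [], []
        for outcome in outcomes:
            for gname, sub in _strata(df, config.stratify):
                if len(sub) < 10:
                    log.warning("stratum %s too small for PLS (%d)", gname, len(sub))
                    continue
                plan = plsmv.McCvPlan(n_repetitions=config.pls_reps,
                                      holdout_fraction=config.pls_holdout,
                                      seed=config.seed)
                cv, profile = plsmv.analyze_spectrum(sub, outcome, plan=plan,
                                                     k_max=config.pls_k_max)
                plan_rows.append({"group": gname, "outcome": outcome,
                                  "selected_k": cv.selected_k,
                                  "has_model": cv.has_model,
                                  "n": len(sub)})
                if profile is not None:
                    pdf = profile.to_frame()
                    pdf.insert(0, "outcome", outcome)
                    pdf.insert(0, "group", gname)
                    sr_rows.append(pdf)
        pd.DataFrame(plan_rows).to_csv(out / "pls_model_selection.csv", index=False)
        sr_df = (pd.concat(sr_rows, ignore_index=True) if sr_rows
                 else pd.DataFrame(columns=["group", "outcome", "band", "sr"]))
        sr_df.to_csv(out / "sr_profiles.csv", index=False)
        if config.figures and len(sr_df):
            _sr_figure(sr_df, out / "figures" / "sr_profiles.png")
        log.info("PLS pattern analysis: %d strata, %d with a model",
                 len(plan_rows), len(sr_rows))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Figure analogues
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _forest_figure(df: pd.DataFrame, path, value: str, title: str) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(df))))
    labels = df["group"] + " / " + df["behavior"] + " / " + df["outcome"]
    ypos = np.arange(len(df))
    ax.errorbar(df[value], ypos,
                xerr=[df[value] - df["ci_low"], df["ci_high"] - df[value]],
                fmt="o", color="k", ecolor="gray", capsize=2)
    ax.axvline(0, color="r", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel(f"{value} (mm$^3$) with 95% CI")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _curves_figure(curves: pd.DataFrame, path) -> None:
    plt = _mpl()
    combos = curves[["group", "receiver"]].drop_duplicates()
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, receiver in zip(axes, ("lpa", "mvpa")):
        for g in combos["group"].unique():
            sub = curves[(curves["group"] == g) & (curves["receiver"] == receiver)]
            if sub.empty:
                continue
            ax.plot(sub["delta_min"], sub["diff_mm3"], label=g)
            ax.fill_between(sub["delta_min"], sub["ci_low"], sub["ci_high"],
                            alpha=0.15)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"SED → {receiver.upper()}")
        ax.set_xlabel("reallocated min/day")
    axes[0].set_ylabel("predicted GMV difference (mm$^3$)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _sr_figure(sr_df: pd.DataFrame, path) -> None:
    plt = _mpl()
    combos = sr_df[["group", "outcome"]].drop_duplicates()
    fig, axes = plt.subplots(len(combos), 1,
                             figsize=(8, 2.8 * len(combos)), squeeze=False)
    for ax, (_, row) in zip(axes.ravel(), combos.iterrows()):
        sub = sr_df[(sr_df["group"] == row["group"])
                    & (sr_df["outcome"] == row["outcome"])]
        x = np.arange(len(sub))
        ax.bar(x, sub["sr"], yerr=[sub["sr"] - sub["ci_low"],
                                   sub["ci_high"] - sub["sr"]],
               color=np.where(sub["sr"] >= 0, "tab:blue", "tab:red"),
               error_kw={"lw": 0.5})
        ax.set_ylim(-1, 1)
        ax.set_xticks(x[::4])
        ax.set_xticklabels(sub["band"].iloc[::4], rotation=90, fontsize=5)
        ax.set_ylabel("selectivity ratio")
        ax.set_title(f"{row['group']} / {row['outcome']}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
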