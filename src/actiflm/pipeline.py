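"""End-to-end orchestration: simulate/ingest -> classify -> three analysis arms.

A :class:`RunConfig` (built in code or from YAML) either points at input
CSVs (activity, diary, covariates, questionnaire, design) or embeds a
simulation specification.  :func:`run_pipeline` executes the functional
permutation test, the summary mixed-model arm (night and day segments,
model-averaged) and the questionnaire change-score arm from a single
ingestion pass, and writes a JSON report plus per-arm CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TrialDesign
from .flm import BasisSpec, FLMResult, pointwise_permutation_test
from .io import (
    build_daily_profiles,
    classify_epochs,
    diary_from_frame,
    read_activity,
    read_covariates,
    read_diary,
    read_snore,
    write_activity,
    write_covariates,
    write_diary,
    write_snore,
)
from .snore import SIGNIFICANCE_THRESHOLD, change_scores, snore_table
from .summary import model_average, summarize_day_night
from .synthetic import (
    ActivityModel,
    CohortSpec,
    SnoreEffectSpec,
    simulate_activity,
    simulate_cohort,
    simulate_snore,
)

log = logging.getLogger("actiflm")

__all__ = ["FLMSettings", "RunConfig", "RunReport", "run_pipeline", "make_figure",
           "simulate_to_dir"]


@dataclass(frozen=True)
class FLMSettings:
    n_perm: int = 500
    alpha: float = 0.05
    grid_size: int = 144
    basis: BasisSpec = BasisSpec()
    scheme: str = "paired"
    transform: str = "log1p"
    min_interval_minutes: float = 0.0


@dataclass
class RunConfig:
    """Inputs plus analysis settings for one pipeline run.

    Exactly one of ``input_dir`` (directory holding ``activity.csv``,
    ``diary.csv``, ``covariates.csv``, ``snore.csv`` and ``design.yaml``)
    or ``simulate`` (truthy; uses the embedded specs) must be provided.
    """

    out_dir: Path
    seed: int = 0
    input_dir: Path | None = None
    simulate: bool = False
    cohort: CohortSpec = CohortSpec()
    activity_model: ActivityModel = ActivityModel()
    snore_effects: SnoreEffectSpec = SnoreEffectSpec()
    design: TrialDesign | None = None  # optional explicit design for simulation
    flm: FLMSettings = FLMSettings()
    lmm_transform: str = "log1p"
    snore_threshold: float = SIGNIFICANCE_THRESHOLD
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        def sub(spec_cls, key):
            return spec_cls(**raw[key]) if key in raw else spec_cls()

        flm_raw = dict(raw.get("flm", {}))
        if "basis" in flm_raw:
            flm_raw["basis"] = BasisSpec(**flm_raw["basis"])
        def tupled(x):
            return tuple(tuple(w) for w in x) if isinstance(x, list) else x
        am_raw = dict(raw.get("activity_model", {}))
        for k in ("harmonics", "effect_windows"):
            if k in am_raw:
                am_raw[k] = tupled(am_raw[k])
        sn_raw = dict(raw.get("snore_effects", {}))
        for k in ("item_means", "item_sds", "drug_shifts", "placebo_shifts", "scale"):
            if k in sn_raw:
                sn_raw[k] = tuple(sn_raw[k])
        return cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            simulate=bool(raw.get("simulate", False)),
            cohort=sub(CohortSpec, "cohort"),
            activity_model=ActivityModel(**am_raw),
            snore_effects=SnoreEffectSpec(**sn_raw),
            design=TrialDesign.from_dict(raw["design"]) if "design" in raw else None,
            flm=FLMSettings(**flm_raw),
            lmm_transform=raw.get("lmm_transform", "log1p"),
            snore_threshold=float(raw.get("snore_threshold", SIGNIFICANCE_THRESHOLD)),
            make_plot=bool(raw.get("make_plot", False)),
        )


@dataclass
class RunReport:
    """Summary of one full pipeline run (regenerable from config + seed)."""

    config: dict
    version: str
    seed: int
    flm: dict
    lmm_nta: dict
    lmm_dta: dict
    snore: dict
    concordance: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _spawned(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_to_dir(config: RunConfig, out: Path) -> None:
    """Generate a full synthetic dataset and write the pipeline CSV dialects."""
    rng_cohort, rng_act, rng_snore, _ = _spawned(config.seed, 4)
    cohort = simulate_cohort(config.cohort, rng_cohort)
    design = config.design or TrialDesign.randomized(
        list(cohort["subject_id"]), rng_cohort
    )
    series, diary = simulate_activity(cohort, design, config.activity_model, rng_act)
    snore = simulate_snore(cohort, design, config.snore_effects, rng_snore)
    out.mkdir(parents=True, exist_ok=True)
    write_activity(series, out / "activity.csv")
    write_diary(diary, out / "diary.csv")
    write_covariates(cohort, out / "covariates.csv")
    write_snore(snore, out / "snore.csv")
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump(design.to_dict(), fh)
    log.info("simulated %d subjects x %d days -> %s", len(cohort), design.n_days, out)


def _load_inputs(config: RunConfig):
    if config.simulate:
        rng_cohort, rng_act, rng_snore, _ = _spawned(config.seed, 4)
        cohort = simulate_cohort(config.cohort, rng_cohort)
        design = config.design or TrialDesign.randomized(
            list(cohort["subject_id"]), rng_cohort
        )
        series, diary = simulate_activity(
            cohort, design, config.activity_model, rng_act
        )
        diaries = diary_from_frame(diary)
        snore = simulate_snore(cohort, design, config.snore_effects, rng_snore)
        return series, diaries, cohort, snore, design
    if config.input_dir is None:
        raise ValueError("config needs either simulate=True or an input_dir")
    d = Path(config.input_dir)
    for name in ("activity.csv", "diary.csv", "covariates.csv", "snore.csv",
                 "design.yaml"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file: {d / name}")
    with open(d / "design.yaml") as fh:
        design = TrialDesign.from_dict(yaml.safe_load(fh))
    return (
        read_activity(d / "activity.csv"),
        read_diary(d / "diary.csv"),
        read_covariates(d / "covariates.csv"),
        read_snore(d / "snore.csv"),
        design,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all three analysis arms and write the unified report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        series, diaries, cohort, snore, design = _load_inputs(config)
        log.info("ingest: %d subjects, %d questionnaire rows",
                 len(series), len(snore))

        stage = "classify"
        labeled = [
            classify_epochs(series[sid], diaries.get(sid), design)
            for sid in sorted(series)
        ]
        log.info("classify: %d labeled epochs",
                 sum(len(l.frame) for l in labeled))

        stage = "flm"
        profiles = build_daily_profiles(
            labeled, grid_size=config.flm.grid_size,
            aggregation="per_condition_mean",
        )
        _, _, _, rng_seed = _spawned(config.seed, 4)
        flm_seed = int(rng_seed.integers(2**31 - 1))
        flm_res = pointwise_permutation_test(
            profiles,
            basis=config.flm.basis,
            transform=config.flm.transform,
            n_perm=config.flm.n_perm,
            alpha=config.flm.alpha,
            scheme=config.flm.scheme,
            seed=flm_seed,
            min_interval_minutes=config.flm.min_interval_minutes,
        )
        _write_flm_curves(flm_res, out / "flm_curves.csv")
        log.info("flm: %d/%d grid points significant, intervals: %s",
                 int(flm_res.significant_mask.sum()), len(flm_res.grid),
                 "; ".join(str(iv) for iv in flm_res.significant_intervals) or "none")

        stage = "lmm"
        table = summarize_day_night(labeled, covariates=cohort)
        table.to_csv(out / "summary_table.csv", index=False)
        lmm = {}
        for segment in ("NTA", "DTA"):
            avg = model_average(table, segment=segment,
                                transform=config.lmm_transform)
            avg.table.to_csv(out / f"lmm_{segment.lower()}.csv")
            lmm[segment] = avg
        log.info("lmm: %d summary rows", len(table))

        stage = "snore"
        diffs = change_scores(snore, design)
        result = snore_table(diffs, threshold=config.snore_threshold)
        result.table.to_csv(out / "snore_table.csv")
        log.info("snore: %d change scores", len(diffs))
    except Exception as exc:
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    concordance = _concordance_note(flm_res, result)
    report = RunReport(
        config=_config_dict(config),
        version=__version__,
        seed=config.seed,
        flm=flm_res.to_dict(),
        lmm_nta=lmm["NTA"].table.to_dict(orient="index"),
        lmm_dta=lmm["DTA"].table.to_dict(orient="index"),
        snore=result.table.to_dict(orient="index"),
        concordance=concordance,
    )
    report.to_json(out / "report.json")
    if config.make_plot:
        make_figure(flm_res, out / "flm_figure.png")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    if d.get("input_dir"):
        d["input_dir"] = str(d["input_dir"])
    if config.design is not None:
        d["design"] = config.design.to_dict()
    return d


def _write_flm_curves(res: FLMResult, path: Path) -> None:
    pd.DataFrame(
        {
            "clock_minute": res.grid,
            "F_obs": res.F_obs,
            "crit": res.crit_curve,
            "p": res.p_curve,
            **{f"mean_{k}": v for k, v in res.mean_curves.items()},
        }
    ).to_csv(path, index=False)


def _concordance_note(flm_res: FLMResult, snore_res) -> str:
    night = [
        iv for iv in flm_res.significant_intervals
        if "drug" in iv.direction.split(">")[-1]  # drug lower
        and _overlaps_night(iv)
    ]
    snore_improved = bool(
        snore_res.table.loc["total_6q", "nsaid_vs_placebo_significant"]
        and snore_res.table.loc["total_6q", "nsaid_vs_placebo_mean_diff"] < 0
    )
    flm_improved = bool(night)
    if flm_improved and snore_improved:
        return ("concordant: reduced drug-condition night activity and "
                "owner-reported sleep improvement")
    if not flm_improved and not snore_improved:
        return "concordant: neither arm indicates a drug effect on night rest"
    return ("discordant: functional and questionnaire arms disagree on a "
            "night-rest improvement")


def _overlaps_night(iv) -> bool:
    night = iv.to_mask(1440)
    centers = np.arange(1440) + 0.5
    in_night = (centers >= 1380) | (centers < 390)
    return bool((night & in_night).any())


def make_figure(result: FLMResult, path: str | Path) -> Path:
    """Two-panel figure: group mean curves; observed F vs critical curve.

    Significant intervals are shaded in both panels.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
    hours = result.grid / 60.0
    colors = {result.conditions[0]: "#c62828", result.conditions[1]: "black"}
    for cond, curve in result.mean_curves.items():
        ax1.plot(hours, curve, label=cond, color=colors.get(cond))
    ax1.set_ylabel(f"mean activity ({result.transform} counts/min)")
    ax1.legend(loc="upper right")
    ax2.plot(hours, result.F_obs, color="black", label="observed F")
    ax2.plot(hours, result.crit_curve, linestyle=":", color="black",
             label=f"point-wise critical value (alpha={result.alpha})")
    ax2.set_xlabel("clock time (h)")
    ax2.set_ylabel("F")
    ax2.legend(loc="upper right")
    for ax in (ax1, ax2):
        for iv in result.significant_intervals:
            if iv.start_minute < iv.end_minute:
                spans = [(iv.start_minute, iv.end_minute)]
            else:
                spans = [(iv.start_minute, 1440.0), (0.0, iv.end_minute)]
            for s, e in spans:
                ax.axvspan(s / 60.0, e / 60.0, color="#fdd835", alpha=0.3, lw=0)
    ax2.set_xlim(0, 24)
    ax2.set_xticks(range(0, 25, 3))
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120, metadata={"Software": "actiflm"})
    plt.close(fig)
    return path
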