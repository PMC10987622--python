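"""End-to-end orchestration: simulate/load -> aggregate -> fit -> post hoc -> proportions.

Every stage writes a tidy table under the run's output directory so any
stage can be rerun or inspected alone; a ``summary.json`` collects fit
statistics, proportions and provenance (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import gam, posthoc, synth
from .errors import ConfigError, InferenceError
from .schedule import PhotoSchedule, period_windows, schedule_from_config

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "compare_regimens", "load_bundle_summary"]

log = logging.getLogger("photogam")


@dataclass
class RunConfig:
    """Validated run configuration (one of synthetic/input, a model, a posthoc block)."""

    schedule: PhotoSchedule
    synthetic: dict | None = None
    input: dict | None = None
    model: dict = field(default_factory=dict)
    posthoc: dict = field(default_factory=dict)
    alpha: float = 0.05
    numbering: str = "exclude_acclimation"
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input is None):
            raise ConfigError("config must set exactly one of 'synthetic' or 'input'")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, cfg: dict, seed: int | None = None) -> "RunConfig":
        if "schedule" not in cfg:
            raise ConfigError("config needs a 'schedule' block or preset name")
        schedule = schedule_from_config(cfg["schedule"])
        return cls(
            schedule=schedule,
            synthetic=cfg.get("synthetic"),
            input=cfg.get("input"),
            model=dict(cfg.get("model", {})),
            posthoc=dict(cfg.get("posthoc", {})),
            alpha=float(cfg.get("alpha", 0.05)),
            numbering=cfg.get("numbering", "exclude_acclimation"),
            seed=int(cfg.get("seed", 0) if seed is None else seed),
            raw=dict(cfg),
        )


@dataclass
class RunBundle:
    """Outputs of one pipeline run."""

    config: RunConfig
    schedule: PhotoSchedule
    fit: gam.GamFit
    series: pd.DataFrame
    contrasts: pd.DataFrame
    mask: pd.DataFrame
    proportions: dict[tuple[str, str], posthoc.PeriodProportion]
    summary: dict
    outdir: Path | None = None


def _synth_config(cfg: RunConfig) -> synth.SynthConfig:
    s = cfg.synthetic or {}
    genos = []
    for g in s.get("genotypes", [{"label": "WT"}]):
        genos.append(
            synth.GenotypeEffect(
                label=g["label"],
                baseline_scale=float(g.get("baseline_scale", 1.0)),
                light_scale=float(g.get("light_scale", 1.0)),
                surge_scale_by_light_duration={
                    int(k): float(v) for k, v in (g.get("surge_scale") or {}).items()
                },
            )
        )
    kwargs = {}
    for src, dst in [
        ("dark_mean", "dark_mean_mm_per_min"),
        ("light_mean", "light_mean_mm_per_min"),
        ("surge_peak", "surge_peak_mm_per_min"),
        ("surge_rise_tau", "surge_rise_tau_s"),
        ("surge_decay_tau", "surge_decay_tau_s"),
        ("zero_prob", "zero_prob"),
        ("lognormal_sigma", "lognormal_sigma"),
        ("assay_sd", "assay_sd"),
        ("fish_sd", "fish_sd"),
    ]:
        if src in s:
            kwargs[dst] = float(s[src])
    return synth.SynthConfig(
        schedule=cfg.schedule,
        n_assays=int(s.get("n_assays", 2)),
        fish_per_group_per_assay=int(s.get("fish_per_group", 12)),
        genotype_effects=tuple(genos),
        base_seed=cfg.seed,
        **kwargs,
    )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps({"raw": cfg.raw, "seed": cfg.seed}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig | dict,
    outdir: str | Path | None = None,
    save_activity: bool = False,
) -> RunBundle:
    """Execute the full analysis from one configuration.

    Stages: (1) simulate or load per-second displacements, (2) rolling-sum
    response per assay x group, (3) REML GAM fit, (4) per-second Tukey
    contrasts and significance mask, (5) per-photo-period proportions of
    significance.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    schedule = config.schedule
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    # -- stage 1: activity table
    if config.synthetic is not None:
        scfg = _synth_config(config)
        log.info("simulate: %d assays x %d fish/group", scfg.n_assays, scfg.fish_per_group_per_assay)
        raw = synth.simulate_experiment(scfg)
        table = agg.validate_activity(raw)
        if outpath is not None and save_activity:
            raw.to_csv(outpath / "activity.csv", index=False)
    else:
        path = config.input.get("tracking_csv")
        if not path:
            raise ConfigError("input block needs 'tracking_csv'")
        table = agg.load_tracking(path, config.input.get("factors"))

    # -- stage 2: response construction
    window_s = int(config.model.get("window_s", 60))
    series = agg.group_mean_series(table, window_s=window_s)
    step = int(config.model.get("downsample", 1))
    if step > 1:
        series = agg.downsample(series, step)
    series = agg.attach_analysis_time(series, schedule)
    if outpath is not None:
        series.to_csv(outpath / "rolling_series.csv", index=False)

    # -- stage 3: model fit
    factor = config.posthoc.get("factor") or config.model.get("by") or table.factors[0]
    linear_factors = tuple(config.model.get("linear_factors", [factor]))
    k = int(config.model.get("k", 40))
    spec = gam.GamSpec(
        response="rsum",
        linear_factors=linear_factors,
        smooths=(gam.SmoothSpec("Time", k, by=config.model.get("by", factor)),),
        random_effects=tuple(config.model.get("random_effects", ["assay_id"])),
    )
    fit_data = series[(series["valid"]) & (series["Time"] >= 1)].reset_index(drop=True)
    fit = gam.fit_reml(
        spec,
        fit_data,
        restarts=int(config.model.get("restarts", 3)),
        seed=config.seed,
    )
    log.info(
        "fit: edf=%.1f lambda=%s dev.expl=%.3f converged=%s",
        fit.edf_total,
        np.array2string(fit.lam, precision=3),
        fit.deviance_explained,
        fit.converged,
    )

    # -- stage 4: per-second contrasts and mask
    times = np.sort(fit_data["Time"].unique())
    contrasts = posthoc.contrast_series(fit, times, factor)
    mask = posthoc.significance_mask(contrasts, alpha=config.alpha)
    contrasts = contrasts.rename(columns={"time_s": "Time"})
    mask = mask.rename(columns={"time_s": "Time"})
    if outpath is not None:
        contrasts.to_csv(outpath / "contrasts.csv", index=False)
        mask.to_csv(outpath / "mask.csv", index=False)

    # -- stage 5: proportions per photo period
    phase = config.posthoc.get("phase", "dark")
    windows = period_windows(schedule, phase, config.numbering)
    wanted = config.posthoc.get("periods")
    if wanted:
        windows = [w for w in windows if w.ordinal in set(int(p) for p in wanted)]
    pairs = config.posthoc.get("pairs")
    if not pairs:
        levels = fit.design.factor_levels[factor]
        pairs = [[levels[0], lev] for lev in levels[1:]]
    proportions: dict[tuple[str, str], posthoc.PeriodProportion] = {}
    prop_rows = []
    for a, b in (tuple(p) for p in pairs):
        for w in windows:
            key = (f"{a}>{b}", f"{phase}{w.ordinal}")
            try:
                pp = posthoc.proportion_significant(mask, w, (a, b), time_column="Time")
            except InferenceError:
                continue
            proportions[key] = pp
            prop_rows.append(
                {
                    "pair": f"{a}>{b}",
                    "period": key[1],
                    "label": pp.period,
                    "proportion": pp.proportion,
                    "n_seconds": pp.n_seconds,
                }
            )
        if len(windows) > 1 and config.posthoc.get("pool", True):
            key = (f"{a}>{b}", f"{phase}_pooled")
            try:
                pp = posthoc.proportion_significant(mask, windows, (a, b), time_column="Time")
            except InferenceError:
                continue
            proportions[key] = pp
            prop_rows.append(
                {
                    "pair": f"{a}>{b}",
                    "period": key[1],
                    "label": pp.period,
                    "proportion": pp.proportion,
                    "n_seconds": pp.n_seconds,
                }
            )
    prop_table = pd.DataFrame(prop_rows)
    if outpath is not None and not prop_table.empty:
        prop_table.to_csv(outpath / "proportions.csv", index=False)

    summary = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "alpha": config.alpha,
            "numbering": config.numbering,
        },
        "schedule": schedule.to_config(),
        "fit": {
            "lambda": fit.lam.tolist(),
            "edf_total": fit.edf_total,
            "edf_terms": fit.edf_terms,
            "scale": fit.scale,
            "reml": fit.reml,
            "aic": fit.aic,
            "deviance_explained": fit.deviance_explained,
            "converged": fit.converged,
            "n_obs": fit.nobs,
            "linear_terms": fit.linear_term_tests().to_dict(orient="records"),
        },
        "proportions": {
            f"{pair}|{period}": {
                "proportion": pp.proportion,
                "n_seconds": pp.n_seconds,
                "label": pp.period,
            }
            for (pair, period), pp in proportions.items()
        },
    }
    if outpath is not None:
        (outpath / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        fit.coef_table().to_csv(outpath / "coefficients.csv", index=False)

    return RunBundle(
        config=config,
        schedule=schedule,
        fit=fit,
        series=series,
        contrasts=contrasts,
        mask=mask,
        proportions=proportions,
        summary=summary,
        outdir=outpath,
    )


def _lookup_proportion(
    bundle: RunBundle, period: str, pair: tuple[str, str]
) -> posthoc.PeriodProportion:
    key = (f"{pair[0]}>{pair[1]}", period)
    if key not in bundle.proportions:
        raise InferenceError(
            f"bundle has no proportion for pair {pair} in period {period!r}; "
            f"available: {sorted(bundle.proportions)}"
        )
    return bundle.proportions[key]


def compare_regimens(
    bundle_a: RunBundle,
    bundle_b: RunBundle,
    period: str,
    pair: tuple[str, str],
    yates: bool = True,
) -> posthoc.PropTestResult:
    """Yates-corrected two-proportion test between two regimens' proportions."""
    pa = _lookup_proportion(bundle_a, period, pair)
    pb = _lookup_proportion(bundle_b, period, pair)
    return posthoc.two_prop_test(
        pa.proportion, pa.n_seconds, pb.proportion, pb.n_seconds, yates=yates
    )


def load_bundle_summary(path: str | Path) -> dict:
    """Read a run's summary.json (for file-based regimen comparisons)."""
    return json.loads(Path(path).read_text())
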