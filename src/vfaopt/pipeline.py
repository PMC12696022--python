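"""End-to-end pipeline: data -> 12 fits -> 12 sweeps -> bootstrap -> tests.

Also hosts the pilot-scale comparison: once an optimum has been chosen from
bench-scale batch data, a pilot run at the optimal conditions is compared to
the model's prediction as a percent relative difference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import bootstrap as bs
from . import regression
from .design import ObservationTable, TreatmentKey, read_observations
from .errors import DomainError, ValidationError, VfaoptError
from .optimize import OptimalPoint, study_domain, sweep
from .regression import CubicSurfaceModel
from .simulate import DEFAULT_NOISE_SD, simulate_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PilotComparison:
    """Model prediction vs pilot observation, in % of the prediction."""

    predicted: float
    observed: float
    relative_difference: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pilot_comparison(predicted: float, observed: float) -> PilotComparison:
    """Percent difference 100 * (predicted - observed) / predicted.

    E.g. a 6975 mg COD/L prediction against a 6792 mg COD/L pilot maximum is
    a 2.6 % difference.
    """
    if not predicted > 0:
        raise DomainError(f"predicted must be positive, got {predicted}")
    return PilotComparison(
        predicted=predicted,
        observed=observed,
        relative_difference=100.0 * (predicted - observed) / predicted,
    )


@dataclass
class PipelineConfig:
    """One configuration object governs every stage; defaults mirror the
    study's stated parameters (0.05 lattice, B = 300, alpha = 0.05, noise SD
    516 mg COD/L)."""

    input_csv: str | None = None
    seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    replicates: int = 3
    bootstrap_b: int = 300
    alpha: float = 0.05
    resolution: float = 0.05
    censor: str = "step"
    bootstrap_center: str = "cell_means"
    df_per_treatment: int | None = None  # None: use the regression residual df
    clip_domain_to_data: bool = True  # never place the optimum outside the sampled span
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("noise_sd", "resolution"):
            if getattr(self, name) < 0 or (name == "resolution" and self.resolution == 0):
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if self.bootstrap_b < 2 or self.replicates < 1:
            raise DomainError("bootstrap_b must be >= 2 and replicates >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    observations: ObservationTable
    models: dict[TreatmentKey, CubicSurfaceModel]
    optima: dict[TreatmentKey, OptimalPoint]
    distributions: dict[TreatmentKey, bs.BootstrapDistribution]
    anova: bs.AnovaResult
    ttest: bs.TwoSampleTTest
    best_treatment: TreatmentKey
    pareto: list[tuple[str, float, bool]]
    summary: str = ""


def _stage(name: str, key: TreatmentKey | None = None):
    """Context wrapper so stage failures name the stage and treatment."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                where = f"stage {name!r}" + (f", treatment {key.label}" if key else "")
                raise VfaoptError(f"{where}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and (optionally) write the report bundle."""
    with _stage("input"):
        if config.input_csv:
            observations = read_observations(config.input_csv)
            logger.info("read observations from %s (%d rows)", config.input_csv, len(observations))
        else:
            observations = simulate_study(
                seed=config.seed, noise_sd=config.noise_sd, replicates=config.replicates
            )
            logger.info("simulated study with seed=%d noise_sd=%g (%d rows)",
                        config.seed, config.noise_sd, len(observations))
    if config.clip_domain_to_data:
        df = observations.df
        domain = study_domain(
            censor=config.censor,
            resolution=config.resolution,
            temp_range=(float(df["temperature"].min()), float(df["temperature"].max())),
            day_range=(float(df["day"].min()), float(df["day"].max())),
        )
    else:
        domain = study_domain(censor=config.censor, resolution=config.resolution)
    treatments = observations.treatments()

    models: dict[TreatmentKey, CubicSurfaceModel] = {}
    optima: dict[TreatmentKey, OptimalPoint] = {}
    for key in treatments:
        with _stage("fit", key):
            models[key] = regression.fit(observations, key)
        with _stage("optimize", key):
            optima[key] = sweep(models[key], domain)

    distributions: dict[TreatmentKey, bs.BootstrapDistribution] = {}
    for key in treatments:
        with _stage("bootstrap", key):
            logger.info("bootstrap for %s: B=%d seed=%d", key.label, config.bootstrap_b, config.seed)
            distributions[key] = bs.bootstrap_optima(
                observations, key, B=config.bootstrap_b, seed=config.seed,
                domain=domain, center=config.bootstrap_center,
            )

    df_pt = config.df_per_treatment
    if df_pt is None:
        df_pt = min(m.residual_df for m in models.values())
    dists = [distributions[k] for k in treatments]
    with _stage("anova"):
        anova = bs.anova_optima(dists, df_per_treatment=df_pt, alpha=config.alpha)
    with _stage("ttest"):
        ttest = bs.t_test_top_two(dists, alpha=config.alpha, df_per_treatment=df_pt)

    best = max(treatments, key=lambda k: optima[k].predicted_vfa)
    with _stage("pareto", best):
        pareto = regression.pareto_rank(models[best], alpha=config.alpha)

    result = PipelineResult(
        config=config,
        observations=observations,
        models=models,
        optima=optima,
        distributions=distributions,
        anova=anova,
        ttest=ttest,
        best_treatment=best,
        pareto=pareto,
    )
    result.summary = _render_summary(result)
    if config.output_dir:
        write_report_bundle(result, config.output_dir)
    return result


def _render_summary(result: PipelineResult) -> str:
    """Human-readable report; 3 decimals for statistics, integers for mg COD/L."""
    lines = ["Treatment ranking by optimal predicted VFA (mg COD/L):"]
    ranked = sorted(result.optima.items(), key=lambda kv: -kv[1].predicted_vfa)
    for i, (key, opt) in enumerate(ranked, start=1):
        model = result.models[key]
        lines.append(
            f"  {i:2d}. {key.label:<12s} {opt.predicted_vfa:7.0f} at "
            f"{opt.temperature:.2f} degC / {opt.day:.2f} d   "
            f"(r2={model.r_squared:.3f}, df={model.residual_df})"
        )
    a = result.anova
    lines += [
        "",
        f"ANOVA of bootstrap optimal VFA: F={a.f_stat:.3f} "
        f"(df {a.df_between}/{a.df_within}), p={a.p_value:.3f}, "
        f"critical F={a.f_critical:.3f} at alpha={a.alpha:g}",
    ]
    t = result.ttest
    lines += [
        f"t-test, two best ({t.treatment1.label} vs {t.treatment2.label}): "
        f"means {t.mean1:.0f} vs {t.mean2:.0f}, SDs {t.sd1:.0f} vs {t.sd2:.0f}, "
        f"t={t.t_stat:.3f}, critical t={t.t_critical:.3f}, "
        f"{'reject' if t.reject_null else 'do not reject'} equal means",
        "",
        f"Pareto |t|-ranking of the best model's terms ({result.best_treatment.label}):",
    ]
    for name, tval, sig in result.pareto:
        lines.append(f"  {name:<6s} |t|={tval:8.3f}  {'significant' if sig else 'ns'}")
    return "\n".join(lines) + "\n"


def write_report_bundle(result: PipelineResult, out_dir: str) -> None:
    """Write CSV/JSON artifacts plus the text summary; full precision in JSON."""
    os.makedirs(out_dir, exist_ok=True)

    def dump(name: str, payload) -> None:
        with open(os.path.join(out_dir, name), "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    result.observations.write_csv(os.path.join(out_dir, "observations.csv"))
    keys = sorted(result.models)
    dump("models.json", [result.models[k].to_dict() for k in keys])
    dump("optima.json", [
        {"treatment": k.label, **result.optima[k].to_dict()} for k in keys
    ])
    pd.concat(
        [result.distributions[k].to_dataframe() for k in keys], ignore_index=True
    ).to_csv(os.path.join(out_dir, "bootstrap_optima.csv"), index=False)
    dump("bootstrap_summary.json", [result.distributions[k].summary() for k in keys])
    dump("anova.json", result.anova.to_dict())
    dump("ttest.json", result.ttest.to_dict())
    dump("pareto.json", [
        {"term": name, "abs_t": tval, "significant": sig} for name, tval, sig in result.pareto
    ])
    dump("config.json", result.config.to_dict())
    with open(os.path.join(out_dir, "summary.txt"), "w", encoding="utf-8") as fh:
        fh.write(result.summary)
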