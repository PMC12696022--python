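"""Bootstrap uncertainty of the production optimum and between-treatment tests.

The optimum of a fitted response surface is the arg-max of a nonlinear
functional of the data; its sampling variability has no convenient closed
form.  A parametric bootstrap propagates replicate noise through the whole
resample -> refit -> re-sweep chain: each pseudo-dataset keeps the design
skeleton and replaces every replicate value by its cell mean plus Gaussian
noise at the treatment's pooled within-cell SD (equal, normal variability in
every experimental cell).  The resulting distributions of optimal VFA feed a
one-way ANOVA across all treatments and a two-sample t-test between the two
best, with the per-group degrees of freedom set explicitly — conventionally
to those left by the polynomial regression, not to B - 1.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ObservationTable, TreatmentKey
from .errors import DomainError, SingularDesignError, ValidationError
from .optimize import FeasibleDomain, OptimalPoint, study_domain, sweep
from .regression import CubicSurfaceModel, fit

logger = logging.getLogger(__name__)

_MAX_RETRIES = 5  # singular refits are retried with a fresh sub-seed, then fail hard


def critical_t(alpha: float, df: int) -> float:
    """Two-sided critical t: the (1 - alpha/2) quantile at df degrees of freedom."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def critical_f(alpha: float, df1: int, df2: int) -> float:
    """Upper critical F: the (1 - alpha) quantile at (df1, df2) degrees of freedom."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise DomainError(f"dfs must be >= 1, got ({df1}, {df2})")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def _cells(rows: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return rows.groupby(["temperature", "day"], sort=True)


def pooled_within_cell_sd(rows: pd.DataFrame) -> float:
    """Pooled SD of replicates around their (temperature, day) cell means."""
    ss, df = 0.0, 0
    for _, cell in _cells(rows):
        n = len(cell)
        if n >= 2:
            v = cell["vfa_mg_cod_per_l"].to_numpy(dtype=float)
            ss += float(np.sum((v - v.mean()) ** 2))
            df += n - 1
    if df == 0:
        raise ValidationError(
            "pooled within-cell SD undefined: no cell has at least 2 replicates"
        )
    return float(np.sqrt(ss / df))


def parametric_resample(
    observations: ObservationTable,
    treatment: TreatmentKey,
    seed: int,
    center: str = "cell_means",
    model: CubicSurfaceModel | None = None,
) -> ObservationTable:
    """One pseudo-dataset on the original design skeleton.

    Each replicate value is replaced by the cell's center plus
    N(0, pooled within-cell SD).  ``center='cell_means'`` (default) makes the
    fewest model assumptions; ``center='fitted'`` centers on the fitted
    surface instead (model-based bootstrap) and requires ``model``.
    """
    rows = observations.subset(treatment)
    if rows.empty:
        raise ValidationError(f"no observations for treatment {treatment.label}")
    sd = pooled_within_cell_sd(rows)
    if center == "cell_means":
        centers = _cells(rows)["vfa_mg_cod_per_l"].transform("mean").to_numpy(dtype=float)
    elif center == "fitted":
        if model is None:
            raise ValidationError("center='fitted' requires a fitted model")
        centers = model.predict(rows["temperature"].to_numpy(), rows["day"].to_numpy())
    else:
        raise ValidationError(f"unknown center {center!r}; use 'cell_means' or 'fitted'")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    noise = rng.normal(0.0, sd, size=len(rows)) if sd > 0 else np.zeros(len(rows))
    out = rows.copy()
    out["vfa_mg_cod_per_l"] = np.maximum(0.0, centers + noise)
    return ObservationTable(out, provenance=f"bootstrap resample seed={seed}")


@dataclass
class BootstrapDistribution:
    """B simulated optima for one treatment, with summary mean/SD of optimal VFA."""

    treatment: TreatmentKey
    optima: list[OptimalPoint]
    B: int
    seed: int
    mean_opt_vfa: float
    sd_opt_vfa: float

    def values(self) -> np.ndarray:
        return np.array([o.predicted_vfa for o in self.optima])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment.label,
                "replicate": np.arange(1, self.B + 1),
                "temperature": [o.temperature for o in self.optima],
                "day": [o.day for o in self.optima],
                "predicted_vfa": [o.predicted_vfa for o in self.optima],
            }
        )

    def summary(self) -> dict:
        return {
            "treatment": self.treatment.label,
            "B": self.B,
            "seed": self.seed,
            "mean_opt_vfa": self.mean_opt_vfa,
            "sd_opt_vfa": self.sd_opt_vfa,
        }


def bootstrap_optima(
    observations: ObservationTable,
    treatment: TreatmentKey,
    B: int = 300,
    seed: int = 0,
    domain: FeasibleDomain | None = None,
    center: str = "cell_means",
) -> BootstrapDistribution:
    """B independent resample -> fit -> sweep cycles for one treatment.

    Deterministic given ``seed``; a singular refit (possible in degenerate
    resamples) is retried with a fresh sub-seed up to 5 times, logged, then
    raised.
    """
    if B < 2:
        raise DomainError(f"B must be >= 2, got {B}")
    domain = domain if domain is not None else study_domain()
    base_model = fit(observations, treatment)  # validates the treatment has a fit
    # salt the stream by treatment so equal seeds never share noise across groups
    salt = zlib.crc32(treatment.label.encode())
    optima: list[OptimalPoint] = []
    for b in range(B):
        for attempt in range(_MAX_RETRIES + 1):
            sub_seed = (int(seed) * 1_000_003 + salt + b * 7 + attempt * 2_654_435) & 0x7FFFFFFF
            try:
                pseudo = parametric_resample(
                    observations, treatment, seed=sub_seed, center=center,
                    model=base_model if center == "fitted" else None,
                )
                model = fit(pseudo, treatment)
                break
            except SingularDesignError:
                logger.warning(
                    "singular refit for %s replicate %d (seed %d), retry %d",
                    treatment.label, b, sub_seed, attempt + 1,
                )
                if attempt == _MAX_RETRIES:
                    raise
        optima.append(sweep(model, domain))
    values = np.array([o.predicted_vfa for o in optima])
    return BootstrapDistribution(
        treatment=treatment,
        optima=optima,
        B=B,
        seed=int(seed),
        mean_opt_vfa=float(values.mean()),
        sd_opt_vfa=float(values.std(ddof=1)),
    )


@dataclass
class AnovaResult:
    """One-way ANOVA of optimal VFA across treatments, regression-adjusted df."""

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    f_critical: float
    alpha: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "ss_between", "ss_within", "ss_total",
            "df_between", "df_within", "df_total",
            "ms_between", "ms_within", "f_stat", "p_value", "f_critical", "alpha",
        )}


def anova_optima(
    distributions: list[BootstrapDistribution],
    df_per_treatment: int,
    alpha: float = 0.05,
) -> AnovaResult:
    """F-test of equal mean optimal VFA with explicit per-group df.

    Each group is treated as a pseudo-sample of size ``df_per_treatment + 1``:
    the mean-square within is the pooled bootstrap variance, the between
    sum of squares scales group-mean spread by the pseudo-sample size, and
    the F statistic is referred to F(k-1, k*df_per_treatment).  With
    ``df_per_treatment = B - 1`` this is exactly the classical one-way ANOVA
    on the bootstrap values; smaller df reproduce the convention of reducing
    the degrees of freedom to those available in the polynomial regression.
    """
    if len(distributions) < 2:
        raise ValidationError("ANOVA requires at least 2 treatment distributions")
    if df_per_treatment < 1:
        raise DomainError(f"df_per_treatment must be >= 1, got {df_per_treatment}")
    sizes = {d.B for d in distributions}
    if len(sizes) != 1:
        raise ValidationError(
            f"mismatched bootstrap sizes across groups: {sorted(sizes)}; "
            "resample to a common B before the ANOVA"
        )
    groups = [d.values() for d in distributions]
    k = len(groups)
    n_pseudo = df_per_treatment + 1
    means = np.array([g.mean() for g in groups])
    grand = means.mean()
    ms_within = float(np.mean([g.var(ddof=1) for g in groups]))
    df_between = k - 1
    df_within = k * df_per_treatment
    ss_between = float(n_pseudo * np.sum((means - grand) ** 2))
    ss_within = ms_within * df_within
    ms_between = ss_between / df_between
    if ms_within == 0.0:  # degenerate (e.g. zero-noise data): decide by ss_between
        f_stat = np.inf if ms_between > 0 else 0.0
    else:
        f_stat = ms_between / ms_within
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        df_total=df_between + df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        f_stat=float(f_stat),
        p_value=float(stats.f.sf(f_stat, df_between, df_within)),
        f_critical=critical_f(alpha, df_between, df_within),
        alpha=alpha,
    )


@dataclass
class TwoSampleTTest:
    """Two-sample comparison of the two best treatments' optimal VFA."""

    treatment1: TreatmentKey
    treatment2: TreatmentKey
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    df1: int
    df2: int
    t_stat: float
    t_critical: float
    reject_null: bool
    alpha: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mean1", "mean2", "sd1", "sd2", "df1", "df2",
            "t_stat", "t_critical", "reject_null", "alpha",
        )}
        d["treatment1"] = self.treatment1.label
        d["treatment2"] = self.treatment2.label
        return d


def t_test_summaries(
    mean1: float, sd1: float, df1: int,
    mean2: float, sd2: float, df2: int,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[float, float, int]:
    """(t statistic, critical t, test df) from group summaries.

    Pooled-variance by default (the equal-variance assumption the bootstrap
    itself makes), with each group's sample size taken as df + 1; Welch as
    an option.
    """
    n1, n2 = df1 + 1, df2 + 1
    if equal_var:
        sp2 = (df1 * sd1**2 + df2 * sd2**2) / (df1 + df2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df_test = df1 + df2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df_test = int(np.floor((v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)))
    t_stat = 0.0 if se == 0 and mean1 == mean2 else (mean1 - mean2) / se
    return float(t_stat), critical_t(alpha, df_test), df_test


def t_test_top_two(
    distributions: list[BootstrapDistribution],
    alpha: float = 0.05,
    df_per_treatment: int | None = None,
    equal_var: bool = True,
) -> TwoSampleTTest:
    """t-test between the two treatments with the highest mean optimal VFA.

    ``df_per_treatment`` defaults to B - 1 (the bootstrap sample df); pass
    the regression residual df to reproduce the reduced-df convention.
    """
    if len(distributions) < 2:
        raise ValidationError("need at least 2 distributions to compare the top two")
    ranked = sorted(distributions, key=lambda d: -d.mean_opt_vfa)
    top, runner = ranked[0], ranked[1]
    df1 = df2 = df_per_treatment if df_per_treatment is not None else top.B - 1
    t_stat, t_crit, _ = t_test_summaries(
        top.mean_opt_vfa, top.sd_opt_vfa, df1,
        runner.mean_opt_vfa, runner.sd_opt_vfa, df2,
        alpha=alpha, equal_var=equal_var,
    )
    return TwoSampleTTest(
        treatment1=top.treatment,
        treatment2=runner.treatment,
        mean1=top.mean_opt_vfa,
        mean2=runner.mean_opt_vfa,
        sd1=top.sd_opt_vfa,
        sd2=runner.sd_opt_vfa,
        df1=df1,
        df2=df2,
        t_stat=t_stat,
        t_critical=t_crit,
        reject_null=bool(abs(t_stat) > t_crit),
        alpha=alpha,
    )
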