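"""Bivariate cubic polynomial regression of VFA production.

Each treatment's VFA response is modeled as a full third-degree polynomial
in temperature ``t`` (°C) and retention day ``d``:

    VFA(t, d) = b0 + b1 t + b2 d + b3 t^2 + b4 t d + b5 d^2
                + b6 t^3 + b7 t^2 d + b8 t d^2 + b9 d^3

fitted by unweighted ordinary least squares on replicate-level rows
(replicates are individual points, never averaged — with replicate noise a
perfect mean model therefore cannot reach r^2 = 1).

Numerical note: raw monomials reach t^3 ~ 1.7e5, so the solve runs on a
column-normalized design matrix and maps coefficients and standard errors
back to the raw monomial scale; t-values are invariant under column scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .design import ObservationTable, TreatmentKey
from .errors import SingularDesignError, UnderDeterminedError

#: Fixed coefficient order of the cubic model.
TERM_NAMES = ("1", "t", "d", "t^2", "t*d", "d^2", "t^3", "t^2*d", "t*d^2", "d^3")

_RCOND = 1e-10  # relative singular-value cutoff for rank checks


def poly_exponents(degree: int) -> list[tuple[int, int]]:
    """(t-power, d-power) pairs of the full bivariate polynomial basis.

    Ordered by total degree, then descending t-power; the degree-3 basis is
    exactly the fixed cubic order above.
    """
    return [(i, k - i) for k in range(degree + 1) for i in range(k, -1, -1)]


def poly_design_matrix(temperature, day, degree: int) -> np.ndarray:
    t = np.asarray(temperature, dtype=float).ravel()
    d = np.asarray(day, dtype=float).ravel()
    if t.size == 0:
        raise UnderDeterminedError("design matrix requires at least one point")
    return np.column_stack([t**i * d**j for i, j in poly_exponents(degree)])


def build_design_matrix(temperature, day) -> np.ndarray:
    """n x 10 cubic design matrix, columns [1, t, d, t^2, t*d, d^2, t^3, t^2*d, t*d^2, d^3]."""
    return poly_design_matrix(temperature, day, 3)


def term_names(degree: int) -> tuple[str, ...]:
    def name(i: int, j: int) -> str:
        parts = []
        if i:
            parts.append("t" if i == 1 else f"t^{i}")
        if j:
            parts.append("d" if j == 1 else f"d^{j}")
        return "*".join(parts) if parts else "1"

    return tuple(name(i, j) for i, j in poly_exponents(degree))


@dataclass
class OlsFit:
    """Raw-scale OLS solution with classical homoscedastic diagnostics."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    r_squared: float
    residual_df: int
    residual_sd: float
    n_rows: int


def _ols(
    X: np.ndarray, y: np.ndarray, names: tuple[str, ...], allow_rank_deficient: bool = False
) -> OlsFit:
    n, p = X.shape
    if n < p + 1 and not allow_rank_deficient:
        raise UnderDeterminedError(
            f"need at least {p + 1} rows to fit {p} coefficients with residual df >= 1, got {n}"
        )
    scales = np.linalg.norm(X, axis=0)
    if np.any(scales == 0):
        dead = [names[i] for i in np.flatnonzero(scales == 0)]
        raise SingularDesignError(f"all-zero design column(s): {', '.join(dead)}")
    Z = X / scales
    # rank check on the conditioned matrix; name the dependent columns
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s >= _RCOND * s[0]))
    if rank < p and not allow_rank_deficient:
        null = np.abs(vt[-1])
        dep = [names[i] for i in np.flatnonzero(null > 0.1)]
        raise SingularDesignError(
            f"design matrix is rank-deficient; dependent column(s): {', '.join(dep)}"
        )
    df = n - rank
    if df < 1:
        raise UnderDeterminedError(f"residual df {df} < 1 with {n} rows and rank {rank}")
    res = sm.OLS(y, Z).fit()
    beta = res.params / scales
    se = res.bse / scales
    resid = y - Z @ res.params
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if (sst == 0.0 and ssr <= 1e-12) else 1.0 - ssr / sst if sst > 0 else -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return OlsFit(
        coefficients=beta,
        standard_errors=se,
        t_values=tvals,
        r_squared=r2,
        residual_df=df,
        residual_sd=float(np.sqrt(ssr / df)),
        n_rows=n,
    )


@dataclass
class CubicSurfaceModel:
    """Fitted cubic surface for one treatment, raw monomial scale (mg COD/L)."""

    treatment: TreatmentKey
    coefficients: np.ndarray
    r_squared: float
    coef_t_values: np.ndarray
    coef_standard_errors: np.ndarray
    residual_df: int
    residual_sd: float
    n_rows: int

    def predict(self, temperature, day):
        values = build_design_matrix(temperature, day) @ self.coefficients
        return float(values[0]) if np.isscalar(temperature) and np.isscalar(day) else values

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        """(10, 2) array of classical OLS CIs for the coefficients."""
        half = stats.t.ppf(1 - alpha / 2, self.residual_df) * self.coef_standard_errors
        return np.column_stack([self.coefficients - half, self.coefficients + half])

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment.label,
            "coefficients": [float(b) for b in self.coefficients],
            "r2": self.r_squared,
            "t_values": [float(t) for t in self.coef_t_values],
            "standard_errors": [float(s) for s in self.coef_standard_errors],
            "residual_df": self.residual_df,
            "residual_sd": self.residual_sd,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CubicSurfaceModel":
        return cls(
            treatment=TreatmentKey.from_label(payload["treatment"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            r_squared=float(payload["r2"]),
            coef_t_values=np.asarray(payload["t_values"], dtype=float),
            coef_standard_errors=np.asarray(payload["standard_errors"], dtype=float),
            residual_df=int(payload["residual_df"]),
            residual_sd=float(payload["residual_sd"]),
            n_rows=int(payload["n_rows"]),
        )


def fit(observations: ObservationTable, treatment: TreatmentKey) -> CubicSurfaceModel:
    """OLS cubic fit for one treatment; requires >= 11 replicate rows."""
    rows = observations.subset(treatment)
    if rows.empty:
        raise UnderDeterminedError(f"no observations for treatment {treatment.label}")
    X = build_design_matrix(rows["temperature"].to_numpy(), rows["day"].to_numpy())
    y = rows["vfa_mg_cod_per_l"].to_numpy(dtype=float)
    sol = _ols(X, y, TERM_NAMES)
    return CubicSurfaceModel(
        treatment=treatment,
        coefficients=sol.coefficients,
        r_squared=sol.r_squared,
        coef_t_values=sol.t_values,
        coef_standard_errors=sol.standard_errors,
        residual_df=sol.residual_df,
        residual_sd=sol.residual_sd,
        n_rows=sol.n_rows,
    )


def predict(model: CubicSurfaceModel, temperature, day):
    """Evaluate the fitted polynomial at (temperature, day)."""
    return model.predict(temperature, day)


def pareto_rank(
    model: CubicSurfaceModel, alpha: float = 0.05
) -> list[tuple[str, float, bool]]:
    """Terms ranked by decreasing |t|, flagged against the two-sided critical t.

    The ranking justifies the polynomial degree: strongly significant cubic
    terms mean a quadratic surface could not represent the response.  The
    intercept is ranked like any other term.
    """
    threshold = stats.t.ppf(1 - alpha / 2, model.residual_df)
    ranked = sorted(
        zip(TERM_NAMES, np.abs(model.coef_t_values)), key=lambda kv: -kv[1]
    )
    return [(name, float(t), bool(t > threshold)) for name, t in ranked]


@dataclass
class DegreeFit:
    degree: int
    n_terms: int
    r_squared: float
    adj_r_squared: float
    residual_df: int


@dataclass
class DegreeComparison:
    """r^2 / adjusted r^2 / residual df across polynomial degrees 2, 3, 4.

    Used to check that degree 3 is a good simplicity/accuracy balance: the
    cubic should clearly beat the quadratic while the quartic should not
    improve much despite spending five more parameters.
    """

    fits: dict[int, DegreeFit] = field(default_factory=dict)

    def __getitem__(self, degree: int) -> DegreeFit:
        return self.fits[degree]


def compare_degrees(
    observations: ObservationTable,
    treatment: TreatmentKey,
    degrees: tuple[int, ...] = (2, 3, 4),
) -> DegreeComparison:
    rows = observations.subset(treatment)
    if rows.empty:
        raise UnderDeterminedError(f"no observations for treatment {treatment.label}")
    t = rows["temperature"].to_numpy()
    d = rows["day"].to_numpy()
    y = rows["vfa_mg_cod_per_l"].to_numpy(dtype=float)
    comparison = DegreeComparison()
    for degree in degrees:
        X = poly_design_matrix(t, d, degree)
        # factorial designs with few temperature levels cannot identify every
        # high-degree monomial (t^4 on four levels); use the minimum-norm
        # projection there, with df from the effective rank
        sol = _ols(X, y, term_names(degree), allow_rank_deficient=True)
        n, p = sol.n_rows, X.shape[1]
        adj = 1.0 - (1.0 - sol.r_squared) * (n - 1) / sol.residual_df
        comparison.fits[degree] = DegreeFit(
            degree=degree,
            n_terms=p,
            r_squared=sol.r_squared,
            adj_r_squared=adj,
            residual_df=sol.residual_df,
        )
    return comparison
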