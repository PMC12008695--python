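"""Hypothesis-testing layer: paired t with Cohen's dz, OLS regression,
moderation and simple mediation with percentile bootstrap, the experience
subgroup contrast, and a-priori sample-size computation.

The mediation follows the classic three-regression decomposition: with
exposure X, mediator M and outcome Y,

    a  :  M = i1 + a·X            (exposure → mediator)
    b, c' :  Y = i2 + c'·X + b·M  (mediator → outcome given exposure)
    c  :  Y = i3 + c·X            (total effect)

all by OLS with unstandardised coefficients; the indirect effect is a·b and
``c = c' + a·b`` holds as an algebraic identity.  Confidence intervals for the
indirect effect use a nonparametric case-resampling percentile bootstrap
(5000 resamples by default); an effect is called significant when the CI
excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """The data cannot support the requested test (zero variance, rank deficiency…)."""


# ---------------------------------------------------------------------------
# paired and two-sample t tests
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """A t-test result with Cohen's effect size and group descriptives.

    ``effect_size`` is Cohen's dz = mean(diff)/sd(diff) for the paired design
    and pooled-SD Cohen's d for the two-sample design.
    """

    statistic: float
    df: float
    pvalue: float
    effect_size: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n: int
    design: str = "paired"

    def as_dict(self) -> dict:
        return {
            "design": self.design,
            "t": self.statistic,
            "df": self.df,
            "p": self.pvalue,
            "effect_size": self.effect_size,
            "mean_x": self.mean_x,
            "mean_y": self.mean_y,
            "sd_x": self.sd_x,
            "sd_y": self.sd_y,
            "n": self.n,
        }


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test with Cohen's dz; pairwise-complete filtering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise DegenerateDataError("paired t needs at least 2 complete pairs")
    d = x - y
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise DegenerateDataError("zero variance of paired differences")
    t = d.mean() / (sd_d / np.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        pvalue=float(p),
        effect_size=float(d.mean() / sd_d),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        n=int(n),
        design="paired",
    )


def two_sample_t(x, y) -> TestResult:
    """Classical pooled-variance two-sample t-test with pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if pooled == 0:
        raise DegenerateDataError("zero pooled variance")
    se = np.sqrt(pooled * (1 / nx + 1 / ny))
    t = (x.mean() - y.mean()) / se
    df = nx + ny - 2
    return TestResult(
        statistic=float(t),
        df=float(df),
        pvalue=float(2 * stats.t.sf(abs(t), df)),
        effect_size=float((x.mean() - y.mean()) / np.sqrt(pooled)),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        n=int(nx + ny),
        design="two-sample",
    )


# ---------------------------------------------------------------------------
# OLS regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Unstandardised OLS fit: coefficients, classical SEs, R², omnibus F."""

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    rsquared: float
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float
    nobs: int

    def as_dict(self) -> dict:
        return {
            "coef": self.params,
            "se": self.bse,
            "t": self.tvalues,
            "p": self.pvalues,
            "r_squared": self.rsquared,
            "F": self.fvalue,
            "F_p": self.f_pvalue,
            "df": [self.df_model, self.df_resid],
            "n": self.nobs,
        }


def _complete_cases(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.dropna()


def ols(outcome, predictors, add_constant: bool = True) -> RegressionResult:
    """OLS of ``outcome`` on ``predictors`` (listwise-complete); wraps statsmodels."""
    X = pd.DataFrame(predictors).reset_index(drop=True)
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    data = pd.concat([y, X], axis=1).dropna()
    if add_constant:
        design = sm.add_constant(data[X.columns], has_constant="add")
    else:
        design = data[X.columns]
    if len(data) <= design.shape[1]:
        raise DegenerateDataError("too few complete cases for the design")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DegenerateDataError("singular design matrix")
    fit = sm.OLS(data["y"], design).fit()
    return RegressionResult(
        params=dict(fit.params),
        bse=dict(fit.bse),
        tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues),
        rsquared=float(fit.rsquared),
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        nobs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# mediation (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------


def _boot_chunks(n_boot: int, n: int) -> list[int]:
    """Split replicates into chunks bounding the (replicates × n) workspace."""
    per_chunk = max(1, 2_000_000 // max(n, 1))
    sizes = [per_chunk] * (n_boot // per_chunk)
    if n_boot % per_chunk:
        sizes.append(n_boot % per_chunk)
    return sizes


def _boot_indirect(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised case-resampling bootstrap of a·b (closed-form 1- and 2-predictor OLS)."""
    n = x.size
    out = [
        _boot_indirect_block(x, m, y, block, rng) for block in _boot_chunks(n_boot, n)
    ]
    return np.concatenate(out)


def _boot_indirect_block(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        det = sxx * smm - sxm**2
        b = (sxx * smy - sxm * sxy) / det
    return a * b


@dataclass
class MediationResults:
    """Simple-mediation estimates with a percentile-bootstrap CI on a·b.

    ``significant`` follows the CI-excludes-zero rule.
    """

    a: float
    a_se: float
    b: float
    b_se: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int | None
    n: int
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "a_se": self.a_se,
            "b": self.b,
            "b_se": self.b_se,
            "total_c": self.c,
            "direct_c_prime": self.c_prime,
            "indirect": self.indirect,
            "indirect_ci": [self.ci_low, self.ci_high],
            "ci_level": self.ci_level,
            "significant": self.significant,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
            **({"variables": self.labels} if self.labels else {}),
        }

    def summary(self) -> str:
        v = self.labels or {"x": "X", "m": "M", "y": "Y"}
        lines = [
            f"Simple mediation: {v.get('x', 'X')} -> {v.get('m', 'M')} -> {v.get('y', 'Y')}"
            f"  (n={self.n})",
            f"  a (X->M)        = {self.a: .4f} (SE {self.a_se:.4f})",
            f"  b (M->Y | X)    = {self.b: .4f} (SE {self.b_se:.4f})",
            f"  c  (total)      = {self.c: .4f}",
            f"  c' (direct)     = {self.c_prime: .4f}",
            f"  a*b (indirect)  = {self.indirect: .4f}, "
            f"{100 * self.ci_level:.0f}% bootstrap CI "
            f"[{self.ci_low: .4f}, {self.ci_high: .4f}] "
            f"({'significant' if self.significant else 'not significant'}; "
            f"{self.n_boot} resamples)",
        ]
        return "\n".join(lines)


class Mediation:
    """Simple mediation model X → M → Y, fitted by three OLS regressions.

    Parameters are array-likes of equal length; incomplete cases are dropped
    listwise.  ``fit`` draws a case-resampling percentile bootstrap for the
    indirect effect.
    """

    def __init__(self, x, m, y, labels: dict[str, str] | None = None):
        frame = pd.DataFrame(
            {
                "x": np.asarray(x, dtype=float),
                "m": np.asarray(m, dtype=float),
                "y": np.asarray(y, dtype=float),
            }
        ).dropna()
        if len(frame) < 10:
            raise DegenerateDataError("mediation needs at least 10 complete cases")
        for col in ("x", "m", "y"):
            if frame[col].var(ddof=1) == 0:
                raise DegenerateDataError(f"zero variance in {col}")
        self.data = frame.reset_index(drop=True)
        self.labels = labels or {}

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exposure: str, mediator: str, outcome: str):
        return cls(
            data[exposure],
            data[mediator],
            data[outcome],
            labels={"x": exposure, "m": mediator, "y": outcome},
        )

    def fit(
        self, n_boot: int = 5000, seed: int | None = None, ci_level: float = 0.95
    ) -> MediationResults:
        d = self.data
        fit_a = sm.OLS(d["m"], sm.add_constant(d[["x"]])).fit()
        fit_b = sm.OLS(d["y"], sm.add_constant(d[["x", "m"]])).fit()
        fit_c = sm.OLS(d["y"], sm.add_constant(d[["x"]])).fit()
        a, b = float(fit_a.params["x"]), float(fit_b.params["m"])
        rng = np.random.default_rng(seed)
        boot = _boot_indirect(
            d["x"].to_numpy(), d["m"].to_numpy(), d["y"].to_numpy(), n_boot, rng
        )
        boot = boot[np.isfinite(boot)]
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        if not (lo <= a * b <= hi):
            # percentile bootstrap does not guarantee containment of the
            # point estimate; surface it rather than hide it
            logger.warning(
                "bootstrap CI [%.4g, %.4g] does not contain the indirect "
                "estimate %.4g", lo, hi, a * b
            )
        return MediationResults(
            a=a,
            a_se=float(fit_a.bse["x"]),
            b=b,
            b_se=float(fit_b.bse["m"]),
            c=float(fit_c.params["x"]),
            c_prime=float(fit_b.params["x"]),
            indirect=a * b,
            ci_low=float(lo),
            ci_high=float(hi),
            ci_level=ci_level,
            n_boot=n_boot,
            seed=seed,
            n=len(d),
            labels=self.labels,
        )


def mediate(x, m, y, n_boot: int = 5000, seed: int | None = None) -> MediationResults:
    """Functional shorthand for ``Mediation(x, m, y).fit(n_boot, seed)``."""
    return Mediation(x, m, y).fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------


def _boot_interaction(
    y: np.ndarray, X: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap the last coefficient of ``y ~ X`` (batched normal equations)."""
    n = y.size
    out = [
        _boot_interaction_block(y, X, block, rng) for block in _boot_chunks(n_boot, n)
    ]
    return np.concatenate(out)


def _boot_interaction_block(
    y: np.ndarray, X: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = y.size
    idx = rng.integers(0, n, size=(n_boot, n))
    Xb = X[idx]  # (B, n, p)
    yb = y[idx]  # (B, n)
    xtx = np.einsum("bni,bnj->bij", Xb, Xb)
    xty = np.einsum("bni,bn->bi", Xb, yb)
    try:
        coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:  # pragma: no cover - pathological resample
        coef = np.stack([np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(xtx, xty)])
    return coef[:, -1]


@dataclass
class ModerationResults:
    """Moderated regression: interaction coefficient, bootstrap CI, ΔR²."""

    interaction: float
    ci_low: float
    ci_high: float
    delta_r2: float
    r2_full: float
    r2_reduced: float
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float
    interaction_pvalue: float
    n_boot: int
    seed: int | None
    n: int

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def as_dict(self) -> dict:
        return {
            "interaction": self.interaction,
            "interaction_ci": [self.ci_low, self.ci_high],
            "interaction_p": self.interaction_pvalue,
            "delta_r2": self.delta_r2,
            "r2_full": self.r2_full,
            "r2_reduced": self.r2_reduced,
            "F": self.fvalue,
            "F_p": self.f_pvalue,
            "df": [self.df_model, self.df_resid],
            "significant": self.significant,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
        }

    def summary(self) -> str:
        return (
            f"Moderation (n={self.n}): interaction = {self.interaction:.4f}, "
            f"95% bootstrap CI [{self.ci_low:.4f}, {self.ci_high:.4f}], "
            f"dR2 = {self.delta_r2:.4f}; overall F({self.df_model:.0f}, "
            f"{self.df_resid:.0f}) = {self.fvalue:.2f}, p = {self.f_pvalue:.4g}"
        )


class Moderation:
    """Moderated OLS: outcome on mean-centred focal predictor, moderator and
    their product.  A binary moderator is left uncentred; a continuous one is
    mean-centred.  ΔR² compares against the model without the product term."""

    def __init__(self, outcome, focal, moderator):
        frame = pd.DataFrame(
            {
                "y": np.asarray(outcome, dtype=float),
                "focal": np.asarray(focal, dtype=float),
                "moderator": np.asarray(moderator, dtype=float),
            }
        ).dropna()
        if len(frame) < 10:
            raise DegenerateDataError("moderation needs at least 10 complete cases")
        self.data = frame.reset_index(drop=True)

    def fit(
        self, n_boot: int = 5000, seed: int | None = None, ci_level: float = 0.95
    ) -> ModerationResults:
        d = self.data
        focal_c = d["focal"] - d["focal"].mean()
        mod_vals = d["moderator"]
        is_binary = set(np.unique(mod_vals)) <= {0.0, 1.0}
        mod_c = mod_vals if is_binary else mod_vals - mod_vals.mean()
        X = pd.DataFrame(
            {
                "const": 1.0,
                "focal": focal_c,
                "moderator": mod_c,
                "interaction": focal_c * mod_c,
            }
        )
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise DegenerateDataError("singular design matrix")
        fit_full = sm.OLS(d["y"], X).fit()
        fit_red = sm.OLS(d["y"], X[["const", "focal", "moderator"]]).fit()
        rng = np.random.default_rng(seed)
        boot = _boot_interaction(d["y"].to_numpy(), X.to_numpy(), n_boot, rng)
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        return ModerationResults(
            interaction=float(fit_full.params["interaction"]),
            ci_low=float(lo),
            ci_high=float(hi),
            delta_r2=float(max(fit_full.rsquared - fit_red.rsquared, 0.0)),
            r2_full=float(fit_full.rsquared),
            r2_reduced=float(fit_red.rsquared),
            fvalue=float(fit_full.fvalue),
            f_pvalue=float(fit_full.f_pvalue),
            df_model=float(fit_full.df_model),
            df_resid=float(fit_full.df_resid),
            interaction_pvalue=float(fit_full.pvalues["interaction"]),
            n_boot=n_boot,
            seed=seed,
            n=len(d),
        )


def moderate(outcome, focal, moderator, n_boot: int = 5000, seed: int | None = None):
    """Functional shorthand for ``Moderation(...).fit(n_boot, seed)``."""
    return Moderation(outcome, focal, moderator).fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# subgroup contrast
# ---------------------------------------------------------------------------


def experience_split_contrast(
    metrics: pd.DataFrame, threshold_years: float = 5.0
) -> tuple[TestResult, dict]:
    """Compare accuracy improvement between early-career (≤ threshold) and
    established (> threshold) participants.

    ``metrics`` needs columns experience_years, accuracy_first, accuracy_final.
    Returns the two-sample test plus the subgroup sizes.
    """
    improvement = metrics["accuracy_final"] - metrics["accuracy_first"]
    early = improvement[metrics["experience_years"] <= threshold_years]
    established = improvement[metrics["experience_years"] > threshold_years]
    if len(early) == 0 or len(established) == 0:
        raise DegenerateDataError(
            f"experience split at {threshold_years} years leaves an empty subgroup"
        )
    result = two_sample_t(early.to_numpy(), established.to_numpy())
    sizes = {
        "threshold_years": threshold_years,
        "n_early_career": int(len(early)),
        "n_established": int(len(established)),
    }
    return result, sizes


# ---------------------------------------------------------------------------
# a-priori sample size
# ---------------------------------------------------------------------------


def f_squared_from_r2(r2: float) -> float:
    """Cohen's f² = R²/(1−R²)."""
    if not 0 <= r2 < 1:
        raise ValueError("R² must lie in [0, 1)")
    return r2 / (1.0 - r2)


def _power_paired_t(n: int, d: float, alpha: float) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.isf(alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def _power_regression(n: int, f2: float, k: int, alpha: float) -> float:
    df2 = n - k - 1
    if df2 < 1:
        return 0.0
    lam = f2 * n
    fcrit = stats.f.isf(alpha, k, df2)
    return float(stats.ncf.sf(fcrit, k, df2, lam))


def achieved_power(
    design: str, n: int, effect_size: float, alpha: float = 0.05, k: int | None = None
) -> float:
    """Power at sample size ``n``: noncentral t (paired) or noncentral F (regression
    omnibus, ``effect_size`` = f², noncentrality λ = f²·N, df1 = k, df2 = N−k−1)."""
    if design == "paired_t":
        return _power_paired_t(n, effect_size, alpha) if n >= 2 else 0.0
    if design == "regression":
        if k is None:
            raise ValueError("regression design requires the predictor count k")
        return _power_regression(n, effect_size, k, alpha)
    raise ValueError("design must be 'paired_t' or 'regression'")


def required_n(
    design: str,
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.80,
    k: int | None = None,
    max_n: int = 1_000_000,
) -> int:
    """Smallest integer N reaching the target power for the given design.

    ``effect_size`` is Cohen's d for ``design='paired_t'`` and f² for
    ``design='regression'`` (use :func:`f_squared_from_r2` to convert).
    """
    if effect_size <= 0:
        raise ValueError("effect size must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    n_min = 2 if design == "paired_t" else (k or 1) + 2
    lo, hi = n_min, n_min
    while achieved_power(design, hi, effect_size, alpha, k) < power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise RuntimeError(f"target power unattainable below N={max_n}")
    # power is monotone increasing in N for these designs: bisect
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(design, mid, effect_size, alpha, k) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)
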