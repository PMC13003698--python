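"""Statistical comparisons used throughout the seasonal analysis.

Circular statistics (mean direction, Watson-Williams high-concentration F
test), Welch/paired t-tests, gamma GLMMs with a season likelihood-ratio
test, the logistic-exposure nest-survival model, and percentile-bootstrap
mean differences.

Mixed models with crossed random intercepts have no gamma-family
implementation in the scientific Python stack, so the optimizer for those
fits is delegated to R's lme4 through a batched Rscript bridge; the model
specification and the likelihood-ratio wiring live here.
"""
from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.genmod.families import links


class NoMeanDirectionError(ValueError):
    """Resultant length is (numerically) zero; the mean direction is undefined."""


class TestUndefinedError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circular_mean(angles_deg) -> tuple[float, float]:
    """Mean direction (degrees in [0, 360)) and mean resultant length R-bar."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise NoMeanDirectionError("empty sample")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        raise NoMeanDirectionError("resultant length ~ 0: no mean direction")
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0 - 1e-9:  # floating-point wrap back to 0
        mean = 0.0
    return mean, rbar


def circular_sd_deg(rbar: float) -> float:
    """Circular standard deviation sqrt(-2 ln R-bar), in degrees."""
    rbar = min(max(rbar, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def estimate_kappa(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from R-bar (Fisher 1993)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups) -> TestResult:
    """Watson-Williams test for a common mean direction across groups.

    High-concentration F approximation with the 1 + 3/(8 kappa)
    correction; a warning is emitted when the estimated concentration is
    below 1, where the approximation is unreliable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    p = len(groups)
    if p < 2 or any(len(g) < 3 for g in groups):
        raise TestUndefinedError("need >= 2 groups with >= 3 angles each")
    n = np.array([len(g) for g in groups])
    N = int(n.sum())
    R_i = []
    for g in groups:
        _, rbar = circular_mean(g)  # raises when resultant ~ 0
        R_i.append(rbar * len(g))
    R_i = np.asarray(R_i)
    a = np.radians(np.concatenate(groups))
    R = float(np.hypot(np.cos(a).sum(), np.sin(a).sum()))
    rbar_w = float(R_i.sum()) / N
    kappa = estimate_kappa(rbar_w)
    if kappa < 1.0:
        warnings.warn(
            "Watson-Williams: estimated concentration < 1; F approximation unreliable",
            stacklevel=2,
        )
    K = 1.0 + 3.0 / (8.0 * kappa)
    num = (N - p) * (R_i.sum() - R)
    den = (p - 1) * (N - R_i.sum())
    F = max(K * num / den, 0.0)
    pval = float(sps.f.sf(F, p - 1, N - p))
    return TestResult(statistic=float(F), df=(p - 1, N - p), p_value=pval,
                      method="Watson-Williams F")


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def two_sample_t(x, y, paired: bool = False) -> TestResult:
    """Paired t-test or Welch's unequal-variance t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise TestUndefinedError("need n >= 2 per group")
    if paired:
        if len(x) != len(y):
            raise TestUndefinedError("paired test needs equal lengths")
        d = x - y
        if np.all(d == 0):
            warnings.warn("paired differences identically zero; reporting t = 0", stacklevel=2)
            return TestResult(0.0, len(d) - 1, 1.0, "paired t (degenerate)")
        r = sps.ttest_rel(x, y)
        return TestResult(float(r.statistic), float(len(d) - 1), float(r.pvalue), "paired t")
    r = sps.ttest_ind(x, y, equal_var=False)
    df = float(r.df) if hasattr(r, "df") else np.nan
    return TestResult(float(r.statistic), df, float(r.pvalue), "Welch t")


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Welch t-test from printed group summaries (mean, SD, n)."""
    r = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    # Welch-Satterthwaite df
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(float(r.statistic), float(df), float(r.pvalue), "Welch t (summaries)")


# ---------------------------------------------------------------------------
# R bridge for mixed models (lme4 via Rscript)
# ---------------------------------------------------------------------------

def _run_r_glmm(mode: str, data: pd.DataFrame) -> pd.DataFrame:
    script = resources.files("petreltrack") / "r" / "glmm.R"
    with tempfile.TemporaryDirectory() as td:
        in_csv = Path(td) / "in.csv"
        out_csv = Path(td) / "out.csv"
        data.to_csv(in_csv, index=False)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), mode, str(in_csv), str(out_csv)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_csv.exists():
            raise ConvergenceError(
                f"lme4 bridge failed (mode={mode}):\n{proc.stderr[-2000:]}"
            )
        return pd.read_csv(out_csv)


def gamma_glmm_lrt_batch(data: pd.DataFrame, response: str) -> pd.DataFrame:
    """Season LRT for a gamma(log) GLMM, batched over a ``replicate`` column.

    Full model: ``response ~ season + sex + stage + (1|bird) + (1|year)``;
    null model drops season. Returns one row per replicate with columns
    ``replicate, chisq, df, p, converged``.
    """
    required = {"replicate", response, "season", "sex", "stage", "bird", "year"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    y = data[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma GLMM requires strictly positive responses")
    d = data.rename(columns={response: "y"})[
        ["replicate", "y", "season", "sex", "stage", "bird", "year"]
    ]
    out = _run_r_glmm("gamma", d)
    out["chisq"] = out["chisq"].clip(lower=0.0)
    return out


def gamma_glmm_lrt(data: pd.DataFrame, response: str) -> TestResult:
    """Likelihood-ratio test for a season effect on one trip metric.

    ``data`` has one row per trip with columns ``season, sex, stage, bird,
    year`` and the positive-valued ``response``.
    """
    if data["season"].nunique() < 2 or data["bird"].nunique() < 2:
        raise TestUndefinedError("need >= 2 seasons and >= 2 individuals")
    d = data.copy()
    d["replicate"] = 0
    res = gamma_glmm_lrt_batch(d, response).iloc[0]
    if not bool(res["converged"]):
        raise ConvergenceError(f"gamma GLMM did not converge for {response}")
    return TestResult(
        statistic=float(res["chisq"]),
        df=float(res["df"]),
        p_value=float(res["p"]),
        method=f"gamma(log) GLMM LRT [{response}]",
    )


# ---------------------------------------------------------------------------
# Logistic-exposure nest survival
# ---------------------------------------------------------------------------

class LogExpLink(links.Logit):
    """Logistic-exposure link: eta = logit(mu^(1/t)) for exposure days t.

    Subclasses Logit so the statsmodels Binomial family accepts it; all
    behaviour is overridden. The link is row-wise: each observation's
    exposure enters its own transform.
    """

    def __init__(self, exposure):
        super().__init__()
        self.t = np.asarray(exposure, dtype=float)
        if np.any(self.t < 1):
            raise ValueError("exposure days must be >= 1")

    def __call__(self, mu):
        p = np.clip(mu, 1e-12, 1 - 1e-12) ** (1.0 / self.t)
        return np.log(p / (1.0 - p))

    def inverse(self, eta):
        return sps.logistic.cdf(eta) ** self.t

    def inverse_deriv(self, eta):
        p = sps.logistic.cdf(eta)
        return self.t * p ** (self.t - 1.0) * p * (1.0 - p)

    def deriv(self, mu):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        p = mu ** (1.0 / self.t)
        return (1.0 / self.t) * mu ** (1.0 / self.t - 1.0) / (p * (1.0 - p))

    def deriv2(self, mu):
        eps = 1e-7
        return (self.deriv(mu + eps) - self.deriv(mu - eps)) / (2 * eps)


def logistic_exposure_lrt(
    intervals: pd.DataFrame, random_effect: str | None = None
) -> TestResult:
    """Group (tagged vs control) LRT under the logistic-exposure model.

    ``intervals`` has columns ``exposure`` (days, >= 1), ``survived``
    (0/1) and ``group``. With ``random_effect`` naming a grouping column,
    the fit is a binomial GLMM with that random intercept (via lme4);
    otherwise a fixed-effects GLM. With all exposures equal to 1 the GLM
    reduces exactly to ordinary logistic regression.
    """
    y = intervals["survived"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise TestUndefinedError("all intervals survived or all failed: group effect separates")
    t = intervals["exposure"].to_numpy(dtype=float)
    g = pd.get_dummies(intervals["group"], drop_first=True).to_numpy(dtype=float)
    if random_effect is not None:
        d = pd.DataFrame(
            {
                "replicate": 0,
                "survived": y,
                "exposure": t,
                "group": intervals["group"].astype(str),
                "re": intervals[random_effect].astype(str),
            }
        )
        res = _run_r_glmm("logexp", d).iloc[0]
        return TestResult(
            statistic=max(float(res["chisq"]), 0.0),
            df=float(res["df"]),
            p_value=float(res["p"]),
            method="logistic-exposure GLMM LRT (lme4)",
        )
    X_full = np.column_stack([np.ones_like(y), g])
    X_null = np.ones((len(y), 1))
    fam = sm.families.Binomial(link=LogExpLink(t))
    full = sm.GLM(y, X_full, family=fam).fit()
    null = sm.GLM(y, X_null, family=fam).fit()
    chisq = max(2.0 * (full.llf - null.llf), 0.0)
    df = X_full.shape[1] - X_null.shape[1]
    return TestResult(
        statistic=float(chisq),
        df=float(df),
        p_value=float(sps.chi2.sf(chisq, df)),
        method="logistic-exposure GLM LRT",
    )


# ---------------------------------------------------------------------------
# Bootstrap mean differences
# ---------------------------------------------------------------------------

def bootstrap_mean_diff(x, y, B: int = 10_000, seed=None) -> tuple[float, float, float]:
    """Percentile-bootstrap 95% CI for mean(y) - mean(x).

    Both groups are resampled with replacement B times; the point estimate
    is the raw-data difference. ``seed`` may be an int or a numpy
    Generator; identical seeds give bit-identical results.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = np.empty(B)
    chunk = 2000
    for i in range(0, B, chunk):
        b = min(chunk, B - i)
        mx = x[rng.integers(0, len(x), size=(b, len(x)))].mean(axis=1)
        my = y[rng.integers(0, len(y), size=(b, len(y)))].mean(axis=1)
        diffs[i : i + b] = my - mx
    lcl, ucl = np.percentile(diffs, [2.5, 97.5])
    return float(y.mean() - x.mean()), float(lcl), float(ucl)
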