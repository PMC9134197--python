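"""Questionnaire scoring, reliability, and trait–parameter correlations.

Covers the individual-differences arm of the pipeline: scoring the ECS,
IRI subscales (EC, PT, PD, FS), SPS and SIAS as item means; Cronbach's
alpha; Bayesian Pearson correlations with a default stretched-beta prior on
the population correlation (Bayes factor for dependence vs independence by
numerical integration of the marginalized likelihood); the full 7 parameter
× 7 scale correlation grid; and the sample-size calculation for detecting a
target correlation, from the exact sampling distribution of r under
bivariate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import betaln, gammaln, hyp2f1
from scipy.stats import pearsonr, t as t_dist

__all__ = [
    "SCALE_ITEM_COUNTS",
    "ScaleScore",
    "CorrelationResult",
    "score_scales",
    "cronbach_alpha",
    "pearson_bf",
    "trait_parameter_table",
    "required_n_correlation",
]

#: Fixed item counts of the instruments.
SCALE_ITEM_COUNTS = {
    "ECS": 15,
    "EC": 7,
    "PT": 7,
    "PD": 7,
    "FS": 7,
    "SPS": 20,
    "SIAS": 20,
}


@dataclass(frozen=True)
class ScaleScore:
    participant_id: str
    scale: str
    score: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    bf10: float
    ci_lower: float
    ci_upper: float
    n: int


def score_scales(
    items: pd.DataFrame,
    key: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Per-participant scale scores as item means.

    ``items`` is long format (participant_id, scale, item, response).
    ``key`` optionally maps a scale name to
    ``{"reverse": {item numbers}, "range": (lo, hi)}``; reverse-keyed items
    are recoded as lo + hi − response before averaging.  Missing items
    raise, listing participant and scale.
    """
    key = key or {}
    df = items.copy()
    for scale, entry in key.items():
        rev = set(entry.get("reverse", ()))
        lo, hi = entry["range"]
        mask = (df["scale"] == scale) & df["item"].isin(rev)
        df.loc[mask, "response"] = lo + hi - df.loc[mask, "response"]
    incomplete = []
    for (pid, scale), grp in df.groupby(["participant_id", "scale"]):
        expected = SCALE_ITEM_COUNTS.get(scale)
        if expected is not None and len(grp) != expected:
            incomplete.append((pid, scale, len(grp)))
    if incomplete:
        raise ValueError(
            "incomplete scales (participant, scale, items found): "
            f"{incomplete[:10]}"
        )
    out = (
        df.groupby(["participant_id", "scale"], as_index=False)["response"]
        .mean()
        .rename(columns={"response": "score"})
    )
    return out


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's α = k/(k−1) · (1 − Σ item variances / total variance).

    ``items`` is respondents × items; requires ≥ 2 items, ≥ 3 respondents,
    and a nonzero total-score variance.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-d array with at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# Bayesian Pearson correlation


def _stretched_beta_logpdf(rho: np.ndarray, kappa: float) -> np.ndarray:
    """Two-sided stretched Beta(1/κ, 1/κ) prior on (−1, 1); κ=1 is uniform."""
    a = 1.0 / kappa
    w = (rho + 1.0) / 2.0
    return (
        (a - 1.0) * (np.log(w) + np.log1p(-w))
        - betaln(a, a)
        - np.log(2.0)
    )


def _log_likelihood_ratio(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """log f(r | ρ, n) − log f(r | 0, n) for the exact sampling density of
    the Pearson correlation under bivariate normality."""
    c = n - 0.5
    num = np.log(hyp2f1(0.5, 0.5, c, (1.0 + rho * r) / 2.0))
    den = np.log(hyp2f1(0.5, 0.5, c, 0.5))
    return (
        0.5 * (n - 1) * np.log1p(-rho**2)
        - (n - 1.5) * np.log1p(-rho * r)
        + num
        - den
    )


def pearson_bf(
    x: np.ndarray,
    y: np.ndarray,
    prior_width: float = 1.0,
    n_grid: int = 2001,
) -> CorrelationResult:
    """Pearson r with BF₁₀ and a 95% central credible interval for ρ.

    The Bayes factor compares dependence (ρ with a stretched-beta prior of
    width ``prior_width``) against independence (ρ = 0), by numerical
    integration of the ρ-marginalized likelihood ratio; the credible
    interval comes from the gridded posterior under the same prior.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input variable")
    r = float(pearsonr(x, y).statistic)
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    grid = np.linspace(-1.0, 1.0, n_grid)[1:-1]
    log_post = _stretched_beta_logpdf(grid, prior_width) + _log_likelihood_ratio(
        grid, r_c, n
    )
    m = log_post.max()
    dens = np.exp(log_post - m)
    z = integrate.trapezoid(dens, grid)
    bf10 = float(z * np.exp(m))
    cdf = integrate.cumulative_trapezoid(dens / z, grid, initial=0.0)
    ci_lower = float(np.interp(0.025, cdf, grid))
    ci_upper = float(np.interp(0.975, cdf, grid))
    return CorrelationResult(r=r, bf10=bf10, ci_lower=ci_lower, ci_upper=ci_upper, n=n)


def trait_parameter_table(
    effects: pd.DataFrame,
    scores: pd.DataFrame,
    prior_width: float = 1.0,
) -> pd.DataFrame:
    """7 parameters × 7 scales grid of Bayesian Pearson correlations.

    ``effects`` is participants × parameter columns (posterior-mean subject
    effects); ``scores`` is the tidy output of :func:`score_scales`.
    Participants must align; unmatched ids raise.
    """
    wide = scores.pivot(index="participant_id", columns="scale", values="score")
    unmatched = sorted(
        set(map(str, effects.index)).symmetric_difference(map(str, wide.index))
    )
    if unmatched:
        raise ValueError(f"participants not present on both sides: {unmatched[:10]}")
    wide = wide.loc[[str(i) for i in effects.index]]
    rows = []
    for param in effects.columns:
        for scale in wide.columns:
            res = pearson_bf(
                effects[param].to_numpy(), wide[scale].to_numpy(), prior_width
            )
            rows.append(
                {
                    "parameter": param,
                    "scale": scale,
                    "r": res.r,
                    "bf10": res.bf10,
                    "ci_lower": res.ci_lower,
                    "ci_upper": res.ci_upper,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power analysis for a correlation


def _r_logpdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact log density of the sample correlation under bivariate
    normality (Hotelling's series form via the Gauss hypergeometric)."""
    r = np.asarray(r, dtype=float)
    return (
        np.log(n - 2.0)
        + gammaln(n - 1.0)
        + 0.5 * (n - 1) * np.log1p(-rho**2)
        + 0.5 * (n - 4) * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0))
    )


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided level-α test of ρ=0 (t-test on r) when the
    true correlation is ``rho``, from the exact distribution of r."""
    if n < 4:
        return 0.0
    t_crit = t_dist.ppf(1 - alpha / 2, n - 2)
    r_crit = t_crit / np.sqrt(t_crit**2 + n - 2)

    def pdf(r):
        return np.exp(_r_logpdf(r, rho, n))

    upper, _ = integrate.quad(pdf, r_crit, 1.0, limit=200)
    lower, _ = integrate.quad(pdf, -1.0, -r_crit, limit=200)
    return float(upper + lower)


def required_n_correlation(
    rho: float,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = True,
    method: str = "exact",
) -> int:
    """Smallest n whose two-sided (or one-sided) test of ρ=0 at level
    ``alpha`` reaches the target power under true ρ=``rho``.

    ``method='exact'`` searches over n with power from the exact sampling
    distribution of r; ``method='fisher'`` is the approximate closed form
    from the Fisher z transform (labeled approximate).
    """
    if not (0 < rho < 1 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("rho, alpha and power must lie strictly in (0, 1)")
    from scipy.stats import norm

    level = alpha if two_sided else 2 * alpha
    if method == "fisher":
        za = norm.ppf(1 - level / 2)
        zb = norm.ppf(power)
        return int(np.ceil(((za + zb) / np.arctanh(rho)) ** 2 + 3))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'fisher'")
    lo, hi = 4, 8
    while correlation_power(rho, hi, level) < power:
        lo, hi = hi, hi * 2
        if hi > 10**7:
            raise ValueError("target power unattainable in a feasible sample")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if correlation_power(rho, mid, level) >= power:
            hi = mid
        else:
            lo = mid
    return hi
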