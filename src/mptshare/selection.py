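"""WAIC model comparison and posterior predictive checking.

WAIC is computed on the deviance scale from the per-trial pointwise
log-likelihood matrix: lppd is the summed log of the posterior-mean
predictive density per trial (stable log-sum-exp), the effective number of
parameters is the summed posterior variance of the pointwise
log-likelihood, and WAIC = −2·(lppd − p_waic).  Lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import CountsData, PosteriorDraws, _pooled_cells, _subject_cells, build_model
from scipy.special import expit

__all__ = [
    "WaicResult",
    "ComparisonResult",
    "waic",
    "compare",
    "posterior_predictive_check",
    "plot_ppc",
]


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale with its pointwise elpd decomposition."""

    lppd: float
    p_waic: float
    waic: float
    se: float
    pointwise_elpd: np.ndarray
    name: str = ""

    @property
    def elpd(self) -> float:
        return self.lppd - self.p_waic


def waic(
    pointwise_loglik: np.ndarray | PosteriorDraws, name: str = ""
) -> WaicResult:
    """WAIC from a draws × trials log-likelihood matrix (or a fitted
    posterior that stored one).

    With a single draw the variance term is 0 by convention.  Non-finite
    entries raise, identifying the offending trial indices.
    """
    if isinstance(pointwise_loglik, PosteriorDraws):
        if pointwise_loglik.pointwise is None:
            raise ValueError("posterior has no stored pointwise log-likelihood")
        ll = np.asarray(pointwise_loglik.pointwise, dtype=np.float64)
    else:
        ll = np.atleast_2d(np.asarray(pointwise_loglik, dtype=np.float64))
    if not np.isfinite(ll).all():
        bad = np.unique(np.nonzero(~np.isfinite(ll))[1])
        raise ValueError(
            f"non-finite log-likelihood entries at trial indices {bad[:20].tolist()}"
        )
    s, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(n)
    elpd_i = lppd_i - p_i
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    w = -2.0 * (lppd - p_waic)
    se = float(np.sqrt(n * np.var(-2.0 * elpd_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(lppd, p_waic, w, se, elpd_i, name)


@dataclass
class ComparisonResult:
    """Ranking of models by WAIC with pairwise elpd differences."""

    results: list[WaicResult]
    table: pd.DataFrame
    pairwise: pd.DataFrame

    def best(self) -> WaicResult:
        return self.results[int(self.table.index[0])]


def compare(results: list[WaicResult]) -> ComparisonResult:
    """Rank models by WAIC (ascending: lower is better).

    Pairwise elpd differences are computed on the shared pointwise units,
    with SE = sqrt(n · var of the pointwise differences); all results must
    therefore come from identical trial sets.
    """
    if not results:
        raise ValueError("nothing to compare")
    n = len(results[0].pointwise_elpd)
    for r in results:
        if len(r.pointwise_elpd) != n:
            raise ValueError(
                "pointwise elpd vectors have mismatched lengths: "
                f"{len(r.pointwise_elpd)} vs {n}"
            )
    order = np.argsort([r.waic for r in results], kind="stable")
    table = pd.DataFrame(
        {
            "model": [results[i].name or f"model{i}" for i in order],
            "waic": [results[i].waic for i in order],
            "se": [results[i].se for i in order],
            "p_waic": [results[i].p_waic for i in order],
            "rank": np.arange(1, len(results) + 1),
        },
        index=order,
    )
    best = results[order[0]]
    table["elpd_diff_vs_best"] = [
        float(np.sum(results[i].pointwise_elpd - best.pointwise_elpd))
        for i in order
    ]
    table["diff_se_vs_best"] = [
        float(
            np.sqrt(
                n
                * np.var(
                    results[i].pointwise_elpd - best.pointwise_elpd, ddof=1
                )
            )
        )
        if n > 1
        else 0.0
        for i in order
    ]
    rows = []
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            d = a.pointwise_elpd - b.pointwise_elpd
            rows.append(
                {
                    "model_a": a.name or f"model{i}",
                    "model_b": b.name or f"model{j}",
                    "elpd_diff": float(d.sum()),
                    "se": float(np.sqrt(n * np.var(d, ddof=1))) if n > 1 else 0.0,
                }
            )
    return ComparisonResult(results, table, pd.DataFrame(rows))


def _theta_per_draw(draws: PosteriorDraws, n_sub: int, rng) -> np.ndarray:
    """(n_sampled_draws, participants, 10) cell probabilities."""
    data = draws.data
    n_part = data.n_participants
    total = draws.n_chains * draws.n_draws
    take = rng.choice(total, size=min(n_sub, total), replace=False)
    if draws.hierarchical:
        alpha = draws.alpha.reshape(-1, 7)[take]
        u = draws.u.reshape(-1, n_part, 7).astype(np.float64)[take]
        probs = expit(alpha[:, None, :] + u)
        return _subject_cells(probs)
    model = build_model(draws.spec)
    flat = np.stack(
        [draws.group[name].reshape(-1)[take] for name in draws.param_names],
        axis=-1,
    )
    cells = _pooled_cells(model, flat)  # (s, 10)
    return np.broadcast_to(cells[:, None, :], (len(take), n_part, 10)).copy()


def posterior_predictive_check(
    draws: PosteriorDraws,
    counts: CountsData | list | None = None,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs posterior-predictive category frequencies per participant.

    For each participant × condition × category: the observed proportion,
    the posterior-predictive mean proportion (the posterior mean of the cell
    probability), and a central 95% predictive interval obtained from
    replicate datasets simulated draw-by-draw.
    """
    data = draws.data if counts is None else (
        counts if isinstance(counts, CountsData) else CountsData.from_counts(counts)
    )
    if data is None:
        raise ValueError("no counts available for the check")
    for p in data.participants:
        if p not in draws.participants and draws.hierarchical:
            raise ValueError(f"participant {p!r} absent from the fit")
    rng = np.random.default_rng(seed)
    theta = _theta_per_draw(draws, n_draws, rng)  # (s, n, 10)
    cm = data.cell_matrix()  # (n, 10)
    cond_slices = {"anger": slice(0, 4), "happiness": slice(4, 8),
                   "neutral": slice(8, 10)}
    cond_cats = {"anger": ("00", "01", "10", "11"),
                 "happiness": ("00", "01", "10", "11"),
                 "neutral": ("1", "0")}
    rows = []
    s = theta.shape[0]
    for cond, sl in cond_slices.items():
        n_trials = cm[:, sl].sum(axis=1)  # (n,)
        th = theta[:, :, sl]
        th = th / th.sum(axis=2, keepdims=True)
        pred_mean = th.mean(axis=0)  # (n, k)
        # replicate datasets: multinomial draw per posterior draw/participant
        k = th.shape[2]
        reps = np.empty((s, len(data.participants), k))
        for i, nt in enumerate(n_trials):
            if nt == 0:
                reps[:, i] = np.nan
                continue
            counts_rep = rng.multinomial(int(nt), th[:, i, :])
            reps[:, i] = counts_rep / nt
        lo = np.nanquantile(reps, 0.025, axis=0)
        hi = np.nanquantile(reps, 0.975, axis=0)
        for i, pid in enumerate(data.participants):
            nt = n_trials[i]
            for ci, cat in enumerate(cond_cats[cond]):
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "category": cat,
                        "n_trials": int(nt),
                        "observed": cm[i, sl][ci] / nt if nt else np.nan,
                        "predicted_mean": pred_mean[i, ci],
                        "predicted_lo": lo[i, ci],
                        "predicted_hi": hi[i, ci],
                    }
                )
    return pd.DataFrame(rows)


def plot_ppc(
    ppc: pd.DataFrame,
    participants: list[str],
    path: str | None = None,
    condition: str = "happiness",
):
    """Bar-and-dot layout: observed frequencies as bars, posterior
    predictive means as dots with 95% predictive whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ppc[(ppc.condition == condition) & ppc.participant_id.isin(participants)]
    fig, axes = plt.subplots(
        1, len(participants), figsize=(2.4 * len(participants), 2.8), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, pid in zip(axes, participants):
        d = sub[sub.participant_id == pid]
        x = np.arange(len(d))
        ax.bar(x, d.observed, color="lightgray", label="observed")
        ax.errorbar(
            x,
            d.predicted_mean,
            yerr=[d.predicted_mean - d.predicted_lo, d.predicted_hi - d.predicted_mean],
            fmt="o",
            color="black",
            markersize=4,
            label="predicted",
        )
        ax.set_xticks(x, d.category)
        ax.set_title(str(pid), fontsize=9)
    axes[0].set_ylabel("proportion")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
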