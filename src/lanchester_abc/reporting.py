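"""Posterior summaries, model-selection tables and distance diagnostics.

Everything here is a pure function of a stored record set: re-running
reporting never re-simulates.  The canonical outputs are tables
(DataFrames / dicts serialisable to CSV/JSON); plotting is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abc import Posterior, accept_at
from .models import Model

__all__ = [
    "PosteriorSummary",
    "summarize_posterior",
    "model_proportion_table",
    "distance_rank_table",
    "joint_scatter_export",
]


@dataclass(frozen=True)
class PosteriorSummary:
    """Location and spread of one parameter's accepted-run sample."""

    parameter: str
    mean: float
    mode: float
    q025: float
    median: float
    q975: float
    n: int

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean,
            "mode": self.mode,
            "q2.5": self.q025,
            "median": self.median,
            "q97.5": self.q975,
            "n": self.n,
        }


def _histogram_mode(x: np.ndarray) -> float:
    """Midpoint of the maximal bin of a Freedman–Diaconis histogram."""
    if np.ptp(x) == 0:
        return float(x[0])
    counts, edges = np.histogram(x, bins="fd")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _kde_mode(x: np.ndarray, gridsize: int = 512) -> float:
    """Argmax of a Gaussian kernel density estimate on a uniform grid."""
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), gridsize)
    return float(grid[np.argmax(kde(grid))])


def summarize_posterior(
    post: Posterior,
    model: Model | None = None,
    mode_estimator: str = "histogram",
) -> dict[str, PosteriorSummary]:
    """Per-parameter summaries (mu, sigma) of the accepted runs.

    ``model`` restricts to one model's accepted runs (required to be
    non-empty); None summarises all accepted runs.  The mode is the
    maximal-bin midpoint of a Freedman–Diaconis histogram by default,
    or the KDE argmax with ``mode_estimator="kde"``; reported peaks of
    a posterior depend on this choice, so both are available.
    """
    df = post.accepted
    if model is not None:
        model = Model.from_name(model)
        df = df[df["model"] == model.label]
        if df.empty:
            raise ValueError(f"no accepted runs for model {model.label!r}")
    if mode_estimator == "histogram":
        mode_fn = _histogram_mode
    elif mode_estimator == "kde":
        mode_fn = _kde_mode
    else:
        raise ValueError("mode_estimator must be 'histogram' or 'kde'")

    out = {}
    for par in ("mu", "sigma"):
        x = df[par].to_numpy()
        q025, med, q975 = np.quantile(x, [0.025, 0.5, 0.975])
        out[par] = PosteriorSummary(
            parameter=par,
            mean=float(x.mean()),
            mode=mode_fn(x),
            q025=float(q025),
            median=float(med),
            q975=float(q975),
            n=len(x),
        )
    return out


def model_proportion_table(
    records: pd.DataFrame,
    tau_list: Sequence[float],
    models: Sequence[Model] | None = None,
) -> pd.DataFrame:
    """Posterior model proportions at each tolerance (one row per tau).

    Each row re-thresholds the same stored records; proportions sum to
    one within a row.
    """
    if models is None:
        models = tuple(Model.from_name(s) for s in pd.unique(records["model"]))
    rows = []
    for tau in tau_list:
        post = accept_at(records, tau, model_set=models)
        counts = post.counts
        row = {"tau": tau, "n_accepted": post.n_accepted}
        total = counts.sum()
        for m in models:
            row[Model.from_name(m).label] = counts[Model.from_name(m).label] / total
        rows.append(row)
    return pd.DataFrame(rows)


def distance_rank_table(post: Posterior) -> pd.DataFrame:
    """Accepted runs ordered by distance: rank 1 is the best run."""
    if post.n_accepted == 0:
        raise ValueError("posterior is empty")
    df = post.accepted.sort_values(["distance", "run_index"]).reset_index(drop=True)
    return pd.DataFrame(
        {"rank": np.arange(1, len(df) + 1), "model": df["model"], "distance": df["distance"]}
    )


def joint_scatter_export(post: Posterior) -> tuple[pd.DataFrame, float]:
    """Accepted (mu, sigma) pairs plus their Spearman rank correlation.

    The correlation quantifies the joint-posterior shape in which large
    sigma values are only retained when mu is also large.
    """
    if post.n_accepted == 0:
        raise ValueError("posterior is empty")
    pairs = post.accepted[["mu", "sigma", "model"]].reset_index(drop=True)
    if post.n_accepted < 2:
        return pairs, float("nan")
    rho = stats.spearmanr(pairs["mu"], pairs["sigma"]).statistic
    return pairs, float(rho)
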