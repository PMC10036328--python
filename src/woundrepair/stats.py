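"""Group comparisons and summary reporting across experimental conditions.

Mirrors the statistics of the original workflow: per-condition mean ± SEM
with either a Kruskal–Wallis omnibus test followed by Dunn's rank-based
pairwise comparisons, or pairwise Welch's t tests.  Significance stars:
* p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ConditionSummary", "ComparisonResult", "compare_conditions", "significance_stars", "dotplot"]

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclasses.dataclass
class ConditionSummary:
    condition: str
    n: int
    mean: float
    sem: float  # SD/√n


@dataclasses.dataclass
class ComparisonResult:
    """Per-condition summaries plus pairwise p-values."""

    summaries: list[ConditionSummary]
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_value, stars, test
    omnibus_p: float | None  # Kruskal–Wallis omnibus (None for Welch)
    test: str

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.summaries])


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[tuple[str, str, float]]:
    """Dunn's z tests on pooled ranks with tie correction, uncorrected p."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # mean rank per group
    mean_ranks = {}
    start = 0
    for k in labels:
        n_k = len(groups[k])
        mean_ranks[k] = ranks[start : start + n_k].mean()
        start += n_k
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((a, b, float(p)))
    return out


def _adjust(pvals: list[float], method: str) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    if method == "none":
        return list(p)
    if method == "bonferroni":
        return list(np.minimum(p * len(p), 1.0))
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, p[idx] * (len(p) - rank))
            adj[idx] = min(running, 1.0)
        return list(adj)
    raise ValueError(f"unknown correction {method!r}; use none|bonferroni|holm")


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    test: str = "kruskal_wallis",
    correction: str = "none",
) -> ComparisonResult:
    """Compare a metric across labelled conditions.

    Parameters
    ----------
    groups
        Mapping condition label → per-wound metric values (each n ≥ 2).
    test
        ``"kruskal_wallis"`` (omnibus + Dunn pairwise follow-up) or
        ``"welch_t"`` (pairwise Welch's t).
    correction
        Multiplicity correction for the pairwise p-values
        (``none``, ``bonferroni`` or ``holm``); raw p-values by default.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n={len(v)} < 2")

    summaries = [
        ConditionSummary(
            condition=k,
            n=len(v),
            mean=float(v.mean()),
            sem=float(v.std(ddof=1) / np.sqrt(len(v))),
        )
        for k, v in arrays.items()
    ]

    omnibus_p: float | None = None
    if test == "kruskal_wallis":
        omnibus_p = float(sps.kruskal(*arrays.values()).pvalue)
        rows = _dunn_pairwise(arrays)
    elif test == "welch_t":
        rows = [
            (a, b, float(sps.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue))
            for a, b in itertools.combinations(arrays, 2)
        ]
    else:
        raise ValueError(f"unknown test {test!r}; use kruskal_wallis|welch_t")

    adj = _adjust([p for *_, p in rows], correction)
    pairwise = pd.DataFrame(
        [
            {
                "group_a": a,
                "group_b": b,
                "p_value": p_adj,
                "stars": significance_stars(p_adj),
                "test": test,
            }
            for (a, b, _), p_adj in zip(rows, adj)
        ]
    )
    return ComparisonResult(
        summaries=summaries, pairwise=pairwise, omnibus_p=omnibus_p, test=test
    )


def dotplot(
    groups: Mapping[str, Sequence[float]],
    ylabel: str = "",
    ax=None,
    seed: int = 0,
):
    """Dotplot of per-wound values with mean ± SEM bars per condition."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 3))
    rng = np.random.default_rng(seed)
    for i, (label, values) in enumerate(groups.items()):
        values = np.asarray(values, dtype=float)
        x = i + rng.uniform(-0.12, 0.12, len(values))
        ax.plot(x, values, "o", ms=4, alpha=0.7)
        mean = values.mean()
        sem = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
        ax.errorbar(i, mean, yerr=sem, fmt="_", color="black", capsize=4, ms=16)
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel(ylabel)
    return ax
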