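"""Differential expression calls with Bayesian FDR control, plus evaluation.

Genes are ranked by descending posterior inclusion probability (PIP) and the
list truncated at the largest prefix whose mean expected false-discovery
contribution (1 - PIP) stays at or below the target level alpha. This bounds
the expected proportion of false discoveries among the declared genes. The
frequentist comparator (the Gaussian baseline) uses Benjamini-Hochberg on
its p-values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import PosteriorSummary

__all__ = [
    "DEResult",
    "select_de_genes",
    "benjamini_hochberg",
    "evaluate_calls",
    "calibration_curve",
    "summaries_to_frame",
]


@dataclass
class DEResult:
    """Ranked gene list with the FDR-truncated discovery set."""

    ranked_genes: list[str]
    pips: np.ndarray              # aligned with ranked_genes
    discovery_set: list[str]
    alpha_fdr: float

    @property
    def n_selected(self) -> int:
        return len(self.discovery_set)

    @property
    def expected_fdr(self) -> float:
        """Mean (1 - PIP) over the discovery set (0 when empty)."""
        m = self.n_selected
        if m == 0:
            return 0.0
        return float(np.mean(1.0 - self.pips[:m]))


def select_de_genes(
    summaries: list[PosteriorSummary], alpha_fdr: float
) -> DEResult:
    """Truncate the PIP-descending ranking to control the Bayesian FDR.

    The discovery set is the longest prefix S_m of the ranking with
    mean_{s in S_m} (1 - PIP_s) <= alpha. Ties in PIP break lexicographically
    on gene id for determinism. The empty set is a valid outcome.
    """
    if not (0.0 < alpha_fdr < 1.0):
        raise ValueError("alpha_fdr must lie in (0,1)")
    order = sorted(summaries, key=lambda t: (-t.pip, t.gene_id))
    pips = np.array([t.pip for t in order])
    genes = [t.gene_id for t in order]
    if len(pips) == 0:
        return DEResult([], pips, [], alpha_fdr)
    cum_mean = np.cumsum(1.0 - pips) / np.arange(1, len(pips) + 1)
    ok = np.flatnonzero(cum_mean <= alpha_fdr)
    m = int(ok[-1]) + 1 if ok.size else 0
    return DEResult(genes, pips, genes[:m], alpha_fdr)


def benjamini_hochberg(pvalues: np.ndarray, alpha_fdr: float) -> np.ndarray:
    """Standard step-up BH rejections (boolean mask, input order)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject, *_ = multipletests(pvalues, alpha=alpha_fdr, method="fdr_bh")
    return reject


def evaluate_calls(
    calls: set[str], truth: set[str], all_genes: set[str]
) -> dict[str, float]:
    """Empirical FDR, TPR and FPR of a call set against known truth."""
    tp = len(calls & truth)
    fp = len(calls - truth)
    fdr = fp / max(1, fp + tp)
    tpr = tp / len(truth) if truth else float("nan")
    negatives = len(all_genes - truth)
    fpr = fp / negatives if negatives else float("nan")
    return {"fdr": fdr, "tpr": tpr, "fpr": fpr, "n_calls": float(len(calls))}


def calibration_curve(
    summaries: list[PosteriorSummary],
    truth: set[str],
    alpha_grid: np.ndarray,
) -> pd.DataFrame:
    """Empirical FDR/TPR of the selection rule across target levels.

    Discovery sets are nested in alpha (prefix property), so the set size is
    monotone nondecreasing along the grid.
    """
    all_genes = {t.gene_id for t in summaries}
    rows = []
    for a in np.asarray(alpha_grid, dtype=float):
        res = select_de_genes(summaries, a)
        m = evaluate_calls(set(res.discovery_set), truth, all_genes)
        rows.append({"alpha": a, "n_selected": res.n_selected, **m})
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[PosteriorSummary], result: DEResult | None = None) -> pd.DataFrame:
    """Tidy per-gene output table (one row per gene)."""
    columns = [
        "gene_id", "pip", "lfc", "lfc_marginal", "lfc_ci_low", "lfc_ci_high",
        "alpha_mean", "selected", "rank", "n_obs", "n_censored", "flag",
    ]
    if not summaries:
        return pd.DataFrame(columns=columns)
    selected = set(result.discovery_set) if result is not None else set()
    rank = {g: r + 1 for r, g in enumerate(result.ranked_genes)} if result else {}
    rows = []
    for t in summaries:
        rows.append(
            {
                "gene_id": t.gene_id,
                "pip": t.pip,
                "lfc": t.beta_mean,
                "lfc_marginal": t.beta_mean_marginal,
                "lfc_ci_low": t.beta_ci[0],
                "lfc_ci_high": t.beta_ci[1],
                "alpha_mean": t.alpha_mean,
                "selected": int(t.gene_id in selected),
                "rank": rank.get(t.gene_id, -1),
                "n_obs": t.n_obs,
                "n_censored": t.n_censored,
                "flag": t.flag,
            }
        )
    return pd.DataFrame(rows).sort_values(["rank"]).reset_index(drop=True)
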