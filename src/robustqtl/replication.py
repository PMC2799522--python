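"""Replication of ER-QTL predictions in an independent two-strain panel.

An ER QTL whose genotype differs between two strains predicts which
strain's replicate measurements should be more variable for that gene.
Replication is assessed per gene with a variance-ratio F-test, after
subtracting a baseline: the mean log2 variance ratio over genes *not*
predicted to differ, which absorbs any global tendency of one strain to
be more variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ReplicationRecord:
    gene_id: str
    predicted_strain: str
    log2_ratio: float          # predicted-strain : other-strain variance
    f_pvalue: float            # one-sided in the predicted direction
    n1: int
    n2: int
    agree: bool


def variance_ratio_ftest(var_hi: float, var_lo: float, n1: int, n2: int,
                         sided: str = "one") -> float:
    """F-test p for a ratio of two sample variances.

    F = var_hi / var_lo with (n1-1, n2-1) degrees of freedom; the upper
    tail probability, doubled (capped at 1) for a two-sided test.  A zero
    variance is degenerate and reported as the boundary p = 0.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if var_hi < 0 or var_lo < 0:
        raise ValueError("variances must be nonnegative")
    if var_lo == 0.0:
        logger.warning("degenerate zero variance in F-test")
        return 0.0
    p = float(stats.f.sf(var_hi / var_lo, n1 - 1, n2 - 1))
    if sided == "two":
        p = min(1.0, 2.0 * p)
    return p


def critical_variance_ratio(n1: int, n2: int, alpha: float = 0.05,
                            sided: str = "two") -> float:
    """Smallest variance ratio reaching significance alpha.

    The F quantile at which the (one- or two-sided) upper-tail test first
    attains p <= alpha; e.g. with seven replicates per strain a ratio of
    about 5.8 is needed for two-sided p = 0.05.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    tail = alpha / 2 if sided == "two" else alpha
    return float(stats.f.isf(tail, n1 - 1, n2 - 1))


def expected_chance_confirmations(n_genes: int, alpha: float = 0.05) -> float:
    """Expected chance count per direction at a two-sided cutoff.

    Under the null each gene lands in either significance tail with
    probability alpha/2, so n_genes * alpha / 2 agreements (and as many
    disagreements) arise by chance.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    return n_genes * alpha / 2.0


def confirmation_excess_p(n_confirmed: int, n_genes: int,
                          alpha: float = 0.05) -> float:
    """Exact binomial upper tail for the observed confirmation count.

    The chance of a gene agreeing at the two-sided cutoff is alpha/2; the
    returned value is P(X >= n_confirmed) for X ~ Binomial(n_genes,
    alpha/2).
    """
    return float(stats.binom.sf(n_confirmed - 1, n_genes, alpha / 2.0))


def eligible_for_replication(values1: np.ndarray, values2: np.ndarray,
                             max_missing: int = 1) -> bool:
    """Missing-data rule: at most ``max_missing`` absent points per group."""
    m1 = int(np.sum(~np.isfinite(np.asarray(values1, float))))
    m2 = int(np.sum(~np.isfinite(np.asarray(values2, float))))
    return m1 <= max_missing and m2 <= max_missing


def baseline_adjusted_ratios(predicted: pd.Series,
                             background: pd.Series) -> pd.Series:
    """Subtract the background mean log2 variance ratio.

    ``predicted`` and ``background`` hold per-gene log2 variance ratios
    (strain A : strain B).  Global scaling of one strain's variances
    shifts every ratio equally and cancels out.  Confirmation = the
    adjusted ratio has the predicted sign.
    """
    if len(background) == 0:
        raise ValueError("background gene set is empty")
    return predicted - float(background.mean())


def replicate_predictions(panel_values: pd.DataFrame, strain_labels: pd.Series,
                          predictions: pd.DataFrame, strain_a: str,
                          strain_b: str, alpha: float = 0.05,
                          max_missing: int = 1) -> pd.DataFrame:
    """Score each predicted gene in a two-strain replication panel.

    ``predictions`` needs columns gene_id, predicted_variable_strain.
    Genes in the panel but not predicted form the baseline background.
    Returns one row per eligible predicted gene with its adjusted log2
    ratio, one-sided F p, and agree/strong-agree calls.
    """
    a_mask = strain_labels == strain_a
    b_mask = strain_labels == strain_b
    n_a, n_b = int(a_mask.sum()), int(b_mask.sum())

    def gene_ratio(gene: str) -> tuple[float, float, float] | None:
        if gene not in panel_values.columns:
            return None
        va = panel_values.loc[a_mask, gene].to_numpy(float)
        vb = panel_values.loc[b_mask, gene].to_numpy(float)
        if not eligible_for_replication(va, vb, max_missing):
            return None
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        s2a, s2b = va.var(ddof=1), vb.var(ddof=1)
        if s2a <= 0 or s2b <= 0:
            return None
        return s2a, s2b, np.log2(s2a / s2b)

    predicted_genes = set(predictions["gene_id"])
    background = pd.Series({
        gene: res[2]
        for gene in panel_values.columns if gene not in predicted_genes
        if (res := gene_ratio(gene)) is not None
    })
    rows = []
    for _, pr in predictions.iterrows():
        res = gene_ratio(pr["gene_id"])
        if res is None:
            continue
        s2a, s2b, log2r = res
        pred = pr["predicted_variable_strain"]
        if pred == strain_a:
            p_one = variance_ratio_ftest(s2a, s2b, n_a, n_b, "one")
        else:
            p_one = variance_ratio_ftest(s2b, s2a, n_b, n_a, "one")
        rows.append({
            "gene_id": pr["gene_id"],
            "predicted_variable_strain": pred,
            "log2_ratio": log2r,
            "f_pvalue_one_sided": p_one,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    adjusted = baseline_adjusted_ratios(out["log2_ratio"].astype(float),
                                        background)
    out["adjusted_log2_ratio"] = adjusted
    pred_sign = np.where(out["predicted_variable_strain"] == strain_a, 1.0, -1.0)
    out["agree"] = np.sign(adjusted) == pred_sign
    out["strong_agree"] = out["agree"] & (out["f_pvalue_one_sided"] <= alpha / 2)
    return out


def compare_ratio_distributions(group_a: np.ndarray,
                                group_b: np.ndarray) -> float:
    """Two-sided two-sample t-test p on two sets of log2 variance ratios."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("degenerate constant groups in t-test")
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b).pvalue)
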