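"""Confound checks for robustness scans.

Four diagnostics, each a pure function of its inputs: a cumulative
p-value inflation curve (population structure or other systematic bias
shows up as an excess of small p-values), a relatedness/co-occurrence
test (stratification makes closely related strains share genotype
classes at hit markers too often), a batch check comparing trait-profile
correlations across sample-pair categories (cage, shipment, neither),
and a hypergeometric enrichment of technically flagged traits among
hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GENO_HET, GENO_MISSING, GenotypePanel, PhenotypePanel


@dataclass
class DiagnosticReport:
    name: str
    statistics: dict
    flag: str           # "pass" | "warn"
    plot_data: dict     # x/y series for rendering


def pvalue_inflation_curve(pvals, warn_deviation: float = 0.05
                           ) -> DiagnosticReport:
    """Empirical CDF of p-values vs the uniform diagonal.

    The max vertical deviation is the one-sample KS statistic against
    Uniform(0,1); under the assumption that true associations are rare,
    a curve hugging the diagonal rules out systematic p-value inflation.
    """
    p = np.sort(np.asarray(pvals, float))
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    deviation = float(max(np.max(ecdf_hi - p), np.max(p - ecdf_lo)))
    return DiagnosticReport(
        name="pvalue_inflation",
        statistics={"max_deviation": deviation, "n": n,
                    "warn_deviation": warn_deviation},
        flag="warn" if deviation > warn_deviation else "pass",
        plot_data={"x": p.tolist(), "y": ecdf_hi.tolist()},
    )


def cooccurrence_vs_distance(g: GenotypePanel, hits: pd.DataFrame,
                             warn_rho: float = -0.3) -> DiagnosticReport:
    """Strain relatedness vs genotype-class sharing at hit markers.

    For every strain pair: Hamming distance over all markers (count of
    differing genotypes) against the frequency of landing in the same
    genotype class at the hit markers.  A strong negative rank
    correlation — close relatives co-occurring in excess — warns of
    population stratification.
    """
    strains = g.strains
    if len(strains) < 3:
        raise ValueError("need at least three strains")
    if hits.empty:
        return DiagnosticReport("cooccurrence_vs_distance", {"n_pairs": 0},
                                "pass", {})
    calls = g.calls.to_numpy()
    valid = ~np.isin(calls, (GENO_HET, GENO_MISSING))
    hit_markers = [m for m in pd.unique(hits["marker_id"]) if m in g.calls.columns]
    hit_idx = [g.marker_ids.index(m) for m in hit_markers]
    dists, coocc = [], []
    for i, j in combinations(range(len(strains)), 2):
        both = valid[i] & valid[j]
        dists.append(int(np.sum(calls[i, both] != calls[j, both])))
        hb = [m for m in hit_idx if both[m]]
        coocc.append(float(np.mean(calls[i, hb] == calls[j, hb])) if hb else np.nan)
    dists = np.asarray(dists, float)
    coocc = np.asarray(coocc, float)
    ok = np.isfinite(coocc)
    rho = (float(stats.spearmanr(dists[ok], coocc[ok]).statistic)
           if ok.sum() >= 3 and np.ptp(coocc[ok]) > 0 else 0.0)
    return DiagnosticReport(
        name="cooccurrence_vs_distance",
        statistics={"spearman_rho": rho, "n_pairs": len(dists),
                    "warn_rho": warn_rho},
        flag="warn" if rho < warn_rho else "pass",
        plot_data={"x": dists.tolist(), "y": coocc.tolist()},
    )


def paired_group_correlation(p: PhenotypePanel,
                             pair_labels: dict[str, list[tuple[str, str]]],
                             warn_delta: float = 0.05) -> DiagnosticReport:
    """Mean trait-profile correlation per sample-pair category.

    ``pair_labels`` maps a category name (e.g. shared cage / shared
    shipment / neither) to its list of same-strain same-sex sample-id
    pairs.  Systematic batch effects make one category's pairs more
    correlated than the rest; a spread of category means beyond
    ``warn_delta`` warns.
    """
    means, sds, counts = {}, {}, {}
    for cat, pairs in pair_labels.items():
        rs = []
        for a, b in pairs:
            va = p.values.loc[a].to_numpy(float)
            vb = p.values.loc[b].to_numpy(float)
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3 or np.ptp(va[ok]) == 0 or np.ptp(vb[ok]) == 0:
                continue
            rs.append(float(np.corrcoef(va[ok], vb[ok])[0, 1]))
        counts[cat] = len(rs)
        means[cat] = float(np.mean(rs)) if rs else None
        sds[cat] = float(np.std(rs, ddof=1)) if len(rs) > 1 else None
    observed = [m for m in means.values() if m is not None]
    spread = float(np.ptp(observed)) if len(observed) > 1 else 0.0
    return DiagnosticReport(
        name="paired_group_correlation",
        statistics={"mean_r": means, "sd_r": sds, "n_pairs": counts,
                    "spread": spread, "warn_delta": warn_delta},
        flag="warn" if spread > warn_delta else "pass",
        plot_data={"categories": list(means), "means": list(means.values())},
    )


def flagged_feature_enrichment(hit_traits: set, flagged_traits: set,
                               background: set,
                               restricted_background: set | None = None,
                               warn_p: float = 0.05) -> DiagnosticReport:
    """Hypergeometric enrichment of flagged traits among hits.

    Used e.g. for probes overlapping known SNPs: a significant excess of
    flagged traits among the hits would point at a technical artifact.
    Computed against the full background and, when given, a restricted
    background (e.g. the most variable traits only).
    """
    if not background:
        raise ValueError("background set is empty")
    if not flagged_traits <= background:
        raise ValueError("flagged traits must be a subset of the background")

    def _enrich(bg: set) -> dict:
        hits = hit_traits & bg
        flagged = flagged_traits & bg
        k = len(hits & flagged)
        p_enrich = float(stats.hypergeom.sf(k - 1, len(bg), len(flagged),
                                            len(hits)))
        return {"n_background": len(bg), "n_hits": len(hits),
                "n_flagged": len(flagged), "n_flagged_hits": k,
                "p_enrichment": p_enrich}

    full = _enrich(background)
    result = {"full_background": full}
    if restricted_background is not None:
        result["restricted_background"] = _enrich(
            restricted_background & background)
    worst = min(v["p_enrichment"] for v in result.values())
    return DiagnosticReport(
        name="flagged_feature_enrichment",
        statistics={**result, "warn_p": warn_p},
        flag="warn" if worst < warn_p else "pass",
        plot_data={},
    )
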