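"""Permutation significance, FDR, bootstraps, and power arithmetic.

Genome-wide inference here is purely permutation-based: genotypes are
re-paired with phenotypes by a random strain-to-strain bijection, which
preserves the full correlation structure among markers and among traits,
and the observed hit count is compared with the permuted distribution.
When two sample strata (e.g. males and females) share the same strain
panel, the *same* bijection must be applied to both, otherwise their
shared genotypes would inflate the chance overlap between strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import GenotypePanel, PhenotypePanel
from .scan import (
    ScanConfig,
    eligible_markers,
    eligible_traits,
    er_scan,
    gr_scan,
    summarize_strains,
)

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_hits: int
    permuted_hit_counts: list[int]
    empirical_p: float
    fdr: float | None
    seed: int
    joint_strata: bool = False


def permute_strain_labels(g: GenotypePanel, rng: np.random.Generator
                          ) -> tuple[GenotypePanel, dict[str, str]]:
    """Re-pair genotypes with phenotypes via one strain bijection.

    Returns a genotype panel in which strain X's row now carries strain
    Y's genotypes, plus the mapping {phenotype strain -> genotype strain}.
    In joint mode, apply the returned panel to every stratum: the single
    shared bijection is what keeps between-stratum overlap honest.
    """
    strains = list(g.calls.index)
    perm = rng.permutation(len(strains))
    mapping = {strains[i]: strains[perm[i]] for i in range(len(strains))}
    permuted = g.calls.loc[[mapping[s] for s in strains]].copy()
    permuted.index = pd.Index(strains, name=g.calls.index.name)
    return GenotypePanel(permuted), mapping


def empirical_scan_p(observed: int, permuted: list[int] | np.ndarray
                     ) -> tuple[float, float | None]:
    """Add-one empirical p and permutation FDR for an observed hit count.

    p = (#{permuted >= observed} + 1) / (B + 1); FDR = min(1,
    mean(permuted) / observed), undefined (None) when observed = 0.
    """
    permuted = np.asarray(permuted)
    if permuted.size < 1:
        raise ValueError("need at least one permutation")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    b = int(np.sum(permuted >= observed))
    p = (b + 1) / (permuted.size + 1)
    fdr = min(1.0, float(permuted.mean()) / observed) if observed > 0 else None
    return p, fdr


def permutation_test(p_strata: dict[str, PhenotypePanel], g: GenotypePanel,
                     cfg: ScanConfig, mode: str, B: int, seed: int,
                     joint: bool = True) -> PermutationResult:
    """Permutation null for the total hit count across strata.

    ``p_strata`` maps stratum name -> phenotype panel; with joint=True
    all strata share each permutation's strain bijection (they must share
    the strain set).  ``mode`` is 'GR' or 'ER'.
    """
    scan_mode = mode.upper()
    if scan_mode not in ("GR", "ER"):
        raise ValueError("mode must be 'GR' or 'ER'")
    scan = gr_scan if scan_mode == "GR" else er_scan
    if joint and len(p_strata) > 1:
        strain_sets = {frozenset(pp.strains) for pp in p_strata.values()}
        if len(strain_sets) > 1:
            raise ValueError("joint permutation requires one shared strain set")
    # strain summaries and eligibility are invariant under genotype
    # relabeling, so compute them once and reuse across permutations
    summaries = {n: summarize_strains(pp, cfg) for n, pp in p_strata.items()}
    traits = {n: eligible_traits(pp, cfg, scan_mode, summaries[n])
              for n, pp in p_strata.items()}
    markers = eligible_markers(g, cfg)

    def _count(geno: GenotypePanel) -> int:
        return sum(
            len(scan(pp, geno, cfg, stratum=n, summary=summaries[n],
                     traits=traits[n], markers=markers))
            for n, pp in p_strata.items()
        )

    observed = _count(g)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(B):
        if joint:
            gp, _ = permute_strain_labels(g, rng)
            counts.append(_count(gp))
        else:
            total = 0
            for n, pp in p_strata.items():
                gp, _ = permute_strain_labels(g, rng)
                total += len(scan(pp, gp, cfg, stratum=n, summary=summaries[n],
                                  traits=traits[n], markers=markers))
            counts.append(total)
    p, fdr = empirical_scan_p(observed, counts)
    return PermutationResult(observed, counts, p, fdr, seed, joint)


def bootstrap_pvalue_ci(samples: dict, statistic, n_boot: int = 1000,
                        level: float = 0.95, seed: int = 0,
                        max_retries: int = 100) -> tuple[float, float, int]:
    """Percentile CI on a scan statistic's nominal p under resampling.

    ``samples`` maps each group key (e.g. strain or trait/environment
    cell) to its vector of raw data points; each bootstrap replicate
    resamples every group with replacement and re-evaluates
    ``statistic(resampled) -> nominal p``.  Degenerate replicates (the
    statistic raises or returns NaN, e.g. a constant group) are redrawn,
    up to ``max_retries`` per replicate; the redraw count is returned.

    Returns (lo, hi, n_redrawn).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            res = {
                k: rng.choice(np.asarray(v, float), size=len(v), replace=True)
                for k, v in samples.items()
            }
            try:
                p = statistic(res)
            except (ValueError, ZeroDivisionError):
                p = np.nan
            if np.isfinite(p):
                break
            redrawn += 1
        pvals[b] = p
    alpha = 1.0 - level
    lo, hi = np.nanquantile(pvals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), redrawn


def sex_specificity_partition(p: PhenotypePanel, g: GenotypePanel,
                              cfg: ScanConfig, mode: str,
                              half_sizes: tuple[int, int],
                              n_partitions: int, seed: int) -> dict:
    """Null distribution of hit counts under sex-blind random halves.

    Samples are repeatedly split into random halves of the given sizes
    (matching the sex-split sizes), each half is scanned, and per-half
    hit counts recorded.  If sex carries no information for these QTL,
    the true sex-split counts should sit within the random-split spread.
    """
    if n_partitions < 2:
        raise ValueError("need at least two partitions")
    if sum(half_sizes) != len(p.samples):
        raise ValueError("half sizes must sum to the sample count")
    scan = gr_scan if mode.upper() == "GR" else er_scan
    rng = np.random.default_rng(seed)
    ids = np.asarray(p.samples.index)
    counts = []
    for _ in range(n_partitions):
        order = rng.permutation(len(ids))
        for lo, hi, name in ((0, half_sizes[0], "half1"),
                             (half_sizes[0], len(ids), "half2")):
            mask = pd.Series(False, index=p.samples.index)
            mask.loc[ids[order[lo:hi]]] = True
            counts.append(len(scan(p.subset(mask), g, cfg, stratum=name)))
    counts = np.asarray(counts, float)
    return {
        "mean": float(counts.mean()),
        "sigma": float(counts.std(ddof=1)),
        "counts": counts.tolist(),
    }


def _strain_balanced_split(samples: pd.DataFrame, rng: np.random.Generator
                           ) -> tuple[pd.Series, pd.Series]:
    """Random halves with per-strain counts as equal as possible."""
    in_first = pd.Series(False, index=samples.index)
    for _, idx in samples.groupby("strain").groups.items():
        ids = rng.permutation(np.asarray(idx))
        n = len(ids)
        take = n // 2 + (rng.integers(2) if n % 2 else 0)
        in_first.loc[ids[:take]] = True
    return in_first, ~in_first


def power_by_split(p: PhenotypePanel, g: GenotypePanel, cfg: ScanConfig,
                   mode: str, n_repeats: int, n_randomizations: int,
                   seed: int) -> dict:
    """Split-half estimate of scan power.

    Per repeat: split samples into strain-balanced halves; scan both;
    estimate each half's FDR and the false-positive overlap frequency
    from genotype randomizations; then

        power = (observed overlaps - expected FP overlaps) / true positives

    where true positives = total hits x (1 - FDR) averaged over halves.
    Returns the mean over repeats; None when no true positives exist.
    """
    scan = gr_scan if mode.upper() == "GR" else er_scan
    rng = np.random.default_rng(seed)
    powers = []
    skipped = 0
    for rep in range(n_repeats):
        m1, m2 = _strain_balanced_split(p.samples, rng)
        halves = [p.subset(m1), p.subset(m2)]
        if any((h.samples.groupby("strain").size() < cfg.min_replicates).any()
               for h in halves):
            skipped += 1
            continue
        hits = [scan(h, g, cfg) for h in halves]
        keys = [set(zip(h["trait_id"], h["marker_id"])) for h in hits]
        observed_overlap = len(keys[0] & keys[1])

        perm_counts = np.zeros((n_randomizations, 2))
        perm_overlap = np.zeros(n_randomizations)
        for b in range(n_randomizations):
            gp, _ = permute_strain_labels(g, rng)
            ph = [scan(h, gp, cfg) for h in halves]
            pk = [set(zip(x["trait_id"], x["marker_id"])) for x in ph]
            perm_counts[b] = [len(k) for k in pk]
            perm_overlap[b] = len(pk[0] & pk[1])
        n_obs = np.array([len(k) for k in keys], float)
        if (n_obs == 0).any():
            skipped += 1
            continue
        fdr = np.minimum(1.0, perm_counts.mean(axis=0) / n_obs)
        tp = n_obs * (1.0 - fdr)
        # FP-overlap frequency per false positive in the smaller list
        mean_perm_pairs = perm_counts.mean(axis=0).min()
        fp_overlap_rate = (perm_overlap.mean() / mean_perm_pairs
                           if mean_perm_pairs > 0 else 0.0)
        expected_fp_overlap = fp_overlap_rate * min(
            n_obs[0] * fdr[0], n_obs[1] * fdr[1])
        total_tp = tp.min()
        if total_tp <= 0:
            skipped += 1
            continue
        powers.append(
            max(0.0, observed_overlap - expected_fp_overlap) / total_tp
        )
    if skipped:
        logger.info("power_by_split: skipped %d of %d repeats", skipped,
                    n_repeats)
    if not powers:
        return {"power": None, "n_used": 0, "n_skipped": skipped}
    return {"power": float(np.mean(powers)), "n_used": len(powers),
            "n_skipped": skipped}


def expected_overlap(n_pairs: int, tp_frac: float, power: float,
                     fp_frac: float, fp_overlap: float) -> float:
    """Expected between-list overlap from composition and power.

    expected = n_pairs * (tp_frac * power + fp_frac * fp_overlap);
    true- and false-positive fractions must sum to one.
    """
    for name, v in [("tp_frac", tp_frac), ("power", power),
                    ("fp_frac", fp_frac), ("fp_overlap", fp_overlap)]:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if abs(tp_frac + fp_frac - 1.0) > 1e-9:
        raise ValueError("tp_frac + fp_frac must equal 1")
    return n_pairs * (tp_frac * power + fp_frac * fp_overlap)


def expected_cross_scan_overlap(n_transcripts: int, tp_frac: float,
                                power: float) -> float:
    """Conservative cross-scan expectation (assumes no FP overlap)."""
    return n_transcripts * tp_frac * power


def poisson_zero_prob(mean: float) -> float:
    """P(zero events) for a Poisson count with the given mean: e^-mean."""
    if mean < 0:
        raise ValueError("mean must be >= 0")
    return float(np.exp(-mean))
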