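"""Cis/trans classification of robustness hits.

An expression trait's hit is *cis* when the marker lies within a fixed
window (default 5 Mb, inclusive) of the measured gene's representative
coordinate on the same chromosome, and *trans* otherwise; unmapped genes
or markers give *unknown*.  Because false positives land in cis only at
the genomic background rate, comparing the observed cis count with its
permutation expectation yields the approximate fraction of true-positive
hits that act in cis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import GenomicMap

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 5_000_000


def classify_hit(gene: tuple[str, int] | None, marker: tuple[str, int] | None,
                 window: int = DEFAULT_CIS_WINDOW) -> str:
    """'cis' | 'trans' | 'unknown' for one gene/marker coordinate pair."""
    if window <= 0:
        raise ValueError("window must be positive")
    if gene is None or marker is None:
        return "unknown"
    gchrom, gpos = gene
    mchrom, mpos = marker
    if str(gchrom) != str(mchrom):
        return "trans"
    return "cis" if abs(int(mpos) - int(gpos)) <= window else "trans"


def annotate_hits(hits: pd.DataFrame, features: GenomicMap,
                  markers: GenomicMap,
                  window: int = DEFAULT_CIS_WINDOW) -> pd.DataFrame:
    """Fill the cis_flag column of a hit table."""
    out = hits.copy()
    out["cis_flag"] = [
        classify_hit(features.position(t), markers.position(m), window)
        for t, m in zip(out["trait_id"], out["marker_id"])
    ]
    return out


def trait_level_cis(hits: pd.DataFrame, features: GenomicMap,
                    markers: GenomicMap,
                    window: int = DEFAULT_CIS_WINDOW) -> pd.Series:
    """Per-trait classification: cis if ANY hit marker is cis.

    Traits whose markers are all unmapped are 'unknown'.
    """
    if hits.empty:
        return pd.Series(dtype=str)
    ann = annotate_hits(hits, features, markers, window)
    def _collapse(flags: pd.Series) -> str:
        if (flags == "cis").any():
            return "cis"
        if (flags == "trans").any():
            return "trans"
        return "unknown"
    return ann.groupby("trait_id")["cis_flag"].apply(_collapse)


def expected_cis_null(permuted_hit_lists: list[pd.DataFrame],
                      features: GenomicMap, markers: GenomicMap,
                      window: int = DEFAULT_CIS_WINDOW,
                      trait_level: bool = True) -> float:
    """Chance cis count: mean over permutation-derived hit lists."""
    if not permuted_hit_lists:
        raise ValueError("no permuted hit lists supplied")
    counts = []
    for hl in permuted_hit_lists:
        if hl.empty:
            counts.append(0)
            continue
        if trait_level:
            flags = trait_level_cis(hl, features, markers, window)
        else:
            flags = annotate_hits(hl, features, markers, window)["cis_flag"]
        counts.append(int((flags == "cis").sum()))
    return float(np.mean(counts))


def expected_cis_random_markers(list_size: int, traits: list[str],
                                features: GenomicMap, markers: GenomicMap,
                                window: int, n_draws: int,
                                seed: int) -> float:
    """Alternative chance-cis estimator: random marker assignment.

    Draws ``list_size`` (trait, marker) pairs uniformly and counts cis
    classifications, averaged over draws.
    """
    rng = np.random.default_rng(seed)
    marker_ids = list(markers.table.index)
    counts = []
    for _ in range(n_draws):
        ts = rng.choice(traits, size=list_size, replace=True)
        ms = rng.choice(marker_ids, size=list_size, replace=True)
        n_cis = sum(
            classify_hit(features.position(t), markers.position(m), window) == "cis"
            for t, m in zip(ts, ms)
        )
        counts.append(n_cis)
    return float(np.mean(counts))


@dataclass
class CisSummary:
    total_hits: int
    fp_total: float
    cis_hits: int
    fp_cis: float


def cis_tp_fraction(cs: CisSummary) -> float | None:
    """Approximate fraction of true-positive hits acting in cis.

    (cis hits - expected false cis hits) / (total hits - expected false
    positives), clamped at 0 when the observed cis count falls below its
    chance expectation; None when the denominator is not positive.
    """
    denom = cs.total_hits - cs.fp_total
    if denom <= 0:
        logger.warning("cis_tp_fraction: no estimated true positives")
        return None
    frac = max(0.0, cs.cis_hits - cs.fp_cis) / denom
    return min(1.0, frac)
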