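"""Genome scans for robustness QTL.

Three scans over (trait, marker) pairs in an inbred strain panel:

* **GR scan** — genetic-robustness QTL.  Per-strain trait medians (which
  average out micro-environmental noise) are grouped by marker genotype
  and tested for unequal dispersion with the median-variant
  Fligner-Killeen statistic.  A genotype class whose strain medians are
  more spread out is less buffered against genetic background variation.
* **ER scan** — environmental-robustness QTL.  Within-strain dispersions
  (SD over replicate individuals, or CV) are correlated with genotype;
  a hit requires the genotype to explain at least ``er_r2_min`` of the
  variation in within-strain variability.
* **macro-ER scan** — robustness to defined environmental treatments.
  Per-strain, per-condition medians are collapsed to an SD across
  condition medians, then fed through the ER machinery.

All scans first exclude any (trait, marker) pair whose trait *median*
associates with genotype at nominal p < ``median_qtl_alpha``, so that
ordinary mean-effect QTL are never reported as robustness QTL.
Genome-wide significance comes from permutation (see
:mod:`robustqtl.permutation`), never from the nominal p alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import batch_fk_two_group, batch_pearson, pearson_pvalue
from .panels import (
    GENO_A,
    GENO_B,
    GenomicMap,
    GenotypePanel,
    PhenotypePanel,
    empty_hit_table,
)

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Thresholds governing trait/marker eligibility and hit calling.

    sigma_min
        Variability floor: traits whose relevant dispersion (between-strain
        SD of medians for GR, median within-strain SD for ER) is below this
        are not scanned.  Default 0.15 (log2 units).
    min_minor_strains
        Marker balance floor: minimum strains carrying the minor homozygous
        class.  None means maximal balance, floor(n_strains / 2) — e.g. 9
        of 19.
    median_qtl_alpha
        Nominal p below which a median-genotype association disqualifies a
        pair (default 0.01).
    er_r2_min
        Minimum fraction of within-strain-variability variance the genotype
        must explain for an ER hit (default 0.5; at 19 strains this
        corresponds to a two-sided nominal p of about 7e-4).
    gr_alpha
        Nominal chi-square p below which a GR pair is listed (default
        1e-3; the most extreme attainable nominal p with a 9/10 strain
        split is about 5e-4, so maximal-separation hits always pass); set
        to 1.0 to emit every tested pair.
    """

    sigma_min: float = 0.15
    min_minor_strains: int | None = None
    median_qtl_alpha: float = 0.01
    er_r2_min: float = 0.5
    gr_alpha: float = 1e-3
    dispersion_metric: str = "SD"  # or "CV"
    cv_mean_floor: float = 1e-8
    min_replicates: int = 3
    min_strains_per_class: int = 3
    cis_window: int = 5_000_000

    def __post_init__(self) -> None:
        if self.dispersion_metric not in ("SD", "CV"):
            raise ValueError("dispersion_metric must be 'SD' or 'CV'")
        for name in ("median_qtl_alpha", "er_r2_min", "gr_alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class StrainSummary:
    """Per-strain trait medians and dispersions for one sample stratum."""

    medians: pd.DataFrame      # strains x traits
    dispersions: pd.DataFrame  # strains x traits (NaN below min_replicates)
    counts: pd.Series          # replicates per strain


def summarize_strains(p: PhenotypePanel, cfg: ScanConfig) -> StrainSummary:
    """Medians and within-strain dispersions per strain.

    Dispersion is the (n-1)-denominator SD of replicate values, or the CV
    (SD / |mean|, mean floored at ``cv_mean_floor``) when configured;
    strains with fewer than ``min_replicates`` samples get NaN dispersion.
    """
    groups = p.values.groupby(p.samples["strain"])
    medians = groups.median()
    sds = groups.std(ddof=1)
    counts = p.samples.groupby("strain").size()
    sds[counts.reindex(sds.index) < cfg.min_replicates] = np.nan
    if cfg.dispersion_metric == "CV":
        means = groups.mean().abs().clip(lower=cfg.cv_mean_floor)
        disp = sds / means
    else:
        disp = sds
    return StrainSummary(medians=medians, dispersions=disp, counts=counts)


def eligible_traits(p: PhenotypePanel, cfg: ScanConfig, mode: str,
                    summary: StrainSummary | None = None) -> list[str]:
    """Traits variable enough to scan.

    GR mode keeps traits whose between-strain SD of strain medians exceeds
    ``sigma_min``; ER mode keeps traits whose *median* within-strain SD
    exceeds it.  Traits with little overall variability cannot show
    dispersion differences between genotype classes.
    """
    if mode not in ("GR", "ER"):
        raise ValueError("mode must be 'GR' or 'ER'")
    s = summary or summarize_strains(p, cfg)
    if mode == "GR":
        sigma = s.medians.std(ddof=1)
    else:
        sigma = s.dispersions.median()
    return [t for t in p.trait_ids if sigma.get(t, np.nan) > cfg.sigma_min]


def eligible_markers(g: GenotypePanel, cfg: ScanConfig) -> list[str]:
    """Markers with balanced allele frequency.

    Requires the minor homozygous class in at least ``min_minor_strains``
    strains (default: maximal balance, floor(n/2)); balanced markers give
    the dispersion tests their greatest power.
    """
    floor = cfg.min_minor_strains
    if floor is None:
        floor = len(g.strains) // 2
    return [m for m in g.marker_ids if g.minor_class_count(m) >= floor]


def median_qtl_filter(medians: np.ndarray, genotype: np.ndarray,
                      alpha: float = 0.01) -> tuple[bool, float]:
    """Keep/exclude decision for a trait/marker pair based on median signal.

    Pearson correlation between strain medians and 0/1 genotype, two-sided
    t p-value at df = n - 2.  Returns (keep, p).  Constant medians have no
    mean signal and are kept.
    """
    medians = np.asarray(medians, float)
    genotype = np.asarray(genotype, float)
    ok = np.isfinite(medians) & np.isfinite(genotype)
    medians, genotype = medians[ok], genotype[ok]
    n = medians.size
    if n < 3 or np.ptp(medians) == 0 or np.ptp(genotype) == 0:
        return True, 1.0
    r = float(batch_pearson(medians[None, :], genotype)[0])
    p = float(pearson_pvalue(r, n))
    return p >= alpha, p


def _marker_layout(g: GenotypePanel, marker_id: str, strains: list[str]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(usable strain index, mask of class B among usable, genotype 0/1)."""
    geno = g.numeric(marker_id).reindex(strains)
    usable = geno.notna().to_numpy()
    gvals = geno.to_numpy(float)[usable]
    return usable, gvals == GENO_B, gvals


def _map_cols(marker_id: str, marker_map: GenomicMap | None
              ) -> tuple[str | None, int | None]:
    if marker_map is None:
        return None, None
    pos = marker_map.position(marker_id)
    return (None, None) if pos is None else pos


def gr_scan(p: PhenotypePanel, g: GenotypePanel, cfg: ScanConfig,
            stratum: str = "all", marker_map: GenomicMap | None = None,
            summary: StrainSummary | None = None,
            traits: list[str] | None = None,
            markers: list[str] | None = None) -> pd.DataFrame:
    """Fligner-Killeen scan of strain medians against every eligible marker."""
    s = summary or summarize_strains(p, cfg)
    traits = traits if traits is not None else eligible_traits(p, cfg, "GR", s)
    markers = markers if markers is not None else eligible_markers(g, cfg)
    strains = [st for st in s.medians.index if st in g.calls.index]
    med = s.medians.loc[strains, traits]

    rows = []
    skipped = 0
    for m in markers:
        usable, mask_b, _ = _marker_layout(g, m, strains)
        n0 = int((~mask_b).sum())
        n1 = int(mask_b.sum())
        if min(n0, n1) < cfg.min_strains_per_class:
            skipped += len(traits)
            continue
        vals = med.to_numpy(float)[usable].T  # traits x usable strains
        finite = np.all(np.isfinite(vals), axis=1)
        geno = mask_b.astype(float)
        keep_r = batch_pearson(vals[finite], geno)
        keep_p = pearson_pvalue(keep_r, n0 + n1)
        d = batch_fk_two_group(vals[finite], mask_b)
        pvals = stats.chi2.sf(d, 1)
        chrom, pos = _map_cols(m, marker_map)
        for t, dd, pp, mp in zip(np.asarray(traits)[finite], d, pvals, keep_p):
            if mp < cfg.median_qtl_alpha:
                continue  # mean-effect QTL masquerading as dispersion
            if pp <= cfg.gr_alpha:
                rows.append(("GR", stratum, t, m, chrom, pos, dd, pp, None))
    if skipped:
        logger.info("gr_scan: skipped %d pairs (class below %d strains)",
                    skipped, cfg.min_strains_per_class)
    return _hits_frame(rows)


def _dispersion_scan(disp: pd.DataFrame, med: pd.DataFrame, g: GenotypePanel,
                     cfg: ScanConfig, scan_type: str, stratum: str,
                     marker_map: GenomicMap | None,
                     traits: list[str], markers: list[str]) -> pd.DataFrame:
    strains = [st for st in disp.index if st in g.calls.index]
    disp = disp.loc[strains, traits]
    med = med.loc[strains, traits]
    rows = []
    for m in markers:
        usable, mask_b, _ = _marker_layout(g, m, strains)
        n0 = int((~mask_b).sum())
        n1 = int(mask_b.sum())
        n = n0 + n1
        if min(n0, n1) < cfg.min_strains_per_class:
            continue
        geno = mask_b.astype(float)
        dvals = disp.to_numpy(float)[usable].T
        mvals = med.to_numpy(float)[usable].T
        finite = np.all(np.isfinite(dvals), axis=1) & np.all(np.isfinite(mvals), axis=1)
        nondeg = finite & (np.ptp(dvals, axis=1) > 0)
        med_p = pearson_pvalue(batch_pearson(mvals[nondeg], geno), n)
        r = batch_pearson(dvals[nondeg], geno)
        rp = pearson_pvalue(r, n)
        chrom, pos = _map_cols(m, marker_map)
        for t, rr, pp, mp in zip(np.asarray(traits)[nondeg], r, rp, med_p):
            if mp < cfg.median_qtl_alpha:
                continue
            if rr * rr >= cfg.er_r2_min:
                rows.append((scan_type, stratum, t, m, chrom, pos, rr, pp, None))
    return _hits_frame(rows)


def er_scan(p: PhenotypePanel, g: GenotypePanel, cfg: ScanConfig,
            stratum: str = "all", marker_map: GenomicMap | None = None,
            summary: StrainSummary | None = None,
            traits: list[str] | None = None,
            markers: list[str] | None = None) -> pd.DataFrame:
    """Correlation scan of within-strain dispersions against genotype."""
    s = summary or summarize_strains(p, cfg)
    traits = traits if traits is not None else eligible_traits(p, cfg, "ER", s)
    markers = markers if markers is not None else eligible_markers(g, cfg)
    return _dispersion_scan(s.dispersions, s.medians, g, cfg, "ER", stratum,
                            marker_map, traits, markers)


def macro_er_scan(p: PhenotypePanel, g: GenotypePanel, cfg: ScanConfig,
                  marker_map: GenomicMap | None = None,
                  markers: list[str] | None = None) -> pd.DataFrame:
    """Robustness to macro-environmental (between-condition) variation.

    Each strain's dispersion input is the SD over its per-condition trait
    medians (micro-environmental noise having been removed by the median);
    with c conditions each SD rests on just c points.  Strains missing a
    condition are dropped per trait.
    """
    if "condition" not in p.samples.columns:
        raise ValueError("macro-ER scan needs a 'condition' column")
    conditions = sorted(p.samples["condition"].dropna().unique())
    if len(conditions) < 2:
        raise ValueError("macro-ER scan needs at least two conditions")
    per_cond = {
        c: p.stratum(condition=c).values.groupby(
            p.stratum(condition=c).samples["strain"]).median()
        for c in conditions
    }
    strains = sorted(set().union(*[set(m.index) for m in per_cond.values()]))
    stacked = np.stack(
        [m.reindex(index=strains, columns=p.trait_ids).to_numpy(float)
         for m in per_cond.values()]
    )  # conditions x strains x traits
    incomplete = np.isnan(stacked).any(axis=0)
    macro_sd = np.std(stacked, axis=0, ddof=1)
    macro_sd[incomplete] = np.nan
    if incomplete.any():
        logger.info("macro_er_scan: %d strain/trait cells missing a "
                    "condition; dropped", int(incomplete.sum()))
    disp = pd.DataFrame(macro_sd, index=strains, columns=p.trait_ids)
    grand_med = pd.DataFrame(np.nanmedian(stacked, axis=0),
                             index=strains, columns=p.trait_ids)
    markers = markers if markers is not None else eligible_markers(g, ScanConfig())
    cfg = cfg
    return _dispersion_scan(disp, grand_med, g, cfg, "MACRO_ER", "all",
                            marker_map, list(p.trait_ids), markers)


def count_nonredundant_hits(hits: pd.DataFrame, g: GenotypePanel) -> int:
    """Hit count after collapsing markers with identical genotype columns."""
    if hits.empty:
        return 0
    rep = {}
    seen: dict[tuple, str] = {}
    for m in g.marker_ids:
        key = tuple(g.calls[m].tolist())
        rep[m] = seen.setdefault(key, m)
    collapsed = hits.assign(_rep=hits["marker_id"].map(rep))
    return int(collapsed.drop_duplicates(["trait_id", "_rep"]).shape[0])


def _hits_frame(rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return empty_hit_table()
    df = pd.DataFrame(rows, columns=[
        "scan_type", "stratum", "trait_id", "marker_id",
        "chrom", "pos", "statistic", "nominal_p", "cis_flag",
    ])
    df["pos"] = df["pos"].astype("Int64")
    return df
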