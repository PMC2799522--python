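"""Synthetic strain panels with planted robustness effects.

The generator emulates a single-sex arm of a 19-strain inbred mouse
panel: 182 individuals, with the strains split into two genotype classes
of 91 individuals each at the causal marker.  Baseline individuals draw
trait values from Normal(0, 1); the affected genotype class draws

* ER effect:    Normal(0, 1.5)           — inflated within-strain spread
* GR effect:    Normal(+/-2, 1)          — strain-level means at +2 for
  half of the affected strains and -2 for the other half, so the class
  medians scatter while each strain stays internally tight
* ER+GR effect: Normal(+/-2, 1.5)        — both at once

As in the scans themselves, any simulated trait whose strain medians
correlate with genotype at nominal p < 0.01 is discarded and
regenerated, so planted effects never leak into the trait median.

Because 182 individuals do not divide evenly over 19 strains, the
baseline class holds 9 strains (one of 11 individuals, eight of 10) and
the affected class 10 strains (one of 10, nine of 9); the affected class
having an even strain count makes the +/-2 sign split exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

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
    write_genotype_panel,
    write_map,
    write_phenotype_panel,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("NULL", "ER", "GR", "ERGR")

ER_THRESHOLDS = tuple(np.round(np.arange(0.20, 0.651, 0.05), 2))  # |r|
GR_THRESHOLDS = tuple(range(2, 12))                               # chi-square


@dataclass
class SimConfig:
    """Generative parameters for one synthetic panel."""

    n_strains: int = 19
    n_individuals: int = 182
    n_class0_strains: int = 9       # baseline genotype class
    base_sigma: float = 1.0
    er_sigma: float = 1.5
    gr_shift: float = 2.0
    median_qtl_alpha: float = 0.01  # discard-and-regenerate cutoff
    regenerate_discards: bool = True
    max_regen_rounds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_sigma <= 0 or self.er_sigma <= 0:
            raise ValueError("sigma values must be positive")
        if not (0 < self.n_class0_strains < self.n_strains):
            raise ValueError("class 0 must hold between 1 and n_strains-1 strains")

    def layout(self) -> "PanelLayout":
        return PanelLayout.from_config(self)


@dataclass
class PanelLayout:
    """Fixed allocation of individuals to strains and genotype classes."""

    strain_sizes: np.ndarray      # individuals per strain
    strain_class: np.ndarray      # 0/1 genotype class per strain
    sample_strain: np.ndarray     # strain index per individual column
    gr_sign: np.ndarray           # +1/-1 per strain (affected class only)

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "PanelLayout":
        k0 = cfg.n_class0_strains
        k1 = cfg.n_strains - k0
        per_class = cfg.n_individuals // 2
        if cfg.n_individuals % 2:
            raise ValueError(
                "n_individuals must be even to balance the genotype classes; "
                f"got {cfg.n_individuals} (try {cfg.n_individuals - 1})"
            )
        sizes = np.concatenate([
            _round_robin(per_class, k0), _round_robin(per_class, k1)
        ])
        strain_class = np.array([0] * k0 + [1] * k1)
        sample_strain = np.repeat(np.arange(cfg.n_strains), sizes)
        sign = np.zeros(cfg.n_strains)
        affected = np.where(strain_class == 1)[0]
        half = len(affected) // 2
        sign[affected[:half]] = 1.0
        sign[affected[half:]] = -1.0
        return cls(sizes, strain_class, sample_strain, sign)

    @property
    def n_strains(self) -> int:
        return len(self.strain_sizes)

    @property
    def genotype01(self) -> np.ndarray:
        return self.strain_class.astype(float)

    def strain_slices(self) -> list[slice]:
        bounds = np.concatenate([[0], np.cumsum(self.strain_sizes)])
        return [slice(int(bounds[i]), int(bounds[i + 1]))
                for i in range(self.n_strains)]


def _round_robin(total: int, k: int) -> np.ndarray:
    base, extra = divmod(total, k)
    return np.array([base + (1 if i < extra else 0) for i in range(k)])


def _draw_traits(scenario: str, n_traits: int, layout: PanelLayout,
                 cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_traits, n_individuals) raw values for one effect class."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    n_ind = int(layout.strain_sizes.sum())
    vals = rng.standard_normal((n_traits, n_ind)) * cfg.base_sigma
    affected = layout.strain_class[layout.sample_strain] == 1
    if scenario in ("ER", "ERGR"):
        vals[:, affected] *= cfg.er_sigma / cfg.base_sigma
    if scenario in ("GR", "ERGR"):
        shift = cfg.gr_shift * layout.gr_sign[layout.sample_strain]
        vals[:, affected] += shift[affected]
    return vals


def strain_medians_and_sds(values: np.ndarray, layout: PanelLayout
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-strain medians and SDs, (n_traits, n_strains) each."""
    slices = layout.strain_slices()
    med = np.column_stack([np.median(values[:, s], axis=1) for s in slices])
    sd = np.column_stack([np.std(values[:, s], axis=1, ddof=1) for s in slices])
    return med, sd


def simulate_trait_class(scenario: str, n_traits: int, cfg: SimConfig,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Simulate one effect class with the discard-and-regenerate rule.

    Returns (values, medians, sds, n_discarded).  Traits whose strain
    medians associate with genotype at p < ``median_qtl_alpha`` are
    replaced by fresh draws (keeping the class size exact) unless
    ``regenerate_discards`` is off, in which case they are dropped.
    """
    layout = cfg.layout()
    geno = layout.genotype01
    values = _draw_traits(scenario, n_traits, layout, cfg, rng)
    med, sd = strain_medians_and_sds(values, layout)
    discarded = 0
    for _ in range(cfg.max_regen_rounds):
        p = pearson_pvalue(batch_pearson(med, geno), layout.n_strains)
        bad = p < cfg.median_qtl_alpha
        if not bad.any():
            break
        discarded += int(bad.sum())
        if not cfg.regenerate_discards:
            keep = ~bad
            return values[keep], med[keep], sd[keep], discarded
        fresh = _draw_traits(scenario, int(bad.sum()), layout, cfg, rng)
        values[bad] = fresh
        med[bad], sd[bad] = strain_medians_and_sds(fresh, layout)
    else:
        raise RuntimeError("discard-and-regenerate loop did not terminate")
    return values, med, sd, discarded


# ---------------------------------------------------------------------------
# interference-ratio study

def detection_rates_er(sds: np.ndarray, layout: PanelLayout,
                       thresholds=ER_THRESHOLDS) -> np.ndarray:
    """Fraction of traits with |r(SD, genotype)| at or above each cutoff."""
    r = np.abs(batch_pearson(sds, layout.genotype01))
    return np.array([(r >= t).mean() for t in thresholds])


def detection_rates_gr(medians: np.ndarray, layout: PanelLayout,
                       thresholds=GR_THRESHOLDS) -> np.ndarray:
    """Fraction of traits whose FK statistic reaches each chi-square cutoff."""
    d = batch_fk_two_group(medians, layout.strain_class == 1)
    return np.array([(d >= t).mean() for t in thresholds])


def interference_ratio_study(cfg: SimConfig, n_traits: int,
                             er_thresholds=ER_THRESHOLDS,
                             gr_thresholds=GR_THRESHOLDS) -> dict:
    """Does a planted GR effect interfere with ER detection (and vice versa)?

    Simulates ``n_traits`` traits per class (ER, GR, ER+GR) and, at each
    threshold, forms the ratio

        detection rate among single-effect traits
        -----------------------------------------
        detection rate among ER+GR traits

    A ratio near one at every cutoff means the second planted effect
    neither masks nor mimics the first.  Returns per-threshold ratio
    tables with normal-approximation 95% Monte-Carlo intervals; a ratio
    is None when its denominator rate is zero.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    out: dict = {"n_traits": n_traits, "discarded": {}}
    _, _, sd_er, d1 = simulate_trait_class("ER", n_traits, cfg, rng)
    _, med_gr, _, d2 = simulate_trait_class("GR", n_traits, cfg, rng)
    _, med_ergr, sd_ergr, d3 = simulate_trait_class("ERGR", n_traits, cfg, rng)
    out["discarded"] = {"ER": d1, "GR": d2, "ERGR": d3}

    er_single = detection_rates_er(sd_er, layout, er_thresholds)
    er_joint = detection_rates_er(sd_ergr, layout, er_thresholds)
    gr_single = detection_rates_gr(med_gr, layout, gr_thresholds)
    gr_joint = detection_rates_gr(med_ergr, layout, gr_thresholds)

    out["er"] = _ratio_table(er_thresholds, er_single, er_joint, n_traits)
    out["gr"] = _ratio_table(gr_thresholds, gr_single, gr_joint, n_traits)
    return out


def _ratio_table(thresholds, single: np.ndarray, joint: np.ndarray,
                 n: int) -> list[dict]:
    rows = []
    for t, ps, pj in zip(thresholds, single, joint):
        if pj == 0.0:
            rows.append({"threshold": float(t), "rate_single": float(ps),
                         "rate_joint": 0.0, "ratio": None,
                         "ci_lo": None, "ci_hi": None})
            continue
        ratio = ps / pj
        # delta-method SE of a ratio of two independent binomial rates
        var = 0.0
        if 0 < ps < 1:
            var += (1 - ps) / (ps * n)
        if 0 < pj < 1:
            var += (1 - pj) / (pj * n)
        half = 1.96 * ratio * np.sqrt(var)
        rows.append({"threshold": float(t), "rate_single": float(ps),
                     "rate_joint": float(pj), "ratio": float(ratio),
                     "ci_lo": float(ratio - half), "ci_hi": float(ratio + half)})
    return rows


def max_ratio(table: list[dict]) -> float:
    ratios = [row["ratio"] for row in table if row["ratio"] is not None]
    if not ratios:
        raise ValueError("no defined ratios in table")
    return max(ratios)


# ---------------------------------------------------------------------------
# mean-QTL masquerade

def simulate_mean_masquerade(cfg: SimConfig, shift_grid: list[float],
                             n_traits: int = 2000,
                             causal_freq: float = 0.5,
                             alpha: float = 0.01) -> pd.DataFrame:
    """Can an ordinary mean QTL slip through as a dispersion QTL?

    A hidden causal variant carried by each affected-class strain
    independently with probability ``causal_freq`` (and absent from the
    baseline class) shifts carrier strains' means, inflating the affected
    class's median dispersion — the signature a GR scan looks for.  For
    each mean shift this returns the rate at which the median filter
    (Pearson p < alpha) disqualifies the trait versus the rate at which
    the FK test alone would have flagged it at the same nominal level
    (d exceeding the chi-square alpha quantile), on the same simulated
    traits with no discard rule applied.

    At ``causal_freq = 1`` every affected strain is shifted and the
    scenario reduces to an ordinary whole-class mean QTL, which the
    median filter excludes essentially always once the shift reaches the
    trait's noise scale.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    geno = layout.genotype01
    affected = np.where(layout.strain_class == 1)[0]
    d_crit = stats.chi2.isf(alpha, 1)
    rows = []
    for shift in shift_grid:
        vals = _draw_traits("NULL", n_traits, layout, cfg, rng)
        carrier_mask = np.zeros((n_traits, layout.n_strains), bool)
        carrier_mask[:, affected] = (
            rng.random((n_traits, len(affected))) < causal_freq
        )
        vals += shift * carrier_mask[:, layout.sample_strain]
        med, _ = strain_medians_and_sds(vals, layout)
        med_p = pearson_pvalue(batch_pearson(med, geno), layout.n_strains)
        d = batch_fk_two_group(med, layout.strain_class == 1)
        rows.append({
            "shift": shift,
            "median_filter_rate": float((med_p < alpha).mean()),
            "fk_rate": float((d >= d_crit).mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# panel and fixture construction

def simulate_panel(cfg: SimConfig, n_traits_per_class: dict[str, int],
                   sex: str | None = None
                   ) -> tuple[PhenotypePanel, GenotypePanel, pd.DataFrame]:
    """Full in-memory panel with one causal marker per effect class.

    ``n_traits_per_class`` maps scenario name -> trait count.  Every
    scenario's traits share one planted marker whose genotype vector is
    the class split; a truth table records (trait, scenario, marker).
    """
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    strain_names = [f"S{i:02d}" for i in range(layout.n_strains)]
    sample_ids, strain_col = [], []
    for i, (name, sl) in enumerate(zip(strain_names, layout.strain_slices())):
        for j in range(sl.stop - sl.start):
            sample_ids.append(f"{name}_r{j:02d}")
            strain_col.append(name)

    blocks, trait_ids, truth_rows = [], [], []
    for scenario, n_tr in n_traits_per_class.items():
        if n_tr == 0:
            continue
        vals, _, _, discarded = simulate_trait_class(scenario, n_tr, cfg, rng)
        if discarded:
            logger.info("simulate_panel: %s regenerated %d traits",
                        scenario, discarded)
        blocks.append(vals)
        for t in range(n_tr):
            tid = f"{scenario}_t{t:03d}"
            trait_ids.append(tid)
            truth_rows.append({"trait_id": tid, "scenario": scenario,
                               "marker_id": "M_causal"})
    values = pd.DataFrame(
        np.vstack(blocks).T if blocks else np.empty((len(sample_ids), 0)),
        index=pd.Index(sample_ids, name="sample_id"), columns=trait_ids,
    )
    meta = pd.DataFrame({"strain": strain_col}, index=values.index)
    if sex is not None:
        meta["sex"] = sex
    pheno = PhenotypePanel(meta, values)
    calls = pd.DataFrame(
        {"M_causal": np.where(layout.strain_class == 1, GENO_B, GENO_A)},
        index=pd.Index(strain_names, name="strain"), dtype=np.int8,
    )
    geno = GenotypePanel(calls)
    return pheno, geno, pd.DataFrame(truth_rows)


def make_fixture(cfg: SimConfig, out_dir, n_traits_per_class=None,
                 n_null_markers: int = 6, chrom_length: int = 100_000_000,
                 n_chromosomes: int = 3) -> dict:
    """Write a complete miniature study to ``out_dir``.

    Produces phenotype/genotype TSVs, a multi-chromosome marker map, a
    feature map that places each planted trait's gene in cis with the
    causal marker (GR traits) or in trans (others), a redundant duplicate
    of the causal marker, and a truth JSON.  Deterministic under the
    config seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / f"{k}.tsv" for k in
             ("phenotype", "genotype", "markers", "features")}
    paths["truth"] = out_dir / "truth.json"
    for p in paths.values():
        if p.exists():
            raise FileExistsError(f"fixture path exists: {p}")
    if n_traits_per_class is None:
        n_traits_per_class = {"NULL": 4, "ER": 3, "GR": 3, "ERGR": 2}

    pheno, geno, truth = simulate_panel(cfg, n_traits_per_class)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    layout = cfg.layout()

    # extra markers: balanced random splits, plus a duplicate of the causal
    calls = geno.calls.copy()
    k_minor = layout.n_strains // 2
    for i in range(n_null_markers):
        minor = rng.choice(layout.n_strains, size=k_minor, replace=False)
        col = np.full(layout.n_strains, GENO_A, dtype=np.int8)
        col[minor] = GENO_B
        calls[f"M_null{i:02d}"] = col
    calls["M_causal_dup"] = calls["M_causal"]
    geno = GenotypePanel(calls)

    marker_ids = list(calls.columns)
    chroms = [str(1 + i % n_chromosomes) for i in range(len(marker_ids))]
    positions = [int(10_000_000 + 7_000_000 * i) for i in range(len(marker_ids))]
    mmap = GenomicMap(pd.DataFrame(
        {"chrom": chroms, "pos": positions},
        index=pd.Index(marker_ids, name="id"),
    ))

    causal_chrom, causal_pos = mmap.position("M_causal")
    feat_rows = {}
    far_chrom = str(((int(causal_chrom)) % n_chromosomes) + 1)
    for tid, scen in zip(truth["trait_id"], truth["scenario"]):
        if scen == "GR":
            feat_rows[tid] = (causal_chrom, causal_pos + 1_000_000)  # cis
        else:
            feat_rows[tid] = (far_chrom, 50_000_000)                 # trans
    fmap = GenomicMap(pd.DataFrame(
        {"chrom": [v[0] for v in feat_rows.values()],
         "pos": [v[1] for v in feat_rows.values()]},
        index=pd.Index(list(feat_rows), name="id"),
    ))

    write_phenotype_panel(pheno, paths["phenotype"])
    write_genotype_panel(geno, paths["genotype"])
    write_map(mmap, paths["markers"])
    write_map(fmap, paths["features"])
    truth_payload = {
        "seed": cfg.seed,
        "causal_marker": "M_causal",
        "redundant_markers": ["M_causal_dup"],
        "traits": truth.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
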