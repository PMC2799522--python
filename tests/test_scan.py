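"""Eligibility filters, median-QTL exclusion, and the three genome scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from robustqtl.panels import GENO_A, GENO_B
from robustqtl.scan import (
    ScanConfig,
    count_nonredundant_hits,
    eligible_markers,
    eligible_traits,
    er_scan,
    gr_scan,
    macro_er_scan,
    median_qtl_filter,
    summarize_strains,
)
from conftest import (
    balanced_marker,
    build_genotype_panel,
    build_phenotype_panel,
    replicated_panel,
)

N_STRAINS = 19
STRAINS = [f"S{i:02d}" for i in range(N_STRAINS)]


def causal_geno():
    return build_genotype_panel({"Mq": balanced_marker(N_STRAINS)}, STRAINS)


def test_eligible_traits_by_mode(rng):
    # trait0: strain medians spread (GR-eligible), tiny replicate noise
    # trait1: replicate noise only (ER-eligible), strain medians tight
    # trait2: constant
    reps = 12
    shift = rng.normal(scale=0.5, size=N_STRAINS)
    t0 = np.vstack([np.full((reps, 1), shift[i])
                    + rng.normal(scale=0.01, size=(reps, 1))
                    for i in range(N_STRAINS)])
    t1 = rng.normal(scale=0.3, size=(reps * N_STRAINS, 1))
    t2 = np.zeros((reps * N_STRAINS, 1))
    panel = build_phenotype_panel(
        np.hstack([t0, t1, t2]), np.repeat(STRAINS, reps).tolist(),
        trait_ids=["gr_like", "er_like", "flat"],
    )
    cfg = ScanConfig()
    assert eligible_traits(panel, cfg, "GR") == ["gr_like"]
    assert eligible_traits(panel, cfg, "ER") == ["er_like"]
    # relaxing the floor only grows the set
    loose = eligible_traits(panel, ScanConfig(sigma_min=1e-6), "GR")
    assert set(loose) >= {"gr_like"}


def test_eligible_markers_balance_rule():
    g = build_genotype_panel({
        "bal": [GENO_A] * 10 + [GENO_B] * 9,
        "skew": [GENO_A] * 17 + [GENO_B] * 2,
    }, STRAINS)
    assert eligible_markers(g, ScanConfig()) == ["bal"]
    assert set(eligible_markers(g, ScanConfig(min_minor_strains=1))) == {
        "bal", "skew"}


def test_median_qtl_filter_decisions():
    geno = np.array(balanced_marker(N_STRAINS), float)
    ordered = np.arange(N_STRAINS, dtype=float)[np.argsort(geno, kind="stable")]
    keep, p = median_qtl_filter(np.sort(geno) * 2 + 0.01 * ordered, np.sort(geno))
    assert not keep and p < 1e-6
    symmetric = np.where(geno == 1, 0.0, 0.0)
    keep2, p2 = median_qtl_filter(symmetric, geno)
    assert keep2  # constant medians carry no mean signal
    balanced = np.tile([1.0, -1.0], 10)[:N_STRAINS] * (1 - geno) \
        + np.tile([1.0, -1.0], 10)[:N_STRAINS] * geno
    keep3, _ = median_qtl_filter(balanced, geno)
    assert keep3


def test_gr_scan_recovers_planted_effect(rng):
    sign = np.zeros(N_STRAINS)
    sign[9:] = np.repeat([2.0, -2.0], [5, 5])  # genotype-B strains split 5/5
    geno_col = [GENO_A] * 9 + [GENO_B] * 10
    panel = replicated_panel(rng, N_STRAINS, 8, 3, strain_shift=sign[:, None] *
                             np.array([1.0, 0.0, 0.0]))
    g = build_genotype_panel({
        "Mq": geno_col,
        "Mnull": balanced_marker(N_STRAINS)[::-1],
    }, STRAINS)
    hits = gr_scan(panel, g, ScanConfig(), stratum="all")
    planted = hits[(hits["trait_id"] == "trait0") & (hits["marker_id"] == "Mq")]
    assert len(planted) == 1
    assert planted["nominal_p"].iloc[0] == hits["nominal_p"].min()


def test_gr_scan_null_calibration(rng):
    panel = replicated_panel(rng, N_STRAINS, 4, 120)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=0.05)
    hits = gr_scan(panel, causal_geno(), cfg)
    # conservative chi-square reference: at most ~5% of 120 pairs listed
    assert len(hits) <= stats.binom.ppf(0.999, 120, 0.05)


def test_gr_scan_sees_only_medians(rng):
    """Shuffling replicates within strains leaves the GR scan unchanged."""
    panel = replicated_panel(rng, N_STRAINS, 5, 4)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=1.0)
    base = gr_scan(panel, causal_geno(), cfg)
    shuffled_vals = panel.values.copy()
    for _, idx in panel.samples.groupby("strain").groups.items():
        shuffled_vals.loc[idx] = shuffled_vals.loc[
            np.asarray(idx)[rng.permutation(len(idx))]].to_numpy()
    panel2 = build_phenotype_panel(shuffled_vals.to_numpy(),
                                   panel.samples["strain"].tolist())
    panel2.values.index = panel.values.index
    again = gr_scan(panel2, causal_geno(), cfg)
    np.testing.assert_allclose(base["statistic"].to_numpy(),
                               again["statistic"].to_numpy(), atol=1e-12)


def test_gr_scan_wide_bimodal_group_is_a_hit_not_median_filtered(rng):
    """Equal-median tight-vs-bimodal genotype groups must be reported."""
    shift = np.zeros(N_STRAINS)
    shift[9:] = np.tile([3.0, -3.0], 5)  # bimodal, median ~0 like class A
    panel = replicated_panel(rng, N_STRAINS, 6,
                             1, strain_shift=shift[:, None],
                             strain_sigma=np.full((N_STRAINS, 1), 0.05))
    g = build_genotype_panel({"Mq": [GENO_A] * 9 + [GENO_B] * 10}, STRAINS)
    hits = gr_scan(panel, g, ScanConfig())
    assert len(hits) == 1


def test_er_scan_recovers_planted_dispersion(rng):
    sigma = np.ones(N_STRAINS)
    sigma[9:] = 1.5
    found = 0
    for rep in range(9):
        # mouse-like replication: ~20 individuals per strain
        panel = replicated_panel(rng, N_STRAINS, 20, 1,
                                 strain_sigma=sigma[:, None])
        g = build_genotype_panel({"Mq": [GENO_A] * 9 + [GENO_B] * 10}, STRAINS)
        hits = er_scan(panel, g, ScanConfig())
        found += int(len(hits) == 1)
    assert found >= 5  # recovered in the majority of simulations


def test_er_scan_invariances(rng):
    panel = replicated_panel(rng, N_STRAINS, 8, 2)
    g = causal_geno()
    cfg = ScanConfig(sigma_min=0.0, er_r2_min=0.01)
    base = er_scan(panel, g, cfg)
    # adding a per-strain constant does not change SDs; the alternating
    # pattern stays uncorrelated with genotype so the median filter
    # excludes the same pairs before and after
    offset = dict(zip(STRAINS, np.tile([0.5, -0.5], 10)[:N_STRAINS]))
    vals = panel.values.add(panel.samples["strain"].map(offset), axis=0)
    shifted = build_phenotype_panel(vals.to_numpy(),
                                    panel.samples["strain"].tolist())
    again = er_scan(shifted, g, cfg)
    np.testing.assert_allclose(base["statistic"].to_numpy(),
                               again["statistic"].to_numpy(), atol=1e-12)
    # identical dispersions across strains -> no hit
    flat = replicated_panel(rng, N_STRAINS, 6, 1,
                            strain_sigma=np.full((N_STRAINS, 1), 1.0))
    flat.values.iloc[:] = np.tile(
        np.linspace(-1, 1, 6)[:, None], (N_STRAINS, 1))
    assert er_scan(flat, g, ScanConfig(sigma_min=0.0)).empty


def test_er_threshold_matches_nominal_p():
    """|r| = sqrt(0.5) at 19 strains sits below nominal p 0.00085."""
    r = np.sqrt(0.5)
    t = r * np.sqrt(17 / (1 - 0.5))
    p = 2 * stats.t.sf(t, 17)
    assert p == pytest.approx(7.1e-4, rel=0.02)
    assert p < 0.00085


def test_macro_er_scan(rng):
    conditions = ["c1", "c2", "c3"]
    # genotype-B strains: condition means spread; genotype-A: constant
    rows, strains, conds = [], [], []
    for i, s in enumerate(STRAINS):
        for ci, c in enumerate(conditions):
            shift = (ci - 1) * 2.0 if i >= 10 else 0.0
            rows.append(rng.normal(loc=shift, scale=0.05, size=(4, 1)))
            strains += [s] * 4
            conds += [c] * 4
    panel = build_phenotype_panel(np.vstack(rows), strains, condition=conds)
    g = build_genotype_panel({"Mq": [GENO_A] * 10 + [GENO_B] * 9}, STRAINS)
    hits = macro_er_scan(panel, g, ScanConfig())
    assert len(hits) == 1
    assert hits["scan_type"].iloc[0] == "MACRO_ER"

    # identical condition medians everywhere -> zero dispersion, no hits
    flat = build_phenotype_panel(
        np.tile(np.linspace(-1, 1, 4)[:, None], (N_STRAINS * 3, 1)),
        strains, condition=conds)
    assert macro_er_scan(flat, g, ScanConfig()).empty


def test_exclusion_asymmetry(rng):
    """Tightening the median filter (smaller alpha) only grows the hit set."""
    sign = np.zeros(N_STRAINS)
    sign[10:] = np.tile([2.0, -2.0], 5)[:9] + 0.3  # slight mean leak
    panel = replicated_panel(rng, N_STRAINS, 6, 6, strain_shift=sign[:, None])
    g = build_genotype_panel({"Mq": [GENO_A] * 10 + [GENO_B] * 9}, STRAINS)
    loose = gr_scan(panel, g, ScanConfig(median_qtl_alpha=0.05, gr_alpha=1.0))
    strict = gr_scan(panel, g, ScanConfig(median_qtl_alpha=0.001, gr_alpha=1.0))
    loose_keys = set(zip(loose["trait_id"], loose["marker_id"]))
    strict_keys = set(zip(strict["trait_id"], strict["marker_id"]))
    assert loose_keys <= strict_keys


def test_nonredundant_hit_counting(rng):
    g = build_genotype_panel({
        "m1": balanced_marker(N_STRAINS),
        "m1dup": balanced_marker(N_STRAINS),
        "m2": balanced_marker(N_STRAINS)[::-1],
    }, STRAINS)
    hits = pd.DataFrame({
        "trait_id": ["t", "t", "t"],
        "marker_id": ["m1", "m1dup", "m2"],
    })
    assert count_nonredundant_hits(hits, g) == 2


def test_summary_min_replicates(rng):
    panel = build_phenotype_panel(rng.standard_normal((5, 1)),
                                  ["A", "A", "A", "B", "B"])
    s = summarize_strains(panel, ScanConfig(min_replicates=3))
    assert np.isfinite(s.dispersions.loc["A"]).all()
    assert s.dispersions.loc["B"].isna().all()
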