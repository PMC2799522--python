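"""Permutation machinery, overlap arithmetic, bootstraps, and power."""

import numpy as np
import pandas as pd
import pytest

from robustqtl.fligner import fk_statistic
from robustqtl.panels import GENO_A, GENO_B, GenotypePanel
from robustqtl.permutation import (
    bootstrap_pvalue_ci,
    empirical_scan_p,
    expected_cross_scan_overlap,
    expected_overlap,
    permutation_test,
    permute_strain_labels,
    poisson_zero_prob,
    power_by_split,
    sex_specificity_partition,
)
from robustqtl.scan import ScanConfig, er_scan, gr_scan
from conftest import (
    balanced_marker,
    build_genotype_panel,
    build_phenotype_panel,
    replicated_panel,
)

N_STRAINS = 10
STRAINS = [f"S{i:02d}" for i in range(N_STRAINS)]


def small_geno(rng=None, n_markers=2):
    cols = {}
    base = balanced_marker(N_STRAINS)
    for m in range(n_markers):
        col = list(base)
        if rng is not None:
            rng.shuffle(col)
        cols[f"M{m}"] = col
    return build_genotype_panel(cols, STRAINS)


def test_identity_permutation_reproduces_observed(rng):
    panel = replicated_panel(rng, N_STRAINS, 4, 6)
    g = small_geno(rng)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=0.5, min_strains_per_class=3)
    base = gr_scan(panel, g, cfg)

    class IdentityRng:
        def permutation(self, n):
            return np.arange(n)

    gp, mapping = permute_strain_labels(g, IdentityRng())
    assert mapping == {s: s for s in STRAINS}
    again = gr_scan(panel, gp, cfg)
    pd.testing.assert_frame_equal(base, again)


def test_permutation_determinism_and_bijection(rng):
    g = small_geno(rng)
    g1, map1 = permute_strain_labels(g, np.random.default_rng(5))
    g2, map2 = permute_strain_labels(g, np.random.default_rng(5))
    assert map1 == map2
    pd.testing.assert_frame_equal(g1.calls, g2.calls)
    assert sorted(map1.values()) == sorted(STRAINS)  # a bijection


def test_joint_permutation_shares_bijection(rng):
    """Male and female strata must see the identical strain relabeling."""
    male = replicated_panel(rng, N_STRAINS, 3, 4)
    female = replicated_panel(rng, N_STRAINS, 3, 4)
    g = small_geno(rng)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=0.9)
    res = permutation_test({"M": male, "F": female}, g, cfg, "GR", B=3,
                           seed=1, joint=True)
    assert res.joint_strata
    # strain-set mismatch is rejected
    odd = replicated_panel(rng, N_STRAINS - 1, 3, 4)
    with pytest.raises(ValueError, match="strain set"):
        permutation_test({"M": male, "F": odd}, g, cfg, "GR", B=2, seed=0,
                         joint=True)


def test_joint_permutation_preserves_cross_stratum_correlation(rng):
    """Relabeling strains cannot change male-female trait correlations."""
    male = replicated_panel(rng, N_STRAINS, 4, 3)
    female = replicated_panel(rng, N_STRAINS, 4, 3)
    g = small_geno(rng)
    med_m = male.values.groupby(male.samples["strain"]).median()
    med_f = female.values.groupby(female.samples["strain"]).median()
    base_corr = [np.corrcoef(med_m[t], med_f[t])[0, 1] for t in med_m.columns]
    gp, mapping = permute_strain_labels(g, np.random.default_rng(8))
    # applying the same strain bijection to both strata's phenotypes
    order = [mapping[s] for s in med_m.index]
    perm_corr = [np.corrcoef(med_m.loc[order, t], med_f.loc[order, t])[0, 1]
                 for t in med_m.columns]
    np.testing.assert_allclose(base_corr, perm_corr, atol=1e-12)


def test_empirical_p_and_fdr_arithmetic():
    p, fdr = empirical_scan_p(500, [0] * 10_000)
    assert p == pytest.approx(1 / 10_001)
    assert p < 0.0001
    assert fdr == 0.0

    p, fdr = empirical_scan_p(100, [63, 64, 62, 63, 63, 64, 62, 63, 63, 64])
    assert fdr == pytest.approx(0.631)

    p, _ = empirical_scan_p(5, [5, 5, 5])
    assert p == 1.0

    _, fdr = empirical_scan_p(0, [1, 2])
    assert fdr is None


def test_fdr_near_one_on_null_data(rng):
    panel = replicated_panel(rng, N_STRAINS, 4, 30)
    g = small_geno(rng)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=0.4)
    res = permutation_test({"all": panel}, g, cfg, "GR", B=40, seed=3)
    assert res.observed_hits > 0
    assert 0.5 < res.fdr <= 1.0


def test_expected_overlap_formula():
    assert expected_overlap(100, 1.0, 1.0, 0.0, 0.0) == 100
    assert expected_overlap(100, 0.4, 0.0, 0.6, 0.0) == 0
    v = expected_overlap(1000, 0.3, 0.285, 0.7, 0.082)
    assert v == pytest.approx(1000 * (0.3 * 0.285 + 0.7 * 0.082))
    with pytest.raises(ValueError, match="equal 1"):
        expected_overlap(10, 0.5, 0.5, 0.4, 0.1)


def test_cross_scan_overlap_and_poisson_zero():
    # 78 transcripts with tp_frac*power chosen to give ~14 expected
    expected = expected_cross_scan_overlap(78, 0.63, 0.285)
    assert expected == pytest.approx(14.0, abs=0.1)
    assert poisson_zero_prob(expected) < 1e-6
    assert poisson_zero_prob(0.0) == 1.0
    assert poisson_zero_prob(2.0) == pytest.approx(np.exp(-2), abs=1e-12)
    with pytest.raises(ValueError):
        poisson_zero_prob(-1.0)


def test_bootstrap_ci_degenerate_and_nesting(rng):
    const = {"g": np.ones(5)}
    lo, hi, _ = bootstrap_pvalue_ci(const, lambda s: float(s["g"].mean()),
                                    n_boot=50, seed=1)
    assert lo == hi == 1.0

    samples = {"a": rng.standard_normal(12), "b": rng.standard_normal(12) * 3}

    def stat(s):
        return fk_statistic([s["a"], s["b"]]).nominal_p

    lo95, hi95, _ = bootstrap_pvalue_ci(samples, stat, n_boot=300, level=0.95,
                                        seed=2)
    lo99, hi99, _ = bootstrap_pvalue_ci(samples, stat, n_boot=300, level=0.99,
                                        seed=2)
    assert lo99 <= lo95 <= hi95 <= hi99


def test_bootstrap_ci_planted_dispersion_significant(rng):
    """A strong planted dispersion difference stays significant under resampling.

    Group sizes mirror a recombinant-inbred panel split (~49 strains per
    genotype class), where the rank test's attainable p floor is deep
    enough for a bootstrap interval to stay clear of 0.05.
    """
    samples = {"tight": rng.normal(scale=0.3, size=49),
               "wide": rng.normal(scale=2.5, size=49)}

    def stat(s):
        return fk_statistic([s["tight"], s["wide"]]).nominal_p

    _, hi, _ = bootstrap_pvalue_ci(samples, stat, n_boot=400, level=0.99,
                                   seed=3)
    assert hi < 0.05


def test_sex_specificity_partition(rng):
    panel = replicated_panel(rng, N_STRAINS, 6, 8)
    g = small_geno(rng)
    cfg = ScanConfig(sigma_min=0.0, gr_alpha=0.5)
    n = len(panel.samples)
    res1 = sex_specificity_partition(panel, g, cfg, "GR", (n // 2, n - n // 2),
                                     n_partitions=3, seed=11)
    res2 = sex_specificity_partition(panel, g, cfg, "GR", (n // 2, n - n // 2),
                                     n_partitions=3, seed=11)
    assert res1 == res2
    assert len(res1["counts"]) == 6
    with pytest.raises(ValueError):
        sex_specificity_partition(panel, g, cfg, "GR", (n // 2, n - n // 2),
                                  n_partitions=1, seed=0)


def test_power_by_split_matches_direct_oracle(rng):
    """Split-half power agrees with a fresh-panel detection-rate oracle."""
    n_strains, reps, n_traits = 19, 20, 25
    strains = [f"S{i:02d}" for i in range(n_strains)]
    sigma = np.ones(n_strains)
    sigma[9:] = 1.6
    geno = build_genotype_panel({"Mq": [GENO_A] * 9 + [GENO_B] * 10}, strains)
    cfg = ScanConfig(min_strains_per_class=3)

    def planted(local_rng, r):
        return replicated_panel(local_rng, n_strains, r, n_traits,
                                strain_sigma=np.tile(sigma[:, None],
                                                     (1, n_traits))[:, :1])

    panel = planted(rng, reps)
    est = power_by_split(panel, geno, cfg, "ER", n_repeats=12,
                         n_randomizations=25, seed=21)
    assert est["power"] is not None

    # oracle: detection rate of the planted marker in fresh half-size panels
    oracle_rng = np.random.default_rng(909)
    detected = total = 0
    for _ in range(30):
        half = planted(oracle_rng, reps // 2)
        hits = er_scan(half, geno, cfg)
        total += n_traits
        detected += len(hits)
    assert est["power"] == pytest.approx(detected / total, abs=0.1)


def test_power_missing_on_null_panel(rng):
    panel = replicated_panel(rng, N_STRAINS, 8, 4)
    g = small_geno(rng)
    est = power_by_split(panel, g, ScanConfig(sigma_min=0.0), "ER",
                         n_repeats=4, n_randomizations=10, seed=5)
    assert est["power"] is None or est["power"] == pytest.approx(0.0, abs=0.2)
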