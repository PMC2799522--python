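import numpy as np
import pandas as pd
import pytest

from robustqtl.panels import GENO_A, GENO_B, GenotypePanel, PhenotypePanel


def build_phenotype_panel(values: np.ndarray, strains: list[str],
                          sex: list[str] | None = None,
                          condition: list[str] | None = None,
                          trait_ids: list[str] | None = None) -> PhenotypePanel:
    """Assemble a panel from a (samples x traits) array and strain labels."""
    n, t = values.shape
    ids = [f"{strains[i]}_r{i}" for i in range(n)]
    trait_ids = trait_ids or [f"trait{j}" for j in range(t)]
    vals = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"),
                        columns=trait_ids)
    meta = pd.DataFrame({"strain": strains}, index=vals.index)
    if sex is not None:
        meta["sex"] = sex
    if condition is not None:
        meta["condition"] = condition
    return PhenotypePanel(meta, vals)


def build_genotype_panel(columns: dict[str, list[int]],
                         strains: list[str]) -> GenotypePanel:
    calls = pd.DataFrame(columns, index=pd.Index(strains, name="strain"),
                         dtype=np.int8)
    return GenotypePanel(calls)


def replicated_panel(rng, n_strains: int, reps: int, n_traits: int,
                     strain_shift: np.ndarray | None = None,
                     strain_sigma: np.ndarray | None = None) -> PhenotypePanel:
    """Gaussian replicate panel with optional per-strain mean/sigma."""
    shift = np.zeros(n_strains) if strain_shift is None else strain_shift
    sigma = np.ones(n_strains) if strain_sigma is None else strain_sigma
    rows, strains = [], []
    for i in range(n_strains):
        rows.append(rng.standard_normal((reps, n_traits)) * sigma[i] + shift[i])
        strains += [f"S{i:02d}"] * reps
    return build_phenotype_panel(np.vstack(rows), strains)


def balanced_marker(n_strains: int) -> list[int]:
    k = n_strains // 2
    return [GENO_A] * (n_strains - k) + [GENO_B] * k


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
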