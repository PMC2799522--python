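"""Panel containers and tab-delimited I/O.

The study design is an inbred strain panel: each strain is genotyped once
(homozygous biallelic calls) and phenotyped in many replicate individuals,
optionally stratified by sex and/or an environmental condition label.
Phenotypes are continuous traits such as log2 expression levels.

File formats (all plain TSV with a header row):

* phenotype: ``sample_id  strain  [sex]  [condition]  <trait...>``
* genotype:  ``strain  <marker...>`` with configurable allele tokens
* map:       ``id  chrom  pos`` (1-based bp); 0-based half-open BED accepted
* hits:      ``scan_type  stratum  trait_id  marker_id  chrom  pos
  statistic  nominal_p  cis_flag``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

# genotype codes
GENO_A = 0
GENO_B = 1
GENO_HET = 2
GENO_MISSING = 3

DEFAULT_GENO_TOKENS = {"A": GENO_A, "B": GENO_B, "H": GENO_HET, "NA": GENO_MISSING,
                       "0": GENO_A, "1": GENO_B}

HIT_COLUMNS = [
    "scan_type", "stratum", "trait_id", "marker_id",
    "chrom", "pos", "statistic", "nominal_p", "cis_flag",
]


class PanelError(ValueError):
    """Raised when a panel file fails validation."""


@dataclass
class PhenotypePanel:
    """Replicated sample-by-trait measurements with strain labels.

    ``samples`` is indexed by sample_id with columns ``strain`` and
    optionally ``sex`` ({F, M}) and ``condition``; ``values`` is a float
    frame (samples x traits) with NaN for missing cells.
    """

    samples: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.values.index):
            raise PanelError("sample metadata and values must share an index")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise PanelError(f"duplicate sample id: {dup!r}")
        if "strain" not in self.samples.columns:
            raise PanelError("required column 'strain' is missing")
        if self.samples["strain"].isna().any():
            raise PanelError("every sample must have a strain")
        if self.values.columns.duplicated().any():
            raise PanelError("trait ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isfinite(self.values.to_numpy(float)) |
                    self.values.isna().to_numpy())
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise PanelError(
                f"non-finite trait value at sample {self.values.index[r]!r}, "
                f"trait {self.values.columns[c]!r}"
            )

    @property
    def strains(self) -> list[str]:
        return sorted(self.samples["strain"].unique())

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, mask: pd.Series) -> "PhenotypePanel":
        return PhenotypePanel(self.samples.loc[mask], self.values.loc[mask])

    def stratum(self, sex: str | None = None, condition: str | None = None) -> "PhenotypePanel":
        """Samples restricted to one sex and/or condition label."""
        mask = pd.Series(True, index=self.samples.index)
        if sex is not None:
            mask &= self.samples["sex"] == sex
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return self.subset(mask)


@dataclass
class GenotypePanel:
    """Strain-level homozygous genotype calls.

    ``calls`` is an int8 frame (strains x markers) over the codes
    {GENO_A, GENO_B, GENO_HET, GENO_MISSING}.  Heterozygous calls are
    never recoded; scanners drop those strains per marker.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            raise PanelError("strain ids must be unique")
        self.calls = self.calls.astype(np.int8)

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def numeric(self, marker_id: str) -> pd.Series:
        """0/1 genotype per strain with NaN for HET/missing calls."""
        col = self.calls[marker_id]
        out = col.astype(float)
        out[col.isin([GENO_HET, GENO_MISSING])] = np.nan
        return out

    def class_counts(self, marker_id: str) -> dict[int, int]:
        vc = self.calls[marker_id].value_counts()
        return {code: int(vc.get(code, 0))
                for code in (GENO_A, GENO_B, GENO_HET, GENO_MISSING)}

    def is_monomorphic(self, marker_id: str) -> bool:
        counts = self.class_counts(marker_id)
        return (counts[GENO_A] == 0) or (counts[GENO_B] == 0)

    def minor_class_count(self, marker_id: str) -> int:
        counts = self.class_counts(marker_id)
        return min(counts[GENO_A], counts[GENO_B])

    def nonredundant_markers(self) -> list[str]:
        """One representative per distinct genotype column (first wins)."""
        seen: dict[tuple, str] = {}
        for m in self.calls.columns:
            key = tuple(self.calls[m].tolist())
            seen.setdefault(key, m)
        return list(seen.values())


@dataclass
class GenomicMap:
    """Marker or trait-feature coordinates: id -> (chrom, pos), 1-based bp."""

    table: pd.DataFrame  # index id, columns chrom (str), pos (int)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise PanelError("map ids must be unique")
        if (self.table["pos"] < 1).any():
            bad = self.table.index[self.table["pos"] < 1][0]
            raise PanelError(f"position < 1 for id {bad!r}")

    def position(self, id_: str) -> tuple[str, int] | None:
        if id_ not in self.table.index:
            return None
        row = self.table.loc[id_]
        return str(row["chrom"]), int(row["pos"])

    def missing_ids(self, ids: list[str]) -> list[str]:
        return [i for i in ids if i not in self.table.index]


# ---------------------------------------------------------------------------
# readers / writers

def read_phenotype_panel(path, schema: dict | None = None) -> PhenotypePanel:
    """Load a phenotype TSV.

    ``schema`` may remap column names, e.g. ``{"strain": "line"}`` if the
    file calls its strain column ``line``.  Non-numeric trait cells other
    than the missing token are parse errors naming the offending cell.
    """
    schema = schema or {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    if "sample_id" not in df.columns:
        raise PanelError("required column 'sample_id' is missing")
    if "strain" not in df.columns:
        raise PanelError("required column 'strain' is missing")
    meta_cols = [c for c in ("sample_id", "strain", "sex", "condition")
                 if c in df.columns]
    trait_cols = [c for c in df.columns if c not in meta_cols]
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PanelError(f"duplicate sample id: {dup!r}")

    values = pd.DataFrame(index=df.index)
    for c in trait_cols:
        raw = df[c].replace({MISSING_TOKEN: np.nan, "": np.nan})
        try:
            values[c] = raw.astype(float)
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            raise PanelError(
                f"non-numeric value {bad.iloc[0]!r} in trait column {c!r}, "
                f"sample {bad.index[0]!r}"
            ) from None
    meta = df[[c for c in meta_cols if c != "sample_id"]].copy()
    panel = PhenotypePanel(meta, values)
    logger.info(
        "phenotype panel: %d samples, %d strains, %d traits",
        len(panel.samples), len(panel.strains), len(panel.trait_ids),
    )
    return panel


def write_phenotype_panel(panel: PhenotypePanel, path) -> None:
    out = pd.concat([panel.samples, panel.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_genotype_panel(path, coding: dict[str, int] | None = None) -> GenotypePanel:
    """Load a strain-by-marker genotype TSV.

    ``coding`` maps raw allele symbols to the four genotype codes; the
    default accepts A/B/H/NA and 0/1.  Unknown tokens are errors naming
    the marker and strain.  A panel whose markers are all monomorphic is
    accepted with a warning.
    """
    coding = coding or DEFAULT_GENO_TOKENS
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "strain" not in df.columns:
        raise PanelError("required column 'strain' is missing")
    df = df.set_index("strain")
    coded = pd.DataFrame(index=df.index, dtype=np.int8)
    for m in df.columns:
        col = df[m]
        unknown = ~col.isin(coding)
        if unknown.any():
            strain = col.index[unknown][0]
            raise PanelError(
                f"unknown genotype token {col[unknown].iloc[0]!r} at "
                f"marker {m!r}, strain {strain!r}"
            )
        coded[m] = col.map(coding).astype(np.int8)
    panel = GenotypePanel(coded)
    mono = [m for m in panel.marker_ids if panel.is_monomorphic(m)]
    if mono and len(mono) == len(panel.marker_ids):
        logger.warning("all %d markers are monomorphic", len(mono))
    elif mono:
        logger.info("%d monomorphic markers", len(mono))
    return panel


def write_genotype_panel(panel: GenotypePanel, path) -> None:
    rev = {GENO_A: "A", GENO_B: "B", GENO_HET: "H", GENO_MISSING: "NA"}
    out = panel.calls.replace(rev)
    out.index.name = "strain"
    out.to_csv(path, sep="\t")


def read_map(path) -> GenomicMap:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "pos": int})
    for col in ("id", "chrom", "pos"):
        if col not in df.columns:
            raise PanelError(f"required column {col!r} is missing")
    return GenomicMap(df.set_index("id"))


def read_bed_map(path) -> GenomicMap:
    """BED (0-based half-open) -> 1-based point map at the start coordinate."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "id"],
                     usecols=[0, 1, 2, 3],
                     dtype={"chrom": str, "start": int, "end": int, "id": str})
    out = pd.DataFrame({"chrom": df["chrom"], "pos": df["start"] + 1})
    out.index = df["id"]
    return GenomicMap(out)


def write_map(gmap: GenomicMap, path) -> None:
    out = gmap.table.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def empty_hit_table() -> pd.DataFrame:
    return pd.DataFrame({
        "scan_type": pd.Series(dtype=str),
        "stratum": pd.Series(dtype=str),
        "trait_id": pd.Series(dtype=str),
        "marker_id": pd.Series(dtype=str),
        "chrom": pd.Series(dtype=str),
        "pos": pd.Series(dtype="Int64"),
        "statistic": pd.Series(dtype=float),
        "nominal_p": pd.Series(dtype=float),
        "cis_flag": pd.Series(dtype=str),
    })


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write a hit table with deterministic column order and sorting."""
    out = hits.copy()
    for col in HIT_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[HIT_COLUMNS]
    unmapped = out["pos"].isna() & out["cis_flag"].notna()
    if unmapped.any():
        logger.warning("%d hits with unmapped markers written as cis_flag="
                       "unknown", int(unmapped.sum()))
        out.loc[unmapped, "cis_flag"] = "unknown"
    out = out.sort_values(
        ["scan_type", "trait_id", "chrom", "pos", "marker_id"],
        kind="mergesort", na_position="last",
    )
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "scan_type": str, "stratum": str, "trait_id": str, "marker_id": str,
        "chrom": str, "nominal_p": float, "statistic": float, "cis_flag": str,
    }, na_values=[MISSING_TOKEN], keep_default_na=False)
    df["pos"] = df["pos"].astype("Int64")
    if ((df["nominal_p"] < 0) | (df["nominal_p"] > 1)).any():
        raise PanelError("nominal_p outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# marker QC

@dataclass
class MarkerQCReport:
    dropped_missing: list[str] = field(default_factory=list)
    het_exclusions: dict[str, list[str]] = field(default_factory=dict)
    monomorphic: list[str] = field(default_factory=list)


def qc_markers(g: GenotypePanel, max_missing_frac: float = 0.5
               ) -> tuple[GenotypePanel, MarkerQCReport]:
    """Drop markers with too much missingness; flag HET strains per marker.

    A marker whose missing fraction exceeds ``max_missing_frac`` is
    discarded.  Heterozygous strains are not recoded — they are listed in
    the report so that scanners ignore them for that marker only.
    Idempotent: applying QC to its own output changes nothing.
    """
    if not (0.0 < max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in (0, 1]")
    n = len(g.strains)
    report = MarkerQCReport()
    keep = []
    for m in g.marker_ids:
        counts = g.class_counts(m)
        if counts[GENO_MISSING] / n > max_missing_frac:
            report.dropped_missing.append(m)
            continue
        keep.append(m)
        if counts[GENO_HET]:
            hets = g.calls.index[g.calls[m] == GENO_HET].tolist()
            report.het_exclusions[m] = hets
        if counts[GENO_A] == 0 or counts[GENO_B] == 0:
            report.monomorphic.append(m)
    if not keep:
        raise PanelError("marker QC removed every marker")
    return GenotypePanel(g.calls[keep].copy()), report
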