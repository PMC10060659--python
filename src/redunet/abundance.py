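"""Gene-abundance data layer.

Containers and operations shared by every analysis stage: RPKM computation
from mapped-read counts, the broad/specialized functional catalog, aggregation
of gene-level abundance to species / functional-category profiles, top-k
feature selection, and plain TSV readers/writers.

Conventions
-----------
* Abundance tables are samples x features (rows = samples).
* Treatments follow the 2x2 grazing x phosphorus factorial: ``G-P-``,
  ``G-P+``, ``G+P-``, ``G+P+`` (ASCII minus).
* "Broad" metabolic categories are carried by essentially all taxa;
  "specialized" (narrow) categories — here the nitrogen-cycle ones — are
  carried by a subset of taxa only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "GeneCatalog",
    "FunctionalCatalogConfig",
    "make_metadata",
    "validate_metadata",
    "compute_rpkm",
    "classify_functions",
    "aggregate",
    "top_features",
    "load_abundance_tsv",
    "load_catalog_tsv",
    "load_metadata_tsv",
    "write_table_tsv",
    "BROAD",
    "SPECIALIZED",
    "TREATMENTS",
]

BROAD = "broad"
SPECIALIZED = "specialized"
TREATMENTS = ("G-P-", "G-P+", "G+P-", "G+P+")

#: Stand-in default functional catalog: 15 broad KEGG-style level-2 metabolic
#: categories plus 4 specialized nitrogen-cycle categories.  The exact mapping
#: used upstream is configurable; this default only fixes the 15/4 split and
#: puts the N cycle on the specialized side (C and P cycles stay broad).
DEFAULT_BROAD_CATEGORIES = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of other amino acids",
    "Glycan biosynthesis and metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation and metabolism",
    "Metabolism of xenobiotics by cytochrome P450",
    "Phosphorus metabolism",
    "Sulfur metabolism",
    "Methane metabolism",
)
DEFAULT_SPECIALIZED_CATEGORIES = (
    "Nitrogen fixation",
    "Nitrification",
    "Denitrification",
    "Dissimilatory nitrate reduction",
)


@dataclass(frozen=True)
class FunctionalCatalogConfig:
    """Mapping from functional category to broad/specialized class."""

    category_class: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {c: k for c, k in self.category_class.items() if k not in (BROAD, SPECIALIZED)}
        if bad:
            raise ValueError(f"invalid func_class values: {bad}")

    @classmethod
    def default(cls) -> "FunctionalCatalogConfig":
        """The default 15-broad / 4-specialized catalog."""
        mapping = {c: BROAD for c in DEFAULT_BROAD_CATEGORIES}
        mapping.update({c: SPECIALIZED for c in DEFAULT_SPECIALIZED_CATEGORIES})
        return cls(mapping)

    def n_by_class(self) -> dict[str, int]:
        out = {BROAD: 0, SPECIALIZED: 0}
        for k in self.category_class.values():
            out[k] += 1
        return out


@dataclass
class GeneCatalog:
    """Per-gene annotation: taxonomy at species rank, KEGG category/pathway,
    broad|specialized class and gene length (bp, >= 100)."""

    frame: pd.DataFrame  # index = gene_id

    REQUIRED = ("species", "category", "pathway", "length_bp")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise ValueError(f"catalog missing column(s): {missing}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dups[:5]}")
        lengths = f["length_bp"]
        if (lengths < 100).any() or (lengths <= 0).any():
            bad = f.index[lengths < 100].tolist()
            raise ValueError(f"gene length_bp must be >= 100 bp; offending genes: {bad[:5]}")
        if "func_class" not in f.columns:
            f["func_class"] = pd.NA

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def subset(self, gene_ids: Iterable[str]) -> "GeneCatalog":
        return GeneCatalog(self.frame.loc[list(gene_ids)].copy())


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix (RPKM or relative units)."""

    data: pd.DataFrame  # index = sample_id, columns = feature ids
    feature_kind: Literal["gene", "species", "category", "species_within_category"] = "gene"
    unit: Literal["rpkm", "relative"] = "rpkm"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids in abundance table")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if self.unit == "relative":
            sums = self.data.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance rows must sum to 1 +/- 1e-9")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def relative(self) -> "AbundanceTable":
        """Row-normalize to relative abundance within the current feature set."""
        sums = self.data.sum(axis=1)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(f"cannot normalize all-zero sample(s): {list(zero.index)}")
        return AbundanceTable(self.data.div(sums, axis=0), self.feature_kind, "relative")

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), self.feature_kind, self.unit)


def make_metadata(
    treatments: Iterable[str] | None = None,
    *,
    replicates: int = 4,
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Construct the 2x2 factorial sample-metadata table.

    The treatment label is always the deterministic concatenation of the
    grazing and phosphorus levels; ``block`` is the replicate id.
    """
    treatments = list(treatments) if treatments is not None else list(TREATMENTS)
    rows = []
    for t in treatments:
        g, p = t[:2], t[2:]
        if g not in ("G-", "G+") or p not in ("P-", "P+"):
            raise ValueError(f"malformed treatment label: {t!r}")
        for b in range(1, replicates + 1):
            rows.append({"sample_id": f"{t}_r{b}", "grazing": g, "phosphorus": p,
                         "treatment": t, "block": b})
    meta = pd.DataFrame(rows).set_index("sample_id")
    if sample_ids is not None:
        ids = list(sample_ids)
        if len(ids) != len(meta):
            raise ValueError("sample_ids length does not match design size")
        meta.index = pd.Index(ids, name="sample_id")
    return meta


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    for col in ("grazing", "phosphorus", "treatment", "block"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column: {col}")
    derived = meta["grazing"].astype(str) + meta["phosphorus"].astype(str)
    if not (derived == meta["treatment"].astype(str)).all():
        bad = meta.index[derived != meta["treatment"]].tolist()
        raise ValueError(f"treatment label != grazing+phosphorus for samples: {bad}")
    return meta


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_rpkm(
    read_counts: pd.DataFrame,
    lengths: pd.Series,
    total_mapped: pd.Series,
) -> AbundanceTable:
    """Reads Per Kilobase per Million mapped reads.

    ``rpkm[s, g] = count[s, g] / (length[g] / 1e3) / (total_mapped[s] / 1e6)``

    Samples with zero mapped reads are rejected (dropped with a logged
    diagnostic); genes without a length are rejected likewise.
    """
    counts = read_counts.copy()
    if (counts.values < 0).any():
        raise ValueError("read counts must be non-negative")

    missing_len = counts.columns.difference(lengths.index)
    if len(missing_len):
        logger.warning("compute_rpkm: rejecting %d gene(s) without length: %s",
                       len(missing_len), list(missing_len[:5]))
        counts = counts.drop(columns=missing_len)
    lengths = lengths.loc[counts.columns].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")

    total = total_mapped.loc[counts.index].astype(float)
    dead = total.index[total <= 0]
    if len(dead):
        logger.warning("compute_rpkm: rejecting sample(s) with zero mapped reads: %s",
                       list(dead))
        counts = counts.drop(index=dead)
        total = total.drop(index=dead)

    vals = counts.values / (lengths.values[None, :] / 1e3) / (total.values[:, None] / 1e6)
    return AbundanceTable(pd.DataFrame(vals, index=counts.index, columns=counts.columns),
                          feature_kind="gene", unit="rpkm")


def classify_functions(catalog: GeneCatalog, config: FunctionalCatalogConfig) -> GeneCatalog:
    """Populate ``func_class`` from the category->class catalog config.

    Every category present in the gene catalog must be mapped; unmapped
    categories raise (no silent default).
    """
    cats = pd.Index(catalog.frame["category"].unique())
    unmapped = sorted(set(cats) - set(config.category_class))
    if unmapped:
        raise ValueError(f"categories missing from functional catalog config: {unmapped}")
    out = catalog.frame.copy()
    out["func_class"] = out["category"].map(config.category_class)
    return GeneCatalog(out)


def aggregate(
    table: AbundanceTable,
    catalog: GeneCatalog,
    by: Literal["species", "category", "species_within_category"],
    func_class: str | None = None,
) -> AbundanceTable:
    """Sum gene-level abundance into species, category, or (species, category)
    features.

    ``func_class`` restricts the genes to one broad/specialized class before
    summing (the "species within functional groups" device).  Genes lacking a
    species annotation are dropped — with a logged count — from species-level
    aggregation but kept for category-level aggregation.
    """
    if table.feature_kind != "gene":
        raise ValueError("aggregate expects a gene-level table")
    if by not in ("species", "category", "species_within_category"):
        raise ValueError(f"unknown aggregation key: {by!r}")

    genes = table.data.columns
    missing = genes.difference(catalog.gene_ids)
    if len(missing):
        raise ValueError(f"genes absent from catalog: {list(missing[:5])}")
    ann = catalog.frame.loc[genes]

    if func_class is not None:
        if ann["func_class"].isna().any():
            raise ValueError("func_class not populated; run classify_functions first")
        keep = ann.index[ann["func_class"] == func_class]
        if len(keep) == 0:
            raise ValueError(f"no genes in func_class {func_class!r}")
        ann = ann.loc[keep]

    if by in ("species", "species_within_category"):
        no_species = ann.index[ann["species"].isna() | (ann["species"] == "")]
        if len(no_species):
            logger.info("aggregate: dropping %d gene(s) without species annotation",
                        len(no_species))
            ann = ann.drop(index=no_species)

    if len(ann) == 0:
        raise ValueError("no genes left to aggregate (empty group set)")

    sub = table.data[ann.index]
    if by == "species":
        key = ann["species"]
    elif by == "category":
        key = ann["category"]
    else:
        key = ann["species"].astype(str) + "||" + ann["category"].astype(str)
    agg = sub.T.groupby(key.values).sum().T.sort_index(axis=1)
    kind = by if by != "species_within_category" else "species_within_category"
    return AbundanceTable(agg, feature_kind=kind, unit=table.unit)


def top_features(
    table: AbundanceTable,
    k: int,
    mode: Literal["mean", "per_sample_union"] = "mean",
) -> tuple[AbundanceTable, float]:
    """Keep the k most abundant features; return (table, coverage fraction).

    Default ranking is by mean relative abundance across samples (ties broken
    by lexicographic feature id) so every sample shares one feature set.  The
    alternative ``per_sample_union`` mode takes the union of each sample's
    top-k features (the per-sample selection style of gene-level network
    figures); its output may exceed k features.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k > table.data.shape[1]:
        raise ValueError(f"k={k} exceeds number of features ({table.data.shape[1]})")
    rel = table.data.div(table.data.sum(axis=1), axis=0)
    if mode == "mean":
        rank = pd.DataFrame({"score": -rel.mean(axis=0)})
        rank["fid"] = rank.index
        keep = rank.sort_values(["score", "fid"]).index[:k]
    elif mode == "per_sample_union":
        keep_set: set[str] = set()
        for _, row in rel.iterrows():
            r = pd.DataFrame({"score": -row})
            r["fid"] = r.index
            keep_set.update(r.sort_values(["score", "fid"]).index[:k])
        keep = pd.Index(sorted(keep_set))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    coverage = float(table.data[keep].values.sum() / table.data.values.sum())
    out = AbundanceTable(table.data[list(keep)].copy(), table.feature_kind, table.unit)
    return out, coverage


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, '.' decimal; gzip accepted transparently)
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, **kw)
    except ValueError as e:
        raise ValueError(f"failed to parse TSV {path}: {e}") from e


def load_abundance_tsv(path, feature_kind: str = "gene", orientation: str = "features_by_samples") -> AbundanceTable:
    """Load an abundance TSV.

    ``features_by_samples`` (the common metagenome layout, rows = genes) is
    transposed into the internal samples x features orientation.
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row id(s) in {path}: {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from e
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return AbundanceTable(df, feature_kind=feature_kind)


def load_catalog_tsv(path) -> GeneCatalog:
    df = _read_tsv(path, dtype={"length_bp": int})
    missing = [c for c in GeneCatalog.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing column(s): {missing}")
    return GeneCatalog(df)


def load_metadata_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dups[:5]}")
    return validate_metadata(df)


def write_table_tsv(obj, path) -> None:
    """Write an AbundanceTable / DataFrame to TSV at full float precision."""
    df = obj.data if isinstance(obj, AbundanceTable) else obj
    df.to_csv(path, sep="\t")
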