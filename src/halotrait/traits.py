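"""Per-taxon functional-trait normalization and summaries.

The central quantity is NACG: the abundance of a category's genes within a
taxon divided by that taxon's abundance, i.e. gene content per unit of
taxon abundance. Pooled scope sums both numerator and denominator over
samples before dividing; per-sample scope forms the ratio within each
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, FunctionCatalog, GeneAbundanceTensor

logger = logging.getLogger("halotrait")

SPECIAL_CATEGORIES = ("overall_KO", "salt_resistance", "c_fixation",
                      "cazyme", "total_c_acquisition")


@dataclass(frozen=True)
class TraitProfile:
    taxon_id: str
    category: str
    nacg: float  # NaN when the taxon has zero abundance in scope
    scope: str   # "pooled" or "per_sample:<sample_id>"


@dataclass(frozen=True)
class InvestmentFraction:
    taxon_id: str
    fraction: float  # in [0, 1]; NaN when overall gene abundance is zero


def resolve_gene_set(catalog: FunctionCatalog, category: str) -> frozenset[str]:
    """Map a category name to its member gene set.

    Accepts the special categories, a mechanism_id, or a pathway label at
    BRITE level 1 or 3.
    """
    if category == "overall_KO":
        return catalog.all_genes
    if category in ("salt_resistance", "c_fixation", "cazyme"):
        return catalog.category_genes(category)
    if category == "total_c_acquisition":
        return catalog.category_genes("c_fixation") | catalog.category_genes("cazyme")
    for m in catalog.mechanisms:
        if m.mechanism_id == category:
            return m.genes
    for level in (1, 3):
        genes = catalog.genes_for_pathway(category, level)
        if genes:
            return genes
    raise ValueError(f"category not resolvable against catalog: {category}")


def _taxon_gene_table(tensor: GeneAbundanceTensor, taxon: str) -> pd.DataFrame:
    sub = tensor.records
    return sub[sub["taxon_id"] == taxon]


def nacg(
    tensor: GeneAbundanceTensor,
    matrix: AbundanceMatrix,
    catalog: FunctionCatalog,
    taxon: str,
    category: str,
    scope: str = "pooled",
) -> TraitProfile | list[TraitProfile]:
    """Normalized abundance of a gene category for one taxon.

    Pooled: (sum over samples & member genes of gene abundance) /
    (sum over samples of taxon abundance), with zero-abundance samples
    excluded from both sums. Per-sample: the same ratio per sample (NaN
    where the taxon is absent); returns one profile per sample.
    """
    genes = resolve_gene_set(catalog, category)
    at = matrix.values.loc[taxon]
    sub = _taxon_gene_table(tensor, taxon)
    sub = sub[sub["gene_id"].isin(genes)]
    per_sample_gene = sub.groupby("sample_id")["abundance"].sum()

    if scope == "pooled":
        keep = at[at > 0]
        if keep.empty:
            logger.warning("taxon %s has zero abundance everywhere; NACG missing", taxon)
            return TraitProfile(taxon, category, np.nan, "pooled")
        num = float(per_sample_gene.reindex(keep.index, fill_value=0.0).sum())
        return TraitProfile(taxon, category, num / float(keep.sum()), "pooled")
    if scope == "per_sample":
        out = []
        for sid in matrix.samples:
            denom = float(at[sid])
            if denom <= 0:
                val = np.nan
            else:
                val = float(per_sample_gene.get(sid, 0.0)) / denom
            out.append(TraitProfile(taxon, category, val, f"per_sample:{sid}"))
        return out
    raise ValueError(f"unknown scope: {scope}")


def nacg_table(
    tensor: GeneAbundanceTensor,
    matrix: AbundanceMatrix,
    catalog: FunctionCatalog,
    categories: list[str],
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorized pooled NACG for many taxa x categories (rows: taxa)."""
    taxa = list(taxa) if taxa is not None else matrix.taxa
    rec = tensor.records
    rec = rec[rec["taxon_id"].isin(taxa)]
    # exclude (taxon, sample) cells where the taxon is absent, matching nacg()
    at = matrix.values.loc[taxa]
    present = at.stack()
    present = present[present > 0]
    key = pd.MultiIndex.from_frame(rec[["taxon_id", "sample_id"]])
    rec = rec[key.isin(present.index)]
    at_total = at.sum(axis=1)
    gene_by_taxon = rec.groupby(["taxon_id", "gene_id"])["abundance"].sum()
    out = pd.DataFrame(index=pd.Index(taxa, name="taxon_id"))
    for category in categories:
        genes = resolve_gene_set(catalog, category)
        mask = gene_by_taxon.index.get_level_values("gene_id").isin(genes)
        num = gene_by_taxon[mask].groupby("taxon_id").sum()
        num = num.reindex(taxa, fill_value=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[category] = np.where(at_total > 0, num / at_total, np.nan)
    return out


def pathway_abundance(
    tensor: GeneAbundanceTensor,
    matrix: AbundanceMatrix,
    catalog: FunctionCatalog,
    taxon: str,
    level: int,
) -> list[TraitProfile]:
    """Pooled NACG per pathway label at BRITE level 1 or 3.

    A gene mapping to several pathways contributes to each of them
    (documented double-counting); genes absent from the catalog are
    ignored with a logged count.
    """
    if level not in (1, 3):
        raise ValueError("level must be 1 or 3")
    labels = catalog.pathway_labels(level)
    sub = _taxon_gene_table(tensor, taxon)
    uncat = set(sub["gene_id"]) - set(catalog.pathway_map)
    if uncat:
        logger.info("taxon %s: ignoring %d uncatalogued gene(s)", taxon, len(uncat))
    out = []
    for label in labels:
        out.append(
            TraitProfile(
                taxon, label,
                _pooled_value(tensor, matrix, catalog, taxon,
                              catalog.genes_for_pathway(label, level)),
                "pooled",
            )
        )
    return out


def _pooled_value(tensor, matrix, catalog, taxon, genes: frozenset[str]) -> float:
    at = matrix.values.loc[taxon]
    keep = at[at > 0]
    if keep.empty:
        return np.nan
    sub = _taxon_gene_table(tensor, taxon)
    sub = sub[sub["gene_id"].isin(genes) & sub["sample_id"].isin(keep.index)]
    return float(sub["abundance"].sum()) / float(keep.sum())


def pathway_nacg_matrix(
    tensor: GeneAbundanceTensor,
    matrix: AbundanceMatrix,
    catalog: FunctionCatalog,
    taxa: list[str],
    level: int = 3,
) -> pd.DataFrame:
    """Taxa x pathway-label pooled-NACG matrix (batch form)."""
    labels = catalog.pathway_labels(level)
    return nacg_table(tensor, matrix, catalog, labels, taxa).rename_axis(
        columns=f"pathway_level{level}"
    )


def per_sample_pathway_matrix(
    tensor: GeneAbundanceTensor,
    matrix: AbundanceMatrix,
    catalog: FunctionCatalog,
    taxa: list[str],
    level: int = 3,
) -> pd.DataFrame:
    """Samples x pathway matrix of community-summed gene abundance per unit
    summed taxon abundance over a taxon set (for along-gradient analyses)."""
    idx = {1: 0, 2: 1, 3: 2}[level]
    rec = tensor.records
    rec = rec[rec["taxon_id"].isin(taxa)].copy()
    rec["label"] = rec["gene_id"].map(
        lambda g: catalog.pathway_map.get(g, (None, None, None))[idx]
    )
    rec = rec[rec["label"].notna()]
    num = rec.pivot_table(
        index="sample_id", columns="label", values="abundance",
        aggfunc="sum", fill_value=0.0,
    )
    denom = matrix.values.loc[taxa].sum(axis=0)
    num = num.reindex(index=matrix.samples, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num.div(denom, axis=0)
    return out.replace([np.inf, -np.inf], np.nan)


def c_acquisition_fraction(
    tensor: GeneAbundanceTensor,
    catalog: FunctionCatalog,
    taxon: str,
) -> InvestmentFraction:
    """Share of a taxon's catalogued gene abundance devoted to C acquisition
    (C-fixation + CAZymes), pooled over samples. Taxon abundance cancels."""
    sub = _taxon_gene_table(tensor, taxon)
    catalogued = sub[sub["gene_id"].isin(catalog.all_genes)]
    total = float(catalogued["abundance"].sum())
    if total <= 0:
        logger.warning("taxon %s has zero catalogued gene abundance", taxon)
        return InvestmentFraction(taxon, np.nan)
    acq = catalog.category_genes("c_fixation") | catalog.category_genes("cazyme")
    num = float(catalogued[catalogued["gene_id"].isin(acq)]["abundance"].sum())
    return InvestmentFraction(taxon, num / total)


def ko_alpha_diversity(tensor: GeneAbundanceTensor, sample: str) -> dict:
    """Richness and Shannon index of genes within one sample (abundance
    summed over taxa)."""
    sub = tensor.records[tensor.records["sample_id"] == sample]
    totals = sub.groupby("gene_id")["abundance"].sum()
    totals = totals[totals > 0]
    richness = int(len(totals))
    if richness == 0:
        return {"richness": 0, "shannon": np.nan}
    p = totals.to_numpy(dtype=float)
    p = p / p.sum()
    shannon = float(-(p * np.log(p)).sum())
    return {"richness": richness, "shannon": shannon}


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (ddof=1); constant rows map to all zeros."""
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
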