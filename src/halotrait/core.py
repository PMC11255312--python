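"""Domain types, dataset I/O and validation shared by every pipeline stage.

The on-disk dataset is a directory of plain-text files::

    samples.tsv         sample_id, ec, <covariate...>
    taxa.tsv            taxon_id, domain, phylum, genus, genome_size_mb
    abundance.tsv       taxon_id + one column per sample
    gene_abundance.tsv  taxon_id, gene_id, sample_id, abundance  (long / tidy)
    catalog.json        pathway map (BRITE levels 1-3) + mechanism definitions
    references.json     salt-tolerant genus patterns + reference genome sizes
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("halotrait")

DOMAINS = ("bacteria", "archaea")
CATEGORIES = ("salt_resistance", "c_fixation", "cazyme")
#: required mechanism counts per category in the default catalog
CATEGORY_SIZES = {"salt_resistance": 3, "c_fixation": 7, "cazyme": 6}


class DatasetError(ValueError):
    """Base class for dataset construction/loading problems."""


class FormatError(DatasetError):
    """A file is missing a required column or has a malformed value."""


class ReferentialIntegrityError(DatasetError):
    """An identifier in one table does not resolve against another."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSet:
    """Samples with their electrical conductivity (dS/m) and covariates."""

    sample_ids: tuple[str, ...]
    ec: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        ids = list(self.sample_ids)
        if len(set(ids)) != len(ids):
            raise DatasetError("sample ids must be unique")
        ec = np.asarray(self.ec, dtype=float)
        if ec.shape != (len(ids),):
            raise DatasetError("ec must have one value per sample")
        # NaN marks a missing EC (reported by validate_dataset); inf and
        # negative values are outright invalid
        if np.any(np.isinf(ec)) or np.any(ec < 0):
            raise DatasetError("ec values must be finite and >= 0")
        object.__setattr__(self, "ec", ec)
        cov = self.covariates
        if len(cov) and (len(cov) != len(ids) or list(cov.index) != ids):
            raise DatasetError("covariates must be indexed by the sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class TaxonTable:
    """Per-taxon metadata: domain, phylum, genus, genome size (Mb)."""

    frame: pd.DataFrame  # index: taxon_id

    def __post_init__(self):
        df = self.frame
        required = {"domain", "phylum", "genus", "genome_size_mb"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"taxa table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate taxon ids: {dups}")
        bad = set(df["domain"]) - set(DOMAINS)
        if bad:
            raise FormatError(f"unknown domains: {sorted(bad)}")
        gs = df["genome_size_mb"]
        if (gs.dropna() <= 0).any():
            raise DatasetError("genome sizes must be > 0 when present")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.frame.index)

    def domain_of(self, taxon_id: str) -> str:
        return self.frame.at[taxon_id, "domain"]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Taxon x sample absolute abundances (rows: taxa, columns: samples)."""

    values: pd.DataFrame

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise DatasetError("abundance matrix ids must be unique")
        arr = v.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise DatasetError("abundances must be finite and >= 0")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def total_abundance(self) -> pd.Series:
        return self.values.sum(axis=1)

    def row(self, taxon_id: str) -> np.ndarray:
        return self.values.loc[taxon_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneAbundanceTensor:
    """Long-format (taxon, gene, sample, abundance) records."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        required = {"taxon_id", "gene_id", "sample_id", "abundance"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(
                f"gene abundance table missing columns: {sorted(missing)}"
            )
        ab = df["abundance"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ab)) or np.any(ab < 0):
            raise DatasetError("gene abundances must be finite and >= 0")
        key = df[["taxon_id", "gene_id", "sample_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise DatasetError(f"duplicate (taxon, gene, sample) triple: {dup}")

    def check_references(self, taxa: TaxonTable, samples: SampleSet) -> None:
        bad_taxa = sorted(set(self.records["taxon_id"]) - set(taxa.taxon_ids))
        if bad_taxa:
            raise ReferentialIntegrityError(
                f"gene abundance references unknown taxa: {bad_taxa}"
            )
        bad_samples = sorted(
            set(self.records["sample_id"]) - set(samples.sample_ids)
        )
        if bad_samples:
            raise ReferentialIntegrityError(
                f"gene abundance references unknown samples: {bad_samples}"
            )

    def for_taxon(self, taxon_id: str) -> pd.DataFrame:
        return self.records[self.records["taxon_id"] == taxon_id]


@dataclass(frozen=True)
class Mechanism:
    mechanism_id: str
    category: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DatasetError(f"unknown mechanism category: {self.category}")
        if not self.genes:
            raise DatasetError(
                f"mechanism {self.mechanism_id} has an empty gene set"
            )


@dataclass(frozen=True)
class FunctionCatalog:
    """Gene -> pathway (BRITE levels 1-3) map plus mechanism membership."""

    pathway_map: Mapping[str, tuple[str, str, str]]
    mechanisms: tuple[Mechanism, ...]

    def mechanisms_in(self, category: str) -> list[Mechanism]:
        if category not in CATEGORIES:
            raise DatasetError(f"unknown category: {category}")
        return [m for m in self.mechanisms if m.category == category]

    def category_genes(self, category: str) -> frozenset[str]:
        return frozenset().union(
            *(m.genes for m in self.mechanisms_in(category))
        )

    @property
    def all_genes(self) -> frozenset[str]:
        genes = set(self.pathway_map)
        for m in self.mechanisms:
            genes |= m.genes
        return frozenset(genes)

    def pathway_labels(self, level: int) -> list[str]:
        idx = {1: 0, 2: 1, 3: 2}[level]
        seen: dict[str, None] = {}
        for labels in self.pathway_map.values():
            seen.setdefault(labels[idx], None)
        return list(seen)

    def genes_for_pathway(self, label: str, level: int) -> frozenset[str]:
        idx = {1: 0, 2: 1, 3: 2}[level]
        return frozenset(
            g for g, labels in self.pathway_map.items() if labels[idx] == label
        )

    def validate_default_shape(self) -> None:
        """Check the 3 / 7 / 6 mechanism-count contract of the default catalog."""
        for category, k in CATEGORY_SIZES.items():
            n = len(self.mechanisms_in(category))
            if n != k:
                raise DatasetError(
                    f"default catalog must define {k} {category} mechanisms, found {n}"
                )


@dataclass(frozen=True)
class ReferenceSets:
    """Published salt-tolerant genus patterns and reference genome sizes."""

    salt_tolerant_genera: tuple[str, ...]
    reference_genomes: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        for phylum, sizes in self.reference_genomes.items():
            if any(s <= 0 for s in sizes):
                raise DatasetError(f"non-positive genome size for {phylum}")

    def genus_matches(self, genus: str | None) -> bool:
        if genus is None or (isinstance(genus, float) and np.isnan(genus)):
            return False
        if not self.salt_tolerant_genera:
            raise DatasetError("empty salt-tolerant genus reference list")
        return any(str(genus).startswith(p) for p in self.salt_tolerant_genera)


class Dataset(NamedTuple):
    samples: SampleSet
    taxa: TaxonTable
    abundance: AbundanceMatrix
    genes: GeneAbundanceTensor
    catalog: FunctionCatalog
    references: ReferenceSets


# ---------------------------------------------------------------------------
# default catalog (placeholder KO sets; users substitute their own)
# ---------------------------------------------------------------------------

_SALT_MECHS = {
    "na_extrusion": ["K10011", "K10012", "K10013"],
    "k_uptake": ["K10021", "K10022", "K10023"],
    "osmolyte": ["K10031", "K10032", "K10033"],
}
_CFIX_MECHS = {
    "calvin_cycle": ["K11011", "K11012", "K11013"],
    "arnon_buchanan": ["K11021", "K11022", "K11023"],
    "hp_bicycle": ["K11031", "K11032", "K11033"],
    "hp_hb_cycle": ["K11041", "K11042", "K11043"],
    "dc_hb_cycle": ["K11051", "K11052", "K11053"],
    "wood_ljungdahl": ["K11061", "K11062", "K11063"],
    "incomplete_rtca": ["K11071", "K11072", "K11073"],
}
_CAZY_MECHS = {
    "AA": ["AA1", "AA2"],
    "CE": ["CE1", "CE4"],
    "CBM": ["CBM2", "CBM6"],
    "GH": ["GH5", "GH13"],
    "PL": ["PL1", "PL9"],
    "GT": ["GT2", "GT4"],
}

_LEVEL1 = {
    "metabolism": "Metabolism",
    "genetic": "Genetic Information Processing",
    "environmental": "Environmental Information Processing",
    "cellular": "Cellular Processes",
}


def default_catalog(n_housekeeping_pathways: int = 10,
                    genes_per_pathway: int = 4) -> FunctionCatalog:
    """Build the shipped placeholder catalog: 3/7/6 mechanisms plus a block
    of 'housekeeping' KOs spread over generic level-3 pathways."""
    pathway_map: dict[str, tuple[str, str, str]] = {}
    level1_cycle = [
        _LEVEL1["metabolism"], _LEVEL1["genetic"],
        _LEVEL1["environmental"], _LEVEL1["cellular"],
    ]
    ko = 20001
    for p in range(n_housekeeping_pathways):
        l1 = level1_cycle[p % len(level1_cycle)]
        l2 = f"{l1} subsystems"
        l3 = f"housekeeping pathway {p + 1:02d}"
        for _ in range(genes_per_pathway):
            pathway_map[f"K{ko:05d}"] = (l1, l2, l3)
            ko += 1
    for mech, genes in _SALT_MECHS.items():
        for g in genes:
            pathway_map[g] = (
                _LEVEL1["environmental"], "Membrane transport",
                f"salt resistance: {mech}",
            )
    for mech, genes in _CFIX_MECHS.items():
        for g in genes:
            pathway_map[g] = (
                _LEVEL1["metabolism"], "Energy metabolism",
                f"carbon fixation: {mech}",
            )
    for cls, fams in _CAZY_MECHS.items():
        for fam in fams:
            pathway_map[fam] = (
                _LEVEL1["metabolism"], "Glycan metabolism",
                f"CAZyme class {cls}",
            )
    mechanisms = tuple(
        [Mechanism(m, "salt_resistance", frozenset(g)) for m, g in _SALT_MECHS.items()]
        + [Mechanism(m, "c_fixation", frozenset(g)) for m, g in _CFIX_MECHS.items()]
        + [Mechanism(m, "cazyme", frozenset(g)) for m, g in _CAZY_MECHS.items()]
    )
    catalog = FunctionCatalog(pathway_map=pathway_map, mechanisms=mechanisms)
    catalog.validate_default_shape()
    return catalog


def default_references() -> ReferenceSets:
    return ReferenceSets(
        salt_tolerant_genera=(
            "Halo", "Salini", "Thio", "Ocean", "Marin",
            "Aquisalimonas", "Aliifodinibius", "Roseovarius",
            "Rubrivirga", "Vibrio",
        ),
        reference_genomes={},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FILES = {
    "samples": "samples.tsv",
    "taxa": "taxa.tsv",
    "abundance": "abundance.tsv",
    "genes": "gene_abundance.tsv",
    "catalog": "catalog.json",
    "references": "references.json",
}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{fname}: missing required column(s) {missing}")


def catalog_to_dict(catalog: FunctionCatalog) -> dict:
    return {
        "pathway_map": {
            g: list(labels) for g, labels in sorted(catalog.pathway_map.items())
        },
        "mechanisms": [
            {
                "mechanism_id": m.mechanism_id,
                "category": m.category,
                "genes": sorted(m.genes),
            }
            for m in catalog.mechanisms
        ],
    }


def catalog_from_dict(doc: dict) -> FunctionCatalog:
    return FunctionCatalog(
        pathway_map={g: tuple(v) for g, v in doc["pathway_map"].items()},
        mechanisms=tuple(
            Mechanism(m["mechanism_id"], m["category"], frozenset(m["genes"]))
            for m in doc["mechanisms"]
        ),
    )


def references_to_dict(refs: ReferenceSets) -> dict:
    return {
        "salt_tolerant_genera": list(refs.salt_tolerant_genera),
        "reference_genomes": {
            p: list(v) for p, v in sorted(refs.reference_genomes.items())
        },
    }


def references_from_dict(doc: dict) -> ReferenceSets:
    return ReferenceSets(
        salt_tolerant_genera=tuple(doc["salt_tolerant_genera"]),
        reference_genomes={
            p: tuple(v) for p, v in doc["reference_genomes"].items()
        },
    )


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    samples, taxa, abundance, genes, catalog, refs = dataset

    sdf = pd.DataFrame({"sample_id": samples.sample_ids, "ec": samples.ec})
    for c in samples.covariates.columns:
        sdf[c] = samples.covariates[c].to_numpy()
    sdf.to_csv(out / _FILES["samples"], sep="\t", index=False)

    taxa.frame.rename_axis("taxon_id").reset_index().to_csv(
        out / _FILES["taxa"], sep="\t", index=False
    )
    abundance.values.rename_axis("taxon_id").reset_index().to_csv(
        out / _FILES["abundance"], sep="\t", index=False
    )
    genes.records.to_csv(out / _FILES["genes"], sep="\t", index=False)
    (out / _FILES["catalog"]).write_text(
        json.dumps(catalog_to_dict(catalog), indent=1, sort_keys=True)
    )
    (out / _FILES["references"]).write_text(
        json.dumps(references_to_dict(refs), indent=1, sort_keys=True)
    )


def load_dataset(indir: str | Path) -> Dataset:
    """Load and cross-validate the six dataset files from a directory."""
    d = Path(indir)
    for key, fname in _FILES.items():
        if not (d / fname).exists():
            raise FormatError(f"missing dataset file: {d / fname}")

    sdf = pd.read_csv(d / _FILES["samples"], sep="\t", dtype={"sample_id": str})
    _require_columns(sdf, ["sample_id", "ec"], _FILES["samples"])
    cov_cols = [c for c in sdf.columns if c not in ("sample_id", "ec")]
    samples = SampleSet(
        sample_ids=tuple(sdf["sample_id"]),
        ec=sdf["ec"].to_numpy(dtype=float),
        covariates=sdf.set_index("sample_id")[cov_cols]
        if cov_cols else pd.DataFrame(),
    )

    tdf = pd.read_csv(
        d / _FILES["taxa"], sep="\t",
        dtype={"taxon_id": str, "genus": "string", "phylum": str},
    )
    _require_columns(
        tdf, ["taxon_id", "domain", "phylum", "genus", "genome_size_mb"],
        _FILES["taxa"],
    )
    taxa = TaxonTable(tdf.set_index("taxon_id"))

    adf = pd.read_csv(d / _FILES["abundance"], sep="\t", dtype={"taxon_id": str})
    _require_columns(adf, ["taxon_id"], _FILES["abundance"])
    abundance = AbundanceMatrix(adf.set_index("taxon_id"))

    gdf = pd.read_csv(
        d / _FILES["genes"], sep="\t",
        dtype={"taxon_id": str, "gene_id": str, "sample_id": str},
    )
    genes = GeneAbundanceTensor(gdf)

    catalog = catalog_from_dict(json.loads((d / _FILES["catalog"]).read_text()))
    refs = references_from_dict(
        json.loads((d / _FILES["references"]).read_text())
    )

    # referential integrity
    bad = sorted(set(abundance.taxa) - set(taxa.taxon_ids))
    if bad:
        raise ReferentialIntegrityError(
            f"abundance matrix references unknown taxa: {bad}"
        )
    bad = sorted(set(abundance.samples) - set(samples.sample_ids))
    if bad:
        raise ReferentialIntegrityError(
            f"abundance matrix references unknown samples: {bad}"
        )
    genes.check_references(taxa, samples)

    dataset = Dataset(samples, taxa, abundance, genes, catalog, refs)
    logger.info(
        "loaded dataset: %d samples, %d taxa, %d gene records, %d catalogued genes",
        samples.n, len(taxa.taxon_ids), len(genes.records), len(catalog.all_genes),
    )
    return dataset


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    counts: dict[str, int]
    taxa_missing_genome_size: list[str]
    uncatalogued_genes: list[str]
    samples_missing_ec: list[str]

    @property
    def issues(self) -> list[str]:
        out = []
        out += [f"taxon {t} lacks genome size"
                for t in self.taxa_missing_genome_size]
        out += [f"gene {g} absent from catalog"
                for g in self.uncatalogued_genes]
        out += [f"sample {s} lacks EC" for s in self.samples_missing_ec]
        return out

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "taxa_missing_genome_size": self.taxa_missing_genome_size,
            "uncatalogued_genes": self.uncatalogued_genes,
            "samples_missing_ec": self.samples_missing_ec,
        }


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report (never mutate) data-completeness issues."""
    samples, taxa, abundance, genes, catalog, _ = dataset
    missing_gs = sorted(
        taxa.frame.index[taxa.frame["genome_size_mb"].isna()].tolist()
    )
    uncat = sorted(set(genes.records["gene_id"]) - set(catalog.all_genes))
    missing_ec = [
        s for s, e in zip(samples.sample_ids, samples.ec) if not np.isfinite(e)
    ]
    report = ValidationReport(
        counts={
            "samples": samples.n,
            "taxa": len(taxa.taxon_ids),
            "gene_records": len(genes.records),
            "catalog_genes": len(catalog.all_genes),
        },
        taxa_missing_genome_size=missing_gs,
        uncatalogued_genes=uncat,
        samples_missing_ec=missing_ec,
    )
    for issue in report.issues:
        logger.warning("validation: %s", issue)
    return report
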