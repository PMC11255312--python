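"""Synthetic gradient datasets with planted ground truth.

Every downstream stage is exercised against data from this module: planted
response classes (linear / thresholded / null), taxon-coupled gene copy
numbers, planted mechanism presence sets, and clade-structured genome sizes.
With all noise switched off the generator is exact, so recovery checks can
assert equality rather than tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AbundanceMatrix,
    Dataset,
    DatasetError,
    FunctionCatalog,
    GeneAbundanceTensor,
    ReferenceSets,
    SampleSet,
    TaxonTable,
    default_catalog,
)

RESPONSE_CLASSES = (
    "linear_pos", "linear_neg", "threshold_pos", "threshold_neg", "null",
)

_POS_CLASSES = {"linear_pos", "threshold_pos"}
_NEG_CLASSES = {"linear_neg", "threshold_neg"}


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _default_counts() -> dict[str, dict[str, int]]:
    # bacteria respond linearly, archaea with a threshold; plus null taxa
    return {
        "bacteria": {
            "linear_pos": 20, "linear_neg": 20,
            "threshold_pos": 0, "threshold_neg": 0, "null": 40,
        },
        "archaea": {
            "linear_pos": 0, "linear_neg": 0,
            "threshold_pos": 25, "threshold_neg": 25, "null": 10,
        },
    }


def _default_genome_log_params() -> dict[str, tuple[float, float]]:
    # log-mean/log-sd (natural log of Mb); medians mirror the direction of
    # the bacterial-streamlining / archaeal-enlargement contrast
    return {
        "pos-bac": (np.log(2.8), 0.20),
        "neg-bac": (np.log(3.9), 0.20),
        "pos-arch": (np.log(3.74), 0.15),
        "neg-arch": (np.log(1.60), 0.15),
        "null-bac": (np.log(3.2), 0.25),
        "null-arch": (np.log(2.2), 0.25),
    }


def _default_completeness() -> dict[str, dict[str, float]]:
    # probability a taxon in a group carries ALL mechanisms of a category
    return {
        "pos-arch": {"salt_resistance": 0.76, "c_fixation": 0.68, "cazyme": 0.70},
        "neg-arch": {"salt_resistance": 0.20, "c_fixation": 0.22, "cazyme": 0.12},
        "pos-bac": {"salt_resistance": 0.30, "c_fixation": 0.345, "cazyme": 0.43},
        "neg-bac": {"salt_resistance": 0.60, "c_fixation": 0.815, "cazyme": 0.695},
        "null-bac": {"salt_resistance": 0.40, "c_fixation": 0.50, "cazyme": 0.50},
        "null-arch": {"salt_resistance": 0.40, "c_fixation": 0.50, "cazyme": 0.50},
    }


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults emulate a 37-sample EC gradient."""

    n_samples: int = 37
    ec_range: tuple[float, float] = (0.14, 13.65)
    ec_values: Sequence[float] | None = None  # overrides ec_range when given
    class_counts: dict[str, dict[str, int]] = field(default_factory=_default_counts)
    n_low_abundance: int = 5  # extra null bacteria below the <100 total filter
    slope_range: tuple[float, float] = (10.0, 18.0)
    base_abundance: tuple[float, float] = (15.0, 35.0)
    breakpoints: dict[str, float] = field(
        default_factory=lambda: {"threshold_pos": 4.2, "threshold_neg": 3.4}
    )
    nb_dispersion: float = 15.0  # NB size parameter k; 0 disables count noise
    gene_noise_cv: float = 0.2  # lognormal CV on gene layer; 0 disables
    copy_range: tuple[int, int] = (1, 4)
    gene_presence_prob: float = 0.7  # per housekeeping KO, per taxon
    genome_log_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_genome_log_params
    )
    completeness_prob: dict[str, dict[str, float]] = field(
        default_factory=_default_completeness
    )
    ref_genus_fraction: float = 0.62  # of genus-identified planted-pos taxa
    genus_missing_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.ec_range
        if not lo < hi:
            raise ConfigError("ec_range min must be < max")
        if self.nb_dispersion < 0 or self.gene_noise_cv < 0:
            raise ConfigError("noise parameters must be >= 0")
        for dom, counts in self.class_counts.items():
            for cls, n in counts.items():
                if cls not in RESPONSE_CLASSES:
                    raise ConfigError(f"unknown response class: {cls}")
                if n < 0:
                    raise ConfigError(f"negative count for {dom}/{cls}")
        for grp, probs in self.completeness_prob.items():
            for cat, p in probs.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"completeness prob out of [0,1]: {grp}/{cat}")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ConfigError(f"unknown synth config keys: {sorted(bad)}")
        kwargs = dict(doc)
        for key in ("ec_range", "slope_range", "base_abundance", "copy_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted parameters, one record per generated taxon."""

    taxa: pd.DataFrame         # taxon_id, domain, response_class, intercept,
                               # slope, breakpoint, genome_group, genome_size_mb
    copy_numbers: pd.DataFrame  # taxon_id, gene_id, copy_number (>0 rows only)
    mechanisms: pd.DataFrame    # taxon_id, category, mechanism_id (present)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.taxa.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        self.copy_numbers.to_csv(
            out / "ground_truth_copy_numbers.tsv", sep="\t", index=False
        )
        self.mechanisms.to_csv(
            out / "ground_truth_mechanisms.tsv", sep="\t", index=False
        )

    def copies_for(self, taxon_id: str) -> dict[str, int]:
        sub = self.copy_numbers[self.copy_numbers["taxon_id"] == taxon_id]
        return dict(zip(sub["gene_id"], sub["copy_number"]))

    def present_mechanisms(self, taxon_id: str, category: str) -> frozenset[str]:
        sub = self.mechanisms
        sub = sub[(sub["taxon_id"] == taxon_id) & (sub["category"] == category)]
        return frozenset(sub["mechanism_id"])


def class_mean(ec: float, response_class: str, params: Mapping[str, float]) -> float:
    """Planted mean abundance at a given EC, floored at zero.

    linear classes: a + b*ec; threshold classes: a below psi, then
    a + b*(ec - psi); null: constant a.
    """
    a = params["intercept"]
    if response_class == "null":
        mean = a
    elif response_class in ("linear_pos", "linear_neg"):
        mean = a + params["slope"] * ec
    elif response_class in ("threshold_pos", "threshold_neg"):
        psi = params["breakpoint"]
        mean = a if ec <= psi else a + params["slope"] * (ec - psi)
    else:
        raise ConfigError(f"unknown response class: {response_class}")
    return max(mean, 0.0)


def _group_label(response_class: str, domain: str) -> str:
    tag = "bac" if domain == "bacteria" else "arch"
    if response_class in _POS_CLASSES:
        return f"pos-{tag}"
    if response_class in _NEG_CLASSES:
        return f"neg-{tag}"
    return f"null-{tag}"


def _draw_class_params(
    cls: str, config: SynthConfig, rng: np.random.Generator
) -> dict[str, float]:
    lo, hi = config.base_abundance
    a = rng.uniform(lo, hi)
    s_lo, s_hi = config.slope_range
    b = rng.uniform(s_lo, s_hi)
    params = {"intercept": a, "slope": 0.0, "breakpoint": np.nan}
    if cls == "null":
        return params
    if cls in _NEG_CLASSES:
        b = -b
    params["slope"] = b
    if cls in ("threshold_pos", "threshold_neg"):
        params["breakpoint"] = config.breakpoints[cls]
        if cls == "threshold_neg":
            # keep the post-break mean positive across the gradient
            span = config.ec_range[1] - params["breakpoint"]
            max_drop = abs(b) * span
            if max_drop >= a:
                params["slope"] = -0.8 * a / span
    elif cls == "linear_neg":
        # intercept large enough that the mean stays positive mid-gradient
        params["intercept"] = a + abs(b) * config.ec_range[1] * 0.6
    return params


def _check_mean_positive_somewhere(
    cls: str, params: Mapping[str, float], ec: np.ndarray
) -> None:
    if all(class_mean(e, cls, params) <= 0 for e in ec):
        raise ConfigError(
            f"class {cls} with params {dict(params)} has non-positive mean "
            "at every EC design point"
        )


def _mechanism_assignment(
    group: str,
    category: str,
    mech_ids: list[str],
    group_members: list[str],
    config: SynthConfig,
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Deterministic complete-count assignment so planted completeness
    fractions are reproduced exactly by noiseless recovery."""
    p = config.completeness_prob.get(group, {}).get(category, 0.5)
    n = len(group_members)
    n_complete = int(round(p * n))
    order = list(group_members)
    rng.shuffle(order)
    out: dict[str, frozenset[str]] = {}
    k = len(mech_ids)
    for i, taxon in enumerate(order):
        if i < n_complete:
            out[taxon] = frozenset(mech_ids)
        else:
            size = int(rng.integers(0, k))  # strict subset, may be empty
            chosen = rng.choice(k, size=size, replace=False) if size else []
            out[taxon] = frozenset(mech_ids[j] for j in chosen)
    return out


def generate_dataset(
    config: SynthConfig, catalog: FunctionCatalog | None = None
) -> tuple[Dataset, GroundTruth]:
    """Generate a full dataset plus its ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = catalog or default_catalog()

    # --- samples -----------------------------------------------------------
    if config.ec_values is not None:
        ec = np.sort(np.asarray(config.ec_values, dtype=float))
        n_samples = len(ec)
    else:
        n_samples = config.n_samples
        ec = np.sort(rng.uniform(*config.ec_range, size=n_samples))
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n_samples))
    samples = SampleSet(sample_ids=sample_ids, ec=ec)

    # --- taxa and their planted response curves ----------------------------
    taxon_rows = []
    plan: list[tuple[str, str, str, dict[str, float]]] = []
    idx = 1
    for domain in ("bacteria", "archaea"):
        counts = config.class_counts.get(domain, {})
        for cls in RESPONSE_CLASSES:
            for _ in range(counts.get(cls, 0)):
                tid = f"T{idx:04d}"
                idx += 1
                params = _draw_class_params(cls, config, rng)
                _check_mean_positive_somewhere(cls, params, ec)
                plan.append((tid, domain, cls, params))
    for _ in range(config.n_low_abundance):
        tid = f"T{idx:04d}"
        idx += 1
        params = {"intercept": 1.0, "slope": 0.0, "breakpoint": np.nan}
        plan.append((tid, "bacteria", "null", params))

    # --- abundance matrix --------------------------------------------------
    n_taxa = len(plan)
    values = np.zeros((n_taxa, n_samples))
    for i, (tid, domain, cls, params) in enumerate(plan):
        mean = np.array([class_mean(e, cls, params) for e in ec])
        if config.nb_dispersion > 0:
            k = config.nb_dispersion
            # NB(mean mu, size k): var = mu + mu^2/k
            p = np.where(mean > 0, k / (k + mean), 1.0)
            values[i] = rng.negative_binomial(k, p)
        else:
            values[i] = mean
    abundance = AbundanceMatrix(
        pd.DataFrame(values, index=[t for t, *_ in plan], columns=sample_ids)
    )

    # --- genome sizes, phyla, genera ---------------------------------------
    genome_sizes = {}
    phyla = {}
    for tid, domain, cls, params in plan:
        grp = _group_label(cls, domain)
        mu, sd = config.genome_log_params[grp]
        genome_sizes[tid] = float(np.exp(rng.normal(mu, sd)))
        if domain == "archaea":
            phyla[tid] = (
                "Euryarchaeota" if cls in _POS_CLASSES else "Thaumarchaeota"
            )
        else:
            phyla[tid] = "Proteobacteria" if rng.random() < 0.7 else "Chloroflexi"

    # genus labels: a deterministic fraction of genus-identified planted-pos
    # taxa carry a reference salt-tolerant genus prefix
    genera: dict[str, str | None] = {}
    pos_taxa = [t for t, d, c, p in plan if c in _POS_CLASSES]
    other_taxa = [t for t, d, c, p in plan if c not in _POS_CLASSES]
    n_missing = int(round(config.genus_missing_fraction * len(pos_taxa)))
    order = list(pos_taxa)
    rng.shuffle(order)
    missing_set = set(order[:n_missing])
    identified = [t for t in order if t not in missing_set]
    n_ref = int(round(config.ref_genus_fraction * len(identified)))
    for j, tid in enumerate(identified):
        genera[tid] = (
            f"Halomonas_{j:03d}" if j < n_ref else f"Bacillus_{j:03d}"
        )
    for tid in missing_set:
        genera[tid] = None
    for j, tid in enumerate(other_taxa):
        genera[tid] = f"Pseudomonas_{j:03d}"

    taxa_frame = pd.DataFrame(
        {
            "taxon_id": [t for t, *_ in plan],
            "domain": [d for _, d, *_ in plan],
            "phylum": [phyla[t] for t, *_ in plan],
            "genus": pd.array(
                [genera[t] for t, *_ in plan], dtype="string"
            ),
            "genome_size_mb": [genome_sizes[t] for t, *_ in plan],
        }
    ).set_index("taxon_id")
    taxa = TaxonTable(taxa_frame)

    # --- gene layer: copy numbers then abundances --------------------------
    housekeeping = sorted(
        set(catalog.pathway_map)
        - set().union(*(m.genes for m in catalog.mechanisms))
    )
    c_lo, c_hi = config.copy_range
    copies: dict[tuple[str, str], int] = {}
    for tid, domain, cls, params in plan:
        for g in housekeeping:
            if rng.random() < config.gene_presence_prob:
                copies[(tid, g)] = int(rng.integers(c_lo, c_hi + 1))

    # planted mechanism presence, grouped by (class-direction, domain)
    mech_rows = []
    groups: dict[str, list[str]] = {}
    for tid, domain, cls, params in plan:
        groups.setdefault(_group_label(cls, domain), []).append(tid)
    for grp in sorted(groups):
        members = groups[grp]
        for category in ("salt_resistance", "c_fixation", "cazyme"):
            mechs = catalog.mechanisms_in(category)
            assignment = _mechanism_assignment(
                grp, category, [m.mechanism_id for m in mechs],
                members, config, rng,
            )
            by_id = {m.mechanism_id: m for m in mechs}
            for tid, present in assignment.items():
                for mid in sorted(present):
                    mech_rows.append((tid, category, mid))
                    for g in sorted(by_id[mid].genes):
                        copies[(tid, g)] = int(rng.integers(c_lo, c_hi + 1))

    # gene abundance = copy_number * taxon abundance * multiplicative noise
    taxon_index = {t: i for i, (t, *_) in enumerate(plan)}
    rec_taxon, rec_gene, rec_sample, rec_ab = [], [], [], []
    cv = config.gene_noise_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    for (tid, g), copy in sorted(copies.items()):
        row = values[taxon_index[tid]]
        if sigma > 0:
            noise = np.exp(rng.normal(-sigma * sigma / 2, sigma, size=n_samples))
        else:
            noise = 1.0
        ab = copy * row * noise
        rec_taxon.extend([tid] * n_samples)
        rec_gene.extend([g] * n_samples)
        rec_sample.extend(sample_ids)
        rec_ab.extend(ab.tolist())
    genes = GeneAbundanceTensor(
        pd.DataFrame(
            {
                "taxon_id": rec_taxon,
                "gene_id": rec_gene,
                "sample_id": rec_sample,
                "abundance": rec_ab,
            }
        )
    )

    # --- references --------------------------------------------------------
    refs = ReferenceSets(
        salt_tolerant_genera=("Halo", "Salini", "Marin"),
        reference_genomes={
            "Euryarchaeota": tuple(
                np.round(np.exp(rng.normal(np.log(2.49), 0.3, size=200)), 6)
            ),
            "Thaumarchaeota": tuple(
                np.round(np.exp(rng.normal(np.log(1.36), 0.2, size=200)), 6)
            ),
        },
    )

    dataset = Dataset(samples, taxa, abundance, genes, catalog, refs)

    truth_taxa = pd.DataFrame(
        {
            "taxon_id": [t for t, *_ in plan],
            "domain": [d for _, d, *_ in plan],
            "response_class": [c for _, _, c, _ in plan],
            "intercept": [p["intercept"] for *_, p in plan],
            "slope": [p["slope"] for *_, p in plan],
            "breakpoint": [p["breakpoint"] for *_, p in plan],
            "genome_group": [
                _group_label(c, d) for _, d, c, _ in plan
            ],
            "genome_size_mb": [genome_sizes[t] for t, *_ in plan],
        }
    )
    truth_copies = pd.DataFrame(
        [(t, g, c) for (t, g), c in sorted(copies.items())],
        columns=["taxon_id", "gene_id", "copy_number"],
    )
    truth_mechs = pd.DataFrame(
        sorted(mech_rows), columns=["taxon_id", "category", "mechanism_id"]
    )
    truth = GroundTruth(truth_taxa, truth_copies, truth_mechs)
    return dataset, truth
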