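"""Mechanism presence calls, UpSet-style exact-subset counts and
completeness distributions for salt-resistance, C-fixation and CAZyme
categories."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .core import CATEGORY_SIZES, FunctionCatalog, GeneAbundanceTensor


@dataclass(frozen=True)
class MechanismProfile:
    taxon_id: str
    category: str
    present_mechanisms: frozenset[str]

    @property
    def completeness(self) -> int:
        return len(self.present_mechanisms)


def mechanism_presence(
    tensor: GeneAbundanceTensor,
    catalog: FunctionCatalog,
    taxon: str,
    category: str,
    min_genes: int = 1,
) -> MechanismProfile:
    """A mechanism is present iff >= min_genes of its member genes have
    positive pooled abundance in the taxon (no abundance floor)."""
    mechs = catalog.mechanisms_in(category)  # raises on unknown category
    sub = tensor.records[tensor.records["taxon_id"] == taxon]
    pooled = sub.groupby("gene_id")["abundance"].sum()
    detected = set(pooled[pooled > 0].index)
    present = frozenset(
        m.mechanism_id for m in mechs if len(m.genes & detected) >= min_genes
    )
    return MechanismProfile(taxon, category, present)


def profiles_for_group(
    tensor: GeneAbundanceTensor,
    catalog: FunctionCatalog,
    taxa: list[str],
    category: str,
    min_genes: int = 1,
) -> list[MechanismProfile]:
    mechs = catalog.mechanisms_in(category)
    rec = tensor.records
    rec = rec[rec["taxon_id"].isin(taxa)]
    pooled = rec.groupby(["taxon_id", "gene_id"])["abundance"].sum()
    pooled = pooled[pooled > 0]
    detected: dict[str, set[str]] = {}
    for tid, gid in pooled.index:
        detected.setdefault(tid, set()).add(gid)
    out = []
    for tid in taxa:
        genes = detected.get(tid, set())
        present = frozenset(
            m.mechanism_id for m in mechs if len(m.genes & genes) >= min_genes
        )
        out.append(MechanismProfile(tid, category, present))
    return out


def upset_counts(profiles: list[MechanismProfile]) -> dict:
    """Exact-subset intersection tallies plus per-mechanism marginals.

    Every taxon lands in exactly one subset (its exact present set,
    including the empty set), so subset counts sum to the group size.
    """
    categories = {p.category for p in profiles}
    if len(categories) > 1:
        raise ValueError(f"profiles mix categories: {sorted(categories)}")
    subsets: Counter[frozenset[str]] = Counter()
    marginals: Counter[str] = Counter()
    for p in profiles:
        subsets[p.present_mechanisms] += 1
        for m in p.present_mechanisms:
            marginals[m] += 1
    return {
        "subset_counts": {
            "+".join(sorted(s)) if s else "(none)": c
            for s, c in sorted(
                subsets.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        },
        "marginals": dict(sorted(marginals.items())),
        "group_size": len(profiles),
    }


def completeness_distribution(
    profiles: list[MechanismProfile], category: str
) -> dict:
    """Histogram of per-taxon completeness 0..K and the all-mechanisms
    fraction (count at K / group size)."""
    k = CATEGORY_SIZES[category]
    hist = {i: 0 for i in range(k + 1)}
    for p in profiles:
        if p.category != category:
            raise ValueError(
                f"profile category {p.category} != requested {category}"
            )
        hist[p.completeness] += 1
    n = len(profiles)
    return {
        "histogram": hist,
        "group_size": n,
        "complete_fraction": (hist[k] / n) if n else None,
    }


def profiles_frame(profiles: list[MechanismProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [p.taxon_id for p in profiles],
            "category": [p.category for p in profiles],
            "present_mechanisms": [
                "+".join(sorted(p.present_mechanisms)) for p in profiles
            ],
            "completeness": [p.completeness for p in profiles],
        }
    )
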