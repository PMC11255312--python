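"""Group contrasts and supporting statistics: Mann-Whitney U (exact for
small untied samples, tie-corrected normal approximation otherwise),
genome-size comparisons, first-order partial correlation, the
difference-threshold biomarker rule, and average-linkage clustering."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import ReferenceSets, TaxonTable

logger = logging.getLogger("halotrait")

EXACT_LIMIT = 12  # max n_a + n_b for enumeration


@dataclass(frozen=True)
class GroupContrast:
    label: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _u_from_ranks(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def _exact_two_sided_p(u: float, n_a: int, n_b: int) -> float:
    """Enumerate all C(n_a+n_b, n_a) rank assignments (untied data)."""
    n = n_a + n_b
    us = []
    base = n_a * (n_a + 1) / 2.0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        us.append(sum(combo) - base)
    us = np.asarray(us)
    nm = n_a * n_b
    u_low = min(u, nm - u)
    u_high = nm - u_low
    p = (np.sum(us <= u_low) + np.sum(us >= u_high)) / len(us)
    return float(min(p, 1.0))


def mann_whitney(a, b, label: str = "", group_a: str = "a",
                 group_b: str = "b") -> GroupContrast:
    """Two-sided Mann-Whitney U. Exact by enumeration when n_a+n_b <= 12
    with no ties; otherwise normal approximation with tie and continuity
    corrections."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u = _u_from_ranks(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n_a + n_b <= EXACT_LIMIT and not has_ties:
        p = _exact_two_sided_p(u, n_a, n_b)
    else:
        n = n_a + n_b
        mean = n_a * n_b / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = (n_a * n_b / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = float(min(2.0 * sps.norm.sf(z), 1.0))
    return GroupContrast(
        label=label, group_a=group_a, group_b=group_b,
        n_a=n_a, n_b=n_b,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        u_statistic=u, p_value=p,
    )


def genome_size_contrasts(
    assignments: pd.DataFrame,
    taxa: TaxonTable,
    refs: ReferenceSets,
    shared_phylum: str = "Proteobacteria",
    min_sized: int = 3,
) -> list[GroupContrast]:
    """Genome-size comparisons: pos vs neg per domain, within the shared
    bacterial phylum, and each archaeal group against its reference phylum
    distribution. Taxa lacking genome size are dropped and counted."""
    if shared_phylum not in set(taxa.frame["phylum"]):
        raise ValueError(f"unknown phylum: {shared_phylum}")

    def sizes(group: str, phylum: str | None = None) -> np.ndarray:
        members = assignments.loc[assignments["group"] == group, "taxon_id"]
        sub = taxa.frame.loc[members]
        if phylum is not None:
            sub = sub[sub["phylum"] == phylum]
        gs = sub["genome_size_mb"]
        n_drop = int(gs.isna().sum())
        if n_drop:
            logger.warning(
                "%s: dropping %d taxa lacking genome size", group, n_drop
            )
        return gs.dropna().to_numpy(dtype=float)

    out: list[GroupContrast] = []

    def add(label, ga, gb, xa, xb):
        if len(xa) < min_sized or len(xb) < min_sized:
            logger.warning(
                "contrast %s skipped: fewer than %d sized taxa per side "
                "(%d vs %d)", label, min_sized, len(xa), len(xb),
            )
            return
        out.append(mann_whitney(xa, xb, label, ga, gb))

    add("genome_size pos-bac vs neg-bac", "pos-bac", "neg-bac",
        sizes("pos-bac"), sizes("neg-bac"))
    add("genome_size pos-arch vs neg-arch", "pos-arch", "neg-arch",
        sizes("pos-arch"), sizes("neg-arch"))
    add(f"genome_size {shared_phylum} pos-bac vs neg-bac",
        "pos-bac", "neg-bac",
        sizes("pos-bac", shared_phylum), sizes("neg-bac", shared_phylum))
    for group in ("pos-arch", "neg-arch"):
        members = assignments.loc[assignments["group"] == group, "taxon_id"]
        if not len(members):
            continue
        phyla = taxa.frame.loc[members, "phylum"]
        modal = phyla.mode()
        if not len(modal):
            continue
        phylum = modal.iloc[0]
        ref = np.asarray(refs.reference_genomes.get(phylum, ()), dtype=float)
        if not len(ref):
            logger.warning("no reference genome sizes for %s", phylum)
            continue
        add(f"genome_size {group} vs all {phylum}", group, f"all-{phylum}",
            sizes(group), ref)
    return out


def partial_corr(x, y, control) -> dict:
    """First-order partial correlation of x and y controlling for z, via
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); p from t with
    n-3 df. Equals the Pearson correlation of the two OLS residual sets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    n = len(x)
    if len(y) != n or len(z) != n:
        raise ValueError("vectors must be aligned")
    if n < 4:
        raise ValueError(f"need >= 4 observations, got {n}")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
    if denom_sq <= 1e-15:
        logger.warning("partial correlation undefined: a variable is "
                       "collinear with the control")
        return {"r_partial": np.nan, "p_value": np.nan, "n": n}
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), df))
    return {"r_partial": r, "p_value": p, "n": n}


def biomarker_pathways(
    nacg_a: pd.DataFrame,
    nacg_b: pd.DataFrame,
    diff_threshold: float = 0.001,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Select pathways differing between two groups: Mann-Whitney p < alpha
    AND |difference of per-taxon group means| > diff_threshold. Direction is
    the sign of mean_a - mean_b."""
    pathways = [c for c in nacg_a.columns if c in nacg_b.columns]
    rows = []
    for pw in pathways:
        a = nacg_a[pw].dropna().to_numpy(dtype=float)
        b = nacg_b[pw].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        contrast = mann_whitney(a, b, pw)
        diff = float(a.mean() - b.mean())
        rows.append((pw, float(a.mean()), float(b.mean()), diff,
                     contrast.p_value))
    df = pd.DataFrame(
        rows, columns=["pathway", "mean_a", "mean_b", "diff", "p_value"]
    )
    pv = df["p_value"].to_numpy()
    if bh_correct and len(df):
        order = np.argsort(pv)
        m = len(pv)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, pv[i] * m / (rank_idx + 1))
            adj[i] = prev
        pv = adj
    df["selected"] = (pv < alpha) & (df["diff"].abs() > diff_threshold)
    df["direction"] = np.sign(df["diff"]).astype(int)
    return df


def hcluster_order(matrix: pd.DataFrame) -> dict:
    """Agglomerative clustering (Euclidean, average linkage): returns leaf
    order, merge heights, and the scipy linkage matrix as a nested list."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows to cluster")
    bad = matrix.index[matrix.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"rows with missing values: {bad}")
    arr = matrix.to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(arr, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link).tolist()
    return {
        "leaf_order": [str(matrix.index[i]) for i in order],
        "merge_heights": [float(h) for h in link[:, 2]],
        "linkage": link.tolist(),
    }
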