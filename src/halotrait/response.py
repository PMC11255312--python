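"""Four-group response construction: abundance filter, per-taxon OLS vs EC,
sign/p classification, top-N selection by total abundance, and validation
against published salt-tolerant genera."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AbundanceMatrix, ReferenceSets, TaxonTable

logger = logging.getLogger("halotrait")

GROUPS = ("pos-bac", "neg-bac", "pos-arch", "neg-arch")


@dataclass(frozen=True)
class RegressionResult:
    taxon_id: str
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_used: int


def taxon_ols(abundance: np.ndarray, ec: np.ndarray,
              taxon_id: str = "") -> RegressionResult:
    """OLS of abundance on EC; two-sided p on the slope (t, n-2 df).

    A perfectly constant response yields slope 0 and p = 1 rather than NaN,
    so degenerate taxa never break batch classification.
    """
    y = np.asarray(abundance, dtype=float)
    x = np.asarray(ec, dtype=float)
    if y.shape != x.shape:
        raise ValueError("abundance and ec must be aligned")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("EC is constant; slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(taxon_id, 0.0, float(y[0]), 1.0, 0.0, n)
    res = sps.linregress(x, y)
    p = float(res.pvalue)
    if not np.isfinite(p):  # perfect fit: t -> inf
        p = 0.0
    return RegressionResult(
        taxon_id, float(res.slope), float(res.intercept),
        p, float(res.rvalue) ** 2, n,
    )


def classify_taxa(
    matrix: AbundanceMatrix,
    taxa: TaxonTable,
    ec: np.ndarray,
    min_total: float = 100.0,
    alpha: float = 0.05,
    bh_correct: bool = False,
    transform: str | None = None,
) -> pd.DataFrame:
    """Direction stage: filter by total abundance, regress, classify by sign.

    Returns one row per taxon with slope/p/total and a direction in
    {positive, negative, none} plus an exclusion reason. ``transform``
    optionally applies log1p to abundances before regression (off by
    default: untransformed absolute abundance).
    """
    if not len(matrix.taxa):
        raise ValueError("empty abundance matrix")
    ec = np.asarray(ec, dtype=float)
    totals = matrix.total_abundance
    rows = []
    pvals: dict[str, float] = {}
    fits: dict[str, RegressionResult] = {}
    for tid in matrix.taxa:
        total = float(totals[tid])
        if total < min_total:
            rows.append((tid, np.nan, np.nan, np.nan, np.nan, total,
                         "none", "low_abundance"))
            continue
        y = matrix.row(tid)
        if transform == "log1p":
            y = np.log1p(y)
        fit = taxon_ols(y, ec, tid)
        fits[tid] = fit
        pvals[tid] = fit.p_value
    adj = dict(pvals)
    if bh_correct and pvals:
        order = sorted(pvals, key=lambda t: pvals[t])
        m = len(order)
        q_prev = 1.0
        for rank, tid in reversed(list(enumerate(order, start=1))):
            q_prev = min(q_prev, pvals[tid] * m / rank)
            adj[tid] = q_prev
    for tid in matrix.taxa:
        if tid not in fits:
            continue
        fit = fits[tid]
        total = float(totals[tid])
        if adj[tid] < alpha and fit.slope != 0:
            direction = "positive" if fit.slope > 0 else "negative"
            reason = "none"
        else:
            direction = "none"
            reason = "nonsignificant"
        rows.append((tid, fit.slope, fit.intercept, fit.p_value,
                     fit.r_squared, total, direction, reason))
    df = pd.DataFrame(
        rows,
        columns=["taxon_id", "slope", "intercept", "p_value", "r_squared",
                 "total_abundance", "direction", "excluded_reason"],
    )
    # restore input row order (filtered rows were appended first)
    df = df.set_index("taxon_id").loc[matrix.taxa].reset_index()
    df["domain"] = df["taxon_id"].map(taxa.frame["domain"])
    return df


def select_response_groups(
    assignments: pd.DataFrame,
    taxa: TaxonTable,
    n_bac: int = 200,
    n_arch: int = 50,
) -> pd.DataFrame:
    """Within each domain x direction stratum keep the top-N taxa by total
    abundance (ties broken by taxon_id); others become not_selected."""
    df = assignments.copy()
    if "domain" not in df.columns:
        df["domain"] = df["taxon_id"].map(taxa.frame["domain"])
    df["group"] = "none"
    df["rank_within_group"] = pd.array([pd.NA] * len(df), dtype="Int64")
    for domain, n_keep in (("bacteria", n_bac), ("archaea", n_arch)):
        for direction, tag in (("positive", "pos"), ("negative", "neg")):
            mask = (df["domain"] == domain) & (df["direction"] == direction)
            stratum = df[mask].sort_values(
                ["total_abundance", "taxon_id"], ascending=[False, True]
            )
            if len(stratum) < n_keep:
                logger.warning(
                    "stratum %s/%s has %d candidates (< %d); keeping all",
                    domain, direction, len(stratum), n_keep,
                )
            keep = stratum.index[:n_keep]
            label = f"{tag}-{'bac' if domain == 'bacteria' else 'arch'}"
            df.loc[keep, "group"] = label
            df.loc[keep, "rank_within_group"] = np.arange(1, len(keep) + 1)
            dropped = stratum.index[n_keep:]
            df.loc[dropped, "excluded_reason"] = "not_selected"
    return df


def reference_validation(
    assignments: pd.DataFrame,
    taxa: TaxonTable,
    refs: ReferenceSets,
) -> dict[str, dict]:
    """Per group: how many genus-identified taxa match a published
    salt-tolerant genus pattern (prefix match)."""
    if not refs.salt_tolerant_genera:
        raise ValueError("empty salt-tolerant genus reference list")
    out: dict[str, dict] = {}
    genus = taxa.frame["genus"]
    for group in GROUPS:
        members = assignments.loc[assignments["group"] == group, "taxon_id"]
        if not len(members):
            out[group] = {
                "n_taxa": 0, "n_genus_identified": 0,
                "n_matching": 0, "fraction": None,
            }
            continue
        g = genus.loc[members]
        identified = g[g.notna()]
        n_match = int(sum(refs.genus_matches(v) for v in identified))
        n_id = int(len(identified))
        out[group] = {
            "n_taxa": int(len(members)),
            "n_genus_identified": n_id,
            "n_matching": n_match,
            "fraction": (n_match / n_id) if n_id else None,
        }
    return out


def group_trend(
    assignments: pd.DataFrame,
    matrix: AbundanceMatrix,
    ec: np.ndarray,
    mode: str = "absolute",
) -> dict[str, RegressionResult]:
    """OLS of summed group abundance (absolute or relative) vs EC."""
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown mode: {mode}")
    ec = np.asarray(ec, dtype=float)
    denom = matrix.values.sum(axis=0).to_numpy(dtype=float)
    out: dict[str, RegressionResult] = {}
    for group in GROUPS:
        members = assignments.loc[
            assignments["group"] == group, "taxon_id"
        ].tolist()
        if not members:
            continue
        summed = matrix.values.loc[members].sum(axis=0).to_numpy(dtype=float)
        x, y = ec, summed
        if mode == "relative":
            keep = denom > 0
            if not keep.all():
                logger.warning(
                    "relative trend for %s: dropping %d zero-total sample(s)",
                    group, int((~keep).sum()),
                )
            x, y = ec[keep], summed[keep] / denom[keep]
        out[group] = taxon_ols(y, x, group)
    return out
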