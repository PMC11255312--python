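"""End-to-end orchestration: run every stage on a loaded dataset and write
the output tables (TSV/JSON) to a directory."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import mechset, rfsel, response, segfit, stats, traits
from .core import CATEGORIES, Dataset, validate_dataset

logger = logging.getLogger("halotrait")


@dataclass
class PipelineConfig:
    min_total: float = 100.0
    alpha: float = 0.05
    n_bac: int = 200
    n_arch: int = 50
    bh_correct: bool = False
    grid_points: int = 201
    segfit_criterion: str = "f_test"
    diff_threshold: float = 0.001
    shared_phylum: str = "Proteobacteria"
    min_genes: int = 1
    rf_trees: int = 100       # scaled down from 1000 for desk-scale runtime
    rf_iterations: int = 20   # scaled down from 100
    rf_folds: int = 10
    rf_cv_trees: int = 50
    rf_k_max: int = 15
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(**doc)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_classify(dataset: Dataset, config: PipelineConfig) -> pd.DataFrame:
    assignments = response.classify_taxa(
        dataset.abundance, dataset.taxa, dataset.samples.ec,
        min_total=config.min_total, alpha=config.alpha,
        bh_correct=config.bh_correct,
    )
    return response.select_response_groups(
        assignments, dataset.taxa, n_bac=config.n_bac, n_arch=config.n_arch
    )


def run_all(
    dataset: Dataset,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute all stages; returns a summary dict and writes every output
    table listed in the module interfaces."""
    config = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    samples, taxa, abundance, tensor, catalog, refs = dataset
    ec = samples.ec

    report = validate_dataset(dataset)
    _write_json(out / "validation.json", report.to_dict())

    # --- response groups ---------------------------------------------------
    assignments = run_classify(dataset, config)
    _tsv(assignments, out / "assignments.tsv")

    trend_rows = []
    trend_fits = {}
    for mode in ("absolute", "relative"):
        fits = response.group_trend(assignments, abundance, ec, mode)
        trend_fits[mode] = fits
        for group, fit in sorted(fits.items()):
            trend_rows.append(
                (group, mode, fit.slope, fit.intercept, fit.p_value,
                 fit.r_squared, fit.n_used)
            )
    _tsv(
        pd.DataFrame(
            trend_rows,
            columns=["group", "mode", "slope", "intercept", "p_value",
                     "r_squared", "n"],
        ),
        out / "group_trends.tsv",
    )
    _write_json(
        out / "reference_validation.json",
        response.reference_validation(assignments, taxa, refs),
    )

    # --- segmented fits ----------------------------------------------------
    seg_rows = []
    for mode in ("absolute", "relative"):
        for group in sorted(trend_fits[mode]):
            members = assignments.loc[
                assignments["group"] == group, "taxon_id"
            ].tolist()
            y = abundance.values.loc[members].sum(axis=0).to_numpy(float)
            if mode == "relative":
                denom = abundance.values.sum(axis=0).to_numpy(float)
                keep = denom > 0
                y = y[keep] / denom[keep]
                x = ec[keep]
            else:
                x = ec
            try:
                fit = segfit.fit_segmented(x, y, config.grid_points)
                fit = segfit.select_model(
                    fit, config.alpha, config.segfit_criterion
                )
            except ValueError as err:
                logger.warning("segfit skipped for %s/%s: %s", group, mode, err)
                continue
            seg_rows.append(
                (group, mode, fit.breakpoint, fit.intercept, fit.left_slope,
                 fit.slope_change, fit.rss_segmented, fit.rss_linear, fit.n,
                 fit.statistic, fit.p_value, fit.chosen_model)
            )
    _tsv(
        pd.DataFrame(
            seg_rows,
            columns=["group", "mode", "breakpoint", "intercept", "left_slope",
                     "slope_change", "rss_segmented", "rss_linear", "n",
                     "statistic", "p_value", "chosen_model"],
        ),
        out / "segfit.tsv",
    )

    # --- traits ------------------------------------------------------------
    grouped = assignments[assignments["group"] != "none"]
    selected_taxa = grouped["taxon_id"].tolist()
    group_of = dict(zip(grouped["taxon_id"], grouped["group"]))

    cats = ["overall_KO", *CATEGORIES, "total_c_acquisition"]
    pooled = traits.nacg_table(tensor, abundance, catalog, cats, selected_taxa)
    pooled.insert(0, "group", [group_of[t] for t in pooled.index])
    _tsv(pooled.reset_index(), out / "traits_pooled.tsv")

    per_sample_rows = []
    for group in sorted(set(group_of.values())):
        members = [t for t in selected_taxa if group_of[t] == group]
        ps = traits.per_sample_pathway_matrix(
            tensor, abundance, catalog, members, level=1
        )
        ps.insert(0, "group", group)
        per_sample_rows.append(ps.reset_index())
    _tsv(pd.concat(per_sample_rows, ignore_index=True),
         out / "traits_per_sample.tsv")

    frac_rows = [
        (t, group_of[t], traits.c_acquisition_fraction(tensor, catalog, t).fraction)
        for t in selected_taxa
    ]
    _tsv(
        pd.DataFrame(frac_rows, columns=["taxon_id", "group", "fraction"]),
        out / "investment_fractions.tsv",
    )

    div_rows = [
        (s, *traits.ko_alpha_diversity(tensor, s).values())
        for s in samples.sample_ids
    ]
    _tsv(
        pd.DataFrame(div_rows, columns=["sample_id", "richness", "shannon"]),
        out / "ko_diversity.tsv",
    )

    # --- mechanism sets ----------------------------------------------------
    prof_frames = []
    upset: dict[str, dict] = {}
    comp_rows = []
    for group in sorted(set(group_of.values())):
        members = [t for t in selected_taxa if group_of[t] == group]
        for category in CATEGORIES:
            profs = mechset.profiles_for_group(
                tensor, catalog, members, category, config.min_genes
            )
            pf = mechset.profiles_frame(profs)
            pf.insert(0, "group", group)
            prof_frames.append(pf)
            upset[f"{group}/{category}"] = mechset.upset_counts(profs)
            dist = mechset.completeness_distribution(profs, category)
            for completeness, count in dist["histogram"].items():
                comp_rows.append((group, category, completeness, count,
                                  dist["complete_fraction"]))
    _tsv(pd.concat(prof_frames, ignore_index=True),
         out / "mechanism_profiles.tsv")
    _write_json(out / "upset_counts.json", upset)
    _tsv(
        pd.DataFrame(
            comp_rows,
            columns=["group", "category", "completeness", "count",
                     "complete_fraction"],
        ),
        out / "completeness.tsv",
    )

    # --- contrasts, biomarker rule, clustering, partial correlation --------
    contrast_rows = []
    try:
        contrasts = stats.genome_size_contrasts(
            assignments, taxa, refs, config.shared_phylum
        )
    except ValueError as err:
        logger.warning("genome-size contrasts skipped: %s", err)
        contrasts = []
    for c in contrasts:
        contrast_rows.append(
            (c.label, c.group_a, c.group_b, c.n_a, c.n_b, c.median_a,
             c.median_b, c.u_statistic, c.p_value)
        )
    # NACG contrasts between paired groups
    for ga, gb in (("pos-bac", "neg-bac"), ("pos-arch", "neg-arch")):
        for cat in cats:
            a = pooled.loc[pooled["group"] == ga, cat].dropna()
            b = pooled.loc[pooled["group"] == gb, cat].dropna()
            if len(a) and len(b):
                c = stats.mann_whitney(a, b, f"nacg {cat} {ga} vs {gb}", ga, gb)
                contrast_rows.append(
                    (c.label, c.group_a, c.group_b, c.n_a, c.n_b, c.median_a,
                     c.median_b, c.u_statistic, c.p_value)
                )
    _tsv(
        pd.DataFrame(
            contrast_rows,
            columns=["label", "group_a", "group_b", "n_a", "n_b", "median_a",
                     "median_b", "u_statistic", "p_value"],
        ),
        out / "contrasts.tsv",
    )

    level3 = {
        group: traits.pathway_nacg_matrix(
            tensor, abundance, catalog,
            [t for t in selected_taxa if group_of[t] == group], level=3,
        )
        for group in sorted(set(group_of.values()))
    }
    bio_frames = []
    for ga, gb in (("pos-bac", "neg-bac"), ("pos-arch", "neg-arch")):
        if ga in level3 and gb in level3:
            bm = stats.biomarker_pathways(
                level3[ga], level3[gb],
                diff_threshold=config.diff_threshold, alpha=config.alpha,
            )
            bm.insert(0, "pair", f"{ga} vs {gb}")
            bio_frames.append(bm)
    if bio_frames:
        _tsv(pd.concat(bio_frames, ignore_index=True), out / "biomarkers.tsv")

    group_means = pd.DataFrame(
        {g: m.mean(axis=0) for g, m in level3.items()}
    ).dropna()
    if len(group_means) >= 2:
        _write_json(out / "cluster_order.json",
                    stats.hcluster_order(group_means))

    pc_rows = []
    overall_ps = traits.per_sample_pathway_matrix(
        tensor, abundance, catalog, selected_taxa, level=1
    ).sum(axis=1).to_numpy(float)
    for cov in samples.covariates.columns:
        res = stats.partial_corr(
            samples.covariates[cov].to_numpy(float), overall_ps, ec
        )
        pc_rows.append((cov, "overall_KO_per_taxon", res["r_partial"],
                        res["p_value"], res["n"]))
    _tsv(
        pd.DataFrame(
            pc_rows, columns=["covariate", "response", "r_partial", "p_value", "n"],
        ),
        out / "partial_correlations.tsv",
    )

    # --- random-forest biomarker selection ---------------------------------
    imp_frames, curve_frames, selected = [], [], {}
    for group in sorted(set(group_of.values())):
        members = [t for t in selected_taxa if group_of[t] == group]
        mat = traits.per_sample_pathway_matrix(
            tensor, abundance, catalog, members, level=3
        ).dropna()
        if len(mat) < 10 or mat.shape[1] < 2:
            logger.warning("rf-select skipped for %s (matrix %s)", group, mat.shape)
            continue
        ec_sub = np.asarray(
            [ec[samples.sample_ids.index(s)] for s in mat.index], dtype=float
        )
        result = rfsel.rf_rank(
            mat, ec_sub, n_trees=config.rf_trees,
            iterations=config.rf_iterations, seed=config.seed, group=group,
        )
        result = rfsel.cv_select_count(
            result, mat, ec_sub, folds=min(config.rf_folds, len(mat)),
            seed=config.seed, n_trees=config.rf_cv_trees,
            k_max=config.rf_k_max,
        )
        imp = result.importances.copy()
        imp.insert(0, "group", group)
        imp_frames.append(imp)
        curve_frames.append(
            pd.DataFrame({
                "group": group,
                "k": np.arange(1, len(result.cv_error) + 1),
                "cv_mse": result.cv_error,
                "cv_se": result.cv_se,
            })
        )
        selected[group] = {
            "selected_count": result.selected_count,
            "pathways": result.selected_pathways(),
            "seed": config.seed,
        }
    if imp_frames:
        _tsv(pd.concat(imp_frames, ignore_index=True), out / "rf_importance.tsv")
        _tsv(pd.concat(curve_frames, ignore_index=True), out / "rf_cv_curve.tsv")
        _write_json(out / "rf_selected.json", selected)

    summary = {
        "n_samples": samples.n,
        "n_taxa": len(taxa.taxon_ids),
        "groups": {
            g: int((assignments["group"] == g).sum())
            for g in response.GROUPS
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    _write_json(out / "summary.json", summary)
    return summary
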