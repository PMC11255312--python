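import numpy as np
import pandas as pd
import pytest

from halotrait.core import (
    AbundanceMatrix,
    ReferenceSets,
    TaxonTable,
)
from halotrait.response import (
    classify_taxa,
    group_trend,
    reference_validation,
    select_response_groups,
    taxon_ols,
)

def _taxa_table(ids, domain="bacteria", genus=None):
    return TaxonTable(
        pd.DataFrame(
            {
                "taxon_id": ids,
                "domain": [domain] * len(ids),
                "phylum": ["Proteobacteria"] * len(ids),
                "genus": pd.array(
                    genus if genus is not None else [None] * len(ids),
                    dtype="string",
                ),
                "genome_size_mb": [3.0] * len(ids),
            }
        ).set_index("taxon_id")
    )


class TestTaxonOLS:
    def test_exact_line(self):
        fit = taxon_ols([2, 4, 6], [1, 2, 3])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-6

    def test_constant_response_p_is_one(self):
        fit = taxon_ols([5, 5, 5, 5], [1, 2, 3, 4])
        assert fit.slope == 0.0
        assert fit.p_value == 1.0

    def test_closed_form_oracle(self):
        # hand computation: Sxx=10, Sxy=9 -> slope 0.9, intercept -0.1;
        # SSE=1.1, SST=9.2 -> r2=0.880435; t=0.9/sqrt((1.1/3)/10)=4.700097
        fit = taxon_ols([1, 2, 2, 3, 5], [1, 2, 3, 4, 5])
        assert fit.slope == pytest.approx(0.9, rel=1e-12)
        assert fit.intercept == pytest.approx(-0.1, rel=1e-9)
        assert fit.r_squared == pytest.approx(0.8804347826086957, rel=1e-12)
        assert fit.p_value == pytest.approx(0.01821985474322239, rel=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 3"):
            taxon_ols([1, 2], [1, 2])

    def test_constant_ec(self):
        with pytest.raises(ValueError, match="constant"):
            taxon_ols([1, 2, 3], [2, 2, 2])


class TestClassify:
    def _matrix(self, rows, ids, samples=None):
        arr = np.asarray(rows, dtype=float)
        cols = samples or [f"S{i}" for i in range(arr.shape[1])]
        return AbundanceMatrix(pd.DataFrame(arr, index=ids, columns=cols))

    def test_total_99_excluded_as_low_abundance(self):
        ec = np.array([1.0, 2.0, 3.0])
        matrix = self._matrix([[33, 33, 33], [50, 60, 70]], ["T1", "T2"])
        out = classify_taxa(matrix, _taxa_table(["T1", "T2"]), ec)
        row = out.set_index("taxon_id").loc["T1"]
        assert row["excluded_reason"] == "low_abundance"
        assert row["direction"] == "none"

    def test_noiseless_increasing_is_positive(self):
        ec = np.linspace(0, 10, 8)
        matrix = self._matrix([100 + 5 * ec], ["T1"])
        out = classify_taxa(matrix, _taxa_table(["T1"]), ec)
        assert out.iloc[0]["direction"] == "positive"

    def test_empty_matrix_errors(self):
        matrix = AbundanceMatrix(pd.DataFrame(index=[], columns=["S1", "S2"]))
        with pytest.raises(ValueError, match="empty"):
            classify_taxa(matrix, _taxa_table([]), np.array([1.0, 2.0]))

    def test_noiseless_recovery_is_exact(self, noiseless_data):
        dataset, truth = noiseless_data
        out = classify_taxa(
            dataset.abundance, dataset.taxa, dataset.samples.ec
        ).set_index("taxon_id")
        merged = truth.taxa.set_index("taxon_id").join(out[["direction"]])
        responsive = merged[
            merged["response_class"].isin(
                ["linear_pos", "linear_neg", "threshold_pos", "threshold_neg"]
            )
        ]
        expected = np.where(
            responsive["response_class"].str.endswith("pos"),
            "positive", "negative",
        )
        assert (responsive["direction"] == expected).all()

    def test_noisy_recovery_at_least_90_percent(self, noisy_data):
        dataset, truth = noisy_data
        out = classify_taxa(
            dataset.abundance, dataset.taxa, dataset.samples.ec
        ).set_index("taxon_id")
        merged = truth.taxa.set_index("taxon_id").join(out[["direction"]])
        responsive = merged[
            merged["response_class"].isin(
                ["linear_pos", "linear_neg", "threshold_pos", "threshold_neg"]
            )
        ]
        expected = np.where(
            responsive["response_class"].str.endswith("pos"),
            "positive", "negative",
        )
        assert (responsive["direction"] == expected).mean() >= 0.90

    def test_scale_equivariance(self, noiseless_data):
        dataset, _ = noiseless_data
        ec = dataset.samples.ec
        base = classify_taxa(dataset.abundance, dataset.taxa, ec, min_total=0)
        scaled_matrix = AbundanceMatrix(dataset.abundance.values * 7.0)
        scaled = classify_taxa(scaled_matrix, dataset.taxa, ec, min_total=0)
        assert (base["direction"] == scaled["direction"]).all()
        np.testing.assert_allclose(
            scaled["slope"], 7.0 * base["slope"], rtol=1e-9
        )
        np.testing.assert_allclose(
            scaled["p_value"], base["p_value"], rtol=1e-9, atol=1e-12
        )

    def test_partition_property(self, noisy_data):
        dataset, _ = noisy_data
        out = select_response_groups(
            classify_taxa(dataset.abundance, dataset.taxa, dataset.samples.ec),
            dataset.taxa, n_bac=10, n_arch=5,
        )
        assert len(out) == len(dataset.abundance.taxa)
        assert out["taxon_id"].is_unique
        # group implies direction and no exclusion
        grouped = out[out["group"] != "none"]
        assert (grouped["direction"] != "none").all()
        assert (grouped["excluded_reason"] == "none").all()
        for g, n_max in [("pos-bac", 10), ("neg-bac", 10),
                         ("pos-arch", 5), ("neg-arch", 5)]:
            assert (out["group"] == g).sum() <= n_max


class TestSelect:
    def _assignments(self, ids, totals, direction="positive"):
        return pd.DataFrame(
            {
                "taxon_id": ids,
                "slope": 1.0,
                "intercept": 0.0,
                "p_value": 0.01,
                "r_squared": 0.9,
                "total_abundance": totals,
                "direction": direction,
                "excluded_reason": "none",
            }
        )

    def test_top_n_by_total(self):
        ids = [f"T{i}" for i in range(5)]
        df = self._assignments(ids, [10, 50, 30, 40, 20])
        out = select_response_groups(df, _taxa_table(ids), n_bac=3, n_arch=1)
        kept = set(out.loc[out["group"] == "pos-bac", "taxon_id"])
        assert kept == {"T1", "T3", "T2"}
        dropped = out[out["group"] == "none"]
        assert (dropped["excluded_reason"] == "not_selected").all()

    def test_tie_broken_by_taxon_id(self):
        ids = ["TB", "TA", "TC"]
        df = self._assignments(ids, [50, 50, 50])
        out = select_response_groups(df, _taxa_table(ids), n_bac=2, n_arch=1)
        kept = set(out.loc[out["group"] == "pos-bac", "taxon_id"])
        assert kept == {"TA", "TB"}  # lexicographic at the cutoff

    def test_rank_unique_within_group(self):
        ids = [f"T{i}" for i in range(6)]
        df = self._assignments(ids, [60, 50, 40, 30, 20, 10])
        out = select_response_groups(df, _taxa_table(ids), n_bac=4, n_arch=1)
        ranks = out.loc[out["group"] == "pos-bac", "rank_within_group"]
        assert sorted(ranks.tolist()) == [1, 2, 3, 4]

    def test_group_sizes_min_of_n_and_stratum(self, noisy_data):
        dataset, truth = noisy_data
        assignments = classify_taxa(
            dataset.abundance, dataset.taxa, dataset.samples.ec
        )
        out = select_response_groups(assignments, dataset.taxa,
                                     n_bac=5, n_arch=50)
        for domain, direction, g, n in [
            ("bacteria", "positive", "pos-bac", 5),
            ("archaea", "positive", "pos-arch", 50),
        ]:
            stratum = assignments[
                (assignments["domain"] == domain)
                & (assignments["direction"] == direction)
            ]
            assert (out["group"] == g).sum() == min(n, len(stratum))


class TestReferenceValidation:
    def _groups(self, genera):
        ids = [f"T{i}" for i in range(len(genera))]
        taxa = _taxa_table(ids, genus=genera)
        df = pd.DataFrame(
            {"taxon_id": ids, "group": ["pos-bac"] * len(ids)}
        )
        return df, taxa

    def test_half_matching(self):
        df, taxa = self._groups(["Halomonas", "Bacillus", None])
        refs = ReferenceSets(("Halo",), {})
        out = reference_validation(df, taxa, refs)
        assert out["pos-bac"]["n_genus_identified"] == 2
        assert out["pos-bac"]["n_matching"] == 1
        assert out["pos-bac"]["fraction"] == pytest.approx(0.5)

    def test_empty_group_fraction_missing(self):
        df, taxa = self._groups(["Halomonas"])
        refs = ReferenceSets(("Halo",), {})
        out = reference_validation(df, taxa, refs)
        assert out["neg-arch"]["fraction"] is None

    def test_empty_reference_list_errors(self):
        df, taxa = self._groups(["Halomonas"])
        refs = ReferenceSets((), {})
        with pytest.raises(ValueError, match="empty"):
            reference_validation(df, taxa, refs)

    def test_planted_fraction_recovered(self, noiseless_data):
        dataset, truth = noiseless_data
        assignments = select_response_groups(
            classify_taxa(dataset.abundance, dataset.taxa, dataset.samples.ec),
            dataset.taxa, n_bac=200, n_arch=50,
        )
        out = reference_validation(assignments, dataset.taxa,
                                   dataset.references)
        # all planted positives are selected noiselessly; the generator
        # plants ref-genus membership in 62% of genus-identified pos taxa
        pos = truth.taxa[truth.taxa["response_class"].isin(
            ["linear_pos", "threshold_pos"])]
        genus = dataset.taxa.frame.loc[pos["taxon_id"], "genus"]
        identified = genus.dropna()
        expected = identified.str.startswith("Halo").mean()
        combined_matching = (
            out["pos-bac"]["n_matching"] + out["pos-arch"]["n_matching"]
        )
        combined_identified = (
            out["pos-bac"]["n_genus_identified"]
            + out["pos-arch"]["n_genus_identified"]
        )
        assert combined_matching / combined_identified == pytest.approx(expected)
        assert expected == pytest.approx(0.62, abs=0.05)


class TestGroupTrend:
    def test_single_taxon_group_equals_own_fit(self):
        ec = np.linspace(0, 10, 12)
        rng = np.random.default_rng(0)
        y = 50 + 3 * ec + rng.normal(0, 2, size=12)
        matrix = AbundanceMatrix(
            pd.DataFrame([y], index=["T1"], columns=[f"S{i}" for i in range(12)])
        )
        assignments = pd.DataFrame({"taxon_id": ["T1"], "group": ["pos-bac"]})
        trend = group_trend(assignments, matrix, ec, "absolute")["pos-bac"]
        own = taxon_ols(y, ec)
        assert trend.slope == pytest.approx(own.slope)
        assert trend.p_value == pytest.approx(own.p_value)

    def test_relative_abundances_sum_to_one(self, noisy_data):
        dataset, _ = noisy_data
        totals = dataset.abundance.values.sum(axis=0)
        rel = dataset.abundance.values.div(totals, axis=1)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, rtol=1e-12)

    def test_planted_positive_slope_sign_recovery(self):
        # 100 light-weight simulations of a planted positive group
        rng = np.random.default_rng(99)
        ec = np.sort(rng.uniform(0.14, 13.65, 37))
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            mu = 50 + 4 * ec
            k = 5.0
            y = rng.negative_binomial(k, k / (k + mu), size=(5, 37)).sum(axis=0)
            matrix = AbundanceMatrix(
                pd.DataFrame([y], index=["G"],
                             columns=[f"S{i}" for i in range(37)])
            )
            assignments = pd.DataFrame({"taxon_id": ["G"], "group": ["pos-bac"]})
            fit = group_trend(assignments, matrix, ec, "absolute")["pos-bac"]
            hits += fit.slope > 0
        assert hits >= 95

    def test_unknown_mode_errors(self, noisy_data):
        dataset, _ = noisy_data
        assignments = pd.DataFrame({"taxon_id": ["T0001"], "group": ["pos-bac"]})
        with pytest.raises(ValueError, match="mode"):
            group_trend(assignments, dataset.abundance, dataset.samples.ec,
                        "log")
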