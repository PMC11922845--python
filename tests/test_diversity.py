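"""Negative-binomial count adjustment and cross-species comparison."""

import numpy as np
import pandas as pd
import pytest

from coniferdiv.diversity import (
    adjust_counts,
    fit_snp_abundance_model,
    group_species,
    species_heterogeneity_test,
    summarize_from_counts,
    summarize_species,
)


def simulate_nb(rng, n, b0=-6.0, b_len=1.0, b_dep=0.3, alpha=0.5, n_species=3):
    lengths = rng.uniform(300, 2500, n)
    depths = rng.uniform(10, 120, n)
    species = rng.integers(0, n_species, n)
    offsets = np.linspace(0.0, 0.4, n_species)
    mu = np.exp(b0 + b_len * np.log(lengths) + b_dep * np.log(depths) + offsets[species])
    lam = rng.gamma(1.0 / alpha, alpha * mu)  # NB2 as gamma-Poisson mixture
    counts = rng.poisson(lam)
    return pd.DataFrame({
        "transcript_id": [f"t{i}" for i in range(n)],
        "species": [f"sp{s+1}" for s in species],
        "snp_count": counts,
        "coding_length": lengths,
        "mean_depth": depths,
    })


@pytest.fixture(scope="module")
def nb_fit_and_table():
    rng = np.random.default_rng(101)
    table = simulate_nb(rng, 3000)
    return fit_snp_abundance_model(table), table


class TestNBFit:
    def test_recovers_generative_coefficients(self, nb_fit_and_table):
        fit, _ = nb_fit_and_table
        se_len = fit.bse["log_length"]
        se_dep = fit.bse["log_depth"]
        assert abs(fit.log_length_coef - 1.0) < 1.96 * se_len
        assert abs(fit.log_depth_coef - 0.3) < 1.96 * se_dep
        assert fit.alpha == pytest.approx(0.5, abs=0.15)

    def test_all_zero_counts_error(self):
        df = pd.DataFrame({
            "transcript_id": ["a", "b"], "species": ["s", "s"],
            "snp_count": [0, 0], "coding_length": [500, 600],
            "mean_depth": [20.0, 30.0],
        })
        with pytest.raises(ValueError, match="zero"):
            fit_snp_abundance_model(df)

    def test_single_species_constant_covariates_intercept_only(self, rng):
        counts = rng.poisson(5.0, 500)
        counts[0] = max(counts[0], 1)
        df = pd.DataFrame({
            "transcript_id": [f"t{i}" for i in range(500)],
            "species": "only", "snp_count": counts,
            "coding_length": 900.0, "mean_depth": 40.0,
        })
        fit = fit_snp_abundance_model(df)
        assert np.exp(fit.intercept) == pytest.approx(counts.mean(), rel=0.02)
        assert fit.log_length_coef == 0.0 and fit.log_depth_coef == 0.0


class TestAdjustment:
    FIT_KW = dict(b0=-6.0, b_len=1.0, b_dep=0.0, alpha=0.4)

    def test_identity_at_reference_covariates(self, nb_fit_and_table):
        fit, table = nb_fit_and_table
        lref, dref = fit.reference_covariates
        at_ref = table.copy()
        at_ref["coding_length"] = lref
        at_ref["mean_depth"] = dref
        adj = adjust_counts(fit, at_ref)
        assert np.allclose(adj, at_ref["snp_count"].to_numpy(float))

    def test_double_length_halves_count_when_coef_is_one(self, nb_fit_and_table):
        fit, table = nb_fit_and_table
        fit2 = type(fit)(**{**fit.__dict__, "log_length_coef": 1.0,
                            "log_depth_coef": 0.0})
        lref, dref = fit2.reference_covariates
        df = pd.DataFrame({
            "transcript_id": ["x"], "species": ["s"], "snp_count": [10],
            "coding_length": [2 * lref], "mean_depth": [dref],
        })
        assert adjust_counts(fit2, df)[0] == pytest.approx(5.0)

    def test_depth_ignored_when_coefficient_zero(self, nb_fit_and_table):
        fit, _ = nb_fit_and_table
        fit0 = type(fit)(**{**fit.__dict__, "log_depth_coef": 0.0})
        lref, dref = fit0.reference_covariates
        df = pd.DataFrame({
            "transcript_id": ["x", "y"], "species": ["s", "s"],
            "snp_count": [7, 7], "coding_length": [lref, lref],
            "mean_depth": [dref, 2 * dref],
        })
        adj = adjust_counts(fit0, df)
        assert adj[0] == pytest.approx(adj[1])

    def test_zeros_stay_zero(self, nb_fit_and_table):
        fit, table = nb_fit_and_table
        adj = adjust_counts(fit, table)
        assert np.all(adj[table["snp_count"].to_numpy() == 0] == 0)

    def test_ranking_invariant_to_common_depth_rescaling(self):
        rng = np.random.default_rng(55)
        table = simulate_nb(rng, 2500)
        scaled = table.copy()
        scaled["mean_depth"] = scaled["mean_depth"] * 3.0

        def ranking(tab):
            fit = fit_snp_abundance_model(tab)
            t = tab.copy()
            t["adjusted_count"] = adjust_counts(fit, t)
            return list(t.groupby("species")["adjusted_count"].mean()
                        .sort_values(ascending=False).index)

        assert ranking(table) == ranking(scaled)


class TestHeterogeneityAndGrouping:
    def test_identical_groups_h_zero(self):
        x = np.arange(10.0)
        h, p = species_heterogeneity_test({"a": x, "b": x.copy()})
        assert h == 0.0

    def test_shifted_group_is_detected(self, rng):
        base = rng.gamma(2.0, 3.0, 500)
        groups = {"a": base, "b": rng.gamma(2.0, 3.0, 500),
                  "c": rng.gamma(2.0, 3.0, 500) * 1.5}
        h, p = species_heterogeneity_test(groups)
        assert p < 1e-6

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            species_heterogeneity_test({"a": [1.0], "b": [1.0, 2.0]})

    def test_identical_distributions_single_group(self, rng):
        data = {f"s{i}": rng.normal(5, 1, 400) for i in range(3)}
        data["s9"] = data["s0"] + rng.normal(0, 1e-6, 400)  # same distribution
        g = group_species({k: rng.permutation(v) for k, v in data.items()})
        # all drawn from one normal: expect a single component most seeds
        assert len(g.groups) <= 2

    def test_disjoint_supports_split(self, rng):
        g = group_species({
            "lo": rng.uniform(0, 1, 300), "hi": rng.uniform(10, 11, 300)
        })
        assert g.groups == [["hi"], ["lo"]]  # ordered by decreasing mean

    def test_groups_form_partition(self, rng):
        data = {f"s{i}": rng.gamma(2, 2 + i, 300) for i in range(5)}
        g = group_species(data)
        flat = [s for grp in g.groups for s in grp]
        assert sorted(flat) == sorted(data)


class TestSummaries:
    def test_derived_cells_from_published_counts(self):
        # white spruce row: 100,128 adjusted SNPs over 16,581 polymorphic
        # transcripts of 18,060 -> mean 6.0, proportion 91.8%
        s = summarize_from_counts("Picea glauca", 18060, 105778, 100128, 16581)
        assert s.mean_snps_per_transcript == 6.0
        assert s.proportion_transcripts_with_snps == 91.8

    def test_zero_polymorphic_transcripts(self):
        s = summarize_from_counts("x", 100, 0, 0.0, 0)
        assert np.isnan(s.mean_snps_per_transcript)
        assert s.proportion_transcripts_with_snps == 0.0

    def test_summarize_species_aggregates(self):
        df = pd.DataFrame({
            "species": ["a", "a", "a", "b", "b"],
            "snp_count": [2, 0, 4, 1, 1],
            "adjusted_count": [2.5, 0.0, 3.5, 1.0, 0.9],
        })
        out = {s.species: s for s in summarize_species(df)}
        assert out["a"].n_transcripts == 3
        assert out["a"].n_transcripts_with_snps_adjusted == 2
        assert out["a"].mean_snps_per_transcript == 3.0
        assert out["b"].proportion_transcripts_with_snps == 100.0
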