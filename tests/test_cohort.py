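import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screensig import generate_cohort
from screensig.cohort import (
    EULER_GAMMA,
    MedianOfRatiosNormalizer,
    activation_score,
    cluster_samples,
    fit_gumbel,
    gumbel_tail_p,
    random_signature_null,
    score_gene_correlation,
    score_table,
    size_factors,
    stratify_deciles,
)
from screensig.types import ValidationError


def _m(data: dict[str, list[float]], genes: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(data)
    df.index = pd.Index(genes, name="gene_id")
    return df


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _m({"a": [5, 9, 100], "b": [5, 9, 100]}, ["g1", "g2", "g3"])
        assert np.allclose(size_factors(counts), 1.0)

    def test_two_gene_hand_oracle(self):
        """A=(2,8), B=(4,16): geomeans (2.828, 11.314); ratio columns are
        constant 1/sqrt(2) and sqrt(2), so the factors are exactly those
        medians and the normalized matrices coincide."""
        counts = _m({"A": [2, 8], "B": [4, 16]}, ["g1", "g2"])
        norm = MedianOfRatiosNormalizer().fit(counts)
        sf = norm.size_factors_
        assert sf["A"] == pytest.approx(1 / math.sqrt(2))
        assert sf["B"] == pytest.approx(math.sqrt(2))
        assert sf["B"] / sf["A"] == pytest.approx(2.0)
        out = norm.transform(counts)
        assert np.allclose(out["A"], out["B"])

    def test_scale_equivariance_exact(self):
        """Multiplying one sample by f multiplies its factor by exactly f
        times the shared geomean adjustment; the ratio of factors scales by f."""
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(40, size=(50, 4)) + 1,
            index=[f"g{i}" for i in range(50)], columns=list("abcd"),
        )
        sf0 = size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf1 = size_factors(scaled)
        # gene geomeans all change by 3**(1/4); every factor absorbs it
        adj = 3 ** (1 / 4)
        assert np.allclose(sf1["c"], 3 * sf0["c"] / adj)
        assert np.allclose(sf1[["a", "b", "d"]], sf0[["a", "b", "d"]] / adj)

    def test_matches_pydeseq2_on_random_matrix(self):
        """Cross-check against the independent DESeq2 reimplementation."""
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(5, 200, size=(60, 1)), size=(60, 10)) + 1,
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(10)],
        )
        ours = size_factors(counts)
        meta = pd.DataFrame({"condition": ["A"] * 10}, index=counts.columns)
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~1", quiet=True
        )
        dds.fit_size_factors()
        theirs = pd.Series(dds.obs["size_factors"].to_numpy(), index=counts.columns)
        # pydeseq2 medians the log-ratios, so with an even reference-gene
        # count the interpolated middle is geometric rather than arithmetic;
        # agreement is exact apart from that interpolation.
        assert np.allclose(ours, theirs, rtol=1e-3)

    def test_no_reference_genes_errors(self):
        counts = _m({"a": [0, 5], "b": [3, 0]}, ["g1", "g2"])
        with pytest.raises(ValidationError, match="filter"):
            size_factors(counts)

    def test_recovers_library_factors_on_synthetic_cohort(self):
        counts, design, truth, _ = generate_cohort(seed=3)
        sf = size_factors(counts)
        r = np.corrcoef(sf, truth.library_factors)[0, 1]
        assert r >= 0.99


class TestStratifyDeciles:
    def test_counts_at_n100_and_n10(self):
        vals = pd.Series(np.arange(100, dtype=float),
                         index=[f"t{i}" for i in range(100)])
        strata = stratify_deciles(vals)
        assert (strata == "low_decile").sum() == 10
        assert (strata == "high_decile").sum() == 10
        assert set(strata[vals < 10]) == {"low_decile"}
        small = stratify_deciles(vals.iloc[:10])
        assert (small == "low_decile").sum() == 1
        assert (small == "high_decile").sum() == 1

    def test_ceil_rule(self):
        vals = pd.Series(np.arange(101, dtype=float),
                         index=[f"t{i}" for i in range(101)])
        strata = stratify_deciles(vals)
        assert (strata == "low_decile").sum() == 11  # ceil(101/10)

    def test_all_ties_stable_and_warns(self, caplog):
        vals = pd.Series(np.ones(20), index=[f"t{i}" for i in range(20)])
        with caplog.at_level("WARNING"):
            strata = stratify_deciles(vals)
        assert (strata == "low_decile").sum() == 2
        assert (strata == "high_decile").sum() == 2
        assert strata["t0"] == "low_decile"  # stable input order
        assert any("tie" in r.message for r in caplog.records)
        pd.testing.assert_series_equal(strata, stratify_deciles(vals))

    def test_permutation_invariance_without_ties(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=50), index=[f"t{i}" for i in range(50)])
        strata = stratify_deciles(vals)
        shuffled = vals.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(
            stratify_deciles(shuffled).sort_index(), strata.sort_index()
        )

    def test_too_few_tumors(self):
        with pytest.raises(ValidationError):
            stratify_deciles(pd.Series(np.arange(9.0)))


class TestActivationScore:
    def test_tumor_at_normal_mean_scores_zero(self):
        m = _m({"n1": [10, 20], "n2": [10, 20], "t1": [10, 20]}, ["g1", "g2"])
        s = activation_score(m, ["g1", "g2"], ["n1", "n2"], ["t1"])
        assert s["t1"] == pytest.approx(0.0)

    def test_three_gene_hand_computation(self):
        """normals (10,10,10), tumor (20,40,10), pc=0 -> 1 + 2 + 0 = 3."""
        m = _m({"n1": [10, 10, 10], "n2": [10, 10, 10], "t1": [20, 40, 10]},
               ["g1", "g2", "g3"])
        s = activation_score(m, ["g1", "g2", "g3"], ["n1", "n2"], ["t1"],
                             pseudocount=0.0)
        assert s["t1"] == pytest.approx(3.0)

    def test_linear_scale(self):
        m = _m({"n1": [10], "n2": [10], "t1": [30]}, ["g1"])
        s = activation_score(m, ["g1"], ["n1", "n2"], ["t1"], scale="linear",
                             pseudocount=0.0)
        assert s["t1"] == pytest.approx(3.0)

    def test_additive_over_signature_partition(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        m = pd.DataFrame(rng.uniform(5, 50, size=(20, 6)), index=genes,
                         columns=["n1", "n2", "t1", "t2", "t3", "t4"])
        tum = ["t1", "t2", "t3", "t4"]
        full = activation_score(m, genes, ["n1", "n2"], tum)
        part = activation_score(m, genes[:7], ["n1", "n2"], tum) + \
            activation_score(m, genes[7:], ["n1", "n2"], tum)
        assert np.allclose(full, part)

    def test_missing_genes_skipped_and_reported(self, caplog):
        m = _m({"n1": [10], "n2": [10], "t1": [20]}, ["g1"])
        with caplog.at_level("WARNING"):
            s = activation_score(m, ["g1", "ghost"], ["n1", "n2"], ["t1"])
        assert any("ghost" in r.message or "absent" in r.message
                   for r in caplog.records)
        assert len(s) == 1

    def test_no_genes_present_errors(self):
        m = _m({"n1": [10], "n2": [10], "t1": [20]}, ["g1"])
        with pytest.raises(ValidationError):
            activation_score(m, ["ghost"], ["n1", "n2"], ["t1"])

    def test_recovers_latent_activation(self):
        counts, design, truth, sig = generate_cohort(seed=8)
        nm = MedianOfRatiosNormalizer().fit(counts).transform(counts)
        tumors = design.index[design["group"] == "tumor"]
        normals = design.index[design["group"] == "normal"]
        s = activation_score(nm, sig, normals, tumors)
        assert np.corrcoef(s, truth.activation)[0, 1] >= 0.9


def ward_oracle_merges(points: np.ndarray) -> list[frozenset]:
    """Greedy Ward agglomeration by exhaustive pair search: at each step merge
    the pair of clusters with minimal within-cluster SSE increase
    |A||B|/(|A|+|B|) · ||mean_A − mean_B||². Returns merged index sets."""
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a = points[list(clusters[i])]
            b = points[list(clusters[j])]
            na, nb = len(a), len(b)
            d2 = float(((a.mean(axis=0) - b.mean(axis=0)) ** 2).sum())
            cost = na * nb / (na + nb) * d2
            if cost < best_cost:
                best, best_cost = (i, j), cost
        i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def scipy_merge_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


class TestClusterSamples:
    def test_two_samples_single_merge_at_euclidean_distance(self):
        m = _m({"a": [0.0, 0.0], "b": [3.0, 4.0]}, ["g1", "g2"])
        res = cluster_samples(m, k_groups=2)
        assert res.linkage.shape == (1, 4)
        assert res.linkage[0, 2] == pytest.approx(5.0)

    def test_four_point_line_k2(self):
        m = _m({"a": [0.0], "b": [0.1], "c": [10.0], "d": [10.1]}, ["g"])
        labels = pd.Series({"a": "L", "b": "L", "c": "R", "d": "R"})
        res = cluster_samples(m, k_groups=2, reference_labels=labels)
        assert res.ari == pytest.approx(1.0)
        assert res.labels["a"] == res.labels["b"]
        assert res.labels["c"] == res.labels["d"]
        assert res.labels["a"] != res.labels["c"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_merge_order_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        m = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(6)])
        res = cluster_samples(m, k_groups=2)
        oracle = ward_oracle_merges(pts)
        assert scipy_merge_sets(res.linkage, 6) == oracle

    def test_merge_heights_monotone(self):
        counts, design, truth, sig = generate_cohort(
            seed=1, n_genes=300, n_signature=30, n_normal=12, n_tumor=40
        )
        m = np.log2(counts.loc[list(sig)] + 1.0)
        res = cluster_samples(m, k_groups=3)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_newick_covers_all_leaves(self):
        m = _m({"a": [0.0], "b": [1.0], "c": [5.0]}, ["g"])
        res = cluster_samples(m, k_groups=2)
        assert res.newick.endswith(";")
        for leaf in ["a", "b", "c"]:
            assert leaf in res.newick

    def test_k_too_large_errors(self):
        m = _m({"a": [0.0], "b": [1.0]}, ["g"])
        with pytest.raises(ValidationError):
            cluster_samples(m, k_groups=3)

    def test_ward_variants_agree_on_well_separated_data(self):
        m = _m({"a": [0.0], "b": [0.1], "c": [10.0], "d": [10.1]}, ["g"])
        d2 = cluster_samples(m, k_groups=2, variant="D2")
        d1 = cluster_samples(m, k_groups=2, variant="D")
        assert (d2.labels == d2.labels["a"]).sum() == (
            d1.labels == d1.labels["a"]
        ).sum()


class TestCorrelationAndNull:
    def test_perfect_correlation(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["t1", "t2", "t3"])
        m = _m({"t1": [2.0**1 - 1], "t2": [2.0**2 - 1], "t3": [2.0**3 - 1]},
               ["g"])
        assert score_gene_correlation(scores, m, "g") == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["t1", "t2", "t3"])
        m = _m({"t1": [2.0**3 - 1], "t2": [2.0**2 - 1], "t3": [2.0**1 - 1]},
               ["g"])
        assert score_gene_correlation(scores, m, "g") == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["t1", "t2", "t3"])
        m = _m({"t1": [1.0], "t2": [2.0], "t3": [4.0]}, ["g"])
        with pytest.raises(ValidationError, match="variance"):
            score_gene_correlation(scores, m, "g")

    def test_gumbel_closed_form_at_mode_plus_gamma_beta(self):
        """At x = μ + γβ (the mean), the upper tail is 1 − exp(−exp(−γ))."""
        p = gumbel_tail_p(2.0 + EULER_GAMMA * 0.5, mu=2.0, beta=0.5)
        assert p == pytest.approx(1 - math.exp(-math.exp(-EULER_GAMMA)), rel=1e-9)

    def test_gumbel_moments_recovered_from_large_sample(self):
        rng = np.random.default_rng(0)
        draws = rng.gumbel(0.0, 1.0, size=100_000)
        mu, beta = fit_gumbel(draws)
        assert abs(mu) <= 0.02
        assert abs(beta - 1.0) <= 0.02

    @given(x=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gumbel_tail_strictly_decreasing(self, x):
        assert gumbel_tail_p(x + 0.01, 0.0, 1.0) < gumbel_tail_p(x, 0.0, 1.0)

    def _small_cohort(self):
        counts, design, truth, sig = generate_cohort(
            seed=2, n_genes=400, n_signature=25, n_normal=15, n_tumor=60
        )
        nm = MedianOfRatiosNormalizer().fit(counts).transform(counts)
        tumors = design.index[design["group"] == "tumor"].tolist()
        normals = design.index[design["group"] == "normal"].tolist()
        return nm, truth, sig, normals, tumors

    def test_null_is_seed_deterministic(self):
        nm, truth, sig, normals, tumors = self._small_cohort()
        n1 = random_signature_null(nm, sig, truth.target_gene, normals, tumors,
                                   n_draws=50, seed=9)
        n2 = random_signature_null(nm, sig, truth.target_gene, normals, tumors,
                                   n_draws=50, seed=9)
        assert np.array_equal(n1.null_r, n2.null_r)
        assert n1.p_value == n2.p_value

    def test_null_excludes_requested_genes(self):
        nm, truth, sig, normals, tumors = self._small_cohort()
        with pytest.raises(ValidationError, match="universe"):
            random_signature_null(
                nm, sig, truth.target_gene, normals, tumors, n_draws=5, seed=0,
                exclude=list(nm.index[:380]),
            )

    def test_negative_observed_correlation_uses_lower_tail(self):
        nm, truth, sig, normals, tumors = self._small_cohort()
        null = random_signature_null(nm, sig, truth.anti_gene, normals, tumors,
                                     n_draws=200, seed=4, exclude=list(sig))
        assert null.observed_r < 0
        assert null.direction == "less"
        assert null.p_value < 0.05

    def test_score_table_strata_and_reference(self):
        counts, design, truth, sig = generate_cohort(
            seed=5, n_genes=400, n_signature=25, n_normal=15, n_tumor=60
        )
        nm = MedianOfRatiosNormalizer().fit(counts).transform(counts)
        table = score_table(nm, sig, design, truth.target_gene)
        assert (table.loc[design["group"] == "normal", "stratum"] == "normal").all()
        assert (table["stratum"] == "low_decile").sum() == 6
        assert (table["stratum"] == "high_decile").sum() == 6
        assert table.loc[design["group"] == "normal", "activation_score"].isna().all()
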