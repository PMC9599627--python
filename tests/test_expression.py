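"""Expression statistics: counting, TMM, dispersion, exact test, BH, DE driver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomshift.config import SampleSheet, SimConfig
from bloomshift.expression import (
    CountMatrix,
    ExpressionError,
    bh_adjust,
    count_reads,
    differential_expression,
    estimate_common_dispersion,
    exact_test_nb,
    tmm_factors,
)
from bloomshift.formats import AlignmentRecord
from bloomshift.simulate import generate_references, simulate_counts_matrix

from conftest import n_contrast_samples


def _aln(read_id, orf_id, nm=0, primary=True):
    return AlignmentRecord(read_id, orf_id, 0, [("M", 50)], nm=nm, is_primary=primary, seq="A" * 50)


class TestCountReads:
    def test_basic_counts_and_lib_size(self):
        alns = {"S1": [_aln("r1", "A"), _aln("r2", "A"), _aln("r3", "A"), _aln("r4", "B")]}
        m = count_reads(alns)
        assert m.counts.loc["A", "S1"] == 3
        assert m.counts.loc["B", "S1"] == 1
        assert m.lib_sizes["S1"] == 4

    def test_empty_sample_all_zero_column(self):
        m = count_reads({"S1": [_aln("r1", "A")], "S2": []})
        assert m.counts["S2"].sum() == 0

    def test_multi_primary_smallest_nm_then_lexicographic(self):
        alns = {"S1": [_aln("r1", "b", nm=2), _aln("r1", "a", nm=2), _aln("r1", "c", nm=5)]}
        m = count_reads(alns)
        assert m.counts.loc["a", "S1"] == 1
        assert m.counts["S1"].sum() == 1

    def test_secondary_alignments_ignored(self):
        m = count_reads({"S1": [_aln("r1", "A"), _aln("r2", "B", primary=False)]})
        assert "B" not in m.counts.index or m.counts.loc["B", "S1"] == 0


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        x = np.tile(np.arange(1, 101)[:, None], (1, 3))
        assert np.allclose(tmm_factors(x), 1.0)

    def test_pure_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, 200)
        x = np.column_stack([col, 2 * col])
        assert np.allclose(tmm_factors(x), 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.negative_binomial(5, 0.1, size=(500, 6))
        f = tmm_factors(x)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_against_published_reference_implementation(self):
        # Frozen oracle: edgeR 4.0.16 calcNormFactors(method="TMM",
        # logratioTrim=0.3, sumTrim=0.05) on this exact matrix.
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 0.05, size=(200, 4)).astype(int)
        hot = rng.choice(200, 10, replace=False)
        x[hot, 3] *= 80  # 5% of ORFs take ~80% of sample 4's counts
        expected = [1.480619061446, 1.470434067859, 1.508008617389, 0.304584139270]
        got = tmm_factors(x)
        assert np.allclose(got, expected, atol=1e-9)
        assert got[3] < 1.0

    def test_zero_library_size_rejected(self):
        with pytest.raises(ExpressionError):
            tmm_factors(np.zeros((10, 2)))


def _nb_counts(rng, phi, mu, shape):
    lam = rng.gamma(1.0 / phi, phi * mu, size=shape) if phi > 0 else np.full(shape, mu)
    return rng.poisson(lam)


class TestDispersion:
    def test_supplied_phi_bypasses_estimation(self):
        m = CountMatrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
        est = estimate_common_dispersion(m, {"a": "g", "b": "g"}, phi=0.37)
        assert est.phi_common == 0.37
        assert est.method == "supplied"

    def test_no_replication_requires_explicit_phi(self):
        m = CountMatrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
        with pytest.raises(ExpressionError, match="dispersion"):
            estimate_common_dispersion(m, {"a": "g1", "b": "g2"})

    def test_poisson_data_gives_near_zero_phi(self):
        rng = np.random.default_rng(10)
        mu = rng.lognormal(3, 1, 2000)[:, None] * np.ones(4)
        x = rng.poisson(mu)
        m = CountMatrix(pd.DataFrame(x, columns=list("abcd")))
        est = estimate_common_dispersion(m, {c: "g" for c in "abcd"})
        assert est.phi_common < 0.02

    def test_nb_phi_point_one_recovered(self):
        rng = np.random.default_rng(7)
        mu = rng.lognormal(3.0, 1.0, 5000)[:, None] * np.array([1.0, 1.2, 0.9, 1.1])
        x = _nb_counts(rng, 0.1, mu, mu.shape)
        m = CountMatrix(pd.DataFrame(x, columns=list("abcd")))
        est = estimate_common_dispersion(m, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert 0.08 <= est.phi_common <= 0.12


def brute_force_exact_p(a, b, phi, n_a=1, n_b=1, tie_rel=1e-7):
    """Independent enumeration oracle using plain lgamma arithmetic."""
    t = a + b
    if t == 0:
        return 1.0
    pa = n_a / (n_a + n_b)
    probs = []
    for k in range(t + 1):
        if phi == 0:
            lp = (
                math.lgamma(t + 1) - math.lgamma(k + 1) - math.lgamma(t - k + 1)
                + k * math.log(pa) + (t - k) * math.log(1 - pa)
            )
        else:
            r_a = (n_a + n_b) * pa / phi
            r_b = (n_a + n_b) * (1 - pa) / phi
            mu_a, mu_b = t * pa, t * (1 - pa)

            def nb(k_, r, mu):
                return (
                    math.lgamma(k_ + r) - math.lgamma(r) - math.lgamma(k_ + 1)
                    + r * (math.log(r) - math.log(r + mu))
                    + (k_ * (math.log(mu) - math.log(r + mu)) if k_ else 0.0)
                )

            lp = nb(k, r_a, mu_a) + nb(t - k, r_b, mu_b)
        probs.append(math.exp(lp))
    total = sum(probs)
    obs = probs[a]
    return min(sum(p for p in probs if p <= obs * (1 + tie_rel)) / total, 1.0)


class TestExactTest:
    def test_equal_counts_give_p_one(self):
        assert exact_test_nb([10], [10], 0.0) == 1.0

    def test_zero_zero_gives_p_one(self):
        assert exact_test_nb([0], [0], 0.5) == 1.0

    def test_extreme_split_two_sided_binomial(self):
        p = exact_test_nb([0], [20], 0.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ExpressionError):
            exact_test_nb([-1], [5], 0.1)

    @pytest.mark.parametrize("phi", [0.0, 0.01, 0.1, 1.0])
    def test_matches_brute_force_small_totals(self, phi):
        for t in (1, 2, 5, 17, 40):
            for a in range(t + 1):
                got = exact_test_nb([a], [t - a], phi)
                want = brute_force_exact_p(a, t - a, phi)
                assert got == pytest.approx(want, abs=1e-12)

    def test_unequal_group_sizes_match_brute_force(self):
        for phi in (0.0, 0.2):
            for a in range(0, 31, 5):
                got = exact_test_nb([a / 2, a / 2], [30 - a], phi, eff_lib_a=2.0, eff_lib_b=1.0)
                want = brute_force_exact_p(a, 30 - a, phi, n_a=2, n_b=1)
                assert got == pytest.approx(want, abs=1e-12)

    @given(
        a=st.integers(0, 60),
        b=st.integers(0, 60),
        phi=st.sampled_from([0.0, 0.05, 0.3, 2.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_under_group_swap(self, a, b, phi):
        p1 = exact_test_nb([a], [b], phi)
        p2 = exact_test_nb([b], [a], phi)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestBhAdjust:
    def test_textbook_triple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_two_values(self):
        assert np.allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance_and_bounds(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), q[perm])


@pytest.fixture(scope="module")
def de_matrix():
    samples = n_contrast_samples(30_000)
    cfg = SimConfig(
        seed=8, n_taxon_groups=2, orfs_per_group=200, dispersion=0.05,
        de_fraction=0.1, de_log2fc=3.0, samples=samples,
    )
    bundle = generate_references(cfg)
    counts = simulate_counts_matrix(bundle)
    sheet = SampleSheet.from_samples(samples)
    return bundle, CountMatrix(counts, sheet, bundle.annotation)


class TestDifferentialExpression:
    def test_null_columns_no_discoveries(self):
        rng = np.random.default_rng(4)
        col = rng.integers(5, 500, 300)
        counts = pd.DataFrame({s: col for s in ["MB1", "MB2", "MB3", "MB4"]})
        sheet = SampleSheet.from_samples(n_contrast_samples(100))
        m = CountMatrix(counts, sheet)
        de = differential_expression(m, "N", phi=0.05)
        assert (de["fdr"] < 0.05).sum() == 0
        assert np.allclose(de["log2fc"], 0.0)

    def test_sign_orientation_depleted_over_replete(self, de_matrix):
        bundle, m = de_matrix
        de = differential_expression(m, "N").set_index("orf_id")
        truth = bundle.truth_table().set_index("orf_id")
        up = truth[truth.log2fc_N > 0].index.intersection(de.index)
        down = truth[truth.log2fc_N < 0].index.intersection(de.index)
        assert (de.loc[up, "log2fc"] > 0).mean() > 0.9
        assert (de.loc[down, "log2fc"] < 0).mean() > 0.9

    def test_empty_contrast_side_rejected(self, de_matrix):
        _, m = de_matrix
        with pytest.raises(ExpressionError, match="empty"):
            differential_expression(m, "Fe")  # no Fe samples in the sheet

    def test_groupwise_vs_taxon_proportion_semantics(self):
        # one group doubles in abundance with unchanged relative physiology:
        # taxon_proportion flags the group, groupwise stays ~null
        samples = n_contrast_samples(50_000)
        cfg = SimConfig(
            seed=12, n_taxon_groups=3, orfs_per_group=150, dispersion=0.01,
            de_fraction=0.0, group_bloom_log2fc=[2.0, 0.0, 0.0], samples=samples,
        )
        bundle = generate_references(cfg)
        m = CountMatrix(
            simulate_counts_matrix(bundle), SampleSheet.from_samples(samples), bundle.annotation
        )
        prop = differential_expression(m, "N", mode="taxon_proportion").set_index("orf_id")
        blooming = bundle.annotation["taxon_group"].iloc[0]
        # proportions are compositional, so the measured change is smaller than
        # the planted +2 but must be clearly positive and significant
        assert prop.loc[blooming, "fdr"] < 0.05
        assert prop.loc[blooming, "log2fc"] > 0.5
        grpw = differential_expression(m, "N", mode="groupwise")
        flagged = (grpw[grpw["taxon_group"] == blooming]["fdr"] < 0.05).mean()
        assert flagged < 0.10

    def test_min_total_filter_drops_sparse_orfs(self):
        counts = pd.DataFrame(
            {"MB1": [0, 100], "MB2": [1, 120], "MB3": [0, 90], "MB4": [2, 110]},
            index=["sparse", "dense"],
        )
        sheet = SampleSheet.from_samples(n_contrast_samples(100))
        m = CountMatrix(counts, sheet)
        de = differential_expression(m, "N", phi=0.1, min_total=5)
        assert de["orf_id"].tolist() == ["dense"]
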