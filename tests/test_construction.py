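"""Network construction: correlation oracle, FDR, ensembles, Pmap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbnet import (
    SUVRDataset,
    apply_pmap_threshold,
    build_ensemble,
    compute_pmap,
    conventional_mbn,
    fdr_correct,
    ms_network,
    pearson_adjacency,
    residualize_covariates,
    select_representative,
    select_representative_index,
)
from mbnet.construction import NetworkEnsemble, ProbabilityMap

from conftest import make_network


def pearson_oracle(x, y):
    """Direct evaluation of the correlation sum formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())


def bh_oracle(pvals, alpha):
    """Brute-force Benjamini-Hochberg step-up: reject the m* smallest
    p-values where m* is the largest i with p_(i) <= i*alpha/m."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    thresh = (np.arange(1, m + 1) * alpha) / m
    below = p[order] <= thresh
    k = np.nonzero(below)[0].max() + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def _dataset(values):
    values = np.asarray(values, float)
    n, d = values.shape
    return SUVRDataset(
        values=values,
        subject_ids=[f"s{i}" for i in range(n)],
        voi_names=[f"V{j}" for j in range(d)],
        group="G",
    )


class TestPearsonAdjacency:
    def test_perfect_linear_dependence(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ds = _dataset(np.column_stack([x, 2 * x + 3, 10 - x]))
        net = pearson_adjacency(ds)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(-1.0)
        assert net.pvalues[0, 1] < 1e-12

    def test_matches_sum_formula_oracle(self):
        p = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        q = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        ds = _dataset(np.column_stack([p, q]))
        net = pearson_adjacency(ds)
        assert abs(net.weights[0, 1] - pearson_oracle(p, q)) < 1e-12

    def test_random_matrix_matches_oracle_everywhere(self):
        rng = np.random.default_rng(8)
        values = 1.0 + 0.3 * rng.random((9, 5))
        net = pearson_adjacency(_dataset(values))
        for i in range(5):
            for j in range(i + 1, 5):
                assert abs(
                    net.weights[i, j] - pearson_oracle(values[:, i], values[:, j])
                ) < 1e-12

    def test_zero_variance_column_names_voi(self):
        values = np.ones((6, 3))
        values[:, 0] = np.linspace(1, 2, 6)
        values[:, 2] = np.linspace(2, 1, 6)
        with pytest.raises(ValueError, match="'V1'"):
            pearson_adjacency(_dataset(values))

    def test_diagonal_zero_and_symmetric(self, small_cohort):
        net = pearson_adjacency(small_cohort["CU"])
        assert np.all(np.diag(net.weights) == 0)
        np.testing.assert_array_equal(net.weights, net.weights.T)


class TestFDRCorrect:
    def _net_with_pvalues(self, pvals_upper, d):
        iu = np.triu_indices(d, k=1)
        p = np.zeros((d, d))
        p[iu] = pvals_upper
        p = p + p.T
        np.fill_diagonal(p, 1.0)
        w = np.full((d, d), 0.5)
        np.fill_diagonal(w, 0.0)
        return make_network(w, pvalues=p)

    def test_all_pvalues_one_kills_everything(self):
        net = self._net_with_pvalues(np.ones(6), 4)
        out = fdr_correct(net, alpha=0.05)
        assert out.edge_mask().sum() == 0

    def test_all_pvalues_zero_keeps_everything(self):
        net = self._net_with_pvalues(np.zeros(6), 4)
        out = fdr_correct(net, alpha=0.05)
        assert out.edge_mask().sum() == 12  # all 6 undirected edges, both triangles

    def test_stepup_hand_case(self):
        # m=4 hand case: thresholds i*alpha/m = .0125/.025/.0375/.05, so the
        # step-up keeps {.001, .02} (p_(2)=.02 <= .025) and rejects the rest
        np.testing.assert_array_equal(
            bh_oracle([0.001, 0.02, 0.04, 0.2], alpha=0.05),
            [True, True, False, False],
        )
        # same p-values embedded in a 4-node network (m=6 edges, two fillers
        # at p=1): thresholds shift to i*.05/6 and only .001 survives — both
        # routes must agree
        pv = np.array([0.001, 0.02, 0.04, 0.2, 1.0, 1.0])
        net = self._net_with_pvalues(pv, 4)
        out = fdr_correct(net, alpha=0.05)
        surviving = out.pvalues[np.triu(out.edge_mask(), 1)]
        assert sorted(surviving) == [0.001]
        iu = np.triu_indices(4, k=1)
        np.testing.assert_array_equal(out.edge_mask()[iu], bh_oracle(pv, 0.05))

    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=6, max_size=6
        ),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_stepup_oracle(self, pvals, alpha):
        net = self._net_with_pvalues(np.array(pvals), 4)
        out = fdr_correct(net, alpha=alpha)
        iu = np.triu_indices(4, k=1)
        np.testing.assert_array_equal(
            out.edge_mask()[iu], bh_oracle(pvals, alpha)
        )

    def test_alpha_monotonicity_of_survival(self, small_cohort):
        net = pearson_adjacency(small_cohort["CU"])
        prev = None
        for alpha in (0.0001, 0.001, 0.01, 0.05):
            edges = fdr_correct(net, alpha).edge_set()
            if prev is not None:
                assert prev <= edges
            prev = edges


class TestBuildEnsemble:
    def test_single_network_contract(self, small_cohort):
        ens = build_ensemble(small_cohort["CU"], n=1, alpha=0.05, seed=4)
        assert len(ens) == 1
        idx = ens.sample_indices[0]
        assert len(idx) == small_cohort["CU"].n_subjects  # size-N with replacement

    def test_equal_seeds_identical_ensembles(self, small_cohort):
        a = build_ensemble(small_cohort["CU"], n=5, alpha=0.05, seed=11)
        b = build_ensemble(small_cohort["CU"], n=5, alpha=0.05, seed=11)
        for na, nb, ia, ib in zip(a.networks, b.networks, a.sample_indices, b.sample_indices):
            np.testing.assert_array_equal(na.weights, nb.weights)
            np.testing.assert_array_equal(ia, ib)

    def test_subsample_mode_sizes(self, small_cohort):
        ens = build_ensemble(
            small_cohort["CU"], n=3, alpha=0.05, mode="subsample", fraction=0.8, seed=1
        )
        n = small_cohort["CU"].n_subjects
        for idx in ens.sample_indices:
            assert len(idx) == round(0.8 * n)
            assert len(set(idx.tolist())) == len(idx)  # without replacement

    def test_identical_rows_rejected(self):
        values = np.tile(np.linspace(1, 2, 4), (8, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            build_ensemble(_dataset(values), n=2, alpha=0.05, seed=0)

    def test_materialized_sample_reproduces_member(self, small_cohort):
        X = small_cohort["CU"]
        ens = build_ensemble(X, n=3, alpha=0.05, seed=2)
        y = ens.materialize_sample(X, 1)
        net = fdr_correct(pearson_adjacency(y), 0.05)
        np.testing.assert_array_equal(net.weights, ens.networks[1].weights)


class TestSelectRepresentative:
    def _random_ensemble(self, n, d, seed):
        rng = np.random.default_rng(seed)
        nets = []
        for _ in range(n):
            a = rng.normal(scale=0.3, size=(d, d))
            w = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(w, 0.0)
            nets.append(make_network(w))
        return NetworkEnsemble(
            networks=nets,
            sample_indices=[np.arange(3)] * n,
            sampling_mode="bootstrap",
            subsample_fraction=1.0,
            alpha=0.05,
            seed=seed,
        )

    def test_identical_members_tie_breaks_to_index_zero(self, toy_network):
        ens = NetworkEnsemble(
            networks=[toy_network] * 4,
            sample_indices=[np.arange(3)] * 4,
            sampling_mode="bootstrap",
            subsample_fraction=1.0,
            alpha=0.05,
            seed=0,
        )
        for criterion in ("mean", "median", "mode"):
            assert select_representative_index(ens, criterion) == 0

    def test_member_equal_to_mean_wins(self):
        ens = self._random_ensemble(2, 5, seed=0)
        mean = ens.mean_matrix()
        nets = [make_network(mean), ens.networks[1]]
        ens2 = NetworkEnsemble(
            networks=nets,
            sample_indices=[np.arange(3)] * 2,
            sampling_mode="bootstrap",
            subsample_fraction=1.0,
            alpha=0.05,
            seed=0,
        )
        # member 0 is not exactly the mean of {member0, member1}, so recompute:
        # the member closer to the elementwise mean must win
        center = ens2.mean_matrix()
        d0 = np.linalg.norm(nets[0].weights - center)
        d1 = np.linalg.norm(nets[1].weights - center)
        expected = 0 if d0 <= d1 else 1
        assert select_representative_index(ens2, "mean") == expected

    @pytest.mark.parametrize("criterion", ["mean", "median"])
    def test_argmin_matches_exhaustive_scan(self, criterion):
        ens = self._random_ensemble(5, 6, seed=3)
        center = ens.mean_matrix() if criterion == "mean" else ens.median_matrix()
        dists = [np.linalg.norm(n.weights - center) for n in ens.networks]
        assert select_representative_index(ens, criterion) == int(np.argmin(dists))

    def test_mode_picks_densest_cluster_member(self):
        # 6 near-identical matrices plus 2 far outliers: the mode criterion
        # must pick a member of the dense cluster
        rng = np.random.default_rng(7)
        base = rng.normal(scale=0.2, size=(5, 5))
        base = np.clip((base + base.T) / 2, -1, 1)
        np.fill_diagonal(base, 0.0)
        nets = [make_network(np.clip(base + rng.normal(scale=0.01, size=base.shape) * 0
                                     + _sym_noise(rng, 5, 0.01), -1, 1)) for _ in range(6)]
        nets += [make_network(_sym_noise(rng, 5, 0.5)) for _ in range(2)]
        ens = NetworkEnsemble(
            networks=nets,
            sample_indices=[np.arange(3)] * 8,
            sampling_mode="bootstrap",
            subsample_fraction=1.0,
            alpha=0.05,
            seed=0,
        )
        assert select_representative_index(ens, "mode") < 6

    def test_representative_is_always_a_member(self, small_cohort):
        ens = build_ensemble(small_cohort["CU"], n=7, alpha=0.05, seed=5)
        for criterion in ("mean", "median", "mode"):
            rep = select_representative(ens, criterion)
            assert any(rep is net for net in ens.networks)


def _sym_noise(rng, d, scale):
    a = rng.normal(scale=scale, size=(d, d))
    w = np.clip((a + a.T) / 2, -1, 1)
    np.fill_diagonal(w, 0.0)
    return w


class TestProbabilityMap:
    def _ensemble_from_masks(self, masks):
        nets = []
        for m in masks:
            m = np.asarray(m, dtype=float)
            w = np.triu(m, 1) * 0.5
            w = w + w.T
            nets.append(make_network(w))
        return NetworkEnsemble(
            networks=nets,
            sample_indices=[np.arange(3)] * len(masks),
            sampling_mode="bootstrap",
            subsample_fraction=1.0,
            alpha=0.05,
            seed=0,
        )

    def test_counts_are_exact_fractions(self):
        on = np.ones((3, 3)) - np.eye(3)
        off = np.zeros((3, 3))
        three_of_four = self._ensemble_from_masks([on, on, on, off])
        pmap = compute_pmap(three_of_four)
        assert pmap.probs[0, 1] == 0.75
        always = compute_pmap(self._ensemble_from_masks([on] * 4))
        assert always.probs[0, 2] == 1.0
        never = compute_pmap(self._ensemble_from_masks([off, off]))
        assert never.probs[0, 1] == 0.0

    def test_entries_reproduce_indicator_counts(self, small_cohort):
        ens = build_ensemble(small_cohort["CU"], n=8, alpha=0.05, seed=3)
        pmap = compute_pmap(ens)
        counts = sum((net.weights != 0).astype(int) for net in ens.networks)
        np.fill_diagonal(counts, 0)
        np.testing.assert_allclose(pmap.probs * 8, counts)

    def test_strict_threshold_boundary(self):
        probs = np.array([[0.0, 0.5, 0.75], [0.5, 0.0, 0.25], [0.75, 0.25, 0.0]])
        pmap = ProbabilityMap(probs=probs, n=4, voi_names=["a", "b", "c"])
        w = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.2], [0.6, 0.2, 0.0]])
        net = make_network(w, voi_names=["a", "b", "c"])
        kept = apply_pmap_threshold(net, pmap, theta=0.5)
        assert kept.weights[0, 1] == 0.0  # 0.5 > 0.5 is False: removed
        assert kept.weights[0, 2] == 0.6  # 0.75 > 0.5: retained
        loose = apply_pmap_threshold(net, pmap, theta=0.0)
        assert loose.weights[0, 1] == 0.4  # 0.5 > 0: retained

    def test_occurrence_count_arithmetic_at_tight_theta(self):
        # theta = 0.9999: with n ensemble members, an edge needs occurrence
        # count k with k/n > 0.9999, i.e. k = n for any n <= 9999
        for n in (4, 500):
            assert (n - 1) / n <= 0.9999
            assert n / n > 0.9999

    def test_dimension_mismatch_rejected(self, toy_network):
        pmap = ProbabilityMap(probs=np.zeros((3, 3)), n=2, voi_names=list("abc"))
        with pytest.raises(ValueError, match="nodes"):
            apply_pmap_threshold(toy_network, pmap, 0.5)

    def test_pmap_never_less_conservative_than_fdr(self, small_cohort):
        res = ms_network(small_cohort["CU"], n=30, alpha=0.05, seed=9)
        rep = res.ensemble.networks[res.representative_index]
        assert res.network.edge_set() <= rep.edge_set()


class TestConventionalAndCovariates:
    def test_equals_ensemble_member_on_identity_draw(self, small_cohort):
        X = small_cohort["CU"]
        direct = conventional_mbn(X, alpha=0.05)
        forced = fdr_correct(pearson_adjacency(X.subset(np.arange(X.n_subjects))), 0.05)
        np.testing.assert_array_equal(direct.weights, forced.weights)

    def test_block_structure_drives_survival(self):
        # two independent blocks: within-block edges survive, between-block
        # survival stays near the false-positive level
        from mbnet import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_subjects={"G": 200},
            d=10,
            block_sizes=(5, 5),
            rho_in=0.8,
            rho_out=0.0,
            seed=12,
        )
        ds = generate_cohort(spec)["G"]
        net = conventional_mbn(ds, alpha=0.05)
        blocks = spec.block_labels
        same = blocks[:, None] == blocks[None, :]
        mask = net.edge_mask()
        within_rate = mask[same & ~np.eye(10, dtype=bool)].mean()
        between_rate = mask[~same].mean()
        assert within_rate > 0.95
        assert between_rate < 0.25

    def test_residualization_removes_covariate_correlation(self):
        rng = np.random.default_rng(5)
        n = 80
        age = rng.uniform(60, 85, n)
        noise = rng.normal(scale=0.05, size=(n, 3))
        values = 1.2 + 0.01 * age[:, None] + noise
        ds = SUVRDataset(
            values=values,
            subject_ids=[f"s{i}" for i in range(n)],
            voi_names=["A", "B", "C"],
            group="G",
            covariates=age[:, None],
            covariate_names=["age"],
        )
        out = residualize_covariates(ds)
        for j in range(3):
            r = np.corrcoef(out.values[:, j], age)[0, 1]
            assert abs(r) < 1e-10
        np.testing.assert_allclose(
            out.values.mean(axis=0), ds.values.mean(axis=0), atol=1e-10
        )

    def test_orthogonal_covariate_leaves_column_unchanged(self):
        n = 40
        cov = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        col = np.concatenate([np.linspace(1, 2, n // 2)] * 2)  # orthogonal to cov
        values = np.column_stack([col, col[::-1]])
        ds = SUVRDataset(
            values=values,
            subject_ids=[f"s{i}" for i in range(n)],
            voi_names=["A", "B"],
            group="G",
            covariates=cov[:, None],
            covariate_names=["site"],
        )
        out = residualize_covariates(ds)
        np.testing.assert_allclose(out.values[:, 0], values[:, 0], atol=1e-10)

    def test_rank_deficient_covariates_rejected(self):
        n = 20
        age = np.linspace(60, 80, n)
        ds = SUVRDataset(
            values=1.0 + np.random.default_rng(0).random((n, 2)),
            subject_ids=[f"s{i}" for i in range(n)],
            voi_names=["A", "B"],
            group="G",
            covariates=np.column_stack([age, 2 * age]),
            covariate_names=["age", "age2x"],
        )
        with pytest.raises(ValueError, match="rank"):
            residualize_covariates(ds)


class TestMSInvariants:
    def test_bootstrap_row_permutation_invariance(self, small_cohort):
        # permuting subjects permutes only which rows a draw picks; with the
        # same seed the drawn row *positions* are equal, so the networks of
        # draw k are built from different subjects — but the full-data
        # network itself is exchangeable over subjects
        X = small_cohort["CU"]
        perm = np.random.default_rng(0).permutation(X.n_subjects)
        net_a = conventional_mbn(X, 0.05)
        net_b = conventional_mbn(X.subset(perm), 0.05)
        np.testing.assert_allclose(net_a.weights, net_b.weights, atol=1e-12)

    def test_combined_correction_subset_property_random_ensembles(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            values = 1.0 + 0.3 * rng.random((20, 8))
            ds = _dataset(values)
            res = ms_network(ds, n=10, alpha=0.05, seed=trial)
            rep = res.ensemble.networks[res.representative_index]
            assert res.network.edge_set() <= rep.edge_set()
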