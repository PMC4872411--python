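"""Network based statistics: edge-wise t, components, permutation FWER."""

import numpy as np
import pytest
from scipy import stats

from fcnet.connectivity import ConnectivityMatrix
from fcnet.nbs import (
    NBSConfig,
    NBSResult,
    altered_connection_counts,
    edgewise_t,
    nbs_test,
    supra_threshold_components,
)


def _cm(z, subject, condition):
    n = z.shape[0]
    return ConnectivityMatrix(
        z=z, region_labels=[f"r{i}" for i in range(n)],
        subject_id=subject, condition=condition,
    )


def _paired_stack(rng, n_subjects=12, n_nodes=15, planted=None, delta=0.0):
    """Paired study stacks: noise z plus optional planted edge differences."""
    mats = []
    for s in range(n_subjects):
        base = rng.standard_normal((n_nodes, n_nodes)) * 0.2
        base = (base + base.T) / 2
        for cond in ("placebo", "drug"):
            noise = rng.standard_normal((n_nodes, n_nodes)) * 0.1
            z = base + (noise + noise.T) / 2
            if cond == "drug" and planted is not None:
                for i, j in planted:
                    z[i, j] += delta
                    z[j, i] += delta
            np.fill_diagonal(z, 0)
            mats.append(_cm(z, f"s{s}", cond))
    return mats


class TestEdgewiseT:
    def test_identical_conditions_all_zero(self, rng):
        mats = []
        for s in range(5):
            z = rng.standard_normal((8, 8))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0)
            mats.append(_cm(z.copy(), f"s{s}", "placebo"))
            mats.append(_cm(z.copy(), f"s{s}", "drug"))
        t = edgewise_t(mats, "paired")
        assert np.allclose(t, 0.0)

    def test_planted_edge_attains_max_t(self, rng):
        mats = _paired_stack(rng, planted=[(2, 7)], delta=0.6)
        t = edgewise_t(mats, "paired")
        assert np.unravel_index(np.argmax(t), t.shape) in [(2, 7), (7, 2)]

    def test_matches_scalar_ttest_oracle(self, rng):
        mats = _paired_stack(rng, n_subjects=8, n_nodes=6)
        t = edgewise_t(mats, "paired")
        placebo = [m for m in mats if m.condition == "placebo"]
        drug = [m for m in mats if m.condition == "drug"]
        for i in range(6):
            for j in range(i + 1, 6):
                d = [dm.z[i, j] for dm in drug]
                p = [pm.z[i, j] for pm in placebo]
                expected = stats.ttest_rel(d, p).statistic
                assert t[i, j] == pytest.approx(expected, abs=1e-12)

    def test_two_group_matches_scipy(self, rng):
        mats = []
        for g, cond in enumerate(("placebo", "drug")):
            for s in range(6):
                z = rng.standard_normal((5, 5)) + g * 0.3
                z = (z + z.T) / 2
                np.fill_diagonal(z, 0)
                mats.append(_cm(z, f"{cond}{s}", cond))
        t = edgewise_t(mats, "two_group")
        drug = np.array([m.z[0, 1] for m in mats if m.condition == "drug"])
        plac = np.array([m.z[0, 1] for m in mats if m.condition == "placebo"])
        expected = stats.ttest_ind(drug, plac, equal_var=True).statistic
        assert t[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_unpairable_subject_rejected(self, rng):
        mats = _paired_stack(rng, n_subjects=3)
        with pytest.raises(ValueError, match="s2"):
            edgewise_t(mats[:-1], "paired")


class TestComponents:
    def test_subthreshold_matrix_gives_nothing(self):
        t = np.full((6, 6), 0.5)
        np.fill_diagonal(t, 0)
        assert supra_threshold_components(t, 3.0) == []

    def test_planted_star_is_single_component(self):
        t = np.zeros((8, 8))
        for leaf in range(1, 6):
            t[0, leaf] = t[leaf, 0] = 5.0
        comps = supra_threshold_components(t, 3.0)
        assert len(comps) == 1
        assert comps[0].size == 5
        assert len(comps[0].nodes) == 6

    def test_two_disjoint_paths_two_components(self):
        t = np.zeros((10, 10))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            t[i, j] = t[j, i] = 5.0
        for i, j in [(5, 6), (6, 7)]:
            t[i, j] = t[j, i] = 5.0
        comps = supra_threshold_components(t, 3.0)
        assert [c.size for c in comps] == [3, 2]

    def test_less_tail_uses_negative_edges(self):
        t = np.zeros((4, 4))
        t[0, 1] = t[1, 0] = -5.0
        assert supra_threshold_components(t, 3.0, "greater") == []
        comps = supra_threshold_components(t, 3.0, "less")
        assert comps[0].edges == [(0, 1)]

    def test_extent_monotone_in_threshold(self, rng):
        t = rng.standard_normal((20, 20)) * 2
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0)
        sizes = []
        for thr in (1.0, 2.0, 3.0):
            comps = supra_threshold_components(t, thr)
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestNbsTest:
    def test_planted_component_recovered(self, rng):
        planted = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
                   (0, 2), (1, 3), (2, 4), (3, 5)]
        mats = _paired_stack(rng, n_subjects=20, n_nodes=30,
                             planted=planted, delta=0.25)
        cfg = NBSConfig(primary_threshold_t=4.0, design="paired",
                        n_permutations=500, seed=1)
        res = nbs_test(mats, cfg)
        assert res.significant
        top = res.components[0]
        found = {tuple(sorted(e)) for e in top.edges}
        truth = {tuple(sorted(e)) for e in planted}
        jaccard = len(found & truth) / len(found | truth)
        assert top.p_fwer <= 0.05
        assert jaccard >= 0.8

    def test_null_data_rarely_significant(self, rng):
        mats = _paired_stack(rng, n_subjects=10, n_nodes=12)
        cfg = NBSConfig(primary_threshold_t=3.0, design="paired",
                        n_permutations=300, seed=2)
        res = nbs_test(mats, cfg)
        for comp in res.components:
            assert comp.p_fwer >= 1.0 / 301

    def test_exact_enumeration_for_small_n(self, rng):
        mats = _paired_stack(rng, n_subjects=6, n_nodes=8)
        cfg = NBSConfig(primary_threshold_t=2.5, design="paired",
                        n_permutations=500, seed=3)
        res = nbs_test(mats, cfg)
        assert res.exact
        assert res.n_permutations == 64  # 2^6 sign patterns
        for comp in res.components:
            assert comp.p_fwer >= 1.0 / 64

    def test_deterministic_given_seed(self, rng):
        mats = _paired_stack(rng, n_subjects=12, n_nodes=10)
        cfg = NBSConfig(primary_threshold_t=2.0, design="paired",
                        n_permutations=200, seed=7)
        r1 = nbs_test(mats, cfg)
        r2 = nbs_test(mats, cfg)
        assert [c.p_fwer for c in r1.components] == [c.p_fwer for c in r2.components]


class TestAlteredConnectionCounts:
    def _result(self, edges, n=6, p=0.01):
        from fcnet.nbs import NBSComponent

        comp = NBSComponent(edges=edges,
                            nodes=sorted({x for e in edges for x in e}),
                            size=len(edges), p_fwer=p)
        return NBSResult(components=[comp], t_matrix=np.zeros((n, n)),
                         region_labels=[f"r{i}" for i in range(n)],
                         alpha=0.05, n_permutations=100, exact=False)

    def test_triangle_component_counts(self):
        res = self._result([(0, 1), (1, 2), (2, 0)])
        counts = altered_connection_counts(res)
        assert counts == {"r0": 2, "r1": 2, "r2": 2}

    def test_star_component_hub_and_leaves(self):
        res = self._result([(0, i) for i in range(1, 6)])
        counts = altered_connection_counts(res)
        assert counts["r0"] == 5
        assert all(counts[f"r{i}"] == 1 for i in range(1, 6))

    def test_counts_sum_to_twice_edge_count(self, rng):
        edges = [(0, 1), (1, 2), (2, 3), (1, 3)]
        res = self._result(edges)
        assert sum(altered_connection_counts(res).values()) == 2 * len(edges)

    def test_no_significant_component_empty(self):
        res = self._result([(0, 1)], p=0.5)
        assert altered_connection_counts(res) == {}
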