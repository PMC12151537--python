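import filecmp

import numpy as np
import pytest

from fcpg import sim
from fcpg.barcode import MISSING


def single_type_params(depth, n_cells=1, n_sites=10_000, p_demeth=0.05, p_remeth=0.05, seed=0, coverage=1.0):
    return sim.SimParams(
        n_sites=n_sites,
        p_demeth=p_demeth,
        p_remeth=p_remeth,
        coverage_rate=coverage,
        seed=seed,
        type_schedule=(sim.TypeSpec("X", "excitatory", (depth, depth), n_cells, ("FC",)),),
    )


class TestClosedForms:
    def test_zero_divisions_fully_methylated(self):
        assert sim.expected_methylation(0, single_type_params(0)) == 1.0

    def test_symmetric_rates_stationary_half(self):
        assert sim.expected_methylation(500, single_type_params(0)) == pytest.approx(0.5, abs=1e-6)

    def test_pure_demethylation_decay(self):
        p = single_type_params(0, p_demeth=0.1, p_remeth=0.0)
        assert sim.expected_methylation(10, p) == pytest.approx(0.9**10)

    def test_sibling_pwd_first_order(self):
        # one division after the split from a methylated start: ~2*p_demeth
        p = single_type_params(0, p_demeth=0.01, p_remeth=0.01)
        assert sim.expected_pwd(1, 1, 0, p) == pytest.approx(2 * 0.01, rel=0.05)

    def test_expected_pwd_against_exhaustive_enumeration(self):
        """Independent oracle: enumerate all state paths for tiny depths."""
        p = single_type_params(0, p_demeth=0.3, p_remeth=0.1)
        T = np.array([[0.9, 0.1], [0.3, 0.7]])  # rows: from-state 0/1

        def brute(depth_a, depth_b, split):
            total = 0.0
            anc = {0: 0.0, 1: 1.0}  # root starts methylated
            for _ in range(split):
                anc = {
                    0: anc[0] * T[0, 0] + anc[1] * T[1, 0],
                    1: anc[0] * T[0, 1] + anc[1] * T[1, 1],
                }
            def leaf_dist(state, k):
                d = {0: 1.0 - state, 1: float(state)}
                for _ in range(k):
                    d = {
                        0: d[0] * T[0, 0] + d[1] * T[1, 0],
                        1: d[0] * T[0, 1] + d[1] * T[1, 1],
                    }
                return d
            for s in (0, 1):
                da = leaf_dist(s, depth_a - split)
                db = leaf_dist(s, depth_b - split)
                total += anc[s] * (da[0] * db[1] + da[1] * db[0])
            return total

        for (a, b, s) in [(1, 1, 0), (3, 2, 1), (4, 4, 4), (5, 2, 0)]:
            assert sim.expected_pwd(a, b, s, p) == pytest.approx(brute(a, b, s), abs=1e-12)

    def test_invalid_split_raises(self):
        with pytest.raises(ValueError):
            sim.expected_pwd(2, 3, 4, single_type_params(0))


class TestSimulate:
    def test_depth_zero_full_coverage_all_methylated(self):
        r = sim.simulate(single_type_params(0, n_cells=1, n_sites=100))
        assert (r.matrix.values == 1).all()
        assert r.matrix.mean_methylation[0] == 1.0

    @pytest.mark.parametrize(
        "p_demeth, p_remeth, k",
        [(0.1, 0.0, 10), (0.05, 0.05, 5), (0.02, 0.08, 20), (0.05, 0.05, 40)],
    )
    def test_mean_methylation_matches_closed_form(self, p_demeth, p_remeth, k):
        params = single_type_params(k, p_demeth=p_demeth, p_remeth=p_remeth, seed=k)
        r = sim.simulate(params)
        m = sim.expected_methylation(k, params)
        se = np.sqrt(m * (1 - m) / params.n_sites)
        assert abs(r.matrix.mean_methylation[0] - m) < 3 * max(se, 1e-4)

    def test_pairwise_pwd_matches_matrix_power_oracle(self):
        params = single_type_params(8, n_cells=6, n_sites=20_000, seed=12)
        r = sim.simulate(params)
        ids = list(r.matrix.cells.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                split = r.truth.divergence_depth(a, b)
                expected = sim.expected_pwd(8, 8, split, params)
                va = r.matrix.values[ids.index(a)]
                vb = r.matrix.values[ids.index(b)]
                observed = (va != vb).mean()
                se = np.sqrt(expected * (1 - expected) / params.n_sites)
                assert abs(observed - expected) < 3 * max(se, 1e-4)

    def test_coverage_masking_rate(self):
        r = sim.simulate(single_type_params(3, n_cells=4, n_sites=5000, coverage=0.2, seed=5))
        frac = (r.matrix.values != MISSING).mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_truth_consistency(self):
        r = sim.simulate(single_type_params(6, n_cells=10, n_sites=50, seed=2))
        for cid in r.truth.cells.index:
            assert len(r.truth.paths[cid]) == r.truth.cells.loc[cid, "exit_depth"] == 6
        assert r.truth.divergence_depth(*list(r.truth.cells.index[:2])) <= 6

    def test_schedule_beyond_tree_capacity_raises(self):
        with pytest.raises(ValueError, match="lineages"):
            sim.simulate(single_type_params(1, n_cells=3))

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        sim.make_fixture("tiny", seed=3, out_dir=tmp_path / "a")
        sim.make_fixture("tiny", seed=3, out_dir=tmp_path / "b")
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")

        def assert_same(c):
            assert not c.diff_files and not c.left_only and not c.right_only
            for sub in c.subdirs.values():
                assert_same(sub)

        assert_same(cmp)

    def test_newick_has_all_cells_as_leaves(self, tiny_result):
        from fcpg import phylo

        t = phylo.TreeResult(tiny_result.truth.newick("sim00"), {})
        tips = {x.name for x in t.tree.tips()}
        assert tips == set(tiny_result.truth.cells.index)


class TestFitFlipRates:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_generating_rates(self, seed):
        true = (0.05, 0.05)
        depths = [2, 4, 6, 8, 10, 13, 16, 20]
        params = sim.SimParams(
            n_sites=5000,
            p_demeth=true[0],
            p_remeth=true[1],
            coverage_rate=1.0,
            seed=seed,
            type_schedule=tuple(
                sim.TypeSpec(f"t{k}", "excitatory", (k, k), min(8, 2**k), ("FC",)) for k in depths
            ),
        )
        r = sim.simulate(params)
        per_type = r.matrix.cells.join(
            r.truth.cells[["exit_depth"]]
        ).assign(m=r.matrix.mean_methylation).groupby("exit_depth")["m"].mean()
        est = sim.fit_flip_rates(per_type.index.to_numpy(), per_type.to_numpy())
        assert est[0] == pytest.approx(true[0], rel=0.2)
        assert est[1] == pytest.approx(true[1], rel=0.2)

    def test_needs_two_depths(self):
        with pytest.raises(ValueError):
            sim.fit_flip_rates([3, 3], [0.5, 0.6])
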