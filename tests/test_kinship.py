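import math

import numpy as np
import pandas as pd
import pytest

from fcpg import distance, kinship, sim
from tests.conftest import random_matrix


def pair_result(pwds, n_shared=40, brains=None):
    n = len(pwds)
    pairs = pd.DataFrame(
        {
            "cell_a": [f"a{i}" for i in range(n)],
            "cell_b": [f"b{i}" for i in range(n)],
            "n_shared": n_shared,
            "n_mismatch": [int(round(p * n_shared)) for p in pwds],
            "pwd": pwds,
            "same_brain": brains if brains is not None else [True] * n,
        }
    )
    return distance.PairResult(pairs, n_pairs_total=n, n_qualifying=n, mean_pwd=float(np.mean(pwds)), mean_n_shared=n_shared)


class TestClosePairs:
    def test_rate_per_million_matches_reference_arithmetic(self):
        # 1385 close pairs among 197 million qualifying pairs -> 7.0 per million
        report = kinship.RelatedPairReport(0.05, 1385, 197_000_000, 197_000_000, 35.0)
        assert report.rate_per_million == pytest.approx(7.0, abs=0.05)

    def test_strict_threshold_and_counts(self):
        result = pair_result([0.0, 0.04, 0.05, 0.2])
        report, close = kinship.close_pairs(result, threshold=0.05)
        assert report.n_close == 2  # pwd == 0.05 is not "closely related"
        assert set(close["pwd"]) == {0.0, 0.04}
        assert report.rate_per_million == pytest.approx(1e6 * 2 / 4)

    def test_no_close_pairs_rate_zero(self):
        report, close = kinship.close_pairs(pair_result([0.3, 0.4]), threshold=0.05)
        assert report.n_close == 0 and report.rate_per_million == 0.0 and len(close) == 0

    def test_empty_pair_table_raises(self):
        empty = distance.PairResult(pd.DataFrame(), 0, 0, float("nan"), float("nan"))
        with pytest.raises(ValueError, match="empty"):
            kinship.close_pairs(empty)

    def test_threshold_monotonicity(self):
        result = pair_result(list(np.linspace(0, 0.5, 21)))
        n = [kinship.close_pairs(result, threshold=t)[0].n_close for t in (0.02, 0.05, 0.1, 0.3)]
        assert n == sorted(n)

    def test_sibling_cells_overrepresented_among_close_pairs(self):
        params = sim.SimParams(
            n_sites=3000,
            p_demeth=0.02,
            p_remeth=0.02,
            coverage_rate=1.0,
            seed=4,
            type_schedule=(sim.TypeSpec("X", "excitatory", (7, 7), 120, ("FC",)),),
        )
        r = sim.simulate(params)
        result = distance.all_pairs(r.matrix)
        report, close = kinship.close_pairs(result, threshold=0.05)
        assert report.n_close > 0
        div = [r.truth.divergence_depth(a, b) for a, b in zip(close["cell_a"], close["cell_b"])]
        all_div = np.mean(
            [
                r.truth.divergence_depth(a, b)
                for i, a in enumerate(r.matrix.cells.index)
                for b in r.matrix.cells.index[i + 1 :]
            ]
        )
        assert np.mean(div) > all_div  # close pairs share recent ancestry


class TestEnrichment:
    def test_reference_rates_give_about_three_fold(self):
        ratio, mean_w, mean_b = kinship.within_between_enrichment([7.0, 7.5, 14.8], [2.8, 3.7, 3.7])
        assert mean_w == pytest.approx(9.77, abs=0.01)
        assert mean_b == pytest.approx(3.4, abs=0.01)
        assert ratio == pytest.approx(2.87, abs=0.02)

    def test_identical_rates_ratio_one(self):
        ratio, *_ = kinship.within_between_enrichment([5.0, 5.0], [5.0])
        assert ratio == 1.0

    def test_zero_between_rate_returns_infinity(self):
        ratio, *_ = kinship.within_between_enrichment([5.0], [0.0])
        assert math.isinf(ratio)


def close_frame(rows):
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "n_shared", "n_mismatch", "pwd", "same_brain"])


def annotations(records):
    return pd.DataFrame(
        records, columns=["cell_id", "brain_id", "major_class", "subtype", "region"]
    ).set_index("cell_id")


class TestFidelity:
    def test_all_inhibitory_pairs_full_fidelity(self):
        ann = annotations([(f"c{i}", "B", "inhibitory", "Pvalb", "FC") for i in range(4)])
        pairs = close_frame([("c0", "c1", 40, 0, 0.0, True), ("c2", "c3", 40, 1, 0.025, True)])
        counts, pct = kinship.fidelity_matrix(pairs, ann, "major_class")
        assert counts.loc["inhibitory", "inhibitory"] == 2
        assert pct["inhibitory"] == 100.0

    def test_single_mixed_pair_zero_for_both(self):
        ann = annotations([("c0", "B", "inhibitory", "Pvalb", "FC"), ("c1", "B", "excitatory", "L2_3", "FC")])
        pairs = close_frame([("c0", "c1", 40, 0, 0.0, True)])
        counts, pct = kinship.fidelity_matrix(pairs, ann, "major_class")
        assert pct["inhibitory"] == 0.0 and pct["excitatory"] == 0.0
        assert counts.loc["inhibitory", "excitatory"] == 1
        assert counts.equals(counts.T)

    def test_unannotated_cell_raises(self):
        ann = annotations([("c0", "B", "inhibitory", "Pvalb", "FC")])
        pairs = close_frame([("c0", "zz", 40, 0, 0.0, True)])
        with pytest.raises(KeyError, match="unannotated"):
            kinship.fidelity_matrix(pairs, ann)

    def test_permuted_labels_converge_to_chance(self):
        rng = np.random.default_rng(3)
        cells = [f"c{i}" for i in range(40)]
        classes = ["inhibitory"] * 30 + ["excitatory"] * 10
        ann = annotations([(c, "B", k, "x", "FC") for c, k in zip(cells, classes)])
        picks = [rng.choice(40, 2, replace=False) for _ in range(60)]
        pairs = close_frame([(cells[i], cells[j], 40, 0, 0.0, True) for i, j in picks])
        null = kinship.permutation_fidelity_null(pairs, ann, "major_class", n_permutations=200, seed=0)
        # analytic chance level for the 3:1 label mix, pairs sampled uniformly:
        # P(both inhibitory)/P(>=1 inhibitory) = (0.75*29/39)/(1-0.25*10/39)
        p_both = 0.75 * 29 / 39
        p_any = 1 - 0.25 * 10 / 39
        assert null["inhibitory"].mean() == pytest.approx(100 * p_both / p_any, abs=4.0)


class TestLocationFidelity:
    def test_all_colocated_pairs_are_hundred_percent(self):
        ann = annotations([(f"c{i}", "B", "excitatory", "L2_3", "FC") for i in range(4)])
        pairs = close_frame([("c0", "c1", 40, 0, 0.0, True), ("c2", "c3", 40, 0, 0.0, True)])
        lf = kinship.location_fidelity(pairs, ann)
        assert lf["excitatory"] == 100.0

    def test_noncortical_pairs_excluded(self):
        ann = annotations(
            [("c0", "B", "inhibitory", "PN", "SC"), ("c1", "B", "inhibitory", "PN", "SC"),
             ("c2", "B", "inhibitory", "Pvalb", "FC"), ("c3", "B", "inhibitory", "Pvalb", "TC")]
        )
        pairs = close_frame([("c0", "c1", 40, 0, 0.0, True), ("c2", "c3", 40, 0, 0.0, True)])
        lf = kinship.location_fidelity(pairs, ann)
        assert lf["inhibitory"] == 0.0  # only the FC-TC cortical pair counts

    def test_radial_placement_beats_tangential(self):
        def percent_same(placement, seed):
            params = sim.SimParams(
                n_sites=3000,
                p_demeth=0.02,
                p_remeth=0.02,
                coverage_rate=1.0,
                seed=seed,
                type_schedule=(sim.TypeSpec("L4_6", "excitatory", (8, 8), 150, ("FC", "TC", "OC", "PC"), placement),),
            )
            r = sim.simulate(params)
            result = distance.all_pairs(r.matrix, store="close")
            _, close = kinship.close_pairs(result)
            return kinship.location_fidelity(close, r.matrix.cells).get("excitatory", 0.0)

        radial = np.mean([percent_same("inherit_region", s) for s in (0, 1, 2)])
        tangential = np.mean([percent_same("random_region", s) for s in (0, 1, 2)])
        assert radial > tangential
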