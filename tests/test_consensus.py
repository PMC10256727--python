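import numpy as np
import pandas as pd
import pytest

from refstab.consensus import (
    competition_ranks,
    passes_correlation_gate,
    ranks_from_ordering,
    reffinder_gm,
    select_pair,
)
from refstab.genorm import PairwiseVariationSeries
from refstab.published import (
    GENORM_FINAL_PAIR,
    PUBLISHED_GM,
    STABILITY_VALUES,
)

from conftest import make_ct


def published_ranks(stratum: str) -> dict[str, pd.Series]:
    sv = STABILITY_VALUES[stratum]
    return {
        "delta_ct": ranks_from_ordering(sv["delta_ct"]),
        "normfinder": ranks_from_ordering(sv["normfinder"]),
        "genorm": ranks_from_ordering(
            sv["genorm"], set(GENORM_FINAL_PAIR[stratum])
        ),
        "bestkeeper": ranks_from_ordering(sv["bestkeeper_sd"]),
    }


class TestCompetitionRanks:
    def test_strictly_ordered(self):
        s = pd.Series({"a": 0.68, "b": 0.74, "c": 0.78})
        assert competition_ranks(s, "asc").tolist() == [1, 2, 3]

    def test_ties_skip(self):
        s = pd.Series({"a": 5.0, "b": 5.0, "c": 7.0})
        assert competition_ranks(s, "asc").tolist() == [1, 1, 3]

    def test_descending_for_correlations(self):
        s = pd.Series({"a": 0.92, "b": 0.5, "c": 0.7})
        assert competition_ranks(s, "desc").tolist() == [1, 3, 2]

    def test_shared_rank_pair_forces_one_one_three(self):
        s = pd.Series({"a": 0.374, "b": 0.374, "c": 0.420, "d": 0.447})
        r = competition_ranks(s, "asc", shared_rank_pairs={"a", "b"})
        assert r.tolist() == [1, 1, 3, 4]


class TestRanksFromOrdering:
    def test_row_order_resolves_printed_ties(self):
        r = ranks_from_ordering([("x", 1.33), ("y", 1.33), ("z", 1.50)])
        assert r.tolist() == [1, 2, 3]

    def test_shared_pair_at_head(self):
        r = ranks_from_ordering(["x", "y", "z"], shared_rank_pairs={"x", "y"})
        assert r.tolist() == [1, 1, 3]


class TestReffinderGM:
    @pytest.mark.parametrize("stratum", ["head", "thorax_abdomen"])
    def test_reproduces_all_published_gm_values(self, stratum):
        cons = reffinder_gm(published_ranks(stratum))
        for gene, expected in PUBLISHED_GM[stratum].items():
            assert cons.table.loc[gene, "gm"] == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("stratum", ["head", "thorax_abdomen"])
    def test_published_order_recovered(self, stratum):
        cons = reffinder_gm(published_ranks(stratum))
        assert cons.top == "novel-m0649-3p"
        assert cons.order[-1] == "U6"

    def test_gm_bounds_and_unanimity(self):
        k = 4
        ranks = {
            m: pd.Series({f"g{i}": i + 1 for i in range(k)})
            for m in ("delta_ct", "normfinder", "genorm", "bestkeeper")
        }
        cons = reffinder_gm(ranks)
        assert cons.table["gm_exact"].between(1, k).all()
        assert cons.table.loc["g0", "gm"] == 1.0
        assert cons.table.loc[f"g{k-1}", "gm"] == float(k)

    def test_symmetric_in_methods(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(5)]
        vecs = [pd.Series(rng.permutation(5) + 1, index=genes) for _ in range(4)]
        methods = ("delta_ct", "normfinder", "genorm", "bestkeeper")
        gm1 = reffinder_gm(dict(zip(methods, vecs))).table["gm_exact"]
        gm2 = reffinder_gm(dict(zip(methods, vecs[::-1]))).table["gm_exact"]
        pd.testing.assert_series_equal(gm1.sort_index(), gm2.sort_index())

    def test_mismatched_gene_sets_error(self):
        ranks = {
            "delta_ct": pd.Series({"a": 1, "b": 2}),
            "normfinder": pd.Series({"a": 1, "b": 2}),
            "genorm": pd.Series({"a": 1, "b": 2}),
            "bestkeeper": pd.Series({"a": 1, "c": 2}),
        }
        with pytest.raises(ValueError, match="different gene sets"):
            reffinder_gm(ranks)


class TestCorrelationGate:
    def test_strict_threshold(self):
        assert passes_correlation_gate(0.899)
        assert not passes_correlation_gate(0.93)
        assert not passes_correlation_gate(0.9)  # boundary: strict <

    def test_sign_insensitive(self):
        assert not passes_correlation_gate(-0.95)
        assert passes_correlation_gate(-0.5)


def _correlated(x, r, rng):
    """A vector with exact Pearson correlation r to x."""
    z = rng.normal(size=x.size)
    x_std = (x - x.mean()) / x.std()
    z = z - z.mean() - np.dot(z - z.mean(), x_std) / np.dot(x_std, x_std) * x_std
    z /= z.std()
    return 25 + r * x_std + np.sqrt(1 - r**2) * z


class TestSelectPair:
    @staticmethod
    def _setup(r_second, r_third):
        rng = np.random.default_rng(42)
        x = rng.normal(25, 1, 20)
        mat = make_ct(
            {
                "P": x.tolist(),
                "B": _correlated(x, r_second, rng).tolist(),
                "C": _correlated(x, r_third, rng).tolist(),
            },
            days=[f"d{i % 5}" for i in range(20)],
        )
        ranks = {
            m: pd.Series({"P": 1, "B": 2, "C": 3})
            for m in ("delta_ct", "normfinder", "genorm", "bestkeeper")
        }
        return mat, reffinder_gm(ranks)

    def test_partner_accepted_below_threshold(self):
        mat, cons = self._setup(0.76, 0.5)
        plan = select_pair(mat, cons)
        assert plan.primary_ref == "P" and plan.partner_ref == "B"
        assert plan.partner_r == pytest.approx(0.76, abs=1e-9)
        assert plan.rejected == []

    def test_highly_correlated_partner_skipped(self):
        mat, cons = self._setup(0.93, 0.899)
        plan = select_pair(mat, cons)
        assert plan.partner_ref == "C"
        assert plan.partner_r == pytest.approx(0.899, abs=1e-9)
        assert plan.rejected[0][0] == "B"
        assert plan.rejected[0][1] == pytest.approx(0.93, abs=1e-9)

    def test_all_rejected_gives_single_reference_plan(self):
        mat, cons = self._setup(0.95, 0.92)
        plan = select_pair(mat, cons)
        assert plan.partner_ref is None and plan.partner_r is None
        assert {g for g, _ in plan.rejected} == {"B", "C"}
        assert plan.references == ["P"]

    def test_recommendation_capped_for_practicality(self):
        mat, cons = self._setup(0.76, 0.5)
        vs = PairwiseVariationSeries(
            v={2: 0.21, 3: 0.18, 4: 0.16, 5: 0.149}, threshold=0.15, recommended_n=5
        )
        plan = select_pair(mat, cons, vs, max_refs=2)
        assert plan.recommended_n == 5 and plan.capped_n == 2
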