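"""Hypergeometric overlap machinery checked against exhaustive enumeration,
plus set intersection, enrichment panels and DAM-signature assembly."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from npsle import (
    GeneSet,
    assemble_dam_signature,
    common_background,
    compute_overlap,
    enrichment_panel,
    hypergeom_tail,
    intersect_signature,
    random_set_enrichment,
)


def enum_tails(N, K, n):
    """Exact tail probabilities by enumerating all C(N, n) draws.

    Marked items are {0..K-1}; returns {k: (P(X>=k), P(X<=k))} as Fractions.
    """
    counts = {}
    total = 0
    for subset in combinations(range(N), n):
        k = sum(1 for x in subset if x < K)
        counts[k] = counts.get(k, 0) + 1
        total += 1
    support = sorted(counts)
    out = {}
    for k in support:
        over = Fraction(sum(c for kk, c in counts.items() if kk >= k), total)
        under = Fraction(sum(c for kk, c in counts.items() if kk <= k), total)
        out[k] = (over, under)
    return out


class TestHypergeomTail:
    def test_k_zero_upper_tail_is_one(self):
        assert hypergeom_tail(100, 10, 10, 0, "over") == pytest.approx(1.0)

    def test_exact_small_case(self):
        # all 210 draws enumerated by hand: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_tail(10, 5, 4, 4, "over") == pytest.approx(5 / 210)

    def test_forced_full_overlap(self):
        assert hypergeom_tail(50, 50, 7, 7, "over") == pytest.approx(1.0)

    def test_matches_enumeration_spot(self):
        for N, K, n in [(8, 3, 4), (12, 6, 5), (9, 9, 3), (7, 0, 4)]:
            tails = enum_tails(N, K, n)
            for k, (over, under) in tails.items():
                assert hypergeom_tail(N, K, n, k, "over") == pytest.approx(
                    float(over), abs=1e-12
                )
                assert hypergeom_tail(N, K, n, k, "under") == pytest.approx(
                    float(under), abs=1e-12
                )

    def test_matches_scipy_at_study_scale(self):
        # cross-check at the scale of a ~7000-gene background
        N, K, n = 7076, 256, 214
        for k in (0, 5, 8, 18, 30):
            assert hypergeom_tail(N, K, n, k, "over") == pytest.approx(
                float(stats.hypergeom.sf(k - 1, N, K, n)), rel=1e-9
            )

    @given(
        st.integers(1, 60).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        )
    )
    def test_tail_complement(self, params):
        N, K, n = params
        lo, hi = max(0, K + n - N), min(K, n)
        for k in range(lo + 1, hi + 1):
            total = hypergeom_tail(N, K, n, k, "over") + hypergeom_tail(
                N, K, n, k - 1, "under"
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 4, 5, "over")
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 4, 2, "over")


class TestCommonBackground:
    def test_identical_and_disjoint(self):
        a = [f"g{i}" for i in range(10)]
        assert common_background(a, a) == frozenset(x.lower() for x in a)
        with pytest.raises(ValueError):
            common_background(["a", "b"], ["c", "d"])

    def test_planted_shared_core(self, rng):
        core = [f"core{i}" for i in range(300)]
        a = core + [f"onlyA{i}" for i in range(500)]
        b = core + [f"onlyB{i}" for i in range(700)]
        assert common_background(a, b) == frozenset(x.lower() for x in core)

    def test_case_insensitive_matching(self):
        assert common_background(["ApoE", "Trem2"], ["APOE", "Cd9"]) == {"apoe"}


class TestIntersectSignature:
    def _sets(self, a_members, b_members, background):
        return (
            GeneSet.from_lists("A", a_members, background),
            GeneSet.from_lists("B", b_members, background),
        )

    def test_subset_recovers_smaller_set(self):
        bg = [f"g{i}" for i in range(50)]
        a, b = self._sets(bg[:5], bg[:20], bg)
        sig, res = intersect_signature(a, b)
        assert sig.members == a.members and res.k == 5

    def test_disjoint_sets(self):
        bg = [f"g{i}" for i in range(30)]
        a, b = self._sets(bg[:5], bg[10:15], bg)
        sig, res = intersect_signature(a, b)
        assert len(sig) == 0 and res.enrichment == 0.0
        assert res.p_over == pytest.approx(1.0)

    def test_planted_core_recovered_and_symmetric(self):
        bg = [f"g{i}" for i in range(200)]
        core = bg[:18]
        a, b = self._sets(core + bg[50:80], core + bg[100:140], bg)
        sig_ab, res_ab = intersect_signature(a, b)
        sig_ba, res_ba = intersect_signature(b, a)
        assert sig_ab.members == frozenset(core) == sig_ba.members
        assert res_ab.p_over == pytest.approx(res_ba.p_over)

    def test_restriction_to_common_background(self):
        a = GeneSet.from_lists("A", ["g1", "g2"], ["g1", "g2", "g3"])
        b = GeneSet.from_lists("B", ["g2", "g4"], ["g2", "g3", "g4"])
        sig, res = intersect_signature(a, b)
        # only g2, g3 are shared background; g1/g4 members drop out
        assert res.N == 2 and sig.members == {"g2"}


class TestEnrichmentPanel:
    def test_chance_level_mean_one(self, rng):
        enr = random_set_enrichment(400, 40, 60, 4000, rng)
        se = enr.std(ddof=1) / np.sqrt(len(enr))
        assert abs(enr.mean() - 1.0) < 3 * se + 1e-9

    def test_forced_and_arithmetic(self):
        bg = [f"g{i}" for i in range(100)]
        ref = GeneSet.from_lists("ref", bg[:20], bg)
        up = GeneSet.from_lists("up", bg[:20], bg)
        res = compute_overlap(up, ref)
        assert res.enrichment == pytest.approx(res.k / (res.K * res.n / res.N))
        # N=100, K=10, n=20, k=4 -> expected 2, enrichment 2
        r2 = compute_overlap(
            GeneSet.from_lists("a", bg[:10], bg),
            GeneSet.from_lists("b", bg[6:26], bg),
        )
        assert (r2.K, r2.n, r2.k) == (10, 20, 4)
        assert r2.expected == pytest.approx(2.0) and r2.enrichment == pytest.approx(2.0)

    def test_panel_shape_and_updown_conflict(self):
        bg = [f"g{i}" for i in range(60)]
        up = GeneSet.from_lists("up", bg[:10], bg)
        down = GeneSet.from_lists("down", bg[10:20], bg)
        over = GeneSet.from_lists("over", bg[5:15], bg)
        under = GeneSet.from_lists("under", bg[40:50], bg)
        panel = enrichment_panel(up, down, over, under, bg)
        assert set(panel) == {("up", "over"), ("up", "under"), ("down", "over"), ("down", "under")}
        assert panel[("up", "over")].k == 5
        bad_down = GeneSet.from_lists("down", bg[5:15], bg)
        with pytest.raises(ValueError):
            enrichment_panel(up, bad_down, over, under, bg)


class TestDamSignature:
    def _de_table(self, genes, sig_genes, direction="up"):
        return pd.DataFrame(
            {
                "significant": [g in sig_genes for g in genes],
                "direction": [direction] * len(genes),
            },
            index=genes,
        )

    def test_empty_and_full(self):
        bg = [f"g{i}" for i in range(30)]
        dam = GeneSet.from_lists("DAM", bg[:10], bg)
        none = self._de_table(bg, set())
        sig, prov = assemble_dam_signature(dam, {"m1": none, "m2": none})
        assert len(sig) == 0 and prov.empty
        allsig = self._de_table(bg, set(bg))
        sig2, _ = assemble_dam_signature(dam, {"m1": allsig, "m2": none})
        assert sig2.members == dam.members

    def test_union_with_provenance_15_genes(self):
        """9 DAM genes differential only in model 1 and 6 only in model 2
        combine into a 15-gene signature with per-model direction labels."""
        bg = [f"g{i}" for i in range(40)]
        dam = GeneSet.from_lists("DAM", bg[:20], bg)
        m1 = self._de_table(bg, set(bg[:9]), "up")
        m2 = self._de_table(bg, set(bg[9:15]), "down")
        sig, prov = assemble_dam_signature(dam, {"m1": m1, "m2": m2})
        assert len(sig) == 15
        assert prov.set_index("gene").loc["g0", "m1"] == "up"
        assert pd.isna(prov.set_index("gene").loc["g0", "m2"])
        assert prov.set_index("gene").loc["g10", "m2"] == "down"
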