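import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancodon import codon_usage as cu
from pancodon.codon_model import STANDARD_CODE

from conftest import make_record


def brute_force_enc(codon_counts):
    """Independent ENC oracle: literal transcription of Wright's estimator,
    written against the raw family lists rather than the library helpers."""
    fams = {
        aa: codons
        for aa, codons in STANDARD_CODE.families.items()
        if len(codons) > 1
    }
    f_values = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in fams.items():
        ns = [codon_counts.get(c, 0) for c in codons]
        m = sum(ns)
        if m < 2:
            continue
        s = sum((n / m) ** 2 for n in ns)
        f_values[len(codons)].append((m * s - 1) / (m - 1))
    fbar = {k: sum(v) / len(v) for k, v in f_values.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(k not in fbar for k in (2, 3, 4, 6)):
        return float("nan")
    if any(fbar[k] <= 0 for k in (2, 3, 4, 6)):
        return 61.0
    val = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(61.0, max(20.0, val))


def brute_force_spearman_r(x, y):
    """Rank-correlation oracle: average ranks computed by hand, then the
    Pearson product-moment formula on the ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestRscu:
    def test_uniform_family_is_one(self):
        out = cu.rscu({"TTT": 5, "TTC": 5})
        assert out["TTT"] == pytest.approx(1.0)
        assert out["TTC"] == pytest.approx(1.0)

    def test_maximal_bias_twofold(self):
        out = cu.rscu({"TTT": 10, "TTC": 0})
        assert out["TTT"] == pytest.approx(2.0)
        assert out["TTC"] == pytest.approx(0.0)

    def test_fourfold_hand_oracle(self):
        out = cu.rscu({"GCT": 6, "GCC": 2, "GCA": 1, "GCG": 1})
        assert [out[c] for c in ("GCT", "GCC", "GCA", "GCG")] == pytest.approx(
            [2.4, 0.8, 0.4, 0.4]
        )

    def test_absent_family_and_onefold_excluded(self):
        out = cu.rscu({"ATG": 3, "TTT": 1})
        assert "ATG" not in out
        assert "GCT" not in out
        assert out["TTT"] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(sorted(STANDARD_CODE.sense_codons)),
            st.integers(0, 50),
            min_size=1,
        )
    )
    def test_family_sums_equal_family_size(self, counts):
        out = cu.rscu(counts)
        for aa in STANDARD_CODE.degenerate_amino_acids():
            fam = STANDARD_CODE.families[aa]
            if any(c in out for c in fam):
                assert sum(out[c] for c in fam) == pytest.approx(len(fam))


class TestDeltaRscu:
    def _matrix(self, per_gene_rscu):
        return pd.DataFrame(per_gene_rscu).T

    def test_identical_classes_give_zero_and_ns(self):
        genes = [
            cu.rscu({"TTT": 3, "TTC": 1, "GCT": 2, "GCC": 2}),
            cu.rscu({"TTT": 1, "TTC": 3, "GCT": 1, "GCC": 0}),
        ]
        m = self._matrix({f"g{i}": g for i, g in enumerate(genes)})
        tab = cu.delta_rscu(m, m.copy(), min_genes=1)
        defined = tab["delta"].dropna()
        assert (defined == 0).all()
        assert (tab.loc[defined.index, "tier"] == "ns").all()

    def test_constant_shift_welch_oracle(self):
        high = self._matrix({f"h{i}": {"TTT": 2.0, "TTC": 0.0} for i in range(3)})
        low = self._matrix({f"l{i}": {"TTT": 0.0, "TTC": 2.0} for i in range(3)})
        tab = cu.delta_rscu(high, low, min_genes=1)
        assert tab.loc["TTT", "delta"] == pytest.approx(2.0)
        assert tab.loc["TTT", "p"] == pytest.approx(0.0)
        assert tab.loc["TTT", "tier"] == "strong"

    def test_swapped_classes_negate_deltas_and_keep_p(self, gryllus_report,
                                                      gryllus_records, gryllus_sim):
        from pancodon import expression

        gm = gryllus_report.gene_metrics
        hi = gm.index[gm["expr_class"] == "high"]
        lo = gm.index[gm["expr_class"] == "low"]
        mat = cu.rscu_matrix(gryllus_records)
        fwd = cu.delta_rscu(mat.loc[hi], mat.loc[lo])
        rev = cu.delta_rscu(mat.loc[lo], mat.loc[hi])
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_low_support_flagged(self):
        high = self._matrix({"h0": {"TGT": 2.0, "TGC": 0.0}})
        low = self._matrix({"l0": {"TGT": 0.0, "TGC": 2.0}})
        tab = cu.delta_rscu(high, low, min_genes=10)
        assert tab.loc["TGT", "low_support"]
        # codon with zero contributing genes anywhere: no crash, just NaN
        assert np.isnan(tab.loc["GCT", "delta"])


class TestSelectOptimal:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("codon")

    def test_pro_tie_break_prefers_better_tier(self):
        tab = self._table(
            [
                {"codon": "CCT", "aa": "P", "delta": 0.158, "tier": "putative", "p": 0.07},
                {"codon": "CCA", "aa": "P", "delta": 0.139, "tier": "significant", "p": 0.01},
                {"codon": "CCC", "aa": "P", "delta": -0.190, "tier": "strong", "p": 1e-4},
                {"codon": "CCG", "aa": "P", "delta": -0.038, "tier": "ns", "p": 0.5},
            ]
        )
        sel = cu.select_optimal_codons(tab)
        assert sel.loc["CCA", "is_primary"]
        assert sel.loc["CCT", "is_optimal"] and not sel.loc["CCT", "is_primary"]

    def test_all_negative_yields_no_optimal(self):
        tab = self._table(
            [
                {"codon": "GAT", "aa": "D", "delta": -0.1, "tier": "strong", "p": 1e-5},
                {"codon": "GAC", "aa": "D", "delta": -0.2, "tier": "ns", "p": 0.9},
            ]
        )
        sel = cu.select_optimal_codons(tab)
        assert not sel["is_optimal"].any()
        assert not sel["is_primary"].any()

    def test_same_tier_largest_delta_wins(self):
        tab = self._table(
            [
                {"codon": "GGT", "aa": "G", "delta": 0.30, "tier": "strong", "p": 1e-5},
                {"codon": "GGA", "aa": "G", "delta": 0.10, "tier": "strong", "p": 1e-6},
            ]
        )
        sel = cu.select_optimal_codons(tab)
        assert sel.loc["GGT", "is_primary"]

    def test_candidate_override_promotes_ns_codon(self):
        tab = self._table(
            [
                {"codon": "TTT", "aa": "F", "delta": 0.062, "tier": "ns", "p": 0.12},
                {"codon": "TTC", "aa": "F", "delta": -0.015, "tier": "ns", "p": 0.6},
            ]
        )
        sel = cu.select_optimal_codons(tab, candidate_overrides=["TTT"])
        assert sel.loc["TTT", "tier"] == "candidate"
        assert sel.loc["TTT", "is_primary"]

    def test_at_most_one_primary_per_amino_acid(self, gryllus_report):
        tab = gryllus_report.delta_rscu
        per_aa = tab[tab["is_primary"]].groupby("aa").size()
        assert (per_aa == 1).all()
        # every primary has positive delta and a non-ns tier
        prim = tab[tab["is_primary"]]
        assert (prim["delta"] > 0).all()
        assert (prim["tier"] != "ns").all()


class TestFop:
    def test_all_optimal(self):
        rec = make_record("ATG" + "GCT" * 5 + "TAA")
        assert cu.fop(rec.codon_counts, {"GCT"}) == pytest.approx(1.0)

    def test_none_optimal_but_eligible(self):
        rec = make_record("ATG" + "GCC" * 5 + "TAA")
        assert cu.fop(rec.codon_counts, {"GCT"}) == pytest.approx(0.0)

    def test_counting_oracle(self):
        # 6 optimal (GCT) of 10 eligible (Ala) codons, plus Met/Trp ignored
        seq = "ATG" + "GCT" * 6 + "GCC" * 4 + "TGG" * 2 + "TAA"
        rec = make_record(seq)
        assert cu.fop(rec.codon_counts, {"GCT"}) == pytest.approx(0.6)

    def test_met_trp_invariance(self):
        base = make_record("ATG" + "GCT" * 3 + "GCC" * 2 + "TAA")
        padded = make_record("ATG" + "ATG" * 7 + "GCT" * 3 + "GCC" * 2 + "TAA")
        opt = {"GCT"}
        assert cu.fop(base.codon_counts, opt) == pytest.approx(
            cu.fop(padded.codon_counts, opt)
        )

    def test_no_eligible_codons_is_nan(self):
        rec = make_record("ATGTGGTAA")
        assert math.isnan(cu.fop(rec.codon_counts, {"GCT"}))

    def test_empty_optimal_set_rejected(self):
        rec = make_record("ATGGCTTAA")
        with pytest.raises(ValueError):
            cu.fop(rec.codon_counts, set())


class TestEnc:
    def test_single_codon_per_amino_acid_scores_20(self):
        counts = {
            STANDARD_CODE.families[aa][0]: 5 for aa in STANDARD_CODE.amino_acids
        }
        assert cu.enc(counts) == pytest.approx(20.0)

    def test_uniform_usage_scores_61(self):
        counts = {
            c: 3
            for aa in STANDARD_CODE.amino_acids
            for c in STANDARD_CODE.families[aa]
        }
        assert cu.enc(counts) == pytest.approx(61.0)

    def test_matches_brute_force_oracle_on_random_genes(self):
        rng = np.random.default_rng(11)
        sense = sorted(STANDARD_CODE.sense_codons)
        for _ in range(50):
            picks = rng.choice(len(sense), size=200)
            counts = {}
            for i in picks:
                counts[sense[i]] = counts.get(sense[i], 0) + 1
            got = cu.enc(counts)
            want = brute_force_enc(counts)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        sense = sorted(STANDARD_CODE.sense_codons)
        counts = {}
        for i in rng.choice(len(sense), size=3000):
            counts[sense[i]] = counts.get(sense[i], 0) + 1
        doubled = {c: 2 * n for c, n in counts.items()}
        # doubling counts keeps proportions; at large m the F estimates and
        # hence ENC are nearly unchanged
        assert cu.enc(doubled) == pytest.approx(cu.enc(counts), abs=0.5)

    def test_ile_imputation_used_when_absent(self):
        counts = {
            c: 4
            for aa in STANDARD_CODE.amino_acids
            if aa != "I"
            for c in STANDARD_CODE.families[aa]
        }
        assert not math.isnan(cu.enc(counts))

    def test_sparse_gene_undefined(self):
        assert math.isnan(cu.enc({"TTT": 1}))

    def test_concentrating_mass_lowers_enc(self):
        uniform = {
            c: 6
            for aa in STANDARD_CODE.amino_acids
            for c in STANDARD_CODE.families[aa]
        }
        biased = dict(uniform)
        for aa in ("A", "G", "P"):
            fam = STANDARD_CODE.families[aa]
            biased[fam[0]] = 20
            for c in fam[1:]:
                biased[c] = 1
        assert cu.enc(biased) < cu.enc(uniform)


class TestGc3:
    def test_all_c_ending(self):
        assert cu.gc3({"GCC": 4, "TTC": 2}) == pytest.approx(1.0)

    def test_half_and_half(self):
        assert cu.gc3({"GCT": 1, "GCC": 1}) == pytest.approx(0.5)

    def test_gc3_plus_at3_is_one(self):
        counts = {"GCT": 3, "GCC": 1, "TTA": 2, "CAG": 4}
        assert cu.gc3(counts) + cu.at3(counts) == pytest.approx(1.0)

    def test_nondegenerate_excluded_by_default(self):
        # ATG and TGG both end in G, so including them raises GC3
        counts = {"ATG": 10, "TGG": 10, "GCT": 1}
        assert cu.gc3(counts) == pytest.approx(0.0)
        assert cu.gc3(counts, include_nondegenerate=True) == pytest.approx(20 / 21)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert cu.spearman(x, x)[0] == pytest.approx(1.0)
        assert cu.spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0]
        y = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        r, p = cu.spearman(x, y)
        assert r == pytest.approx(brute_force_spearman_r(x, y))
        assert 0.0 < p <= 1.0

    def test_constant_vector_flagged(self):
        r, p = cu.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)


class TestMeanAbsDelta:
    def test_zero_table(self):
        codons = [
            c
            for aa in STANDARD_CODE.degenerate_amino_acids()
            for c in STANDARD_CODE.families[aa]
        ]
        tab = pd.DataFrame({"delta": 0.0}, index=pd.Index(codons, name="codon"))
        mean, se = cu.mean_abs_delta(tab)
        assert mean == 0.0 and se == 0.0

    def test_missing_codons_listed(self):
        tab = pd.DataFrame(
            {"delta": [0.1]}, index=pd.Index(["GCT"], name="codon")
        )
        with pytest.raises(ValueError, match="GCC"):
            cu.mean_abs_delta(tab)


class TestCompareDistributions:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, p = cu.compare_distributions(a, list(a), method="t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        u, p = cu.compare_distributions(a, list(a), method="mwu")
        assert u == pytest.approx(len(a) * len(a) / 2)  # null mean of U

    def test_disjoint_support_extreme_u(self):
        a = list(range(20))
        b = [x + 100 for x in a]
        u, p = cu.compare_distributions(a, b, method="mwu")
        assert u in (0.0, 400.0)
        assert p < 1e-6

    def test_welch_textbook_oracle(self):
        a = [2.1, 2.5, 2.3, 2.7]
        b = [1.1, 1.0, 1.4, 1.2, 1.3]
        t, p = cu.compare_distributions(a, b, method="t")
        # hand-computed Welch statistic
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t_hand = (ma - mb) / math.sqrt(va / len(a) + vb / len(b))
        assert t == pytest.approx(t_hand)
        assert p < 0.01
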