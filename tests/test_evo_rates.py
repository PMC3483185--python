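import itertools
import math

import numpy as np
import pytest

from tissuecodon.codon_core import CodingSequence, GeneticCode, validate_cds
from tissuecodon.evo_rates import (
    CodonAlignment,
    align_proteins_global,
    group_contrast,
    ng86_pair,
    ng86_sites,
    thread_codons,
)
from tissuecodon.synthetic_data import apply_substitutions


# ------------------------------------------------------------- alignment


class TestAlignment:
    def test_identical_sequences_gap_free(self):
        a, b = align_proteins_global("MKVLW", "MKVLW")
        assert a == b == "MKVLW"

    def test_single_gap(self):
        a, b = align_proteins_global("MKV", "MV")
        assert a == "MKV" and b == "M-V"

    def test_score_matches_exhaustive_oracle_short_pairs(self):
        # brute-force optimal score by enumerating all global alignments
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        gap_open, gap_extend = 4.0, 1.0

        def brute(a, b):
            best = -math.inf

            def rec(i, j, score, last):
                nonlocal best
                if i == len(a) and j == len(b):
                    best = max(best, score)
                    return
                if i < len(a) and j < len(b):
                    rec(i + 1, j + 1, score + blosum[a[i], b[j]], "m")
                if i < len(a):
                    pen = gap_extend if last == "a" else gap_open
                    rec(i + 1, j, score - pen, "a")
                if j < len(b):
                    pen = gap_extend if last == "b" else gap_open
                    rec(i, j + 1, score - pen, "b")

            rec(0, 0, 0.0, None)
            return best

        def score_of(ga, gb):
            s, last = 0.0, None
            for x, y in zip(ga, gb):
                if x == "-":
                    s -= gap_extend if last == "b" else gap_open
                    last = "b"
                elif y == "-":
                    s -= gap_extend if last == "a" else gap_open
                    last = "a"
                else:
                    s += blosum[x, y]
                    last = "m"
            return s

        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            a = "".join(rng.choice(aas, size=int(rng.integers(2, 6))))
            b = "".join(rng.choice(aas, size=int(rng.integers(2, 6))))
            ga, gb = align_proteins_global(a, b, gap_open, gap_extend)
            assert score_of(ga, gb) == pytest.approx(brute(a, b))

    def test_rejects_bad_symbols_and_empty(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_proteins_global("MKX1", "MK")
        with pytest.raises(ValueError, match="empty"):
            align_proteins_global("", "MK")


class TestThreadCodons:
    def test_gap_free_keeps_all_codons(self, code):
        a = CodingSequence("a", "ATGAAATTT")
        b = CodingSequence("b", "ATGAAGTTC")
        aln = align_proteins_global(a.translate(code), b.translate(code))
        caln = thread_codons(aln, a, b, code)
        assert caln.codons_a == ["ATG", "AAA", "TTT"]
        assert caln.codons_b == ["ATG", "AAG", "TTC"]

    def test_gap_column_dropped(self, code):
        a = CodingSequence("a", "ATGAAAGTT")  # M K V
        b = CodingSequence("b", "ATGGTT")  # M V
        aln = align_proteins_global(a.translate(code), b.translate(code))
        caln = thread_codons(aln, a, b, code)
        assert len(caln) == 2
        assert caln.codons_a == ["ATG", "GTT"]

    def test_translation_consistency_and_length_check(self, code):
        a = CodingSequence("a", "ATGAAA")
        b = CodingSequence("b", "ATGAAGTTT")
        with pytest.raises(ValueError, match="does not match CDS"):
            thread_codons(("MK", "MK"), a, b, code)


# ------------------------------------------------------------------ NG86


def sites_oracle(codon, code):
    """Independent enumeration of synonymous site fractions."""
    s = 0.0
    aa = code.codon_to_aa[codon]
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        sense = [m for m in muts if code.codon_to_aa[m] != "*"]
        if sense:
            s += sum(code.codon_to_aa[m] == aa for m in sense) / len(sense)
    return s, 3 - s


def pathway_oracle(ca, cb, code):
    """Average syn/nonsyn steps over stop-free orders of the differences."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNg86Sites:
    @pytest.mark.parametrize(
        "codon,s", [("TTT", 1 / 3), ("GCT", 1.0), ("ATG", 0.0)]
    )
    def test_hand_enumeration(self, code, codon, s):
        got_s, got_n = ng86_sites(codon, code)
        assert got_s == pytest.approx(s)
        assert got_s + got_n == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self, code):
        for codon in code.sense_codons:
            got = ng86_sites(codon, code)
            want = sites_oracle(codon, code)
            assert got == pytest.approx(want, abs=1e-12)

    def test_stop_codon_rejected(self, code):
        with pytest.raises(ValueError):
            ng86_sites("TAA", code)


class TestNg86Pair:
    def test_identical_sequences(self, code):
        aln = CodonAlignment("p", ["ATG", "GCT"], ["ATG", "GCT"])
        r = ng86_pair(aln, code)
        assert r.dS == 0.0 and r.dN == 0.0 and r.Sd == 0.0 and r.Nd == 0.0

    def test_worked_example_phe(self, code):
        aln = CodonAlignment("p", ["TTT"] * 10, ["TTT"] * 9 + ["TTC"])
        r = ng86_pair(aln, code)
        assert r.S == pytest.approx(10 / 3)
        assert r.Sd == pytest.approx(1.0)
        assert r.pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(-0.75 * math.log(0.6))
        assert r.dS == pytest.approx(0.3831, abs=1e-4)
        assert r.dN == 0.0

    def test_all_codon_pairs_match_pathway_oracle(self, code):
        # conservation too: Sd + Nd equals the pathway-averaged number of
        # observed differences for every sense-codon pair
        for ca in code.sense_codons[::5]:
            for cb in code.sense_codons[::5]:
                want = pathway_oracle(ca, cb, code)
                aln = CodonAlignment("p", [ca], [cb])
                if want is None:
                    with pytest.warns(UserWarning, match="no stop-free"):
                        with pytest.raises(ValueError):
                            ng86_pair(aln, code)
                    continue
                r = ng86_pair(aln, code)
                assert (r.Sd, r.Nd) == pytest.approx(want, abs=1e-12)
                ndiff = sum(a != b for a, b in zip(ca, cb))
                assert r.Sd + r.Nd == pytest.approx(ndiff)

    def test_site_conservation_and_symmetry(self, code):
        rng = np.random.default_rng(1)
        codons = list(code.sense_codons)
        for _ in range(20):
            L = int(rng.integers(3, 30))
            a = [codons[i] for i in rng.integers(0, 61, size=L)]
            b = [codons[i] for i in rng.integers(0, 61, size=L)]
            pairs_ok = all(
                pathway_oracle(x, y, code) is not None for x, y in zip(a, b)
            )
            if not pairs_ok:
                continue
            r_ab = ng86_pair(CodonAlignment("p", a, b), code)
            r_ba = ng86_pair(CodonAlignment("p", b, a), code)
            assert r_ab.S + r_ab.N == pytest.approx(3 * L, abs=1e-9)
            assert (r_ab.S, r_ab.Sd) == pytest.approx((r_ba.S, r_ba.Sd))
            assert (r_ab.N, r_ab.Nd) == pytest.approx((r_ba.N, r_ba.Nd))

    def test_saturation_undefined(self, code):
        # Leu CTT against Lys AAA at every column: huge pN
        aln = CodonAlignment("p", ["CTT"] * 30, ["AAA"] * 30)
        r = ng86_pair(aln, code)
        assert math.isnan(r.dN) or r.dN > 0  # saturation flagged as NaN
        if math.isnan(r.dN):
            assert r.saturated


class TestSynonymousOnlyEvolution:
    def test_dn_zero_and_ds_monotone(self, code):
        rng = np.random.default_rng(7)
        base = "".join(
            rng.choice(
                [c for c in code.sense_codons if code.codon_to_aa[c] not in "MW"],
                size=120,
            )
        )
        prev_ds = -1.0
        for k in (0, 10, 25, 45):
            ds_vals = []
            for rep in range(5):
                rep_rng = np.random.default_rng([7, k, rep])
                derived = apply_substitutions(base, k, 0, code, rep_rng)
                aln = CodonAlignment(
                    "p",
                    [base[i : i + 3] for i in range(0, len(base), 3)],
                    [derived[i : i + 3] for i in range(0, len(derived), 3)],
                )
                r = ng86_pair(aln, code)
                assert r.dN == 0.0
                ds_vals.append(r.dS)
            ds = float(np.mean(ds_vals))
            assert ds > prev_ds or (k == 0 and ds == 0.0)
            prev_ds = ds


class TestGroupContrast:
    def _rates(self, code, k_pairs, k_syn, k_non, tag, seed):
        rng = np.random.default_rng(seed)
        codons = [c for c in code.sense_codons if code.codon_to_aa[c] not in "MW"]
        out = []
        for i in range(k_pairs):
            base = "".join(rng.choice(codons, size=100))
            der = apply_substitutions(base, k_syn, k_non, code, rng)
            aln = CodonAlignment(
                f"{tag}{i}",
                [base[j : j + 3] for j in range(0, len(base), 3)],
                [der[j : j + 3] for j in range(0, len(der), 3)],
            )
            out.append(ng86_pair(aln, code))
        return out

    def test_planted_ordering_recovered(self, code):
        hi = self._rates(code, 8, 25, 10, "hi", 1)
        lo = self._rates(code, 8, 8, 3, "lo", 2)
        groups = {r.pair_id: "specific" for r in hi}
        groups |= {r.pair_id: "non_specific" for r in lo}
        df = group_contrast(hi + lo, groups).set_index(["statistic", "group"])
        assert df.loc[("dS", "specific"), "mean"] > df.loc[("dS", "non_specific"), "mean"]
        assert df.loc[("dN", "specific"), "mean"] > df.loc[("dN", "non_specific"), "mean"]

    def test_degenerate_single_pair_group(self, code):
        hi = self._rates(code, 1, 20, 8, "hi", 3)
        lo = self._rates(code, 1, 5, 2, "lo", 4)
        groups = {hi[0].pair_id: "specific", lo[0].pair_id: "non_specific"}
        df = group_contrast(hi + lo, groups)
        assert df["p_rank_test"].isna().all()
        assert df["mean"].notna().all()

    def test_empty_group_errors(self, code):
        hi = self._rates(code, 2, 10, 4, "hi", 5)
        with pytest.raises(ValueError, match="two non-empty"):
            group_contrast(hi, {r.pair_id: "specific" for r in hi})
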