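import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutmir.io import DataError, GeneCatalog, parse_lineage
from gutmir.simulate import simulate_catalog
from gutmir.targets import (
    DEFAULT_PARAMS,
    ScoringParams,
    assign_all,
    assign_hit_taxon,
    bit_score,
    evalue,
    find_hits,
    revcomp,
    search_catalog,
    solve_lambda,
)
from oracles import best_seeded_segment_per_strand

MIR21 = "TAGCTTATCAGACTGATGTTGA"

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestRevcomp:
    def test_examples(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAAC") == "GTTT"

    @settings(derandomize=True, max_examples=50)
    @given(dna)
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_invalid_char(self):
        with pytest.raises(DataError):
            revcomp("ACGN")


class TestSolveLambda:
    def test_short_query_defaults(self):
        lam = solve_lambda(1, -3)
        assert lam == pytest.approx(1.374, abs=1e-3)
        # the root actually satisfies the defining equation
        assert 0.25 * math.exp(lam) + 0.75 * math.exp(-3 * lam) == \
            pytest.approx(1.0, abs=1e-8)

    def test_plus_minus_one_closed_form(self):
        # 0.25 e^l + 0.75 e^-l = 1 -> e^l = 3 (quadratic root)
        assert solve_lambda(1, -1) == pytest.approx(math.log(3), abs=1e-6)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            solve_lambda(1, 0)

    def test_params_validate(self):
        DEFAULT_PARAMS.validate()
        with pytest.raises(ValueError):
            ScoringParams(lambda_=1.5).validate()


class TestBitScoreAndEvalue:
    @pytest.mark.parametrize("raw,expected", [
        (15, 30.2), (16, 32.2), (17, 34.2), (18, 36.2),
    ])
    def test_printed_ladder(self, raw, expected):
        assert round(bit_score(raw), 1) == expected

    def test_zero_score(self):
        assert round(bit_score(0), 1) == 0.5  # (-ln 0.711)/ln 2

    def test_constant_increment(self):
        inc = DEFAULT_PARAMS.lambda_ / math.log(2)
        for s in range(0, 30):
            assert bit_score(s + 1) - bit_score(s) == pytest.approx(inc)

    def test_evalue_arithmetic(self):
        assert evalue(10.0, 22, 1000) == pytest.approx(22000 / 1024)

    def test_evalue_monotone_and_linear(self):
        assert evalue(20, 22, 1000) < evalue(10, 22, 1000)
        assert evalue(10, 22, 2000) == pytest.approx(2 * evalue(10, 22, 1000))


class TestFindHits:
    def test_verbatim_plant_forward(self):
        gene = "A" * 30 + MIR21 + "C" * 30
        hits = find_hits(MIR21, gene)
        best = hits[0]
        assert best.strand == "+"
        assert best.length == len(MIR21)
        assert best.identities == best.length
        assert (best.s_start, best.s_end) == (30, 30 + len(MIR21))
        assert (best.q_start, best.q_end) == (0, len(MIR21))

    def test_revcomp_plant_minus_strand(self):
        gene = "A" * 30 + revcomp(MIR21) + "C" * 30
        hits = find_hits(MIR21, gene)
        best = hits[0]
        assert best.strand == "-"
        assert best.length == len(MIR21)
        assert (best.s_start, best.s_end) == (30, 30 + len(MIR21))

    def test_strand_symmetry(self):
        rng = np.random.default_rng(51)
        gene = "".join(rng.choice(list("ACGT"), 300)) + MIR21
        fwd = find_hits(MIR21, gene, _loose())
        rev = find_hits(revcomp(MIR21), gene, _loose())
        assert len(fwd) == len(rev)
        assert sorted(h.raw_score for h in fwd) == \
            sorted(h.raw_score for h in rev)
        # coordinates mirror: a + hit becomes a - hit at the same subject span
        fw = {(h.s_start, h.s_end, h.raw_score) for h in fwd}
        rv = {(h.s_start, h.s_end, h.raw_score) for h in rev}
        assert fw == rv

    def test_disjoint_word_alphabets_no_hits(self):
        # query alternates A/C; an all-G subject offers only GGGGGGG
        # forward and CCCCCCC on its reverse complement -- no shared 7-mer
        query = "ACACACACACACACACACACAC"
        subject = "G" * 200
        assert find_hits(query, subject, _loose()) == []

    def test_raw_score_identity_relation(self):
        rng = np.random.default_rng(53)
        gene = "".join(rng.choice(list("ACGT"), 500))
        gene = gene[:100] + MIR21[:10] + gene[110:]
        for h in find_hits(MIR21, gene, _loose()):
            assert h.raw_score == h.identities - 3 * (h.length - h.identities)
            assert h.q_end - h.q_start == h.s_end - h.s_start == h.length

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        params = _loose()
        checked = 0
        for _ in range(60):
            qlen = int(rng.integers(7, 26))
            slen = int(rng.integers(50, 2001))
            q = "".join(rng.choice(list("ACGT"), qlen))
            s = "".join(rng.choice(list("ACGT"), slen))
            oracle = best_seeded_segment_per_strand(q, s)
            hits = find_hits(q, s, params)
            for strand in "+-":
                got = [h.raw_score for h in hits if h.strand == strand]
                if oracle[strand] is None:
                    assert got == []
                else:
                    assert max(got) == oracle[strand]
                    checked += 1
        assert checked > 5  # ensure the instances were non-trivial


def _loose() -> ScoringParams:
    return ScoringParams(min_identity=0.0, e_max=float("inf"))


class TestSearchCatalog:
    def test_planted_sites_found_with_printed_scores(self):
        cat, truth = simulate_catalog(
            n_genes=50,
            planted_sites=[("m1", MIR21, "Akkermansia", 15, 10, "-")],
            seed=3)
        hits = search_catalog({"m1": MIR21}, cat)
        planted = {s["gene_id"] for s in truth.planted_sites}
        found = hits[hits.gene_id.isin(planted)]
        assert len(found) >= 10
        assert (found["bit_score"] >= 30.2).all()
        assert (found.groupby("gene_id")["bit_score"].max() == 30.2).all()

    def test_e_max_zero_empty(self):
        cat, _ = simulate_catalog(
            n_genes=20, planted_sites=[("m1", MIR21, None, 15, 2, "-")],
            seed=4)
        hits = search_catalog({"m1": MIR21}, cat,
                              ScoringParams(e_max=0.0))
        assert len(hits) == 0

    def test_duplicating_catalog_doubles_hits(self):
        cat, _ = simulate_catalog(
            n_genes=30, planted_sites=[("m1", MIR21, None, 16, 3, "-")],
            seed=5)
        doubled = GeneCatalog(
            cat.gene_ids + [g + "_copy" for g in cat.gene_ids],
            {**cat.sequences,
             **{g + "_copy": cat.sequences[g] for g in cat.gene_ids}},
        )
        h1 = search_catalog({"m1": MIR21}, cat, _loose())
        h2 = search_catalog({"m1": MIR21}, doubled, _loose())
        assert len(h2) == 2 * len(h1)
        # bit scores unchanged (E-values scale with catalog size instead)
        assert sorted(h2["bit_score"])[::2] == sorted(h1["bit_score"])

    def test_empty_catalog_rejected(self):
        with pytest.raises(DataError):
            search_catalog({"m1": MIR21}, GeneCatalog([], {}))


class TestAssignHitTaxon:
    @staticmethod
    def _table():
        from gutmir.io import OtuTable
        lineages = [
            parse_lineage("p_B;c_B;o_B;f_Porphyromonadaceae;"
                          "g_Parabacteroides"),
            parse_lineage("p_B;c_B;o_B;f_Bacteroidaceae;g_Bacteroides"),
            parse_lineage("p_B;c_B;o_B;f_Bacteroidaceae;g_Bacteroides"),
            parse_lineage("p_F;c_C;o_C;f_Mixed;g_One"),
            parse_lineage("p_F;c_C;o_C;f_Mixed;g_Two"),
        ]
        counts = np.array([[100, 10, 20, 50, 50],
                           [200, 15, 25, 60, 40]])
        return OtuTable(["s1", "s2"], [f"O{i}" for i in range(5)],
                        counts, lineages)

    @staticmethod
    def _catalog():
        seqs = {f"g{i}": "ACGT" * 10 for i in range(5)}
        lineages = {
            "g0": parse_lineage("f_Porphyromonadaceae"),  # family only
            "g1": parse_lineage("f_Bacteroidaceae;g_Bacteroides;s_xyz"),
            "g2": parse_lineage("f_Bacteroidaceae;g_Bacteroides"),
            "g3": parse_lineage("f_Mixed"),  # no dominant genus
            # g4 unclassified
        }
        return GeneCatalog(list(seqs), seqs, lineages, {"g1": "COG0001"})

    def _hit(self, gene):
        import pandas as pd
        return pd.Series({"gene_id": gene, "mirna_id": "m1",
                          "bit_score": 30.2, "evalue": 4.6})

    def test_family_with_single_genus_collapses(self):
        tgt = assign_hit_taxon(self._hit("g0"), self._catalog(), self._table())
        assert len(tgt) == 1
        assert tgt[0].taxon_key == "Parabacteroides"
        assert tgt[0].level == "genus_collapsed_from_family"

    def test_species_level_expands_to_otus(self):
        tgt = assign_hit_taxon(self._hit("g1"), self._catalog(), self._table())
        assert {t.taxon_key for t in tgt} == {"O1", "O2"}
        assert all(t.level == "otu" for t in tgt)

    def test_genus_level_direct(self):
        tgt = assign_hit_taxon(self._hit("g2"), self._catalog(), self._table())
        assert [t.taxon_key for t in tgt] == ["Bacteroides"]
        assert tgt[0].level == "genus"

    def test_mixed_family_yields_nothing(self):
        assert assign_hit_taxon(self._hit("g3"), self._catalog(),
                                self._table()) == []

    def test_unclassified_gene_yields_nothing(self):
        assert assign_hit_taxon(self._hit("g4"), self._catalog(),
                                self._table()) == []

    def test_assign_all_drops_unclassified(self):
        import pandas as pd
        hits = pd.DataFrame([self._hit(g) for g in ("g0", "g2", "g4")])
        tgts = assign_all(hits, self._catalog(), self._table())
        assert {t.gene_id for t in tgts} == {"g0", "g2"}
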