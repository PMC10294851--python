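"""CDS extraction, RSCU, and NG86 Ka/Ks against independent oracles."""

import math
from itertools import permutations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocompare.annotation_io import GeneFeature, MitogenomeRecord, ValidationError
from mitocompare.codon_evolution import (INVERTEBRATE_MITO, extract_cds,
                                         ng86_pairwise, ng86_site_counts,
                                         pcg_codon_counts, rscu,
                                         stop_class_from_trailing)
from mitocompare.synthetic_data import (SimulationConfig, mutate_coding_pair,
                                        simulate_genome)

CODE = INVERTEBRATE_MITO
SENSE = CODE.sense_codons


# ---------------------------------------------------------------------------
# Independent brute-force oracle: per-codon site fractions by direct neighbor
# enumeration, pairwise differences by explicit pathway listing.
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    syn_fraction = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            other = codon[:pos] + base + codon[pos + 1:]
            if other in CODE.stops:
                continue
            outcomes.append(CODE.forward[other] == CODE.forward[codon])
        if outcomes:
            syn_fraction += sum(outcomes) / len(outcomes)
    return syn_fraction


def oracle_pair(seq_a, seq_b):
    """(S, N, Sd, Nd) by full enumeration, one codon pair at a time."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(seq_a, seq_b):
        sa, sb = oracle_sites(ca), oracle_sites(cb)
        S += (sa + sb) / 2
        N += (3 - sa + 3 - sb) / 2
        positions = [i for i in range(3) if ca[i] != cb[i]]
        paths = []
        for order in permutations(positions):
            cur, steps, legal = ca, [], True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in CODE.stops:
                    legal = False
                    break
                steps.append(CODE.forward[cur] == CODE.forward[nxt])
                cur = nxt
            if legal:
                paths.append(steps)
        if positions and paths:
            Sd += sum(sum(p) for p in paths) / len(paths)
            Nd += sum(len(p) - sum(p) for p in paths) / len(paths)
    return S, N, Sd, Nd


class TestSiteCounts:
    def test_phe_third_position_only(self):
        s, n = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_gly_fourfold_with_ser_neighbors(self):
        # all three third-position changes synonymous; AGA is Ser under the
        # invertebrate mitochondrial code, so position 1 contributes nothing
        s, n = ng86_site_counts("GGA")
        assert s == pytest.approx(1.0) and n == pytest.approx(2.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng86_site_counts("TAA")

    @pytest.mark.parametrize("codon", SENSE)
    def test_conservation_and_oracle_agreement(self, codon):
        s, n = ng86_site_counts(codon)
        assert s + n == pytest.approx(3.0)
        assert s == pytest.approx(oracle_sites(codon))


class TestPairwise:
    def test_identical_sequences(self):
        r = ng86_pairwise(["ATG", "AAA", "GGA"], ["ATG", "AAA", "GGA"])
        assert r.Sd == r.Nd == 0.0 and r.Ka == r.Ks == 0.0
        assert math.isnan(r.ratio)  # 0/0: flagged, never spuriously positive

    def test_symmetry(self, rng):
        codons = ["ATT"] * 50
        other = mutate_coding_pair(codons, 4, 7, seed=1)
        a = ng86_pairwise(codons, other)
        b = ng86_pairwise(other, codons)
        assert (a.S, a.N, a.Sd, a.Nd) == (b.S, b.N, b.Sd, b.Nd)

    def test_synonymous_only_pair_gives_zero_ka(self):
        base = ["ATT", "GGA", "CCT", "GTT"] * 25
        mutated = mutate_coding_pair(base, 10, 0, seed=2)
        r = ng86_pairwise(base, mutated)
        assert r.Ka == 0.0 and r.Ks > 0.0

    def test_planted_change_counts_recovered_exactly(self):
        base = ["ATT"] * 200
        mutated = mutate_coding_pair(base, 5, 15, seed=3)
        r = ng86_pairwise(base, mutated)
        assert (r.Sd, r.Nd) == (5.0, 15.0)

    def test_oracle_agreement_single_codon_exhaustive(self):
        """Every sense-codon pair: implementation equals full enumeration."""
        for ca in SENSE:
            for cb in SENSE:
                got = ng86_pairwise([ca], [cb])
                exp = oracle_pair([ca], [cb])
                assert (got.S, got.N, got.Sd, got.Nd) == \
                    tuple(pytest.approx(x) for x in exp), (ca, cb)

    def test_oracle_agreement_short_sequences(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 4))
            a = [SENSE[i] for i in rng.integers(len(SENSE), size=k)]
            b = [SENSE[i] for i in rng.integers(len(SENSE), size=k)]
            got = ng86_pairwise(a, b)
            S, N, Sd, Nd = oracle_pair(a, b)
            assert got.S == pytest.approx(S) and got.N == pytest.approx(N)
            assert got.Sd == pytest.approx(Sd) and got.Nd == pytest.approx(Nd)

    def test_ratio_monotone_in_planted_ratio(self):
        base = ["ATT", "GGA", "CCT", "GTT", "GCT"] * 60
        ratios = []
        for n_nonsyn in (2, 8, 20):
            mutated = mutate_coding_pair(base, 8, n_nonsyn, seed=7)
            ratios.append(ng86_pairwise(base, mutated).ratio)
        assert ratios == sorted(ratios)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ng86_pairwise(["ATG"], ["ATG", "AAA"])


class TestRscu:
    def test_uniform_family_is_one(self):
        table = rscu({"TTT": 10, "TTC": 10}).as_dict()
        assert table["TTT"] == table["TTC"] == 1.0

    def test_fully_biased_twofold_family(self):
        table = rscu({"TTT": 20, "TTC": 0}).as_dict()
        assert table["TTT"] == 2.0 and table["TTC"] == 0.0

    def test_maximal_bias_equals_degeneracy(self):
        # GGN glycine family is 4-fold under this code
        table = rscu({"GGA": 4, "GGC": 0, "GGG": 0, "GGT": 0}).as_dict()
        assert table["GGA"] == 4.0

    def test_stop_codons_rejected(self):
        with pytest.raises(ValidationError):
            rscu({"TAA": 3})

    @given(st.dictionaries(st.sampled_from(SENSE), st.integers(0, 50),
                           max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_family_sums_equal_degeneracy(self, counts):
        table = rscu(counts)
        by_aa = {}
        for codon, aa, _count, value in table.rows:
            by_aa.setdefault(aa, []).append(value)
        for aa, values in by_aa.items():
            if aa in table.empty_families:
                assert all(v == 0.0 for v in values)
            else:
                assert sum(values) == pytest.approx(len(values))


class TestExtractCds:
    def test_toy_plus_strand_gene(self):
        rec = MitogenomeRecord(id="toy", length=9, features=[
            GeneFeature("atp8", 1, 9, "+", "PCG")], sequence="ATGAAATAA")
        cds = extract_cds(rec, "atp8")
        assert cds.codons == ("ATG", "AAA", "TAA")
        assert cds.start_codon == "ATG" and cds.stop_class == "TAA"
        assert cds.trailing_len == 0

    def test_minus_strand_gene_reverse_complemented(self):
        # genome carries revcomp(ATGAAATAA) = TTATTTCAT
        rec = MitogenomeRecord(id="toy", length=9, features=[
            GeneFeature("atp8", 1, 9, "-", "PCG")], sequence="TTATTTCAT")
        assert extract_cds(rec, "atp8").codons == ("ATG", "AAA", "TAA")

    def test_incomplete_stop_from_trailing_remainder(self):
        rec = MitogenomeRecord(id="toy", length=10, features=[
            GeneFeature("atp8", 1, 10, "+", "PCG")], sequence="ATGAAACCCT")
        cds = extract_cds(rec, "atp8")
        assert cds.trailing_len == 1 and cds.stop_class == "T-"
        assert 3 * len(cds.codons) + cds.trailing_len == 10

    @pytest.mark.parametrize("size, expected", [(1669, "T-"), (922, "T-"),
                                                (1534, "T-"), (1002, "TAA")])
    def test_stop_class_from_annotated_sizes(self, size, expected):
        # annotated pteromalid gene spans: size mod 3 determines the
        # incomplete-stop class (e.g. nad5 at 1669 bp ends on a bare T)
        assert stop_class_from_trailing(size % 3, "TAA") == expected

    def test_annotated_incomplete_stops_in_fixtures(self, records):
        nad5 = records["M_similadanacus"].feature("nad5")
        assert nad5.size == 1669 and nad5.size % 3 == 1
        assert nad5.stop_codon == "T-"
        nad2 = records["P_vindemmiae"].feature("nad2")
        assert nad2.size == 1002 and nad2.size // 3 == 334
        assert (nad2.start_codon, nad2.stop_codon, nad2.strand) == \
            ("ATT", "TAA", "-")

    def test_simulated_genomes_extract_cleanly(self):
        rec = simulate_genome(SimulationConfig(seed=13))
        for feat in rec.features_of_type("PCG"):
            cds = extract_cds(rec, feat.name)
            assert 3 * len(cds.codons) + cds.trailing_len == feat.size
            assert cds.internal_stops == ()
            assert cds.start_codon == feat.start_codon
            assert cds.stop_class == feat.stop_codon

    def test_non_pcg_rejected(self, records):
        with pytest.raises(ValidationError):
            extract_cds(simulate_genome(SimulationConfig(seed=1)), "trnA")


def test_pcg_codon_counts_exclude_stops():
    rec = simulate_genome(SimulationConfig(seed=21))
    counts = pcg_codon_counts(rec)
    assert not any(CODE.is_stop(c) for c in counts)
    assert sum(counts.values()) > 3000  # 13 genes of realistic length
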