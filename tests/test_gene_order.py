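"""Breakpoint distances, conserved blocks, and event classification."""

import numpy as np
import pytest

from mitocompare.annotation_io import ValidationError
from mitocompare.gene_order import (ANCESTRAL_INSECT_ORDER, GeneOrder,
                                    RearrangementEvent, apply_event,
                                    breakpoint_distance, classify_events,
                                    order_from_record, parse_order_text,
                                    pbd_matrix, shared_blocks,
                                    write_order_text)
from mitocompare.synthetic_data import apply_rearrangement, random_event


def brute_force_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Independent oracle: count adjacencies of `a` absent from `b` by
    direct neighbor-listing on the restricted circular orders."""
    shared = sorted(set(a.names) & set(b.names))

    def adjacencies(order):
        names = [g for g in order.names if g in shared]
        pairs = set()
        for i, x in enumerate(names):
            y = names[(i + 1) % len(names)]
            pairs.add(tuple(sorted((x, y))))
        return pairs
    return len(adjacencies(a) - adjacencies(b))


def random_order(rng, n=20, id="rand") -> GeneOrder:
    pool = list(ANCESTRAL_INSECT_ORDER.genes)
    idx = rng.permutation(len(pool))[:n]
    genes = tuple((pool[i][0], "+" if rng.random() < 0.7 else "-") for i in idx)
    return GeneOrder(id=id, genes=genes)


class TestGeneOrderType:
    def test_rotation_and_reflection_equivalence(self):
        genes = (("trnI", "+"), ("nad2", "-"), ("trnW", "-"), ("cox1", "+"))
        o = GeneOrder(id="a", genes=genes)
        rotated = GeneOrder(id="b", genes=genes[2:] + genes[:2])
        reflected = GeneOrder(id="c", genes=tuple(
            (g, "-" if s == "+" else "+") for g, s in reversed(genes)))
        assert o == rotated == reflected

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            GeneOrder(id="x", genes=(("cox1", "+"), ("cox1", "-")))

    def test_text_round_trip(self, orders):
        text = write_order_text(list(orders.values()))
        again = parse_order_text(text)
        assert [o.genes for o in again] == [o.genes for o in orders.values()]

    def test_orders_follow_annotation_coordinates(self, orders):
        assert orders["P_vindemmiae"].names[:4] == ("trnR", "trnI", "nad2", "trnW")
        assert orders["M_similadanacus"].names[:3] == ("trnI", "nad2", "trnW")

    def test_singleton_order(self, records):
        from mitocompare.annotation_io import GeneFeature, MitogenomeRecord
        rec = MitogenomeRecord(id="toy", length=100, features=[
            GeneFeature("cox1", 1, 50, "+", "PCG")])
        assert order_from_record(rec).names == ("cox1",)


class TestBreakpointDistance:
    def test_muscidifurax_pair_identical(self, orders):
        assert breakpoint_distance(orders["M_similadanacus"],
                                   orders["M_sinesensilla"]) == 0

    def test_pvin_vs_muscidifurax(self, orders):
        assert breakpoint_distance(orders["P_vindemmiae"],
                                   orders["M_similadanacus"]) == 5

    def test_pvin_vs_nasonia(self, orders):
        assert breakpoint_distance(orders["N_vitripennis"],
                                   orders["P_vindemmiae"]) == 5

    def test_cr_convention_changes_distance_by_at_most_two(self, records):
        with_cr = {k: order_from_record(r, include_cr=True)
                   for k, r in records.items()}
        without = {k: order_from_record(r, include_cr=False)
                   for k, r in records.items()}
        keys = list(records)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d1 = breakpoint_distance(with_cr[a], with_cr[b])
                d2 = breakpoint_distance(without[a], without[b])
                assert abs(d1 - d2) <= 2
        # for the trnR-relocation pair both conventions agree
        assert breakpoint_distance(without["P_vindemmiae"],
                                   without["M_similadanacus"]) == 5

    def test_single_gene_transposition_distance_three(self, rng):
        base = random_order(rng, n=10, id="base")
        # move one gene to a non-adjacent destination
        ev = RearrangementEvent(kind="transposition",
                                segment=(base.names[0],), after=base.names[4])
        moved = apply_event(base, ev)
        assert breakpoint_distance(base, moved) == 3

    def test_symmetry_rotation_invariance_and_oracle(self, rng):
        for _ in range(200):
            a = random_order(rng, n=int(rng.integers(6, 24)), id="a")
            b = GeneOrder(id="b", genes=tuple(
                (g, "+" if rng.random() < 0.5 else "-")
                for g in rng.permutation(list(a.names))))
            d = breakpoint_distance(a, b)
            assert d == breakpoint_distance(b, a) == brute_force_distance(a, b)
            k = int(rng.integers(len(a.genes)))
            rotated = GeneOrder(id="a", genes=a.genes[k:] + a.genes[:k])
            reflected = GeneOrder(id="a", genes=tuple(
                (g, "-" if s == "+" else "+") for g, s in reversed(a.genes)))
            assert breakpoint_distance(rotated, b) == d
            assert breakpoint_distance(reflected, b) == d

    def test_too_few_shared_genes(self):
        a = GeneOrder(id="a", genes=(("cox1", "+"), ("cox2", "+"), ("cox3", "+")))
        b = GeneOrder(id="b", genes=(("cox1", "+"), ("nad1", "+"), ("nad2", "+")))
        with pytest.raises(ValidationError, match="shared genes"):
            breakpoint_distance(a, b)


class TestPbdMatrix:
    def test_four_genome_matrix(self, orders):
        m = pbd_matrix(list(orders.values()))
        ids = {k: o.id for k, o in orders.items()}
        assert m[ids["M_similadanacus"], ids["M_sinesensilla"]] == 0
        assert m[ids["M_similadanacus"], ids["N_vitripennis"]] == 0
        assert m[ids["P_vindemmiae"], ids["M_similadanacus"]] == 5
        assert m[ids["P_vindemmiae"], ids["N_vitripennis"]] == 5
        assert (m.values.values == m.values.values.T).all()
        assert (np.diag(m.values.values) == 0).all()

    def test_duplicated_order_gives_zero_matrix(self, orders):
        base = orders["M_similadanacus"]
        copies = [GeneOrder(id=f"c{i}", genes=base.genes) for i in range(4)]
        m = pbd_matrix(copies)
        assert (m.values.values == 0).all()

    def test_matrix_equals_elementwise_oracle(self, orders):
        m = pbd_matrix(list(orders.values()))
        for a in orders.values():
            for b in orders.values():
                if a.id != b.id:
                    assert m[a.id, b.id] == brute_force_distance(a, b)


class TestSharedBlocks:
    def test_fixture_blocks_contain_named_conserved_runs(self, orders):
        blocks = shared_blocks(list(orders.values()))
        joined = ["-".join(b.genes) for b in blocks]
        assert any("cox3-atp6-atp8" in j for j in joined)
        assert any("trnI-nad2-trnW-trnY-trnS1" in j for j in joined)

    def test_pvin_carries_inverted_trnE_trnF_block(self, orders):
        blocks = shared_blocks(list(orders.values()))
        ef = next(b for b in blocks if set(b.genes) == {"trnE", "trnF"})
        assert ef.inverted == (orders["P_vindemmiae"].id,)

    def test_identical_orders_give_single_spanning_block(self, orders):
        a = orders["M_similadanacus"]
        b = GeneOrder(id="copy", genes=a.genes)
        blocks = shared_blocks([a, b])
        assert len(blocks) == 1 and len(blocks[0]) == len(a.genes)

    def test_transposition_blocks_are_inter_breakpoint_segments(self, rng):
        base = random_order(rng, n=15, id="base")
        ev = random_event(base, "transposition", rng, max_segment=4)
        moved = apply_rearrangement(base, ev)
        blocks = shared_blocks([base, moved], min_len=1)
        assert sum(len(b) for b in blocks) == len(base.genes)
        # blocks never overlap and are contiguous in both orders
        seen = [g for b in blocks for g in b.genes]
        assert sorted(seen) == sorted(base.names)
        adj_a, adj_b = base.adjacency_set(), moved.adjacency_set()
        for b in blocks:
            for x, y in zip(b.genes, b.genes[1:]):
                assert frozenset((x, y)) in adj_a and frozenset((x, y)) in adj_b


class TestClassifyEvents:
    def test_identical_orders_no_events(self, orders):
        a = orders["M_similadanacus"]
        assert classify_events(a, orders["M_sinesensilla"]) == []

    def test_pvin_events_include_inversion_and_trnR_relocation(self, orders):
        events = classify_events(orders["M_similadanacus"],
                                 orders["P_vindemmiae"])
        kinds = {(e.kind, e.segment) for e in events}
        assert ("inversion", ("trnE", "trnF")) in kinds
        assert ("reverse_transposition", ("trnR",)) in kinds
        # trnR flips strand between the two arrangements, hence the
        # relocation is reported as a reverse transposition
        assert all(e.kind != "tdrl_or_complex" for e in events)

    def test_replay_reproduces_target(self, orders):
        src, tgt = orders["M_similadanacus"], orders["P_vindemmiae"]
        cur = src
        for e in classify_events(src, tgt):
            cur = apply_event(cur, e)
        assert cur == tgt

    def test_gene_set_mismatch_rejected(self, orders):
        partial = orders["M_similadanacus"].restrict(
            set(orders["M_similadanacus"].names) - {"trnI"})
        with pytest.raises(ValidationError, match="restrict"):
            classify_events(partial, orders["P_vindemmiae"])

    def test_planted_inversions_recovered_exactly(self):
        base = ANCESTRAL_INSECT_ORDER
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ev = random_event(base, "inversion", rng)
            mutated = apply_rearrangement(base, ev)
            recovered = classify_events(base, mutated)
            assert len(recovered) == 1
            assert recovered[0].kind == "inversion"
            assert recovered[0].segment == ev.segment

    def test_planted_transpositions_recovered(self):
        base = ANCESTRAL_INSECT_ORDER
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ev = random_event(base, "transposition", rng)
            mutated = apply_rearrangement(base, ev)
            recovered = classify_events(base, mutated)
            assert len(recovered) == 1
            assert recovered[0].kind == "transposition"
            cur = apply_event(base, recovered[0])
            assert cur == mutated

    def test_double_inversion_applied_twice_is_identity(self, rng):
        base = ANCESTRAL_INSECT_ORDER
        ev = random_event(base, "inversion", rng)
        assert apply_event(apply_event(base, ev), ev) == base
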