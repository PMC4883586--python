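"""Parsing, direction resolution, and impact-matrix construction."""

import numpy as np
import pandas as pd
import pytest

from cmpscore.reaction_network import (
    Direction,
    NetworkFilterConfig,
    build_model,
    metabolite_adjacency,
    parse_reaction_map,
    resolve_directions,
)

from conftest import naive_raw_matrix, random_small_network


class TestParse:
    def test_forward_line(self):
        (e,) = parse_reaction_map(["R1: 00010: A => B"])
        assert e.reaction_id == "R1" and e.pathway_id == "00010"
        assert e.substrates == (("A", 1.0),)
        assert e.products == (("B", 1.0),)
        assert e.direction is Direction.FORWARD

    def test_reverse_line_is_side_swapped(self):
        (e,) = parse_reaction_map(["R2: 00020: A <= B"])
        assert e.substrates == (("B", 1.0),)
        assert e.products == (("A", 1.0),)
        assert e.direction is Direction.FORWARD

    def test_reversible_line_with_coefficients(self):
        coeffs = {"R3": {"A": 1, "B": 2, "C": 1}}
        (e,) = parse_reaction_map(["R3: 00030: A + B <=> C"], coeffs)
        assert e.substrates == (("A", 1.0), ("B", 2.0))
        assert e.products == (("C", 1.0),)
        assert e.direction is Direction.REVERSIBLE

    def test_malformed_lines_skipped_and_counted(self, caplog):
        lines = ["garbage", "R1: 00010: A => B", "R2: 00010: A + => B", "R3: 00010: A => A + B"]
        with caplog.at_level("WARNING"):
            entries = parse_reaction_map(lines)
        assert [e.reaction_id for e in entries] == ["R1"]
        assert "3 malformed" in caplog.text

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            parse_reaction_map([])
        with pytest.raises(ValueError):
            parse_reaction_map(["", "  "])

    def test_unknown_coefficient_compound_names_reaction(self):
        with pytest.raises(ValueError, match="R1"):
            parse_reaction_map(["R1: 00010: A => B"], {"R1": {"Z": 2}})


class TestResolveDirections:
    def test_consistent_forward(self):
        entries = parse_reaction_map(["R1: 00010: A => B", "R1: 00020: A => B"])
        assert resolve_directions(entries)["R1"] is Direction.FORWARD

    def test_conflicting_orientations_become_reversible(self):
        entries = parse_reaction_map(["R2: 00010: A => B", "R2: 00020: B => A"])
        assert resolve_directions(entries)["R2"] is Direction.REVERSIBLE

    def test_any_reversible_occurrence_wins(self):
        entries = parse_reaction_map(["R3: 00010: A <=> B", "R3: 00020: A => B"])
        assert resolve_directions(entries)["R3"] is Direction.REVERSIBLE


class TestBuildModel:
    def test_two_gene_chain(self):
        entries = parse_reaction_map(["R1: 00010: A => B", "R2: 00010: B => C"])
        model = build_model(
            entries, resolve_directions(entries), {"g1": {"R1"}, "g2": {"R2"}}
        )
        expected = pd.DataFrame(
            [[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]],
            index=["A", "B", "C"],
            columns=["g1", "g2"],
        )
        pd.testing.assert_frame_equal(model.matrix, expected)

    def test_stoichiometric_coefficients_normalize_per_row(self):
        entries = parse_reaction_map(
            ["R1: 00010: A + B => C"], {"R1": {"A": 1, "B": 2, "C": 1}}
        )
        model = build_model(entries, resolve_directions(entries), {"g1": {"R1"}})
        assert model.raw.at["B", "g1"] == -2.0
        # single-entry rows renormalize to unit sign mass
        assert model.matrix.at["A", "g1"] == -1.0
        assert model.matrix.at["B", "g1"] == -1.0
        assert model.matrix.at["C", "g1"] == 1.0

    def test_reversible_reactions_contribute_nothing(self):
        entries = parse_reaction_map(["R1: 00010: A => B", "R2: 00010: C <=> D"])
        model = build_model(
            entries, resolve_directions(entries), {"g1": {"R1"}, "g2": {"R2"}}
        )
        assert set(model.metabolites) == {"A", "B"}
        assert set(model.genes) == {"g1"}

    def test_all_reversible_raises_empty_model(self):
        entries = parse_reaction_map(["R1: 00010: A <=> B"])
        with pytest.raises(ValueError, match="empty model"):
            build_model(entries, resolve_directions(entries), {"g1": {"R1"}})

    def test_multi_pathway_reaction_counts_once(self):
        # the same reaction annotated in two pathways contributes one impact
        entries = parse_reaction_map(["R1: 00010: A => B", "R1: 00020: A => B"])
        model = build_model(entries, resolve_directions(entries), {"g1": {"R1"}})
        assert model.raw.at["A", "g1"] == -1.0
        assert model.raw.at["B", "g1"] == 1.0

    def test_provenance_signs_match_cells(self, planted):
        model = planted["model"]
        for (m, g), records in model.provenance.items():
            cell = model.matrix.at[m, g]
            assert records
            roles = {role for _, role, _ in records}
            if cell > 0:
                assert "produces" in roles
            elif cell < 0:
                assert "consumes" in roles

    def test_row_sign_sums_normalized(self, planted):
        mat = planted["model"].matrix.to_numpy()
        neg = np.where(mat < 0, mat, 0).sum(axis=1)
        pos = np.where(mat > 0, mat, 0).sum(axis=1)
        assert np.all((neg == 0) | (np.abs(neg + 1) < 1e-9))
        assert np.all((pos == 0) | (np.abs(pos - 1) < 1e-9))
        assert not np.any((neg == 0) & (pos == 0))  # no all-zero row

    def test_line_order_invariance(self):
        rng = np.random.default_rng(7)
        lines, _, gene_map = random_small_network(rng)
        entries = parse_reaction_map(lines)
        shuffled_lines = list(lines)
        rng.shuffle(shuffled_lines)
        entries2 = parse_reaction_map(shuffled_lines)
        try:
            m1 = build_model(entries, resolve_directions(entries), gene_map)
        except ValueError:
            pytest.skip("drawn network has no usable reactions")
        m2 = build_model(entries2, resolve_directions(entries2), gene_map)
        pd.testing.assert_frame_equal(m1.matrix, m2.matrix)

    def test_raw_matrix_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 30:
            lines, meta, gene_map = random_small_network(rng)
            expected = naive_raw_matrix(meta, gene_map)
            entries = parse_reaction_map(lines)
            directions = resolve_directions(entries)
            if expected is None:
                with pytest.raises(ValueError):
                    build_model(entries, directions, gene_map)
                continue
            model = build_model(entries, directions, gene_map)
            pd.testing.assert_frame_equal(model.raw, expected)
            checked += 1

    def test_gene_removal_never_adds_provenance(self):
        rng = np.random.default_rng(4)
        lines, meta, gene_map = random_small_network(rng)
        entries = parse_reaction_map(lines)
        directions = resolve_directions(entries)
        if naive_raw_matrix(meta, gene_map) is None or len(gene_map) < 2:
            pytest.skip("degenerate draw")
        full = build_model(entries, directions, gene_map)
        reduced_map = dict(gene_map)
        reduced_map.pop(sorted(reduced_map)[0])
        try:
            reduced = build_model(entries, directions, reduced_map)
        except ValueError:
            return
        for cell, records in reduced.provenance.items():
            assert len(records) <= len(full.provenance.get(cell, records))


class TestAdjacency:
    def test_forward_reaction_links(self):
        entries = parse_reaction_map(["R1: 00010: A => B"])
        adj = metabolite_adjacency(None, entries, resolve_directions(entries))
        assert adj == [("A", "B", "synthesizing")]

    def test_reversible_reaction_links(self):
        entries = parse_reaction_map(["R1: 00010: A <=> B"])
        adj = metabolite_adjacency(None, entries, resolve_directions(entries))
        assert adj == [("A", "B", "reversible")]

    def test_cosubstrates_are_depleting_links(self):
        entries = parse_reaction_map(["R1: 00010: A + B => C"])
        adj = metabolite_adjacency(None, entries, resolve_directions(entries))
        assert ("A", "B", "depleting") in adj
        assert ("A", "C", "synthesizing") in adj and ("B", "C", "synthesizing") in adj

    def test_unconnected_compounds_have_no_record(self):
        entries = parse_reaction_map(["R1: 00010: A => B", "R2: 00020: C => D"])
        adj = metabolite_adjacency(None, entries, resolve_directions(entries))
        assert not any({u, v} == {"A", "C"} for u, v, _ in adj)
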