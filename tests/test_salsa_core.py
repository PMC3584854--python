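import pytest
from Bio.Align import substitution_matrices

from conftest import run_family_pipeline
from salsa.exceptions import InputError, IntegrityError
from salsa.salsa_core import (
    AMINO_ACIDS,
    SalsaCell,
    SalsaTable,
    blosum62,
    build_salsa_table,
    classify_match,
    derive_consensus,
    max_score,
    round_half_away,
    score_match,
    signature_from_row,
)

LETTERS = AMINO_ACIDS + "X"
OMPDC_REFERENCES = ["1dbt", "1dvj", "1dqw", "1l2u", "2za1"]


class TestBlosum62:
    def test_printed_signature_diagonal(self):
        assert blosum62("D", "D") == 6
        assert blosum62("K", "K") == 5
        assert blosum62("H", "H") == 8
        assert blosum62("P", "P") == 7
        assert blosum62("R", "R") == 5
        assert sum(blosum62(c, c) for c in "DKDKDHPR") == 48

    def test_alanine_diagonal(self):
        assert blosum62("A", "A") == 4

    def test_matches_independent_transcription_entrywise(self):
        reference = substitution_matrices.load("BLOSUM62")
        for a in LETTERS:
            for b in LETTERS:
                assert blosum62(a, b) == int(reference[a][b]), (a, b)

    def test_symmetric(self):
        for a in LETTERS:
            for b in LETTERS:
                assert blosum62(a, b) == blosum62(b, a)

    def test_x_conventions(self):
        assert blosum62("X", "X") == -1
        for c in "AST":
            assert blosum62("X", c) == 0
        for c in "CPW":
            assert blosum62("X", c) == -2

    def test_unknown_code_errors(self):
        with pytest.raises(InputError):
            blosum62("B", "A")


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (100 * 39 / 48, 81),
        (100 * -5 / 97, -5),
        (100 * 30 / 50, 60),
        (100 * 11 / 51, 22),
        (0.5, 1),
        (-0.5, -1),
        (2.0, 2),
    ])
    def test_printed_percentages(self, value, expected):
        assert round_half_away(value) == expected


class TestCellAndTableIO:
    def test_cell_string_forms(self):
        assert str(SalsaCell.residue("D", 11)) == "D11"
        assert str(SalsaCell.residue("n", 168, predicted=False)) == "n168"
        assert str(SalsaCell.gap()) == "-"

    def test_cell_parse_roundtrip(self):
        for text in ["D11", "n168", "-", "K105", "t187", "A1B"]:
            assert str(SalsaCell.parse(text)) == text

    def test_cell_parse_rejects_junk(self):
        with pytest.raises(InputError):
            SalsaCell.parse("D11!")

    def test_table_tsv_roundtrip(self, table2):
        again = SalsaTable.from_tsv(table2.to_tsv())
        assert again.structure_order == table2.structure_order
        assert again.position_order == table2.position_order
        assert again.cells == table2.cells
        assert again.annotations == table2.annotations

    def test_fixture_row_contents(self, table2):
        row = table2.row("1dbt")
        assert [str(c) for c in row] == ["D11", "K33", "D60", "K62", "D65", "H88", "P182", "R215"]
        assert all(c.predicted for c in row)

    def test_fixture_unpredicted_cell(self, table2):
        cell = table2.cell("2aqw", "6")
        assert (cell.code1, cell.res_seq, cell.predicted) == ("N", 168, False)

    def test_gh16_gaps(self, table3):
        gaps = [p for p in table3.position_order if table3.cell("3h3l", p).is_gap]
        assert gaps == ["2", "4", "11"]

    def test_abdh_first_cell(self, table5):
        assert str(table5.cell("3q1t", "1")) == "D155"
        assert len(table5.position_order) == 7


class TestBuildTable:
    def test_generator_family_occupancy(self, toy_family):
        _, _, _, pm, table = run_family_pipeline(toy_family)
        non_gap = sum(
            0 if table.cell(sid, pid).is_gap else 1
            for sid in table.structure_order for pid in table.position_order
        )
        assert non_gap == toy_family.planted_positions.occupancy()

    def test_empty_position_map_zero_columns(self, toy_family):
        from salsa.local_alignment import PositionMap
        from salsa.site_prediction import select_top_fraction

        structures = toy_family.structures
        sites = [select_top_fraction(r, 0.16) for r in toy_family.rankings]
        pm = PositionMap(structures[0].structure_id,
                         [s.structure_id for s in structures], [])
        table = build_salsa_table(pm, sites, structures)
        assert table.position_order == []
        assert table.structure_order == [s.structure_id for s in structures]

    def test_unknown_residue_errors(self, toy_family):
        from salsa.local_alignment import PositionMap
        from salsa.site_prediction import select_top_fraction
        from salsa.structure_io import ResidueKey

        structures = toy_family.structures
        sites = [select_top_fraction(r, 0.16) for r in toy_family.rankings]
        pm = PositionMap(structures[0].structure_id,
                         [s.structure_id for s in structures],
                         [{structures[0].structure_id: ResidueKey("Z", 999, "")}])
        with pytest.raises(IntegrityError):
            build_salsa_table(pm, sites, structures)


class TestDeriveConsensus:
    def test_ompdc_signature(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        assert signature.codes() == "DKDKDHPR"
        supports = {p.position_id: p.support for p in signature.positions}
        assert supports == {"1": 5, "2": 5, "3": 5, "4": 5, "5": 5, "6": 4, "7": 5, "8": 5}

    def test_two_of_five_column_dropped(self, table2):
        # rewrite position 6 so only two references (1dbt, 1dvj) agree on H
        cells = dict(table2.cells)
        cells[("1dqw", "6")] = SalsaCell.residue("W", 122)
        cells[("1l2u", "6")] = SalsaCell.residue("Y", 99)
        mutated = SalsaTable(table2.structure_order, table2.position_order, cells)
        signature = derive_consensus(mutated, OMPDC_REFERENCES)
        assert signature.codes() == "DKDKDPR"
        assert "6" not in signature.position_ids()

    def test_all_rows_identical_full_support(self, table2):
        signature = derive_consensus(table2, ["1dbt"] * 1)
        assert signature.codes() == "DKDKDHPR"
        assert all(p.support == 1 and p.reference_count == 1 for p in signature.positions)

    def test_modal_tie_drops_position(self, table2):
        cells = dict(table2.cells)
        # 2 x H vs 2 x Y among predicted cells at position 6
        cells[("1dqw", "6")] = SalsaCell.residue("Y", 122)
        cells[("1l2u", "6")] = SalsaCell.residue("Y", 99)
        mutated = SalsaTable(table2.structure_order, table2.position_order, cells)
        assert "6" not in derive_consensus(mutated, OMPDC_REFERENCES).position_ids()

    def test_unpredicted_cells_do_not_count(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        position6 = next(p for p in signature.positions if p.position_id == "6")
        assert position6.support == 4  # 2za1's n165 is unpredicted

    def test_empty_reference_rows_errors(self, table2):
        with pytest.raises(InputError):
            derive_consensus(table2, [])

    def test_threshold_out_of_range_errors(self, table2):
        with pytest.raises(InputError):
            derive_consensus(table2, OMPDC_REFERENCES, majority_threshold=0.4)

    def test_generator_family_consensus(self, toy_family):
        _, _, _, _, table = run_family_pipeline(toy_family)
        signature = derive_consensus(table, table.structure_order)
        assert signature.codes() == toy_family.site.codes


class TestScoring:
    def test_reference_row_scores_maximum(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        score = score_match(table2.row("1dbt", signature.position_ids()), signature)
        assert (score.raw, score.max, score.percent) == (48, 48, 100)

    def test_query_2aqw(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        score = score_match(table2.row("2aqw", signature.position_ids()), signature)
        assert (score.raw, score.percent) == (39, 81)

    def test_2za1_scores_like_2aqw(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        score = score_match(table2.row("2za1", signature.position_ids()), signature)
        assert (score.raw, score.percent) == (39, 81)

    def test_gh16_query(self, table3):
        signature = signature_from_row(table3, "2ayh")
        assert max_score(signature) == 97
        score = score_match(table3.row("3h3l", signature.position_ids()), signature,
                            gap_penalty=-3)
        assert (score.raw, score.percent) == (-5, -5)

    def test_ech_maximum(self, table4):
        assert max_score(signature_from_row(table4, "1ey3")) == 51

    def test_abdh_comparison(self, table5):
        signature = signature_from_row(table5, "3q1t")
        assert max_score(signature) == 50
        score = score_match(table5.row("2j5s", signature.position_ids()), signature)
        assert (score.raw, score.percent) == (30, 60)

    def test_length_mismatch_errors(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        with pytest.raises(InputError):
            score_match(table2.row("1dbt")[:-1], signature)

    def test_self_match_is_maximum_property(self, table2, table3, table4, table5):
        for table, row in [(table2, "1dbt"), (table3, "2ayh"),
                           (table4, "1ey3"), (table5, "3q1t")]:
            signature = signature_from_row(table, row)
            score = score_match(table.row(row, signature.position_ids()), signature)
            fully_predicted = all(
                c.predicted for c in table.row(row, signature.position_ids())
            )
            if fully_predicted:
                assert score.raw == score.max
                assert score.percent == 100
            else:
                assert score.raw <= score.max

    def test_diagonal_dominance(self, table2):
        # swapping a matching predicted residue for any other never helps
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        base_row = table2.row("1dbt", signature.position_ids())
        base = score_match(base_row, signature).raw
        for i, cons in enumerate(signature.positions):
            for substitute in AMINO_ACIDS:
                row = list(base_row)
                row[i] = SalsaCell.residue(substitute, row[i].res_seq)
                assert score_match(row, signature).raw <= base

    def test_unpredict_flip_never_helps_when_x_value_lower(self):
        # over all consensus/actual pairs: flipping predicted->unpredicted moves
        # the contribution to blosum62(cons, X); never an increase when that
        # value is <= the predicted value
        for cons in AMINO_ACIDS:
            for actual in AMINO_ACIDS:
                predicted_value = blosum62(cons, actual)
                flipped_value = blosum62(cons, "X")
                if flipped_value <= predicted_value:
                    sig = _single_position_signature(cons)
                    up = score_match([SalsaCell.residue(actual, 1)], sig).raw
                    down = score_match([SalsaCell.residue(actual, 1, predicted=False)], sig).raw
                    assert down <= up

    def test_raw_never_exceeds_max_for_consensus_signatures(self, table2):
        signature = derive_consensus(table2, OMPDC_REFERENCES)
        for sid in table2.structure_order:
            score = score_match(table2.row(sid, signature.position_ids()), signature)
            assert score.raw <= score.max

    def test_empty_signature_max_errors(self):
        from salsa.salsa_core import ConsensusSignature
        with pytest.raises(InputError):
            max_score(ConsensusSignature([]))


def _single_position_signature(code):
    from salsa.salsa_core import ConsensusPosition, ConsensusSignature
    return ConsensusSignature([ConsensusPosition("1", code, 1, 1)])


class TestClassifyMatch:
    def make_score(self, percent):
        from salsa.salsa_core import MatchScore
        return MatchScore(raw=percent, max=100, percent=percent, per_position=[])

    def test_ordering_and_incompatible_flag(self):
        report = classify_match({"ompdc": self.make_score(81), "gh16": self.make_score(-5)})
        assert [e.label for e in report.ranked] == ["ompdc", "gh16"]
        assert report.best == ["ompdc"]
        assert not report.ranked[0].incompatible
        assert report.ranked[1].incompatible

    def test_single_candidate(self):
        report = classify_match({"abdh": self.make_score(60)})
        assert report.best == ["abdh"]
        assert not report.tie
        assert not report.ranked[0].incompatible

    def test_tie_reported_in_input_order(self):
        report = classify_match({"b_first": self.make_score(50), "a_second": self.make_score(50)})
        assert report.tie
        assert report.best == ["b_first", "a_second"]

    def test_empty_errors(self):
        with pytest.raises(InputError):
            classify_match({})
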