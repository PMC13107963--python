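"""I/O round trips, cleaning-filter semantics, pairing and split contracts."""

import numpy as np
import pytest

from perturbdiff.data_io import (DataError, ExpressionMatrix, PairingError,
                                 PerturbationRecord, SplitError, SplitSpec,
                                 filter_invalid_smiles, filter_rare_compounds,
                                 load_expression, make_splits, pair_records,
                                 rdkit_smiles_validator, write_expression)


def _record(i, smiles="CCO", role="perturbed", cell_line="CL0", pair_id="c0"):
    return PerturbationRecord(sample_id=f"s{i}", pair_id=pair_id,
                              cell_line=cell_line, smiles=smiles,
                              dose=1.0 if role == "perturbed" else 0.0,
                              time=6.0 if role == "perturbed" else 0.0,
                              role=role)


class TestExpressionIO:
    def test_tsv_round_trip_is_bit_identical(self, small_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_expression(small_matrix, path)
        loaded = load_expression(path)
        assert loaded.sample_ids == small_matrix.sample_ids
        assert loaded.gene_ids == small_matrix.gene_ids
        assert np.array_equal(loaded.values, small_matrix.values)

    def test_gct_and_tsv_agree_for_the_same_matrix(self, small_matrix, tmp_path):
        write_expression(small_matrix, tmp_path / "m.tsv")
        write_expression(small_matrix, tmp_path / "m.gct", format="gct")
        a = load_expression(tmp_path / "m.tsv")
        b = load_expression(tmp_path / "m.gct", format="gct")
        assert a.sample_ids == b.sample_ids and a.gene_ids == b.gene_ids
        assert np.array_equal(a.values, b.values)

    def test_gct_header_is_checked(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.3\n2\t2\n")
        with pytest.raises(DataError, match="#1.2"):
            load_expression(path, format="gct")

    def test_missing_values_fail_fast(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("sample_id\tg1\tg2\na\t1.0\t\nb\t2.0\t3.0\n")
        with pytest.raises(DataError):
            load_expression(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError, match="sample_ids"):
            ExpressionMatrix(np.zeros((2, 2)), ["a", "a"], ["g1", "g2"])
        with pytest.raises(DataError, match="gene_ids"):
            ExpressionMatrix(np.zeros((2, 2)), ["a", "b"], ["g", "g"])


class TestRareCompoundFilter:
    def test_exactly_five_is_kept_four_is_removed(self):
        records = ([_record(i, smiles="CCO") for i in range(5)]
                   + [_record(10 + i, smiles="CCN") for i in range(4)])
        kept = filter_rare_compounds(records, min_count=5)
        smiles = {r.smiles for r in kept}
        assert smiles == {"CCO"}
        assert len(kept) == 5

    def test_min_count_one_is_identity(self):
        records = [_record(i, smiles=s) for i, s in enumerate(["CCO", "CCN", "C"])]
        assert filter_rare_compounds(records, min_count=1) == records

    def test_counts_by_compound(self):
        records = ([_record(i, "CCO") for i in range(10)]
                   + [_record(20 + i, "CCN") for i in range(5)]
                   + [_record(40, "C")])
        kept = filter_rare_compounds(records, min_count=5)
        assert {r.smiles for r in kept} == {"CCO", "CCN"}

    def test_spelling_variants_count_as_one_compound(self):
        records = [_record(0, "CCO"), _record(1, "OCC"), _record(2, "CCO")]
        kept = filter_rare_compounds(records, min_count=3)
        assert len(kept) == 3

    def test_idempotent(self):
        records = ([_record(i, "CCO") for i in range(6)]
                   + [_record(10 + i, "CCN") for i in range(2)])
        once = filter_rare_compounds(records, min_count=5)
        twice = filter_rare_compounds(once, min_count=5)
        assert once == twice

    def test_controls_pass_through(self):
        records = [_record(0, smiles="", role="control"), _record(1, "CCN")]
        kept = filter_rare_compounds(records, min_count=5)
        assert [r.role for r in kept] == ["control"]


class TestSmilesFilter:
    def test_valid_smiles_retained_invalid_removed(self):
        records = [_record(0, "CCO"), _record(1, "C(C("), _record(2, "CCN"),
                   _record(3, "xyz123"), _record(4, "c1ccccc1"), _record(5, "CC")]
        kept = filter_invalid_smiles(records, rdkit_smiles_validator)
        assert [r.sample_id for r in kept] == ["s0", "s2", "s4", "s5"]

    def test_idempotent(self):
        records = [_record(0, "CCO"), _record(1, "C(C(")]
        once = filter_invalid_smiles(records)
        assert filter_invalid_smiles(once) == once

    def test_raising_validator_is_wrapped(self):
        def bad(_):
            raise RuntimeError("boom")
        with pytest.raises(DataError, match="s0"):
            filter_invalid_smiles([_record(0)], bad)


class TestPairing:
    def test_one_control_shared_by_two_perturbed(self):
        records = [_record(0, role="control", pair_id="c0"),
                   _record(1, pair_id="c0"), _record(2, pair_id="c0")]
        pairs = pair_records(records)
        assert len(pairs) == 2
        assert {p.control_id for p in pairs} == {"s0"}

    def test_dangling_pair_id_is_dropped(self):
        records = [_record(0, role="control", pair_id="c0"),
                   _record(1, pair_id="c0"), _record(2, pair_id="nowhere")]
        assert len(pair_records(records)) == 1

    def test_mismatched_cell_line_is_dropped(self):
        records = [_record(0, role="control", pair_id="c0", cell_line="CL0"),
                   _record(1, pair_id="c0", cell_line="CL1")]
        assert pair_records(records) == []

    def test_ambiguous_control_raises(self):
        records = [_record(0, role="control", pair_id="c0"),
                   _record(1, role="control", pair_id="c0")]
        with pytest.raises(PairingError):
            pair_records(records)

    def test_simulator_output_pairs_every_perturbed_row(self, tiny_sim):
        from perturbdiff.data_io import records_from_metadata
        records = records_from_metadata(tiny_sim["metadata"])
        pairs = pair_records(records)
        assert len(pairs) == (tiny_sim["metadata"].role == "perturbed").sum()


class TestSplits:
    @staticmethod
    def _compound_records(n_compounds, per=3):
        smiles = ["CCO", "CCN", "CCC", "CCCl", "CCBr", "CCF", "CCI", "CC=C"]
        out = []
        for j in range(n_compounds):
            for i in range(per):
                out.append(_record(j * per + i, smiles=smiles[j]))
        return out

    def test_unseen_compound_partition_arithmetic(self):
        records = self._compound_records(8)
        folds = make_splits(records, SplitSpec("unseen_compound", 4, seed=0))
        assert len(folds) == 4
        all_test = set()
        for train, test in folds:
            train_c = {r.smiles for r in train}
            test_c = {r.smiles for r in test}
            assert len(test_c) == 2 and len(train_c) == 6
            assert not train_c & test_c
            all_test |= test_c
        assert len(all_test) == 8

    def test_unseen_cell_line_one_per_fold(self):
        records = [_record(i, cell_line=f"CL{i % 4}") for i in range(12)]
        folds = make_splits(records, SplitSpec("unseen_cell_line", 4, seed=1))
        for _, test in folds:
            assert len({r.cell_line for r in test}) == 1

    def test_same_seed_gives_identical_folds(self):
        records = self._compound_records(8)
        spec = SplitSpec("unseen_compound", 4, seed=9)
        assert make_splits(records, spec) == make_splits(records, spec)

    def test_too_few_entities_raises(self):
        records = self._compound_records(2)
        with pytest.raises(SplitError):
            make_splits(records, SplitSpec("unseen_compound", 4, seed=0))

    def test_controls_ride_with_training_sets(self):
        records = ([_record(99, role="control", pair_id="c0", smiles="")]
                   + self._compound_records(4))
        folds = make_splits(records, SplitSpec("unseen_compound", 4, seed=0))
        for train, test in folds:
            assert any(r.role == "control" for r in train)
            assert all(r.role == "perturbed" for r in test)
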