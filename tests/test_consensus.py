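import numpy as np
import pytest

from tssmine import consensus as cons
from tssmine import msa
from tssmine import synthetic_data as sd


def _profile_from_counts(counts_rows):
    """Build a ColumnProfile from per-column {symbol: count} dicts."""
    n_rows = sum(counts_rows[0].values())
    counts = np.zeros((len(counts_rows), 6), dtype=np.int64)
    order = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    for c, row in enumerate(counts_rows):
        assert sum(row.values()) == n_rows
        for sym, n in row.items():
            counts[c, order[sym]] = n
    return cons.ColumnProfile(counts=counts, n_rows=n_rows)


def _aln_from_rows(rows, reference_id=None):
    return msa.MultipleAlignment(tuple(rows), reference_id=reference_id)


class TestColumnFrequencies:
    def test_uniform_column(self):
        aln = _aln_from_rows([(f"r{i}", "A") for i in range(10)])
        profile = cons.column_frequencies(aln)
        assert profile.column_frequencies(0)["A"] == 1.0

    def test_reference_excluded_by_default(self):
        aln = _aln_from_rows([("ref", "G"), ("a", "A"), ("b", "A")], reference_id="ref")
        profile = cons.column_frequencies(aln)
        assert profile.n_rows == 2
        assert profile.column_frequencies(0)["A"] == 1.0
        with_ref = cons.column_frequencies(aln, include_reference=True)
        assert with_ref.n_rows == 3

    def test_matches_brute_force_tally(self, rng):
        # the implementation path is vectorised; the oracle is a plain loop
        for _ in range(100):
            n_rows = int(rng.integers(2, 12))
            n_cols = int(rng.integers(1, 30))
            rows = [
                (f"r{i}", "".join(rng.choice(list("ACGT-"), size=n_cols)))
                for i in range(n_rows)
            ]
            profile = cons.column_frequencies(_aln_from_rows(rows))
            for c in range(n_cols):
                column = [row[1][c] for row in rows]
                expected = {s: column.count(s) for s in "ACGT"}
                expected["gap"] = column.count("-")
                got = profile.column_frequencies(c)
                for sym, count in expected.items():
                    assert got[sym] == pytest.approx(count / n_rows)


class TestCallConsensus:
    def test_published_variable_vector_is_n(self):
        # A 43% > G 22% > C 19% > T 14%: no base reaches 60%
        profile = _profile_from_counts([{"A": 43, "G": 22, "C": 19, "T": 16}])
        result = cons.call_consensus(profile)
        assert result.consensus == "N"
        assert result.variable[0][1]["A"] == pytest.approx(0.43)

    def test_near_threshold_vector_is_n(self):
        # 55.9% C / 43.7% A: close to but under the 60% threshold
        profile = _profile_from_counts([{"C": 559, "A": 437, "G": 4}])
        result = cons.call_consensus(profile)
        assert result.consensus == "N"

    def test_threshold_is_inclusive(self):
        profile = _profile_from_counts([{"G": 6, "A": 4}])
        assert cons.call_consensus(profile, 0.60).consensus == "G"

    def test_gap_majority_is_deletion_column(self):
        profile = _profile_from_counts([{"-": 7, "A": 3}, {"A": 10, "-": 0}])
        result = cons.call_consensus(profile)
        assert result.consensus == "A"
        assert result.deletion_columns == (0,)
        assert result.col_calls == ("-", "A")

    def test_threshold_monotonicity(self, rng):
        counts = [
            {s: int(n) for s, n in zip("ACGT-", row)}
            for row in rng.multinomial(20, [0.3, 0.25, 0.2, 0.15, 0.1], size=200)
        ]
        profile = _profile_from_counts(counts)
        low = cons.call_consensus(profile, 0.55)
        high = cons.call_consensus(profile, 0.75)
        n_low = {c for c, _ in low.variable}
        n_high = {c for c, _ in high.variable}
        assert n_low <= n_high  # raising the threshold never resolves an N


class TestMapToReference:
    def test_gap_free_alignment_has_no_indels(self, model):
        rows = [("ref", model.sequence)] + [(f"c{i}", model.sequence) for i in range(3)]
        aln = _aln_from_rows(rows, reference_id="ref")
        result = cons.call_consensus(cons.column_frequencies(aln))
        result = cons.map_to_reference(result, aln, model)
        assert result.insertions == ()
        assert result.deletions == ()
        assert result.consensus == model.sequence

    def test_conserved_insertion_recorded_with_anchor(self, model):
        pos = 500  # 0-based offset: insertion between offsets 499 and 500
        ref_row = model.sequence[:pos] + "-" + model.sequence[pos:]
        copy = model.sequence[:pos] + "A" + model.sequence[pos:]
        rows = [("ref", ref_row)] + [(f"c{i}", copy) for i in range(5)]
        aln = _aln_from_rows(rows, reference_id="ref")
        result = cons.map_to_reference(
            cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        assert len(result.insertions) == 1
        ins = result.insertions[0]
        assert ins.bases == "A"
        assert model.to_offset(ins.anchor) == pos - 1

    def test_insertion_in_60pct_of_copies_recovered(self, model):
        pos = 700
        ref_row = model.sequence[:pos] + "-" + model.sequence[pos:]
        with_ins = model.sequence[:pos] + "G" + model.sequence[pos:]
        without = model.sequence[:pos] + "-" + model.sequence[pos:]
        rows = [("ref", ref_row)]
        rows += [(f"i{k}", with_ins) for k in range(6)]
        rows += [(f"w{k}", without) for k in range(4)]
        aln = _aln_from_rows(rows, reference_id="ref")
        result = cons.map_to_reference(
            cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        assert [ins.bases for ins in result.insertions] == ["G"]

    def test_deletion_mapped_to_reference_position(self, model):
        pos = 321
        deleted = model.sequence[:pos] + "-" + model.sequence[pos + 1:]
        rows = [("ref", model.sequence)] + [(f"c{i}", deleted) for i in range(5)]
        aln = _aln_from_rows(rows, reference_id="ref")
        result = cons.map_to_reference(
            cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        assert len(result.deletions) == 1
        assert model.to_offset(result.deletions[0]) == pos

    def test_missing_reference_row_is_error(self, model):
        aln = _aln_from_rows([("a", "ACGT"), ("b", "ACGT")])
        result = cons.call_consensus(cons.column_frequencies(aln))
        with pytest.raises(ValueError, match="reference"):
            cons.map_to_reference(result, aln, model)

    def test_determinism(self, model, small_sim):
        from tssmine import homology_search as hs

        records, _ = small_sim
        hits = hs.filter_by_length(hs.find_hits(records, model.sequence), model.length)
        elements = hs.extract_hit_sequences(records, hits)
        aln = msa.align(elements, (model.name, model.sequence))
        r1 = cons.map_to_reference(cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        r2 = cons.map_to_reference(cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        assert r1.consensus == r2.consensus
        assert r1.variable == r2.variable


class TestParameterRecovery:
    def test_consensus_recovers_ancestor_where_majority_clears_threshold(self, model):
        """Star-phylogeny divergence at 10%: the majority call equals the
        ancestor exactly at sites whose realized majority is >= 60%."""
        n, p_sub = 30, 0.10
        params = sd.SimParams(seed=71, genome_length=1, n_copies=n, p_sub=p_sub)
        copies = [sd.mutate_copy(model.sequence, params, np.random.default_rng(900 + i))[0]
                  for i in range(n)]
        rows = [("ref", model.sequence)] + [(f"c{i}", s) for i, s in enumerate(copies)]
        aln = _aln_from_rows(rows, reference_id="ref")
        result = cons.call_consensus(cons.column_frequencies(aln))
        for col in range(model.length):
            column = [s[col] for s in copies]
            top, count = max(((b, column.count(b)) for b in "ACGT"), key=lambda x: x[1])
            if count / n >= 0.60:
                assert result.consensus[col] == top
                if top == model.sequence[col]:
                    continue
            else:
                assert result.consensus[col] == "N"
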