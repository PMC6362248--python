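import dataclasses

import numpy as np
import pytest

from tssmine import annotate as ann
from tssmine import consensus as cons
from tssmine import msa
from tssmine import synthetic_data as sd
from tssmine.sequence_io import FeaturePosition, Span, TransposonModel, translate


class TestCodonEffect:
    @pytest.mark.parametrize("cds_pos,ref,new,aa", [
        (99, "A", "G", "K"),   # AAA -> AAG, Lys
        (378, "A", "C", "R"),  # CGA -> CGC, Arg
        (384, "G", "A", "K"),  # AAG -> AAA, Lys
        (513, "G", "A", "K"),  # AAG -> AAA, Lys
        (636, "C", "A", "I"),  # ATC -> ATA, Ile
    ])
    def test_third_codon_synonymous_changes(self, model, cds_pos, ref, new, aa):
        eff = ann.codon_effect(cds_pos, ref, new, model)
        assert eff.kind == "synonymous"
        assert eff.aa_ref == aa
        assert eff.codon_position == 3

    def test_nonsynonymous_change(self, model):
        # first codon position of the AAG codon at CDS 643-645
        eff = ann.codon_effect(643, "A", "T", model)
        assert eff.kind == "nonsynonymous"
        assert eff.codon_position == 1
        assert (eff.aa_ref, eff.aa_new) == ("K", "*")

    def test_ambiguous_new_base(self, model):
        assert ann.codon_effect(99, "A", "N", model).kind == "ambiguous"

    def test_reference_base_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="mismatch"):
            ann.codon_effect(99, "C", "G", model)

    def test_agrees_with_translation_oracle_on_random_cds(self, rng):
        """Every single-base substitution over a 999-nt random CDS, checked
        against translating the whole mutated CDS."""
        cds = "".join(rng.choice(list("ACGT"), size=999))
        seq = "A" * 30 + cds + "T" * 30
        model = TransposonModel(
            name="oracle", sequence=seq,
            left_itr=Span(0, 20), cds=Span(30, 1029), right_itr=Span(1035, 1055),
        )
        ref_protein = translate(cds)
        for pos in range(1, 1000):
            ref_base = cds[pos - 1]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                eff = ann.codon_effect(pos, ref_base, alt, model)
                mutated = cds[: pos - 1] + alt + cds[pos:]
                same = translate(mutated) == ref_protein
                assert (eff.kind == "synonymous") == same


class TestBindingRegion:
    def test_inside_and_half_open_boundary(self, model):
        # left ITR binding region spans offsets [2, 30) -> positions 3..30
        assert ann.classify_binding_region(FeaturePosition("left_itr", 3), model) is True
        assert ann.classify_binding_region(FeaturePosition("left_itr", 30), model) is True
        assert ann.classify_binding_region(FeaturePosition("left_itr", 31), model) is False

    def test_unevaluable_without_spans(self, model):
        bare = dataclasses.replace(model, binding_regions=())
        assert ann.classify_binding_region(FeaturePosition("left_itr", 5), bare) is None

    def test_non_itr_position_rejected(self, model):
        with pytest.raises(ValueError, match="ITR"):
            ann.classify_binding_region(FeaturePosition("cds", 5), model)


class TestIndelEffect:
    def _rec(self, feature, pos, kind, bases):
        fp = FeaturePosition(feature, pos)
        if kind == "insertion":
            return ann.DifferenceRecord(fp, "insertion", "", bases)
        return ann.DifferenceRecord(fp, "deletion", bases, "")

    def test_single_base_cds_insertion_is_frameshift(self, model):
        eff = ann.indel_effect(self._rec("cds", 718, "insertion", "A"), model)
        assert eff.kind == "frameshift"

    def test_codon_multiple_insertion_in_frame(self, model):
        eff = ann.indel_effect(self._rec("cds", 100, "insertion", "AAA"), model)
        assert eff.kind == "in_frame_indel"

    def test_itr_indel_has_no_codon_effect(self, model):
        assert ann.indel_effect(self._rec("left_itr", 10, "insertion", "A"), model) is None

    def test_cds_deletion_frameshift(self, model):
        assert ann.indel_effect(self._rec("cds", 10, "deletion", "AC"), model).kind == "frameshift"


def _consensus_for(rows, model, feature="full"):
    aln = msa.MultipleAlignment(tuple(rows), reference_id="ref")
    result = cons.call_consensus(cons.column_frequencies(aln))
    return cons.map_to_reference(result, aln, model, feature)


class TestDiffConsensus:
    def test_identical_consensus_is_empty_diff(self, model):
        rows = [("ref", model.sequence)] + [(f"c{i}", model.sequence) for i in range(3)]
        assert ann.diff_consensus(_consensus_for(rows, model), model) == []

    def test_planted_left_itr_substitutions_reported(self, model):
        setup = sd.demo_variant_setup(model)
        ancestor_no_ins = model.sequence
        for pos, base in setup["expected"]["left_itr_substitutions"]:
            off = model.to_offset(FeaturePosition("left_itr", pos))
            ancestor_no_ins = ancestor_no_ins[:off] + base + ancestor_no_ins[off + 1:]
        rows = [("ref", model.sequence)] + [(f"c{i}", ancestor_no_ins) for i in range(4)]
        records = ann.diff_consensus(_consensus_for(rows, model), model)
        left = [r for r in records if r.feature_position.feature == "left_itr"]
        assert [(r.feature_position.position, r.consensus_base) for r in left] == \
            setup["expected"]["left_itr_substitutions"]
        assert all(r.in_binding_region is False for r in left)

    def test_variable_column_carries_frequency_vector(self, model):
        off = model.to_offset(FeaturePosition("cds", 643))
        variants = []
        for i, base in enumerate(["G"] * 5 + ["C"] * 3 + ["T"] * 2):
            variants.append((f"c{i}", model.sequence[:off] + base + model.sequence[off + 1:]))
        rows = [("ref", model.sequence)] + variants
        records = ann.diff_consensus(_consensus_for(rows, model), model)
        assert len(records) == 1
        r = records[0]
        assert r.kind == "variable"
        assert r.feature_position == FeaturePosition("cds", 643)
        assert r.frequency_vector["G"] == pytest.approx(0.5)
        assert r.codon_effect.kind == "ambiguous"

    def test_every_mismatch_appears_exactly_once(self, model, rng):
        # mutate the ancestor at random sites; all copies identical -> the
        # consensus equals the mutated ancestor, and the diff must list
        # exactly the mutated positions
        seq = list(model.sequence)
        positions = sorted(rng.choice(model.length, size=25, replace=False).tolist())
        for off in positions:
            old = seq[off]
            seq[off] = "ACGT"[("ACGT".index(old) + 1) % 4]
        mutated = "".join(seq)
        rows = [("ref", model.sequence)] + [(f"c{i}", mutated) for i in range(4)]
        records = ann.diff_consensus(_consensus_for(rows, model), model)
        got = sorted(model.to_offset(r.feature_position) for r in records)
        assert got == positions
        assert all(r.kind == "substitution" for r in records)


class TestReport:
    def test_empty_report_states_zero_differences(self):
        text, tsv = ann.render_report([])
        assert "identical to the reference" in text
        assert ann.parse_report(tsv) == []

    def test_tsv_round_trip(self, model):
        setup = sd.demo_variant_setup(model)
        rows = [("ref", model.sequence)] + [
            (f"c{i}", setup["ancestor"]) for i in range(5)
        ]
        # align to handle the planted insertion
        aln = msa.align([(f"c{i}", setup["ancestor"]) for i in range(5)],
                        ("ref", model.sequence))
        result = cons.map_to_reference(
            cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        records = ann.diff_consensus(result, model)
        assert records
        _, tsv = ann.render_report(records)
        assert ann.parse_report(tsv) == records

    def test_summary_counts_match_records(self, model):
        setup = sd.demo_variant_setup(model)
        aln = msa.align([(f"c{i}", setup["ancestor"]) for i in range(5)],
                        ("ref", model.sequence))
        result = cons.map_to_reference(
            cons.call_consensus(cons.column_frequencies(aln)), aln, model)
        records = ann.diff_consensus(result, model)
        text, _ = ann.render_report(records)
        n_left = sum(1 for r in records
                     if r.feature_position and r.feature_position.feature == "left_itr")
        assert f"[left_itr] substitutions={n_left}" in text
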