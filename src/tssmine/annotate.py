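"""Annotate consensus-vs-reference differences.

Every position where the consensus differs from the reference transposon
becomes one :class:`DifferenceRecord` carrying its feature-local 1-based
position, whether it falls inside a transposase binding region (for ITR
positions), and — for CDS positions — the codon-level effect.  Synonymy
is evaluated one substitution at a time against the *reference* codon;
the annotator reports frame consequences of indels and never adjusts
frames silently.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .consensus import ConsensusResult
from .sequence_io import FeaturePosition, TransposonModel, translate


@dataclasses.dataclass(frozen=True)
class CodonEffect:
    kind: str  # synonymous | nonsynonymous | frameshift | in_frame_indel | ambiguous | partial_codon
    codon_position: Optional[int] = None  # 1/2/3 within the codon
    ref_codon: str = ""
    new_codon: str = ""
    aa_ref: str = ""
    aa_new: str = ""

    def describe(self) -> str:
        if self.kind == "synonymous":
            return f"synonymous({self.aa_ref})"
        if self.kind == "nonsynonymous":
            return f"nonsynonymous({self.aa_ref}->{self.aa_new})"
        return self.kind


@dataclasses.dataclass(frozen=True)
class DifferenceRecord:
    feature_position: Optional[FeaturePosition]  # None only for a 5'-terminal insertion anchor
    kind: str  # substitution | variable | insertion | deletion
    ref_base: str
    consensus_base: str
    in_binding_region: Optional[bool] = None  # None = not an ITR position / unevaluable
    codon_effect: Optional[CodonEffect] = None
    frequency_vector: Optional[dict] = None


def classify_binding_region(pos: FeaturePosition, model: TransposonModel) -> Optional[bool]:
    """True/False for ITR positions inside/outside a configured binding
    region; None when the model ships no spans for that ITR (unevaluable)."""
    if pos.feature not in ("left_itr", "right_itr"):
        raise ValueError(f"binding regions are only defined within ITRs, got {pos.feature}")
    regions = model.binding_regions_for(pos.feature)
    if not regions:
        return None
    offset = model.to_offset(pos)
    return any(br.span.contains(offset) for br in regions)


def codon_effect(cds_pos: int, ref_base: str, new_base: str, model: TransposonModel) -> CodonEffect:
    """Effect of a single substitution at a 1-based CDS position."""
    cds_seq = model.feature_sequence("cds")
    if not (1 <= cds_pos <= len(cds_seq)):
        raise ValueError(f"CDS position {cds_pos} outside CDS of length {len(cds_seq)}")
    rel = (cds_pos - 1) - model.cds_frame
    if rel < 0:
        return CodonEffect(kind="partial_codon")
    codon_idx, codon_pos = divmod(rel, 3)
    c0 = model.cds_frame + codon_idx * 3
    if c0 + 3 > len(cds_seq):
        return CodonEffect(kind="partial_codon", codon_position=codon_pos + 1)
    ref_codon = cds_seq[c0 : c0 + 3]
    if ref_codon[codon_pos] != ref_base.upper():
        raise ValueError(
            f"reference base mismatch at CDS position {cds_pos}: model has "
            f"{ref_codon[codon_pos]!r}, record says {ref_base!r}"
        )
    if new_base.upper() == "N":
        return CodonEffect(kind="ambiguous", codon_position=codon_pos + 1, ref_codon=ref_codon)
    new_codon = ref_codon[:codon_pos] + new_base.upper() + ref_codon[codon_pos + 1 :]
    aa_ref = translate(ref_codon)
    aa_new = translate(new_codon)
    kind = "synonymous" if aa_ref == aa_new else "nonsynonymous"
    return CodonEffect(
        kind=kind, codon_position=codon_pos + 1,
        ref_codon=ref_codon, new_codon=new_codon, aa_ref=aa_ref, aa_new=aa_new,
    )


def indel_effect(record: DifferenceRecord, model: TransposonModel) -> Optional[CodonEffect]:
    """Frame consequence of an insertion/deletion record: frameshift when
    the indel length is not a codon multiple and it lies inside the CDS."""
    if record.kind not in ("insertion", "deletion"):
        raise ValueError("indel_effect applies to insertion/deletion records")
    fp = record.feature_position
    if fp is None or fp.feature != "cds":
        return None
    length = len(record.consensus_base) if record.kind == "insertion" else len(record.ref_base)
    return CodonEffect(kind="frameshift" if length % 3 else "in_frame_indel")


def _sort_key(model: TransposonModel, rec: DifferenceRecord):
    if rec.feature_position is None:
        return -0.5
    off = model.to_offset(rec.feature_position)
    return off + (0.5 if rec.kind == "insertion" else 0.0)


def diff_consensus(result: ConsensusResult, model: TransposonModel) -> list[DifferenceRecord]:
    """One record per position where the mapped consensus differs from the
    reference (substitutions, N's, insertions, deletions), in feature order."""
    if not result.is_mapped:
        raise ValueError("consensus must be mapped to the reference first")
    records: list[DifferenceRecord] = []
    variable_by_index = {}
    col_to_idx = {c: i for i, c in enumerate(result.columns)}
    for c, fv in result.variable:
        variable_by_index[col_to_idx[c]] = fv

    for idx, char in enumerate(result.consensus):
        fp = result.ref_positions[idx]
        if fp is None:
            continue  # insertion columns handled below
        ref_base = model.sequence[model.to_offset(fp)]
        if char == ref_base:
            continue
        in_br = classify_binding_region(fp, model) if fp.feature in ("left_itr", "right_itr") else None
        if char == "N":
            records.append(DifferenceRecord(
                feature_position=fp, kind="variable", ref_base=ref_base, consensus_base="N",
                in_binding_region=in_br,
                codon_effect=codon_effect(fp.position, ref_base, "N", model) if fp.feature == "cds" else None,
                frequency_vector=variable_by_index.get(idx),
            ))
        else:
            records.append(DifferenceRecord(
                feature_position=fp, kind="substitution", ref_base=ref_base, consensus_base=char,
                in_binding_region=in_br,
                codon_effect=codon_effect(fp.position, ref_base, char, model) if fp.feature == "cds" else None,
            ))

    for ins in result.insertions:
        rec = DifferenceRecord(
            feature_position=ins.anchor, kind="insertion", ref_base="", consensus_base=ins.bases,
            in_binding_region=(
                classify_binding_region(ins.anchor, model)
                if ins.anchor is not None and ins.anchor.feature in ("left_itr", "right_itr")
                else None
            ),
        )
        rec = dataclasses.replace(rec, codon_effect=indel_effect(rec, model))
        records.append(rec)

    # merge consecutive deleted reference positions into single records
    for group in _group_deletions(result.deletions, model):
        ref_bases = "".join(model.sequence[model.to_offset(fp)] for fp in group)
        rec = DifferenceRecord(
            feature_position=group[0], kind="deletion", ref_base=ref_bases, consensus_base="",
            in_binding_region=(
                classify_binding_region(group[0], model)
                if group[0].feature in ("left_itr", "right_itr") else None
            ),
        )
        rec = dataclasses.replace(rec, codon_effect=indel_effect(rec, model))
        records.append(rec)

    records.sort(key=lambda r: _sort_key(model, r))
    return records


def _group_deletions(deletions: Sequence[FeaturePosition], model: TransposonModel):
    groups: list[list[FeaturePosition]] = []
    last_off = None
    for fp in sorted(deletions, key=model.to_offset):
        off = model.to_offset(fp)
        if last_off is not None and off == last_off + 1:
            groups[-1].append(fp)
        else:
            groups.append([fp])
        last_off = off
    return groups


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_TSV_HEADER = (
    "feature\tposition\tkind\tref\talt\tin_binding_region\tcodon_position\teffect\t"
    "ref_codon\tnew_codon\taa_ref\taa_new\tfreq_A\tfreq_C\tfreq_G\tfreq_T\tfreq_gap"
)


def render_report(records: Sequence[DifferenceRecord], metadata: Optional[dict] = None) -> tuple[str, str]:
    """Render records as (human-readable summary, machine-readable TSV)."""
    metadata = metadata or {}
    lines = ["Consensus vs reference differences", "=" * 34]
    for k, v in metadata.items():
        lines.append(f"{k}: {v}")
    if not records:
        lines.append("No differences: the consensus is identical to the reference.")
    by_feature: dict[str, list[DifferenceRecord]] = {}
    for r in records:
        feat = r.feature_position.feature if r.feature_position else "full"
        by_feature.setdefault(feat, []).append(r)
    for feat in ("left_itr", "cds", "right_itr", "full"):
        recs = by_feature.get(feat, [])
        if not recs:
            continue
        n_sub = sum(r.kind == "substitution" for r in recs)
        n_var = sum(r.kind == "variable" for r in recs)
        n_ind = sum(r.kind in ("insertion", "deletion") for r in recs)
        lines.append(f"\n[{feat}] substitutions={n_sub} variable(N)={n_var} indels={n_ind}")
        if feat in ("left_itr", "right_itr"):
            outside = sum(r.in_binding_region is False for r in recs)
            inside = sum(r.in_binding_region is True for r in recs)
            uneval = sum(r.in_binding_region is None for r in recs)
            lines.append(f"  binding regions: inside={inside} outside={outside} unevaluable={uneval}")
        if feat == "cds":
            effects: dict[str, int] = {}
            for r in recs:
                if r.codon_effect:
                    effects[r.codon_effect.kind] = effects.get(r.codon_effect.kind, 0) + 1
            if effects:
                lines.append("  codon effects: " + ", ".join(f"{k}={v}" for k, v in sorted(effects.items())))
        for r in recs:
            pos = r.feature_position.position if r.feature_position else "5'"
            desc = {
                "substitution": f"{r.ref_base}->{r.consensus_base}",
                "variable": f"{r.ref_base}->N",
                "insertion": f"+{r.consensus_base}",
                "deletion": f"-{r.ref_base}",
            }[r.kind]
            extra = f" [{r.codon_effect.describe()}]" if r.codon_effect else ""
            br = {True: " (in binding region)", False: " (outside binding regions)", None: ""}[r.in_binding_region]
            lines.append(f"  pos {pos}: {desc}{extra}{br}")
    text = "\n".join(lines) + "\n"

    tsv_lines = [_TSV_HEADER]
    for r in records:
        fp = r.feature_position
        eff = r.codon_effect
        fv = r.frequency_vector
        tsv_lines.append("\t".join([
            fp.feature if fp else "none",
            str(fp.position) if fp else "",
            r.kind,
            r.ref_base,
            r.consensus_base,
            {True: "yes", False: "no", None: "NA"}[r.in_binding_region],
            str(eff.codon_position) if eff and eff.codon_position else "",
            eff.kind if eff else "",
            eff.ref_codon if eff else "",
            eff.new_codon if eff else "",
            eff.aa_ref if eff else "",
            eff.aa_new if eff else "",
            *[(repr(fv[s]) if fv else "") for s in ("A", "C", "G", "T", "gap")],
        ]))
    tsv = "\n".join(tsv_lines) + "\n"
    return text, tsv


def parse_report(tsv: str) -> list[DifferenceRecord]:
    """Inverse of the TSV half of :func:`render_report`."""
    lines = [ln for ln in tsv.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0] != _TSV_HEADER:
        raise ValueError("unrecognized differences TSV header")
    records = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(_TSV_HEADER.split("\t")):
            raise ValueError(f"malformed differences TSV row: {ln!r}")
        feature, pos, kind, ref, alt, in_br, codon_pos, eff_kind = f[:8]
        ref_codon, new_codon, aa_ref, aa_new = f[8:12]
        fv_fields = f[12:]
        fp = FeaturePosition(feature, int(pos)) if feature != "none" and pos else None
        eff = None
        if eff_kind:
            eff = CodonEffect(
                kind=eff_kind,
                codon_position=int(codon_pos) if codon_pos else None,
                ref_codon=ref_codon, new_codon=new_codon, aa_ref=aa_ref, aa_new=aa_new,
            )
        fv = None
        if any(fv_fields):
            fv = dict(zip(("A", "C", "G", "T", "gap"), (float(x) for x in fv_fields)))
        records.append(DifferenceRecord(
            feature_position=fp, kind=kind, ref_base=ref, consensus_base=alt,
            in_binding_region={"yes": True, "no": False, "NA": None}[in_br],
            codon_effect=eff, frequency_vector=fv,
        ))
    return records
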