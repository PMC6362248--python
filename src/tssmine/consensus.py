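"""Majority-rule consensus with an inclusive frequency threshold.

Per alignment column the nucleotide frequencies are tallied over the
counted rows (the reference row is excluded by default, and gaps count in
the denominator as a fifth symbol).  A base is called when its frequency
reaches the threshold (default 60%, *inclusive*); a column whose gap
frequency reaches the threshold emits nothing (a deletion relative to the
reference); anything else is a variable position written as 'N' and
carried with its full frequency vector for separate study.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np

from .msa import MultipleAlignment
from .sequence_io import FeaturePosition, TransposonModel

SYMBOLS = ("A", "C", "G", "T", "-")
_SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
_OTHER = len(SYMBOLS)  # bucket for ambiguity codes in input rows


@dataclasses.dataclass(frozen=True)
class ColumnProfile:
    """Per-column symbol counts over the counted rows."""

    counts: np.ndarray  # (n_cols, 6): A C G T gap other
    n_rows: int

    @property
    def n_cols(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_rows

    def column_frequencies(self, col: int) -> dict[str, float]:
        f = self.frequencies[col]
        return {"A": float(f[0]), "C": float(f[1]), "G": float(f[2]),
                "T": float(f[3]), "gap": float(f[4])}


@dataclasses.dataclass(frozen=True)
class Insertion:
    """Consensus bases absent from the reference, anchored to the
    reference position immediately preceding them (None at the 5' end)."""

    anchor: Optional[FeaturePosition]
    bases: str


@dataclasses.dataclass(frozen=True)
class ConsensusResult:
    consensus: str
    columns: tuple[int, ...]  # alignment column of each consensus symbol
    col_calls: tuple[str, ...]  # per alignment column: base, 'N' or '-'
    deletion_columns: tuple[int, ...]
    variable: tuple[tuple[int, dict], ...]  # (alignment column, freq vector)
    threshold: float
    profile: ColumnProfile
    # filled by map_to_reference
    ref_positions: Optional[tuple] = None  # FeaturePosition or None per consensus index
    insertions: tuple = ()
    deletions: tuple = ()
    variable_positions: tuple = ()  # (FeaturePosition or None, freq vector)
    reference_feature: str = "full"

    @property
    def is_mapped(self) -> bool:
        return self.ref_positions is not None


def column_frequencies(aln: MultipleAlignment, include_reference: bool = False) -> ColumnProfile:
    """Exact per-column tallies; gap is a counted fifth symbol."""
    rows = [s for rid, s in aln.rows if include_reference or rid != aln.reference_id]
    if not rows:
        raise ValueError("no rows to count")
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(len(rows), -1)
    counts = np.zeros((mat.shape[1], 6), dtype=np.int64)
    for sym, idx in _SYMBOL_INDEX.items():
        counts[:, idx] = (mat == ord(sym)).sum(axis=0)
    counts[:, _OTHER] = len(rows) - counts[:, :5].sum(axis=1)
    return ColumnProfile(counts=counts, n_rows=len(rows))


def call_consensus(profile: ColumnProfile, threshold: float = 0.60) -> ConsensusResult:
    """Call the majority consensus; the threshold is inclusive (>=)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    freqs = profile.frequencies
    consensus: list[str] = []
    columns: list[int] = []
    col_calls: list[str] = []
    deletion_columns: list[int] = []
    variable: list[tuple[int, dict]] = []
    for c in range(profile.n_cols):
        base_f = freqs[c, :4]
        best = int(np.argmax(base_f))  # argmax is deterministic: lowest index on ties
        if base_f[best] >= threshold:
            sym = SYMBOLS[best]
            consensus.append(sym)
            columns.append(c)
            col_calls.append(sym)
        elif freqs[c, 4] >= threshold:
            deletion_columns.append(c)
            col_calls.append("-")
        else:
            consensus.append("N")
            columns.append(c)
            col_calls.append("N")
            variable.append((c, profile.column_frequencies(c)))
    return ConsensusResult(
        consensus="".join(consensus),
        columns=tuple(columns),
        col_calls=tuple(col_calls),
        deletion_columns=tuple(deletion_columns),
        variable=tuple(variable),
        threshold=threshold,
        profile=profile,
    )


def map_to_reference(result: ConsensusResult, aln: MultipleAlignment, model: TransposonModel,
                     feature: str = "full") -> ConsensusResult:
    """Attach reference coordinates to a consensus.

    ``feature`` names the model feature the alignment's reference row
    corresponds to (the full sequence for whole-element strategies, or a
    single feature for per-feature searches).  Consensus bases at
    reference-gap columns become insertion records anchored to the
    preceding reference position; deletion columns over reference bases
    become deletion records.
    """
    ref_row = aln.reference_row()  # raises when there is no reference row
    span = model.feature_span(feature)
    if len(ref_row.replace("-", "")) != len(span):
        raise ValueError(
            f"reference row length {len(ref_row.replace('-', ''))} does not match "
            f"feature {feature!r} length {len(span)}"
        )
    col_to_consensus = {c: i for i, c in enumerate(result.columns)}
    deletion_cols = set(result.deletion_columns)

    ref_positions: list[Optional[FeaturePosition]] = [None] * len(result.consensus)
    insertions: list[Insertion] = []
    deletions: list[FeaturePosition] = []
    last_fp: Optional[FeaturePosition] = None
    pending_ins: Optional[list] = None  # [anchor, bases]

    ref_off = span.start
    for c in range(aln.n_cols):
        ref_char = ref_row[c]
        if ref_char != "-":
            fp = model.to_feature_position(ref_off)
            if c in col_to_consensus:
                ref_positions[col_to_consensus[c]] = fp
            elif c in deletion_cols:
                deletions.append(fp)
            last_fp = fp
            ref_off += 1
            pending_ins = None
        else:
            if c in col_to_consensus:
                sym = result.consensus[col_to_consensus[c]]
                if pending_ins is None:
                    pending_ins = [last_fp, sym]
                    insertions.append(pending_ins)
                else:
                    pending_ins[1] += sym
            # deletion column over a reference gap: nothing to record

    variable_positions = tuple(
        (ref_positions[col_to_consensus[c]], fv) for c, fv in result.variable
    )
    return dataclasses.replace(
        result,
        ref_positions=tuple(ref_positions),
        insertions=tuple(Insertion(a, b) for a, b in insertions),
        deletions=tuple(deletions),
        variable_positions=variable_positions,
        reference_feature=feature,
    )


def reference_calls(result: ConsensusResult, model: TransposonModel) -> dict[int, str]:
    """Map full-sequence reference offsets to the consensus call at that
    position (base, 'N', or '-' for deletions)."""
    if not result.is_mapped:
        raise ValueError("consensus has not been mapped to a reference")
    calls: dict[int, str] = {}
    for idx, fp in enumerate(result.ref_positions):
        if fp is not None:
            calls[model.to_offset(fp)] = result.consensus[idx]
    for fp in result.deletions:
        calls[model.to_offset(fp)] = "-"
    return calls


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------


def write_frequency_table(result: ConsensusResult, aln: MultipleAlignment,
                          model: Optional[TransposonModel], path: str | Path,
                          header_lines: tuple[str, ...] = ()) -> None:
    """Per-column TSV: counts, frequencies (0.1% precision) and the call."""
    profile = result.profile
    col_to_consensus = {c: i for i, c in enumerate(result.columns)}
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("column\tref_feature\tref_position\t" +
                 "\t".join(f"n_{s if s != '-' else 'gap'}" for s in SYMBOLS) +
                 "\t" + "\t".join(f"f_{s if s != '-' else 'gap'}" for s in SYMBOLS) +
                 "\tcall\n")
        freqs = profile.frequencies
        for c in range(profile.n_cols):
            feature, pos = "", ""
            if result.is_mapped and c in col_to_consensus:
                fp = result.ref_positions[col_to_consensus[c]]
                if fp is None:
                    feature, pos = "insertion", ""
                else:
                    feature, pos = fp.feature, str(fp.position)
            counts = "\t".join(str(int(x)) for x in profile.counts[c, :5])
            fr = "\t".join(f"{100 * x:.1f}" for x in freqs[c, :5])
            fh.write(f"{c}\t{feature}\t{pos}\t{counts}\t{fr}\t{result.col_calls[c]}\n")


def write_variable_report(result: ConsensusResult, path: str | Path,
                          header_lines: tuple[str, ...] = ()) -> None:
    """TSV of variable ('N') positions with their frequency vectors."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("column\tref_feature\tref_position\tf_A\tf_C\tf_G\tf_T\tf_gap\n")
        for i, (c, fv) in enumerate(result.variable):
            feature, pos = "", ""
            if result.is_mapped:
                fp = result.variable_positions[i][0]
                if fp is None:
                    feature = "insertion"
                else:
                    feature, pos = fp.feature, str(fp.position)
            fr = "\t".join(f"{100 * fv[s]:.1f}" for s in ("A", "C", "G", "T", "gap"))
            fh.write(f"{c}\t{feature}\t{pos}\t{fr}\n")
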