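"""Multiple alignment of recovered elements, with automated curation.

Two engines share one output type:

* ``builtin`` — deterministic center-star progressive alignment anchored
  on the reference (or the longest sequence), with affine-gap pairwise
  alignments (match +1, mismatch -1, gap open -4, extend -1).
* ``mafft`` — subprocess adapter around an external MAFFT binary; the
  mode can be forced, or chosen by a 200-sequence heuristic.

Curation replaces the traditional manual pruning of alignment rows with a
reproducible rule: any non-reference row whose gap fraction exceeds a
threshold (default 10%) is dropped.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .sequence_io import read_fasta, write_fasta


@dataclasses.dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows over common columns; at most one row is the reference."""

    rows: tuple[tuple[str, str], ...]
    reference_id: Optional[str] = None
    curation_dropped: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        n = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != n:
                raise ValueError(f"row {rid!r} has length {len(row)} != {n}")
        if self.reference_id is not None and self.reference_id not in {r for r, _ in self.rows}:
            raise ValueError(f"reference row {self.reference_id!r} not in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def reference_row(self) -> str:
        if self.reference_id is None:
            raise ValueError("alignment has no reference row")
        return self.row(self.reference_id)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


def _make_aligner(match: float = 1, mismatch: float = -1, gap_open: float = -4,
                  gap_extend: float = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _pairwise_profile(aligner: Align.PairwiseAligner, center: str, other: str):
    """Per-center-position view of the best global alignment of ``other``.

    Returns (ins_before, aligned) where ins_before[j] holds the bases of
    ``other`` inserted before center position j (index L = after the end)
    and aligned[j] is the ``other`` character aligned to center base j
    ('-' for a deletion).
    """
    L = len(center)
    aln = aligner.align(center, other)[0]
    coords = aln.coordinates
    ins_before = [""] * (L + 1)
    aligned = ["-"] * L
    for s in range(coords.shape[1] - 1):
        c0, c1 = int(coords[0, s]), int(coords[0, s + 1])
        o0, o1 = int(coords[1, s]), int(coords[1, s + 1])
        if c1 > c0 and o1 > o0:  # aligned block
            for off in range(c1 - c0):
                aligned[c0 + off] = other[o0 + off]
        elif c1 == c0 and o1 > o0:  # insertion in other before center pos c0
            ins_before[c0] += other[o0:o1]
        # c1 > c0 and o1 == o0: deletion in other; aligned stays '-'
    return ins_before, aligned


def align(sequences: Sequence[tuple[str, str]], reference: Optional[tuple[str, str]] = None,
          *, engine: str = "builtin", mafft_mode: str = "auto",
          scores: tuple[float, float, float, float] = (1, -1, -4, -1)) -> MultipleAlignment:
    """Align sequences (optionally with a reference row placed first).

    The builtin engine is a center-star progressive alignment anchored on
    the reference, or on the longest sequence when no reference is given.
    Requesting the external engine when the binary is missing raises; it
    never falls back silently.
    """
    if len(sequences) + (1 if reference else 0) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [rid for rid, _ in sequences] + ([reference[0]] if reference else [])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    if engine == "mafft":
        return _align_mafft(sequences, reference, mafft_mode)
    if engine != "builtin":
        raise ValueError(f"unknown alignment engine {engine!r}")

    if reference is not None:
        center_id, center = reference
        others = list(sequences)
    else:
        center_id, center = max(sequences, key=lambda r: (len(r[1]), -sequences.index(r)))
        others = [r for r in sequences if r[0] != center_id]

    aligner = _make_aligner(*scores)
    profiles = [(rid, _pairwise_profile(aligner, center, seq)) for rid, seq in others]
    L = len(center)
    master_ins = [0] * (L + 1)
    for _, (ins_before, _) in profiles:
        for j in range(L + 1):
            master_ins[j] = max(master_ins[j], len(ins_before[j]))

    def build_row(ins_before, aligned):
        parts = []
        for j in range(L):
            ins = ins_before[j]
            parts.append(ins + "-" * (master_ins[j] - len(ins)))
            parts.append(aligned[j])
        ins = ins_before[L]
        parts.append(ins + "-" * (master_ins[L] - len(ins)))
        return "".join(parts)

    center_row = build_row([""] * (L + 1), list(center))
    rows = []
    if reference is not None:
        rows.append((center_id, center_row))
        rows.extend((rid, build_row(*prof)) for rid, prof in profiles)
    else:
        by_id = {rid: build_row(*prof) for rid, prof in profiles}
        by_id[center_id] = center_row
        rows = [(rid, by_id[rid]) for rid, _ in sequences]
    out = MultipleAlignment(tuple(rows), reference_id=reference[0] if reference else None)
    _check_roundtrip(out, sequences, reference)
    return out


def _check_roundtrip(aln: MultipleAlignment, sequences, reference):
    inputs = dict(sequences)
    if reference is not None:
        inputs[reference[0]] = reference[1]
    for rid, _ in aln.rows:
        if aln.ungapped(rid) != inputs[rid].upper().replace("-", ""):
            raise AssertionError(f"alignment row {rid!r} does not ungap to its input")


def _align_mafft(sequences, reference, mode: str) -> MultipleAlignment:
    if shutil.which("mafft") is None:
        raise FileNotFoundError("external aligner requested but 'mafft' is not on PATH")
    records = ([reference] if reference else []) + list(sequences)
    n = len(records)
    if mode == "auto":
        # heuristic switch at 200 sequences: iterative refinement for the
        # small sets, fast progressive for the large ones
        mode = "linsi" if n <= 200 else "fftns2"
    flags = {"fftns2": ["--retree", "2"], "linsi": ["--localpair", "--maxiterate", "1000"]}
    if mode not in flags:
        raise ValueError(f"unknown MAFFT mode {mode!r}")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        # index-based ids: mafft truncates/alters long ids
        write_fasta([(f"s{i}", seq) for i, (_, seq) in enumerate(records)], inp)
        proc = subprocess.run(
            ["mafft", *flags[mode], "--quiet", str(inp)],
            capture_output=True, text=True, check=True,
        )
        out_path = Path(tmp) / "out.fasta"
        out_path.write_text(proc.stdout)
        aligned = read_fasta(out_path)
    order = {f"s{i}": i for i in range(n)}
    rows = [None] * n
    for rid, seq in aligned:
        rows[order[rid]] = (records[order[rid]][0], seq.upper())
    aln = MultipleAlignment(tuple(rows), reference_id=reference[0] if reference else None)
    _check_roundtrip(aln, sequences, reference)
    return aln


def curate(aln: MultipleAlignment, max_gap_fraction: float = 0.10) -> MultipleAlignment:
    """Drop non-reference rows whose gap fraction exceeds the threshold,
    then delete columns left all-gap by the removal."""
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    kept, dropped = [], []
    for rid, row in aln.rows:
        if rid == aln.reference_id:
            kept.append((rid, row))
            continue
        gap_frac = row.count("-") / len(row)
        if gap_frac > max_gap_fraction:
            dropped.append(rid)
        else:
            kept.append((rid, row))
    if not kept:
        raise ValueError("curation removed every row")
    cols = [i for i in range(len(kept[0][1])) if any(row[i] != "-" for _, row in kept)]
    new_rows = tuple((rid, "".join(row[i] for i in cols)) for rid, row in kept)
    return MultipleAlignment(
        new_rows,
        reference_id=aln.reference_id,
        curation_dropped=tuple(aln.curation_dropped) + tuple(dropped),
    )


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    write_fasta(aln.rows, path)


def read_alignment(path: str | Path, reference_id: Optional[str] = None) -> MultipleAlignment:
    return MultipleAlignment(tuple(read_fasta(path)), reference_id=reference_id)
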