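"""Two-step "transposase trim" search.

A transposase (CDS) hit alone cannot distinguish a mobile element from an
ITR-less transposase-homologous gene.  The trim search therefore extends
every CDS hit by a fixed flank (default 500 nt) on each side and keeps the
hit only when the left ITR is detectable in the upstream flank and the
right ITR in the downstream flank — both taken in *query orientation*, so
retention is strand-invariant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from . import homology_search as hs
from .homology_search import Hit, SearchParams
from .sequence_io import TransposonModel, reverse_complement


@dataclasses.dataclass(frozen=True)
class TrimParams:
    """Flank length and ITR detection thresholds.

    The defaults (identity 0.75 over at least 80% of the ITR query) are
    permissive enough for ~90%-identity family members while making a
    chance 227-nt match inside a 500-nt flank vanishingly unlikely.
    """

    flank: int = 500
    itr_min_identity: float = 0.75
    itr_min_coverage: float = 0.80
    search: SearchParams = dataclasses.field(default_factory=SearchParams)

    def __post_init__(self):
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        for f in (self.itr_min_identity, self.itr_min_coverage):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class _ItrLocation:
    """ITR detection inside an oriented flank (element-axis coordinates)."""

    start: int  # on the oriented window
    end: int


def _oriented_window(chrom_seq: str, hit: Hit, flank: int) -> tuple[str, int, int]:
    """Window = hit span +- flank, oriented so the element reads left-to-right.

    Returns (oriented sequence, genomic window start, genomic window end).
    """
    a = max(0, hit.start - flank)
    b = min(len(chrom_seq), hit.end + flank)
    window = chrom_seq[a:b].upper()
    if hit.strand == "-":
        window = reverse_complement(window)
    return window, a, b


def _find_itr(flank_seq: str, itr_query: str, params: TrimParams) -> _ItrLocation | None:
    if len(flank_seq) < params.search.word_size:
        return None
    hits = hs.find_hits([("flank", flank_seq)], itr_query, params.search)
    best = None
    for h in hits:
        coverage = (h.q_end - h.q_start) / len(itr_query)
        if h.strand == "+" and h.identity >= params.itr_min_identity and coverage >= params.itr_min_coverage:
            if best is None or h.score > best.score:
                best = h
    if best is None:
        return None
    return _ItrLocation(best.start, best.end)


def _locate_itrs(chrom_seq: str, hit: Hit, model: TransposonModel, params: TrimParams):
    """Locate both ITRs in the oriented flanks of a CDS hit.

    Returns (left location, right location, window metadata); either
    location is None when the ITR is not detected (including flanks fully
    clipped at a chromosome end).
    """
    window, a, b = _oriented_window(chrom_seq, hit, params.flank)
    # position of the CDS hit on the oriented window axis
    if hit.strand == "+":
        cds_lo, cds_hi = hit.start - a, hit.end - a
    else:
        cds_lo, cds_hi = b - hit.end, b - hit.start
    up_flank = window[:cds_lo]
    down_flank = window[cds_hi:]
    left_q = model.feature_sequence("left_itr")
    right_q = model.feature_sequence("right_itr")
    left = _find_itr(up_flank, left_q, params)
    right = _find_itr(down_flank, right_q, params)
    if right is not None:
        right = _ItrLocation(right.start + cds_hi, right.end + cds_hi)
    return left, right, (window, a, b)


def trim_search(genome, cds_hits: Sequence[Hit], model: TransposonModel,
                params: TrimParams | None = None) -> list[Hit]:
    """Keep CDS hits whose 500-nt flanks contain both ITRs; dedupe afterwards."""
    params = params or TrimParams()
    seqs = dict(hs._normalise_genome(genome))
    retained = []
    for h in cds_hits:
        left, right, _ = _locate_itrs(seqs[h.chrom], h, model, params)
        if left is not None and right is not None:
            retained.append(h)
    return hs.dedupe_hits(retained, genome)


def assemble_full_elements(genome, retained_hits: Sequence[Hit], model: TransposonModel,
                           params: TrimParams | None = None) -> list[tuple[str, str]]:
    """Assemble each retained CDS hit into a full-length, query-oriented
    element spanning the detected left-ITR start through the right-ITR end.

    Element ids encode the genomic span as ``chrom:start-end(strand)``.
    """
    params = params or TrimParams()
    seqs = dict(hs._normalise_genome(genome))
    elements = []
    for h in retained_hits:
        left, right, (window, a, b) = _locate_itrs(seqs[h.chrom], h, model, params)
        if left is None or right is None:
            raise ValueError(f"hit {h.id} did not pass trim verification")
        if left.end > right.start:
            raise ValueError(f"element {h.id}: overlapping ITR detections")
        seq = window[left.start : right.end]
        if h.strand == "+":
            g_start, g_end = a + left.start, a + right.end
        else:
            g_start, g_end = b - right.end, b - left.start
        elements.append((f"{h.chrom}:{g_start}-{g_end}({h.strand})", seq))
    return elements
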