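"""Permissive seed-and-extend homology search for transposon copies.

The search mirrors a BLAT-style permissive parameterisation: short exact
seeds (default word size 11) sampled along the genome with a small stride
(default 5), optionally allowing one mismatch per seed, chained on
diagonal bands and extended with a local alignment.  It is meant to
recover *all* family members down to ~75% identity on desk-scale genomes;
bit-compatibility with an external tool is available through the PSL
adapter (:func:`read_psl` / :func:`write_psl`).

Coordinates are 0-based half-open on the target; minus-strand hits report
query coordinates on the plus (input) strand of the query, as in PSL.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import reverse_complement

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

MATCH = 1
MISMATCH = -1
GAP = -2

# ungapped identity a seed neighbourhood must reach before it is chained;
# rejects the large background of spurious one-mismatch seed matches while
# keeping >=75%-identity family members (hundreds of seeds per copy)
SEED_VERIFY_IDENTITY = 0.65
SEED_VERIFY_EXT = 25  # nt of context on each side of the seed


@dataclasses.dataclass(frozen=True)
class SearchParams:
    """Tuning of the built-in search.

    Defaults mirror a permissive external-tool setup: ``step`` is the seed
    sampling stride on the target and ``allow_one_mismatch`` admits seeds
    with a single mismatching base.  ``xdrop`` is retained for
    compatibility with score-drop extension schemes; the local-DP
    extension used here does not consult it.
    """

    word_size: int = 11
    step: int = 5
    allow_one_mismatch: bool = True
    xdrop: int = 20
    min_identity: float = 0.0
    min_score: int = 0
    match: int = MATCH
    mismatch: int = MISMATCH
    gap: int = GAP

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class Hit:
    """One genomic locus matched by a query.

    ``matches``/``mismatches``/``q_gaps``/``t_gaps`` partition the aligned
    columns; ``q_start``/``q_end`` are plus-strand query coordinates.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matches: int
    mismatches: int
    q_gaps: int
    t_gaps: int
    q_start: int
    q_end: int
    q_size: int
    score: int
    q_name: str = "query"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty hit span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError("query span outside query")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def aligned_len(self) -> int:
        return self.matches + self.mismatches + self.q_gaps + self.t_gaps

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_len if self.aligned_len else 0.0

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


# ---------------------------------------------------------------------------
# encoding / seeding helpers
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (no ambiguous base)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (codes >= 4).astype(np.int32)
    cb = np.concatenate([[0], np.cumsum(bad)])
    valid = (cb[k:] - cb[:-k]) == 0
    clean = np.where(codes >= 4, 0, codes).astype(np.int64)
    acc = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        acc = acc * 4 + clean[j : j + n - k + 1]
    return acc, valid


def _query_index(query: str, params: SearchParams):
    """Map k-mer code -> list of (query position, strand) including one-off neighbours."""
    k = params.word_size
    index: dict[int, list[tuple[int, str]]] = {}
    oriented = {}
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        qc = _encode(qseq)
        oriented[strand] = qc
        codes, valid = _kmer_codes(qc, k)
        powers = [4 ** (k - 1 - p) for p in range(k)]
        for qpos in np.nonzero(valid)[0]:
            code = int(codes[qpos])
            entry = (int(qpos), strand)
            index.setdefault(code, []).append(entry)
            if params.allow_one_mismatch:
                for p in range(k):
                    cur = int(qc[qpos + p])
                    for b in range(4):
                        if b != cur:
                            index.setdefault(code + (b - cur) * powers[p], []).append(entry)
    keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    keys.sort()
    return index, keys, oriented


def _verify_seed(gcodes: np.ndarray, qcodes: np.ndarray, gpos: int, qpos: int, k: int) -> bool:
    left = min(SEED_VERIFY_EXT, qpos, gpos)
    right = min(SEED_VERIFY_EXT, len(qcodes) - qpos - k, len(gcodes) - gpos - k)
    g = gcodes[gpos - left : gpos + k + right]
    q = qcodes[qpos - left : qpos + k + right]
    ident = np.mean((g == q) & (g < 4))
    return ident >= SEED_VERIFY_IDENTITY


# ---------------------------------------------------------------------------
# local alignment (linear gap penalty, vectorised rows)
# ---------------------------------------------------------------------------


def _local_align(q: np.ndarray, w: np.ndarray, match: int, mismatch: int, gap: int):
    """Smith-Waterman with linear gaps; returns span/statistics of the best hit.

    The within-row (gap-in-query) dependency is resolved with a running
    maximum over ``tmp[k] + gap*(j-k)``, which is exact for linear gap
    costs.  Scores fit int16 for desk-scale queries.
    """
    m, n = len(q), len(w)
    if m == 0 or n == 0:
        return None
    S = np.zeros((m + 1, n + 1), dtype=np.int16)
    decay = -gap
    ramp = decay * np.arange(n, dtype=np.int32)
    for i in range(1, m + 1):
        prev = S[i - 1]
        qi = q[i - 1]
        sub = np.where((w == qi) & (w < 4) & (qi < 4), match, mismatch).astype(np.int32)
        tmp = np.maximum(prev[:-1] + sub, prev[1:].astype(np.int32) + gap)
        np.maximum(tmp, 0, out=tmp)
        run = np.maximum.accumulate(tmp + ramp)
        S[i, 1:] = (run - ramp).astype(np.int16)
    flat = int(np.argmax(S))
    i, j = divmod(flat, n + 1)
    score = int(S[i, j])
    if score <= 0:
        return None
    i_end, j_end = i, j
    matches = mismatches = q_gaps = t_gaps = 0
    while S[i, j] > 0:
        s = int(S[i, j])
        if i > 0 and j > 0:
            is_match = q[i - 1] == w[j - 1] and q[i - 1] < 4
            if s == int(S[i - 1, j - 1]) + (match if is_match else mismatch):
                if is_match:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and s == int(S[i - 1, j]) + gap:
            q_gaps += 1
            i -= 1
            continue
        if j > 0 and s == int(S[i, j - 1]) + gap:
            t_gaps += 1
            j -= 1
            continue
        break
    return {
        "score": score,
        "q_span": (i, i_end),
        "w_span": (j, j_end),
        "matches": matches,
        "mismatches": mismatches,
        "q_gaps": q_gaps,
        "t_gaps": t_gaps,
    }


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _normalise_genome(genome) -> list[tuple[str, str]]:
    if isinstance(genome, Mapping):
        return list(genome.items())
    return list(genome)


def find_hits(genome, query: str, params: SearchParams | None = None, *, q_name: str = "query") -> list[Hit]:
    """Find all copies of ``query`` in ``genome`` on both strands.

    ``genome`` is a list of ``(id, sequence)`` records or a mapping.
    Seeds are sampled every ``params.step`` nt, verified ungapped, chained
    within a diagonal band of +-10% of the query length, and each chain is
    extended by local alignment over its candidate window.  Output order
    is deterministic: (chrom, start, strand).
    """
    params = params or SearchParams()
    query = query.upper()
    qlen = len(query)
    k = params.word_size
    if qlen < k:
        raise ValueError(f"query length {qlen} < word_size {k}")
    records = _normalise_genome(genome)
    if not records:
        return []
    index, keys, oriented_q = _query_index(query, params)
    band = max(int(0.10 * qlen), k)
    hits: list[Hit] = []
    for chrom, seq in records:
        gcodes = _encode(seq.upper())
        codes, valid = _kmer_codes(gcodes, k)
        if len(codes) == 0:
            continue
        sample = np.arange(0, len(codes), params.step)
        sample = sample[valid[sample]]
        if len(sample) == 0:
            continue
        member = np.isin(codes[sample], keys)
        seeds: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        for gpos in sample[member]:
            gpos = int(gpos)
            for qpos, strand in index[int(codes[gpos])]:
                if _verify_seed(gcodes, oriented_q[strand], gpos, qpos, k):
                    seeds[strand].append((gpos, qpos))
        for strand in "+-":
            strand_seeds = sorted(set(seeds[strand]))
            chains = _chain_seeds(strand_seeds, qlen, band)
            for chain in chains:
                hit = _extend_chain(
                    chain, gcodes, oriented_q[strand], chrom, strand, qlen, band, params, q_name
                )
                if hit is not None:
                    hits.append(hit)
    hits = _resolve_overlaps(hits)
    if params.min_identity > 0:
        hits = [h for h in hits if h.identity >= params.min_identity]
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def _chain_seeds(seeds: list[tuple[int, int]], qlen: int, band: int):
    """Single-linkage chaining of (gpos, qpos) seeds on diagonal bands."""
    chains: list[dict] = []
    active: list[dict] = []
    for gpos, qpos in seeds:
        diag = gpos - qpos
        active = [c for c in active if gpos - c["last_g"] <= qlen]
        placed = False
        for c in active:
            if abs(diag - c["diag0"]) <= band:
                c["seeds"].append((gpos, qpos))
                c["last_g"] = gpos
                placed = True
                break
        if not placed:
            c = {"diag0": diag, "seeds": [(gpos, qpos)], "last_g": gpos}
            chains.append(c)
            active.append(c)
    return chains


def _extend_chain(chain, gcodes, qcodes, chrom, strand, qlen, band, params: SearchParams, q_name):
    glen = len(gcodes)
    gstart = max(0, min(g - q for g, q in chain["seeds"]) - band)
    gend = min(glen, max(g + (qlen - q) for g, q in chain["seeds"]) + band)
    res = _local_align(qcodes, gcodes[gstart:gend], params.match, params.mismatch, params.gap)
    if res is None or res["score"] <= params.min_score:
        return None
    ws, we = res["w_span"]
    qs, qe = res["q_span"]
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    return Hit(
        chrom=chrom,
        start=gstart + ws,
        end=gstart + we,
        strand=strand,
        matches=res["matches"],
        mismatches=res["mismatches"],
        q_gaps=res["q_gaps"],
        t_gaps=res["t_gaps"],
        q_start=qs,
        q_end=qe,
        q_size=qlen,
        score=res["score"],
        q_name=q_name,
    )


def _resolve_overlaps(hits: list[Hit]) -> list[Hit]:
    """Among hits overlapping by >50% of the shorter (either strand — an
    element whose ITRs mirror each other also aligns full-length on the
    wrong strand), keep the higher score, then the leftmost start."""
    kept: list[Hit] = []
    by_key: dict[str, list[Hit]] = {}
    for h in hits:
        by_key.setdefault(h.chrom, []).append(h)
    for group in by_key.values():
        group.sort(key=lambda h: (-h.score, h.start, h.end, h.strand))
        accepted: list[Hit] = []
        for h in group:
            clash = False
            for a in accepted:
                ov = min(h.end, a.end) - max(h.start, a.start)
                if ov > 0.5 * min(h.length, a.length):
                    clash = True
                    break
            if not clash:
                accepted.append(h)
        kept.extend(accepted)
    return kept


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_by_length(hits: Sequence[Hit], query_len: int, max_dev: float = 0.10) -> list[Hit]:
    """Keep hits whose span length deviates from ``query_len`` by at most
    ``max_dev`` (fractional); deviation strictly greater is discarded."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    limit = max_dev * query_len
    return [h for h in hits if abs(h.length - query_len) <= limit]


def filter_by_identity(hits: Sequence[Hit], min_identity: float) -> list[Hit]:
    """Keep hits with identity at least ``min_identity`` (inclusive)."""
    return [h for h in hits if h.identity >= min_identity]


def extract_hit_sequences(genome, hits: Sequence[Hit]) -> list[tuple[str, str]]:
    """Extract hit sequences in query orientation (minus hits reverse-complemented)."""
    seqs = dict(_normalise_genome(genome))
    out = []
    for h in hits:
        if h.chrom not in seqs:
            raise ValueError(f"hit {h.id}: unknown chromosome {h.chrom!r}")
        chrom_seq = seqs[h.chrom]
        if h.end > len(chrom_seq):
            raise ValueError(f"hit {h.id}: span outside chromosome of length {len(chrom_seq)}")
        s = chrom_seq[h.start : h.end].upper()
        if h.strand == "-":
            s = reverse_complement(s)
        out.append((h.id, s))
    return out


def dedupe_hits(hits: Sequence[Hit], genome) -> list[Hit]:
    """Remove sequence duplicates: among hits whose extracted (oriented)
    sequences are identical, retain the representative with the lowest
    (chrom, start, strand). Input order is preserved otherwise."""
    extracted = extract_hit_sequences(genome, hits)
    reps: dict[str, Hit] = {}
    for h, (_, s) in zip(hits, extracted):
        cur = reps.get(s)
        if cur is None or (h.chrom, h.start, h.strand) < (cur.chrom, cur.start, cur.strand):
            reps[s] = h
    keep = {id(h) for h in reps.values()}
    return [h for h in hits if id(h) in keep]


# ---------------------------------------------------------------------------
# PSL adapter
# ---------------------------------------------------------------------------

_PSL_COLS = 21


def write_psl(hits: Sequence[Hit], path: str | Path, *, t_sizes: Mapping[str, int] | None = None,
              header: bool = False) -> None:
    """Write hits as single-block PSL rows (UCSC 21-column layout)."""
    t_sizes = t_sizes or {}
    with open(path, "w") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write("match\tmis-\trep.\tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ\tQ\tQ\tQ\tT\tT\tT\tT\tblock\tblockSizes\tqStarts\ttStarts\n")
            fh.write("\tmatch\tmatch\t\tcount\tbases\tcount\tbases\t\tname\tsize\tstart\tend\tname\tsize\tstart\tend\tcount\n")
            fh.write("-" * 120 + "\n")
        for h in hits:
            row = [
                h.matches, h.mismatches, 0, 0,
                1 if h.q_gaps else 0, h.q_gaps,
                1 if h.t_gaps else 0, h.t_gaps,
                h.strand, h.q_name, h.q_size, h.q_start, h.q_end,
                h.chrom, t_sizes.get(h.chrom, 0), h.start, h.end,
                1, f"{h.length},", f"{h.q_start},", f"{h.start},",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_psl(path: str | Path) -> list[Hit]:
    """Read a PSL file (with or without the 5-line header) into hits."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < _PSL_COLS:
                fields = line.split()
            if not fields[0] or not fields[0][0].isdigit():
                continue  # header lines
            if len(fields) != _PSL_COLS:
                raise ValueError(f"{path}:{lineno}: expected {_PSL_COLS} PSL columns, got {len(fields)}")
            try:
                matches = int(fields[0])
                mismatches = int(fields[1])
                q_gaps = int(fields[5])
                t_gaps = int(fields[7])
                strand = fields[8]
                q_name = fields[9]
                q_size = int(fields[10])
                q_start, q_end = int(fields[11]), int(fields[12])
                chrom = fields[13]
                t_start, t_end = int(fields[15]), int(fields[16])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PSL row ({exc})") from exc
            hits.append(Hit(
                chrom=chrom, start=t_start, end=t_end, strand=strand,
                matches=matches, mismatches=mismatches, q_gaps=q_gaps, t_gaps=t_gaps,
                q_start=q_start, q_end=q_end, q_size=q_size,
                score=matches - mismatches - 2 * (q_gaps + t_gaps),
                q_name=q_name,
            ))
    return hits
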