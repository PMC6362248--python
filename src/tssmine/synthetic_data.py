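"""Synthetic genomes with planted transposon copies and full ground truth.

The generator embodies a star-phylogeny neutral-divergence model: every
planted copy diverges independently from one ancestral element by i.i.d.
per-site substitutions (transition:transversion ratio ``kappa``) and
optional indels, so a majority-rule consensus over enough copies recovers
the ancestor wherever the realized majority clears the threshold.  Decoys
are ITR-less transposase-like insertions (the case the trim search must
reject), and copies can be truncated to emulate degenerate elements.

Every random draw derives from one mandatory seed through per-copy
substreams, so a given parameter set reproduces byte-identical genomes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sequence_io import (
    BindingRegion,
    FeaturePosition,
    Span,
    TransposonModel,
    reverse_complement,
)

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """A site where a chosen fraction of copies carries a non-ancestral base."""

    position: int  # 0-based offset on the ancestor
    alleles: tuple[tuple[str, float], ...]  # (base, carrier_fraction), disjoint carriers


@dataclasses.dataclass(frozen=True)
class SimParams:
    seed: int
    genome_length: int = 2_000_000
    gc_content: float = 0.5
    n_copies: int = 50
    p_sub: float = 0.03
    kappa: float = 2.0
    p_indel: float = 0.0
    indel_mean: float = 2.0
    truncation_prob: float = 0.0
    truncation_extent: tuple[float, float] = (0.1, 0.5)
    n_decoys: int = 0
    strand_prob: float = 0.5
    min_gap: int = 1200  # keeps flank windows of neighbouring insertions disjoint
    n_chroms: int = 1
    variant_sites: tuple[VariantSite, ...] = ()

    def __post_init__(self):
        for name in ("p_sub", "p_indel", "gc_content", "strand_prob", "truncation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclasses.dataclass(frozen=True)
class CopyTruth:
    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str  # planted sequence in ancestor orientation (post truncation)
    log: tuple = ()
    trunc_left: int = 0
    trunc_right: int = 0
    is_decoy: bool = False


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    copies: tuple[CopyTruth, ...]
    decoys: tuple[CopyTruth, ...]
    ancestor: str
    model: TransposonModel
    params: SimParams


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------


def _draw_substitution(base: str, kappa: float, rng: np.random.Generator) -> str:
    ts_prob = kappa / (kappa + 2.0)
    if rng.random() < ts_prob:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(0, 2)]


def mutate_copy(ancestor: str, params: SimParams, rng: np.random.Generator) -> tuple[str, tuple]:
    """Apply i.i.d. substitutions/indels; the log replays exactly.

    Log entries: ``('sub', pos, ref, alt)``, ``('ins', pos, '', bases)``
    (bases inserted before ancestor position ``pos``) and
    ``('del', pos, deleted, '')`` — positions are ancestor coordinates.
    """
    out: list[str] = []
    log: list[tuple] = []
    n = len(ancestor)
    i = 0
    while i < n:
        if params.p_indel > 0 and rng.random() < params.p_indel:
            if rng.random() < 0.5:
                length = int(rng.geometric(1.0 / params.indel_mean))
                bases = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
                out.append(bases)
                log.append(("ins", i, "", bases))
            else:
                length = min(int(rng.geometric(1.0 / params.indel_mean)), n - i)
                log.append(("del", i, ancestor[i : i + length], ""))
                i += length
                continue
        base = ancestor[i]
        if base in _TRANSITION and rng.random() < params.p_sub:
            alt = _draw_substitution(base, params.kappa, rng)
            log.append(("sub", i, base, alt))
            out.append(alt)
        else:
            out.append(base)
        i += 1
    return "".join(out), tuple(log)


def replay_log(ancestor: str, log: Sequence[tuple]) -> str:
    """Reapply a mutation log to the ancestor (exact reconstruction)."""
    subs = {e[1]: e[3] for e in log if e[0] == "sub"}
    dels = {e[1]: len(e[2]) for e in log if e[0] == "del"}
    ins = {e[1]: e[3] for e in log if e[0] == "ins"}
    out: list[str] = []
    n = len(ancestor)
    i = 0
    while i <= n:
        if i in ins:
            out.append(ins[i])
        if i == n:
            break
        if i in dels:
            i += dels[i]
            continue
        out.append(subs.get(i, ancestor[i]))
        i += 1
    return "".join(out)


def plant_variant_site(copies: Sequence[str], position: int, base: str,
                       carrier_fraction: float, rng: np.random.Generator) -> list[str]:
    """Give exactly ``round(carrier_fraction * n)`` copies the variant base."""
    if not (0.0 <= carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must be in [0, 1]")
    n = len(copies)
    k = round(carrier_fraction * n)
    carriers = set(rng.permutation(n)[:k].tolist())
    out = []
    for idx, seq in enumerate(copies):
        if idx in carriers:
            seq = seq[:position] + base + seq[position + 1 :]
        out.append(seq)
    return out


def _apply_variant_sites(copies: list[str], sites: Sequence[VariantSite],
                         rng: np.random.Generator) -> list[str]:
    n = len(copies)
    for site in sites:
        perm = rng.permutation(n)
        cursor = 0
        for base, fraction in site.alleles:
            k = round(fraction * n)
            for idx in perm[cursor : cursor + k]:
                s = copies[idx]
                copies[idx] = s[: site.position] + base + s[site.position + 1 :]
            cursor += k
    return copies


def _truncate(seq: str, params: SimParams, rng: np.random.Generator) -> tuple[str, int, int]:
    if params.truncation_prob <= 0 or rng.random() >= params.truncation_prob:
        return seq, 0, 0
    lo, hi = params.truncation_extent
    cut = int(len(seq) * rng.uniform(lo, hi))
    if rng.random() < 0.5:
        return seq[cut:], cut, 0
    return seq[: len(seq) - cut], 0, cut


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def generate_genome(model: TransposonModel, params: SimParams,
                    ancestor: Optional[str] = None) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Plant diverged copies and decoys into an i.i.d. background genome.

    ``ancestor`` defaults to the model sequence; pass a variant sequence
    to emulate a family whose true ancestor differs from the search query.
    Copies/decoys overwrite the background at uniformly drawn,
    non-overlapping locations (separated by ``min_gap``), reverse-
    complemented with probability ``strand_prob``.
    """
    ancestor = (ancestor or model.sequence).upper()
    ss = np.random.SeedSequence(params.seed)
    n_items = params.n_copies + params.n_decoys
    children = ss.spawn(3 + n_items)
    bg_rng = np.random.default_rng(children[0])
    place_rng = np.random.default_rng(children[1])
    variant_rng = np.random.default_rng(children[2])
    item_seeds = children[3:]

    copies = [ancestor] * params.n_copies
    copies = _apply_variant_sites(copies, params.variant_sites, variant_rng)

    planted: list[dict] = []
    for i in range(params.n_copies):
        rng = np.random.default_rng(item_seeds[i])
        seq, log = mutate_copy(copies[i], params, rng)
        seq, tl, tr = _truncate(seq, params, rng)
        planted.append({"id": f"copy_{i:04d}", "seq": seq, "log": log,
                        "tl": tl, "tr": tr, "decoy": False})
    decoy_src = ancestor[model.cds.start : min(model.cds.end, len(ancestor))]
    for i in range(params.n_decoys):
        rng = np.random.default_rng(item_seeds[params.n_copies + i])
        seq, log = mutate_copy(decoy_src, params, rng)
        planted.append({"id": f"decoy_{i:04d}", "seq": seq, "log": log,
                        "tl": 0, "tr": 0, "decoy": True})

    # chromosomes
    chrom_len = params.genome_length // params.n_chroms
    chrom_names = [f"chr{c + 1}" for c in range(params.n_chroms)]
    backgrounds = {name: _random_background(chrom_len, params.gc_content, bg_rng)
                   for name in chrom_names}

    # uniform non-overlapping placement
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}
    placements = []
    for item in planted:
        length = len(item["seq"])
        placed = False
        for _ in range(2000):
            chrom = chrom_names[int(place_rng.integers(0, params.n_chroms))]
            if chrom_len - length <= 0:
                break
            start = int(place_rng.integers(0, chrom_len - length))
            lo, hi = start - params.min_gap, start + length + params.min_gap
            if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                strand = "-" if place_rng.random() < params.strand_prob else "+"
                placements.append((item, chrom, start, strand))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: could not place {item['id']} "
                f"({params.n_copies} copies + {params.n_decoys} decoys in {params.genome_length} nt)"
            )

    copy_truths, decoy_truths = [], []
    for item, chrom, start, strand in placements:
        seq = item["seq"]
        inserted = reverse_complement(seq) if strand == "-" else seq
        arr = np.frombuffer(inserted.encode("ascii"), dtype=np.uint8)
        backgrounds[chrom][start : start + len(arr)] = arr
        truth = CopyTruth(
            copy_id=item["id"], chrom=chrom, start=start, end=start + len(seq),
            strand=strand, seq=seq, log=item["log"],
            trunc_left=item["tl"], trunc_right=item["tr"], is_decoy=item["decoy"],
        )
        (decoy_truths if item["decoy"] else copy_truths).append(truth)

    records = [(name, backgrounds[name].tobytes().decode("ascii")) for name in chrom_names]
    truth = SyntheticTruth(
        copies=tuple(sorted(copy_truths, key=lambda t: t.copy_id)),
        decoys=tuple(sorted(decoy_truths, key=lambda t: t.copy_id)),
        ancestor=ancestor,
        model=model,
        params=params,
    )
    return records, truth


def write_truth_table(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tchrom\tstart\tend\tstrand\tn_subs\tn_indels\ttrunc_left\ttrunc_right\tis_decoy\n")
        for t in list(truth.copies) + list(truth.decoys):
            n_subs = sum(e[0] == "sub" for e in t.log)
            n_indels = sum(e[0] in ("ins", "del") for e in t.log)
            fh.write(f"{t.copy_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                     f"{n_subs}\t{n_indels}\t{t.trunc_left}\t{t.trunc_right}\t{int(t.is_decoy)}\n")


# ---------------------------------------------------------------------------
# packaged demo model (synthetic)
# ---------------------------------------------------------------------------

_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if a + b + c not in ("TAA", "TAG", "TGA")]

# CDS codons pinned to the Sleeping Beauty codons at the positions where the
# Salmo salar Tss1 consensus is known to differ (1-based CDS coordinates).
_PINNED_CODONS = {97: "AAA", 376: "CGA", 382: "AAG", 511: "AAG", 634: "ATC", 643: "AAG"}
# ITR reference bases at the published difference/variable positions (1-based
# within the ITR); chosen so the known consensus variant differs from them.
_LEFT_ITR_REF = {31: "A", 61: "T", 88: "C", 105: "A", 138: "A"}
_RIGHT_ITR_REF = {60: "G", 87: "T", 176: "G"}


def demo_model() -> TransposonModel:
    """Deterministic synthetic reference transposon with Sleeping-Beauty-like
    geometry (227-nt ITRs, 1022-nt CDS, 1638 nt total).

    This is a synthetic stand-in, NOT the real Sleeping Beauty sequence:
    the backbone is random, the right ITR is a slightly diverged reverse
    complement of the left, and only the codons/bases at the positions
    where the published salmon consensus differs from Sleeping Beauty are
    pinned, so annotation demos reproduce the published difference classes
    on synthetic sequence.  Binding-region spans are synthetic, editable
    config values.
    """
    rng = np.random.default_rng(20190204)

    left = [BASES[b] for b in rng.integers(0, 4, size=227)]
    for pos, base in _LEFT_ITR_REF.items():
        left[pos - 1] = base
    left_itr = "".join(left)

    spacer1 = "".join(BASES[b] for b in rng.integers(0, 4, size=73))

    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=340)]
    for cds_pos, codon in _PINNED_CODONS.items():
        codons[(cds_pos - 1) // 3] = codon
    cds = "".join(codons) + "GT"  # 1022 nt: 340 codons + trailing partial codon
    assert len(cds) == 1022

    spacer2 = "".join(BASES[b] for b in rng.integers(0, 4, size=89))

    right = list(reverse_complement(left_itr))
    for pos in (12, 45, 101, 140, 200):  # mild divergence between the two ITRs
        right[pos] = _TRANSITION[right[pos]]
    for pos, base in _RIGHT_ITR_REF.items():
        right[pos - 1] = base
    right_itr = "".join(right)

    sequence = left_itr + spacer1 + cds + spacer2 + right_itr
    assert len(sequence) == 1638
    return TransposonModel(
        name="tss1_demo_synthetic",
        sequence=sequence,
        left_itr=Span(0, 227),
        cds=Span(300, 1322),
        right_itr=Span(1411, 1638),
        cds_frame=0,
        binding_regions=(
            BindingRegion("left_itr", Span(2, 30)),
            BindingRegion("left_itr", Span(192, 220)),
            BindingRegion("right_itr", Span(1416, 1444)),
            BindingRegion("right_itr", Span(1600, 1628)),
        ),
    )


def demo_variant_setup(model: TransposonModel, n_copies: int = 50) -> dict:
    """Ancestor + variant sites reproducing the published Tss1 consensus
    difference table on the synthetic demo model.

    The ancestor carries the seven ITR substitutions (left 31/61/88/105,
    right 60/87/176), the five synonymous third-codon CDS substitutions
    (99, 378, 384, 513, 636) and the conserved single-base insertion after
    CDS position 718; the two variable sites (left ITR 138 and CDS 643)
    are planted as population mixtures below the 60% threshold.
    """
    seq = list(model.sequence)

    def set_fp(feature, pos, base):
        seq[model.to_offset(FeaturePosition(feature, pos))] = base

    left_subs = [(31, "G"), (61, "C"), (88, "T"), (105, "G")]
    right_subs = [(60, "A"), (87, "C"), (176, "C")]
    cds_subs = [(99, "G"), (378, "C"), (384, "A"), (513, "A"), (636, "A")]
    for pos, base in left_subs:
        set_fp("left_itr", pos, base)
    for pos, base in right_subs:
        set_fp("right_itr", pos, base)
    for pos, base in cds_subs:
        set_fp("cds", pos, base)
    insert_at = model.to_offset(FeaturePosition("cds", 718)) + 1  # after CDS position 718
    ancestor = "".join(seq[:insert_at]) + "A" + "".join(seq[insert_at:])

    variant_sites = (
        # left ITR 138: ~56% C vs ancestral A -> variable (N), just under threshold
        VariantSite(model.to_offset(FeaturePosition("left_itr", 138)), (("C", 0.56),)),
        # CDS 643: A/G/C/T mixture with no base reaching 60%
        VariantSite(model.to_offset(FeaturePosition("cds", 643)),
                    (("G", 0.22), ("C", 0.20), ("T", 0.14))),
    )
    return {
        "ancestor": ancestor,
        "variant_sites": variant_sites,
        "expected": {
            "left_itr_substitutions": left_subs,
            "right_itr_substitutions": right_subs,
            "cds_substitutions": cds_subs,
            "insertion_anchor_cds": 718,
            "variable_positions": [("left_itr", 138), ("cds", 643)],
        },
    }
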