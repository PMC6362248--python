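"""Sequence input/output and the reference transposon model.

A Tc1/mariner element is modelled as a nucleotide sequence carrying three
ordered features — a left inverted terminal repeat (ITR), a transposase
coding sequence (CDS), and a right ITR — plus the transposase binding
regions nested inside each ITR.  Internally every span is a 0-based
half-open interval on the full sequence; user-facing reports use 1-based
positions *within* the named feature, the convention used throughout the
transposon literature ("position 31 of the left repeat").
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

IUPAC_CHARS = set("ACGTRYSWKMBDHVN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"


@dataclasses.dataclass(frozen=True)
class Span:
    """0-based half-open interval on the model sequence."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, offset: int) -> bool:
        return self.start <= offset < self.end


@dataclasses.dataclass(frozen=True)
class BindingRegion:
    """Transposase binding region, nested inside its parent ITR."""

    itr: str  # "left_itr" or "right_itr"
    span: Span


@dataclasses.dataclass(frozen=True)
class FeaturePosition:
    """1-based position within a named feature (or the full sequence)."""

    feature: str  # left_itr | right_itr | cds | full
    position: int

    def __post_init__(self):
        if self.feature not in ("left_itr", "right_itr", "cds", "full"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.position < 1:
            raise ValueError("feature positions are 1-based")


@dataclasses.dataclass(frozen=True)
class TransposonModel:
    """Reference transposon with its feature coordinate system.

    ``cds_frame`` is the reading-frame offset (0/1/2) of the first codon
    within the CDS span; it is an explicit field because a CDS span length
    need not be a codon multiple (Sleeping Beauty's transposase region is
    quoted at 1022 nt).
    """

    name: str
    sequence: str
    left_itr: Span
    right_itr: Span
    cds: Span
    cds_frame: int = 0
    binding_regions: tuple[BindingRegion, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(f"non-IUPAC characters in model sequence: {sorted(bad)}")
        n = len(seq)
        for label in ("left_itr", "cds", "right_itr"):
            sp = getattr(self, label)
            if not (0 <= sp.start < sp.end <= n):
                raise ValueError(f"{label} span [{sp.start},{sp.end}) outside sequence of length {n}")
        if not (self.left_itr.end <= self.cds.start and self.cds.end <= self.right_itr.start):
            raise ValueError("features must be ordered left_itr < cds < right_itr without overlap")
        if self.cds_frame not in (0, 1, 2):
            raise ValueError("cds_frame must be 0, 1 or 2")
        for br in self.binding_regions:
            parent = getattr(self, br.itr, None)
            if br.itr not in ("left_itr", "right_itr"):
                raise ValueError(f"binding region parent must be an ITR, got {br.itr!r}")
            if not (parent.start <= br.span.start and br.span.end <= parent.end):
                raise ValueError(
                    f"binding region [{br.span.start},{br.span.end}) not nested in {br.itr}"
                )

    # -- feature coordinate system -------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_span(self, feature: str) -> Span:
        if feature == "full":
            return Span(0, self.length)
        if feature in ("left_itr", "right_itr", "cds"):
            return getattr(self, feature)
        raise ValueError(f"unknown feature {feature!r}")

    def feature_sequence(self, feature: str) -> str:
        sp = self.feature_span(feature)
        return self.sequence[sp.start : sp.end]

    def to_offset(self, pos: FeaturePosition) -> int:
        """FeaturePosition -> 0-based offset on the full sequence."""
        sp = self.feature_span(pos.feature)
        if pos.position > len(sp):
            raise ValueError(f"{pos} outside feature of length {len(sp)}")
        return sp.start + pos.position - 1

    def to_feature_position(self, offset: int) -> FeaturePosition:
        """0-based full-sequence offset -> FeaturePosition.

        ITR and CDS features take precedence; offsets in spacer regions
        report 1-based positions on the full sequence.
        """
        if not (0 <= offset < self.length):
            raise ValueError(f"offset {offset} outside [0, {self.length})")
        for feature in ("left_itr", "cds", "right_itr"):
            sp = self.feature_span(feature)
            if sp.contains(offset):
                return FeaturePosition(feature, offset - sp.start + 1)
        return FeaturePosition("full", offset + 1)

    def binding_regions_for(self, itr: str) -> list[BindingRegion]:
        return [br for br in self.binding_regions if br.itr == itr]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; IUPAC ambiguity codes are tolerated (they are
    matched as mismatches downstream).  Empty files, duplicate record ids
    and non-IUPAC characters are rejected with the offending record named.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"{path}: duplicated record id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)} (line {_find_bad_line(path, bad)})"
            )
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _find_bad_line(path: Path, bad_chars: set[str]) -> int:
    """Locate the first line containing an offending character (error path only)."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return i
    return 0


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Elementary sequence ops
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


def translate(cds_seq: str, frame: int = 0) -> str:
    """Translate with the standard genetic code.

    The trailing partial codon is dropped; stop codons read '*'; any codon
    containing a character outside A/C/G/T (including N) reads 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    s = cds_seq.upper()[frame:]
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        aas.append(_CODON_MAP.get(codon, "X"))
    return "".join(aas)


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------


def load_model(config: dict | str | Path) -> TransposonModel:
    """Build a validated :class:`TransposonModel` from a config mapping or YAML file.

    The config names the sequence (literal ``sequence`` or ``sequence_path``
    to a single-record FASTA) and all feature spans as 0-based half-open
    intervals::

        name: my_transposon
        sequence: ACGT...
        features:
          left_itr:  {start: 0, end: 227}
          cds:       {start: 300, end: 1322, frame: 0}
          right_itr: {start: 1411, end: 1638}
        binding_regions:
          - {itr: left_itr, start: 2, end: 30}
    """
    base_dir = Path(".")
    if not isinstance(config, dict):
        path = Path(config)
        base_dir = path.parent
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if "sequence" in config:
        seq = str(config["sequence"])
    elif "sequence_path" in config:
        seq_path = Path(config["sequence_path"])
        if not seq_path.is_absolute():
            seq_path = base_dir / seq_path
        records = read_fasta(seq_path)
        seq = records[0][1]
    else:
        raise ValueError("model config needs 'sequence' or 'sequence_path'")
    feats = config.get("features", {})
    for needed in ("left_itr", "cds", "right_itr"):
        if needed not in feats:
            raise ValueError(f"model config missing feature {needed!r}")
    spans = {k: Span(int(v["start"]), int(v["end"])) for k, v in feats.items()}
    brs = tuple(
        BindingRegion(br["itr"], Span(int(br["start"]), int(br["end"])))
        for br in config.get("binding_regions", [])
    )
    return TransposonModel(
        name=str(config.get("name", "transposon")),
        sequence=seq,
        left_itr=spans["left_itr"],
        cds=spans["cds"],
        right_itr=spans["right_itr"],
        cds_frame=int(feats["cds"].get("frame", 0)),
        binding_regions=brs,
    )


def model_to_config(model: TransposonModel) -> dict:
    """Inverse of :func:`load_model` (with a literal sequence)."""
    return {
        "name": model.name,
        "sequence": model.sequence,
        "features": {
            "left_itr": {"start": model.left_itr.start, "end": model.left_itr.end},
            "cds": {"start": model.cds.start, "end": model.cds.end, "frame": model.cds_frame},
            "right_itr": {"start": model.right_itr.start, "end": model.right_itr.end},
        },
        "binding_regions": [
            {"itr": br.itr, "start": br.span.start, "end": br.span.end}
            for br in model.binding_regions
        ],
    }


def save_model(model: TransposonModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_config(model), fh, sort_keys=False)
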