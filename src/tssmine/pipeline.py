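"""End-to-end pipeline: search -> filter -> (trim) -> dedupe -> align ->
curate -> consensus -> annotate -> tree, with per-stage artifacts.

Each run writes every intermediate product into the output directory so
genome-scale runs can be inspected or resumed per stage, and stamps every
tabular artifact with a hash of the configuration.  With the builtin
aligner and a fixed seed, re-running an identical configuration produces
byte-identical artifacts (wall-clock timings go to the log stream only,
never into artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

from . import annotate as ann
from . import consensus as cons
from . import homology_search as hs
from . import msa
from . import phylogeny as phylo
from . import trim_search as ts
from .sequence_io import TransposonModel, load_model, read_fasta, write_fasta

logger = logging.getLogger("tssmine")

STRATEGIES = ("full", "left_itr", "right_itr", "cds", "trim")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    genome: object  # path or list of (id, seq)
    model: object  # path, config dict, or TransposonModel
    outdir: object  # path
    strategy: str = "full"
    search: hs.SearchParams = dataclasses.field(default_factory=hs.SearchParams)
    trim: ts.TrimParams = dataclasses.field(default_factory=ts.TrimParams)
    max_length_dev: float = 0.10
    min_identity: float = 0.0
    curation_max_gap_fraction: float = 0.10
    consensus_threshold: float = 0.60
    include_reference_in_counts: bool = False
    aligner: str = "builtin"
    mafft_mode: str = "auto"
    tree: bool = True
    tree_correction: str = "k2p"
    bootstrap: int = 0
    psl_in: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not (0.0 < self.consensus_threshold <= 1.0):
            raise ValueError("consensus_threshold must be in (0, 1]")
        if not (0.0 <= self.curation_max_gap_fraction <= 1.0):
            raise ValueError("curation_max_gap_fraction must be in [0, 1]")


@dataclasses.dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    model: TransposonModel
    stage_counts: dict
    hits: list
    elements: list
    alignment: msa.MultipleAlignment
    curated: msa.MultipleAlignment
    profile: cons.ColumnProfile
    consensus: cons.ConsensusResult
    differences: list
    newick: Optional[str]
    artifacts: dict


def _config_fingerprint(config: RunConfig, genome_records, model: TransposonModel) -> str:
    payload = dataclasses.asdict(config)
    payload["genome"] = hashlib.sha256(
        "".join(f">{i}\n{s}\n" for i, s in genome_records).encode()
    ).hexdigest()
    payload["model"] = hashlib.sha256(model.sequence.encode()).hexdigest()
    payload["outdir"] = None
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str, counts: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    logger.info("stage=%s wall_s=%.2f", name, dt)
    return out


def run(config: RunConfig) -> PipelineResult:
    """Execute the configured strategy and write all stage artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    genome = config.genome if isinstance(config.genome, list) else read_fasta(config.genome)
    if isinstance(config.model, TransposonModel):
        model = config.model
    else:
        model = load_model(config.model)
    fingerprint = _config_fingerprint(config, genome, model)
    header = (f"config={fingerprint}",)

    feature = "cds" if config.strategy == "trim" else config.strategy
    query = model.feature_sequence(feature)

    if config.psl_in:
        hits = _stage("read_psl", counts, hs.read_psl, config.psl_in)
    else:
        hits = _stage("search", counts, hs.find_hits, genome, query, config.search,
                      q_name=f"{model.name}:{feature}")
    counts["search"] = len(hits)

    hits = _stage("length_filter", counts, hs.filter_by_length, hits, len(query),
                  config.max_length_dev)
    counts["length_filter"] = len(hits)

    if config.min_identity > 0:
        hits = _stage("identity_filter", counts, hs.filter_by_identity, hits, config.min_identity)
    counts["identity_filter"] = len(hits)

    if config.strategy == "trim":
        hits = _stage("trim_search", counts, ts.trim_search, genome, hits, model, config.trim)
        counts["trim_search"] = len(hits)
        elements = _stage("assemble", counts, ts.assemble_full_elements, genome, hits, model,
                          config.trim)
        ref_feature = "full"
    else:
        hits = _stage("dedupe", counts, hs.dedupe_hits, hits, genome)
        counts["dedupe"] = len(hits)
        elements = _stage("extract", counts, hs.extract_hit_sequences, genome, hits)
        ref_feature = feature
    counts["elements"] = len(elements)

    ref_seq = model.feature_sequence(ref_feature)
    alignment = _stage("align", counts, msa.align, elements, (model.name, ref_seq),
                       engine=config.aligner, mafft_mode=config.mafft_mode)
    curated = _stage("curate", counts, msa.curate, alignment, config.curation_max_gap_fraction)
    counts["curated_rows"] = curated.n_rows - 1  # reference excluded

    profile = _stage("frequencies", counts, cons.column_frequencies, curated,
                     config.include_reference_in_counts)
    result = _stage("consensus", counts, cons.call_consensus, profile,
                    config.consensus_threshold)
    result = _stage("map", counts, cons.map_to_reference, result, curated, model, ref_feature)
    counts["consensus_length"] = len(result.consensus)
    counts["variable_positions"] = len(result.variable)

    differences = _stage("diff", counts, ann.diff_consensus, result, model)
    counts["differences"] = len(differences)
    text_report, tsv_report = ann.render_report(
        differences,
        {"config": fingerprint, "strategy": config.strategy, "n_elements": len(elements)},
    )

    newick = None
    if config.tree and curated.n_rows >= 3:
        def build_tree():
            if config.bootstrap > 0:
                tree = phylo.bootstrap_support(curated, config.bootstrap, config.seed,
                                               config.tree_correction)
            else:
                dm = phylo.pairwise_distances(curated, config.tree_correction, on_saturation="p")
                tree = phylo.neighbor_joining(dm)
            return phylo.tree_to_newick(tree)
        newick = _stage("tree", counts, build_tree)

    artifacts = _write_artifacts(outdir, header, fingerprint, config, model, genome, hits,
                                 elements, alignment, curated, result, tsv_report, text_report,
                                 newick, counts)
    return PipelineResult(
        config=config, config_hash=fingerprint, model=model, stage_counts=counts,
        hits=hits, elements=elements, alignment=alignment, curated=curated,
        profile=profile, consensus=result, differences=differences,
        newick=newick, artifacts=artifacts,
    )


def _write_artifacts(outdir: Path, header, fingerprint, config, model, genome, hits, elements,
                     alignment, curated, result, tsv_report, text_report, newick, counts) -> dict:
    artifacts = {}

    def reg(name, path):
        artifacts[name] = str(path)
        return path

    t_sizes = {i: len(s) for i, s in genome}
    hs.write_psl(hits, reg("hits_psl", outdir / "hits.psl"), t_sizes=t_sizes)
    with open(reg("hits_tsv", outdir / "hits.tsv"), "w") as fh:
        fh.write(f"# {header[0]}\n")
        fh.write("chrom\tstart\tend\tstrand\tlength\tmatches\tmismatches\tq_gaps\tt_gaps\t"
                 "q_start\tq_end\tscore\tidentity\n")
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.length}\t{h.matches}\t"
                     f"{h.mismatches}\t{h.q_gaps}\t{h.t_gaps}\t{h.q_start}\t{h.q_end}\t"
                     f"{h.score}\t{h.identity:.4f}\n")
    write_fasta(elements, reg("elements", outdir / "elements.fasta"))
    msa.write_alignment(alignment, reg("alignment", outdir / "alignment.fasta"))
    msa.write_alignment(curated, reg("alignment_curated", outdir / "alignment_curated.fasta"))
    cons.write_frequency_table(result, curated, model,
                               reg("frequencies", outdir / "frequencies.tsv"), header)
    cons.write_variable_report(result, reg("variable", outdir / "variable_positions.tsv"), header)

    consensus_records = [(f"consensus_{config.strategy}", result.consensus)]
    if result.reference_feature == "full":
        for feat, seq in consensus_by_feature(result, model).items():
            consensus_records.append((f"consensus_{config.strategy}_{feat}", seq))
    write_fasta(consensus_records, reg("consensus", outdir / "consensus.fasta"))

    with open(reg("consensus_calls", outdir / "consensus_calls.tsv"), "w") as fh:
        fh.write(f"# {header[0]}\n")
        fh.write("ref_offset\tfeature\tposition\tcall\n")
        calls = cons.reference_calls(result, model)
        for off in sorted(calls):
            fp = model.to_feature_position(off)
            fh.write(f"{off}\t{fp.feature}\t{fp.position}\t{calls[off]}\n")

    with open(reg("differences", outdir / "differences.tsv"), "w") as fh:
        fh.write(f"# {header[0]}\n")
        fh.write(tsv_report)
    (outdir / "report.txt").write_text(text_report)
    artifacts["report"] = str(outdir / "report.txt")
    if newick is not None:
        (outdir / "tree.nwk").write_text(newick + "\n")
        artifacts["tree"] = str(outdir / "tree.nwk")

    log = {
        "config_hash": fingerprint,
        "strategy": config.strategy,
        "seed": config.seed,
        "parameters": {
            "search": dataclasses.asdict(config.search),
            "trim": dataclasses.asdict(config.trim),
            "max_length_dev": config.max_length_dev,
            "min_identity": config.min_identity,
            "curation_max_gap_fraction": config.curation_max_gap_fraction,
            "consensus_threshold": config.consensus_threshold,
        },
        "stage_counts": counts,
        "curation_dropped": list(curated.curation_dropped),
    }
    with open(reg("run_log", outdir / "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return artifacts


def consensus_by_feature(result: cons.ConsensusResult, model: TransposonModel) -> dict[str, str]:
    """Split a full-length mapped consensus into per-feature sequences
    (insertion bases follow the feature of their anchor)."""
    if not result.is_mapped:
        raise ValueError("consensus must be mapped first")
    parts: dict[str, list[str]] = {"left_itr": [], "cds": [], "right_itr": []}
    last_feature = None
    for idx, char in enumerate(result.consensus):
        fp = result.ref_positions[idx]
        feature = fp.feature if fp is not None else last_feature
        if feature in parts:
            parts[feature].append(char)
        last_feature = feature
    return {k: "".join(v) for k, v in parts.items() if v}


@dataclasses.dataclass(frozen=True)
class ConsensusComparison:
    ids: tuple[str, ...]
    agreement_pct: tuple  # pairwise matrix (tuple of tuples)
    overall_pct: float  # % of reference positions where all consensuses agree
    n_positions: int


def compare_consensuses(results: Sequence[cons.ConsensusResult], model: TransposonModel,
                        ids: Optional[Sequence[str]] = None) -> ConsensusComparison:
    """Per-position agreement between strategy consensuses on the shared
    reference coordinate system; 'N' calls compare as 'N'."""
    if len(results) < 2:
        raise ValueError("need at least 2 consensuses to compare")
    features = {r.reference_feature for r in results}
    if len(features) != 1:
        raise ValueError(f"consensuses map to different reference features: {features}")
    span = model.feature_span(features.pop())
    ids = tuple(ids) if ids else tuple(f"consensus_{i}" for i in range(len(results)))
    calls = [cons.reference_calls(r, model) for r in results]
    positions = list(range(span.start, span.end))
    n = len(results)
    matrix = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            agree = sum(calls[i][p] == calls[j][p] for p in positions)
            matrix[i][j] = matrix[j][i] = 100.0 * agree / len(positions)
    all_agree = sum(len({c[p] for c in calls}) == 1 for p in positions)
    return ConsensusComparison(
        ids=ids,
        agreement_pct=tuple(tuple(row) for row in matrix),
        overall_pct=100.0 * all_agree / len(positions),
        n_positions=len(positions),
    )
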