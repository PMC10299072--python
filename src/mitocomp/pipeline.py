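"""One-command comparative-mitogenomics pipeline.

``run_pipeline`` drives every analysis over a set of annotated genomes
(plus optional per-gene codon-aware alignments) and writes the full table
bundle: composition and skews, codon usage (RSCU, ENC, positional GC,
ENC-GC3 and neutrality plot data with the fitted line and the
selection/mutation shares), start/stop codon validation, sliding-window
nucleotide diversity, pairwise distance matrices, Ka/Ks, gene orders and
rearrangement calls with TDRL bounds, control-region tandem repeats, a
neighbor-joining tree, and a JSON manifest (package version, config,
input checksums) that makes every table re-derivable.

Partial inputs degrade gracefully: genomes without a control region skip
the repeat scan, and missing alignments skip the alignment-based tables —
always with a machine-greppable warning code on stderr, never silently.
Output is a pure function of (inputs, config, seed).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import (
    bias_summary,
    count_codons,
    enc_expected,
    genetic_code,
    neutrality_fit,
    rscu,
)
from .composition import region_composition
from .divergence import (
    AlignmentSet,
    kaks_matrix,
    mean_pairwise,
    nj_tree,
    pairwise_distance,
    read_fasta_alignment,
    sliding_window_pi,
)
from .gene_order import compare_orders, extract_gene_order, load_reference_order
from .genome_io import (
    AnnotatedMitogenome,
    extract_gene_sequence,
    feature_table,
    parse_genbank,
    validate_pcg_codons,
)
from .tandem_repeats import find_tandem_repeats, repeats_table

logger = logging.getLogger("mitocomp")

_TSV = dict(sep="\t", index=False, float_format="%.6g")


@dataclass
class PipelineConfig:
    """Declarative pipeline settings; defaults are the study-standard ones
    (translation table 5, 100 bp windows with 25 bp step, cox1 anchor)."""

    inputs: list[str] = field(default_factory=list)
    alignments: str | None = None          # directory of per-gene FASTA
    output_dir: str = "mitocomp_out"
    anchor: str = "cox1"
    table_id: int = 5
    window: int = 100
    step: int = 25
    distance_model: str = "MCL-composite"
    gap_policy: str = "complete"
    repeat_params: dict = field(default_factory=dict)
    reference_order: str | None = None     # TSV path; packaged default if None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(config: PipelineConfig):
    if config.reference_order is None:
        return load_reference_order()
    from .gene_order import GeneOrderPermutation

    genes = []
    for line in Path(config.reference_order).read_text().splitlines()[1:]:
        if line.strip():
            name, _ftype, strand = line.split("\t")
            genes.append((name, strand))
    return GeneOrderPermutation(tuple(genes), "reference")


def _load_alignments(config: PipelineConfig) -> dict[str, AlignmentSet]:
    out: dict[str, AlignmentSet] = {}
    if config.alignments is None:
        logger.warning("W-NO-ALIGNMENTS: alignment-based tables skipped")
        return out
    for path in sorted(Path(config.alignments).glob("*.fa*")):
        gene = path.stem
        try:
            out[gene] = read_fasta_alignment(path, gene, codon_aware=True)
        except Exception as exc:
            logger.warning("W-BAD-ALIGNMENT %s: %s", path, exc)
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all analyses; returns a name -> path map of the written bundle."""
    if not config.inputs:
        raise ValueError("no input genomes")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "distances").mkdir(exist_ok=True)
    written: dict[str, Path] = {}

    genomes = [parse_genbank(p) for p in sorted(config.inputs)]
    reference = _load_reference(config)
    alignments = _load_alignments(config)

    def emit(name: str, frame: pd.DataFrame, sub: str = "") -> None:
        path = out / sub / name if sub else out / name
        frame.to_csv(path, **_TSV)
        written[f"{sub}/{name}" if sub else name] = path

    # features / composition / codon validation -----------------------------
    emit("features.tsv", pd.concat([feature_table(g) for g in genomes]))
    emit("composition.tsv", pd.concat([region_composition(g) for g in genomes]))
    emit("codon_validation.tsv", pd.DataFrame(
        {"genome": g.identifier, **row.__dict__}
        for g in genomes for row in validate_pcg_codons(g)))

    # codon usage ------------------------------------------------------------
    code = genetic_code(config.table_id)
    usage_rows, summary_rows, points = [], [], []
    for g in genomes:
        seqs = [extract_gene_sequence(g, f.name)
                for f in sorted(g.features_of_type("PCG"), key=lambda f: f.name)]
        table = count_codons(seqs, config.table_id)
        values = rscu(table)
        usage_rows += [
            {"genome": g.identifier, "codon": c, "aa": code[c],
             "count": table.counts[c], "rscu": values[c]}
            for c in sorted(code)
        ]
        s = bias_summary(seqs, config.table_id)
        summary_rows.append({
            "genome": g.identifier, "ENC": s.enc, "ENC_reliable": s.enc_reliable,
            "GC1": s.gc1, "GC2": s.gc2, "GC3": s.gc3, "GC12": s.gc12,
            "used_codons": table.used_codon_count(),
        })
        points.append((s.gc3, s.gc12))
    emit("codon_usage.tsv", pd.DataFrame(usage_rows))
    summary = pd.DataFrame(summary_rows)
    emit("bias_summary.tsv", summary)
    emit("enc_gc3_plotdata.tsv", summary.assign(
        ENC_expected=[enc_expected(v) for v in summary["GC3"]]
    )[["genome", "GC3", "ENC", "ENC_expected"]])

    neut = summary[["genome", "GC3", "GC12"]]
    emit("neutrality_plotdata.tsv", neut)
    if len(points) >= 3:
        try:
            fit = neutrality_fit(points)
            emit("neutrality_fit.tsv", pd.DataFrame([{
                "slope": fit.slope, "intercept": fit.intercept, "r": fit.r,
                "p_value": fit.p_value, "n": fit.n,
                "mutation_share_pct": fit.mutation_share_pct,
                "selection_share_pct": fit.selection_share_pct,
            }]))
        except Exception as exc:
            logger.warning("W-NEUTRALITY-FIT: %s", exc)
    else:
        logger.warning("W-NEUTRALITY-FIT: fewer than 3 genomes, fit skipped")

    # alignment-based: Pi, distances, Ka/Ks, NJ ------------------------------
    if alignments:
        windows, kaks_frames, means = [], [], []
        concat_taxa = None
        concat_seqs = None
        for gene, aln in sorted(alignments.items()):
            try:
                wd = sliding_window_pi(aln, config.window, config.step,
                                       deletion=config.gap_policy)
                windows.append(wd.to_frame().assign(overall_pi=wd.overall_pi))
            except Exception as exc:
                logger.warning("W-PI %s: %s", gene, exc)
            mat = pairwise_distance(aln, config.distance_model)
            mat.to_csv(out / "distances" / f"{gene}.{config.distance_model}.tsv",
                       sep="\t", float_format="%.6g")
            written[f"distances/{gene}.{config.distance_model}.tsv"] = (
                out / "distances" / f"{gene}.{config.distance_model}.tsv")
            means.append({"gene": gene, "model": config.distance_model,
                          "mean_distance": mean_pairwise(mat),
                          "mean_distance_incl_saturated":
                              mean_pairwise(mat, skip_saturated=False)})
            if aln.codon_aware:
                try:
                    kaks_frames.append(kaks_matrix(aln, config.table_id))
                except Exception as exc:
                    logger.warning("W-KAKS %s: %s", gene, exc)
            if sorted(aln.taxa) == sorted(alignments[min(alignments)].taxa):
                if concat_taxa is None:
                    concat_taxa = list(aln.taxa)
                    concat_seqs = ["" for _ in concat_taxa]
                idx = [aln.taxa.index(t) for t in concat_taxa]
                concat_seqs = [s + aln.sequences[i] for s, i in zip(concat_seqs, idx)]
        if windows:
            emit("pi_windows.tsv", pd.concat(windows))
        emit("distance_means.tsv", pd.DataFrame(means))
        if kaks_frames:
            emit("kaks.tsv", pd.concat(kaks_frames))
        if concat_taxa and len(concat_taxa) >= 3:
            concat = AlignmentSet("concatenated", concat_taxa, concat_seqs)
            tree = nj_tree(pairwise_distance(concat, config.distance_model))
            tree_path = out / f"nj.{config.distance_model}.nwk"
            tree_path.write_text(tree + "\n")
            written[f"nj.{config.distance_model}.nwk"] = tree_path

    # gene order -------------------------------------------------------------
    order_rows, call_rows = [], []
    for g in genomes:
        try:
            order = extract_gene_order(g, config.anchor)
        except Exception as exc:
            logger.warning("W-ORDER %s: %s", g.identifier, exc)
            continue
        order_rows.append({
            "genome": g.identifier,
            "order": " ".join(f"{'-' if s == 'N' else ''}{n}" for n, s in order.genes),
        })
        try:
            for call in compare_orders(order, reference):
                call_rows.append({
                    "genome": g.identifier, "kind": call.kind,
                    "genes": ",".join(call.moved_genes),
                    "flank_before": call.dest_flanks[0],
                    "flank_after": call.dest_flanks[1],
                    "tdrl_events": ("NA" if call.tdrl_events is None
                                    else call.tdrl_events),
                })
        except Exception as exc:
            logger.warning("W-REARRANGEMENT %s: %s", g.identifier, exc)
    emit("gene_orders.tsv", pd.DataFrame(order_rows))
    emit("rearrangements.tsv", pd.DataFrame(
        call_rows, columns=["genome", "kind", "genes", "flank_before",
                            "flank_after", "tdrl_events"]))

    # control-region repeats -------------------------------------------------
    repeat_frames = []
    for g in genomes:
        try:
            cr = extract_gene_sequence(g, "CR")
        except KeyError:
            logger.warning("W-CR-MISSING %s: repeat scan skipped", g.identifier)
            continue
        hits = find_tandem_repeats(cr, **config.repeat_params)
        if hits:
            repeat_frames.append(repeats_table(hits, g.identifier))
    emit("repeats.tsv",
         pd.concat(repeat_frames) if repeat_frames else
         pd.DataFrame(columns=["genome", "start", "end", "period", "copies",
                               "identity", "consensus", "partial_leading",
                               "partial_trailing"]))

    # manifest ---------------------------------------------------------------
    manifest = {
        "mitocomp_version": __version__,
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in sorted(config.inputs)},
        "outputs": sorted(written),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest.json"] = manifest_path
    return written
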