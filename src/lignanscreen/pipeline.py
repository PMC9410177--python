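"""End-to-end orchestration: census -> synteny -> screen -> promoters -> qPCR.

The pipeline consumes a directory of standard-format inputs (the layout
written by :func:`lignanscreen.simulate.write_dataset`, or equivalently
prepared real data), runs every stage in order and writes all stage
tables plus a human-readable markdown report and a JSON summary.  Runs
are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import census as census_mod
from . import promoter as promoter_mod
from . import qpcr as qpcr_mod
from . import screen as screen_mod
from . import synteny as synteny_mod
from .errors import ConfigurationError, ValidationError
from .screen import PanelSpec, ScreenConfig

logger = logging.getLogger(__name__)

FAMILIES = ("POD", "LAC")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    ``input_dir`` must contain the standard bundle: per-variety GFF3 and
    domain-hit tables, scan.tsv, edges.tsv, anchor tables, genome and
    expression files (see the simulator's ``write_dataset``).
    """

    input_dir: Path
    out_dir: Path
    varieties: tuple[str, ...]
    reference_variety: str
    white_variety: str
    black_variety: str
    organ_varieties: tuple[str, ...]
    oil_varieties: tuple[str, ...]
    calibrator_sample: str | None = None
    qpcr_reference_gene: str = "SiACT7"
    min_score: float = 50.0
    min_anchors: int = 5
    max_gap: int = 25
    promoter_length: int = 2000
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        screen = ScreenConfig(**raw.pop("screen", {}))
        for key in ("varieties", "organ_varieties", "oil_varieties"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(input_dir=Path(raw.pop("input_dir")),
                   out_dir=Path(raw.pop("out_dir")),
                   screen=screen, **raw)

    @classmethod
    def for_dataset(cls, input_dir: str | Path, out_dir: str | Path,
                    **overrides) -> "PipelineConfig":
        """Infer variety roles from a simulator-written dataset directory."""
        input_dir = Path(input_dir)
        varieties = sorted(
            p.stem for p in input_dir.glob("*.gff3") if p.stem != "arabidopsis")
        if len(varieties) < 6:
            raise ConfigurationError(
                f"PipelineConfig: expected >= 6 variety GFF3 files in {input_dir}")
        varieties.sort(key=lambda v: (len(v), v))  # var1 < var2 < ... < var10
        kwargs = dict(
            input_dir=input_dir, out_dir=Path(out_dir),
            varieties=tuple(varieties), reference_variety=varieties[0],
            organ_varieties=(varieties[0],),
            oil_varieties=tuple(varieties[1:4]),
            white_variety=varieties[4], black_variety=varieties[5])
        kwargs.update(overrides)
        return cls(**kwargs)

    def required_paths(self) -> dict[str, Path]:
        d = self.input_dir
        paths = {
            "scan": d / "scan.tsv",
            "edges": d / "edges.tsv",
            "anchors_intra": d / "anchors_intra.tsv",
            "anchors_cross": d / "anchors_cross.tsv",
            "gff_arabidopsis": d / "arabidopsis.gff3",
            "genome": d / "genome.fasta",
            "elements": d / "elements.tsv",
            "binding_map": d / "binding_map.tsv",
            "expression": d / "expression.tsv",
            "samples": d / "samples.tsv",
            "profile": d / "profile.tsv",
            "ct": d / "ct.tsv",
        }
        for var in self.varieties:
            paths[f"gff_{var}"] = d / f"{var}.gff3"
            for fam in FAMILIES:
                paths[f"hits_{fam}_{var}"] = d / f"{fam.lower()}_hits_{var}.domtbl"
        return paths

    def validate_paths(self) -> None:
        missing = [str(p) for p in self.required_paths().values() if not p.exists()]
        if missing:
            raise ConfigurationError(f"missing input paths: {missing}")


@dataclass
class PipelineResult:
    assignments: dict[str, list]                 # family -> FamilyAssignment
    per_variety_counts: dict[str, dict[str, int]]  # family -> variety -> n
    orthogroups: list
    intersection_counts: dict
    blocks_intra: list
    blocks_cross: list
    duplication_calls: list
    synteny_fractions: dict[str, tuple[int, int]]
    screen_report: pd.DataFrame
    final_candidates: list[str]
    category_table: pd.DataFrame
    enrichment: pd.DataFrame
    qpcr_relative: pd.DataFrame
    qpcr_r2: float
    summary: dict


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs and write the report bundle."""
    config.screen.validate()
    config.validate_paths()
    paths = config.required_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: family census -----------------------------------------
    scan_table = census_mod.read_scan_table(paths["scan"])
    assignments: dict[str, list] = {fam: [] for fam in FAMILIES}
    accepted_by_variety: dict[str, dict[str, list[str]]] = {f: {} for f in FAMILIES}
    gene_family: dict[str, str] = {}
    gene_variety: dict[str, str] = {}
    for var in config.varieties:
        for fam in FAMILIES:
            hits = census_mod.read_domtblout(paths[f"hits_{fam}_{var}"])
            calls = census_mod.call_family_members(hits, fam)
            calls = census_mod.verify_domains(calls, scan_table)
            assignments[fam].extend(calls)
            accepted = census_mod.accepted_gene_ids(calls)
            accepted_by_variety[fam][var] = accepted
            for g in accepted:
                gene_family[g] = fam
                gene_variety[g] = var

    per_variety_counts = {
        fam: {var: len(accepted_by_variety[fam][var]) for var in config.varieties}
        for fam in FAMILIES}
    count_summaries = {fam: census_mod.summarize_counts(per_variety_counts[fam])
                       for fam in FAMILIES}

    # ---- stage 2: orthogroups -------------------------------------------
    edges = census_mod.read_similarity_edges(paths["edges"])
    edges = edges[edges["gene_a"].isin(gene_variety) & edges["gene_b"].isin(gene_variety)]
    groups = census_mod.cluster_orthogroups(edges, gene_variety, config.min_score)
    groups, intersections = census_mod.classify_orthogroups(groups, config.varieties)

    # ---- stage 3: synteny and duplication --------------------------------
    ref = config.reference_variety
    ref_genes = synteny_mod.assign_ranks(
        synteny_mod.read_gff3_genes(paths[f"gff_{ref}"]))
    at_genes = synteny_mod.assign_ranks(
        synteny_mod.read_gff3_genes(paths["gff_arabidopsis"]))
    anchors_intra = synteny_mod.read_anchor_table(paths["anchors_intra"])
    anchors_cross = synteny_mod.read_anchor_table(paths["anchors_cross"])
    blocks_intra = synteny_mod.chain_collinear_blocks(
        anchors_intra, ref_genes, ref_genes,
        max_gap=config.max_gap, min_anchors=config.min_anchors)
    blocks_cross = synteny_mod.chain_collinear_blocks(
        anchors_cross, ref_genes, at_genes,
        max_gap=config.max_gap, min_anchors=config.min_anchors)
    strong = edges[edges["score"] >= config.min_score]
    ref_gene_ids = {g.gene_id for g in ref_genes}
    paralog_pairs = sorted(
        {tuple(sorted((a, b)))
         for a, b in strong[["gene_a", "gene_b"]].itertuples(index=False)
         if a in ref_gene_ids and b in ref_gene_ids and a != b})
    calls = synteny_mod.classify_duplicates(paralog_pairs, blocks_intra, ref_genes)
    synteny_fractions = {}
    for fam in FAMILIES:
        fam_ref = {g for g in ref_gene_ids if gene_family.get(g) == fam}
        if fam_ref:
            synteny_fractions[fam] = synteny_mod.interspecies_synteny_fraction(
                fam_ref, blocks_cross)

    # ---- stage 4: expression screen --------------------------------------
    expr = screen_mod.ExpressionMatrix.from_tsv(paths["expression"], paths["samples"])
    profile = screen_mod.KineticProfile.from_tsv(paths["profile"])
    panels = PanelSpec(organ_varieties=config.organ_varieties,
                       oil_varieties=config.oil_varieties,
                       white_variety=config.white_variety,
                       black_variety=config.black_variety)
    report = screen_mod.run_screen(expr, profile, groups, panels, config.screen)
    finals = screen_mod.final_candidates(report)

    # ---- stage 5: promoters and regulation -------------------------------
    from Bio import SeqIO
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(paths["genome"], "fasta")}
    cand_models = [g for g in ref_genes if g.gene_id in finals]
    promoters = promoter_mod.extract_promoters(cand_models, genome,
                                               config.promoter_length)
    elements = promoter_mod.read_element_table(paths["elements"])
    occurrences = promoter_mod.scan_motifs(promoters, elements)
    category_table = promoter_mod.categorize_elements(
        occurrences, elements, sorted(promoters))
    binding_map = promoter_mod.read_binding_map(paths["binding_map"])
    background = set(expr.genes)
    enrichment = (promoter_mod.tf_enrichment(set(finals), binding_map, background)
                  if finals else pd.DataFrame(
                      columns=["family", "k", "K", "n", "N", "p", "q"]))

    # ---- stage 6: qPCR validation -----------------------------------------
    ct = qpcr_mod.read_ct_table(paths["ct"])
    ct_samples = sorted(set(ct["sample"]))
    calibrator = config.calibrator_sample or ct_samples[0]
    relative = qpcr_mod.ddct(ct, config.qpcr_reference_gene, calibrator)
    shared_genes = [g for g in relative.index if g in set(expr.genes)]
    fpkm_shared = expr.fpkm.loc[shared_genes, [
        s for s in relative.columns if s in expr.fpkm.columns]]
    qpcr_r2 = (qpcr_mod.concordance(relative.loc[shared_genes, fpkm_shared.columns],
                                    fpkm_shared)
               if fpkm_shared.size >= 3 else float("nan"))

    # ---- outputs ----------------------------------------------------------
    class_counts = {cls: sum(1 for og in groups if og.cls == cls)
                    for cls in ("core", "shared", "specific")}
    dup_counts: dict[str, int] = {"tandem": 0, "segmental": 0, "dispersed": 0}
    for call in calls:
        dup_counts[call.cls] += 1
    summary = {
        "thresholds": {
            "min_score": config.min_score,
            "min_anchors": config.min_anchors,
            "max_gap": config.max_gap,
            "screen": vars(config.screen),
        },
        "per_variety_counts": per_variety_counts,
        "count_summaries": {fam: {"mean": m, "sd": s}
                            for fam, (m, s) in count_summaries.items()},
        "orthogroup_classes": class_counts,
        "n_orthogroups": len(groups),
        "duplication_classes": dup_counts,
        "synteny_fractions": {fam: {"count": c, "percent": p}
                              for fam, (c, p) in synteny_fractions.items()},
        "final_candidates": finals,
        "top_tf_families": enrichment["family"].head(5).tolist()
                           if len(enrichment) else [],
        "qpcr_r2": qpcr_r2,
    }

    census_mod.census_table(groups).to_csv(out / "orthogroups.tsv", sep="\t",
                                           index=False)
    synteny_mod.blocks_table(blocks_intra).to_csv(out / "blocks_intra.tsv",
                                                  sep="\t", index=False)
    synteny_mod.blocks_table(blocks_cross).to_csv(out / "blocks_cross.tsv",
                                                  sep="\t", index=False)
    synteny_mod.calls_table(calls).to_csv(out / "duplication_calls.tsv",
                                          sep="\t", index=False)
    report.to_csv(out / "screen_report.tsv", sep="\t", float_format="%.6g")
    promoter_mod.occurrences_table(occurrences).to_csv(
        out / "motif_occurrences.tsv", sep="\t", index=False)
    category_table.to_csv(out / "element_categories.tsv", sep="\t")
    enrichment.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")
    relative.to_csv(out / "qpcr_relative.tsv", sep="\t", float_format="%.6g")

    result = PipelineResult(
        assignments=assignments, per_variety_counts=per_variety_counts,
        orthogroups=groups, intersection_counts=intersections,
        blocks_intra=blocks_intra, blocks_cross=blocks_cross,
        duplication_calls=calls, synteny_fractions=synteny_fractions,
        screen_report=report, final_candidates=finals,
        category_table=category_table, enrichment=enrichment,
        qpcr_relative=relative, qpcr_r2=qpcr_r2, summary=summary)
    write_report(result, out)
    return result


REQUIRED_SUMMARY_KEYS = {
    "thresholds": dict, "per_variety_counts": dict, "count_summaries": dict,
    "orthogroup_classes": dict, "n_orthogroups": int,
    "duplication_classes": dict, "synteny_fractions": dict,
    "final_candidates": list, "top_tf_families": list,
}


def validate_summary(summary: dict) -> None:
    """Schema check for the JSON summary; raises ValidationError on gaps."""
    for key, typ in REQUIRED_SUMMARY_KEYS.items():
        if key not in summary:
            raise ValidationError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValidationError(
                f"summary key {key!r} has type {type(summary[key]).__name__}, "
                f"expected {typ.__name__}")
    if "qpcr_r2" not in summary:
        raise ValidationError("summary missing key 'qpcr_r2'")


def write_report(result: PipelineResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the markdown report and JSON summary for a finished run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = result.summary
    validate_summary(s)
    lines = ["# Peroxidase/laccase pan-genome screen report", ""]
    lines.append("## Thresholds")
    lines.append("```")
    lines.append(json.dumps(s["thresholds"], indent=2, sort_keys=True))
    lines.append("```")
    lines.append("## Family census")
    for fam, stats in sorted(s["count_summaries"].items()):
        counts = s["per_variety_counts"][fam]
        lines.append(
            f"- {fam}: mean {stats['mean']:.1f} +/- sd {stats['sd']:.1f} "
            f"(reported {round(stats['mean'])} +/- {round(stats['sd'])}); "
            f"per variety: "
            + ", ".join(f"{v}={n}" for v, n in sorted(counts.items())))
    oc = s["orthogroup_classes"]
    lines.append(f"- orthogroups: {s['n_orthogroups']} total — "
                 f"{oc['core']} core, {oc['shared']} shared, "
                 f"{oc['specific']} variety-specific")
    lines.append("## Duplication and synteny")
    dc = s["duplication_classes"]
    lines.append(f"- paralog pairs: {dc['segmental']} segmental, "
                 f"{dc['tandem']} tandem, {dc['dispersed']} dispersed")
    for fam, frac in sorted(s["synteny_fractions"].items()):
        lines.append(f"- {fam}: {frac['count']} genes syntenic with the "
                     f"outgroup ({frac['percent']}%)")
    lines.append("## Candidate screen")
    if s["final_candidates"]:
        lines.append("- final candidates: " + ", ".join(s["final_candidates"]))
    else:
        lines.append("- final candidates: none passed all criteria")
    lines.append("## Regulation")
    lines.append("- top TF families: "
                 + (", ".join(s["top_tf_families"]) or "n/a"))
    lines.append("## qPCR concordance")
    lines.append(f"- R^2 (log2 relative expression vs log2 FPKM+1): "
                 f"{s['qpcr_r2']:.4f}")
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(s, indent=1, sort_keys=True,
                                    default=_jsonable) + "\n")
    return md_path, json_path


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)
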