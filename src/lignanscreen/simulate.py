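"""Synthetic pan-genome, expression and qPCR data with known ground truth.

Every pipeline input can be generated here with a planted answer key, so
each stage — and the end-to-end screen — is testable without any
download.  The generator emulates the structure of the study system: six
sesame-like varieties with a configurable core-orthogroup fraction;
peroxidase/laccase domain-hit tables in which decoys sit strictly above
the E-value acceptance threshold; tandem, segmental and dispersed
paralog pairs laid into a chromosome-scale gene order (segmental pairs
inside generated collinear blocks, one block per chromosome pair);
cross-species anchor sets covering a configurable fraction of each
family; 2-kb promoters with planted cis-elements; a multi-panel FPKM
matrix (multi-organ, high/low-oil time series, white/black seed time
series) with multiplicative lognormal noise; and Ct tables back-computed
from expression.

Planted candidate genes carry a seed-preferential rise-and-fall
trajectory peaking around 20 DAA and declining afterwards, the shape of
seed (+)-pinoresinol accumulation; confounders include a constitutively
expressed seed gene (removed only by the kinetic flatness rule), genes
peaking late, organ-dominant genes and ubiquitous background genes.

A fixed ``rng_seed`` makes every output byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import DomainHit
from .errors import ConfigurationError, ValidationError
from .promoter import BUILTIN_ELEMENTS, CisElement
from .screen import ExpressionMatrix, KineticProfile, PanelSpec
from .synteny import AnchorPair, GeneModel

FAMILY_PROFILES = {"POD": "PF00141", "LAC": "TIGR03390"}
FAMILY_DOMAIN_NAMES = {"POD": "peroxidase", "LAC": "laccase"}

TF_FAMILIES = ("MYB", "NAC", "bZIP", "HSF", "HD-ZIP", "MIKC_MADS", "WRKY", "AP2")

#: cis-elements planted into candidate promoters (name, offset on the
#: promoter 5'->3'); MBS is the MYB binding site.
CANDIDATE_MOTIF_PLAN = (
    ("MBS", 120), ("MBS", 400), ("MBS", 900),
    ("ABRE", 600), ("G-box", 1200), ("RY-element", 1500),
)


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the design of the source pan-genome study: six
    varieties, seed sampling from 5 to 30 days after anthesis, five
    organs, and family sizes on the order of the real peroxidase (POD)
    and laccase (LAC) censuses.  ``family_sizes`` counts orthogroups per
    family; the reference variety's gene count also includes the planted
    paralog duplicates.
    """

    n_varieties: int = 6
    family_sizes: dict[str, int] = field(
        default_factory=lambda: {"POD": 65, "LAC": 42})
    core_fraction: float = 0.625
    n_planted_candidates: int = 4
    stages: tuple[int, ...] = (5, 8, 10, 15, 20, 23, 25, 30)
    tissues: tuple[str, ...] = ("seed", "root", "leaf", "stem", "capsule")
    noise_sd: float = 0.15
    decoy_evalue_range: tuple[float, float] = (1e-4, 0.5)
    rng_seed: int = 0
    # pan-genome structure
    n_chromosomes: int = 8
    n_decoys: int = 12
    n_spurious: int = 4
    n_segmental_pairs: dict[str, int] = field(
        default_factory=lambda: {"POD": 18, "LAC": 20})
    n_tandem_pairs: dict[str, int] = field(
        default_factory=lambda: {"POD": 1, "LAC": 0})
    n_dispersed_pairs: dict[str, int] = field(
        default_factory=lambda: {"POD": 1, "LAC": 1})
    synteny_fraction: dict[str, float] = field(
        default_factory=lambda: {"POD": 0.37, "LAC": 0.54})
    min_score: float = 50.0  # similarity threshold the edges are built around
    promoter_length: int = 2000
    # expression shape
    candidate_peak_daa: float = 18.0
    candidate_peak_width: float = 0.18
    candidate_baseline: float = 6.0
    # qPCR
    ct_intercept: float = 35.0

    def validate(self) -> None:
        if self.n_varieties < 1:
            raise ConfigurationError("SimConfig.n_varieties must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ConfigurationError("SimConfig.core_fraction must be in [0, 1]")
        if self.n_planted_candidates < 0:
            raise ConfigurationError("SimConfig.n_planted_candidates must be >= 0")
        if list(self.stages) != sorted(set(self.stages)) or not self.stages:
            raise ConfigurationError("SimConfig.stages must be strictly increasing")
        if "seed" not in self.tissues:
            raise ConfigurationError("SimConfig.tissues must include 'seed'")
        if self.noise_sd < 0:
            raise ConfigurationError("SimConfig.noise_sd must be >= 0")
        lo, hi = self.decoy_evalue_range
        if not (1e-5 < lo < hi):
            raise ConfigurationError(
                "SimConfig.decoy_evalue_range must lie strictly above the "
                "1e-5 acceptance threshold")
        if self.n_chromosomes < 2:
            raise ConfigurationError("SimConfig.n_chromosomes must be >= 2")
        for name, table in (("family_sizes", self.family_sizes),):
            if not table or any(v <= 0 for v in table.values()):
                raise ConfigurationError(f"SimConfig.{name} must be positive")
        total = sum(self.family_sizes.values())
        if self.n_planted_candidates > total:
            raise ConfigurationError(
                "SimConfig.n_planted_candidates exceeds the total gene count")

    @property
    def varieties(self) -> list[str]:
        return [f"var{i + 1}" for i in range(self.n_varieties)]

    @property
    def reference_variety(self) -> str:
        return self.varieties[0]


@dataclass
class TruthLabels:
    """Planted ground truth for every downstream stage."""

    candidate_genes: set[str]
    orthogroup_classes: dict[str, str]          # og id -> core|shared|specific
    duplication_calls: dict[tuple[str, str], str]
    planted_motifs: dict[str, list[tuple[str, int, str]]]
    # bookkeeping beyond the headline labels
    gene_orthogroup: dict[str, str] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)
    decoy_genes: set[str] = field(default_factory=set)
    spurious_genes: set[str] = field(default_factory=set)
    reference_genes: list[str] = field(default_factory=list)
    gene_profile_class: dict[str, str] = field(default_factory=dict)
    syntenic_genes: set[str] = field(default_factory=set)
    flat_confounder: str | None = None
    reference_housekeeping: str = "SiACT7"


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    truth: TruthLabels
    gene_models: dict[str, list[GeneModel]]       # variety -> genes (unranked)
    at_genes: list[GeneModel]
    domain_hits: dict[tuple[str, str], list[DomainHit]]  # (variety, family)
    scan_table: dict[str, set[str]]
    edges: pd.DataFrame                            # gene_a, gene_b, score
    anchors_intra: list[AnchorPair]
    anchors_cross: list[AnchorPair]
    genome: dict[str, str]                         # reference genome
    promoters: dict[str, str]                      # reference promoters
    elements: tuple[CisElement, ...]
    binding_map: dict[str, set[str]]


def _bump(stage: float, peak: float, width: float) -> float:
    """Lognormal-shaped rise-and-fall curve, 1.0 at the peak."""
    return math.exp(-(math.log(stage / peak)) ** 2 / (2.0 * width ** 2))


# ---------------------------------------------------------------------------
# pan-genome


def simulate_pangenome(cfg: SimConfig) -> SimulatedDataset:
    """Generate the full pan-genome input bundle plus its truth labels."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0]))
    varieties = cfg.varieties
    ref = cfg.reference_variety
    families = sorted(cfg.family_sizes)

    # --- orthogroups and per-variety genes -------------------------------
    og_classes: dict[str, str] = {}
    og_members: dict[str, dict[str, list[str]]] = {}
    gene_og: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for fam in families:
        n_og = cfg.family_sizes[fam]
        n_core = int(round(cfg.core_fraction * n_og))
        for i in range(n_og):
            og_id = f"OG_{fam}_{i + 1:04d}"
            if i < n_core:
                present = list(varieties)
            elif cfg.n_varieties == 1:
                present = [ref]
            else:
                j = i - n_core
                others = varieties[1:]
                if j % 2 == 0:  # keep the reference annotation size stable
                    k = int(rng.integers(0, cfg.n_varieties - 1))
                    present = [ref] + sorted(
                        rng.choice(others, size=k, replace=False).tolist())
                else:
                    k = int(rng.integers(1, cfg.n_varieties))
                    present = sorted(rng.choice(others, size=k, replace=False).tolist())
            if len(present) == cfg.n_varieties:
                og_classes[og_id] = "core"
            elif len(present) == 1:
                og_classes[og_id] = "specific"
            else:
                og_classes[og_id] = "shared"
            og_members[og_id] = {}
            for var in present:
                gene = f"{var}_{fam}{i + 1:03d}"
                og_members[og_id].setdefault(var, []).append(gene)
                gene_og[gene] = og_id
                family_of[gene] = fam

    # --- paralog planting in the reference variety -----------------------
    ref_base = sorted(g for g in gene_og if g.startswith(f"{ref}_"))
    dup_calls: dict[tuple[str, str], str] = {}
    seg_pairs: list[tuple[str, str]] = []
    tandem_pairs: list[tuple[str, str]] = []
    dispersed_pairs: list[tuple[str, str]] = []

    def _make_dup(source: str) -> str:
        dup = source + "D"
        og = gene_og[source]
        og_members[og].setdefault(ref, []).append(dup)
        gene_og[dup] = og
        family_of[dup] = family_of[source]
        return dup

    for fam in families:
        pool = [g for g in ref_base if family_of[g] == fam]
        pool = [str(g) for g in rng.permutation(pool)]
        need = (cfg.n_segmental_pairs.get(fam, 0)
                + cfg.n_tandem_pairs.get(fam, 0)
                + cfg.n_dispersed_pairs.get(fam, 0))
        if need > len(pool):
            raise ConfigurationError(
                f"SimConfig.n_segmental_pairs/n_tandem_pairs/n_dispersed_pairs: "
                f"not enough {fam} genes in the reference variety ({len(pool)})")
        it = iter(pool)
        for _ in range(cfg.n_segmental_pairs.get(fam, 0)):
            src = next(it)
            seg_pairs.append((src, _make_dup(src)))
        for _ in range(cfg.n_tandem_pairs.get(fam, 0)):
            src = next(it)
            tandem_pairs.append((src, _make_dup(src)))
        for _ in range(cfg.n_dispersed_pairs.get(fam, 0)):
            src = next(it)
            dispersed_pairs.append((src, _make_dup(src)))
    for pair in seg_pairs:
        dup_calls[pair] = "segmental"
    for pair in tandem_pairs:
        dup_calls[pair] = "tandem"
    for pair in dispersed_pairs:
        dup_calls[pair] = "dispersed"

    # segmental pairs are grouped into collinear blocks, one block per
    # adjacent chromosome pair; trailing remainders merge into the last
    # block so every block reaches the chainer's minimum anchor count
    block_size = 6
    blocks: list[list[tuple[str, str]]] = [
        seg_pairs[i:i + block_size] for i in range(0, len(seg_pairs), block_size)]
    if len(blocks) >= 2 and len(blocks[-1]) < 5:
        blocks[-2].extend(blocks.pop())
    if len(blocks) > cfg.n_chromosomes - 2:
        raise ConfigurationError(
            "SimConfig.n_segmental_pairs: too many blocks for n_chromosomes")

    # --- reference chromosome layout -------------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    ref_all = ref_base + [p[1] for p in seg_pairs + dispersed_pairs]
    placed: dict[str, str] = {}
    runs: list[tuple[str, list[str]]] = []  # (chrom, ordered gene run)
    for b, block in enumerate(blocks):
        c_src = chroms[b % cfg.n_chromosomes]
        c_dup = chroms[(b + 1) % cfg.n_chromosomes]
        src_run = [p[0] for p in block]
        dup_run = [p[1] for p in block]
        runs.append((c_src, src_run))
        runs.append((c_dup, dup_run))
        for g in src_run:
            placed[g] = c_src
        for g in dup_run:
            placed[g] = c_dup
    for src, dup in dispersed_pairs:
        c_src = chroms[int(rng.integers(0, cfg.n_chromosomes))]
        others = [c for c in chroms if c != c_src]
        placed[src] = c_src
        placed[dup] = others[int(rng.integers(0, len(others)))]
    remaining = [g for g in ref_all if g not in placed]
    counts = {c: 0 for c in chroms}
    for g in placed.values():
        counts[g] += 1
    for g in rng.permutation(remaining):
        target = min(chroms, key=lambda c: (counts[c], c))
        placed[str(g)] = target
        counts[target] += 1

    order: dict[str, list[str]] = {}
    for c in chroms:
        members = sorted(g for g, cc in placed.items() if cc == c)
        order[c] = [str(g) for g in rng.permutation(members)]
    for c, run in runs:  # enforce each run's relative order on its chromosome
        slots = sorted(order[c].index(g) for g in run)
        for slot, gene in zip(slots, run):
            order[c][slot] = gene
    for src, dup in tandem_pairs:  # tandem duplicates sit right next door
        c = placed[src]
        order[c].insert(order[c].index(src) + 1, dup)
        placed[dup] = c

    def _lay_out(chrom_order: Mapping[str, list[str]]) -> list[GeneModel]:
        genes = []
        for c in sorted(chrom_order):
            for j, gid in enumerate(chrom_order[c]):
                start = 5000 + j * 6000
                length = int(rng.integers(1200, 3500))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(gid, c, start, start + length - 1, strand))
        return genes

    gene_models: dict[str, list[GeneModel]] = {ref: _lay_out(order)}
    for var in varieties[1:]:
        var_genes = sorted(g for g in gene_og if g.startswith(f"{var}_"))
        shuffled = [str(g) for g in rng.permutation(var_genes)]
        var_order: dict[str, list[str]] = {c: [] for c in chroms}
        for i, g in enumerate(shuffled):
            var_order[chroms[i % cfg.n_chromosomes]].append(g)
        gene_models[var] = _lay_out(var_order)

    # --- cross-species synteny -------------------------------------------
    ref_rank_order = {g.gene_id: (g.chrom, g.start)
                      for g in gene_models[ref]}
    selected: set[str] = set()
    for fam in families:
        fam_genes = [g for g in ref_all + [p[1] for p in tandem_pairs]
                     if family_of[g] == fam]
        fam_genes = sorted(fam_genes)
        quota = int(round(cfg.synteny_fraction.get(fam, 0.0) * len(fam_genes)))
        selected.update(str(g) for g in rng.permutation(fam_genes)[:quota])
    # repair: a chromosome carrying fewer selections than a minimal block
    # cannot form one; move those selections to the best-covered chromosome
    min_block = 5

    def _per_chrom() -> dict[str, list[str]]:
        table: dict[str, list[str]] = {c: [] for c in chroms}
        for g in sorted(selected):
            table[placed[g]].append(g)
        return table

    for _ in range(len(chroms)):  # bounded: each pass empties one chromosome
        per_chrom = _per_chrom()
        bad = [c for c in chroms if 0 < len(per_chrom[c]) < min_block]
        if not bad:
            break
        c = bad[0]
        # prefer targets that are already viable or will become so
        rest = sorted((x for x in chroms if x != c),
                      key=lambda x: (-len(per_chrom[x]), x))
        for g in per_chrom[c]:
            selected.discard(g)
            fam = family_of[g]
            for target in rest:
                spare = [x for x in order[target]
                         if x not in selected and family_of.get(x) == fam]
                if spare:
                    selected.add(spare[0])
                    break
    # any chromosome still below a viable block sheds its selections
    per_chrom = _per_chrom()
    for c in chroms:
        if 0 < len(per_chrom[c]) < min_block:
            selected -= set(per_chrom[c])

    at_genes: list[GeneModel] = []
    anchors_cross: list[AnchorPair] = []
    for ci, c in enumerate(chroms):
        chosen = [g for g in order[c] if g in selected]
        if not chosen:
            continue
        at_chrom = f"Atchr{ci + 1}"
        for j, g in enumerate(chosen):
            at_id = f"At_{ci + 1}_{j + 1:03d}"
            start = 3000 + j * 4000
            at_genes.append(GeneModel(at_id, at_chrom, start, start + 1500, "+"))
            anchors_cross.append(AnchorPair(g, at_id, float(rng.uniform(50, 200))))
    # non-chainable noise anchors (below any minimum block size)
    noise_sources = [g.gene_id for g in gene_models[ref] if g.chrom == chroms[0]][:4]
    for j, g in enumerate(noise_sources):
        at_id = f"At_noise_{j + 1:03d}"
        at_genes.append(GeneModel(at_id, "Atchr_noise", 2000 + j * 4000,
                                  3500 + j * 4000, "+"))
        anchors_cross.append(AnchorPair(g, at_id, float(rng.uniform(50, 200))))

    anchors_intra = [AnchorPair(a, b, float(rng.uniform(50, 200)))
                     for a, b in seg_pairs]
    half = chroms[cfg.n_chromosomes // 2]
    noise_a = [g.gene_id for g in gene_models[ref] if g.chrom == chroms[0]][:4]
    noise_b = [g.gene_id for g in gene_models[ref] if g.chrom == half][:4]
    anchors_intra += [AnchorPair(a, b, float(rng.uniform(50, 200)))
                      for a, b in zip(noise_a, noise_b)]

    # --- domain-hit tables and scan table --------------------------------
    domain_hits: dict[tuple[str, str], list[DomainHit]] = {}
    scan_table: dict[str, set[str]] = {}
    decoy_genes: set[str] = set()
    spurious_genes: set[str] = set()
    lo, hi = cfg.decoy_evalue_range
    for var in varieties:
        var_members = sorted(g for g in gene_og
                             if g.split("_", 1)[0] == var)
        for fam in families:
            hits: list[DomainHit] = []
            for g in var_members:
                if family_of[g] != fam:
                    continue
                e_full = float(10.0 ** rng.uniform(-30, -8))
                start = int(rng.integers(5, 40))
                hits.append(DomainHit(
                    gene_id=g, profile_id=FAMILY_PROFILES.get(fam, fam),
                    full_evalue=e_full, dom_ievalue=e_full * 3.0,
                    ali_start=start, ali_end=start + int(rng.integers(150, 260)),
                    bit_score=float(rng.uniform(120, 420))))
                scan_table[g] = {FAMILY_DOMAIN_NAMES.get(fam, fam.lower())}
            fam_idx = families.index(fam)
            for j in range(cfg.n_decoys):
                if j % len(families) != fam_idx:
                    continue
                g = f"{var}_DEC{j + 1:03d}"
                decoy_genes.add(g)
                e_full = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                start = int(rng.integers(5, 40))
                hits.append(DomainHit(
                    gene_id=g, profile_id=FAMILY_PROFILES.get(fam, fam),
                    full_evalue=e_full, dom_ievalue=min(e_full * 1.5, 0.9),
                    ali_start=start, ali_end=start + int(rng.integers(30, 80)),
                    bit_score=float(rng.uniform(5, 20))))
            for j in range(cfg.n_spurious):
                if j % len(families) != fam_idx:
                    continue
                g = f"{var}_SPU{j + 1:03d}"
                spurious_genes.add(g)
                e_full = float(10.0 ** rng.uniform(-12, -7))
                start = int(rng.integers(5, 40))
                hits.append(DomainHit(
                    gene_id=g, profile_id=FAMILY_PROFILES.get(fam, fam),
                    full_evalue=e_full, dom_ievalue=e_full * 2.0,
                    ali_start=start, ali_end=start + int(rng.integers(80, 160)),
                    bit_score=float(rng.uniform(40, 80))))
                scan_table[g] = {"cupredoxin"}
            hits.sort(key=lambda h: h.gene_id)
            domain_hits[(var, fam)] = hits

    # --- similarity edges -------------------------------------------------
    edge_rows: list[tuple[str, str, float]] = []
    for og_id in sorted(og_members):
        members = sorted(g for lst in og_members[og_id].values() for g in lst)
        for a, b in zip(members, members[1:]):
            edge_rows.append((a, b, float(rng.uniform(70, 95))))
    og_ids = sorted(og_members)
    all_genes = sorted(gene_og)
    for _ in range(len(og_ids)):
        a, b = rng.choice(all_genes, size=2, replace=False)
        if gene_og[a] != gene_og[b]:
            edge_rows.append((str(a), str(b), float(rng.uniform(5, 40))))
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "score"])

    # --- candidates and expression archetypes ----------------------------
    core_base = [g for g in ref_base
                 if og_classes[gene_og[g]] == "core"]
    if cfg.n_planted_candidates > len(core_base):
        raise ConfigurationError(
            "SimConfig.n_planted_candidates exceeds the core gene count")
    by_fam = {fam: [g for g in core_base if family_of[g] == fam]
              for fam in families}
    candidates: list[str] = []
    fam_cycle = [families[i % len(families)]
                 for i in range(cfg.n_planted_candidates)]
    pools = {fam: [str(g) for g in rng.permutation(by_fam[fam])] for fam in families}
    for fam in fam_cycle:
        pool = pools[fam] or [g for f in families for g in pools[f]]
        candidates.append(pool.pop(0))
    candidates = sorted(candidates)

    ref_expression_genes = sorted(set(ref_all) | {p[1] for p in tandem_pairs})
    profile_class: dict[str, str] = {}
    rest = [g for g in ref_expression_genes if g not in candidates]
    flat = None
    flat_pool = [g for g in rest if og_classes[gene_og[g]] == "core"]
    if cfg.n_planted_candidates > 0 and flat_pool:
        flat = flat_pool[int(rng.integers(0, len(flat_pool)))]
    shuffled_rest = [str(g) for g in rng.permutation([g for g in rest if g != flat])]
    n_late = max(1, len(shuffled_rest) // 10)
    n_organ = max(1, (3 * len(shuffled_rest)) // 10)
    for g in candidates:
        profile_class[g] = "candidate"
    if flat is not None:
        profile_class[flat] = "flat"
    for i, g in enumerate(shuffled_rest):
        if i < n_late:
            profile_class[g] = "late"
        elif i < n_late + n_organ:
            profile_class[g] = "organ"
        else:
            profile_class[g] = "background"

    # --- genome, promoters and planted motifs ----------------------------
    elements = BUILTIN_ELEMENTS
    element_by_name = {e.name: e for e in elements}
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    promoters: dict[str, str] = {}
    planted_motifs: dict[str, list[tuple[str, int, str]]] = {}
    ref_genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models[ref]:
        ref_genes_by_chrom.setdefault(g.chrom, []).append(g)
    for c in sorted(ref_genes_by_chrom):
        genes_c = ref_genes_by_chrom[c]
        size = max(g.end for g in genes_c) + cfg.promoter_length + 1000
        seq = rng.choice(bases, size=size)
        for g in genes_c:
            lo_i = (g.start - 1 - cfg.promoter_length if g.strand == "+"
                    else g.end)
            promoter = seq[lo_i:lo_i + cfg.promoter_length]
            if g.strand == "-":
                promoter = _revcomp_array(promoter)
            if g.gene_id in candidates:
                plan = []
                for name, offset in CANDIDATE_MOTIF_PLAN:
                    motif = element_by_name[name].consensus
                    concrete = _concretize(motif, rng)
                    promoter[offset - 1:offset - 1 + len(concrete)] = list(concrete)
                    plan.append((name, offset, "+"))
                planted_motifs[g.gene_id] = plan
            if g.strand == "+":
                seq[lo_i:lo_i + cfg.promoter_length] = promoter
            else:
                seq[lo_i:lo_i + cfg.promoter_length] = _revcomp_array(promoter)
            promoters[g.gene_id] = "".join(promoter)
        genome[c] = "".join(seq)

    # --- TF binding map ----------------------------------------------------
    binding_map: dict[str, set[str]] = {}
    for fam in TF_FAMILIES:
        bound = {g for g in ref_expression_genes if rng.random() < 0.15}
        if fam == "MYB":
            bound |= set(candidates)
        else:
            bound -= set(candidates)
            # each non-MYB family may keep at most one candidate by chance
            keep = [g for g in candidates if rng.random() < 0.15][:1]
            bound |= set(keep)
        binding_map[fam] = bound

    truth = TruthLabels(
        candidate_genes=set(candidates),
        orthogroup_classes=og_classes,
        duplication_calls=dup_calls,
        planted_motifs=planted_motifs,
        gene_orthogroup=gene_og,
        family_of=family_of,
        decoy_genes=decoy_genes,
        spurious_genes=spurious_genes,
        reference_genes=ref_expression_genes,
        gene_profile_class=profile_class,
        syntenic_genes={a.gene_a for a in anchors_cross
                        if not a.gene_b.startswith("At_noise")},
        flat_confounder=flat,
    )
    return SimulatedDataset(
        cfg=cfg, truth=truth, gene_models=gene_models, at_genes=at_genes,
        domain_hits=domain_hits, scan_table=scan_table, edges=edges,
        anchors_intra=anchors_intra, anchors_cross=anchors_cross,
        genome=genome, promoters=promoters, elements=elements,
        binding_map=binding_map)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_array(arr: np.ndarray) -> np.ndarray:
    return np.array(["".join(b).translate(_COMPLEMENT) for b in arr[::-1]])


def _concretize(consensus: str, rng: np.random.Generator) -> str:
    """Pick one concrete realization of an IUPAC consensus."""
    from .promoter import IUPAC

    return "".join(IUPAC[c][int(rng.integers(0, len(IUPAC[c])))]
                   for c in consensus.upper())


# ---------------------------------------------------------------------------
# expression


def default_panels(cfg: SimConfig) -> PanelSpec:
    """The three-dataset layout the generator emits.

    Multi-organ panel: the reference variety across all organs and
    stages.  Oil panel: varieties 2-4, seed only, stages >= 10 DAA.
    Color panel: variety 5 (white-seeded) and 6 (black-seeded), seed,
    all stages.
    """
    v = cfg.varieties
    if len(v) < 6:
        raise ConfigurationError(
            "SimConfig.n_varieties must be >= 6 for the three expression panels")
    return PanelSpec(organ_varieties=(v[0],), oil_varieties=tuple(v[1:4]),
                     white_variety=v[4], black_variety=v[5])


def _mean_fpkm(cls: str, tissue: str, stage: int, cfg: SimConfig,
               amp: float, organ_tissue: str) -> float:
    peak, width = cfg.candidate_peak_daa, cfg.candidate_peak_width
    if cls == "candidate":
        if tissue == "seed":
            return cfg.candidate_baseline + amp * _bump(stage, peak, width)
        return 1.0
    if cls == "flat":
        return 20.0 if tissue == "seed" else 1.0
    if cls == "late":
        if tissue == "seed":
            return 0.2 + amp * _bump(stage, 29.0, 0.15)
        return 0.3
    if cls == "organ":
        if tissue == organ_tissue:
            return 25.0
        return 0.5 if tissue == "seed" else 1.0
    if cls == "housekeeping":
        return 40.0
    return 3.0  # ubiquitous background


def simulate_expression(cfg: SimConfig, truth: TruthLabels) -> ExpressionMatrix:
    """FPKM matrix over the three panels with lognormal noise.

    Genes are the reference variety's family members plus one
    housekeeping gene; sample means follow each gene's planted archetype
    and each observation is mean * exp(N(0, noise_sd)).
    """
    cfg.validate()
    if not truth.reference_genes:
        raise ValidationError("truth has no reference genes; run simulate_pangenome")
    panels = default_panels(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))

    samples: list[tuple[str, str, str, int, int]] = []
    for tissue in cfg.tissues:
        for stage in cfg.stages:
            samples.append((f"{panels.organ_varieties[0]}_{tissue}_{stage}",
                            panels.organ_varieties[0], tissue, stage, 1))
    for var in panels.oil_varieties:
        for stage in (s for s in cfg.stages if s >= 10):
            samples.append((f"{var}_seed_{stage}", var, "seed", stage, 1))
    for var in (panels.white_variety, panels.black_variety):
        for stage in cfg.stages:
            samples.append((f"{var}_seed_{stage}", var, "seed", stage, 1))
    sample_df = pd.DataFrame(
        samples, columns=["sample_id", "variety", "tissue", "stage", "replicate"]
    ).set_index("sample_id")

    genes = list(truth.reference_genes) + [truth.reference_housekeeping]
    non_seed = [t for t in cfg.tissues if t != "seed"] or ["seed"]
    amp = {g: float(rng.uniform(40, 80)) for g in genes}
    organ_tissue = {g: non_seed[int(rng.integers(0, len(non_seed)))] for g in genes}

    values = np.empty((len(genes), len(sample_df)))
    for i, g in enumerate(genes):
        cls = ("housekeeping" if g == truth.reference_housekeeping
               else truth.gene_profile_class.get(g, "background"))
        for j, (variety, tissue, stage, _) in enumerate(
                sample_df[["variety", "tissue", "stage", "replicate"]]
                .itertuples(index=False)):
            values[i, j] = _mean_fpkm(cls, tissue, int(stage), cfg,
                                      amp[g], organ_tissue[g])
    if cfg.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, cfg.noise_sd, size=values.shape))
    fpkm = pd.DataFrame(values, index=genes, columns=sample_df.index)
    fpkm.index.name = "gene_id"
    return ExpressionMatrix(fpkm, sample_df)


def simulate_pinoresinol_profile(stages: Sequence[int]) -> KineticProfile:
    """Parametric seed (+)-pinoresinol accumulation curve.

    A lognormal-shaped rise-and-fall, peaking at 20 DAA, evaluated at the
    given stages.  The published accumulation data are figure-derived and
    not printed; this parametric stand-in reproduces their qualitative
    shape (rise through mid seed filling, decline toward maturity).
    """
    if not stages:
        raise ValidationError("stages must be nonempty")
    if list(stages) != sorted(set(stages)):
        raise ValidationError("stages must be strictly increasing")
    content = tuple(100.0 * _bump(float(s), 20.0, 0.25) for s in stages)
    return KineticProfile(tuple(int(s) for s in stages), content)


def simulate_ct(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    reference_gene: str,
    ct_sd: float,
    seed: int,
    intercept: float = 35.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Back-compute a Ct table from FPKM: Ct = b - log2(FPKM + 1) + noise.

    Three technical replicates per gene x sample by default.  The
    reference gene's planted Ct uses its across-sample mean FPKM, so it
    is exactly constant at ct_sd = 0 — the housekeeping assumption of
    relative quantification.
    """
    missing = set(genes) - set(expr.genes)
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {sorted(missing)}")
    if reference_gene not in set(expr.genes):
        raise ValidationError(f"reference gene {reference_gene!r} absent from expression matrix")
    rng = np.random.default_rng(seed)
    rows = []
    ref_mean = float(expr.fpkm.loc[reference_gene].mean())
    for gene in list(genes) + [reference_gene]:
        for sample in expr.fpkm.columns:
            fpkm = ref_mean if gene == reference_gene else float(expr.fpkm.loc[gene, sample])
            base_ct = intercept - math.log2(fpkm + 1.0)
            for rep in range(1, n_replicates + 1):
                noise = float(rng.normal(0.0, ct_sd)) if ct_sd > 0 else 0.0
                rows.append((gene, sample, rep, base_ct + noise))
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])


# ---------------------------------------------------------------------------
# serialization


def write_domtblout(hits: Sequence[DomainHit], path: Path, qlen: int = 300) -> None:
    header = ("#                                                               "
              "--- full sequence --- -------------- this domain --------------\n"
              "# target name        accession   tlen query name           "
              "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
              "i-Evalue  score  bias  from    to  from    to  from    to  acc "
              "description of target\n")
    with path.open("w") as fh:
        fh.write(header)
        for h in hits:
            fh.write(
                f"{h.gene_id:<20s} -{'':>10s} {h.ali_end + 50:5d} "
                f"{h.profile_id:<20s} -{'':>10s} {qlen:5d} "
                f"{h.full_evalue:9.3g} {h.bit_score:6.1f} 0.0 1 1 "
                f"{h.dom_ievalue:9.3g} {h.dom_ievalue:9.3g} {h.bit_score:6.1f} 0.0 "
                f"1 {qlen} {h.ali_start} {h.ali_end} {max(1, h.ali_start - 2)} "
                f"{h.ali_end + 2} 0.95 -\n")


def write_gff3(genes: Sequence[GeneModel], path: Path, source: str = "lignanscreen") -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_fasta(seqs: Mapping[str, str], path: Path, width: int = 80) -> None:
    with path.open("w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_dataset(ds: SimulatedDataset, outdir: str | Path,
                  expr: ExpressionMatrix | None = None,
                  profile: KineticProfile | None = None,
                  ct: pd.DataFrame | None = None) -> dict[str, Path]:
    """Serialize a simulated dataset to the pipeline's input formats.

    Output is deterministic byte-for-byte for a fixed configuration.
    Returns a name -> path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for var, genes in sorted(ds.gene_models.items()):
        p = outdir / f"{var}.gff3"
        write_gff3(genes, p)
        paths[f"gff_{var}"] = p
    write_gff3(ds.at_genes, outdir / "arabidopsis.gff3")
    paths["gff_arabidopsis"] = outdir / "arabidopsis.gff3"

    for (var, fam), hits in sorted(ds.domain_hits.items()):
        p = outdir / f"{fam.lower()}_hits_{var}.domtbl"
        write_domtblout(hits, p)
        paths[f"hits_{fam}_{var}"] = p

    scan_rows = [(g, d) for g in sorted(ds.scan_table)
                 for d in sorted(ds.scan_table[g])]
    p = outdir / "scan.tsv"
    pd.DataFrame(scan_rows).to_csv(p, sep="\t", header=False, index=False)
    paths["scan"] = p

    p = outdir / "edges.tsv"
    ds.edges.to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths["edges"] = p

    for name, anchors in (("anchors_intra", ds.anchors_intra),
                          ("anchors_cross", ds.anchors_cross)):
        p = outdir / f"{name}.tsv"
        pd.DataFrame([(a.gene_a, a.gene_b, a.score) for a in anchors],
                     columns=["gene_a", "gene_b", "score"]).to_csv(
            p, sep="\t", index=False, float_format="%.4f")
        paths[name] = p

    write_fasta(ds.genome, outdir / "genome.fasta")
    write_fasta(ds.promoters, outdir / "promoters.fasta")
    paths["genome"] = outdir / "genome.fasta"
    paths["promoters"] = outdir / "promoters.fasta"

    from .promoter import write_element_table
    write_element_table(ds.elements, outdir / "elements.tsv")
    paths["elements"] = outdir / "elements.tsv"
    binding_rows = [(fam, g) for fam in sorted(ds.binding_map)
                    for g in sorted(ds.binding_map[fam])]
    p = outdir / "binding_map.tsv"
    pd.DataFrame(binding_rows, columns=["family", "gene"]).to_csv(
        p, sep="\t", index=False)
    paths["binding_map"] = p

    if expr is not None:
        expr.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
        paths["expression"] = outdir / "expression.tsv"
        paths["samples"] = outdir / "samples.tsv"
    if profile is not None:
        pd.DataFrame({"stage": profile.stages, "content": profile.content}
                     ).to_csv(outdir / "profile.tsv", sep="\t", index=False,
                              float_format="%.6g")
        paths["profile"] = outdir / "profile.tsv"
    if ct is not None:
        ct.to_csv(outdir / "ct.tsv", sep="\t", index=False, float_format="%.6g")
        paths["ct"] = outdir / "ct.tsv"

    truth_json = {
        "candidate_genes": sorted(ds.truth.candidate_genes),
        "orthogroup_classes": dict(sorted(ds.truth.orthogroup_classes.items())),
        "duplication_calls": [
            {"gene_a": a, "gene_b": b, "cls": cls}
            for (a, b), cls in sorted(ds.truth.duplication_calls.items())],
        "planted_motifs": {k: [list(t) for t in v]
                           for k, v in sorted(ds.truth.planted_motifs.items())},
        "gene_orthogroup": dict(sorted(ds.truth.gene_orthogroup.items())),
        "decoy_genes": sorted(ds.truth.decoy_genes),
        "spurious_genes": sorted(ds.truth.spurious_genes),
        "reference_genes": list(ds.truth.reference_genes),
        "gene_profile_class": dict(sorted(ds.truth.gene_profile_class.items())),
        "syntenic_genes": sorted(ds.truth.syntenic_genes),
        "flat_confounder": ds.truth.flat_confounder,
        "reference_housekeeping": ds.truth.reference_housekeeping,
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth_json, indent=1, sort_keys=True) + "\n")
    paths["truth"] = p
    return paths


def simulate_all(cfg: SimConfig) -> tuple[SimulatedDataset, ExpressionMatrix,
                                          KineticProfile, pd.DataFrame]:
    """Convenience wrapper: pan-genome, expression, kinetic profile, Ct."""
    ds = simulate_pangenome(cfg)
    expr = simulate_expression(cfg, ds.truth)
    profile = simulate_pinoresinol_profile(list(cfg.stages))
    panels = default_panels(cfg)
    white = expr.subset(varieties=[panels.white_variety], tissue="seed")
    ct = simulate_ct(white, sorted(ds.truth.candidate_genes),
                     ds.truth.reference_housekeeping, ct_sd=0.2,
                     seed=cfg.rng_seed + 17, intercept=cfg.ct_intercept)
    return ds, expr, profile, ct
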