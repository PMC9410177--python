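"""Multi-stage expression screen for (+)-pinoresinol synthase candidates.

The screen mirrors how seed-lignan biosynthesis genes are prioritized
from bulk RNA-seq of a diverse variety panel.  Three expression filters
run in sequence over an FPKM matrix —

1. seed preference: mean seed FPKM at least ``seed_fold`` times the best
   non-seed organ, with a ``min_expr`` floor (multi-organ panel);
2. early expression: detectable FPKM at every variety's earliest sampled
   stage of the high/low-oil seed time series;
3. seed-color panel: detectable FPKM at the white-seeded variety's early
   stages (lignan-rich white seeds), presence rather than dominance;

followed by a kinetic-concordance rule against the (+)-pinoresinol
accumulation curve (trajectory must peak before the last stage, decline
by the late stages, and not be flat — the rule that removes constitutively
expressed genes) and a pan-genome core-membership requirement.  Every
gene keeps a full audit record; the final candidate set is the
conjunction of all criteria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import Orthogroup
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

TISSUES = ("seed", "root", "leaf", "stem", "capsule")


@dataclass
class ScreenConfig:
    """Thresholds of the candidate screen.

    min_expr:       FPKM floor for "expressed" (default 1.0)
    seed_fold:      seed-over-best-other-organ fold change (default 2.0)
    color_max_stage: latest DAA counted as "early" in the seed-color
                    panel (default 8, i.e. the 5- and 8-DAA samples)
    decline_stage:  DAA from which the trajectory must have declined
                    (default 23)
    decline_ratio:  late-stage mean FPKM must be <= this fraction of the
                    peak (default 0.7)
    flat_cv:        minimum coefficient of variation across stages; a
                    flatter trajectory is excluded as constitutive
                    (default 0.3)
    pseudocount:    added before log2 (default 1.0)
    """

    min_expr: float = 1.0
    seed_fold: float = 2.0
    color_max_stage: int = 8
    decline_stage: int = 23
    decline_ratio: float = 0.7
    flat_cv: float = 0.3
    pseudocount: float = 1.0

    def validate(self) -> None:
        for name in ("min_expr", "seed_fold", "decline_ratio",
                     "flat_cv", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"ScreenConfig.{name} must be positive")
        if self.decline_ratio >= 1:
            raise ConfigurationError("ScreenConfig.decline_ratio must be < 1")


@dataclass
class PanelSpec:
    """Which varieties make up each of the three expression datasets."""

    organ_varieties: tuple[str, ...]
    oil_varieties: tuple[str, ...]
    white_variety: str
    black_variety: str


class ExpressionMatrix:
    """Genes x samples FPKM with (variety, tissue, stage, replicate) labels.

    ``fpkm`` is a DataFrame indexed by gene id with sample-id columns;
    ``samples`` is indexed by sample id with columns variety, tissue,
    stage (days after anthesis, int) and replicate.
    """

    def __init__(self, fpkm: pd.DataFrame, samples: pd.DataFrame):
        missing = {"variety", "tissue", "stage", "replicate"} - set(samples.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
        if not fpkm.columns.equals(samples.index):
            samples = samples.loc[fpkm.columns]
        if (fpkm.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be nonnegative")
        key = samples[["variety", "tissue", "stage", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("(variety, tissue, stage, replicate) must be unique")
        self.fpkm = fpkm
        self.samples = samples

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    def subset(self, *, varieties: Sequence[str] | None = None,
               tissue: str | None = None) -> "ExpressionMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if varieties is not None:
            mask &= self.samples["variety"].isin(varieties)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        cols = self.samples.index[mask]
        return ExpressionMatrix(self.fpkm[cols], self.samples.loc[cols])

    def mean_by(self, keys: Sequence[str]) -> pd.DataFrame:
        """Replicate-averaged means: genes x unique sample-key groups."""
        grouped = self.fpkm.T.groupby([self.samples[k] for k in keys]).mean().T
        return grouped

    @classmethod
    def from_tsv(cls, fpkm_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        fpkm = pd.read_csv(fpkm_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(fpkm, samples)

    def to_tsv(self, fpkm_path: str | Path, samples_path: str | Path) -> None:
        self.fpkm.to_csv(fpkm_path, sep="\t", float_format="%.6g")
        self.samples.to_csv(samples_path, sep="\t")


@dataclass
class KineticProfile:
    """Relative metabolite content by developmental stage (DAA)."""

    stages: tuple[int, ...]
    content: tuple[float, ...]

    def __post_init__(self):
        if not self.stages:
            raise ValidationError("KineticProfile needs at least one stage")
        if list(self.stages) != sorted(set(self.stages)):
            raise ValidationError("KineticProfile stages must be strictly increasing")
        if any(c < 0 for c in self.content):
            raise ValidationError("KineticProfile content must be nonnegative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.content, index=list(self.stages))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KineticProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(int(s) for s in df["stage"]),
                   tuple(float(c) for c in df["content"]))


# ---------------------------------------------------------------------------
# operations


def log_transform(fpkm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount); strictly order-preserving."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    values = fpkm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("FPKM values must be nonnegative")
    return pd.DataFrame(np.log2(values + pseudocount),
                        index=fpkm.index, columns=fpkm.columns)


def seed_preference_filter(
    expr: ExpressionMatrix, cfg: ScreenConfig
) -> tuple[pd.Series, pd.Series]:
    """Stage 1: seed-preferential expression in the multi-organ panel.

    Replicates (and stages) are averaged per tissue first.  A gene passes
    iff mean seed FPKM >= seed_fold * max non-seed tissue mean (inclusive)
    and mean seed FPKM >= min_expr.  Returns (pass boolean, fold) per
    gene; fold is +inf when no non-seed tissue shows expression.
    """
    tissues = set(expr.samples["tissue"])
    if "seed" not in tissues:
        raise ValidationError("multi-organ panel lacks seed samples")
    if len(tissues) < 2:
        raise ValidationError("multi-organ panel needs at least one non-seed tissue")
    by_tissue = expr.mean_by(["tissue"])
    seed = by_tissue["seed"]
    others = by_tissue.drop(columns="seed").max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = seed / others
    fold[(others == 0) & (seed > 0)] = math.inf
    fold[(others == 0) & (seed == 0)] = 0.0
    passed = (seed >= cfg.seed_fold * others) & (seed >= cfg.min_expr)
    return passed, fold


def early_expression_filter(
    expr: ExpressionMatrix, cfg: ScreenConfig
) -> pd.Series:
    """Stage 2: expressed at every variety's earliest stage (oil panel).

    Passes iff replicate-mean FPKM >= min_expr at the earliest sampled
    stage of each variety in the seed time series.
    """
    seed_expr = expr.subset(tissue="seed")
    if seed_expr.samples.empty:
        raise ValidationError("oil panel has no seed samples")
    means = seed_expr.mean_by(["variety", "stage"])
    passed = pd.Series(True, index=expr.genes)
    for variety, stages in seed_expr.samples.groupby("variety")["stage"]:
        earliest = int(stages.min())
        passed &= means[(variety, earliest)] >= cfg.min_expr
    return passed


def seedcolor_filter(
    expr: ExpressionMatrix, cfg: ScreenConfig, white_variety: str
) -> pd.Series:
    """Stage 3: present early in the white-seeded (lignan-rich) variety.

    Passes iff FPKM >= min_expr at every white-variety seed stage up to
    ``color_max_stage`` DAA.  Presence, not dominance over the black
    variety, is required — a constitutively expressed gene survives this
    stage and is only removed by the kinetic rule.
    """
    if white_variety not in set(expr.samples["variety"]):
        raise ValidationError(f"white variety {white_variety!r} absent from color panel")
    white = expr.subset(varieties=[white_variety], tissue="seed")
    early_stages = sorted(s for s in set(white.samples["stage"]) if s <= cfg.color_max_stage)
    if not early_stages:
        raise ValidationError(
            f"white variety has no seed samples at <= {cfg.color_max_stage} DAA"
        )
    means = white.mean_by(["stage"])
    passed = pd.Series(True, index=expr.genes)
    for stage in early_stages:
        passed &= means[stage] >= cfg.min_expr
    return passed


def kinetic_concordance(
    trajectory: pd.Series, profile: KineticProfile, cfg: ScreenConfig
) -> tuple[bool, int, float, float]:
    """Kinetic rule: rise-and-fall matching metabolite accumulation.

    ``trajectory`` is stage (DAA) -> FPKM for one gene in the reference
    (white) variety.  Pass requires (a) the peak stage strictly before
    the last sampled stage, (b) mean FPKM over stages >= decline_stage at
    most decline_ratio * peak FPKM, and (c) coefficient of variation
    across stages >= flat_cv (excludes constitutively expressed genes).
    The Pearson correlation with the metabolite profile over shared
    stages is reported but not thresholded.

    Returns (pass, peak_stage, observed_decline_ratio, correlation).
    """
    trajectory = trajectory.sort_index()
    if len(trajectory) < 4:
        raise ValidationError("kinetic rule needs >= 4 sampled stages")
    values = trajectory.to_numpy(dtype=float)
    stages = trajectory.index.to_numpy()
    peak_idx = int(values.argmax())
    peak_stage = int(stages[peak_idx])
    peak_val = float(values[peak_idx])

    late = values[stages >= cfg.decline_stage]
    decline_obs = float(late.mean() / peak_val) if peak_val > 0 and late.size else math.nan

    mean = float(values.mean())
    cv = float(values.std(ddof=0) / mean) if mean > 0 else 0.0

    prof = profile.as_series()
    shared = [s for s in stages if s in prof.index]
    if len(shared) >= 3:
        x = trajectory.loc[shared].to_numpy(dtype=float)
        y = prof.loc[shared].to_numpy(dtype=float)
        if x.std() > 0 and y.std() > 0:
            corr = float(np.corrcoef(x, y)[0, 1])
        else:
            corr = math.nan
    else:
        corr = math.nan

    ok = (
        peak_stage < int(stages[-1])
        and not math.isnan(decline_obs)
        and decline_obs <= cfg.decline_ratio
        and cv >= cfg.flat_cv
    )
    return ok, peak_stage, decline_obs, corr


def core_membership_filter(
    genes: Sequence[str], orthogroups: Sequence[Orthogroup]
) -> pd.Series:
    """Retain genes whose orthogroup is classed core.

    Genes absent from every orthogroup are treated as non-core with a
    logged warning rather than an error.
    """
    core_genes: set[str] = set()
    all_genes: set[str] = set()
    for og in orthogroups:
        for members in og.members.values():
            all_genes.update(members)
            if og.cls == "core":
                core_genes.update(members)
    passed = pd.Series(False, index=list(genes))
    for gene in genes:
        if gene not in all_genes:
            logger.warning("gene %s absent from all orthogroups; treated as non-core", gene)
        passed[gene] = gene in core_genes
    return passed


def run_screen(
    expr: ExpressionMatrix,
    profile: KineticProfile,
    orthogroups: Sequence[Orthogroup],
    panels: PanelSpec,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full candidate screen; returns the per-gene audit report.

    Filters run in the documented order (seed preference -> early oil ->
    seed color -> kinetic -> core membership).  Each stage's boolean and
    the stage-specific statistics are recorded for every gene, so the
    report doubles as an audit trail; ``final`` is the conjunction of all
    stage booleans.  Columns: stage1_seed_pref, seed_fold, stage2_early_oil,
    stage3_color, kinetic_pass, peak_stage, decline_ratio_observed,
    kinetic_corr, core_member, final.
    """
    cfg = cfg or ScreenConfig()
    cfg.validate()
    genes = expr.genes
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["stage1_seed_pref", "seed_fold", "stage2_early_oil",
                     "stage3_color", "kinetic_pass", "peak_stage",
                     "decline_ratio_observed", "kinetic_corr",
                     "core_member", "final"])

    organ = expr.subset(varieties=panels.organ_varieties)
    s1, fold = seed_preference_filter(organ, cfg)

    oil = expr.subset(varieties=panels.oil_varieties)
    s2 = early_expression_filter(oil, cfg)

    color = expr.subset(varieties=[panels.white_variety, panels.black_variety])
    s3 = seedcolor_filter(color, cfg, panels.white_variety)

    white_means = (expr.subset(varieties=[panels.white_variety], tissue="seed")
                   .mean_by(["stage"]))
    kin = {g: kinetic_concordance(white_means.loc[g], profile, cfg) for g in genes}
    kin_pass = pd.Series({g: kin[g][0] for g in genes})
    peak = pd.Series({g: kin[g][1] for g in genes})
    decline = pd.Series({g: kin[g][2] for g in genes})
    corr = pd.Series({g: kin[g][3] for g in genes})

    core = core_membership_filter(list(genes), orthogroups)

    report = pd.DataFrame({
        "stage1_seed_pref": s1.reindex(genes),
        "seed_fold": fold.reindex(genes),
        "stage2_early_oil": s2.reindex(genes),
        "stage3_color": s3.reindex(genes),
        "kinetic_pass": kin_pass.reindex(genes),
        "peak_stage": peak.reindex(genes),
        "decline_ratio_observed": decline.reindex(genes),
        "kinetic_corr": corr.reindex(genes),
        "core_member": core.reindex(genes),
    })
    report["final"] = (report["stage1_seed_pref"] & report["stage2_early_oil"]
                       & report["stage3_color"] & report["kinetic_pass"]
                       & report["core_member"])
    report.index.name = "gene_id"
    return report


def final_candidates(report: pd.DataFrame) -> list[str]:
    if report.empty:
        return []
    return sorted(report.index[report["final"]])
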