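"""Collinear-block detection and tandem/segmental paralog classification.

Genes are ranked along their chromosomes by start coordinate; homologous
anchor pairs are chained into collinear blocks with a longest-chain
dynamic programme over gene ranks (both orientations, bounded rank gaps),
extracting chains greedily longest-first until none reaches the minimum
anchor count.  Paralog pairs are then classed tandem (rank-adjacent on
one chromosome), segmental (anchored inside an intragenomic block) or
dispersed.  Cross-species blocks support the family synteny fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

DEFAULT_MAX_GAP = 25
DEFAULT_MIN_ANCHORS = 5
DEFAULT_TANDEM_MAX_RANK_GAP = 1


@dataclass
class GeneModel:
    """A gene locus: 1-based closed coordinates plus a chromosome rank."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    score: float = 1.0


@dataclass
class CollinearBlock:
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"


@dataclass(frozen=True)
class DuplicationCall:
    pair: tuple[str, str]
    cls: str  # tandem | segmental | dispersed


def assign_ranks(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Number genes 1..n along each chromosome by start coordinate.

    Ties break by end then gene_id; duplicate gene ids are rejected.
    Returns new GeneModel objects; input order is preserved in the output.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    ranks: dict[str, int] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        ordered = sorted(chrom_genes, key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(ordered, start=1):
            ranks[g.gene_id] = i
    return [
        GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, ranks[g.gene_id])
        for g in genes
    ]


def _resolve(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    table = {g.gene_id: g for g in genes}
    for g in table.values():
        if g.rank is None:
            raise ValidationError(f"gene {g.gene_id} has no rank; call assign_ranks")
    return table


def _chain_step_ok(prev: tuple[int, int], cur: tuple[int, int],
                   direction: int, max_gap: int) -> bool:
    da = cur[0] - prev[0]
    db = (cur[1] - prev[1]) * direction
    return 0 < da <= max_gap and 0 < db <= max_gap


def _best_chain(points: list[tuple[int, int, int]], direction: int,
                max_gap: int) -> list[int]:
    """Lexicographically-smallest maximum-length chain over anchor points.

    ``points`` are (rank_a, rank_b, index) tuples sorted by (rank_a,
    rank_b); direction +1 chains rank_b increasing, -1 decreasing.
    Returns indices into ``points``.  F[i] = longest chain starting at i
    (DP right to left); the chain is then rebuilt greedily, at each step
    taking the smallest (rank_a, rank_b) continuation that preserves the
    maximum, which pins down a unique deterministic chain.
    """
    n = len(points)
    if n == 0:
        return []
    F = [1] * n
    for i in range(n - 1, -1, -1):
        pi = (points[i][0], points[i][1])
        for j in range(i + 1, n):
            pj = (points[j][0], points[j][1])
            if _chain_step_ok(pi, pj, direction, max_gap) and F[j] + 1 > F[i]:
                F[i] = F[j] + 1
    best = max(F)
    # greedy lexicographic reconstruction
    chain: list[int] = []
    candidates = [i for i in range(n) if F[i] == best]
    cur = min(candidates, key=lambda i: (points[i][0], points[i][1]))
    chain.append(cur)
    remaining = best - 1
    while remaining:
        nxt = [
            j for j in range(cur + 1, n)
            if F[j] == remaining
            and _chain_step_ok((points[cur][0], points[cur][1]),
                               (points[j][0], points[j][1]), direction, max_gap)
        ]
        cur = min(nxt, key=lambda j: (points[j][0], points[j][1]))
        chain.append(cur)
        remaining -= 1
    return chain


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Within one chromosome pair, repeatedly extract the longest chain of
    anchors whose side-A ranks increase strictly and whose side-B ranks
    increase (orientation ``same``) or decrease (``inverted``) strictly,
    consecutive rank gaps bounded by ``max_gap`` on both sides.  Ties:
    longer chain wins; equal lengths prefer orientation ``same``, then the
    lexicographically smallest (rank_a, rank_b) anchor sequence.  Used
    anchors are removed and chaining repeats until no chain reaches
    ``min_anchors``.  Blocks are reported sorted by (chrom_a, chrom_b,
    first rank_a).
    """
    table_a = _resolve(genes_a)
    table_b = _resolve(genes_b)
    by_pair: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for anc in anchors:
        try:
            ga, gb = table_a[anc.gene_a], table_b[anc.gene_b]
        except KeyError as exc:
            raise ValidationError(f"anchor references unknown gene {exc.args[0]!r}")
        by_pair.setdefault((ga.chrom, gb.chrom), []).append((ga.rank, gb.rank, anc))

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        pool = sorted(by_pair[(ca, cb)], key=lambda t: (t[0], t[1]))
        while True:
            points = [(ra, rb, i) for i, (ra, rb, _) in enumerate(pool)]
            if len(points) < min_anchors:
                break
            chains = {}
            for direction, name in ((1, "same"), (-1, "inverted")):
                chains[name] = _best_chain(points, direction, max_gap)
            if len(chains["same"]) >= len(chains["inverted"]):
                chosen, orientation = chains["same"], "same"
            else:
                chosen, orientation = chains["inverted"], "inverted"
            if len(chosen) < min_anchors:
                break
            picked = [pool[points[i][2]] for i in chosen]
            blocks.append(
                CollinearBlock(
                    anchors=[p[2] for p in picked],
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                )
            )
            used = {id(p[2]) for p in picked}
            pool = [t for t in pool if id(t[2]) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b,
                               _resolve_rank(table_a, b.anchors[0].gene_a)))
    return blocks


def _resolve_rank(table: Mapping[str, GeneModel], gene_id: str) -> int:
    return table[gene_id].rank  # type: ignore[return-value]


def classify_duplicates(
    paralog_pairs: Sequence[tuple[str, str]],
    blocks: Sequence[CollinearBlock],
    ranked_genes: Sequence[GeneModel],
    tandem_max_rank_gap: int = DEFAULT_TANDEM_MAX_RANK_GAP,
) -> list[DuplicationCall]:
    """Class each paralog pair as tandem, segmental or dispersed.

    tandem: same chromosome and |rank difference| <= ``tandem_max_rank_gap``
    (MCScanX-style adjacency); segmental: the pair is an anchor of an
    intragenomic collinear block; dispersed: everything else.  The three
    classes are exhaustive and exclusive.
    """
    table = _resolve(ranked_genes)
    anchored = set()
    for blk in blocks:
        for anc in blk.anchors:
            anchored.add(frozenset((anc.gene_a, anc.gene_b)))
    calls = []
    for a, b in paralog_pairs:
        try:
            ga, gb = table[a], table[b]
        except KeyError as exc:
            raise ValidationError(f"paralog pair references unknown gene {exc.args[0]!r}")
        if ga.chrom == gb.chrom and abs(ga.rank - gb.rank) <= tandem_max_rank_gap:
            cls = "tandem"
        elif frozenset((a, b)) in anchored:
            cls = "segmental"
        else:
            cls = "dispersed"
        calls.append(DuplicationCall(pair=(a, b), cls=cls))
    return calls


def interspecies_synteny_fraction(
    family_genes: set[str],
    blocks: Sequence[CollinearBlock],
) -> tuple[int, int]:
    """Count family genes anchored in >= 1 cross-species block.

    Returns (count, percent) where percent = 100 * count / |family_genes|
    rounded to the nearest integer, the reporting convention used for
    family conservation summaries (e.g. 31 of 83 -> 37%).
    """
    if not family_genes:
        raise ValidationError("family_genes must be nonempty")
    side_a = {anc.gene_a for blk in blocks for anc in blk.anchors}
    count = len(family_genes & side_a)
    percent = int(round(100.0 * count / len(family_genes)))
    return count, percent


# ---------------------------------------------------------------------------
# I/O


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file into unranked GeneModels."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes"],
        dtype={"seqid": str, "attributes": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        if row.type != "gene":
            continue
        gene_id = None
        for part in str(row.attributes).split(";"):
            key, _, value = part.partition("=")
            if key.strip() == "ID":
                gene_id = value.strip()
        if gene_id is None:
            raise ValidationError(f"gene feature without ID attribute at {row.seqid}:{row.start}")
        genes.append(GeneModel(gene_id, str(row.seqid), int(row.start),
                               int(row.end), str(row.strand)))
    return genes


def read_anchor_table(path: str | Path) -> list[AnchorPair]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [AnchorPair(a, b, float(s))
            for a, b, s in df[["gene_a", "gene_b", "score"]].itertuples(index=False)]


def blocks_table(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    rows = []
    for i, blk in enumerate(blocks, start=1):
        for anc in blk.anchors:
            rows.append((f"block{i:04d}", blk.chrom_a, blk.chrom_b,
                         blk.orientation, anc.gene_a, anc.gene_b))
    return pd.DataFrame(rows, columns=["block_id", "chrom_a", "chrom_b",
                                       "orientation", "gene_a", "gene_b"])


def calls_table(calls: Sequence[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a, b, c.cls) for c in calls for a, b in [c.pair]],
        columns=["gene_a", "gene_b", "cls"],
    )
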