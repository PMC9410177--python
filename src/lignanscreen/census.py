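"""Gene-family census from HMM domain hits across a pan-genome.

Family members (peroxidases, POD; laccases, LAC) are called from
``hmmsearch`` domain-hit tables with an inclusive E-value threshold of
1e-5 on both the full-sequence E-value and the per-domain independent
E-value, then verified against an independent domain-scan table to drop
spurious hits.  Accepted genes from all varieties are clustered into
orthogroups (single-linkage connected components of a score-thresholded
similarity graph) and each orthogroup is classed core (present in every
variety), shared (in several) or variety-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

DEFAULT_E_FULL = 1e-5
DEFAULT_E_DOM = 1e-5

#: Domain names a verified member of each family must carry in the
#: domain-scan table (PfamScan-style).
FAMILY_DOMAINS = {"POD": "peroxidase", "LAC": "laccase"}


@dataclass(frozen=True)
class DomainHit:
    """One HMM profile match on one protein (one domtblout row)."""

    gene_id: str
    profile_id: str
    full_evalue: float
    dom_ievalue: float
    ali_start: int
    ali_end: int
    bit_score: float

    def __post_init__(self):
        if self.full_evalue <= 0 or self.dom_ievalue <= 0:
            raise ValidationError(
                f"E-values must be positive for {self.gene_id}: "
                f"{self.full_evalue}, {self.dom_ievalue}"
            )
        if self.ali_start > self.ali_end:
            raise ValidationError(
                f"alignment start {self.ali_start} > end {self.ali_end} "
                f"for {self.gene_id}"
            )


class Status(str, Enum):
    ACCEPTED = "accepted"
    REJECTED_THRESHOLD = "rejected_threshold"
    REJECTED_SPURIOUS = "rejected_spurious"


@dataclass
class FamilyAssignment:
    """Family call for one gene with the domain hits supporting it."""

    gene_id: str
    family: str  # "POD" | "LAC"
    status: Status
    evidence: list[DomainHit] = field(default_factory=list)


@dataclass
class Orthogroup:
    """A cluster of genes across varieties with a pan-genome class."""

    og_id: str
    members: dict[str, list[str]]  # variety -> gene ids
    cls: str | None = None  # core | shared | specific

    def varieties_present(self) -> frozenset[str]:
        return frozenset(v for v, genes in self.members.items() if genes)


@dataclass
class CensusSummary:
    per_variety_counts: dict[str, int]
    mean: float
    sd: float
    intersection_counts: dict[frozenset[str], int]


# ---------------------------------------------------------------------------
# domtblout parsing

# hmmsearch --domtblout has 22 whitespace-delimited columns followed by a
# free-text description.  The ones we consume, 0-based:
#   0  target (gene) name      3  query (profile) name
#   6  full-sequence E-value   12 this-domain i-Evalue   13 this-domain score
#   17 ali from                18 ali to
_DOMTBL_MIN_COLS = 22


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table into :class:`DomainHit` rows.

    Comment lines (``#``) are skipped; malformed rows raise
    :class:`ParseError` carrying the 1-based line number.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ParseError(
                    f"expected >= {_DOMTBL_MIN_COLS} columns, got {len(cols)}",
                    line=lineno,
                )
            try:
                hit = DomainHit(
                    gene_id=cols[0],
                    profile_id=cols[3],
                    full_evalue=float(cols[6]),
                    dom_ievalue=float(cols[12]),
                    ali_start=int(cols[17]),
                    ali_end=int(cols[18]),
                    bit_score=float(cols[13]),
                )
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from exc
            except ValidationError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[DomainHit],
    e_full: float = DEFAULT_E_FULL,
    e_dom: float = DEFAULT_E_DOM,
) -> list[DomainHit]:
    """Keep hits with ``full_evalue <= e_full`` and ``dom_ievalue <= e_dom``.

    Both comparisons are inclusive, matching the reporting semantics of
    ``hmmsearch -E/--domE``.
    """
    if e_full <= 0 or e_dom <= 0:
        raise ValidationError("E-value thresholds must be positive")
    return [h for h in hits if h.full_evalue <= e_full and h.dom_ievalue <= e_dom]


def call_family_members(
    hits: Iterable[DomainHit],
    family: str,
    e_full: float = DEFAULT_E_FULL,
    e_dom: float = DEFAULT_E_DOM,
) -> list[FamilyAssignment]:
    """Group hits per gene and call threshold-level family membership.

    Duplicate domain rows for one gene are merged under a single
    assignment keeping every hit as evidence.  A gene is accepted at this
    stage iff at least one of its hits passes both thresholds; domain
    verification (:func:`verify_domains`) runs afterwards.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out = []
    for gene_id in sorted(by_gene):
        ev = by_gene[gene_id]
        passing = filter_hits(ev, e_full, e_dom)
        status = Status.ACCEPTED if passing else Status.REJECTED_THRESHOLD
        out.append(FamilyAssignment(gene_id, family, status, ev))
    return out


def verify_domains(
    candidates: Sequence[FamilyAssignment],
    scan_table: Mapping[str, set[str]],
) -> list[FamilyAssignment]:
    """Demote threshold-accepted genes lacking their family's named domain.

    ``scan_table`` maps gene id to the set of domain names found by an
    independent scan; a missing gene counts as an empty set.  Genes whose
    set lacks the family domain (``peroxidase`` / ``laccase``) become
    ``rejected_spurious``; already-rejected genes are passed through.
    """
    out = []
    for cand in candidates:
        required = FAMILY_DOMAINS[cand.family]
        status = cand.status
        if status is Status.ACCEPTED:
            domains = scan_table.get(cand.gene_id, set())
            if required not in domains:
                status = Status.REJECTED_SPURIOUS
        out.append(FamilyAssignment(cand.gene_id, cand.family, status, cand.evidence))
    return out


def read_scan_table(path: str | Path) -> dict[str, set[str]]:
    """Read a PfamScan-style two-column TSV (gene_id, domain name)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "domain"], dtype=str)
    table: dict[str, set[str]] = {}
    for gene, dom in zip(df["gene_id"], df["domain"]):
        table.setdefault(gene, set()).add(dom)
    return table


# ---------------------------------------------------------------------------
# orthogrouping


def read_similarity_edges(path: str | Path) -> pd.DataFrame:
    """Read a similarity edge TSV with columns gene_a, gene_b, score."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = {"gene_a", "gene_b", "score"}
    if not expected.issubset(df.columns):
        raise ParseError(f"similarity table must have columns {sorted(expected)}")
    return df


def cluster_orthogroups(
    edges: pd.DataFrame,
    gene_variety: Mapping[str, str],
    min_score: float,
) -> list[Orthogroup]:
    """Cluster genes into orthogroups by single-linkage on similarity.

    Connected components of the graph whose edges have
    ``score >= min_score``; every gene in ``gene_variety`` with no
    qualifying edge forms a singleton group.  Group ids are assigned in
    lexicographic order of each component's smallest member, which makes
    the output deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(gene_variety)
    for gene_a, gene_b, score in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        for gene in (gene_a, gene_b):
            if gene not in gene_variety:
                raise ValidationError(f"edge references unknown gene {gene!r}")
        if score >= min_score:
            g.add_edge(gene_a, gene_b)
    components = sorted(nx.connected_components(g), key=min)
    groups = []
    for i, comp in enumerate(components, start=1):
        members: dict[str, list[str]] = {}
        for gene in sorted(comp):
            members.setdefault(gene_variety[gene], []).append(gene)
        groups.append(Orthogroup(og_id=f"OG{i:05d}", members=members))
    return groups


def classify_orthogroups(
    groups: Sequence[Orthogroup],
    varieties: Sequence[str],
) -> tuple[list[Orthogroup], dict[frozenset[str], int]]:
    """Assign core/shared/specific classes and tally variety intersections.

    core = members in every listed variety; specific = members in exactly
    one; shared = anything in between.  The intersection counts are keyed
    by the exact present-variety subset (upset-plot style) and sum to the
    number of orthogroups.
    """
    if not varieties:
        raise ValidationError("varieties must be nonempty")
    known = set(varieties)
    intersections: dict[frozenset[str], int] = {}
    for og in groups:
        present = og.varieties_present()
        unknown = present - known
        if unknown:
            raise ValidationError(
                f"orthogroup {og.og_id} has members from unlisted "
                f"varieties {sorted(unknown)}"
            )
        if present == known:
            og.cls = "core"
        elif len(present) == 1:
            og.cls = "specific"
        else:
            og.cls = "shared"
        intersections[present] = intersections.get(present, 0) + 1
    return list(groups), intersections


def summarize_counts(per_variety_counts: Mapping[str, int]) -> tuple[float, float]:
    """Mean and sample standard deviation of per-variety member counts.

    Uses the n-1 denominator; a single variety gives sd 0.  The reporting
    layer rounds both to integers (e.g. six laccase counts of 56, 48, 45,
    42, 40 and 35 summarize to 44 +/- 7).
    """
    if not per_variety_counts:
        raise ValidationError("per_variety_counts must be nonempty")
    values = np.asarray(list(per_variety_counts.values()), dtype=float)
    mean = float(values.mean())
    sd = 0.0 if values.size == 1 else float(values.std(ddof=1))
    return mean, sd


def accepted_gene_ids(assignments: Iterable[FamilyAssignment]) -> list[str]:
    return [a.gene_id for a in assignments if a.status is Status.ACCEPTED]


def census_table(groups: Sequence[Orthogroup]) -> pd.DataFrame:
    """Long-format orthogroup membership table (og_id, cls, variety, gene_id)."""
    rows = []
    for og in groups:
        for variety in sorted(og.members):
            for gene in og.members[variety]:
                rows.append((og.og_id, og.cls, variety, gene))
    return pd.DataFrame(rows, columns=["og_id", "cls", "variety", "gene_id"])
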