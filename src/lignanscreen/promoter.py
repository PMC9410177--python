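"""Promoter extraction, cis-element scanning and TF-family enrichment.

Promoters are the 2 kb upstream of the annotated gene start (strand
aware, truncated at contig edges).  Cis-acting elements given as IUPAC
consensus strings are located by exact degenerate matching on both
strands; occurrences are tallied per functional category (hormonal,
light, stress, development, other).  Transcription-factor family
over-representation among candidate promoters is tested with the
upper-tail hypergeometric distribution and Benjamini-Hochberg FDR
adjustment across families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .synteny import GeneModel

PROMOTER_LENGTH = 2000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CATEGORIES = ("hormonal", "light", "stress", "development", "other")


@dataclass(frozen=True)
class CisElement:
    """A named promoter element with an IUPAC consensus and a category."""

    name: str
    consensus: str
    category: str

    def __post_init__(self):
        if not self.consensus:
            raise ValidationError(f"element {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(
                f"element {self.name}: invalid IUPAC letters {sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"element {self.name}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class MotifOccurrence:
    promoter_id: str
    element: str
    start: int  # 1-based on the given promoter string
    strand: str  # + | -


#: Small built-in element set (PlantCARE-style names and consensi) used by
#: the simulator and the examples; analyses of real promoters should load
#: a full table with read_element_table.
BUILTIN_ELEMENTS: tuple[CisElement, ...] = (
    CisElement("ABRE", "ACGTG", "hormonal"),
    CisElement("TGACG-motif", "TGACG", "hormonal"),
    CisElement("GARE-motif", "TCTGTTG", "hormonal"),
    CisElement("G-box", "CACGTG", "light"),
    CisElement("GT1-motif", "GGTTAA", "light"),
    CisElement("Box4", "ATTAAT", "light"),
    CisElement("MBS", "CAACTG", "stress"),
    CisElement("ARE", "AAACCA", "stress"),
    CisElement("LTR", "CCGAAA", "stress"),
    CisElement("O2-site", "GATGAYRTGR", "development"),
    CisElement("CAT-box", "GCCACT", "development"),
    CisElement("RY-element", "CATGCATG", "development"),
    CisElement("CAAT-box", "CCAAT", "other"),
    CisElement("TATA-box", "TATAWAW", "other"),
)


def read_element_table(path: str | Path) -> list[CisElement]:
    """Read a TSV with columns name, consensus, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [CisElement(r.name_, r.consensus, r.category)
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def write_element_table(elements: Sequence[CisElement], path: str | Path) -> None:
    pd.DataFrame(
        [(e.name, e.consensus, e.category) for e in elements],
        columns=["name", "consensus", "category"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoters(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    length: int = PROMOTER_LENGTH,
) -> dict[str, str]:
    """Cut the ``length``-bp region upstream of each gene start.

    Plus-strand genes take genomic bases [start - length, start - 1]
    (1-based closed, truncated at position 1); minus-strand genes take
    [end + 1, end + length] reverse-complemented.  The returned string is
    5'->3' relative to the gene.  A plus-strand gene starting at position
    1 yields an empty promoter (kept, so downstream tables stay complete).
    """
    promoters: dict[str, str] = {}
    for gene in genes:
        if gene.chrom not in genome:
            raise ValidationError(f"chromosome {gene.chrom!r} missing from genome")
        seq = genome[gene.chrom]
        if gene.strand == "+":
            lo = max(1, gene.start - length)
            promoter = seq[lo - 1: gene.start - 1]
        else:
            promoter = str(Seq(seq[gene.end: gene.end + length]).reverse_complement())
        promoters[gene.gene_id] = promoter.upper()
    return promoters


# ---------------------------------------------------------------------------
# motif scanning


def _consensus_regex(consensus: str) -> re.Pattern:
    # character classes over the unambiguous bases only, so N in the
    # sequence never matches (conservative)
    parts = []
    for letter in consensus.upper():
        bases = IUPAC.get(letter)
        if bases is None:
            raise ValidationError(f"invalid IUPAC letter {letter!r} in {consensus!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    promoters: Mapping[str, str],
    elements: Sequence[CisElement],
) -> list[MotifOccurrence]:
    """Report every match of every element on both strands.

    Minus-strand matches are found by scanning with the reverse-complement
    consensus and are reported with strand '-' and the plus-strand
    coordinate of the match start on the given promoter string.
    """
    occurrences: list[MotifOccurrence] = []
    for element in elements:
        fwd = _consensus_regex(element.consensus)
        rc = str(Seq(element.consensus.upper()).reverse_complement())
        rev = _consensus_regex(rc)
        palindromic = rc == element.consensus.upper()
        for pid in promoters:
            seq = promoters[pid].upper()
            for m in fwd.finditer(seq):
                occurrences.append(MotifOccurrence(pid, element.name, m.start() + 1, "+"))
            if not palindromic:
                for m in rev.finditer(seq):
                    occurrences.append(MotifOccurrence(pid, element.name, m.start() + 1, "-"))
    occurrences.sort(key=lambda o: (o.promoter_id, o.element, o.start, o.strand))
    return occurrences


def categorize_elements(
    occurrences: Sequence[MotifOccurrence],
    elements: Sequence[CisElement],
    promoter_ids: Sequence[str],
) -> pd.DataFrame:
    """Zero-filled per-gene occurrence counts by functional category."""
    cat_of = {e.name: e.category for e in elements}
    table = pd.DataFrame(0, index=list(promoter_ids), columns=list(CATEGORIES))
    for occ in occurrences:
        if occ.element not in cat_of:
            raise ValidationError(f"occurrence of unknown element {occ.element!r}")
        table.loc[occ.promoter_id, cat_of[occ.element]] += 1
    table.index.name = "gene_id"
    return table


# ---------------------------------------------------------------------------
# TF enrichment


def read_binding_map(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV with columns family, gene into family -> bound genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    table: dict[str, set[str]] = {}
    for fam, gene in zip(df["family"], df["gene"]):
        table.setdefault(fam, set()).add(gene)
    return table


def tf_enrichment(
    target_genes: set[str],
    binding_map: Mapping[str, set[str]],
    background_genes: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of TF families in a gene set.

    For each family with bound-gene set B: N = |background|,
    K = |B & background|, n = |target|, k = |B & target|, and
    p = P[X >= k] for X ~ Hypergeometric(N, K, n).  p-values are BH
    adjusted across families; rows are sorted by (q, p, family) so the
    top row is the most enriched family.
    """
    if not target_genes <= background_genes:
        extra = sorted(target_genes - background_genes)[:5]
        raise ValidationError(f"target genes not in background: {extra}")
    N, n = len(background_genes), len(target_genes)
    rows = []
    for family in sorted(binding_map):
        bound = binding_map[family] & background_genes
        K = len(bound)
        k = len(bound & target_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((family, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["family", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    df = df.sort_values(["q", "p", "family"], kind="mergesort").reset_index(drop=True)
    return df


def occurrences_table(occurrences: Sequence[MotifOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.promoter_id, o.element, o.start, o.strand) for o in occurrences],
        columns=["promoter_id", "element", "start", "strand"],
    )
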