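"""qPCR relative expression (2^-ddCt) and RNA-seq concordance.

Technical replicates are averaged to a mean Ct per (gene, sample);
dCt subtracts the reference gene within each sample, ddCt subtracts the
calibrator sample within each gene, and relative expression is
2^-ddCt (amplification efficiency fixed at 2, no efficiency
correction).  Concordance with RNA-seq is the squared Pearson
correlation between log2 relative expression and log2(FPKM + 1) over
shared (gene, sample) points.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ValidationError


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns gene, sample, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    missing = {"gene", "sample", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns {sorted(missing)}")
    if not np.isfinite(df["ct"]).all():
        raise ValidationError("Ct values must be finite")
    return df


def ddct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression 2^-ddCt per (gene, sample).

    Returns a genes x samples DataFrame (reference gene excluded).  The
    calibrator sample's column is exactly 1 for every gene by
    construction, and the whole table is invariant to adding a constant
    to every Ct.
    """
    mean_ct = records.groupby(["gene", "sample"])["ct"].mean().unstack("sample")
    if reference_gene not in mean_ct.index:
        raise ValidationError(f"reference gene {reference_gene!r} missing from Ct table")
    ref = mean_ct.loc[reference_gene]
    if ref.isna().any():
        gaps = sorted(ref.index[ref.isna()])
        raise ValidationError(
            f"reference gene {reference_gene!r} not measured in samples {gaps}")
    if calibrator_sample not in mean_ct.columns:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} missing from Ct table")
    targets = mean_ct.drop(index=reference_gene)
    if targets[calibrator_sample].isna().any():
        gaps = sorted(targets.index[targets[calibrator_sample].isna()])
        raise ValidationError(
            f"calibrator sample {calibrator_sample!r} not measured for genes {gaps}")
    dct = targets.sub(ref, axis=1)
    ddct_values = dct.sub(dct[calibrator_sample], axis=0)
    rel = np.power(2.0, -ddct_values)
    rel.index.name = "gene"
    return rel


def concordance(
    qpcr_values: pd.DataFrame,
    rnaseq_fpkm: pd.DataFrame,
    pseudocount: float = 1.0,
) -> float:
    """R^2 between log2 qPCR relative expression and log2(FPKM + pc).

    Both inputs are genes x samples; only shared (gene, sample) cells are
    used and at least 3 are required.  Returns NaN when either axis has
    zero variance (R^2 undefined).
    """
    q = qpcr_values.stack()
    r = rnaseq_fpkm.stack()
    shared = q.index.intersection(r.index)
    if len(shared) < 3:
        raise ValidationError(
            f"concordance needs >= 3 shared (gene, sample) points, got {len(shared)}")
    x = np.log2(q.loc[shared].to_numpy(dtype=float))
    y = np.log2(r.loc[shared].to_numpy(dtype=float) + pseudocount)
    if x.std() == 0 or y.std() == 0:
        return math.nan
    rho = pearsonr(x, y).statistic
    return float(rho * rho)
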