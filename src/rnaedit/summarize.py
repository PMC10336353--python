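"""Descriptive analytics over accepted/differential editing sites: flanking
sequence-context motif, functional-category table, group presence Venn
accounting (sites and genes), top-k differential table, and PCA of editing
levels."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import EditingSite
from .genes import revcomp
from .io import SampleSheet

BASES = "ACGT"


class SummaryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sequence-context motif

def motif_matrix(sites: list[EditingSite], genome: dict[str, str],
                 flank: int = 6) -> pd.DataFrame:
    """Base frequencies at coding-strand positions -flank..+flank around the
    edited adenosines.  Rows A/C/G/T, columns the relative positions; each
    column sums to 1 and the centre column has frequency(A) = 1.  Sites too
    close to a chromosome edge are dropped."""
    if not sites:
        raise SummaryError("no sites for motif computation")
    counts = np.zeros((4, 2 * flank + 1), dtype=float)
    used = 0
    for s in sites:
        seq = genome[s.chrom]
        if s.pos - flank < 0 or s.pos + flank >= len(seq):
            continue
        context = seq[s.pos - flank:s.pos + flank + 1]
        if s.strand == "-":
            context = revcomp(context)
        for j, b in enumerate(context):
            if b in BASES:
                counts[BASES.index(b), j] += 1
        used += 1
    if used == 0:
        raise SummaryError("all sites fell within `flank` of a chrom edge")
    freq = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(freq, index=list(BASES),
                        columns=[str(p) for p in range(-flank, flank + 1)])


# ---------------------------------------------------------------------------
# functional categories

def category_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """category -> (count, percent); counts partition the site set."""
    counts = annotated["category"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame({
        "category": counts.index,
        "count": counts.values,
        "percent": 100.0 * counts.values / total,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# group Venn accounting

def group_presence_venn(annotated: pd.DataFrame, sheet: SampleSheet,
                        min_level: float = 0.01) -> pd.DataFrame:
    """Shared/unique counts between the two groups, for sites and genes.

    A site is present in a group when at least one sample of that group has
    editing level >= min_level; a gene is present when any of its sites is.
    """
    lab1, lab2 = sheet.labels
    cols1 = [f"level:{s}" for s in sheet.samples_in(lab1)]
    cols2 = [f"level:{s}" for s in sheet.samples_in(lab2)]
    in1 = (annotated[cols1] >= min_level).any(axis=1)
    in2 = (annotated[cols2] >= min_level).any(axis=1)
    genes1 = set(annotated.loc[in1, "gene"])
    genes2 = set(annotated.loc[in2, "gene"])
    rows = [
        {"unit": "sites",
         "shared": int((in1 & in2).sum()),
         f"unique_{lab1}": int((in1 & ~in2).sum()),
         f"unique_{lab2}": int((in2 & ~in1).sum())},
        {"unit": "genes",
         "shared": len(genes1 & genes2),
         f"unique_{lab1}": len(genes1 - genes2),
         f"unique_{lab2}": len(genes2 - genes1)},
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-k table

def top_table(diff: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Top k DRE sites ranked by GLM p (ties: Fisher p, then site id)."""
    if k <= 0:
        raise SummaryError("k must be positive")
    dre = diff[diff["is_dre"]].copy()
    dre["_fp"] = dre["fisher_p"].fillna(np.inf)
    dre = dre.sort_values(["glm_p", "_fp", "site"], kind="mergesort")
    return dre.drop(columns="_fp").head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA of editing levels

def pca_editing(levels: np.ndarray, sample_ids: list[str]
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a samples x sites editing-level matrix.

    Columns are centred (not scaled); the decomposition is the SVD of the
    centred matrix, equivalent to eigendecomposition of the sample
    covariance.  Returns (scores table with PC1/PC2 per sample, variance
    fractions in percent, non-increasing, summing to <= 100)."""
    X = np.asarray(levels, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise SummaryError("need >= 2 samples and >= 2 sites for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        frac = np.zeros(min(X.shape))
        scores = np.zeros((X.shape[0], 2))
    else:
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = S ** 2
        frac = 100.0 * var / var.sum()
        scores = U[:, :2] * S[:2]
    df = pd.DataFrame({"sample": sample_ids,
                       "PC1": scores[:, 0], "PC2": scores[:, 1]})
    return df, frac
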