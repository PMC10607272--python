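"""Hybrid index, interclass heterozygosity, and hybrid-class assignment.

All computations run on ancestry-informative (diagnostic) loci: loci fixed
for alternative alleles in the two parental populations (FST = 1).  With
fully diagnostic codominant markers the maximum-likelihood hybrid index
reduces exactly to the allele-count proportion, so the closed form is used:

    h = (# parent-B alleles) / (2 * genotyped diagnostic loci)
    H = (# heterozygous diagnostic loci) / (genotyped diagnostic loci)

Class thresholds: pure individuals have h exactly 0 or 1; intermediate
hybrid indices (> 0.25 and < 0.75) with high heterozygosity (>= 0.5) are
recent-generation hybrids and with low heterozygosity (< 0.5)
later-generation hybrids; h in (0, 0.25] or [0.75, 1) is backcrossed toward
the respective parent.  An F1-consistent flag marks h = 0.5 with H = 1
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, DiagnosticPanel, GenotypeMatrix, oriented_diagnostic_calls

CLASS_LABELS = ("pure_A", "pure_B", "recent_generation", "later_generation",
                "backcross_A", "backcross_B", "unclassified")


def hybrid_index(oriented_calls: np.ndarray) -> np.ndarray:
    """Per-sample proportion of parent-B alleles over genotyped diagnostic loci.

    ``oriented_calls``: samples x loci counts of the parent-B allele
    (-1 = missing).  Samples with zero genotyped loci are NaN.
    """
    calls = np.atleast_2d(np.asarray(oriented_calls))
    genotyped = calls != MISSING
    n = genotyped.sum(axis=1)
    b_alleles = np.where(genotyped, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n > 0, b_alleles / np.maximum(2 * n, 1), np.nan)
    return h.astype(float)


def interclass_het(oriented_calls: np.ndarray) -> np.ndarray:
    """Per-sample fraction of genotyped diagnostic loci that are heterozygous."""
    calls = np.atleast_2d(np.asarray(oriented_calls))
    genotyped = calls != MISSING
    n = genotyped.sum(axis=1)
    het = ((calls == 1) & genotyped).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return H.astype(float)


def classify(h: float, H: float) -> str:
    """Hybrid class from (hybrid index, interclass heterozygosity)."""
    if np.isnan(h) or np.isnan(H):
        return "unclassified"
    if h == 0.0:
        return "pure_A"
    if h == 1.0:
        return "pure_B"
    if 0.25 < h < 0.75:
        return "recent_generation" if H >= 0.5 else "later_generation"
    if h <= 0.25:
        return "backcross_A"
    return "backcross_B"


def is_f1_consistent(h: float, H: float) -> bool:
    """True for the exact F1 expectation: h = 0.5 and H = 1."""
    return h == 0.5 and H == 1.0


@dataclass
class HybridProfiles:
    """Per-sample hybrid profiles (triangle-plot coordinates plus labels)."""

    table: pd.DataFrame  # sample, h, H, n_loci, class, f1_consistent

    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def classify_profiles(gm: GenotypeMatrix, panel: DiagnosticPanel,
                      min_loci: int = 3) -> HybridProfiles:
    """Hybrid profiles for every sample from an oriented diagnostic panel.

    Samples genotyped at fewer than ``min_loci`` panel loci are left
    unclassified (with a warning).
    """
    oriented = oriented_diagnostic_calls(gm, panel)
    h = hybrid_index(oriented)
    H = interclass_het(oriented)
    n = (oriented != MISSING).sum(axis=1)
    labels = []
    for i in range(len(gm.samples)):
        if n[i] < min_loci:
            labels.append("unclassified")
        else:
            labels.append(classify(h[i], H[i]))
    n_un = labels.count("unclassified")
    if n_un:
        warnings.warn(f"{n_un} samples unclassified (fewer than {min_loci} "
                      "genotyped diagnostic loci)")
    flags = [n[i] >= min_loci and is_f1_consistent(h[i], H[i])
             for i in range(len(gm.samples))]
    return HybridProfiles(pd.DataFrame({
        "sample": gm.samples, "h": h, "H": H, "n_loci": n,
        "class": labels, "f1_consistent": flags,
    }))
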