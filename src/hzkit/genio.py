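"""Genotype matrices: reading, variant filtering, differentiation, diagnostic markers.

The in-memory container is a samples x loci matrix of alternate-allele counts
(0, 1, 2) with -1 for missing calls.  Readers accept VCF v4.x (GT field,
biallelic SNPs only; parsed with cyvcf2) and a plain genotype TSV dialect
(rows = samples, columns = loci, values 0/1/2/NA).  Locus identifiers encode
their parent locus/contig as "<locus>_<snp>", which drives the
one-random-SNP-per-locus filter.

Variant filters mirror a Stacks *populations*-style pass: minimum minor
allele count, maximum observed heterozygosity, per-population completeness
(genotyped in at least a fraction r of samples in at least p populations),
then optionally one random SNP per parent locus.  Per-locus differentiation
is the Weir & Cockerham (1984) theta estimator; diagnostic
(ancestry-informative) loci are those fixed for alternative alleles in the
two parental reference sets (FST = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ParseError

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, alternate-allele counts with -1 = missing."""

    samples: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.samples = [str(s) for s in self.samples]
        self.loci = [str(l) for l in self.loci]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids")
        if len(set(self.loci)) != len(self.loci):
            raise FormatError("duplicate locus ids")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise FormatError(f"{bad.sum()} genotype calls outside {{-1,0,1,2}}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_group(self, locus_id: str) -> str:
        """Parent locus key: everything before the last underscore."""
        return locus_id.rsplit("_", 1)[0] if "_" in locus_id else locus_id

    @property
    def locus_groups(self) -> list[str]:
        return [self.locus_group(l) for l in self.loci]

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[str(s)] for s in ids], dtype=int)
        except KeyError as e:
            raise FormatError(f"unknown sample id {e.args[0]!r}") from None

    def subset(self, samples=None, loci=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples) if samples is None else self.sample_index(samples)
        if loci is None:
            cols = np.arange(self.n_loci)
        else:
            pos = {l: i for i, l in enumerate(self.loci)}
            cols = np.array([pos[str(l)] for l in loci], dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.loci[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    # -- TSV dialect -------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.calls.astype(object), index=self.samples,
                          columns=self.loci)
        df = df.where(df != MISSING, other="NA")
        df.index.name = "sample"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        except Exception as e:
            raise ParseError(f"cannot parse genotype TSV {path}: {e}") from e
        calls = df.to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls)
        if not np.isin(calls, (-1, 0, 1, 2)).all():
            raise ParseError(f"genotype TSV {path} has values outside 0/1/2/NA")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   calls.astype(np.int8))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF; multi-allelic records are skipped."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:
        raise ParseError(f"cannot open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    loci: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            if len(gt) != 3:  # [allele0, allele1, phased]
                raise FormatError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS} sample "
                    f"{samples[i]}")
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        locus_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        loci.append(locus_id)
        cols.append(col)
    if n_skipped:
        log.info("skipped %d multi-allelic records", n_skipped)
    calls = (np.column_stack(cols) if cols
             else np.empty((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(samples, loci, calls)
    gm.n_multiallelic_skipped = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Write a minimal VCF v4.2 (one biallelic SNP per record, GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hzkit\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(gm.loci):
            gts = "\t".join(code[int(g)] for g in gm.calls[:, j])
            fh.write(f"{chrom}\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or genotype TSV (inferred from suffix)."""
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return GenotypeMatrix.from_tsv(path)
    raise ParameterError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterPolicy:
    """Variant filters applied in order: minor-allele count, observed
    heterozygosity, per-population completeness, one random SNP per locus."""

    min_mac: int = 3
    max_obs_het: float = 0.5
    completeness_r: float = 0.8
    min_pops_present: int = 1
    one_random_snp_per_locus: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.max_obs_het <= 1.0):
            raise ParameterError("max_obs_het must be in [0, 1]")
        if not (0.0 <= self.completeness_r <= 1.0):
            raise ParameterError("completeness r must be in [0, 1]")
        if self.min_pops_present < 1:
            raise ParameterError("min_pops_present must be >= 1")
        if self.min_mac < 0:
            raise ParameterError("min_mac must be >= 0")


def _as_pop_series(gm: GenotypeMatrix, groups) -> pd.Series:
    s = pd.Series(groups)
    missing = [smp for smp in gm.samples if smp not in s.index]
    if missing:
        raise ParameterError(f"samples without population assignment: {missing[:5]}")
    return s.loc[gm.samples]


def filter_variants(gm: GenotypeMatrix, groups, policy: FilterPolicy) -> GenotypeMatrix:
    """Apply the filter policy; returns a new matrix (possibly empty, with warning)."""
    pops = _as_pop_series(gm, groups)
    calls = gm.calls
    genotyped = calls != MISSING
    n_geno = genotyped.sum(axis=0)
    alt = np.where(genotyped, calls, 0).sum(axis=0)
    total = 2 * n_geno
    mac = np.minimum(alt, total - alt)
    keep = mac >= policy.min_mac

    n_het = ((calls == 1) & genotyped).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_geno > 0, n_het / np.maximum(n_geno, 1), 0.0)
    keep &= het_frac <= policy.max_obs_het

    pops_ok = np.zeros(gm.n_loci, dtype=int)
    for pop in pops.unique():
        rows = np.nonzero((pops == pop).to_numpy())[0]
        frac = genotyped[rows].sum(axis=0) / len(rows)
        pops_ok += (frac >= policy.completeness_r).astype(int)
    keep &= pops_ok >= policy.min_pops_present

    kept_loci = [l for l, k in zip(gm.loci, keep) if k]

    if policy.one_random_snp_per_locus and kept_loci:
        rng = np.random.default_rng(policy.seed)
        by_group: dict[str, list[str]] = {}
        for l in sorted(kept_loci):  # lexicographic for platform stability
            by_group.setdefault(gm.locus_group(l), []).append(l)
        chosen = set()
        for grp in sorted(by_group):
            members = by_group[grp]
            chosen.add(members[rng.integers(len(members))])
        kept_loci = [l for l in kept_loci if l in chosen]

    if not kept_loci:
        warnings.warn("all loci removed by filters; returning empty matrix")
    return gm.subset(loci=kept_loci)


# ---------------------------------------------------------------------------
# allele frequencies and differentiation
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqs:
    """Per-locus alternate-allele frequency with genotyped-sample counts.

    Loci with zero genotyped samples carry frequency NaN (undefined flag)."""

    loci: list[str]
    freq: np.ndarray
    n_genotyped: np.ndarray

    @property
    def undefined(self) -> np.ndarray:
        return np.isnan(self.freq)


def allele_freqs(gm: GenotypeMatrix, group) -> AlleleFreqs:
    """Alternate-allele frequencies in a sample group (missing calls excluded)."""
    group = list(group)
    if not group:
        raise ParameterError("group must be non-empty")
    sub = gm.calls[gm.sample_index(group)]
    genotyped = sub != MISSING
    n = genotyped.sum(axis=0)
    alt = np.where(genotyped, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
    return AlleleFreqs(list(gm.loci), freq.astype(float), n)


def fst_per_locus(gm: GenotypeMatrix, group_a, group_b,
                  clamp: bool = True) -> np.ndarray:
    """Per-locus Weir & Cockerham (1984) theta between two sample groups.

    Loci with fewer than two genotyped samples in either group are NaN.
    With ``clamp`` the estimate is clipped to [0, 1] (selection semantics);
    otherwise the raw ratio (which may be negative) is returned.
    """
    A = gm.calls[gm.sample_index(list(group_a))]
    B = gm.calls[gm.sample_index(list(group_b))]
    out = np.full(gm.n_loci, np.nan)
    r = 2.0
    for j in range(gm.n_loci):
        stats = []
        ok = True
        for sub in (A[:, j], B[:, j]):
            g = sub[sub != MISSING]
            if g.size < 2:
                ok = False
                break
            ni = g.size
            pi = g.sum() / (2.0 * ni)
            hi = float(np.mean(g == 1))
            stats.append((ni, pi, hi))
        if not ok:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom if denom != 0.0 else 0.0
        out[j] = min(max(theta, 0.0), 1.0) if clamp else theta
    return out


@dataclass
class DiagnosticPanel:
    """Ancestry-informative loci with orientation.

    ``orientation`` is +1 when the alternate allele marks parent B (alt fixed
    in B, absent in A) and -1 for the reverse."""

    loci: list[str]
    orientation: np.ndarray

    def __len__(self) -> int:
        return len(self.loci)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"locus": self.loci, "orientation": self.orientation}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DiagnosticPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["locus"].astype(str).tolist(),
                   df["orientation"].to_numpy(dtype=int))


def select_diagnostic(gm: GenotypeMatrix, parental_a, parental_b,
                      min_n: int = 2) -> DiagnosticPanel:
    """Loci fixed for alternative alleles between the parental reference sets.

    Requires exact frequencies 0 and 1 (either orientation) with at least
    ``min_n`` genotyped samples per side.  Returns the panel with orientation.
    """
    a = set(map(str, parental_a))
    b = set(map(str, parental_b))
    if a & b:
        raise ParameterError(f"parental sets overlap: {sorted(a & b)[:5]}")
    fa = allele_freqs(gm, sorted(a))
    fb = allele_freqs(gm, sorted(b))
    enough = (fa.n_genotyped >= min_n) & (fb.n_genotyped >= min_n)
    with np.errstate(invalid="ignore"):
        plus = enough & (fa.freq == 0.0) & (fb.freq == 1.0)
        minus = enough & (fa.freq == 1.0) & (fb.freq == 0.0)
    loci, orient = [], []
    for j, locus in enumerate(gm.loci):
        if plus[j]:
            loci.append(locus)
            orient.append(1)
        elif minus[j]:
            loci.append(locus)
            orient.append(-1)
    if not loci:
        warnings.warn("no diagnostic loci found")
    return DiagnosticPanel(loci, np.array(orient, dtype=int))


def oriented_diagnostic_calls(gm: GenotypeMatrix, panel: DiagnosticPanel) -> np.ndarray:
    """Counts of the parent-B allele at panel loci (missing stays -1)."""
    sub = gm.subset(loci=panel.loci).calls
    out = sub.copy()
    flip = panel.orientation == -1
    cols = np.nonzero(flip)[0]
    for j in cols:
        g = out[:, j]
        out[:, j] = np.where(g == MISSING, MISSING, 2 - g)
    return out
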