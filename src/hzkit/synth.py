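"""Synthetic hybrid-zone datasets with known truth.

Emulates the statistical structure of a reduced-representation SNP panel
sampled across a secondary-contact zone between two parental gene pools:

* individuals placed along a 1D transect crossing a straight north-south
  baseline, with true ancestry q following a known sigmoid cline;
* a set of diagnostic loci (fixed differences between the pools) and a set
  of background loci whose parental allele frequencies are drawn from a Beta
  distribution independently per pool;
* genotypes drawn binomially from the ancestry-mixed allele frequency;
* a binary mitochondrial haplogroup following its own (possibly offset)
  cline, mimicking mtDNA/nuclear discordance;
* genotypes masked missing completely at random.

A separate explicit-pedigree generator produces parental, F1, F2 and
backcross classes at diagnostic loci under free recombination, for testing
hybrid-class expectations (F1: hybrid index 0.5, heterozygosity 1).

Default scenario values mirror the scale of the motivating field system: a
~150-individual transect over +/-150 km, a 30-km-wide nuclear cline, 40
diagnostic plus 400 background loci, and 10% missing genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cline import ClineModelSpec, ClineParams, cline_eval
from .errors import ParameterError
from .genio import MISSING, GenotypeMatrix, write_vcf

#: reference origin for converting planar transect km to lon/lat output
ORIGIN_LON = 135.0
ORIGIN_LAT = 35.0

_FIXED01 = ClineModelSpec(scaling="fixed01", tails="none", likelihood="bernoulli")

PEDIGREE_CLASSES = ("P1", "P2", "F1", "F2", "BC1_P1", "BC1_P2", "BC2_P1", "BC2_P2")


def _default_cline() -> ClineParams:
    return ClineParams(center=0.0, width=30.0)


@dataclass
class ZoneScenario:
    """Parameters of a simulated hybrid zone.

    ``true_cline`` drives nuclear ancestry; ``mt_cline`` drives the
    haplogroup indicator and may be offset in centre to emulate
    mito-nuclear discordance.  ``bg_divergence`` gives the Beta(a, b) from
    which each pool's allele frequency at background loci is drawn
    independently.
    """

    n_individuals: int = 150
    transect_halfspan: float = 150.0
    true_cline: ClineParams = field(default_factory=_default_cline)
    mt_cline: ClineParams = field(default_factory=_default_cline)
    n_diag_loci: int = 40
    n_bg_loci: int = 400
    bg_divergence: tuple[float, float] = (2.0, 2.0)
    missing_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.n_diag_loci + self.n_bg_loci < 1:
            raise ParameterError("need at least one locus (diagnostic or background)")
        if self.n_diag_loci < 0 or self.n_bg_loci < 0:
            raise ParameterError("locus counts must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.transect_halfspan <= 0:
            raise ParameterError("transect_halfspan must be > 0")
        self.true_cline.validate()
        self.mt_cline.validate()
        if self.bg_divergence[0] <= 0 or self.bg_divergence[1] <= 0:
            raise ParameterError("Beta parameters must be > 0")

    @classmethod
    def from_json(cls, path) -> "ZoneScenario":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("true_cline", "mt_cline"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ClineParams(**raw[key])
        if "bg_divergence" in raw:
            raw["bg_divergence"] = tuple(raw["bg_divergence"])
        return cls(**raw)


@dataclass
class SampleTable:
    """Per-individual metadata: coordinates, population label, haplogroup."""

    table: pd.DataFrame  # sample, lon, lat, pop, haplogroup

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))


@dataclass
class TruthTable:
    """Simulation truth: position, true ancestry, haplogroup probability."""

    table: pd.DataFrame  # sample, x_km, q_true, hap_prob, locus truth appended wide

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def simulate_zone(scenario: ZoneScenario) -> tuple[GenotypeMatrix, SampleTable, TruthTable]:
    """Simulate genotypes, metadata and truth for one hybrid-zone transect.

    Positions are uniform on [-halfspan, +halfspan] east-west; the true
    baseline is the north-south line at x = 0, so transect distance equals
    the east coordinate.  At each diagnostic locus the parent-2 (alternate)
    allele count is Binomial(2, q_i); at background locus l with pool
    frequencies f1_l, f2_l it is Binomial(2, q_i f2_l + (1 - q_i) f1_l).
    The haplogroup indicator is Bernoulli(mt_cline(x_i)).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_individuals
    hs = scenario.transect_halfspan

    x = rng.uniform(-hs, hs, size=n)
    northing = rng.uniform(-hs, hs, size=n)
    q = np.asarray(cline_eval(scenario.true_cline, _FIXED01, x), dtype=float)
    hap_p = np.asarray(cline_eval(scenario.mt_cline, _FIXED01, x), dtype=float)

    n_diag, n_bg = scenario.n_diag_loci, scenario.n_bg_loci
    a, b = scenario.bg_divergence
    f1 = rng.beta(a, b, size=n_bg)
    f2 = rng.beta(a, b, size=n_bg)

    # pool-2 allele frequency per individual x locus
    freq_diag = np.broadcast_to(q[:, None], (n, n_diag))
    freq_bg = q[:, None] * f2[None, :] + (1.0 - q[:, None]) * f1[None, :]
    calls = np.concatenate([
        rng.binomial(2, freq_diag), rng.binomial(2, freq_bg)], axis=1).astype(np.int8)

    mask = rng.random(calls.shape) < scenario.missing_rate
    calls[mask] = MISSING

    hap = (rng.random(n) < hap_p).astype(int)

    samples = [f"ind{i:04d}" for i in range(n)]
    loci = ([f"diag{j:04d}_1" for j in range(n_diag)]
            + [f"bg{j:04d}_1" for j in range(n_bg)])
    gm = GenotypeMatrix(samples, loci, calls)

    from .geometry import km_to_lonlat

    lonlat = km_to_lonlat(np.stack([x, northing], axis=1), ORIGIN_LON, ORIGIN_LAT)
    meta = SampleTable(pd.DataFrame({
        "sample": samples,
        "lon": lonlat[:, 0], "lat": lonlat[:, 1],
        "pop": np.where(x < 0, "A", "B"),
        "haplogroup": np.where(hap == 1, "B", "A"),
    }))
    truth = TruthTable(pd.DataFrame({
        "sample": samples, "x_km": x, "q_true": q, "hap_prob": hap_p,
    }))
    return gm, meta, truth


# ---------------------------------------------------------------------------
# explicit pedigrees
# ---------------------------------------------------------------------------

@dataclass
class PedigreeScenario:
    """Explicit-pedigree hybrid classes at diagnostic loci."""

    n_per_class: int = 100
    classes: tuple[str, ...] = PEDIGREE_CLASSES
    n_diag_loci: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        if self.n_diag_loci < 1:
            raise ParameterError("n_diag_loci must be >= 1")
        unknown = [c for c in self.classes if c not in PEDIGREE_CLASSES]
        if unknown:
            raise ParameterError(f"unknown pedigree classes: {unknown}")


def _gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid genotype under free recombination.

    Per locus the transmitted allele is parent-2 with probability g/2."""
    return (rng.random(genotype.shape) < genotype / 2.0).astype(np.int8)


def _make_individual(cls: str, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    p1 = np.zeros(n_loci, dtype=np.int8)
    p2 = np.full(n_loci, 2, dtype=np.int8)
    f1 = np.ones(n_loci, dtype=np.int8)
    if cls == "P1":
        return p1
    if cls == "P2":
        return p2
    if cls == "F1":
        return f1
    if cls == "F2":
        return _gamete(f1, rng) + _gamete(f1, rng)
    if cls == "BC1_P1":
        return _gamete(f1, rng) + _gamete(p1, rng)
    if cls == "BC1_P2":
        return _gamete(f1, rng) + _gamete(p2, rng)
    if cls in ("BC2_P1", "BC2_P2"):
        parent = p1 if cls.endswith("P1") else p2
        bc1 = _gamete(f1, rng) + _gamete(parent, rng)
        return _gamete(bc1, rng) + _gamete(parent, rng)
    raise ParameterError(f"unknown pedigree class {cls!r}")


def simulate_pedigree(scenario: PedigreeScenario) -> tuple[GenotypeMatrix, list[str]]:
    """Simulate diagnostic-locus genotypes for explicit hybrid classes.

    Returns the genotype matrix (alternate allele = parent-2 allele) and the
    true class label per individual.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    rows, labels, samples = [], [], []
    i = 0
    for cls in scenario.classes:
        for _ in range(scenario.n_per_class):
            rows.append(_make_individual(cls, scenario.n_diag_loci, rng))
            labels.append(cls)
            samples.append(f"{cls}_{i:04d}")
            i += 1
    loci = [f"diag{j:04d}_1" for j in range(scenario.n_diag_loci)]
    gm = GenotypeMatrix(samples, loci, np.vstack(rows))
    return gm, labels


def write_zone(outdir, gm: GenotypeMatrix, meta: SampleTable, truth: TruthTable) -> None:
    """Write a simulated zone as VCF + metadata TSV + truth TSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, out / "genotypes.vcf")
    meta.to_tsv(out / "samples.tsv")
    truth.to_tsv(out / "truth.tsv")
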