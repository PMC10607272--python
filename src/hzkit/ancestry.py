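"""Supervised two-pool admixture proportion (q-value) estimation.

Given reference alternate-allele frequencies for two parental gene pools A
and B, each individual's ancestry proportion q (fraction of the genome
derived from pool B) is estimated by maximising the binomial genotype
likelihood

    L(q) = prod_l Binomial(g_l; 2, q f_Bl + (1 - q) f_Al)

over q in [0, 1], skipping missing genotypes.  This is a deterministic
supervised analogue of an admixture-model clustering run at K = 2 with the
parental allele frequencies held fixed; allele copies within an individual
are treated as independent draws from the mixed frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ParameterError
from .genio import MISSING, GenotypeMatrix

#: reference frequencies are clamped to [FREQ_EPS, 1 - FREQ_EPS]
FREQ_EPS = 1e-6
#: grid used to detect flat likelihoods and to bracket the optimum
_GRID = np.linspace(0.0, 1.0, 101)
FLAT_TOL = 1e-9


@dataclass
class AncestryResult:
    """Per-sample q estimates.

    ``q`` is NaN and ``flat`` True where the likelihood carries no
    information (no usable loci, or identical pool frequencies)."""

    samples: list[str]
    q: np.ndarray
    loglik: np.ndarray
    n_loci_used: np.ndarray
    flat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.samples, "q": self.q, "loglik": self.loglik,
            "n_loci": self.n_loci_used, "flat_likelihood": self.flat,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def q_series(self) -> pd.Series:
        return pd.Series(self.q, index=self.samples, name="q")


def _individual_loglik(g: np.ndarray, fa: np.ndarray, fb: np.ndarray, q: float) -> float:
    f = q * fb + (1.0 - q) * fa
    # log Binomial(g; 2, f) = log C(2, g) + g log f + (2 - g) log(1 - f)
    const = math.log(2.0) * int(np.sum(g == 1))
    return const + float(np.sum(g * np.log(f) + (2 - g) * np.log1p(-f)))


def estimate_q(gm: GenotypeMatrix, freqs_a: np.ndarray, freqs_b: np.ndarray) -> AncestryResult:
    """Maximum-likelihood q per individual, by bounded 1D search (|dq| < 1e-6).

    ``freqs_a``/``freqs_b`` are per-locus alternate-allele frequencies over
    ``gm.loci`` (NaN entries are dropped per individual along with missing
    genotypes).  The flat-likelihood flag is set when the log-likelihood
    varies by less than 1e-9 over a grid on [0, 1].
    """
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    if freqs_a.shape != (gm.n_loci,) or freqs_b.shape != (gm.n_loci,):
        raise ParameterError("frequency vectors must match the locus set")
    if gm.n_loci < 1:
        raise ParameterError("need at least one locus")
    fa_all = np.clip(freqs_a, FREQ_EPS, 1.0 - FREQ_EPS)
    fb_all = np.clip(freqs_b, FREQ_EPS, 1.0 - FREQ_EPS)
    defined = ~(np.isnan(freqs_a) | np.isnan(freqs_b))

    n = gm.n_samples
    q_hat = np.full(n, np.nan)
    ll_hat = np.full(n, np.nan)
    n_used = np.zeros(n, dtype=int)
    flat = np.zeros(n, dtype=bool)

    for i in range(n):
        usable = defined & (gm.calls[i] != MISSING)
        n_used[i] = int(usable.sum())
        if n_used[i] == 0:
            flat[i] = True
            continue
        g = gm.calls[i, usable].astype(float)
        fa = fa_all[usable]
        fb = fb_all[usable]
        grid_ll = np.array([_individual_loglik(g, fa, fb, q) for q in _GRID])
        if grid_ll.max() - grid_ll.min() < FLAT_TOL:
            flat[i] = True
        res = minimize_scalar(lambda q: -_individual_loglik(g, fa, fb, q),
                              bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        # the bounded search can stall off a boundary optimum; keep the better
        # of the search result and the best grid point
        j = int(np.argmax(grid_ll))
        if grid_ll[j] > -res.fun:
            q_hat[i], ll_hat[i] = float(_GRID[j]), float(grid_ll[j])
        else:
            q_hat[i], ll_hat[i] = float(res.x), float(-res.fun)
    return AncestryResult(list(gm.samples), q_hat, ll_hat, n_used, flat)


def parental_allele_freqs(gm: GenotypeMatrix, samples, pseudocount: float = 0.5) -> np.ndarray:
    """Reference pool frequencies from designated parental individuals.

    A pseudo-count (default 0.5 per allele class) keeps non-diagnostic loci
    away from exact 0/1; loci with no genotyped parental sample are NaN.
    """
    sub = gm.calls[gm.sample_index(list(samples))]
    genotyped = sub != MISSING
    n = genotyped.sum(axis=0)
    alt = np.where(genotyped, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (alt + pseudocount) / (2.0 * n + 2.0 * pseudocount)
    return np.where(n > 0, freq, np.nan)


def designate_parentals(q: pd.Series, threshold: float = 0.98):
    """Split samples into (parental A, parental B, admixed) by q thresholds.

    Strict inequalities, as in "q-values > 0.98": q < 1 - threshold is
    parental A, q > threshold parental B, anything else (including exactly
    the threshold, or NaN) admixed.
    """
    if not (0.5 < threshold < 1.0):
        raise ParameterError("threshold must be in (0.5, 1)")
    q = pd.Series(q)
    a = q.index[q < 1.0 - threshold].tolist()
    b = q.index[q > threshold].tolist()
    admixed = [s for s in q.index if s not in set(a) and s not in set(b)]
    return a, b, admixed
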