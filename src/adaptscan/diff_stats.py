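"""Weir-Cockerham F_ST: per-site variance components, genome-wide
ratio-of-averages estimate, and the top-decile threshold used to curate
outlier SNPs.

The estimator decomposes allelic variance at each bi-allelic site into
three components: ``a`` (among populations), ``b`` (among individuals
within populations) and ``c`` (within individuals), computed from the
per-population sample sizes n_i, alt-allele frequencies p_i and observed
heterozygote frequencies h_i:

    n_bar = mean(n_i)
    n_c   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
    p_bar = sum(n_i p_i) / (r n_bar)
    s2    = sum(n_i (p_i - p_bar)^2) / ((r-1) n_bar)
    h_bar = sum(n_i h_i) / (r n_bar)

    a = (n_bar/n_c) * (s2 - (p_bar q_bar - s2 (r-1)/r - h_bar/4)/(n_bar-1))
    b = (n_bar/(n_bar-1)) * (p_bar q_bar - s2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar))
    c = h_bar / 2

with q_bar = 1 - p_bar and r the number of populations (2 in this
pipeline's scan path; the component math supports r >= 2). Per-site
theta = a/(a+b+c) may be negative and is retained as computed; the
genome-wide value is the ratio of averages sum(a)/sum(a+b+c), which is
far less biased at low-information sites than averaging per-site ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("adaptscan")

#: Quantile interpolation rule for the outlier threshold (numpy's
#: "linear": threshold = x[k] + (h-k)*(x[k+1]-x[k]) with h=(n-1)q).
QUANTILE_METHOD = "linear"


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham variance components.

    ``theta`` is NaN where a site is undefined (a population entirely
    missing) or the total component a+b+c <= 0.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.a + self.b + self.c

    @property
    def theta(self) -> np.ndarray:
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            th = self.a / tot
        return np.where(np.isfinite(tot) & (tot > 0), th, np.nan)


@dataclass
class FstResult:
    """Per-SNP theta plus the genome-wide ratio-of-averages estimate."""

    components: FstComponents
    genomewide: float

    @property
    def per_snp(self) -> np.ndarray:
        return self.components.theta


def _pop_summaries(gm: GenotypeMatrix):
    """Per-population (n_i, p_i, h_i) arrays of shape (r, n_sites)."""
    levels = gm.samples.levels
    ns, ps, hs = [], [], []
    for level in levels:
        idx = gm.samples.group_indices(level)
        d = gm.dosage[idx, :]
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
            h = (d == 1).sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns), np.array(ps), np.array(hs)


def wc_components_from_counts(n, p, h) -> FstComponents:
    """Vectorised Weir-Cockerham components from per-population summaries.

    Parameters are (r, n_sites) arrays of sample sizes, alt-allele
    frequencies and observed heterozygote frequencies. Sites where any
    population has no data, or where n_bar <= 1, come out NaN.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    r = n.shape[0]
    if r < 2:
        raise ValueError("need >= 2 populations")

    valid = (n > 0).all(axis=0)
    nbar = n.mean(axis=0)
    valid &= nbar > 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        pq = pbar * (1.0 - pbar)

        a = (nbar / nc) * (
            s2 - (pq - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - s2 * (r - 1) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return FstComponents(a, b, c)


def wc_components(gm: GenotypeMatrix) -> FstComponents:
    """Per-site Weir-Cockerham components for all sites of a genotype
    matrix, grouping samples by their population labels."""
    levels = gm.samples.levels
    if len(levels) < 2:
        raise ValueError("need >= 2 population labels for F_ST")
    n, p, h = _pop_summaries(gm)
    return wc_components_from_counts(n, p, h)


def fst_genomewide(components: FstComponents) -> float:
    """Genome-wide F_ST as the ratio of summed components over sites where
    the components are defined (NOT the mean of per-site ratios)."""
    ok = np.isfinite(components.a)
    if not ok.any():
        raise ValueError("no sites with defined variance components")
    denom = components.total[ok].sum()
    if denom == 0:
        raise ValueError("total variance component sums to zero")
    return float(components.a[ok].sum() / denom)


def fst(gm: GenotypeMatrix) -> FstResult:
    comp = wc_components(gm)
    return FstResult(comp, fst_genomewide(comp))


def fst_quantile_threshold(per_snp_theta, q: float = 0.90):
    """Empirical q-quantile of the defined per-site theta values (negative
    values included) and the strict above-threshold mask.

    Returns ``(threshold, mask)`` where ``mask[j]`` is True iff
    ``theta[j] > threshold`` (strict; undefined theta is never above).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    theta = np.asarray(per_snp_theta, dtype=float)
    defined = np.isfinite(theta)
    if defined.sum() < 10:
        raise ValueError("need >= 10 sites with defined theta")
    threshold = float(
        np.quantile(theta[defined], q, method=QUANTILE_METHOD)
    )
    mask = np.zeros_like(theta, dtype=bool)
    mask[defined] = theta[defined] > threshold
    return threshold, mask


def fst_table(gm: GenotypeMatrix, result: FstResult, q: float = 0.90,
              ) -> pd.DataFrame:
    """Per-SNP TSV layout: coordinates, components, theta, top-decile flag."""
    thr, mask = fst_quantile_threshold(result.per_snp, q)
    df = gm.variant_frame()[["scaffold", "pos"]].copy()
    df["a"] = result.components.a
    df["b"] = result.components.b
    df["c"] = result.components.c
    df["theta"] = result.per_snp
    df[f"above_q{int(round(q*100))}"] = mask
    df.attrs["threshold"] = thr
    df.attrs["quantile_method"] = QUANTILE_METHOD
    return df
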