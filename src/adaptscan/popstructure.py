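"""Population structure: allele frequencies, genotype PCA, within-group
projection distances, and KING-robust kinship.

The PCA here is the source of the PC1 covariate used by the
local-adaptation scan: it summarises genome-wide structure so the
per-SNP association model can condition on it. Two scalings are offered:
``patterson`` (centre each site by twice its allele frequency and divide
by the binomial standard deviation sqrt(p(1-p)), the population-genetics
standard) and ``center_only``. Missing dosages are mean-imputed per site
before the decomposition, so imputed cells contribute nothing to
between-sample differences.

KING-robust estimates pairwise kinship from shared-heterozygote and
opposite-homozygote counts; it is robust to allele-frequency
misspecification under population structure. Duplicate samples score
exactly 0.5, parent-offspring pairs about 0.25, and cross-population
pairs go negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("adaptscan")


@dataclass
class PcaResult:
    """Sample projections and per-axis variance explained (percent).

    Axes are ordered by decreasing variance explained; the only
    indeterminacy is a per-axis sign flip.
    """

    projections: np.ndarray  # samples x axes
    variance_explained: np.ndarray  # percent per axis
    scaling_mode: str
    sample_id: list

    @property
    def n_axes(self) -> int:
        return self.projections.shape[1]

    @property
    def pc1(self) -> np.ndarray:
        return self.projections[:, 0]

    def to_frame(self, populations=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.projections,
            columns=[f"PC{i+1}" for i in range(self.n_axes)],
        )
        df.insert(0, "sample_id", self.sample_id)
        if populations is not None:
            df.insert(1, "population", list(populations))
        return df


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients; diagonal fixed at 0.5 by
    convention (self-kinship is not estimated from data)."""

    values: np.ndarray
    sample_id: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_id, columns=self.sample_id
        )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix, by: bool | None = None):
    """Per-site alt-allele frequency, overall or per population group.

    freq = (sum of dosages) / (2 x non-missing count); a group with zero
    non-missing genotypes at a site yields NaN there.

    Parameters
    ----------
    by : None or True
        ``None`` -> overall frequencies (1-D array). ``True`` -> dict of
        population level -> frequency array.
    """
    if by:
        out = {}
        for level in gm.samples.levels:
            idx = gm.samples.group_indices(level)
            out[level] = _freq(gm.dosage[idx, :])
        return out
    return _freq(gm.dosage)


def _freq(dosage: np.ndarray) -> np.ndarray:
    obs = dosage != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, dosage, 0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, p, np.nan)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, scaling_mode: str = "patterson") -> PcaResult:
    """Genotype PCA via SVD of the (imputed, scaled) dosage matrix.

    Sites that are entirely missing raise (run the filters first); in
    ``patterson`` mode monomorphic sites carry no information and are
    silently dropped before scaling.
    """
    if gm.n_samples < 2 or gm.n_variants < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 sites")
    if scaling_mode not in ("patterson", "center_only"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")

    d = gm.dosage.astype(float)
    obs = d != MISSING
    if not obs.any(axis=0).all():
        raise ValueError(
            "some sites are entirely missing; apply_filters first"
        )
    n_obs = obs.sum(axis=0)
    p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_obs)

    if scaling_mode == "patterson":
        poly = (p > 0.0) & (p < 1.0)
        d, obs, p = d[:, poly], obs[:, poly], p[poly]
        if d.shape[1] < 2:
            raise ValueError("fewer than 2 polymorphic sites for PCA")

    x = np.where(obs, d, 2.0 * p) - 2.0 * p  # mean-impute then centre
    if scaling_mode == "patterson":
        x /= np.sqrt(p * (1.0 - p))

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    # fix signs deterministically: largest-|loading| entry of each axis > 0
    for k in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
    eig = s**2
    keep = eig > max(eig[0], 1.0) * 1e-12 if eig.size else slice(0)
    proj = u[:, keep] * s[keep]
    ve = 100.0 * eig[keep] / eig.sum()
    return PcaResult(proj, ve, scaling_mode, list(gm.samples.sample_id))


def projection_distances(pca_result: PcaResult, labels) -> pd.DataFrame:
    """Per-group mean and s.d. of pairwise Euclidean distances among the
    group's sample projections, over all retained axes.

    Singleton groups are reported as NaN with a warning.
    """
    labels = np.asarray(list(labels), dtype=object)
    rows = []
    seen = {}
    for lv in labels:
        seen.setdefault(lv, None)
    for level in seen:
        idx = np.flatnonzero(labels == level)
        if idx.size < 2:
            warnings.warn(
                f"group {level!r} has a single sample; distance undefined",
                stacklevel=2,
            )
            rows.append((level, np.nan, np.nan, 0))
            continue
        pts = pca_result.projections[idx]
        dists = [
            float(np.linalg.norm(pts[i] - pts[j]))
            for i, j in combinations(range(len(idx)), 2)
        ]
        rows.append((level, float(np.mean(dists)), float(np.std(dists)),
                     len(dists)))
    return pd.DataFrame(
        rows, columns=["population", "mean_distance", "sd_distance",
                       "n_pairs"]
    )


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

def kinship_king(gm: GenotypeMatrix) -> KinshipMatrix:
    """Pairwise KING-robust kinship over jointly non-missing sites.

    For a pair (i, j):

        phi = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))

    where all counts are restricted to sites called in both samples. A
    pair with zero heterozygous sites in both samples gets NaN with a
    warning. The estimate is invariant to ref/alt relabelling at any site.
    """
    d = gm.dosage
    n = gm.n_samples
    obs = d != MISSING
    het = d == 1
    hom0 = d == 0
    hom2 = d == 2

    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 0.5)
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            n_hethet = int((het[i] & het[j] & both).sum())
            n_opp = int(
                ((hom0[i] & hom2[j]) | (hom2[i] & hom0[j]))[both].sum()
            )
            denom = int((het[i] & both).sum()) + int((het[j] & both).sum())
            if denom == 0:
                undefined.append((gm.samples.sample_id[i],
                                  gm.samples.sample_id[j]))
                continue
            phi = (n_hethet - 2.0 * n_opp) / denom
            vals[i, j] = vals[j, i] = float(np.clip(phi, -1.0, 0.5))
    if undefined:
        warnings.warn(
            f"{len(undefined)} pair(s) with no heterozygous sites; "
            "kinship undefined (NaN)",
            stacklevel=2,
        )
    return KinshipMatrix(vals, list(gm.samples.sample_id))
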