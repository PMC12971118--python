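"""Local-adaptation outlier scan.

At each SNP the alternate-allele count of a diploid individual (0, 1 or 2
out of 2 allele trials) is modelled as a binomial logistic regression on
two covariates: the individual's PC1 projection, which conditions the
test on genome-wide population structure, and the habitat/population
label. Two nested models are fitted per SNP,

    null:  logit(AF) = mu + b1 * PC1
    full:  logit(AF) = mu + b1 * PC1 + b2 * Site

and compared with a likelihood-ratio test (chi-square, 1 df). Because the
chi-square reference is unreliable at these sample sizes, significance is
assessed against a permutation null: the habitat labels are shuffled
across individuals (group sizes preserved, PC1 staying attached to its
individual, the same shuffle applied to every SNP within a replicate) and
the scan re-run; a SNP is significant when its real p-value strictly
beats at least 95% of its own permuted p-values. Candidates are the
significant SNPs that also sit above the F_ST top-decile threshold.

PC1 is computed once from the real data and is NOT recomputed inside
permutations — only the label covariate is exchanged under the null.

Fitting is a batched iteratively-reweighted-least-squares (IRLS) Newton
scheme over all SNPs simultaneously (missing genotypes enter with zero
weight), which is what makes L x (n_perm + 1) model fits tractable.
Complete separation at strongly differentiated sites is handled by
clipping the linear predictor; such fits are flagged and their p-values
used as computed at the last iterate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import chi2

from .diff_stats import FstResult, fst_quantile_threshold
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("adaptscan")

_TRIALS = 2.0  # diploid: two allele draws per individual per SNP
_ETA_CLIP = 30.0
_ETA_BOUND = 15.0  # |linear predictor| beyond this = boundary/separated fit
_MAX_ITER = 50
_TOL = 1e-8


# ---------------------------------------------------------------------------
# Batched binomial IRLS
# ---------------------------------------------------------------------------

def _batch_irls(X: np.ndarray, Y: np.ndarray, obs: np.ndarray,
                max_iter: int = _MAX_ITER, tol: float = _TOL):
    """Fit ``L`` independent binomial logistic models sharing design ``X``.

    Parameters
    ----------
    X : (n, p) design matrix (common to all SNPs).
    Y : (L, n) alt-allele counts; entries at unobserved cells are ignored.
    obs : (L, n) boolean, True where the genotype is non-missing.

    Returns
    -------
    beta : (L, p), deviance : (L,), loglik : (L,), converged : (L,) bool,
    n_iter : (L,) int, boundary : (L,) bool
    """
    Y = np.asarray(Y, dtype=float)
    obs = np.asarray(obs, dtype=bool)
    L, n = Y.shape
    p = X.shape[1]
    yobs = np.where(obs, Y, 0.0)

    # saturated log-likelihood (for deviance); y log(y/m) terms via xlogy
    ll_sat = (
        xlogy(yobs, yobs / _TRIALS) + xlogy(_TRIALS - yobs,
                                            1.0 - yobs / _TRIALS)
    )
    ll_sat = np.where(obs, ll_sat, 0.0).sum(axis=1)
    log_choose = np.where(obs & (yobs == 1.0), math.log(2.0), 0.0).sum(axis=1)

    beta = np.zeros((L, p))
    n2 = _TRIALS * obs.sum(axis=1)
    p0 = (yobs.sum(axis=1) + 0.5) / (n2 + 1.0)
    beta[:, 0] = np.log(p0 / (1.0 - p0))

    dev = np.full(L, np.inf)
    conv = np.zeros(L, dtype=bool)
    iters = np.zeros(L, dtype=int)
    ridge = 1e-10 * np.eye(p)

    active = np.ones(L, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = np.clip(beta[idx] @ X.T, -_ETA_CLIP, _ETA_CLIP)
        pi = expit(eta)
        mu = _TRIALS * pi
        w = _TRIALS * pi * (1.0 - pi) * obs[idx]
        resid = (yobs[idx] - mu) * obs[idx]

        xtwx = np.einsum("kn,np,nq->kpq", w, X, X) + ridge
        xtwz = np.einsum("kn,np->kp", w * eta + resid, X)
        beta[idx] = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]

        eta_new = np.clip(beta[idx] @ X.T, -_ETA_CLIP, _ETA_CLIP)
        pi_new = expit(eta_new)
        ll = (
            xlogy(yobs[idx], pi_new)
            + xlogy(_TRIALS - yobs[idx], 1.0 - pi_new)
        )
        ll = np.where(obs[idx], ll, 0.0).sum(axis=1)
        dev_new = 2.0 * (ll_sat[idx] - ll)
        done = np.abs(dev_new - dev[idx]) < tol
        dev[idx] = dev_new
        iters[idx] += 1
        conv[idx] = done
        active[idx[done]] = False

    # final log-likelihood incl. binomial coefficient, and boundary flag
    eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    pi = expit(eta)
    ll = xlogy(yobs, pi) + xlogy(_TRIALS - yobs, 1.0 - pi)
    loglik = np.where(obs, ll, 0.0).sum(axis=1) + log_choose
    boundary = ((np.abs(eta) >= _ETA_BOUND) & obs).any(axis=1)
    dev = np.maximum(dev, 0.0)
    return beta, dev, loglik, conv, iters, boundary


# ---------------------------------------------------------------------------
# Single-site API
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """One fitted binomial logistic model at one SNP."""

    coefficients: dict
    deviance: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool
    obs_index: tuple  # indices of individuals used in the fit
    dropped_site_term: bool = False


def fit_site_glm(alt_counts, pc1, site_label=None,
                 max_iter: int = _MAX_ITER, tol: float = _TOL) -> GlmFit:
    """Fit one SNP's binomial logistic model.

    Individuals with a missing genotype (negative or NaN ``alt_counts``)
    are dropped from the fit together with their covariates. With
    ``site_label=None`` the null model (intercept + PC1) is fitted;
    otherwise the full model adds the binary site term. A site term that
    is constant among the fitted individuals is rank-deficient; the
    redundant column is dropped and the fit flagged.
    """
    y = np.asarray(alt_counts, dtype=float)
    pc1 = np.asarray(pc1, dtype=float)
    keep = np.isfinite(y) & (y >= 0)
    if keep.sum() < 3:
        raise ValueError("need >= 3 individuals with non-missing genotype")
    y = y[keep]
    x1 = pc1[keep]

    cols = [np.ones(y.size), x1]
    names = ["intercept", "pc1"]
    dropped = False
    if site_label is not None:
        lab = np.asarray(list(site_label), dtype=object)[keep]
        levels = pd.unique(lab)
        if len(levels) < 2:
            dropped = True
        else:
            if len(levels) > 2:
                raise ValueError("site_label must be binary")
            cols.append((lab == levels[1]).astype(float))
            names.append("site")
    X = np.column_stack(cols)

    beta, dev, ll, conv, iters, bound = _batch_irls(
        X, y[None, :], np.ones((1, y.size), dtype=bool),
        max_iter=max_iter, tol=tol,
    )
    return GlmFit(
        coefficients=dict(zip(names, beta[0])),
        deviance=float(dev[0]),
        loglik=float(ll[0]),
        converged=bool(conv[0]),
        n_iter=int(iters[0]),
        boundary=bool(bound[0]),
        obs_index=tuple(np.flatnonzero(keep)),
        dropped_site_term=dropped,
    )


def lrt(null_fit: GlmFit, full_fit: GlmFit):
    """Likelihood-ratio test of the nested pair.

    Returns ``(stat, p)`` with stat = deviance(null) - deviance(full)
    floored at zero and p the upper chi-square(1) tail probability. The
    fits must be on identical individual subsets.
    """
    if null_fit.obs_index != full_fit.obs_index:
        raise ValueError(
            "fits use different individual subsets: "
            f"{null_fit.obs_index} vs {full_fit.obs_index}"
        )
    stat = max(null_fit.deviance - full_fit.deviance, 0.0)
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Permutation scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP scan outcome across the real fit and all permutations."""

    variants: list  # (scaffold, pos) keys, scan order
    lrt_stat: np.ndarray
    p_real: np.ndarray
    p_perm: np.ndarray  # (n_snps, n_perm)
    n_perm_beaten: np.ndarray
    significant: np.ndarray
    converged_real: np.ndarray
    n_perm_nonconverged: np.ndarray
    n_perm: int
    seed: int
    null_mode: str = "per_snp"

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [v[0] for v in self.variants],
                "pos": [v[1] for v in self.variants],
                "lrt_stat": self.lrt_stat,
                "p_real": self.p_real,
                "n_perm_beaten": self.n_perm_beaten,
                "significant": self.significant,
                "converged_real": self.converged_real,
                "n_perm_nonconverged": self.n_perm_nonconverged,
            }
        )


def _scan_fits(dosage, obs, X_null, X_full):
    """Fit null and full batches; return per-SNP (stat, p, converged)."""
    _, dev_n, _, conv_n, _, _ = _batch_irls(X_null, dosage, obs)
    _, dev_f, _, conv_f, _, _ = _batch_irls(X_full, dosage, obs)
    stat = np.maximum(dev_n - dev_f, 0.0)
    return stat, chi2.sf(stat, df=1), conv_n & conv_f


def permutation_scan(gm: GenotypeMatrix, pc1, labels=None,
                     n_perm: int = 100, seed: int = 0,
                     null_mode: str = "per_snp") -> ScanResult:
    """Run the full permutation scan over every SNP of ``gm``.

    ``labels`` defaults to the matrix's own sample populations and must
    have exactly two levels. Each of the ``n_perm`` replicates draws one
    uniform permutation of the label vector over individuals (group sizes
    preserved; a draw identical to the real labelling is retained) and
    applies it to every SNP. Per SNP, ``n_perm_beaten`` counts the
    permuted p-values that the real p-value strictly beats; significance
    requires beating at least ceil(0.95 * n_perm) of them. In
    ``null_mode="pooled"`` the real p-value is instead compared against
    the pooled permuted p-values of all SNPs. The RNG is fully determined
    by ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null_mode not in ("per_snp", "pooled"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    if labels is None:
        labels = gm.samples.population
    labels = np.asarray(list(labels), dtype=object)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 label levels, got {len(levels)}")

    pc1 = np.asarray(pc1, dtype=float)
    n = gm.n_samples
    if pc1.shape != (n,) or labels.shape != (n,):
        raise ValueError("pc1/labels must match the sample count")

    dosage = gm.dosage.T.astype(float)  # (L, n)
    obs = gm.dosage.T != MISSING
    lab01 = (labels == levels[1]).astype(float)

    X_null = np.column_stack([np.ones(n), pc1])
    X_full = np.column_stack([np.ones(n), pc1, lab01])

    stat, p_real, conv_real = _scan_fits(dosage, obs, X_null, X_full)

    rng = np.random.default_rng(seed)
    L = dosage.shape[0]
    p_perm = np.empty((L, n_perm))
    nonconv = np.zeros(L, dtype=int)
    for k in range(n_perm):
        perm_lab = lab01[rng.permutation(n)]
        Xk = np.column_stack([np.ones(n), pc1, perm_lab])
        _, pk, convk = _scan_fits(dosage, obs, X_null, Xk)
        p_perm[:, k] = pk
        nonconv += ~convk

    beaten = (p_real[:, None] < p_perm).sum(axis=1)
    if null_mode == "per_snp":
        significant = beaten >= math.ceil(0.95 * n_perm)
    else:
        pooled = np.sort(p_perm.reshape(-1))
        pooled_beaten = pooled.size - np.searchsorted(
            pooled, p_real, side="right"
        )
        significant = pooled_beaten >= math.ceil(0.95 * pooled.size)

    keys = [(v.scaffold, v.position) for v in gm.variants]
    logger.info(
        "scan: %d SNPs, %d permutations, %d significant (%s null)",
        L, n_perm, int(significant.sum()), null_mode,
    )
    return ScanResult(
        variants=keys, lrt_stat=stat, p_real=p_real, p_perm=p_perm,
        n_perm_beaten=beaten, significant=significant,
        converged_real=conv_real, n_perm_nonconverged=nonconv,
        n_perm=n_perm, seed=seed, null_mode=null_mode,
    )


# ---------------------------------------------------------------------------
# Candidate curation
# ---------------------------------------------------------------------------

def candidate_outliers(scan: ScanResult, fst: FstResult,
                       variants=None, q: float = 0.90) -> pd.DataFrame:
    """Intersect the permutation-significant set with the F_ST top decile.

    ``fst`` must cover the same SNPs in the same order as the scan; pass
    ``variants`` (the (scaffold, pos) keys of the F_ST table) to have the
    correspondence checked explicitly.

    Returns a DataFrame of candidate SNPs with their theta and real
    p-value carried along; by construction the set is a subset of both
    the significant set and the top-decile set.
    """
    theta = fst.per_snp
    if len(theta) != scan.n_snps:
        raise ValueError(
            f"scan covers {scan.n_snps} SNPs but F_ST covers {len(theta)}"
        )
    if variants is not None:
        for i, (a, b) in enumerate(zip(scan.variants, variants)):
            if tuple(a) != tuple(b):
                raise ValueError(
                    f"SNP lists disagree first at index {i}: "
                    f"scan {tuple(a)} vs fst {tuple(b)}"
                )
    threshold, top_mask = fst_quantile_threshold(theta, q)
    keep = scan.significant & top_mask
    df = pd.DataFrame(
        {
            "scaffold": [v[0] for v in scan.variants],
            "pos": [v[1] for v in scan.variants],
            "theta": theta,
            "p_real": scan.p_real,
            "lrt_stat": scan.lrt_stat,
        }
    )[keep]
    df.attrs["fst_threshold"] = threshold
    df.attrs["quantile"] = q
    return df.reset_index(drop=True)
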