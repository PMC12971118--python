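"""Genotype input/output and site filtering.

Reads multi-sample VCFs into an in-memory genotype matrix (samples x
variants, alt-allele dosages 0/1/2 with a missing sentinel, per-genotype
depth) and applies the hard site filters used ahead of the population
structure and local-adaptation analyses: per-genotype depth masking,
bi-allelic restriction, per-site missing-rate cap, and a folded
minor-allele-frequency floor.

Coordinates follow the VCF convention (1-based, inclusive). Multi-allelic
records are read as-is (alt-allele dosage sums every non-reference allele)
and flagged; the bi-allelic filter drops them rather than decomposing them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("adaptscan")

#: Sentinel for a missing dosage or depth in the integer matrices.
MISSING = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A single variant record.

    Attributes
    ----------
    scaffold : str
        Contig/scaffold identifier.
    position : int
        1-based coordinate. Must be >= 1.
    ref : str
        Reference allele (non-empty).
    alt : tuple of str
        Alternate alleles (at least one, each non-empty).
    id : str or None
        Optional record identifier.
    """

    scaffold: str
    position: int
    ref: str
    alt: tuple
    id: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if len(self.alt) < 1 or any(not a for a in self.alt):
            raise ValueError("need >= 1 non-empty alt allele")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1


@dataclass
class SampleTable:
    """Sample metadata: unique sample IDs and their population labels."""

    sample_id: list
    population: list

    def __post_init__(self):
        if len(self.sample_id) != len(self.population):
            raise ValueError("sample_id and population length mismatch")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("sample_ids must be unique")

    def __len__(self):
        return len(self.sample_id)

    @property
    def levels(self) -> list:
        """Population levels in first-appearance order."""
        seen = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def group_indices(self, level) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.population, dtype=object) == level)
        if idx.size == 0:
            raise KeyError(f"population level {level!r} not in sample table")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "population": self.population}
        )

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "population"} <= set(df.columns):
            # headerless 2-column form
            df = pd.read_csv(
                path, sep="\t", dtype=str, header=None,
                names=["sample_id", "population"],
            )
        return cls(list(df["sample_id"]), list(df["population"]))


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with per-genotype depth.

    ``dosage[i, j]`` is the number of alternate alleles carried by sample
    ``i`` at variant ``j`` (0, 1 or 2), or :data:`MISSING`. ``depth`` is the
    per-genotype read depth, :data:`MISSING` where unavailable.
    """

    samples: SampleTable
    variants: list
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        n, m = len(self.samples), len(self.variants)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.dosage.shape != (n, m) or self.depth.shape != (n, m):
            raise ValueError(
                f"dosage/depth must be {n} samples x {m} variants, got "
                f"{self.dosage.shape} / {self.depth.shape}"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing genotypes."""
        return (self.dosage == MISSING).mean(axis=0)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples,
            variants=[self.variants[j] for j in index],
            dosage=self.dosage[:, index],
            depth=self.depth[:, index],
        )

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [v.scaffold for v in self.variants],
                "pos": [v.position for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [",".join(v.alt) for v in self.variants],
            }
        )


@dataclass(frozen=True)
class FilterConfig:
    """Hard site-filter thresholds.

    Defaults mirror the analysis defaults: bi-allelic sites only, per-site
    missing rate <= 5% (after depth masking), folded minor-allele frequency
    >= 5% over non-missing genotypes, per-genotype depth >= 4x.
    """

    biallelic_only: bool = True
    max_missing_rate: float = 0.05
    min_global_af: float = 0.05
    min_depth: int = 4

    def __post_init__(self):
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.min_global_af <= 0.5:
            raise ValueError("min_global_af is folded; must be in [0, 0.5]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterReport:
    """Per-rule removal tallies, in application order.

    Invariant: ``n_input == removed_biallelic + removed_missing +
    removed_af + n_retained`` (depth masking removes genotypes, not sites,
    so it reports masked genotype cells instead).
    """

    n_input: int
    genotypes_depth_masked: int
    removed_biallelic: int
    removed_missing: int
    removed_af: int
    n_retained: int

    def __post_init__(self):
        total = (
            self.removed_biallelic + self.removed_missing
            + self.removed_af + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"report counts not conserved: {total} != {self.n_input}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input_sites", "depth_masked_genotypes",
                    "removed_not_biallelic", "removed_missing_rate",
                    "removed_low_maf", "retained_sites",
                ],
                "count": [
                    self.n_input, self.genotypes_depth_masked,
                    self.removed_biallelic, self.removed_missing,
                    self.removed_af, self.n_retained,
                ],
            }
        )


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset=None, populations=None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles in the GT field; any GT
    containing a missing allele ('.') becomes the missing sentinel. Depth
    comes from the per-genotype DP format field where present, otherwise
    missing. Variant order is preserved; multi-allelic records are kept
    as-is (the bi-allelic filter handles them later).

    Parameters
    ----------
    path : str
        VCF path, plain text or bgzipped.
    sample_subset : list of str, optional
        Restrict to these samples (order as given). A name absent from the
        header raises ``KeyError`` naming the sample.
    populations : dict, optional
        sample_id -> population label. Samples without an entry get "NA".
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad paths
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    header_samples = list(vcf.samples)
    if sample_subset is not None:
        for s in sample_subset:
            if s not in header_samples:
                raise KeyError(
                    f"requested sample {s!r} absent from VCF header"
                )
        vcf.close()
        vcf = VCF(str(path), samples=list(sample_subset))
        samples = list(vcf.samples)
    else:
        samples = header_samples

    variants = []
    dos_cols = []
    dep_cols = []
    for rec in vcf:
        variants.append(
            Variant(
                scaffold=rec.CHROM,
                position=rec.POS,
                ref=rec.REF,
                alt=tuple(rec.ALT) if rec.ALT else ("<NON_REF>",),
                id=rec.ID,
            )
        )
        # gt_types collapses multi-allelic hets; count alt alleles directly
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col = phase
        alleles = gts[:, :-1]
        miss = (alleles < 0).any(axis=1)
        dos = (alleles > 0).sum(axis=1).astype(np.int16)
        dos[miss] = MISSING
        dos_cols.append(dos)
        try:
            dp = rec.format("DP")
        except Exception:
            dp = None
        if dp is None:
            dep_cols.append(np.full(len(samples), MISSING, dtype=np.int32))
        else:
            dp = dp.reshape(-1).astype(np.int64)
            dp = np.where(dp < 0, MISSING, dp)  # cyvcf2 encodes '.' as <0
            dep_cols.append(dp.astype(np.int32))
    vcf.close()

    n, m = len(samples), len(variants)
    dosage = (
        np.stack(dos_cols, axis=1) if m else np.empty((n, 0), dtype=np.int16)
    )
    depth = (
        np.stack(dep_cols, axis=1) if m else np.empty((n, 0), dtype=np.int32)
    )
    pops = [
        (populations or {}).get(s, "NA") for s in samples
    ]
    table = SampleTable(samples, pops)
    return GenotypeMatrix(table, variants, dosage, depth)


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def folded_maf(dosage: np.ndarray) -> np.ndarray:
    """Per-site folded (minor) allele frequency over non-missing genotypes.

    Sites with zero non-missing genotypes get NaN.
    """
    d = np.asarray(dosage, dtype=float)
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_obs)
    p = np.where(n_obs > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()):
    """Apply the site filters in fixed order; return (filtered, report).

    Order: (1) per-genotype depth masking (DP < min_depth -> missing, done
    before the missing-rate test so low-coverage calls count as missing),
    (2) bi-allelic restriction, (3) per-site missing-rate cap, (4) folded
    MAF floor over the remaining non-missing genotypes. Returns an empty
    matrix (with a warning, not an error) if every site is removed.
    """
    if gm.n_samples == 0:
        raise ValueError("genotype matrix has no samples")

    dosage = gm.dosage.copy()
    depth = gm.depth
    n_input = gm.n_variants

    # 1. depth mask: only where depth is known and genotype present
    low = (depth != MISSING) & (depth < cfg.min_depth) & (dosage != MISSING)
    dosage[low] = MISSING
    n_masked = int(low.sum())

    masked = GenotypeMatrix(gm.samples, gm.variants, dosage, depth)

    # 2. bi-allelic
    if cfg.biallelic_only:
        bi = np.array([v.is_biallelic for v in gm.variants], dtype=bool)
    else:
        bi = np.ones(n_input, dtype=bool)
    removed_bi = int(n_input - bi.sum())

    # 3. missing rate (on depth-masked dosages)
    miss_ok = masked.missing_fraction() <= cfg.max_missing_rate
    removed_miss = int((bi & ~miss_ok).sum())

    # 4. folded MAF
    maf = folded_maf(dosage)
    with np.errstate(invalid="ignore"):
        af_ok = maf >= cfg.min_global_af
    af_ok &= ~np.isnan(maf)
    removed_af = int((bi & miss_ok & ~af_ok).sum())

    keep = np.flatnonzero(bi & miss_ok & af_ok)
    out = masked.take_variants(keep)
    report = FilterReport(
        n_input=n_input,
        genotypes_depth_masked=n_masked,
        removed_biallelic=removed_bi,
        removed_missing=removed_miss,
        removed_af=removed_af,
        n_retained=len(keep),
    )
    if n_input and not len(keep):
        warnings.warn("all sites removed by filters", stacklevel=2)
    logger.info(
        "filters: %d sites in, %d retained (%d non-biallelic, %d missing-rate,"
        " %d low-MAF; %d genotypes depth-masked)",
        n_input, len(keep), removed_bi, removed_miss, removed_af, n_masked,
    )
    return out, report


# ---------------------------------------------------------------------------
# Matrix/report text output
# ---------------------------------------------------------------------------

def matrix_to_frame(gm: GenotypeMatrix) -> pd.DataFrame:
    """Sites-as-rows TSV layout: scaffold, pos, ref, alt, then one dosage
    column per sample ('NA' for missing on disk)."""
    df = gm.variant_frame()
    for i, s in enumerate(gm.samples.sample_id):
        col = gm.dosage[i, :].astype(object)
        col[gm.dosage[i, :] == MISSING] = pd.NA
        df[s] = col
    return df


def write_matrix(gm: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as TSV (missing as 'NA')."""
    matrix_to_frame(gm).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path, populations=None) -> GenotypeMatrix:
    """Read a TSV written by :func:`write_matrix` (depth is not stored and
    comes back missing)."""
    df = pd.read_csv(path, sep="\t")
    meta = ["scaffold", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    variants = [
        Variant(str(r.scaffold), int(r.pos), str(r.ref),
                tuple(str(r.alt).split(",")))
        for r in df.itertuples()
    ]
    dos = df[samples].to_numpy(dtype=float).T
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int16)
    depth = np.full_like(dos, MISSING, dtype=np.int32)
    pops = [(populations or {}).get(s, "NA") for s in samples]
    return GenotypeMatrix(SampleTable(samples, pops), variants, dos, depth)


def write_report(report: FilterReport, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
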