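"""Synthetic genotype data with known truth.

Generates two weakly diverged populations under the Balding-Nichols
model: each site draws an ancestral frequency p uniformly on a bounded
interval, then each population's present-day frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), whose dispersion parameter F is the
expected genome-wide F_ST. This directly parameterises the one structure
statistic the scan pipeline estimates, needs no external simulator, and
produces independent sites — matching the per-SNP association model (no
linkage disequilibrium is simulated).

On top of the neutral background the generator plants a small set of
divergent ("locally adapted") loci whose population frequencies are a
symmetric offset of +/- d/2 around the ancestral value, guaranteeing an
allele-frequency gap of exactly ``adaptive_divergence`` while keeping
both populations polymorphic. A minority of individuals are admixed:
each of their alleles is drawn from population 1's frequency with
probability q and population 2's otherwise, producing the continuous
PCA gradient seen in weakly structured, gene-flow-connected samples.
Genotypes are then thinned with uniform missingness.

Defaults emulate the study conditions the pipeline targets: 11 + 7
diploid individuals, F = 0.0084, ~5% missing genotypes, 16 planted
loci, admixed individuals with up to 50% ancestry from the other
population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable, Variant

logger = logging.getLogger("adaptscan")

#: Constant per-genotype depth written by the simulator (clears the 4x
#: depth filter by default).
SIM_DEPTH = 10


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the emulated study conditions."""

    n_pop1: int = 11
    n_pop2: int = 7
    n_sites: int = 5000
    fst_param: float = 0.0084
    n_adaptive: int = 16
    adaptive_divergence: float = 0.6
    admix_fraction: float = 0.2
    admix_q: float = 0.5
    missing_rate: float = 0.05
    ancestral_freq_range: tuple = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        for name in ("admix_fraction", "admix_q", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.fst_param < 1.0:
            raise ValueError("fst_param must be in (0, 1)")
        if self.n_adaptive > self.n_sites:
            raise ValueError("n_adaptive cannot exceed n_sites")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be within (0, 1)")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery and power checks."""

    adaptive_site_indices: np.ndarray
    pop_freqs: np.ndarray  # (2, n_sites) true per-population frequencies
    ancestry_q: np.ndarray  # per-individual proportion of pop-1 ancestry

    def to_frame(self) -> pd.DataFrame:
        n_sites = self.pop_freqs.shape[1]
        adaptive = np.zeros(n_sites, dtype=bool)
        adaptive[self.adaptive_site_indices] = True
        return pd.DataFrame(
            {
                "site_index": np.arange(n_sites),
                "p_pop1": self.pop_freqs[0],
                "p_pop2": self.pop_freqs[1],
                "adaptive": adaptive,
            }
        )


def simulate(params: SimParams = SimParams()):
    """Draw one synthetic dataset; returns (GenotypeMatrix, SimTruth).

    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.n_sites
    F = params.fst_param
    lo, hi = params.ancestral_freq_range

    # neutral sites: BN frequencies around a uniform ancestral draw
    p_anc = rng.uniform(lo, hi, size=L)
    shape = (1.0 - F) / F
    pop_freqs = rng.beta(
        p_anc * shape, (1.0 - p_anc) * shape, size=(2, L)
    )

    # planted sites: exact symmetric offset around the ancestral value,
    # ancestral draw restricted so the offset never needs clipping
    d = params.adaptive_divergence
    adaptive_idx = np.sort(
        rng.choice(L, size=params.n_adaptive, replace=False)
    )
    if params.n_adaptive:
        a_lo, a_hi = max(lo, 0.01 + d / 2.0), min(hi, 0.99 - d / 2.0)
        if a_lo >= a_hi:
            raise ValueError(
                f"adaptive_divergence={d} infeasible within ancestral "
                f"frequency bounds {params.ancestral_freq_range}; widen "
                "the bounds or lower the divergence"
            )
        p_mid = rng.uniform(a_lo, a_hi, size=params.n_adaptive)
        sign = rng.choice([-1.0, 1.0], size=params.n_adaptive)
        pop_freqs[0, adaptive_idx] = p_mid + sign * d / 2.0
        pop_freqs[1, adaptive_idx] = p_mid - sign * d / 2.0

    # individual ancestry: q = share of alleles drawn from population 1
    n1, n2 = params.n_pop1, params.n_pop2
    n = n1 + n2
    q = np.concatenate([np.ones(n1), np.zeros(n2)])
    n_admix = int(round(params.admix_fraction * n))
    if n_admix:
        admixed = rng.choice(n, size=n_admix, replace=False)
        other_share = rng.uniform(0.0, params.admix_q, size=n_admix)
        # pull each admixed individual's ancestry toward the other pop
        q[admixed] = np.where(
            q[admixed] == 1.0, 1.0 - other_share, other_share
        )

    # per-allele ancestry draws, then allele draws from that pop's freq
    from_pop1 = rng.random(size=(n, 2, L)) < q[:, None, None]
    p_allele = np.where(from_pop1, pop_freqs[0], pop_freqs[1])
    alleles = rng.random(size=(n, 2, L)) < p_allele
    dosage = alleles.sum(axis=1).astype(np.int16)

    miss = rng.random(size=(n, L)) < params.missing_rate
    dosage[miss] = MISSING
    depth = np.full((n, L), SIM_DEPTH, dtype=np.int32)
    depth[miss] = MISSING

    samples = SampleTable(
        [f"pop1_{i+1:02d}" for i in range(n1)]
        + [f"pop2_{i+1:02d}" for i in range(n2)],
        ["pop1"] * n1 + ["pop2"] * n2,
    )
    variants = [
        Variant("sim_scaffold_1", j + 1, "A", ("T",)) for j in range(L)
    ]
    gm = GenotypeMatrix(samples, variants, dosage, depth)
    truth = SimTruth(adaptive_idx, pop_freqs, q)
    logger.info(
        "simulated %d+%d samples x %d sites (F=%g, %d planted, seed=%d)",
        n1, n2, L, F, params.n_adaptive, params.seed,
    )
    return gm, truth


def export_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal diploid VCF (GT:DP) for the matrix.

    Missing dosage becomes './.'; missing depth becomes '.'. Round-trips
    exactly through :func:`adaptscan.genotype_io.read_vcf`.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
                 '"Read Depth">\n')
        scaffolds = {v.scaffold: None for v in gm.variants}
        for sc in scaffolds:
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples.sample_id) + "\n"
        )
        for j, v in enumerate(gm.variants):
            cells = []
            for i in range(gm.n_samples):
                dp = gm.depth[i, j]
                dp_s = "." if dp == MISSING else str(int(dp))
                cells.append(f"{gt_map[int(gm.dosage[i, j])]}:{dp_s}")
            fh.write(
                f"{v.scaffold}\t{v.position}\t{v.id or '.'}\t{v.ref}\t"
                f"{','.join(v.alt)}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells) + "\n"
            )


def write_truth(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_sample_table(gm: GenotypeMatrix, path) -> None:
    gm.samples.to_frame().to_csv(path, sep="\t", index=False)
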