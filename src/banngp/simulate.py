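"""Synthetic dairy-cattle-style data: genotypes, gene maps, trait
architectures and de-regressed proofs with heterogeneous reliabilities.

The generator mirrors the modelling assumptions of the annotated network:
SNP effects are drawn from a sparse three-component normal mixture
(large / moderate / small effects), a fraction of SNP-sets carry one
pairwise product interaction between causal SNPs, and pseudo-phenotypes
(DRPs) are the true genetic values plus per-animal noise whose variance
follows the reliability weighting (1 - REL)/REL.

Linkage disequilibrium is produced by a first-order autoregressive
Gaussian copula over haplotype alleles within chromosomes — a controllable
knob, not a coalescent simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GeneAnnotation, GeneRecord, GenotypeMatrix, TraitRecord, VariantRecord
from .snp_sets import SNPSetPartition

# Mean inter-SNP spacing used when no chromosome length is given; gives the
# ~2 SNPs / 100 kb density of a 50k bovine chip.
_DEFAULT_SPACING_BP = 50_000


@dataclass
class SimArchitecture:
    """Genetic architecture of a simulated trait.

    pi_causal
        Proportion of SNPs with a non-zero additive effect.
    mixture_props, mixture_vars
        Weights and variances of the large/moderate/small effect
        components the causal effects are drawn from.
    epistasis_frac
        Fraction of SNP-sets holding >= 2 causal SNPs that receive one
        pairwise product-term interaction.
    n_enriched_sets
        If given, causal SNPs are confined to this many randomly chosen
        SNP-sets (set-level enrichment); otherwise causality is spread
        uniformly across the genome.
    h2_target
        Narrow-plus-epistatic heritability the residual noise is
        calibrated to.
    """

    pi_causal: float = 0.05
    mixture_props: tuple[float, float, float] = (0.1, 0.3, 0.6)
    mixture_vars: tuple[float, float, float] = (0.1, 0.01, 0.001)
    epistasis_frac: float = 0.0
    n_enriched_sets: int | None = None
    h2_target: float = 0.33
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi_causal <= 1.0:
            raise ValueError(f"pi_causal {self.pi_causal} outside [0, 1]")
        if abs(sum(self.mixture_props) - 1.0) > 1e-9:
            raise ValueError("mixture_props must sum to 1")
        if any(v <= 0 for v in self.mixture_vars):
            raise ValueError("mixture variances must be positive")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError(f"h2_target {self.h2_target} outside (0, 1)")


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery checks."""

    beta_true: np.ndarray  # J additive effects on standardized dosages
    interaction_terms: list[tuple[str, int, int, float]]  # (set_id, j, k, effect)
    tbv: np.ndarray  # n total genetic values (additive + interactions)
    realized_h2: float
    causal_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_sets: list[str] = field(default_factory=list)


def simulate_genotypes(
    n: int,
    J: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.0,
    chrom_count: int = 1,
    seed: int = 0,
    chrom_length_bp: int | None = None,
) -> GenotypeMatrix:
    """Draw biallelic dosages as sums of two haplotypes with AR(1) LD.

    Haplotype alleles come from a Gaussian copula: a latent first-order
    autoregressive process with parameter ``ld_rho`` is thresholded at the
    per-SNP allele frequency, so marginal frequencies are exact and
    adjacent SNPs on a chromosome are correlated. Chromosomes are
    independent; positions are uniform on each chromosome.
    """
    if n < 1 or J < 1:
        raise ValueError("n and J must both be >= 1")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(chrom_count, J // chrom_count)
    per_chrom[: J % chrom_count] += 1
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for c, j_c in enumerate(per_chrom, start=1):
        if j_c == 0:
            continue
        length = chrom_length_bp if chrom_length_bp is not None else j_c * _DEFAULT_SPACING_BP
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=j_c, replace=False))
        freqs = rng.uniform(maf_low, maf_high, size=j_c)
        # latent AR(1) per haplotype, thresholded at Phi^-1(freq)
        latent = np.empty((2 * n, j_c))
        latent[:, 0] = rng.standard_normal(2 * n)
        innov_sd = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, j_c):
            latent[:, j] = ld_rho * latent[:, j - 1] + innov_sd * rng.standard_normal(2 * n)
        alleles = (latent < stats.norm.ppf(freqs)[None, :]).astype(np.int8)
        columns.append((alleles[:n] + alleles[n:]).astype(float))
        variants.extend(
            VariantRecord(f"chr{c}_snp{i + 1}", f"{c}", int(p), "A", "B")
            for i, p in enumerate(pos)
        )
    dosages = np.concatenate(columns, axis=1)
    sample_ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, variants)


def simulate_gene_map(
    variants: list[VariantRecord],
    gene_density: float = 10.0,
    gene_len_bp: tuple[int, int] = (20_000, 80_000),
    seed: int = 0,
) -> GeneAnnotation:
    """Place non-overlapping genes along each chromosome.

    ``gene_density`` is in genes per Mb. Each chromosome is cut into
    equal slots, one gene placed uniformly within each slot, which
    guarantees non-overlap; some SNPs will fall between genes so the
    intergenic grouping is exercised downstream.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    lo, hi = gene_len_bp
    if not 1 <= lo <= hi:
        raise ValueError(f"bad gene length range {gene_len_bp}")
    rng = np.random.default_rng(seed)
    span_by_chrom: dict[str, int] = {}
    for v in variants:
        span_by_chrom[v.chrom] = max(span_by_chrom.get(v.chrom, 0), v.pos_bp)
    records: list[GeneRecord] = []
    for chrom in sorted(span_by_chrom):
        span = span_by_chrom[chrom]
        n_genes = int(round(gene_density * span / 1e6))
        if n_genes == 0:
            continue
        slot = span // n_genes
        if slot <= hi:
            raise ValueError(
                f"chromosome {chrom}: density {gene_density}/Mb with genes up to "
                f"{hi} bp cannot be placed without overlap (slot {slot} bp)"
            )
        for i in range(n_genes):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(i * slot + 1, (i + 1) * slot - length + 1))
            records.append(GeneRecord(f"{chrom}G{i + 1:04d}", chrom, start, start + length - 1))
    return GeneAnnotation(records)


def _standardized_dosages(g: GenotypeMatrix) -> np.ndarray:
    X = g.dosages
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def simulate_phenotypes(
    g: GenotypeMatrix,
    partition: SNPSetPartition,
    arch: SimArchitecture,
) -> tuple[np.ndarray, SimTruth]:
    """Draw sparse mixture effects, optional within-set interactions, and a
    phenotype whose noise is calibrated so var(tbv)/var(phenotype) equals
    ``arch.h2_target`` in the realized sample.
    """
    if partition.n_snps != g.n_variants:
        raise ValueError("partition does not match the genotype matrix")
    rng = np.random.default_rng(arch.seed)
    n, J = g.dosages.shape
    X = _standardized_dosages(g)

    n_causal = int(round(arch.pi_causal * J))
    if arch.n_enriched_sets is not None:
        chosen = rng.choice(partition.G, size=min(arch.n_enriched_sets, partition.G),
                            replace=False)
        pool = np.concatenate(
            [np.asarray(partition.sets[s].snp_indices) for s in chosen]
        ) if len(chosen) else np.array([], dtype=int)
        causal_sets = [partition.sets[s].set_id for s in chosen]
        n_causal = min(n_causal, pool.size)
        causal = np.sort(rng.choice(pool, size=n_causal, replace=False)) if n_causal else np.array([], dtype=int)
    else:
        causal = np.flatnonzero(rng.random(J) < arch.pi_causal)
        causal_sets = []

    beta = np.zeros(J)
    if causal.size:
        comps = rng.choice(3, size=causal.size, p=np.asarray(arch.mixture_props))
        sds = np.sqrt(np.asarray(arch.mixture_vars))[comps]
        beta[causal] = rng.standard_normal(causal.size) * sds

    tbv = X @ beta
    interactions: list[tuple[str, int, int, float]] = []
    if arch.epistasis_frac > 0.0:
        eligible = [
            s for s in partition.sets
            if np.isin(s.snp_indices, causal).sum() >= 2
        ]
        n_epi = int(round(arch.epistasis_frac * len(eligible)))
        if not eligible:
            warnings.warn("epistasis requested but no set holds two causal SNPs; "
                          "no interaction terms emitted")
        elif n_epi > 0:
            picked = rng.choice(len(eligible), size=n_epi, replace=False)
            # interaction effects drawn from the large-effect component so the
            # non-additive share is material
            epi_sd = np.sqrt(arch.mixture_vars[0])
            for s_i in picked:
                s = eligible[s_i]
                members = np.asarray(s.snp_indices)[
                    np.isin(s.snp_indices, causal)
                ]
                j1, j2 = rng.choice(members, size=2, replace=False)
                eff = float(rng.standard_normal() * epi_sd)
                interactions.append((s.set_id, int(j1), int(j2), eff))
                tbv = tbv + eff * X[:, j1] * X[:, j2]

    var_g = float(np.var(tbv, ddof=1))
    if var_g > 0.0:
        e = rng.standard_normal(n)
        # orthogonalize against tbv and rescale so the realized variance
        # ratio hits the target exactly
        e = e - (e @ tbv) / (tbv @ tbv) * tbv
        e *= np.sqrt(var_g * (1.0 - arch.h2_target) / arch.h2_target / np.var(e, ddof=1))
        y = tbv + e
        realized_h2 = var_g / float(np.var(y, ddof=1))
    else:
        y = rng.standard_normal(n)
        realized_h2 = 0.0
    truth = SimTruth(
        beta_true=beta,
        interaction_terms=interactions,
        tbv=tbv,
        realized_h2=realized_h2,
        causal_idx=causal,
        causal_sets=causal_sets,
    )
    return y, truth


def simulate_drp(
    truth: SimTruth,
    phenotype: np.ndarray,
    rel_range: tuple[float, float] = (0.5, 0.9),
    h2: float = 0.33,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> list[TraitRecord]:
    """Build de-regressed proofs: tbv plus noise scaled by (1-REL)/REL.

    Each animal's reliability is uniform on ``rel_range``; the noise
    variance var(tbv)*(1-REL)/REL makes the squared correlation between
    DRP and true genetic value approximately REL in expectation, matching
    the diagonal residual weighting used by the reliability-weighted
    mixed model.
    """
    lo, hi = rel_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError(f"rel_range {rel_range} must satisfy 0 < low <= high < 1")
    rng = np.random.default_rng(seed)
    n = truth.tbv.shape[0]
    rel = rng.uniform(lo, hi, size=n)
    var_g = float(np.var(truth.tbv, ddof=1))
    if var_g == 0.0:
        var_g = float(np.var(phenotype, ddof=1))
    noise = rng.standard_normal(n) * np.sqrt(var_g * (1.0 - rel) / rel)
    drp = truth.tbv + noise
    ids = sample_ids if sample_ids is not None else [f"ind{i + 1}" for i in range(n)]
    from .io import derive_trait_weights

    return derive_trait_weights(
        [TraitRecord(ids[i], float(drp[i]), float(rel[i]), h2) for i in range(n)]
    )
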