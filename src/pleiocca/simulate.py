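"""Synthetic multi-cohort GWAS generator with known pleiotropic architecture.

Emulates the real inputs of a summary-statistic pleiotropy study: a
reference genotype panel with blockwise LD, p disease traits each measured
in its *own* cohort (mirroring independent consortia), per-SNP univariate
regression outputs (beta, se, p, n), a gene map, and ground truth about
which genes carry effects shared across traits.

Genotypes come from thresholded latent Gaussians: per gene-block, a latent
AR(1) Gaussian vector is dichotomised at each SNP's allele-frequency
quantile, twice per individual (two haplotypes), and summed to a 0/1/2
dosage.  This induces controllable LD decay within blocks and independence
across blocks.  Effects are specified per SNP on the standardized-genotype
scale, so the truth is directly comparable to standardized betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cca import CcaResult, bartlett_chi2
from .reference import ReferencePanel
from .sumstats import REQUIRED_COLUMNS, SummaryStats


@dataclass
class CausalGene:
    """A gene whose member SNPs all carry ``effect`` on every trait in ``traits``."""

    gene_index: int
    traits: tuple[int, ...]
    effect: float


@dataclass
class SimConfig:
    seed: int = 0
    n_reference: int = 400
    n_cohorts: tuple[int, ...] = (5000, 5000, 5000, 5000, 5000)
    n_snps: int = 480
    n_genes: int = 60
    block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_genes: list[CausalGene] = field(default_factory=list)
    resid_trait_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_snps < self.n_genes or self.n_genes < 1:
            raise ValueError("need n_snps >= n_genes >= 1")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if min(self.n_cohorts) < 10 or self.n_reference < 10:
            raise ValueError("cohort and reference sizes must be >= 10")
        for cg in self.causal_genes:
            if not (0 <= cg.gene_index < self.n_genes):
                raise ValueError(f"causal gene index {cg.gene_index} out of range")
            if any(t < 0 or t >= self.p for t in cg.traits):
                raise ValueError("causal trait index out of range")

    @property
    def p(self) -> int:
        return len(self.n_cohorts)

    @property
    def snps_per_gene(self) -> int:
        return self.n_snps // self.n_genes


@dataclass
class SimTruth:
    """Ground truth: which SNPs/genes affect which traits."""

    causal_genes: list[CausalGene]
    effect_matrix: np.ndarray  # n_snps x p, standardized-genotype scale
    causal_gene_names: list[str]
    generator_version: str = "1"

    def causal_snps(self, trait: int) -> np.ndarray:
        return np.flatnonzero(self.effect_matrix[:, trait] != 0.0)


# ---------------------------------------------------------------------------
# population model


def _block_structure(config: SimConfig):
    """Gene blocks: consecutive runs of SNPs; remainder SNPs join the last gene."""
    sizes = np.full(config.n_genes, config.snps_per_gene, dtype=int)
    sizes[-1] += config.n_snps - sizes.sum()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return starts, sizes


def _snp_metadata(config: SimConfig) -> pd.DataFrame:
    starts, sizes = _block_structure(config)
    # genes spaced 100 kb apart on one chromosome, SNPs 1 kb apart
    rows = []
    for b, (s0, sz) in enumerate(zip(starts, sizes)):
        base = 1 + b * 100_000
        for k in range(sz):
            i = s0 + k
            rows.append((f"rs{i:06d}", "1", base + 1000 * k, "A", "G"))
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "A1", "A2"])


def _draw_mafs(config: SimConfig) -> np.ndarray:
    """Per-SNP population MAFs — a fixed property of the simulated population,
    shared by the reference panel and every cohort (stream 1 of the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _draw_dosages(
    config: SimConfig, mafs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dosages for n individuals under the latent-Gaussian block model."""
    starts, sizes = _block_structure(config)
    G = np.empty((n, config.n_snps), dtype=np.int8)
    thresh = stats.norm.ppf(mafs)  # latent < quantile(maf) -> carrier allele
    for s0, sz in zip(starts, sizes):
        if config.block_rho > 0.0:
            corr = config.block_rho ** np.abs(
                np.subtract.outer(np.arange(sz), np.arange(sz))
            )
            L = np.linalg.cholesky(corr)
            h1 = rng.standard_normal((n, sz)) @ L.T
            h2 = rng.standard_normal((n, sz)) @ L.T
        else:
            h1 = rng.standard_normal((n, sz))
            h2 = rng.standard_normal((n, sz))
        t = thresh[s0 : s0 + sz]
        G[:, s0 : s0 + sz] = (h1 < t).astype(np.int8) + (h2 < t).astype(np.int8)
    return G


def simulate_reference(config: SimConfig) -> ReferencePanel:
    """Reference panel of ``n_reference`` individuals; monomorphic SNPs resampled.

    Pure function of the config (seed included), so repeated calls are
    byte-identical.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mafs = _draw_mafs(config)
    G = _draw_dosages(config, mafs, config.n_reference, rng)
    # resample rare monomorphic columns so every MAF is positive
    for _ in range(100):
        bad = np.flatnonzero(G.min(axis=0) == G.max(axis=0))
        if len(bad) == 0:
            break
        for j in bad:
            t = stats.norm.ppf(mafs[j])
            h = rng.standard_normal((config.n_reference, 2))
            G[:, j] = (h < t).sum(axis=1).astype(np.int8)
    else:
        raise RuntimeError("simulate_reference: could not avoid monomorphic sites")
    return ReferencePanel(snps=_snp_metadata(config), G=G)


def gene_table(config: SimConfig) -> pd.DataFrame:
    """Gene regions (glist dialect columns) matching the simulated layout."""
    starts, sizes = _block_structure(config)
    rows = []
    for b, (s0, sz) in enumerate(zip(starts, sizes)):
        base = 1 + b * 100_000
        rows.append(("1", base, base + 1000 * (sz - 1), f"GENE{b:03d}"))
    return pd.DataFrame(rows, columns=["CHR", "START", "END", "NAME"])


def write_gene_list(config: SimConfig, path) -> None:
    gt = gene_table(config)
    with open(path, "w") as fh:
        for _, r in gt.iterrows():
            fh.write(f"{r.CHR} {r.START} {r.END} {r.NAME}\n")


def _effect_matrix(config: SimConfig) -> np.ndarray:
    starts, sizes = _block_structure(config)
    E = np.zeros((config.n_snps, config.p))
    for cg in config.causal_genes:
        s0, sz = starts[cg.gene_index], sizes[cg.gene_index]
        for t in cg.traits:
            E[s0 : s0 + sz, t] = cg.effect
    return E


def _univariate_gwas(G: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP simple linear regression of y on each dosage column."""
    n = len(y)
    Gc = G.astype(float) - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxy = Gc.T @ yc
    beta = sxy / sxx
    rss = (yc @ yc) - beta * sxy
    se = np.sqrt(np.maximum(rss, 1e-300) / (n - 2) / sxx)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_gwas(
    config: SimConfig, with_joint_cohort: bool = False
) -> tuple[list[SummaryStats], SimTruth, dict | None]:
    """Per-trait disjoint cohorts, phenotypes, and univariate GWAS outputs.

    Each trait t gets an independent cohort of ``n_cohorts[t]`` individuals
    drawn from the same population model.  The phenotype is the sum of the
    standardized-genotype effects plus Gaussian noise scaled so the trait
    variance is ~1 (error if the implied heritability exceeds 1).  With
    ``with_joint_cohort`` an extra cohort measuring *all* traits on one
    sample is returned for oracle comparisons, using ``resid_trait_corr``
    as the residual trait correlation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    mafs = _draw_mafs(config)
    meta = _snp_metadata(config)
    E = _effect_matrix(config)

    gene_names = [f"GENE{cg.gene_index:03d}" for cg in config.causal_genes]
    truth = SimTruth(
        causal_genes=list(config.causal_genes),
        effect_matrix=E,
        causal_gene_names=gene_names,
    )

    studies = []
    for t, n in enumerate(config.n_cohorts):
        G = _draw_dosages(config, mafs, n, rng)
        Gs = G.astype(float)
        Gs = (Gs - Gs.mean(axis=0)) / np.maximum(Gs.std(axis=0), 1e-12)
        signal = Gs @ E[:, t]
        var_sig = signal.var()
        if var_sig >= 1.0:
            raise ValueError(
                f"trait {t}: implied genetic variance {var_sig:.3f} >= 1; "
                "reduce effect sizes"
            )
        y = signal + rng.standard_normal(n) * np.sqrt(1.0 - var_sig)
        beta, se, p = _univariate_gwas(G, y)
        table = meta.copy()
        table["BETA"] = beta
        table["SE"] = se
        table["P"] = p
        table["N"] = n
        studies.append(
            SummaryStats(disease=f"trait{t}", table=table[list(REQUIRED_COLUMNS)], n=n)
        )

    joint = None
    if with_joint_cohort:
        n = min(config.n_cohorts)
        G = _draw_dosages(config, mafs, n, rng)
        Gs = G.astype(float)
        Gs = (Gs - Gs.mean(axis=0)) / np.maximum(Gs.std(axis=0), 1e-12)
        R = (
            np.asarray(config.resid_trait_corr, dtype=float)
            if config.resid_trait_corr is not None
            else np.eye(config.p)
        )
        L = np.linalg.cholesky(R + 1e-12 * np.eye(config.p))
        noise = rng.standard_normal((n, config.p)) @ L.T
        signal = Gs @ E
        scale = np.sqrt(np.maximum(1.0 - signal.var(axis=0), 1e-12))
        Y = signal + noise * scale[None, :]
        joint = {"G": G, "Y": Y}
    return studies, truth, joint


# ---------------------------------------------------------------------------
# individual-level CCA oracle (independent of the covariance-based engine)


def oracle_cca(genotypes: np.ndarray, traits: np.ndarray, unit_id: str = "oracle") -> CcaResult:
    """Textbook CCA on individual-level data via the QR/SVD route.

    Standardizes both blocks, takes thin QR factors, and reads the canonical
    correlations off the singular values of Qx' Qy.  Deliberately shares no
    code with the covariance-based engine beyond the Bartlett formula.
    """
    X = np.atleast_2d(np.asarray(genotypes, dtype=float))
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("oracle_cca: row mismatch between blocks")
    if np.any(X.std(axis=0) == 0) or np.any(Y.std(axis=0) == 0):
        raise ValueError("oracle_cca: constant column")
    Xc = (X - X.mean(axis=0)) / X.std(axis=0)
    Yc = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    qx, rx = np.linalg.qr(Xc)
    if np.min(np.abs(np.diag(rx))) < 1e-8 * n:
        raise np.linalg.LinAlgError("oracle_cca: rank-deficient genotype block")
    qy, _ = np.linalg.qr(Yc)
    rhos = np.linalg.svd(qx.T @ qy, compute_uv=False)
    rhos = np.clip(rhos[: min(X.shape[1], Y.shape[1])], 0.0, 1.0 - 1e-8)
    g, p = X.shape[1], Y.shape[1]
    statistic, df, pvalue = bartlett_chi2(rhos, n, g, p)
    return CcaResult(
        unit_id=unit_id, unit_type="oracle", g=g, p=p, r=float(rhos[0]),
        statistic=float(max(statistic, 0.0)), df=df, pvalue=float(pvalue),
        n_eff=n,
    )
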