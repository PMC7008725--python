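"""Summary-statistic canonical correlation analysis.

Individual-level CCA finds the linear combinations of a genotype block X and
a trait block Y with maximal correlation.  With only univariate GWAS outputs
available, the same canonical correlations can be recovered from a block
covariance matrix

    Sigma = [[Sigma_XX, Sigma_XY],
             [Sigma_XY', Sigma_YY]]

whose blocks are estimated separately: Sigma_XX from a reference genotype
panel of matched ancestry, Sigma_XY from standardized regression
coefficients beta / (se * sqrt(n)) (which approximate genotype-trait
correlations), and Sigma_YY from the Pearson correlation between the columns
of the standardized-beta matrix across many SNPs.  Because the blocks come
from different samples the assembled matrix need not be a valid covariance;
an iterative off-diagonal shrinkage restores positive semidefiniteness
before the CCA eigenproblem is solved.

Significance uses Bartlett's chi-square approximation to Wilks' Lambda over
all canonical correlations, with g*p degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .reference import GeneRegion, ReferencePanel
from .sumstats import BetaPanel

log = logging.getLogger(__name__)

#: canonical correlations are kept this far below 1 so log(1 - r^2) is finite
R_CLIP = 1e-8
#: eigenvalue tolerance under which the full covariance counts as PSD
PSD_TOL = 1e-8
#: ridge target for the smallest Sigma_XX eigenvalue during whitening
XX_RIDGE_TOL = 1e-6


@dataclass
class StandardizedBetaPanel:
    """Betas rescaled to the correlation scale: entry = beta / (se * sqrt(n))."""

    snps: "object"
    diseases: list[str]
    Bstd: np.ndarray
    N: np.ndarray


@dataclass
class CovarianceBundle:
    """The assembled block covariance for one SNP or gene unit."""

    unit_id: str
    sigma_xx: np.ndarray
    sigma_xy: np.ndarray
    sigma_yy: np.ndarray
    full: np.ndarray
    psd: bool
    shrink_iterations: int = 0
    min_eigenvalue: float = 0.0

    @property
    def g(self) -> int:
        return self.sigma_xx.shape[0]

    @property
    def p(self) -> int:
        return self.sigma_yy.shape[0]


@dataclass
class CcaResult:
    """Leading canonical correlation and its Bartlett chi-square test."""

    unit_id: str
    unit_type: str  # "snp" | "gene"
    g: int
    p: int
    r: float
    statistic: float
    df: int
    pvalue: float
    n_eff: int
    shrink_iterations: int = 0


def standardize_beta(panel: BetaPanel) -> StandardizedBetaPanel:
    """Rescale betas to the correlation scale, beta / (se * sqrt(n)).

    Equivalently the per-study z-score divided by sqrt(n); for standardized
    genotypes and traits this approximates the sample genotype-trait
    correlation.
    """
    if not np.all(panel.SE > 0):
        i, j = np.argwhere(~(panel.SE > 0))[0]
        raise ValueError(
            f"standardize_beta: non-positive SE at snp "
            f"{panel.snps['SNP'].iloc[i]}, study {panel.diseases[j]}"
        )
    if not np.all(panel.N > 0):
        raise ValueError("standardize_beta: non-positive sample size")
    Bstd = panel.B / (panel.SE * np.sqrt(panel.N)[None, :])
    return StandardizedBetaPanel(
        snps=panel.snps, diseases=list(panel.diseases), Bstd=Bstd, N=panel.N.copy()
    )


def estimate_sigma_yy(std: StandardizedBetaPanel) -> np.ndarray:
    """Trait-trait correlation: Pearson correlation of standardized-beta columns.

    Computed over ALL harmonized SNPs (before pruning) — the estimate
    improves with the number of SNPs, and pruning is only needed for the
    genotype side.
    """
    if std.Bstd.shape[0] < 3:
        raise ValueError("estimate_sigma_yy: need at least 3 SNP rows")
    sd = std.Bstd.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"estimate_sigma_yy: constant beta column for {std.diseases[j]}")
    if std.Bstd.shape[1] == 1:
        return np.ones((1, 1))
    s = np.corrcoef(std.Bstd, rowvar=False)
    return (s + s.T) / 2.0


def estimate_sigma_xx(panel: ReferencePanel, members: np.ndarray) -> np.ndarray:
    """Genotype correlation of the member SNPs from the reference panel."""
    members = np.asarray(members, dtype=np.intp)
    if members.size == 0:
        raise ValueError("estimate_sigma_xx: empty member set")
    if members.size == 1:
        return np.ones((1, 1))
    s = np.corrcoef(panel.G[:, members].astype(float), rowvar=False)
    return (s + s.T) / 2.0


def _min_eig(full: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(full)[0])


def assemble_full_cov(
    sigma_xx: np.ndarray,
    sigma_xy: np.ndarray,
    sigma_yy: np.ndarray,
    unit_id: str = "",
) -> CovarianceBundle:
    """Stack the three blocks into the full (g+p) x (g+p) matrix and test PSD."""
    sigma_xx = np.atleast_2d(np.asarray(sigma_xx, dtype=float))
    sigma_yy = np.atleast_2d(np.asarray(sigma_yy, dtype=float))
    sigma_xy = np.asarray(sigma_xy, dtype=float).reshape(
        sigma_xx.shape[0], sigma_yy.shape[0]
    )
    g, p = sigma_xy.shape
    if sigma_xx.shape != (g, g) or sigma_yy.shape != (p, p):
        raise ValueError("assemble_full_cov: non-conformable blocks")
    full = np.block([[sigma_xx, sigma_xy], [sigma_xy.T, sigma_yy]])
    mev = _min_eig(full)
    return CovarianceBundle(
        unit_id=unit_id,
        sigma_xx=sigma_xx,
        sigma_xy=sigma_xy,
        sigma_yy=sigma_yy,
        full=full,
        psd=mev >= -PSD_TOL,
        min_eigenvalue=mev,
    )


def shrink_to_psd(
    bundle: CovarianceBundle,
    factor: float = 0.999,
    tol: float = PSD_TOL,
    max_iter: int = 10**5,
) -> CovarianceBundle:
    """Multiply all off-diagonal entries by ``factor`` until the matrix is PSD.

    The diagonal is never touched and off-diagonal magnitudes only shrink,
    so the loop converges for any ``factor`` < 1 (guarded by ``max_iter``).
    Blocks are rebuilt from the shrunk full matrix so they stay consistent.
    """
    if not (0.0 < factor < 1.0):
        raise ValueError("shrink factor must lie in (0, 1)")
    full = bundle.full.copy()
    g = bundle.g
    it = 0
    mev = _min_eig(full)
    off = ~np.eye(full.shape[0], dtype=bool)
    while mev < tol:
        if it >= max_iter:
            raise RuntimeError(
                f"shrink_to_psd: {bundle.unit_id or 'unit'} not PSD after {max_iter} iterations"
            )
        full[off] *= factor
        it += 1
        mev = _min_eig(full)
    if it == 0:
        return bundle
    return replace(
        bundle,
        sigma_xx=full[:g, :g],
        sigma_xy=full[:g, g:],
        sigma_yy=full[g:, g:],
        full=full,
        psd=True,
        shrink_iterations=bundle.shrink_iterations + it,
        min_eigenvalue=mev,
    )


def _inv_sqrt(mat: np.ndarray, ridge_tol: float, unit_id: str) -> np.ndarray:
    """Symmetric inverse square root, with a ridge when nearly singular."""
    w, v = np.linalg.eigh(mat)
    eps = max(0.0, ridge_tol - w[0])
    if eps > 0.0:
        w = w + eps
    if w[0] <= 0.0:
        raise np.linalg.LinAlgError(
            f"covariance block for {unit_id or 'unit'} singular beyond ridge repair"
        )
    return (v / np.sqrt(w)) @ v.T


def bartlett_chi2(
    rhos: np.ndarray, n_eff: int, g: int, p: int
) -> tuple[float, int, float]:
    """Bartlett's chi-square on Wilks' Lambda over all canonical correlations."""
    lam = float(np.prod(1.0 - rhos**2))
    statistic = -(n_eff - 1 - (g + p + 1) / 2.0) * np.log(lam)
    df = g * p
    return statistic, df, float(stats.chi2.sf(statistic, df))


def cca_from_cov(
    bundle: CovarianceBundle, n_eff: int, unit_type: str = "snp"
) -> CcaResult:
    """Canonical correlations from a PSD covariance bundle.

    The correlations are the singular values of
    Sigma_XX^{-1/2} Sigma_XY Sigma_YY^{-1/2}, clipped just below 1 so the
    Wilks log stays finite.
    """
    if not bundle.psd:
        raise ValueError(
            f"cca_from_cov: bundle {bundle.unit_id!r} is not PSD; shrink it first"
        )
    g, p = bundle.g, bundle.p
    if n_eff <= g + p + 1:
        raise ValueError(f"cca_from_cov: n_eff={n_eff} too small for g={g}, p={p}")
    xh = _inv_sqrt(bundle.sigma_xx, XX_RIDGE_TOL, bundle.unit_id)
    yh = _inv_sqrt(bundle.sigma_yy, XX_RIDGE_TOL, bundle.unit_id)
    rhos = np.linalg.svd(xh @ bundle.sigma_xy @ yh, compute_uv=False)
    rhos = np.clip(rhos, 0.0, 1.0 - R_CLIP)
    statistic, df, pvalue = bartlett_chi2(rhos, n_eff, g, p)
    return CcaResult(
        unit_id=bundle.unit_id,
        unit_type=unit_type,
        g=g,
        p=p,
        r=float(rhos[0]),
        statistic=float(max(statistic, 0.0)),
        df=df,
        pvalue=min(max(pvalue, np.nextafter(0, 1)), 1.0),
        n_eff=int(n_eff),
        shrink_iterations=bundle.shrink_iterations,
    )


def effective_n(N: np.ndarray, rule: str = "min") -> int:
    """Single effective sample size across studies of different sizes.

    ``min`` (default, conservative), ``harmonic`` or ``mean``.
    """
    N = np.asarray(N, dtype=float)
    if rule == "min":
        return int(N.min())
    if rule == "harmonic":
        return int(len(N) / np.sum(1.0 / N))
    if rule == "mean":
        return int(N.mean())
    raise ValueError(f"unknown n_eff rule {rule!r}")


def _unit_cca(
    sigma_xx: np.ndarray,
    sigma_xy: np.ndarray,
    sigma_yy: np.ndarray,
    unit_id: str,
    n_eff: int,
    unit_type: str,
    shrink_factor: float,
) -> CcaResult:
    bundle = assemble_full_cov(sigma_xx, sigma_xy, sigma_yy, unit_id)
    if not bundle.psd:
        bundle = shrink_to_psd(bundle, factor=shrink_factor)
    return cca_from_cov(bundle, n_eff, unit_type=unit_type)


def snp_scan(
    std: StandardizedBetaPanel,
    sigma_yy: np.ndarray,
    kept: np.ndarray,
    n_eff: int,
    shrink_factor: float = 0.999,
) -> list[CcaResult]:
    """Univariate-SNP / multivariate-phenotype scan over the pruned SNPs."""
    one = np.ones((1, 1))
    ids = std.snps["SNP"].to_numpy()
    results = []
    for i in np.asarray(kept, dtype=np.intp):
        results.append(
            _unit_cca(one, std.Bstd[i : i + 1, :], sigma_yy, str(ids[i]),
                      n_eff, "snp", shrink_factor)
        )
    return results


def gene_scan(
    std: StandardizedBetaPanel,
    panel: ReferencePanel,
    genes: list[GeneRegion],
    sigma_yy: np.ndarray,
    kept: np.ndarray,
    n_eff: int,
    shrink_factor: float = 0.999,
) -> list[CcaResult]:
    """Multivariate-SNP / multivariate-phenotype scan, one result per gene.

    Gene membership is restricted to the pruned SNP set; genes left with no
    members are skipped (logged).  Sigma_XX comes from the reference panel.
    """
    kept_set = np.zeros(panel.n_snps, dtype=bool)
    kept_set[np.asarray(kept, dtype=np.intp)] = True
    results = []
    n_skipped = 0
    for gene in genes:
        members = gene.member_snps[kept_set[gene.member_snps]]
        if len(members) == 0:
            n_skipped += 1
            continue
        if len(members) >= panel.n_individuals:
            log.warning(
                "gene %s: %d member SNPs >= %d reference individuals; "
                "Sigma_XX is rank-deficient and ridge-repaired",
                gene.name, len(members), panel.n_individuals,
            )
        sigma_xx = estimate_sigma_xx(panel, members)
        results.append(
            _unit_cca(sigma_xx, std.Bstd[members, :], sigma_yy, gene.name,
                      n_eff, "gene", shrink_factor)
        )
    if n_skipped:
        log.info("gene_scan: skipped %d genes with no pruned member SNPs", n_skipped)
    return results


def results_to_frame(results: list[CcaResult]):
    """Tabulate scan results (tab-delimited friendly)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "unit_type": r.unit_type,
                "g": r.g,
                "p": r.p,
                "r": r.r,
                "statistic": r.statistic,
                "df": r.df,
                "pvalue": r.pvalue,
                "n_eff": r.n_eff,
                "shrink_iterations": r.shrink_iterations,
            }
            for r in results
        ]
    )
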