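"""Reference genotype panel: LD estimation, PLINK-style pruning, gene regions.

The reference panel supplies what summary statistics cannot: the genotype
correlation structure (Sigma_XX) of the study population.  It is loaded from
a VCF or a plain dosage matrix, and used for minor-allele frequencies,
pairwise LD (r^2), sliding-window LD pruning and SNP-to-gene assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import _chrom_key

log = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Dosage matrix (individuals x SNPs, entries 0/1/2) with SNP metadata.

    Columns of ``snps``: SNP, CHR, POS, A1 (counted allele), A2.  Constant
    columns and sites with missing calls are excluded at load so every MAF is
    strictly positive and LD is always defined.
    """

    snps: pd.DataFrame
    G: np.ndarray

    def __post_init__(self) -> None:
        if self.G.shape[1] != len(self.snps):
            raise ValueError("dosage matrix / metadata SNP count mismatch")

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = self.G.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, indices: np.ndarray) -> "ReferencePanel":
        return ReferencePanel(
            snps=self.snps.iloc[indices].reset_index(drop=True),
            G=self.G[:, indices],
        )


@dataclass
class GeneRegion:
    """A named genomic interval with the panel SNP indices falling inside it.

    ``start``/``end`` are 1-based and inclusive on both ends (glist
    convention); no flanking window is added.
    """

    name: str
    chrom: str
    start: int
    end: int
    member_snps: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")

    @property
    def n_members(self) -> int:
        return len(self.member_snps)


def _sort_snp_table(snps: pd.DataFrame, G: np.ndarray):
    order = snps.sort_values(
        by=["CHR", "POS", "SNP"],
        key=lambda c: c.map(_chrom_key) if c.name == "CHR" else c,
    ).index.to_numpy()
    return snps.iloc[order].reset_index(drop=True), G[:, order]


def load_reference(path: str | Path) -> ReferencePanel:
    """Load a reference panel from a VCF (``.vcf``/``.vcf.gz``) or dosage TSV.

    VCF sites that are multiallelic, non-SNP, carry a missing genotype, or
    are monomorphic in the sample are dropped (counts logged).  The dosage
    dialect is a TSV with columns SNP, CHR, POS, A1, A2 then one column per
    individual holding 0/1/2.
    """
    path = Path(path)
    if ".vcf" in path.suffixes or path.suffix == ".vcf":
        return _load_vcf(path)
    return _load_dosage(path)


def _load_vcf(path: Path) -> ReferencePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    rows, cols = [], []
    n_multi = n_missing = n_const = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        gt = v.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=unknown (gts012)
        if (gt == 3).any():
            n_missing += 1
            continue
        dos = gt.astype(np.int8)
        if dos.min() == dos.max():
            n_const += 1
            continue
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, v.ALT[0], v.REF))
        cols.append(dos)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic SNP sites")
    if n_multi or n_missing or n_const:
        log.info(
            "%s: dropped %d multiallelic/non-SNP, %d with missing calls, %d monomorphic",
            path, n_multi, n_missing, n_const,
        )
    snps = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "A1", "A2"])
    G = np.column_stack(cols)
    snps, G = _sort_snp_table(snps, G)
    return ReferencePanel(snps=snps, G=G)


def _load_dosage(path: Path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    meta_cols = ["SNP", "CHR", "POS", "A1", "A2"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage matrix missing column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"{path}: dosage matrix has no sample columns")
    G = df[sample_cols].to_numpy(dtype=np.int8).T  # individuals x SNPs
    keep = G.min(axis=0) != G.max(axis=0)
    n_const = int((~keep).sum())
    if n_const:
        log.info("%s: dropped %d monomorphic sites", path, n_const)
    if not keep.any():
        raise ValueError(f"{path}: no polymorphic sites")
    snps, G = _sort_snp_table(df.loc[:, meta_cols].reset_index(drop=True), G)
    keep = G.min(axis=0) != G.max(axis=0)
    return ReferencePanel(snps=snps[keep].reset_index(drop=True), G=G[:, keep])


def write_vcf(panel: ReferencePanel, path: str | Path) -> Path:
    """Write the panel as a minimal GT-only VCF (text, uncompressed)."""
    path = Path(path)
    n = panel.n_individuals
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.snps["CHR"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(f"S{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in panel.snps.iterrows():
            gts = "\t".join(code[int(x)] for x in panel.G[:, j])
            # A1 is the counted (ALT) allele, A2 the REF allele
            fh.write(
                f"{row.CHR}\t{row.POS}\t{row.SNP}\t{row.A2}\t{row.A1}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def ld_r2(panel: ReferencePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage columns i and j."""
    if i == j:
        raise ValueError("ld_r2 requires two distinct SNPs")
    x = panel.G[:, i].astype(float)
    y = panel.G[:, j].astype(float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _prune_window(corr2: np.ndarray, maf: np.ndarray, alive: np.ndarray,
                  idx: np.ndarray, r2_max: float) -> int:
    """Greedy within-window removal; returns number removed.

    Offending pairs are visited in (i, j) index order; the smaller-MAF SNP
    goes, ties removing the later-positioned one.
    """
    removed = 0
    local_alive = alive[idx]
    while True:
        live = np.flatnonzero(local_alive)
        if len(live) < 2:
            break
        sub = corr2[np.ix_(live, live)]
        iu, ju = np.triu_indices(len(live), k=1)
        offending = sub[iu, ju] > r2_max
        if not offending.any():
            break
        k = int(np.argmax(offending))  # first offending pair in scan order
        a, b = live[iu[k]], live[ju[k]]
        # a precedes b in position; drop smaller MAF, ties drop the later SNP
        drop = a if maf[idx[a]] < maf[idx[b]] else b
        local_alive[drop] = False
        removed += 1
    alive[idx] = local_alive
    return removed


def prune(
    panel: ReferencePanel,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """LD-prune with SNP-count windows (PLINK ``--indep-pairwise`` idiom).

    Per chromosome, windows of ``window_snps`` advance by ``step_snps`` over
    the currently surviving SNPs; within a window every pair with
    r^2 > ``r2_max`` loses its smaller-MAF member.  Passes repeat until a
    full sweep removes nothing, so no surviving window contains an offending
    pair.  Returns sorted indices of survivors.
    """
    if not (window_snps >= step_snps >= 1):
        raise ValueError("need window_snps >= step_snps >= 1")
    maf = panel.maf
    alive = np.ones(panel.n_snps, dtype=bool)
    Gc = panel.G.astype(float)
    Gc -= Gc.mean(axis=0)
    norm = np.sqrt((Gc ** 2).sum(axis=0))
    Gc /= norm

    for chrom in dict.fromkeys(panel.snps["CHR"]):
        chrom_idx = np.flatnonzero((panel.snps["CHR"] == chrom).to_numpy())
        while True:
            removed_this_pass = 0
            survivors = chrom_idx[alive[chrom_idx]]
            if len(survivors) < 2:
                break
            starts = range(0, max(len(survivors) - 1, 1), step_snps)
            for s in starts:
                idx = survivors[s : s + window_snps]
                idx = idx[alive[idx]]
                if len(idx) < 2:
                    continue
                corr2 = (Gc[:, idx].T @ Gc[:, idx]) ** 2
                removed_this_pass += _prune_window(corr2, maf, alive, idx, r2_max)
            if removed_this_pass == 0:
                break
    return np.flatnonzero(alive)


def read_gene_list(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited gene list: chrom start end name (glist dialect)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 'chrom start end name'")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from None
    return pd.DataFrame(rows, columns=["CHR", "START", "END", "NAME"])


def assign_snps_to_genes(
    panel: ReferencePanel, gene_list: pd.DataFrame | str | Path
) -> tuple[list[GeneRegion], np.ndarray]:
    """Assign panel SNPs to gene intervals (1-based, both ends inclusive).

    A SNP inside k overlapping genes belongs to all k.  Genes with no member
    SNPs are omitted.  Returns the gene regions plus indices of SNPs falling
    in no gene.
    """
    if not isinstance(gene_list, pd.DataFrame):
        gene_list = read_gene_list(gene_list)
    chrom = panel.snps["CHR"].to_numpy()
    pos = panel.snps["POS"].to_numpy()
    genes: list[GeneRegion] = []
    in_gene = np.zeros(panel.n_snps, dtype=bool)
    for _, row in gene_list.iterrows():
        mask = (chrom == str(row["CHR"])) & (pos >= row["START"]) & (pos <= row["END"])
        members = np.flatnonzero(mask)
        if len(members) == 0:
            continue
        in_gene[members] = True
        genes.append(
            GeneRegion(
                name=row["NAME"],
                chrom=str(row["CHR"]),
                start=int(row["START"]),
                end=int(row["END"]),
                member_snps=members,
            )
        )
    return genes, np.flatnonzero(~in_gene)
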