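"""Bundled example data.

One small table ships with the package: published gene-level results from a
seven-disease autoimmune/autoinflammatory pleiotropy analysis (67 genes,
diseases CEL, IBD, MS, PBC, RA, SLE, T1D).  Each row carries the gene's
multivariate CCA p-value, its seven per-disease gene-based association
p-values (floored at 1e-6 by the originating tool's 10^6-draw Monte-Carlo
null), the gene's chromosome, member-SNP count, leading canonical
correlation, and a literature-curated confirmed/novel label.  It serves as
a worked input for the refinement stage: 41,274 SNPs and 11,516 genes were
tested, so the Bonferroni gates are 0.05/41,274 and 0.05/11,516.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: test counts behind the published Bonferroni thresholds
AUTOIMMUNE7_M_SNPS = 41_274
AUTOIMMUNE7_M_GENES = 11_516
AUTOIMMUNE7_DISEASES = ("CEL", "IBD", "MS", "PBC", "RA", "SLE", "T1D")


def load_autoimmune7() -> pd.DataFrame:
    """The 67-gene autoimmune pleiotropy table (see module docstring)."""
    ref = resources.files("pleiocca.data") / "autoimmune7_pleiotropic_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def autoimmune7_inputs():
    """Split the bundled table into refinement-stage inputs.

    Returns ``(gene_cca, gene_assoc, novelty_map)``: the gene-level CCA
    p-value table, the long-form per-disease gene-association table, and the
    confirmed/novel annotation map.
    """
    df = load_autoimmune7()
    gene_cca = df[["gene", "metacca_p"]].rename(columns={"metacca_p": "pvalue"})
    long = df.melt(
        id_vars="gene",
        value_vars=[f"p_{d}" for d in AUTOIMMUNE7_DISEASES],
        var_name="disease",
        value_name="pvalue",
    )
    long["disease"] = long["disease"].str.removeprefix("p_")
    novelty = dict(zip(df["gene"], df["gene_type"]))
    return gene_cca, long, novelty
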