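"""Bonferroni thresholds, the pleiotropic-gene intersection filter, reports.

A gene is called *pleiotropic* when it passes both gates: its multivariate
CCA p-value beats the Bonferroni gene threshold (strict <, alpha / number of
genes tested), and its per-disease gene-based p-value reaches the
gene-association cutoff for at least one disease (<=, because Monte-Carlo
p-values are floored at 1/(n_sims+1) and a floored value counts as an
association).  Genes associated with two or more diseases are additionally
flagged multi-disease.  Confirmed-vs-novel status is literature curation and
enters only as a user-supplied annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class RefineConfig:
    m_snps: int
    m_genes: int
    alpha: float = 0.05
    gene_p_threshold: float = 1.00e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.m_snps < 1 or self.m_genes < 1:
            raise ValueError("m_snps and m_genes must be >= 1")

    @property
    def snp_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_snps)

    @property
    def gene_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_genes)


@dataclass
class PleiotropyCall:
    gene: str
    metacca_p: float
    disease_ps: dict[str, float]
    selected: bool
    n_assoc: int
    multi_disease: bool
    novelty: str = "unknown"  # confirmed | novel | unknown


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha / m — the family-wise significance cutoff for m tests."""
    if m < 1:
        raise ValueError("bonferroni_threshold: m must be >= 1")
    return alpha / m


def refine_pleiotropic(
    gene_cca: pd.DataFrame,
    gene_assoc: pd.DataFrame,
    config: RefineConfig,
    novelty_map: dict[str, str] | None = None,
) -> list[PleiotropyCall]:
    """Intersect the multivariate scan with the per-disease gene tests.

    ``gene_cca`` needs columns gene, pvalue; ``gene_assoc`` either long form
    (gene, disease, pvalue) or wide form (gene + one p column per disease).
    Genes missing from either table are excluded (logged).  Output sorted by
    gene name.
    """
    if gene_cca["gene"].duplicated().any():
        dup = gene_cca["gene"][gene_cca["gene"].duplicated()].tolist()
        raise ValueError(f"refine_pleiotropic: duplicate gene rows in CCA table: {dup[:5]}")
    if {"disease", "pvalue"} <= set(gene_assoc.columns):
        wide = gene_assoc.pivot(index="gene", columns="disease", values="pvalue")
    else:
        wide = gene_assoc.set_index("gene")
        if wide.index.duplicated().any():
            raise ValueError("refine_pleiotropic: duplicate gene rows in association table")

    cca = gene_cca.set_index("gene")["pvalue"]
    shared = sorted(set(cca.index) & set(wide.index))
    dropped = (set(cca.index) | set(wide.index)) - set(shared)
    if dropped:
        log.info("refine_pleiotropic: %d genes missing from one input, excluded", len(dropped))

    calls = []
    for gene in shared:
        mp = float(cca.loc[gene])
        ps = {d: float(v) for d, v in wide.loc[gene].items() if np.isfinite(v)}
        n_assoc = sum(v <= config.gene_p_threshold for v in ps.values())
        selected = (mp < config.gene_threshold) and n_assoc >= 1
        calls.append(
            PleiotropyCall(
                gene=gene,
                metacca_p=mp,
                disease_ps=ps,
                selected=selected,
                n_assoc=n_assoc,
                multi_disease=selected and n_assoc >= 2,
                novelty="unknown",
            )
        )
    if novelty_map:
        calls = classify_novelty(calls, novelty_map)
    return calls


def classify_novelty(
    calls: list[PleiotropyCall], novelty_map: dict[str, str]
) -> list[PleiotropyCall]:
    """Attach confirmed/novel labels from an annotation map; unmapped → unknown."""
    norm = {g: str(v).strip().lower() for g, v in novelty_map.items()}
    for call in calls:
        label = norm.get(call.gene, "unknown")
        call.novelty = label if label in ("confirmed", "novel") else "unknown"
    return calls


def summarize_calls(calls: list[PleiotropyCall]) -> dict:
    sel = [c for c in calls if c.selected]
    return {
        "n_genes_evaluated": len(calls),
        "n_selected": len(sel),
        "n_multi_disease": sum(c.multi_disease for c in sel),
        "n_confirmed": sum(c.novelty == "confirmed" for c in sel),
        "n_novel": sum(c.novelty == "novel" for c in sel),
        "n_unknown": sum(c.novelty == "unknown" for c in sel),
        "n_confirmed_multi_disease": sum(
            c.novelty == "confirmed" and c.multi_disease for c in sel
        ),
    }


def emit_report(
    calls: list[PleiotropyCall],
    scan_results: pd.DataFrame | None,
    config: RefineConfig,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the selected-gene table, a gene-features table, and a JSON summary.

    The first table lists each selected gene's CCA p, per-disease p's and
    flags; the second adds chrom, member-SNP count and canonical r pulled
    from ``scan_results`` (gene-level scan output) when provided.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sel = [c for c in calls if c.selected]
    diseases = sorted({d for c in calls for d in c.disease_ps})

    rows = []
    for c in sel:
        row = {"gene": c.gene, "metacca_p": c.metacca_p}
        row.update({f"p_{d}": c.disease_ps.get(d, np.nan) for d in diseases})
        row.update({"n_assoc": c.n_assoc, "multi_disease": c.multi_disease,
                    "novelty": c.novelty})
        rows.append(row)
    t1 = pd.DataFrame(rows, columns=["gene", "metacca_p",
                                     *[f"p_{d}" for d in diseases],
                                     "n_assoc", "multi_disease", "novelty"])
    p1 = directory / "pleiotropic_genes.tsv"
    t1.to_csv(p1, sep="\t", index=False, float_format="%.6e")

    feats = []
    scan = (scan_results.set_index("unit_id")
            if scan_results is not None and len(scan_results) else None)
    for c in sel:
        row = {"gene": c.gene, "chrom": "", "n_snps": "", "r": "",
               "metacca_p": c.metacca_p, "novelty": c.novelty}
        if scan is not None and c.gene in scan.index:
            row["n_snps"] = int(scan.at[c.gene, "g"])
            row["r"] = float(scan.at[c.gene, "r"])
        feats.append(row)
    t2 = pd.DataFrame(feats, columns=["gene", "chrom", "n_snps", "r",
                                      "metacca_p", "novelty"])
    p2 = directory / "gene_features.tsv"
    t2.to_csv(p2, sep="\t", index=False, float_format="%.6e")

    summary = {
        **summarize_calls(calls),
        "alpha": config.alpha,
        "m_snps": config.m_snps,
        "m_genes": config.m_genes,
        "snp_threshold": config.snp_threshold,
        "gene_threshold": config.gene_threshold,
        "gene_p_threshold": config.gene_p_threshold,
    }
    p3 = directory / "summary.json"
    p3.write_text(json.dumps(summary, indent=2))
    return {"pleiotropic_genes": p1, "gene_features": p2, "summary": p3}
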