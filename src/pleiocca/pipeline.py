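"""End-to-end orchestration: harmonize -> prune -> annotate -> scan -> refine.

The pipeline consumes either real input files (per-disease summary
statistics, a reference VCF/dosage matrix, a gene list) or a ``simulate``
block, runs every stage in order, writes each stage's output under the run
directory, and records a manifest (config digest, per-stage counts and wall
times, seeds).  With ``resume=True`` stages whose output files already exist
are reloaded rather than recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cca, genetest, refine, simulate
from .reference import ReferencePanel, assign_snps_to_genes, load_reference, read_gene_list, prune
from .sumstats import BetaPanel, harmonize, read_sumstats

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_digest: str
    seed: int | None
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def align_to_reference(panel: BetaPanel, reference: ReferencePanel):
    """Restrict both panels to their shared SNPs, in identical order.

    Both are already (chrom, pos)-sorted, so masking preserves a common
    order.  Errors out if nothing overlaps.
    """
    shared = set(panel.snps["SNP"]) & set(reference.snps["SNP"])
    if not shared:
        raise ValueError("no SNPs shared between summary panel and reference panel")
    pm = panel.snps["SNP"].isin(shared).to_numpy()
    rm = reference.snps["SNP"].isin(shared).to_numpy()
    sub_panel = BetaPanel(
        snps=panel.snps[pm].reset_index(drop=True),
        diseases=panel.diseases,
        B=panel.B[pm],
        SE=panel.SE[pm],
        N=panel.N,
        harmonization_log=panel.harmonization_log,
    )
    sub_ref = reference.subset(np.flatnonzero(rm))
    if not np.array_equal(
        sub_panel.snps["SNP"].to_numpy(), sub_ref.snps["SNP"].to_numpy()
    ):
        raise AssertionError("alignment failed: divergent SNP order")
    return sub_panel, sub_ref


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sim_config_from_block(block: dict, seed: int | None) -> simulate.SimConfig:
    causal = [
        simulate.CausalGene(
            gene_index=int(c["gene"]), traits=tuple(c["traits"]), effect=float(c["effect"])
        )
        for c in block.get("causal_genes", [])
    ]
    kwargs = {
        k: block[k]
        for k in ("n_reference", "n_snps", "n_genes", "block_rho", "maf_range")
        if k in block
    }
    if "n_cohorts" in block:
        kwargs["n_cohorts"] = tuple(block["n_cohorts"])
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    return simulate.SimConfig(
        seed=int(block.get("seed", seed or 0)), causal_genes=causal, **kwargs
    )


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    resume: bool = False,
) -> RunManifest:
    """Run every stage; returns the manifest (also written to outdir)."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("seed")
    manifest = RunManifest(config_digest=_digest(config), seed=seed)

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    # ---- inputs ---------------------------------------------------------
    with stage("inputs"):
        if "simulate" in config:
            sim_cfg = _sim_config_from_block(config["simulate"], seed)
            reference = simulate.simulate_reference(sim_cfg)
            studies, truth, _ = simulate.simulate_gwas(sim_cfg)
            gene_list = simulate.gene_table(sim_cfg)
            (outdir / "truth.json").write_text(
                json.dumps(
                    {
                        "causal_gene_names": truth.causal_gene_names,
                        "causal_genes": [
                            {"gene": c.gene_index, "traits": list(c.traits),
                             "effect": c.effect}
                            for c in truth.causal_genes
                        ],
                    },
                    indent=2,
                )
            )
        else:
            studies = [
                read_sumstats(p, column_map=config.get("column_map"))
                for p in config["sumstats"]
            ]
            reference = load_reference(config["reference"])
            gene_list = read_gene_list(config["genes"])

    # ---- harmonize ------------------------------------------------------
    with stage("harmonize"):
        panel = harmonize(studies, config.get("ambiguous_policy", "drop"))
        panel, reference = align_to_reference(panel, reference)
    manifest.counts["snps_harmonized"] = panel.n_snps
    manifest.counts["diseases"] = panel.n_diseases

    # ---- trait correlation (all harmonized SNPs, pre-pruning) ----------
    with stage("sigma_yy"):
        std = cca.standardize_beta(panel)
        sigma_yy = cca.estimate_sigma_yy(std)

    # ---- prune ----------------------------------------------------------
    with stage("prune"):
        kept = prune(
            reference,
            window_snps=int(config.get("prune_window", 50)),
            step_snps=int(config.get("prune_step", 5)),
            r2_max=float(config.get("prune_r2", 0.2)),
        )
        pruned_path = outdir / "pruned_snps.txt"
        pruned_path.write_text(
            "\n".join(reference.snps["SNP"].iloc[kept]) + "\n"
        )
    manifest.counts["snps_pruned"] = int(len(kept))

    # ---- gene annotation ------------------------------------------------
    with stage("annotate"):
        genes, out_of_gene = assign_snps_to_genes(reference, gene_list)
    manifest.counts["genes_with_snps"] = len(genes)
    manifest.counts["snps_out_of_gene"] = int(len(out_of_gene))

    n_eff = cca.effective_n(panel.N, config.get("n_eff_rule", "min"))
    shrink_factor = float(config.get("shrink_factor", 0.999))

    # ---- SNP-level scan -------------------------------------------------
    snp_path = outdir / "snp_scan.tsv"
    with stage("snp_scan"):
        if resume and snp_path.exists():
            snp_results = pd.read_csv(snp_path, sep="\t")
        else:
            snp_results = cca.results_to_frame(
                cca.snp_scan(std, sigma_yy, kept, n_eff, shrink_factor)
            )
            snp_results.to_csv(snp_path, sep="\t", index=False, float_format="%.10e")
    manifest.counts["snps_scanned"] = len(snp_results)

    # ---- gene-level scan ------------------------------------------------
    gene_path = outdir / "gene_scan.tsv"
    with stage("gene_scan"):
        if resume and gene_path.exists():
            gene_results = pd.read_csv(gene_path, sep="\t")
        else:
            gene_results = cca.results_to_frame(
                cca.gene_scan(std, reference, genes, sigma_yy, kept, n_eff, shrink_factor)
            )
            gene_results.to_csv(gene_path, sep="\t", index=False, float_format="%.10e")
    manifest.counts["genes_scanned"] = len(gene_results)

    # ---- per-disease gene-based test -----------------------------------
    kept_mask = np.zeros(reference.n_snps, dtype=bool)
    kept_mask[kept] = True
    members_override = {
        g.name: g.member_snps[kept_mask[g.member_snps]] for g in genes
    }
    gt_path = outdir / "gene_disease_tests.tsv"
    with stage("gene_tests"):
        if resume and gt_path.exists():
            assoc = pd.read_csv(gt_path, sep="\t")
        else:
            assoc = genetest.gene_test_scan(
                panel,
                reference,
                genes,
                n_sims=int(config.get("n_sims", 10**6)),
                seed=seed,
                members_override=members_override,
            )
            assoc.to_csv(gt_path, sep="\t", index=False, float_format="%.10e")

    # ---- refine + report ------------------------------------------------
    with stage("refine"):
        rc = refine.RefineConfig(
            m_snps=max(len(snp_results), 1),
            m_genes=max(len(gene_results), 1),
            alpha=float(config.get("alpha", 0.05)),
            gene_p_threshold=float(config.get("gene_p_threshold", 1.0e-6)),
        )
        calls = refine.refine_pleiotropic(
            gene_results.rename(columns={"unit_id": "gene"})[["gene", "pvalue"]],
            assoc,
            rc,
            novelty_map=config.get("novelty_map"),
        )
        outputs = refine.emit_report(calls, gene_results, rc, outdir)
    manifest.counts["genes_selected"] = sum(c.selected for c in calls)
    manifest.counts["genes_multi_disease"] = sum(
        c.multi_disease for c in calls if c.selected
    )

    manifest.outputs = {
        "pruned_snps": str(pruned_path),
        "snp_scan": str(snp_path),
        "gene_scan": str(gene_path),
        "gene_disease_tests": str(gt_path),
        **{k: str(v) for k, v in outputs.items()},
    }
    sidecar = {
        "alpha": rc.alpha,
        "snp_threshold": rc.snp_threshold,
        "gene_threshold": rc.gene_threshold,
        "gene_p_threshold": rc.gene_p_threshold,
        "n_eff_rule": config.get("n_eff_rule", "min"),
        "n_eff": int(n_eff),
        "shrink_factor": shrink_factor,
        "seed": seed,
    }
    (outdir / "run_params.json").write_text(json.dumps(sidecar, indent=2))
    manifest.save(outdir / "manifest.json")
    return manifest
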