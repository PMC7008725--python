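"""Reading, validation and cross-study harmonization of GWAS summary statistics.

A *summary-statistic* file holds one univariate regression result per SNP
(effect estimate beta, its standard error, p-value and sample size) for one
disease/trait.  Multi-trait methods need those per-trait results aligned to a
single effect-allele convention; :func:`harmonize` builds that aligned panel,
flipping beta signs where a study reports the opposite allele orientation and
dropping strand-ambiguous (A/T, C/G) sites by default.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column names, in file order
REQUIRED_COLUMNS = ("SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "N")

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


class SumstatsFormatError(ValueError):
    """File-level problem: missing columns, unparseable rows."""


class SumstatsValidationError(ValueError):
    """Record-level problem: invalid SE, p-value or allele codes."""


@dataclass
class SummaryStats:
    """Univariate GWAS results for one disease.

    ``table`` columns: SNP, CHR, POS, A1 (effect allele), A2, BETA, SE, P, N.
    ``n`` is the scalar study sample size (median of the N column when that
    column varies per SNP).
    """

    disease: str
    table: pd.DataFrame
    n: int = 0

    def __post_init__(self) -> None:
        if self.n == 0 and len(self.table):
            self.n = int(self.table["N"].median())

    def __len__(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        t = self.table
        dup = t["SNP"][t["SNP"].duplicated()]
        if len(dup):
            raise SumstatsValidationError(
                f"{self.disease}: duplicate snp ids: {sorted(set(dup))[:5]}"
            )
        bad_se = t.loc[~(t["SE"] > 0), "SNP"]
        if len(bad_se):
            raise SumstatsValidationError(
                f"{self.disease}: SE must be > 0; offending snp ids: {list(bad_se)[:10]}"
            )
        bad_p = t.loc[~((t["P"] > 0) & (t["P"] <= 1)), "SNP"]
        if len(bad_p):
            raise SumstatsValidationError(
                f"{self.disease}: p-values must lie in (0, 1]; offending snp ids: {list(bad_p)[:10]}"
            )
        same = t.loc[t["A1"] == t["A2"], "SNP"]
        if len(same):
            raise SumstatsValidationError(
                f"{self.disease}: effect and other allele identical for: {list(same)[:10]}"
            )
        bad_allele = t.loc[
            ~(t["A1"].isin(_VALID_ALLELES) & t["A2"].isin(_VALID_ALLELES)), "SNP"
        ]
        if len(bad_allele):
            raise SumstatsValidationError(
                f"{self.disease}: non-ACGT allele codes for: {list(bad_allele)[:10]}"
            )


@dataclass
class BetaPanel:
    """Per-SNP regression results aligned across diseases.

    ``snps`` (columns SNP, CHR, POS, A1, A2) fixes the panel's effect-allele
    convention; ``B`` and ``SE`` are S x p matrices in that convention; ``N``
    holds the p per-study sample sizes.
    """

    snps: pd.DataFrame
    diseases: list[str]
    B: np.ndarray
    SE: np.ndarray
    N: np.ndarray
    harmonization_log: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def zscores(self) -> np.ndarray:
        """S x p matrix of per-study z-scores beta/se."""
        return self.B / self.SE


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    disease: str | None = None,
) -> SummaryStats:
    """Read one tab-delimited summary-statistic file.

    ``column_map`` maps file header names onto the canonical names
    (e.g. ``{"rsid": "SNP", "effect": "BETA"}``).  A missing P column is
    recomputed from beta/se; a per-SNP N column is reduced to the study
    median.  Raises :class:`SumstatsFormatError` for missing columns and
    :class:`SumstatsValidationError` (with snp ids) for bad records.
    """
    path = Path(path)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"SNP": str, "CHR": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "P"]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required column(s) {missing}")
    if "P" not in df.columns:
        from scipy import stats

        df["P"] = 2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
        log.warning("%s: no P column; recomputed from beta/se", path)

    bad = df.index[df[["BETA", "SE"]].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +2: header + 1-based
        raise SumstatsFormatError(f"{path}: missing beta/se on line(s) {lines[:10]}")

    df["CHR"] = df["CHR"].astype(str)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    df["POS"] = df["POS"].astype(np.int64)

    n_dup = int(df["SNP"].duplicated().sum())
    if n_dup:
        log.warning("%s: %d duplicate snp ids; keeping first occurrence", path, n_dup)
        df = df.drop_duplicates("SNP", keep="first").reset_index(drop=True)

    if df["N"].nunique() > 1:
        log.warning("%s: per-SNP N column; using study median", path)

    name = disease or path.name.split(".")[0]
    ss = SummaryStats(disease=name, table=df.reset_index(drop=True))
    ss.validate()
    return ss


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _AMBIGUOUS_PAIRS


def _chrom_key(chrom: str):
    """Natural chromosome ordering: numeric first, then X/Y/MT lexically."""
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def harmonize(
    studies: list[SummaryStats], ambiguous_policy: str = "drop"
) -> BetaPanel:
    """Align studies onto the SNPs present in all of them.

    The first study fixes the panel's effect-allele convention.  A later
    study's record matches either directly (same A1/A2) or swapped (A1/A2
    exchanged), in which case its beta sign is flipped.  Records whose allele
    pair cannot be reconciled are dropped, as are strand-ambiguous A/T and
    C/G SNPs under ``ambiguous_policy="drop"`` (the default; ``"keep"``
    retains them).  Rows come out sorted by (chrom, pos).
    """
    if not studies:
        raise ValueError("harmonize: need at least one study")
    if ambiguous_policy not in ("keep", "drop"):
        raise ValueError(f"ambiguous_policy must be keep|drop, got {ambiguous_policy!r}")
    for s in studies:
        s.validate()

    common = set(studies[0].table["SNP"])
    for s in studies[1:]:
        common &= set(s.table["SNP"])
    if not common:
        raise ValueError("harmonize: no common SNPs across studies")

    ref = studies[0].table.set_index("SNP")
    keep: list[str] = []
    n_ambiguous = 0
    n_mismatch = 0
    flip = {s.disease: [] for s in studies}

    tables = {s.disease: s.table.set_index("SNP") for s in studies}
    for snp in common:
        a1, a2 = ref.at[snp, "A1"], ref.at[snp, "A2"]
        if ambiguous_policy == "drop" and _is_ambiguous(a1, a2):
            n_ambiguous += 1
            continue
        ok = True
        flips = {}
        for s in studies[1:]:
            b1 = tables[s.disease].at[snp, "A1"]
            b2 = tables[s.disease].at[snp, "A2"]
            if (b1, b2) == (a1, a2):
                flips[s.disease] = False
            elif (b1, b2) == (a2, a1):
                flips[s.disease] = True
            else:
                ok = False
                break
        if not ok:
            n_mismatch += 1
            continue
        keep.append(snp)
        for d, f in flips.items():
            if f:
                flip[d].append(snp)

    if not keep:
        raise ValueError("harmonize: no common SNPs survive allele reconciliation")
    if n_mismatch:
        log.warning("harmonize: dropped %d SNPs with irreconcilable alleles", n_mismatch)

    meta = ref.loc[keep, ["CHR", "POS", "A1", "A2"]].reset_index()
    meta = meta.sort_values(
        by=["CHR", "POS", "SNP"], key=lambda c: c.map(_chrom_key) if c.name == "CHR" else c
    ).reset_index(drop=True)
    order = list(meta["SNP"])

    p = len(studies)
    B = np.empty((len(order), p))
    SE = np.empty((len(order), p))
    N = np.empty(p, dtype=np.int64)
    for j, s in enumerate(studies):
        t = tables[s.disease].loc[order]
        b = t["BETA"].to_numpy(dtype=float).copy()
        if flip[s.disease]:
            mask = np.isin(order, flip[s.disease])
            b[mask] = -b[mask]
        B[:, j] = b
        SE[:, j] = t["SE"].to_numpy(dtype=float)
        N[j] = s.n

    return BetaPanel(
        snps=meta,
        diseases=[s.disease for s in studies],
        B=B,
        SE=SE,
        N=N,
        harmonization_log={
            "n_common": len(common),
            "n_kept": len(order),
            "n_ambiguous_dropped": n_ambiguous,
            "n_allele_mismatch_dropped": n_mismatch,
            "n_sign_flipped": {d: len(v) for d, v in flip.items()},
        },
    )


def write_sumstats(panel: BetaPanel, directory: str | Path) -> list[Path]:
    """Write one read_sumstats-compatible file per disease, plus a JSON sidecar.

    Refuses an empty panel; output ordering follows the panel row order so a
    write/read/harmonize round-trip is exact.
    """
    if panel.n_snps == 0:
        raise ValueError("write_sumstats: refusing to write an empty panel")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from scipy import stats

    paths = []
    for j, disease in enumerate(panel.diseases):
        df = panel.snps.copy()
        df["BETA"] = panel.B[:, j]
        df["SE"] = panel.SE[:, j]
        df["P"] = 2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
        df["N"] = panel.N[j]
        out = directory / f"{disease}.sumstats.tsv"
        df[list(REQUIRED_COLUMNS)].to_csv(out, sep="\t", index=False, float_format="%.17g")
        paths.append(out)
    sidecar = directory / "panel.json"
    sidecar.write_text(
        json.dumps(
            {
                "diseases": panel.diseases,
                "N": [int(x) for x in panel.N],
                "harmonization_log": panel.harmonization_log,
            },
            indent=2,
        )
    )
    return paths


def read_panel(directory: str | Path) -> BetaPanel:
    """Re-assemble a harmonized panel written by :func:`write_sumstats`.

    Re-harmonizes with ``ambiguous_policy="keep"``: the written panel already
    reflects whatever ambiguity policy produced it, so re-reading must not
    drop further SNPs (harmonize is idempotent on its own output).
    """
    directory = Path(directory)
    meta = json.loads((directory / "panel.json").read_text())
    studies = [
        read_sumstats(directory / f"{d}.sumstats.tsv", disease=d)
        for d in meta["diseases"]
    ]
    for s, n in zip(studies, meta["N"]):
        s.n = int(n)
    return harmonize(studies, ambiguous_policy="keep")
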