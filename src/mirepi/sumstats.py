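"""Reading, harmonization, and QC of GWAS summary statistics.

Summary statistics are held as pandas DataFrames in the canonical 11-column
layout (SNP CHR BP A1 A2 BETA SE P N FRQ INFO) plus a derived Z column.
Harmonization aligns both traits' effect alleles to a reference panel's minor
allele, strand-flipping where that reconciles the alleles, and drops
strand-ambiguous (A/T, C/G) pairs and non-SNP records so that downstream
z-score products are orientation-consistent.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

CANONICAL = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "FRQ", "INFO"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_VALID = set("ACGT")


def _with_z(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["Z"] = np.where(df["SE"] > 0, df["BETA"] / df["SE"], 0.0)
    return df


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    n_default: float | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into the canonical layout.

    ``column_map`` maps file column names to canonical names (``OR`` is also
    recognized and converted to BETA = log OR).  Rows with unparseable or
    invalid numerics (SE <= 0, P outside (0, 1]) are dropped and the count is
    logged.  A per-SNP N column is optional when ``n_default`` is given.  When
    the file has no SE column, Z is recovered from P and the sign of BETA and
    SE is back-filled as BETA / Z.
    """
    raw = pd.read_csv(path, sep=sep)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    if "OR" in raw.columns and "BETA" not in raw.columns:
        raw["BETA"] = np.log(pd.to_numeric(raw["OR"], errors="coerce"))
    required = ["SNP", "A1", "A2", "BETA", "P"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    df = pd.DataFrame({"SNP": raw["SNP"].astype(str)})
    df["CHR"] = raw["CHR"].astype(str) if "CHR" in raw.columns else ""
    df["BP"] = pd.to_numeric(raw.get("BP", np.nan), errors="coerce")
    df["A1"] = raw["A1"].astype(str).str.upper()
    df["A2"] = raw["A2"].astype(str).str.upper()
    for col in ("BETA", "P"):
        df[col] = pd.to_numeric(raw[col], errors="coerce")
    df["SE"] = pd.to_numeric(raw["SE"], errors="coerce") if "SE" in raw.columns else np.nan
    if "N" in raw.columns:
        df["N"] = pd.to_numeric(raw["N"], errors="coerce")
    elif n_default is not None:
        df["N"] = float(n_default)
    else:
        raise ValueError("no N column and no n_default supplied")
    df["FRQ"] = pd.to_numeric(raw.get("FRQ", np.nan), errors="coerce")
    df["INFO"] = pd.to_numeric(raw.get("INFO", 1.0), errors="coerce")

    if "SE" not in raw.columns:
        z = np.sign(df["BETA"]) * norm.isf(df["P"] / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["SE"] = np.where(z != 0, df["BETA"] / z, np.nan)

    n0 = len(df)
    ok = (
        df["BETA"].notna()
        & df["SE"].notna()
        & (df["SE"] > 0)
        & df["P"].notna()
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & df["N"].notna()
    )
    df = df[ok]
    dropped = n0 - len(df)
    if dropped:
        log.info("read_sumstats: dropped %d unparseable/invalid row(s)", dropped)
    # duplicate snp ids: keep the record with the largest N
    df = df.sort_values("N", ascending=False, kind="stable").drop_duplicates("SNP")
    df = df.sort_index().reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("zero rows survive parsing")
    df.attrs["n_dropped"] = dropped
    return _with_z(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    df[CANONICAL].to_csv(path, sep="\t", index=False)


def _align_to_panel(ss: pd.DataFrame, panel_alleles: pd.DataFrame) -> pd.DataFrame:
    df = ss.merge(panel_alleles, on="SNP", how="inner", suffixes=("", "_panel"))
    a1, a2 = df["A1"].to_numpy(), df["A2"].to_numpy()
    snp_ok = (
        np.isin(a1, list(_VALID))
        & np.isin(a2, list(_VALID))
        & (a1 != a2)
    )
    ambiguous = np.array([(x, y) in _AMBIGUOUS for x, y in zip(a1, a2)], dtype=bool)
    p1, p2 = df["A1_panel"].to_numpy(), df["A2_panel"].to_numpy()

    same = (a1 == p1) & (a2 == p2)
    swap = (a1 == p2) & (a2 == p1)
    c1 = np.array([_COMPLEMENT.get(x, "N") for x in a1])
    c2 = np.array([_COMPLEMENT.get(x, "N") for x in a2])
    same_f = (c1 == p1) & (c2 == p2)
    swap_f = (c1 == p2) & (c2 == p1)

    keep = snp_ok & ~ambiguous & (same | swap | same_f | swap_f)
    flip = swap | swap_f
    df = df[keep].copy()
    flip = flip[keep]
    df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
    df.loc[flip, "Z"] = -df.loc[flip, "Z"]
    df.loc[flip, "FRQ"] = 1.0 - df.loc[flip, "FRQ"]
    df["A1"] = df["A1_panel"]
    df["A2"] = df["A2_panel"]
    df["CHR"] = df["CHR_panel"]
    df["BP"] = df["BP_panel"]
    return df.drop(columns=[c for c in df.columns if c.endswith("_panel")])


def harmonize(ss1: pd.DataFrame, ss2: pd.DataFrame, panel) -> tuple:
    """Align two traits' summary statistics to a panel's allele orientation.

    Intersects both tables with the panel on SNP id, orients effect alleles to
    the panel's minor allele (sign-flipping BETA/Z and complementing FRQ on
    swap), strand-flips A<->T / C<->G when that reconciles the alleles, and
    drops strand-ambiguous pairs, indels/non-SNPs, and irreconcilable records.
    Returns both tables restricted to the common SNPs, in panel order.
    """
    panel_alleles = pd.DataFrame(
        {
            "SNP": np.asarray(panel.snp_ids, dtype=str),
            "A1_panel": np.asarray(panel.a1, dtype=str),
            "A2_panel": np.asarray(panel.a2, dtype=str),
            "CHR_panel": np.asarray(panel.chrom, dtype=str),
            "BP_panel": np.asarray(panel.bp),
            "_order": np.arange(panel.n_snps),
        }
    )
    h1 = _align_to_panel(_with_z(ss1), panel_alleles)
    h2 = _align_to_panel(_with_z(ss2), panel_alleles)
    common = np.intersect1d(h1["SNP"], h2["SNP"])
    if len(common) == 0:
        raise ValueError("no SNPs shared between traits and panel after harmonization")
    h1 = h1[h1["SNP"].isin(common)].sort_values("_order").drop(columns="_order")
    h2 = h2[h2["SNP"].isin(common)].sort_values("_order").drop(columns="_order")
    return h1.reset_index(drop=True), h2.reset_index(drop=True)


def qc_filter(ss: pd.DataFrame, maf_min: float = 0.001, info_min: float = 0.9) -> pd.DataFrame:
    """Keep records with min(FRQ, 1-FRQ) > maf_min and INFO > info_min (strict)."""
    frq = ss["FRQ"]
    maf = np.minimum(frq, 1.0 - frq)
    keep = (maf > maf_min) & (ss["INFO"] > info_min)
    keep &= frq.notna() & ss["INFO"].notna()
    return ss[keep.fillna(False)].reset_index(drop=True)
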