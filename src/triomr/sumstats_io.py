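"""Reading, validation, standardization and harmonization of summary statistics.

Summary-statistics tables for the three omics layers (cis-eQTL, mQTL, GWAS)
share a common schema: one row per SNP x feature association carrying a
Z-score and a per-association sample size.  Effects are put on the
standardized (SD-per-SD) scale as ``beta = Z / sqrt(N)`` with sampling
variance ``1 / N``, which places molecular-QTL and GWAS effects on a common
scale for Mendelian randomization.

Only biallelic SNVs with A/C/G/T alleles are accepted; multi-allelic
variants and indels are rejected row-wise (the rejection report records
them).  Coordinates are 1-based, genome build GRCh37 unless the caller
records otherwise in the table metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AUTOSOMES = frozenset(str(i) for i in range(1, 23))
#: strand-ambiguous (palindromic) allele pairs
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

LAYERS = ("eqtl", "mqtl", "gwas")
_FEATURE_COLUMN = {"eqtl": "gene_id", "mqtl": "metabolite_id", "gwas": None}
_SHARED_COLUMNS = [
    "snp_id", "chr", "pos", "effect_allele", "other_allele",
    "zscore", "n", "pvalue",
]


class SchemaError(ValueError):
    """Input file violates the mandatory schema (fatal)."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP x trait association on the standardized scale."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    zscore: float
    n: int
    pvalue: float
    std_beta: float
    std_se: float

    @classmethod
    def from_row(cls, row: pd.Series) -> "SumStatRecord":
        return cls(
            snp_id=row["snp_id"], chromosome=row["chr"], position=int(row["pos"]),
            effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            zscore=float(row["zscore"]), n=int(row["n"]), pvalue=float(row["pvalue"]),
            std_beta=float(row["std_beta"]), std_se=float(row["std_se"]),
        )


@dataclass
class AssociationTable:
    """Validated association table for one omics layer.

    ``df`` holds one row per (feature_id, snp_id) with the canonical columns
    plus derived ``std_beta``/``std_se``.  ``rejections`` records rows dropped
    during validation, with the reason.
    """

    layer: str
    df: pd.DataFrame
    rejections: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def features(self) -> list[str]:
        return list(dict.fromkeys(self.df["feature_id"]))

    def feature_slice(self, feature_id: str) -> pd.DataFrame:
        """All records for one feature, indexed by snp_id."""
        out = self.df[self.df["feature_id"] == feature_id]
        out = out.set_index("snp_id", drop=False)
        out.index.name = None
        return out


def two_sided_p(zscore):
    """Two-sided p-value under the standard normal, vectorized."""
    z = np.abs(np.asarray(zscore, dtype=float))
    return 2.0 * ndtr(-z)


def standardize_effect(zscore, n):
    """Standardized effect and its SE from a Z-score and sample size.

    ``std_beta = Z / sqrt(N)``, ``std_se = 1 / sqrt(N)``.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr <= 1):
        raise ValueError("sample size must be >= 2 to standardize effects")
    root_n = np.sqrt(n_arr)
    z = np.asarray(zscore, dtype=float)
    beta = z / root_n
    se = 1.0 / root_n
    if np.isscalar(zscore) or (beta.ndim == 0):
        return float(beta), float(se)
    return beta, se


def _validate_rows(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split raw rows into valid records and a rejection report."""
    reasons = pd.Series("", index=raw.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        bad = mask & (reasons == "")
        reasons[bad] = reason

    ea = raw["effect_allele"].astype(str).str.upper()
    oa = raw["other_allele"].astype(str).str.upper()
    _flag(~ea.isin(VALID_BASES) | ~oa.isin(VALID_BASES), "allele not a single A/C/G/T base")
    _flag(ea == oa, "effect_allele equals other_allele")

    pos = pd.to_numeric(raw["pos"], errors="coerce")
    _flag(pos.isna() | (pos < 1) | (pos != pos.round()), "position not a positive integer")

    z = pd.to_numeric(raw["zscore"], errors="coerce")
    _flag(~np.isfinite(z.fillna(np.inf)), "zscore not finite")

    n = pd.to_numeric(raw["n"], errors="coerce")
    _flag(n.isna() | (n < 2) | (n != n.round()), "sample size not an integer >= 2")

    pstr = raw["pvalue"].astype(str).str.strip()
    p_missing = pstr.isin({".", "", "nan", "NA"})
    p = pd.to_numeric(raw["pvalue"], errors="coerce")
    _flag(~p_missing & (p.isna() | (p < 0) | (p > 1)), "pvalue outside [0, 1]")

    _flag(raw["chr"].astype(str).str.strip() == "", "missing chromosome")
    _flag(raw["snp_id"].astype(str).str.strip() == "", "missing snp_id")

    valid = reasons == ""
    df = raw.loc[valid].copy()
    df["effect_allele"] = ea[valid]
    df["other_allele"] = oa[valid]
    df["chr"] = df["chr"].astype(str).str.strip()
    df["pos"] = pos[valid].astype(np.int64)
    df["zscore"] = z[valid].astype(float)
    df["n"] = n[valid].astype(np.int64)
    # stored p wins when present; otherwise derive from Z (two-sided normal)
    derived = two_sided_p(df["zscore"].to_numpy())
    df["pvalue"] = np.where(p_missing[valid], derived, p[valid].astype(float))
    df["std_beta"], df["std_se"] = standardize_effect(
        df["zscore"].to_numpy(), df["n"].to_numpy()
    )

    rej = raw.loc[~valid, ["snp_id"]].copy()
    rej["reason"] = reasons[~valid]
    return df.reset_index(drop=True), rej.reset_index(drop=True)


def read_association_table(
    path: str | Path, layer: str, feature_id: str | None = None,
    build: str = "GRCh37",
) -> AssociationTable:
    """Read and validate a tab-separated summary-statistics file.

    ``layer`` selects the schema: eQTL files carry a leading ``gene_id``
    column, mQTL files ``metabolite_id``; GWAS files carry one phenotype per
    file whose name is given by ``feature_id`` (defaults to the file stem).
    Missing p-values are encoded as ``.`` and derived from the Z-score.
    Rows violating record invariants are dropped and logged, never fatal;
    schema violations (missing columns, duplicated (feature, snp) pairs,
    empty files) are fatal.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)

    feature_col = _FEATURE_COLUMN[layer]
    expected = ([feature_col] if feature_col else []) + _SHARED_COLUMNS
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if len(raw) == 0:
        raise SchemaError(f"{path}: empty table")

    if feature_col:
        raw = raw.rename(columns={feature_col: "feature_id"})
    else:
        raw = raw.copy()
        raw["feature_id"] = feature_id if feature_id is not None else path.stem.removesuffix(".tsv")

    dup = raw.duplicated(subset=["feature_id", "snp_id"])
    if dup.any():
        pairs = raw.loc[dup, ["feature_id", "snp_id"]].head(5).to_records(index=False)
        raise SchemaError(f"{path}: duplicate (feature, snp) pairs, e.g. {list(pairs)}")

    df, rej = _validate_rows(raw)
    if len(df) == 0:
        raise SchemaError(f"{path}: no valid rows after validation")
    if len(rej):
        logger.warning("%s: rejected %d row(s) during validation", path, len(rej))

    cols = ["feature_id"] + _SHARED_COLUMNS + ["std_beta", "std_se"]
    return AssociationTable(
        layer=layer, df=df[cols], rejections=rej,
        meta={"path": str(path), "build": build},
    )


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write a validated table back to the layer's TSV schema."""
    feature_col = _FEATURE_COLUMN[table.layer]
    out = table.df[["feature_id"] + _SHARED_COLUMNS].copy()
    if feature_col:
        out = out.rename(columns={"feature_id": feature_col})
    else:
        out = out.drop(columns=["feature_id"])
    out.to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame, drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Align exposure and outcome effects to a shared effect allele.

    Both inputs are feature slices (one feature each) with allele columns and
    ``std_beta``/``std_se``.  SNPs present in both are retained; outcome
    effects are sign-flipped when the outcome's (effect, other) alleles are
    swapped relative to the exposure, strand complements are tried before
    dropping, and mismatching or (optionally) strand-ambiguous A/T / C/G
    pairs are dropped, as are non-autosomal SNPs.

    Returns one row per retained SNP with exposure-oriented alleles and
    columns ``beta_exposure``/``gamma_outcome`` plus their SEs, sample sizes
    and p-values.
    """
    exp = exposure.reset_index(drop=True)
    out = outcome.reset_index(drop=True)
    merged = exp.merge(
        out, on="snp_id", suffixes=("_exp", "_out"), how="inner", validate="1:1"
    )
    if len(merged) == 0:
        return _empty_harmonized()

    merged = merged[merged["chr_exp"].isin(AUTOSOMES)]

    ea_e, oa_e = merged["effect_allele_exp"], merged["other_allele_exp"]
    ea_o, oa_o = merged["effect_allele_out"], merged["other_allele_out"]
    comp = lambda s: s.map(COMPLEMENT)

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    comp_same = (comp(ea_o) == ea_e) & (comp(oa_o) == oa_e)
    comp_swapped = (comp(ea_o) == oa_e) & (comp(oa_o) == ea_e)

    flip = (~same & swapped) | (~same & ~swapped & ~comp_same & comp_swapped)
    keep = same | swapped | comp_same | comp_swapped
    if drop_ambiguous:
        ambiguous = [
            (a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea_e, oa_e)
        ]
        keep &= ~pd.Series(ambiguous, index=merged.index)

    merged = merged[keep]
    sign = np.where(flip[keep], -1.0, 1.0)

    res = pd.DataFrame({
        "snp_id": merged["snp_id"],
        "chr": merged["chr_exp"],
        "pos": merged["pos_exp"],
        "effect_allele": merged["effect_allele_exp"],
        "other_allele": merged["other_allele_exp"],
        "beta_exposure": merged["std_beta_exp"].to_numpy(),
        "se_exposure": merged["std_se_exp"].to_numpy(),
        "n_exposure": merged["n_exp"].to_numpy(),
        "pvalue_exposure": merged["pvalue_exp"].to_numpy(),
        "gamma_outcome": sign * merged["std_beta_out"].to_numpy(),
        "se_outcome": merged["std_se_out"].to_numpy(),
        "n_outcome": merged["n_out"].to_numpy(),
        "pvalue_outcome": merged["pvalue_out"].to_numpy(),
    }).reset_index(drop=True)
    return res


def _empty_harmonized() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "snp_id", "chr", "pos", "effect_allele", "other_allele",
        "beta_exposure", "se_exposure", "n_exposure", "pvalue_exposure",
        "gamma_outcome", "se_outcome", "n_outcome", "pvalue_outcome",
    ])


def concat_tables(tables: list[AssociationTable]) -> AssociationTable:
    """Concatenate same-layer tables (e.g. several one-phenotype GWAS files)."""
    layers = {t.layer for t in tables}
    if len(layers) != 1:
        raise ValueError(f"cannot concatenate mixed layers: {layers}")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    if df.duplicated(subset=["feature_id", "snp_id"]).any():
        raise SchemaError("duplicate (feature, snp) pairs across concatenated tables")
    rej = pd.concat([t.rejections for t in tables], ignore_index=True)
    return AssociationTable(layer=layers.pop(), df=df, rejections=rej,
                            meta={"paths": [t.meta.get("path") for t in tables]})
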