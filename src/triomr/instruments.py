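"""Instrumental-variable selection: significance filters and LD pruning.

Instruments for each exposure are autosomal, non-strand-ambiguous SNPs
passing the layer significance threshold (cis-eQTL p < 1.8e-5, mQTL
p < 1e-7), greedily pruned to pairwise r^2 < 0.01.  After pruning the LD
matrix is approximated by the identity, which is what the downstream IVW
estimator uses.  SNPs with larger standardized effects on the outcome than
on the exposure are removed as likely reverse-causal or confounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats_io import AMBIGUOUS_PAIRS, AUTOSOMES

P_THRESHOLD_EQTL = 1.8e-5
P_THRESHOLD_MQTL = 1.0e-7
R2_MAX = 0.01
MIN_IVS = 3


class InsufficientInstruments(Exception):
    """Exposure left with fewer than ``min_ivs`` instruments (recorded, not fatal)."""

    def __init__(self, exposure_id: str, n_surviving: int, stage: str):
        self.exposure_id = exposure_id
        self.n_surviving = n_surviving
        self.stage = stage
        super().__init__(
            f"{exposure_id}: only {n_surviving} instrument(s) survive {stage}"
        )


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered SNP list."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} SNPs")
        if k and not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 diagonal must be 1")
        if k and not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise ValueError("r2 must be symmetric")
        if k and (self.r2.min() < -1e-9 or self.r2.max() > 1 + 1e-9):
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def submatrix(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass
class InstrumentSet:
    """Pruned, significant IVs for one exposure."""

    exposure_id: str
    snp_ids: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    ld: LDMatrix

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se_beta = np.asarray(self.se_beta, dtype=float)

    def __len__(self) -> int:
        return len(self.snp_ids)


def ld_from_genotypes(dosages: pd.DataFrame) -> LDMatrix:
    """Pairwise r^2 from a samples x SNPs dosage matrix (0/1/2).

    Constant SNP columns are excluded with a warning (their correlation is
    undefined).
    """
    X = dosages.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate LD")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(dosages.columns, keep) if not k]
        warnings.warn(f"excluding constant SNP column(s) from LD: {dropped}")
    cols = [c for c, k in zip(dosages.columns, keep) if k]
    r = np.corrcoef(X[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    r2 = np.clip(r ** 2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(cols, r2)


def greedy_prune(candidates: pd.DataFrame, ld: LDMatrix, r2_max: float = R2_MAX) -> list[str]:
    """Greedy LD pruning in ascending p-value order.

    ``candidates`` needs columns ``snp_id`` and ``pvalue``.  Candidates are
    visited from most to least significant (p ties broken lexicographically
    by snp_id); a candidate is kept iff its r^2 with every already-kept SNP
    is below ``r2_max``.  The kept list preserves visit order.
    """
    order = candidates[["snp_id", "pvalue"]].sort_values(
        ["pvalue", "snp_id"], kind="mergesort"
    )
    kept: list[str] = []
    for snp in order["snp_id"]:
        if all(ld.lookup(snp, k) < r2_max for k in kept):
            kept.append(snp)
    return kept


def select_instruments(
    table_slice: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float,
    r2_max: float = R2_MAX,
    min_ivs: int = MIN_IVS,
    exposure_id: str | None = None,
) -> InstrumentSet:
    """Select significant, independent instruments for one exposure.

    ``table_slice`` is an AssociationTable feature slice.  Filters to
    autosomal, non-strand-ambiguous SNPs with p below the layer threshold
    that are covered by the LD reference, then greedy-prunes at ``r2_max``.
    Raises :class:`InsufficientInstruments` when fewer than ``min_ivs``
    survive.  The attached LD is the identity when pruning removed at least
    one candidate (the post-pruning approximation), otherwise the r^2
    submatrix.
    """
    df = table_slice
    if exposure_id is None:
        exposure_id = str(df["feature_id"].iloc[0]) if len(df) else "<empty>"

    mask = df["chr"].isin(AUTOSOMES)
    amb = [
        (a, b) in AMBIGUOUS_PAIRS
        for a, b in zip(df["effect_allele"], df["other_allele"])
    ]
    mask &= ~pd.Series(amb, index=df.index)
    mask &= df["pvalue"] < p_threshold
    cand = df[mask]

    not_in_ld = [s for s in cand["snp_id"] if s not in ld]
    if not_in_ld:
        warnings.warn(
            f"{exposure_id}: {len(not_in_ld)} significant SNP(s) missing from LD reference"
        )
        cand = cand[~cand["snp_id"].isin(not_in_ld)]

    if len(cand) < min_ivs:
        raise InsufficientInstruments(exposure_id, len(cand), "significance/QC filters")

    kept = greedy_prune(cand, ld, r2_max=r2_max)
    if len(kept) < min_ivs:
        raise InsufficientInstruments(exposure_id, len(kept), "LD pruning")

    pruned_any = len(kept) < len(cand)
    sub = cand.set_index("snp_id").loc[kept]
    ld_out = LDMatrix.identity(kept) if pruned_any else ld.submatrix(kept)
    return InstrumentSet(
        exposure_id=exposure_id,
        snp_ids=kept,
        beta=sub["std_beta"].to_numpy(),
        se_beta=sub["std_se"].to_numpy(),
        ld=ld_out,
    )


def reverse_effect_filter(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop SNPs whose outcome effect exceeds the exposure effect in magnitude.

    A |gamma| > |beta| instrument on the standardized scale suggests reverse
    causality or confounding; retained rows satisfy |gamma| <= |beta|.
    Order-preserving and idempotent.
    """
    keep = pairs["gamma_outcome"].abs() <= pairs["beta_exposure"].abs()
    return pairs[keep].reset_index(drop=True)
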