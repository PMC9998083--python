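"""Multivariable MR mediation: direct effects and the dilution-corrected slope.

Including a mediating metabolite and its instruments alongside a transcript
in one multivariable regression isolates the transcript's *direct* effect on
the phenotype:

    alpha = (B' C^-1 B)^-1 (B' C^-1 gamma)

where ``B`` is n x 2 (column 1: transcript effects, column 2: metabolite
effects over the joint instrument list) and the direct effect is the first
element.  The indirect (mediated) effect is defined by subtraction from the
univariable total effect, so total = direct + indirect holds exactly.

Across many triplets, the proportion of the total effect that is direct is
the through-origin regression slope of direct on total effects.  Because the
total effects are themselves estimates, that slope is attenuated; the
errors-in-variables correction divides it by

    1 - sum(SE(total)^2) / sum(total^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import InstrumentSet, LDMatrix, R2_MAX
from .mr_core import _as_matrix, _cho_solve
from .sumstats_io import two_sided_p

MIN_IVS_MVMR = 3
CONDITION_LIMIT = 1e6


class CollinearityError(ValueError):
    """The two exposure columns are too collinear for a stable MVMR fit."""


class DilutionUndefinedError(ValueError):
    """Noise-to-signal ratio >= 1: the dilution correction is undefined."""


@dataclass
class JointInstruments:
    """Union instrument list for one transcript-metabolite pair."""

    snp_ids: list[str]
    B: np.ndarray          # n x 2 standardized effects (transcript, metabolite)
    C: np.ndarray          # LD matrix over the union (identity after pruning)
    var_B: np.ndarray      # n x 2 sampling variances
    dropped: list[tuple[str, str]] = field(default_factory=list)


def build_joint_instruments(
    transcript_ivs: InstrumentSet,
    metabolite_ivs: InstrumentSet,
    ld: LDMatrix,
    transcript_effects: pd.DataFrame,
    metabolite_effects: pd.DataFrame,
    r2_max: float = R2_MAX,
    min_ivs_mvmr: int = MIN_IVS_MVMR,
) -> JointInstruments:
    """Union the two instrument sets and assemble the n x 2 effect matrix.

    Cross-set SNP pairs in LD (r^2 >= ``r2_max``) are resolved by keeping the
    transcript-set member (the transcript is the exposure whose direct effect
    is the estimand).  Effects for every retained SNP are looked up in the
    full per-feature effect frames (indexed by snp_id, columns ``std_beta``
    and ``std_se``), not only the instrument entries; SNPs missing from
    either frame are dropped with a warning.
    """
    dropped: list[tuple[str, str]] = []
    t_set = list(transcript_ivs.snp_ids)
    union: list[str] = list(t_set)
    for snp in metabolite_ivs.snp_ids:
        if snp in union:
            continue
        conflict = any(
            snp in ld and t in ld and ld.lookup(snp, t) >= r2_max for t in t_set
        )
        if conflict:
            dropped.append((snp, "cross-set LD with transcript instrument"))
            continue
        union.append(snp)

    rows = []
    kept: list[str] = []
    for snp in union:
        if snp not in transcript_effects.index or snp not in metabolite_effects.index:
            dropped.append((snp, "missing cross-layer effect"))
            continue
        t_row = transcript_effects.loc[snp]
        m_row = metabolite_effects.loc[snp]
        rows.append((
            float(t_row["std_beta"]), float(m_row["std_beta"]),
            float(t_row["std_se"]) ** 2, float(m_row["std_se"]) ** 2,
        ))
        kept.append(snp)
    if dropped:
        warnings.warn(f"joint instruments: dropped {len(dropped)} SNP(s)")
    if len(kept) < min_ivs_mvmr:
        raise ValueError(
            f"only {len(kept)} joint instrument(s) remain (< {min_ivs_mvmr})"
        )
    arr = np.asarray(rows, dtype=float)
    return JointInstruments(
        snp_ids=kept, B=arr[:, :2], C=np.eye(len(kept)), var_B=arr[:, 2:],
        dropped=dropped,
    )


def mvmr_direct_effect(
    B, gamma, C=None, var_B=None, var_gamma=None,
) -> tuple[float, float]:
    """Direct effect (first exposure) and its delta-method variance.

    Solves ``alpha = (B' C^-1 B)^-1 B' C^-1 gamma`` and returns
    ``(alpha[0], var(alpha[0]))``.  The variance combines the outcome-noise
    term ``S^-1 B'C^-1 diag(var_gamma) C^-1 B S^-1`` with exposure-noise
    gradient terms: differentiating alpha with respect to entry B[i, k]
    gives ``S^-1 (e_k r_i - (C^-1 B)[i]  alpha_k)`` with
    ``r = C^-1 (gamma - B alpha)``.
    """
    B = np.asarray(B, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    n, p = B.shape
    if p != 2:
        raise ValueError("B must have exactly 2 columns")
    if n < MIN_IVS_MVMR:
        raise ValueError(f"{n} instruments < {MIN_IVS_MVMR}")
    C = _as_matrix(C, n)

    Ci_B = _cho_solve(C, B)
    S = B.T @ Ci_B
    # collinearity screen on the whitened design
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT**2:
        raise CollinearityError(
            f"exposure columns nearly collinear (cond(B'C^-1 B) = {cond:.3g})"
        )
    Sinv = np.linalg.solve(S, np.eye(2))
    alpha = Sinv @ (Ci_B.T @ gamma)

    if var_gamma is None:
        var_gamma = np.zeros(n)
    var_gamma = np.broadcast_to(np.asarray(var_gamma, dtype=float), (n,))
    J_g = Sinv @ Ci_B.T                      # 2 x n
    cov_out = (J_g * var_gamma) @ J_g.T

    var_exp0 = 0.0
    if var_B is not None:
        var_B = np.asarray(var_B, dtype=float)
        r = _cho_solve(C, gamma - B @ alpha)
        # gradient of alpha[0] wrt B[i, k]
        term1 = np.outer(r, Sinv[0, :])                      # n x 2
        term2 = np.outer(Ci_B @ Sinv[0, :], alpha)           # n x 2
        G0 = term1 - term2
        var_exp0 = float(np.sum(G0**2 * var_B))

    return float(alpha[0]), max(float(cov_out[0, 0]) + var_exp0, 0.0)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition for one triplet."""

    transcript_id: str
    metabolite_id: str
    phenotype_id: str
    total_effect: float
    direct_effect: float
    indirect_effect: float
    proportion_direct: float
    se_total: float = np.nan
    se_direct: float = np.nan
    se_indirect: float = np.nan
    p_total: float = np.nan
    p_direct: float = np.nan
    n_ivs_mvmr: int = 0
    proportion_defined: bool = True


def decompose(
    total: float, direct: float,
    transcript_id: str = "", metabolite_id: str = "", phenotype_id: str = "",
    se_total: float = np.nan, se_direct: float = np.nan, n_ivs_mvmr: int = 0,
) -> MediationResult:
    """Mediation decomposition: indirect = total - direct (exact by definition)."""
    indirect = total - direct
    defined = abs(total) >= 1e-12
    proportion = direct / total if defined else np.nan
    se_ind = float(np.sqrt(se_total**2 + se_direct**2)) if np.isfinite(se_total) else np.nan
    p_total = float(two_sided_p(total / se_total)) if se_total and np.isfinite(se_total) and se_total > 0 else np.nan
    p_direct = float(two_sided_p(direct / se_direct)) if se_direct and np.isfinite(se_direct) and se_direct > 0 else np.nan
    return MediationResult(
        transcript_id=transcript_id, metabolite_id=metabolite_id,
        phenotype_id=phenotype_id,
        total_effect=float(total), direct_effect=float(direct),
        indirect_effect=float(indirect), proportion_direct=proportion,
        se_total=se_total, se_direct=se_direct, se_indirect=se_ind,
        p_total=p_total, p_direct=p_direct,
        n_ivs_mvmr=n_ivs_mvmr, proportion_defined=defined,
    )


@dataclass
class DilutionFit:
    """Through-origin slope of direct on total effects, dilution-corrected."""

    slope_raw: float
    slope_corrected: float
    se_terms: float
    signal_terms: float
    ci_low: float
    ci_high: float
    n_triplets: int
    n_boot: int
    intercept_used: bool = False


def _origin_slope(direct: np.ndarray, total: np.ndarray, intercept: bool) -> float:
    if intercept:
        x = np.column_stack([np.ones_like(total), total])
        coef, *_ = np.linalg.lstsq(x, direct, rcond=None)
        return float(coef[1])
    return float(np.sum(direct * total) / np.sum(total**2))


def dilution_corrected_slope(
    direct_effects, total_effects, se_totals,
    n_boot: int = 2000, seed=None, intercept: bool = False,
) -> DilutionFit:
    """Proportion of direct effect across triplets, corrected for dilution.

    Regression of direct on total effects (through the origin by default);
    the raw slope is divided by ``1 - sum(SE(total)^2) / sum(total^2)`` to
    undo errors-in-variables attenuation from noise in the total-effect
    estimates.  The CI is a percentile bootstrap over triplets.
    """
    d = np.asarray(direct_effects, dtype=float)
    t = np.asarray(total_effects, dtype=float)
    se = np.asarray(se_totals, dtype=float)
    if not (len(d) == len(t) == len(se)) or len(d) < 3:
        raise ValueError("need equal-length vectors of at least 3 triplets")
    if np.any(se < 0):
        raise ValueError("se_totals must be nonnegative")

    def corrected(di, ti, si):
        raw = _origin_slope(di, ti, intercept)
        se_terms = float(np.sum(si**2))
        signal = float(np.sum(ti**2))
        ratio = se_terms / signal
        if ratio >= 1:
            raise DilutionUndefinedError(
                f"noise-to-signal ratio {ratio:.3g} >= 1"
            )
        return raw, raw / (1.0 - ratio), se_terms, signal

    raw, corr, se_terms, signal = corrected(d, t, se)

    rng = np.random.default_rng(seed)
    boot = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, len(d), size=len(d))
        try:
            boot[b] = corrected(d[idx], t[idx], se[idx])[1]
        except DilutionUndefinedError:
            continue
    ok = boot[np.isfinite(boot)]
    if len(ok):
        lo, hi = np.percentile(ok, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return DilutionFit(
        slope_raw=raw, slope_corrected=corr,
        se_terms=se_terms, signal_terms=signal,
        ci_low=float(lo), ci_high=float(hi),
        n_triplets=len(d), n_boot=n_boot, intercept_used=intercept,
    )
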