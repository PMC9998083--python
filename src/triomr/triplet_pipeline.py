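"""Scan orchestration, FDR control, triplet assembly and mediation.

Three univariable MR scans are run: transcript->metabolite (TM),
metabolite->phenotype (MP) and transcript->phenotype (TP).  Each scan
BH-adjusts its p-values over the full family of instrumentable
exposure x outcome pairs.  Causal triplets are the inner join of
FDR-significant TM and MP hits on the shared metabolite; the composite
false-discovery rate of a triplet surviving two independent 5% screens is
1 - 0.95^2 = 9.75%.  A significant TP link is *not* required: triplets
whose total effect is not individually detectable are the method's main
gain over transcriptome-wide MR alone, and the TP fit (when the pair was
tested) is attached with its q-value for reporting.

For every triplet the mediation stage builds the joint instrument set,
estimates the MVMR direct effect, decomposes the TP total into direct +
indirect, and finally regresses direct on total effects across triplets
with the dilution correction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments as iv
from . import mr_core, mvmr_mediation, sumstats_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, loadable from flat YAML."""

    p_threshold_eqtl: float = iv.P_THRESHOLD_EQTL
    p_threshold_mqtl: float = iv.P_THRESHOLD_MQTL
    r2_max: float = iv.R2_MAX
    min_ivs: int = iv.MIN_IVS
    min_ivs_mvmr: int = mvmr_mediation.MIN_IVS_MVMR
    fdr_level: float = 0.05
    alpha_q: float = mr_core.Q_ALPHA
    drop_ambiguous: bool = True
    dilution_intercept: bool = False
    n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def p_threshold(self, layer: str) -> float:
        return {"eqtl": self.p_threshold_eqtl, "mqtl": self.p_threshold_mqtl}[layer]


def bh_fdr(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values.

    ``m`` is the family size; when larger than ``len(pvalues)`` the missing
    tests are implicitly assigned p = 1 (they occupy the top ranks), which
    lets scan families count instrumentable pairs that produced no fit.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-D vector")
    if len(p) and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m cannot be smaller than len(pvalues)")
    if k == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


@dataclass
class ScanResult:
    """One univariable MR scan with BH q-values over the full pair family."""

    scan: str                       # "TM", "MP" or "TP"
    results: pd.DataFrame           # one row per completed exposure x outcome fit
    tested_pair_count: int
    audit: pd.DataFrame             # rejected exposures / skipped pairs
    fits: dict = field(default_factory=dict)   # (exposure, outcome) -> MRFit

    def hits(self, q_level: float) -> pd.DataFrame:
        return self.results[self.results["qvalue"] <= q_level]


_RESULT_COLUMNS = [
    "exposure_id", "outcome_id", "alpha_hat", "se_alpha", "z_stat", "pvalue",
    "n_ivs_initial", "n_ivs_final", "removed_snps", "qc_flags", "qvalue",
]


def select_scan_instruments(
    exposures: sumstats_io.AssociationTable,
    ld: iv.LDMatrix,
    config: PipelineConfig,
) -> tuple[dict[str, iv.InstrumentSet], list[dict]]:
    """Instrument every exposure feature; return sets and an audit of rejections."""
    p_thr = config.p_threshold(exposures.layer)
    sets: dict[str, iv.InstrumentSet] = {}
    audit: list[dict] = []
    for fid in exposures.features():
        try:
            sets[fid] = iv.select_instruments(
                exposures.feature_slice(fid), ld, p_thr,
                r2_max=config.r2_max, min_ivs=config.min_ivs, exposure_id=fid,
            )
        except iv.InsufficientInstruments as exc:
            audit.append({
                "stage": "instrument_selection", "exposure_id": fid,
                "outcome_id": "", "reason": str(exc),
            })
    return sets, audit


def scan(
    exposures: sumstats_io.AssociationTable,
    outcomes: sumstats_io.AssociationTable,
    ld: iv.LDMatrix,
    config: PipelineConfig,
    name: str,
    instrument_sets: dict[str, iv.InstrumentSet] | None = None,
) -> ScanResult:
    """Univariable MR of every instrumentable exposure against every outcome.

    The FDR family is all instrumentable-exposure x outcome pairs; pairs
    that cannot be fitted after harmonization and the reverse-effect filter
    are audited and count in the BH denominator with an implicit p = 1.
    """
    if instrument_sets is None:
        instrument_sets, audit = select_scan_instruments(exposures, ld, config)
    else:
        audit = []
    if not instrument_sets:
        raise RuntimeError(
            f"scan {name}: no instrumentable exposures "
            f"(see audit: {len(audit)} rejections)"
        )
    outcome_ids = outcomes.features()
    outcome_slices = {oid: outcomes.feature_slice(oid) for oid in outcome_ids}
    exposure_slices = {
        eid: exposures.feature_slice(eid) for eid in instrument_sets
    }
    tested_pair_count = len(instrument_sets) * len(outcome_ids)

    rows = []
    fits: dict[tuple[str, str], mr_core.MRFit] = {}
    for eid, inst in instrument_sets.items():
        exp_slice = exposure_slices[eid].loc[
            lambda d: d["snp_id"].isin(inst.snp_ids)
        ]
        for oid in outcome_ids:
            pairs = sumstats_io.harmonize(
                exp_slice, outcome_slices[oid],
                drop_ambiguous=config.drop_ambiguous,
            )
            pairs = iv.reverse_effect_filter(pairs)
            if len(pairs) < config.min_ivs:
                audit.append({
                    "stage": "pair_fit", "exposure_id": eid, "outcome_id": oid,
                    "reason": f"{len(pairs)} instruments after harmonization"
                              f"/reverse-effect filter (< {config.min_ivs})",
                })
                continue
            fit = mr_core.run_univariable_mr(
                eid, oid,
                pairs["beta_exposure"].to_numpy(),
                pairs["se_exposure"].to_numpy(),
                pairs["gamma_outcome"].to_numpy(),
                pairs["se_outcome"].to_numpy(),
                snp_ids=pairs["snp_id"].tolist(),
                min_ivs=config.min_ivs, alpha_q=config.alpha_q,
            )
            fits[(eid, oid)] = fit
            rows.append({
                "exposure_id": eid, "outcome_id": oid,
                "alpha_hat": fit.alpha_hat, "se_alpha": fit.se_alpha,
                "z_stat": fit.z_stat, "pvalue": fit.pvalue,
                "n_ivs_initial": fit.n_ivs_initial,
                "n_ivs_final": fit.n_ivs_final,
                "removed_snps": ",".join(s for _, s in fit.q_diag.removal_order),
                "qc_flags": ";".join(fit.q_diag.flags),
            })
    results = pd.DataFrame(rows, columns=_RESULT_COLUMNS[:-1])
    results["qvalue"] = (
        bh_fdr(results["pvalue"].to_numpy(), m=tested_pair_count)
        if len(results) else np.array([])
    )
    return ScanResult(
        scan=name, results=results, tested_pair_count=tested_pair_count,
        audit=pd.DataFrame(audit, columns=["stage", "exposure_id", "outcome_id",
                                           "reason"]),
        fits=fits,
    )


def composite_fdr(q_level: float, n_screens: int = 2) -> float:
    """FDR of an object surviving ``n_screens`` independent screens at ``q_level``:
    1 - (1 - q_level)^n_screens."""
    if not 0 <= q_level <= 1:
        raise ValueError("q_level must lie in [0, 1]")
    if n_screens < 1:
        raise ValueError("n_screens must be >= 1")
    return 1.0 - (1.0 - q_level) ** n_screens


@dataclass
class Triplet:
    """A transcript-metabolite-phenotype causal chain passing both screens."""

    transcript_id: str
    metabolite_id: str
    phenotype_id: str
    tm_row: pd.Series
    mp_row: pd.Series
    tp_row: pd.Series | None = None
    mediation: mvmr_mediation.MediationResult | None = None
    concordant: bool | None = None
    mediation_flag: str = ""


def assemble_triplets(
    tm: ScanResult, mp: ScanResult, tp: ScanResult | None = None,
    q_level: float = 0.05,
) -> list[Triplet]:
    """Join FDR-significant TM and MP hits on the shared metabolite.

    The TP fit is attached whenever the transcript-phenotype pair was tested,
    significant or not; the concordance flag (sign(alpha_TM * alpha_MP) ==
    sign(alpha_TP)) is computed only when the TP link itself passes the FDR
    level.
    """
    tm_hits = tm.hits(q_level)
    mp_hits = mp.hits(q_level)
    tp_index: dict[tuple[str, str], pd.Series] = {}
    if tp is not None:
        for _, row in tp.results.iterrows():
            tp_index[(row["exposure_id"], row["outcome_id"])] = row

    triplets = []
    for _, tm_row in tm_hits.iterrows():
        linked = mp_hits[mp_hits["exposure_id"] == tm_row["outcome_id"]]
        for _, mp_row in linked.iterrows():
            tp_row = tp_index.get((tm_row["exposure_id"], mp_row["outcome_id"]))
            concordant = None
            if tp_row is not None and tp_row["qvalue"] <= q_level:
                concordant = bool(
                    np.sign(tm_row["alpha_hat"] * mp_row["alpha_hat"])
                    == np.sign(tp_row["alpha_hat"])
                )
            triplets.append(Triplet(
                transcript_id=tm_row["exposure_id"],
                metabolite_id=tm_row["outcome_id"],
                phenotype_id=mp_row["outcome_id"],
                tm_row=tm_row, mp_row=mp_row, tp_row=tp_row,
                concordant=concordant,
            ))
    return triplets


def run_mediation_stage(
    triplets: list[Triplet],
    eqtl: sumstats_io.AssociationTable,
    mqtl: sumstats_io.AssociationTable,
    gwas: sumstats_io.AssociationTable,
    ld: iv.LDMatrix,
    config: PipelineConfig,
    transcript_instruments: dict[str, iv.InstrumentSet] | None = None,
    metabolite_instruments: dict[str, iv.InstrumentSet] | None = None,
) -> mvmr_mediation.DilutionFit | None:
    """Fill each triplet's MediationResult and fit the dilution-corrected slope.

    Per triplet: union of the transcript's and the metabolite's instruments
    (cross-set LD conflicts resolved in the transcript's favour), metabolite
    and GWAS effects harmonized to the transcript's allele orientation, the
    MVMR direct effect, then decomposition against the TWMR total from the
    TP scan.  MVMR failures flag the triplet and leave its mediation empty.
    Returns the across-triplet dilution fit (None when fewer than 3 triplets
    have both a mediation result and a TP total).
    """
    if transcript_instruments is None:
        transcript_instruments, _ = select_scan_instruments(eqtl, ld, config)
    if metabolite_instruments is None:
        metabolite_instruments, _ = select_scan_instruments(mqtl, ld, config)

    eqtl_slices: dict[str, pd.DataFrame] = {}
    mqtl_slices: dict[str, pd.DataFrame] = {}
    gwas_slices: dict[str, pd.DataFrame] = {}

    for trip in triplets:
        tid, mid, pid = trip.transcript_id, trip.metabolite_id, trip.phenotype_id
        if trip.tp_row is None:
            trip.mediation_flag = "no_tp_fit"
            continue
        t_inst = transcript_instruments.get(tid)
        m_inst = metabolite_instruments.get(mid)
        if t_inst is None or m_inst is None:
            trip.mediation_flag = "missing_instrument_set"
            continue
        t_slice = eqtl_slices.setdefault(tid, eqtl.feature_slice(tid))
        m_slice = mqtl_slices.setdefault(mid, mqtl.feature_slice(mid))
        g_slice = gwas_slices.setdefault(pid, gwas.feature_slice(pid))
        union = list(dict.fromkeys([*t_inst.snp_ids, *m_inst.snp_ids]))
        t_at_union = t_slice[t_slice["snp_id"].isin(union)]
        # harmonize both other layers to the transcript's allele orientation
        m_h = sumstats_io.harmonize(
            t_at_union, m_slice, drop_ambiguous=config.drop_ambiguous,
        ).set_index("snp_id")
        g_h = sumstats_io.harmonize(
            t_at_union, g_slice, drop_ambiguous=config.drop_ambiguous,
        ).set_index("snp_id")
        shared = [s for s in union if s in m_h.index and s in g_h.index]
        t_eff = pd.DataFrame({
            "std_beta": m_h.loc[shared, "beta_exposure"],
            "std_se": m_h.loc[shared, "se_exposure"],
        })
        m_eff = pd.DataFrame({
            "std_beta": m_h.loc[shared, "gamma_outcome"],
            "std_se": m_h.loc[shared, "se_outcome"],
        })
        try:
            joint = mvmr_mediation.build_joint_instruments(
                t_inst, m_inst, ld, t_eff, m_eff,
                r2_max=config.r2_max, min_ivs_mvmr=config.min_ivs_mvmr,
            )
            gamma = g_h.loc[joint.snp_ids, "gamma_outcome"].to_numpy()
            var_gamma = g_h.loc[joint.snp_ids, "se_outcome"].to_numpy() ** 2
            direct, var_direct = mvmr_mediation.mvmr_direct_effect(
                joint.B, gamma, joint.C, var_B=joint.var_B, var_gamma=var_gamma,
            )
        except (ValueError, mr_core.LDDecompositionError) as exc:
            trip.mediation_flag = f"mvmr_rejected: {exc}"
            logger.warning("triplet %s-%s-%s: %s", tid, mid, pid, exc)
            continue
        trip.mediation = mvmr_mediation.decompose(
            total=float(trip.tp_row["alpha_hat"]), direct=direct,
            transcript_id=tid, metabolite_id=mid, phenotype_id=pid,
            se_total=float(trip.tp_row["se_alpha"]),
            se_direct=float(np.sqrt(var_direct)),
            n_ivs_mvmr=len(joint.snp_ids),
        )

    done = [t for t in triplets if t.mediation is not None]
    if len(done) < 3:
        return None
    return mvmr_mediation.dilution_corrected_slope(
        [t.mediation.direct_effect for t in done],
        [t.mediation.total_effect for t in done],
        [t.mediation.se_total for t in done],
        n_boot=config.n_boot, seed=config.seed,
        intercept=config.dilution_intercept,
    )


def triplets_to_frame(triplets: list[Triplet]) -> pd.DataFrame:
    """Flatten triplets (and their mediation, when present) for TSV export."""
    rows = []
    for t in triplets:
        row = {
            "transcript_id": t.transcript_id,
            "metabolite_id": t.metabolite_id,
            "phenotype_id": t.phenotype_id,
            "alpha_tm": t.tm_row["alpha_hat"], "q_tm": t.tm_row["qvalue"],
            "alpha_mp": t.mp_row["alpha_hat"], "q_mp": t.mp_row["qvalue"],
            "alpha_tp": t.tp_row["alpha_hat"] if t.tp_row is not None else np.nan,
            "q_tp": t.tp_row["qvalue"] if t.tp_row is not None else np.nan,
            "concordant": t.concordant,
            "mediation_flag": t.mediation_flag,
        }
        m = t.mediation
        row.update({
            "total_effect": m.total_effect if m else np.nan,
            "se_total": m.se_total if m else np.nan,
            "direct_effect": m.direct_effect if m else np.nan,
            "se_direct": m.se_direct if m else np.nan,
            "indirect_effect": m.indirect_effect if m else np.nan,
            "proportion_direct": m.proportion_direct if m else np.nan,
            "n_ivs_mvmr": m.n_ivs_mvmr if m else 0,
        })
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    tm: ScanResult
    mp: ScanResult
    tp: ScanResult
    triplets: list[Triplet]
    dilution: mvmr_mediation.DilutionFit | None


def run_pipeline(
    eqtl: sumstats_io.AssociationTable,
    mqtl: sumstats_io.AssociationTable,
    gwas: sumstats_io.AssociationTable,
    ld: iv.LDMatrix,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """The full discovery pipeline: three scans, triplets, mediation, dilution."""
    config = config or PipelineConfig()
    t_sets, t_audit = select_scan_instruments(eqtl, ld, config)
    m_sets, m_audit = select_scan_instruments(mqtl, ld, config)
    tm = scan(eqtl, mqtl, ld, config, "TM", instrument_sets=t_sets)
    tm.audit = pd.concat([pd.DataFrame(t_audit, columns=tm.audit.columns), tm.audit],
                         ignore_index=True)
    mp = scan(mqtl, gwas, ld, config, "MP", instrument_sets=m_sets)
    mp.audit = pd.concat([pd.DataFrame(m_audit, columns=mp.audit.columns), mp.audit],
                         ignore_index=True)
    tp = scan(eqtl, gwas, ld, config, "TP", instrument_sets=t_sets)
    triplets = assemble_triplets(tm, mp, tp, q_level=config.fdr_level)
    dilution = run_mediation_stage(
        triplets, eqtl, mqtl, gwas, ld, config,
        transcript_instruments=t_sets, metabolite_instruments=m_sets,
    )
    return PipelineResult(tm=tm, mp=mp, tp=tp, triplets=triplets,
                          dilution=dilution)
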