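"""Planted-truth synthetic multi-omics studies for end-to-end testing.

Generates a genotype reference panel with block LD structure and matched
cis-eQTL / mQTL / GWAS summary-statistics tables in which a known causal
chain (transcript -> metabolite -> phenotype) is planted.  Effects are
generated directly on the standardized scale: each feature's instrument
effects are scaled so their squared sum equals the feature's heritability,
marginal effects propagate through the chain (metabolite = own instruments
+ sum of upstream transcript effects x alpha_TM; phenotype = direct +
mediated), and each layer observes the true marginal effect plus
Normal(0, 1/N_layer) estimation noise per SNP.  A truth table records every
planted effect and the implied totals.

LD within a panel block is induced by allele copying: every SNP in a block
copies each of its two allele draws from the block's index SNP with
probability sqrt(r), otherwise draws fresh at the block MAF.  This
preserves the marginal MAF exactly and gives pairwise dosage correlation
~ r within the block (r between the index SNP and members is sqrt(r)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats_io import AssociationTable, two_sided_p

_NONAMBIGUOUS_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

N_EQTL_DEFAULT = 31_684
N_MQTL_DEFAULT = 8_000
N_GWAS_DEFAULT = 300_000


@dataclass
class ReferencePanel:
    """Genotype dosage panel plus its variant map."""

    dosages: pd.DataFrame      # samples x SNPs, values 0/1/2
    variants: pd.DataFrame     # snp_id, chr, pos, effect_allele, other_allele, maf, block

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)


def generate_reference_panel(
    n_samples: int = 1000,
    n_snps: int = 300,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 5,
    within_block_r: float = 0.0,
    ambiguous_fraction: float = 0.0,
    seed=None,
) -> ReferencePanel:
    """Dosage panel with independent LD blocks and a variant map.

    Positions are 1-based and spaced 10 kb; blocks cycle through the 22
    autosomes.  ``ambiguous_fraction`` of SNPs receive A/T or C/G allele
    pairs (useful for harmonization tests); the rest are non-ambiguous.
    """
    if n_samples < 50:
        raise ValueError("need at least 50 panel samples")
    if not 0 <= within_block_r < 1:
        raise ValueError("within_block_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    q_copy = np.sqrt(within_block_r)

    n_blocks = int(np.ceil(n_snps / ld_block_size))
    dosage = np.empty((n_samples, n_snps), dtype=np.int8)
    rows = []
    snp = 0
    for b in range(n_blocks):
        size = min(ld_block_size, n_snps - b * ld_block_size)
        maf_block = rng.uniform(*maf_range)
        index_alleles = rng.random((n_samples, 2)) < maf_block
        chrom = str(b % 22 + 1)
        for k in range(size):
            if within_block_r > 0:
                maf = maf_block
                fresh = rng.random((n_samples, 2)) < maf
                copy = rng.random((n_samples, 2)) < q_copy
                alleles = np.where(copy, index_alleles, fresh)
            else:
                maf = rng.uniform(*maf_range)
                alleles = rng.random((n_samples, 2)) < maf
            dosage[:, snp] = alleles.sum(axis=1)
            if rng.random() < ambiguous_fraction:
                ea, oa = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
            else:
                ea, oa = _NONAMBIGUOUS_PAIRS[rng.integers(len(_NONAMBIGUOUS_PAIRS))]
            rows.append({
                "snp_id": f"rs{snp + 1:06d}", "chr": chrom,
                "pos": (snp + 1) * 10_000, "effect_allele": ea,
                "other_allele": oa, "maf": maf, "block": b,
            })
            snp += 1
    variants = pd.DataFrame(rows)
    dosages = pd.DataFrame(
        dosage, columns=variants["snp_id"].tolist(),
        index=[f"sample{i + 1}" for i in range(n_samples)],
    )
    dosages.index.name = "sample_id"
    return ReferencePanel(dosages=dosages, variants=variants)


@dataclass
class TranscriptTruth:
    gene_id: str
    h2: float = 0.06
    n_causal_snps: int = 6
    snp_ids: list[str] | None = None
    beta: np.ndarray | None = None


@dataclass
class MetaboliteTruth:
    metabolite_id: str
    h2: float = 0.04
    n_causal_snps: int = 5
    alpha_tm: dict[str, float] = field(default_factory=dict)
    snp_ids: list[str] | None = None
    beta: np.ndarray | None = None


@dataclass
class PhenotypeTruth:
    name: str
    direct: dict[str, float] = field(default_factory=dict)
    alpha_mp: dict[str, float] = field(default_factory=dict)


@dataclass
class TruthSpec:
    """Planted causal structure and per-layer study sizes."""

    transcripts: list[TranscriptTruth]
    metabolites: list[MetaboliteTruth]
    phenotypes: list[PhenotypeTruth]
    n_eqtl: int = N_EQTL_DEFAULT
    n_mqtl: int = N_MQTL_DEFAULT
    n_gwas: int = N_GWAS_DEFAULT
    seed: int | None = None

    def __post_init__(self):
        ids = (
            [t.gene_id for t in self.transcripts]
            + [m.metabolite_id for m in self.metabolites]
            + [p.name for p in self.phenotypes]
        )
        if len(ids) != len(set(ids)):
            raise ValueError("feature identifiers must be unique across layers")
        for t in self.transcripts:
            if not 0 < t.h2 < 1:
                raise ValueError(f"{t.gene_id}: h2 must lie in (0, 1)")
        for m in self.metabolites:
            if not 0 < m.h2 < 1:
                raise ValueError(f"{m.metabolite_id}: h2 must lie in (0, 1)")
        known_t = {t.gene_id for t in self.transcripts}
        known_m = {m.metabolite_id for m in self.metabolites}
        for m in self.metabolites:
            unknown = set(m.alpha_tm) - known_t
            if unknown:
                raise ValueError(f"{m.metabolite_id}: unknown transcripts {unknown}")
        for p in self.phenotypes:
            if set(p.direct) - known_t or set(p.alpha_mp) - known_m:
                raise ValueError(f"{p.name}: references undefined features")


@dataclass
class SyntheticStudy:
    """Generated summary statistics plus the planted-truth bookkeeping."""

    eqtl: AssociationTable
    mqtl: AssociationTable
    gwas: AssociationTable
    truth_table: pd.DataFrame
    panel: ReferencePanel
    truth: TruthSpec


def _assign_instruments(panel: ReferencePanel, truth: TruthSpec, rng) -> None:
    """Fill in causal SNPs and scaled effects for features lacking them.

    Instruments are drawn one per LD block (so planted instruments are
    mutually independent) without reuse across features; effects are drawn
    Normal and rescaled so sum(beta^2) = h2 exactly.
    """
    variants = panel.variants
    nonambiguous = variants[
        ~variants.apply(
            lambda r: (r["effect_allele"], r["other_allele"]) in _AMBIGUOUS_PAIRS,
            axis=1,
        )
    ]
    block_reps = nonambiguous.groupby("block").head(1)  # one candidate per block
    pool = block_reps["snp_id"].tolist()
    rng.shuffle(pool)
    taken = 0

    def draw(n: int) -> list[str]:
        nonlocal taken
        if taken + n > len(pool):
            raise ValueError(
                "reference panel has too few LD blocks for the requested instruments"
            )
        out = pool[taken:taken + n]
        taken += n
        return out

    for feat in [*truth.transcripts, *truth.metabolites]:
        if feat.snp_ids is None:
            n = len(feat.beta) if feat.beta is not None else feat.n_causal_snps
            feat.snp_ids = draw(n)
        if feat.beta is None:
            # near-equal magnitudes: planted instruments emulate QTLs that
            # pass their layer's significance threshold (Normal-drawn effects
            # would leave many below it at realistic N)
            k = len(feat.snp_ids)
            raw = rng.choice([-1.0, 1.0], size=k) * rng.uniform(0.95, 1.05, size=k)
            feat.beta = raw * np.sqrt(feat.h2 / np.sum(raw**2))
        else:
            feat.beta = np.asarray(feat.beta, dtype=float)
            total = float(np.sum(feat.beta**2))
            if total >= 1.0:
                raise ValueError(
                    f"instrument variance {total:.3f} >= 1 over-allocates heritability"
                )


def _marginal_vectors(panel: ReferencePanel, truth: TruthSpec):
    """True standardized marginal effect of every panel SNP, per feature."""
    snps = panel.snp_ids
    idx = {s: i for i, s in enumerate(snps)}
    t_marg = {}
    for t in truth.transcripts:
        v = np.zeros(len(snps))
        v[[idx[s] for s in t.snp_ids]] = t.beta
        t_marg[t.gene_id] = v
    m_marg = {}
    for m in truth.metabolites:
        v = np.zeros(len(snps))
        v[[idx[s] for s in m.snp_ids]] = m.beta
        for gid, a_tm in m.alpha_tm.items():
            v = v + a_tm * t_marg[gid]
        m_marg[m.metabolite_id] = v
    p_marg = {}
    for p in truth.phenotypes:
        v = np.zeros(len(snps))
        for gid, a in p.direct.items():
            v = v + a * t_marg[gid]
        for mid, a in p.alpha_mp.items():
            v = v + a * m_marg[mid]
        p_marg[p.name] = v
    return t_marg, m_marg, p_marg


def _layer_table(
    panel: ReferencePanel, marginals: dict[str, np.ndarray], n: int,
    layer: str, rng, noise: bool,
) -> AssociationTable:
    variants = panel.variants
    frames = []
    for fid, true_eff in marginals.items():
        obs = true_eff.copy()
        if noise:
            obs = obs + rng.normal(0.0, np.sqrt(1.0 / n), size=len(obs))
        z = obs * np.sqrt(n)
        df = pd.DataFrame({
            "feature_id": fid,
            "snp_id": variants["snp_id"],
            "chr": variants["chr"],
            "pos": variants["pos"],
            "effect_allele": variants["effect_allele"],
            "other_allele": variants["other_allele"],
            "zscore": z,
            "n": n,
            "pvalue": two_sided_p(z),
            "std_beta": obs,
            "std_se": 1.0 / np.sqrt(n),
        })
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return AssociationTable(
        layer=layer, df=df, rejections=pd.DataFrame(columns=["snp_id", "reason"]),
        meta={"synthetic": True, "n": n},
    )


def _truth_table(truth: TruthSpec) -> pd.DataFrame:
    """Every planted (transcript, metabolite, phenotype) path with implied totals."""
    rows = []
    m_by_id = {m.metabolite_id: m for m in truth.metabolites}
    for p in truth.phenotypes:
        for t in truth.transcripts:
            direct = p.direct.get(t.gene_id, 0.0)
            mediated = 0.0
            for m in truth.metabolites:
                a_tm = m.alpha_tm.get(t.gene_id, 0.0)
                a_mp = p.alpha_mp.get(m.metabolite_id, 0.0)
                mediated += a_tm * a_mp
            total = direct + mediated
            for m in truth.metabolites:
                a_tm = m.alpha_tm.get(t.gene_id, 0.0)
                a_mp = p.alpha_mp.get(m.metabolite_id, 0.0)
                if a_tm == 0.0 and a_mp == 0.0 and direct == 0.0:
                    continue
                rows.append({
                    "transcript_id": t.gene_id,
                    "metabolite_id": m.metabolite_id,
                    "phenotype_id": p.name,
                    "alpha_tm": a_tm, "alpha_mp": a_mp,
                    "direct": direct, "mediated_total": mediated,
                    "implied_total": total,
                })
    return pd.DataFrame(
        rows, columns=[
            "transcript_id", "metabolite_id", "phenotype_id",
            "alpha_tm", "alpha_mp", "direct", "mediated_total", "implied_total",
        ],
    )


def generate_multiomics_sumstats(
    panel: ReferencePanel, truth: TruthSpec, seed=None, noise: bool = True,
) -> SyntheticStudy:
    """Generate eQTL, mQTL and GWAS tables with a planted causal chain."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    _assign_instruments(panel, truth, rng)
    t_marg, m_marg, p_marg = _marginal_vectors(panel, truth)
    eqtl = _layer_table(panel, t_marg, truth.n_eqtl, "eqtl", rng, noise)
    mqtl = _layer_table(panel, m_marg, truth.n_mqtl, "mqtl", rng, noise)
    gwas = _layer_table(panel, p_marg, truth.n_gwas, "gwas", rng, noise)
    return SyntheticStudy(
        eqtl=eqtl, mqtl=mqtl, gwas=gwas,
        truth_table=_truth_table(truth), panel=panel, truth=truth,
    )


# ---------------------------------------------------------------------------
# presets

def triplet_truth(
    n_transcripts: int = 5, n_metabolites: int = 4,
    alpha_tm: float = 0.3, alpha_mp: float = 0.2, direct: float = 0.0,
    seed: int | None = None,
) -> TruthSpec:
    """One planted transcript->metabolite->phenotype chain among null features."""
    transcripts = [TranscriptTruth(f"gene{i + 1}") for i in range(n_transcripts)]
    metabolites = [MetaboliteTruth(f"met{i + 1}") for i in range(n_metabolites)]
    metabolites[0].alpha_tm = {"gene1": alpha_tm}
    phenotype = PhenotypeTruth(
        "phenotype1", direct={"gene1": direct}, alpha_mp={"met1": alpha_mp},
    )
    return TruthSpec(transcripts, metabolites, [phenotype], seed=seed)


def null_truth(
    n_transcripts: int = 100, n_metabolites: int = 10, seed: int | None = None,
) -> TruthSpec:
    """Global null: every feature instrumented, no cross-layer effects."""
    return TruthSpec(
        [TranscriptTruth(f"gene{i + 1}") for i in range(n_transcripts)],
        [MetaboliteTruth(f"met{i + 1}") for i in range(n_metabolites)],
        [PhenotypeTruth("phenotype1")],
        seed=seed,
    )


def hub_truth(seed: int | None = None) -> TruthSpec:
    """One transcript feeding several metabolites that hit the same phenotype,
    mimicking a desaturase-locus style mQTL hub."""
    transcripts = [TranscriptTruth(f"gene{i + 1}") for i in range(6)]
    metabolites = [MetaboliteTruth(f"met{i + 1}") for i in range(5)]
    for i, a in enumerate([-0.5, -0.35, -0.3]):
        metabolites[i].alpha_tm = {"gene1": a}
    phenotype = PhenotypeTruth(
        "phenotype1",
        direct={"gene1": 0.01},
        alpha_mp={"met1": 0.1, "met2": 0.08, "met3": 0.12},
    )
    return TruthSpec(transcripts, metabolites, [phenotype], seed=seed)


def generate_dilution_dataset(
    n_triplets: int = 500, proportion_direct: float = 0.8,
    total_sd: float = 0.08, se_total: float = 0.03, se_direct: float = 0.01,
    seed=None,
) -> pd.DataFrame:
    """Triplet-level effect estimates with known direct-effect proportion.

    True total effects are Normal(0, total_sd^2); true direct effects are
    ``proportion_direct`` times the total.  Observed totals and directs add
    independent Normal noise with the stated SEs, so the through-origin
    slope of observed direct on observed total is attenuated by the classic
    errors-in-variables factor that the dilution correction undoes.
    """
    rng = np.random.default_rng(seed)
    total_true = rng.normal(0.0, total_sd, size=n_triplets)
    direct_true = proportion_direct * total_true
    total_obs = total_true + rng.normal(0.0, se_total, size=n_triplets)
    direct_obs = direct_true + rng.normal(0.0, se_direct, size=n_triplets)
    return pd.DataFrame({
        "triplet_id": [f"triplet{i + 1}" for i in range(n_triplets)],
        "total_true": total_true, "direct_true": direct_true,
        "total_effect": total_obs, "se_total": se_total,
        "direct_effect": direct_obs, "se_direct": se_direct,
    })


PRESETS = ("triplet", "null", "fads-like-hub", "dilution")


def write_preset(preset: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit a ready-to-run fixture: panel TSV, three summary-stat TSVs,
    truth table and a config file (or, for ``dilution``, a triplet-effects
    table)."""
    from .sumstats_io import write_association_table
    from .triplet_pipeline import PipelineConfig

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if preset == "dilution":
        df = generate_dilution_dataset(seed=seed)
        paths["triplet_effects"] = out_dir / "triplet_effects.tsv"
        df.to_csv(paths["triplet_effects"], sep="\t", index=False)
        return paths

    if preset == "triplet":
        truth = triplet_truth(seed=seed)
        panel = generate_reference_panel(n_samples=1000, n_snps=120,
                                         ld_block_size=1, seed=seed)
    elif preset == "null":
        truth = null_truth(seed=seed)
        panel = generate_reference_panel(n_samples=1000, n_snps=700,
                                         ld_block_size=1, seed=seed)
    elif preset == "fads-like-hub":
        truth = hub_truth(seed=seed)
        panel = generate_reference_panel(n_samples=1000, n_snps=150,
                                         ld_block_size=1, seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")

    study = generate_multiomics_sumstats(panel, truth, seed=seed)
    paths["panel"] = out_dir / "panel.tsv"
    panel.dosages.to_csv(paths["panel"], sep="\t")
    # the GWAS schema carries no phenotype column; the file stem names it
    gwas_stem = truth.phenotypes[0].name
    for name, stem, table in (("eqtl", "eqtl", study.eqtl),
                              ("mqtl", "mqtl", study.mqtl),
                              ("gwas", gwas_stem, study.gwas)):
        paths[name] = out_dir / f"{stem}.tsv"
        write_association_table(table, paths[name])
    paths["truth"] = out_dir / "truth.tsv"
    study.truth_table.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = out_dir / "config.yaml"
    PipelineConfig(seed=seed).to_yaml(paths["config"])
    return paths
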