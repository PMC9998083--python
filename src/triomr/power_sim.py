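"""Monte-Carlo power comparison: direct MR versus two-step mediation.

A transcript affects a phenotype partly through a metabolite.  Two
parameters index the scenario grid: ``rho``, the proportion of the total
transcript-phenotype effect (``alpha_tp``) that is direct, and ``sigma``,
the ratio of the transcript-to-metabolite to the metabolite-to-phenotype
effect.  For each cell the engine simulates the three univariable MR
analyses (transcript->phenotype "TP", transcript->metabolite "TM",
metabolite->phenotype "MP") on summary statistics drawn on the standardized
scale and compares

    power_diff = power_TP - power_TM * power_MP,

the advantage of the direct transcriptome-wide test over requiring both
links of the mediation chain to reach significance.

Per-instrument exposure effects are drawn as Normal(0, h2 / n_ivs) so their
expected squared sum equals the exposure heritability; observed outcome
effects add Normal(0, 1/N_outcome) estimation noise, and (optionally)
observed exposure effects add Normal(0, 1/N_exposure) noise.  Every
simulated fit runs the same IVW + delta-variance + heterogeneity-filter
machinery as the real pipeline (the filter can be disabled for speed).

Two readings of the chain-effect parameterization are provided.  The
``literal`` mode uses the printed recipes ``alpha_tm = alpha_tp (1-rho)
sigma`` and ``alpha_mp = alpha_tp (1-rho) / sigma``; note their product is
``(alpha_tp (1-rho))^2`` and their ratio ``sigma^2``.  The ``consistent``
mode instead solves the two constraints ``alpha_tm * alpha_mp =
alpha_tp (1-rho)`` and ``alpha_tm / alpha_mp = sigma`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.stats import chi2, norm

from . import mr_core

RHO_GRID_DEFAULT = (-2.0, 2.0, 51)
SIGMA_GRID_DEFAULT = (0.1, 10.0, 51)


@dataclass
class SimulationScenario:
    """One point of the power-comparison design (defaults = study conditions)."""

    rho: float = 0.0
    sigma: float = 1.0
    alpha_tp: float = 0.035
    h2_transcript: float = 0.06
    h2_metabolite: float = 0.04
    n_ivs_transcript: int = 6
    n_ivs_metabolite: int = 5
    n_gwas: int = 300_000
    n_eqtl: int = 32_000
    n_mqtl: int = 8_000
    n_transcripts: int = 500
    n_metabolites: int = 80
    n_repeats: int = 10
    alpha_level: float = 0.05
    effect_mode: str = "literal"
    exposure_noise: bool = True
    q_filter: bool = True
    mp_budget: int = 4_000
    min_ivs: int = 3
    alpha_q: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for h2 in (self.h2_transcript, self.h2_metabolite):
            if not 0 < h2 < 1:
                raise ValueError("heritabilities must lie in (0, 1)")
        for n in (self.n_gwas, self.n_eqtl, self.n_mqtl):
            if n < 2:
                raise ValueError("sample sizes must be >= 2")
        if self.effect_mode not in ("literal", "consistent"):
            raise ValueError("effect_mode must be 'literal' or 'consistent'")


def derive_chain_effects(scenario: SimulationScenario) -> tuple[float, float]:
    """Transcript->metabolite and metabolite->phenotype effects for a scenario."""
    a_tp, rho, sigma = scenario.alpha_tp, scenario.rho, scenario.sigma
    if scenario.effect_mode == "literal":
        return a_tp * (1 - rho) * sigma, a_tp * (1 - rho) / sigma
    prod = a_tp * (1 - rho)
    a_tm = np.sqrt(abs(prod) * sigma)
    a_mp = np.sqrt(abs(prod) / sigma)
    if prod < 0:
        a_mp = -a_mp
    return float(a_tm), float(a_mp)


def _fit_ivw_identity(
    b: np.ndarray, g: np.ndarray, var_b: float, var_g: float,
    min_ivs: int, q_filter: bool, q_crit: np.ndarray,
) -> float:
    """Fast identity-C univariable MR; returns the causal-effect Z statistic.

    Mirrors :func:`triomr.mr_core.run_univariable_mr` exactly (same
    estimator, delta variance, global-Q-gated heterogeneity loop and
    tie-breaks) for the common simulation case of scalar variances and
    identity LD.  ``q_crit[k]`` is the chi-square critical value at k
    degrees of freedom.
    """
    while True:
        s = b @ b
        u = b @ g
        a = u / s
        J_b = (g - 2.0 * a * b) / s
        var_a = var_g / s + var_b * (J_b @ J_b)
        if not q_filter:
            break
        d = g - a * b
        var_d = var_g + b**2 * var_a + var_g * a**2 + var_b * var_a
        T = d**2 / var_d
        if T.sum() <= q_crit[len(b) - 1] or len(b) <= min_ivs:
            break
        worst = np.lexsort((np.abs(b), -np.abs(d)))[0]
        b = np.delete(b, worst)
        g = np.delete(g, worst)
    return a / np.sqrt(var_a)


def simulate_univariable_power(
    effect: float, h2: float, n_ivs: int, n_exposure: int, n_outcome: int,
    n_reps: int, alpha_level: float = 0.05, exposure_noise: bool = True,
    seed=None, q_filter: bool = True, min_ivs: int = 3, alpha_q: float = 0.05,
) -> float:
    """Fraction of simulated MR fits reaching p < alpha_level.

    Per repetition: true per-IV exposure effects ~ Normal(0, h2/n_ivs);
    observed outcome effects = effect * true + Normal(0, 1/n_outcome);
    observed exposure effects add Normal(0, 1/n_exposure) noise when
    ``exposure_noise``.  Each repetition is fit with the pipeline's IVW
    machinery (delta-method SE, optional heterogeneity filter).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    b_true = rng.normal(0.0, np.sqrt(h2 / n_ivs), size=(n_reps, n_ivs))
    g_obs = effect * b_true + rng.normal(0.0, np.sqrt(1.0 / n_outcome),
                                         size=(n_reps, n_ivs))
    if exposure_noise:
        b_obs = b_true + rng.normal(0.0, np.sqrt(1.0 / n_exposure),
                                    size=(n_reps, n_ivs))
        var_b = 1.0 / n_exposure
    else:
        b_obs = b_true
        var_b = 0.0
    var_g = 1.0 / n_outcome
    # q_crit[k] = critical value for a k-instrument set (df = k - 1)
    q_crit = np.concatenate([[np.inf], chi2.isf(alpha_q, df=np.arange(1, n_ivs))])
    z_crit = float(norm.isf(alpha_level / 2.0))
    hits = 0
    for r in range(n_reps):
        z = _fit_ivw_identity(
            b_obs[r], g_obs[r], var_b, var_g, min_ivs, q_filter, q_crit,
        )
        hits += abs(z) > z_crit
    return hits / n_reps


def analytic_power_oracle(
    effect: float, h2: float, n_ivs: int, n_outcome: int,
    alpha_level: float = 0.05, n_draws: int = 100_000, seed=None,
) -> float:
    """Closed-form power check for the no-exposure-noise regime.

    Conditional on the instruments, the IVW Z statistic is
    Normal(|effect| * sqrt(N_outcome * sum(beta^2)), 1) with
    sum(beta^2) ~ (h2/n_ivs) * chi^2(n_ivs); power averages the two-sided
    normal tail over draws of that sum.
    """
    rng = np.random.default_rng(seed)
    ssq = (h2 / n_ivs) * rng.chisquare(n_ivs, size=n_draws)
    ncp = abs(effect) * np.sqrt(n_outcome * ssq)
    z_crit = norm.isf(alpha_level / 2.0)
    power = norm.sf(z_crit - ncp) + norm.cdf(-z_crit - ncp)
    return float(power.mean())


@dataclass
class PowerCell:
    """Power of the three MR analyses for one (rho, sigma) scenario."""

    power_tp: float
    power_tm: float
    power_mp: float

    @property
    def power_mediation(self) -> float:
        return self.power_tm * self.power_mp

    @property
    def power_diff(self) -> float:
        return self.power_tp - self.power_tm * self.power_mp


def _child_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        return list(seed.spawn(n))
    return list(np.random.SeedSequence(seed).spawn(n))


def simulate_scenario(scenario: SimulationScenario, seed=None) -> PowerCell:
    """Simulate the three analyses for one scenario and collect their power."""
    a_tm, a_mp = derive_chain_effects(scenario)
    s_tp, s_tm, s_mp = _child_seeds(
        seed if seed is not None else scenario.seed, 3
    )
    common = dict(
        alpha_level=scenario.alpha_level, exposure_noise=scenario.exposure_noise,
        q_filter=scenario.q_filter, min_ivs=scenario.min_ivs,
        alpha_q=scenario.alpha_q,
    )
    power_tp = simulate_univariable_power(
        scenario.alpha_tp, scenario.h2_transcript, scenario.n_ivs_transcript,
        scenario.n_eqtl, scenario.n_gwas, n_reps=scenario.n_transcripts,
        seed=s_tp, **common,
    )
    power_tm = simulate_univariable_power(
        a_tm, scenario.h2_transcript, scenario.n_ivs_transcript,
        scenario.n_eqtl, scenario.n_mqtl, n_reps=scenario.n_transcripts,
        seed=s_tm, **common,
    )
    n_mp = min(scenario.n_transcripts * scenario.n_metabolites, scenario.mp_budget)
    power_mp = simulate_univariable_power(
        a_mp, scenario.h2_metabolite, scenario.n_ivs_metabolite,
        scenario.n_mqtl, scenario.n_gwas, n_reps=n_mp,
        seed=s_mp, **common,
    )
    return PowerCell(power_tp=power_tp, power_tm=power_tm, power_mp=power_mp)


def rho_grid(spec: tuple[float, float, int] = RHO_GRID_DEFAULT) -> np.ndarray:
    lo, hi, n = spec
    return np.linspace(lo, hi, n)


def sigma_grid(spec: tuple[float, float, int] = SIGMA_GRID_DEFAULT) -> np.ndarray:
    """Geometric spacing: sigma is a ratio, treated log-symmetrically around 1."""
    lo, hi, n = spec
    return np.geomspace(lo, hi, n)


@dataclass
class PowerGrid:
    """rho x sigma grid of repeat-averaged power values."""

    rho_values: np.ndarray
    sigma_values: np.ndarray
    power_tp: np.ndarray       # sigma x rho
    power_tm: np.ndarray
    power_mp: np.ndarray
    scenario: SimulationScenario = None
    n_repeats: int = 10
    seed: int | None = None

    @property
    def power_mediation(self) -> np.ndarray:
        return self.power_tm * self.power_mp

    @property
    def power_diff(self) -> np.ndarray:
        return self.power_tp - self.power_mediation

    def to_tsv(self, quantity: str) -> str:
        """Matrix export: rows = sigma descending, columns = rho ascending."""
        mat = getattr(self, quantity)
        order = np.argsort(self.sigma_values)[::-1]
        lines = ["sigma\\rho\t" + "\t".join(f"{r:.10g}" for r in self.rho_values)]
        for i in order:
            row = "\t".join(f"{v:.10g}" for v in mat[i])
            lines.append(f"{self.sigma_values[i]:.10g}\t{row}")
        return "\n".join(lines) + "\n"

    def manifest(self) -> dict:
        sc = asdict(self.scenario) if self.scenario else {}
        return {
            "scenario": sc,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "rho_values": [float(r) for r in self.rho_values],
            "sigma_values": [float(s) for s in self.sigma_values],
            "effect_mode_note": (
                "literal mode follows the printed recipes alpha_tm = "
                "alpha_tp*(1-rho)*sigma and alpha_mp = alpha_tp*(1-rho)/sigma, "
                "whose product is alpha_tp^2*(1-rho)^2 and ratio sigma^2; "
                "consistent mode enforces product = alpha_tp*(1-rho) and "
                "ratio = sigma exactly."
            ),
        }


def power_grid(
    base: SimulationScenario,
    rho_values=None, sigma_values=None,
    n_repeats: int = 10, seed: int = 0,
) -> PowerGrid:
    """Evaluate the scenario over the full grid, averaging over repeats.

    Each (cell, repeat) gets a deterministic seed derived from
    (seed, rho index, sigma index, repeat), so runs are reproducible and
    parallelizable.
    """
    rho_values = rho_grid() if rho_values is None else np.asarray(rho_values, float)
    sigma_values = (
        sigma_grid() if sigma_values is None else np.asarray(sigma_values, float)
    )
    shape = (len(sigma_values), len(rho_values))
    tp = np.zeros(shape)
    tm = np.zeros(shape)
    mp = np.zeros(shape)
    for i, sig in enumerate(sigma_values):
        for j, rho in enumerate(rho_values):
            cells = []
            for rep in range(n_repeats):
                ss = np.random.SeedSequence([int(seed), i, j, rep])
                sc = replace(base, rho=float(rho), sigma=float(sig))
                cells.append(simulate_scenario(sc, seed=ss))
            tp[i, j] = np.mean([c.power_tp for c in cells])
            tm[i, j] = np.mean([c.power_tm for c in cells])
            mp[i, j] = np.mean([c.power_mp for c in cells])
    return PowerGrid(
        rho_values=rho_values, sigma_values=sigma_values,
        power_tp=tp, power_tm=tm, power_mp=mp,
        scenario=base, n_repeats=n_repeats, seed=seed,
    )
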