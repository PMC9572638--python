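"""Synthetic multi-environment trial generator with known ground truth.

Every downstream stage (ANOVA, variance components, drought screening,
AMMI) is validated against trials generated here, because the effects that
those stages try to recover are drawn explicitly:

    value = grand_mean + g_i + h_k + sum_r lambda_r * u_ir * v_kr + eps

with genotype effects ``g`` and harvest (environment) effects ``h``
centred to sum to zero exactly, a low-rank genotype-by-harvest interaction
built from orthonormalised Gaussian score vectors, and iid Gaussian
residual error. One pseudo-random stream per call, seeded from the spec;
no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SpecError
from .trial_io import TrialRecord

__all__ = [
    "SimulationSpec", "FeedQualitySpec", "GroundTruth",
    "generate_met", "generate_paired_stress_trial", "generate_feed_quality",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a balanced staged-harvest trial simulation.

    Defaults emulate the scale of a tropical forage regrowth trial: 84
    genotypes cut over 6 harvest rounds with 2 replicates, per-plant total
    dry weight with grand mean 10, genotypic variance 4 (genotypic CV 20%)
    and unit residual variance.
    """

    n_genotypes: int = 84
    n_harvests: int = 6
    n_replicates: int = 2
    regimes: tuple[str, ...] = ("wet",)
    sigma2_g: float = 4.0
    sigma2_e: float = 1.0
    env_effect_sd: float = 1.0
    interaction_rank: int = 2
    interaction_sd: float = 0.5
    grand_mean: float = 10.0
    trait: str = "TDW"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genotypes, self.n_harvests, self.n_replicates) < 1:
            raise SpecError("counts must be >= 1")
        for name in ("sigma2_g", "sigma2_e", "env_effect_sd", "interaction_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.interaction_rank < 0:
            raise SpecError("interaction_rank must be >= 0")
        limit = min(self.n_genotypes, self.n_harvests) - 1
        if self.interaction_rank > limit:
            raise SpecError(
                f"interaction_rank {self.interaction_rank} exceeds "
                f"min(n_genotypes, n_harvests) - 1 = {limit}")
        if not self.regimes:
            raise SpecError("at least one regime is required")


@dataclass(frozen=True)
class GroundTruth:
    """Effects drawn for one simulated trial."""

    grand_mean: float
    genotypes: tuple[str, ...]
    harvests: tuple[int, ...]
    genotype_effects: np.ndarray        # (n,), sums to zero exactly
    harvest_effects: np.ndarray         # (m,), sums to zero exactly
    lambdas: np.ndarray                 # (rank,), descending
    genotype_scores: np.ndarray         # (n, rank), orthonormal columns
    harvest_scores: np.ndarray          # (m, rank), orthonormal columns
    interaction: np.ndarray             # (n, m)
    tolerant_genotypes: tuple[str, ...] = ()
    stress_multipliers: dict = field(default_factory=dict)


def _centered_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    x = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return x - x.mean()


def _orthonormal_centered(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Orthonormal columns inside the sum-to-zero subspace of R^n."""
    if rank == 0:
        return np.zeros((n, 0))
    a = rng.normal(size=(n, rank))
    a -= a.mean(axis=0)          # column space now lies in the sum-zero subspace
    q, r = np.linalg.qr(a)
    # fix reflection ambiguity so output is a deterministic function of the draw
    q *= np.sign(np.diag(r))
    return q


def _interaction_matrix(rng: np.random.Generator, spec: SimulationSpec):
    n, m, rank = spec.n_genotypes, spec.n_harvests, spec.interaction_rank
    u = _orthonormal_centered(rng, n, rank)
    v = _orthonormal_centered(rng, m, rank)
    # lambda_r scaled so a rank-1 term has per-cell RMS interaction_sd;
    # 1/r decay keeps the singular values distinct and ordered
    lambdas = np.array([spec.interaction_sd * math.sqrt(n * m) / (r + 1)
                        for r in range(rank)])
    omega = (u * lambdas) @ v.T if rank else np.zeros((n, m))
    return lambdas, u, v, omega


def _genotype_labels(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"G{i + 1:0{width}d}" for i in range(n))


def generate_met(spec: SimulationSpec) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a balanced multi-environment (multi-harvest) trial.

    Returns the long-format records together with the drawn ground truth.
    Every (regime, genotype, harvest, replicate) combination is present.
    Identical spec (including seed) gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m, reps = spec.n_genotypes, spec.n_harvests, spec.n_replicates
    g = _centered_normal(rng, n, math.sqrt(spec.sigma2_g))
    h = _centered_normal(rng, m, spec.env_effect_sd)
    lambdas, u, v, omega = _interaction_matrix(rng, spec)
    genotypes = _genotype_labels(n)
    harvests = tuple(range(1, m + 1))

    expected = spec.grand_mean + g[:, None] + h[None, :] + omega
    records: list[TrialRecord] = []
    sd_e = math.sqrt(spec.sigma2_e)
    for regime in spec.regimes:
        noise = rng.normal(0.0, sd_e, (n, m, reps)) if sd_e > 0 else np.zeros((n, m, reps))
        for i, geno in enumerate(genotypes):
            for k, harv in enumerate(harvests):
                for rep in range(reps):
                    records.append(TrialRecord(
                        geno, regime, harv, rep + 1, spec.trait,
                        float(expected[i, k] + noise[i, k, rep])))
    truth = GroundTruth(spec.grand_mean, genotypes, harvests, g, h,
                        lambdas, u, v, omega)
    return records, truth


#: Dry-season yield multipliers for genotypes without any planted tolerance:
#: per-harvest biomass under stress falls to roughly 15% of the wet-season
#: expectation, the magnitude of the dry-season reduction seen in irrigated
#: forage stress trials of this design.
DEFAULT_STRESS_MULTIPLIERS = {"MWS": 0.15, "SWS": 0.14}

#: Fraction of the stress penalty that planted "tolerant" genotypes retain:
#: a tolerant genotype loses only 20% of what a susceptible one loses.
DEFAULT_TOLERANT_PENALTY_FRACTION = 0.2


def generate_paired_stress_trial(
    spec: SimulationSpec,
    stress_yield_multiplier: dict[str, float] | float | None = None,
    tolerance_fraction: float = 0.2,
    tolerant_penalty_fraction: float = DEFAULT_TOLERANT_PENALTY_FRACTION,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a wet-season trial paired with stressed dry-season regimes.

    Wet-regime biomass is drawn as in :func:`generate_met`; each stress
    regime scales the wet expectation by a multiplier in (0, 1]. A seeded
    random subset of genotypes (``tolerance_fraction`` of them) is planted
    as tolerant and retains only ``tolerant_penalty_fraction`` of the yield
    penalty. The tolerant identities are returned in the ground truth so a
    screening statistic computed downstream can be scored against them.
    """
    spec.validate()
    if not 0.0 <= tolerance_fraction <= 1.0:
        raise SpecError("tolerance_fraction must be in [0, 1]")
    if not 0.0 <= tolerant_penalty_fraction <= 1.0:
        raise SpecError("tolerant_penalty_fraction must be in [0, 1]")
    if stress_yield_multiplier is None:
        multipliers = dict(DEFAULT_STRESS_MULTIPLIERS)
    elif isinstance(stress_yield_multiplier, dict):
        multipliers = dict(stress_yield_multiplier)
    else:
        multipliers = {r: float(stress_yield_multiplier)
                       for r in DEFAULT_STRESS_MULTIPLIERS}
    for regime, mult in multipliers.items():
        if not 0.0 < mult <= 1.0:
            raise SpecError(f"stress multiplier for {regime} must be in (0, 1], got {mult}")

    base = replace(spec, regimes=("wet",))
    records, truth = generate_met(base)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    n = spec.n_genotypes
    n_tolerant = math.ceil(tolerance_fraction * n)
    shuffled = list(truth.genotypes)
    rng.shuffle(shuffled)
    tolerant = tuple(sorted(shuffled[:n_tolerant]))
    tolerant_mask = np.array([g in set(tolerant) for g in truth.genotypes])

    expected = (truth.grand_mean + truth.genotype_effects[:, None]
                + truth.harvest_effects[None, :] + truth.interaction)
    sd_e = math.sqrt(spec.sigma2_e)
    for regime, mult in multipliers.items():
        eff = np.where(tolerant_mask,
                       1.0 - (1.0 - mult) * tolerant_penalty_fraction, mult)
        noise = (rng.normal(0.0, sd_e, (n, spec.n_harvests, spec.n_replicates))
                 if sd_e > 0 else np.zeros((n, spec.n_harvests, spec.n_replicates)))
        for i, geno in enumerate(truth.genotypes):
            for k, harv in enumerate(truth.harvests):
                for rep in range(spec.n_replicates):
                    records.append(TrialRecord(
                        geno, regime, harv, rep + 1, spec.trait,
                        float(expected[i, k] * eff[i] + noise[i, k, rep])))
    truth = replace(truth, tolerant_genotypes=tolerant,
                    stress_multipliers=multipliers)
    return records, truth


# Feed-quality trait scales follow the whole-plant wet-season means of
# tropical forage grasses: fibre fractions NDF/ADF/ADL and organic matter
# as % of dry matter, crude protein % DM, in vitro organic matter
# digestibility % and metabolisable energy in MJ/kg DM.
_DEFAULT_FQ_MEANS = {"NDF": 67.6, "ADF": 41.3, "ADL": 3.9, "OM": 82.7,
                     "CP": 12.1, "IVOMD": 55.2, "Me": 7.7}
_DEFAULT_FQ_SDS = {"NDF": 3.0, "ADF": 3.0, "ADL": 0.6, "OM": 2.0,
                   "CP": 2.5, "IVOMD": 3.0, "Me": 0.5}

FIBER_TRAITS = ("NDF", "ADF", "ADL")
DIGESTIBILITY_TRAITS = ("CP", "IVOMD", "Me")


@dataclass(frozen=True)
class FeedQualitySpec:
    """Per-genotype feed-quality trait distribution.

    Fibre fractions are negatively correlated with protein, digestibility
    and energy, which are mutually positively correlated — the structure a
    forage quality assay shows.
    """

    means: dict = field(default_factory=lambda: dict(_DEFAULT_FQ_MEANS))
    sds: dict = field(default_factory=lambda: dict(_DEFAULT_FQ_SDS))
    cp_fiber_corr: float = -0.5
    within_fiber_corr: float = 0.6
    within_digestibility_corr: float = 0.6

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.means)

    def correlation_matrix(self) -> np.ndarray:
        traits = self.traits
        for rho in (self.cp_fiber_corr, self.within_fiber_corr,
                    self.within_digestibility_corr):
            if not -1.0 <= rho <= 1.0:
                raise SpecError(f"correlation target {rho} outside [-1, 1]")
        p = len(traits)
        corr = np.eye(p)
        for a in range(p):
            for b in range(a + 1, p):
                ta, tb = traits[a], traits[b]
                if ta in FIBER_TRAITS and tb in FIBER_TRAITS:
                    rho = self.within_fiber_corr
                elif ta in DIGESTIBILITY_TRAITS and tb in DIGESTIBILITY_TRAITS:
                    rho = self.within_digestibility_corr
                elif {ta, tb} & set(FIBER_TRAITS) and {ta, tb} & set(DIGESTIBILITY_TRAITS):
                    rho = self.cp_fiber_corr
                else:
                    rho = 0.0
                corr[a, b] = corr[b, a] = rho
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise SpecError(
                f"implied correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})")
        return corr


def generate_feed_quality(fq: FeedQualitySpec, n_genotypes: int, seed: int,
                          regime: str = "wet") -> list[TrialRecord]:
    """Draw one correlated feed-quality trait vector per genotype."""
    if n_genotypes < 1:
        raise SpecError("n_genotypes must be >= 1")
    corr = fq.correlation_matrix()
    traits = fq.traits
    sds = np.array([fq.sds[t] for t in traits])
    means = np.array([fq.means[t] for t in traits])
    cov = corr * np.outer(sds, sds)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(means, cov, size=n_genotypes,
                                    method="svd")
    records = []
    for i, geno in enumerate(_genotype_labels(n_genotypes)):
        for j, trait in enumerate(traits):
            records.append(TrialRecord(geno, regime, 1, 1, trait,
                                       float(draws[i, j])))
    return records
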