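"""Case-control SNP data simulator with three generating scenarios.

The generator produces replicate case-control datasets from logistic
outcome models over dominantly coded, mutually independent biallelic SNPs
(Hardy-Weinberg genotype sampling with per-SNP minor allele frequencies
drawn uniformly from [0.15, 0.45]):

* ``marginal`` - six SNPs with equal dominant marginal odds ratios,
* ``gene_gene`` - three weak marginal SNPs (OR 1.2) plus one product
  interaction of dominant indicators with a varied odds ratio,
* ``gxe`` - marginal ORs 1.2/1.5/1.8, a fixed SNP1 x SNP4 interaction
  (OR 1.8), a marginal environmental variable E1 (OR 1.2 per IQR) and a
  gene-environment product E2 x SNP_j with a varied per-IQR odds ratio;
  (E1, E2) are bivariate normal with mean 20, variance 10 and correlation
  rho in {0.5, 0.9}.

The model intercept is calibrated once per design by Monte-Carlo bisection
so that the expected case fraction is ~50% (case-control-balanced data).
Environmental odds ratios are specified per theoretical interquartile
range of the normal margin, i.e. beta = log(OR) / (2 * z_0.75 * sigma).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, ndtri

from .genotype_data import PhenotypeVector, SNPMatrix

__all__ = [
    "SimulationDesign",
    "Term",
    "TrueModel",
    "SimulatedDataset",
    "scenario1_design",
    "scenario2_design",
    "scenario3_design",
    "null_design",
    "as_null",
    "enumerate_scenario_settings",
    "normal_iqr",
    "or_per_iqr_to_beta",
    "draw_mafs",
    "simulate_genotypes",
    "simulate_environment",
    "build_true_model",
    "linear_predictor",
    "calibrate_intercept",
    "simulate_outcome",
    "generate_replicates",
    "true_model_predict",
]

SCENARIOS = ("marginal", "gene_gene", "gxe")

#: number of model (potentially influential) SNPs per scenario
_N_MODEL_SNPS = {"marginal": 6, "gene_gene": 5, "gxe": 5}


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation setting."""

    scenario: str
    sample_size: int = 2000
    n_noise: int = 45
    snp_or: Optional[float] = None                    # marginal scenario: common OR of the six SNPs
    marginal_ors: tuple[float, ...] = ()              # gene_gene / gxe marginal ORs
    interaction_or: Optional[float] = None            # gene-gene product OR
    interaction_pair: Optional[tuple[int, int]] = None  # 1-based SNP indices (j, k)
    env1_or: Optional[float] = None                   # gxe: marginal OR of E1 per IQR
    gxe_or: Optional[float] = None                    # gxe: OR of E2 x SNP_j per IQR
    gxe_index: Optional[int] = None                   # 1-based j in {2, 5}
    env_mean: float = 20.0
    env_variance: float = 10.0
    env_correlation: Optional[float] = None
    maf_range: tuple[float, float] = (0.15, 0.45)
    target_case_fraction: float = 0.5
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        ors = [self.snp_or, self.interaction_or, self.env1_or, self.gxe_or, *self.marginal_ors]
        if any(o is not None and o <= 0 for o in ors):
            raise ValueError("all odds ratios must be > 0")
        if self.scenario == "marginal":
            if self.snp_or is None:
                raise ValueError("marginal scenario requires snp_or")
        elif self.scenario == "gene_gene":
            if len(self.marginal_ors) != 3 or self.interaction_or is None or self.interaction_pair is None:
                raise ValueError("gene_gene scenario requires marginal_ors (3), interaction_or, interaction_pair")
        else:  # gxe
            if (
                len(self.marginal_ors) != 3
                or self.interaction_or is None
                or self.interaction_pair is None
                or self.env1_or is None
                or self.gxe_or is None
                or self.gxe_index is None
                or self.env_correlation is None
            ):
                raise ValueError(
                    "gxe scenario requires marginal_ors (3), interaction_or, interaction_pair, "
                    "env1_or, gxe_or, gxe_index and env_correlation"
                )
            if not (-1 < self.env_correlation < 1):
                raise ValueError("env_correlation must lie in (-1, 1)")
            if self.env_variance <= 0:
                raise ValueError("env_variance must be > 0")

    @property
    def n_model_snps(self) -> int:
        return _N_MODEL_SNPS[self.scenario]

    @property
    def n_snps(self) -> int:
        return self.n_model_snps + self.n_noise


@dataclass(frozen=True)
class Term:
    """One linear-predictor term: a coefficient on a predictor descriptor.

    kind is one of ``snp_d`` (dominant indicator of one SNP),
    ``snp_d_product`` (product of dominant indicators), ``env`` (an
    environmental column), ``env_snp_d`` (environment x dominant indicator).
    SNP and environment indices are 0-based.
    """

    kind: str
    beta: float
    snps: tuple[int, ...] = ()
    env: Optional[int] = None


@dataclass
class TrueModel:
    """Calibrated generating model: intercept plus coefficient terms."""

    intercept: float
    terms: list[Term]

    @property
    def needs_environment(self) -> bool:
        return any(t.kind in ("env", "env_snp_d") for t in self.terms)

    def predict_risk(self, genotypes, environment=None) -> np.ndarray:
        return true_model_predict(self, genotypes, environment)


@dataclass
class SimulatedDataset:
    """One replicate: genotypes, optional environment, outcome, and provenance."""

    genotypes: SNPMatrix
    outcome: PhenotypeVector
    true_model: TrueModel
    mafs: np.ndarray
    replicate_index: int
    environment: Optional[np.ndarray] = None  # N x 2 (E1, E2) for the gxe scenario


# ---------------------------------------------------------------------------
# design factories and sweeps

def scenario1_design(snp_or: float, n_noise: int, sample_size: int, **kw) -> SimulationDesign:
    return SimulationDesign(scenario="marginal", snp_or=snp_or, n_noise=n_noise,
                            sample_size=sample_size, **kw)


def scenario2_design(interaction_or: float, n_noise: int, interaction_pair: tuple[int, int],
                     sample_size: int = 2000, **kw) -> SimulationDesign:
    return SimulationDesign(scenario="gene_gene", marginal_ors=(1.2, 1.2, 1.2),
                            interaction_or=interaction_or, interaction_pair=interaction_pair,
                            n_noise=n_noise, sample_size=sample_size, **kw)


def scenario3_design(gxe_or: float, gxe_index: int, env_correlation: float,
                     n_noise: int = 45, sample_size: int = 2000, **kw) -> SimulationDesign:
    return SimulationDesign(scenario="gxe", marginal_ors=(1.2, 1.5, 1.8),
                            interaction_or=1.8, interaction_pair=(1, 4),
                            env1_or=1.2, gxe_or=gxe_or, gxe_index=gxe_index,
                            env_correlation=env_correlation, n_noise=n_noise,
                            sample_size=sample_size, **kw)


def null_design(n_snps: int = 50, sample_size: int = 1000, **kw) -> SimulationDesign:
    """Design whose outcome is independent of all SNPs (all ORs 1, intercept 0)."""
    return scenario1_design(snp_or=1.0, n_noise=n_snps - _N_MODEL_SNPS["marginal"],
                            sample_size=sample_size, **kw)


def as_null(design: SimulationDesign) -> SimulationDesign:
    """Same design shell with every effect odds ratio set to 1 (null model)."""
    repl: dict = {}
    if design.snp_or is not None:
        repl["snp_or"] = 1.0
    if design.marginal_ors:
        repl["marginal_ors"] = tuple(1.0 for _ in design.marginal_ors)
    for f in ("interaction_or", "env1_or", "gxe_or"):
        if getattr(design, f) is not None:
            repl[f] = 1.0
    return dataclasses.replace(design, **repl)


def enumerate_scenario_settings(scenario: str, **kw) -> list[SimulationDesign]:
    """All design points of one scenario sweep (27 / 45 / 20 settings)."""
    designs: list[SimulationDesign] = []
    if scenario == "marginal":
        for or_ in (1.2, 1.5, 1.8):
            for noise in (4, 14, 44):
                for n in (500, 1000, 2000):
                    designs.append(scenario1_design(or_, noise, n, **kw))
    elif scenario == "gene_gene":
        for or_ in (1.2, 1.5, 1.8, 2.1, 2.4):
            for noise in (5, 15, 45):
                for pair in ((1, 2), (1, 4), (4, 5)):
                    designs.append(scenario2_design(or_, noise, pair, **kw))
    elif scenario == "gxe":
        for or_ in (1.2, 1.5, 1.8, 2.1, 2.4):
            for j in (2, 5):
                for rho in (0.5, 0.9):
                    designs.append(scenario3_design(or_, j, rho, **kw))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return designs


# ---------------------------------------------------------------------------
# elementary generators

def normal_iqr(sigma2: float) -> float:
    """Theoretical interquartile range of N(mu, sigma2): 2 * z_0.75 * sigma."""
    return 2.0 * ndtri(0.75) * np.sqrt(sigma2)


def or_per_iqr_to_beta(odds_ratio: float, sigma2: float) -> float:
    """Coefficient of a normal environmental variable whose OR is given per IQR."""
    if odds_ratio <= 0 or sigma2 <= 0:
        raise ValueError("odds_ratio and sigma2 must be > 0")
    return float(np.log(odds_ratio) / normal_iqr(sigma2))


def draw_mafs(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform MAF draws, one per SNP, redrawn for every replicate."""
    lo, hi = design.maf_range
    return rng.uniform(lo, hi, size=design.n_snps)


def simulate_genotypes(mafs: Sequence[float], n: int, rng: np.random.Generator) -> SNPMatrix:
    """Hardy-Weinberg genotypes: each entry ~ Binomial(2, MAF), columns independent."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs < 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in [0, 0.5]")
    vals = rng.binomial(2, mafs, size=(n, len(mafs)))
    return SNPMatrix(values=vals)


def simulate_environment(design: SimulationDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Bivariate normal (E1, E2) rows with mean mu, variance sigma2, correlation rho."""
    if design.scenario != "gxe":
        raise ValueError("environmental variables are only defined for the gxe scenario")
    mu = np.array([design.env_mean, design.env_mean])
    cov = design.env_variance * np.array(
        [[1.0, design.env_correlation], [design.env_correlation, 1.0]]
    )
    return rng.multivariate_normal(mu, cov, size=n)


# ---------------------------------------------------------------------------
# the generating model

def _build_terms(design: SimulationDesign) -> list[Term]:
    terms: list[Term] = []
    if design.scenario == "marginal":
        beta = float(np.log(design.snp_or))
        terms = [Term("snp_d", beta, snps=(i,)) for i in range(6)]
    elif design.scenario == "gene_gene":
        for i, or_ in enumerate(design.marginal_ors):
            terms.append(Term("snp_d", float(np.log(or_)), snps=(i,)))
        j, k = design.interaction_pair
        terms.append(Term("snp_d_product", float(np.log(design.interaction_or)), snps=(j - 1, k - 1)))
    else:
        for i, or_ in enumerate(design.marginal_ors):
            terms.append(Term("snp_d", float(np.log(or_)), snps=(i,)))
        j, k = design.interaction_pair
        terms.append(Term("snp_d_product", float(np.log(design.interaction_or)), snps=(j - 1, k - 1)))
        terms.append(Term("env", or_per_iqr_to_beta(design.env1_or, design.env_variance), env=0))
        terms.append(Term("env_snp_d", or_per_iqr_to_beta(design.gxe_or, design.env_variance),
                          snps=(design.gxe_index - 1,), env=1))
    return terms


def linear_predictor(model: TrueModel, genotypes, environment=None) -> np.ndarray:
    """Evaluate intercept + sum of terms per sample."""
    vals = genotypes.values if isinstance(genotypes, SNPMatrix) else np.asarray(genotypes)
    dom = (vals != 0).astype(float)
    eta = np.full(vals.shape[0], model.intercept, dtype=float)
    env = None if environment is None else np.asarray(environment, dtype=float)
    for t in model.terms:
        if t.kind == "snp_d":
            eta += t.beta * dom[:, t.snps[0]]
        elif t.kind == "snp_d_product":
            contrib = np.ones(vals.shape[0])
            for s in t.snps:
                contrib = contrib * dom[:, s]
            eta += t.beta * contrib
        elif t.kind == "env":
            if env is None:
                raise ValueError("model contains environmental terms but no environment was given")
            eta += t.beta * env[:, t.env]
        elif t.kind == "env_snp_d":
            if env is None:
                raise ValueError("model contains environmental terms but no environment was given")
            eta += t.beta * env[:, t.env] * dom[:, t.snps[0]]
        else:  # pragma: no cover - guarded by Term construction
            raise ValueError(f"unknown term kind {t.kind!r}")
    return eta


def calibrate_intercept(
    design: SimulationDesign,
    rng: Optional[np.random.Generator] = None,
    n_calibration: int = 200_000,
    tol: float = 0.005,
    max_iter: int = 100,
) -> float:
    """Monte-Carlo bisection of the intercept to hit the target case fraction.

    A single large calibration sample is drawn with MAFs redrawn per
    individual, marginalizing over the MAF distribution (replicates
    redraw their MAF vectors, so the per-setting intercept must balance
    the case fraction on average over MAF draws, not for one particular
    draw).  The mean of logistic(b0 + eta0) over that sample is strictly
    increasing in b0, so bisection on [-20, 20] is exact up to the
    Monte-Carlo error of the sample.
    """
    terms = _build_terms(design)
    if all(t.beta == 0.0 for t in terms) and design.target_case_fraction == 0.5:
        return 0.0
    rng = np.random.default_rng(design.seed) if rng is None else rng
    lo_maf, hi_maf = design.maf_range
    maf_rows = rng.uniform(lo_maf, hi_maf, size=(n_calibration, design.n_snps))
    geno = SNPMatrix(rng.binomial(2, maf_rows))
    env = simulate_environment(design, n_calibration, rng) if design.scenario == "gxe" else None
    eta0 = linear_predictor(TrueModel(0.0, terms), geno, env)
    target = design.target_case_fraction

    def frac(b0: float) -> float:
        return float(np.mean(expit(b0 + eta0)))

    lo, hi = -20.0, 20.0
    if frac(lo) > target or frac(hi) < target:
        raise RuntimeError("failed to bracket the intercept in [-20, 20]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) <= tol and hi - lo < 1e-3:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_true_model(design: SimulationDesign, rng: Optional[np.random.Generator] = None,
                     calibrate: bool = True, **calib_kw) -> TrueModel:
    """Construct the scenario's generating model, optionally calibrating b0."""
    terms = _build_terms(design)
    b0 = calibrate_intercept(design, rng=rng, **calib_kw) if calibrate else 0.0
    return TrueModel(intercept=b0, terms=terms)


def simulate_outcome(model: TrueModel, genotypes, environment=None,
                     rng: Optional[np.random.Generator] = None) -> PhenotypeVector:
    """Bernoulli outcomes with success probability logistic(linear predictor)."""
    rng = np.random.default_rng() if rng is None else rng
    risk = expit(linear_predictor(model, genotypes, environment))
    return PhenotypeVector((rng.random(len(risk)) < risk).astype(int))


def true_model_predict(model: TrueModel, genotypes, environment=None) -> np.ndarray:
    """Oracle risk: logistic(linear predictor) of the generating model."""
    return expit(linear_predictor(model, genotypes, environment))


def generate_replicates(design: SimulationDesign,
                        n_replicates: Optional[int] = None) -> list[SimulatedDataset]:
    """Independent replicate datasets with a shared, once-calibrated true model.

    Per-replicate generators are spawned from the design seed, so runs are
    reproducible and replicates mutually independent.
    """
    n_replicates = design.n_replicates if n_replicates is None else n_replicates
    ss = np.random.SeedSequence(design.seed)
    calib_ss, *rep_ss = ss.spawn(n_replicates + 1)
    model = build_true_model(design, rng=np.random.default_rng(calib_ss))
    out: list[SimulatedDataset] = []
    for r, child in enumerate(rep_ss):
        rng = np.random.default_rng(child)
        mafs = draw_mafs(design, rng)
        geno = simulate_genotypes(mafs, design.sample_size, rng)
        env = simulate_environment(design, design.sample_size, rng) if design.scenario == "gxe" else None
        y = simulate_outcome(model, geno, env, rng)
        out.append(SimulatedDataset(genotypes=geno, outcome=y, true_model=model,
                                    mafs=mafs, replicate_index=r, environment=env))
    return out
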