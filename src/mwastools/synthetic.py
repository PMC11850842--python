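"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates full-sib family relatedness blocks, AR(1)-correlated probes along
each chromosome, a binary exposure with small standardized effects at
designated probes, covariate confounding, dispensing streams consistent
with a known true exposure state, and external cohorts scored by a trained
profile-score model.  Every generator is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import PrescriptionRecord
from .mps import MpsModel
from .mwas import MethylationMatrix, RelatednessMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "make_families_grm",
    "simulate_methylation",
    "simulate_phenotypes",
    "simulate_prescriptions",
    "simulate_external_cohorts",
    "make_cohort",
]

_GENE_CYCLE = [f"GENE{k}" for k in range(1, 41)]


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_probes: int = 1000
    n_families: int = 50
    family_size: int = 2
    causal_probes: tuple = ()
    causal_effect: float = 0.02
    exposure_prevalence: float = 0.2
    local_corr: float = 0.0
    probe_spacing_bp: int = 200
    n_chromosomes: int = 4
    h2_family: float = 0.0
    confounder_effects: dict = field(default_factory=dict)
    exposure_covariate_logodds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.exposure_prevalence < 1.0):
            raise ValueError("exposure prevalence must lie strictly in (0, 1)")
        if not (0.0 <= self.local_corr < 1.0):
            raise ValueError("local_corr must lie in [0, 1)")
        if not (0.0 <= self.h2_family < 1.0):
            raise ValueError("h2_family must lie in [0, 1)")
        if self.n_families * self.family_size > self.n_samples:
            raise ValueError("family samples exceed n_samples")
        self.causal_probes = tuple(self.causal_probes)


@dataclass
class SyntheticCohort:
    methylation: MethylationMatrix
    annotation: pd.DataFrame
    grm: RelatednessMatrix
    phenotypes: pd.DataFrame
    prescriptions: list
    truth_exposure: pd.Series  # per-sample true exposure flag
    truth_effects: pd.Series  # per-probe true effect, zero off the causal set
    config: SimulationConfig = None


def _sample_ids(n: int) -> np.ndarray:
    return np.array([f"S{i:05d}" for i in range(n)], dtype=object)


def _probe_ids(m: int) -> np.ndarray:
    return np.array([f"cg{j:07d}" for j in range(m)], dtype=object)


def make_families_grm(
    n_families: int, family_size: int, n_unrelated: int, seed: int = 0
) -> RelatednessMatrix:
    """Block-diagonal full-sib GRM: diagonal 1, within-family 0.5.

    The sample order is shuffled with ``seed`` so family members are not
    contiguous, which exercises downstream alignment.
    """
    if min(n_families, family_size, n_unrelated) < 0:
        raise ValueError("counts must be non-negative")
    n = n_families * family_size + n_unrelated
    if n < 1:
        raise ValueError("at least one sample required")
    K = np.eye(n)
    for f in range(n_families):
        lo = f * family_size
        block = slice(lo, lo + family_size)
        K[block, block] = 0.5
    np.fill_diagonal(K, 1.0)
    perm = np.random.default_rng(seed).permutation(n)
    K = K[np.ix_(perm, perm)]
    return RelatednessMatrix(K, _sample_ids(n), kind="GRM")


def _make_annotation(config: SimulationConfig) -> pd.DataFrame:
    m = config.n_probes
    probes = _probe_ids(m)
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom
        chroms.append(f"chr{c + 1}")
        positions.append(1 + (j % per_chrom) * config.probe_spacing_bp)
    return pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": chroms,
            "position": positions,
            "gene": [_GENE_CYCLE[j % len(_GENE_CYCLE)] for j in range(m)],
            "on_450k": [j % 2 == 0 for j in range(m)],
            "on_epic": True,
            "is_smoking_proxy": False,
        }
    )


def simulate_methylation(
    config: SimulationConfig,
    exposure: np.ndarray,
    grm: RelatednessMatrix,
    covariates: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """M-value matrix with AR(1) local correlation and a family component.

    Probe j for sample i is ``mu_j + beta_j * exposure_i + sum_c gamma_c *
    c_i + family_ij + noise_ij`` where the family component has variance
    ``h2_family`` through the GRM and the noise is AR(1)-correlated across
    adjacent probes within a chromosome (variance ``1 - h2_family``).
    """
    exposure = np.asarray(exposure, dtype=float)
    n, m = config.n_samples, config.n_probes
    if exposure.size != n:
        raise ValueError("exposure length must equal n_samples")
    if grm.n != n:
        raise ValueError("GRM dimension must equal n_samples")
    annotation = _make_annotation(config)
    probe_set = set(annotation["probe_id"])
    missing = [p for p in config.causal_probes if p not in probe_set]
    if missing:
        raise ValueError(f"causal probes not in annotation: {missing}")

    rng = np.random.default_rng(config.seed)
    mu = rng.normal(0.0, 0.2, size=m)
    beta = np.zeros(m)
    idx = {p: j for j, p in enumerate(annotation["probe_id"])}
    for p in config.causal_probes:
        beta[idx[p]] = config.causal_effect

    # AR(1) innovations along probes within each chromosome
    noise = np.empty((m, n))
    phi = config.local_corr
    scale = np.sqrt(1.0 - phi**2)
    chrom = annotation["chromosome"].to_numpy()
    eps = rng.standard_normal((m, n))
    for j in range(m):
        if j > 0 and chrom[j] == chrom[j - 1]:
            noise[j] = phi * noise[j - 1] + scale * eps[j]
        else:
            noise[j] = eps[j]

    values = mu[:, None] + np.outer(beta, exposure) + np.sqrt(1.0 - config.h2_family) * noise
    if config.h2_family > 0:
        eigval, eigvec = np.linalg.eigh(grm.values)
        L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        fam = (L @ rng.standard_normal((n, m))).T  # m x n, covariance = GRM per probe
        values += np.sqrt(config.h2_family) * fam
    if covariates is not None and config.confounder_effects:
        for cov_name, gamma in config.confounder_effects.items():
            c = np.asarray(covariates[cov_name], dtype=float)
            c = (c - c.mean()) / (c.std(ddof=1) if c.std(ddof=1) > 0 else 1.0)
            values += gamma * c[None, :]

    mat = MethylationMatrix(values, annotation["probe_id"].to_numpy(), grm.sample_ids.copy(), scale="M")
    return mat, annotation


def simulate_phenotypes(config: SimulationConfig, grm: RelatednessMatrix) -> pd.DataFrame:
    """Covariate table plus a true exposure flag.

    Exposure is Bernoulli at the configured prevalence, optionally shifted
    on the log-odds scale by standardized covariates via
    ``exposure_covariate_logodds`` (the confounding pathway).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples
    age = rng.normal(50.0, 12.0, size=n)
    sex = rng.choice(["F", "M"], size=n)
    smoking = rng.normal(0.0, 1.0, size=n)
    mono = rng.beta(4, 40, size=n)
    lymph = rng.beta(10, 25, size=n)
    pheno = pd.DataFrame(
        {
            "sample_id": grm.sample_ids,
            "age": age,
            "sex": sex,
            "smoking_proxy_M": smoking,
            "monocyte_prop": mono,
            "lymphocyte_prop": lymph,
            "batch": rng.choice(["b1", "b2", "b3"], size=n),
            "draw_day": rng.integers(300, 3000, size=n),
            "lifetime_MDD": rng.random(n) < 0.25,
            "bipolar": rng.random(n) < 0.01,
        }
    ).set_index("sample_id")

    logit = np.log(config.exposure_prevalence / (1 - config.exposure_prevalence))
    eta = np.full(n, logit)
    for cov_name, coef in config.exposure_covariate_logodds.items():
        c = pheno[cov_name]
        c = (c == "M").astype(float) if c.dtype == object else c.astype(float)
        c = (c - c.mean()) / (c.std(ddof=1) if c.std(ddof=1) > 0 else 1.0)
        eta = eta + coef * c.to_numpy()
    exposure = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    pheno["true_exposure"] = exposure.astype(int)
    pheno["reported_use"] = pheno["true_exposure"]  # self-report mirrors truth here
    return pheno


def simulate_prescriptions(
    truth: pd.Series,
    draw_dates: pd.Series,
    seed: int = 0,
    excluded_fraction: float = 0.0,
    coverage_days: int = 28,
    lead_days: int = 7,
    tail_days: int = 7,
    grace_days: int = 30,
) -> list:
    """Dispensing streams consistent with a known exposure truth.

    True-exposed samples get a chain of 28-day dispensations whose merged
    period starts at least ``lead_days`` before the draw and covers it.
    True-unexposed samples get no records, except a configurable fraction
    that receives a stale stream ending more than ``tail_days`` before the
    draw — the classifier must mark those EXCLUDED.
    """
    if not truth.index.equals(draw_dates.index):
        raise ValueError("truth and draw dates must share sample ids")
    rng = np.random.default_rng(seed)
    records: list[PrescriptionRecord] = []
    for sid in truth.index:
        draw = int(draw_dates[sid])
        if truth[sid]:
            lead = int(rng.integers(max(lead_days, 10), 250))
            day = draw - lead
            # consecutive refills every `coverage_days` until the draw is covered
            while True:
                records.append(
                    PrescriptionRecord(sid, day, "040303", float(coverage_days), 1.0)
                )
                if day + coverage_days > draw:
                    break
                day += coverage_days
        elif rng.random() < excluded_fraction:
            end_gap = int(rng.integers(tail_days + grace_days + 1, 400))
            day = draw - end_gap - coverage_days
            records.append(
                PrescriptionRecord(sid, day, "040303", float(coverage_days), 1.0)
            )
    return records


def simulate_external_cohorts(
    model: MpsModel,
    k: int,
    n_per_cohort: int,
    score_effect: float,
    seed: int = 0,
    prevalence: float = 0.3,
    probe_noise_sd: float = 0.0,
) -> list:
    """External cohorts whose computed score tracks a latent standard-normal
    score driving exposure through a logistic model.

    Returns ``[(methylation, exposure, covariates), ...]``.  Weighted-probe
    values are ``sign(w_j) * s_i`` plus optional noise, so the
    externally-standardized weighted sum reproduces the latent score up to
    a positive affine map.
    """
    if model.n_weights < 1:
        raise ValueError("model has no nonzero weights")
    out = []
    rng = np.random.default_rng(seed)
    probes = list(model.weights)
    signs = np.array([np.sign(model.weights[p]) or 1.0 for p in probes])
    alpha = np.log(prevalence / (1 - prevalence))
    for c in range(k):
        s = rng.standard_normal(n_per_cohort)
        values = np.outer(signs, s)
        if probe_noise_sd > 0:
            values = values + probe_noise_sd * rng.standard_normal(values.shape)
        eta = alpha + score_effect * s
        exposure = (rng.random(n_per_cohort) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        sample_ids = np.array([f"C{c}_{i:05d}" for i in range(n_per_cohort)], dtype=object)
        mat = MethylationMatrix(values, np.array(probes, dtype=object), sample_ids, scale="M")
        covariates = pd.DataFrame(
            {"age": rng.normal(50, 10, n_per_cohort)}, index=sample_ids
        )
        out.append((mat, pd.Series(exposure, index=sample_ids), covariates))
    return out


def make_cohort(config: SimulationConfig, excluded_fraction: float = 0.0) -> SyntheticCohort:
    """End-to-end cohort: GRM, phenotypes, methylation, and prescriptions."""
    n_unrelated = config.n_samples - config.n_families * config.family_size
    grm = make_families_grm(config.n_families, config.family_size, n_unrelated, config.seed)
    pheno = simulate_phenotypes(config, grm)
    mat, annotation = simulate_methylation(
        config, pheno["true_exposure"].to_numpy(), grm, covariates=pheno
    )
    prescriptions = simulate_prescriptions(
        pheno["true_exposure"].astype(bool),
        pheno["draw_day"],
        seed=config.seed + 2,
        excluded_fraction=excluded_fraction,
    )
    effects = pd.Series(0.0, index=mat.probe_ids)
    for p in config.causal_probes:
        effects[p] = config.causal_effect
    return SyntheticCohort(
        methylation=mat,
        annotation=annotation,
        grm=grm,
        phenotypes=pheno,
        prescriptions=prescriptions,
        truth_exposure=pheno["true_exposure"].astype(bool),
        truth_effects=effects,
        config=config,
    )
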