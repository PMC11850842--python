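"""Methylation profile score: sparse L1 training, external scoring,
per-cohort logistic association, and DerSimonian-Laird meta-analysis.

Training regresses the relatedness-residualized phenotype on masked
standardized probes with 10-fold cross-validated LASSO (mixing parameter
1); the penalty minimizing mean CV error is kept.  External cohorts are
scored as a weighted sum of (by default their own) standardized probe
values; probes a cohort lacks are skipped and reported as coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .mwas import MethylationMatrix

__all__ = [
    "MpsModel",
    "CohortAssociation",
    "MetaResult",
    "train_mps",
    "score_mps",
    "cohort_association",
    "dl_meta",
]


@dataclass
class MpsModel:
    """Sparse probe-weight model with its training standardization stats."""

    weights: dict  # probe_id -> weight, nonzero only
    train_mean: dict
    train_sd: dict
    mask_description: str
    cv_folds: int
    seed: int
    penalty: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        bad = [p for p, w in self.weights.items() if not np.isfinite(w)]
        if bad:
            raise ValueError(f"non-finite weights for probes: {bad}")

    @property
    def n_weights(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class CohortAssociation:
    cohort: str
    beta: float
    se: float
    p: float
    nagelkerke_r2: float
    n_exposed: int
    n_unexposed: int
    model_type: str
    flagged: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0.0 <= self.nagelkerke_r2 <= 1.0):
            raise ValueError("Nagelkerke R^2 must lie in [0, 1]")


@dataclass(frozen=True)
class MetaResult:
    beta_pooled: float
    se_pooled: float
    ci95: tuple
    Q: float
    df: int
    tau2: float
    i2_percent: float
    k: int


def train_mps(
    y_res: np.ndarray,
    Z: MethylationMatrix,
    mask=None,
    n_folds: int = 10,
    seed: int = 0,
    penalty: float | None = None,
    n_alphas: int = 100,
) -> MpsModel:
    """Cross-validated LASSO of a residualized phenotype on masked probes.

    ``penalty=None`` selects the penalty at minimum mean CV error over a
    descending path; a fixed ``penalty`` skips cross-validation (used by
    the closed-form oracle checks).  Fold assignment is seeded, so the fit
    is deterministic.
    """
    y = np.asarray(y_res, dtype=float)
    if y.size != Z.n_samples:
        raise ValueError("phenotype and methylation must be sample-aligned")
    if y.size < n_folds:
        raise ValueError("fewer samples than folds")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")

    if mask is not None:
        mask = set(mask)
        keep = np.array([p in mask for p in Z.probe_ids])
        if not keep.any():
            raise ValueError("mask excludes every probe")
        mask_desc = f"mask({keep.sum()} of {Z.n_probes} probes)"
    else:
        keep = np.ones(Z.n_probes, dtype=bool)
        mask_desc = f"all({Z.n_probes} probes)"

    X = Z.values[keep].T  # samples x probes
    probes = Z.probe_ids[keep]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)

    if penalty is None:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        # eps keeps the path away from near-zero penalties, where coordinate
        # descent converges very slowly on locally correlated probes
        est = LassoCV(cv=cv, alphas=n_alphas, eps=5e-2, max_iter=3000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        alpha = float(est.alpha_)
        coefs, intercept = est.coef_, float(est.intercept_)
    else:
        est = Lasso(alpha=penalty, max_iter=50000, tol=1e-10)
        est.fit(X, y)
        alpha = float(penalty)
        coefs, intercept = est.coef_, float(est.intercept_)

    nz = np.flatnonzero(coefs)
    return MpsModel(
        weights={str(probes[j]): float(coefs[j]) for j in nz},
        train_mean={str(probes[j]): float(means[j]) for j in nz},
        train_sd={str(probes[j]): float(sds[j]) for j in nz},
        mask_description=mask_desc,
        cv_folds=n_folds,
        seed=seed,
        penalty=alpha,
        intercept=intercept,
    )


def score_mps(
    model: MpsModel,
    M_ext: MethylationMatrix,
    standardize: str = "external",
) -> tuple[pd.Series, dict]:
    """Weighted-sum score of an external cohort.

    ``standardize="external"`` z-scores each weighted probe with the
    cohort's own mean/SD; ``"training"`` reuses the training statistics.
    Missing probes are skipped and counted in the coverage report.
    """
    if standardize not in ("external", "training"):
        raise ValueError(f"unknown standardization {standardize!r}")
    lookup = {p: i for i, p in enumerate(M_ext.probe_ids)}
    used, skipped = [], []
    score = np.zeros(M_ext.n_samples)
    for probe, w in model.weights.items():
        idx = lookup.get(probe)
        if idx is None:
            skipped.append(probe)
            continue
        x = M_ext.values[idx]
        if standardize == "external":
            sd = x.std(ddof=1)
            if sd == 0:
                skipped.append(probe)
                continue
            z = (x - x.mean()) / sd
        else:
            z = (x - model.train_mean[probe]) / model.train_sd[probe]
        score += w * z
        used.append(probe)
    if not used:
        raise ValueError("no weighted probes overlap the external cohort")
    coverage = {
        "n_weights": model.n_weights,
        "n_used": len(used),
        "n_skipped": len(skipped),
        "skipped": skipped,
    }
    return pd.Series(score, index=M_ext.sample_ids, name="mps"), coverage


def _nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(-2.0 * (ll_full - ll_null) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def cohort_association(
    score,
    exposure,
    covariates: pd.DataFrame | None = None,
    clusters=None,
    cohort: str = "cohort",
) -> CohortAssociation:
    """Logistic association of exposure with the (standardized) score.

    With ``clusters`` the model is fit by exchangeable-correlation
    estimating equations with robust standard errors; the Nagelkerke
    pseudo-R^2 is then taken from an auxiliary plain logistic fit, since
    estimating equations have no likelihood.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(exposure, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("exposure must be binary 0/1")
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need at least 10 samples in each exposure class")

    z = (score - score.mean()) / score.std(ddof=1)
    X = pd.DataFrame({"score": z})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.astype(float))
    X_null = X.drop(columns="score")

    flagged = None
    if clusters is not None:
        groups = np.asarray(clusters)
        model_type = "gee-exchangeable"
        fit = sm.GEE(
            y, X, groups=groups, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        beta = float(fit.params["score"])
        se = float(fit.bse["score"])
        p = float(fit.pvalues["score"])
        # likelihood-free model: pseudo-R^2 from an auxiliary GLM
        glm_full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        glm_null = sm.GLM(y, X_null, family=sm.families.Binomial()).fit()
        r2 = _nagelkerke(glm_full.llf, glm_null.llf, y.size)
    else:
        model_type = "glm"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0)
                if not fit.mle_retvals.get("converged", True):
                    raise RuntimeError("logit did not converge")
            except Exception:
                # separation fallback: iteration-capped IRLS, flagged in output
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=25)
                flagged = "penalized-fallback"
            null_fit = sm.GLM(y, X_null, family=sm.families.Binomial()).fit()
        beta = float(fit.params["score"])
        se = float(fit.bse["score"])
        p = float(2.0 * sps.norm.sf(abs(beta / se)))
        r2 = _nagelkerke(float(fit.llf), float(null_fit.llf), y.size)

    return CohortAssociation(
        cohort=cohort, beta=beta, se=se, p=p, nagelkerke_r2=r2,
        n_exposed=int((y == 1).sum()), n_unexposed=int((y == 0).sum()),
        model_type=model_type, flagged=flagged,
    )


def dl_meta(associations) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort effects.

    Moment estimator: ``tau2 = max(0, (Q - (k-1)) / C)`` with
    ``C = sum(w) - sum(w^2)/sum(w)`` and fixed-effect weights
    ``w = 1/se^2``; when ``Q <= k-1`` the pooling collapses to
    fixed-effect inverse-variance weighting.
    """
    assoc = list(associations)
    if not assoc:
        raise ValueError("meta-analysis requires at least one cohort")
    beta = np.array([a.beta for a in assoc], dtype=float)
    se = np.array([a.se for a in assoc], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    k = beta.size

    w = 1.0 / se**2
    beta_f = float((w * beta).sum() / w.sum())
    Q = float((w * (beta - beta_f) ** 2).sum())
    if k == 1:
        tau2 = 0.0
        i2 = 0.0
    else:
        C = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
        i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0

    w_star = 1.0 / (se**2 + tau2)
    beta_r = float((w_star * beta).sum() / w_star.sum())
    se_pooled = float(w_star.sum() ** -0.5)
    ci = (beta_r - 1.96 * se_pooled, beta_r + 1.96 * se_pooled)
    return MetaResult(beta_r, se_pooled, ci, Q, k - 1, float(tau2), float(i2), k)
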