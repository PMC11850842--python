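"""Mixed-model methylome-wide association.

The engine follows the standard omics mixed-model workflow:

1. beta values are transformed to M-values and standardized per probe;
2. an omics-relatedness matrix (ORM) ``Z'Z / m`` is built from the
   standardized matrix;
3. the phenotype is residualized for relatedness by REML/BLUP against a
   kinship kernel;
4. each probe is tested in ``y = X c + z_j b_j + u + e`` with
   ``u ~ N(0, sigma_o^2 * Omega)``; effects are per 1 SD of M-value.

REML uses a single eigendecomposition of the kernel and a bounded 1-D
search over the log variance ratio.  ``mode="fast"`` estimates the ratio
once under the probe-free null and reuses it for every probe (GLS);
``mode="exact"`` re-optimizes per probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "MethylationMatrix",
    "RelatednessMatrix",
    "beta_to_m",
    "standardize_probes",
    "compute_orm",
    "reml_blup_residualize",
    "run_mwas",
    "compare_effect_sets",
    "SIGNIFICANCE_THRESHOLD",
]

#: methylome-wide significance threshold for case-control MWAS
SIGNIFICANCE_THRESHOLD = 9.42e-8

_LOG_RATIO_BOUNDS = (-10.0, 10.0)  # variance ratio restricted to e^-10 .. e^10
_REML_XATOL = 1e-8


@dataclass
class MethylationMatrix:
    """Probe x sample matrix of methylation values.

    ``scale`` is one of ``"beta"``, ``"M"``, ``"standardized-M"``.
    """

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray
    scale: str = "M"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.shape != (self.probe_ids.size, self.sample_ids.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.probe_ids.size} probes x {self.sample_ids.size} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != ids.size:
                raise ValueError(f"duplicate {name} ids")
        if self.scale not in ("beta", "M", "standardized-M"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "beta" and ((self.values <= 0) | (self.values >= 1)).any():
            raise ValueError("beta-scale values must lie strictly in (0, 1)")

    @property
    def n_probes(self) -> int:
        return self.probe_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def probe_index(self, probe_ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in lookup]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return np.array([lookup[p] for p in probe_ids])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids])
        return MethylationMatrix(
            self.values[:, idx], self.probe_ids.copy(), np.asarray(sample_ids, dtype=object),
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class RelatednessMatrix:
    """Symmetric random-effect kernel (GRM or ORM) with sample ids."""

    values: np.ndarray
    sample_ids: np.ndarray
    kind: str = "GRM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = self.sample_ids.size
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relatedness matrix must be symmetric")
        if self.kind not in ("GRM", "ORM"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.sample_ids.size

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def validate_psd(self, tol: float = 1e-8) -> None:
        if self.min_eigenvalue() < -tol:
            raise ValueError("relatedness matrix is not positive semi-definite")

    def subset_samples(self, sample_ids) -> "RelatednessMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids])
        return RelatednessMatrix(
            self.values[np.ix_(idx, idx)], np.asarray(sample_ids, dtype=object), self.kind
        )


def beta_to_m(beta):
    """``M = log2(beta / (1 - beta))``; strictly increasing on (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if ((beta <= 0) | (beta >= 1)).any():
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def standardize_probes(mat: MethylationMatrix) -> tuple[MethylationMatrix, list]:
    """Scale each probe to mean 0, unit sample variance (ddof=1).

    Zero-variance probes are dropped and returned as a warning record.
    """
    if mat.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    values = mat.values
    if mat.scale == "beta":
        values = beta_to_m(values)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(mat.probe_ids[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance probes", stacklevel=2)
    if not keep.any():
        raise ValueError("all probes have zero variance")
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    out = MethylationMatrix(
        z, mat.probe_ids[keep], mat.sample_ids.copy(), scale="standardized-M"
    )
    return out, dropped


def compute_orm(Z: MethylationMatrix) -> RelatednessMatrix:
    """Omics-relatedness matrix ``Z'Z / m`` over m standardized probes."""
    if Z.scale != "standardized-M":
        raise ValueError("ORM requires a standardized matrix")
    if Z.n_probes == 0:
        raise ValueError("cannot build ORM from zero probes")
    omega = Z.values.T @ Z.values / Z.n_probes
    omega = (omega + omega.T) / 2.0
    return RelatednessMatrix(omega, Z.sample_ids.copy(), kind="ORM")


def _reml_profile(yr: np.ndarray, Xr: np.ndarray, eigvals: np.ndarray):
    """Profiled REML over the log variance ratio on rotated data.

    Returns (log_delta, neg2ll_at_opt, fn) where fn(log_delta) gives the
    negative restricted log-likelihood (up to a constant).
    """
    n, p = Xr.shape

    def negll(log_delta: float) -> float:
        v = np.exp(log_delta) * eigvals + 1.0
        w = 1.0 / v
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (w * yr)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(np.sum(w * r * r))
        if rss <= 0:
            return np.inf
        s2 = rss / (n - p)
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(s2) + np.log(v).sum() + logdet_xtwx)

    res = minimize_scalar(
        negll, bounds=_LOG_RATIO_BOUNDS, method="bounded",
        options={"xatol": _REML_XATOL},
    )
    return float(res.x), float(res.fun), negll


def _gls_fit(yr, Xr, w):
    """Weighted LS on rotated data -> (beta, cov_unscaled, rss, df_resid)."""
    n, p = Xr.shape
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (w * yr)
    cov_unscaled = np.linalg.inv(XtWX)
    beta = cov_unscaled @ XtWy
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    return beta, cov_unscaled, rss, n - p


def reml_blup_residualize(
    y: np.ndarray, K: RelatednessMatrix
) -> tuple[np.ndarray, float, float]:
    """Residualize a phenotype for relatedness by REML + BLUP.

    Fits ``y = 1*mu + g + e`` with ``g ~ N(0, sigma_g^2 K)`` and returns
    ``(y - mu_hat - g_hat, sigma_g2, sigma_e2)`` where ``g_hat`` is the
    BLUP of the random effect.
    """
    y = np.asarray(y, dtype=float)
    if y.size != K.n:
        raise ValueError("phenotype length must match kernel dimension")
    eigvals, U = np.linalg.eigh(K.values)
    if eigvals[0] < -1e-8:
        raise ValueError("kernel is not positive semi-definite")
    eigvals = np.clip(eigvals, 0.0, None)

    yr = U.T @ y
    Xr = U.T @ np.ones((y.size, 1))
    log_delta, _, _ = _reml_profile(yr, Xr, eigvals)
    delta = np.exp(log_delta)

    w = 1.0 / (delta * eigvals + 1.0)
    beta, _, rss, df = _gls_fit(yr, Xr, w)
    sigma_e2 = rss / df
    sigma_g2 = delta * sigma_e2

    # BLUP in the eigenbasis: shrink each rotated residual by delta*d/(1+delta*d)
    marg = yr - Xr @ beta
    g_rot = (delta * eigvals) / (delta * eigvals + 1.0) * marg
    g_hat = U @ g_rot
    mu_hat = float(beta[0])
    residuals = y - mu_hat - g_hat
    return residuals, float(sigma_g2), float(sigma_e2)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad or names}")


def run_mwas(
    y_res: np.ndarray,
    Z: MethylationMatrix,
    covariates: pd.DataFrame | None,
    omega: RelatednessMatrix | None,
    mode: str = "fast",
    analysis: str = "mwas",
) -> pd.DataFrame:
    """Per-probe mixed-model association scan.

    ``omega=None`` drops the random effect entirely (the model collapses to
    per-probe OLS/GLS on the identity kernel).  Returns a result frame with
    columns ``probe_id, beta, se, p, n, analysis, significant`` (effects
    per 1 SD of M-value; Wald two-sided normal p; significance at
    ``SIGNIFICANCE_THRESHOLD``).
    """
    if mode not in ("fast", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(y_res, dtype=float)
    n = y.size
    if Z.n_samples != n or (omega is not None and omega.n != n):
        raise ValueError("phenotype, methylation, and kernel must be sample-aligned")
    if omega is not None and not np.array_equal(Z.sample_ids, omega.sample_ids):
        raise ValueError("methylation and kernel sample ids differ")

    names = ["intercept"]
    cols = [np.ones(n)]
    if covariates is not None and covariates.shape[1] > 0:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    _check_design(X, names)

    if omega is None:
        # no random effect (identity kernel): rotation is a no-op
        eigvals, U = np.ones(n), None
        yr, Xr, Zr = y, X, Z.values
    else:
        eigvals, U = np.linalg.eigh(omega.values)
        eigvals = np.clip(eigvals, 0.0, None)
        yr = U.T @ y
        Xr = U.T @ X
        Zr = Z.values @ U  # row j is probe j in the rotated basis

    m = Z.n_probes
    betas = np.empty(m)
    ses = np.empty(m)

    if mode == "fast":
        log_delta, _, _ = _reml_profile(yr, Xr, eigvals)
        w = 1.0 / (np.exp(log_delta) * eigvals + 1.0)
        # Frisch-Waugh: sweep X out of y and every probe under the weights
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWXi = np.linalg.inv(XtWX)
        proj = lambda v: v - Xr @ (XtWXi @ (Xr.T @ (w * v)))
        y_t = proj(yr)
        Z_t = Zr - (Zr * w) @ Xr @ XtWXi @ Xr.T
        ztz = np.einsum("ij,j,ij->i", Z_t, w, Z_t)
        zty = Z_t @ (w * y_t)
        yty = float(np.sum(w * y_t * y_t))
        df = n - X.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            betas = zty / ztz
            rss = yty - betas * zty
            sigma2 = np.clip(rss, 0.0, None) / df
            ses = np.sqrt(sigma2 / ztz)
    else:
        for j in range(m):
            Xj = np.column_stack([Xr, Zr[j]])
            log_delta, _, _ = _reml_profile(yr, Xj, eigvals)
            w = 1.0 / (np.exp(log_delta) * eigvals + 1.0)
            beta, cov_u, rss, df = _gls_fit(yr, Xj, w)
            sigma2 = rss / df
            betas[j] = beta[-1]
            ses[j] = np.sqrt(sigma2 * cov_u[-1, -1])

    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = betas / ses
    pvals = np.clip(2.0 * sps.norm.sf(np.abs(zstat)), np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "probe_id": Z.probe_ids,
            "beta": betas,
            "se": ses,
            "p": pvals,
            "n": n,
            "analysis": analysis,
            "significant": pvals < SIGNIFICANCE_THRESHOLD,
        }
    )


def compare_effect_sets(
    resA: pd.DataFrame, resB: pd.DataFrame, probes=None
) -> dict:
    """Compare two MWAS result sets over their shared probes.

    Returns Pearson R (with two-sided p) across shared probes, a per-probe
    difference test ``z = (bA - bB) / sqrt(seA^2 + seB^2)``, and the ratio
    of mean effects over ``probes`` (all shared probes when omitted).
    """
    merged = resA.merge(resB, on="probe_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least 3 shared probes to compare effect sets")
    r, r_p = sps.pearsonr(merged["beta_a"], merged["beta_b"])

    z = (merged["beta_a"] - merged["beta_b"]) / np.sqrt(
        merged["se_a"] ** 2 + merged["se_b"] ** 2
    )
    diff_p = 2.0 * sps.norm.sf(np.abs(z))
    per_probe = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "beta_a": merged["beta_a"],
            "beta_b": merged["beta_b"],
            "z_diff": z,
            "p_diff": diff_p,
        }
    )

    sub = merged if probes is None else merged[merged["probe_id"].isin(set(probes))]
    mean_b = float(sub["beta_b"].mean())
    ratio = float(sub["beta_a"].mean()) / mean_b if mean_b != 0 else np.nan
    return {
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "n_shared": int(len(merged)),
        "per_probe": per_probe,
        "mean_effect_ratio": ratio,
    }
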