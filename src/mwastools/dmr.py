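"""Differentially methylated regions.

Candidates are runs of nearby nominally significant probes with a shared
effect direction; each candidate is tested by an inverse-variance-weighted
meta-analysis of the per-probe effects whose variance accounts for the
sample correlation between member probes' methylation.  Bonferroni
correction uses the total number of candidates tested in the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mwas import MethylationMatrix

__all__ = ["DmrCandidate", "DmrResult", "find_candidate_regions", "dmr_test", "run_dmr"]

DEFAULT_MAX_GAP_BP = 500
DEFAULT_P_THRESH = 0.05
DEFAULT_MIN_PROBES = 2


@dataclass(frozen=True)
class DmrCandidate:
    chromosome: str
    start_bp: int
    end_bp: int
    probe_ids: tuple
    direction: int  # +1 or -1, common sign of member effects

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a candidate region needs at least 2 probes")
        if self.end_bp < self.start_bp:
            raise ValueError("region end before start")


@dataclass(frozen=True)
class DmrResult:
    candidate: DmrCandidate
    beta_region: float
    se_region: float
    z: float
    p: float
    p_adj: float
    n_candidates_total: int


def find_candidate_regions(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    p_thresh: float = DEFAULT_P_THRESH,
    min_probes: int = DEFAULT_MIN_PROBES,
    enumerate_subregions: bool = False,
) -> list[DmrCandidate]:
    """Enumerate candidate regions from an MWAS result set.

    Probes are filtered to ``p < p_thresh``, ordered along the genome, and
    grouped into maximal runs of same-sign effects with inter-probe gaps
    ``<= max_gap``.  With ``enumerate_subregions`` every contiguous window
    of length >= ``min_probes`` inside each run is also emitted, which is
    what makes candidate counts large on real data.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    missing = [p for p in results["probe_id"] if p not in ann.index]
    if missing:
        raise KeyError(f"probes missing from annotation: {missing[:10]}")

    hits = results[results["p"] < p_thresh].copy()
    if hits.empty:
        return []
    hits["chromosome"] = [ann.at[p, "chromosome"] for p in hits["probe_id"]]
    hits["position"] = [int(ann.at[p, "position"]) for p in hits["probe_id"]]
    hits["sign"] = np.sign(hits["beta"]).astype(int)
    hits = hits[hits["sign"] != 0]
    hits = hits.sort_values(["chromosome", "position"], kind="mergesort")

    runs: list[pd.DataFrame] = []
    for _, chrom_df in hits.groupby("chromosome", sort=False):
        start = 0
        rows = chrom_df.reset_index(drop=True)
        for i in range(1, len(rows) + 1):
            boundary = i == len(rows) or (
                rows.at[i, "position"] - rows.at[i - 1, "position"] > max_gap
                or rows.at[i, "sign"] != rows.at[i - 1, "sign"]
            )
            if boundary:
                if i - start >= min_probes:
                    runs.append(rows.iloc[start:i])
                start = i

    def _mk(window: pd.DataFrame) -> DmrCandidate:
        return DmrCandidate(
            chromosome=str(window["chromosome"].iloc[0]),
            start_bp=int(window["position"].iloc[0]),
            end_bp=int(window["position"].iloc[-1]),
            probe_ids=tuple(window["probe_id"]),
            direction=int(window["sign"].iloc[0]),
        )

    candidates: list[DmrCandidate] = []
    for run in runs:
        if enumerate_subregions:
            k = len(run)
            for width in range(min_probes, k + 1):
                for lo in range(0, k - width + 1):
                    candidates.append(_mk(run.iloc[lo : lo + width]))
        else:
            candidates.append(_mk(run))
    return candidates


def dmr_test(
    candidate: DmrCandidate,
    results: pd.DataFrame,
    Z: MethylationMatrix,
    rho_shrink: float = 1e-6,
) -> DmrResult:
    """Correlation-adjusted inverse-variance meta-analysis of one region.

    With weights ``w_i = 1/se_i^2``::

        B      = sum(w b) / sum(w)
        Var(B) = sum_ij w_i w_j rho_ij se_i se_j / (sum w)^2

    where ``rho`` is the sample correlation of member probes' methylation.
    With identity ``rho`` this reduces exactly to fixed-effect IVW meta.
    """
    res = results.set_index("probe_id")
    probes = list(candidate.probe_ids)
    beta = res.loc[probes, "beta"].to_numpy(dtype=float)
    se = res.loc[probes, "se"].to_numpy(dtype=float)
    if (se <= 0).any():
        raise ValueError("member standard errors must be positive")

    rows = Z.values[Z.probe_index(probes)]
    rho = np.corrcoef(rows)
    if not np.all(np.isfinite(rho)):
        raise ValueError("member probe correlation matrix is singular or NaN")
    rho = rho + rho_shrink * np.eye(len(probes))

    w = 1.0 / se**2
    sw = w.sum()
    b_region = float((w * beta).sum() / sw)
    var = float((np.outer(w * se, w * se) * rho).sum() / sw**2)
    if var <= 0:
        raise ValueError("non-positive region variance")
    se_region = float(np.sqrt(var))
    z = b_region / se_region
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return DmrResult(candidate, b_region, se_region, float(z), p, p_adj=p, n_candidates_total=1)


def run_dmr(
    results: pd.DataFrame,
    Z: MethylationMatrix,
    annotation: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    p_thresh: float = DEFAULT_P_THRESH,
    min_probes: int = DEFAULT_MIN_PROBES,
    enumerate_subregions: bool = False,
) -> list[DmrResult]:
    """Test every candidate region; Bonferroni-adjust over all candidates."""
    candidates = find_candidate_regions(
        results, annotation, max_gap, p_thresh, min_probes, enumerate_subregions
    )
    if not candidates:
        return []
    total = len(candidates)
    out = []
    for cand in candidates:
        r = dmr_test(cand, results, Z)
        out.append(
            DmrResult(
                cand, r.beta_region, r.se_region, r.z, r.p,
                p_adj=min(1.0, r.p * total), n_candidates_total=total,
            )
        )
    out.sort(key=lambda r: r.p_adj)
    return out


def dmr_results_frame(results: list[DmrResult]) -> pd.DataFrame:
    """Tabular view of DMR results (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "chromosome": [r.candidate.chromosome for r in results],
            "start_bp": [r.candidate.start_bp for r in results],
            "end_bp": [r.candidate.end_bp for r in results],
            "n_probes": [len(r.candidate.probe_ids) for r in results],
            "probe_ids": [",".join(r.candidate.probe_ids) for r in results],
            "beta": [r.beta_region for r in results],
            "se": [r.se_region for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
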