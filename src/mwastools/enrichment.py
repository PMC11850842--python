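"""Cross-study concordance of association results.

Two tools: an exact hypergeometric overlap test for top CpG/gene sets, and
a circular-permutation enrichment between two genome-ordered result sets.
The permutation scheme rotates one study's top-hit indicator along the
genome, preserving its local correlation structure, and corrects over all
threshold pairs by comparing against the per-permutation best statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OverlapTest",
    "EnrichmentResult",
    "hypergeometric_overlap",
    "top_hits",
    "circular_enrichment",
]

DEFAULT_FRACTIONS = (0.001, 0.005, 0.01)


@dataclass(frozen=True)
class OverlapTest:
    set_a_size: int
    set_b_size: int
    overlap: int
    background_size: int
    p_upper_tail: float


@dataclass
class PairEnrichment:
    fraction_a: float
    fraction_b: float
    table: tuple  # (a, b, c, d): both-top, A-only, B-only, neither
    odds_ratio: float
    log_or: float
    p_empirical: float


@dataclass
class EnrichmentResult:
    pairs: list
    best_pair: tuple
    p_corrected: float
    n_permutations: int
    seed: int
    statistic: str = "log-odds-ratio (Haldane 0.5 on zero cells)"


def hypergeometric_overlap(a, b, background) -> OverlapTest:
    """Exact upper-tail overlap test: ``P(X >= |a & b|)`` for hypergeometric
    X with population ``|background|``, ``|a|`` successes, ``|b|`` draws."""
    a, b, background = set(a), set(b), set(background)
    if not a <= background or not b <= background:
        raise ValueError("both sets must be contained in the background")
    overlap = len(a & b)
    n_bg, n_a, n_b = len(background), len(a), len(b)
    # sf(k-1) is the exact tail sum P(X >= k)
    p = float(sps.hypergeom.sf(overlap - 1, n_bg, n_a, n_b))
    return OverlapTest(n_a, n_b, overlap, n_bg, min(1.0, p))


def _concordant(resA: pd.DataFrame, resB: pd.DataFrame, annotation: pd.DataFrame | None):
    """Merge two result sets on probe, keep concordant signs, genome order."""
    merged = resA.merge(resB, on="probe_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("result sets share no probes")
    if annotation is not None:
        ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
        merged["chromosome"] = [ann.at[p, "chromosome"] for p in merged["probe_id"]]
        merged["position"] = [int(ann.at[p, "position"]) for p in merged["probe_id"]]
        merged = merged.sort_values(["chromosome", "position"], kind="mergesort")
    conc = merged[np.sign(merged["beta_a"]) == np.sign(merged["beta_b"])]
    if conc.empty:
        raise ValueError("no probes with concordant effect direction")
    return conc.reset_index(drop=True)


def _mark_top(p: np.ndarray, beta: np.ndarray, probe_ids: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask of the top ceil(fraction*m) probes by ascending p.

    Ties broken by larger |beta|, then probe id.
    """
    m = p.size
    k = int(np.ceil(fraction * m))
    order = np.lexsort((probe_ids, -np.abs(beta), p))
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def top_hits(
    results: pd.DataFrame,
    fraction: float,
    reference: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> pd.Series:
    """Genome-ordered binary vector marking the top hits of ``results``
    among probes whose effect direction agrees with ``reference``."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    conc = _concordant(results, reference, annotation)
    mask = _mark_top(
        conc["p_a"].to_numpy(), conc["beta_a"].to_numpy(),
        conc["probe_id"].to_numpy(), fraction,
    )
    return pd.Series(mask, index=conc["probe_id"], name=f"top_{fraction:g}")


def _pair_stat(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple:
    a = int(np.sum(mask_a & mask_b))
    b = int(np.sum(mask_a & ~mask_b))
    c = int(np.sum(~mask_a & mask_b))
    d = int(np.sum(~mask_a & ~mask_b))
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5  # Haldane correction
    orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return (a, b, c, d), float(orr), float(np.log(orr))


def circular_enrichment(
    resA: pd.DataFrame,
    resB: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    n_perm: int = 999,
    seed: int = 0,
    annotation: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """Circular-permutation enrichment between two MWAS result sets.

    For every pair of top fractions (fA, fB) the observed 2x2 table of
    A-top x B-top over concordant probes is summarized by its log odds
    ratio.  The null rotates B's indicator vectors by a shared uniform
    offset per permutation (A fixed); per-pair empirical p is the plus-one
    estimator, and the corrected p compares the observed best log OR
    against the per-permutation best over all pairs.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    conc = _concordant(resA, resB, annotation)
    m = len(conc)
    p_a, b_a = conc["p_a"].to_numpy(), conc["beta_a"].to_numpy()
    p_b, b_b = conc["p_b"].to_numpy(), conc["beta_b"].to_numpy()
    ids = conc["probe_id"].to_numpy()

    fractions = sorted(fractions)
    max_k = int(np.ceil(max(fractions) * m))
    if max_k >= m:
        raise ValueError("fewer shared probes than the largest top count")

    masks_a = {f: _mark_top(p_a, b_a, ids, f) for f in fractions}
    masks_b = {f: _mark_top(p_b, b_b, ids, f) for f in fractions}

    pairs: list[PairEnrichment] = []
    obs_stats = {}
    for fa in fractions:
        for fb in fractions:
            table, orr, log_or = _pair_stat(masks_a[fa], masks_b[fb])
            obs_stats[(fa, fb)] = log_or
            pairs.append(PairEnrichment(fa, fb, table, orr, log_or, p_empirical=np.nan))

    rng = np.random.default_rng(seed)
    exceed = {key: 0 for key in obs_stats}
    best_obs = max(obs_stats.values())
    best_exceed = 0
    for _ in range(n_perm):
        offset = int(rng.integers(1, m))  # offset 0 would reproduce the observed table
        perm_best = -np.inf
        for fa in fractions:
            ma = masks_a[fa]
            for fb in fractions:
                mb = np.roll(masks_b[fb], offset)
                _, _, log_or = _pair_stat(ma, mb)
                if log_or >= obs_stats[(fa, fb)]:
                    exceed[(fa, fb)] += 1
                perm_best = max(perm_best, log_or)
        if perm_best >= best_obs:
            best_exceed += 1

    for pe in pairs:
        pe.p_empirical = (1 + exceed[(pe.fraction_a, pe.fraction_b)]) / (1 + n_perm)
    p_corrected = (1 + best_exceed) / (1 + n_perm)
    best_pair = max(obs_stats, key=obs_stats.get)
    return EnrichmentResult(pairs, best_pair, float(p_corrected), n_perm, seed)
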