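"""Comparing CMP-score variation with measured metabolite variation.

Because CMP scores are relative, each metabolite is evaluated on *pairwise
differences* across samples: the vector of signed differences in CMP score
between sample pairs is correlated with the corresponding vector of
differences in measured abundance.  Signed differences over the pair set
are antisymmetric (d_ji = -d_ij), so the correlation is computed over the
full set of ordered pairs - equivalently, an uncentered (cosine)
correlation on the i < j half for Pearson, and the same on signed centered
ranks for Spearman.  This makes the statistic exactly invariant to sample
relabeling while preserving the sign that separates positive from negative
coupling.  Significance comes from a Mantel permutation test: sample
labels of the measured vector are permuted (the permutation unit is the
sample, which respects the dependence among pairs sharing a sample), the
difference vector is recomputed, and one-sided empirical p-values are
taken as

    p_pos = (#{rho_perm >= rho_obs} + 1) / (n_perm + 1)

(and analogously for the lower tail).  Multiple testing is corrected with
Storey q-values, separately for the positive and negative tails; a
metabolite is *well-predicted* when rho > 0 with p_pos and q_pos below the
threshold, and *anti-predicted* when rho < 0 with p_neg and q_neg below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "PredictionConfig",
    "pairwise_differences",
    "mantel_test",
    "MantelResult",
    "compute_qvalues",
    "predict_metabolites",
    "classify",
]

WELL = "well_predicted"
ANTI = "anti_predicted"
NS = "not_significant"
NA = "not_evaluable"


@dataclass
class PredictionConfig:
    """Settings for the per-metabolite Mantel comparison.

    ``correlation`` is 'spearman' (default: prediction level is defined as
    the Spearman correlation of pairwise differences) or 'pearson'.
    """

    n_permutations: int = 10000
    correlation: str = "spearman"
    p_threshold: float = 0.01
    q_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not (0 < self.p_threshold < 1 and 0 < self.q_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError("correlation must be 'spearman' or 'pearson'")


def pairwise_differences(values) -> np.ndarray:
    """Signed differences ``v_i - v_j`` over ordered sample pairs i < j."""
    v = np.asarray(values, dtype=float)
    iu, ju = np.triu_indices(len(v), 1)
    return v[iu] - v[ju]


def _row_cosine(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Uncentered correlation of each row with ``vec`` (NaN where undefined).

    For antisymmetric pair-difference vectors the mean over the full
    ordered-pair set is exactly zero, so the cosine over the i < j half IS
    the Pearson correlation over all ordered pairs.
    """
    num = rows @ vec
    den = np.sqrt((rows**2).sum(axis=1) * (vec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, np.nan)


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    """Centered ranks of each row's differences over the full ordered-pair set.

    Ranks are taken over the concatenation of ``d`` and ``-d`` (the i > j
    half), then centered by the grand mean; the result is an odd function
    of ``d``, which keeps the Spearman statistic invariant to sample
    relabeling.
    """
    D = np.atleast_2d(diffs)
    m = D.shape[1]
    full = np.concatenate([D, -D], axis=1)
    r = rankdata(full, axis=1)[:, :m] - (2 * m + 1) / 2.0
    return r if diffs.ndim > 1 else r[0]


@dataclass
class MantelResult:
    rho: float
    p_pos: float
    p_neg: float
    n_pairs: int
    evaluable: bool = True


def mantel_test(
    cmp_values,
    met_values,
    cfg: PredictionConfig,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test on signed pairwise-difference vectors.

    Samples where either input is missing are excluded up front, which
    removes exactly the pairs with a missing endpoint from both difference
    vectors symmetrically.  Fewer than 3 usable samples, or a
    zero-variance difference vector, yields a non-evaluable result.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    x = np.asarray(cmp_values, dtype=float)
    y = np.asarray(met_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("CMP and metabolite vectors differ in length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    n_pairs = n * (n - 1) // 2
    if n < 3:
        return MantelResult(np.nan, np.nan, np.nan, n_pairs, evaluable=False)

    iu, ju = np.triu_indices(n, 1)
    dx = x[iu] - x[ju]
    dy = y[iu] - y[ju]
    if np.ptp(dx) == 0 or np.ptp(dy) == 0:
        return MantelResult(np.nan, np.nan, np.nan, n_pairs, evaluable=False)

    spearman = cfg.correlation == "spearman"
    a = _signed_ranks(dx) if spearman else dx
    b = _signed_ranks(dy) if spearman else dy
    rho = float(_row_cosine(b[None, :], a)[0])

    P = cfg.n_permutations
    perm = np.tile(y, (P, 1))
    perm = rng.permuted(perm, axis=1)
    d_perm = perm[:, iu] - perm[:, ju]
    if spearman:
        d_perm = _signed_ranks(d_perm)
    rho_perm = _row_cosine(d_perm, a)
    rho_perm = np.nan_to_num(rho_perm, nan=0.0)

    eps = 1e-12
    p_pos = (np.count_nonzero(rho_perm >= rho - eps) + 1) / (P + 1)
    p_neg = (np.count_nonzero(rho_perm <= rho + eps) + 1) / (P + 1)
    return MantelResult(rho, p_pos, p_neg, n_pairs)


def estimate_pi0(pvalues, bandwidth: float = 0.15) -> float:
    """Overall null proportion, estimated with a lambda-grid smoother.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on the
    grid 0.05 ... 0.95 (step 0.05), smoothed with a Gaussian kernel in
    lambda and evaluated at the largest grid point, then clamped to
    (0, 1].  The kernel acts as a boundary-local average, which keeps the
    estimate stable where the raw grid values are noisiest.
    """
    p = np.asarray(pvalues, dtype=float)
    lam = np.arange(0.05, 1.0, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    w = np.exp(-0.5 * ((lam - lam[-1]) / bandwidth) ** 2)
    pi0 = float(np.sum(w * pi0_lam) / np.sum(w))
    return min(max(pi0, 1e-8), 1.0)


def compute_qvalues(pvalues) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    With fewer than 10 p-values the pi0 estimate is unstable, so pi0
    falls back to 1 (equivalent to Benjamini-Hochberg step-up).
    q-values are monotone non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 10:
        log.info("fewer than 10 p-values: using pi0 = 1 (BH step-up)")
        pi0 = 1.0
    else:
        pi0 = estimate_pi0(p)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def predict_metabolites(
    cmp: pd.DataFrame,
    metabolites: pd.DataFrame,
    cfg: PredictionConfig | None = None,
) -> pd.DataFrame:
    """Run the Mantel comparison for every metabolite with a CMP score.

    Returns a DataFrame indexed by metabolite with columns ``rho``,
    ``p_pos``, ``p_neg``, ``n_pairs``, ``q_pos``, ``q_neg`` and ``class``.
    Only metabolites present in both tables are evaluated; samples are
    aligned by identifier.
    """
    cfg = cfg or PredictionConfig()
    shared_samples = [s for s in cmp.columns if s in metabolites.columns]
    if len(shared_samples) < 3:
        raise ValueError("fewer than 3 shared samples")
    shared_mets = [m for m in metabolites.index if m in cmp.index]
    if not shared_mets:
        raise ValueError("no metabolites shared between CMP table and measurements")
    n_unscored = metabolites.shape[0] - len(shared_mets)
    if n_unscored:
        log.info("%d measured metabolite(s) have no CMP score and are skipped", n_unscored)

    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    for met in shared_mets:
        res = mantel_test(
            cmp.loc[met, shared_samples],
            metabolites.loc[met, shared_samples],
            cfg,
            rng=rng,
        )
        rows.append((met, res.rho, res.p_pos, res.p_neg, res.n_pairs, res.evaluable))
    df = pd.DataFrame(
        rows, columns=["metabolite", "rho", "p_pos", "p_neg", "n_pairs", "evaluable"]
    ).set_index("metabolite")
    return classify(df, cfg)


def classify(results: pd.DataFrame, cfg: PredictionConfig | None = None) -> pd.DataFrame:
    """Attach q-values and the well-/anti-predicted class labels.

    q-values are computed separately across metabolites for the positive
    and the negative tails.  ``well_predicted`` requires rho > 0 with both
    p_pos and q_pos below the thresholds; ``anti_predicted`` mirrors this
    on the negative tail.
    """
    cfg = cfg or PredictionConfig()
    df = results.copy()
    ev = df["evaluable"].fillna(False).astype(bool)
    df["q_pos"] = np.nan
    df["q_neg"] = np.nan
    if ev.any():
        df.loc[ev, "q_pos"] = compute_qvalues(df.loc[ev, "p_pos"].to_numpy())
        df.loc[ev, "q_neg"] = compute_qvalues(df.loc[ev, "p_neg"].to_numpy())

    labels = pd.Series(NS, index=df.index, dtype=object)
    labels[~ev] = NA
    well = ev & (df["rho"] > 0) & (df["p_pos"] < cfg.p_threshold) & (df["q_pos"] < cfg.q_threshold)
    anti = ev & (df["rho"] < 0) & (df["p_neg"] < cfg.p_threshold) & (df["q_neg"] < cfg.q_threshold)
    labels[well] = WELL
    labels[anti] = ANTI
    df["class"] = labels
    return df
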