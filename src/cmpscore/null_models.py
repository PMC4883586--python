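"""Null models: randomized metabolic networks and metabolite-label permutation.

Two complementary significance checks guard against artifacts of the data's
covariance structure:

1. *Network randomization* - the signed bipartite gene-metabolite graph is
   shuffled with degree-preserving double-edge swaps restricted to
   same-sign edge pairs (so every gene and metabolite keeps its number of
   producing and consuming links), the model is rebuilt and renormalized,
   and the whole prediction pipeline is re-run.  The empirical p-value
   asks how often a randomized network yields at least as many
   well-predicted metabolites as the real one.

2. *Label permutation adjacency test* - with network topology fixed,
   metabolite labels (and with them the well-/anti-predicted classes) are
   shuffled over node positions to ask whether anti-predicted metabolites
   sit next to well-predicted ones (via synthesizing, depleting or
   reversible links) more often than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmp_scores import compute_cmp
from .prediction import WELL, ANTI, PredictionConfig, predict_metabolites
from .reaction_network import StoichiometricModel

log = logging.getLogger(__name__)

__all__ = [
    "NullModelConfig",
    "shuffle_network",
    "network_null_test",
    "AdjacencyTestResult",
    "adjacency_permutation_test",
]

LINK_TYPES = ("synthesizing", "depleting", "reversible")


@dataclass
class NullModelConfig:
    n_random_networks: int = 100
    n_edge_swaps: int = 5000
    n_label_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_random_networks", "n_edge_swaps", "n_label_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _renormalize_rows(mat: np.ndarray) -> np.ndarray:
    neg = np.where(mat < 0, mat, 0.0)
    pos = np.where(mat > 0, mat, 0.0)
    neg_sum = -neg.sum(axis=1, keepdims=True)
    pos_sum = pos.sum(axis=1, keepdims=True)
    out = np.where(mat < 0, mat / np.where(neg_sum > 0, neg_sum, 1.0), mat)
    out = np.where(mat > 0, out / np.where(pos_sum > 0, pos_sum, 1.0), out)
    return out


def shuffle_network(
    model: StoichiometricModel,
    n_edge_swaps: int = 5000,
    rng: np.random.Generator | None = None,
    max_reject_factor: int = 100,
) -> StoichiometricModel:
    """Degree-preserving randomization of the gene-metabolite graph.

    Edges are the nonzero cells of the model's filtered (pre-normalization)
    matrix, carrying their signed weight.  A swap picks two edges of the
    same sign, ``(m1, g1)`` and ``(m2, g2)``, and rewires them to
    ``(m1, g2)`` and ``(m2, g1)``; swaps that would duplicate an existing
    edge (of either sign) or share a node are rejected.  Every node's
    signed degree (count of positive and of negative links) is conserved.
    Weights travel with their edge and rows are re-sign-normalized after
    rebuilding.

    If fewer than ``n_edge_swaps`` swaps succeed within
    ``max_reject_factor * n_edge_swaps`` attempts, a warning reports the
    achieved count.
    """
    rng = rng or np.random.default_rng()
    mets = model.metabolites
    genes = model.genes
    raw = model.raw.reindex(index=mets, columns=genes, fill_value=0.0).to_numpy(dtype=float)

    mi, gi = np.nonzero(raw)
    weights = raw[mi, gi]
    edges = [[int(m), int(g), float(w)] for m, g, w in zip(mi, gi, weights)]
    pos_idx = [k for k, e in enumerate(edges) if e[2] > 0]
    neg_idx = [k for k, e in enumerate(edges) if e[2] < 0]
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("need at least 2 edges of each sign to shuffle")
    occupied = {(e[0], e[1]) for e in edges}

    prov_by_edge = {
        (mets[e[0]], genes[e[1]]): model.provenance.get((mets[e[0]], genes[e[1]]), [])
        for e in edges
    }

    achieved = 0
    tries = 0
    max_tries = max_reject_factor * n_edge_swaps
    n_pos = len(pos_idx)
    n_all = n_pos + len(neg_idx)
    while achieved < n_edge_swaps and tries < max_tries:
        tries += 1
        pool = pos_idx if rng.integers(n_all) < n_pos else neg_idx
        k1, k2 = rng.choice(len(pool), size=2, replace=False)
        e1, e2 = edges[pool[k1]], edges[pool[k2]]
        m1, g1, w1 = e1
        m2, g2, w2 = e2
        if m1 == m2 or g1 == g2:
            continue
        if (m1, g2) in occupied or (m2, g1) in occupied:
            continue
        occupied.discard((m1, g1))
        occupied.discard((m2, g2))
        e1[1], e2[1] = g2, g1
        occupied.add((m1, g2))
        occupied.add((m2, g1))
        achieved += 1
    if achieved < n_edge_swaps:
        log.warning("achieved only %d of %d requested edge swaps", achieved, n_edge_swaps)

    shuffled = np.zeros_like(raw)
    prov: dict[tuple[str, str], list] = {}
    for m, g, w in edges:
        shuffled[m, g] = w
        # provenance travels with the edge weight it annotated
    # rebuild provenance by matching original edges to their new position
    for k, (m, g, w) in enumerate(edges):
        src_m, src_g = (mi[k], gi[k])
        prov[(mets[m], genes[g])] = prov_by_edge.get((mets[src_m], genes[src_g]), [])

    # signed degree sequences are an invariant of the swap; verify every run
    for sign in (1, -1):
        orig_mask = (raw * sign) > 0
        new_mask = (shuffled * sign) > 0
        if not (
            (orig_mask.sum(axis=0) == new_mask.sum(axis=0)).all()
            and (orig_mask.sum(axis=1) == new_mask.sum(axis=1)).all()
        ):
            raise AssertionError("edge swap violated the signed degree sequence")

    matrix = pd.DataFrame(_renormalize_rows(shuffled), index=mets, columns=genes)
    raw_df = pd.DataFrame(shuffled, index=mets, columns=genes)
    return StoichiometricModel(matrix=matrix, raw=raw_df, provenance=prov)


def network_null_test(
    model: StoichiometricModel,
    G: pd.DataFrame,
    metabolites: pd.DataFrame,
    pred_cfg: PredictionConfig | None = None,
    cfg: NullModelConfig | None = None,
) -> dict:
    """Is the well-predicted count higher than random networks produce?

    Runs the prediction stage end-to-end on ``cfg.n_random_networks``
    randomized models and reports
    ``p = (#{random count >= observed} + 1) / (n + 1)``.
    Replicates that fail are logged and excluded.
    """
    pred_cfg = pred_cfg or PredictionConfig()
    cfg = cfg or NullModelConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    observed = predict_metabolites(compute_cmp(model, G), metabolites, pred_cfg)
    obs_count = int((observed["class"] == WELL).sum())

    random_counts: list[int] = []
    n_failed = 0
    for _ in range(cfg.n_random_networks):
        try:
            shuffled = shuffle_network(model, cfg.n_edge_swaps, rng=rng)
            res = predict_metabolites(compute_cmp(shuffled, G), metabolites, pred_cfg)
            random_counts.append(int((res["class"] == WELL).sum()))
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            log.warning("randomized-network replicate failed: %s", exc)
    if n_failed:
        log.warning("%d of %d replicates failed and were excluded", n_failed, cfg.n_random_networks)
    n = len(random_counts)
    if n == 0:
        raise RuntimeError("all randomized-network replicates failed")
    p = (sum(c >= obs_count for c in random_counts) + 1) / (n + 1)
    return {
        "observed_well_predicted": obs_count,
        "random_counts": random_counts,
        "n_replicates": n,
        "p_value": p,
    }


@dataclass
class AdjacencyTestResult:
    observed: dict[str, int]
    observed_total: int
    p_values: dict[str, float]
    p_total: float
    n_permutations: int
    null_totals: list[int] = field(default_factory=list, repr=False)
    degenerate: bool = False


def adjacency_permutation_test(
    adjacency: list[tuple[str, str, str]],
    classes: pd.Series | dict,
    cfg: NullModelConfig | None = None,
) -> AdjacencyTestResult:
    """Are anti-predicted metabolites adjacent to well-predicted ones?

    Counts unordered anti<->well adjacencies per link type, then permutes
    the metabolite labels over the fixed network topology
    ``cfg.n_label_permutations`` times and reports upper-tail empirical
    p-values per link type and for the total.

    With no anti-predicted or no well-predicted metabolite among the
    network nodes the result is degenerate: all counts 0, p = 1.
    """
    cfg = cfg or NullModelConfig()
    classes = pd.Series(classes)
    nodes = sorted({u for u, _, _ in adjacency} | {v for _, v, _ in adjacency})
    if not nodes:
        return AdjacencyTestResult({t: 0 for t in LINK_TYPES}, 0, {t: 1.0 for t in LINK_TYPES}, 1.0, 0, degenerate=True)
    node_pos = {n: i for i, n in enumerate(nodes)}
    labels = np.array([str(classes.get(n, "")) for n in nodes], dtype=object)
    is_well = labels == WELL
    is_anti = labels == ANTI
    if not is_well.any() or not is_anti.any():
        return AdjacencyTestResult({t: 0 for t in LINK_TYPES}, 0, {t: 1.0 for t in LINK_TYPES}, 1.0, 0, degenerate=True)

    u_idx = np.array([node_pos[u] for u, _, _ in adjacency])
    v_idx = np.array([node_pos[v] for _, v, _ in adjacency])
    t_idx = np.array([LINK_TYPES.index(t) for _, _, t in adjacency])

    def _counts(well: np.ndarray, anti: np.ndarray) -> np.ndarray:
        hit = (well[u_idx] & anti[v_idx]) | (anti[u_idx] & well[v_idx])
        return np.bincount(t_idx[hit], minlength=len(LINK_TYPES))

    obs = _counts(is_well, is_anti)
    rng = np.random.default_rng(cfg.rng_seed)
    n_perm = cfg.n_label_permutations
    ge_type = np.zeros(len(LINK_TYPES), dtype=int)
    ge_total = 0
    null_totals = []
    for _ in range(n_perm):
        perm = rng.permutation(len(nodes))
        c = _counts(is_well[perm], is_anti[perm])
        ge_type += c >= obs
        ge_total += int(c.sum() >= obs.sum())
        null_totals.append(int(c.sum()))

    p_type = {t: float((ge_type[i] + 1) / (n_perm + 1)) for i, t in enumerate(LINK_TYPES)}
    return AdjacencyTestResult(
        observed={t: int(obs[i]) for i, t in enumerate(LINK_TYPES)},
        observed_total=int(obs.sum()),
        p_values=p_type,
        p_total=float((ge_total + 1) / (n_perm + 1)),
        n_permutations=n_perm,
        null_totals=null_totals,
    )
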