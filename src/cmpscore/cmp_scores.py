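"""Community metabolite potential (CMP) scores.

``CMP = M @ G``: the normalized signed impact matrix times the gene
abundance matrix.  A CMP score captures the relative capacity of a
sample's metagenome to accumulate (positive) or deplete (negative) a
metabolite; only *between-sample differences* are meaningful, not absolute
values, and the score is not a flux or concentration prediction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reaction_network import StoichiometricModel

log = logging.getLogger(__name__)

__all__ = ["compute_cmp", "compute_single_taxon_cmp"]


def compute_cmp(model: StoichiometricModel, G: pd.DataFrame) -> pd.DataFrame:
    """Score every modeled metabolite in every sample.

    Genes present in only one of the model and ``G`` are dropped (the model
    defines the enzymatic scope; a logged count records the mismatch).
    Raises when no gene is shared.
    """
    shared = [g for g in model.genes if g in G.index]
    if not shared:
        raise ValueError("no genes shared between model and gene abundance table")
    n_dropped = (len(model.genes) - len(shared)) + (G.shape[0] - len(shared))
    if n_dropped:
        log.info("ignoring %d gene(s) outside the model/abundance overlap", n_dropped)
    return model.matrix[shared] @ G.loc[shared].astype(float)


def compute_single_taxon_cmp(
    model: StoichiometricModel,
    taxa: pd.DataFrame,
    genomes: pd.DataFrame,
    taxon_id: str,
) -> pd.DataFrame:
    """CMP scores a single taxon would generate on its own.

    Equivalent to re-deriving the metagenome from ``taxon_id`` alone (no
    normalization hook, so single-taxon scores stay additive: their sum
    over taxa equals the community CMP).  A taxon with no modeled genes or
    zero abundance everywhere yields an all-zero table.
    """
    if taxon_id not in taxa.index or taxon_id not in genomes.index:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    shared = [g for g in model.genes if g in genomes.columns]
    abund = taxa.loc[taxon_id].astype(float).to_numpy()
    if not shared:
        return pd.DataFrame(
            0.0, index=model.metabolites, columns=taxa.columns
        )
    copies = genomes.loc[taxon_id, shared].astype(float).to_numpy()
    G_t = pd.DataFrame(
        np.outer(copies, abund), index=shared, columns=taxa.columns
    )
    return model.matrix[shared] @ G_t
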