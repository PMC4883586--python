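"""Gene-abundance inference and metabolite-table preprocessing.

The community's metagenome content ``G`` (gene x sample) is either measured
directly (e.g. shotgun metagenomics) or inferred as the product of genome
gene copy numbers and taxon abundances:

    G[g, s] = sum_t abundance[t, s] * copies[t, g]

Measured metabolite tables are preprocessed by summing peaks that map to
the same compound ID and discarding metabolites quantified in too few
samples.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "infer_gene_abundance",
    "collapse_duplicate_metabolites",
    "filter_rare_metabolites",
    "align_samples",
]


def _check_nonnegative(df: pd.DataFrame, name: str) -> None:
    if (df.fillna(0).to_numpy() < 0).any():
        raise ValueError(f"{name} contains negative entries")


def infer_gene_abundance(
    taxa: pd.DataFrame,
    genomes: pd.DataFrame,
    normalizer: Callable[[pd.Series], pd.Series] | None = None,
) -> pd.DataFrame:
    """Infer the gene x sample abundance matrix from community composition.

    Parameters
    ----------
    taxa
        taxa x samples non-negative abundance table.
    genomes
        taxa x genes non-negative copy-number table (reference genome
        annotations).
    normalizer
        Optional per-sample-column transform (e.g. an external copy-number
        correction) applied after the product; default is no normalization.

    Notes
    -----
    Taxa missing from ``genomes`` are dropped with a warning; with no
    overlap at all a ``ValueError`` is raised.  All-zero gene rows are
    dropped.  Without a normalizer the result is linear and additive over
    taxa, which underpins single-taxon contributor analysis.
    """
    _check_nonnegative(taxa, "taxon abundance")
    _check_nonnegative(genomes, "genome content")
    shared = [t for t in taxa.index if t in genomes.index]
    if not shared:
        raise ValueError("no overlapping taxa between abundance and genome tables")
    dropped = len(taxa.index) - len(shared)
    if dropped:
        log.warning("dropping %d taxa without reference genome content", dropped)

    G = genomes.loc[shared].T.astype(float) @ taxa.loc[shared].astype(float)
    if normalizer is not None:
        G = G.apply(normalizer, axis=0)
    G = G.loc[G.abs().sum(axis=1) > 0]
    return G


def collapse_duplicate_metabolites(raw: pd.DataFrame) -> pd.DataFrame:
    """Sum rows sharing a compound ID (multiple peaks, one metabolite).

    Missing values count as 0 when summed with a number; a value that is
    missing in every duplicate row stays missing.
    """
    # min_count=1 keeps all-NaN groups as NaN instead of 0
    return raw.groupby(level=0, sort=False).sum(min_count=1)


def filter_rare_metabolites(table: pd.DataFrame, min_nonzero: int = 5) -> pd.DataFrame:
    """Drop metabolites with nonzero abundance in fewer than ``min_nonzero`` samples.

    A sample counts toward the tally only when its value is present and
    nonzero.  Raises if nothing survives.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    counts = ((table != 0) & table.notna()).sum(axis=1)
    removed = table.index[counts < min_nonzero]
    for met in removed:
        log.info("discarding %s: nonzero in %d < %d samples", met, counts[met], min_nonzero)
    out = table.loc[counts >= min_nonzero]
    if out.empty:
        raise ValueError("all metabolites removed by the rare-metabolite filter")
    return out


def align_samples(*tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict tables to their shared samples, preserving first table's order."""
    shared: Sequence[str] = [
        s for s in tables[0].columns if all(s in t.columns for t in tables[1:])
    ]
    if not shared:
        raise ValueError("no samples shared across tables")
    n_dropped = sum(t.shape[1] - len(shared) for t in tables)
    if n_dropped:
        log.warning("dropping %d unmatched sample column(s) during alignment", n_dropped)
    return [t[list(shared)] for t in tables]
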