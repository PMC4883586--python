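"""Key species, gene, and reaction contributors to CMP scores.

A *key species* for a metabolite is a taxon whose single-taxon CMP score
(computed from that taxon's abundance alone) has Pearson correlation > 0.5
across samples with the community-wide CMP score.  A *key gene* is a gene
whose link to the metabolite, when deleted (the matrix entry zeroed, with
no renormalization), drops the Pearson correlation between the original
and perturbed CMP rows below 0.5.  Every reaction catalysed by a key gene
is a key reaction contributor; a metabolite whose key reactions all
produce it is synthesis-driven, all consume it degradation-driven.

Undefined correlations (constant vectors) follow the limiting behaviour of
the thresholds: a taxon generating a constant (typically zero) score shows
no evidence of contribution and is not key, while a gene whose deletion
leaves a constant score was the only support of that score and is key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmp_scores import compute_cmp, compute_single_taxon_cmp
from .gene_abundance import infer_gene_abundance
from .reaction_network import StoichiometricModel

log = logging.getLogger(__name__)

__all__ = [
    "ContributorConfig",
    "ContributorReport",
    "key_species",
    "key_genes",
    "key_reactions",
    "classify_drive",
    "analyze_contributors",
]


@dataclass
class ContributorConfig:
    species_corr_threshold: float = 0.5  # key if correlation above
    gene_corr_threshold: float = 0.5  # key if correlation below

    def __post_init__(self) -> None:
        for t in (self.species_corr_threshold, self.gene_corr_threshold):
            if not (0 < t < 1):
                raise ValueError("correlation thresholds must lie in (0, 1)")


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between matching rows; NaN where undefined."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, np.nan)


def key_species(
    model: StoichiometricModel,
    taxa: pd.DataFrame,
    genomes: pd.DataFrame,
    community_cmp: pd.DataFrame | None = None,
    cfg: ContributorConfig | None = None,
) -> pd.DataFrame:
    """Correlate each taxon's solo CMP scores with the community scores.

    Returns a tidy frame (metabolite, contributor_id, correlation, is_key).
    ``community_cmp`` must come from an un-normalized gene table so that
    single-taxon scores are additive components of it; when omitted it is
    recomputed internally without a normalizer.
    """
    cfg = cfg or ContributorConfig()
    if community_cmp is None:
        community_cmp = compute_cmp(model, infer_gene_abundance(taxa, genomes))
    comm = community_cmp.to_numpy(dtype=float)
    rows = []
    for taxon in taxa.index:
        if taxon not in genomes.index:
            continue
        solo = compute_single_taxon_cmp(model, taxa, genomes, taxon)
        solo = solo.reindex(index=community_cmp.index, columns=community_cmp.columns, fill_value=0.0)
        corr = _rowwise_pearson(solo.to_numpy(dtype=float), comm)
        for met, r in zip(community_cmp.index, corr):
            rows.append((met, taxon, r, bool(r > cfg.species_corr_threshold) if np.isfinite(r) else False))
    return pd.DataFrame(rows, columns=["metabolite", "contributor_id", "correlation", "is_key"])


def key_genes(
    model: StoichiometricModel,
    G: pd.DataFrame,
    community_cmp: pd.DataFrame | None = None,
    cfg: ContributorConfig | None = None,
) -> pd.DataFrame:
    """Link-deletion analysis: which genes does each CMP score depend on?

    For every nonzero matrix entry M[m, g], the perturbed score row is the
    original minus ``M[m, g] * G[g, :]`` (zeroing the link without
    renormalizing the row).  The gene is key when the Pearson correlation
    between original and perturbed rows falls below the threshold, or when
    the perturbed row is constant (the link was the score's sole support).
    """
    cfg = cfg or ContributorConfig()
    if community_cmp is None:
        community_cmp = compute_cmp(model, G)
    samples = list(community_cmp.columns)
    shared = [g for g in model.genes if g in G.index]
    Gm = G.loc[shared, samples].astype(float)
    rows = []
    for met in community_cmp.index:
        orig = community_cmp.loc[met, samples].to_numpy(dtype=float)
        mrow = model.matrix.loc[met, shared]
        for gene in shared:
            w = mrow[gene]
            if w == 0:
                continue
            pert = orig - w * Gm.loc[gene].to_numpy()
            r = _rowwise_pearson(orig[None, :], pert[None, :])[0]
            is_key = bool(r < cfg.gene_corr_threshold) if np.isfinite(r) else True
            rows.append((met, gene, r, is_key))
    return pd.DataFrame(rows, columns=["metabolite", "contributor_id", "correlation", "is_key"])


def key_reactions(model: StoichiometricModel, gene_report: pd.DataFrame) -> pd.DataFrame:
    """Reactions catalysed by key genes, via per-cell model provenance."""
    rows = []
    key = gene_report[gene_report["is_key"]]
    for met, gene in zip(key["metabolite"], key["contributor_id"]):
        for rid, role, _coeff in model.provenance.get((met, gene), []):
            rows.append((met, rid, role, gene))
    df = pd.DataFrame(rows, columns=["metabolite", "reaction_id", "role", "gene"])
    return df.drop_duplicates(subset=["metabolite", "reaction_id", "role"]).reset_index(drop=True)


def classify_drive(reaction_report: pd.DataFrame, metabolites) -> pd.Series:
    """Per-metabolite drive label from key reaction roles.

    All key reactions produce the metabolite -> ``synthesis``; all consume
    it -> ``degradation``; both roles present -> ``mixed``; no key
    reactions -> ``none``.
    """
    drive = pd.Series("none", index=pd.Index(metabolites, name="metabolite"), dtype=object)
    for met, grp in reaction_report.groupby("metabolite"):
        roles = set(grp["role"])
        if roles == {"produces"}:
            drive[met] = "synthesis"
        elif roles == {"consumes"}:
            drive[met] = "degradation"
        elif roles:
            drive[met] = "mixed"
    return drive


@dataclass
class ContributorReport:
    species: pd.DataFrame
    genes: pd.DataFrame
    reactions: pd.DataFrame
    drive: pd.Series

    def to_tidy(self) -> pd.DataFrame:
        """Single long-format table of all contributor records."""
        sp = self.species.assign(contributor_type="species", role="", drive="")
        gn = self.genes.assign(contributor_type="gene", role="", drive="")
        rx = self.reactions.rename(columns={"reaction_id": "contributor_id"}).assign(
            contributor_type="reaction", correlation=np.nan, is_key=True
        )
        rx["drive"] = self.drive.reindex(rx["metabolite"]).to_numpy()
        cols = ["metabolite", "contributor_type", "contributor_id", "correlation", "is_key", "role", "drive"]
        return pd.concat([sp[cols], gn[cols], rx[cols]], ignore_index=True)


def analyze_contributors(
    model: StoichiometricModel,
    taxa: pd.DataFrame,
    genomes: pd.DataFrame,
    cfg: ContributorConfig | None = None,
) -> ContributorReport:
    """Full contributor analysis from community composition tables."""
    cfg = cfg or ContributorConfig()
    G = infer_gene_abundance(taxa, genomes)
    community_cmp = compute_cmp(model, G)
    sp = key_species(model, taxa, genomes, community_cmp, cfg)
    gn = key_genes(model, G, community_cmp, cfg)
    rx = key_reactions(model, gn)
    drive = classify_drive(rx, community_cmp.index)
    return ContributorReport(species=sp, genes=gn, reactions=rx, drive=drive)
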