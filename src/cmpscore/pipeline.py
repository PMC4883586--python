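"""End-to-end pipeline orchestration: files in, reports out.

Stages: reaction network construction -> gene abundance (inferred from
taxa + genomes, or supplied directly) -> CMP scores -> Mantel prediction ->
contributor analysis -> optional null models.  All stage outputs are
written as TSV next to a JSON summary of counts, seeds and dropped-feature
tallies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .contributors import ContributorConfig, analyze_contributors
from .cmp_scores import compute_cmp
from .gene_abundance import (
    align_samples,
    collapse_duplicate_metabolites,
    filter_rare_metabolites,
    infer_gene_abundance,
)
from .null_models import (
    NullModelConfig,
    adjacency_permutation_test,
    network_null_test,
)
from .prediction import ANTI, WELL, PredictionConfig, predict_metabolites
from .reaction_network import (
    NetworkFilterConfig,
    build_model,
    metabolite_adjacency,
    parse_reaction_map,
    resolve_directions,
    write_model,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_by_category"]


@dataclass
class RunConfig:
    """Paths and stage settings for one pipeline run.

    Either (``taxa_path`` and ``genomes_path``) or ``gene_abundance_path``
    must be provided.
    """

    reactions_path: str = ""
    gene_map_path: str = ""
    metabolites_path: str = ""
    output_dir: str = "cmpscore_out"
    taxa_path: str | None = None
    genomes_path: str | None = None
    gene_abundance_path: str | None = None
    coefficients_path: str | None = None
    min_nonzero_samples: int = 5
    run_contributors: bool = True
    run_network_null: bool = False
    run_adjacency_test: bool = True
    network: NetworkFilterConfig = field(default_factory=NetworkFilterConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    contributors: ContributorConfig = field(default_factory=ContributorConfig)
    null_models: NullModelConfig = field(default_factory=NullModelConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, sub in (
            ("network", NetworkFilterConfig),
            ("prediction", PredictionConfig),
            ("contributors", ContributorConfig),
            ("null_models", NullModelConfig),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("reactions_path", "gene_map_path", "metabolites_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p!r} does not exist")
        has_taxa = self.taxa_path and self.genomes_path
        if not has_taxa and not self.gene_abundance_path:
            raise ValueError(
                "provide either taxa_path + genomes_path or gene_abundance_path"
            )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the JSON-ready summary."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- reaction network
    coeffs = (
        cio.read_coefficient_table(cfg.coefficients_path)
        if cfg.coefficients_path
        else None
    )
    entries = _stage("reaction_network")(parse_reaction_map)(
        cio.read_reaction_lines(cfg.reactions_path), coeffs
    )
    directions = resolve_directions(entries)
    gene_map = cio.read_gene_reaction_map(cfg.gene_map_path)
    model = _stage("reaction_network")(build_model)(entries, directions, gene_map, cfg.network)
    write_model(model, outdir / "model_matrix.tsv", outdir / "model_provenance.tsv")

    # --- gene abundance
    taxa = genomes = None
    if cfg.taxa_path and cfg.genomes_path:
        taxa = cio.read_feature_table(cfg.taxa_path)
        genomes = cio.read_feature_table(cfg.genomes_path)
        G = _stage("gene_abundance")(infer_gene_abundance)(taxa, genomes)
    else:
        G = cio.read_feature_table(cfg.gene_abundance_path)
    cio.write_feature_table(G, outdir / "gene_abundance.tsv", index_label="gene")

    # --- metabolite preprocessing
    mets_raw = cio.read_feature_table(cfg.metabolites_path)
    n_raw = mets_raw.shape[0]
    mets = collapse_duplicate_metabolites(mets_raw)
    mets = _stage("metabolite_preprocessing")(filter_rare_metabolites)(
        mets, cfg.min_nonzero_samples
    )
    G, mets = align_samples(G, mets)
    if taxa is not None:
        taxa = taxa[G.columns]

    # --- CMP + prediction
    cmp = _stage("cmp_scores")(compute_cmp)(model, G)
    cio.write_feature_table(cmp, outdir / "cmp_scores.tsv", index_label="compound")
    results = _stage("prediction")(predict_metabolites)(cmp, mets, cfg.prediction)
    results.to_csv(outdir / "predictions.tsv", sep="\t")

    class_counts = results["class"].value_counts().to_dict()
    n_eval = int(results["evaluable"].sum())
    summary = {
        "version": __version__,
        "n_metabolites_measured": int(n_raw),
        "n_metabolites_modeled": len(model.metabolites),
        "n_metabolites_evaluated": int(results.shape[0]),
        "n_metabolites_evaluable": n_eval,
        "n_genes_modeled": len(model.genes),
        "n_samples": int(G.shape[1]),
        "class_counts": {k: int(v) for k, v in class_counts.items()},
        "well_predicted_fraction": float((results["class"] == WELL).sum() / max(n_eval, 1)),
        "anti_predicted_fraction": float((results["class"] == ANTI).sum() / max(n_eval, 1)),
        "seeds": {
            "prediction": cfg.prediction.rng_seed,
            "null_models": cfg.null_models.rng_seed,
        },
    }

    # --- contributors
    if cfg.run_contributors and taxa is not None:
        report = _stage("contributors")(analyze_contributors)(
            model, taxa, genomes, cfg.contributors
        )
        report.to_tidy().to_csv(outdir / "contributors.tsv", sep="\t", index=False)
        key_sp = report.species[report.species["is_key"]]
        summary["n_key_species_records"] = int(key_sp.shape[0])
        summary["n_key_gene_records"] = int(report.genes["is_key"].sum())

    # --- null models
    adjacency = metabolite_adjacency(model, entries, directions)
    if cfg.run_adjacency_test:
        adj = _stage("adjacency_test")(adjacency_permutation_test)(
            adjacency, results["class"], cfg.null_models
        )
        summary["adjacency_test"] = {
            "observed": adj.observed,
            "observed_total": adj.observed_total,
            "p_values": adj.p_values,
            "p_total": adj.p_total,
            "degenerate": adj.degenerate,
        }
    if cfg.run_network_null:
        nt = _stage("network_null")(network_null_test)(
            model, G, mets, cfg.prediction, cfg.null_models
        )
        summary["network_null"] = {
            "observed_well_predicted": nt["observed_well_predicted"],
            "random_counts": nt["random_counts"],
            "p_value": nt["p_value"],
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def summarize_by_category(
    results: pd.DataFrame, category_map: dict[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Class counts per metabolite category (unmapped -> 'unassigned')."""
    category_map = pd.Series(category_map if category_map is not None else {}, dtype=object)
    cats = pd.Series(
        [category_map.get(m, "unassigned") for m in results.index], index=results.index
    )
    out = (
        results.assign(category=cats)
        .groupby("category")["class"]
        .value_counts()
        .unstack(fill_value=0)
    )
    out.columns.name = None
    return out
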