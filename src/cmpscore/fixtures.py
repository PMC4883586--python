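"""Synthetic communities with planted metabolite-control ground truth.

The generator emulates the data a taxonomy-metabolomics integration study
collects: sparse log-normal taxon abundances, binary genome gene content,
a KEGG-dialect reaction file linking genes to metabolites, and measured
metabolite abundances that are linear-plus-noise functions of the true
community metabolite potential.  Each measured metabolite is planted as

- *producer-controlled*: abundance = coupling * z(CMP) + noise, so its
  variation should be recovered as well-predicted;
- *consumer-controlled*: abundance = -coupling * z(CMP) + noise
  (environment/consumer control), recoverable as anti-predicted;
- *null*: pure noise, independent of the community.

Every metabolite ``M_i`` is produced from a dedicated precursor compound
``X_i`` by one reaction ``R_i`` catalysed by one gene; the taxa carrying
that gene are the metabolite's generating taxa.  Decoy content exercises
the model filters: a currency compound attached as a by-product to many
reactions (removed by the currency filter when enough genes are involved)
and reversible reactions (excluded by the directionality filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cmp_scores import compute_cmp
from .gene_abundance import infer_gene_abundance
from .reaction_network import NetworkFilterConfig, build_model, parse_reaction_map, resolve_directions

log = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "FixtureTruth", "Fixture", "generate_fixture", "evaluate_recovery"]

PRODUCER = "should_be_well_predicted"
CONSUMER = "should_be_anti_predicted"
NULL = "null"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic community experiment.

    Defaults describe the standard planted experiment: 20 samples, 30% of
    metabolites producer-controlled and 20% consumer-controlled at a 3:1
    signal-to-noise ratio (coupling 3.0 against unit noise), the rest
    independent of the community.
    """

    n_taxa: int = 12
    n_genes: int = 60
    n_metabolites: int = 60
    n_samples: int = 20
    frac_producer_controlled: float = 0.3
    frac_consumer_controlled: float = 0.2
    frac_independent: float = 0.5
    coupling_strength: float = 3.0
    noise_sd: float = 1.0
    genome_density: float = 0.1
    sparsity: float = 0.2  # probability a taxon abundance is zeroed in a sample
    n_reversible_decoys: int = 4
    n_currency_decoys: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_producer_controlled
            + self.frac_consumer_controlled
            + self.frac_independent
        )
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError("control-class fractions must sum to 1")
        if self.n_samples < 6:
            raise ValueError("need at least 6 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be non-negative")
        if self.n_metabolites > self.n_genes:
            raise ValueError(
                "infeasible spec: each planted metabolite needs its own gene "
                f"({self.n_metabolites} metabolites > {self.n_genes} genes)"
            )


@dataclass
class FixtureTruth:
    """Planted ground truth: control class and generators per metabolite."""

    classes: dict[str, str]
    generating_taxa: dict[str, set[str]]
    generating_genes: dict[str, set[str]]


@dataclass
class Fixture:
    taxa: pd.DataFrame  # taxa x samples
    genomes: pd.DataFrame  # taxa x genes
    reaction_lines: list[str]
    gene_map: dict[str, set[str]]
    metabolites: pd.DataFrame  # measured metabolites x samples
    truth: FixtureTruth
    cmp_true: pd.DataFrame = field(repr=False)

    def write(self, outdir) -> dict[str, Path]:
        """Write all inputs in the formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reactions": outdir / "reactions.lst",
            "gene_map": outdir / "gene_reaction_map.tsv",
            "taxa": outdir / "taxon_abundance.tsv",
            "genomes": outdir / "genome_content.tsv",
            "metabolites": outdir / "metabolite_abundance.tsv",
            "truth": outdir / "truth.tsv",
        }
        paths["reactions"].write_text("\n".join(self.reaction_lines) + "\n")
        cio.write_gene_reaction_map(self.gene_map, paths["gene_map"])
        cio.write_feature_table(self.taxa, paths["taxa"], index_label="taxon")
        cio.write_feature_table(self.genomes, paths["genomes"], index_label="taxon")
        cio.write_feature_table(self.metabolites, paths["metabolites"], index_label="compound")
        truth_df = pd.DataFrame(
            {
                "class": pd.Series(self.truth.classes),
                "generating_taxa": {
                    m: ",".join(sorted(v)) for m, v in self.truth.generating_taxa.items()
                },
                "generating_genes": {
                    m: ",".join(sorted(v)) for m, v in self.truth.generating_genes.items()
                },
            }
        )
        truth_df.to_csv(paths["truth"], sep="\t", index_label="compound")
        return paths


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate one fully reproducible synthetic study from its spec."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.rng_seed)

    samples = [f"S{i+1:02d}" for i in range(spec.n_samples)]
    taxa_ids = [f"T{i+1:02d}" for i in range(spec.n_taxa)]
    gene_ids = [f"K{i+1:05d}" for i in range(spec.n_genes)]
    met_ids = [f"C{i+1:05d}" for i in range(spec.n_metabolites)]
    pre_ids = [f"X{i+1:05d}" for i in range(spec.n_metabolites)]

    # --- taxon abundances: log-normal with sparsity-driven zeroing
    abund = rng.lognormal(mean=0.0, sigma=1.0, size=(spec.n_taxa, spec.n_samples))
    abund[rng.random(abund.shape) < spec.sparsity] = 0.0
    taxa = pd.DataFrame(abund, index=taxa_ids, columns=samples)

    # --- genome content: guaranteed generating carrier + Bernoulli background
    genomes = (rng.random((spec.n_taxa, spec.n_genes)) < spec.genome_density).astype(int)
    for i in range(spec.n_metabolites):
        genomes[i % spec.n_taxa, i] = 1  # round-robin generating taxon carries gene i
    genomes = pd.DataFrame(genomes, index=taxa_ids, columns=gene_ids)

    # --- reactions: gene i catalyses R_i: X_i => M_i (+ currency by-product)
    currency_ids = [f"CUR{i+1:03d}" for i in range(spec.n_currency_decoys)]
    lines: list[str] = []
    gene_map: dict[str, set[str]] = {}
    for i, (met, pre) in enumerate(zip(met_ids, pre_ids)):
        rid = f"R{i+1:05d}"
        rhs = met
        if currency_ids:
            rhs += " + " + currency_ids[i % spec.n_currency_decoys]
        lines.append(f"{rid}: 00010: {pre} => {rhs}")
        gene_map.setdefault(gene_ids[i], set()).add(rid)
    # spare genes (no planted metabolite) catalyse nothing; reversible decoys
    # attach to the first few genes and contribute no directional signal
    n_rev = min(spec.n_reversible_decoys, spec.n_metabolites // 2)
    for k in range(n_rev):
        rid = f"RV{k+1:04d}"
        a, b = met_ids[2 * k], met_ids[2 * k + 1]
        lines.append(f"{rid}: 00020: {a} <=> {b}")
        gene_map.setdefault(gene_ids[k], set()).add(rid)

    entries = parse_reaction_map(lines)
    directions = resolve_directions(entries)
    model = build_model(entries, directions, gene_map, NetworkFilterConfig())

    # --- true CMP through the production code path
    G = infer_gene_abundance(taxa, genomes)
    cmp_true = compute_cmp(model, G)

    # --- planted classes (deterministic shuffle of the class layout)
    n_prod = int(round(spec.frac_producer_controlled * spec.n_metabolites))
    n_cons = int(round(spec.frac_consumer_controlled * spec.n_metabolites))
    classes_flat = (
        [PRODUCER] * n_prod
        + [CONSUMER] * n_cons
        + [NULL] * (spec.n_metabolites - n_prod - n_cons)
    )
    rng.shuffle(classes_flat)
    classes = dict(zip(met_ids, classes_flat))

    met_values = np.empty((spec.n_metabolites, spec.n_samples))
    for i, met in enumerate(met_ids):
        noise = rng.normal(0.0, spec.noise_sd, spec.n_samples)
        signal = np.zeros(spec.n_samples)
        cls = classes[met]
        if cls != NULL and spec.coupling_strength > 0:
            row = cmp_true.loc[met].to_numpy(dtype=float)
            sd = row.std()
            if sd == 0:  # degenerate community signal: demote to null
                classes[met] = NULL
                log.warning("%s has constant CMP; planted as null instead", met)
            else:
                z = (row - row.mean()) / sd
                sign = 1.0 if cls == PRODUCER else -1.0
                signal = sign * spec.coupling_strength * z
        met_values[i] = 10.0 + signal + noise  # baseline keeps values abundance-like
    if spec.coupling_strength == 0:
        classes = {m: NULL for m in met_ids}
    metabolites = pd.DataFrame(met_values, index=met_ids, columns=samples)

    generating_taxa = {
        met: {
            t
            for t in taxa_ids
            if genomes.at[t, gene_ids[i]] > 0 and taxa.loc[t].sum() > 0
        }
        for i, met in enumerate(met_ids)
    }
    generating_genes = {met: {gene_ids[i]} for i, met in enumerate(met_ids)}
    truth = FixtureTruth(classes, generating_taxa, generating_genes)

    return Fixture(
        taxa=taxa,
        genomes=genomes,
        reaction_lines=lines,
        gene_map=gene_map,
        metabolites=metabolites,
        truth=truth,
        cmp_true=cmp_true,
    )


def evaluate_recovery(truth: FixtureTruth, results: pd.DataFrame) -> dict:
    """Confusion counts and rates of planted-class recovery.

    ``results`` is the classified prediction table.  Well-predicted
    recovery is scored against the producer-controlled class,
    anti-predicted recovery against the consumer-controlled class, and
    null specificity is the fraction of null metabolites left unflagged.
    """
    from .prediction import ANTI, WELL

    cls = results["class"]
    planted = pd.Series(truth.classes)
    planted = planted.reindex(cls.index)

    def _rates(target_class: str, predicted_label: str) -> dict:
        in_class = planted == target_class
        out_class = planted.notna() & ~in_class
        tp = int((in_class & (cls == predicted_label)).sum())
        fn = int(in_class.sum()) - tp
        fp = int((out_class & (cls == predicted_label)).sum())
        tn = int(out_class.sum()) - fp
        sens = tp / max(tp + fn, 1)
        spec_ = tn / max(tn + fp, 1)
        return {"tp": tp, "fn": fn, "fp": fp, "tn": tn, "sensitivity": sens, "specificity": spec_}

    nulls = planted == NULL
    null_spec = float(((cls != WELL) & (cls != ANTI) & nulls).sum() / max(nulls.sum(), 1))
    return {
        "producer": _rates(PRODUCER, WELL),
        "consumer": _rates(CONSUMER, ANTI),
        "null_specificity": null_spec,
        "n_metabolites": int(planted.notna().sum()),
    }
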