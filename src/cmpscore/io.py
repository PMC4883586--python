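"""TSV readers and writers for the tables the pipeline exchanges.

All feature tables share one layout: first column = feature identifier
(taxon, KO, or KEGG compound), header row = sample identifiers.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature x sample TSV (first column = feature ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def write_feature_table(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gene_reaction_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV ``gene<TAB>reaction_id`` into a mapping."""
    out: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            gene, rid = parts
            out[gene].add(rid)
    if not out:
        raise ValueError(f"{path}: empty gene-reaction map")
    return dict(out)


def write_gene_reaction_map(gene_map: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_map):
            for rid in sorted(gene_map[gene]):
                fh.write(f"{gene}\t{rid}\n")


def read_coefficient_table(path) -> dict[str, dict[str, float]]:
    """Read a TSV ``reaction_id<TAB>compound_id<TAB>coefficient``."""
    out: dict[str, dict[str, float]] = defaultdict(dict)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            rid, cid, coeff = parts
            out[rid][cid] = float(coeff)
    return dict(out)


def read_reaction_lines(path) -> list[str]:
    return Path(path).read_text().splitlines()
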