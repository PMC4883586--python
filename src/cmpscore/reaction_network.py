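"""Stoichiometric gene-metabolite impact network construction.

Builds the signed metabolite x gene matrix ``M`` at the heart of community
metabolite potential (CMP) scoring.  For every irreversible reaction
catalysed by an enzyme coded by gene *x* that converts substrate *A* (with
stoichiometric coefficient *c*) into product *B* (coefficient *d*), the raw
matrix receives ``M[A, x] -= c`` and ``M[B, x] += d``.  Reversible reactions
carry no directional information and are excluded, as are ubiquitous
"currency" metabolites (cofactor-like compounds touched by reactions that
are associated with many genes).  Finally each row is sign-normalized so
that its negative entries sum to -1 and its positive entries sum to +1,
making each cell the *relative* capacity of a gene to deplete or accumulate
a metabolite.

Reaction input follows the KEGG ``reaction_mapformula.lst`` dialect::

    R00001: 00010: C00001 + C00002 => C00003
    R00002: 00020: C00004 <=> C00005

with one line per (reaction, pathway) occurrence and direction arrows
``=>``, ``<=`` or ``<=>``.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "ReactionEntry",
    "NetworkFilterConfig",
    "StoichiometricModel",
    "parse_reaction_map",
    "resolve_directions",
    "build_model",
    "metabolite_adjacency",
    "write_model",
]


class Direction(str, Enum):
    """Resolved reaction directionality."""

    FORWARD = "forward"
    REVERSIBLE = "reversible"


@dataclass(frozen=True)
class ReactionEntry:
    """One reaction occurrence in one pathway context.

    ``substrates`` and ``products`` are tuples of ``(compound_id,
    coefficient)`` pairs with all coefficients positive.  Lines written with
    the ``<=`` arrow are normalized at parse time by swapping sides, so a
    stored entry is either ``FORWARD`` (left-to-right) or ``REVERSIBLE``.
    """

    reaction_id: str
    pathway_id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    direction: Direction

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"{self.reaction_id}: empty reaction side")
        subs = {c for c, _ in self.substrates}
        prods = {c for c, _ in self.products}
        if subs & prods:
            raise ValueError(
                f"{self.reaction_id}: compounds {sorted(subs & prods)} appear on both sides"
            )
        for c, k in self.substrates + self.products:
            if not k > 0:
                raise ValueError(f"{self.reaction_id}: non-positive coefficient for {c}")


@dataclass
class NetworkFilterConfig:
    """Filtering rules applied while building the impact matrix.

    currency_gene_cutoff
        A metabolite connected (after the directionality filter) to
        reactions associated with at least this many distinct genes is
        treated as a currency metabolite and removed.  Default 30.
    drop_reversible
        Exclude reversible reactions from the matrix (the standard
        behaviour; setting this to False treats every reaction as forward
        in its as-written orientation, for exploration only).
    """

    currency_gene_cutoff: int = 30
    drop_reversible: bool = True

    def __post_init__(self) -> None:
        if self.currency_gene_cutoff < 1:
            raise ValueError("currency_gene_cutoff must be >= 1")


#: provenance record: (reaction_id, role, raw coefficient)
ProvRecord = tuple[str, str, float]


@dataclass
class StoichiometricModel:
    """Normalized signed metabolite x gene impact matrix with provenance.

    Attributes
    ----------
    matrix
        metabolites x genes DataFrame after filtering and row
        sign-normalization (negatives sum to -1, positives to +1 per row).
    raw
        The unfiltered accumulated matrix before currency filtering,
        pruning and normalization (kept for auditing and randomization).
    provenance
        ``(metabolite, gene) -> [(reaction_id, 'produces'|'consumes',
        coefficient), ...]`` for every nonzero cell of ``matrix``.
    """

    matrix: pd.DataFrame
    raw: pd.DataFrame
    provenance: dict[tuple[str, str], list[ProvRecord]] = field(repr=False)

    @property
    def metabolites(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)


_LINE_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([^:\s]+)\s*:\s*(.+?)\s*$")
_ARROW_RE = re.compile(r"\s*(<=>|=>|<=)\s*")


def _parse_side(side: str) -> dict[str, float] | None:
    """Split a `+`-separated compound list; duplicates sum. None if malformed."""
    out: dict[str, float] = {}
    for token in side.split("+"):
        token = token.strip()
        if not token or ":" in token:
            return None
        out[token] = out.get(token, 0.0) + 1.0
    return out or None


def parse_reaction_map(
    lines: Iterable[str],
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
) -> list[ReactionEntry]:
    """Parse reaction lines in the ``reaction_mapformula.lst`` dialect.

    Parameters
    ----------
    lines
        Iterable of text lines ``RID: PATHID: LHS <dir> RHS``.
    coefficients
        Optional ``reaction_id -> {compound_id: coefficient}`` overrides;
        compounds absent from the table default to coefficient 1.

    Returns
    -------
    One :class:`ReactionEntry` per well-formed line.  ``<=`` lines are
    normalized by swapping sides (direction becomes forward).  Malformed
    lines (bad structure, empty side, a compound on both sides) are skipped
    with a logged warning and counted.

    Raises
    ------
    ValueError
        If the input is empty / yields no entries, or if the coefficient
        table references a compound unknown to its reaction.
    """
    coefficients = coefficients or {}
    entries: list[ReactionEntry] = []
    n_seen = 0
    n_bad = 0
    compounds_by_rid: dict[str, set[str]] = defaultdict(set)

    for line in lines:
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        n_seen += 1
        m = _LINE_RE.match(line)
        if not m:
            n_bad += 1
            log.warning("skipping malformed reaction line: %r", line.strip())
            continue
        rid, pid, formula = m.groups()
        parts = _ARROW_RE.split(formula)
        if len(parts) != 3:
            n_bad += 1
            log.warning("skipping line without a single direction arrow: %r", line.strip())
            continue
        lhs_txt, arrow, rhs_txt = parts
        lhs = _parse_side(lhs_txt)
        rhs = _parse_side(rhs_txt)
        if lhs is None or rhs is None or set(lhs) & set(rhs):
            n_bad += 1
            log.warning("skipping malformed reaction sides: %r", line.strip())
            continue
        if arrow == "<=":  # normalize right-to-left reactions by swapping sides
            lhs, rhs = rhs, lhs
            direction = Direction.FORWARD
        elif arrow == "=>":
            direction = Direction.FORWARD
        else:
            direction = Direction.REVERSIBLE

        table = coefficients.get(rid, {})

        def _pairs(side: dict[str, float]) -> tuple[tuple[str, float], ...]:
            return tuple(
                (c, float(table.get(c, dup))) for c, dup in sorted(side.items())
            )

        entries.append(ReactionEntry(rid, pid, _pairs(lhs), _pairs(rhs), direction))
        compounds_by_rid[rid].update(lhs)
        compounds_by_rid[rid].update(rhs)

    if n_seen == 0:
        raise ValueError("empty reaction input")
    if not entries:
        raise ValueError("no reaction lines could be parsed")
    if n_bad:
        log.warning("skipped %d malformed reaction line(s)", n_bad)

    for rid, table in coefficients.items():
        if rid in compounds_by_rid:
            unknown = set(table) - compounds_by_rid[rid]
            if unknown:
                raise ValueError(
                    f"coefficient table references unknown compound(s) "
                    f"{sorted(unknown)} for reaction {rid}"
                )
    return entries


def resolve_directions(entries: list[ReactionEntry]) -> dict[str, Direction]:
    """Resolve one direction per reaction across its pathway occurrences.

    A reaction is forward-only when every occurrence agrees on one
    orientation; an occurrence annotated reversible anywhere, or two
    occurrences with opposite orientations, makes the reaction reversible
    (the conservative choice, since conflicting annotations carry no usable
    directional signal).
    """
    if not entries:
        raise ValueError("no reaction entries")
    grouped: dict[str, list[ReactionEntry]] = defaultdict(list)
    for e in entries:
        grouped[e.reaction_id].append(e)

    out: dict[str, Direction] = {}
    for rid, group in grouped.items():
        if any(e.direction is Direction.REVERSIBLE for e in group):
            out[rid] = Direction.REVERSIBLE
            continue
        subs: set[str] = set()
        prods: set[str] = set()
        direction = Direction.FORWARD
        for e in group:
            s = {c for c, _ in e.substrates}
            p = {c for c, _ in e.products}
            if s & prods or p & subs:
                direction = Direction.REVERSIBLE
                break
            subs |= s
            prods |= p
        out[rid] = direction
    return out


def _canonical_sides(
    entries: list[ReactionEntry],
    directions: Mapping[str, Direction],
    include_reversible: bool = False,
) -> dict[str, tuple[dict[str, float], dict[str, float]]]:
    """Union substrate/product sets per reaction over pathway occurrences."""
    sides: dict[str, tuple[dict[str, float], dict[str, float]]] = {}
    for e in entries:
        d = directions[e.reaction_id]
        if d is Direction.REVERSIBLE and not include_reversible:
            continue
        subs, prods = sides.setdefault(e.reaction_id, ({}, {}))
        for c, k in e.substrates:
            subs[c] = max(subs.get(c, 0.0), k)
        for c, k in e.products:
            prods[c] = max(prods.get(c, 0.0), k)
    return sides


def build_model(
    entries: list[ReactionEntry],
    directions: Mapping[str, Direction],
    gene_map: Mapping[str, set[str]],
    cfg: NetworkFilterConfig | None = None,
) -> StoichiometricModel:
    """Accumulate, filter and normalize the metabolite x gene impact matrix.

    Pipeline: directionality filter (reversible reactions contribute
    nothing) -> currency-metabolite filter (metabolites whose surviving
    reactions associate with ``cfg.currency_gene_cutoff`` or more distinct
    genes are removed) -> zero-row/zero-column pruning -> per-row sign
    normalization (negatives sum to -1, positives to +1).

    Raises ``ValueError("empty model")`` when every row is filtered away.
    """
    cfg = cfg or NetworkFilterConfig()
    for g, rids in gene_map.items():
        if not rids:
            raise ValueError(f"gene {g} maps to no reactions")

    usable = _canonical_sides(
        entries, directions, include_reversible=not cfg.drop_reversible
    )

    raw: dict[tuple[str, str], float] = defaultdict(float)
    prov: dict[tuple[str, str], list[ProvRecord]] = defaultdict(list)
    for gene in sorted(gene_map):
        for rid in sorted(gene_map[gene]):
            if rid not in usable:
                continue
            subs, prods = usable[rid]
            for c, k in subs.items():
                raw[(c, gene)] -= k
                prov[(c, gene)].append((rid, "consumes", k))
            for c, k in prods.items():
                raw[(c, gene)] += k
                prov[(c, gene)].append((rid, "produces", k))

    if not raw:
        raise ValueError("empty model: gene map references no usable reactions")

    mets = sorted({m for m, _ in raw})
    genes = sorted({g for _, g in raw})
    raw_df = pd.DataFrame(0.0, index=mets, columns=genes)
    for (m, g), v in raw.items():
        raw_df.at[m, g] = v

    # currency filter: distinct genes associated via gene_map with any
    # surviving reaction touching the metabolite
    reaction_genes: dict[str, set[str]] = defaultdict(set)
    for gene, rids in gene_map.items():
        for rid in rids:
            if rid in usable:
                reaction_genes[rid].add(gene)
    met_genes: dict[str, set[str]] = defaultdict(set)
    for rid, (subs, prods) in usable.items():
        for c in (*subs, *prods):
            met_genes[c] |= reaction_genes[rid]
    currency = [m for m in mets if len(met_genes[m]) >= cfg.currency_gene_cutoff]
    if currency:
        log.info("removing %d currency metabolite(s): %s", len(currency), currency)

    mat = raw_df.drop(index=currency)
    mat = mat.loc[mat.abs().sum(axis=1) > 0, :]
    if mat.empty:
        raise ValueError("empty model")
    mat = mat.loc[:, mat.abs().sum(axis=0) > 0]

    norm = mat.to_numpy(copy=True)
    neg = np.where(norm < 0, norm, 0.0)
    pos = np.where(norm > 0, norm, 0.0)
    neg_sum = -neg.sum(axis=1, keepdims=True)
    pos_sum = pos.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(norm < 0, norm / np.where(neg_sum > 0, neg_sum, 1.0), norm)
        norm = np.where(norm > 0, norm / np.where(pos_sum > 0, pos_sum, 1.0), norm)
    matrix = pd.DataFrame(norm, index=mat.index, columns=mat.columns)

    kept_prov = {
        (m, g): records
        for (m, g), records in prov.items()
        if m in matrix.index and g in matrix.columns and matrix.at[m, g] != 0
    }
    return StoichiometricModel(matrix=matrix, raw=raw_df, provenance=kept_prov)


def metabolite_adjacency(
    model: StoichiometricModel | None,
    entries: list[ReactionEntry],
    directions: Mapping[str, Direction],
) -> list[tuple[str, str, str]]:
    """Metabolite-metabolite links implied by shared reactions.

    Returns ``(met_u, met_v, link_type)`` records where ``link_type`` is

    - ``synthesizing``: a forward reaction produces ``v`` from ``u``;
    - ``depleting``: a forward reaction consumes ``u`` and ``v`` together;
    - ``reversible``: the compounds sit on opposite sides of a reversible
      reaction.

    When ``model`` is given, records are restricted to its metabolites.
    """
    records: set[tuple[str, str, str]] = set()
    for e in entries:
        d = directions[e.reaction_id]
        subs = sorted({c for c, _ in e.substrates})
        prods = sorted({c for c, _ in e.products})
        if d is Direction.REVERSIBLE:
            for s in subs:
                for p in prods:
                    records.add((s, p, "reversible"))
        else:
            for s in subs:
                for p in prods:
                    records.add((s, p, "synthesizing"))
            for s1, s2 in combinations(subs, 2):
                records.add((s1, s2, "depleting"))
    if model is not None:
        keep = set(model.metabolites)
        records = {r for r in records if r[0] in keep and r[1] in keep}
    return sorted(records)


def write_model(model: StoichiometricModel, matrix_path, provenance_path=None) -> None:
    """Serialize the matrix (and optionally provenance) as TSV."""
    model.matrix.to_csv(matrix_path, sep="\t", index_label="compound")
    if provenance_path is not None:
        rows = [
            (m, g, rid, role, coeff)
            for (m, g), records in sorted(model.provenance.items())
            for rid, role, coeff in records
        ]
        pd.DataFrame(
            rows, columns=["compound", "gene", "reaction", "role", "coefficient"]
        ).to_csv(provenance_path, sep="\t", index=False)
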