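import numpy as np
import pandas as pd
import pytest

import cmpscore as c


@pytest.fixture(scope="session")
def planted():
    """Default planted synthetic study plus its built model and tables."""
    fx = c.generate_fixture(c.FixtureSpec(rng_seed=1))
    entries = c.parse_reaction_map(fx.reaction_lines)
    directions = c.resolve_directions(entries)
    model = c.build_model(entries, directions, fx.gene_map)
    G = c.infer_gene_abundance(fx.taxa, fx.genomes)
    cmp = c.compute_cmp(model, G)
    return {
        "fx": fx,
        "entries": entries,
        "directions": directions,
        "model": model,
        "G": G,
        "cmp": cmp,
    }


def random_small_network(rng, max_reactions=8, max_genes=6):
    """Random tiny reaction set + gene map for oracle comparisons.

    Each reaction occurs in exactly one pathway line so a naive
    per-(gene, reaction, compound) accumulation is unambiguous.
    """
    n_r = int(rng.integers(1, max_reactions + 1))
    n_g = int(rng.integers(1, max_genes + 1))
    compounds = [f"C{i}" for i in range(6)]
    lines, meta = [], {}
    for i in range(n_r):
        k = rng.permutation(len(compounds))
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        subs = [compounds[j] for j in k[:n_sub]]
        prods = [compounds[j] for j in k[n_sub : n_sub + n_prod]]
        arrow = "=>" if rng.random() < 0.75 else "<=>"
        rid = f"R{i}"
        lines.append(f"{rid}: 0001{i}: {' + '.join(subs)} {arrow} {' + '.join(prods)}")
        meta[rid] = (subs, prods, arrow)
    gene_map = {}
    for j in range(n_g):
        rids = rng.choice(n_r, size=int(rng.integers(1, n_r + 1)), replace=False)
        gene_map[f"g{j}"] = {f"R{i}" for i in rids}
    return lines, meta, gene_map


def naive_raw_matrix(meta, gene_map):
    """Independent triple-loop accumulation of the raw impact matrix.

    Only single-direction (=>) reactions contribute: each substrate adds -1
    and each product +1 for every gene mapped to the reaction.
    """
    cells = {}
    for gene, rids in gene_map.items():
        for rid in rids:
            subs, prods, arrow = meta[rid]
            if arrow != "=>":
                continue
            for s in subs:
                cells[(s, gene)] = cells.get((s, gene), 0.0) - 1.0
            for p in prods:
                cells[(p, gene)] = cells.get((p, gene), 0.0) + 1.0
    if not cells:
        return None
    mets = sorted({m for m, _ in cells})
    genes = sorted({g for _, g in cells})
    out = pd.DataFrame(0.0, index=mets, columns=genes)
    for (m, g), v in cells.items():
        out.at[m, g] = v
    return out
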