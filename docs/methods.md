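# Methods

This note documents the modelling choices, numerical conventions and known
limitations of the package, in the order the pipeline runs.

## Stoichiometric impact matrix

Reaction input follows the KEGG `reaction_mapformula.lst` dialect: one
line per (reaction, pathway) occurrence, `RID: PATHID: LHS <dir> RHS`,
with `=>`, `<=` or `<=>` arrows.  The dialect carries no stoichiometric
coefficients, so coefficients default to 1 and an optional
`(reaction, compound, coefficient)` TSV overrides them.  Lines written
right-to-left (`<=`) are normalized by swapping sides at parse time.
Malformed lines — including lines with a compound on both sides, which
would violate the substrate/product disjointness the matrix construction
assumes — are skipped, logged and counted rather than aborting a large
import.

**Direction resolution.**  A reaction may appear in several pathway
contexts.  It is treated as irreversible only when every occurrence agrees
on one orientation; an explicit `<=>` anywhere, or two occurrences with
opposite orientations, makes it reversible.  This is the conservative
choice: conflicting annotations carry no usable directional signal, and
only irreversible reactions contribute to the matrix.  When one reaction
lists different compound subsets in different pathways, the union of the
sides is used and the reaction contributes once per gene (not once per
pathway occurrence).

**Filter order** is directionality → currency → zero-row/zero-column
pruning → row normalization.  The currency filter counts the distinct
genes associated, via the gene→reaction map, with any surviving
(irreversible) reaction touching the metabolite, and removes the
metabolite when that count reaches the cutoff (default 30).  Counting
after the directionality filter means a metabolite hub of purely
reversible reactions is removed as a zero row, not as currency; the
alternative order (counting before dropping reversible reactions) would
remove strictly more metabolites and is not what the construction
narrative implies, but the cutoff is configurable for sensitivity
analysis.

**Normalization.**  Each surviving row is scaled so negative entries sum
to −1 and positive entries to +1 (independently).  Cells then express each
gene's *relative* share of the community's capacity to deplete or
accumulate that metabolite.  The invariant is asserted to 1e−9 in tests.

Per-cell provenance — which reaction, in which role (produces/consumes),
with which raw coefficient — is retained for every nonzero cell and drives
the key-reaction attribution later.

## Gene abundance and preprocessing

`G[g, s] = Σ_t abundance[t, s] · copies[t, g]`.  The product is linear and
additive over taxa, which is what makes single-taxon attribution exact.
An optional per-sample-column normalizer hook accommodates externally
normalized gene tables; it defaults to a no-op and is deliberately
bypassed in single-taxon calculations so additivity holds.

Metabolite tables are preprocessed by (1) summing rows that map to the
same compound ID — a missing value counts as 0 when summed with a number
and stays missing only when all duplicates are missing — and
(2) discarding metabolites with nonzero, non-missing abundance in fewer
than 5 samples (configurable).  Samples are aligned across tables by exact
identifier match; unmatched samples are dropped with a logged count.

## The prediction test

CMP scores are relative, so each metabolite is compared to its
measurements through *signed pairwise differences* across samples.
Signed differences over ordered pairs are antisymmetric
(`d_ji = −d_ij`), and the correlation is therefore computed over the full
ordered-pair set: for Pearson this reduces to the uncentered (cosine)
correlation of the i < j half (the full-set means are exactly zero), and
for Spearman the differences are first mapped to centered ranks over the
doubled set `{d, −d}`.  This form is exactly invariant to relabeling the
samples, keeps the sign information that separates positive from negative
coupling, and equals ±1 when the two difference vectors agree (or
anti-agree) in rank order.  Spearman is the default; Pearson is available.

The permutation unit is the **sample label** of the measured vector (not
individual pair entries, which are dependent through shared samples).
Each of the `P` permutations (default 10,000) recomputes the difference
vector and the statistic; one-sided empirical p-values use the standard
add-one form `p = (#{ρ_perm ≥ ρ_obs} + 1)/(P + 1)`, so `p ≥ 1/(P+1)` and
the test is exact-level for exchangeable nulls.  Permuted statistics are
compared to the observed one with a 1e−12 tie tolerance, and the observed
statistic is computed by the same code path as the permuted ones so float
ties resolve consistently.

Samples where either the CMP score or the measurement is missing are
excluded before differencing, which removes exactly the pairs with a
missing endpoint from both vectors symmetrically.  Fewer than 3 usable
samples, or a zero-variance difference vector on either side, makes the
metabolite *not evaluable*.

**Multiple testing.**  Storey q-values are computed separately across
metabolites for the positive-tail and negative-tail p-values (the two
one-sided hypotheses are distinct families).  π0 is estimated on the
λ grid 0.05…0.95 (step 0.05) from `#{p > λ}/(m(1 − λ))`, smoothed with a
Gaussian kernel in λ (bandwidth 0.15) and evaluated at the largest grid
point, clamped to (0, 1].  The kernel acts as a boundary-local average:
the raw grid values get noisy as λ → 1, and spline fits chase that noise
at exactly the point where the estimate is read off.  With fewer than 10
p-values the smoother is meaningless and π0 falls back to 1, which makes
the q-values coincide with Benjamini–Hochberg.  Tail-area q-values (not
local false discovery rates) are used throughout, with the dual cutoff
`p < 0.01` and `q < 0.01` for classification.

## Contributor attribution

*Key species*: Pearson correlation across samples between the single-taxon
CMP row and the community CMP row; key if > 0.5.  A taxon generating a
constant (typically all-zero) score shows no evidence of contribution, so
an undefined correlation means *not key*.

*Key genes*: the matrix link `M[m, g]` is zeroed — the perturbed score row
is `original − M[m, g] · G[g, :]` — with **no renormalization** of the
row, because the question is what the score loses without that one link,
not what a rebuilt model would say.  Key if the correlation between
original and perturbed rows falls below 0.5; a perturbed row that is
constant means the link was the score's only support, so an undefined
correlation means *key*.  Both conventions are the limiting behaviour of
the thresholds.

Key reactions are read off the provenance records of (metabolite,
key-gene) cells; a metabolite whose key reactions all produce it is
synthesis-driven, all consume it degradation-driven, otherwise mixed (or
none when no gene is key).

## Null models

**Network randomization.**  The edges are the nonzero cells of the
filtered, pre-normalization matrix, carrying their signed weights.  A
double-edge swap picks two edges *of the same sign*, `(m1, g1)` and
`(m2, g2)`, and rewires to `(m1, g2)`, `(m2, g1)`; swaps that would
duplicate an existing edge (of either sign) or share a node are rejected.
This conserves every node's signed degree — each gene keeps its number of
produced and consumed metabolites and vice versa — which is asserted after
every shuffle.  Weights travel with their edges and rows are
re-sign-normalized after rebuilding, since normalization is part of model
construction.  Each randomized network (default 5,000 successful
exchanges; a bounded rejection budget logs a warning if fewer are
achievable) is pushed through the full prediction pipeline, and the
empirical p-value asks how often a random network matches the real
network's well-predicted count.

**Adjacency permutation test.**  Metabolite–metabolite links are typed by
the shared reaction: `synthesizing` (substrate→product of an irreversible
reaction), `depleting` (co-substrates consumed together), `reversible`
(opposite sides of a reversible reaction).  With topology fixed, the
class labels are permuted over node positions (default 1,000 times) and
upper-tail p-values are reported per link type and for the total.  With
no anti-predicted or no well-predicted metabolite among the network nodes
the result is degenerate by construction (counts 0, p = 1).

## Synthetic communities

The generator emulates the data shape the framework consumes: log-normal
taxon abundances with a 0.2 per-entry zeroing probability (sparsity),
Bernoulli(0.1) binary genome content plus one guaranteed carrier per
gene, a reaction file in which each measured metabolite `M_i` is produced
from a dedicated unmeasured precursor `X_i` by one gene, reversible decoy
reactions (excluded by the directionality filter but visible to the
adjacency test) and a currency by-product attached to every reaction
(removed by the currency filter whenever the network spans at least 30
genes).  Measured abundances are `10 + s·coupling·z(CMP_true) + N(0,
noise_sd)` with `s = +1` for producer-controlled metabolites, `−1` for
consumer-controlled ones and pure noise for independent ones.  The default
conditions are 12 taxa, 60 genes, 60 metabolites, 20 samples, 30%/20%/50%
producer/consumer/independent and coupling 3.0 against unit noise (a 3:1
signal-to-noise ratio).  `CMP_true` is computed through the production
model-construction code path; an independent naive implementation lives in
the test suite as the oracle.

What the generator does **not** emulate: compositional (relative-
abundance) constraints, measurement error models of qPCR/16S or mass
spectrometry, phylogenetically correlated genome content, metabolites
shaped by several unrelated reactions at once, or cross-feeding dynamics.
Passing recovery tests therefore show that the pipeline's inference is
correct *when its generative assumptions hold*, not that real communities
satisfy those assumptions.

## Problem sizes and numerical conventions

Tests and the acceptance script use 2,000 Mantel permutations for planted
and calibration communities (enough to resolve the 0.01 cutoff with
comfortable margin), 499 permutations inside the 19-replicate network
null (where only the relative well-predicted counts matter), exhaustive
enumeration at n = 5–6 samples as the permutation oracle, and 100+ random
micro-networks for the exact construction oracle.  The library defaults
remain 10,000 permutations and 100 random networks.

Degenerate inputs: empty reaction input, an all-filtered model, empty
gene overlap and an all-filtered metabolite table raise errors naming the
condition; unknown taxa raise `KeyError`; replicate failures inside the
network null are logged and excluded from the p-value denominator.

## Known limitations

- Direction information is taken at face value from the reaction file;
  no thermodynamic or flux-based inference recovers signal lost from
  reversible reactions.
- CMP is a capacity score: gene regulation, expression, kinetics and host
  contributions are outside the model.
- The currency cutoff (30 genes) is a heuristic inherited from network
  analyses of ubiquitous cofactors; at very small network sizes the
  filter cannot trigger.
- The π0 kernel smoother is biased upward (conservative) when the signal
  fraction is large, since it averages the λ-grid near — but not at — the
  boundary.
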