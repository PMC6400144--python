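# Methods

`ctldscreen` re-implements, as a tested library, a candidate-receptor
screening workflow for β-glucan (C-type lectin) receptors: given a proteome
with C-type lectin-like domain (CTLD) annotations plus macrophage expression
data, it scans for glucan-binding signature motifs, applies expression and
differential-expression criteria under a paired design, runs term
over-representation, clusters CTLD sequences, and looks for conserved
micro-synteny in a duplicated (tetraploid-style) genome. This note records
the models, the defaults and why, and what the synthetic benchmark does and
does not show.

## Motif scanning and architecture

Signatures are expressed in a small PROSITE-flavoured grammar: literal
residues, `x` wildcards, `[AB]` alternation and bounded wildcard repetition
`x{m,n}` (1 ≤ m ≤ n ≤ 9). The built-in signatures are the Dectin-1
glucan-binding motifs `WxH` and `WxHx{1,4}Y`, the five-spacer variant
`WxHx{5}Y` observed in fish receptor candidates, and the ITAM signature
`Yxx[LI]`. The matcher reports **every** distinct `(start, end)` match,
overlaps and nested bounded-repetition variants included; downstream
consumers filter. An `X` (unknown residue) in a sequence satisfies a
wildcard but never a literal — an unknown residue cannot be asserted equal
to one. By default whole proteins are scanned and hits are then classified
against CTLD intervals (`--scope domain` restricts the scan to
CTLD-bearing proteins instead); this choice is exposed because published
screens differ in whether the motif search or the domain intersection comes
first.

Hits are classified against CTLD intervals (1-based inclusive coordinates
throughout, the Pfam/EMBOSS reporting style): `IN_DOMAIN` when fully
contained, `NEAR_BOUNDARY` when partially overlapping or within a margin of
a domain edge, `OUTSIDE` otherwise. The margin defaults to 10 residues —
about one motif length of slack around the predicted domain borders, since
domain-boundary predictions are themselves approximate and biologically
relevant motifs have been observed just outside them. The classifying
domain is recorded (nearest on ties).

Transmembrane segments are called with a Kyte–Doolittle sliding window:
a window is positive when its mean hydropathy exceeds the threshold, and
overlapping positive windows merge into maximal segments. Defaults are the
classic window 19 / threshold 1.6. This is a transparent hydropathy
heuristic, not an HMM topology model; on real proteomes its TM counts will
differ from dedicated predictors, which is acceptable here because TM
presence is used as coarse architecture evidence only.

A protein is flagged *Dectin-1-like* when it has ≥ 1 CTLD with a WxH inside,
≥ 1 TM segment, and **one or two** ITAMs. The upper bound reflects the
archetype: Dectin-1 signals through a single hemITAM, and receptor
candidates reported with this "complete" architecture carry one or two;
proteins with many YxxL/I occurrences (up to 7 occur in the worked-example
tables) are better explained as repeated incidental matches. Each single
`Yxx[LI]` occurrence counts as one ITAM; canonical paired-ITAM spacing is
not enforced.

## Expression criteria

RPKM uses the standard definition `counts × 10⁹ / (libsize × length)` with
library size the column sum. The constitutive-expression criterion is mean
RPKM across unstimulated (control) samples ≥ 50 (inclusive), the screening
threshold for "expressed in macrophages"; when a reference gene (default
`actb`) is present, expression is also reported as a fraction of it, since
the threshold corresponds to roughly 1.5 % of β-actin expression in the
emulated setting.

Differential expression preserves the structural contributions of the
original two-package analysis — a paired contrast per fish/culture, two
independent tests, dual thresholds, and an intersection consensus — with
two transparent stand-ins. Negative-binomial GLM machinery (dispersion
trends, empirical-Bayes fits, TMM/median-of-ratios normalization) is
deliberately **not** re-implemented. Per pair *i*,
`d_i = log2((stim_i + 0.5)/sf_stim) − log2((ctrl_i + 0.5)/sf_ctrl)` on
library-size-scaled counts (pseudocount 0.5 keeps zeros well-defined;
column-sum scaling is simple and monotone).

* **Method A** — one-sample moderated t on `{d_i}`: gene variances are
  shrunk toward the median gene variance with `prior_df = 4`
  pseudo-degrees of freedom (stabilizes small-n tests without re-deriving
  empirical-Bayes fits), BH-adjusted, significant at q ≤ 0.05.
* **Method B** — exact sign-flip permutation of `{d_i}` (all `2^n` flips
  for n ≤ 12 pairs, seeded Monte-Carlo beyond), two-sided p on the mean
  statistic, significant when both raw p ≤ 0.05 **and** BH-adjusted
  p ≤ 0.05 (the edgeR-style double rule).

A gene is a consensus DEG only when both methods call it. All-zero genes
get p = 1 and a `none` direction sentinel. BH/BY use the standard step-up
with stable-sort tie-breaking and cumulative minima.

**Known limitation — discreteness of the exact test.** The two-sided
sign-flip p-value has a floor of `2/2^n`: 0.25 at n = 3 (method B can never
reach 0.05 there) and 0.03125 at n = 6. At n = 6 the raw threshold is
reachable, but with ~1000 genes the BH-adjusted threshold is not: null
genes hit the floor with probability 1/32, so on the default synthetic
design ≈ 80 genes tie at p = 0.03125 and the smallest attainable q is
≈ 0.39. The double rule therefore makes method B — and hence the consensus
— empty at this scale, and the consensus power benchmark reports ~0 %
recovery while the moderated-t arm alone recovers ≥ 95 % of planted genes
at zero observed false positives. Exact BH-controlled consensus at small n
needs either more pairs (n ≥ 11 gives a floor below 0.001) or a continuous
second test; both rules are kept as specified and the benchmark reports
both arms honestly.

Cross-stimulus concordance classifies consensus DEGs of two stimuli as
shared-concordant (same direction), shared-discordant, or private, with
Venn counts.

## Term enrichment

Over-representation is the hypergeometric upper tail `P[X ≥ k]` for `k` of
`n` target genes annotated with a term that covers `K` of `N` background
genes, computed via `scipy.stats.hypergeom`; adjustment is selectable
between BH (the GO-style screen) and BY (the more conservative pathway-style
screen), enriched at q ≤ 0.05. Genes without annotation stay in the
background — the universe is "all annotated genes", not "all genes with a
term". Ontology-graph propagation, term redundancy reduction and
rank-based (mHG) statistics are out of scope; term counts from live
databases are inherently non-reproducible, so the module works on explicit
term maps. An optional collapsing step maps duplicated paralogue ids to
unique reference ids through the ortholog map before testing.

## CTLD clustering

Clustering of CTLD sequences (sliced from proteins by domain interval;
multiple CTLDs per protein numbered 1, 2, … from the N-terminus) is
p-distance + neighbor-joining with column-bootstrap support, a desk-scale
stand-in for maximum-likelihood inference — clustering claims on real CTLD
sets are therefore qualitative. Choices fixed for reproducibility:

* **pairwise deletion** — a site contributes to a pair only when neither
  sequence has `-` or `X` there (preserves signal in sparsely aligned CTLD
  sets; note complete-column deletion, the default of some ML suites,
  differs);
* NJ Q-criterion ties broken by the lexicographically smallest cluster-id
  pair (a cluster is named by its smallest leaf id); negative branch-length
  estimates clamped to 0 with the deficit logged;
* bootstrap resamples alignment columns with replacement (default 500
  replicates, seeded); support of an internal bipartition of the full-data
  tree is the percentage of replicates containing it; failing replicates
  (e.g. a pair losing all comparable sites) are skipped and counted, with a
  warning past 10 %.

NJ is consistent on additive matrices; the test suite verifies exact
topology recovery against 200 random generating trees and agreement with an
independent NJ implementation.

## Micro-synteny

Anchors are ortholog pairs co-resident on one (reference chromosome, target
scaffold) combination; blocks are extension-maximal chains of anchors,
strictly monotone in gene-order index on both genomes (both orientations),
with at most `max_gap` intervening non-anchor genes between consecutive
anchors on each genome. Gap is measured in genes, not base pairs — robust
to the scale difference between a chromosome-level reference and a
fragmented scaffold assembly. `min_anchors` defaults to 3: published
synteny calls of this kind rest on a handful of co-localized genes, and two
shared genes are too weak to call conservation; the parameter is exposed.
Every target copy of a duplicated ortholog chains independently, so a
single reference region can yield parallel blocks on two scaffolds —
exactly the tetraploid two-copies pattern. All maximal chains are reported
without conflict resolution. Candidate flagging reports every *resident*
CTLD-class gene inside a block's target span, not just anchors, because a
receptor gene can sit inside a conserved neighbourhood without itself
having a mapped ortholog.

## Candidate integration

The universe is every protein with ≥ 1 CTLD annotation. C1 = WxH inside a
CTLD; C2 = mean control RPKM ≥ threshold; C3 = consensus DEG in ≥ 1
stimulus; C4 = inside a synteny block. C4 is additive evidence, not a
filter: the reported candidate union is C1 ∪ C2 ∪ C3 with C4 flags
attached. Gene and protein ids are treated as identical by default, with an
optional explicit mapping table. The packaged worked-example tables expand
parenthesised paralogue entries into separate records that inherit the
row's attributes unless overridden; on those tables the screen reproduces
13 WxH candidates, 12 expressed, 6 regulated (2 by both stimuli), a
25-candidate union, and 4 complete Dectin-1-like architectures.

## Synthetic data

The generator defines the benchmark conditions; one master seed fans out to
fixed child seeds per data type (offsets +1 proteome, +2 counts, +3 maps,
+4 terms), and identical configs give byte-identical outputs.

* **Proteome** — background residues i.i.d. uniform over the 20-letter
  alphabet (the simplest null for false-positive-rate checks); CTLDs are
  fixed-length (110 aa, a typical CTLD span) intervals, one per CTLD
  protein; motifs are instantiated from their patterns with spacer residues
  drawn from a filler alphabet that avoids the motif literals and strongly
  hydrophobic residues, and planted at a configured location class; TM
  stretches are 21-residue poly-I/L/V/F runs, guaranteed calls for the
  hydropathy caller. Planting is best-effort under collision avoidance; the
  truth manifest records exactly what was planted, and because the
  background can create extra legitimate hits, recovery tests check
  *planted ⊆ found* against a fresh re-scan, never set equality.
* **Counts** — negative binomial with `Var = μ + φμ²` (Poisson at φ → 0),
  gene base means log-uniform on [20, 500], library sizes log-uniform on
  [0.8 M, 1.2 M] (exercises RPKM normalization), dispersion 0.1 — moderate
  biological replication noise. The default paired design is 6
  fish × (control + curdlan + MacroGard-style stimulus); the emulated
  study's own layout (3 cultures per stimulus, 5 unstimulated samples) is
  available via `n_pairs=3, n_extra_controls=2` — the two sample counts are
  exposed independently rather than reconciled. 50 of 1000 genes per
  stimulus get a planted |log2 fold change| of 2, sign random per gene.
* **Gene maps** — reference chromosomes of 30 ordered genes; every
  reference gene has 1 or 2 target copies (duplication factor 2 emulates
  the tetraploid genome); planted blocks occupy consecutive reference runs
  and are laid out co-ordered on one dedicated scaffold per copy with at
  most the planted `max_gap` unmapped fillers between anchors (one filler
  per block is a CTLD-class resident); all other copies land on singleton
  scaffolds, emulating a fragmented assembly and making planted blocks
  exactly the maximal chains.

What passing synthetic tests show: the algorithms find what is, by
construction, present, at the stated noise levels, and control false calls
on the stated nulls. What they do not show: performance on real proteomes
(domain-boundary error, compositional bias, homopolymer stretches), real
RNA-seq (dispersion trends, outliers, batch effects), or real assemblies
(missassembly, tandem duplication) — the real-data headline numbers of the
emulated study (e.g. its genome-wide DEG counts and 239-protein universe)
depend on external genomes and databases and are explicitly not
reproduction targets.

## Problem sizes and runtime

Default benchmark sizes — 60 proteins, 1000 genes × 18 samples, 2 × 30-gene
chromosomes, ≤ 500 bootstrap replicates on ≤ 40 CTLD sequences — were
chosen so the whole suite and the acceptance script complete in seconds on
one core while every oracle comparison stays exhaustive (all `2^n` sign
flips, all hypergeometric tails to N = 25, brute-force chain enumeration).
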