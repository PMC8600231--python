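# Methods

This note documents the models, rules and numerical choices behind
`xylemtrn`, and what the synthetic benchmarks do and do not establish.

## Differential expression

The expression unit is FPKM-like and nonnegative; all fold changes are
computed on `log2(x + pseudocount)` with pseudocount 1, as
`mean_b − mean_a` of per-replicate log values. This makes log2 FC exactly
antisymmetric under swapping the compared stages.

The per-gene significance test is a **Welch (unequal-variance) two-sample
t-test** on the log2 replicate values, with Benjamini–Hochberg adjustment
applied within each comparison (month 2 vs 1, month 3 vs 1) across all
genes. The thresholds are |log2 FC| ≥ 1 and adjusted p < 0.01, passed in at
least one comparison. Both thresholds are flags (`--lfc`, `--alpha-rna`);
0.01 is the default, with 0.05 a common looser choice.

Two caveats are deliberate and documented rather than hidden:

* The Welch test is a self-contained stand-in for a count-model RNA-seq
  caller (which would pool dispersion information across genes). With
  three replicates its raw p-values bottom out near 1e-4–1e-3, so after BH
  over a thousand genes the filter has limited power at moderate effects:
  in the packaged simulation (effect 2.0, noise 0.3 log2 units, 100 true
  risers among 1,000 genes) roughly 55–80 of 100 planted genes pass per
  seed, with false positives well under 3%. At the stronger planted effects
  of the study-composition dataset (effect 3.0, noise 0.25) recovery is
  complete because each gene gets two chances (the 2v1 and 3v1
  comparisons).
* "Fold change ≥ 1 or ≤ −1" is interpreted on the log2 scale; a *raw*
  fold-change of −1 is impossible for nonnegative data.

## Trajectory groups and soft clustering

Per-gene stage means of log2(x+1) are reduced to two steps, d1 = m2 − m1
and d2 = m3 − m2. Steps inside a **dead zone** of ε = 0.25 log2 units (a
quarter of the DEG threshold, configurable) count as zero. Sign pairs map
to groups: non-negative/non-negative (not both zero) → I, −/+ → II,
non-positive/non-positive → III, +/− → IV, both zero → flat. Every gene
receives exactly one label.

Soft clustering is classic **fuzzy c-means** (Bezdek alternating
optimization): c = 12 clusters, fuzzifier m = 2, Euclidean distance on
per-gene z-scored stage-mean profiles. Constant profiles cannot be z-scored
and are excluded beforehand. Memberships are row-stochastic; the hard label
is the argmax with ties broken toward the lowest cluster index; the
objective is non-increasing across iterations and iteration stops when the
largest membership change falls below 1e-6 (cap 500 iterations).
Initialization is a seeded random membership matrix, so results are
deterministic for a fixed seed. Cluster centers are themselves
three-vectors and are mapped to trajectory groups with the same dead-zone
classifier, which is how clusters roll up into groups I–IV.

## Promoter windows and element scanning

Promoters are the 2,000 bp immediately upstream of (excluding) the TSS,
written 5′→3′ toward the gene: for minus-strand genes this is the reverse
complement of the downstream window. Windows truncate (never pad) at contig
edges. Coordinates throughout are 0-based half-open in promoter-forward
orientation (BED convention), so hits export bit-exactly to BED6.

Degenerate consensi are parsed from `ACGT`, `N` (any base) and alternative
groups `(A/T)` / `[A/T]`. Scanning reports **all overlapping occurrences on
both strands** by default (plus/minus selectable; whether the original
analysis was double-stranded is unstated, and both-strand scanning is the
conservative superset). A minus-strand occurrence is found by matching the
reverse-complemented motif against the forward strand, which lands hits
directly in promoter-forward coordinates. `N` in the subject matches
nothing (conservative); matching is case-insensitive. Presence/absence, not
count, drives all downstream rules.

The shipped defaults are: SMRE `ACC(A/T)A(A/C)(T/C)` (7 bp, 8 variants);
W-box `TTGAC(C/T)` (the canonical WRKY element — named but not spelled out
in the source study); TGTG `TGTG[T/G/C]`; and a 19-bp degenerate SNBE
consensus `(T/A)NN(C/T)(T/C/G)TNNNNNNNA(A/C)GN(A/C/T)(A/C/T)` from the NAC
master-switch literature. All four are config entries, not code, and fully
overridable — the SNBE in particular is cited from prior work rather than
defined in the study, so it must not be a hard-coded literal.

## Network rules

Layers are assigned in rule order: (1) WND role → layer 1 — master switches
are identified by annotation and deliberately excluded from scanning;
(2) upregulated TF with SNBE but no SMRE → layer 2; (3) upregulated TF with
SMRE (alone or with SNBE) → layer 3; (4) cell wall / PCD role → layer 4.
TFs with neither element are reported as unplaced rather than guessed. The
source study's curated second layer is larger than its SNBE-only count
because it adds literature-confirmed members; a layer-override TSV lets
users pin genes to reproduce such curated placements, and a curated-edge
TSV merges literature edges tagged `evidence=literature`.

Edges are generated exhaustively from four element rules (WND → any
lower-layer SNBE gene; layer-2/3 MYB → any strictly lower SMRE gene;
layer-3 WRKY → layer-4 W-box genes; NAC072/NAC045-class orthologs →
layer-4 PCD genes with TGTG), then deduplicated and sorted by (source
layer, source, target, element) for byte-stable exports. Because every rule
requires source layer < target layer, the network is acyclic by
construction, and every predicted edge's element is verifiable in the
target's profile.

## Proteome integration

Protein fold change is the **raw ratio of stage means** (pseudocount 0 by
default; a zero reference mean yields an infinite fold change, which passes
the magnitude criterion and is logged). Thresholds: fold change ≥ 2 or
≤ 0.5 with BH-adjusted p < 0.05 — the printed lower bound "−0.5" in the
source is read as the ratio 0.5, since a ratio cannot be negative. The
significance test and BH machinery are shared with the transcript side.

Concordance compares per-comparison direction calls (up/down/ns):
*consistent* means agreement at every comparison where both molecules are
significant, with at least one such comparison; *discordant* means
disagreement at one or more jointly significant comparisons; otherwise
*untestable*. The rule that produced the study's published 121/72 split is
not stated there; this sign-agreement rule is one defensible
operationalization and is symmetric in the two omics layers. Tightening
either alpha can only move calls toward `ns`, so proteins never become
testable under a stricter threshold.

## Synthetic data

The generator emulates the statistical structure of the study's deposited
data without downloading it: 3 stages × 3 replicates, log2-normal replicate
noise (additive Normal(0, σ) on the log2 scale, matching the log2(FPKM+1)
working scale), and i.i.d. uniform A/C/G/T promoter background — the
simplest null under which the expected background hit count has the closed
form 2(W−L+1)V/4^L per gene for a motif with V variants of length L in a
W-bp double-stranded window. Defaults: base level 20, effect size 2.0,
noise 0.3 log2 units (a typical replicate CV for moderately expressed
genes); a warning is raised when effect < 2σ since recovery is then not
guaranteed. Planted trajectory shapes, relative to month 1 in units of the
effect size e: I = (0, +e, +2e), II = (0, −e, 0), III = (0, −e, −2e),
IV = (0, +e, 0), so every non-flat step has magnitude e. Planted elements
never overlap; minus-strand plantings write the reverse complement so a
scan recovers the planted (gene, offset, strand) exactly. All randomness
flows from one integer seed through local numpy generators — identical
configuration and seed give byte-identical files.

The **study-composition dataset** plants the published composition: 8 WNDs;
116 upregulated TFs partitioned 9 SNBE-only / 14 SMRE-only / 93 both (with
family splits echoing the study where the rules leave freedom: 17 NAC and
13 WRKY among the dual-element TFs, 9 MYB among the SMRE-only); 98 cell
wall genes (8 primary + 6 secondary without SNBE, 84 with both, 30 with an
added W-box); 47 PCD genes all carrying SNBE, 40 with TGTG; 121 consistent
and 72 discordant proteins; 10 flat TFs and 200 flat background genes
(479 genes total). Because degenerate elements occur by chance in uniform
2-kb background at rates of order one-to-ten per gene, this fixture
additionally (a) rejection-samples planted variants so no variant embeds a
second element and (b) re-randomizes background bases until scanning finds
exactly the planted occurrences. Plain `generate_promoters` output keeps
its chance hits — that is what the analytic background-rate check tests.

What passing on this data shows — and does not. It shows the code paths
compute what they claim: the scanner is exact against brute-force
enumeration, planted truth is recovered at the stated effect sizes, the
rules reproduce a known composition. It does not show that the Welch
stand-in matches a count-model caller on real RNA-seq, that real promoters
(GC-skewed, repeat-rich) behave like uniform background, or that the
sign-agreement concordance rule matches the study's unpublished one.

## Problem sizes

The packaged simulations are sized for quick iteration: 479–1,000 genes,
2-kb windows, 3×3 matrices. The scanner-oracle suite uses 1,000 random 2-kb
sequences; Monte-Carlo checks use 12–20 seeds; the BH cross-check uses
10,000 p-values. The full test suite runs in well under a minute of compute
plus ~20 s for the end-to-end fixtures.
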