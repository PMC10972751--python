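# Methods

## The scripted scenario and what the simulator emulates

`wgdkit.scenario.default_scenario()` encodes a dated species tree —
outgroup (600 Ma), cyclostome–gnathostome split (520 Ma), gnathostome crown
(456 Ma, with a 430 Ma split inside), hagfish–lamprey split (457 Ma) — and
three polyploidizations:

| event | kind | copy divergence(s) | retention/copy |
|---|---|---|---|
| 1R | auto-tetraploidy, vertebrate stem | 527 Ma (per-CLG rediploidization) | 0.9 |
| 2R_JV | allo-tetraploidy, gnathostome stem | 508 Ma (alpha–beta progenitor split) | 0.8 |
| 2R_CY | two-step hexaploidy, cyclostome stem | 511 Ma (deep) and 493 Ma (shallow) | 0.7 |

One designated CLG (index 1 by default) has a lineage-specific
rediploidization of the shallow cyclostome pair: instead of diverging at
493 Ma on the cyclostome stem, the two copies diverge independently at
431 Ma (hagfish-like) and 442 Ma (lamprey-like).  In the emitted gene
trees every duplication node's age equals its scheduled divergence age
exactly; gene loss is i.i.d. per copy per terminal lineage with the
retentions above (chosen so that cyclostome segments show the heavier
losses typical of hexaploid descendants); the outgroup copy is never lost
so that families remain rootable.

Sequences evolve ungapped under a 20-state equal-exchangeability
("Poisson") model — chosen because its closed forms (transition
probabilities, p-distance expectation, ML distance) provide independent
oracles for the test suite; empirical matrices can be loaded from a
PAML-style file.  The default rate is 5e-4 substitutions/site/Myr, set so
that the 450–530 Myr divergences of interest sit well below saturation at
300-site genes (root-to-tip ≈ 0.3 substitutions/site).  Karyotypes place
each surviving gene on a chromosome: one chromosome per post-WGD unit by
default, with a hagfish-like fusion plan grouping 2–6 units (never two of
the same CLG) per chromosome and shuffling within-chromosome gene order.

Depth tracks are negative-binomial with variance mean + noise·mean² (noise
0.05 by default); the NB mean is adjusted so the distribution's **mode**
equals the requested modal coverage (32x germline, 54x soma).  Planted
germline-specific regions have soma mean 0 and germline mean scaled by the
copy ratio.  The simulator does not model indels, rearrangement
breakpoints, read-level errors or repeat sequence content — so passing
tests demonstrate the statistical machinery, not robustness to alignment
error or mapping artefacts on real data.

## Paralogon trees

Per CLG, families passing relaxed selection (≥ 2 distinct gnathostome
paralogons among α1/α2/β1/β2; strict mode requires ≥ 3) are concatenated
into a supermatrix keyed by (species, segment): gnathostome rows by
paralogon label from the reference classification, cyclostome rows by
chromosomal identity, outgroup rows as a single linked set.  Tandem
duplicates keep the copy with more resolved sites; rows under 20% occupancy
are dropped (all-gap-ish rows destabilise likelihoods).

Tree inference follows "distance start + likelihood over candidate
resolutions": a neighbor-joining tree on Poisson-corrected p-distances,
plus two hypothesis-driven resolutions of the deep structure — the
1R-copy-clade topology (gnathostome α1/β1 vs α2/β2 anchors, cyclostome rows
assigned to copies by average-linkage clustering of their patristic
distances with a likelihood-guided subtree-reassignment pass) and the
lineage-clade alternative.  Branch lengths of each candidate are first fit
by least squares against the NJ patristic distances and then optimized by
coordinate ascent on the exact one-dimensional likelihood per branch
(cached conditional vectors, with a per-sweep monotonicity guard).  The
maximum-likelihood candidate is the reported tree.  No general NNI/SPR
search is performed; the candidate set is the explicit space of deep
hypotheses.

Supports: shallow bipartitions carry ordinary distance-bootstrap
percentages (site resampling, NJ per replicate).  The deep duplication
node's support is the RELL bootstrap proportion — the fraction of
site-resampled replicates whose per-site log-likelihood sum prefers a
1R-bearing candidate — which pools the concatenated signal the way a full
ML bootstrap would, at a fraction of the cost.

Dating is strict-clock constrained least squares: node ages minimise
Σ(branch length − rate·duration)² under parent-older-than-child ordering
and calibration bounds, with the global rate profiled out (after the
substitution u = rate·age the problem is linear and solved in closed form;
ordering violations are handled by an active-set scheme that merges the
offending ages, the classic treatment of tree-ordered isotonic least
squares).  A binary root's two edges contribute a single combined residual
because the root's position along its edge is not identifiable under a
clock.  The default calibration pins every intact gnathostome-crown copy
(three species, one segment) at 456 Ma; given one absolute calibration the
solution is scale-invariant in the branch lengths.  This is a deliberate,
deterministic stand-in for Bayesian relaxed-clock dating: adequate for
clock-like simulations, optimistic for rate-heterogeneous real data.

## Rediploidization tests

Family-level: families pass criteria (i)–(iv) — a gnathostome species
retaining both 1R copies, at least one hagfish and one lamprey gene, an
outgroup gene, and at most 10 possible ancestral topologies.  Ancestral
topologies assign cyclostome (species, segment) units jointly (chromosomal
orthologies merge units) to the two 1R clades; the lineage-specific
topology groups genes by lineage.  Constraint clades are resolved against
the data by anchor-rooted NJ; each candidate is branch-length optimized and
compared by RELL.  For the verdicts we report one-sided
Kishino–Hasegawa p-values of each candidate against the best tree rather
than the SH procedure: with a handful of candidates and 300-site families
the SH maximization correction removes essentially all power, while the
KH-vs-best comparison matches the decision actually taken (reject at
α = 0.05).  A family's verdict is `ancestral` only if every
lineage-specific topology is rejected and at least one ancestral topology
survives, and symmetrically (a `majority` policy is available).

CLG-level flagging of lineage-specific rediploidization follows the
divergence-time reading: a cyclostome duplication node joining two segments
of a single lineage at an age clearly younger than the tree's own
hagfish–lamprey speciation ages.  Two guards make this robust at desk
scale: the two sides of the duplication must share at least 50 resolved
supermatrix columns (rows with disjoint family coverage have no data
constraining their relative placement and can collapse to spuriously young
nodes), and the reading must be confirmed by a concatenation-level
constrained topology test — the two cross-lineage groupings of the
candidate segment pair against the within-lineage grouping — with the
lineage-grouped topology preferred by likelihood.  Family-level verdicts on
the same pair are tallied alongside, mirroring the situation where only a
small number of gene trees is testable.

## Elimination scan

Modal depth is the plain mode over positions with depth ≥ 1 (ties toward
the smaller value).  Masking: positions below one third of modal coverage
in *both* samples, or above three times modal in both, are excluded; an
absolute low rule (< 10x in both) and a higher multiple are available for
high-copy runs.  Unmasked positions are grouped left-to-right into
intervals of exactly 500 valid bases (spanning masked gaps; the final
interval per contig may be partial).  Interval scores are
log2((germ/modal_g)/(soma/modal_s)) with germ and soma means over valid
bases clamped to [a, A] and [b, B] (defaults 10 and 1e8; intervals with
both raw means below their minimum clamps are dropped).  Segmentation is
recursive splitting on the maximal two-sample |t| over *segments* (i, j) —
the circular statistic; a single changepoint statistic fails when a contig
carries more than one inserted region — accepted when a permutation test
gives p < 0.01 (1000 permutations by default, with early stopping and a
shortcut for |t| ≥ 8, far beyond any permutation maximum at these sizes).
Segments with mean score ≥ 2.0 (a 4-fold normalized enrichment; the cutoff
is configurable because no canonical value exists) merge into
germline-specific regions.  Repeat spans are (mean covered germ depth /
modal) × covered bases with coverage meaning depth > 10; abundant k-mers
are those above 3× the modal copy number; read–repeat alignments are kept
when they cover > 80% of the repeat or > 80% of the read; somatic repeat
families need > 200 hits within some 1-Mb window (on every chromosome in
"centromeric" mode).

## Problem sizes and numerical choices

The default recovery run uses 17 CLGs × 20 families × 300 sites, 100
bootstrap replicates and 500 RELL draws — sizes at which each CLG analysis
takes seconds and the complete chain minutes, chosen as the package's
standard demonstration scale.  Branch lengths live in [1e-8, 20];
optimization stops at ΔlnL < 1e-6 or the sweep limit; pattern compression
is exact; likelihood scaling is per-node, per-pattern.  Gamma rate
heterogeneity (4 discrete categories) is available but off by default on
simulator data, which is generated without rate heterogeneity.  Ties in
NJ's Q matrix and in mutual-best-hit scores are broken by index/lexical
order so every result is reproducible bit for bit given a seed.

## Known limitations

* The clock is strict; systematic rate variation in real data will bias
  ages in ways the recovery tests cannot reveal.
* The deep-candidate set covers the 1R-copy vs lineage-grouping
  hypotheses; pathologies outside that space (e.g. partial tetrasomy
  mosaics) would surface only through the NJ candidate.
* Family-level rediploidization tests are underpowered at 300 sites — as
  in real analyses of this design, most families are individually
  inconclusive, and the CLG-level reading carries the conclusion.
* The similarity search is a shared-k-word counter with identity
  rescoring: adequate for indel-free simulated proteomes, not a substitute
  for a real aligner on real data (the interfaces accept external hit
  tables for that).
* bedGraph depth input assumes integer per-base depths; the scan's
  robustness to mapping artefacts (multi-mappers, collapsed repeats) is
  outside what the generator emulates.
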