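# Methods

## Interactor grading

The grading operates on an integer ESC matrix with ≥ 2 bait and ≥ 2
control replicates. Rules apply in a fixed precedence:

1. **Control dominance** (mean control ESC strictly greater than mean bait
   ESC) excludes the protein outright; no p-value is reported. The rule is
   read as a per-protein comparison of replicate means, and strictness
   follows from "higher": ties are kept.
2. **Single-entry rule**: a protein detected (count > 0) in at most one
   bait replicate is a contaminant regardless of its p-value. A switch
   (`single_entry_across_all`) applies the rule across all samples instead.
3. **The p-value ladder**: a two-sided two-sample *t*-test of bait versus
   control replicate counts bins survivors into A `[0, 0.1)`,
   B `[0.1, 0.25]`, C `(0.25, 0.5)`, contaminant `[0.5, 1]`. B is closed at
   both ends; A and C are open at the shared boundaries.

The test is the classic pooled-variance Student's *t* (a `welch=True`
switch exposes the unequal-variance variant). Counts enter untransformed.
Degenerate rows take the limiting value of the statistic: zero pooled
variance with equal means gives p = 1, with unequal means p = 0. All bait
columns form one group — the package does not distinguish in-cell from
in-lysate captures; users who want separate tests should grade the two
designs as separate tables.

Because the two-sided p-value is (under the null) independent of the sign
of the mean difference, conditioning on surviving the control-dominance
filter leaves the null p-distribution uniform; the measured grade-A
fraction among tested proteins is 0.10 at Poisson mean 50 (see the
acceptance script's `null_grade_a_fraction`). At low Poisson means (≈ 3)
the discreteness of counts distorts the t reference distribution and the
null A-fraction deviates from 10%; the grading is still usable as a
ranking but the bands lose their literal frequentist reading there.

## PPI reference

Two tab-separated dialects are parsed into `(id_a, id_b, taxon_a,
taxon_b)` records: a BioGRID-tab-like table addressed by column name, and
a MITAB-2.5-like table addressed by position (fields 1, 2, 10, 11 with
`uniprotkb:` / `taxid:NNNN(name)` prefixes). Malformed lines go to a
rejects report instead of aborting a parse; only a missing mandatory
header column is fatal. Inter-species records are retained and flagged.

Ortholog mapping replaces each foreign endpoint by its human identifier
via an explicit `(source_id, source_taxon) → human_id` table; human
endpoints map to themselves. Records with any unmappable endpoint are
dropped to an unmapped report — the merged network lives entirely in human
identifier space. Merging deduplicates unordered pairs across sources,
keeps the union of source labels as provenance, and drops self-loops (the
topology statistics assume a simple graph). No alias unification beyond
the ortholog table is attempted, and no evidence-type (physical vs
genetic) filter is applied; both are documented limitations.

## Network assembly and topology

Node set: detected proteins ∪ documented interactors of the chaperome
(database neighbors of the chaperome members, overridable) ∪ chaperome
members present in the database; edges are induced from the merged
reference, and nodes without any induced edge are kept as isolates.
Classes: `chaperome`; `direct_interactor` for a non-chaperome node
adjacent to a chaperome node; `indirect` otherwise. Documented-but-
undetected interactors carry `reduced=True`, the semantic equivalent of
rendering them as dots in a map figure. Edge weights 10000/100/1 by layer;
edges between two direct interactors fall to the residual tier (weight 1)
since only chaperome-touching edges are up-weighted. The weights are
emphasis/layout weights: topology metrics are computed on the unweighted
simple graph. Both the average local clustering coefficient (degree < 2
contributes 0) and global transitivity are reported, since "clustering
coefficient" is ambiguous between them; centralization uses the Freeman
degree normalization (1 for a star, 0 for regular graphs, undefined and
reported as 0 with a warning for n < 3).

## Dual-bait co-occurrence test

Universe: the rows of the supplied detection matrix (for real data this is
naturally the union of interactors detected by either bait). Prevalences
p̂A, p̂B are the column means. Each null replicate draws n independent
indicator pairs — implemented either literally (`sim_path="pairs"`) or as
one Binomial(n, p̂A·p̂B) variate (`sim_path="binomial"`, the default; the
two are distributionally identical and the equivalence is tested). The
two-sided p is twice the smaller inclusive tail at the observed count,
capped at 1. Inclusive tails avoid anti-conservative zero tails; an
optional `add_one` smoothing ((r+1)/(n_sims+1)) guarantees strictly
positive p for users who need it, but is off by default to match the plain
empirical definition. The exact counterpart uses the Binomial CDF/SF
directly.

**Calibration caveat.** Because the prevalences are estimated from the
same data that produces the observed overlap, the plug-in null is
positively correlated with the observation and the test is markedly
conservative: at n = 2000 and prevalences 0.5/0.6 the measured type-I
error at α = 0.05 is ≈ 0.002, whereas the same tails evaluated with
*known* prevalences give ≈ 0.0475. This is a property of the method as
defined, not of the implementation; rejections are therefore trustworthy
(the size never exceeds the nominal level) but the test sacrifices power
near the null. Power at dependence 0.3 (n = 2000) is ≈ 1.0. The
`calibrate` harness reproduces both numbers and uses the exact form per
dataset, which is the n_sims → ∞ limit of the Monte-Carlo procedure.

## Enrichment

One-sided (greater) Fisher's exact test per gene set on the 2×2 table
formed inside an explicit background universe, BH-adjusted across sets.
The background defaults to the union of all set members plus the query —
an explicit, reproducible default, though enrichment results are always
sensitive to background choice and a measured background (e.g. all
proteins quantifiable in the experiment) is preferable when available.
`entities_ratio` is set size over background size (the Reactome
convention) and `found_ratio` overlap over query size. The optional
hierarchy rollup annotates every node of a parent→child set tree with its
own enrichment, marking zero-overlap nodes `empty` (the "borderless node"
semantic of pathway maps); cycles are rejected.

## Synthetic data

The generators define the default study conditions used throughout the
tests and the acceptance script.

* **ESC tables** — proteins × (3 bait + 3 control) Poisson counts;
  background mean 3 (a plausible low-abundance spectral count for a
  gel-band LC-MS/MS workflow), planted true interactors at 10× enrichment
  in bait columns only, and 5% independent per-cell dropout applied after
  the draw to mimic stochastic MS detection. Counts can optionally be
  drawn negative-binomial (`dispersion`) to stress-test the t-based
  grading under over-dispersion. These distributional choices are
  conventions: real ESC depth and dispersion vary by instrument and
  workflow, and the generator does not model peptide-level identification,
  shared peptides, or abundance-dependent dropout — so passing tests
  demonstrate correctness of the statistical machinery, not robustness to
  every real-data pathology.
* **Dual-bait detections** — paired Bernoulli indicators with a target
  correlation realized in closed form as a linear interpolation between
  the independence table and the Fréchet upper/lower bound; the mixture
  weight is |d|/r_bound, so the Pearson correlation of the two columns
  equals the configured dependence exactly, and unachievable targets are
  rejected with the achievable interval. The exact joint 2×2 table is
  recorded in the ground truth. All configured rows are emitted, including
  (0,0) rows, so the empirical prevalences converge to the configured
  values.
* **PPI fixtures** — a three-layer random graph (chaperome core, shell,
  outer; default edge probabilities 0.8/0.25/0.05 over 50 nodes with an
  8-member core) whose edges are attributed to human, mouse or yeast taxa
  and split across the two file dialects with deliberate overlap, so that
  parsing, ortholog mapping and deduplication are all exercised; a
  configurable fraction of foreign identifiers is missing from the
  ortholog table. The planted GMT set is the chaperome core plus a few of
  its direct neighbors, so it is enriched among chaperome-adjacent
  proteins; decoy sets are uniform draws.

All generators are deterministic functions of config + seed, emitting
byte-identical files on reruns.

## Pipeline

Stages run in dependency order (optional simulate → grade → merge →
network → co-occurrence → enrichment), each consuming only the serialized
outputs of its predecessors; a failure halts with a stage-named error.
The manifest records version, config echo, per-stage wall-clock, surfaced
warnings (exclusions, unmapped records, rejected lines, isolates, empty
gene sets) and a sha256 checksum per output file. In an end-to-end
simulated run the PPI fixture shares the ESC protein namespace with the
planted true interactors placed first, so the chaperome core consists of
bait-detected proteins — the configuration in which the planted enrichment
signal is recoverable from the graded query.

## Problem sizes

The default validation experiments use: 200 random tables up to 500
proteins for the grading oracle; 5000 proteins for null calibration; 10⁶
Monte-Carlo replicates for the co-occurrence convergence grid
(n ∈ {5, 10, 50}); 1000 simulated datasets of 2000 interactors for size
and 200 for power; graphs up to 40 nodes for the brute-force topology
sweep; and a 1000-protein / 120-node end-to-end run with 2×10⁴
co-occurrence simulations. These sizes give Monte-Carlo error well inside
every asserted tolerance while keeping a full validation run to well under
a minute of CPU.

## Known limitations

* Identifier handling assumes one canonical ID per protein; alias
  resolution and release-specific symbol drift are out of scope.
* The grading applies no multiple-testing correction — by design, the
  grades are descriptive confidence tiers, not FWER/FDR-controlled calls.
* The co-occurrence test's plug-in conservatism (above) means borderline
  dependence can go undetected at small n.
* Enrichment p-values depend on the supplied gene-set collection and
  background; no live pathway-database access is attempted.
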