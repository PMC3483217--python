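# Methods

## Longevity-network construction

The interactome is a simple undirected graph over canonical gene ids:
self-loops are removed and reversed duplicate rows collapse at assembly,
never later.  Given a core set of known longevity-associated genes (LAGs),
the longevity network is built in three steps: (1) restrict the core to
genes present in the interactome, (2) add all first-order interaction
partners of those genes, (3) take the largest connected component (by node
count) of the subgraph induced on core-plus-partners.  Induced semantics
means partner–partner edges inside the candidate node set are retained.
Component ties are broken by core-gene count, then by lexicographically
smallest sorted node list, so the construction is deterministic.  Two
invariants are asserted on every build: the result is connected, and every
partner node is adjacent to at least one core gene.  `coverage_fraction`
reports how much of the interactome-present core the single component
retains.

## Interconnectivity and its permutation null

A gene set's interconnectivity is the fraction of its interactome-present
members with at least one edge to a *different* member; members absent from
the interactome are excluded from the denominator but reported.  The null
draws `n_present` nodes per permutation and recomputes the fraction.  Two
sampling modes exist:

* `uniform` (default): nodes drawn uniformly without replacement, the
  literal meaning of "randomized gene sets of the same size";
* `degree_matched`: nodes drawn within 10 degree-quantile bins, preserving
  the observed set's bin occupancy.  Uniform sampling is anti-conservative
  for high-degree gene sets, so reports always state the mode used.

The empirical p-value uses the add-one formula
`p = (1 + #{null >= obs}) / (1 + N)`, which can never be 0 and makes
"p < 0.001" exactly attainable at N = 999.  Because the statistic lives on
the grid j/n_present, heavy ties make the add-one p-value conservative for
small sets; calibration checks therefore use sets of ~40 genes, where the
grid is fine enough that the p-value distribution is close to uniform
(Kolmogorov–Smirnov statistic ≈ 0.07 against uniform in the shipped test).
Identical seeds give bit-identical results: candidate nodes are sorted
before any draw.

## Cross-species transfer

Orthology is a set of (species-A gene, species-B gene) pairs; in-paralogy
makes it many-to-many.  Transferring a gene set takes the union of all
orthologs of all members ("non-redundant" = set union on canonical ids; no
best-hit collapsing, because cluster semantics give no principled collapse
rule).  Unmapped genes are dropped from the result but always enumerated in
the mapping report, so `|input| = |mapped| + |unmapped|` holds per transfer.

## Candidate selection

Three criteria, applied as pure set algebra so filter order is irrelevant:
membership in the native-network partner set or the mapped foreign-network
partner set; absence from the union of all supplied species' known-LAG
lists; and essentiality (a caller-supplied set, or derivable from a
phenotype table with qualifying terms defaulting to embryonic lethal,
larval lethal, larval arrest, sterile).  RNAi-clone availability is a
separate final intersection.  Provenance (native-only / foreign-only /
shared) always partitions the candidate set, and every pool gene appears
exactly once in the candidates or in the per-gene exclusion trail.

## Screen analytics

**Thrashing classifier.**  Per scoring day the relative change
`(treated − control) / control` is computed; a record is called *long* when
at least 3 of 4 days show a change ≥ +10% and no day shows ≤ −10%
(*short* symmetric).  The opposite-direction veto is what "consistent"
means here: plain 3-of-4 counting would accept a +25/+25/+25/−25 record.
One consequence, covered by a property test: raising the threshold can only
weaken a directional call to none, but may turn a vetoed none into a
directional call (the veto point falls below the larger threshold); long
and short never flip.  A day with control fraction 0 cannot support a
relative change and is excluded as indeterminate; a record with all four
days indeterminate is an error.

**Survival statistics.**  Kaplan–Meier fitting and the two-group log-rank
test are delegated to lifelines; the package defines the derived measures.
The KM mean is the area under the survival step function up to the largest
death time (equal to the arithmetic mean of death times when censoring is
absent — asserted exactly in tests); the median is the first time the curve
reaches 0.5 or below.  "Maximum lifespan" is the mean age at death of the
longest-lived ⌈n/4⌉ deaths per group, and both effect measures are percent
changes relative to control.  The test suite cross-checks the log-rank
statistic against an independent hand-rolled risk-set-table computation to
1e-8 on random censored fixtures.  No multiple-testing correction is
applied across genes: the screen's design is per-gene p < 0.05.

**Screen bookkeeping.**  Verification frequency is verified/screened as a
percent; extrapolation projects the longitudinal confirmation rate onto all
preliminary hits and *truncates* (floor) the projected count before taking
its percentage — floor(101·19/45) = 42, floor(55·11/12) = 50 — because
half-up rounding would inflate the first projection.  All percentages use
half-up rounding, 1 decimal by default, integers for detection rates.
Long-effect summaries deduplicate genes listed by both network sources.

## The synthetic world

The generator emulates the statistical structure the pipeline assumes, not
biological nomenclature:

* **Interactome**: Barabási–Albert preferential attachment (default
  n = 800, m = 3), giving the heavy-tailed degree distribution of real PPI
  networks; Erdős–Rényi and power-law configuration models are available.
* **Planted core**: 50 genes densified to 4x the background pair density —
  the "more interconnected than chance" property of real LAG sets — with
  boost 1 defined as identity.
* **Essentiality**: Bernoulli labels (35% background) with 2x enrichment in
  the core, mirroring the LAG–essentiality association.
* **Orthology**: each gene mirrored into a second species with 80%
  coverage; 10% of mapped genes gain an extra paralog.
* **Lifespans**: Gompertz mortality, hazard `a·exp(b·t)` with rate of aging
  b = 0.30/day and baseline hazard a = 7.734e-4/day, giving a control mean
  lifespan of 18 days.  This targets an *eri-1*-background assay at 20 °C:
  such controls are slightly short-lived, and the day-15/17/19/21 thrashing
  window then spans the steep mortality phase (control survival ~0.88 down
  to ~0.47), which is what gives the 10%-change classifier its power.  With
  a 20-day mean, day-15 survival sits near 0.94 and a 1.3x lifespan factor
  cannot move it by 10% in relative terms.  A gene's lifespan factor f
  rescales time (T = f·T_baseline), so f = 1.25 shifts mean lifespan +25%
  by construction; 10% of animals are right-censored at a uniform fraction
  of their death time (bagging and wall deaths in a real assay).
* **Thrashing**: per day, survival fractions are binomial draws of 30
  scored animals at the group's true survival probability, with a matched
  control draw per record.

A single master seed spawns fixed per-component child seeds
(`numpy.random.SeedSequence`), so every generator is a pure function of
(parameters, seed) and regenerating one component never perturbs another;
the written world is byte-identical across runs.  Default world sizes were
chosen so the selection funnel yields ~100 screened candidates carrying 20
planted effects (12 long at f = 1.3, 8 short at f = 0.7).

**What the world does not emulate**: correlated false negatives of RNAi
(dilution, off-target effects), batch structure across assay plates, degree
bias of literature-curated interactomes, gene-specific censoring, or real
identifier namespaces.  Passing tests therefore demonstrate the pipeline's
statistical correctness and power under its stated model, not performance
on any real interactome.

## The reference screen dataset

`longnet.reference_screen` ships the raw tallies of a published 374-gene
worm RNAi screen of longevity-network candidates (screened / preliminary /
retested / verified counts per candidate class, two genome-wide baseline
screens, and the verified per-gene effect tables).  These are inputs, in
the way classic packages ship canonical datasets; every summary statistic
is recomputed from them through the screen-analysis operations at run time.
Its candidate-composition counts (228 + 272 with an overlap of 54, totalling
500) are reported as printed even though they are not mutually consistent;
the clone-level arithmetic (190 + 227 − 43 = 374) is consistent and is the
one used in computations.

## Numerical conventions and limitations

* Rounding is half-up everywhere (`decimal.Decimal`), matching how screen
  tables are conventionally printed; raw values are reported alongside
  rounded ones in pipeline JSON.
* Graph and permutation determinism relies on sorted node order before any
  random draw; reports serialize with sorted keys and no timestamps.
* The permutation null does not model degree-biased ascertainment unless
  `degree_matched` is requested; for literature-derived gene sets the
  uniform null overstates significance.
* Gompertz parameter recovery assumes proportional time-scaling of
  lifespans; hazard-crossing effects (e.g., early harm, late benefit) are
  outside the generator's model.
* The thrashing classifier's power depends on where the scoring window sits
  on the survival curve; the defaults place it in the mortality phase, and
  the shipped power checks (≥80% long calls at f = 1.3) hold under those
  defaults, not universally.
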