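# Methods

## The inference procedure

`sipcall` operates on pooled amplicon read libraries from a density-gradient
SIP experiment. For each treatment the input is six libraries — H, M and L
pools of the ¹³C treatment and of its ¹²C control — or, upstream of that,
per-fraction count tables with measured buoyant densities, which the pooling
stage collapses using the boundaries

* heavy: BD ≥ `bd_heavy_min` (default 1.730 g ml⁻¹, inclusive),
* light: BD ≤ `bd_light_max` (default 1.715 g ml⁻¹, inclusive),
* middle: the open interval between.

Replicate gradients of one treatment are summed count-wise before relative
abundances are computed, mirroring the pooling of replicate DNA before
sequencing. When measured densities sit exactly on a boundary they follow the
inclusivities above; there is no rounding step.

The classifier is a deterministic threshold rule (see README for the four
criteria and the LP definition). Deliberately absent: replicate-level
variance modelling, multiple-testing correction, and quantitative enrichment
(atom-fraction-excess) estimation — the method is categorical, and layering
inference machinery on top would change it. Comparisons 1 and 2 are strict
inequalities, 3 and 4 inclusive; the inclusive comparisons are evaluated with
an absolute tolerance of 1e-9 because decimal percentages (0.5, 0.1) are not
exactly representable in binary and a difference printed as 0.10 must not
fail by 4e-16. Phylotypes absent from a comparison library count as RA = 0:
at the measured depth, absence of reads is evidence of absence, and skipping
such phylotypes would bias toward labeling.

LPs are normalized per fraction class over that fraction's own potentially
labeled set, so the H and M sets each sum to 100 and are reported side by
side; a phylotype labeled in both is "labeled" with both calls retained.
The importance threshold (LP ≥ 5%) is inclusive.

### Filters

Routing is by marker gene. 16S and *mxaF* tables lose phylotypes whose
dataset-wide total is 1 (individual-library singletons survive if the total
reaches 2). ITS tables lose phylotypes with fewer than `its_min_reads`
(default 3) reads, then every library is rarefied to `its_rarefy_depth`
(default 1503) counts by uniform subsampling without replacement
(multivariate hypergeometric draw); libraries shallower than the target are
dropped with a logged warning. Each library draws from its own seed
sub-stream keyed on the library id, so results do not depend on column
order. All filters drop all-zero rows and are idempotent, and all run before
any relative abundance is computed.

### Substrate-range synthesis

Rows are the phylotypes labeled or weakly labeled in a chosen anchor
treatment (each tagged with its H or M fraction of origin); columns are every
(treatment, fraction class) comparison in the dataset; cells are
major / minor / unlabeled. Phylotypes labeled only in non-anchor treatments
do not appear. A merged view keeps the strongest state per treatment. Rows
are flagged `potential_crossfeeder` when the phylotype is labeled or weakly
labeled in any ¹³CO₂ treatment, `negligible` when it is not, and
`not_assessable` when the dataset has no CO₂ treatment — labeling in a CO₂
treatment means the apparent substrate assimilation could instead be
secondary fixation of respired ¹³CO₂.

## The synthetic gradient model

The simulator exists so that every stage of the pipeline can be verified
against known ground truth at desk scale. It emulates:

* **Community structure** — log-normal relative abundances
  (`abundance_lognormal_sd`, default 1.0, a typical amplicon rank-abundance
  spread), GC content uniform on `gc_range`, and a chosen subset of taxa
  carrying a ¹³C atom fraction. The labeled subset defaults to the most
  abundant taxa so the labeling signal is observable at realistic depths.
* **Buoyant density** — linear in GC with a full-labeling shift:
  ρ = 1.660 + 0.098·GC + 0.036·a (g ml⁻¹), the classical GC–density relation
  plus the conventional density gap between unlabeled and fully ¹³C-labeled
  DNA. Intermediate atom fractions interpolate linearly.
* **Fractionation** — a taxon's DNA disperses normally (sd `dispersion_sd`)
  about its mean density and is binned into 10 fractions with fixed edges
  (default 1.690 + 0.008·k g ml⁻¹, outer bins unbounded). Bin midpoints give
  the fraction densities the pooling stage consumes; the default geometry
  places 4 fraction midpoints in L, 2 in M and 4 in H.
* **Sequencing** — `read_depth` reads per treatment (default 2×10⁴), drawn
  in one multinomial over (taxon × fraction) cells with probabilities
  proportional to DNA mass. This emulates sequencing depth that follows DNA
  amount: a fraction holding no DNA yields no reads. The ¹²C control shares
  the identical community with every atom fraction forced to zero.

### Parameter defaults and why

* `dispersion_sd = 0.0015 g ml⁻¹`. Two constraints pin this down. A fully
  labeled mid-GC taxon (GC 0.55, ρ = 1.7499) must band essentially entirely
  in H — true for any sd below ~0.005. And the mechanism behind the weak
  label class — fully labeled DNA of GC < 40% bands in M, *not* H — must
  hold in the model: a GC-0.30 fully labeled taxon sits at ρ = 1.7254,
  1.15σ-per-0.0046 below the 1.730 boundary, so its Gaussian tail above
  1.730 must stay small enough that tail mass alone cannot reach the
  classifier's 0.5% abundance floor in a realistically occupied H library.
  That requires sd ≲ 0.0018; 0.0015 satisfies both with margin. Larger
  dispersions make the model call fully labeled low-GC taxa "labeled" via
  tail mass — a statement about the model's resolution, not about the
  organism.
* `gc_range = (0.40, 0.65)`. The lower bound encodes the working assumption
  that genome GC exceeds 40% for the bulk of the community. The upper bound
  keeps unlabeled DNA out of the heavy window: under the linear density
  model, unlabeled DNA reaches 1.730 g ml⁻¹ at GC ≈ 0.714, and the
  H-versus-control comparison presumes the control's heavy pool is nearly
  empty. Communities with abundant very-high-GC members (e.g. some
  Actinobacteria at GC > 0.70) violate that operating envelope and would
  produce heavy-pool background in both treatments; the simulator can
  represent them, but the defaults stay inside the envelope.
* `read_depth = 20 000` per treatment — the order of magnitude of a pooled
  amplicon library, and deep enough that a 0.5%-abundance signal is ~100
  reads.

### The analytic ground-truth oracle

`ground_truth_status` computes each pool's *expected* relative abundances —
DNA-mass weights summed over the pool's fractions and renormalized within
the pool — for both treatments and pushes them through the same four
criteria the pipeline applies. One gate makes the oracle the expectation of
the actual measurement rather than an abstract limit: a pool whose expected
read count (depth × mass share) is below one read yields no library and
all-zero abundances. Without the gate, renormalizing the vanishing trace
mass of, say, a ¹²C control's heavy pool (mass share ~10⁻⁶) produces
"abundances" of tens of percent that no finite sequencing run could observe,
and the oracle would disagree with the pipeline precisely where both should
be certain.

### What the simulator does not model

PCR amplification bias and primer mismatch, chimeras, gradient asymmetries
and fraction-volume variation, DNA recovery losses, and cross-feeding
dynamics (a cross-feeder can be emulated by assigning an intermediate atom
fraction by hand). Passing tests on synthetic data therefore demonstrate
that the procedure's logic is implemented correctly and behaves as designed
under its stated assumptions — not that those assumptions hold in any
particular soil.

## Statistical behavior worth knowing

* **The M ("weakly labeled") class is permissive by construction.** In the
  middle window both treatments carry substantial unlabeled DNA, so
  criterion 1 is close to a fair coin for an abundant unlabeled taxon and
  criterion 4's 0.1-point floor is within counting noise at 10⁴-read depths;
  null simulations show several false weak calls per treatment. The H class
  is the reliable one: in null simulations (no labeled taxa, 100 seeded
  replicates at depth 2×10⁴) the mean number of false "labeled" calls per
  replicate is ≈ 0. Weak labels should be read as hypotheses.
* **Determinism.** Every stochastic stage (community draw, sequencing,
  rarefaction) flows from a single configured seed with derived sub-streams;
  re-running a pipeline with the same inputs and seed reproduces every
  output byte-for-byte.
* **Desk-scale test sizes.** The test and acceptance suites use 10–10⁴-taxon
  communities, 10³-replicate property sweeps and 100-replicate null
  calibrations at depth 2×10⁴ — sizes chosen so the full suite runs in
  seconds while keeping counting-noise margins (≥ 5 binomial standard
  deviations for recovery checks) explicit.

## Known limitations

* Criterion 4 reads "the difference in the compared fractions" as the
  ¹³C-minus-¹²C difference within the same fraction class (H with H, M with
  M), paralleling criterion 1. The alternative reading (H-versus-L within
  the ¹³C treatment) coincides with this one whenever control abundances are
  small, which covers the dominant calls; datasets with abundant control
  signal in H could distinguish the readings.
* The linear GC–density relation and the Gaussian dispersion are idealized;
  real gradients show tailing and wall effects that blur the pool
  boundaries.
* The pipeline treats the OTU table as given: clustering, denoising,
  chimera removal and taxonomy are upstream concerns.
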