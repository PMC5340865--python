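# Methods

## The problem

16S rRNA amplicon surveys that ship fecal samples at room temperature (citizen
science, remote fieldwork) accumulate reads from a handful of fast-growing
taxa — predominantly *Gammaproteobacteria* — that multiply in the tube during
transit. Because amplicon data are compositional, those "blooms" do not merely
add noise: every extra bloom read depresses the apparent relative abundance of
every other taxon, distorting ordinations, taxonomy profiles, and diversity
statistics, and creating spurious separation between shipped and fresh-frozen
cohorts in meta-analysis. bloomcull identifies candidate bloom sequences at
the resolution of exact denoised sOTUs, removes them by exact sequence match,
and quantifies what the removal changes downstream.

## Detection model

Candidate blooms are scored on two axes.

**Storage axis.** In a controlled storage experiment, each subject has a
frozen day-0 baseline and room-temperature samples at days *t* > 0. For each
feature and comparison we compute `log2(c_t / c_0)` with three numerical
conventions:

* *Depth normalization.* Both samples' counts are rescaled to the smaller of
  the two totals before anything else, so a count threshold means the same
  thing at unequal sequencing depths.
* *Detection floor* (default 10 reads). A comparison in which both rescaled
  counts are below the floor carries no information and is excluded; a
  feature excluded from every comparison is marked absent-from-storage.
* *One-sided clamping.* A single sub-floor count is clamped up to the floor,
  so a bloom exploding from a near-zero baseline receives a finite, still
  large, fold change instead of an infinite or discarded one.

A feature's storage score is the maximum linear fold change over all
(study, subject, day) comparisons — blooms need only manifest somewhere.

**Cross-study axis.** A shipped cohort is compared against several
fresh-frozen cohorts sharing its feature space. The score is
`min over frozen studies of mean_freq_shipped / max(mean_freq_frozen, pseudo)`
with `pseudo = 1e-6` (about one read at typical depth) guarding empty
denominators. Taking the minimum over frozen studies is what gives the rule
its specificity: population differences can elevate a taxon against one
cohort, but a transit bloom should be elevated against *all* of them.

**Selection.** A feature is called a candidate when any of three criteria
fires: both axes reach 2-fold; the storage axis alone reaches 50-fold; or the
feature was never observed in the storage studies but reaches 2-fold on the
cross-study axis. Comparisons are inclusive (≥) and all thresholds are
configurable. The rule is deterministic — no per-feature hypothesis test —
because the question is not statistical significance but operational
enrichment.

**Severity ranking.** Candidates are ranked by
`severity = mean shipped relative frequency × log2(max(min_cross_fold, 1) + 1)`,
i.e. by how much of the shipped data a bloom occupies, tempered by how
enriched it is. This ranking is this package's own convention (callers may
supply any ordering); it exists so that "filter the top k" is well defined,
and ties break toward the lexicographically smaller sequence for
reproducibility.

## Filtering

Matching is exact on the 5′ prefix: bloom and feature sequences are trimmed
to the shorter of the two lengths and compared literally — no mismatches, no
indels. sOTUs from a common primer share their 5′ start, so prefix identity
is the correct notion of "the same sequence read to a different length". The
same convention (trim to the global minimum length) aligns feature spaces
when tables from different studies are merged; trim length is overridable.

Filtering drops matched feature columns and nothing else; surviving counts
are bit-identical, and `sum(original) = sum(filtered) + reads_removed` holds
in exact integer arithmetic. Samples emptied by filtering are kept and
flagged, never silently dropped — downstream rarefaction handles them
explicitly. Per-sample dropped-read fractions are reported with their
quartiles (linear interpolation between order statistics). In meta-analysis
the filter must be applied identically to every study; removing blooms from
the shipped cohort only would introduce exactly the bias the filter exists to
remove.

## Evaluation battery

* **Rarefaction**: subsampling without replacement (multivariate
  hypergeometric), deterministic per seed; samples below the target depth are
  dropped. The default depth for sweeps is 90% of the smallest sample total
  *after* filtering the full bloom list, so a single depth is attainable at
  every nested filter level.
* **Alpha diversity**: observed richness on rarefied counts. It is the
  simplest metric whose planted ground truth the generator can control
  exactly (see below); no phylogeny is required.
* **Kruskal-Wallis** across age categories, tie-corrected, chi-square
  p-values (scipy); the degenerate all-identical case returns H = 0, p = 1.
* **Bray-Curtis** on per-sample relative frequencies;
  `BC = Σ|u−v| / Σ(u+v)`.
* **PCoA** by classical metric scaling: double-center `−½D²`,
  eigendecompose, scale eigenvectors by the square roots of positive
  eigenvalues. Bray-Curtis is non-Euclidean, so negative eigenvalues occur;
  they are reported but excluded from coordinates and from the
  proportion-explained denominator.
* **Nested sweeps**: at each filter depth k (top-k blooms by severity), the
  age-diversity Kruskal-Wallis and the mean Bray-Curtis over random
  cross-study sample pairs (default 1,000 per study pair, drawn with
  replacement, re-drawn per depth with seed `seed + k`). The same rarefaction
  seed is reused across depths so depth-to-depth differences reflect
  filtering, not resampling noise.
* **Class-level taxonomy summaries**: per-sample frequencies summed by the
  `c__` rank of a Greengenes-style lineage (absent rank → "unclassified"),
  averaged per study unweighted.

## The synthetic-data generator

The generator exists so that detection, filtering and evaluation can be
validated end-to-end against known ground truth. Its model:

* Per-sample baseline compositions are symmetric Dirichlet (default
  concentration 10 over 500 features), i.e. a diverse, fairly even gut-like
  profile with realistic sample-to-sample dispersion.
* Planted blooms (default 5 features) grow exponentially with time at room
  temperature: after *t* days a bloom's relative mass is multiplied by
  `2^(rate·t)` (default 2 doublings/day) and the composition renormalized —
  the minimal compositional model of taxa that keep dividing in the tube.
  One bloom at baseline frequency *f* therefore reaches
  `f·A / (1 + f·(A−1))`, `A = 2^(rate·t)`, a closed form the tests check.
* Sequencing is multinomial at fixed depth (default 5,000 reads). No
  overdispersion beyond the Dirichlet baseline, keeping expectations exact.
* The storage design is 3 subjects with a frozen day-0 baseline and
  room-temperature samples at days 1 and 4.
* The cohort design is one shipped study plus 3 fresh-frozen studies of 50
  samples each. Shipped samples spend Uniform(4, 5) days in transit, which
  at the default growth rate puts every shipped sample at roughly 70–90%
  bloom content. This saturated regime is a deliberate design choice: what
  masks a diversity signal at filter depth 0 is that nearly all of a rarefied
  sample's reads are bloom reads (so richness reflects transit time, not
  biology), and saturation achieves that for every shipped sample rather
  than only the longest-shipped ones.
* The age effect on alpha diversity is planted structurally: each age
  category (default "young"/"elderly") has a fixed random subset of
  non-bloom features (default 0 and 100) zeroed in its samples. The masked
  features' mass is redistributed over the surviving *non-bloom* features
  only. Renormalizing the whole vector instead would raise baseline bloom
  load in the low-richness category and thereby confound age with bloom
  content; redistributing within the non-bloom block keeps the planted
  effect orthogonal to the blooms, which is precisely what lets the sweep
  demonstrate masking at depth 0 and recovery after filtering.
* Taxonomy assigns a *Gammaproteobacteria* lineage to every planted bloom
  (the class real transit blooms overwhelmingly belong to) and to a small
  background fraction (2%) of other features — real guts contain legitimate
  low-abundance members of the class, which is why the class profile does
  not collapse to zero after filtering.

What the generator does **not** emulate: PCR/chimera artifacts, primer bias,
overdispersed (Dirichlet-multinomial) sequencing noise, phylogenetic
structure, realistic rank-abundance curves (the Dirichlet baseline is far
more even than a real gut), bloom growth saturation at long times, or
population-level composition differences between cohorts. Passing tests on
these simulations therefore demonstrate that the algorithms are correct and
that the pipeline recovers planted signals under its stated model — not that
any particular real cohort is bloom-free after filtering.

## Numerical and design choices

* Thresholds are inclusive (≥); "2-fold or more" is read literally.
* Storage fold changes are computed on depth-normalized counts (not
  rarefied counts, not frequencies): normalization to the smaller depth
  makes the read floor meaningful, while preserving integer-scale intuition.
* Sample pairs for the distance sweep are drawn with replacement;
  independence across depths is deliberate (a per-depth derived seed), so
  each depth is an unbiased estimate rather than a paired trajectory.
* Merging sums counts of sequences that collide after trimming, preserving
  total reads exactly; merge order fixes feature order (first appearance).
* Zero-total samples are dropped (with a record) wherever frequencies are
  required, and kept-but-flagged wherever counts are filtered.
* Default problem sizes for the simulation-based validation (500 features,
  4 × 50 samples, depth 5,000, 20 seeds) were chosen as the smallest
  conditions under which the planted effects are comfortably identifiable by
  the analytic power considerations above; they keep the full validation
  suite and the acceptance script fast on a laptop.

## Known limitations

* The severity score has no external definition; rankings from other tools
  can be substituted but will change nested-sweep x-axes.
* Prefix-trim matching assumes a shared 5′ primer; mixed-primer
  meta-analyses would need an alignment-based matcher, which is out of scope.
* The chi-square approximation for Kruskal-Wallis is poor below ~5 samples
  per group; the implementation does not switch to exact enumeration.
* BIOM support covers the 2.1 HDF5 core (ids + CSR matrices) and the classic
  TSV dialect; per-observation embedded metadata in BIOM files is ignored.
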