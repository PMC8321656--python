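# Methods

## Variant identity and set arithmetic

Every operation in the pipeline reduces to membership tests on the variant
identity key (chrom, pos, ref, alt).  Input is normalized only superficially
— a leading `chr` prefix is stripped, alleles are uppercased — and indels
are *not* left-normalized: inputs are assumed to come from a single variant
caller per cohort, and re-normalizing identities inside the pipeline could
silently merge or split keys and corrupt the count bookkeeping that the
whole argument rests on.  Contigs outside 1–22, X, Y are dropped (with a
logged count) so that chromosome-level logic, in particular the chrY
sex-discordance check, operates on a closed universe.

Germline subtraction is pure key membership; heterozygous/homozygous state
is deliberately ignored because the subtraction acts on variant lists, not
genotypes.  The common-polymorphism filter removes a variant iff its
population frequency is present and ≥ `af_threshold` (default 0.001) in at
least `min_databases` (default 2) of the consulted databases.  A database in
which the variant was never observed contributes nothing: absence is *not*
frequency zero, because "not catalogued" is precisely the property that
makes a variant a somatic candidate.  Removed variants are returned, not
discarded — the donor-overlap analysis needs the common side too.

## Tri-classification of shared coding variants

Shared coding variants are labelled by a precedence chain: (1) ExAC
frequency absent or ≤ 9.4×10⁻⁵ → probably somatic; (2) ExAC in
[10⁻⁴, 9×10⁻⁴] → rare donor germline; (3) donor-tumor AF in [0.49, 0.51]
→ donor heterozygous germline; (4) otherwise unclassified.  Two genuinely
open choices are resolved here and exposed as parameters:

* **Precedence when bands overlap** (e.g. ExAC 5×10⁻⁴ *and* donor AF 0.50):
  the ExAC band wins, because population frequency is the more specific
  evidence and the published tiers are disjoint counts.
* **ExAC-absent → probably somatic**: a variant unobserved in a catalog of
  tens of thousands of exomes is rarer than any observed frequency.

Note the chain leaves a gap (ExAC in (9.4×10⁻⁵, 10⁻⁴)); variants there fall
through to rules 3/4 rather than being silently absorbed into a band.

## Purity and clonality

Under a diploid, copy-neutral model a heterozygous truncal driver sits on
one of two alleles in every tumor cell, so `purity% = AF × 2 × 100`,
rounded half away from zero and clamped at 100 with a `capped` flag
(AF > 0.5 implies copy-number change or sampling noise, which the model
does not interpret).  No CNV/LOH correction is applied — this is the
method's stated scope, and drivers inside imbalanced regions will bias the
estimate; the `capped` flag at least makes the >0.5 case visible.  The 95%
interval on AF is Wilson (not Wald): depths are moderate and AF can be
near 0.  Clonality is assessed only pairwise, as the ratio of a candidate
subclonal driver's AF to the truncal driver's AF (≈ the fraction of tumor
cells carrying it); full subclonal deconvolution is out of scope.

**Estimator noise.** At mean depth 200 the single-site estimate has a
standard deviation of about `sqrt(200·q(1−q))` ≈ 6–7 purity points
(q = purity/2).  Individual samples therefore scatter by several points
around truth — exactly as the study's per-lesion estimates should be read
— while the mean absolute error across many replicates is ~4–5.5 points.
The recovery test asserts the mean-error form.

## MLPA model

Peaks are intra-normalized by the mean of the panel's reference probes
(arithmetic mean; the commercial analysis software's exact algorithm is
proprietary, and the arithmetic mean preserves the scale-invariance that
matters: multiplying every peak of a sample by a constant changes no
ratio).  The per-probe ratio divides the sample's intra-normalized value by
the mean across reference samples, with a t-interval on that reference mean
propagated through the division as the 95% range.  Borders are strict —
loss < 0.7, gain > 1.3, a ratio exactly on a border is normal — and the
region verdict is the majority probe call when it reaches half the
in-region probes, ties resolving toward the abnormal call (screening
favors sensitivity); both choices are configurable.

## The simulator

The simulator generates what the pipeline needs to be tested end to end,
with ground truth:

* **Catalog** (`n_common` default 320,000; rare entries allocated per
  individual, default 700): common entries carry a latent population
  frequency uniform in [0.001, 0.5] — a deliberately flat spectrum, since
  these model variants *already ascertained as common* in reference
  databases, not a neutral site-frequency spectrum — jittered per database
  (lognormal-free multiplicative Gaussian, sd 0.1) and guaranteed present
  at ≥ 0.001 in at least two databases.  Rare entries are present in a
  random half of the databases at frequencies uniform in [10⁻⁶, 9×10⁻⁴].
  With these defaults a germline carries ≈ 1.3×10⁵ variants, matching the
  scale of a whole-exome call set.
* **Germlines** follow Hardy–Weinberg genotype frequencies (hom f², het
  2f(1−f)); rare variants are private and heterozygous.  A male germline
  carries 20 hemizygous chrY variants (AF 1.0) by default; a female
  germline carries none, so any chrY content of a female host's lesion is
  donor-origin by construction.
* **Tumors**: somatic variants are assigned to clones; a variant in a clone
  of fraction c has AF 0.5·c in a pure tumor.  Exactly one clone is truncal
  (fraction 1.0).  Somatic variants inside a homozygous-loss CNV carried by
  their own clone are not emitted (both alleles lost); planting a driver
  inside its own loss is a configuration error.  Germline variants are
  retained regardless of CNVs — a copy-neutral simplification.  The default
  CNV is the CDKN2A/B focal deletion span chr9:21,948,801–22,163,300.
* **Rendering** at purity p: tumor-lineage variants are diluted to p × AF;
  the host's own germline variants are emitted at their constitutional AF
  (0.5 het) irrespective of purity.  (Physically, residual normal cells
  would put host-het AF at 0.5·(1−p); the simpler convention is used
  because host-germline variants are subtracted by key before any AF is
  interpreted, so only their presence matters.)  When a polymorphism is
  carried by both individuals the larger expected AF wins and the origin
  label records the collision.  Depth is Poisson(mean_depth, default 200 —
  the scale of the study's exome coverage), alt reads are
  Binomial(depth, AF), and a variant is emitted iff ≥ 1 alt read: a
  minimal detection model.  The 1% LNA-PCR limit is carried as
  `detection_limit_af` and only drives detectability flags.  Exome-capture
  dropout is a free per-sample parameter (default 0) rather than being
  fitted to any reported number.
* **MLPA**: expected in-region ratio is 1 − purity for a homozygous loss
  (residual normal tissue keeps contributing signal), 1 − purity/2 for a
  het loss, 1 + purity/2 for a gain, 1 elsewhere; observed ratio adds
  Gaussian noise (default sd 0.03) and every sample gets a global scale
  factor that intra-normalization must undo.  Reference samples are named
  for the HapMap cell lines conventionally used as MLPA controls.
* **Default cohort**: male donor; donor tumor sampled at purity 0.50 with
  a truncal BRAF V600E clone (1,200 private mutations) and a PIK3CA E545K
  subclone (fraction 0.04, i.e. AF ≈ 1% at purity 0.5 — at the LNA
  detection limit and below the WES limit); a female recipient
  contributing blood and a metastasis at purity 0.97 in which the PIK3CA
  clone has expanded to near-clonal; two male recipients with lesions at
  purity 0.78.  Per-lesion private mutations (default 300) model
  post-transplant acquisition.

What the simulator does **not** model, and hence what passing tests do not
establish about real data: sequencing error and artifactual calls,
capture-region structure (dropout is uniform, not targeted), linkage
between sites, population substructure in the frequency catalog, indel
representation ambiguity, and copy-number effects on allelic fractions
outside the configured CNVs.  Recovery rates measured here are therefore
upper bounds for well-behaved input, not claims about raw sequencing.

## Verdict thresholds

The transmitted/not-transmitted thresholds (overlap ≥ 80%, clean ≤ 5%,
≥ 5 chrY, ≥ 2 shared drivers; driver list BRAF, PIK3CA, SDHC, DDR2,
FANCD2) are this package's operating defaults, not published constants:
the underlying evidence in a genuine transmission case is not marginal
(donor overlap ~85–95% against ~0–5% for recipient-origin tumors), so any
threshold in the wide gap separates the cases.  They are exposed in
`DecisionThresholds`, and each verdict records which rules fired.

## Numerical conventions

Percentages round half away from zero: donor overlap to one decimal,
the common-subset percentage to the nearest integer, purity to the nearest
integer percent.  Overlap of an empty profile is 0.0%.  AF is undefined
(None, `NA` in TSV) at depth 0 rather than 0.  All randomness flows from a
single `numpy` Generator seeded by the cohort config, so identical configs
produce byte-identical output files.

## Problem sizes in the test suite

Unit and property tests run on reduced cohorts (catalogs of ~10³–10⁴
entries, clones of tens to hundreds of mutations) chosen so the suite
exercises every code path at the same statistical regime (depth 200,
study purities) in well under a minute of simulation; the published count
arithmetic is checked at full scale (~1.6–2×10⁵-variant profiles) where it
is exact set arithmetic and cheap.  Verdict-recovery properties use 100
independent cohorts per condition.
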