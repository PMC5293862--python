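# Methods

This note documents the models, defaults and design choices behind
`grassmet`, and what validation on synthetic data does and does not show.

## The synthetic survey

The generator emulates a population-scale metabotyping survey: `P`
populations, a range of genotypes per population, `r` clonal replicates
per genotype, assayed in `B` randomized batches that each carry bulk
control samples. Two presets are built in:

- **default** — 10 populations × 6 genotypes × 5 replicates, 12 batches,
  2 controls/batch (324 samples). Used by the tests and the acceptance
  script so everything runs in seconds on one CPU.
- **full** — 23 populations, 3–25 genotypes per population pinned to 233
  genotypes total, 5 replicates, 36 batches; the survey-scale design.

### Signal model

A cell's intensity for metabolite *m*, genotype *g*, population *p*,
sample *s* in batch *b* is

    I = base_m · presence_m(p) · geno_m(g) · exp(δ_{m,b} + σ_sh·λ_b·ε_{m,s}
        + σ_ind·λ_b·ε'_{row,s})

with

- `base_m` — metabolite abundance, log₁₀-uniform in [5.2, 6.5]
  (quantitative-differential metabolites in [5.3, 6.0]; showcase
  presence/absence markers at 10⁶·⁵–10⁷ so the population signature
  dominates profile distances, as qualitative variation does in real
  surveys);
- `presence_m(p)` — population multiplier. Invariant metabolites: 1
  everywhere. "Exclusive"/"absent" metabolites: 0/1 patterns (three
  glycosides exclusive to the first population, one alkaloid exclusive to
  the second, four compounds absent from both — a North-African-ecotype
  analogue). Quantitative metabolites: log-normal multipliers standardized
  to an exact log-sd of 1.0, so every draw is genuinely differential at
  the configured effect size;
- `geno_m(g)` — between-genotype biological variation, log-normal with
  sd 0.7 (plant secondary metabolites vary severalfold between genotypes);
- `δ_{m,b}` — batch location shift, N(0, 0.5²) per (compound, batch),
  applied identically to every isotope level of the compound (instrument
  response drifts per chemical species, not per detected row);
- technical noise with replicate cv ≈ `noise_cv` (default 0.2), split
  into a component shared across the compound's isotope envelope within a
  sample (injection/extraction scales the whole spectrum) and a small
  independent per-row residual (fraction 0.25 of the cv); `λ_b` is a
  per-batch noise-scale factor, log-normal sd 0.15.

Absent metabolites are rendered at a positive baseline-noise floor
(uniform in [0.5, 1.5]×10³), not zero — peak-filling in raw processing
produces filled noise values, so "absent" never means a literal zero.
Detected m/z carries a uniform ±5 ppm error per row, well inside the
20 ppm matching window. Isotope envelopes follow the binomial ¹³C model
([M+k]/[M] = C(n,k)(p/(1−p))ᵏ, p = 0.0107) restricted to [M], [M+1] and,
when above 10× the floor, [M+2]; the metabolite library caps carbon counts
at 40 so [M]/[M+1] > 2 stays attainable.

### Row formation and RT misalignment

Detected peak rows emerge from an alignment-like step: ions sharing an
m/z channel (20 ppm) have one apex RT per batch (isomer RT + batch drift,
uniform ±0.25 min); apexes are clustered by single-linkage with a gap
threshold (0.05 min) and each cluster becomes a row. Alignment resolves
drift for well-separated peaks, so single-isomer metabolites see only 10%
residual drift (no splitting); metabolites with closely eluting isomers
(thesinine rhamnoside, 2 isomers 0.2 min apart; the chlorogenic-acid
analogue, 3 isomers 0.18 min apart) get the full drift, which splits them
into more rows than there are isomers. Which row a given sample's signal
lands in follows the sample's own apex (batch drift + N(0, 0.03 min)
jitter), so fill patterns are batch-linked but not batch-deterministic.
A gap threshold of 0.04 min reproduces roughly six detected rows for a
two-isomer pair over 18 batches, the canonical misalignment outcome; the
0.05 default yields slightly fatter rows at the default 12-batch scale.

### What the generator does not emulate

Chromatographic peak shapes and raw spectra (only peak-table statistics);
ESI adducts beyond [M+H]⁺/[M−H]⁻; in-source fragment rows in the
intensity matrix (fragments appear in the pseudo-spectra library);
run-order drift within a batch; missingness other than injected outliers.
Passing tests therefore demonstrate correctness of the statistical
machinery under a controlled, known-truth regime — not performance on any
particular real instrument's quirks.

## QC pipeline

Fixed order: merge → batch-correct → residual-batch filter → replicate
outlier removal → invariance filter. Only batch correction alters
surviving intensities; every other stage removes rows or blanks cells.

- **Merging** joins rows within 20 ppm and 0.2 min (transitive closure,
  per-sample maximum, identity from the most intense member) and iterates
  to a fixpoint, making the operation idempotent. Duplicates arise from
  split detection of one chromatographic peak, so the maximum — not the
  sum — is the right reconstruction.
- **Batch correction** is the parametric empirical-Bayes location/scale
  adjustment: per-peak standardization, per-batch location effects shrunk
  toward a normal prior and scale effects toward an inverse-gamma prior,
  hyperparameters estimated by moments across peaks, conditional
  posteriors solved by fixed-point iteration (relative tolerance 1e-4).
  All model-based stages operate on ln(x+1); outputs return to the raw
  scale. The model is ill-posed for rows that mix detected signal with
  fill-in floor values; such rows are reshaped rather than corrected,
  which mirrors what happens to misaligned peaks in practice.
- **Residual-batch filter** removes peaks whose corrected log intensity
  still shows a batch effect (one-way ANOVA, p < 0.05). Constant peaks
  get p = 1 (retained) — the filter targets batch structure, and a
  constant peak has none. On null data the removal fraction calibrates to
  α; after correction it is conservative (≈0), because the EB adjustment
  removes batch means almost exactly.
- **Outlier removal** examines replicate groups with cv > 0.2 and blanks
  cells with |modified Z| > 3, most extreme first, recomputing after each
  removal, at most ⌊n/2⌋ blanked cells per group counting pre-existing
  blanks — this makes the pass idempotent. mad = 0 defines all scores as
  0: constant replicates contain no outliers. The trigger runs on
  corrected intensities (the paper-stage ordering leaves the reference
  scale unstated; post-correction is the scale on which replicates are
  comparable across batches), and |Z| is two-sided.
- **Invariance filter** removes peaks with Kruskal–Wallis p > 0.05 across
  populations, computed on genotype replicate medians. Constant peaks are
  removed (p defined as 1): the filter's purpose is retaining biological
  contrast. It runs once.
- **PCA QC** operates on log, peak-centered data; the control/experimental
  separation in PC1–PC2 (silhouette > 0) is the overall quality readout.

Re-running the whole QC on its own output changes nothing in the hard
filters; the EB step applies a vanishing second adjustment that can flip
a p-value sitting exactly at a threshold, so end-to-end stability is
near-exact rather than bitwise (tested as ≥95% row retention and
intensity drift below noise).

## De-isotoping

Candidate partners sit 1.00336 Da (¹³C−¹²C, charge 1 — small-molecule ESI
of this compound class is singly charged) above the seed within 20 ppm
and 0.2 min of apex RT; the group must correlate (Pearson r > 0.9 across
all samples, ≥3 shared non-missing) and the mean-intensity ratios must
satisfy [M]/[M+1] > 2 and [M+1]/[M+2] > 2 (mean across samples: robust to
metabolites absent from some populations). Groups are assembled greedily
in descending monoisotopic mean intensity, ties by ascending m/z, each
peak joining at most one group; when a seed has several viable partners
the one closest to the expected spacing wins. The greedy order resolves
conflicts the criteria themselves leave open; an exhaustive
pair/triple-enumeration oracle in `grassmet.reference` confirms the
implementation on random tables. De-isotoping runs after batch
correction, where envelope correlations are clean; split isomer rows
whose fill patterns diverge between isotope levels legitimately fail the
criteria and survive — as their real counterparts do.

## Differential mining

Statistics run on genotype replicate medians (the clone is the unit of
independence). The moderated one-way test shrinks per-peak residual
variances toward a common prior: with s²_g on d_g df, the prior
(d₀, s₀²) solves the moment equations of log s²_g (digamma/trigamma
inversion), and F̃_g = MS_between/s̃²_g with s̃²_g = (d₀s₀² + d_g s²_g)/
(d₀ + d_g) is referred to F(k−1, d₀ + d_g). d₀ = 0 reproduces classical
ANOVA exactly; d₀ = ∞ uses the common prior variance. The implementation
was verified against the reference R implementation of this shrinkage on
a fixed dataset (agreement to 8 decimals; the numbers are frozen in the
test suite). FDR control is Benjamini–Hochberg.

Ranking gates peaks at mean intensity > 1e5 and orders by moderated F
(ties by peak id). The ranking statistic is recorded in the result
metadata, as the specific ranking method behind the original top-50 lists
is not identifiable; moderated F within the intensity gate reproduces the
gate-then-top-k behavior with a fully specified statistic.

Population profiles are the median across a population's genotypes of
the genotype medians, on raw intensity — presence/absence contrast is
what separates populations, and logs would compress it; UPGMA
(average linkage, Euclidean) with Newick export runs on the profile
vectors. A step-by-step merge oracle validates topology and heights.

## Isobaric peak aggregation

All rows within target_mz·(1 ± ppm/10⁶) (optionally an RT window) are
summed per sample, missing contributing zero, so splitting any row's
intensity across isomeric rows leaves aggregates exactly unchanged. The
across-population F-test runs on genotype medians by default
(`unit="genotype"`); `unit="sample"` provides the naive per-sample test
that ignores clonal structure. The misalignment scenario
(`grassmet.scenarios.cga_misalignment`) renders the survey, batch-corrects
it, and contrasts the two: split rows of the invariant three-isomer
metabolite reach p < 0.05 under the naive per-row test (their
batch-linked fill patterns violate its independence assumptions), while
the RT-windowed aggregate tested at the genotype level recovers
invariance. The RT window (3.49–4.55 min) covers the isomer cluster and
excludes isobaric metabolites eluting elsewhere — the reason aggregation
windows should be RT-restricted in practice. Because single-run p-values
are stochastic, the scenario reports medians over 7 replicate renders.

## Annotation

Three evidence criteria: (1) an isotope partner at +1.00336 Da within
20 ppm whose RT falls inside the target's [rtmin, rtmax]; (2) the
correlated co-eluting group (r > 0.9, apex within 0.05 min — the same
detected apex bin) as candidate in-source fragments; (3) neutral-loss
decomposition. Decomposition prefers losses directly evidenced by
observed fragment mass differences (walking parent → fragments →
aglycone), then fewest moieties, then lexicographic symbol order; the
moiety list is reported aglycone-outward (the reverse of loss order from
the parent), matching conventional names. A single-loss gap between the
parent and a library aglycone is accepted on exact mass alone (a
standard mass-based annotation hypothesis; the evidence record marks the
aglycone as "inferred" rather than "observed"), but multi-moiety
decompositions require an observed aglycone ion or fragment ladder —
combinatorial mass coincidences grow too fast to name on arithmetic
alone. Kaempferol and luteolin share C₁₅H₁₀O₆ and are always reported as
an ambiguous set. Hexose is written Glc and deoxyhexose Rha by field
convention; the evidence list records the assumption. Glycosylation
positions and linkages are never inferred. Moiety masses are monoisotopic
neutral-loss values; nominal 162/146/204/248 matching agrees within the
ppm window. Perloline's library entry stores its published calculated
m/z (333.1234, [M+H]⁺) directly, as no formula is published alongside it;
the chlorogenic-acid entry stores the formula C₁₆H₁₈O₉, and
`chem.cga_reference_discrepancy()` reports the ≈3 ppm mismatch with the
quoted 353.0867 [M−H]⁻ value instead of silently matching either.

## Numerical choices and degenerate inputs

- Proton mass 1.007276 Da for adducts (not the hydrogen atom mass);
  validated by reproducing the four printed 4-decimal reference values.
- Missing values are excluded pairwise everywhere and never imputed.
- Correlations need ≥3 shared non-missing samples; otherwise the pair is
  skipped without a claim.
- Empty aggregation windows and unannotatable peaks are results with
  notices, not errors.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`; identical seed + config gives
  byte-identical outputs.
- Positive and negative ion mode are separate runs end to end.

## Validation scale

Tests and the acceptance script use the default preset (~550 peak rows ×
324 samples), 100-table oracle sweeps for de-isotoping (≤50 peaks) and
UPGMA (4–8 leaves), and 7 replicate renders for the stochastic
misalignment scenario; the whole suite runs in about a minute on one CPU.
The full 233-genotype preset exercises the same code paths at survey
scale and is available behind `preset="full"`.
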