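# Methods

This note documents the models, parameter choices and numerical conventions
behind the pipeline, and what the synthetic cohort does and does not
emulate.

## The measurement model

A CE-TOF instrument records centroided ion signals (m/z, intensity,
migration time) over m/z 350–3000. A tryptic peptide of neutral
monoisotopic mass M appears as one or more isotope-resolved charge
envelopes: at charge z the monoisotopic peak sits at (M + z·1.00728)/z and
successive isotopologues are spaced 1.00235/z apart. All masses are
monoisotopic throughout; the proton mass (1.00728 Da), isotope spacing
(1.00235 Da) and water (18.01056 Da) are fixed named constants, and residue
masses come from the standard monoisotopic table (via pyteomics).

## Spectral processing

**Noise floor.** The instrument "random noise" level is estimated as
1.4826 × the median absolute deviation of the intensities lying below the
sample's median intensity. The sub-median restriction keeps abundant
analyte peaks out of the estimate; the 1.4826 factor makes the MAD
consistent for a Gaussian floor. The estimator is accurate (to ~10%) when
the sub-median population is dominated by an approximately Gaussian
baseline; for other floor shapes it is an order-of-magnitude estimate,
which is all the S/N > 4 gate requires. A constant peak list would give a
zero estimate and is clamped to machine epsilon. This estimator is a design
choice — the acquisition software's noise definition is not public — and is
isolated in one function.

**Charge inference and deconvolution.** Envelopes are assembled greedily
from intensity-ordered seed peaks: for each candidate charge 1–10 the chain
of co-migrating peaks spaced 1.00235/z (within 20 ppm of the seed m/z) is
collected and the longest chain wins. Chains of length one carry no charge
information and are discarded, which also removes essentially all decoy
noise peaks surviving the S/N filter. The charge is re-derived from the
final chain spacings. Neutral masses from different charge states of one
molecule are merged when they agree within the identity mass tolerance and
co-migrate within the CE window; the merged feature carries the *sum* of
the envelope intensities (whether the original acquisition software sums or
takes the maximum is unstated; summing is asserted here and tested as
such), the union of charge states, and an intensity-weighted centroid mass.

## Calibration and normalisation

Reference signals are consensus clusters detected in ≥ 35% of samples
(threshold configurable); their canonical coordinates are across-sample
medians. Per sample, observed time and mass are regressed onto the
canonical values by OLS — separately, since the two drifts are physically
unrelated — with one optional trim pass at 3 SD of the time residuals.
When matching a sample's features to the reference list, the time window is
widened 3× relative to the identity window because pre-calibration drift
can exceed the post-calibration identity criterion; the mass tolerance
disambiguates. Fitted slopes outside (0.5, 2.0), or fewer than 5 matched
references, are calibration failures: the sample is flagged and excluded,
never silently passed. The canonical frame (cohort medians) is itself a
convention; any affine frame would do.

Intensity normalisation is median-ratio scaling on internal standards:
candidate standards are consensus peptides with detection frequency ≥ 0.8
whose case/control rank-sum p exceeds 0.5 (no hint of disease association),
of which the top k = 22 by frequency are used — the count honours the
reference workflow and is configurable, not a hard constraint. Each
sample's factor is (median over samples of per-sample median standard
intensity) / (that sample's median standard intensity), so scaling is
idempotent. Samples with fewer than 3 detected standards keep factor 1 and
are flagged.

## Consensus matching

Two features are the same peptide when |Δmass| ≤ tol(mass) and |Δtime| ≤
win(time)·time, where tol rises linearly from 50 ppm at 800 Da to 75 ppm at
15 kDa and win from 2% at 19 min to 5% at 50 min, both clamped outside the
anchors. The window is interpreted as a symmetric half-width; that reading
is isolated in `ToleranceModel` should the one-sided interpretation ever be
preferred. Clustering is greedy in descending intensity (ties broken by
mass, time, sample id, so the result is deterministic and
permutation-invariant): a feature joins the nearest in-tolerance consensus
(Euclidean distance in tolerance-normalised units, evaluated at the
consensus centroid) that does not yet contain its sample, else seeds a new
one. Centroids are intensity-weighted means. A global graph-partition
matcher could trade speed for marginally better splits; at desk scale the
greedy solution is adequate and O(n log n)-ish. Consensuses seen in only
one sample are removed as sporadic.

## Annotation

The digest enumerates tryptic peptides (cleave C-terminal to K/R except
before P) with up to one missed cleavage by default, fixed
carbamidomethyl-C, and all combinations of oxidised Met / hydroxylated Pro
up to two variable sites per peptide (a combinatorial bound, configurable).
Assignment is by monoisotopic mass within the identity tolerance; among
multiple candidates, those whose predicted CE charge (1 + #K + #R + #H —
the N-terminus and every basic side chain protonated at the acidic
separation pH; His counts because pH ≈ 2 is far below its pKa) matches an
observed charge state are preferred, then smallest |mass error|, fewer
modifications, lexicographic sequence. Unannotated consensuses are retained
in outputs but excluded from protein statistics. Proteins with fewer than
two distinct assigned sequences are dropped. No fragment-spectrum scoring
or decoy-FDR is attempted: in this artifact the generator's truth plays the
role of the sequenced-peptide list.

## Differential statistics

Protein abundance in a sample is the arithmetic mean of the protein's
detected peptide intensities, 0 when none is detected (the zero convention
feeds the tests; a detected-only mean is available behind a flag). The
variance-ratio F-test at α = 0.05 gates the location test: compatible
variances → equal-variance t-test, otherwise Mann-Whitney. The reference
description of this gate conflates variance testing with normality testing;
the literal variance-ratio test is implemented and the gate is swappable.
Fold change is mean(case)/mean(control); its dispersion is reported as the
SD of per-case-sample values over the control mean (the published
dispersion column is not defined anywhere; this reading is isolated in one
function). BH adjustment uses m = all tested proteins — with the published
19-of-97 example, this is the only choice that reproduces the printed
adjusted values at ranks 2–6; the printed values at ranks ≥ 7 are not
reproducible from the printed raw p-values under any rank assignment
(plausibly computed from unrounded p-values) and are not asserted anywhere.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not instrument physics:

- **Proteome.** Random proteins (default 97, matching the study's identified
  set; the analysis scripts use 30 for a desk-scale demonstration) with K/R
  residue frequencies of 5.5% each, giving tryptic fragments of ~10
  residues; each protein is redrawn until its digest has ≥ 2 fully cleaved
  peptides in the sequenced mass range 804–3953 Da. Only such in-range,
  fully cleaved peptides are emitted, and peptides whose every charge
  envelope would fall outside m/z 350–3000 are dropped as unobservable.
- **Abundance.** Protein base abundances are lognormal (median 5·10⁴
  counts, σ = 0.7) with lognormal peptide ionisation factors (σ = 0.4); no
  published abundance distribution exists for vitreous peptides, so
  lognormal is an assumption, not a claim. Case samples multiply a
  protein's abundance by its fold change; by default ~20% of proteins are
  upregulated with effect sizes resampled from the 19 published
  differential fold changes (1.65–35.3, all > 1). Intensity noise is
  multiplicative lognormal with CV 0.2; per-sample gains are lognormal
  (σ = 0.3).
- **Migration.** t ∝ M^(2/3)/z mapped affinely onto 19–50 min — the
  classical electrophoretic mobility scaling; the reference workflow states
  only a qualitative composition–migration correlation. The charge driving
  mobility is the solution-phase (predicted) charge, so all ESI charge
  states of a peptide co-migrate. Each peptide ionises at its predicted
  charge and one above (intensity split 0.7/0.3).
- **Isotopes.** A binomial "averagine-like" model: ~44.5 heavy-atom trials
  per kDa at p = 0.011 per trial; isotopologues below 1% of the envelope
  are not emitted. Exact isotopologue chemistry is out of scope.
- **Distortions.** Per-sample linear drift in time (slope SD 1%, intercept
  SD 0.1 min) and mass (slope SD 5 ppm, intercept SD 2 mDa), plus white
  measurement jitter (2 ppm mass, 0.05 min time). Detection is
  peptide-level Bernoulli, independent across samples (default 0.8; 0.95
  for the 22 invariant internal-standard peptides, which always belong to
  fold-1 proteins). Missingness is therefore missing-completely-at-random;
  real intensity-dependent censoring is *not* emulated.
- **Decoys.** A uniform noise floor (default: as many decoy peaks as real
  ones, intensities uniform below 4× the injected noise level of 30
  counts) gives the S/N filter real work.

Everything is deterministic given the cohort seed (per-sample RNG streams
are derived from it), and regeneration is byte-identical.

**What passing tests do and do not show.** The generator reproduces the
pipeline's *assumed* structure — linear drift, multiplicative noise, MCAR
missingness, clean isotope envelopes. Recovery rates measured on it bound
what the pipeline can do when its assumptions hold; they say nothing about
nonlinear time warping, intensity-dependent missingness, chimeric spectra
or real isotope fine structure.

## Problem sizes and numerical conventions

The analysis scripts and the recovery tests use a 20-case / 15-control
cohort. Stage-level recovery checks run on ~50–70-peptide samples, where
near-isobar interference is negligible; the end-to-end run uses the full
97-protein proteome (~600k peaks, under a minute on one CPU). Tolerances in
tests follow the quantities' own scales: exact equality for tolerance
anchors, 1e-9 for algebraic identities, simulation envelopes (binomial 99%
bands) for stochastic rates.

Tie-breaks are fixed everywhere (lower mass, fewer modifications,
lexicographic order) so every stage is deterministic and
permutation-invariant; degenerate inputs (constant intensities, empty peak
lists, zero-variance groups) have documented conventions rather than
exceptions wherever a convention is defensible.

## Known limitations

- **Near-isobar interference.** Peptides within the identity mass tolerance
  that co-migrate are merged — in deconvolution (intensity absorbed into
  one feature) or matching (mixed consensus). Tryptic peptide masses
  cluster in ~1 Da bands, so at proteome scale (~1500 peptides) a few
  percent of peptides interfere; an abundant differential peptide can then
  contaminate a null protein's abundance and produce a false positive with
  a genuine (data-level) signal. This is a physical resolution limit of
  tolerance-based label-free matching, not a statistics failure; the
  differential report's protein-level FDR is therefore nominal only with
  respect to statistical noise.
- The migration model is a one-parameter scaling law; no attempt is made to
  model sequence-specific mobility beyond charge and mass.
- No profile-mode spectra, no MS2 simulation, no nonlinear (spline/LOESS)
  time warping, no external-database enrichment analyses.
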