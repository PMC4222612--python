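# Methods

This note records the models implemented in `rbpscreen`, the defaults that
matter, what the synthetic data do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Differential expression: one-class SAM

Each strain is compared to wild type on two-colour arrays with 2–3
replicate log2 ratios per feature. After loess normalization (below), the
per-feature statistic is

    d_i = m_i / (s_i + s0)

where m_i is the mean log-ratio across replicates, s_i its standard error,
and s0 the fudge factor that stops low-variance features from dominating
the ranking. s0 is selected from the {0, 5, …, 100} percentiles of the s_i
distribution by minimizing the coefficient of variation of the
window-wise MAD of d across s-percentile windows (100 windows for tables of
≥1000 features, ~n/10 otherwise).

The null distribution comes from sign-flip assignments of the replicate
columns, fully enumerated whenever 2^k fits the permutation budget (k = 3
replicates gives 8 assignments). Two small-sample choices depart from the
textbook recipe and are deliberate:

- **The identity assignment is excluded** from the null set — it reproduces
  the observed statistics exactly and, with only 4–8 assignments in total,
  contaminates every tail count with the observed calls themselves.
- **The expected false-call count uses the add-one permutation correction**
  (Phipson & Smyth 2010): (1 + total permuted exceedances)/(B + 1) rather
  than a median or mean of per-permutation counts. With a handful of
  permutations the median/mean count is exactly zero for the most extreme
  observed feature in a large fraction of *pure-null* datasets (the
  observed and permuted maxima are exchangeable and mutually correlated),
  which would report FDR = 0 and call noise. The add-one numerator is never
  zero, so a single feature can only be called when the evidence clears
  roughly B+1 permutations' worth of clean tails. Measured under the null
  conditions used in the tests (2000 features, 3 replicates, 200 runs),
  ~1% of runs produce any call at a 5% target FDR, while a 10-sigma
  spike-in is recovered completely.

Calls at a target FDR use the smallest delta (margin over the expected
order statistics) whose estimated FDR is at or below the target; π0 is
estimated from the central 50% of the permuted d values. Per-feature
q-values are the lowest estimated FDR among the deltas at which the feature
is called. With 2 replicates only 3 non-identity sign assignments exist and
the q-value granularity is correspondingly coarse; this is reported, not
hidden. Probe pairs are aggregated by the mean of their log-ratios per
replicate, with discordant pairs (opposite signs, both |M| > 1) flagged
rather than dropped.

## Normalization

Loess normalization removes intensity-dependent dye bias by subtracting a
lowess fit of M on A per replicate (statsmodels lowess, `it=0`, default
span 0.4). The span must be small relative to the wavelength of the bias:
the default suits the smooth monotone-to-banana shapes of real two-colour
bias, while the oscillatory stress case in the tests (0.5·sin(A), ~1.3
periods across the intensity range) needs span ≈ 0.2 to leave residual
decile medians under 0.05. Stability experiments are median-centred instead
(the labelled/total comparison has no meaningful global zero).

## Half-life estimation

First-order decay at steady state gives f = 1 − 2^(−t/T) for a t-minute
4sU pulse, inverted as T = −t·ln2/ln(1−f). The estimator is exact on the
model; its error is entirely inherited from f. Labelling time is per-sample
metadata (7 or 10 min), never global. f ≤ 0 is reported as an infinite
half-life with a warning (unresolvable within the pulse); f ≥ 1 is
rejected. Array ratios are mapped to fractions by f = clip(c·2^r, ε, 1−ε)
with c anchored so the genome-median fraction equals a declared anchor
(default 0.2) — the original calibration lives in prior work and is not
restated here, so the anchor is this package's declared substitute; rows at
the clipping boundary (ε = 10⁻⁴) are flagged censored. Replicates are
combined by computing T per replicate and taking the median, which is
robust to the occasional clipped fraction. Stability changes between
strains feed the per-replicate log2 half-life ratios back into the same SAM
machinery (or a fold-change threshold, for quick looks).

## RIp-chip predictive-value cutoff

C(k) is the cumulative count of regulated genes in the top k of the
enrichment ranking; B(k) = k·|S|/N is its exact expectation under random
ordering (an optional seeded shuffle baseline exists for diagnostics, but
the analytic line is the default since it is the shuffle's mean). Slopes
are estimated over sliding windows of 50 genes, and k\* is the start of the
first run of 3 consecutive windows whose C-slope is at most 1.25× the
B-slope. The original procedure picks this point by eye; window, ratio and
persistence are this package's operationalization and are exposed as
parameters. Ties in enrichment are broken by gene id, making k\* invariant
under any strictly monotone transformation of the scores. Targets are the
intersection of the top-k\* sets of the two biological replicates.

## Splicing classifier

Counts are converted to CPM with a 0.5 pseudocount; replicate libraries are
summed per condition before the mutant/wt ratio is formed (per-replicate
ratios are reported for diagnostics). With thresholds θ_up = 2 and
θ_flat = 1.5: both ratios ≥ θ_up ⇒ splicing defect; intron ratio ≥ θ_up
with EIJ ratio within θ_flat of 1 ⇒ intron turnover; intron ratio < θ_up ⇒
unchanged; anything else is ambiguous rather than forced into a class. The
strain verdict requires ≥10 supporting introns and a majority over the
competing class. Junction-read extraction is upstream of this package; the
minimum junction overhang used to define an EIJ read travels as table
metadata. Classification is invariant to joint rescaling of all library
sizes.

## Overlap statistics

All enrichment claims use the upper-tail hypergeometric P(X ≥ k) with an
explicit universe per comparison; mismatched universes raise rather than
being silently intersected, because the screen's comparisons switch between
the coding (5037), ncRNA (496) and intron (1491) universes and N changes
every p-value. Expected overlaps are reported to two decimals (never
rounded to integers). Benjamini–Hochberg adjustment is available for
multi-strain reporting; the per-comparison p-values themselves are raw.

## Registry accounting

Proteins may carry several domain-family assignments; unique-protein counts
deduplicate by protein id and conflicting essentiality annotations fail
loudly. The essential percentage is truncated (not rounded) at one decimal,
the reporting convention of the screen's summary tables (47/136 → 34.5).
Essentiality enrichment is the exact upper-tail binomial
P(X ≥ k | n, p_genome). Deletion verification declares a strain verified
iff every probe of its deleted gene sits at or below background in the
mutant channel; background defaults to the 5th percentile of that strain's
full signal distribution, since silenced probes populate the array's low
tail. Genes without probes stay unchecked (they needed gene-specific PCR in
practice).

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed); identical seeds give
byte-identical tables, and truth labels always travel with the data.
Defaults encode the study conditions:

- regulons of 4–104 genes per affected strain, mostly up-regulated, with
  log2 effect 2.0 ± 0.2 and replicate noise sd 0.2;
- a screen of 74 strains, 25 of them affected, whose true regulons
  partition 816 distinct coding genes into 483 up-only, 287 down-only and
  46 both-direction genes (the published partition is internally
  inconsistent — its three printed components sum to 862 — so the
  consistent partition preserving the union, the down-only and the
  both-direction counts is used);
- first-order decay with class-median half-lives of 31 / 30.5 / 14.5
  minutes (coding / ncRNA / intron), log-normal spread 0.5, and
  multiplicative log-normal replicate noise with CV 12.6% applied to the
  labelled fraction before clipping — a CV is a multiplicative statistic,
  hence multiplicative noise;
- RIp-chip enrichments standard-normal with bound targets shifted by 5
  units, two independent replicates;
- negative-binomial read counts parameterized by (mean, dispersion), with
  dispersion 0.1 and two libraries per condition (the classifier sums
  replicate libraries; with a single library per condition the dispersion
  alone puts ~0.45 log-sd on every ratio and no threshold can separate the
  regimes at fold 4);
- 3′-UTR-like sequences as i.i.d. uniform RNA with the motif written at a
  uniform random position into a configurable fraction of targets.

None of this emulates probe-level image artifacts, spatial array effects,
gene–gene expression correlation, sequence composition bias, or the
mapping ambiguity of real junction reads. Passing tests therefore
demonstrate that the callers recover the structure they were designed for
at realistic noise levels — not that they are robust to every pathology of
real arrays or libraries.

## Scale of the shipped analyses

Tests and the acceptance script run the screen at its native scale (5037
coding genes × 74 strains, 496 ncRNAs, 1491 introns, 3000 features per
decay class) with 200-run null calibrations; the full acceptance pass
completes in well under a minute on one CPU. Screen-level counts recovered
by the callers carry their false-positive/negative noise — the
differential-expression union lands within a few percent above the planted
816 because each affected strain contributes a handful of false calls at a
5% FDR.

## Known limitations

- Two-class (unpaired) SAM, array spatial correction and background
  subtraction are out of scope.
- Non-steady-state decay models (chase experiments), transcription-rate
  estimation and 4sU incorporation bias correction are out of scope; the
  anchor calibration is declared, not estimated.
- The RIp-chip cutoff assumes the regulated set is measured on the same
  universe as the ranking; a minimum-enrichment floor in addition to rank
  is not applied.
- Motif matching is exact, single-strand, on the RNA alphabet; degenerate
  IUPAC codes and de-novo motif discovery are explicitly excluded.
- qPCR efficiencies are inputs (default 2.0); standard-curve estimation is
  not implemented.
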