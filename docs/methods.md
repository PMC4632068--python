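# Methods

This note documents the models implemented in `pbodykit`, the choices made
where the underlying procedures are underdetermined, and what the synthetic
data does and does not establish.

## AP-MS quantitation (`pbodykit.apms`)

Spectral counts are a label-free abundance proxy whose expectation scales
with protein length and peptide detectability. The APEX correction divides
each protein's count `n_ir` by its expected peptide observability `O_i`
(a strictly positive, precomputed per-protein score) and renormalizes
within the run:

    apex_ir = C * (n_ir / O_i) / sum_k (n_kr / O_k)

`C` defaults to 1 (relative abundances); a flag lets `C` be the run total
so scores read as corrected pseudo-counts. Normalization is per run by
default; whether the original analyses normalized per run or globally is
not recoverable, so both are exposed (`per_run`).

Bait renormalization divides every score by the bait's score in the same
run, turning prey abundances into stoichiometries relative to the purified
complex; the bait maps to exactly 1.

Paired condition comparison uses the pooled two-sample Z test on count
fractions `p_j = n_j / N_j`:

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/N1 + 1/N2))

A pooled fraction of 0 or 1 makes the test undefined; that is reported as a
null result (NaN), not an error. Per-pair abundance ratios use a
pseudocount for zero scores — half the smallest nonzero bait-normalized
score in the pair — which keeps ratios finite without letting the
replacement dominate real signal. A protein's condition trend requires
unanimity: `minus` only if every evaluated pair has ratio > 1, `plus` only
if every pair is < 1, otherwise `inconsistent` (a ratio of exactly 1 breaks
unanimity).

## Specificity scoring and filter cascade (`pbodykit.saint`)

Control purifications from untagged strains estimate each prey's
nonspecific bead-binding level. The scorer is a transparent two-component
Poisson posterior with the same interface and [0, 1] semantics as SAINT
scores; it is SAINT-*style*, not SAINT-identical (the published tool's
internals involve additional modeling this package does not claim to
reproduce). Per prey `i` and bait replicate `r` with count `x`:

* contaminant rate `lambda0 = max(m_i * N_r, lambda_min)` where `m_i` is
  the prey's mean control count per unit depth and `N_r` the replicate's
  total count (depth scaling), with floor `lambda_min = 0.1` so preys never
  seen in controls still have a proper null;
* interaction rate `lambda1 = max(condition mean count, 2 * lambda0)` — the
  factor 2 keeps the alternative from collapsing onto the null when a prey
  sits at background;
* posterior `p_r = pi f1(x) / (pi f1(x) + (1 - pi) f0(x))` with Poisson
  components and prior `pi = 0.1`, computed on the log-odds scale.

The condition score is the mean posterior over that condition's replicates,
so one spurious replicate cannot carry a prey. The final-list cascade then
requires (1) ≥ 2 unique peptides in some run (a flag switches to the
strictly-greater reading), (2) identification (count > 0) in ≥ 2 bait runs,
and (3) score > 0.5 (strict) in at least one condition. Condition-specific
labeling requires a unanimous trend plus score > 0.6 in the trend condition
and < 0.4 in the other, both strict.

## I-DIRT classification (`pbodykit.idirt`)

Light (bait-tagged) and heavy (untagged) cultures are lysed frozen and
mixed 1:1 before purification, so a prey bound in vivo is drawn only from
the light culture while a post-lysis exchanger samples both equally.
Peptide light fraction is `A_L / (A_L + A_H)` from precursor elution areas;
the log2 ratio uses an optional pseudocount (default 0, with hard exclusion
of zero-area channels, since ratios are only meaningful for detected
pairs). Protein aggregation is the median of peptide log2 ratios (robust
to outlier peptides; an intensity-weighted mean is available — which of the
two the original XPRESS-based analysis used is not recoverable). The
in-vivo call is strictly `log2 > 0`: a 50:50 protein is *not* called
in vivo.

## Low-complexity detection (`pbodykit.seqcomplexity`)

The scanner is the trigger/extend/merge core of the SEG algorithm with its
canonical parameters: window W = 12, trigger entropy K1 = 2.2 bits,
extension entropy K2 = 2.5 bits, and a minimum merged-segment length of 35
residues. Windows at or below K1 seed candidates; candidates extend over
contiguous windows at or below K2; overlapping or adjacent candidates
merge. The final minimal-probability subsequence refinement of full SEG is
deliberately omitted; this shifts reported boundaries by at most W − 1
residues, which the tests bound against ground truth. Non-standard letters
(e.g. X) are excluded from the entropy alphabet and the denominator, so
unknown-rich windows are not spuriously low complexity. The Q/N scan
(fraction of Q+N ≥ 0.3 in an 80-residue window, boundary inclusive) is a
compositional proxy for prion-like domains; an externally supplied
prediction list is the preferred source of prion flags.

## Set statistics (`pbodykit.setstats`)

Overlap significance is the upper-tail hypergeometric probability
P(X ≥ k), summed in log space so extreme tails (1e-44-scale) do not
underflow. The universe is always an explicit parameter: enrichment
p-values depend strongly on the background, and no default is assumed.
Benjamini–Hochberg correction is the standard step-up procedure
(statsmodels). Note that BH is *not* idempotent: re-adjusting an adjusted
vector re-inflates it by the m/j factors, so only dominance (q ≥ p) and
rank monotonicity are invariants.

## Array enrichment calling (`pbodykit.array`)

Per replicate: (1) subtract the per-channel median of negative-control
probes, floor at 1.0 (so the log is defined for below-background values),
log2-transform; (2) normalize the total/IP pair by two-array cyclic loess —
fit a lowess trend (span 0.4, 2 robustness iterations) of M = IP − total
against A = (IP + total)/2 and split the fitted trend evenly between
channels, leaving A untouched; below 30 points the smoother is unstable and
the pair passes through with a warning; (3) average each transcript's
probes; (4) drop transcripts whose mean total log signal is below the 0.95
quantile of the negative-control log signal, whose probe CV in either
channel exceeds 0.5, or with any total-channel probe at the scanner ceiling
(65535); (5) fit OLS of mean IP log signal on mean total log signal and
call a transcript enriched when it lies strictly above the upper limit of
the two-sided 95% **prediction** band (nominal upper-tail rate 2.5%).

The prediction band is the operative reading of "outside the upper
confidence interval of the regression line": with ~1000 transcripts a
mean-line CI is degenerately narrow and would call nearly half the points;
`band_kind="mean_ci"` is provided to mirror the literal wording.
Consensus requires enrichment in ≥ 2 biological replicates and no
enrichment in the mock (tag-only) IP.

The variability filter takes the maximum probe CV over both channels: the
enrichment statistic depends on both, and a transcript whose IP probes are
corrupted (e.g. one floored probe) but whose total probes are quiet would
otherwise leak an extreme residual into the fit, inflating the residual SD
and making the band conservative everywhere.

## Synthetic data (`pbodykit.simulate`)

Defaults encode the emulated study design: 3 minus-glucose + 2 plus-glucose
bait IPs, 10 control runs, 16 minus- and 6 plus-condition-specific preys,
an I-DIRT mix, a probe array with 3 probes per transcript and 1559
negative-control features, 3 biological replicates plus a mock IP.

* **AP-MS**: every protein has a homogeneous baseline bead-binding rate
  (`contaminant_rate`, default 5 expected counts) present in controls and
  bait runs alike; designed interactors are multiplied by
  `enrichment_fold` (default 4) in bait runs (condition-specific preys in
  one condition only); the bait carries the largest rate and is absent
  from controls (untagged strains). Rates are rescaled so each run's
  expected total equals `depth` (5000, a realistic per-run spectral yield),
  then Poisson noise is applied (negative binomial with configurable
  dispersion optional). Unique peptides are binomial in the count (rate
  0.25) with floor 1, capped at the count. Observabilities are log-uniform
  on [0.1, 1] (APEX needs strictly positive scores).
* **I-DIRT**: class exchange fraction `e` gives expected light fraction
  `phi = 1 − 0.5 e`; per peptide a log-normal total intensity is split
  `phi : 1 − phi` with independent log-scale noise (SD 0.05) per channel.
  Defaults: 40 in-vivo proteins at e = 0.2, 20 exchangers at e = 1, 5
  peptides each.
* **Array**: transcript log2 abundances are N(8, 1.5); IP tracks total
  through a capture line (slope 1, intercept 0, so enrichment is purely the
  spike term) plus `spike_log2fc` (default +2 for 50 of 1000 transcripts)
  and probe noise (SD 0.2); raw intensities are exponentiated log signals
  plus additive scanner background (N(100, 10)); negative controls carry
  background only; the mock pair has no spikes.
* **Sequences**: background residues from an approximate yeast proteome
  composition (or uniform); 20 of 100 sequences receive a 40-residue
  poly-Q or Q/N-repeat insert at a recorded position.

What the generators deliberately do not emulate: peptide-level
identification error, run-order/batch effects, correlated contaminant
structure across control runs, probe sequence-specific affinity bias, and
saturation of the IP channel. Passing spike-in tests therefore demonstrate
that the statistics recover the designed signal under clean count/intensity
noise at realistic sizes — not that real datasets of this design are free
of the upstream artifacts these models exclude.

## Problem sizes and determinism

All simulation-backed tests and the acceptance script run at the design
sizes above (300 proteins x 15 runs, 1000 peptides, 1000 transcripts x 4
hybridization pairs, 100 sequences), which complete in seconds. Every
generator is driven by a single integer seed through
`numpy.random.default_rng` and is bit-for-bit reproducible; the analysis
stages (loess, OLS, posteriors) are deterministic.

## Known limitations

* The specificity scorer is a deliberate simplification; absolute score
  values are not comparable to SAINTexpress output, only the ranking/
  thresholding semantics.
* SEG boundaries are approximate to within one window length.
* The prediction band assumes homoscedastic residuals; the quality filter
  removes the worst heteroscedastic transcripts but calibration degrades
  if the filter thresholds are relaxed on background-dominated data.
* Headline counts from the motivating experimental design (e.g. sizes of
  published final lists) depend on the original raw spectra and array
  data and are not reproducible from synthetic inputs; the package's
  claims are the property-based recoveries its tests compute.
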