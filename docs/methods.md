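# Methods

This note records the models the package implements, the conventions it
fixes where the underlying biology leaves room, and what the synthetic
data do and do not establish.

## Consensus model and site scanning

A response element (RE) half-site is a decamer matching the degenerate
IUPAC pattern `RRRCWWGYYY`; a full site is two half-sites on the same
strand separated by a 0–13 nt spacer. Scanning is exhaustive naive window
matching on both strands — at the intended scale (promoter fragments,
reporter constructs, RE panels) nothing faster is warranted. Conventions:

* Coordinates are 0-based half-open internally; site sequences are
  reported 5'→3' on the site's strand, and RE positions are numbered 1–20
  on the spacer-removed 20-mer.
* `N` in a scanned sequence counts as a mismatch against any non-N
  pattern symbol: an unknown base is not evidence of conformance.
* Both strands are always scanned. A palindromic window matches on both
  strands and is reported twice; `dedupe` collapses such duplicates onto
  the forward strand.
* All overlapping full-site assemblies are reported (no greedy
  selection); output is ordered by start, then spacer, then strand.
* A **¾-site** is operationalized as a half-site that pairs with no other
  half-site but has one immediately adjacent (spacer-0) fully conforming
  quarter: `RRRCW` 3' of it or `WGYYY` 5' of it in its own reading frame.
  When both flanks conform, the 3' quarter is taken (an arbitrary,
  documented tie-break). This adjacency rule is an interpretation; the
  non-canonical site panels in the literature are described at figure
  level only.
* The default scan allows 0 mismatches per half-site; downstream
  signature scoring deliberately accepts *any* 20-mer, since most
  validated physiological REs depart from the consensus somewhere.

## The RY/WW signature code

On the 20-mer, the four RY slots are positions 2–3 = `GG`, 8–9 = `CC`,
12–13 = `GG`, 18–19 = `CC`; the WW motifs are positions 5–6 and 15–16
(labelled AT/TA/AA/TT, or `other` if either base is not A/T). The
response prediction for the change-of-spectrum mutant is categorical —
*reduced* iff the RY count is 0, *enhanced* otherwise — and the numeric
score is a package convention:

```
score = ry_count + 0.5 · [at least one WW motif ∈ {AA, TT}]
```

Its only contract is monotonicity consistent with the observed ordering:
strictly increasing in the RY count, with the non-AT W core as a
secondary additive bonus. The bonus is deliberately not a veto: the
GGGCA full site has AT cores in both half-sites yet is strongly bound and
enhanced, so 4/4 RY dominates. The `indeterminate` class is reserved for
future rules and is never produced by the default predictor; whether the
0.67–1.5 "similar" band should map onto it is not decidable from sequence
alone. No prediction is attempted for super-transactivating alleles
(e.g. p73 S260N): their phenotype is independent of this code and records
are only annotated as expected super-trans. WW ranks (AT > AA/TT > TA >
other) order expected wild-type activity; no torsional-flexibility
modelling is attempted.

## Transactivation classification and association statistics

Fold induction is the replicate mean of normalized reporter readings
(light units per µg soluble protein or per OD600) divided by the
normalized empty-vector background; replicate aggregation is the mean,
with dispersion carried for display only. The mutant/WT ratio is
classified with strict outer inequalities — enhanced > 1.5, reduced
< 0.67, similar otherwise (boundaries inclusive in *similar*) — so every
positive ratio lands in exactly one class.

The Fisher test is the exact two-sided point-probability convention: with
margins fixed, sum the hypergeometric point probabilities not exceeding
that of the observed table, with a 1e-7 relative guard for
floating-point ties. Association between sequence features and classes is
tested at half-site resolution (two half-sites per RE — the layout behind
the 44-vs-18 denominators of the worked example), for either of two
half-site features: a WW motif in a given label set (default {AA, TT}),
or presence of at least one satisfied RY slot. All half-sites are
counted, regardless of whether their core is a W core. The RY dose
dependence ("enhancement proportional to the RY count") is summarized as
the Spearman rank correlation of ratio vs RY count across all REs —
deliberately a rank statistic, since only the ordering is claimed.
Reported p-values are raw; no multiple-testing correction is applied, and
the CLI says so in its output metadata.

## Dinucleotide logos

Six slots (RR1 2–3, WW1 5–6, YY1 8–9, RR2 12–13, WW2 15–16, YY2 18–19)
are summarized by exact empirical dinucleotide frequencies over the RE
set, spacer-removed; the 20×4 per-position mononucleotide matrix is
computed on the same set as the conventional-logo baseline, and slot
joints marginalize exactly onto it. Rendering is frequency-proportional —
no information-content (bits) scaling and no small-sample correction —
with glyph height strictly proportional to frequency. By default all
dinucleotides at or above `min_freq` (default 0.05) are drawn, consensus-
compatible ones in full colour and others greyed; `consensus_only`
restricts to consensus-compatible dinucleotides. Whether a published
paired-frequency display should draw from all REs or only
consensus-conforming half-sites is ambiguous; both are available (filter
upstream, then render).

## Binding-curve fitting

Raw polarization is converted linearly to fraction bound between free-
and bound-DNA endpoints (clipped to [0, 1] with a flag). The titration is
fitted to the Hill equation on total protein concentration,

```
f(c) = f0 + (fmax − f0) · c^h / (EC50^h + c^h)
```

with EC50 reported as K_d under the assumed stoichiometry (one dimer per
12 bp half-site, one tetramer per 20 bp full site). No ligand-depletion
correction is applied by default even though the 50 nM DNA concentration
is not always negligible against K_d — this matches the EC50 ≡ K_d
reporting convention the fits emulate; a quadratic depletion-corrected
1:1 isotherm is available behind a flag.

Numerical choices: replicates pooled, unweighted least squares;
initialization from the interpolated half-max crossing (EC50), h = 1,
f0/fmax from the response extremes; five multi-starts with EC50 jittered
×{0.2, 0.5, 1, 2, 5}; bounds h ∈ [0.2, 5], EC50 ∈ [min positive conc/10,
100× max conc]; trust-region solver tolerances 1e-12. The
zero-concentration anchor constrains f0. A fit is **censored** when the
largest observed response covers less than 60% of the fitted span or the
fitted EC50 exceeds the top concentration; a censored fit reports
K_d > (top concentration) rather than a point estimate, and affinity
ratios involving a censored side become one-sided bounds. The 60%
threshold is a package convention; published ">top" calls do not state
their rule.

Default titration design: 18 points — a zero anchor plus 17 log-spaced
concentrations from 1 to 20 000 nM — matching the design of the
fluorescence-polarization experiments this module emulates (grid spacing
within the stated range is the package's choice; the published design
states only the endpoints and count).

## Synthetic data

The generator emulates the study conditions at three stages.

**RE panels.** Each RE is a consensus-conforming 20-mer with its RY count
drawn from `ry_mix` (default 0.25/0.20/0.20/0.20/0.15 over 0–4, a panel
weighted toward the low-RY REs that dominate physiological sets), slots
chosen uniformly, WW labels drawn per half-site from `ww_mix` (default
uniform over AT/TA/AA/TT, giving P(AA or TT) = 0.5 per half-site — close
to the observed composition of classified panels), and spacer from
`spacer_mix` (default point mass at 0, as almost all full-site REs in
such panels have no spacer). Mismatches (rate 0.1) are confined to the
four positions that are neither RY slots, WW positions nor the invariant
core C/G, so recomputed profiles always equal the recorded truth.

**Reporter activities.** WT fold induction is lognormal(log 12, 0.5) —
the scale of a responsive reporter over background. The mutant/WT log
ratio is `β0 + β_ry·ry_count + β_ww·[any WW ∈ {AA,TT}] + N(0, σ)` with
defaults β0 = log 0.5, β_ry = log 1.6, β_ww = log 1.3, σ = 0.2: reduced
at 0/4 RY, similar at 2/4 without the AA/TT bonus, enhanced from 3/4 (or
2/4 with the bonus). These effect sizes are package conventions — the
source observations give directions and thresholds, not a generative
model. Replicate readings render the drawn fold induction exactly (all
stochasticity lives in the fold-induction draw), so zero-noise configs
compose deterministically.

**Titrations.** Hill curves on the 18-point grid with i.i.d. Gaussian
noise per replicate.

What passing simulation tests show — and do not. The generators share the
analysis's positional definitions, so closure tests (truth always
re-scores) validate bookkeeping, not biology. The power result (RY
association detected in >80% of replicates at n = 50) shows the coded
effect is detectable at panel scale *under the generator's effect model*;
real panels add correlated replicate noise, RE-specific baselines,
chromatin and isoform effects that are explicitly not modelled. The
WW-feature association is intentionally weak under the default effect
sizes (β_ww = log 1.3): the generator's power acceptance therefore tests
the RY-presence feature, the association its effect model actually
encodes, while the WW feature remains the worked-example test.

A note on null calibration: the exact two-sided Fisher p-value is
conservative, with an atom at p = 1 whose mass equals the hypergeometric
mode probability (≈0.1 at panel-scale margins). Its null distribution is
therefore *valid* (P(p ≤ α) ≤ α, asserted by test) but not exactly
uniform, and a KS uniformity test at several hundred replicates will
reject for any correct exact implementation at these sample sizes.

## Known limitations

* The ¾-site adjacency rule and the ConA/ConD/ConH fixture sequences are
  reconstructions (marked as such in the packaged table), not verbatim
  published sequences.
* The score's WW bonus (0.5) is ordinal, not calibrated to effect size.
* No PWM/energy scoring: the code is categorical by design.
* Hill fits assume a shared f0/fmax per curve and pooled replicates; no
  global fitting across curves, no weighting options.
* The scanner is naive (no indexing); genome-scale input is out of scope.
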