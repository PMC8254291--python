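# Methods

## The nonadditivity model

A double-transformation cycle (DTC) is four compounds (c1, c2, c3, c4)
forming four matched molecular pairs, with transformation A applied
c1→c2 and c4→c3 and transformation B applied c1→c4 and c2→c3. The
statistic

ΔΔpAct = (pAct₂ − pAct₁) − (pAct₃ − pAct₄)

is zero under a Free–Wilson (additive) SAR model, in which every
substituent contributes a fixed activity increment independent of the rest
of the molecule. The sign of ΔΔpAct depends on the orientation of the
cycle; the magnitude does not. Cycles are stored in a canonical
orientation: the lexicographically smaller transformation key plays role
A, both transformations depart from c1 in their canonical (lexicographic)
direction, and ties (A = B) are broken by compound id. This makes signed
output reproducible while all classification uses |ΔΔpAct|.

**Noise propagation.** Under i.i.d. per-measurement noise of standard
deviation σ_exp, the four measurement errors add in quadrature:
Var(ΔΔpAct) = 4σ². The null is therefore N(0, (2σ_exp)²), and the
significance threshold is set at 2σ_exp — 0.6 log units for homogeneous
(replicate-rich, single-protocol) data at σ_exp = 0.3, 1.0 log units for
heterogeneous public data at σ_exp = 0.5. "Strong" nonadditivity is a
fixed 2.0 log units. These thresholds are *thresholds*, not hypothesis
tests: a pure-noise cycle exceeds 2σ_exp with probability
2(1 − Φ(1)) ≈ 31.7% regardless of σ_exp, and no multiple-testing
correction is applied, matching the framework's intent of flagging
candidates for inspection rather than controlling an error rate.

**Per-compound profiles.** Each cycle contributes one signed shift to each
of its four members. The shift is defined as observed-minus-additive
expectation with the focal compound re-oriented to the doubly-transformed
corner c3: shift = (p_focal + p_opposite) − (p_adjacent1 + p_adjacent2).
Compounds on one diagonal of a cycle receive +|ΔΔpAct|·sign, the other
diagonal the negative, so a compound whose activity is boosted by δ beyond
additivity shows mean shift +δ across its cycles. The 95% null band is
±1.96·2σ_exp/√n_cycles. Two per-compound significance rules are
available: the default flags a compound when *any* of its cycles is
significant (this is what the per-assay "compounds with significant NA"
count uses); the alternative (`mean_outside_ci`) flags compounds whose
mean shift leaves the null band. The per-compound table reports both
candidate scalar summaries, max |ΔΔpAct| and mean |ΔΔpAct|, since either
is a defensible per-compound "NA value".

**Assay summaries** report cycle and compound counts, significant/strong
tallies, moments of the signed ΔΔpAct sample (kurtosis is *excess*
kurtosis, normal = 0, and is labelled as such), and a Kolmogorov–Smirnov
p-value against N(0, s) with the sample standard deviation s plugged in —
an acknowledged approximation that biases the p-value upward slightly.
Pairwise distribution comparisons use Kruskal–Wallis and two-sided
Mann–Whitney U on the signed samples; all-tied inputs return NaN.

## Curation

Eight ordered steps (order is part of the contract and covered by tests):
structure standardization (RDKit cleanup, charge neutralization, canonical
tautomer; unparseable records dropped), optional endpoint allowlist,
removal of missing/qualified("<", ">")/nonpositive values, removal of
unrecognised units (recognised: M, mM, uM, nM, pM, fM, plus a "logged"
marker), conversion to pActivity with rejection outside the *open*
interval (2.0, 11.0) log units (10 mM and 10 pM themselves are dropped —
the conservative reading of "lower/higher than") and rejection of
pre-logged values carrying a unit, replicate handling per compound id
(drop the compound when max−min > 2.5 log units, else keep the median),
duplicate-structure resolution keeping the highest pActivity, a 70
heavy-atom cap (heavy = atomic number > 1), and a 25-compound minimum
assay size. Replicates are resolved per id *before* structures are
deduplicated, following the printed step order; the original tooling may
have interleaved these differently, which matters only for pathological
id/structure combinations. Counts in and out of every step are reported
for audit. The proprietary standardizer used for the original in-house
data is unavailable; the open standardizer will deviate on a small
fraction of real ChEMBL structures, so per-assay counts on real data are
expected to differ slightly.

## Matched pairs

Fragmentation follows the Hussain–Rea single-cut scheme: every single,
acyclic bond between heavy atoms is cut, yielding a context and a variable
fragment, each carrying one attachment point. Canonical SMILES of the
fragments serve as keys, so identical contexts from different molecules
collide. Design choices, each a documented divergence risk when comparing
against other MMP dialects:

* single cuts only (DTCs need single-attachment transformations);
* hydrogen replacements are not generated — only existing heavy-heavy
  bonds are cut;
* the "at most ⅓ of the molecule" transformation-size rule is applied to
  the variable fragment of **both** molecules of a pair, as a strict real
  comparison (variable heavy atoms ≤ H/3);
* transformation direction is canonicalized lexicographically on the
  variable keys.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
A `FreeWilsonSpec` fixes a scaffold with numbered attachment points,
per-site substituent alphabets with additive contributions (log units) and
a baseline; `NAInjection` adds an interaction δ when two named
substituents co-occur at two named sites. True pActivities are exact, and
`ground_truth_cycles` enumerates every designed DTC with its closed-form
ΔΔpAct (interactions between a varied and a fixed site cancel across the
cycle's diagonals; only injections on the varied site pair survive).
Measurement emulation draws Gaussian noise per replicate, re-expresses
values in sampled raw units (µM/nM; the unit round trip is lossless to
well below 1e-9 log units), and can inject qualified records and
duplicate registrations to exercise curation.

The default substituent alphabet (methyl, ethyl, chloro, fluoro, methoxy,
amino, bromo, cyano) deliberately excludes hydrogen — an H corner forms no
matched pair under bond-cut-only fragmentation — and tautomer-labile
groups such as hydroxy next to ring nitrogens, which the standardizer
could rewrite into a different scaffold form.

**The reference study assay** emulates the sparse cycle structure of
public SAR collections: 110 independent 2×2 Free–Wilson series (440
compounds, one designed cycle per series), each on a structurally distinct
aza-biphenyl core. Cores differ in ring nitrogen patterns; the central
biaryl bond is the core's only acyclic bond and either half always
exceeds ⅓ of the molecule, so the pair index can only cut at the R-group
attachments and contexts from different series can never collide — the
assembled cycle set provably equals the designed one. 10% of series carry
one interaction of |δ| = 2.0 log units (alternating sign) on the corner
combining the last substituents of both sites; measurement noise is
σ = 0.3. A dense combinatorial library would be the wrong model here:
with ~150 cycles per compound and a 31.7% per-cycle null exceedance,
essentially every compound would be flagged significant under the
"any cycle" rule, which is not how sparse public assays behave.

## QSAR study

Compounds are labelled from their profiles: *nonadditive* when flagged
significant, *additive* when in cycles but never flagged, *no_dtc*
otherwise. Featurization is Morgan radius-3 **count** fingerprints folded
to 2048 (ECFP6-style; length is a knob). Splits:

* `dtc_split` — additive compounds stratified 80/20 by pActivity decile
  into train/additive-test; nonadditive compounds are a hold-out never
  trained on;
* `all_split` — as above with no_dtc compounds assumed additive;
* `ab_split` — greedy, seeded assignment over cycles: corners c1, c2, c4
  to training, the doubly-transformed c3 to test; once a compound holds a
  role it keeps it and conflicting cycles are skipped. The published
  description of this strategy lives in supplementary material not
  reproduced here, so this implementation is a seeded, documented
  interpretation, isolated behind one function, not an exact reproduction.

Models: random forest, RBF-SVM (standardized inputs) and PLS, tuned by
randomized search maximizing 5-fold CV R², then refit on the full
training set. The full protocol's budget is 500 trials; the bundled study
drivers use a compact RF space (100–300 trees) with 4 trials, which is
ample for these library sizes and keeps the whole analysis suite at
desk-scale runtimes. Evaluation reports R² and RMSE on continuous
predictions plus a dichotomized view (active iff pActivity > 5.0;
exactly 5.0 is class 0) scored by MCC with the full confusion matrix;
single-class test sets yield a flagged NaN MCC.

**Mixin.** Fractions 0.6% (Q1), 1.3% (median) and 2.6% (Q3) of
training-set size are drawn from the nonadditive pool by a seeded
stratified ordering whose prefixes are nested (Q1 ⊂ median ⊂ Q3), and the
NA hold-out is the complement of the Q3 draw — identical across fractions
for a seed, so all models are scored on the same compounds. Fractions are
interpreted relative to training-set size. Flatness of the scan is
summarized as the largest |mean paired MCC difference vs the 0% model|
across fractions, compared with the across-seed standard deviation of
those differences (a guard of 1e-12 covers the all-identical case).

## What the synthetic results do and do not show

The generator reproduces the *mechanics* of real SAR data — unit noise,
replicates, qualified records, duplicate registrations, sparse cycles,
interaction terms — but not its chemistry: real nonadditivity has
structural causes and correlates with scaffold families, assay artifacts
are not Gaussian, and real fingerprint space is far less blocked than a
library of independent series. Passing tests therefore validate the
statistics, the bookkeeping and the split logic, and the *direction* of
the ML findings (models degrade on nonadditive hold-outs; tiny mixins do
not move additive-test MCC), not any particular performance number on
real assays. Counts on real ChEMBL data will additionally drift with the
standardizer and MMP dialect, as noted above.

## Numerical choices and degenerate inputs

* ΔΔpAct is exact floating-point arithmetic; additive fixtures are
  checked to 1e-9.
* Assay summaries with < 2 cycles report NaN moments; empty cycle lists
  give zero counts and NaN statistics rather than errors.
* Stratification bins are pActivity deciles (`qcut`, degenerate bins
  merged; singleton strata folded into a catch-all bin).
* Zero-variance training responses abort model training with a clear
  message.
* Monte-Carlo tolerances in tests follow closed-form standard errors
  (e.g. std of 100k-cycle null known to ±0.0022, checked at ±0.01).
* All randomness flows through explicit seeds (`numpy.random.Generator`);
  reruns are byte-identical.
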