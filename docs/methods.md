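# Methods

This note documents the statistical procedures pairscan implements, the
assumptions behind them, the synthetic data model used to validate them, and
the design choices made where the underlying analyses left details open.

## Peptidome statistics

**Unit of analysis.** A peptide quantification table: peptide sequences with
charge states and per-sample precursor intensities (arbitrary units), plus a
sample design with `treatment` and `cell` factors. Missing intensity cells
mean *not detected* and are kept as missing, never coerced to zero, at the
table level. Before any statistic, precursor quantities are summed across
charge states per peptide sequence; a cell missing in every charge state
remains missing (the sum of nothing is not zero).

**Cleavage classification.** The proteasome's catalytic β-subunits determine
the residue left at a peptide's C-terminus. The immunoproteasome (β1i/β2i/β5i)
favours hydrophobic and basic C-termini; the constitutive proteasome also
produces acidic and small-polar ones. A peptide is classified solely by its
final residue: immunoproteasome-type for {F, Y, L, I, V, W, M, R, K},
constitutive-type for {D, E, S, T, A, G, Q, N}. The remaining residues
{C, H, P} belong to neither diagnostic set and are left *unassigned* —
forcing them into a class would fabricate signal — and are excluded from both
the numerator and the denominator of the ratio.

**IP fraction.** Per sample, with raw intensity w_i and class c_i,

    IP fraction = Σ_{c_i = IP} w_i / Σ_{c_i ∈ {IP, PP}} w_i .

The default is this bounded fraction IP/(IP+PP); an odds mode IP/PP is
selectable because the quantity is often labelled a ratio. A zero denominator
yields NaN (undefined), never 0, which would wrongly read as "no
immunoproteasome activity".

**Length fraction.** The intensity share of peptides of 8–12 residues — the
window favourable for MHC class I loading — over *all* detected peptides
regardless of class. Both window endpoints are inclusive.

**Aggregation score.** An abundance-weighted mean of per-peptide
aggregation-propensity scores, restricted to peptides of 6–15 residues
(inclusive); out-of-window peptides contribute to neither sum. Weights are
raw, not log, intensities. The scorer is a pluggable contract
(sequence → score, deterministic); the default is a composition heuristic —
fraction of β/amyloid-prone residues (V, I, L, F, Y, W, M, C) minus fraction
of aggregation-breaking residues (P, G, D, E, K, R), rescaled to [0, 1] — a
documented stand-in, not a trained aggregation model.

**Group comparison.** Any per-sample statistic is compared by two-way ANOVA
with treatment and cell as factors plus their interaction (statsmodels OLS,
type-II sums of squares; identical to the textbook decomposition for
balanced designs), followed by Tukey's HSD over the treatment×cell cell
means. A constant response is flagged degenerate rather than producing a 0/0
F statistic; a design cell with fewer than two replicates is an error naming
the cell.

## Differential matrix analysis

The standard label-free pipeline, in this order:

1. **Transform**: x ↦ log2(x + 1) on raw non-negative intensities; missing
   stays missing. Fixed points 0→0, 1→1, 3→2.
2. **Missingness filter**: a feature is excluded iff its missing fraction
   *strictly* exceeds 25% within at least one condition (1 of 4 replicates
   missing — exactly 25% — is retained). Filtered features are also excluded
   from the multiple-testing family.
3. **KNN imputation** (k = 5 by default): the distance between two features
   is the root-mean-square difference over their co-observed samples
   (normalising by the co-observed count keeps distances comparable across
   missingness patterns); a missing cell takes the unweighted mean of that
   sample's values in the k nearest features observed there. Observed cells
   are never modified. k, the metric and the feature-wise orientation are
   conventions recorded in output metadata, since they are choices, not
   forced.
4. **Moderated fit**: per-feature two-group least squares; residual variances
   s²_g (d_g df) are shrunk toward a prior s₀² (d₀ df):

       s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
       t_g = logFC_g / (s̃_g √(1/n_a + 1/n_b))  on  d₀ + d_g df.

   (d₀, s₀²) are estimated by moment-matching the log residual variances
   against the digamma/trigamma identities of the scaled-F model, with a
   Newton inversion of the trigamma function; if the observed spread of
   log-variances is no larger than expected from finite replication alone,
   d₀ = ∞ and every feature is pooled to s₀². An explicit `prior_df` override
   makes the two limits reachable configurations: d₀ = 0 reproduces the
   ordinary two-sample t exactly, d₀ → ∞ gives pooled-variance, normal-
   reference behaviour.
5. **BH step-up**: q_(i) = min_{j≥i} min(1, m p_(j)/j) over the features
   actually tested; FDR < 0.05 calls significance.

**Overlap accounting** is exact set arithmetic over deduplicated identifier
lists (only-A / only-B / shared).

## Structure-motif signature

Inputs are per-protein structure profiles: sequence, 3-state secondary
structure (H/E/C; an 8-state DSSP-style string is collapsed by the standard
{G,H,I}→H, {B,E}→E, rest→C rule), and per-residue relative solvent
accessibility in [0, 1]. Structure prediction, DSSP and SASA computation are
upstream of this package.

1. **Segmentation** into maximal same-state runs; spans are 0-based
   half-open and tile the protein exactly.
2. **Composite enumeration**: every window of 3 consecutive runs whose
   combined span is 25–35 residues (inclusive) is a candidate motif.
3. **Exposure filter**: a residue is exposed iff rSASA *strictly* exceeds
   0.2; a motif is retained iff its exposed fraction *strictly* exceeds 40%.
   Both thresholds are knife-edge by construction and tested as such
   (perturbing a 0.2-valued residue by +ε flips it).
4. **Composition features**: the 20 single-residue fractions; grouped
   fractions — acidic (D/E), positive (K/R/H), charged (D/E/K/R), charged
   incl. H, polar (S/T/N/Q), hydrophobic (A/V/I/L/F/Y/W/M), aromatic (F/Y/W),
   amide (N/Q) — each exactly the sum of its members; and two net-charge
   summaries, frac(K+R) − frac(D+E) and a variant adding +0.1·frac(H)
   (two minimal explicit readings of an otherwise underdetermined feature).
   Features can be computed over the full motif or the exposed residues
   only; zero exposed residues makes the exposed-scope features NaN.
5. **Scoring**: motifs are embedded (pluggable embedder; the synthetic
   composition-map embedder in tests; cropping context is the motif span
   with a configurable flank, default 0) and scored with the full-protein
   classifier's probability output. Both share one model object.
6. **Quartile contrast**: the top and bottom quartiles of the *global* score
   distribution (linear-interpolation percentiles) form the high/low groups;
   motifs tying a quartile boundary join neither group, so one score value
   can never straddle both. Per feature: group medians and a two-sided
   Mann–Whitney U test — exact enumeration of all group assignments (ties
   handled exactly) when both groups have ≤ 8 members, otherwise the normal
   approximation with tie and continuity corrections — then BH across the
   feature panel.

The U statistic divided by n₁n₀ is identically the ROC AUC of the scores
against the grouping; this duality is asserted in tests.

## Classification harness

Binary protein classification from fixed-length embedding vectors over
repeated random protein-level 70/30 train/test splits (20 by default,
unstratified — a stratified option exists; a draw leaving either fold without
both classes is resampled with bounded retries, since a single-class test
fold would make AUC undefined). The model is unit-variance standardisation,
an L1-penalised linear selection stage (features with nonzero coefficients
are kept; if none survive, all features are kept with a logged warning), and
an L2-penalised logistic head — all fit on the training fold only, so test
items never influence scaling or selection. Regularisation strengths, the
solver and standardisation are configuration, recorded in output; there is
no nested CV. Performance is ROC AUC (ties count ½), summarised by the
median and the 16th/84th percentiles with the linear-interpolation
percentile definition — pinned because the summary is part of the contract.
A single-feature abundance baseline runs through the identical harness for
side-by-side comparison.

## Synthetic data model

The generators plant every quantity the pipeline estimates, so recovery is
checkable end-to-end without any external data.

- **Peptidome**: peptide lengths 6–25; residues i.i.d. uniform except the
  planted C-terminal class (Bernoulli at the planted IP fraction; intensities
  independent of class, so the intensity-weighted estimator converges to the
  planted value) and the planted 8–12 aa window share, handled identically.
  Per-treatment fractions (strictly inside (0,1)) are planted by
  condition-specific intensity multipliers. Raw intensities are log-normal
  (log-mean 14, log-sd 1.2, natural-log scale) — label-free precursor
  intensities are classically right-skewed. ~20% of peptides are emitted at
  two charge states with the intensity split, to exercise charge collapsing.
  No homology structure is simulated.
- **Tau-like parent**: a random 441-residue sequence with the
  PHF6-containing marker peptide HVPGGGSVQIVYKPVDLSK embedded mid-sequence —
  a synthetic stand-in, not a real tau isoform. Peptides are cut from it by
  choosing endpoints among immunoproteasome-type or constitutive-type
  positions with the planted probability, so the C-terminal class is planted
  through the cut site, as cleavage specificity would do.
- **Intensity matrix**: built on the log2 scale around a log-normal baseline
  and exponentiated as 2^L − 1, so log2(x+1) recovers the planted shift of
  ±de_log2fc in n_de features exactly. Per-feature noise variances follow a
  scaled inverse-chi-squared prior (scale 0.5², df 6) — precisely the model
  the moderated fit assumes — so the d₀ estimator has a true value (6) to
  recover, and it does (estimate within (4, 9) at 3000 features).
  Missingness is completely at random by default; an intensity-dependent
  left-censoring mode exists because real label-free missingness is often
  abundance-driven, and the choice between them cannot be settled from the
  analyses this package reproduces.
- **Structures**: secondary structure from a 3-state Markov chain (strong
  self-transitions giving DSSP-like run lengths; started in H, which makes
  the degenerate identity-transition case exactly all-H); rSASA i.i.d.
  Beta(1.6, 3.0) (right-skewed, ~30% of residues above 0.2); positive-class
  sequences get their total D/E emission probability raised by
  `acidic_enrichment_delta` (default 0.08), other residues rescaled.
- **Embeddings**: a fixed random linear map (seeded independently of items)
  of the item's 20-dim residue composition, scaled by `embedding_signal`,
  plus isotropic Gaussian noise with a per-item noise stream keyed by item
  identity — the same item always embeds identically, regardless of batch
  order. Signal 0 is pure noise (chance AUC); the default 10 gives a
  moderate, realistic regime (median AUC ≈ 0.8 at 200 proteins). Because the
  within-class composition sampling noise passes through the same map as the
  signal, AUC does not approach 1 by raising the signal alone; the
  strong-signal validation condition is delta = 0.15, proteins of 300–600
  residues and signal 25, which separates essentially completely.
- **Identifier lists** with an exactly planted overlap.
- **Seeding**: one master seed expands into per-generator child seeds keyed
  by generator name (CRC32-based), so adding a generator never perturbs the
  others; all generators are pure functions of (config, seed).

**What the generator does not emulate:** MS acquisition physics, retention
time, spectral interference, peptide homology and shared-peptide protein
inference, realistic protein families, or structure-aware embeddings.
Passing tests therefore demonstrate that the estimators recover what was
planted under these idealised conditions — correctness of the statistical
machinery — not that the pipeline's conclusions transfer to any particular
real dataset.

## Numerical choices and degenerate inputs

- Strict inequalities exactly as stated throughout (missingness > 25%,
  rSASA > 0.2, exposed fraction > 40%); inclusive length windows 8–12 and
  6–15.
- Undefined statistics (zero denominators, zero exposed residues, constant
  responses) return NaN or a degenerate flag, never a silent 0.
- Trigamma inversion by Newton iteration with asymptotic guards at both
  extremes; d₀ = ∞ handled as the pooled-variance limit with a normal
  reference distribution.
- KNN neighbour ties (zero measure for continuous data) break by feature
  order via stable sort.
- Exact MWU enumerates all C(n₁+n₂, n₁) assignments with a 1e-9 tolerance
  on the U comparison; the two-sided p is twice the smaller tail, capped at 1.
- BH is implemented once (`differential.bh_adjust`) and reused by the motif
  contrast, so the two stages cannot drift apart.

## Problem sizes

The shipped demo (`configs/demo.yaml`) uses 1500 background + 300
tau-derived peptides over 16 samples, an 800×8 matrix with 80 planted
features, 60 proteins and 20 splits — sizes chosen so the full pipeline,
the test suite and the acceptance script each complete in well under a
minute on a single core while every Monte-Carlo check retains comfortable
power. Validation checks that need more resolution scale up locally (5000
peptides for fraction recovery, 1000 features for DE recovery, 500 proteins
for the null-AUC check, 3000 features for prior-df recovery).

## Known limitations

- The default aggregation scorer is a composition heuristic, suitable only
  for exercising the weighting machinery; substantive aggregation analysis
  requires plugging in a trained model.
- Real ESM-style embeddings and predicted structures are pluggable inputs;
  nothing here computes them, and reported AUCs on synthetic embeddings are
  properties of the generator, not of any real proteome.
- The moderated fit covers two-group contrasts; multi-factor designs go
  through the peptidome ANOVA path instead of arbitrary contrast matrices.
- How peptides with C/H/P C-termini were treated in the original analyses is
  not documented; the explicit "unassigned" rule here is a conservative
  choice, not a verified reproduction.
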