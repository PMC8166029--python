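# Methods

## Scope and design

`zjscreen` implements the computational spine of a formula-to-compound
discovery workflow: literature mining by word embeddings, zebrafish
high-content screen quantification and hit calling, LC-MS identification by
reference-standard matching, and comparative-Ct expression analysis. Wet-lab
steps (disease induction, fraction chemistry, imaging hardware) are outside
the package; their outputs are emulated by seeded generators with known
ground truth, so every claim the tests make is a claim about algorithmic
behaviour under a stated data model, not about real biology.

## Synthetic corpus

The corpus generator produces pre-tokenized sentences (token identity
carries all semantics; orthography and segmentation are exercised separately
by the dictionary segmenter). Each sentence names exactly one formula.
A planted pair (f, s) makes symptom s co-occur in f's sentences with
probability `p_assoc` (default 0.9); every other formula–symptom
combination co-occurs at the background rate `p_bg` (default 0.02).
Defaults: 10 formulae, 10 symptoms, 30 filler tokens, 2000 sentences of
12 tokens, one planted pair.

Background slots mix a shared filler vocabulary with a formula-specific
topic (each slot draws from the formula's own filler subset with
probability `topic_weight = 0.5`). This emulates the topical structure of
real literature — texts about a prescription share vocabulary about its
indication domain — and it is what gives input-vector cosine similarity
(the convention used when ranking word2vec neighbours) second-order signal.
A corpus whose background is uniform noise has *only* first-order
co-occurrence structure, which input vectors alone do not encode; with
`topic_weight = 0`, association mining should use the center·context score
instead. What passing tests show: the planted association is recoverable
under this topical data model. What they do not show: performance on real
Chinese-language biomedical text, whose vocabulary statistics, synonymy and
segmentation errors are far richer.

## Skip-gram embeddings

Training maximises the skip-gram negative-sampling objective
log σ(u_ctx·v_cen) + Σᵢ log σ(−u_negᵢ·v_cen) for each (center, context)
pair within a per-position window drawn uniformly from 1..`window`,
negatives sampled from the unigram distribution raised to 3/4. Updates are
plain SGD applied per pair in corpus order, with the learning rate decaying
linearly from 0.025 to 1e-4 over the run and frequent-word subsampling at
t = 1e-3. Embedding size 100 and seed 0 are the defaults; window 5,
5 epochs, 5 negatives, min_count 1 follow common word2vec practice. All are
config-exposed.

Numerical choices: input vectors initialise uniform in ±0.5/d, output
vectors at zero (so first-epoch gradients are driven by co-occurrence, not
by random vector geometry); the sigmoid argument is clamped at ±30 and
per-pair losses floored at 1e-12 before the log; a non-finite epoch loss
aborts with diagnostics. The inner loop is numba-compiled; a pure-numpy
per-pair loss/gradient (`sgns_pair_loss_grad`) is the analytic reference
and is verified against central finite differences.

`workers` is accepted and recorded for provenance but training always runs
sequentially: asynchronous multi-worker (hogwild) updates would make runs
irreproducible, and at the corpus sizes this package targets they buy
nothing. Determinism is a contract: fixed seed ⇒ bit-identical vectors.

## Association ranking and validation

Associations are cosine similarities between input vectors; within a query,
candidates sort by descending score with lexicographic tie-break, so output
order is stable. Multi-query scores aggregate by the arithmetic mean
(`max` selectable). Bidirectional validation takes each query symptom's
top-k formulae and looks up the symptom's rank in each formula's own
symptom ranking; consistency is the fraction of pairs with reverse rank
≤ k. It is reported for the query symptoms: asking it of symptoms with no
planted association measures nothing (their "top" formulae are noise), and
on the default corpus doing so yields ~0.4 by construction. 2-D maps use
t-SNE (scikit-learn) on the input vectors with a fixed random state.

## Image model and quantification

Synthetic frames are uint16, flat background (5000) plus Gaussian-profile
spots (peak 20000, profile σ = radius/3 so ~99% of a spot lies within its
nominal radius, default 5 px), optional additive Gaussian noise, clipped
and rounded. Spot centers stay strictly on their side of the ROI polygon
with a clearance of one spot radius, and pairwise separations exceed twice
the radius — the regime in which counting is well-posed. The generator does
not attempt realistic anatomy, autofluorescence gradients, or z-stack
artifacts; accuracy numbers quantify the detector under this model only.

Quantification: the frame is Gaussian-smoothed (σ = 1 px; configurable,
0 disables), a threshold is estimated from in-ROI pixels (Otsu default, or
fixed), 8-connected components below 4 px are discarded, and a component
counts iff its centroid lies inside the polygon. Pre-smoothing is essential
under noise: Otsu on raw noisy pixels can split the background mode (the
spot fraction of the histogram is small) and explode the component count;
smoothing tightens the background so the bimodality Otsu assumes actually
holds. That failure mode can still occur on very sparse frames — it
accounts for the occasional outlier in the noisy-accuracy check — and a
fixed threshold is the escape hatch. Boundary points count as inside
(ray-casting with an explicit on-edge test), so spots on a hand-drawn
outline are kept; mean ROS intensity is the arithmetic mean over pixels
whose centers fall inside the polygon. Images are assumed single-plane;
project stacks upstream.

## Plate model and hit calling

Neutrophil counts are Poisson — the simplest strictly-positive count model;
ROS intensities are log-normal (σ_log = 0.2). Defaults λ_control = 5 and
λ_model = 20 keep the recovery-rate denominator well away from zero; ROS
log-means 6.9/7.6 give a model/control intensity ratio near 2. A candidate's
true effect e ∈ [0, 1] interpolates linearly between model and control
parameters (for ROS, in log-mean space), making e commensurate with the
recovery-rate scale: e = 1 restores control, e = 0 is inert. With 10
embryos per arm the design separates e = 0.9 from e = 0.2 essentially
deterministically, which is what the parameter-recovery checks exercise.

Hit calling uses group means (consistent with the "average intensity"
convention of the ROS criterion), strict inequalities at both thresholds
(R > 0.6, ρ < 0.7; equality is not a hit), and no clipping of R — negative
or >1 values flag harmful or super-effective arms. No multiple-testing
correction is applied by default. The group-mean choice, thresholds, and
minimum group size (5, warning below) are config-exposed.

## Peak matching

References are 13 compounds (flavonoid/isoflavone glycosides, a saponin,
coumarins, quaternary alkaloids) with m/z computed from molecular formulas
at run time (monoisotopic; [M+H]⁺/[M−H]⁻, intact cations for the
quaternary alkaloids) and synthetic retention times spread over a
15-minute gradient — placeholders, not measurements. The observed-peak
generator jitters each reference by a magnitude drawn uniform in
[jitter/2, jitter] with random sign (the nominal jitter level is then
representative of actual errors, not an upper tail, and a tolerance below
jitter/2 provably matches nothing); decoys land ≥ 3× the stated matching
tolerance from every reference. Matching is greedy one-to-one within ion
mode: candidate pairs inside both tolerances (defaults 10 ppm, 0.2 min)
are taken in order of |ppm error|, ties by |rt error| then reference name.
Greedy was chosen over global optimal assignment for transparency; the two
coincide when tolerances are small against reference spacing. Fragment
(MS2) evidence is out of scope — "identification" here means precursor
m/z + RT agreement with a standard.

## Expression analysis

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the control-group
mean ΔCt of the same gene; fold change is 2^−ΔΔCt. Perfect amplification
efficiency is assumed, as in the standard comparative-Ct method.

## Pipeline and reproducibility

A validated YAML config (unknown keys rejected) drives mine → screen →
images → msmatch. Stage seeds derive from the global seed by fixed offsets;
each stage writes to its own subdirectory; a failure quarantines that
stage's partial output and aborts with the stage named. The manifest
records the config hash and SHA-256 of every output; re-running a config
reproduces the checksums bit-for-bit (the TIFF writer emits no
timestamps). The bundled demo uses the default study conditions and runs
in seconds; the acceptance script scales its simulations (200 screens,
10 corpus seeds, 2×100 frames, 1000 null draws) to finish in well under a
minute on one CPU while keeping Monte-Carlo error small against the margins
it reports.

## Known limitations

- The corpus model has no polysemy, morphology or document length
  variation; segmentation is exercised on synthetic dictionaries only.
- Otsu-based counting degrades when spots are very sparse or clumped;
  separations ≤ 2·radius are outside the generator's contract and will
  merge.
- The plate model ignores plate-position effects, dropout and
  overdispersion; real screens would motivate a negative-binomial option.
- Peak matching ignores isotope patterns and fragment spectra; ambiguous
  isobars separated by less than the ppm tolerance cannot be told apart
  except by retention time.
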