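# Methods

`gazespeech` re-implements, as a tested pipeline, a multi-task multimodal
classification analysis for dementia screening: speech/language and
eye-movement data from four short tasks — pupil calibration (gaze only),
picture description (gaze + speech), paragraph reading (gaze + speech) and
memory description (speech only) — are reduced to fixed feature schemas,
classified per task and modality, and fused by averaging predicted
probabilities. Because the clinical recordings behind the original
analysis are private, the pipeline ships with a synthetic cohort generator
that reproduces the data *structure* and the *directions* of the reported
patient/control differences; everything downstream is exercised on that
synthetic cohort.

## Synthetic cohort generator

Each participant is a draw of latent generative parameters around
group-level means. For every latent, the patient mean is
`control + delta * effect_scale`, so `effect_scale = 0` makes the groups
statistically identical (the null-effect tests rely on this), and
`effect_scale = 1` gives the default study conditions. Between-participant
variability is drawn identically for both groups, so classes overlap and
classification is a statistical problem, not a lookup.

Emulated signal families and their directions (patients relative to
controls):

| family | direction | where it shows up |
|---|---|---|
| square-wave-jerk-like excursion rate, amplitude spread | + | pupil-calibration saccade count/speed SD, shorter mean fixations |
| attention to window/curtain picture regions, dwell length | − | picture AoI fixation and transition features |
| re-fixations, regressive saccades, per-word fixation time | + | reading gaze features, overall reading duration |
| information-unit mention probability | − | picture information-unit counts |
| unfilled pause rate/length, filler rate | + | pause/fluency features (pauses always ≥ 250 ms) |
| sentence length, subordination | − | syntactic complexity features |
| per-stream acoustic variance (MFCC 8, 12, 2 down; MFCC 3 up), means (MFCC 4/5/3, energy up), shape (MFCC 6, energy acceleration) | mixed | acoustic moment features |

Effect *magnitudes* are free parameters of the generator — the source
analysis reports only directions — and were fixed once so that
single-task model AUCs on a full-size cohort (79 + 83) land in the
0.7–0.8 region, the performance regime the method is meant to operate in.
They are design choices of this package, not estimates of the clinical
effect sizes, and the pipeline's tests assert reproduction *in kind*
(direction, ordering, fusion synergy), never the clinical AUC values.

Other generator conventions: screen coordinates in pixels (1920×1080,
origin top-left, y down); timestamps in ms; pupil diameters in mm; gaze
sampled at 120 Hz; one 10-ms frame per row in the 43-stream acoustic
matrices (12 MFCCs + energy + a 13th cepstral stream, each with velocity
and acceleration, plus zero-crossing rate — a reconstruction chosen to
make 43 × 4 moments = 172 features and to include every stream named in
the source's importance tables). Transcripts carry POS tags, syllable
counts and parse-rule count annotations drawn from fixed inventories
shipped as package data, so linguistic features are computable offline and
deterministically; the bundled psycholinguistic norms are a small
synthetic MRC-style table, replaceable by user-supplied norms.

A fraction of participants (default 36/162) is assigned degraded gaze by a
seeded draw stratified by group; their streams fail the validity screen
and they enter language models only. Identical spec + seed reproduces the
cohort byte-for-byte (every stream has its own counter-based seed
sequence).

What the generator does *not* emulate: real saccade dynamics (main
sequence), microsaccades, head movement, semantic content of speech, age
or cognitive-score confounding, audio waveforms. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it recovers
configured group structure — not that the clinical effect sizes or the
published AUCs are reproduced.

## Gaze event processing

Fixations are detected with the standard dispersion-threshold algorithm
(I-DT): maximal windows of valid samples whose summed x+y range stays
within 40 px and which span at least 60 ms (the 60-ms minimum is the one
constant the protocol fixes; the dispersion value and the algorithm choice
are this package's, since the original events came from vendor software).
Gaps over 200 ms between valid samples (blinks, tracking loss) break
windows. Saccades connect consecutive fixations; speed is
distance/duration and is undefined (missing) for zero-duration gaps; the
turn angle of the first saccade is 0 by convention. Pupil series combine
the two eyes (mean when both valid, else the valid eye) and are
standardized by subtracting the participant's mean pupil diameter during
the pupil-calibration task; with no valid calibration sample all pupil
features are missing. Participants are rejected when fewer than 75% of
their gaze samples are valid (threshold exposed in config). AoI assignment
is point-in-polygon with boundaries counting as inside and first-listed
AoI winning overlaps.

## Feature schemas

Eye (all gaze tasks): 6 fixation + 22 saccade + 6 pupil summary features.
The 22-saccade inventory is not enumerated in the source; the inventory
here (count, rate; sum/mean/SD/max of distance, duration, absolute angle
and relative angle; mean/SD/max/min of speed) satisfies the published
count and contains every saccade feature the source names, but cannot be
claimed identical to the original toolkit's. Picture and reading add
per-AoI templates (9 fixation + 6 pupil per AoI; 2 transition features
per ordered AoI pair — the published per-group counts are read as
templates because the importance tables name per-AoI instances), and
reading adds 17 regression/pass/wrap-up features. A "pass" over word *w*
ends when a fixation lands on a word with a higher reading-order index;
re-reading fixations are those on already-passed words; wrap-up gaze is
fixation time on sentence-final words.

Language: picture = 13 information units + 97 text + 172 acoustic = 282;
memory = 269 (no information units); reading = 12 fluency + 172 acoustic
= 184. Vocabulary richness uses the natural-log convention for Honoré's
statistic `R = 100·ln N / (1 − V₁/V)` (undefined when every type is a
hapax) and Brunet's index `W = N^(V^−0.165)`. Acoustic moments are
population variance and Fisher (excess) kurtosis; zero-variance streams
have skewness/kurtosis 0 by convention; the skewness/kurtosis pair stands
in for the source's loosely defined "distribution of" feature family.
Repetitiveness uses cosine similarity over per-utterance word-count
vectors with a 0.9 near-duplicate threshold. The "exterior" information
unit is treated as a synonym group of the window unit (configurable).

Missing-value policy throughout: statistics of empty event sets are NaN,
never zero — zeros would alias true measurements. Counts and rates of
empty sets are genuinely 0, and regression statistics are 0 when no
regressive saccade occurred (absence of regression is a measurement).

## Classification and fusion

Per CV fold: training-fold median imputation; for LR and GNB, correlation
feature selection — drop features with |Pearson r| < 0.2 against the
label, then for every surviving pair with |r| ≥ 0.85 drop the member with
the lower label correlation (ties keep the earlier schema column; the
published inequality direction for the pairwise filter is treated as a
typographical slip, since removing *low*-correlation pairs would discard
nearly everything). RF skips selection. Hyperparameters follow the study:
L2 logistic regression at the common library default strength (C = 1.0,
features in raw units so odds ratios are per raw unit), Gaussian naive
Bayes with priors estimated from data, random forest with 10 trees,
minimum split 2, Gini impurity, unlimited depth, per-fold seeded.

If selection leaves nothing, the fold's model returns a flat 0.5. This
matters: an earlier train-prevalence fallback differed between the eye and
language training subsets, and averaged through fusion it ranked
gaze-valid against gaze-invalid test participants in a fold-composition-
dependent way, biasing null-cohort AUCs a few points below 0.5.

Fusion is unweighted probability averaging: eye and language within
picture and reading, then across the four per-task models. Gaze-rejected
participants contribute language data only and receive the mean of their
three language-bearing task probabilities. Cross-algorithm task fusion is
rejected as a contract violation.

## Evaluation and statistics

Stratified 10-fold CV repeated 10 times with distinct seeded shuffles;
performance is AUC (Mann–Whitney form, ties one half), averaged over all
100 fold records. The "±" dispersion is the SD over the 10 per-repeat
mean AUCs (the repeat as unit of analysis softens fold dependence; the
across-fold SD is computed alongside, and the source does not state its
unit). Model comparisons run ANOVA on per-repeat means with Tukey-HSD
pairwise adjustment at α = 0.05, organised into three batteries: models
vs a uniform-random dummy (H1), novel vs established tasks (H2), task
fusion vs individual tasks (H3). LR feature importance ranks coefficients
by Wald t-statistics with standard errors from the unpenalised observed
information at the (weakly penalised) solution — the source is silent on
how t-statistics coexist with L2 — and reports odds ratios
`exp(coefficient)` with 95% CIs; separation is flagged and carries no CI.

## Null behaviour and test problem sizes

A subtle property worth documenting: on any *single* finite cohort with
`effect_scale = 0`, chance feature–label associations (max |t| ≈ 3.5–4
over the 500–3600-column eye feature blocks) exceed the |r| ≥ 0.2
selection threshold and hold in every fold of that cohort, so per-model
CV AUC on one null cohort can sit 0.1 or more away from 0.5 without any
defect — the expectation over cohorts is 0.5 (verified empirically). The
null-soundness test therefore averages over two large (200 + 200) null
cohorts, where chance correlations fall below the selection threshold.
The fusion-synergy test uses five 40 + 40 cohorts at default task
durations with 5×2 CV; the demonstration analysis uses the full 79 + 83
cohort with 10×10 CV. These sizes are the package's choices for a
desk-scale, deterministic test suite.

## Known limitations

The generator's effect magnitudes are stipulated, not estimated; absolute
AUCs on synthetic cohorts are properties of those choices. The CFG-rule
and POS inventories are small fixed sets, far poorer than a real parser's
output. The acoustic stream decomposition reproducing the 172-feature
count is a plausible reconstruction. Tukey inference treats per-repeat
mean AUCs as exchangeable replicates; repeats share the cohort, so the
batteries are anti-conservative with respect to cohort-level resampling —
a property of the replicated protocol itself, visible in the null tests.
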