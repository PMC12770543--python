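# Methods

## Problem and scope

`speechscreen` implements an interpretable screening pipeline for
Alzheimer's disease and related dementias (ADRD) from picture-description
speech transcripts. The pipeline has five stages: (1) linguistic feature
extraction into a fixed 100-dimensional vector; (2) a random-forest
classifier producing an ADRD probability per participant; (3) a
random-forest regressor predicting MMSE (Mini-Mental State Examination,
0–30, higher = better cognition); (4) traffic-light risk stratification of
the predicted probabilities for triage; (5) attribution, calibration and
subgroup-fairness reporting. Because the corpora this kind of analysis is
usually run on (DementiaBank picture-description corpora, clinical pilot
recordings) are access-restricted, the package ships a first-class synthetic
cohort generator and all validation is performed on simulated cohorts.
Audio handling, ASR, diarisation and translation are out of scope:
transcripts enter as plain text files.

## Tokenization

No universal tokenization standard exists for ASR-style transcripts, so the
rule is fixed and documented: text is lowercased; a word is a maximal run of
letters/digits optionally joined by internal apostrophes (`it's`); all other
characters separate tokens. Sentences split on `.`, `!`, `?` followed by
whitespace or end of text; text without terminal punctuation is one
sentence. The tokenizer is idempotent on its own output and sentence spans
always partition the token list.

## The 100-feature vector

Five lexical-semantic indices over token count N, type count V and hapax
count V1 (types occurring exactly once):

- **CTTR** (corrected type-token ratio), Carroll's variant `V / sqrt(2N)`.
  Several "corrected TTR" variants exist; Carroll's is the common choice and
  is pinned here.
- **Brunet's index** `W = N^(V^-0.165)` with the classical constant 0.165;
  lower W = richer vocabulary.
- **Honoré's statistic** `R = 100 ln N / (1 - V1/V)`; higher R = richer
  vocabulary. When every type is a hapax (V1 = V) the denominator is floored
  at `1/(2V)` — the value a text would have if one type gained a second
  occurrence — capping R instead of letting it diverge.
- **Propositional idea density**: the fraction of tokens tagged verb,
  adjective, adverb, adposition or conjunction. Tagging is behind a
  `tokens -> tags` interface; the default is a deterministic rule-based
  tagger (closed-class word lists, then suffix rules, else NOUN). It is
  deliberately coarse: it makes idea density computable and reproducible
  without an external NLP model, and a statistical tagger can be swapped in
  for real-language work.
- **Consecutive duplicate words**: count of positions repeating the
  previous token, a simple perseveration marker.

Structural and composite features:

- **Words per sentence** `N / n_sentences`.
- **Analytic-thinking composite**: the published Categorical-Dynamic Index,
  `30 + article% + preposition% − personal_pronoun% − impersonal_pronoun% −
  auxiliary_verb% − conjunction% − adverb% − negation%`, clamped to
  [0, 100]. This is an open formula with the same intent as proprietary
  "analytic thinking" scores: categorical (noun/article/preposition-heavy)
  language scores high, dynamic (pronoun/verb/adverb-heavy) language low.
- **Disfluency aggregate**: the sum of the nonfluency, filler and assent
  category proportions, z-scored across the cohort (zero-variance cohorts
  map to 0). The z-scoring is a cohort-level operation performed by
  `extract_feature_table`; per-transcript extraction reports the raw sum.
  The normalisation deliberately uses the whole table it is given — callers
  who need strict train/test isolation can extract the two splits
  separately.

The remaining 92 features are word-category proportions from a dictionary
in the LIWC (Linguistic Inquiry and Word Count) style: each category lists
literal tokens, prefix patterns (`know*`) and token bigrams written with an
underscore (`you_know`); a token may match multiple categories; a bigram
match counts one token against N. The packaged dictionary is an **open
stand-in** with 92 categories — the proprietary LIWC-22 word lists are not
reproduced; the counting mechanics, the category inventory (pronoun
subtypes, function-word classes, affect, cognition, social, time, lifestyle
and conversational categories) and the fixed category order are the
reproducible content. Any dictionary in the documented format can be
substituted.

## Synthetic cohort generator

Each participant carries a latent severity `s ∈ [0, 1]`. Diagnosis is ADRD
iff `s > 0.35`, so the ADRD class spans mild-to-severe impairment. Severity
is drawn per class — CN: `0.35·Beta(1, 6)`; ADRD: `0.35 + 0.65·Beta(1,
2.8)` — so the MMSE mixture (via `MMSE = clamp(round(29 − 22 s + ε), 0,
30)`, ε ~ N(0, 1.5²)) reproduces a training-cohort profile of roughly 22.9
(SD 7) with CN means near 28 and ADRD means near 17. Demographics default
to age 68 (SD 6.8) years and 34% male; sex and age are sampled
independently of severity, so the generator is demographically fair by
construction and any parity gap measured downstream is estimation noise.

Transcripts are token streams from a severity-dependent mixture over
category word pools and a general content pool (a closed ~1200-word lexicon
built from the dictionary's own single-token patterns plus screened
pseudo-words that match no dictionary pattern). With increasing severity,
at `effect_size="strong"`: personal-pronoun, impersonal-pronoun, adverb,
nonfluency, filler and assent rates rise; article, preposition, family and
fulfilment-word rates fall; the active content vocabulary shrinks by up to
65% (lowering CTTR and Honoré's R); mean sentence length falls from 9
toward 5.5 words; and the adjacent-duplicate probability rises from 0.01
toward 0.09. `weak` halves every shift; `none` removes them all, giving an
exchangeable null cohort. Shift magnitudes are simulation choices — the
source analyses report effect *directions*, not sizes — chosen so that
single-feature group differences are modest relative to token-sampling
noise and the detection problem is informative rather than trivial.

Each participant's randomness comes from an independent stream seeded by
`(cohort_seed, participant_index)`, so enlarging a cohort never reshuffles
existing participants. The train/test split is 70:30, stratified by
diagnosis.

## Models and evaluation protocol

Detection: `RandomForestClassifier` with 50 trees, depth 16. Severity:
`RandomForestRegressor` with a minimum of two samples per leaf. Remaining
hyperparameters follow scikit-learn defaults; the run manifest records
library versions. Validation uses 10-fold cross-validation (stratified for
detection), reporting fold mean (SD) and out-of-fold scores — each sample
scored exactly once. Test evaluation uses a 10-repeat bootstrap: each
repeat refits on a with-replacement resample of the training set (size
n_train, redrawn if single-class) and evaluates on the fixed test set. The
95% CI is mean ± 1.96 SD across repeats: with only 10 repeats, percentile
intervals are too coarse and the SD-of-the-mean too optimistic for a
variability statement. Classification metrics are sensitivity, specificity,
accuracy (threshold 0.5 unless triage thresholds apply) and ROC-AUC (the
positive-outscores-negative probability, ties ½); regression metrics are
MAE and RMSE in MMSE points. Calibration is checked with an equal-width
10-bin reliability curve on out-of-fold scores. MMSE severity groups follow
the clinical convention CN (26, 30], MCI (20, 26], moderate [10, 20],
severe [0, 10); binary labelling from MMSE alone uses the standard cutoff
of 26 (impaired iff MMSE ≤ 26).

## Risk stratification

Zones are Green `[0, t_low]` (low risk, predicted negative), Amber
`(t_low, t_high]` (abstain) and Red `(t_high, 1]` (high risk, predicted
positive), with right-closed boundaries. Thresholds are selected by
exhaustive grid search on validation (out-of-fold) scores: every pair with
`t_low ≤ t_high` on a 0.05 grid is evaluated on the retained (non-Amber)
set; pairs with coverage below 0.5 or undefined retained metrics are
dropped; the rest are ranked lexicographically by retained Youden's J
(= sensitivity + specificity − 1), then retained ROC-AUC, then coverage,
with exact ties broken toward the smaller pair to limit overfitting. The
0.05 resolution, 0.5 coverage floor and lexicographic objective are design
choices where the procedure is otherwise under-determined: a coarser 0.10
grid cannot express thresholds such as 0.45/0.65, coverage must be bounded
away from zero for a selective report to be meaningful, and the objective
order puts the joint sensitivity/specificity criterion first because that
is the stated clinical intent. The full search trace is emitted for audit.

## Attribution and fairness

Tree-mode attributions decompose each prediction along every tree's
decision path: at each split the change in node mean (class-1 fraction for
the classifier) is credited to the split feature; the root mean is the base
value. Averaged over trees, base + contributions reconstructs the forest
output exactly (local accuracy; tested at 1e-6), and for a depth-1 stump
the decomposition coincides with the exact Shapley value. Unlike full
interventional Shapley values, credit at deeper splits is conditional on
the path taken — rankings from correlated features should be read with
that in mind. A permutation-importance mode (global only) is available as
a model-agnostic alternative.

Subgroup reports compute the full metric set per sex, per median-split age
group (no standard clinical age bins exist for this task) and per MMSE
severity group; groups below a minimum size are flagged, not dropped.
Demographic parity is the largest pairwise difference in
positive-prediction rates; sensitivity/specificity gaps (equalized-odds
style) are reported alongside. Rank associations (predicted probability vs
MMSE) use Spearman's correlation with mid-ranks for ties; zero-variance
inputs are flagged undefined rather than propagating NaN.

## Problem sizes and seeds

The shipped validation and acceptance runs use cohorts of 400–500
participants (e.g. 450 split 300/150) — large enough that effect-direction,
calibration and fairness checks are stable, small enough to run in minutes
on one CPU. All randomness flows from explicit integer seeds; repeated runs
are byte-identical.

## Limitations

The generator emulates category-rate, lexical-diversity and structural
effects; it does not model discourse coherence, topic drift, ASR errors,
code-switching or real word-frequency distributions, so passing tests
demonstrate the pipeline's correctness and statistical behaviour, not
clinical performance on real speech. The stand-in dictionary's word lists
are small; on real transcripts they would under-count categories compared
to a full lexicon. The rule-based tagger is coarse, which mainly affects
the idea-density feature. MMSE-based labels and severity groups inherit all
the known limitations of MMSE as a staging instrument.
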