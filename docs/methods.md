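# Methods

This note records the models implemented in `reviewfactors`, the defaults
and why they were chosen, and what the synthetic experiments do and do not
establish.

## Synthetic corpus model

The generator emulates an app-store review corpus with the exact
statistical structure the analysis chain assumes, so that every stage can
be scored against known ground truth.

Per review *i* of app *a*:

- topic mixture θᵢ ~ Dirichlet(α\*) (symmetric, default α\* = 0.3 — sparse
  but multi-topic documents, typical of short reviews);
- tokens: length ~ Poisson(40), each token draws a topic from θᵢ and a
  word from that topic's distribution φₖ ~ Dirichlet(β\* = 0.05) over a
  synthetic vocabulary `w0001…wNNNN` (default V = 300). Small β\* makes
  topics well separated; real review language is far messier (see
  *Limitations*);
- regime: the review is positive-deviating with probability
  logistic(c₀ + θᵢ·c), default c = 0 (a fair coin);
- latent deviation magnitude m = θᵢ·β_PD + ε (positive regime) or
  θᵢ·β_ND + ε (negative regime), ε ~ N(0, σ²) with σ = 0.5, clamped to
  [0, 4];
- star rating = round(clamp(R_a ± m, 1, 5)), where the app base rating
  R_a is uniform on {2.5, 3.0, …, 4.5} (half stars round away from zero).
  The grid leaves headroom for both positive and negative deviations
  under the clamp;
- sentiment label consistent with the rating (≥4 positive, 3 neutral,
  ≤2 negative).

The two-regime construction is essential: a single symmetric latent
deviation would force |β_PD| = |β_ND| for every topic and no asymmetry
could be planted. Default effect vectors plant two motivational topics
(β_PD = 1.2, 0.9; β_ND ≤ 0), two hygienic topics (β_ND = 1.8, 2.2;
β_PD ≤ 0) and one null topic. The implied factor class of each topic
follows deterministically from the sign pattern of (β_PD, β_ND).

Contamination (exact duplicates, bot rows, sentiment flips contradicting
the rating, empty texts) is appended from an independent RNG sub-stream —
derived with `SeedSequence.spawn` — so turning contamination on or off
never perturbs the clean text. Each injected row carries a provenance tag
(`duplicate`, `bot`, `contradiction`, `empty`), which is what lets the
tests assert that each filter removes *exactly* the rows of its kind.
Injected counts are `round(rate × n_clean)` so bookkeeping is exact.

## Preprocessing

Filters run in a fixed order: missing text → bot predicate → duplicates →
sentiment consistency → tokenization emptiness. A `FilterLedger` counts
removals per step and enforces `n_in = n_out + Σ removed`.

- Duplicate key: (app_id, rating, case-folded whitespace-normalized
  text). Review/user ids are excluded because stores anonymize them
  inconsistently, so identical text from "different" users still counts
  as one review.
- The consistency screen keeps a row iff (rating 1–2, negative), (3,
  neutral) or (4–5, positive). It is idempotent by construction.
- Sentiment is a pluggable callable `str → polarity`; the default is a
  deliberately tiny signed lexicon (a placeholder interface, not a
  serious classifier), and the synthetic pipeline bypasses scoring by
  emitting labels directly. Bot detection is likewise a pluggable row
  predicate whose default trusts a `bot_flag` column.
- Tokenization lowercases, drops purely numeric/punctuation tokens and
  stop words, applies a variant→canonical synonym map token-wise, and
  drops rows left empty (counted separately). An optional lemmatizer hook
  covers morphological normalization of English.

## Topic model

LDA is fitted by collapsed Gibbs sampling; a token's topic is resampled
proportional to `(n_dk − i + α)(n_kw − i + β)/(n_k − i + Vβ)`. Kernels
are numba-compiled and single-threaded; the in-kernel RNG is seeded from
the model seed, so fits are deterministic.

- Defaults α = 50/K, β = 0.01, 1000 sweeps with 500 burn-in, single
  chain, point estimate from the final state:
  θ = (n_dk + α)/(len_d + Kα), φ = (n_kw + β)/(n_k + Vβ). For the small,
  well-separated synthetic corpora used in tests, 200–300 sweeps and
  α = 0.1 are sufficient and much faster; the recovery experiments use
  those.
- Perplexity is exp(−Σ log Σₖ θ_dk φ_kw / N). For held-out documents θ is
  obtained by fold-in Gibbs (50 sweeps) with φ frozen; out-of-vocabulary
  tokens are an error rather than silently smoothed.
- Topic-number selection fits each candidate K on a seeded 90/10 split
  and evaluates held-out perplexity. Beyond the number of real topics the
  curve flattens into a plateau whose wiggles are sampler noise, and the
  raw argmin then drifts toward the largest candidate. The selector
  therefore treats candidates within 2% (relative) of the minimum as
  ties and picks the smallest — the same parsimony logic as the
  one-standard-error rule in cross-validation. `rel_tol=0` restores the
  raw argmin, and `override=` forces a choice, since topic counts are in
  practice also judged by interpretability of the topics themselves.
- Ties anywhere (dominant-topic assignment, keyword ranking) break toward
  the lowest index / vocabulary order, for determinism.
- Topic labels are user-supplied metadata; the model never names topics.

## Deviations and descriptive statistics

The app's overall rating is the unrounded mean of its observed star
ratings; a column override accepts the true store-displayed aggregate
when it is known (stores may round or weight). PD/ND are the clamped
positive/negative parts of `rating − overall`; clamping to [0, 4] is
enforced although it cannot bind when the overall rating lies in [1, 5].
Percentages (satisfaction rate = share of ratings ≥ 4; topic shares) are
rounded half-up to 2 decimals, matching how such tables are printed.

## Censored regression

The two-limit Tobit log-likelihood mixes density terms for interior
observations with Φ mass terms at each limit. Numerical choices:

- optimization in (β, log σ) so the scale is unconstrained; BFGS with the
  analytic score, on the *mean* log-likelihood so the gradient tolerance
  (1e-8, 500 iterations max) is independent of n; started from OLS on
  the uncensored rows with σ₀ = their residual SD;
- standard errors from the inverse observed information, computed as a
  central-difference Hessian at the optimum in the (β, σ)
  parameterization; z statistics, normal 95% CIs and two-sided p-values
  (large-n asymptotics, α = 0.05);
- non-convergence is flagged on the results object, not raised;
- the constructor rejects rank-deficient designs and names the collinear
  columns (SVD null space). The canonical trap — a full probability
  simplex plus an intercept — is caught this way; the paired analysis
  avoids it by dropping a reference topic (default: the largest-share
  topic) whenever an intercept is included.
- the upper limit (default 4) rarely binds in practice and can be
  disabled (`upper=None`).

With an intercept and a dropped reference topic, each coefficient is the
effect of topic j *relative to the reference topic*; sign-based factor
classification is then relative too. Fitting without an intercept on the
full simplex estimates absolute topic effects, and the recovery
experiments use that form.

VIF_j = 1/(1 − R²_j) from regressing column j on the remaining columns
plus an intercept; exact collinearity yields ∞ with a warning.

## Asymmetry and classification

W = (|β_PD| − |β_ND|)²/(SE²_PD + SE²_ND), referred to χ²₁. The
cross-model covariance is set to zero — a working assumption, since both
models are fitted to the same reviews and a joint covariance is not
estimated. A paired-bootstrap variant (resample reviews, refit both
models, bootstrap SE of |β_PD| − |β_ND|) is provided to quantify the
assumption's error. |·| is non-differentiable at 0, so W is best behaved
when at least one coefficient is clearly nonzero; near-null topics should
be read through the classification rule rather than W.

Classification at level α (default 0.05): motivational = significant
positive PD effect without a significant positive ND effect; hygienic =
the converse; mixed = both; otherwise not significant. No
multiple-testing correction is applied across topics (per-topic
reporting); a Holm-adjusted Wald p-value column is emitted alongside.

Calibration facts worth knowing: under the null a topic is flagged
(significant positive in either model) with probability ≈ 2 × α/2 ≈ 4.9%,
so with K topics the chance that *all* are clean is (1 − 0.049)^K — about
0.82 at K = 4. The test suite therefore checks the per-topic flag rate,
and the Wald test's type-I error directly (rejection rate within
[0.03, 0.07] at nominal 0.05 over 1000 replicates).

## Problem sizes used in tests and the acceptance script

Chosen to make every check statistically meaningful at desk scale: LDA
recovery and K-selection on 500 documents × ~60 tokens, V = 300, K\* = 5;
the perplexity oracle on 20 documents; Tobit recovery at n = 5000 (~30–40%
censored) with CI coverage over 200 replicates at n = 1000; Wald
calibration over 1000 replicates at n = 2000; classification recovery at
n = 10,000 with 8 topics (3 motivational, 3 hygienic, 2 null). Descriptive
rates are recomputed from the published marginal counts (e.g. 87,773 of
116,686 reviews rated ≥ 4 → 75.22%).

## Limitations

- Synthetic text is exchangeable bag-of-words from well-separated
  topics; passing recovery tests says the sampler and selection logic are
  correct, not that K topics are recoverable from real, noisy, mixed-
  language reviews with heavy-tailed lengths and near-duplicate phrasing.
- The default sentiment lexicon is a stub; real use requires a trained
  polarity model behind the same interface.
- The overall-rating proxy (mean of observed ratings) differs from
  store-displayed aggregates, which may be weighted or rounded; PD/ND
  magnitudes shift accordingly.
- The Wald denominator ignores the cross-model covariance; use the
  bootstrap variant when that matters.
- Single-chain LDA point estimates carry label-switching and local-mode
  risk; the tests handle matching explicitly (greedy cosine matching) and
  real analyses should compare seeds.
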