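# reviewfactors

Tools for asking *why* app users are satisfied or dissatisfied, from
nothing but their star ratings and review text. The package was built
around satisfaction analysis of mobile health (blood-pressure management)
apps, where the two-factor (Herzberg) theory predicts that the drivers of
satisfaction (**motivational factors**) and of dissatisfaction
(**hygienic factors**) are distinct and asymmetric — but every stage is
generic to any review corpus with 1–5 star ratings.

The analysis chain:

1. **Cleaning** — duplicate removal, bot filtering, empty-text removal,
   and a sentiment–rating consistency screen (a 1–2 star review whose text
   is not negative is treated as contradictory and dropped). Every removal
   is counted in a ledger with the invariant `n_in = n_out + Σ removed`.
2. **Topic extraction** — latent Dirichlet allocation fitted by collapsed
   Gibbs sampling; the number of topics K is chosen from a held-out
   perplexity curve. Each review gets a topic-probability vector θ and a
   dominant topic.
3. **Rating deviations** — each review's star rating r is compared with
   its app's overall rating R: the positive deviation PD = clamp(r − R, 0, 4)
   measures satisfaction beyond expectation, the negative deviation
   ND = clamp(R − r, 0, 4) dissatisfaction. PD and ND are mutually
   exclusive and censored within [0, 4].
4. **Censored regression** — PD and ND are each regressed on the topic
   probabilities with a two-limit Tobit model,
   `y* = θβ + ε, ε ~ N(0, σ²)`, `y = clamp(y*, 0, 4)`,
   estimated by maximum likelihood (BFGS with the analytic score; SEs from
   the observed information). VIF diagnostics guard against
   multicollinearity.
5. **Asymmetry** — for each topic a Wald statistic
   `W = (|β_PD| − |β_ND|)² / (SE_PD² + SE_ND²)` (χ²₁ under H₀) tests
   whether the topic's push on satisfaction differs from its push on
   dissatisfaction, and the topic is classified as motivational, hygienic,
   mixed, or not significant.

A synthetic corpus generator (`reviewfactors.synthetic`) produces review
tables with exactly the structure this chain assumes — LDA text, censored
deviation ratings with planted asymmetric effects, and tagged
contamination — so the whole pipeline is testable without scraped data.

## Worked example

```python
from reviewfactors import GeneratorConfig, RunConfig, run_pipeline, report

cfg = RunConfig(
    outdir="demo_run", seed=42,
    generator=GeneratorConfig(n_apps=10, reviews_per_app=60, seed=42),
    k=5, lda_iters=200, lda_burn_in=100,
)
run_pipeline(cfg)
print(report("demo_run"))
```

```
Review two-factor analysis report
==================================
reviews in: 600   out: 600   removed: 0 {'bot': 0, 'contradiction': 0, 'duplicate_blank_language': 0, 'empty_after_stopwords': 0, 'no_text': 0}

[CN]
  reviews: 300
  satisfaction rate: 31.67%
  topics (K): 5
  log-likelihood  PD: -248.833  ND: -263.574
  largest topic: topic_0 (67/300, 22.33%)
    topic_1: not_significant
    topic_2: hygienic
    topic_3: not_significant
    topic_4: hygienic
...
```

The run directory holds every intermediate artifact: the corpus, the
cleaning ledger, per-group topic shares and keywords, both Tobit
coefficient tables (factor, β, 95% CI, SE, p), VIF values, and the
asymmetry table with Wald statistics and factor classes. The satisfaction
rate is the percentage of reviews rated 4 stars or more; the factor
classes are read from the paired fits at the 0.05 level. When an
intercept is included, one reference topic is dropped to break the
simplex collinearity and coefficients are interpreted *relative to that
reference topic*; fit with `intercept=False` (as in
`run_two_factor_analysis(theta, pd, nd, intercept=False)`) to estimate
absolute topic effects.

The same stages are available as a CLI:

```bash
reviewfactors simulate --out corpus_dir --seed 1
reviewfactors preprocess corpus_dir/corpus.csv --out clean_dir
reviewfactors topics clean_dir/clean.csv --out topics_dir --k 5
reviewfactors run-all --config config.json
reviewfactors report run_dir
```

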