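# evlm — evidential analysis for normal linear models

`evlm` replaces the accept/reject logic of classical F tests on nested
normal linear models (t-tests, regression, fixed-effects ANOVA) with an
*evidential* analysis: it measures how strongly the data support one
model over the other, designs studies so that the probabilities of
*misleading* evidence are capped, and quantifies the uncertainty of the
evidence itself by resampling.  It is aimed at applied statisticians and
quantitative biologists who already work with `y ~ N(Xβ, σ²I)` and want
more from a model comparison than a p-value.

## The statistic

For model 1 nested in model 2 by q linear restrictions, the evidence
function is the difference of Schwarz information criteria,

    ΔSIC = SIC₁ − SIC₂ = n·log(1 + q·F/(n−r)) − q·log n,

a monotone transform of the nested-model F statistic (n observations, r
mean parameters in the full model).  ΔSIC < k₁ is strong evidence for
the restricted model, ΔSIC > k₂ strong evidence for the full model, and
anything between is inconclusive.  ΔSIC/n consistently estimates the
difference of Kullback–Leibler divergences of the two models from the
data-generating process, so it is comparable across data sets.

Because ΔSIC is a function of F, its pre-data distribution is a
noncentral F(q, n−r, λ).  The investigator fixes a per-observation
relative effect size δ — the largest departure from model 1, in residual
standard deviations, still considered negligible — giving a boundary
noncentrality λ = nδ².  Thresholds k₁, k₂ are the evidence transforms of
noncentral-F quantiles chosen so both misleading-evidence probabilities
are capped (M₂ ≤ γ₂, M₁ ≤ γ₁) at that boundary, and both vanish as n
grows — unlike the fixed Type-1 rate of a classical test.  Post data,
the same distribution yields P₂, the largest probability of evidence as
misleading as observed, and the smallest δ the data can rule out.
Parametric, semiparametric-residual, and stratified balanced
nonparametric bootstraps estimate the sampling distribution of ΔSIC, its
confidence intervals, and the apparent reliability (aR) of the model
identification.  See `docs/methods.md` for the full account.

## Worked example: interactions in a two-way ANOVA

The packaged `citrus()` fixture holds fruit yields of 24 citrus trees —
3 varieties × 4 pesticides, 2 trees per cell.  Is there a
variety-by-pesticide interaction?

```python
import evlm

data = evlm.citrus()
print(evlm.anova_table(data, ["pest", "tree", "pest:tree"]).round(4))
#            df         SS         MS        F       p
# pest        3  2227.4583   742.4861  17.5563  0.0001
# tree        2  3996.0833  1998.0417  47.2443  0.0000
# pest:tree   6   456.9167    76.1528   1.8007  0.1817
# Error      12   507.5000    42.2917      NaN     NaN
```

The classical test stalls at F = 1.80, p = 0.18.  The evidential view:

```python
design = evlm.build_design(data, ["1", "tree", "pest", "tree:pest"])
inter = [c for c in design.column_names if ":" in c]
cmp_ = evlm.compare_nested_A(data, design, inter)
ev = evlm.delta_sic_from_F(cmp_.F, cmp_.n, cmp_.r, cmp_.q)
print(f"Delta-SIC = {ev.delta_sic:.2f}")        # Delta-SIC = -3.66

d = evlm.design_thresholds(24, 12, 6, delta=0.5)  # indifference: 0.5 sigma
print(f"k1 = {d.k1:.1f}, k2 = {d.k2:.1f}")      # k1 = -12.9, k2 = 13.3
print(evlm.classify(ev.delta_sic, d).category)  # inconclusive

d1 = evlm.design_thresholds(24, 12, 6, delta=1.0)
print(evlm.classify(ev.delta_sic, d1).category)  # strong_model1
```

With a half-σ indifference zone the study cannot resolve the question
(−12.9 < −3.66 < 13.3); with a one-σ zone the data are strong evidence
that any interaction is smaller than one standard deviation per
observation.  The smallest effect size the data rule out at the 0.05
level, and the bootstrap view of the evidence's own variability:

```python
evlm.delta_for_strong_evidence(ev.delta_sic, 24, 12, 6, 0.05)["root"]
# 0.94
pair = evlm.ModelPair(design, tuple(inter))
cfg = evlm.BootstrapConfig(model_pair=pair, B=1024, seed=0)
boot = evlm.parametric_bootstrap(evlm.fit(data, design), cfg)
s = evlm.summarize(boot)
print(f"mean = {s.mean:.2f}, aR = {s.aR:.2f}, "
      f"90% CI = ({s.ci_delta_sic[0]:.1f}, {s.ci_delta_sic[1]:.1f})")
# mean = 2.76, aR = 0.59, 90% CI = (-9.6, 17.9)
```

The wide interval and aR near one half say the 24 observations are
simply not enough to settle the interaction question — a far more
actionable conclusion than "fail to reject".

The same analyses run from the shell:

```sh
evlm analyze --fixture citrus --model1 tree+pest --model2 "tree*pest" --delta 0.5
evlm design --n 24 --r 12 --q 6 --delta 0.5
evlm samplesize --k -2.94 --which k1 --gamma 0.05 --delta 0.42 --q 1 --r 1
evlm bootstrap --fixture citrus --model1 tree+pest --model2 "tree*pest" \
    --method stratified --B 1024 --seed 1 --edf edf.csv
```

CSV input is supported via `--input file.csv --response y --factors a,b`.

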