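# gridrun

Declarative, fault-tolerant hyper-parameter grid experiments for
classification.

`gridrun` is for anyone who needs to evaluate many classifier
configurations on a dataset — a model-selection sweep, a baseline
comparison, a sanity scan over a regularisation knob — without writing
orchestration code and without losing a night of computation to a crash
at experiment 199 of 200.  A short XML document declares the dataset,
the evaluation strategy and the hyper-parameter ranges; the package
expands it into the full Cartesian grid of experiments, runs them in
parallel, commits one verifiable result file per experiment, resumes
interrupted runs by skipping completed work, and writes a summary
ranking the configurations.

## The model

A ranged hyper-parameter is a value set `{v₁, …, vₘ}` or an interval
materialised by index, `vᵢ = start + i·step` for `vᵢ ≤ end` (computed in
exact decimal arithmetic).  An algorithm with ranges R₁, …, R_q
contributes `∏ⱼ |Rⱼ|` experiments; the grid is their concatenation over
algorithms, so the total is `Σ_a ∏_j |R_{aj}|`.  Each experiment is
scored by leave-one-out cross-validation, stratified or unstratified
k-fold, or a seeded percentage split, pooling predictions into a single
confusion matrix `C` with `accuracy = tr(C)/n`, per-class
precision/recall/F1, and Cohen's
`κ = (p_o − p_e)/(1 − p_e)` from the marginals.

Every experiment's identifier is a content digest of (dataset,
algorithm, parameters, evaluation) and its randomness derives from
`sha256(master_seed ∥ id)` — which is why results are bit-identical
whether you run on 1 worker or 8, straight through or killed and
resumed.  See `docs/methods.md` for the full account and
`docs/schema.md` for the XML reference.

## Worked example

Generate a synthetic 3-class dataset and sweep two learners — k-nearest
neighbours over k = 1…10 and a decision stump over its minimum leaf size
1…10 — under leave-one-out cross-validation.  The whole 20-experiment
batch is this 11-line specification (`spec.xml`):

```xml
<experiments>
  <dataset path="demo.arff"/>
  <evaluation strategy="loocv"/>
  <algorithm key="knn">
    <param name="k" start="1" step="1" end="10"/>
  </algorithm>
  <algorithm key="stump">
    <param name="min_leaf" start="1" step="1" end="10"/>
  </algorithm>
  <output dir="results"/>
</experiments>
```

```
$ gridrun synth --out demo.arff --n-samples 120 --n-numeric 6 --n-nominal 2 \
    --n-classes 3 --class-sep 2.5 --missing-rate 0.02 --seed 1
wrote 120 x 9 dataset to demo.arff

$ gridrun expand spec.xml | head -3
knn__k-1__62fd8f6e	knn	k=1
knn__k-2__91f95b0e	knn	k=2
knn__k-3__8806ca62	knn	k=3

$ gridrun run spec.xml --workers 2
20 experiments: 20 succeeded, 0 failed (20 run, 0 resumed)
```

`results/` now holds one `<id>.result` file per experiment plus
`summary.csv`:

```
experiment_id,algorithm,k,min_leaf,strategy,n_instances,accuracy,kappa,status
knn__k-1__62fd8f6e,knn,1,,loocv,120,0.6916666666666667,0.5375,success
knn__k-2__91f95b0e,knn,2,,loocv,120,0.6666666666666666,0.49999999999999994,success
...
# best knn: knn__k-7__78129c38 params[k=7] accuracy=0.825
# best stump: stump__min_leaf-1__86d75fc7 params[min_leaf=1] accuracy=0.6083333333333333
```

Reading: each row is one experiment's pooled leave-one-out confusion
summarised as accuracy and kappa over the 120 instances; the trailing
block names the best configuration per algorithm (here 7-NN at 82.5 %
accuracy; the stump tops out at 60.8 % because one split cannot separate
three classes).  Each result file echoes its configuration, the full
confusion matrix and per-class metrics, and ends with a digest footer:

```
[confusion]
levels = c0,c1,c2
row.c0 = 32,4,4
row.c1 = 2,36,2
...
[provenance]
duration_s = 0.034
payload_sha256 = 1f202ccefe3f...
```

Kill the run at any point and `gridrun run spec.xml --resume` continues
from the completed set; only files whose footer digest verifies are
trusted.  `gridrun validate spec.xml` checks a specification without
running anything.

The same machinery is available as a library:

```python
import gridrun as g
spec = g.parse_spec(open("spec.xml").read())
report = g.run(spec, workers=4)
best = max((o for o in report.outcomes if o.status == "success"),
           key=lambda o: o.result.metrics.accuracy)
```

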