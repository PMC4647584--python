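# XML specification schema reference

One document = one batch of experiments.  Encoding is UTF-8.  Unknown
elements and attributes are rejected.

```
<experiments>                           exactly one, root
  <dataset path="..." [class="..."]/>   exactly one
  <evaluation strategy="..." .../>      exactly one
  <algorithm key="...">                 one or more
    <param .../>                        zero or more
  </algorithm>
  <output dir="..."/>                   exactly one
  <run [workers="..."] [seed="..."]/>   at most one
</experiments>
```

## `<dataset>`

| attribute | required | meaning |
|-----------|----------|---------|
| `path`    | yes      | ARFF (`.arff`) or CSV (`.csv`) file |
| `class`   | no       | class attribute name, or `last` (default) |

## `<evaluation>`

| `strategy` | further attributes |
|------------|--------------------|
| `loocv`    | none |
| `kfold`    | `k` (required, ≥ 2); `stratified` = `true` (default) / `false`; `seed` (default 0) |
| `split`    | `fraction` (required, in (0,1)); `seed` (default 0) |

Attributes belonging to a different strategy are schema errors.

## `<algorithm>` and `<param>`

`key` selects a registered learner (built-ins: `zeror`, `knn` with
parameter `k`, `stump` with parameter `min_leaf`).

Each `<param name="...">` takes exactly one of three forms:

| form      | attributes            | example |
|-----------|------------------------|---------|
| fixed     | `value`               | `<param name="k" value="3"/>` |
| value set | `values` (comma list) | `<param name="k" values="1,3,5"/>` |
| interval  | `start`, `step`, `end`| `<param name="c" start="0.05" step="0.05" end="0.5"/>` |

Mixing forms on one param, duplicate param names within an algorithm,
zero steps, and steps pointing away from `end` are all errors.

## `<run>`

| attribute | meaning |
|-----------|---------|
| `workers` | positive integer or `auto` (logical cores − 1; default) |
| `seed`    | master seed (default 0) from which each experiment's seed is derived |

## Worked example (11 non-blank lines, 20 experiments)

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
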