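# kinsig

Kinetic-signature classification of stimulated-cell expression time
courses by Bayesian model comparison.

After an acute stimulus, a promoter's expression time course typically
follows one of a small number of prototypical shapes: a rapid **early
peak** that decays back toward baseline, a **late peak**, a transient
**dip**, a monotonic **decay**, or a slow, essentially **linear**
drift. `kinsig` fits all five shapes to each replicated time course,
computes the Bayesian evidence (marginal likelihood, log Z) of each by
nested sampling, and assigns the course to the signature whose evidence
clearly dominates — or to **no decision** when the evidences, with
their uncertainties, do not separate a single winner.

The five signatures are parameterised by a basal level `p1`, a maximal
change `p2`, and a timing parameter:

- **early / late peak**: `y = p1 + p2 (1 − e^{δt})`, then exponential
  relaxation back to `p1` after the switch time `t_s`, with
  `δ = ln(0.1)/t_s` so that the curve attains exactly **90%** of `p2`
  at `t = t_s`. Early peaks have `t_s < 240` min, late peaks
  `t_s ≥ 240` min.
- **dip**: the mirror image — the course drops by 90% of `p2` at
  `t_s`, then relaxes back up.
- **decay**: `y = p1 + p2 e^{−δt}` with half-life `t_h`
  (`δ = ln 2 / t_h`).
- **linear**: `y = p1 + p2 · t / T_end`.

Replicate scatter is modelled with an L1 (Laplace / maximum-entropy)
likelihood whose per-time-point scale is the mean absolute deviation of
the replicates around the model curve, making the fit robust to
heavy-tailed expression noise. Downstream helpers cover the standard
follow-up statistics: hypergeometric gene-set enrichment with BH FDR,
switch-time binning, transcription completion-time contours,
travelling ratios, rank-sum group comparisons, window read counts and
miRNA-target over-representation.

## Worked example

Simulate one noisy early-peak course and classify it:

```python
from kinsig import KineticSignatureModel, SignatureParams
from kinsig.simulate import GRID_16PT_480, simulate_time_course

truth = SignatureParams("early_peak", p1=15.0, p2=25.0, t_s=60.0)
course = simulate_time_course(truth, GRID_16PT_480, n_rep=3, noise_b=1.25, seed=42)

model = KineticSignatureModel(course)
res = model.fit(seed=42)
print(res.summary())
```

```
Kinetic signature model selection
======================================================================
cluster: sim   time points: 16   T_end: 480 min   rule: bayes_factor
selected category: early_peak
----------------------------------------------------------------------
kind             log Z      sd  parameters (posterior mean +/- sd)
early_peak      -32.10    0.31  p1=15.1+/-0.46, p2=25.6+/-1.1, t_s=61.2+/-2.4
late_peak       -47.36    0.25  p1=14.7+/-1.1, p2=1.13+/-1.3, t_s=353+/-62
dip             -44.64    0.22  p1=12.3+/-2.3, p2=10+/-8.1, t_s=355+/-1e+02
decay           -42.78    0.25  p1=14.3+/-1.5, p2=30.6+/-12, t_h=66.9+/-78
linear          -47.05    0.26  p1=16.7+/-2.1, p2=-2.18+/-3.6
======================================================================
```

The generating parameters (`p1=15`, `p2=25`, `t_s=60`) are recovered
within posterior uncertainty, and the early-peak evidence beats every
alternative by more than ten log units. `res.params()` returns the
posterior-mean `SignatureParams`, `res.predict(t)` the fitted curve,
and `res.plot()` the data with the selected model overlaid.

Whole datasets go through `classify_dataset` (one assignment row per
cluster, with all five evidences and their uncertainties) or the CLI:

```sh
kinsig simulate --out-dir demo --per-category 10 --seed 1
kinsig classify --matrix demo/matrix.tsv --meta demo/samples.tsv \
    --out demo/assignments.tsv --seed 1
# ieg_genes.tsv: one gene id per line (last column is used)
kinsig enrich --assignments demo/assignments.tsv \
    --gene-set ieg_genes.tsv --out demo/enrichment.tsv
```

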