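# brainmse

Multiscale-entropy mapping of brain complexity from resting-state
BOLD-like signals, for researchers studying how signal irregularity at
node, edge, network, and whole-brain level relates to behavior.

The package implements, as a tested pipeline:

* **Sample entropy and multiscale entropy (MSE).** For a series of
  length N, `SampEn(m, r, N) = −ln(A/B)` where B counts template pairs of
  length m within Chebyshev distance `r·SD` (self-matches excluded) and A
  the corresponding m+1 pairs; MSE evaluates SampEn on coarse-grained
  copies (non-overlapping block means, scale factor l) with the tolerance
  anchored to the scale-1 SD. Estimation failures (no matching patterns)
  are first-class data, masked and propagated, never raised.
* **Phase-coherence dynamic connectivity.** Instantaneous phases θ(t)
  from the analytic signal give edge series
  `dFC(i,j,t) = cos(θ_i(t) − θ_j(t))`; 90 nodes yield 4005 edges.
  Neuronal complexity (nMSE) is the MSE of node signals; functional
  complexity (eMSE) is the MSE of edge series; edge-based nMSE averages a
  node's incident edges.
* **CSF-based parameter selection.** The 48-combination grid
  (m ∈ {1,2,3}, r = 0.05…0.80) is screened by the relative error
  `RE = 1.96·σ/μ²` of SampEn over white-noise-like CSF reference signals,
  with a 0.1 acceptance threshold and failure exclusion.
* **Behavioral prediction.** Leave-one-subject-out linear-kernel SVR on
  correlation-ranked features (ranked inside each fold), with permutation
  significance for the predicted-vs-actual correlation.
* **A synthetic cohort generator** producing signals with the structure
  the analysis assumes (network-shared slow oscillations + 1/f background
  + white noise, white-noise CSF, a score coupled to planted nodes'
  noise levels), so the full pipeline is testable without restricted
  data.

## Worked example

The `analysis/` scripts run the full study on a synthetic cohort
(20 subjects × 20 nodes, four 300-point runs, nodes 1–4 planted):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_select_parameters.py
python analysis/03_map_complexity.py
python analysis/04_predict_behavior.py
```

Step 02 prints the parameter-selection result on this cohort:

```
relative-error surface: 48 (m,r) combinations x 10 scales, 20 failed cells (m=3 with small tolerances)
acceptable at RE <= 0.1 (literal variant): 10 combinations
  best for m=1: r=0.05 (mean RE across scales 0.0247)
  best for m=2: r=0.15 (mean RE across scales 0.0573)
  best for m=3: r=0.20 (mean RE across scales 0.1034)
```

Failures cluster at m = 3 with small tolerances and the per-m best
tolerances grow with m — longer patterns need wider match radii. Step 03
maps complexity at the m = 3, r = 0.2 operating point:

```
group-mean whole-brain profiles (scales 1..10):
  nMSE: 2.00 1.84 1.80 1.81 1.85 1.87 1.88 1.84 1.82 1.82
  eMSE: 1.54 1.78 1.78 1.75 1.71 1.67 1.65 1.62 1.59 1.57
paired nMSE vs eMSE, worst scale 3: t19 = 2.53, p = 0.0203 (uncorrected)
divergence map (scale 10 - scale 2): 88.4% of edges decrease (0 excluded for failures)
```

Neuronal complexity exceeds functional complexity at every scale, and
the edge profile shows the characteristic initial rise followed by a
decline. Step 04 predicts the behavioral score from each measure's
features; on this small demonstration cohort the edge-derived measures
carry the planted signal (e.g. `eMSE: LOSO r = 0.675, permutation
p = 0.010`) while nMSE with 20 subjects does not reach significance —
at the verification scale of 60 subjects it recovers the signal with
median r ≈ 0.69 (see below).

The same pipeline is scriptable via the CLI:

```sh
brainmse all --out results/demo --seed 1
```

Each subcommand (`simulate`, `params`, `complexity`, `predict`, `all`)
writes its resolved configuration next to its outputs; identical seeds
reproduce byte-identical results.

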