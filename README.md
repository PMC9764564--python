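# costnet

Cost-thresholded graph analysis of resting-state functional brain networks,
with a synthetic cohort generator for end-to-end validation.

## The scientific problem

Resting-state fMRI studies of clinical populations (here: Alzheimer's disease
with and without depressive symptoms, versus healthy controls) often compare
the *topology* of whole-brain functional networks rather than individual
connections.  The standard workflow, which this package implements as a
tested, reusable pipeline, is:

1. **Connectivity.** For each subject, the preprocessed ROI time series
   (T × 90 regions of the AAL parcellation) yield a 90 × 90 Pearson
   correlation matrix.
2. **Cost thresholding.** Because correlation matrices are dense, graphs are
   formed at a fixed *cost* (sparsity) s: the K = round(s·N(N−1)/2) strongest
   positive correlations become undirected weighted edges (weight = r).  This
   is repeated over the grid s = 0.05, 0.06, …, 0.40, giving nested graphs.
3. **Graph metrics.** On each weighted graph, with edge length 1/w:
   global efficiency E_glob = mean over ordered pairs of 1/d(i,j);
   nodal efficiency E_nod(i) = (1/(N−1)) Σ_j 1/d(i,j);
   local efficiency E_loc = mean over nodes of the efficiency of each node's
   neighbour subgraph; binary nodal degree; normalised betweenness
   centrality; and the small-world indices γ = Cp/Cp_rand, λ = Lp/Lp_rand,
   σ = γ/λ against degree-preserving (Maslov–Sneppen) null ensembles.
4. **AUC integration.** Each metric's curve across the cost grid is reduced
   to one number per subject by the trapezoidal area under the curve, so
   inference does not depend on an arbitrary threshold.
5. **Group inference.** ANCOVA (partial F on the group indicators, adjusting
   for age, sex and head motion) per metric and node, pairwise post-hoc
   t-tests on covariate-residualised AUCs with Bonferroni correction
   (family = 90 nodes per nodal metric), demographics (ANOVA / χ²),
   Jarque–Bera normality screens, and Pearson correlations with clinical
   scores (MMSE, HAMD, NPI).
6. **Motion QC.** Mean framewise displacement (Power) and mean relative RMS
   displacement from the rigid-body realignment parameters, plus the
   2.5 mm / 2.5° inclusion gate.

Because the motivating study's raw scans are not publicly deposited, the
package also ships a first-class synthetic cohort generator
(`costnet.synthetic`): Watts–Strogatz small-world templates with group
effects planted as edge-weight multipliers (global attenuation in both
patient groups; decreased basal-ganglia-like and increased frontal/parietal
nodal weights in the depressed group), Gaussian time series with the
template-derived covariance, published-table phenotype distributions, and
gated motion traces.  Every pipeline stage can therefore be exercised against
known ground truth.

## Worked example

```bash
costnet synthesize --out demo/cohort --seed 5 --n-per-group 4,3,3
cat > demo/config.yaml <<EOF
cohort_dir: demo/cohort
out_dir: demo/run
cost_min: 0.10
cost_max: 0.20
cost_step: 0.05
metrics: [global_efficiency, local_efficiency, nodal_efficiency, nodal_degree]
EOF
costnet run-all --config demo/config.yaml
```

prints

```
wrote 10 subjects to demo/cohort
run complete: demo/run
```

and `demo/run/` then contains the per-stage TSVs (`connectivity/`,
`metrics.tsv`, `auc.tsv`, `omnibus.tsv`, `posthoc.tsv`, …), a provenance
`manifest.json`, and `report.txt`.  In the report, the
"Global metrics: pairwise post-hoc" section lists rows such as

```
           metric  node        pair  t_stat   p_raw  p_bonferroni  direction  family_size
global_efficiency   NaN  D-AD vs NC   -3.74 0.01344       0.04031         -1            3
 local_efficiency   NaN  D-AD vs NC  -6.543 0.001249      0.003746         -1            3
```

meaning the depressed patient group's AUC global efficiency is significantly
lower than the controls' (direction −1 = first group minus second group is
negative) after Bonferroni correction over the three group pairs — the
planted control-versus-patient efficiency gap, recovered even at this demo's
tiny sample size.  Re-running with the same config reproduces the output
directory byte for byte.

The same analysis is available as a library:

```python
from costnet.synthetic import CohortSpec, simulate_cohort
from costnet.analysis import cohort_auc_table, cohort_phenotype_frame
from costnet.inference import posthoc_pairwise

cohort = simulate_cohort(CohortSpec(seed=0))        # 24/20/20 subjects
aucs = cohort_auc_table(cohort)                     # AUC per metric and node
post = posthoc_pairwise(aucs, cohort_phenotype_frame(cohort))
```

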