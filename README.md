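# neurocpm

Connectome-predictive modelling (CPM) of behavioral self-regulation in
children, for researchers studying brain–behavior relationships in
multi-site pediatric resting-state fMRI cohorts (e.g. typically developing
children and children with Autism Spectrum Disorder, whose parent-report
behavioral-regulation scores span a wide dimensional range).

## What it does

Given per-participant node timecourses (or ready-made connectivity
matrices) and a phenotype table, the package:

1. **Builds functional connectomes** — for each pair of parcellation nodes
   *i, j* (268-node whole-brain atlas by default), the edge value is the
   Fisher-transformed Pearson correlation of their mean BOLD timecourses,
   `z_ij = atanh(r_ij)` (|r| clamped at 1 − 1e−7 so every edge is finite).
2. **Applies participant exclusion rules** — missing behavior, parent-report
   inconsistency score > 7, head motion > 4 mm maximum absolute
   displacement, and behavioral scores > 3 SD from the sample mean
   (per-measure).
3. **Masks confounded edges** — edges correlated with z-scored head motion
   (Pearson, p < 0.05) or different between acquisition sites (Welch t,
   p < 0.05) are removed before any modelling.
4. **Selects and summarizes edges** — every surviving edge is correlated
   with the z-scored behavioral score over the training sample; edges with
   p < 0.01 are kept, split by correlation sign into a *positive* and a
   *negative* network, and summed per participant into a scalar network
   strength `s = Σ z_ij`.
5. **Fits and cross-validates a linear model** — OLS from network strength
   to behavior, evaluated by the Spearman correlation r_s between observed
   and predicted scores under leave-one-out, stratified split-half, and
   site-to-site cross-validation (selection and fitting are redone inside
   every training fold).
6. **Tests significance by permutation** — behavior is shuffled n_perm
   times (5000 by default) and the *entire* pipeline re-run per shuffle;
   `p = (1 + #{null r_s ≥ observed r_s}) / (n_perm + 1)`.
   The parametric p of the LOO r_s is used only as a follow-up gate
   (fold dependence makes it anticonservative).
7. **Checks specificity** — per-diagnosis-group evaluation, cross-domain
   correlation tables (motion, IQ, social-symptom scores, the other
   behavioral domains, age) Bonferroni-corrected at 0.05/7, and rank-based
   partial correlations controlling for diagnosis.

A seeded synthetic multi-site cohort generator (`neurocpm.simulate`)
emulates the statistical structure of a 276-child two-site cohort — planted
behavior-coupled edges (negative tail), motion-coupled edges, site-shifted
edges, group-shifted T-scores — so the full pipeline is testable end to end
without any imaging download.

## Worked example

```python
import neurocpm as nc

# a seeded 90-node synthetic cohort with the default planted structure
cfg = nc.SimulationConfig(node_count=90, seed=7)
cohort = nc.generate_cohort(cfg)
ds = cohort.to_dataset()

result = nc.analyze(ds, measure="inhibit", tail="negative",
                    config=nc.AnalysisConfig(n_perm=500), seed=7)
print(f"retained n = {result.loo.n}, "
      f"valid edges = {result.mask.n_valid}/{result.mask.valid.size}")
print(f"LOO Spearman rs = {result.loo.rs:.3f} "
      f"(parametric p = {result.loo.p_parametric:.2e})")
print(f"permutation p = {result.permutation.p_perm:.4f} "
      f"({result.permutation.n_perm} shuffles)")
```

prints

```
retained n = 276, valid edges = 3155/4005
LOO Spearman rs = 0.913 (parametric p = 1.97e-108)
permutation p = 0.0020 (500 shuffles)
```

The cohort passes the exclusion rules untouched (n = 276); 850 of the 4005
edges are removed by the motion and site masks; the negative-tail network
predicts the held-out inhibition T-scores at r_s = 0.91 (the planted effect
spreads over 120 edges, so the summed network strength is a strong
predictor), and none of the 500 shuffled pipelines reaches the observed
r_s except by the +1 in the numerator — the permutation p is at its lattice
minimum, 1/501.

The same analyses are available from the shell:

```bash
neurocpm simulate --out-dir fixtures/ --seed 7 --node-count 90
neurocpm loo --phenotype fixtures/phenotype.csv --fc-dir fixtures/ \
             --measure inhibit --tail negative --out inhibit_loo.json
neurocpm permute --phenotype fixtures/phenotype.csv --fc-dir fixtures/ \
                 --measure inhibit --tail negative --n-perm 5000 --seed 7 \
                 --out inhibit_perm.json
```

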