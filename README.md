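# fclustfd

Fuzzy k-medoids clustering of longitudinal symptom-diary data via
penalized B-spline functionals.

Daily mobile-health diaries for allergic rhinoconjunctivitis record six
symptom intensities (0–3) and a rescue-medication category (0–3) per
patient per day. Such data are noisy, gappy, and yet carry clear
seasonal structure driven by pollen exposure. `fclustfd` implements the
full analysis chain for finding groups of patients with similar symptom
courses:

1. **Scoring** — ARTSS (mean of the six symptoms), RMS (medication
   category), CSMS = ARTSS + RMS ∈ [0, 6], normalized to [0, 1].
2. **Preprocessing** — exclude patients with more than 37.5 % missing
   days and degenerate (zero-variance) recorders; impute leading,
   trailing and interior gaps by carrying/linear interpolation.
3. **Smoothing** — each series becomes a functional
   x_i(t) = Σ_p c_ip φ_p(t) in a shared B-spline basis (q interior
   knots, order m, dimension s = q + m), fitted by penalized least
   squares SSE + λ∫(D²x)²dt; the cohort-wide (q, m, λ) minimizes
   TGCV(q, m) = Σ_i GCV_i with λ = 10^g searched over g ∈ [−30, 20].
4. **Clustering** — fuzzy k-medoids on the coefficient matrix **C**:
   minimize Σ_i Σ_l u_il^f d²(c_i, h_l) with prototypes h_l constrained
   to observed units, memberships u_il on the simplex, fuzziness
   f = 1.5; multi-start alternating optimization.
5. **Validation** — number of clusters chosen by the fuzzy silhouette
   FS(k) = Σ_i (u_ig − u_ig′)^γ s(i) / Σ_i (u_ig − u_ig′)^γ; partition
   agreement by the adjusted Rand index.
6. **Pollen association** — the ARp index: one-sided permutation
   Spearman tests between patient and pollen spline coefficients;
   significant correlations normalized per patient so ARp ∈ [0, 1].

The clustering and smoothing stages are scikit-learn estimators
(`FuzzyKMedoids`, `FuzzyKMeans`, `PenalizedBSplineSmoother`) and compose
with sklearn pipelines; every stage is also available as a plain
function and as a `fclustfd` CLI subcommand (`simulate`, `score`,
`preprocess`, `fit`, `cluster`, `validate`, `associate`, `pipeline`).

## Worked example

Generate a synthetic 60-patient cohort with three planted clusters
(severe, mild, pollen-tracking) and run the whole pipeline:

```python
import fclustfd as fc

design = fc.CohortDesign(patients_per_cluster=20, n_days=40, seed=11)
records, truth, pollen = fc.generate_cohort(design)

config = fc.PipelineConfig(q_options=(10, 15), m_options=(4,),
                           k_range=(2, 3, 4), n_perm=999, seed=11)
result = fc.run_pipeline(records, config, pollen=pollen)

print("retained patients:", result.cohort.n_patients)
print(result.grid.table.to_string(index=False))
print("selected k:", result.selected_k)
print(result.arp_summary.round(2).to_string())
```

Output:

```
retained patients: 60
           model_label  m  q   lambda     TGCV
B-splines 3.54545-days  4 10 7.943282 0.166501
 B-splines 2.4375-days  4 15 7.943282 0.166221
selected k: 3
           mean_ARp_Gramineae  mean_ARp_Olea  mean_ARp_Urticaceae  pct_ARp1_Gramineae  pct_ARp1_Olea  pct_ARp1_Urticaceae
cluster_1                0.03           0.02                 0.10                0.00            0.0                 10.0
cluster_2                0.48           0.45                 0.07                0.00            0.0                  0.0
cluster_3                0.07           0.02                 0.06                5.00            0.0                  5.0
Total                    0.19           0.16                 0.08                1.67            0.0                  5.0
```

All 60 simulated patients survive the missingness cut-off. The
grid search picks the 15-knot cubic model (lowest TGCV, 0.1662) with a
shared λ ≈ 7.94, and the fuzzy silhouette peaks at k = 3
(FS = 0.95 against 0.81 at k = 2), recovering the three planted
clusters. In the ARp table, cluster 2 — the pollen-tracking group — has
by far the highest membership-weighted mean ARp for Gramineae (0.48 vs
0.03/0.07), with the remainder of its association mass on Olea, whose
simulated season overlaps the Gramineae one; the flat-symptom clusters
show only the background rate of spurious significances.

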