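# tmepipe

Tumor-microenvironment (TME) image-feature analysis for lung adenocarcinoma:
from nuclei centroid maps of H&E slides to a prediction of survival benefit
from EGFR tyrosine-kinase-inhibitor (TKI) therapy, and on to the gene
programs associated with the predictive features.

The package is for computational pathology and biostatistics groups who
have per-nucleus classification output (position + one of six cell classes:
tumor, stroma, lymphocyte, red blood cell, macrophage, karyorrhexis) and
want a tested, reproducible implementation of the downstream analysis:

1. **Image features** — the slide's tumor region is the set of 500×500 px
   tiles with ≥ 10 tumor nuclei; up to 100 patches of 1024×1024 px are
   sampled from it. Per patch, six cell densities and six Delaunay-graph
   interaction fractions

   `I(tumor, X) = #edges(tumor–X) / #edges incident to a tumor cell`

   are computed and averaged to slide and patient level, along with the
   tumor/stroma ratio (TSR).
2. **Survival-benefit model** — an elastic-net-penalized Cox model of
   overall survival on the 12 features, fitted on TKI-treated patients
   (`BenefitCoxModel.fit() → BenefitCoxResults`). The risk score Σβⱼfⱼ is
   dichotomized at the cohort median into predicted-to-benefit /
   predicted-not-to-benefit; validation uses Kaplan–Meier/log-rank and a
   multivariate treatment-by-group interaction Cox model adjusted for age,
   sex, smoking status and surgery. Interaction-fraction effects are
   reported per 10-percentage-point increment, HR₁₀ = exp(0.1 β).
3. **Image-genomics** — genes with > 20% zeros removed, per-gene Spearman
   rho against an image feature, preranked GSEA on the rho-ordered list
   (weighted KS running sum, gene-label permutations, BH adjustment), a
   patient-ID-shuffle negative control, and marker-panel summaries.
4. **Synthetic data** — generators for cell maps (tumor nests with a
   stroma-mixing dial θ), proportional-hazards cohorts with planted
   effects, and expression matrices with planted gene–feature correlations,
   so the whole pipeline is testable without clinical data.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Run the bundled synthetic study — 80 patients, one slide each, per-patient
stromal mixing θ ~ U(0,1), survival simulated with protective tumor–tumor
(per-10% HR 0.73) and harmful tumor–stroma (per-10% HR 1.53) effects:

```bash
tmepipe run --config configs/synthetic_study.yaml
cat out/synthetic_study/evaluation.json
```

```json
{
  "logrank_chi_square": 6.75,
  "logrank_p": 0.0094,
  "group_sizes": {"predicted_not_to_benefit": 20, "predicted_to_benefit": 21},
  "interaction_hr": 0.102,
  "interaction_ci": [0.027, 0.381],
  "interaction_p": 0.00069,
  "n": 80,
  "n_events": 59
}
```

Among the simulated TKI-treated patients, the predicted-to-benefit group
survives significantly longer (log-rank p ≈ 0.009), and the
treatment-by-group interaction HR of 0.10 (p ≈ 7×10⁻⁴) says treatment is
associated with a far lower hazard in the predicted-to-benefit group than
in the other — the model separates benefiters from non-benefiters on data
where such structure truly exists. `out/synthetic_study/` also holds the
feature table, the serialized model with its coefficients, per-patient risk
scores and groups, KM curve tables, the gene ranking and the enrichment
table (the planted gene set tops it). Exact numbers depend on the seed in
the config; every artifact is reproduced byte-for-byte on rerun.

The same stages are available as a library (see `tmepipe.features`,
`tmepipe.survival`, `tmepipe.genomics`, `tmepipe.simulate`) and as CLI
subcommands `features | fit | predict | evaluate | gsea | simulate | run`.

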