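# mirlink

Integrative miRNA–mRNA expression analysis for quiescent versus activated
hepatic stellate cells (HSCs), built as a reusable, tested pipeline.

Quiescent HSCs (qHSCs) are the vitamin-A-storing pericytes of the healthy
liver; on fibrogenic injury they activate into collagen-producing
myofibroblast-like cells (aHSCs). Because miRNAs repress their target mRNAs,
a miRNA that is high in qHSCs and anticorrelated with activation-induced
genes is a candidate suppressor of activation. `mirlink` finds such miRNAs
by combining three sources of evidence for every miRNA–gene pair:

1. **Differential expression.** miRNA abundance comes from TaqMan-array Ct
   values normalized to RNU6 (−ΔCt = −(Ct_miRNA − Ct_RNU6), a log2 scale);
   genes come as log2 intensities. Genes are called qHSC-specific when they
   are ≥2-fold above both hepatocytes and LSECs in qHSCs and ≥1.5-fold down
   on activation; activation-induced genes need ≥2-fold enrichment in aHSCs
   and a significant (Student t-test, p ≤ 0.05) up-regulation. miRNAs use a
   1.5-fold cut for down- and a 2-fold cut for up-regulation, both with
   p ≤ 0.05.
2. **Negative correlation.** Every deregulated miRNA is Pearson-correlated
   with every deregulated mRNA across the shared HSC samples; the two-sided
   p-values form one family for Benjamini–Hochberg adjustment.
3. **Sequence-based prediction.** Each pair's p_database from a
   MicroCosm-style target-prediction table.

A pair is called *functional* when FDR < 0.05, r < 0 and p_database < 0.05.
The network summaries then report targets per miRNA, the quiescence panel
(miRNAs with > 6 functional targets), per-class target statistics, and the
fraction of activation-induced genes covered by the panel.

A synthetic-data module generates the full study design (paired
quiescent/activated donors, hepatocyte and LSEC reference samples, a planted
repression network, and a prediction table with controllable sensitivity and
false-positive rate), so the entire pipeline is testable without external
data. The bundled 31-row quiescence panel table ships as packaged data in
as-printed and normalized forms.

## Worked example

Run the synthetic demo end to end (library or CLI — `mirlink run-all --out out/`):

```python
from mirlink import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=1))
res = run_pipeline(cfg, out_dir="out")
print("selected pairs:", res.report["n_selected_pairs"])
print("precision:", round(res.evaluation["precision"], 3),
      "recall:", round(res.evaluation["recall"], 3))
print(res.report["class_target_stats"][0])
```

prints

```
selected pairs: 402
precision: 0.841 recall: 0.904
{'class_label': 'q_associated', 'n_mirnas': 20, 'mean_targets': 14.95,
 'sd_targets': 2.72..., 'mean_targets_nonzero': 14.95, ...,
 'pct_above_panel_min': 100}
```

i.e. with 4 donor pairs, 20 quiescence miRNAs averaging 15 planted targets,
3-log2 effects and 0.25-sd noise, the three-filter selection recovers 90% of
the planted repressive pairs at 84% precision, and the recovered
targets-per-miRNA statistics match the planted design. `out/` holds every
intermediate table (−ΔCt matrix, differential table, full and selected pair
tables, panel, JSON summary report) plus the simulation truth sidecar.

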