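# priism

Frequency-domain recomposition of circadian time-series gene expression.

A large fraction of a plant genome oscillates under control of the circadian
clock, and abiotic stresses (cold, heat, drought) disrupt those oscillations —
damping amplitudes, shifting phases, lengthening periods. Fold-change-based
discovery of stress-response genes then confuses two very different things: a
gene genuinely upregulated by the treatment, and a clock-controlled gene whose
rhythm merely slipped out of sync between conditions. `priism` separates them.

Each gene's expression time course (log-scale, per condition) is split into
three independent expression patterns:

- **treatment component** — frequencies below the clock band: the slow,
  adaptive response to the treatment;
- **clock component** — the circadian clock frequency range (CCFR), located
  from the spectra of the core clock genes (in *Arabidopsis*: *CCA1*, *LHY*,
  *PRR7*, *PRR9*, *ELF4*, *GI*, *LUX*, *TOC1*);
- **noise component** — everything above the clock band.

## Method

The time course is interpolated onto a uniform grid (cubic B-spline),
segmented into overlapping frames aligned with the light/dark cycle (a 26-h
first frame, then 24-h frames starting at each light/dark transition), and
mean-shifted per frame so the DC bin vanishes. Within each frame the discrete
Fourier transform

$$G_n = \sum_{k=0}^{K-1} g(kT)\, e^{-i 2\pi nk/N}, \qquad n = 0,\dots,N-1$$

produces the spectrum. Frequency bins where a core clock gene's relative
amplitude exceeds 0.7 are *dominant*; the union over the clock genes defines
the CCFR $[f_{c\_min}, f_{c\_max}]$. Within it, each bin's weight is the
clock genes' summed power, min–max normalized:

$$w_n = \frac{\sum_m |G_{mn}|^2 - \min(\mathcal{G})}{\max(\mathcal{G}) - \min(\mathcal{G})}$$

The spectrum is partitioned into treatment ($[0, c_{min}-1]$), clock
($[c_{min}, c_{max}]$, scaled by $w_n$ — a tapering band-pass) and noise
(the remainder) bands, each closed under the conjugate mirror $n \mapsto N-n$.
Inverse-transforming each band gives three zero-mean series per frame; the
removed frame mean is added back in proportion to each band's share of the
spectrum's power (DC bin included, so most of the baseline returns to the
treatment component). Frames are blended with centre-weighted triangular
weights into full-length component series that sum exactly to the original.

Downstream, genes are ranked by fold change (treatment − control, log scale) —
its maximum over time or its value at a chosen timepoint — or by distance in a
PCA score plot, and scored against a gold-standard list by an ROC walk whose
headline number is the recall at the rank where true positives equal false
positives.

## Worked example

```python
from priism import PriismDecomposer, fold_change, rank_genes, roc
from priism.synthdata import SimConfig, simulate

control, treatment, truth = simulate(SimConfig(seed=1))  # 200 genes, 30 planted responders
parts = {}
for label, m in (("control", control), ("treatment", treatment)):
    dec = PriismDecomposer().fit(m)          # learns per-frame clock vectors
    parts[label] = dec.transform(m)          # {'treatment','clock','noise'}
print(dec.clock_vector_table().to_string(index=False))

fc = fold_change(parts["control"]["treatment"], parts["treatment"]["treatment"])
rl = rank_genes(fc, "fc_at_time", at_time_h=26.0)
result = roc(rl, set(truth.responder_ids))
print(f"recall at TP=FP: {result.recall_at_tp_eq_fp:.2f}")
```

prints

```
condition  frame  c_min  c_max weights  f_min_cpd  f_max_cpd
treatment      0      1      1       1   0.923077   0.923077
treatment      1      1      1       1   1.000000   1.000000
treatment      2      1      1       1   1.000000   1.000000
treatment      3      1      1       1   0.923077   0.923077
recall at TP=FP: 1.00
```

The clock vector table shows the learned clock band sitting at one cycle per
day in every frame of the treatment condition, and ranking genes by their
treatment-component fold change at the 26-hour response peak recovers all 30
planted responders before true positives are overtaken by false positives.

The same pipeline is available from the shell:

```sh
priism simulate --outdir sim/
priism decompose --control sim/control.tsv --treatment sim/treatment.tsv --outdir parts/
priism evaluate --control sim/control.tsv --treatment sim/treatment.tsv \
    --gold sim/gold.txt --statistic max_fc --out ranked.tsv
```

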