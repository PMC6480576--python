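# datquant

Quantification of striatal dopamine-transporter (DAT) SPECT scans for
Parkinson's disease staging, plus a digital phantom to exercise the whole
analysis without patient data.

In DAT imaging (e.g. ⁹⁹ᵐTc-TRODAT-1 SPECT) the striatum is the hottest
structure in the brain, and both its activity volume and the shape of the
whole-brain count histogram change as the disease progresses.  `datquant`
implements the full chain:

1. **Phantom simulation** — ellipsoidal brain with two bilateral striatal
   ellipsoids whose size and peak uptake fall with stage (healthy / mild /
   severe), Gaussian reconstruction blur, Poisson counting noise, and
   per-subject biological jitter.
2. **Segmentation** — whole-brain ROI by a single count threshold
   (default 15, strict `>`), and the striatal region by 3D seed region
   growing: seed at the global count maximum, neighbours join while their
   count stays ≥ 50% of the seed count (26-connectivity by default).
3. **Features** — six per-subject statistics.  From the whole-brain
   sample x₁…xₙ (mean x̄, median Md, sample SD):

   | feature | formula |
   |---|---|
   | SK  | [Σ(xᵢ−x̄)³/(n−1)] / [Σ(xᵢ−x̄)²/(n−1)]^(3/2) |
   | KUR | [Σ(xᵢ−x̄)⁴/(n−1)] / [Σ(xᵢ−x̄)²/(n−1)]² |
   | CSK | (n_below − n_above)/n_total |
   | MES | 3(x̄ − Md)/SD |

   and from the grown striatal region: DTAV (region volume, mL) and DTAM
   (region count maximum).
4. **Group statistics** — descriptive stats with t-based 95% CIs,
   Mann–Whitney U, tie-corrected Kruskal–Wallis, Dunn–Bonferroni post hoc.
5. **Classification** — multinomial logistic regression and RBF-kernel SVM
   on the variable groups SK, KUR, FAV={DTAV}, FAD={SK,KUR},
   FADV={SK,KUR,DTAV}, evaluated on a single 50/50 split with a full
   validity panel: sensitivity, specificity, PPV, NPV, accuracy,
   one-vs-rest rank AUC and Cohen's kappa.

## Worked example

```python
from datquant import PhantomParams, generate_phantom, compute_features

lv = generate_phantom("mild", PhantomParams(), seed=42)
fv = compute_features(lv.volume)
for k, v in fv.as_dict().items():
    print(f"  {k:5s} = {v:8.3f}")
```

prints

```
  SK    =    1.223
  KUR   =   12.426
  CSK   =   -0.229
  MES   =   -0.577
  DTAV  =   19.575
  DTAM  =  330.000
```

The mild-stage phantom's brain histogram is right-skewed (SK > 0) and
leptokurtic (KUR > 3) because the striatal hot region adds a high-count
tail; the grown striatal region measures 19.6 mL (the configured mild
bilateral volume is 15.8 mL — growth at 50% of max slightly dilates the
boundary at mild contrast), and DTAM is the 330-count striatal peak.
Healthy phantoms give larger DTAV and more positive SK, severe ones
smaller and near-zero/negative, so cohort means are strictly ordered
healthy > mild > severe in both features.

The same pipeline runs from the shell:

```bash
datquant simulate --n 10 10 10 --seed 7 --out runs/sim
datquant extract --manifest runs/sim/manifest.csv --out runs/features.csv
datquant stats --features runs/features.csv --out runs/stats.json
datquant classify --features runs/features.csv --seed 0 --out runs/validity.json
# or everything at once, simulating inline:
datquant run-all --n 30 30 30 --seed 0 --out runs/full
```

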