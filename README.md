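# methgrad

Analysis pipeline for linking per-cytosine DNA-modification densities to a
within-cell-type transcriptional gradient, modelled on the lactase (*Lct*)
gradient of mouse villi enterocytes along the nine segments of the small
intestine.

Enterocytes are histologically identical along the gut, yet *Lct* mRNA rises
from the duodenum to a peak in the proximal jejunum (segment 3) and then
declines steadily to the distal ileum (segment 9).  `methgrad` asks whether
per-cytosine DNA modification densities — measured by targeted bisulfite
sequencing over the *Lct*–*Mcm6* locus — track that gradient, and whether age
(infant P6 vs adult P60/P90) and diet (lactose-containing vs lactose-free
milk after weaning) reshape both.

It is written for epigenomics analysts who have per-cytosine count tables
(methylated reads / total reads per site and sample) rather than raw reads.

## What it computes

For every cytosine *i* with density vector $d_i$ across samples and relative
mRNA $e$:

* **Density**: $d = m/t$ kept only where total reads $t > 30$; sites with
  group-mean density $> 90\%$ can be masked (saturation filter).
* **Association**: Pearson $r_i = \mathrm{corr}(d_i, e)$, two-sided $p_i$
  from $t = r\sqrt{(n-2)/(1-r^2)}$, reported as the signed log p
  $\mathrm{SLP}_i = \mathrm{sign}(r_i)\,(-\log_{10} p_i)$, Bonferroni-adjusted
  over the tested universe $m$ (significance at $p_{\text{adj}} < 0.01$).
* **Clusters**: maximal runs of $\ge 3$ significant cytosines with
  consecutive gaps $\le 500$ bp and a common correlation sign.
* **Contrasts**: per-cytosine group deltas (adult − infant; lac− − LAC+)
  with Welch t-tests on per-mouse densities, LOESS-smoothed positional delta
  curves, and one-way / factorial (Type II) / repeated-measures ANOVA with
  Tukey HSD for region summaries.
* **Expression**: relative mRNA by $2^{-\Delta\Delta C_t}$ against an
  endogenous control and a segment-3 reference group.
* **ChIP-qPCR**: percent input
  $100 \cdot f \cdot 2^{C_t^{\text{input}} - C_t^{\text{IP}}}$ for input
  fraction $f$, with matched-IgG subtraction floored at zero.

A synthetic-data module simulates the whole experiment (negative-binomial
coverage, binomial methylated reads, planted clusters) with named scenarios
whose planted effect sizes are the recovery targets: GRAD-1 (cluster density
34.7% at segment 3 rising to 77.1% at segment 9), AGE-1 (+30/+18/+12
percentage-point adult gains at segments 7/1/3), DIET-1 (5.2/4.7/3.6/6.4 pp
lactose-induced decreases) and NULL-1 (no link; type-I calibration).

## Worked example

```sh
methgrad run-all --scenario GRAD-1 --seed 1 --out out/
```

simulates the full locus (7,580 cytosines, 609 CpG; 9 segments x 6 mice),
computes densities, associates every cytosine with the simulated mRNA
gradient, and calls clusters.  The log reports:

```
coverage filter (>30 reads): 21142/409320 cells missing
testing universe m=7580; significant sites=18
cluster calls: 1
```

and `out/assoc/clusters.bed` contains the single recovered call:

```
chrLct	16673	17100	chrLct:16674-17100	18	-
```

i.e. one negative-direction cluster of 18 CpGs — exactly the planted C1
cluster whose density runs inversely to the mRNA gradient.  The same library
calls are available in Python:

```python
import methgrad as mg

ds = mg.simulate_scenario("GRAD-1", seed=1)
dm = mg.compute_density(ds.counts)                      # >30-read filter
mrna = ds.expression.set_index("sample")["rel_mrna"]
res = mg.associate_sites(dm, mrna)                      # r, p, SLP, Bonferroni
calls = mg.detect_clusters(res)                         # >=3 sites / 500 bp
```

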