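# senhic

Multi-layer analysis of 3D genome architecture from Hi-C contact maps,
built for studies of cellular senescence — where chromatin typically
decompacts, compartmentalization weakens, TADs destabilize and loops
are lost — and validated end to end on synthetic maps with planted
ground truth.

## Who it is for

Computational genomicists comparing chromatin architecture between
conditions (e.g. proliferating vs senescent cells) from binned
intra-chromosomal contact matrices. The package covers the full
analysis ladder:

| layer | what is computed |
|---|---|
| matrix | ICE balancing, observed/expected, contact probability P(s) and its decay exponent, exact down-sampling, effective resolution, cis fraction |
| compartments | PC1 A/B calling, switch classification, saddle-plot strength, distance-stratified interval-pair strength (<10 Mb / 10–30 Mb / >30 Mb) |
| TADs | insulation score and boundaries, TAD calling, aggregate TAD analysis, consolidation score CS, intra-TAD connectivity iTC, degree of disorder DoD, two-pass Mahalanobis differential TADs, rearrangement classification (unchanged/shift/split/merge/complex), proportional compartment assignment |
| loops | donut-background loop calling (FDR 0.1), aggregate peak analysis, length/compartment/switch/TAD/CTCF/enhancer–promoter annotation, differential loops (`cacut`/`cmcut`) |
| DCIs | cyclic-loess joint normalization, exact per-pixel tests (log2 CPM > 2, \|log2 FC\| > 1.2, adj. p < 0.05, span ≤ 2 Mb), per-TAD down-fraction summaries with covariate Spearman correlations, Fisher and logistic enrichment |
| 3D | stress-minimization embedding of a region, focus-locus Euclidean distance profiles with paired Wilcoxon comparison |
| simulation | planted decay/compartments/TADs/loops/biases, condition pairs with controlled perturbations, matched accessibility/CTCF/peak/gene tracks |

The core quantities follow the field's standard definitions: PC1 is the
leading eigenvector of the Pearson-correlation matrix of the O/E map;
saddle strength is the intra-corner over inter-corner mean of the
PC1-decile O/E matrix; the insulation score of bin *i* is
log2(mean of the *w×w* square upstream×downstream of *i* / chromosome
mean); iTC = intra-TAD mass / (intra + one-end-in-TAD mass);
loop significance requires a Poisson upper tail against donut,
lower-left, horizontal and vertical local expectations simultaneously.
The synthetic intensity model is

```
lambda_ij = B_i B_j (|i-j| b)^(-alpha) exp(c_eff p_i p_j) (1 + e_T 1[same TAD]) (1 + f_L K_ij)
```

so every analysis layer can be checked by recovering the parameter it
targets (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from senhic import simulate as sim, matrix as mx, domains as dom, loops as lp

cfg = sim.loop_config(seed=1)              # 20 Mb @ 10 kb, 8 TADs, 24 loops
cm, truth = sim.simulate_matrix(cfg)       # Poisson counts, 30M contacts
bal = mx.ice_balance(cm, mask_fraction=0.0)

print(round(mx.contact_decay(cm).slope, 3))
ins = dom.insulation(bal, window_bp=500_000)
tads = dom.call_tads(ins, min_tad_bins=20)
print(len(tads), "TADs at", [int(b) for b in ins.boundaries])
calls = lp.call_loops(cm, bal)
apa = lp.apa(bal, calls)
print(len(calls), "loops, APA center", round(apa.center_enrichment, 2))
```

prints

```
-1.232
8 TADs at [260, 487, 747, 1006, 1241, 1498, 1734]
25 loops, APA center 3.54
```

The fitted slope is steeper than the planted exponent α = 1 because the
1–10 Mb fit range overlaps the ~2.5 Mb TADs, whose intra-domain
enrichment adds short-range mass (on a TAD-free genome the same fit
returns −1.00 ± 0.01). The seven called boundaries are exactly the
seven planted interior boundaries, recovering the 8 planted TADs; 25
loops are called with 24 planted, and the aggregate peak analysis
center enrichment of 3.5 reflects the planted focal strength f_L = 2
(peak multiplier 3) concentrated by the Gaussian dot.

A full synthetic validation run over every stage:

```bash
senhic run-all --seed 1 --outdir senhic_run
```

writes balanced matrices, PC1/insulation bedGraphs, TAD/loop/DCI tables
and a `manifest.json`.

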