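# celltag-demux

Sample demultiplexing for pooled single-cell experiments labeled with
**CellTag Indexes** — heritable 8-nt DNA barcodes expressed as polyadenylated
transcripts from the 3′ UTR of a lentiviral GFP construct. Each sample in a
pool is transduced with one predefined index tag before mixing; after
sequencing, every cell's tag UMI counts reveal its sample of origin. This
package takes you from tagged reads to per-cell sample labels:

1. **extract** — find the tag inside its constant flanking motif on each read
   and build a UMI-deduplicated cell × tag count matrix;
2. **collapse** — merge sequencing-error variants onto abundant centroid
   sequences by sphere clustering;
3. **classify** — the core *dynamic binarization* classifier assigning each
   cell a singlet tag, a multiplet call, or non-determined;
4. **occupancy** — a randomized test for per-cluster enrichment or depletion
   of a tagged population;
5. **simulate / evaluate** — a synthetic-data generator with ground truth,
   and metrics against it.

It is written for anyone multiplexing samples with expressed barcodes —
species-mixing controls, competitive transplants, or any pooled design where
genetic background cannot distinguish the samples.

## The classifier

Let `x_ij` be the UMI count of index tag `j` in cell `i` over the selected
tags. Counts are log-normalized per cell,

```
C_ij = ln(1 + s · x_ij / Σ_j x_ij)        (scale s = 10 by default)
```

so that `C` reflects tag composition rather than depth. For each tag `j` a
Gaussian kernel density `D_j` (Scott's bandwidth, fitted across all cells,
draws clamped at 0) models its expression. Cell `i` is scored against the
tag's population by the sampled proportion

```
P_ij = |{ s ∈ S : s ≥ C_ij }| / |S| ,   S = 1000 draws from D_j ,
```

averaged over 50 independent rounds. A small `P_ij` places the cell in the
upper tail of tag `j`'s expression — a significant signal. Per cell, with
`m = min_j P_ij`:

- `m ≥ 0.762`, or no tag counts at all → **NonDetermined**;
- otherwise `T = { j : P_ij − m ≤ δ }` with baseline cutoff `δ = 0.238`;
  one member → **Singlet** of that tag, two or more → **Multiplet** of `T`.

The number of multiplets is compared with the droplet-loading expectation
`multiplet % = 0.0007589 · n_cells + 0.0527214`; when calls exceed 1.5× the
expected count, an optional checkpoint retains only the most multiplet-like
calls (smallest gap between the two lowest proportions) and returns the rest
to their minimum tag.

## Worked example

```python
from celltag_demux import CellTagDemux, SimConfig, evaluate, simulate_count_matrix

cfg = SimConfig(seed=1)                       # 2 samples x 5000 cells
matrix, truth = simulate_count_matrix(cfg)
model = CellTagDemux(matrix, expected_tags=["TGCTATAT", "GTTGGCTA"])
res = model.fit(seed=1)
print(res.summary())
```

```
CellTag demultiplexing results
==============================
cells:                  10000
tags:                   TGCTATAT, GTTGGCTA
singlets:               8273
multiplets:             1048
non-determined:         679
percent classified:     93.2%
expected multiplet %:   7.6417%
multiplet checkpoint:   not triggered
delta / nd threshold:   0.238 / 0.762
sampling:               1000 draws x 50 iterations (seed=1)
singlets per tag:
  GTTGGCTA: 4141
  TGCTATAT: 4132
```

8273 cells are confidently assigned to one of the two samples (4132 vs 4141 —
the pools were mixed in equal proportions), 1048 droplets show significant
signal from both indexes, and 679 cells carry too little tag signal to call
(the simulation transduces 90% of cells). Scoring against the generator's
ground truth:

```python
metrics = evaluate(res.classification, truth)
```

```
singlet_accuracy: 0.936        # true singlets called as exactly their tag
singlet_tag_recovery: 1.000    # true singlets whose label contains their tag
multiplet_recall: 0.943
non_determined_rate: 0.068
kappa: 0.890                   # Cohen's kappa vs truth, determined tagged cells
```

The same pipeline is available from the shell:

```bash
celltag simulate --seed 1 --reads --out sim/
celltag extract  --reads sim/reads.csv --flank5 GGTTAACTCGAG --flank3 GAATTCTAGCAA --out ext/
celltag collapse --matrix ext/matrix --max-dist 1 --out coll/
celltag classify --matrix coll/matrix --tags tags.txt --seed 1 --out cls/
celltag evaluate --classification cls/classification.csv --truth sim/truth.csv --out metrics.json
```

Every stage writes a `manifest.json` (parameters, seed, input checksums,
version) sufficient to re-run it exactly.

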