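# spanmrf

Marker-gene-informed probabilistic cell/spot-type assignment for spatially
resolved transcriptomics (SRT).

Unsupervised clustering pipelines for SRT data assign biological identities
only after the fact, by inspecting aggregated expression of anonymous
clusters; marker-based annotators built for dissociated single-cell data
(CellAssign, SCINA) use the marker information directly but ignore where
each spot sits in the tissue. `spanmrf` implements SPAN, a model that does
both: a negative-binomial mixture whose components are anchored to known
over-expressed marker genes, coupled to a hidden Markov random field (HMRF)
prior over the spot neighbor graph that encourages neighboring spots to
share a type. It is aimed at analysts of barcoded-array data (10x Visium,
classic ST) and imaging-based data (osmFISH, MERFISH) who have a curated
marker panel and want named, spatially coherent type assignments.

## Model

Counts of marker gene *g* at spot *i* under latent type *z_i = k* follow a
negative binomial,

    y_ig | z_i = k  ~  NB(mu_igk, phi_igk),
    log mu_igk = log s_i + delta_gk * rho_gk + beta_g0 + sum_p beta_gp x_ip,

with size factor *s_i*, binary marker indicator *rho* (gene *g* marks type
*k*), marker log fold change *delta_gk* > 0 (log-normal prior), base
expression *beta_g0*, and optional covariates *x_ip* such as one-hot batch
indicators. The inverse-dispersion *phi* (Var = mu + mu^2/phi) is tied to
the mean through a learned sum of radial basis functions. Labels carry a
Potts-like HMRF prior on the neighbor graph,

    p(z) ∝ exp( sum_k eta_k n_k − sum_{k<l} zeta_kl n_kl ),  zeta_kl > 0,

penalizing discordant neighbor pairs. Training pretrains the mixture by
MAP EM, then alternates (i) gradient updates of the mixture parameters
under the current hard labels, (ii) pseudolikelihood estimation of
(eta, zeta), and (iii) an iterated-conditional-modes (ICM) sweep assigning
each spot its locally optimal type, until fewer than 0.1% of labels change.

The package also ships a Splatter-style synthetic SRT generator (gamma gene
means, log-normal DE factors and library sizes, NB counts on layered spatial
domains, with spatial-noise / marker-corruption / batch-effect scenarios)
and the standard assignment metrics (accuracy, macro F1, multiclass MCC,
Hungarian label matching).

## Worked example

```python
from spanmrf import (SPANModel, SimConfig, simulate_dataset, marker_view,
                     score_assignment)

data = simulate_dataset(SimConfig(n_spots=400, n_genes=800, K=3, sigma=0.5, seed=7))
counts, markers = marker_view(data)          # counts restricted to the 42-gene panel
model = SPANModel(counts, markers, coords=data.coords)
result = model.fit(seed=7)
print(result.summary())
acc, f1, mcc = score_assignment(data.z_true, result.z)
print(f"accuracy {acc:.3f}  macro-F1 {f1:.3f}  MCC {mcc:.3f}")
```

Output:

```
SPAN spatial cell-type assignment
==============================================
spots: 400    types: 3
ICM iterations: 7    converged: True
final label-change fraction: 0.0000

type              n_spots    frac  mean conf      eta
type_0                133   0.333      0.997    0.000
type_1                133   0.333      0.995    0.003
type_2                134   0.335      0.992    0.084

pairwise smoothing zeta: mean 1.416  min 1.397  max 1.431
accuracy 0.995  macro-F1 0.995  MCC 0.993
```

The summary lists, per type, the number of assigned spots, their fraction,
the mean posterior confidence of those assignments, and the fitted external
field `eta`; the `zeta` line shows how strongly the fitted field penalizes
discordant neighbors. Here the three simulated bands are recovered almost
perfectly. `result.posterior` holds the per-spot assignment probabilities,
`result.mixture_params.delta` the fitted marker log fold changes, and
`result.save(outdir)` writes `labels.csv`, `posterior.csv` and
`params.json`.

The same pipeline is available from the shell:

```sh
span simulate --config sim.yaml --out data/
span fit --counts data/counts.mtx --genes data/genes.tsv \
    --barcodes data/barcodes.tsv --markers data/markers.csv \
    --coords data/coords.csv --platform st --out fit/
span score --truth data/truth.csv --pred fit/labels.csv
```

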