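# soilcnet

Analysis toolkit for a three-treatment soil incubation study design: how green
manure and biochar amendments change the composition of dissolved organic
carbon (DOC), the complexity of microbial co-occurrence networks, and
cumulative soil carbon mineralization — and how the first two drive the third.

## Scientific problem

A paddy-soil fertilization experiment compares three treatments — mineral
fertilizer only (`NPK`), mineral fertilizer + green manure (`GM`), and mineral
fertilizer + green manure + biochar (`GMC`) — with eight replicate pots each.
Three data streams are collected per sample:

1. **DOC fluorescence.** Excitation–emission matrices (EEMs) on an instrument
   lattice of excitation 200–450 nm (5 nm steps) by emission 250–600 nm (1 nm
   steps). After Raman-area normalization, blank subtraction and scatter
   excision, the spectra are summarized by the indices BIX, HIX and FI, and
   decomposed by non-negative PARAFAC into humic-like components
   (default peak geometry: C1 280/401 nm microbial humic acid-like,
   C2 355/443 nm and C3 275/468 nm terrestrial humic acid-like), validated by
   split-half Tucker congruence.
2. **Microbial communities.** Bacterial and fungal OTU count tables, analyzed
   by Bray–Curtis ordination (PCoA), PERMANOVA, and significant-Spearman
   co-occurrence networks (Benjamini–Hochberg adjusted p < 0.01) whose
   average clustering coefficient is the network-complexity proxy; Louvain
   modules get WGCNA-style eigengenes correlated against DOC variables.
3. **Carbon mineralization.** Alkali-trap titration during a 30-day
   incubation (openings on days 1, 3, 5, 7, 10, 15, 20, 25, 30), converted to
   cumulative CO2-C via the trap stoichiometry
   `CO2-C (mg/kg) = ΔV · M_HCl · 12.01 / 2 / m_soil`.

A driver analysis then attributes cumulative mineralization to DOC
characteristics versus network complexity with a permutation-tested random
forest (%IncMSE) and two-block variance partitioning.

Raw measurements for the original study are not publicly available, so the
package ships a calibrated synthetic generator (`soilcnet.synth`) that
reproduces the study's statistical structure with known ground truth: trilinear
EEM cubes with shared scatter backgrounds, planted correlation modules in the
OTU tables, treatment-silenced modules that order network complexity
GMC ≥ GM ≥ NPK, and titration records from decaying emission curves. Every
analysis is validated against this generator's truth.

## Worked example

```python
from soilcnet import synth
from soilcnet.eem import correct_eems, compute_indices
from soilcnet.parafac import fit_parafac
from soilcnet.mineralization import cumulative_mineralization

design = synth.SynthDesign(seed=7)              # 3 treatments x 8 replicates
cube, blank, truth = synth.gen_eem_dataset(design)
corrected = correct_eems(cube, blank)
model = fit_parafac(corrected, n_components=3, n_starts=4, seed=7)
print("explained variance:", round(model.explained_variance, 4))
print("emission peaks (nm):", model.em_peaks().tolist())

idx = compute_indices(corrected)
print(idx.groupby(idx.index.str.split("_").str[0])["BIX"].mean().round(3))

titr, _ = synth.gen_mineralization(design)
print(cumulative_mineralization(titr).treatment_summary().round(1))
```

Output (bit-reproducible for the fixed seeds):

```
explained variance: 0.9995
emission peaks (nm): [400.0, 443.0, 468.0]
sample
GM     0.599
GMC    0.708
NPK    0.626
Name: BIX, dtype: float64
             mean   se  n
treatment
GM         2927.6  2.1  8
GMC        3425.9  4.3  8
NPK        2589.3  4.8  8
```

The fitted emission peaks recover the generating 401/443/468 nm geometry, the
biochar co-incorporation treatment has the highest BIX (most
microbially-derived DOC), and cumulative mineralization orders
GMC > GM > NPK.

The same analyses are scriptable end to end:

```sh
soilcnet run --config config.yaml        # full pipeline from YAML
soilcnet simulate --seed 7 --out data/   # synthetic dataset + ground truth
soilcnet eem --samples data/eems --blank data/blank --out out/
soilcnet parafac --in out/corrected --components 3 --seed 7 --out out/parafac
soilcnet network --otu data/otu.tsv --meta data/metadata.tsv --seed 7 --out out/net
soilcnet mineralization --titration data/titration.tsv --out out/mz
```

A minimal pipeline config:

```yaml
seed: 7
output_dir: run_out
simulate: {}          # default study design; or provide `inputs:` paths
```

## Reproduction

`scripts/acceptance.py` runs the main computations on synthetic data under a
single seed and writes the headline quantities as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

On seed 1 this reports, among other quantities: PARAFAC explained variance
0.9993 with minimum Tucker congruence 0.99998 against the generating spectra,
split-half pass rate 1.0 on structured cubes and fail rate 1.0 on pure-noise
cubes, planted-module recovery ARI 0.907, a null significant-edge fraction of
0.0 at adjusted p < 0.01, PERMANOVA null rejection rate 0.02 at alpha 0.05,
and cumulative mineralization means 2580 / 2928 / 3423 mg/kg for
NPK / GM / GMC. Runtime is about 3 minutes on one CPU; all randomness derives
from `--seed`.

Model assumptions, parameter defaults and numerical choices are documented in
`docs/methods.md`.
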