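# gmnet

Single-subject grey matter networks and their association with longitudinal
cognitive decline.

## The problem

Patterns of grey matter morphology can be described as a network: many small
cortical regions (nodes) connected whenever their grey matter intensity
patterns are statistically similar within one individual's structural MRI
scan.  Graph theory then quantifies each brain's organization — and a shift
toward a *more random* topology (normalized clustering γ and normalized path
length λ moving toward 1) is a candidate early marker of neurodegeneration,
potentially preceding measurable cognitive impairment.

`gmnet` implements the full analysis chain for testing whether such network
parameters predict subsequent cognitive decline:

1. **Network extraction** — a grey matter density volume (native space,
   values in [0, 1]) is tiled into 3×3×3-voxel cubes; connectivity is the
   Pearson correlation of the 27 corresponding voxel intensities between
   cubes; cubes connect when their correlation exceeds a subject-specific
   threshold calibrated by a within-cube permutation scheme so that at most
   5% of retained connections are expected to be spurious.
2. **Graph parameters** — basic (network size, degree, connectivity density)
   and higher-order (clustering coefficient C, characteristic path length L,
   betweenness centrality) parameters, plus their normalized forms

   γ = C / ⟨C_rand⟩,  λ = L / ⟨L_rand⟩,  small-world = γ / λ,

   where ⟨·⟩ averages 20 degree-preserving (Maslov–Sneppen rewired)
   reference networks.
3. **Regional averaging** — nodal parameters averaged within the regions of
   an aligned integer parcellation (90 regions for an AAL-style atlas) for
   local tests.
4. **Cognitive preprocessing** — neuropsychological raw scores z-scored
   against the baseline distribution (timed tests sign-inverted so lower =
   worse), missing scores multiply imputed by chained equations (m = 15),
   and composite domain scores (attention, memory, executive, language,
   global cognition) formed as unweighted means.
5. **Longitudinal models** — per network measure × domain, a linear mixed
   model `domain ~ time + measure + measure:time + age + sex + education +
   total GM volume + scanner` with a random subject intercept (REML); the
   measure×time coefficient is the association with annual change.
   Estimates are pooled over imputations with Rubin's rules and corrected
   with the Benjamini–Yekutieli FDR step-up procedure.  Local (per-region)
   models additionally adjust for local grey matter volume.

Because clinical imaging cohorts cannot ship with the code, a first-class
synthetic-data module generates every input with known ground truth:
volumes whose inter-cube similarity is planted through shared latent
intensity patterns, contiguous parcellations, and longitudinal cohorts
drawn from a mixed model with a known network×time interaction and
configurable per-test missingness.

## Worked example

```python
import numpy as np
from gmnet import (VolumeSpec, generate_gm_volume, extract_network,
                   compute_metrics)

vol, truth = generate_gm_volume(VolumeSpec(latent_loading=0.9,
                                           noise_sd=0.1, seed=1))
res = extract_network(vol, spurious_rate=0.05, n_permutations=1000, seed=1)
print(res.nodes.n_nodes, res.network.n_edges, round(res.threshold.cutoff, 3))
# 64 10 0.683
```

The 64-cube volume yields a 10-edge network at a calibrated cutoff of
r = 0.683: all 8 planted cube pairs are recovered, plus 2 chance
connections — the calibration bounds the *expected* spurious share at 5%
per subject, and averaged over volumes the realized share stays under it
(see below).

The analysis drivers under `analysis/` run the whole study on a synthetic
cohort of 200 subjects (run them in order; outputs land in `results/`).
`04_fit_global_models.py` prints, among others:

```
  gamma                  language         annual_change beta =  0.108 +/- 0.021  p_fdr = 0.0000
planted effect check - gamma x time on language: beta = 0.108 +/- 0.021 (generative truth 0.10)
```

i.e. the planted association — lower normalized clustering at baseline,
steeper language decline of 0.10 SD per year per SD of γ — is recovered by
the full pipeline (volumes → networks → γ → mixed models → Rubin pooling →
FDR) at its true magnitude and flagged as significant, while the planted
null effects (memory, attention at baseline, ...) are not.

## Layout

```
src/gmnet/          library: synthetic, extract, graph, regional,
                    cognition, longitudinal, experiments
analysis/01..05     numbered study drivers (simulate → extract → preprocess
                    → global models → local models)
tests/              pytest suite incl. brute-force oracles
scripts/acceptance.py   calibration recomputation
docs/methods.md     model and design notes
```
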