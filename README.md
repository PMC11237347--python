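# streamofd

Occupancy-frequency-distribution (OFD) analysis of stream insect
metacommunities across nested spatial extents and dispersal strategies.

## What it does, and for whom

OFDs — histograms of how many species occupy a given fraction of sites —
discriminate between community-assembly hypotheses: metapopulation dynamics
predict a *bimodal* OFD (a satellite mode of rare species plus a core mode
of widespread ones), niche control predicts a *unimodal* right-skewed OFD,
and an unstructured community gives a flat/random one. Both the spatial
extent of sampling and the dispersal strategy of the organisms shift these
shapes. This package is for community ecologists who want to test those
shifts on nested stream-survey data (or simulated equivalents) with a fully
reproducible pipeline:

1. **Dispersal groups** — fuzzy-coded dispersal traits (affinities 0-3) are
   standardized to within-trait proportions, imputed along the taxonomy,
   converted to a Gower dissimilarity matrix and Ward-clustered into groups;
   ANOSIM verifies the separation and indicator (multilevel pattern)
   analysis names the trait categories that define each group.
2. **Resampling** — elementary sample units are resampled into annually
   representative samples (ARS: one unit per season from one reach, pooled)
   and spatially representative samples (SRS: 16/15/16/16 ARSs at
   reach/subbasin/basin/region extent), with a 10-taxon ARS richness floor.
3. **RSOC inference** — per SRS and group, the ranked species occupancy
   curve O_(i) (relative occupancy against descending rank R_i) is fitted by
   Levenberg–Marquardt least squares with five candidate models
   (exponential concave, power exponential aR^b e^{-cR}, two sigmoids, and
   linear); AICc Akaike weights w_i = e^{-Δ_i/2}/Σe^{-Δ_j/2} are summed per
   OFD pattern family (bimodal: the sigmoids plus the power exponential when
   its fitted b > 0; unimodal: exponential concave plus power exponential
   with b ≤ 0; random: linear).
4. **Summaries** — mean pattern probabilities with percentile confidence
   intervals, evidence ratios ER = w̄_i/w̄_j for pattern pairs, mean taxa
   numbers, and OFD histograms over the SRS ensemble.

A mechanistic synthetic-community generator (core/satellite detection
mixtures, per-group spatial turnover, the exact 8-reach × 4-season ×
20-unit design) makes every stage testable without field data.

## Worked example

```python
import dataclasses
import streamofd as s

# a community in the "well-connected, core-rich" regime
cfg = dataclasses.replace(s.regime_presets()["bimodal_reach"], seed=1)
community = s.generate_community(cfg)          # 640 sample units, 141 taxa

# dispersal groups from the matching synthetic trait table
groups, anosim_res, wss = s.cluster_traits(s.generate_traits(cfg), k=3, seed=1)
print(groups.sizes(), f"ANOSIM R={anosim_res.R:.2f} (p={anosim_res.p})")

# 300-SRS ensembles at the smallest and largest extent
cube = s.PresenceCube(community)
for extent in ("reach", "region"):
    rcfg = s.ResamplingConfig(n_srs=300, seed=1)
    records, _ = s.analyze_extent(cube, extent, dict(groups.labels), rcfg)
    m = records[["w_bimodal", "w_unimodal", "w_random"]].mean()
    print(f"{extent:7s} bimodal={m.w_bimodal:.3f} "
          f"unimodal={m.w_unimodal:.3f} random={m.w_random:.3f}")
```

prints

```
{'DG1': 42, 'DG2': 58, 'DG3': 41} ANOSIM R=1.00 (p=0.001)
reach   bimodal=1.000 unimodal=0.000 random=0.000
region  bimodal=1.000 unimodal=0.000 random=0.000
```

Three cleanly separated dispersal groups (ANOSIM R = 1 on low-noise
synthetic traits), and — in this high-core, low-turnover regime — a
dominant bimodal pattern probability: most taxa are either near-ubiquitous
cores or rare satellites, so the ranked occupancy curve has the plateau-
and-drop shape of a sigmoid. The `unimodal_region` preset reverses this at
the region extent. A shell interface covers the same stages
(`streamofd simulate | traits-cluster | resample | rsoc | summarize | run`).

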