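# fociquant

Per-nucleus quantification of the DNA double-strand-break (DSB) response in
multi-channel high-content fluorescence images.

Ionizing radiation and many chemotherapeutics induce DSBs; cells mark them
with phosphorylated histone H2AX (γH2AX) and recruit repair factors such as
53BP1 to the break sites, both visible as punctate nuclear **foci** after
immunostaining. The conventional readout — counting γH2AX foci per cell —
breaks down at high damage doses, where foci are dense and overlapping and
merge into conglomerates, and it depends on manually tuned thresholds
because staining background varies from cell to cell within one field.

`fociquant` implements a threshold-free alternative for screening-scale
image sets:

1. **Per-nucleus cropping.** Nuclei are segmented from the DAPI channel
   (Otsu threshold, morphological cleanup, removal of border-clipped and
   out-of-size objects), outlined, and cropped by a fill-and-subtract rule
   so each sub-image contains exactly one nucleus — even when bounding
   rectangles overlap.
2. **Fuzzy c-means foci segmentation.** Within each nucleus, pixel gray
   levels are clustered by fuzzy c-means (FCM) into *c* classes (default
   *c* = 3, the single structural parameter); the highest-centroid cluster
   is the foci class. Because clustering is per nucleus, the effective
   threshold adapts to each cell's own background.
3. **Intensity-based metrics.** For each nucleus and channel the package
   reports the foci count, the total foci area, and the integrated foci
   intensity

   &nbsp;&nbsp;&nbsp;&nbsp;*I*<sub>sum</sub> = Σ<sub>(i,j)∈S</sub> *I*(i,j),

   summed over the foci support *S*. Intensity is additive under optical
   projection, so *I*<sub>sum</sub> stays informative when foci overlap.
4. **Co-localization ratio.** Recruitment of the repair protein (red,
   53BP1) to DSB sites (green, γH2AX) is quantified per nucleus as

   &nbsp;&nbsp;&nbsp;&nbsp;*Ra* = Σ<sub>(i,j)∈S<sub>G</sub></sub> *I*<sub>R</sub>(i,j) / Σ<sub>(i,j)∈S<sub>G</sub></sub> *I*<sub>G</sub>(i,j),

   the red foci intensity inside the green foci support over the total
   green foci intensity — a readout of DSB-response inhibition.
5. **Group statistics.** Two-sided Wilcoxon rank-sum tests between
   treatment groups, mean ± SD, coefficient of variation, and the
   percentage difference |d₁−d₂|/min(d₁,d₂)×100 between two measurements.

A synthetic-scene generator renders fields of elliptical nuclei with
per-cell backgrounds and Gaussian foci at a controllable co-localization
fraction φ, with full ground truth, so the entire pipeline is testable
without microscope data.

## Worked example

Simulate a two-group plate in which the treated group has reduced red→green
co-localization (φ = 0.8 vs 0.2), then run the pipeline:

```bash
fociquant simulate -o demo --n-fields 2 --seed 1 --field-size 384 \
    --n-nuclei 8 --min-separation-px 10 \
    --coloc-fraction 0.8 --group2-coloc-fraction 0.2
fociquant run demo/manifest.csv -o demo/out
```

```
4 fields, 32 nuclei
measurements: demo/out/measurements.csv
comparison:   demo/out/comparison.csv
```

`measurements.csv` holds one row per nucleus × channel
(`well_id, field_id, group, nucleus_id, channel, foci_count, foci_area_px,
foci_intensity_sum, ra, coloc_count, coloc_area_px, flags`):

```
w1,f0,control,0,green,5,70,415974,,,,
w1,f0,control,0,red,6,78,519658,0.745746128363792,4.0,48.0,
```

`comparison.csv` compares every metric between the groups:

```
                  metric         mean1         mean2 p_formatted
        green_foci_count      7.562500      7.437500       0.774
      green_foci_area_px    108.562500    105.625000       0.806
green_foci_intensity_sum 643520.250000 632417.500000       0.985
          red_foci_count      6.750000      6.750000       1.000
        red_foci_area_px    104.500000    105.375000       0.806
  red_foci_intensity_sum 641032.375000 682536.812500       0.440
                      ra      0.771671      0.291714      <0.001
```

Counts, areas and intensities are indistinguishable between the groups —
the same amount of damage and of repair protein is present — but the
co-localization ratio collapses from 0.77 to 0.29 (p < 0.001), recovering
the simulated recruitment defect. The library API mirrors the CLI:
`segment_nuclei`, `crop_nucleus`, `fcm_cluster`, `extract_foci`,
`count_foci`, `integrate_intensity`, `coloc_ratio`, `compare_groups`,
`generate_scene`, `truth_match`.

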