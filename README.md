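# stip

Functional stratification of tumor cell lines from label-free, real-time
confluence kinetics.

`stip` is for groups running live-cell imaging compatibility screens of
non-cytotoxic immunomodulatory formulations: instead of asking whether a
stimulus kills cells, it asks whether a tumor line's proliferative rhythm
is *stimulated*, *inhibited* or *unchanged* by exposure, and whether that
answer is reproducible across technical replicates and production batches.
It takes IncuCyte-style wide CSV exports of per-well confluence (decimal
comma or point), a plate map, and optional cumulative cell-death and
cytokine (CBA-style) tables, and produces phenotype calls with an evidence
trail, a composite ranking, QC verdicts, a compatibility matrix and a
cluster map. A seeded synthetic plate simulator generates complete
datasets with ground truth, so the full pipeline is testable without
instrument data.

## The model

For each treated group and its matched control (n ≥ 2 replicates on a
shared hourly 0–48 h grid), curves are baseline-normalized and smoothed
(3-point moving average) for divergence analysis, and per-timepoint
Welch t-tests compare the arms. The phenotype call uses three criteria on
the relative final-confluence divergence Δ/control:

* **Type I (stimulatory)**: Δ/control ≥ +20%, sustained ≥ 12 consecutive
  hours, p < 0.05 at ≥ 5 timepoints;
* **Type II (inhibitory)**: the mirror image at ≤ −20%;
* **Type III (neutral)**: |Δ/control| < 10% without significance;
* responses between the bands are reported **indeterminate**, and any
  response whose cumulative cell death exceeds 5% is
  **cytotoxic-confounded** and receives no type.

The IFN-γ/IL-10 ratio (ratio of group means) is recorded as a congruence
marker — low (< 3) for permissive/trophic profiles, high (> 6) for
suppressive ones — but never overrides kinetics.

Lines are ranked by the Functional Stratification Index, a cohort
z-scored composite of five kinetic parameters,

    FSI = scale · (0.30 z(Δrel) + 0.20 z(slope) + 0.15 z(±duration)
                   + 0.25 z(AUC) − 0.10 z(CV)),

and clustered (Euclidean distance, Ward-D2 linkage, silhouette-selected
k) into functional compatibility groups. QC enforces intra-assay CV
bounds (≤ 8% active / ≤ 5% neutral lines) and interbatch reproducibility
(final-confluence CV < 10%, onset CV < 8%, Δ spread ≤ 10 points, category
concordance). See `docs/methods.md` for every rule, default and design
choice.

## Worked example

Simulate a default 8-line plate (treated + control triplicates, death and
cytokine channels) and analyze it:

```bash
stip simulate --seed 7 --out sim/
stip analyze --confluence sim/confluence.csv --plate-map sim/plate_map.csv \
             --death sim/death.csv --cytokines sim/cytokines.csv --out results/
```

`results/calls.json` then contains one call per line × formulation, e.g.
(abridged; ratio is the treated panel's IFN-γ/IL-10):

```
BEWO    stimulatory  Type I    ratio 1.66
U87     stimulatory  Type I    ratio 1.50
LUDLU   stimulatory  Type I    ratio 1.20
A375    inhibitory   Type II   ratio 6.94
PANC-1  inhibitory   Type II   ratio 6.60
MCF-7   neutral      Type III  ratio 1.01
HEPG2   neutral      Type III  ratio 1.13
LNCAP-C42 neutral    Type III  ratio 0.94
```

and `results/fsi.csv` ranks the cohort:

```
cell_line  rank        fsi
     BEWO     1  26.415207
      U87     2   8.396076
    LUDLU     3   4.608906
    HEPG2     4  -1.082091
    MCF-7     5  -2.103464
LNCAP-C42     6  -2.278349
     A375     7 -16.869777
   PANC-1     8 -17.086507
```

Stimulated lines come out positive, inhibited lines negative, inert lines
near zero; `qc.json` reports `overall_pass: true` for this plate, and
`cluster.json` / `similarity.csv` hold the compatibility clustering. The
same analysis is available in-process via
`stip.run_analyze(traces, plate_map, death, cytokines)`, and
`stip config --show` prints every threshold with override markers.

The package also ships the reference eight-line validation cohort
(`stip.reference`): its printed kinetic metrics reclassify 8/8 into their
reported categories, the default-weight FSI reproduces the reported sign
pattern and complete rank order, and Ward-D2 clustering recovers the
permissive {BEWO, U87, LUDLU} / suppressive {A375, PANC-1} / inert
{MCF-7, HEPG2, LNCAP-C42} partition at k = 3.

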