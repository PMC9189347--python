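# confinetrack

Quantitative motility analysis of lymphoma cells migrating in
microfabricated channels, plus proteomic profiling of the motility
machinery — with a synthetic-movie generator that makes the whole
pipeline testable against ground truth.

## The problem

Classic Hodgkin lymphoma (cHL), its rare T-cell-derived variant and
anaplastic large cell lymphoma (ALCL) all carry CD30⁺ tumour cells but
differ sharply in how those cells move.  Confining cells in straight
PDMS microchannels (8 µm wide, imaged every 10 min) reduces migration
to an effectively one-dimensional walk whose speed and persistence
distinguish the entities; channels with 4 µm constrictions (imaged
every 4 min) probe whether the nucleus is deformable enough to squeeze
through an endothelial-gap-sized throat.  This package reimplements the
full analysis chain for such experiments:

1. **Segmentation** — per frame: median filter, subtraction of the
   per-pixel *temporal-median background* (removes the static channel
   walls), mean filter, **black top-hat** to enhance the dark cells, and
   a **Yen threshold** with morphological cleanup.
2. **Tracking** — two-pass **linear-assignment-problem (LAP)** tracking:
   frame-to-frame linking (gate 100 px) with a penalty on cross-lane
   (*y*) displacement, then gap closing (gate 150 px, up to 15 missed
   frames).
3. **Motility metrics** — step-based velocity
   `v = ‖Δr‖ · pixel_size / (Δt · frame_interval)` (µm/min) and
   straightness `S = net displacement / path length ∈ [0, 1]`, per track
   and per condition, with one-way ANOVA + Bonferroni, Mann–Whitney, or
   Kruskal–Wallis + Dunn group comparisons.
4. **Constriction passage** — how many cells clear each constriction and
   the frame-quantized time `(exit − entry) × frame_interval` each cell
   needs for the first one.
5. **Proteomics** — UPGMA (average-linkage, Euclidean) clustering of a
   normalized protein-intensity matrix, globally and on a
   motility-protein subset, plus group fold changes and group mean
   intensities (e.g. for lamin A/B1/B2).

Because raw experimental movies are rarely shareable, the package ships
a first-class simulator: cells rendered as dark ellipses (optionally
with a trailing uropod) performing a persistent random walk along the
channel axis, with scripted transit delays at constrictions and exact
per-frame ground truth.  Every downstream stage is validated against
that ground truth.

## Worked example

```sh
confinetrack run --seed 1 --outdir demo_run
```

simulates three straight-channel conditions programmed at the slow
(0.4 µm/min, T-cHL-like), intermediate (0.9, cHL-like) and fast
(1.5, ALCL-like) velocity regimes, one constriction movie with scripted
transit delays of 5/7/9/12 frames, and a synthetic proteomics fixture;
then segments, tracks and summarizes everything.  The condition summary
(`demo_run/condition_summary.tsv`) reads:

```
condition  n_tracks  mean_track_speed_um_min  mean_straightness
alcl_like         8                    1.477              0.138
 chl_like         8                    0.901              0.231
tchl_like         8                    0.402              0.160
```

The programmed ordering slow < intermediate < fast is recovered within
a few percent.  The constriction movie yields first-passage times of
20/28/36/48 min (`constr_first_passage.tsv`) — exactly the scripted
delays times the 4-min frame interval — and passage counts per
constriction of 4/4/4/3 (the slowest cell runs out of frames at the
last throat).  On the proteomics fixture the planted 1.5-fold motility-
protein effect comes back with median 1.495 (range 1.41–1.62), and the
motility-subset dendrogram (`dendrogram_motility.nwk`) places the
T-cHL samples on the ALCL side while the global dendrogram splits by
B- versus T-lineage.

Each stage is also available as a library function
(`simulate_straight_movie`, `segment_movie`, `track_movie`,
`track_metrics`, `detect_passages`, `hierarchical_cluster`, …) and as a
CLI subcommand (`simulate`, `segment`, `track`, `metrics`,
`constrictions`, `cluster`, `run`) reading and writing TIFF/CSV/TSV and
Newick files.

## Layout

```
src/confinetrack/   geometry, movie, simulate, segment, track, metrics,
                    constrictions, proteome, evaluate, pipeline, cli
tests/              unit + property tests and the end-to-end suite
scripts/acceptance.py
docs/methods.md     models, parameter choices, limitations
```
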