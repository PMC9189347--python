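"""Config-driven orchestration: simulate → segment → track → metrics /
constrictions → cluster, with a run manifest for reproducibility.

A run is described by a single YAML/dict config.  Every stochastic
stage draws from seeds derived deterministically from the top-level
``seed``, so re-running the same config reproduces byte-identical
artifacts; the manifest records parameters, seeds, the package version
and SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constrictions import (count_passages, detect_passages,
                            events_to_dataframe, first_passage_times)
from .geometry import constriction_channel, straight_channel
from .metrics import compare_groups, summarize_conditions, track_metrics
from .movie import read_movie, write_movie
from .proteome import group_fold_change, hierarchical_cluster, simulate_protein_matrix
from .segment import SegmentationParams, detections_to_dataframe, segment_movie
from .simulate import (CellSpec, NoiseParams, simulate_constriction_movie,
                       simulate_straight_movie, write_ground_truth,
                       write_scripted_passages)
from .track import LinkingParams, track_movie, tracks_to_dataframe

log = logging.getLogger("confinetrack")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def demo_config(seed: int = 1) -> dict:
    """A small three-condition demo emulating the slow (T-cHL-like),
    intermediate (cHL-like) and fast (ALCL-like) velocity regimes, plus
    one constriction movie and a synthetic proteomics fixture."""
    movies = []
    for name, speed in (("tchl_like", 0.4), ("chl_like", 0.9), ("alcl_like", 1.5)):
        movies.append({"name": name, "kind": "straight", "condition": name,
                       "n_cells": 8, "speed_um_per_min": speed,
                       "switch_prob": 0.2, "mode": "A2" if speed > 1.2 else "A1",
                       "n_frames": 40, "noise_sigma": 4.0, "length_um": 420.0})
    movies.append({"name": "constr", "kind": "constriction", "condition": "constr",
                   "n_cells": 4, "speed_um_per_min": 3.0, "n_frames": 60,
                   "noise_sigma": 0.0, "transit_delays": [5, 7, 9, 12],
                   "length_um": 320.0})
    return {"seed": seed,
            "movies": movies,
            "segmentation": {},
            "linking": {},
            "min_track_length": 5,
            "stats_test": "kruskal_dunn",
            "constriction_margin_px": 3.5,
            "proteome": {"n_proteins": 300, "n_motility": 40,
                         "fold": 1.5, "noise": 0.05}}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _movie_geometry(spec: dict):
    if spec["kind"] == "straight":
        return straight_channel(n_lanes=spec["n_cells"],
                                length_um=spec.get("length_um", 400.0))
    return constriction_channel(n_lanes=spec["n_cells"],
                                length_um=spec.get("length_um", 320.0))


def _simulate_movie(spec: dict, seed: int):
    geom = _movie_geometry(spec)
    noise = NoiseParams(gaussian_sigma=float(spec.get("noise_sigma", 0.0)),
                        seed=seed)
    radius = float(spec.get("radius_um", 3.5 if spec["kind"] == "straight" else 4.0))
    cells = [CellSpec(mode=spec.get("mode", "A1"),
                      speed_um_per_min=float(spec.get("speed_um_per_min", 0.9)),
                      switch_prob=float(spec.get("switch_prob", 0.1)),
                      radius_um=radius)
             for _ in range(int(spec["n_cells"]))]
    if spec["kind"] == "straight":
        return geom, *simulate_straight_movie(geom, cells, int(spec["n_frames"]), noise)
    delays = spec["transit_delays"]
    return geom, *simulate_constriction_movie(geom, cells, int(spec["n_frames"]),
                                              noise, delays)


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the configured stages; returns the run directory.

    Raises before any stage runs if the config references missing input
    files.  On stage failure the exception names the failing stage and
    partial artifacts are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    # validate referenced inputs up front
    for spec in config.get("movies", []):
        if "input_tiff" in spec and not Path(spec["input_tiff"]).exists():
            raise FileNotFoundError(f"movie {spec['name']!r}: input TIFF "
                                    f"{spec['input_tiff']} does not exist")

    seed = int(config.get("seed", 0))
    seg_params = SegmentationParams(**config.get("segmentation", {}))
    link_params = LinkingParams(**config.get("linking", {}))
    min_len = int(config.get("min_track_length", 5))
    artifacts = []
    per_track_tables = []

    try:
        for idx, spec in enumerate(config.get("movies", [])):
            stage = f"movie:{spec['name']}"
            log.info("running %s", stage)
            movie_seed = seed + 1000 * idx
            if "input_tiff" in spec:
                geom = _movie_geometry(spec)
                stack = read_movie(spec["input_tiff"])
                gt = None
            else:
                geom, stack, gt = _simulate_movie(spec, movie_seed)
                tiff = outdir / f"{spec['name']}.tif"
                write_movie(stack, tiff)
                write_ground_truth(gt, outdir / f"{spec['name']}_truth.csv")
                artifacts += [tiff, outdir / f"{spec['name']}_truth.csv"]
                if spec["kind"] == "constriction":
                    write_scripted_passages(gt, outdir / f"{spec['name']}_scripted.csv")
                    artifacts.append(outdir / f"{spec['name']}_scripted.csv")
            dets = segment_movie(stack, seg_params)
            det_path = outdir / f"{spec['name']}_detections.csv"
            detections_to_dataframe(dets).to_csv(det_path, index=False)
            tracks = track_movie(dets, link_params, min_track_length=min_len)
            trk_path = outdir / f"{spec['name']}_tracks.csv"
            tracks_to_dataframe(tracks).to_csv(trk_path, index=False)
            artifacts += [det_path, trk_path]
            per_track_tables.append(track_metrics(
                tracks, geom.frame_interval_min, geom.pixel_size_um,
                condition=spec.get("condition", spec["name"]),
                min_track_length=min_len))
            if spec["kind"] == "constriction":
                margin = float(config.get("constriction_margin_px", 4.0))
                events = [e for tr in tracks if not tr.flagged_short
                          for e in detect_passages(tr, geom, margin)]
                ev_path = outdir / f"{spec['name']}_passages.csv"
                events_to_dataframe(events).to_csv(ev_path, index=False)
                counts = count_passages(events, geom.n_constrictions)
                cnt_path = outdir / f"{spec['name']}_passage_counts.tsv"
                pd.DataFrame({"constriction_index": np.arange(1, len(counts) + 1),
                              "n_cells": counts}).to_csv(cnt_path, sep="\t", index=False)
                times, _ = first_passage_times(events)
                fp_path = outdir / f"{spec['name']}_first_passage.tsv"
                pd.DataFrame({"track_id": list(times),
                              "first_passage_min": list(times.values())}
                             ).to_csv(fp_path, sep="\t", index=False)
                artifacts += [ev_path, cnt_path, fp_path]

        if per_track_tables:
            stage = "metrics"
            per_track = pd.concat(per_track_tables, ignore_index=True)
            pt_path = outdir / "per_track_metrics.csv"
            per_track.to_csv(pt_path, index=False)
            summary = summarize_conditions(per_track)
            sm_path = outdir / "condition_summary.tsv"
            summary.to_csv(sm_path, sep="\t", index=False)
            artifacts += [pt_path, sm_path]
            groups = {c: g.loc[g["included"], "mean_step_speed_um_min"].dropna().to_numpy()
                      for c, g in per_track.groupby("condition")}
            groups = {c: v for c, v in groups.items() if len(v) >= 3}
            if len(groups) >= 2:
                res = compare_groups(groups, config.get("stats_test", "kruskal_dunn"))
                stats_path = outdir / "group_comparison.json"
                payload = {k: v for k, v in res.items() if k != "posthoc"}
                if "posthoc" in res:
                    payload["posthoc"] = res["posthoc"].to_dict(orient="records")
                stats_path.write_text(json.dumps(payload, indent=2))
                artifacts.append(stats_path)

        if "proteome" in config:
            stage = "proteome"
            log.info("running proteome stage")
            pconf = dict(config["proteome"])
            matrix = simulate_protein_matrix(seed=seed + 90000, **pconf)
            mx_path = outdir / "protein_matrix.tsv"
            matrix.data.to_csv(mx_path, sep="\t")
            ann_path = outdir / "sample_annotation.tsv"
            pd.DataFrame({"sample": matrix.samples,
                          "group": [matrix.sample_groups[s] for s in matrix.samples]}
                         ).to_csv(ann_path, sep="\t", index=False)
            artifacts += [mx_path, ann_path]
            for which in ("all", "motility"):
                dend = hierarchical_cluster(matrix, subset=which)
                nwk = outdir / f"dendrogram_{which}.nwk"
                nwk.write_text(dend.to_newick() + "\n")
                mg = outdir / f"merges_{which}.tsv"
                pd.DataFrame(dend.linkage,
                             columns=["node_a", "node_b", "height", "n_leaves"]
                             ).to_csv(mg, sep="\t", index=False)
                artifacts += [nwk, mg]
            flagged = matrix.data.index[matrix.motility]
            fc = group_fold_change(matrix, flagged, "T-cHL", "cHL")
            fc_path = outdir / "fold_changes_motility.tsv"
            fc.to_csv(fc_path, sep="\t")
            artifacts.append(fc_path)
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return outdir
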