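"""Step-based motility metrics and group-comparison statistics.

Step velocity: for consecutive track observations separated by Δt
frames (Δt ≥ 1, including across closed gaps),

    speed = Euclidean displacement × pixel_size / (Δt × frame_interval)

in µm/min.  Straightness is net displacement divided by total path
length, a dimensionless value in [0, 1]: 1 for a perfectly straight
run, near 0 for a cell that flips backward and forward.  (The ratio is
oriented displacement/path so that reported values live in [0, 1];
cells with path length below one pixel have undefined straightness and
are excluded from straightness statistics.)

Per-condition aggregation reports both the mean of per-track mean
speeds (primary) and the pooled mean over all steps (secondary).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

MIN_TRACK_LENGTH = 5          # observations; shorter tracks are flagged
MIN_PATH_LENGTH_PX = 1.0      # below this, straightness is undefined


def step_velocities(track, frame_interval_min: float,
                    pixel_size_um: float = 1.0) -> np.ndarray:
    """Per-step speeds (µm/min) of one track; empty for a single point."""
    if frame_interval_min <= 0 or pixel_size_um <= 0:
        raise ValueError("calibration values must be > 0")
    frames = np.asarray(track.frames, dtype=float)
    x = np.asarray(track.x, dtype=float)
    y = np.asarray(track.y, dtype=float)
    if len(frames) < 2:
        return np.empty(0)
    dt = np.diff(frames) * frame_interval_min
    dist = np.hypot(np.diff(x), np.diff(y)) * pixel_size_um
    return dist / dt


def straightness(track) -> float:
    """Net displacement over path length, in [0, 1]; NaN when the path
    is shorter than one pixel (undefined)."""
    x = np.asarray(track.x, dtype=float)
    y = np.asarray(track.y, dtype=float)
    if len(x) < 2:
        return float("nan")
    path = float(np.hypot(np.diff(x), np.diff(y)).sum())
    if path < MIN_PATH_LENGTH_PX:
        return float("nan")
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return min(net / path, 1.0)


def track_metrics(tracks, frame_interval_min: float, pixel_size_um: float = 1.0,
                  condition: str | None = None,
                  min_track_length: int = MIN_TRACK_LENGTH) -> pd.DataFrame:
    """Per-track metric table for one movie/condition."""
    rows = []
    for tr in tracks:
        speeds = step_velocities(tr, frame_interval_min, pixel_size_um)
        x = np.asarray(tr.x, dtype=float)
        y = np.asarray(tr.y, dtype=float)
        path = float(np.hypot(np.diff(x), np.diff(y)).sum()) * pixel_size_um if len(x) > 1 else 0.0
        net = float(np.hypot(x[-1] - x[0], y[-1] - y[0])) * pixel_size_um if len(x) > 1 else 0.0
        rows.append({
            "track_id": tr.track_id,
            "condition": condition,
            "n_observations": len(tr.frames),
            "n_steps": len(speeds),
            "mean_step_speed_um_min": float(speeds.mean()) if len(speeds) else float("nan"),
            "straightness": straightness(tr),
            "path_length_um": path,
            "net_displacement_um": net,
            "included": len(tr.frames) >= min_track_length,
        })
    return pd.DataFrame(rows)


def summarize_conditions(per_track: pd.DataFrame) -> pd.DataFrame:
    """Per-condition aggregates over included tracks.

    ``mean_track_speed`` averages per-track mean speeds (primary
    statistic); ``pooled_step_speed`` weights tracks by their number of
    steps (secondary).  Tracks with undefined straightness contribute to
    velocity but are excluded from the straightness mean.
    """
    inc = per_track[per_track["included"]]
    if len(inc) == 0:
        raise ValueError("no tracks pass the minimum-length filter")
    out = []
    for cond, grp in inc.groupby("condition", dropna=False):
        speeds = grp["mean_step_speed_um_min"].dropna()
        weights = grp.loc[speeds.index, "n_steps"]
        pooled = float((speeds * weights).sum() / weights.sum()) if weights.sum() else float("nan")
        out.append({
            "condition": cond,
            "n_tracks": len(grp),
            "mean_track_speed_um_min": float(speeds.mean()),
            "pooled_step_speed_um_min": pooled,
            "mean_straightness": float(grp["straightness"].dropna().mean()),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# group comparisons

def _bonferroni(p: float, k: int) -> float:
    return min(1.0, p * k)


def mann_whitney(a, b) -> dict:
    """Two-sided Mann–Whitney U test; exact when both groups are small
    (n ≤ 8) and tie-free, normal approximation with tie correction
    otherwise."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = (len(a) <= 8 and len(b) <= 8
             and len(np.unique(pooled)) == len(pooled))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return {"test": "mann_whitney", "statistic": float(res.statistic),
            "pvalue": float(res.pvalue)}


def dunn_posthoc(groups: dict, adjust: bool = True) -> pd.DataFrame:
    """Dunn's rank-based z-tests for all pairs after Kruskal–Wallis.

    Uses the pooled-rank formulation with tie correction:
    z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i + 1/n_j))
    with T = Σ(t³ − t) over tied groups; two-sided p-values, Bonferroni
    adjusted across the k(k−1)/2 pairs when ``adjust``.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start:start + len(v)].mean()
        sizes[name] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": g1, "group_b": g2, "z": z,
                     "pvalue": _bonferroni(p, len(pairs)) if adjust else p})
    return pd.DataFrame(rows)


def compare_groups(groups: dict, test: str) -> dict:
    """Run the declared group-comparison test.

    ``test`` is one of ``"anova_bonferroni"`` (one-way ANOVA with
    Bonferroni-adjusted pairwise t post-tests), ``"mann_whitney"``
    (two groups) or ``"kruskal_dunn"`` (Kruskal–Wallis with Dunn's
    post-test, Bonferroni adjusted).  The choice of test is a declared
    input, never inferred from the data.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in values):
        raise ValueError("each group needs at least 3 observations")
    if test == "mann_whitney":
        if len(values) != 2:
            raise ValueError("mann_whitney compares exactly 2 groups")
        return mann_whitney(values[0], values[1])
    if test == "anova_bonferroni":
        f, p = stats.f_oneway(*values)
        pairs = list(itertools.combinations(range(len(names)), 2))
        posthoc = []
        for i, j in pairs:
            t, pt = stats.ttest_ind(values[i], values[j])
            posthoc.append({"group_a": names[i], "group_b": names[j],
                            "t": float(t), "pvalue": _bonferroni(float(pt), len(pairs))})
        return {"test": "anova_bonferroni", "statistic": float(f),
                "pvalue": float(p), "posthoc": pd.DataFrame(posthoc)}
    if test == "kruskal_dunn":
        h, p = stats.kruskal(*values)
        return {"test": "kruskal_dunn", "statistic": float(h),
                "pvalue": float(p), "posthoc": dunn_posthoc(groups)}
    raise ValueError(f"unknown test {test!r}")
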