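"""Permutation-null FDR model for tiling-array binding peaks.

For each chromosome arm and replicate, probe values are randomly permuted
within the arm (the null assumes exchangeable probes) and the frequency of
runs is tabulated over a grid of small peak heights (0.10-1.25 log2, step
0.05) and widths (6-15 consecutive probes), averaging 20 randomizations
per cell. The empirical FDR of a grid cell is the mean null run count
divided by the observed run count at the same (height, width), capped at
1. Because run counts decay geometrically in both height and width, the
surface ln FDR = a + b*h + c*w is fitted by least squares over usable
cells and extrapolated to the (taller, broader) observed peaks, which are
individually far beyond the directly measurable grid.

Replicate consensus: peaks whose intervals overlap across replicates are
clustered; clusters represented in every replicate become consensus peaks
spanning the union interval and carrying the *worst* (largest) member FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConsensusPeak, Peak, ProbeLayout, RatioTrack
from .peak_calling import run_lengths_above

__all__ = [
    "DEFAULT_HEIGHTS", "DEFAULT_WIDTHS", "DEFAULT_ITERATIONS",
    "NullPeakGrid", "FDRModel", "randomize_arm", "count_runs_grid",
    "build_null_grid", "fdr_table", "fit_exponential_decay", "assign_fdr",
    "consensus_across_replicates", "assign_fdrs_lazily",
]

#: Height grid 0.10..1.25 log2 in steps of 0.05 (24 levels). The range is
#: the measurable small-peak regime; the step is a design choice dense
#: enough to constrain a 3-parameter surface.
DEFAULT_HEIGHTS: np.ndarray = np.round(np.arange(0.10, 1.25 + 1e-9, 0.05), 2)
#: Width grid: 6..15 consecutive probes.
DEFAULT_WIDTHS: np.ndarray = np.arange(6, 16)
DEFAULT_ITERATIONS = 20

MIN_USABLE_CELLS = 6


@dataclass
class NullPeakGrid:
    """Mean null and observed run counts over the (height, width) grid."""

    arm_id: str
    replicate_id: str
    heights: np.ndarray
    widths: np.ndarray
    iterations: int
    mean_null_count: np.ndarray   # shape (n_heights, n_widths)
    observed_count: np.ndarray    # same shape, integer counts


@dataclass
class FDRModel:
    """Fitted exponential-decay FDR surface ln FDR = a + b*h + c*w.

    On well-formed data both slopes are negative: false discovery decays
    with increasing peak height and width.
    """

    arm_id: str
    replicate_id: str
    a: float
    b: float
    c: float
    n_cells: int
    resid_rms: float

    def predict_fdr(self, height: float, width: float) -> float:
        return min(1.0, math.exp(self.a + self.b * height + self.c * width))


def randomize_arm(track: RatioTrack, seed_or_rng: int | np.random.Generator) -> RatioTrack:
    """Uniform random permutation of the arm's probe values.

    The value multiset is preserved exactly; only positions are shuffled.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return track.copy_with(values=rng.permutation(track.values))


def count_runs_grid(values: np.ndarray, heights: np.ndarray,
                    widths: np.ndarray) -> np.ndarray:
    """Count maximal runs of >= w probes >= h for every grid cell.

    Returns an (n_heights, n_widths) integer array. Uses the same
    run-length rule as peak calling, so observed and null counts are
    directly comparable.
    """
    counts = np.zeros((len(heights), len(widths)), dtype=np.int64)
    for i, h in enumerate(heights):
        lens = run_lengths_above(values, float(h))
        if lens.size:
            counts[i] = (lens[:, None] >= widths[None, :]).sum(axis=0)
    return counts


def build_null_grid(track: RatioTrack,
                    heights: np.ndarray = DEFAULT_HEIGHTS,
                    widths: np.ndarray = DEFAULT_WIDTHS,
                    iterations: int = DEFAULT_ITERATIONS,
                    seed: int | np.random.SeedSequence = 0) -> NullPeakGrid:
    """Tabulate mean null and observed run counts for one arm/replicate.

    Each randomization draws its permutation from a per-iteration stream
    derived by counter from ``seed``, so changing ``iterations`` never
    reshuffles earlier draws.
    """
    if track.n_probes == 0:
        raise ValueError("track is empty")
    heights = np.asarray(heights, dtype=float)
    widths = np.asarray(widths, dtype=np.int64)
    total = np.zeros((len(heights), len(widths)), dtype=np.float64)
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for it in range(iterations):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=base.entropy, spawn_key=base.spawn_key + (it,)))
        permuted = rng.permutation(track.values)
        total += count_runs_grid(permuted, heights, widths)
    observed = count_runs_grid(track.values, heights, widths)
    return NullPeakGrid(arm_id=track.arm_id, replicate_id=track.replicate_id,
                        heights=heights, widths=widths, iterations=iterations,
                        mean_null_count=total / iterations, observed_count=observed)


def fdr_table(grid: NullPeakGrid) -> pd.DataFrame:
    """Empirical FDR(h, w) = mean null count / observed count, capped at 1.

    Cells with zero observed count carry no rate and are marked unusable;
    cells with zero mean null count (ln 0 undefined) are marked zero-null
    and likewise excluded from the surface fit rather than pseudocounted.
    """
    rows = []
    for i, h in enumerate(grid.heights):
        for j, w in enumerate(grid.widths):
            null = float(grid.mean_null_count[i, j])
            obs = int(grid.observed_count[i, j])
            if obs > 0:
                fdr = min(1.0, null / obs)
            else:
                fdr = np.nan
            rows.append({
                "height": float(h), "width": int(w),
                "mean_null_count": null, "observed_count": obs, "fdr": fdr,
                "usable": obs > 0 and null > 0.0,
            })
    return pd.DataFrame(rows)


def fit_exponential_decay(table: pd.DataFrame,
                          arm_id: str = "", replicate_id: str = "") -> FDRModel:
    """Least-squares fit of ln FDR = a + b*height + c*width over usable cells."""
    cells = table[table["usable"] & (table["fdr"] > 0)]
    if len(cells) < MIN_USABLE_CELLS:
        raise ValueError(
            f"only {len(cells)} usable FDR cells (< {MIN_USABLE_CELLS}); "
            "use a denser grid or check for degenerate data"
        )
    y = np.log(cells["fdr"].to_numpy())
    X = np.column_stack([np.ones(len(cells)),
                         cells["height"].to_numpy(),
                         cells["width"].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return FDRModel(arm_id=arm_id, replicate_id=replicate_id,
                    a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                    n_cells=int(len(cells)),
                    resid_rms=float(np.sqrt(np.mean(resid ** 2))))


def assign_fdr(peak: Peak, model: FDRModel) -> Peak:
    """Attach the model's (possibly extrapolated) FDR to a peak in place."""
    peak.fdr = model.predict_fdr(peak.height_log2, peak.width_probes)
    return peak


def consensus_across_replicates(peaks_by_replicate: Mapping[str, Sequence[Peak]],
                                n_required: int | str = "all") -> list[ConsensusPeak]:
    """Cluster overlapping peaks across replicates into consensus peaks.

    Peaks (from any replicate) whose intervals overlap by >= 1 bp are
    chained into clusters per arm. A cluster represented in at least
    ``n_required`` distinct replicates ("all" = every replicate given)
    becomes a ConsensusPeak with the union interval and the max member
    FDR; other clusters are discarded.
    """
    replicate_ids = list(peaks_by_replicate)
    need = len(replicate_ids) if n_required == "all" else int(n_required)
    all_peaks = [p for peaks in peaks_by_replicate.values() for p in peaks]
    by_arm: dict[str, list[Peak]] = {}
    for p in all_peaks:
        if p.fdr is None:
            raise ValueError("consensus requires per-replicate FDRs on every peak")
        by_arm.setdefault(p.arm_id, []).append(p)

    out: list[ConsensusPeak] = []
    for arm, peaks in by_arm.items():
        peaks.sort(key=lambda p: (p.start_bp, p.end_bp))
        cluster: list[Peak] = []
        cluster_end = -1

        def flush() -> None:
            reps = {p.replicate_id for p in cluster}
            if len(reps) >= need:
                out.append(ConsensusPeak(
                    arm_id=arm,
                    start_bp=min(p.start_bp for p in cluster),
                    end_bp=max(p.end_bp for p in cluster),
                    members=sorted(cluster, key=lambda p: p.replicate_id),
                    fdr=max(p.fdr for p in cluster),
                ))

        for p in peaks:
            if cluster and p.start_bp < cluster_end:
                cluster.append(p)
                cluster_end = max(cluster_end, p.end_bp)
            else:
                if cluster:
                    flush()
                cluster = [p]
                cluster_end = p.end_bp
        if cluster:
            flush()
    out.sort(key=lambda c: (c.arm_id, c.start_bp))
    return out


def assign_fdrs_lazily(tracks_by_replicate: Mapping[str, Mapping[str, RatioTrack]],
                       layouts: Mapping[str, ProbeLayout],
                       peaks_by_replicate: Mapping[str, Sequence[Peak]],
                       heights: np.ndarray = DEFAULT_HEIGHTS,
                       widths: np.ndarray = DEFAULT_WIDTHS,
                       iterations: int = DEFAULT_ITERATIONS,
                       seed: int = 0,
                       ) -> tuple[dict[str, list[Peak]], dict[tuple[str, str], FDRModel]]:
    """Assign FDRs to all observed peaks, building null models on demand.

    A null grid + decay surface is fitted per (arm, replicate) — but only
    for combinations that actually have observed peaks, since the FDR of a
    peak can only come from its own arm and replicate's null. Seeds are
    derived by counter from ``seed`` per (arm index, replicate index,
    iteration).

    Returns the peaks (with ``fdr`` set) and the fitted models.
    """
    arm_index = {arm: i for i, arm in enumerate(layouts)}
    models: dict[tuple[str, str], FDRModel] = {}
    out: dict[str, list[Peak]] = {}
    for ri, (rep, peaks) in enumerate(peaks_by_replicate.items()):
        out[rep] = list(peaks)
        arms_needed = sorted({p.arm_id for p in peaks}, key=lambda a: arm_index[a])
        for arm in arms_needed:
            key = (arm, rep)
            if key not in models:
                ss = np.random.SeedSequence((seed, arm_index[arm], ri))
                grid = build_null_grid(tracks_by_replicate[rep][arm],
                                       heights=heights, widths=widths,
                                       iterations=iterations, seed=ss)
                models[key] = fit_exponential_decay(fdr_table(grid),
                                                    arm_id=arm, replicate_id=rep)
        for p in out[rep]:
            assign_fdr(p, models[(p.arm_id, rep)])
    return out, models
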