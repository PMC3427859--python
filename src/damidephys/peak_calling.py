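"""Run-based peak detection on normalized ratio tracks.

A binding peak is a maximal run of consecutive probes whose log2 ratio is
at or above a height threshold, kept when the run spans at least a minimum
number of probes. The production thresholds are a 2-fold ratio change
(log2 >= 1.0) over >= 8 consecutive probes (roughly 900 bp at ~55 bp
spacing). Only enrichment (positive) runs are called.

Peak height is the *minimum* probe value within the run: that makes "a
peak of height h and width w" mean exactly "a run of >= w probes >= h",
the same counting rule the permutation null uses, so observed peaks and
null frequencies live on one scale.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Peak, ProbeLayout, RatioTrack

__all__ = ["DEFAULT_HEIGHT_THRESHOLD", "DEFAULT_MIN_WIDTH", "find_runs",
           "peak_height", "call_observed_peaks", "run_lengths_above"]

DEFAULT_HEIGHT_THRESHOLD = 1.0  # log2 units; 2-fold ratio change
DEFAULT_MIN_WIDTH = 8           # consecutive probes


def run_lengths_above(values: np.ndarray, height_threshold: float) -> np.ndarray:
    """Lengths of all maximal runs of values >= height_threshold.

    Shared by peak calling and the permutation-null grid so both count
    runs identically. Ties at the threshold are included (>=).
    """
    mask = values >= height_threshold
    if not mask.any():
        return np.zeros(0, dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def _run_bounds(values: np.ndarray, height_threshold: float
                ) -> tuple[np.ndarray, np.ndarray]:
    mask = values >= height_threshold
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    return starts, ends


def find_runs(track: RatioTrack, layout: ProbeLayout,
              height_threshold: float, min_width: int) -> list[Peak]:
    """All maximal runs of >= min_width consecutive probes >= height_threshold.

    Runs are maximal (flanking probes are below threshold or the track
    ends), non-overlapping, and returned in genomic order. No gap
    tolerance: a single sub-threshold probe terminates a run.
    """
    if height_threshold <= 0:
        raise ValueError("height_threshold must be > 0")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if track.n_probes != layout.n_probes:
        raise ValueError("track and layout disagree on probe count")
    starts, ends = _run_bounds(track.values, height_threshold)
    peaks: list[Peak] = []
    for s, e in zip(starts, ends):
        if e - s < min_width:
            continue
        last = int(e - 1)
        peaks.append(Peak(
            arm_id=track.arm_id,
            replicate_id=track.replicate_id,
            first_probe=int(s),
            last_probe=last,
            start_bp=int(layout.starts[s]),
            end_bp=int(layout.starts[last] + layout.lengths[last]),
            height_log2=float(track.values[s:e].min()),
        ))
    return peaks


def peak_height(track: RatioTrack, peak: Peak) -> float:
    """Minimum probe value over the run — the largest h for which the whole
    run still exceeds h."""
    if peak.first_probe < 0 or peak.last_probe >= track.n_probes:
        raise ValueError("peak indices outside track")
    return float(track.values[peak.first_probe:peak.last_probe + 1].min())


def call_observed_peaks(track: RatioTrack, layout: ProbeLayout,
                        height_threshold: float = DEFAULT_HEIGHT_THRESHOLD,
                        min_width: int = DEFAULT_MIN_WIDTH) -> list[Peak]:
    """Call binding peaks at the production thresholds (log2 >= 1.0, >= 8 probes)."""
    return find_runs(track, layout, height_threshold, min_width)
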