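"""Dye-swap orientation and median normalization of ratio tracks.

Order of operations: the dye-swapped replicate is re-oriented first, then
each replicate is median-normalized. (Medians do not commute with sign
flips, so the order matters; orienting first puts all replicates in the
same signal orientation before their scales are aligned.)

The median is taken over the whole array per replicate (all arms pooled),
not per arm — per-arm medians would interact with the per-arm permutation
null downstream.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .core import RatioTrack

__all__ = ["orient_dye_swap", "median_normalize", "median_normalize_replicate",
           "prepare_replicate"]


def orient_dye_swap(track: RatioTrack) -> RatioTrack:
    """Restore a dye-swapped track's orientation by negating its values.

    Unflagged tracks are returned unchanged (as a copy); the operation is
    idempotent because the flag is cleared on the oriented copy.
    """
    if track.dye_swapped:
        return track.copy_with(values=-track.values, dye_swapped=False)
    return track.copy_with(values=track.values.copy())


def median_normalize(track: RatioTrack) -> RatioTrack:
    """Subtract the track's own median so the output median is exactly 0."""
    if track.n_probes == 0:
        raise ValueError("cannot normalize an empty track")
    med = float(np.median(track.values))
    return track.copy_with(values=track.values - med)


def median_normalize_replicate(tracks: Mapping[str, RatioTrack]) -> dict[str, RatioTrack]:
    """Median-normalize one replicate's arms against their pooled median.

    All arms of the replicate are shifted by the same (array-wide) median,
    so inter-arm level differences survive while the replicate as a whole
    is centred.
    """
    if not tracks:
        raise ValueError("no tracks given")
    pooled = np.concatenate([t.values for t in tracks.values()])
    med = float(np.median(pooled))
    return {arm: t.copy_with(values=t.values - med) for arm, t in tracks.items()}


def prepare_replicate(tracks: Mapping[str, RatioTrack]) -> dict[str, RatioTrack]:
    """Orient (if dye-swapped) then median-normalize one replicate's arms."""
    oriented = {arm: orient_dye_swap(t) for arm, t in tracks.items()}
    return median_normalize_replicate(oriented)
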