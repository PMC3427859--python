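"""Desk-scale synthetic tiling arrays with known planted binding peaks.

The generator emulates the study design the analysis was built for: a
Nimblegen-style layout of 50-75-mer probes spaced ~55 bp apart, three
biological replicates with one dye-swap, i.i.d. Gaussian probe noise in
log2 space, and rectangular planted enrichment peaks. Gaussian noise is a
stand-in — the noise law of real probes is unknown — chosen because it
satisfies the exchangeability the permutation null assumes, which makes
FDR-calibration tests interpretable.

Everything is a pure function of (config, planted peaks, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GeneModel, PlantedPeak, ProbeLayout, RatioTrack

__all__ = ["ArraySimConfig", "make_layout", "make_genes", "plant_and_simulate",
           "default_planted_peaks"]

#: (height_log2, width_probes) pairs used for the standard 20-peak recovery
#: experiment. Low peaks are broad and tall peaks narrow, so that — at the
#: reference noise of 0.3 log2 — every peak presents a run of >= 8 probes
#: above the 1.0 log2 detection threshold in all three replicates with
#: probability > 99.9% (exact longest-run DP, computed before any data).
RECOVERY_PEAK_CLASSES: tuple[tuple[float, int], ...] = (
    (1.5, 48), (1.7, 30), (2.0, 18), (2.2, 12), (2.5, 10),
)


@dataclass(frozen=True)
class ArraySimConfig:
    """Geometry and noise of the simulated array.

    Defaults mirror the emulated study design: ~55 bp probe spacing,
    50-75 bp probes, three replicates with the last one dye-swapped, and
    0.3 log2 units of per-probe Gaussian noise (a realistic two-colour
    array ratio spread).
    """

    n_arms: int = 2
    probes_per_arm: int = 5000
    spacing_bp: int = 55
    probe_len_range: tuple[int, int] = (50, 75)
    noise_sd: float = 0.3
    n_replicates: int = 3
    dye_swap_replicate: int | None = 2
    seed: int = 0
    arm_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dye_swap_replicate is not None and not (
                0 <= self.dye_swap_replicate < self.n_replicates):
            raise ValueError("dye_swap_replicate out of range")
        if self.probes_per_arm < 20:
            raise ValueError("probes_per_arm must be >= 20")

    def arms(self) -> tuple[str, ...]:
        if self.arm_names:
            return self.arm_names
        return tuple(f"arm{i + 1}" for i in range(self.n_arms))

    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(f"rep{i + 1}" for i in range(self.n_replicates))


_JITTER_BP = 10  # max deviation of each inter-probe gap from spacing_bp


def _rng(config: ArraySimConfig, *key: int) -> np.random.Generator:
    # counter-derived streams: layout / noise / genes do not share draws
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def make_layout(config: ArraySimConfig) -> dict[str, ProbeLayout]:
    """Probe grids at spacing_bp +/- uniform jitter (<= 10 bp), per arm."""
    layouts: dict[str, ProbeLayout] = {}
    for ai, arm in enumerate(config.arms()):
        rng = _rng(config, 0, ai)
        gaps = config.spacing_bp + rng.integers(-_JITTER_BP, _JITTER_BP + 1,
                                                size=config.probes_per_arm)
        starts = np.cumsum(gaps) - gaps[0]
        lengths = rng.integers(config.probe_len_range[0], config.probe_len_range[1] + 1,
                               size=config.probes_per_arm)
        layouts[arm] = ProbeLayout(arm_id=arm, starts=starts, lengths=lengths)
    return layouts


def make_genes(config: ArraySimConfig, layouts: dict[str, ProbeLayout],
               gene_span_bp: tuple[int, int] = (2000, 6000),
               gap_bp: tuple[int, int] = (1000, 8000)) -> list[GeneModel]:
    """Tile the arms with synthetic transcription units.

    Gaps between adjacent genes are drawn to straddle the 5 kb target
    window, so peak-to-gene assignments have non-trivial known answers.
    Strands alternate, giving divergent and convergent neighbour pairs.
    """
    genes: list[GeneModel] = []
    for ai, arm in enumerate(config.arms()):
        rng = _rng(config, 1, ai)
        layout = layouts[arm]
        arm_end = int(layout.starts[-1] + layout.lengths[-1])
        pos, k = int(rng.integers(0, 2000)), 0
        while pos < arm_end:
            span = int(rng.integers(gene_span_bp[0], gene_span_bp[1] + 1))
            end = min(pos + span, arm_end)
            if end - pos >= 200:
                strand = "+" if k % 2 == 0 else "-"
                genes.append(GeneModel(gene_id=f"{arm}_g{k:04d}", arm_id=arm,
                                       tx_start=pos, tx_end=end, strand=strand))
                k += 1
            pos = end + int(rng.integers(gap_bp[0], gap_bp[1] + 1))
    return genes


def default_planted_peaks(config: ArraySimConfig,
                          layouts: dict[str, ProbeLayout],
                          classes: Sequence[tuple[float, int]] = RECOVERY_PEAK_CLASSES,
                          peaks_per_class_per_arm: int = 2,
                          margin_probes: int = 50) -> list[PlantedPeak]:
    """Place the standard recovery peak set, non-overlapping, per arm.

    Peaks are spread evenly across each arm with at least ``margin_probes``
    of clean baseline between them and away from arm ends.
    """
    planted: list[PlantedPeak] = []
    for ai, arm in enumerate(config.arms()):
        rng = _rng(config, 2, ai)
        n_per_arm = len(classes) * peaks_per_class_per_arm
        n_probes = layouts[arm].n_probes
        slot = (n_probes - 2 * margin_probes) // n_per_arm
        widest = max(w for _, w in classes)
        if slot < widest + margin_probes + 1:
            raise ValueError(
                f"arm {arm} too small for {n_per_arm} planted peaks of width "
                f"up to {widest} with margin {margin_probes}")
        specs = [c for c in classes for _ in range(peaks_per_class_per_arm)]
        order = rng.permutation(len(specs))
        for si, slot_i in enumerate(range(n_per_arm)):
            height, width = specs[order[si]]
            lo = margin_probes + slot_i * slot
            hi = lo + slot - width - margin_probes
            first = int(rng.integers(lo, max(lo + 1, hi)))
            planted.append(PlantedPeak(arm_id=arm, first_probe_index=first,
                                       width_probes=width, height_log2=height))
    return planted


def _check_non_overlapping(planted: Sequence[PlantedPeak]) -> None:
    by_arm: dict[str, list[PlantedPeak]] = {}
    for p in planted:
        by_arm.setdefault(p.arm_id, []).append(p)
    for arm, plist in by_arm.items():
        plist = sorted(plist, key=lambda p: p.first_probe_index)
        for a, b in zip(plist, plist[1:]):
            if b.first_probe_index <= a.last_probe_index:
                raise ValueError(
                    f"planted peaks overlap on arm {arm}: probes "
                    f"[{a.first_probe_index}, {a.last_probe_index}] and "
                    f"[{b.first_probe_index}, {b.last_probe_index}]"
                )


def plant_and_simulate(layouts: dict[str, ProbeLayout],
                       planted: Sequence[PlantedPeak],
                       config: ArraySimConfig,
                       ) -> dict[str, dict[str, RatioTrack]]:
    """Simulate per-replicate ratio tracks with planted peaks.

    Each probe value is baseline 0, plus ``height_log2`` inside a planted
    peak, plus independent Gaussian(0, noise_sd) noise per replicate. The
    dye-swap replicate's stored values are negated and flagged; they are
    restored downstream by ``orient_dye_swap``.

    Returns ``tracks[replicate_id][arm_id]``.
    """
    _check_non_overlapping(planted)
    for p in planted:
        if p.arm_id not in layouts:
            raise ValueError(f"planted peak on unknown arm {p.arm_id}")
        if p.last_probe_index >= layouts[p.arm_id].n_probes:
            raise ValueError(f"planted peak on arm {p.arm_id} extends past the layout")

    signal: dict[str, np.ndarray] = {
        arm: np.zeros(lay.n_probes) for arm, lay in layouts.items()
    }
    for p in planted:
        signal[p.arm_id][p.first_probe_index:p.last_probe_index + 1] += p.height_log2

    tracks: dict[str, dict[str, RatioTrack]] = {}
    for ri, rep in enumerate(config.replicate_ids()):
        tracks[rep] = {}
        for ai, arm in enumerate(config.arms()):
            rng = _rng(config, 3, ri, ai)
            values = signal[arm] + rng.normal(0.0, config.noise_sd, size=signal[arm].size) \
                if config.noise_sd > 0 else signal[arm].copy()
            swapped = config.dye_swap_replicate == ri
            if swapped:
                values = -values
            tracks[rep][arm] = RatioTrack(replicate_id=rep, arm_id=arm,
                                          values=values, dye_swapped=swapped)
    return tracks
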