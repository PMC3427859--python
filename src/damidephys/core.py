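"""Core domain types shared across the DamID analysis modules.

Coordinate convention: all genomic intervals are 0-based, half-open
(BED-compatible). GFF3 input/output is converted at the I/O boundary.
Probe identity is (arm, start); probe length is carried for interval output
but plays no role in peak arithmetic, which works in probe counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ProbeLayout",
    "GeneModel",
    "RatioTrack",
    "Peak",
    "ConsensusPeak",
    "PlantedPeak",
    "TargetCall",
]


@dataclass(frozen=True)
class ProbeLayout:
    """Ordered probe grid for one chromosome arm.

    Parameters
    ----------
    arm_id : str
        Chromosome-arm label (e.g. ``"2L"``).
    starts : ndarray of int
        Probe start coordinates in bp, strictly increasing.
    lengths : ndarray of int
        Probe lengths in bp (nominally 50-75 for the emulated array design).
    """

    arm_id: str
    starts: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        lengths = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "lengths", lengths)
        if starts.shape != lengths.shape:
            raise ValueError("starts and lengths must have equal length")
        if starts.size and np.any(np.diff(starts) <= 0):
            raise ValueError(f"probe starts not strictly increasing on arm {self.arm_id}")

    @property
    def n_probes(self) -> int:
        return int(self.starts.size)

    def probe_interval(self, index: int) -> tuple[int, int]:
        """Half-open genomic interval covered by one probe."""
        return int(self.starts[index]), int(self.starts[index] + self.lengths[index])


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit: the genomic span targets are measured against."""

    gene_id: str
    arm_id: str
    tx_start: int
    tx_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tx_start < 0:
            raise ValueError(f"gene {self.gene_id}: negative coordinate")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"gene {self.gene_id}: tx_end <= tx_start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class RatioTrack:
    """Per-probe log2(Dam-fusion / Dam-only) signal for one arm, one replicate.

    ``dye_swapped`` marks a replicate hybridised with the fluorophores
    exchanged; its stored ratios have inverted orientation until
    :func:`damidephys.normalization.orient_dye_swap` is applied.
    """

    replicate_id: str
    arm_id: str
    values: np.ndarray
    dye_swapped: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("ratio values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("ratio values must be finite")

    @property
    def n_probes(self) -> int:
        return int(self.values.size)

    def copy_with(self, **kw) -> "RatioTrack":
        return replace(self, **kw)


@dataclass
class Peak:
    """A run of consecutive probes above the detection threshold.

    Height is the *minimum* probe value in the run: a peak of height H and
    width W is, for every h <= H, a run of >= W probes >= h, which keeps the
    observed-peak definition consistent with the permutation-null run counts.
    """

    arm_id: str
    replicate_id: str
    first_probe: int
    last_probe: int
    start_bp: int
    end_bp: int
    height_log2: float
    fdr: float | None = None

    @property
    def width_probes(self) -> int:
        return self.last_probe - self.first_probe + 1

    def __post_init__(self) -> None:
        if self.last_probe < self.first_probe:
            raise ValueError("peak last_probe < first_probe")
        if self.end_bp <= self.start_bp:
            raise ValueError("peak end_bp <= start_bp")


@dataclass
class ConsensusPeak:
    """A binding event supported by overlapping peaks in every replicate.

    The interval is the union of the member intervals; the FDR is the worst
    (largest) member FDR, i.e. a consensus peak is only as credible as its
    least credible replicate.
    """

    arm_id: str
    start_bp: int
    end_bp: int
    members: list[Peak] = field(default_factory=list)
    fdr: float = 1.0

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("consensus end_bp <= start_bp")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("consensus fdr outside [0, 1]")


@dataclass(frozen=True)
class PlantedPeak:
    """Ground-truth binding event injected by the array simulator."""

    arm_id: str
    first_probe_index: int
    width_probes: int
    height_log2: float

    def __post_init__(self) -> None:
        if self.width_probes < 1:
            raise ValueError("planted width_probes must be >= 1")
        if self.height_log2 <= 0:
            raise ValueError("planted height_log2 must be > 0")

    @property
    def last_probe_index(self) -> int:
        return self.first_probe_index + self.width_probes - 1


@dataclass
class TargetCall:
    """A gene with at least one passing binding event within the window."""

    gene_id: str
    peaks: list[ConsensusPeak]
    best_fdr: float
    min_distance_bp: int

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)
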