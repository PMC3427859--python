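"""Readers and writers for every on-disk artifact of the DamID arm.

Formats are deliberately plain text (probe table TSV, bedGraph tracks,
BED6+1 peaks, GFF3 genes, TSV target table) so fixtures diff cleanly.
Every writer round-trips with its reader: coordinates exactly, ratio values
to six decimals.

Coordinates are 0-based half-open internally and in BED/bedGraph output;
GFF3 (1-based, closed) is converted at this boundary.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import gffutils

from .core import ConsensusPeak, GeneModel, Peak, ProbeLayout, RatioTrack, TargetCall

PROBE_LEN_RANGE = (50, 75)
RATIO_DECIMALS = 6


class FormatError(ValueError):
    """Malformed input file (carries the offending line number where known)."""


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def read_probe_layout(path: str | os.PathLike) -> dict[str, ProbeLayout]:
    """Read a tab-delimited probe table (columns: arm, start, length).

    Returns one :class:`ProbeLayout` per arm with probes sorted as given;
    unsorted or duplicate starts within an arm are rejected with the
    offending line number. Probe lengths outside [50, 75] raise a warning
    but are retained.
    """
    arms: dict[str, list[tuple[int, int]]] = {}
    last_start: dict[str, tuple[int, int]] = {}  # arm -> (start, lineno)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0].strip() != "arm":
            raise FormatError(f"{path}: line 1: expected header 'arm\\tstart\\tlength'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            arm, start_s, length_s = fields[0], fields[1], fields[2]
            try:
                start, length = int(start_s), int(length_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if arm in last_start and start <= last_start[arm][0]:
                kind = "duplicate" if start == last_start[arm][0] else "unsorted"
                raise FormatError(f"{path}: line {lineno}: {kind} start {start} on arm {arm}")
            if not (PROBE_LEN_RANGE[0] <= length <= PROBE_LEN_RANGE[1]):
                warnings.warn(
                    f"{path}: line {lineno}: probe length {length} outside "
                    f"[{PROBE_LEN_RANGE[0]}, {PROBE_LEN_RANGE[1]}]; retained",
                    stacklevel=2,
                )
            last_start[arm] = (start, lineno)
            arms.setdefault(arm, []).append((start, length))
    out: dict[str, ProbeLayout] = {}
    for arm, rows in arms.items():
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        lengths = np.array([r[1] for r in rows], dtype=np.int64)
        out[arm] = ProbeLayout(arm_id=arm, starts=starts, lengths=lengths)
    return out


def write_probe_layout(layouts: dict[str, ProbeLayout] | Iterable[ProbeLayout],
                       path: str | os.PathLike) -> None:
    if isinstance(layouts, dict):
        layouts = layouts.values()
    with open(path, "w") as fh:
        fh.write("arm\tstart\tlength\n")
        for layout in layouts:
            for start, length in zip(layout.starts, layout.lengths):
                fh.write(f"{layout.arm_id}\t{int(start)}\t{int(length)}\n")


# ---------------------------------------------------------------------------
# bedGraph ratio tracks
# ---------------------------------------------------------------------------

def read_ratio_track(path: str | os.PathLike, layouts: dict[str, ProbeLayout],
                     replicate_id: str = "", dye_swapped: bool = False,
                     ) -> dict[str, RatioTrack]:
    """Read a bedGraph with one interval per probe into per-arm tracks.

    Every interval must start at a probe start of its arm's layout; probes
    with no interval are an error naming their indices.
    """
    index_of: dict[str, dict[int, int]] = {
        arm: {int(s): i for i, s in enumerate(lay.starts)} for arm, lay in layouts.items()
    }
    values: dict[str, np.ndarray] = {
        arm: np.full(lay.n_probes, np.nan) for arm, lay in layouts.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            arm, start = fields[0], int(fields[1])
            if arm not in index_of:
                raise FormatError(f"{path}: line {lineno}: unknown arm {arm}")
            if start not in index_of[arm]:
                raise FormatError(
                    f"{path}: line {lineno}: interval start {start} matches no probe on arm {arm}"
                )
            values[arm][index_of[arm][start]] = float(fields[3])
    tracks: dict[str, RatioTrack] = {}
    for arm, vals in values.items():
        missing = np.flatnonzero(np.isnan(vals))
        if missing.size:
            raise FormatError(
                f"{path}: arm {arm}: missing values for probe indices "
                f"{', '.join(map(str, missing.tolist()))}"
            )
        tracks[arm] = RatioTrack(replicate_id=replicate_id, arm_id=arm,
                                 values=vals, dye_swapped=dye_swapped)
    return tracks


def write_ratio_track(tracks: dict[str, RatioTrack] | Iterable[RatioTrack],
                      layouts: dict[str, ProbeLayout], path: str | os.PathLike) -> None:
    if isinstance(tracks, dict):
        tracks = tracks.values()
    with open(path, "w") as fh:
        for track in tracks:
            layout = layouts[track.arm_id]
            if track.n_probes != layout.n_probes:
                raise ValueError(
                    f"track for arm {track.arm_id} has {track.n_probes} values, "
                    f"layout has {layout.n_probes} probes"
                )
            for start, length, value in zip(layout.starts, layout.lengths, track.values):
                fh.write(
                    f"{track.arm_id}\t{int(start)}\t{int(start + length)}\t"
                    f"{value:.{RATIO_DECIMALS}f}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_genes_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse GFF3 ``gene`` features into :class:`GeneModel`s.

    GFF3 is 1-based closed; coordinates are shifted to 0-based half-open on
    ingest. A gene without an ID attribute, or with end <= start after
    conversion, is rejected.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if "ID" not in feat.attributes:
            raise FormatError(f"{path}: gene at {feat.seqid}:{feat.start} lacks ID attribute")
        gene_id = feat.attributes["ID"][0]
        tx_start, tx_end = feat.start - 1, feat.end  # to 0-based half-open
        if tx_end <= tx_start:
            raise FormatError(f"{path}: gene {gene_id}: end <= start")
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(GeneModel(gene_id=gene_id, arm_id=feat.seqid,
                               tx_start=tx_start, tx_end=tx_end, strand=strand))
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.arm_id}\t.\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED peaks and target tables
# ---------------------------------------------------------------------------

def _bed_score(height: float) -> int:
    return int(round(min(max(height, 0.0), 10.0) * 100))


def write_peaks_bed(peaks: Sequence[Peak | ConsensusPeak], path: str | os.PathLike) -> None:
    """Write peaks as BED6+1 with the FDR in column 7 (``NA`` when unset)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            if isinstance(p, ConsensusPeak):
                name, height, fdr = f"consensus_{i}", max(
                    (m.height_log2 for m in p.members), default=0.0), p.fdr
            else:
                name = f"peak_{p.replicate_id}_{i}"
                height, fdr = p.height_log2, p.fdr
            fdr_s = "NA" if fdr is None else f"{fdr:.6g}"
            fh.write(
                f"{p.arm_id}\t{p.start_bp}\t{p.end_bp}\t{name}\t{_bed_score(height)}\t.\t{fdr_s}\n"
            )


def read_peaks_bed(path: str | os.PathLike) -> list[ConsensusPeak]:
    """Read a BED6+1 peak file back as interval+FDR records (for round trips)."""
    out: list[ConsensusPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}: line {lineno}: expected BED6+1")
            fdr = 1.0 if f[6] == "NA" else float(f[6])
            out.append(ConsensusPeak(arm_id=f[0], start_bp=int(f[1]), end_bp=int(f[2]),
                                     members=[], fdr=fdr))
    return out


def write_target_table(targets: Sequence[TargetCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_peaks\tbest_fdr\tmin_distance_bp\n")
        for t in targets:
            fh.write(f"{t.gene_id}\t{t.n_peaks}\t{t.best_fdr:.6g}\t{t.min_distance_bp}\n")


def read_target_table(path: str | os.PathLike) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
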