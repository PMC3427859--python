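"""Model/Results interface over the DamID binding analysis.

`DamidBindingModel` bundles the inputs of the binding-site analysis (probe
layouts, per-replicate ratio tracks, gene annotation) with its tuning
parameters; `fit()` runs orientation, normalization, peak calling, the
permutation-null FDR surface fits, replicate consensus and gene-target
assignment, returning a `DamidResults` carrying every intermediate table
plus a printable `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fdr_model, io_formats, normalization, peak_calling, synthetic_damid, \
    target_assignment
from .core import ConsensusPeak, GeneModel, Peak, ProbeLayout, RatioTrack, TargetCall
from .fdr_model import FDRModel

__all__ = ["DamidBindingModel", "DamidResults"]


@dataclass
class DamidResults:
    """Fitted results of the binding analysis."""

    model: "DamidBindingModel"
    peaks_by_replicate: dict[str, list[Peak]]
    fdr_models: dict[tuple[str, str], FDRModel]
    consensus_peaks: list[ConsensusPeak]
    targets: list[TargetCall]
    seed: int

    @property
    def n_target_genes(self) -> int:
        return target_assignment.count_target_genes(self.targets)

    def consensus_frame(self) -> pd.DataFrame:
        rows = [{"arm": c.arm_id, "start_bp": c.start_bp, "end_bp": c.end_bp,
                 "n_replicates": len({m.replicate_id for m in c.members}),
                 "fdr": c.fdr} for c in self.consensus_peaks]
        return pd.DataFrame(rows, columns=["arm", "start_bp", "end_bp",
                                           "n_replicates", "fdr"])

    def target_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": t.gene_id, "n_peaks": t.n_peaks, "best_fdr": t.best_fdr,
                 "min_distance_bp": t.min_distance_bp} for t in self.targets]
        return pd.DataFrame(rows, columns=["gene_id", "n_peaks", "best_fdr",
                                           "min_distance_bp"])

    def fdr_model_frame(self) -> pd.DataFrame:
        rows = [{"arm": k[0], "replicate": k[1], "a": m.a, "b": m.b, "c": m.c,
                 "n_cells": m.n_cells, "resid_rms": m.resid_rms}
                for k, m in self.fdr_models.items()]
        return pd.DataFrame(rows, columns=["arm", "replicate", "a", "b", "c",
                                           "n_cells", "resid_rms"])

    def summary(self) -> str:
        m = self.model
        n_rep_peaks = {r: len(p) for r, p in self.peaks_by_replicate.items()}
        lines = [
            "DamID binding analysis",
            "=" * 54,
            f"arms: {len(m.layouts)}   probes: {sum(l.n_probes for l in m.layouts.values())}"
            f"   replicates: {len(m.tracks)}   genes: {len(m.genes)}",
            f"peak calling: log2 ratio >= {m.height_threshold} over >= {m.min_width} probes",
            f"per-replicate peaks: {n_rep_peaks}",
            f"null: {m.iterations} permutations/cell, heights "
            f"{m.heights[0]:.2f}..{m.heights[-1]:.2f}, widths "
            f"{int(m.widths[0])}..{int(m.widths[-1])} (seed {self.seed})",
        ]
        for k, fm_ in sorted(self.fdr_models.items()):
            lines.append(f"  ln FDR [{k[0]}/{k[1]}] = {fm_.a:+.2f} {fm_.b:+.2f}*h "
                         f"{fm_.c:+.2f}*w  ({fm_.n_cells} cells, rms {fm_.resid_rms:.2f})")
        sig = [c for c in self.consensus_peaks if c.fdr < m.fdr_threshold]
        lines += [
            f"consensus peaks (all replicates): {len(self.consensus_peaks)}; "
            f"at FDR < {m.fdr_threshold:g}: {len(sig)}",
            f"target genes (peak within {m.window_bp} bp): {self.n_target_genes}",
        ]
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rep, peaks in self.peaks_by_replicate.items():
            io_formats.write_peaks_bed(peaks, out / f"peaks_{rep}.bed")
        io_formats.write_peaks_bed(self.consensus_peaks, out / "consensus_peaks.bed")
        io_formats.write_target_table(self.targets, out / "targets.tsv")
        self.fdr_model_frame().to_csv(out / "fdr_models.tsv", sep="\t", index=False)


@dataclass
class DamidBindingModel:
    """The binding-site analysis, parameterised and ready to fit.

    Thresholds default to the production analysis: peaks of >= 8
    consecutive probes over a 2-fold (1.0 log2) ratio change; null grid of
    heights 0.10-1.25 log2 and widths 6-15 probes at 20 randomizations per
    cell; consensus across all replicates with the worst member FDR;
    targets at FDR < 0.1% within 5 kb of a transcription unit.
    """

    layouts: Mapping[str, ProbeLayout]
    tracks: Mapping[str, Mapping[str, RatioTrack]]   # replicate -> arm -> track
    genes: Sequence[GeneModel] = field(default_factory=list)
    height_threshold: float = peak_calling.DEFAULT_HEIGHT_THRESHOLD
    min_width: int = peak_calling.DEFAULT_MIN_WIDTH
    heights: np.ndarray = field(default_factory=lambda: fdr_model.DEFAULT_HEIGHTS)
    widths: np.ndarray = field(default_factory=lambda: fdr_model.DEFAULT_WIDTHS)
    iterations: int = fdr_model.DEFAULT_ITERATIONS
    consensus_required: int | str = "all"
    fdr_threshold: float = target_assignment.DEFAULT_FDR_THRESHOLD
    window_bp: int = target_assignment.DEFAULT_WINDOW_BP
    nearest_only: bool = False

    @classmethod
    def from_files(cls, probe_table, track_paths: Mapping[str, str], genes_gff3=None,
                   dye_swap_replicate: str | None = None, **kw) -> "DamidBindingModel":
        """Build from a probe table, per-replicate bedGraphs and a GFF3."""
        layouts = io_formats.read_probe_layout(probe_table)
        tracks = {
            rep: io_formats.read_ratio_track(path, layouts, replicate_id=rep,
                                             dye_swapped=(rep == dye_swap_replicate))
            for rep, path in track_paths.items()
        }
        genes = io_formats.read_genes_gff3(genes_gff3) if genes_gff3 else []
        return cls(layouts=layouts, tracks=tracks, genes=genes, **kw)

    @classmethod
    def from_simulation(cls, config: synthetic_damid.ArraySimConfig,
                        planted=None, genes=None, **kw
                        ) -> tuple["DamidBindingModel", list]:
        """Simulate an array and return (model, planted truth set)."""
        layouts = synthetic_damid.make_layout(config)
        if genes is None:
            genes = synthetic_damid.make_genes(config, layouts)
        if planted is None:
            planted = synthetic_damid.default_planted_peaks(config, layouts)
        tracks = synthetic_damid.plant_and_simulate(layouts, planted, config)
        return cls(layouts=layouts, tracks=tracks, genes=genes, **kw), planted

    def fit(self, seed: int = 0) -> DamidResults:
        """Run the full analysis; ``seed`` drives the permutation null."""
        prepared = {rep: normalization.prepare_replicate(trs)
                    for rep, trs in self.tracks.items()}
        peaks_by_rep = {
            rep: [p for arm, tr in trs.items()
                  for p in peak_calling.find_runs(tr, self.layouts[arm],
                                                  self.height_threshold, self.min_width)]
            for rep, trs in prepared.items()
        }
        peaks_by_rep, models = fdr_model.assign_fdrs_lazily(
            prepared, self.layouts, peaks_by_rep,
            heights=self.heights, widths=self.widths,
            iterations=self.iterations, seed=seed)
        consensus = fdr_model.consensus_across_replicates(
            peaks_by_rep, n_required=self.consensus_required)
        targets = target_assignment.assign_targets(
            consensus, self.genes, fdr_threshold=self.fdr_threshold,
            window_bp=self.window_bp, nearest_only=self.nearest_only)
        return DamidResults(model=self, peaks_by_replicate=peaks_by_rep,
                            fdr_models=models, consensus_peaks=consensus,
                            targets=targets, seed=seed)
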