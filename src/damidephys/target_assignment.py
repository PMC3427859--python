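"""Gene-level target calls from consensus binding peaks.

A gene is a target when a binding event with FDR < 0.1% lies within 5 kb
of its transcription unit (the full tx_start..tx_end span, not the TSS
alone). All genes within the window are called — a single intergenic peak
between two divergently transcribed genes supports both; an optional
nearest-gene-only mode restricts each peak to its closest gene(s).
"""

from __future__ import annotations

from typing import Sequence

from .core import ConsensusPeak, GeneModel, TargetCall

__all__ = ["DEFAULT_FDR_THRESHOLD", "DEFAULT_WINDOW_BP", "peak_gene_distance",
           "assign_targets", "count_target_genes"]

DEFAULT_FDR_THRESHOLD = 0.001  # strict: FDR < 0.1%
DEFAULT_WINDOW_BP = 5000


def peak_gene_distance(peak: ConsensusPeak, gene: GeneModel) -> int:
    """Gap in bp between a peak and a transcription unit; 0 when they overlap.

    Both intervals are half-open; the distance is strand-independent and
    symmetric. Caller must ensure both lie on the same arm.
    """
    if peak.arm_id != gene.arm_id:
        raise ValueError(
            f"distance undefined across arms ({peak.arm_id} vs {gene.arm_id})")
    if peak.start_bp < gene.tx_end and gene.tx_start < peak.end_bp:
        return 0
    if peak.end_bp <= gene.tx_start:
        return gene.tx_start - peak.end_bp
    return peak.start_bp - gene.tx_end


def assign_targets(peaks: Sequence[ConsensusPeak], genes: Sequence[GeneModel],
                   fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                   window_bp: int = DEFAULT_WINDOW_BP,
                   nearest_only: bool = False) -> list[TargetCall]:
    """Call every gene with >= 1 passing peak within ``window_bp`` as a target.

    A peak passes when its FDR is strictly below ``fdr_threshold``. With
    ``nearest_only`` a peak supports only the gene(s) at minimal distance
    from it (ties — e.g. a peak equidistant from two divergent genes —
    still support all tied genes).
    """
    passing = [p for p in peaks if p.fdr < fdr_threshold]
    support: dict[str, list[tuple[ConsensusPeak, int]]] = {}

    if nearest_only:
        genes_by_arm: dict[str, list[GeneModel]] = {}
        for g in genes:
            genes_by_arm.setdefault(g.arm_id, []).append(g)
        for p in passing:
            cands = [(peak_gene_distance(p, g), g) for g in genes_by_arm.get(p.arm_id, [])]
            cands = [(d, g) for d, g in cands if d <= window_bp]
            if not cands:
                continue
            dmin = min(d for d, _ in cands)
            for d, g in cands:
                if d == dmin:
                    support.setdefault(g.gene_id, []).append((p, d))
    else:
        for g in genes:
            for p in passing:
                if p.arm_id != g.arm_id:
                    continue
                d = peak_gene_distance(p, g)
                if d <= window_bp:
                    support.setdefault(g.gene_id, []).append((p, d))

    calls = []
    for gene_id in sorted(support):
        pairs = support[gene_id]
        calls.append(TargetCall(
            gene_id=gene_id,
            peaks=[p for p, _ in pairs],
            best_fdr=min(p.fdr for p, _ in pairs),
            min_distance_bp=min(d for _, d in pairs),
        ))
    return calls


def count_target_genes(targets: Sequence[TargetCall]) -> int:
    """Number of distinct target genes."""
    return len({t.gene_id for t in targets})
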