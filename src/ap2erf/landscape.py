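"""Chromosomal distribution summaries and tandem duplication clusters.

Same-group genes repeated at short chromosomal distances are the
signature of recent local (tandem) duplication; clusters are maximal
runs of same-group genes whose adjacent midpoint gaps stay below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genemodel import GeneModel

DEFAULT_MAX_GAP_BP = 100_000


@dataclass(frozen=True)
class GenomicCluster:
    chromosome: str
    members: tuple[str, ...]       # gene ids ordered by position
    group: str
    span_bp: int
    max_adjacent_gap_bp: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")


def placements_table(models: Sequence[GeneModel],
                     assignments: pd.DataFrame) -> pd.DataFrame:
    """Join gene placements (midpoint positions) with family/group labels."""
    pos = pd.DataFrame(
        [{"gene_id": m.gene_id, "chromosome": m.chromosome,
          "position": m.midpoint} for m in models])
    return pos.merge(assignments[["gene_id", "family", "group"]],
                     on="gene_id", how="inner")


def chromosome_counts(placements: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-chromosome family/group counts plus the unplaced gene count.

    Also reports each group's fraction of its chromosome's genes.
    """
    unplaced = int(placements["chromosome"].isna().sum())
    placed = placements.dropna(subset=["chromosome"])
    counts = (placed.groupby(["chromosome", "family", "group"], dropna=False)
              .size().rename("count").reset_index())
    per_chrom = placed.groupby("chromosome").size()
    counts["fraction_of_chromosome"] = counts.apply(
        lambda r: r["count"] / per_chrom[r["chromosome"]], axis=1)
    return counts, unplaced


def find_tandem_clusters(
    placements: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    min_size: int = 2,
    same_group: bool = True,
) -> list[GenomicCluster]:
    """Maximal runs of nearby same-group genes on a chromosome.

    Genes are ordered by midpoint per chromosome; a run extends while the
    next gene has the same group (when ``same_group``) and lies within
    ``max_gap`` bp of the previous member.
    """
    clusters: list[GenomicCluster] = []
    placed = placements.dropna(subset=["chromosome"])
    for chrom, sub in placed.groupby("chromosome"):
        sub = sub.sort_values(["position", "gene_id"], kind="mergesort")
        run: list[tuple[str, float, str]] = []

        def flush() -> None:
            if len(run) >= min_size:
                gaps = [int(b[1] - a[1]) for a, b in zip(run, run[1:])]
                clusters.append(GenomicCluster(
                    chromosome=chrom,
                    members=tuple(g for g, _, _ in run),
                    group=run[0][2],
                    span_bp=int(run[-1][1] - run[0][1]),
                    max_adjacent_gap_bp=max(gaps),
                ))

        for r in sub.itertuples():
            key = r.group if same_group else "*"
            if run and key == run[-1][2] and (r.position - run[-1][1]) <= max_gap:
                run.append((r.gene_id, r.position, key))
            else:
                flush()
                run = [(r.gene_id, r.position, key)]
        flush()
    return clusters


def clusters_table(clusters: Sequence[GenomicCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chromosome": c.chromosome, "group": c.group,
          "n_members": len(c.members), "members": ";".join(c.members),
          "span_bp": c.span_bp, "max_adjacent_gap_bp": c.max_adjacent_gap_bp}
         for c in clusters])


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of paralogous-segment annotations (0-based,
    half-open; 4th column = segment label)."""
    seg = pd.read_csv(path, sep="\t", header=None,
                      names=["chromosome", "start", "end", "label"])
    if (seg["start"] < 0).any() or (seg["start"] >= seg["end"]).any():
        raise ValueError("malformed segment interval(s) in BED")
    return seg


def segment_annotation(placements: pd.DataFrame,
                       segments: pd.DataFrame) -> pd.Series:
    """Map each gene to the label of the segment containing its midpoint.

    Segments use the BED half-open convention: a gene exactly on an end
    coordinate falls outside, one on a start coordinate falls inside.
    Genes outside all segments (or unplaced) get NA.
    """
    labels = {}
    for r in placements.itertuples():
        label = None
        if pd.notna(r.chromosome):
            sub = segments[segments["chromosome"] == r.chromosome]
            for s in sub.itertuples():
                if s.start <= r.position < s.end:
                    label = s.label
                    break
        labels[r.gene_id] = label
    return pd.Series(labels, name="segment")
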