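"""qPCR relative-expression profiles (ΔCt) across tissues.

Ct is the amplification cycle at which fluorescence crosses a fixed
threshold; lower Ct means higher transcript abundance. Relative
expression for a gene in a sample is

    ΔCt = Ct_HK − Ct_gene

where Ct_HK is the arithmetic mean Ct of four housekeeping genes in the
same sample-replicate (averaging Ct arithmetically is the log-scale
equivalent of geometric averaging of linear quantities). Higher ΔCt
means higher expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_DETECTION_CUTOFF = 40.0
EFFICIENCY_WINDOW = (1.7, 2.0)

CT_COLUMNS = ["gene_id", "tissue", "stage", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format Ct observations plus the housekeeping set.

    ``data`` columns: gene_id, tissue, stage, replicate, ct (NaN = not
    detected). ``efficiency`` optionally maps primer (gene) ids to the
    per-primer amplification efficiency estimated upstream.
    """

    data: pd.DataFrame
    hk_genes: tuple[str, str, str, str]
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if len(self.hk_genes) != 4:
            raise ValueError("exactly 4 housekeeping genes are required")
        genes = set(self.data["gene_id"])
        absent = [g for g in self.hk_genes if g not in genes]
        if absent:
            raise ValueError(f"housekeeping gene(s) absent from table: {absent}")

    @property
    def samples(self) -> pd.DataFrame:
        return (self.data[["tissue", "stage", "replicate"]]
                .drop_duplicates().reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 hk_genes: Sequence[str]) -> "CtTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(data=df, hk_genes=tuple(hk_genes))


@dataclass
class RelExpression:
    """Per-replicate ΔCt values and per-condition summaries."""

    delta_ct: pd.DataFrame        # gene_id, tissue, stage, replicate, delta_ct
    condition_stats: pd.DataFrame  # gene_id, tissue, stage, mean, sd, n
    hk_genes: tuple[str, ...]
    dropped_replicates: list[tuple] = field(default_factory=list)
    ct_data: pd.DataFrame | None = None


def normalize(ct: CtTable) -> RelExpression:
    """ΔCt = mean HK Ct − gene Ct, per gene per sample-replicate.

    A sample-replicate in which any housekeeping gene failed (NA Ct) is
    excluded for all genes, with a warning: its normalizer is undefined.
    """
    df = ct.data.copy()
    hk = df[df["gene_id"].isin(ct.hk_genes)]
    hk_stats = hk.groupby(["tissue", "stage", "replicate"])["ct"].agg(
        ["mean", "count", lambda s: s.isna().any()])
    hk_stats.columns = ["hk_mean", "hk_n", "hk_has_na"]
    bad = hk_stats[hk_stats["hk_has_na"] | (hk_stats["hk_n"] < 4)].index.tolist()
    if bad:
        warnings.warn(f"excluding {len(bad)} replicate(s) with failed "
                      f"housekeeping measurements: {bad}")
    df = df.merge(hk_stats.reset_index()[["tissue", "stage", "replicate",
                                          "hk_mean", "hk_has_na"]],
                  on=["tissue", "stage", "replicate"], how="left")
    df = df[~df["hk_has_na"].fillna(True)]
    df["delta_ct"] = df["hk_mean"] - df["ct"]
    delta = df[["gene_id", "tissue", "stage", "replicate", "delta_ct"]]
    stats = (delta.dropna(subset=["delta_ct"])
             .groupby(["gene_id", "tissue", "stage"])["delta_ct"]
             .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
             .reset_index())
    return RelExpression(delta_ct=delta.reset_index(drop=True),
                         condition_stats=stats,
                         hk_genes=ct.hk_genes,
                         dropped_replicates=bad,
                         ct_data=ct.data)


def detectability(rel: RelExpression,
                  cutoff: float = DEFAULT_DETECTION_CUTOFF) -> pd.Series:
    """True for genes with at least one Ct below the detection cutoff in
    at least one sample; all-NA genes never reached detectable levels."""
    if rel.ct_data is None:
        raise ValueError("RelExpression lacks the underlying Ct data")
    ok = rel.ct_data.assign(det=lambda d: d["ct"] < cutoff)
    return ok.groupby("gene_id")["det"].any()


def condition_matrix(rel: RelExpression) -> pd.DataFrame:
    """Genes x conditions matrix of mean ΔCt (columns = tissue/stage)."""
    stats = rel.condition_stats.copy()
    stats["condition"] = stats["tissue"] + "/" + stats["stage"]
    return stats.pivot(index="gene_id", columns="condition", values="mean")


def _pairwise_complete_euclidean(mat: np.ndarray, min_overlap: int = 2) -> np.ndarray:
    """Euclidean distance over shared non-NA columns, rescaled to the full
    number of columns; pairs sharing < min_overlap conditions get the
    maximum observed distance (joined last)."""
    n, p = mat.shape
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            k = int(shared.sum())
            if k < min_overlap:
                undefined.append((i, j))
                continue
            diff = mat[i, shared] - mat[j, shared]
            d[i, j] = d[j, i] = float(np.sqrt((diff ** 2).sum() * p / k))
    if undefined:
        worst = d.max()
        for i, j in undefined:
            d[i, j] = d[j, i] = worst * 2 + 1.0
    return d


def cluster_genes(rel: RelExpression,
                  genes: Sequence[str] | None = None,
                  min_overlap: int = 2) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage hierarchical clustering of expression profiles.

    Operates on condition-mean ΔCt vectors; genes with no measurable
    condition are excluded with a warning. Returns (leaf order, scipy
    linkage matrix, dendrogram as Newick).
    """
    mat = condition_matrix(rel)
    if genes is not None:
        mat = mat.loc[[g for g in genes if g in mat.index]]
    all_na = mat.index[mat.isna().all(axis=1)]
    if len(all_na):
        warnings.warn(f"excluding {len(all_na)} gene(s) with no "
                      f"measurable condition from clustering")
        mat = mat.drop(index=all_na)
    if len(mat) < 2:
        raise ValueError("clustering needs >= 2 genes with data")
    ids = list(mat.index)
    d = _pairwise_complete_euclidean(mat.to_numpy(), min_overlap)
    z = hierarchy.average(squareform(d, checks=False))
    order = [ids[i] for i in hierarchy.leaves_list(z)]
    newick = _linkage_to_newick(z, ids)
    return order, z, newick


def _linkage_to_newick(z: np.ndarray, ids: Sequence[str]) -> str:
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(render(c, tree.dist) for c in (tree.left, tree.right))
    return f"({inner});"


def efficiency_qc(ct: CtTable,
                  lo: float = EFFICIENCY_WINDOW[0],
                  hi: float = EFFICIENCY_WINDOW[1]) -> pd.DataFrame:
    """Flag primers whose amplification efficiency falls outside
    [lo, hi] (bounds inclusive)."""
    if not ct.efficiency:
        raise ValueError("no per-primer efficiencies present")
    rows = [{"gene_id": g, "efficiency": e, "passed": lo <= e <= hi}
            for g, e in ct.efficiency.items()]
    return pd.DataFrame(rows)
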