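"""Differential expression by ΔΔCt and gene-group enrichment.

The ΔΔCt of a gene between two stages of the same tissue is the change
in its housekeeping-normalized relative expression,

    ΔΔCt = mean_b(ΔCt) − mean_a(ΔCt),

which equals the log2 fold change under the perfect-efficiency (2.0)
amplification convention. Genes with |log2FC| at or above a threshold
(default 2, i.e. 4-fold) are called up/down regulated. Per-group
overrepresentation among the called genes is tested with a one-sided
Fisher's exact test against the catalogue background.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import RelExpression

DEFAULT_LOG2FC_THRESHOLD = 2.0


def ddct_fold_change(rel: RelExpression, tissue: str,
                     stage_a: str, stage_b: str) -> pd.DataFrame:
    """Per-gene log2 fold change (ΔΔCt) between two stages of a tissue.

    log2FC is the difference of condition-mean ΔCt (stage_b − stage_a);
    the SD is that of replicate-wise ΔΔCt values over replicates present
    in both stages (requires >= 2 paired replicates, else NaN). Genes
    missing a stage entirely get NaN with a reason.
    """
    d = rel.delta_ct
    sub = d[(d["tissue"] == tissue) & (d["stage"].isin([stage_a, stage_b]))]
    if sub.empty or set(sub["stage"]) != {stage_a, stage_b}:
        raise ValueError(f"both stages {stage_a!r}/{stage_b!r} must be "
                         f"present for tissue {tissue!r}")
    rows = []
    for gene, g in sub.groupby("gene_id"):
        a = g[g["stage"] == stage_a].dropna(subset=["delta_ct"])
        b = g[g["stage"] == stage_b].dropna(subset=["delta_ct"])
        if a.empty or b.empty:
            missing = stage_a if a.empty else stage_b
            rows.append({"gene_id": gene, "log2fc": np.nan, "sd": np.nan,
                         "n_pairs": 0, "reason": f"no data in stage {missing}"})
            continue
        log2fc = b["delta_ct"].mean() - a["delta_ct"].mean()
        pa = a.set_index("replicate")["delta_ct"]
        pb = b.set_index("replicate")["delta_ct"]
        shared = pa.index.intersection(pb.index)
        paired = (pb.loc[shared] - pa.loc[shared])
        sd = float(paired.std(ddof=1)) if len(paired) >= 2 else np.nan
        rows.append({"gene_id": gene, "log2fc": float(log2fc), "sd": sd,
                     "n_pairs": len(paired), "reason": ""})
    return pd.DataFrame(rows)


def call_degs(fcs: pd.DataFrame,
              threshold_log2: float = DEFAULT_LOG2FC_THRESHOLD,
              assignments: pd.DataFrame | None = None,
              tissue: str | None = None) -> pd.DataFrame:
    """Partition genes into up / down / unchanged at |log2FC| >= threshold.

    Accepts any table with gene_id and a log2 fold-change column
    (``log2fc`` or ``fold_change_log2``). Records are sorted by
    descending |log2FC|; single-replicate calls (no SD) are flagged
    low-confidence rather than dropped.
    """
    df = fcs.copy()
    if "log2fc" not in df.columns:
        df = df.rename(columns={"fold_change_log2": "log2fc"})
    df = df.dropna(subset=["log2fc"])
    df["direction"] = "unchanged"
    df.loc[df["log2fc"] >= threshold_log2, "direction"] = "up"
    df.loc[df["log2fc"] <= -threshold_log2, "direction"] = "down"
    df["low_confidence"] = df["sd"].isna() if "sd" in df.columns else False
    if tissue is not None:
        df["tissue"] = tissue
    if assignments is not None:
        df = df.merge(assignments[["gene_id", "family", "group"]],
                      on="gene_id", how="left")
    return (df.reindex(df["log2fc"].abs()
                       .sort_values(ascending=False, kind="mergesort").index)
            .reset_index(drop=True))


def fisher_from_counts(k: int, n: int, K: int, N: int) -> float:
    """One-sided (greater) Fisher p: probability of >= k in-group genes
    among n draws from a catalogue of N genes of which K are in-group."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError("inconsistent 2x2 counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_group_enrichment(
    deg_genes: Sequence[str],
    catalogue_groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    background_counts: Mapping[str, int] | None = None,
    background_total: int | None = None,
) -> pd.DataFrame:
    """Per-group overrepresentation among DEGs, one-sided Fisher test.

    ``catalogue_groups`` labels every catalogue gene with its group (the
    background); alternatively pass ``background_counts``/``_total``
    directly (e.g. printed whole-genome counts). No multiple-testing
    correction is applied to the reported p (the convention for a single
    planned contrast); a Benjamini-Hochberg column is emitted alongside.
    """
    groups = pd.Series(dict(catalogue_groups)) if not isinstance(
        catalogue_groups, pd.Series) else catalogue_groups
    if background_counts is None:
        background_counts = groups.value_counts().to_dict()
        background_total = len(groups)
    if background_total is None:
        raise ValueError("background_total required with background_counts")
    deg_genes = list(deg_genes)
    n = len(deg_genes)
    deg_group = groups.reindex(deg_genes)
    rows = []
    for group, K in sorted(background_counts.items()):
        if K == 0:
            continue  # no catalogue members: nothing to test
        k = int((deg_group == group).sum())
        p = fisher_from_counts(k, n, K, background_total)
        rows.append({"group": group, "k": k, "n": n, "K": K,
                     "N": background_total, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] <= alpha
    return df


def cross_tissue_sets(deg_lists: Mapping[str, Sequence[str]],
                      groups: Mapping[str, str] | None = None) -> dict:
    """Set algebra over named DEG lists with exact, case-sensitive names.

    Returns intersections and asymmetric differences for every list
    pair, plus per-group tallies per list when group labels are given.
    """
    if len(deg_lists) < 2:
        raise ValueError("need >= 2 DEG lists")
    sets = {name: set(genes) for name, genes in deg_lists.items()}
    names = list(sets)
    out: dict = {"lists": {k: sorted(v) for k, v in sets.items()},
                 "sizes": {k: len(v) for k, v in sets.items()},
                 "pairs": {}}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out["pairs"][f"{a}&{b}"] = {
                "intersection": sorted(sets[a] & sets[b]),
                f"only_{a}": sorted(sets[a] - sets[b]),
                f"only_{b}": sorted(sets[b] - sets[a]),
            }
    if groups is not None:
        g = pd.Series(dict(groups))
        out["group_tallies"] = {
            name: g.reindex(sorted(members)).value_counts().to_dict()
            for name, members in sets.items()}
    return out


def profile_correlation(x: Sequence[float], y: Sequence[float],
                        method: str = "spearman") -> float:
    """Correlation between two expression vectors over non-NA pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("need >= 3 paired non-NA values")
    if method == "spearman":
        return float(stats.spearmanr(x[keep], y[keep]).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x[keep], y[keep]).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# bundled printed-table fixtures

def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled printed table (``table1_counts``, ``table2_skin``,
    ``table3_flesh``) as a DataFrame, names kept exactly as printed."""
    ref = importlib.resources.files("ap2erf.fixtures").joinpath(f"{name}.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def split_family_group(family_group: pd.Series) -> pd.DataFrame:
    """Split printed 'Family-Group' labels (e.g. 'ERF-IX', 'AP2', 'RAV')
    into family and group columns."""
    fams, groups = [], []
    for label in family_group:
        if isinstance(label, str) and label.startswith("ERF-"):
            fams.append("ERF")
            groups.append(label[4:])
        else:
            fams.append(label)
            groups.append(None)
    return pd.DataFrame({"family": fams, "group": groups})
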