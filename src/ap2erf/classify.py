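"""Family and group assignment for AP2-domain proteins.

Family follows domain architecture:

* exactly one AP2 domain, no B3  -> ERF family
* two or more AP2 domains, no B3 -> AP2 family (tandem double domain)
* one AP2 domain plus a B3 domain -> RAV family
* no AP2 domain -> unclassified (excluded from the catalogue)

ERF-family genes are then placed into whole-protein similarity groups
(I-X, VI-L, Xb-L) by nearest labeled reference under global alignment,
corroborated by conserved motifs (CM) outside the DNA-binding domain.
A divergent single-AP2 gene whose nearest reference overall is the
Soloist exemplar is reassigned to the Soloist family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._align import align_identity, make_aligner
from .profile import DomainHit

DEFAULT_MIN_GROUP_SIMILARITY = 0.3
MOTIF_MAX_MISMATCHES = 1


@dataclass(frozen=True)
class ReferenceEntry:
    """A labeled reference protein (Arabidopsis-style panel member)."""

    ref_id: str
    sequence: str
    family: str               # ERF | AP2 | RAV | Soloist
    group: str | None         # only ERF references carry a group
    motif_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family == "ERF" and self.group is None:
            raise ValueError(f"{self.ref_id}: ERF reference requires a group")
        if self.family != "ERF" and self.group is not None:
            raise ValueError(f"{self.ref_id}: non-ERF reference must not have a group")


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str                       # ERF | AP2 | RAV | Soloist | unclassified
    group: str | None
    nearest_ref: str | None
    similarity: float
    motifs_matched: int
    evidence: list[DomainHit] = field(default_factory=list)


def classify_family(hits: Sequence[DomainHit]) -> str:
    """Family from domain architecture alone."""
    n_ap2 = sum(1 for h in hits if h.domain_kind == "AP2")
    n_b3 = sum(1 for h in hits if h.domain_kind == "B3")
    if n_ap2 == 0:
        return "unclassified"
    if n_b3 >= 1:
        return "RAV"
    if n_ap2 >= 2:
        return "AP2"
    return "ERF"


def nearest_reference(
    query: str,
    panel: Sequence[ReferenceEntry],
    aligner=None,
) -> tuple[str, float]:
    """Best-matching reference by global-alignment identity.

    Identity is computed over aligned columns excluding any column where
    either sequence has a gap; ties break to the lexicographically
    smallest reference id.
    """
    if not query:
        raise ValueError("empty query sequence")
    if not panel:
        raise ValueError("empty reference panel")
    if aligner is None:
        aligner = make_aligner()
    best_id, best_sim = None, -1.0
    for ref in sorted(panel, key=lambda r: r.ref_id):
        sim = align_identity(query, ref.sequence, aligner)
        if sim > best_sim:
            best_id, best_sim = ref.ref_id, sim
    return best_id, best_sim


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def count_motifs(
    sequence: str,
    motifs: Sequence[str],
    exclude: Sequence[tuple[int, int]] = (),
    max_mismatches: int = MOTIF_MAX_MISMATCHES,
) -> int:
    """Count conserved motifs present outside the domain interval(s).

    A motif matches if some window outside every excluded interval agrees
    with the consensus up to ``max_mismatches`` substitutions.
    """
    found = 0
    for motif in motifs:
        m = len(motif)
        hit = False
        for i in range(len(sequence) - m + 1):
            if any(i < e and i + m > s for s, e in exclude):
                continue
            if _hamming_at_most(sequence[i:i + m], motif, max_mismatches):
                hit = True
                break
        if hit:
            found += 1
    return found


def assign_group(
    gene_id: str,
    sequence: str,
    family: str,
    hits: Sequence[DomainHit],
    panel: Sequence[ReferenceEntry],
    min_similarity: float = DEFAULT_MIN_GROUP_SIMILARITY,
    aligner=None,
) -> FamilyAssignment:
    """Group assignment plus Soloist resolution for one gene.

    ERF genes take the group of the nearest ERF-family reference when the
    similarity clears ``min_similarity``; a single-AP2 gene whose nearest
    reference overall is a Soloist exemplar becomes family Soloist.
    Motif matches are corroborating evidence only, never a veto.
    """
    if aligner is None:
        aligner = make_aligner()
    by_id = {r.ref_id: r for r in panel}
    nearest_id, nearest_sim = nearest_reference(sequence, panel, aligner)

    group: str | None = None
    motifs_matched = 0
    fam = family
    if fam == "ERF" and by_id[nearest_id].family == "Soloist":
        fam = "Soloist"
    elif fam == "ERF":
        erf_panel = [r for r in panel if r.family == "ERF"]
        if erf_panel:
            erf_id, erf_sim = nearest_reference(sequence, erf_panel, aligner)
            if erf_sim >= min_similarity:
                ref = by_id[erf_id]
                group = ref.group
                domain_intervals = [(h.start, h.end) for h in hits]
                motifs_matched = count_motifs(sequence, ref.motif_patterns,
                                              exclude=domain_intervals)
            nearest_id, nearest_sim = erf_id, erf_sim
    return FamilyAssignment(
        gene_id=gene_id,
        family=fam,
        group=group,
        nearest_ref=nearest_id,
        similarity=nearest_sim,
        motifs_matched=motifs_matched,
        evidence=list(hits),
    )


def classify_proteome(
    proteins: Mapping[str, str],
    hit_table: pd.DataFrame,
    panel: Sequence[ReferenceEntry],
    min_similarity: float = DEFAULT_MIN_GROUP_SIMILARITY,
) -> pd.DataFrame:
    """Assign family and group to every protein in the catalogue.

    Returns a table with one row per protein: gene_id, family, group,
    nearest_ref, similarity, motifs_matched, n_ap2, n_b3.
    """
    from .profile import hits_for

    aligner = make_aligner()
    rows = []
    for pid in proteins:
        hits = hits_for(hit_table, pid)
        family = classify_family(hits)
        if family == "unclassified":
            rows.append({"gene_id": pid, "family": family, "group": None,
                         "nearest_ref": None, "similarity": float("nan"),
                         "motifs_matched": 0,
                         "n_ap2": 0,
                         "n_b3": sum(1 for h in hits if h.domain_kind == "B3")})
            continue
        asg = assign_group(pid, proteins[pid], family, hits, panel,
                           min_similarity, aligner)
        rows.append({"gene_id": pid, "family": asg.family, "group": asg.group,
                     "nearest_ref": asg.nearest_ref,
                     "similarity": asg.similarity,
                     "motifs_matched": asg.motifs_matched,
                     "n_ap2": sum(1 for h in hits if h.domain_kind == "AP2"),
                     "n_b3": sum(1 for h in hits if h.domain_kind == "B3")})
    return pd.DataFrame(rows)


def catalogue_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Family/group count table over a catalogue (unclassified excluded)."""
    cat = assignments[assignments["family"] != "unclassified"]
    rows = []
    for family in ("ERF", "RAV", "AP2", "Soloist"):
        sub = cat[cat["family"] == family]
        if family == "ERF":
            for group, n in sub.groupby("group", dropna=False).size().items():
                rows.append({"family": family,
                             "group": group if pd.notna(group) else None,
                             "count": int(n)})
        else:
            rows.append({"family": family, "group": None, "count": len(sub)})
    return pd.DataFrame(rows)


def ratio_table(counts_a: Mapping[str, int] | pd.Series,
                counts_b: Mapping[str, int] | pd.Series) -> pd.Series:
    """Per-group count ratios a/b, rounded to 2 decimals.

    Groups with a zero denominator get NaN (a ratio is not printed).
    """
    a = pd.Series(dict(counts_a), dtype=float)
    b = pd.Series(dict(counts_b), dtype=float)
    ratios = (a / b.reindex(a.index)).round(2)
    return ratios.where(b.reindex(a.index) > 0)
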