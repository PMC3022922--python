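"""Gene models and automated gene-prediction quality control.

Automated proteome predictions are error-prone: unrealistically long
introns, several single-domain genes fused into one model, and short
pseudogenic loci. This module applies three reliability rules:

* flag models containing an intron longer than 10 kb;
* split models whose protein carries two or more AP2/ERF domains, when
  the nearest reference belongs to the single-domain ERF family (a
  tandem double AP2 domain is the legitimate architecture of the AP2
  family and is left intact);
* flag probable pseudogenes: a short predicted protein together with at
  least two very long introns, excluded from the catalogue downstream.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .profile import DomainHit

LONG_INTRON_BP = 10_000
PSEUDOGENE_MIN_PROTEIN_AA = 100
PSEUDOGENE_MIN_LONG_INTRONS = 2

_SPLIT_SUFFIXES = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene: exon structure plus the encoded protein.

    Exons are genomic intervals in the 1-based inclusive GFF3 dialect,
    sorted and non-overlapping; introns are the gaps between consecutive
    exons.
    """

    gene_id: str
    chromosome: str | None
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_id: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")

    @property
    def introns(self) -> tuple[int, ...]:
        """Intron lengths in bp (gaps between consecutive exons)."""
        return tuple(s2 - e1 - 1 for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def midpoint(self) -> float:
        s, e = self.span
        return (s + e) / 2.0


@dataclass
class SplitProduct:
    product_id: str
    start: int            # protein coords, 0-based half-open
    end: int
    domain: tuple[int, int]   # the single AP2 domain, original protein coords


@dataclass
class QCResult:
    gene_id: str
    flags: set[str] = field(default_factory=set)
    max_intron_bp: int = 0
    n_erf_domains: int = 0
    split_products: list[SplitProduct] = field(default_factory=list)


def flag_long_introns(model: GeneModel, max_intron: int = LONG_INTRON_BP) -> QCResult:
    """Flag a model iff any intron is strictly longer than ``max_intron`` bp."""
    introns = model.introns
    longest = max(introns, default=0)
    res = QCResult(gene_id=model.gene_id, max_intron_bp=longest)
    if longest > max_intron:
        res.flags.add("long_intron")
    return res


def split_fused_model(
    model: GeneModel,
    protein_seq: str,
    hits: Sequence[DomainHit],
    nearest_ref_family: str,
) -> QCResult:
    """Split a multi-AP2-domain model into single-domain products.

    A protein with >= 2 AP2 domains is either a legitimate AP2-family
    protein (tandem double domain) or a fusion of several ERF genes.
    When the nearest reference is ERF-family, the protein is cut at the
    midpoints between adjacent domain hits, yielding one product per
    domain, suffixed ``_a``, ``_b``, ... in order.
    """
    ap2_hits = sorted([h for h in hits if h.domain_kind == "AP2"],
                      key=lambda h: h.start)
    if len(ap2_hits) < 2:
        raise ValueError(f"{model.gene_id}: not a split candidate (<2 AP2 hits)")
    res = QCResult(gene_id=model.gene_id, n_erf_domains=len(ap2_hits))
    res.flags.add("multi_domain")
    if nearest_ref_family == "AP2":
        # tandem architecture is the defining feature of the AP2 family
        res.split_products = []
        res.flags.discard("multi_domain")
        return res
    cuts = [0]
    for h1, h2 in zip(ap2_hits, ap2_hits[1:]):
        cuts.append((h1.end + h2.start) // 2)
    cuts.append(len(protein_seq))
    for k, h in enumerate(ap2_hits):
        res.split_products.append(SplitProduct(
            product_id=f"{model.gene_id}_{_SPLIT_SUFFIXES[k]}",
            start=cuts[k],
            end=cuts[k + 1],
            domain=(h.start, h.end),
        ))
    return res


def flag_pseudogene(
    model: GeneModel,
    min_protein_len: int = PSEUDOGENE_MIN_PROTEIN_AA,
    min_long_introns: int = PSEUDOGENE_MIN_LONG_INTRONS,
    long_intron: int = LONG_INTRON_BP,
) -> QCResult:
    """Flag probable pseudogenes: short protein AND >= 2 introns > 10 kb."""
    res = QCResult(gene_id=model.gene_id,
                   max_intron_bp=max(model.introns, default=0))
    n_long = sum(1 for i in model.introns if i > long_intron)
    if model.protein_length < min_protein_len and n_long >= min_long_introns:
        res.flags.add("pseudogene")
    return res


def run_qc(
    models: Sequence[GeneModel],
    proteins: Mapping[str, str],
    hit_table: pd.DataFrame,
    nearest_family: Mapping[str, str] | None = None,
    max_intron: int = LONG_INTRON_BP,
    min_protein_len: int = PSEUDOGENE_MIN_PROTEIN_AA,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Apply all QC rules to a proteome.

    ``nearest_family`` maps protein ids (for multi-AP2 proteins) to the
    family of their nearest reference; proteins absent from the mapping
    are treated as ERF-like and split.

    Returns ``(qc_report, kept_proteins, product_parent)`` where
    ``kept_proteins`` is the post-QC protein set (pseudogenes removed,
    fused models replaced by their split products) and ``product_parent``
    maps split-product ids back to the fused model's protein id.
    """
    from .profile import hits_for

    nearest_family = nearest_family or {}
    rows = []
    kept: dict[str, str] = {}
    parents: dict[str, str] = {}
    for model in models:
        seq = proteins[model.protein_id]
        intron_res = flag_long_introns(model, max_intron)
        pseudo_res = flag_pseudogene(model, min_protein_len)
        flags = intron_res.flags | pseudo_res.flags
        ap2_hits = hits_for(hit_table, model.protein_id, "AP2")
        n_dom = len(ap2_hits)
        products: list[SplitProduct] = []
        if n_dom >= 2 and "pseudogene" not in flags:
            fam = nearest_family.get(model.protein_id, "ERF")
            split_res = split_fused_model(model, seq, ap2_hits, fam)
            flags |= split_res.flags
            products = split_res.split_products
        if "pseudogene" in flags:
            pass  # excluded from the catalogue
        elif products:
            for p in products:
                kept[p.product_id] = seq[p.start:p.end]
                parents[p.product_id] = model.protein_id
        else:
            kept[model.protein_id] = seq
        rows.append({
            "gene_id": model.gene_id,
            "protein_id": model.protein_id,
            "flags": ";".join(sorted(flags)),
            "max_intron_bp": intron_res.max_intron_bp,
            "n_erf_domains": n_dom,
            "split_products": ";".join(p.product_id for p in products),
        })
    report = pd.DataFrame(rows)
    return report, kept, parents


# ---------------------------------------------------------------------------
# GFF3 I/O

def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features in GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            chrom = m.chromosome if m.chromosome is not None else "chrUn"
            s, e = m.span
            fh.write(f"{chrom}\t.\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{chrom}\t.\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.t;Parent={m.gene_id};"
                     f"protein_id={m.protein_id};"
                     f"protein_length={m.protein_length}\n")
            for i, (xs, xe) in enumerate(m.exons, 1):
                fh.write(f"{chrom}\t.\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t"
                         f"ID={m.gene_id}.exon{i};Parent={m.gene_id}.t\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3` (or any GFF3 with
    gene -> mRNA -> exon features and a protein_length mRNA attribute)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((e.start, e.end)
                           for e in db.children(mrna, featuretype="exon"))
            plen = int(mrna.attributes.get("protein_length", ["0"])[0])
            pid = mrna.attributes.get("protein_id", [mrna.id])[0]
            chrom = None if gene.seqid == "chrUn" else gene.seqid
            models.append(GeneModel(
                gene_id=gene.id,
                chromosome=chrom,
                strand=gene.strand,
                exons=tuple(exons),
                protein_id=pid,
                protein_length=plen,
            ))
    return models
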