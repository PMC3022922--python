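"""Synthetic study inputs with known ground truth.

The pipeline's real inputs — a labeled reference panel of AP2/ERF
proteins, a predicted proteome with gene models, and qPCR Ct tables —
are not all publicly deposited, so this module generates stand-ins with
planted structure:

* a reference panel whose groups carry distinct AP2-domain variants and
  group-specific conserved motifs; AP2-family references carry a tandem
  double domain, RAV references an additional B3 domain, and a single
  divergent Soloist exemplar;
* a target proteome of mutated copies of panel members, with planted
  defects (fused multi-domain models, > 10 kb introns, pseudogenes) and
  tandem same-group gene clusters on simulated chromosomes;
* Ct tables with replicate noise, planted log2 fold changes between
  ripening stages, undetectable genes, and an over-enriched group among
  the planted up-regulated genes.

Every record emitted is covered by a GroundTruth entry so downstream
recovery is directly checkable; a fixed seed reproduces outputs
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import ReferenceEntry
from .expression import CtTable
from .genemodel import GeneModel, write_gff3

AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII",
                  "IX", "X", "VI-L", "Xb-L")
DEFAULT_TISSUES = (
    ("leaf", "na"), ("stem", "na"), ("inflorescence", "na"),
    ("skin", "veraison"), ("skin", "ripe"),
    ("flesh", "veraison"), ("flesh", "ripe"),
)

#: divergence of per-group AP2-domain variants from the shared core; the
#: AP2 domain itself is strongly conserved across groups (group identity
#: lives mainly outside the DNA-binding domain)
GROUP_DOMAIN_DIVERGENCE = 0.04
#: divergence of the AP2-family tandem domains and the RAV AP2 domain
FAMILY_DOMAIN_DIVERGENCE = 0.06
#: divergence of the Soloist exemplar's AP2 domain from the core —
#: markedly diverged yet still recognizable as an AP2 domain
SOLOIST_DOMAIN_DIVERGENCE = 0.12
#: within-group domain variation of panel members, as a fraction of the
#: target substitution rate: a curated reference panel is far less
#: diverged from its group consensus than noisy genome predictions are
PANEL_DOMAIN_NOISE_FACTOR = 0.25


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the study design: 12 ERF similarity groups, four
    housekeeping genes, at least three replicates per sample, two
    ripening stages for berry skin and flesh, and replicate noise of a
    well-run qPCR plate (~0.3 Ct).
    """

    seed: int = 0
    n_groups: int = 12
    refs_per_group: int = 3
    targets_per_group: int = 4
    ap2_refs: int = 3
    rav_refs: int = 3
    ap2_targets: int = 3
    rav_targets: int = 3
    soloist_targets: int = 1
    domain_length_ap2: int = 58
    domain_length_b3: int = 50
    substitution_rate: float = 0.05
    n_fused_models: int = 2
    n_long_intron_models: int = 2
    n_pseudogenes: int = 1
    hk_genes: tuple[str, str, str, str] = ("VvHK1", "VvHK2", "VvHK3", "VvHK4")
    tissues: tuple[tuple[str, str], ...] = DEFAULT_TISSUES
    replicates: int = 3
    ct_base_mean: float = 24.0
    rep_noise_sd: float = 0.3
    planted_log2fc: dict = field(default_factory=dict)  # gene -> {tissue: f}
    enriched_group: str = "IX"
    enrichment_fraction: float = 0.5
    n_planted_degs: int = 30
    n_undetectable: int = 5
    detection_cutoff: float = 40.0
    n_chromosomes: int = 5
    cluster_gap_bp: tuple[int, int] = (15_000, 35_000)
    n_unplaced: int = 2
    efficiency_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.hk_genes) != 4:
            raise ValueError("exactly 4 housekeeping genes are required")
        if self.refs_per_group < 1:
            raise ValueError("refs_per_group must be >= 1")
        if not (0 <= self.enrichment_fraction <= 1):
            raise ValueError("enrichment_fraction must be in [0, 1]")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return DEFAULT_GROUPS[: self.n_groups]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hk_genes" in raw:
            raw["hk_genes"] = tuple(raw["hk_genes"])
        if "tissues" in raw:
            raw["tissues"] = tuple(tuple(t) for t in raw["tissues"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class GroundTruth:
    """Planted truth for every emitted record."""

    family: dict[str, str] = field(default_factory=dict)
    group: dict[str, str | None] = field(default_factory=dict)
    domains: dict[str, list] = field(default_factory=dict)   # id -> [(kind, s, e)]
    defects: dict[str, str] = field(default_factory=dict)    # gene -> defect label
    fused_components: dict[str, list] = field(default_factory=dict)
    source_ref: dict[str, str] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_group: str | None = None
    undetectable: list[str] = field(default_factory=list)
    motif_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(asdict(self)), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# sequence helpers

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation: each site flips to a different residue
    with probability ``rate`` (positions are preserved)."""
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        choices = [a for a in AA if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _diverge(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Deterministically substitute a fixed fraction of sites."""
    chars = list(seq)
    k = int(round(fraction * len(chars)))
    sites = rng.choice(len(chars), size=k, replace=False)
    for i in sites:
        choices = [a for a in AA if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# reference panel

@dataclass
class ReferencePanel:
    entries: list[ReferenceEntry]
    seed_alignments: dict[str, list[str]]       # "AP2"/"B3" -> gap-free seqs
    group_domains: dict[str, str]               # group -> AP2 consensus variant
    group_motifs: dict[str, list[str]]
    domain_intervals: dict[str, list] = field(default_factory=dict)
    # ref_id -> [(kind, start, end)], 0-based half-open protein coords

    @property
    def by_family(self) -> dict[str, list[ReferenceEntry]]:
        out: dict[str, list[ReferenceEntry]] = {}
        for e in self.entries:
            out.setdefault(e.family, []).append(e)
        return out

    def write(self, fasta_path: str | Path, labels_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.ref_id}\n{e.sequence}\n")
        rows = [{"ref_id": e.ref_id, "family": e.family,
                 "group": e.group if e.group is not None else "NA",
                 "motifs": ";".join(e.motif_patterns)}
                for e in self.entries]
        pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)


def make_reference_panel(cfg: SimConfig) -> ReferencePanel:
    """Build the labeled reference panel and domain seed alignments.

    Each ERF group gets its own AP2-domain consensus variant plus 1-3
    group-specific conserved motifs placed outside the domain. AP2-family
    references carry two tandem AP2 copies, RAV references an additional
    B3 domain, and exactly one Soloist exemplar carries a strongly
    divergent AP2 domain. Seed alignments are gap-free by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    core_ap2 = _rand_seq(rng, cfg.domain_length_ap2)
    core_b3 = _rand_seq(rng, cfg.domain_length_b3)

    group_domains = {g: _diverge(rng, core_ap2, GROUP_DOMAIN_DIVERGENCE)
                     for g in cfg.group_labels}
    ap2_dom1 = _diverge(rng, core_ap2, FAMILY_DOMAIN_DIVERGENCE)
    ap2_dom2 = _diverge(rng, core_ap2, FAMILY_DOMAIN_DIVERGENCE)
    rav_ap2 = _diverge(rng, core_ap2, FAMILY_DOMAIN_DIVERGENCE)
    soloist_ap2 = _diverge(rng, core_ap2, SOLOIST_DOMAIN_DIVERGENCE)

    group_motifs = {
        g: [_rand_seq(rng, 7) for _ in range(int(rng.integers(1, 4)))]
        for g in cfg.group_labels
    }

    entries: list[ReferenceEntry] = []
    intervals: dict[str, list] = {}
    panel_noise = cfg.substitution_rate * PANEL_DOMAIN_NOISE_FACTOR

    # whole-protein similarity is what defines the groups, so members of
    # a group (and of the AP2/RAV families) share flank templates outside
    # the DNA-binding domain(s), lightly mutated per member
    def flank_templates(n_len: int, c_len: int) -> tuple[str, str]:
        return _rand_seq(rng, n_len), _rand_seq(rng, c_len)

    group_flanks = {g: flank_templates(int(rng.integers(30, 51)), 35)
                    for g in cfg.group_labels}

    for g in cfg.group_labels:
        n_tpl, c_tpl = group_flanks[g]
        motif_block = ""
        for m in group_motifs[g]:
            motif_block += m + _rand_seq(rng, 5)
        for j in range(cfg.refs_per_group):
            dom = _mutate(rng, group_domains[g], panel_noise)
            n_flank = _mutate(rng, n_tpl, panel_noise)
            tail = _mutate(rng, motif_block, panel_noise / 2) + \
                _mutate(rng, c_tpl, panel_noise)
            seq = n_flank + dom + _rand_seq(rng, 0) + tail
            rid = f"AtERF-{g}-{j + 1}"
            entries.append(ReferenceEntry(
                ref_id=rid, sequence=seq, family="ERF",
                group=g, motif_patterns=tuple(group_motifs[g])))
            s = len(n_flank)
            intervals[rid] = [("AP2", s, s + len(dom))]
    ap2_n, ap2_c = flank_templates(35, 30)
    ap2_linker = _rand_seq(rng, 25)
    for j in range(cfg.ap2_refs):
        d1 = _mutate(rng, ap2_dom1, panel_noise)
        d2 = _mutate(rng, ap2_dom2, panel_noise)
        n_flank = _mutate(rng, ap2_n, panel_noise)
        linker = _mutate(rng, ap2_linker, panel_noise)
        seq = n_flank + d1 + linker + d2 + _mutate(rng, ap2_c, panel_noise)
        rid = f"AtAP2-{j + 1}"
        entries.append(ReferenceEntry(
            ref_id=rid, sequence=seq, family="AP2", group=None))
        s1 = len(n_flank)
        s2 = s1 + len(d1) + len(linker)
        intervals[rid] = [("AP2", s1, s1 + len(d1)),
                          ("AP2", s2, s2 + len(d2))]
    rav_n, rav_c = flank_templates(35, 25)
    rav_linker = _rand_seq(rng, 20)
    for j in range(cfg.rav_refs):
        d = _mutate(rng, rav_ap2, panel_noise)
        b3 = _mutate(rng, core_b3, panel_noise)
        n_flank = _mutate(rng, rav_n, panel_noise)
        linker = _mutate(rng, rav_linker, panel_noise)
        seq = n_flank + d + linker + b3 + _mutate(rng, rav_c, panel_noise)
        rid = f"AtRAV-{j + 1}"
        entries.append(ReferenceEntry(
            ref_id=rid, sequence=seq, family="RAV", group=None))
        s1 = len(n_flank)
        s2 = s1 + len(d) + len(linker)
        intervals[rid] = [("AP2", s1, s1 + len(d)),
                          ("B3", s2, s2 + len(b3))]
    # the Soloist diverged early from the AP2 family: its single domain is
    # strongly diverged from the core, and its body is a diverged copy of
    # the AP2-family template (so it attaches near the AP2 clade in trees)
    sol_n = _diverge(rng, ap2_n, 0.3)
    sol_c = _diverge(rng, ap2_c + ap2_linker[:10], 0.3)
    seq = sol_n + soloist_ap2 + sol_c
    entries.append(ReferenceEntry(
        ref_id="AtSoloist-1", sequence=seq, family="Soloist", group=None))
    intervals["AtSoloist-1"] = [("AP2", len(sol_n),
                                 len(sol_n) + len(soloist_ap2))]

    # seed alignments = the realized domain instances of the panel itself
    # (gap-free by construction: substitutions only, equal length)
    by_id = {e.ref_id: e.sequence for e in entries}
    seed_alignments: dict[str, list[str]] = {"AP2": [], "B3": []}
    for rid, doms in intervals.items():
        for kind, s, e in doms:
            seed_alignments[kind].append(by_id[rid][s:e])
    if len(seed_alignments["B3"]) < 2:
        seed_alignments["B3"].append(_mutate(rng, core_b3, 0.05))
    return ReferencePanel(entries=entries, seed_alignments=seed_alignments,
                          group_domains=group_domains,
                          group_motifs=group_motifs,
                          domain_intervals=intervals)


def read_panel(fasta_path: str | Path,
               labels_path: str | Path) -> list[ReferenceEntry]:
    from Bio import SeqIO
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    labels = pd.read_csv(labels_path, sep="\t", keep_default_na=False)
    entries = []
    for r in labels.itertuples():
        motifs = tuple(m for m in str(r.motifs).split(";") if m)
        group = None if r.group in ("NA", "") else r.group
        entries.append(ReferenceEntry(ref_id=r.ref_id, sequence=seqs[r.ref_id],
                                      family=r.family, group=group,
                                      motif_patterns=motifs))
    return entries


# ---------------------------------------------------------------------------
# target proteome and gene models

@dataclass
class TargetGenome:
    proteins: dict[str, str]
    models: list[GeneModel]
    truth: GroundTruth

    def write(self, fasta_path: str | Path, gff_path: str | Path,
              truth_path: str | Path | None = None) -> None:
        with open(fasta_path, "w") as fh:
            for pid, seq in self.proteins.items():
                fh.write(f">{pid}\n{seq}\n")
        write_gff3(self.models, gff_path)
        if truth_path is not None:
            self.truth.to_json(truth_path)


def make_target_genome(cfg: SimConfig, panel: ReferencePanel) -> TargetGenome:
    """Emit a proteome FASTA + GFF3 gene models + ground truth.

    Targets are substitution-mutated copies of panel members (domain
    positions preserved). Planted defects: ``n_fused_models`` concatenate
    2-3 single-domain ERF proteins, ``n_long_intron_models`` carry one
    intron > 10 kb, and pseudogenes are < 100 aa with two > 10 kb
    introns. The first up-to-four targets of each ERF group are placed
    in a tandem run (< 50 kb midpoint gaps) on the group's home
    chromosome; ``n_unplaced`` genes get no chromosome.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = GroundTruth()
    proteins: dict[str, str] = {}
    meta: dict[str, dict] = {}      # gene -> placement request
    serial = 0

    def add_target(ref: ReferenceEntry, prefix: str) -> str:
        nonlocal serial
        serial += 1
        gid = f"{prefix}{serial:04d}"
        seq = _mutate(rng, ref.sequence, cfg.substitution_rate)
        proteins[gid] = seq
        truth.family[gid] = ref.family if ref.family != "Soloist" else "Soloist"
        truth.group[gid] = ref.group
        truth.source_ref[gid] = ref.ref_id
        truth.domains[gid] = list(panel.domain_intervals[ref.ref_id])
        if ref.family == "ERF":
            truth.motif_counts[gid] = len(ref.motif_patterns)
        return gid

    fams = panel.by_family
    erf_by_group: dict[str, list[str]] = {}
    for g in cfg.group_labels:
        refs = [r for r in fams.get("ERF", []) if r.group == g]
        for k in range(cfg.targets_per_group):
            ref = refs[int(rng.integers(len(refs)))]
            gid = add_target(ref, "VvG")
            erf_by_group.setdefault(g, []).append(gid)
    for k in range(cfg.ap2_targets):
        ref = fams["AP2"][int(rng.integers(len(fams["AP2"])))]
        add_target(ref, "VvA")
    for k in range(cfg.rav_targets):
        ref = fams["RAV"][int(rng.integers(len(fams["RAV"])))]
        add_target(ref, "VvR")
    for k in range(cfg.soloist_targets):
        add_target(fams["Soloist"][0], "VvS")

    # fused models: fresh mutated ERF copies concatenated 2-3 at a time
    erf_refs = fams.get("ERF", [])
    for k in range(cfg.n_fused_models):
        n_comp = 2 if k % 2 == 0 else 3   # alternate 2- and 3-gene fusions
        comps = []
        offset = 0
        seq_parts = []
        for _ in range(n_comp):
            ref = erf_refs[int(rng.integers(len(erf_refs)))]
            part = _mutate(rng, ref.sequence, cfg.substitution_rate)
            doms = [(kind, s + offset, e + offset)
                    for kind, s, e in panel.domain_intervals[ref.ref_id]]
            comps.append({"source_ref": ref.ref_id, "group": ref.group,
                          "start": offset, "end": offset + len(part),
                          "domains": doms})
            seq_parts.append(part)
            offset += len(part)
        serial += 1
        gid = f"VvF{serial:04d}"
        proteins[gid] = "".join(seq_parts)
        truth.defects[gid] = "fused"
        truth.fused_components[gid] = comps
        truth.family[gid] = "ERF"
        truth.group[gid] = None
        truth.domains[gid] = [d for c in comps for d in c["domains"]]

    # pseudogenes: short protein, two very long introns
    pseudo_ids = []
    for k in range(cfg.n_pseudogenes):
        serial += 1
        gid = f"VvP{serial:04d}"
        proteins[gid] = _rand_seq(rng, 80)
        truth.defects[gid] = "pseudogene"
        truth.family[gid] = "pseudogene"
        truth.group[gid] = None
        truth.domains[gid] = []
        pseudo_ids.append(gid)

    # long-intron defects: mark ordinary ERF targets (outside clusters)
    long_intron_ids = []
    flat = [g for ids in erf_by_group.values() for g in ids[4:]]
    if len(flat) < cfg.n_long_intron_models:
        flat = [g for ids in erf_by_group.values() for g in ids]
    for gid in flat[: cfg.n_long_intron_models]:
        truth.defects[gid] = "long_intron"
        long_intron_ids.append(gid)

    # --- gene model construction and chromosome placement -----------------
    models: list[GeneModel] = []
    cursors = {f"chr{i + 1}": int(1e5) for i in range(cfg.n_chromosomes)}
    chrom_names = list(cursors)

    def build_model(gid: str, chrom: str | None, start: int,
                    introns: Sequence[int]) -> GeneModel:
        plen = len(proteins[gid])
        cds = 3 * plen + 3
        n_ex = len(introns) + 1
        bounds = np.linspace(0, cds, n_ex + 1).astype(int)
        exons = []
        pos = start
        for i in range(n_ex):
            ex_len = int(bounds[i + 1] - bounds[i])
            exons.append((pos, pos + ex_len - 1))
            if i < len(introns):
                pos += ex_len + introns[i]
            else:
                pos += ex_len
        return GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                         exons=tuple(exons), protein_id=gid,
                         protein_length=plen)

    def introns_for(gid: str) -> list[int]:
        introns = [int(rng.integers(200, 2000))
                   for _ in range(int(rng.integers(1, 4)))]
        if gid in long_intron_ids:
            introns[0] = int(rng.integers(12_000, 36_000))
        elif gid in pseudo_ids:
            introns = [int(rng.integers(11_000, 20_000)),
                       int(rng.integers(11_000, 20_000))]
        return introns

    # tandem clusters: first up-to-4 targets of each ERF group
    for i, g in enumerate(cfg.group_labels):
        chrom = chrom_names[i % len(chrom_names)]
        members = erf_by_group.get(g, [])[:4]
        if len(members) >= 2:
            cluster_members = []
            for gid in members:
                start = cursors[chrom]
                m = build_model(gid, chrom, start, introns_for(gid))
                models.append(m)
                cluster_members.append(gid)
                gap = int(rng.integers(*cfg.cluster_gap_bp))
                cursors[chrom] = m.span[1] + gap
            cursors[chrom] += 400_000   # separate clusters from whatever follows
            truth.clusters.append({"chromosome": chrom, "group": g,
                                   "members": cluster_members})
        else:
            for gid in members:
                start = cursors[chrom]
                m = build_model(gid, chrom, start, introns_for(gid))
                models.append(m)
                cursors[chrom] = m.span[1] + 400_000

    placed = {m.gene_id for m in models}
    remaining = [gid for gid in proteins if gid not in placed]
    # unplaced genes are ordinary targets, never the planted defect models
    ordinary = [g for g in remaining if g not in truth.defects]
    unplaced = set(ordinary[: cfg.n_unplaced])
    for gid in remaining:
        introns = introns_for(gid)
        if gid in unplaced:
            chrom = None
            start = int(1e5)
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = cursors[chrom]
        m = build_model(gid, chrom, start, introns)
        models.append(m)
        if chrom is not None:
            cursors[chrom] = m.span[1] + 400_000

    return TargetGenome(proteins=proteins, models=models, truth=truth)


# ---------------------------------------------------------------------------
# Ct tables

def vitis_like_universe(cfg: SimConfig) -> pd.DataFrame:
    """A 149-gene catalogue with the family/group proportions of the
    grapevine AP2/ERF superfamily (used when no catalogue is supplied)."""
    sizes = {"I": 5, "II": 8, "III": 22, "IV": 5, "V": 11, "VI": 5,
             "VII": 3, "VIII": 11, "IX": 40, "X": 10, "VI-L": 2, "Xb-L": 0}
    rows = []
    i = 0
    for g, n in sizes.items():
        for _ in range(n):
            i += 1
            rows.append({"gene_id": f"VvE{i:04d}", "family": "ERF", "group": g})
    for _ in range(6):
        i += 1
        rows.append({"gene_id": f"VvE{i:04d}", "family": "RAV", "group": None})
    for _ in range(20):
        i += 1
        rows.append({"gene_id": f"VvE{i:04d}", "family": "AP2", "group": None})
    i += 1
    rows.append({"gene_id": f"VvE{i:04d}", "family": "Soloist", "group": None})
    return pd.DataFrame(rows)


def plant_deg_truth(cfg: SimConfig, universe: pd.DataFrame,
                    rng: np.random.Generator,
                    tissue: str = "skin") -> dict[str, dict[str, float]]:
    """Draw planted up-regulated genes: ``enrichment_fraction`` of the
    ``n_planted_degs`` come from the enriched group, the rest uniformly
    from the other genes; fold changes are uniform in [2.5, 6] log2."""
    in_group = universe.loc[universe["group"] == cfg.enriched_group,
                            "gene_id"].tolist()
    out_group = universe.loc[universe["group"] != cfg.enriched_group,
                             "gene_id"].tolist()
    n_in = int(round(rng.binomial(cfg.n_planted_degs, cfg.enrichment_fraction)))
    n_in = min(n_in, len(in_group))
    n_out = cfg.n_planted_degs - n_in
    chosen = (list(rng.choice(in_group, size=n_in, replace=False)) +
              list(rng.choice(out_group, size=n_out, replace=False)))
    return {g: {tissue: float(rng.uniform(2.5, 6.0))} for g in chosen}


def make_ct_table(cfg: SimConfig,
                  universe: pd.DataFrame | None = None
                  ) -> tuple[CtTable, GroundTruth]:
    """Generate a Ct table with planted expression structure.

    Housekeeping genes draw Ct ~ Normal(ct_base_mean, rep_noise_sd) in
    every sample. A gene with planted log2FC f between the two stages of
    a tissue has its later-stage mean Ct shifted by −f (each PCR cycle
    is a doubling under perfect efficiency). Undetectable genes are all
    NA, and any Ct above the detection cutoff becomes NA.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if universe is None:
        universe = vitis_like_universe(cfg)
    genes = universe["gene_id"].tolist()
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene ids in universe")

    planted = cfg.planted_log2fc
    if not planted:
        planted = plant_deg_truth(cfg, universe, rng)
    unknown = [g for g in planted if g not in set(genes)]
    if unknown:
        raise ValueError(f"planted gene(s) not in universe: {unknown}")

    truth = GroundTruth(enriched_group=cfg.enriched_group)
    truth.log2fc = {g: dict(v) for g, v in planted.items()}

    candidates = [g for g in genes if g not in planted]
    truth.undetectable = candidates[: cfg.n_undetectable]
    undetectable = set(truth.undetectable)

    gene_offset = {g: float(rng.normal(0, 2.0)) for g in genes}
    tissue_offset = {t: float(rng.normal(0, 1.0))
                     for t in {tt for tt, _ in cfg.tissues}}
    # second stage of each tissue, for applying planted shifts
    stages_per_tissue: dict[str, list[str]] = {}
    for t, s in cfg.tissues:
        stages_per_tissue.setdefault(t, [])
        if s not in stages_per_tissue[t]:
            stages_per_tissue[t].append(s)

    rows = []
    for tissue, stage in cfg.tissues:
        for rep in range(1, cfg.replicates + 1):
            for g in cfg.hk_genes:
                ct = rng.normal(cfg.ct_base_mean, cfg.rep_noise_sd)
                rows.append((g, tissue, stage, rep, ct))
            for g in genes:
                if g in undetectable:
                    rows.append((g, tissue, stage, rep, np.nan))
                    continue
                mean = cfg.ct_base_mean + gene_offset[g] + tissue_offset[tissue]
                shift = planted.get(g, {}).get(tissue, 0.0)
                stages = stages_per_tissue[tissue]
                if shift and len(stages) >= 2 and stage == stages[1]:
                    mean -= shift
                ct = rng.normal(mean, cfg.rep_noise_sd) if cfg.rep_noise_sd \
                    else mean
                rows.append((g, tissue, stage, rep, ct))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "stage",
                                     "replicate", "ct"])
    df.loc[df["ct"] > cfg.detection_cutoff, "ct"] = np.nan

    efficiency: dict[str, float] = {}
    if cfg.efficiency_range is not None:
        lo, hi = cfg.efficiency_range
        efficiency = {g: float(rng.uniform(lo, hi)) for g in genes}
    return (CtTable(data=df, hk_genes=tuple(cfg.hk_genes),
                    efficiency=efficiency), truth)
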