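"""Position-specific scoring matrices for AP2 and B3 DNA-binding domains.

The AP2/ERF superfamily is defined by the presence of the ~60-aa AP2
DNA-binding domain; the RAV family additionally carries a B3 domain.
Domains are detected by scoring every window of a protein against a
log-odds profile built from a gap-free seed alignment of known domain
instances, and keeping windows whose score is a large enough fraction of
the profile's maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: default minimum relative score for calling a domain hit, calibrated
#: for SMART-like sensitivity: genuine domains up to ~20% divergence
#: from the seed consensus stay above it, while random 20-letter windows
#: score far below zero on the relative scale
DEFAULT_MIN_RELATIVE_SCORE = 0.45


@dataclass(frozen=True)
class ProfileMatrix:
    """Log-odds profile (bits) over the 20 amino acids.

    ``weights[c, a]`` is the score in bits for amino acid ``a`` at profile
    column ``c``; ``background`` is the amino-acid frequency vector the
    odds are taken against.
    """

    domain_kind: str
    weights: np.ndarray          # (length, 20), bits
    background: np.ndarray       # (20,), sums to 1
    pseudocount: float

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != 20:
            raise ValueError("weights must be (length, 20)")
        if self.weights.shape[0] < 10:
            raise ValueError("profile length must be >= 10")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("profile weights must be finite")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    @property
    def max_score(self) -> float:
        """Maximum attainable score: best residue at every column."""
        return float(self.weights.max(axis=1).sum())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.weights, columns=list(AMINO_ACIDS))
        df.insert(0, "column", np.arange(self.length))
        with open(path, "w") as fh:
            fh.write(f"# domain_kind={self.domain_kind}\n")
            fh.write(f"# pseudocount={float(self.pseudocount)!r}\n")
            fh.write("# background="
                     + ",".join(repr(float(b)) for b in self.background) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("# ") and "=" in line:
                key, val = line[2:].rstrip("\n").split("=", 1)
                meta[key] = val
        df = pd.read_csv(path, sep="\t", comment="#")
        weights = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        background = np.array([float(x) for x in meta["background"].split(",")])
        return cls(
            domain_kind=meta["domain_kind"],
            weights=weights,
            background=background,
            pseudocount=float(meta["pseudocount"]),
        )


@dataclass(frozen=True)
class DomainHit:
    """A scored domain interval on a protein (0-based, half-open)."""

    protein_id: str
    domain_kind: str
    start: int
    end: int
    score: float
    relative_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit interval")


def build_profile(
    seed_alignment: Sequence[str],
    kind: str,
    pseudocount: float = 4.0,
    background: np.ndarray | None = None,
) -> ProfileMatrix:
    """Build a log-odds profile from a gap-free seed alignment.

    For column ``c`` and residue ``a`` with count ``n_ac`` over ``n``
    sequences, the weight is

        log2( ((n_ac + pseudocount * bg_a) / (n + pseudocount)) / bg_a )

    so an uninformative column (counts proportional to background) scores
    ~0 everywhere and a perfectly conserved column scores close to
    ``log2(1/bg_a)`` for the consensus residue.
    """
    seqs = [s.upper() for s in seed_alignment]
    if len(seqs) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged seed alignment: sequences differ in length")
    if any("-" in s for s in seqs):
        raise ValueError("seed alignment must be gap-free")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)

    counts = np.zeros((length, 20))
    for s in seqs:
        for c, aa in enumerate(s):
            try:
                counts[c, _AA_INDEX[aa]] += 1
            except KeyError:
                raise ValueError(f"non-standard residue {aa!r} in seed alignment")
    n = len(seqs)
    freqs = (counts + pseudocount * background) / (n + pseudocount)
    weights = np.log2(freqs / background)
    return ProfileMatrix(domain_kind=kind, weights=weights,
                         background=background, pseudocount=pseudocount)


def _encode(sequence: str) -> np.ndarray:
    """Map residues to profile column indices; unknowns score 0 (index 20)."""
    return np.array([_AA_INDEX.get(aa, 20) for aa in sequence.upper()], dtype=np.intp)


def window_scores(sequence: str, profile: ProfileMatrix) -> np.ndarray:
    """Score of every window of profile length along the protein."""
    enc = _encode(sequence)
    L = profile.length
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.zeros(0)
    # 21st column of zeros absorbs non-standard residues
    w = np.hstack([profile.weights, np.zeros((L, 1))])
    scores = np.zeros(n_win)
    for c in range(L):
        scores += w[c, enc[c:c + n_win]]
    return scores


def scan(
    sequence: str,
    profile: ProfileMatrix,
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
    protein_id: str = "query",
) -> list[DomainHit]:
    """Scan a protein for domain hits above a relative-score threshold.

    All windows are scored; windows with ``score / max_score >= threshold``
    are kept, overlapping candidates of the same kind are resolved greedily
    by descending score (ties to the leftmost start), and surviving hits
    are returned sorted by start position.

    A protein shorter than the profile yields an empty list.
    """
    if not (0 < min_relative_score <= 1):
        raise ValueError("min_relative_score must be in (0, 1]")
    scores = window_scores(sequence, profile)
    if scores.size == 0:
        return []
    max_score = profile.max_score
    rel = scores / max_score
    candidates = np.flatnonzero(rel >= min_relative_score)
    # greedy non-overlap resolution: best score first, leftmost on ties
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    taken: list[int] = []
    for i in order:
        if all(abs(i - j) >= profile.length for j in taken):
            taken.append(i)
    hits = [
        DomainHit(
            protein_id=protein_id,
            domain_kind=profile.domain_kind,
            start=int(i),
            end=int(i) + profile.length,
            score=float(scores[i]),
            relative_score=float(rel[i]),
        )
        for i in sorted(taken)
    ]
    return hits


def scan_proteome(
    proteins: Mapping[str, str] | str | Path,
    profiles: Mapping[str, ProfileMatrix],
    min_relative_score: float | Mapping[str, float] = DEFAULT_MIN_RELATIVE_SCORE,
) -> pd.DataFrame:
    """Scan every protein with every profile; return a tidy hit table.

    ``proteins`` is either a mapping id -> sequence or a FASTA path.
    Rows are ordered by (protein_id, start) and carry columns
    protein_id, kind, start, end, score, relative_score.
    """
    if isinstance(proteins, (str, Path)):
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(proteins), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate protein id: {rec.id}")
            records[rec.id] = str(rec.seq)
        proteins = records
    else:
        ids = list(proteins)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein ids in input mapping")

    rows = []
    for pid in proteins:
        seq = proteins[pid]
        for kind, profile in profiles.items():
            thr = (min_relative_score[kind]
                   if isinstance(min_relative_score, Mapping)
                   else min_relative_score)
            for hit in scan(seq, profile, thr, protein_id=pid):
                rows.append((pid, kind, hit.start, hit.end,
                             hit.score, hit.relative_score))
    df = pd.DataFrame(rows, columns=["protein_id", "kind", "start", "end",
                                     "score", "relative_score"])
    return df.sort_values(["protein_id", "start"], kind="mergesort").reset_index(drop=True)


def hits_for(df: pd.DataFrame, protein_id: str, kind: str | None = None) -> list[DomainHit]:
    """Materialize DomainHit objects for one protein from a hit table."""
    sub = df[df["protein_id"] == protein_id]
    if kind is not None:
        sub = sub[sub["kind"] == kind]
    return [
        DomainHit(protein_id=r.protein_id, domain_kind=r.kind,
                  start=int(r.start), end=int(r.end),
                  score=float(r.score), relative_score=float(r.relative_score))
        for r in sub.itertuples()
    ]
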