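"""Exact pairwise alignment and the alignment-score (AS) edge metric.

Sequence similarity networks threshold edges on an "alignment score": the
negative log10 of an E-value-like quantity for the pair.  Here that score is
made self-contained: optimal affine-gap alignment under BLOSUM62 (gap of
length k costs open + k·extend, BLAST convention, default 11/1), converted to
bits with fixed Karlin–Altschul constants and to an E-value with the pairwise
m·n search space:

    bits = (λ·raw − ln K) / ln 2
    E    = m·n · 2^(−bits)
    AS   = −log10 E

λ = 0.267 and K = 0.041 are the standard gapped BLOSUM62-11-1 values, fixed
so AS is reproducible without a search engine.  The ambiguity code X scores 0
against everything.  Percent identity is identities over non-gap aligned
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from sqgsuite.records import ProteinRecord, VALID_RESIDUES

#: gapped BLOSUM62, gap open 11 / extend 1 Karlin–Altschul parameters
LAMBDA = 0.267
K_PARAM = 0.041

GAP_OPEN = 11
GAP_EXTEND = 1


@dataclass(frozen=True)
class ScoredPair:
    """A pairwise alignment result: the SSN edge payload."""

    id_a: str
    id_b: str
    raw_score: float
    bit_score: float
    evalue_like: float
    alignment_score_AS: float
    percent_identity: float
    aligned_length: int
    mode: str = "local"

    def swap(self) -> "ScoredPair":
        return ScoredPair(
            self.id_b, self.id_a, self.raw_score, self.bit_score,
            self.evalue_like, self.alignment_score_AS,
            self.percent_identity, self.aligned_length, self.mode,
        )


@lru_cache(maxsize=8)
def _blosum62_x0() -> substitution_matrices.Array:
    """BLOSUM62 with every score involving the ambiguity code X set to 0."""
    m = substitution_matrices.load("BLOSUM62").copy()
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


def _make_aligner(mode: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _blosum62_x0()
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{name}: non-protein characters {sorted(bad)}")
    return seq


def bit_score(raw: float, lam: float = LAMBDA, k: float = K_PARAM) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def evalue_like(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def alignment_score(ev: float) -> float:
    """AS = −log10 E; capped so a numerically zero E-value stays finite."""
    return -math.log10(max(ev, 1e-300))


def align_pair(
    seq_a: str,
    seq_b: str,
    mode: str = "local",
    id_a: str = "a",
    id_b: str = "b",
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
    lam: float = LAMBDA,
    k: float = K_PARAM,
) -> ScoredPair:
    """Optimal affine-gap alignment of two protein sequences.

    ``mode`` is ``local`` (Smith–Waterman) or ``global`` (Needleman–Wunsch,
    end gaps penalised).  Identity is identities / non-gap aligned columns.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_seq(seq_a, id_a)
    _check_seq(seq_b, id_b)
    aligner = _make_aligner(mode, gap_open, gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    raw = float(alignments.score)

    identities = mismatches = 0
    aln_len = 0
    try:
        aln = alignments[0]
        counts = aln.counts()
        identities, mismatches = counts.identities, counts.mismatches
        aln_len = aln.length
    except IndexError:  # empty optimal local alignment
        pass
    aligned_cols = identities + mismatches
    pct = 100.0 * identities / aligned_cols if aligned_cols else 0.0

    bits = bit_score(raw, lam, k)
    ev = evalue_like(bits, len(seq_a), len(seq_b))
    return ScoredPair(
        id_a=id_a, id_b=id_b, raw_score=raw, bit_score=bits,
        evalue_like=ev, alignment_score_AS=alignment_score(ev),
        percent_identity=pct, aligned_length=int(aln_len), mode=mode,
    )


def all_vs_all(
    records: Sequence[ProteinRecord],
    mode: str = "local",
    **kwargs,
) -> list[ScoredPair]:
    """One ScoredPair per unordered pair of records.

    Results are a pure function of the pair, so the list is independent of
    evaluation order (pairs are emitted in sorted-id order).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    by_id = {r.id: r for r in records}
    out = []
    for ida, idb in combinations(sorted(ids), 2):
        out.append(
            align_pair(by_id[ida].seq, by_id[idb].seq, mode=mode,
                       id_a=ida, id_b=idb, **kwargs)
        )
    return out


def write_edges_tsv(pairs: Iterable[ScoredPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tAS\tpct_id\tbit_score\traw_score\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.alignment_score_AS:.6g}\t"
                f"{p.percent_identity:.6g}\t{p.bit_score:.6g}\t"
                f"{p.raw_score:.6g}\n"
            )


def read_edges_tsv(path: str | Path) -> list[ScoredPair]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            bits = float(f[idx["bit_score"]])
            out.append(ScoredPair(
                id_a=f[idx["id_a"]], id_b=f[idx["id_b"]],
                raw_score=float(f[idx.get("raw_score", idx["bit_score"])]),
                bit_score=bits,
                evalue_like=10.0 ** (-float(f[idx["AS"]])),
                alignment_score_AS=float(f[idx["AS"]]),
                percent_identity=float(f[idx["pct_id"]]),
                aligned_length=0,
            ))
    return out
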