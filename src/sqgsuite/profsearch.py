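"""Iterative profile search: define a protein family by searching with a
position-specific scoring model until the retrieved set is stable.

The family-definition procedure is: build a scoring model from a seed domain
alignment, search a sequence database, realign the hits to the model, rebuild
and re-search, and stop when the retrieved set of identifiers no longer
changes (exact set equality — the "stable set" criterion).  The model here is
a PSSM with Henikoff position-based sequence weighting and
background-frequency pseudocounts, scored against targets by local
affine-gap dynamic programming; statistical significance comes from a Gumbel
(EVD) fit to the scores of shuffled-composition decoys.  This keeps the full
iterate-to-stability procedure while avoiding a profile-HMM engine; it is a
stated simplification, not an emulation of any particular search tool.

Scores are in half-bits (2·log2 odds); gap costs follow the open 11 /
extend 1 convention of the pairwise module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from sqgsuite.records import AMINO_ACIDS, ProteinRecord

#: BLOSUM62 background amino-acid frequencies
BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BG = np.array([BACKGROUND[a] for a in AMINO_ACIDS])
_BG /= _BG.sum()

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Profile:
    """Per-position half-bit log-odds scores over the 20 residues.

    ``columns`` is (length, 21): 20 residue scores plus a zero column for the
    ambiguity code X.  ``kept_columns`` maps profile positions back to the
    source MSA columns that survived the >50%-gap mask.
    """

    columns: np.ndarray
    pseudocount_weight: float
    source_msa_ids: tuple[str, ...]
    kept_columns: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.columns.shape[0]


def build_profile(
    msa: Sequence[tuple[str, str]] | dict[str, str],
    pseudocount_weight: float = 0.5,
) -> Profile:
    """PSSM from an aligned set of sequences.

    Columns with more than 50% gaps are masked out of the profile.  Observed
    frequencies use Henikoff position-based weights; ``pseudocount_weight``
    background pseudo-observations (effective counts) regularise rare
    columns.  Deterministic.
    """
    items = list(msa.items()) if isinstance(msa, dict) else list(msa)
    if len(items) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ids = tuple(i for i, _ in items)
    seqs = [s.upper() for _, s in items]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged MSA: aligned lengths differ")

    # residue index per cell; -1 for gap/X (treated as missing)
    mat = np.full((len(seqs), width), -1, dtype=int)
    for r, s in enumerate(seqs):
        for c, ch in enumerate(s):
            if ch in GAP_CHARS or ch == "X":
                continue
            if ch not in _AA_INDEX:
                raise ValueError(f"invalid residue {ch!r} in MSA")
            mat[r, c] = _AA_INDEX[ch]

    gap_frac = (mat < 0).mean(axis=0)
    if np.any(gap_frac == 1.0):
        raise ValueError("all-gap column in MSA")
    keep = np.flatnonzero(gap_frac <= 0.5)
    if keep.size == 0:
        raise ValueError("no columns survive the >50%-gap mask")

    # Henikoff position-based weights over the kept columns
    weights = np.zeros(len(seqs))
    for c in keep:
        col = mat[:, c]
        present = col >= 0
        residues, counts = np.unique(col[present], return_counts=True)
        r = len(residues)
        count_of = dict(zip(residues, counts))
        for s_i in np.flatnonzero(present):
            weights[s_i] += 1.0 / (r * count_of[col[s_i]])
    if weights.sum() == 0:
        weights[:] = 1.0
    weights /= weights.sum()

    alpha = float(pseudocount_weight)
    scores = np.zeros((keep.size, 21))
    for out_c, c in enumerate(keep):
        col = mat[:, c]
        present = col >= 0
        wsum = weights[present].sum()
        freq = np.zeros(20)
        for s_i in np.flatnonzero(present):
            freq[col[s_i]] += weights[s_i]
        if wsum > 0:
            freq /= wsum
        n_c = int(present.sum())
        blended = (n_c * freq + alpha * _BG) / (n_c + alpha)
        scores[out_c, :20] = 2.0 * np.log2(blended / _BG)
    return Profile(
        columns=scores, pseudocount_weight=alpha,
        source_msa_ids=ids, kept_columns=tuple(int(c) for c in keep),
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, 20) for ch in seq], dtype=int)


def score_sequence(
    profile: Profile, seq: str,
    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
    traceback: bool = False,
):
    """Best local profile-vs-sequence alignment score (Gotoh, affine gaps).

    The row recurrence is fully vectorised: the horizontal (affine-gap)
    maximum is a running cumulative maximum, since chaining two adjacent
    gaps is never better than one longer gap.  With ``traceback`` the
    profile-aligned target string and the 1-based target span are returned.
    """
    if profile.length == 0:
        raise ValueError("empty profile")
    idx = _encode(seq)
    n = idx.size
    L = profile.length
    S = profile.columns
    W = gap_open + gap_extend
    ge = gap_extend
    jext = np.arange(1, n + 1) * ge

    H_rows = np.zeros((L + 1, n + 1)) if traceback else None
    G_rows = np.zeros((L + 1, n + 1)) if traceback else None
    F_rows = np.full((L + 1, n + 1), -np.inf) if traceback else None

    prevH = np.zeros(n + 1)
    prevF = np.full(n + 1, -np.inf)
    best = 0.0
    best_pos = (0, 0)
    for i in range(1, L + 1):
        srow = S[i - 1]
        F = np.maximum(prevH - W, prevF - ge)
        diag = prevH[:-1] + srow[idx]
        G = np.maximum(0.0, np.maximum(diag, F[1:]))
        A = np.maximum.accumulate(G + jext)
        H = G.copy()
        if n > 1:
            ecand = A[:-1] - W - jext[1:] + ge
            H[1:] = np.maximum(G[1:], ecand)
        Hfull = np.concatenate([[0.0], H])
        if traceback:
            H_rows[i] = Hfull
            G_rows[i] = np.concatenate([[0.0], G])
            F_rows[i] = F
        row_best = int(np.argmax(H))
        if H[row_best] > best:
            best = float(H[row_best])
            best_pos = (i, row_best + 1)
        prevH = Hfull
        prevF = F
    if not traceback:
        return best

    aligned = ["-"] * L
    j_hit: list[int] = []
    i, j = best_pos
    tol = 1e-9
    if best > 0:
        while i > 0 and j > 0 and H_rows[i][j] > tol:
            h = H_rows[i][j]
            if abs(h - G_rows[i][j]) <= tol:
                g = G_rows[i][j]
                dval = H_rows[i - 1][j - 1] + S[i - 1][idx[j - 1]]
                if abs(g - dval) <= tol:
                    aligned[i - 1] = seq[j - 1]
                    j_hit.append(j)
                    i, j = i - 1, j - 1
                elif abs(g - F_rows[i][j]) <= tol:
                    # vertical gap: profile positions consumed against a gap
                    while (i > 1
                           and abs(F_rows[i][j] - (F_rows[i - 1][j] - ge)) <= tol
                           and not abs(F_rows[i][j]
                                       - (H_rows[i - 1][j] - W)) <= tol):
                        i -= 1
                    i -= 1
                else:  # g == 0
                    break
            else:
                # horizontal gap: jump back to its opening column
                target = H_rows[i][j]
                k = j - 1
                while k >= 1:
                    if abs(G_rows[i][k] - W - (j - k - 1) * ge - target) <= tol:
                        break
                    k -= 1
                if k < 1:
                    break
                j = k
    span = (min(j_hit), max(j_hit)) if j_hit else (0, 0)
    return best, "".join(aligned), span


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    best_score: float
    evalue: float
    aligned_span: tuple[int, int]  # 1-based inclusive target coordinates

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def calibrate_gumbel(
    profile: Profile, database: Sequence[ProteinRecord],
    n_decoys: int = 200, seed: int = 0,
    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
) -> tuple[float, float]:
    """Gumbel (loc, scale) fitted to profile scores of shuffled decoys."""
    from sqgsuite.syndata import make_decoys  # deferred: avoid import cycle

    decoys = make_decoys(list(database), n_decoys, seed=seed,
                         prefix="_calib")
    scores = np.array([
        score_sequence(profile, d.seq, gap_open, gap_extend) for d in decoys
    ])
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(max(scale, 1e-9))


def search(
    profile: Profile,
    database: Sequence[ProteinRecord],
    evalue_cutoff: float = 1e-3,
    n_decoys: int = 200,
    seed: int = 0,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> list[SearchHit]:
    """Score every target; E-values from the decoy-calibrated Gumbel tail.

    E(score) = N_database · P_gumbel(S ≥ score), floored at 1e-300 so an
    E-value cutoff of 0 returns no hits.  Hits are sorted by (E-value, id).
    """
    if not database:
        raise ValueError("database must be non-empty")
    loc, scale = calibrate_gumbel(profile, database, n_decoys, seed,
                                  gap_open, gap_extend)
    hits = []
    for rec in database:
        score, aligned, span = score_sequence(
            profile, rec.seq, gap_open, gap_extend, traceback=True
        )
        ev = max(len(database) * float(gumbel_r.sf(score, loc, scale)),
                 1e-300)
        if ev <= evalue_cutoff:
            hits.append(SearchHit(rec.id, float(score), ev, span))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def realign_hits(
    profile: Profile, hits: Sequence[SearchHit],
    database: Sequence[ProteinRecord],
    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
) -> list[tuple[str, str]]:
    """Hit sequences re-threaded onto the profile columns via the local DP
    trace (insertions relative to the profile are dropped)."""
    by_id = {r.id: r for r in database}
    out = []
    for h in hits:
        _, aligned, _ = score_sequence(
            profile, by_id[h.target_id].seq, gap_open, gap_extend,
            traceback=True,
        )
        out.append((h.target_id, aligned))
    return out


@dataclass(frozen=True)
class ConvergenceResult:
    final_ids: tuple[str, ...]
    n_iterations: int
    set_sizes: tuple[int, ...]
    status: str  # "converged" | "not converged" | "oscillating"


def iterate_to_convergence(
    seed_msa: Sequence[tuple[str, str]] | dict[str, str],
    database: Sequence[ProteinRecord],
    evalue_cutoff: float = 1e-3,
    max_iters: int = 10,
    n_decoys: int = 200,
    seed: int = 0,
    pseudocount_weight: float = 0.5,
) -> ConvergenceResult:
    """Search, realign, rebuild, repeat until the retrieved id set is stable.

    Convergence is exact set equality with the previous round (the seed MSA
    ids count as round zero, so a database containing only the seed
    converges in one iteration).  A set that recurs non-consecutively is
    flagged ``oscillating``; otherwise hitting ``max_iters`` with a changed
    set reports ``not converged``.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    items = (list(seed_msa.items()) if isinstance(seed_msa, dict)
             else list(seed_msa))
    current_msa = items
    prev = frozenset(i for i, _ in items)
    history = [prev]
    sizes: list[int] = []
    status = "not converged"
    n_done = 0
    for _ in range(max_iters):
        profile = build_profile(current_msa,
                                pseudocount_weight=pseudocount_weight)
        hits = search(profile, database, evalue_cutoff,
                      n_decoys=n_decoys, seed=seed)
        ids = frozenset(h.target_id for h in hits)
        n_done += 1
        sizes.append(len(ids))
        if ids == history[-1]:
            status = "converged"
            final = ids
            break
        if ids in history[:-1]:
            status = "oscillating"
            final = ids
            break
        history.append(ids)
        current_msa = realign_hits(profile, hits, database)
        final = ids
    if not sizes:
        final = prev
    return ConvergenceResult(
        final_ids=tuple(sorted(final)),
        n_iterations=n_done,
        set_sizes=tuple(sizes),
        status=status,
    )
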