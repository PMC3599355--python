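"""Protein alignment, percent identity and evolutionary distances.

Global pairwise alignment uses affine-gap (Gotoh) dynamic programming with a
BLOSUM62 substitution matrix and ClustalW-like penalties (gap open 10,
extend 0.5; a gap of length L costs open + (L-1)*extend). The multiple
aligner is guide-tree progressive: UPGMA on 1 - identity/100 from all
pairwise alignments, then profile-profile merges leaf-to-root with the same
scoring. Tie-breaking in the traceback is fixed (diagonal, then up, then
left) so alignments are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage

from .records import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
_NEG = -1.0e30  # effectively -inf, safe under +/- arithmetic


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 canonical residues, as a float array."""
    from Bio.Align import substitution_matrices

    full = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = full[a][b]
    return m


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix (20x20 over ACDEFGHIKLMNPQRSTVWY) + gap penalties."""

    matrix: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 0.5


_DEFAULT_SCORING: Scoring | None = None


def default_scoring() -> Scoring:
    global _DEFAULT_SCORING
    if _DEFAULT_SCORING is None:
        _DEFAULT_SCORING = Scoring(blosum62_matrix())
    return _DEFAULT_SCORING


class Alignment:
    """An ordered list of (taxon id, gapped residue string) rows.

    All rows have equal length, no column is all-gaps, and removing gaps from
    a row reproduces the input sequence exactly.
    """

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("alignment needs at least one row")
        length = len(rows[0][1])
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        for rid, s in rows:
            if len(s) != length:
                raise ValueError(f"row {rid} has length {len(s)} != {length}")
        if length and any(
            all(s[j] == GAP for _, s in rows) for j in range(length)
        ):
            raise ValueError("all-gap column in alignment")
        self.rows: list[tuple[str, str]] = list(rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def ungapped(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s.replace(GAP, "")
        raise KeyError(rid)

    def encoded(self) -> np.ndarray:
        """Integer-encode rows: residue index 0..19, gap = -1."""
        out = np.empty((len(self.rows), self.length), dtype=np.int8)
        for i, (_, s) in enumerate(self.rows):
            out[i] = [AA_INDEX.get(c, -1) for c in s]
        return out

    def to_fasta(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for rid, s in self.rows:
                fh.write(f">{rid}\n{s}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(rows)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc} in sequence") from None


def _gotoh(S: np.ndarray, open_: float, ext: float):
    """Affine-gap global DP over a precomputed column-score matrix S (n x m).

    States: M (both consumed), X (gap in second sequence, 'up'),
    Y (gap in first sequence, 'left'). Returns the three score matrices.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -open_ - np.arange(n) * ext
    if m:
        Y[0, 1:] = -open_ - np.arange(m) * ext
    jj = np.arange(1, m + 1) * ext
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = best_prev + S[i - 1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - open_, X[i - 1] - ext
        )
        X[i, 0] = -open_ - (i - 1) * ext
        # Y row is a running-max scan: Y[i,j] = max(max(M,X)[i,j-1]-open, Y[i,j-1]-ext)
        t = np.maximum(M[i, :-1], X[i, :-1]) - open_ + jj
        Y[i, 1:] = np.maximum.accumulate(t) - jj
        Y[i, 0] = _NEG
    return M, X, Y


def _traceback(M, X, Y, open_, ext):
    """Walk back from (n, m) preferring diagonal, then up, then left on ties."""
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax prefers M > X > Y on exact ties
    path: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:  # M: consumed a_i and b_j
            val = M[i, j]
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            prev_best = max(cands)
            state = cands.index(prev_best)
            i, j = i - 1, j - 1
        elif state == 1:  # X: consumed a_i against a gap
            val = X[i, j]
            cands = (M[i - 1, j] - open_, X[i - 1, j] - ext, Y[i - 1, j] - open_)
            for s in (0, 1, 2):
                if cands[s] == val:
                    state = s
                    break
            else:  # numeric slack on boundary rows
                state = int(np.argmax(cands))
            i -= 1
        else:  # Y: consumed b_j against a gap
            val = Y[i, j]
            cands = (M[i, j - 1] - open_, X[i, j - 1] - open_, Y[i, j - 1] - ext)
            for s in (0, 1, 2):
                if cands[s] == val:
                    state = s
                    break
            else:
                state = int(np.argmax(cands))
            j -= 1
    path.reverse()
    return path


def pairwise_global_align(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    ids: tuple[str, str] = ("seq1", "seq2"),
) -> tuple[Alignment, float]:
    """Optimal global alignment of two protein sequences under affine gaps."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or default_scoring()
    ia, ib = _encode(a), _encode(b)
    S = scoring.matrix[np.ix_(ia, ib)]
    M, X, Y = _gotoh(S, scoring.gap_open, scoring.gap_extend)
    n, m = len(a), len(b)
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    path = _traceback(M, X, Y, scoring.gap_open, scoring.gap_extend)
    ga, gb = [], []
    i = j = 0
    au, bu = a.upper(), b.upper()
    for state in path:
        if state == 0:
            ga.append(au[i]); gb.append(bu[j]); i += 1; j += 1
        elif state == 1:
            ga.append(au[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(bu[j]); j += 1
    return Alignment([(ids[0], "".join(ga)), (ids[1], "".join(gb))]), score


def percent_identity(aln: Alignment, denominator: str = "scored_columns") -> float:
    """Percent identity of a two-row alignment.

    ``scored_columns`` (default): 100 x identical pairs / columns with at
    least one residue. ``shorter_sequence``: divide by the shorter ungapped
    sequence length instead.
    """
    if len(aln) != 2:
        raise ValueError("percent_identity needs exactly two rows")
    s1, s2 = aln.rows[0][1], aln.rows[1][1]
    ident = sum(1 for x, y in zip(s1, s2) if x == y and x != GAP)
    if denominator == "scored_columns":
        denom = sum(1 for x, y in zip(s1, s2) if x != GAP or y != GAP)
    elif denominator == "shorter_sequence":
        denom = min(len(s1.replace(GAP, "")), len(s2.replace(GAP, "")))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("alignment has no scorable columns")
    return 100.0 * ident / denom


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (L x 20); gaps contribute zero weight."""
    L = len(rows[0])
    f = np.zeros((L, 20))
    for s in rows:
        idx = np.array([AA_INDEX.get(c, -1) for c in s])
        mask = idx >= 0
        f[np.arange(L)[mask], idx[mask]] += 1.0
    return f / len(rows)


def _merge_profiles(
    rows_a: list[tuple[str, str]],
    rows_b: list[tuple[str, str]],
    scoring: Scoring,
) -> list[tuple[str, str]]:
    fa = _profile_freqs([s for _, s in rows_a])
    fb = _profile_freqs([s for _, s in rows_b])
    S = fa @ scoring.matrix @ fb.T
    M, X, Y = _gotoh(S, scoring.gap_open, scoring.gap_extend)
    path = _traceback(M, X, Y, scoring.gap_open, scoring.gap_extend)
    out_a = {rid: [] for rid, _ in rows_a}
    out_b = {rid: [] for rid, _ in rows_b}
    i = j = 0
    for state in path:
        if state == 0:
            for rid, s in rows_a:
                out_a[rid].append(s[i])
            for rid, s in rows_b:
                out_b[rid].append(s[j])
            i += 1; j += 1
        elif state == 1:
            for rid, s in rows_a:
                out_a[rid].append(s[i])
            for rid, _ in rows_b:
                out_b[rid].append(GAP)
            i += 1
        else:
            for rid, _ in rows_a:
                out_a[rid].append(GAP)
            for rid, s in rows_b:
                out_b[rid].append(s[j])
            j += 1
    merged = [(rid, "".join(out_a[rid])) for rid, _ in rows_a]
    merged += [(rid, "".join(out_b[rid])) for rid, _ in rows_b]
    return merged


def progressive_msa(
    seqs: list[tuple[str, str]], scoring: Scoring | None = None
) -> Alignment:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA (average linkage) on d = 1 - identity/100 from
    all pairwise global alignments; profiles are merged leaf-to-root. Output
    row order equals input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [rid for rid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    for rid, s in seqs:
        if not s:
            raise ValueError(f"empty sequence {rid}")
    scoring = scoring or default_scoring()

    n = len(seqs)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_global_align(seqs[i][1], seqs[j][1], scoring)
            condensed.append(1.0 - percent_identity(aln) / 100.0)
    Z = linkage(np.asarray(condensed), method="average")

    profiles: dict[int, list[tuple[str, str]]] = {
        i: [(rid, s.upper())] for i, (rid, s) in enumerate(seqs)
    }
    for k, (left, right, _, _) in enumerate(Z):
        a = profiles.pop(int(left))
        b = profiles.pop(int(right))
        profiles[n + k] = _merge_profiles(a, b, scoring)
    (merged,) = profiles.values()
    by_id = dict(merged)
    return Alignment([(rid, by_id[rid]) for rid in ids])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise evolutionary distances over an ordered taxon set."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(header, np.array(rows))


def distance_matrix(msa: Alignment, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances from a multiple alignment.

    p-distance is mismatches over scorable columns with pairwise gap deletion
    (columns where either row is gapped are skipped for that pair). The
    "poisson" model applies the multiple-hit correction d = -ln(1 - p) and
    fails for saturated pairs (p >= 1).
    """
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    enc = msa.encoded()
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            scorable = int(both.sum())
            if scorable == 0:
                raise ValueError(
                    f"no shared ungapped columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = float(np.sum(enc[i][both] != enc[j][both])) / scorable
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {msa.ids[i]}/{msa.ids[j]} (p={p}) "
                        "has infinite Poisson distance"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(msa.ids), d)
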