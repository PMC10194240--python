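"""Global protein alignment: pairwise Gotoh and progressive multiple alignment.

Pairwise alignment is Needleman–Wunsch with affine gaps (Gotoh), scored with
BLOSUM62 and gap penalties of 11 to open and 1 to extend, where "open" is
charged on the first gapped column (so a length-k gap costs 11 + (k-1)).
Multiple alignment is progressive: a UPGMA guide tree over pairwise identity
distances, then profile–profile alignment at each internal node.  All tie
breaks are fixed (diagonal over up over left), so output is deterministic
given input order.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

GAP_OPEN = 11.0
GAP_EXTEND = 1.0
GAP = "-"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SCORE = np.array(_BLOSUM62)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-amino-acid symbol in sequence: {exc}") from exc


def substitution_score(a: str, b: str) -> float:
    return float(_SCORE[_AA_INDEX[a.upper()], _AA_INDEX[b.upper()]])


def global_align(a: str, b: str) -> tuple[float, str, str]:
    """Gotoh global alignment; returns (score, gapped_a, gapped_b)."""
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    sub = _SCORE[np.ix_(ea, eb)]  # n x m

    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal, consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)

    for i in range(1, n + 1):
        Mi1, Xi1 = M[i - 1], X[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        si = sub[i - 1]
        # X: vertical gap, column-independent recurrence
        np.maximum(Mi1 - GAP_OPEN, Xi1 - GAP_EXTEND, out=Xi)
        # M and Y depend on the previous column within the row
        best_prev = np.maximum(np.maximum(Mi1, Xi1), Y[i - 1])
        for j in range(1, m + 1):
            Mi[j] = best_prev[j - 1] + si[j - 1]
            Yi[j] = max(Mi[j - 1] - GAP_OPEN, Xi[j - 1] - GAP_OPEN, Yi[j - 1] - GAP_EXTEND)

    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback: prefer M (diagonal), then X (up), then Y (left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = "M" if M[i, j] >= max(X[i, j], Y[i, j]) else ("X" if X[i, j] >= Y[i, j] else "Y")
    while i > 0 or j > 0:
        if i == 0:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        if state == "M":
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = (
                "M"
                if M[i, j] >= prev - 1e-9 and M[i, j] >= max(X[i, j], Y[i, j])
                else ("X" if X[i, j] >= Y[i, j] else "Y")
            )
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            from_m = M[i - 1, j] - GAP_OPEN
            from_x = X[i - 1, j] - GAP_EXTEND
            state = "M" if from_m >= from_x else "X"
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            from_m = M[i, j - 1] - GAP_OPEN
            from_x = X[i, j - 1] - GAP_OPEN
            from_y = Y[i, j - 1] - GAP_EXTEND
            best = max(from_m, from_x, from_y)
            state = "M" if from_m >= best - 1e-9 else ("X" if from_x >= best - 1e-9 else "Y")
            j -= 1
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def alignment_identity(ga: str, gb: str) -> float:
    """Fraction of identical residues over columns that are not dual gaps."""
    pairs = [(x, y) for x, y in zip(ga, gb) if not (x == GAP and y == GAP)]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x == y and x != GAP) / len(pairs)


def map_columns(reference: str, query: str) -> dict[int, str]:
    """Align ``query`` to ``reference`` and map reference columns to residues.

    Returns {1-based reference column -> query residue or '-'} so that
    alignment-frame residue rules can be checked against a query sequence.
    """
    _, gref, gqry = global_align(reference, query)
    mapping: dict[int, str] = {}
    col = 0
    for r, q in zip(gref, gqry):
        if r != GAP:
            col += 1
            mapping[col] = q
    return mapping


# --------------------------- progressive MSA --------------------------------


class _Profile:
    """Counts-per-column view of a growing alignment."""

    __slots__ = ("rows", "counts")

    def __init__(self, rows: list[str]):
        self.rows = rows
        length = len(rows[0])
        counts = np.zeros((length, len(_ALPHABET) + 1))  # +1 gap column
        for row in rows:
            for i, aa in enumerate(row):
                if aa == GAP:
                    counts[i, -1] += 1
                else:
                    counts[i, _AA_INDEX[aa]] += 1
        self.counts = counts

    def __len__(self) -> int:
        return self.counts.shape[0]


_GAP_RESIDUE_SCORE = -4.0  # scoring a residue against an existing gap column


def _column_scores(p: _Profile, q: _Profile) -> np.ndarray:
    """Expected BLOSUM62 score between every column pair of two profiles."""
    pa, pg = p.counts[:, :-1], p.counts[:, -1:]
    qa, qg = q.counts[:, :-1], q.counts[:, -1:]
    np_tot = p.counts.sum(axis=1, keepdims=True)
    nq_tot = q.counts.sum(axis=1, keepdims=True)
    cross = pa @ _SCORE @ qa.T
    gap_terms = pg @ qa.sum(axis=1, keepdims=True).T + pa.sum(axis=1, keepdims=True) @ qg.T
    return (cross + _GAP_RESIDUE_SCORE * gap_terms) / (np_tot @ nq_tot.T)


def _align_profiles(p: _Profile, q: _Profile) -> _Profile:
    sub = _column_scores(p, q)
    n, m = len(p), len(q)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        np.maximum(Mi1 - GAP_OPEN, Xi1 - GAP_EXTEND, out=Xi)
        best_prev = np.maximum(np.maximum(Mi1, Xi1), Yi1)
        si = sub[i - 1]
        for j in range(1, m + 1):
            Mi[j] = best_prev[j - 1] + si[j - 1]
            Yi[j] = max(Mi[j - 1] - GAP_OPEN, Xi[j - 1] - GAP_OPEN, Yi[j - 1] - GAP_EXTEND)

    # traceback
    ops: list[str] = []
    i, j = n, m
    state = "M" if M[i, j] >= max(X[i, j], Y[i, j]) else ("X" if X[i, j] >= Y[i, j] else "Y")
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == "M":
            ops.append("M")
            i, j = i - 1, j - 1
            state = "M" if M[i, j] >= max(X[i, j], Y[i, j]) else ("X" if X[i, j] >= Y[i, j] else "Y")
        elif state == "X":
            ops.append("X")
            from_m = M[i - 1, j] - GAP_OPEN
            from_x = X[i - 1, j] - GAP_EXTEND
            state = "M" if from_m >= from_x else "X"
            i -= 1
        else:
            ops.append("Y")
            from_m = M[i, j - 1] - GAP_OPEN
            from_x = X[i, j - 1] - GAP_OPEN
            from_y = Y[i, j - 1] - GAP_EXTEND
            best = max(from_m, from_x, from_y)
            state = "M" if from_m >= best - 1e-9 else ("X" if from_x >= best - 1e-9 else "Y")
            j -= 1
    ops.reverse()

    new_rows = []
    for row in p.rows:
        it = iter(row)
        new_rows.append("".join(next(it) if op in ("M", "X") else GAP for op in ops))
    for row in q.rows:
        it = iter(row)
        new_rows.append("".join(next(it) if op in ("M", "Y") else GAP for op in ops))
    return _Profile(new_rows)


def _upgma_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA merge order over a condensed distance matrix; returns merge pairs
    referring to cluster ids (leaves 0..n-1, internal nodes n, n+1, ...)."""
    n = dist.shape[0]
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int]] = []
    next_id = n
    while len(active) > 1:
        (a, b), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b))
        members = active[a] + active[b]
        sizes = {k: len(v) for k, v in active.items()}
        new_d = {}
        for k in active:
            if k in (a, b):
                continue
            da = d[(min(a, k), max(a, k))]
            db = d[(min(b, k), max(b, k))]
            new_d[(k, next_id)] = (da * sizes[a] + db * sizes[b]) / (sizes[a] + sizes[b])
        del active[a], active[b]
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        for (k, nid), v in new_d.items():
            d[(min(k, nid), max(k, nid))] = v
        active[next_id] = members
        next_id += 1
    return merges


def align_members(sequences: list[str]) -> list[str]:
    """Progressive multiple alignment of protein sequences.

    Requires ≥2 non-empty sequences; returns equal-length gapped strings in
    the input order.
    """
    if len(sequences) < 2:
        raise ValueError("align_members requires at least two sequences")
    if any(not s for s in sequences):
        raise ValueError("align_members: empty sequence")
    n = len(sequences)
    if n == 2:
        _, ga, gb = global_align(sequences[0], sequences[1])
        return [ga, gb]

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ga, gb = global_align(sequences[i], sequences[j])
            dist[i, j] = dist[j, i] = 1.0 - alignment_identity(ga, gb)

    profiles: dict[int, tuple[_Profile, list[int]]] = {
        i: (_Profile([sequences[i]]), [i]) for i in range(n)
    }
    next_id = n
    for a, b in _upgma_order(dist):
        pa, ia = profiles.pop(a)
        pb, ib = profiles.pop(b)
        profiles[next_id] = (_align_profiles(pa, pb), ia + ib)
        next_id += 1
    (final, order), = profiles.values()
    out = [""] * n
    for row, orig in zip(final.rows, order):
        out[orig] = row
    return out
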