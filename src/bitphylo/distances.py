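"""Transform raw bit scores into the symmetric bit-score distance matrix.

The chain is: repair missing scores so every query has strictly
positive values everywhere; normalise each row by its maximum
(self-hit included); weight the two directed normalised scores by the
overlap of the two queries' hit profiles; average into a symmetric
similarity S in (0, 1]; and take d = -log S.  A distance of 0 means
the pair is mutually top-scoring with perfectly overlapping hit sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .scoring import RawScoreMatrix


class DistanceError(ValueError):
    pass


class NoOverlapError(DistanceError):
    """Two queries share no hits; the inference cannot be completed."""


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, entries in (0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise DistanceError("similarity matrix must be symmetric")
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise DistanceError("similarities must lie in (0, 1]")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, non-negative, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise DistanceError("distance matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise DistanceError("distances must be finite")
        if np.any(np.diag(v) != 0):
            raise DistanceError("diagonal must be zero")
        if np.any(v < 0):
            raise DistanceError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def fill_missing_scores(m: RawScoreMatrix) -> RawScoreMatrix:
    """Replace zero entries in each query row by s_min(query) / 2.

    The replacement is strictly below every observed score for that
    query, keeps -log finite, and preserves score ranking.  Repaired
    entries are NOT added to the hit mask, so overlap weights are
    unaffected by the repair.
    """
    scores = m.scores.copy()
    for i, sid in enumerate(m.ids):
        row = scores[i]
        nz = row > 0
        if not nz.any():
            raise DistanceError(f"query {sid!r} has no non-zero scores")
        row[~nz] = row[nz].min() / 2.0
    return replace(m, scores=scores, hit_mask=m.hit_mask.copy())


def overlap_weight(m: RawScoreMatrix, a: str, b: str,
                   form: str = "dice") -> float:
    """Hit-profile overlap weight in (0, 1].

    ``dice`` (default): 2 n_AB / (n_A + n_B); ``max``: n_AB / max(n_A, n_B).
    Both equal 1 exactly when the two hit sets coincide.  Zero overlap is
    an error: with disjoint hit profiles the inference cannot proceed.
    """
    n_a, n_b = m.n_hits(a), m.n_hits(b)
    n_ab = m.n_overlap(a, b)
    if n_ab == 0:
        raise NoOverlapError(
            f"no overlap between hit sets of {a!r} and {b!r}; "
            "inference cannot be completed")
    if form == "dice":
        return 2.0 * n_ab / (n_a + n_b)
    if form == "max":
        return n_ab / max(n_a, n_b)
    raise ValueError(f"unknown overlap form {form!r}")


def similarity(m: RawScoreMatrix, overlap_form: str = "dice") -> SimilarityMatrix:
    """Symmetrised, overlap-weighted, row-normalised similarity matrix.

    Expects a repaired matrix (every entry positive).  For each ordered
    pair the normalised score is s(A,B)/s_max(A); the two directions are
    weighted by their overlap weights and averaged.
    """
    if np.any(m.scores <= 0):
        raise DistanceError("similarity() requires fill_missing_scores first")
    n = m.n
    hits = m.hit_mask
    n_hits = hits.sum(axis=1).astype(float)
    n_overlap = (hits[:, None, :] & hits[None, :, :]).sum(axis=2).astype(float)
    if np.any(n_overlap == 0):
        i, j = np.argwhere(n_overlap == 0)[0]
        raise NoOverlapError(
            f"no overlap between hit sets of {m.ids[i]!r} and {m.ids[j]!r}; "
            "inference cannot be completed")
    if overlap_form == "dice":
        w = 2.0 * n_overlap / (n_hits[:, None] + n_hits[None, :])
    elif overlap_form == "max":
        w = n_overlap / np.maximum(n_hits[:, None], n_hits[None, :])
    else:
        raise ValueError(f"unknown overlap form {overlap_form!r}")
    s_hat = m.scores / m.scores.max(axis=1, keepdims=True)
    weighted = w * s_hat
    sim = (weighted + weighted.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, None, 1.0)
    return SimilarityMatrix(list(m.ids), sim)


def to_distance(sm: SimilarityMatrix) -> DistanceMatrix:
    """d(A,B) = -log S(A,B) (natural log); zero diagonal, finite, >= 0."""
    d = -np.log(sm.values)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(sm.ids), d)


def raw_to_distance(m: RawScoreMatrix, overlap_form: str = "dice") -> DistanceMatrix:
    """Full chain: missing-score repair -> similarity -> -log distance."""
    return to_distance(similarity(fill_missing_scores(m), overlap_form))


def triangle_violations(d: DistanceMatrix, tol: float = 1e-9) -> int:
    """Count ordered triples violating d(i,k) <= d(i,j) + d(j,k).

    Reported, not asserted: modular proteins can make real bit-score
    distances non-metric even though simulated families rarely do.
    """
    v = d.values
    n = d.n
    count = 0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for k in range(n):
                if k in (i, j):
                    continue
                if v[i, k] > v[i, j] + v[j, k] + tol:
                    count += 1
    return count


def write_phylip(d: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix with relaxed (whitespace-free) names."""
    with open(path, "w") as fh:
        fh.write(f"{d.n}\n")
        for i, sid in enumerate(d.ids):
            row = " ".join(f"{x:.6f}" for x in d.values[i])
            fh.write(f"{sid}  {row}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln for ln in tokens if ln.strip()]
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for ln in lines[1:n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:n + 1]])
    values = np.array(rows)
    return DistanceMatrix(ids, (values + values.T) / 2.0)
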