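"""Gamma/BLOSUM62 sequence-change model and replicate generation.

Each BLOSUM62 row is remapped so its best-scoring substitution sits at
distance 0 and every other substitution at a positive integer distance
B'(i,j) = B_max(i) - B(i,j).  The replacement probability for a site
holding amino acid i is an exponential-decay weight over that distance
— the Gamma density with shape 1 and scale theta evaluated at B'(i,j)
— shared uniformly across the tie group of amino acids at the same
distance, then normalised into a proper per-row distribution.  Sites
are perturbed independently; positions holding ambiguity codes
(B, Z, X, U) are never mutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .sequences import AMBIGUOUS_AA, STANDARD_AA, ProteinSequence, SequenceSet

#: the fitted optimum of the Gamma scale on simulated families
DEFAULT_THETA = 1.9644

AA_ORDER = list(STANDARD_AA)
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class PerturbationError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """Remapped substitution distances plus the Gamma scale theta.

    Attributes
    ----------
    scores : (20, 20) int array, original substitution scores, indexed
        by :data:`AA_ORDER`.
    remapped : (20, 20) int array, B_max(i) - B(i,j) >= 0; every row
        attains 0.
    theta : Gamma scale (shape fixed at 1); theta == 0 disables
        perturbation entirely.
    """

    scores: np.ndarray
    remapped: np.ndarray
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise PerturbationError("theta must be >= 0")
        if self.remapped.shape != (20, 20):
            raise PerturbationError("expected a complete 20x20 matrix")
        if np.any(self.remapped < 0) or np.any(self.remapped.min(axis=1) != 0):
            raise PerturbationError("remap must be >= 0 with row minimum 0")

    def b_max(self, i: str) -> int:
        return int(self.scores[_AA_INDEX[i]].max())

    def remapped_distance(self, i: str, j: str) -> int:
        return int(self.remapped[_AA_INDEX[i], _AA_INDEX[j]])

    def tie_group(self, i: str, distance: int) -> set[str]:
        """Amino acids j sharing remapped distance ``distance`` in row i."""
        row = self.remapped[_AA_INDEX[i]]
        return {AA_ORDER[j] for j in np.where(row == distance)[0]}

    def gamma_pdf(self, x: float) -> float:
        """f(x; shape 1, scale theta) = (1/theta) exp(-x/theta)."""
        if self.theta <= 0:
            raise PerturbationError("theta must be > 0 for density evaluation")
        return math.exp(-x / self.theta) / self.theta

    def raw_weight(self, i: str, j: str) -> float:
        """Unnormalised weight f(B'(i,j); 1, theta) / |tie group|."""
        x = self.remapped_distance(i, j)
        return self.gamma_pdf(x) / len(self.tie_group(i, x))

    def probability_matrix(self) -> np.ndarray:
        """(20, 20) row-stochastic matrix of per-site replacement probabilities."""
        if self.theta == 0:
            return np.eye(20)
        weights = np.exp(-self.remapped / self.theta) / self.theta
        for i in range(20):
            row = self.remapped[i]
            _, inverse, counts = np.unique(row, return_inverse=True,
                                           return_counts=True)
            weights[i] /= counts[inverse]
        return weights / weights.sum(axis=1, keepdims=True)


def remap_matrix(matrix=None, theta: float = DEFAULT_THETA) -> SubstitutionModel:
    """Build a :class:`SubstitutionModel` from a substitution matrix.

    ``matrix`` may be None (bundled BLOSUM62), a biopython
    substitution_matrices Array, or a path to an NCBI-format matrix file.
    Only the 20 standard amino-acid rows/columns are used.
    """
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    elif isinstance(matrix, (str, bytes)) or hasattr(matrix, "__fspath__"):
        with open(matrix) as fh:
            matrix = substitution_matrices.read(fh)
    missing = [a for a in AA_ORDER if a not in matrix.alphabet]
    if missing:
        raise PerturbationError(
            f"substitution matrix lacks standard residues: {missing}")
    scores = np.array([[int(matrix[i, j]) for j in AA_ORDER] for i in AA_ORDER])
    remapped = scores.max(axis=1, keepdims=True) - scores
    return SubstitutionModel(scores=scores, remapped=remapped, theta=theta)


def substitution_probability(model: SubstitutionModel, i: str, j: str) -> float:
    """Normalised probability of replacing amino acid i by j at one site."""
    p = model.probability_matrix()
    return float(p[_AA_INDEX[i], _AA_INDEX[j]])


def perturb(seqs: SequenceSet, model: SubstitutionModel,
            seed: int | np.random.Generator) -> SequenceSet:
    """Resample every standard-residue position from its row distribution.

    Lengths and ids are preserved; ambiguity codes pass through
    unchanged; the output is deterministic given the seed.  With
    theta == 0 the input is returned unmodified (no-perturbation mode).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.theta == 0:
        return SequenceSet([ProteinSequence(s.id, s.residues) for s in seqs])
    prob = model.probability_matrix()
    # one concatenated pass, then split back per sequence
    lengths = [len(s) for s in seqs]
    concat = "".join(s.residues for s in seqs)
    codes = np.frombuffer(concat.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for aa, k in _AA_INDEX.items():
        lut[ord(aa)] = k
    idx = lut[codes]
    out = codes.copy()
    aa_bytes = np.frombuffer(STANDARD_AA.encode("ascii"), dtype=np.uint8)
    for k in range(20):
        mask = idx == k
        cnt = int(mask.sum())
        if cnt:
            out[mask] = aa_bytes[rng.choice(20, size=cnt, p=prob[k])]
    perturbed = out.tobytes().decode("ascii")
    result, offset = [], 0
    for s, ln in zip(seqs, lengths):
        result.append(ProteinSequence(s.id, perturbed[offset:offset + ln]))
        offset += ln
    return SequenceSet(result)


def make_replicates(seqs: SequenceSet, model: SubstitutionModel, n: int,
                    seed: int) -> list[SequenceSet]:
    """n independently perturbed copies, one spawned RNG stream each.

    Replicate k always sees the same stream for a given master seed, so
    replicate sets are bit-identical across runs.
    """
    if n < 1:
        raise PerturbationError("replicate count must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    return [perturb(seqs, model, np.random.default_rng(s)) for s in streams]


# re-export for callers that only need the tolerated-code set
__all__ = [
    "DEFAULT_THETA", "AA_ORDER", "SubstitutionModel", "PerturbationError",
    "remap_matrix", "substitution_probability", "perturb", "make_replicates",
    "AMBIGUOUS_AA",
]
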