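"""All-vs-all local-alignment bit scores and per-query hit profiles.

Two routes produce the same :class:`RawScoreMatrix`:

* an internal Smith-Waterman engine (BLOSUM62, affine gaps) whose raw
  scores are converted to bits with the Karlin-Altschul parameters of
  the gapped blastp scoring regime, and
* a parser for external blastp tabular output (outfmt-6-like).

The internal engine scores every ordered pair exhaustively; entries
whose bit score falls below a configurable hit threshold are recorded
as zero ("no hit"), reproducing the hit/no-hit structure a database
search would give.  Internal scores approximate but do not equal
blastp scores, which use seeding heuristics and composition statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import SequenceSet


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class AlignerParams:
    """Smith-Waterman scoring parameters and bit-score conversion.

    Defaults are the gapped blastp regime: BLOSUM62, gap open 11,
    gap extend 1, Karlin-Altschul lambda=0.267 and K=0.041.  A gap of
    length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    hit_threshold_bits: float = 15.0

    def to_bits(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2.0)


@dataclass
class RawScoreMatrix:
    """Asymmetric all-vs-all bit scores with per-query hit profiles.

    ``scores[i, j]`` is the bit score for subject ``ids[j]`` using query
    ``ids[i]``; zero means "no hit".  ``hit_mask`` records which entries
    count as hits for overlap weighting — missing-score repair fills
    values without enlarging hit sets.
    """

    ids: list[str]
    scores: np.ndarray
    hit_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.scores.shape != (n, n) or self.hit_mask.shape != (n, n):
            raise ScoringError("score/hit matrices must be |ids| x |ids|")
        if np.any(self.scores < 0):
            raise ScoringError("bit scores must be non-negative")
        if np.any(np.diag(self.scores) <= 0):
            bad = [self.ids[i] for i in np.where(np.diag(self.scores) <= 0)[0]]
            raise ScoringError(f"zero self-score for {bad}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.index(a), self.index(b)])

    def s_max(self, a: str) -> float:
        """Maximum bit score observed for query ``a`` (self-hit included)."""
        return float(self.scores[self.index(a)].max())

    def s_min(self, a: str) -> float:
        """Minimum non-zero bit score observed for query ``a``."""
        row = self.scores[self.index(a)]
        nz = row[row > 0]
        return float(nz.min())

    def hits(self, a: str) -> set[str]:
        """Subjects with a non-zero score for query ``a`` (includes ``a``)."""
        i = self.index(a)
        return {self.ids[j] for j in np.where(self.hit_mask[i])[0]}

    def n_hits(self, a: str) -> int:
        return int(self.hit_mask[self.index(a)].sum())

    def n_overlap(self, a: str, b: str) -> int:
        i, j = self.index(a), self.index(b)
        return int((self.hit_mask[i] & self.hit_mask[j]).sum())


_SCORING_ALPHABET_SUB = str.maketrans({"U": "X"})  # BLOSUM62 has no U row


def _make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # biopython charges open_gap_score for the first gapped position, BLAST
    # charges open + extend for a length-1 gap
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def compute_scores_internal(seqs: SequenceSet,
                            params: AlignerParams | None = None) -> RawScoreMatrix:
    """Score every ordered pair with the internal Smith-Waterman engine.

    Raw local-alignment scores are symmetric, so only the upper triangle
    is aligned and mirrored.  Self-scores are always recorded as hits;
    off-diagonal entries below ``params.hit_threshold_bits`` become 0.
    """
    params = params or AlignerParams()
    aligner = _make_aligner(params)
    n = len(seqs)
    ids = seqs.ids
    clean = [s.residues.translate(_SCORING_ALPHABET_SUB) for s in seqs]
    bits = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw = aligner.score(clean[i], clean[j])
            bits[i, j] = bits[j, i] = params.to_bits(raw)
    hit_mask = bits >= params.hit_threshold_bits
    np.fill_diagonal(hit_mask, True)
    scores = np.where(hit_mask, bits, 0.0)
    if np.any(np.diag(scores) <= 0):
        raise ScoringError("a self-alignment scored <= 0 bits; "
                           "check aligner parameters")
    return RawScoreMatrix(list(ids), scores, hit_mask)


def parse_blast_tabular(path: str | Path, ids: list[str]) -> RawScoreMatrix:
    """Build a RawScoreMatrix from blastp tabular output (outfmt 6).

    Columns used: qseqid, sseqid, bitscore (column 12 when 12+ columns
    are present, else column 3); extra columns are ignored.  The best
    bit score per (query, subject) pair is kept; absent pairs score 0.
    """
    idx = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    scores = np.zeros((n, n))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ScoringError(f"line {lineno}: expected >=3 columns")
            q, s = parts[0], parts[1]
            bit_col = parts[11] if len(parts) >= 12 else parts[2]
            for sid in (q, s):
                if sid not in idx:
                    raise ScoringError(f"line {lineno}: unknown id {sid!r}")
            try:
                bit = float(bit_col)
            except ValueError as exc:
                raise ScoringError(
                    f"line {lineno}: bad bit score {bit_col!r}") from exc
            i, j = idx[q], idx[s]
            scores[i, j] = max(scores[i, j], bit)
    hit_mask = scores > 0
    return RawScoreMatrix(list(ids), scores, hit_mask)
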