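"""Consensus-motif scanning and mouse-human sequence identity.

A position-weight matrix is turned into a log-odds model against a uniform
background with a Laplace pseudocount (+0.25 per cell, +1 per column), and
a region "has a consensus site" when any window on either strand scores at
least 80% of the model's score range above its minimum.  Sequence identity
of a pairwise alignment is the number of identical (non-gap) columns
divided by the *shorter* ungapped sequence length, so a short sequence
perfectly contained in a longer one scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO, motifs as bio_motifs

from .intervals_io import AnalysisConfig

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PWMModel:
    """A count matrix with its derived log-odds scores and hit threshold."""

    model_id: str
    counts: np.ndarray          # 4 x L, rows A,C,G,T
    logodds: np.ndarray         # 4 x L
    min_score: float
    max_score: float
    threshold: float

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def build_pwm(counts: np.ndarray, cfg: AnalysisConfig, model_id: str = "pwm") -> PWMModel:
    """Log-odds model from a 4xL count matrix.

    Frequencies are ``(count + 0.25) / (colsum + 1)`` and log-odds are taken
    against the uniform background 0.25, so an uninformative column scores 0
    for every base.  The hit threshold sits at ``pwm_threshold_frac`` (80%)
    of the way from the model's minimum to its maximum achievable score.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4 or counts.ndim != 2:
        raise ValueError("counts must be a 4xL matrix (rows A,C,G,T)")
    if (counts < 0).any():
        raise ValueError("negative counts")
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("zero-sum column in count matrix")
    freqs = (counts + 0.25) / (colsums + 1.0)
    logodds = np.log2(freqs / 0.25)
    min_score = float(logodds.min(axis=0).sum())
    max_score = float(logodds.max(axis=0).sum())
    threshold = min_score + cfg.pwm_threshold_frac * (max_score - min_score)
    return PWMModel(model_id, counts, logodds, min_score, max_score, threshold)


def read_jaspar_pfms(path: str | Path, cfg: AnalysisConfig) -> dict[str, PWMModel]:
    """Read one or more JASPAR-format PFMs into scoring models."""
    models: dict[str, PWMModel] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            model_id = m.matrix_id or m.name
            models[model_id] = build_pwm(counts, cfg, model_id)
    return models


@dataclass
class MotifHit:
    found: bool
    best_score: float | None = None
    position: int | None = None
    strand: str | None = None


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, code in _BASE_TO_INT.items():
        out[arr == ord(base)] = code
    return out


def _window_scores(encoded: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing non-ACGT characters are -inf."""
    L = logodds.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([logodds, np.full((1, L), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # -inf + -inf
        return padded[windows, np.arange(L)].sum(axis=1)


def has_consensus(seq: str, pwm: PWMModel) -> MotifHit:
    """Scan both strands; a hit is any window scoring >= the model threshold.

    Sequences shorter than the model return a no-hit with a warning.
    Reverse-strand hits are reported at the forward-strand window start.
    """
    L = pwm.length
    if len(seq) < L:
        warnings.warn(f"sequence shorter than PWM ({len(seq)} < {L})", stacklevel=2)
        return MotifHit(False)
    encoded = _encode(seq)
    fwd = _window_scores(encoded, pwm.logodds)
    rc_logodds = pwm.logodds[::-1, ::-1]  # scan forward seq with the RC model
    rev = _window_scores(encoded, rc_logodds)
    best_f, best_r = fwd.max(), rev.max()
    if not np.isfinite(best_f) and not np.isfinite(best_r):
        return MotifHit(False)
    if best_f >= best_r:
        best, pos, strand = float(best_f), int(fwd.argmax()), "+"
    else:
        best, pos, strand = float(best_r), int(rev.argmax()), "-"
    return MotifHit(best >= pwm.threshold, best, pos, strand)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in reversed(seq.upper()))


@dataclass
class AlignedPair:
    """Two gapped sequences of equal aligned length."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned lengths differ")
        if len(self.seq1) == 0:
            raise ValueError("empty alignment")

    @property
    def len1(self) -> int:
        return sum(1 for c in self.seq1 if c != "-")

    @property
    def len2(self) -> int:
        return sum(1 for c in self.seq2 if c != "-")


def identity_score(pair: AlignedPair) -> float:
    """Identical non-gap columns / min(ungapped lengths), case-insensitive."""
    len1, len2 = pair.len1, pair.len2
    if len1 == 0 or len2 == 0:
        raise ValueError("degenerate alignment (an all-gap row)")
    matches = sum(
        1
        for a, b in zip(pair.seq1.upper(), pair.seq2.upper())
        if a == b and a != "-"
    )
    return matches / min(len1, len2)


def read_pairwise_maf(path: str | Path) -> dict[str, AlignedPair]:
    """Read two-row MAF blocks keyed by region id.

    Sequence names are ``<species>.<region_id>``; the region id keys the
    returned mapping and the two rows become the aligned pair in file order.
    """
    pairs: dict[str, AlignedPair] = {}
    for block in AlignIO.parse(str(path), "maf"):
        if len(block) != 2:
            raise ValueError("expected two-row MAF blocks")
        rec1, rec2 = block[0], block[1]
        region = rec1.id.split(".", 1)[1] if "." in rec1.id else rec1.id
        pairs[region] = AlignedPair(str(rec1.seq), str(rec2.seq))
    return pairs


def write_pairwise_maf(
    path: str | Path, pairs: dict[str, AlignedPair], species: tuple[str, str] = ("mouse", "human")
) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for region_id in pairs:
            p = pairs[region_id]
            fh.write("a score=0.000000\n")
            for name, seq, size in (
                (f"{species[0]}.{region_id}", p.seq1, p.len1),
                (f"{species[1]}.{region_id}", p.seq2, p.len2),
            ):
                fh.write(f"s {name} 0 {size} + {size} {seq}\n")
            fh.write("\n")
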