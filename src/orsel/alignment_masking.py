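"""Adaptive confidence-threshold masking of codon alignments.

Codon alignments carry per-codon alignment reliability scores in [0, 1]
(per sequence × column, or a single score per column). Unreliable codons
are masked before downstream dN/dS testing, but masking too much starves
the selection test of signal. The threshold is therefore chosen adaptively:
start high (0.8) and lower it in steps of 0.1 until no more than 20% of
codons are masked. Codons strictly below the chosen threshold are replaced
by ``NNN`` (or gaps), everything else is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError

__all__ = ["MaskedAlignment", "adaptive_mask", "mask_report",
           "codon_view", "join_codons"]


@dataclass
class MaskedAlignment:
    names: list[str]
    codons: np.ndarray          # (n_seq, n_codon) array of 3-letter strings
    chosen_threshold: float
    masked_fraction: float
    overflow: bool              # True when even the floor exceeds max_fraction
    mask: np.ndarray            # boolean (n_seq, n_codon)


def codon_view(seqs: list[str]) -> np.ndarray:
    """Split aligned nucleotide sequences into an (n_seq, n_codon) array."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise DimensionError(f"unequal alignment lengths: {sorted(lengths)}")
    (L,) = lengths
    if L % 3:
        raise DimensionError(f"alignment length {L} is not a multiple of 3")
    return np.array([[s[i:i + 3] for i in range(0, L, 3)] for s in seqs])


def join_codons(codons: np.ndarray) -> list[str]:
    return ["".join(row) for row in codons]


def _score_matrix(scores, n_seq: int, n_codon: int) -> np.ndarray:
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:  # per-column scores broadcast over sequences
        if S.shape[0] != n_codon:
            raise DimensionError(
                f"per-column scores length {S.shape[0]} != {n_codon} codon columns")
        S = np.broadcast_to(S, (n_seq, n_codon)).copy()
    elif S.shape != (n_seq, n_codon):
        raise DimensionError(
            f"score matrix shape {S.shape} != alignment shape {(n_seq, n_codon)}")
    if np.nanmin(S) < 0 or np.nanmax(S) > 1:
        raise ValueError("confidence scores outside [0, 1]")
    return S


def _grid(start: float, step: float, floor: float) -> list[float]:
    ts, i = [], 0
    while True:
        t = round(start - i * step, 10)
        if t < floor - 1e-12:
            break
        ts.append(max(t, floor))
        i += 1
    return ts


def adaptive_mask(names: list[str], seqs: list[str], scores,
                  start: float = 0.8, step: float = 0.1,
                  max_fraction: float = 0.2, floor: float = 0.0,
                  mask_char: str = "NNN") -> MaskedAlignment:
    """Mask codons below an adaptively chosen confidence threshold.

    The threshold is the largest value on the grid
    ``start, start - step, ... >= floor`` whose strict-inequality mask
    (score < t) covers at most *max_fraction* of the codons. If even the
    floor masks more than that, the floor is used and ``overflow`` is set.

    Scores may be an (n_seq, n_codon) matrix (per-residue masking) or a
    length-n_codon vector (per-column masking of whole columns).
    """
    codons = codon_view(seqs)
    n_seq, n_codon = codons.shape
    S = _score_matrix(scores, n_seq, n_codon)
    total = S.size
    chosen, frac, overflow = floor, None, True
    for t in _grid(start, step, floor):
        f = float((S < t).sum()) / total
        if f <= max_fraction:
            chosen, frac, overflow = t, f, False
            break
    if frac is None:
        chosen = floor
        frac = float((S < floor).sum()) / total
    mask = S < chosen
    masked = codons.copy()
    masked[mask] = mask_char
    return MaskedAlignment(names=list(names), codons=masked,
                           chosen_threshold=float(chosen),
                           masked_fraction=frac, overflow=overflow, mask=mask)


def mask_report(batch: list[MaskedAlignment]) -> pd.DataFrame:
    """Per-alignment threshold/fraction table (one row per alignment)."""
    rows = [{"index": i, "threshold": m.chosen_threshold,
             "masked_fraction": m.masked_fraction, "overflow": m.overflow,
             "n_seq": len(m.names), "n_codon": m.codons.shape[1]}
            for i, m in enumerate(batch)]
    return pd.DataFrame(rows, columns=["index", "threshold", "masked_fraction",
                                       "overflow", "n_seq", "n_codon"])
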