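"""Alignment-derived quantities: percent identity, smoothed conservation, TM vote."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .errors import FormatError, ParameterError

__all__ = [
    "read_alignment",
    "percent_identity",
    "smooth_conservation",
    "consensus_tm",
]

_GAP = "-"


def read_alignment(path: Union[str, Path], fmt: str | None = None) -> MultipleSeqAlignment:
    """Read an aligned FASTA or Clustal file (format sniffed from extension)."""
    path = Path(path)
    if fmt is None:
        fmt = {"aln": "clustal", "clustal": "clustal"}.get(
            path.suffix.lstrip(".").lower(), "fasta"
        )
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sequence identifiers")
    return aln

def percent_identity(aln: MultipleSeqAlignment, id1: str, id2: str) -> float:
    """Pairwise percent identity over columns where both sequences are non-gap.

    This pairwise-ungapped denominator matches the convention behind reported
    Clustal-Omega identities; symmetric in its two identifiers.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    for ident in (id1, id2):
        if ident not in seqs:
            raise KeyError(f"identifier {ident!r} not in alignment")
    s1, s2 = seqs[id1], seqs[id2]
    both = [(a, b) for a, b in zip(s1, s2) if a != _GAP and b != _GAP]
    if not both:
        raise ParameterError(f"{id1}/{id2}: no columns where both are ungapped")
    same = sum(a == b for a, b in both)
    return 100.0 * same / len(both)


def smooth_conservation(track: pd.Series, window: int = 9) -> pd.Series:
    """Centered moving average of a per-residue conservation track.

    The window must be odd; edges shrink to the available span so no positions
    are dropped and a constant track is returned unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    if not track.index.is_monotonic_increasing:
        raise ParameterError("track positions must be strictly increasing")
    smoothed = track.rolling(window, center=True, min_periods=1).mean()
    smoothed.name = track.name
    return smoothed


def consensus_tm(votes: pd.DataFrame, min_votes: int = 3) -> pd.Series:
    """Consensus transmembrane call: TM iff >= ``min_votes`` predictors agree.

    ``votes`` is residues x predictors, boolean. The default of three agreeing
    predictors is the standard consensus rule for multi-predictor TM tracks.
    """
    if votes.shape[1] < 1:
        raise ParameterError("need at least one predictor column")
    if min_votes < 1 or min_votes > votes.shape[1]:
        raise ParameterError(
            f"min_votes must be in [1, {votes.shape[1]}], got {min_votes}"
        )
    counts = votes.astype(bool).sum(axis=1)
    out = counts >= min_votes
    out.name = "tm"
    return out
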