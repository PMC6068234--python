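"""Channel-lining electrostatic change score.

A variant on a channel-lining residue is scored by the absolute change in
free-amino-acid isoelectric point, |pI(mut) − pI(wt)|; variants off the lining
score 0 rather than being dropped.  The reference line is the maximum pI
change achievable between two uncharged amino acids: a score above it is only
possible when the substitution involves a charged residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .structure import Structure
from .variants import AminoAcidProperties, Variant, delta_property

__all__ = [
    "ChannelLining",
    "read_lining",
    "channel_score",
    "uncharged_reference",
    "axis_lining",
]


@dataclass(frozen=True)
class ChannelLining:
    """Residue positions lining the channel interior in either conformation."""

    positions: frozenset[int]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise ParameterError("channel lining must be non-empty")

    def __contains__(self, position: int) -> bool:
        return position in self.positions


def read_lining(path: Union[str, Path], source: str | None = None) -> ChannelLining:
    """One residue number per line (TSV/plain text, '#' comments allowed)."""
    positions = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("\t")[0].strip()
        if not line or line.startswith("#"):
            continue
        try:
            positions.add(int(line))
        except ValueError:
            raise FormatError(f"{path}: bad residue number {line!r}") from None
    return ChannelLining(frozenset(positions), source or str(path))


def channel_score(
    v: Variant, lining: ChannelLining, table: AminoAcidProperties
) -> float:
    """|pI(mut) − pI(wt)| for lining variants, 0 otherwise."""
    if v.position not in lining:
        return 0.0
    return delta_property(v, table, "pI")


def uncharged_reference(table: AminoAcidProperties) -> float:
    """Maximum |pI(a) − pI(b)| over pairs of uncharged amino acids.

    Drawn as the reference line under the per-variant scores: exceeding it
    requires a charge change.
    """
    unchg = table.uncharged()
    return max(
        abs(table.pi[a] - table.pi[b]) for a, b in itertools.combinations(unchg, 2)
    )


def axis_lining(
    structure: Structure,
    bundle1: list[str],
    bundle2: list[str],
    radius: float = 10.0,
) -> ChannelLining:
    """Heuristic lining: residues whose Cα lies near the inter-bundle axis.

    The channel axis is taken as the segment joining the Cα centroids of the
    two helix bundles (helix ids per bundle); residues within ``radius`` Å of
    that segment are flagged.  This is a geometric stand-in for a
    solvent-accessibility definition and is labelled as such in its output.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")

    def centroid(helix_ids: list[str]) -> np.ndarray:
        pts = []
        for hid in helix_ids:
            lo, hi = structure.helix_map[hid]
            for (c, r) in structure.ca_residues():
                if lo <= r <= hi:
                    pts.append(structure.atoms[structure.ca_atom_index(c, r)].xyz)
        return np.asarray(pts, dtype=float).mean(axis=0)

    a, b = centroid(bundle1), centroid(bundle2)
    ab = b - a
    denom = float(ab @ ab)
    positions = set()
    for (c, r) in structure.ca_residues():
        p = np.asarray(structure.atoms[structure.ca_atom_index(c, r)].xyz)
        t = 0.5 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        if np.linalg.norm(p - (a + t * ab)) <= radius:
            positions.add(r)
    return ChannelLining(frozenset(positions), source="axis-heuristic")


def score_table(
    variants: list[Variant],
    lining: ChannelLining,
    table: AminoAcidProperties,
) -> pd.DataFrame:
    """Per-variant scores with the exceeds-reference flag (tabular output)."""
    ref = uncharged_reference(table)
    rows = [
        {
            "variant": str(v),
            "label": v.label.value,
            "in_lining": v.position in lining,
            "channel_score": channel_score(v, lining, table),
        }
        for v in variants
    ]
    df = pd.DataFrame(rows)
    df["exceeds_reference"] = df["channel_score"] > ref
    df.attrs["uncharged_reference"] = ref
    return df
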