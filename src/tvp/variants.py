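"""Missense variants: parsing, validation against a structure, property deltas.

Variants use protein-change nomenclature on author residue numbering
(e.g. ``R132W``).  Physico-chemical deltas are absolute differences of
free-amino-acid isoelectric point (Lehninger table, shipped as package data
and swappable) or Kyte–Doolittle hydropathy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Union

import pandas as pd
from Bio.SeqUtils import seq1
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .errors import DataError, FormatError, ParameterError
from .structure import Structure

__all__ = [
    "VariantLabel",
    "Variant",
    "AminoAcidProperties",
    "parse_variant",
    "read_variant_table",
    "write_variant_table",
    "validate_variants",
    "delta_property",
    "load_default_properties",
    "CANONICAL_AA",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_VARIANT_RE = re.compile(rf"^([{CANONICAL_AA}])(\d+)([{CANONICAL_AA}])$")

_POSITIVE = set("KRH")
_NEGATIVE = set("DE")


class VariantLabel(str, Enum):
    BENIGN = "benign"
    PATHOGENIC = "pathogenic"
    VUS = "vus"
    WT = "wt"


@dataclass(frozen=True)
class Variant:
    wt_aa: str
    position: int
    mut_aa: str
    label: VariantLabel = VariantLabel.VUS
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise ParameterError(f"non-canonical amino acid {aa!r}")
        if self.wt_aa == self.mut_aa and self.label != VariantLabel.WT:
            raise ParameterError(
                f"{self}: identical wt/mut requires the 'wt' label"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ParameterError(f"MAF must lie in [0, 1], got {self.maf}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class AminoAcidProperties:
    """Per-residue pI, hydropathy and charge class for the 20 canonical AAs."""

    pi: dict[str, float]
    hydropathy: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("pi", self.pi), ("hydropathy", self.hydropathy)):
            if set(table) != set(CANONICAL_AA):
                raise ParameterError(f"{name} table must cover exactly the 20 canonical AAs")

    @staticmethod
    def charge_class(aa: str) -> Literal["positive", "negative", "uncharged"]:
        if aa in _POSITIVE:
            return "positive"
        if aa in _NEGATIVE:
            return "negative"
        if aa not in CANONICAL_AA:
            raise ParameterError(f"non-canonical amino acid {aa!r}")
        return "uncharged"

    def uncharged(self) -> list[str]:
        return [aa for aa in CANONICAL_AA if self.charge_class(aa) == "uncharged"]


def load_default_properties(pi_table: Union[str, Path, None] = None) -> AminoAcidProperties:
    """Lehninger free-amino-acid pI (packaged TSV) + Kyte–Doolittle hydropathy."""
    if pi_table is None:
        source = resources.files("tvp.data").joinpath("pi_lehninger.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(pi_table, sep="\t", comment="#")
    pi = dict(zip(df["aa"], df["pi"].astype(float)))
    return AminoAcidProperties(pi=pi, hydropathy=dict(_KYTE_DOOLITTLE))


def parse_variant(
    text: str,
    label: VariantLabel | str = VariantLabel.VUS,
    maf: float | None = None,
) -> Variant:
    """Parse protein-change shorthand like ``"R132W"``.

    The label is attached separately (variant tables carry it in their own
    column); non-canonical letters (e.g. stop ``X``) are rejected.
    """
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise FormatError(f"cannot parse variant string {text!r}")
    return Variant(m.group(1), int(m.group(2)), m.group(3), VariantLabel(label), maf)


def read_variant_table(path: Union[str, Path]) -> list[Variant]:
    """Read a TSV with columns ``variant``, ``label`` and optional ``maf``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["variant"].duplicated().any():
        dup = df.loc[df["variant"].duplicated(), "variant"].iloc[0]
        raise DataError(f"{path}: duplicate variant {dup!r}")
    out = []
    for _, row in df.iterrows():
        maf = row.get("maf")
        maf = None if pd.isna(maf) else float(maf)
        out.append(parse_variant(row["variant"], VariantLabel(row["label"]), maf))
    return out


def write_variant_table(variants: Iterable[Variant], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "variant": [str(v) for v in variants],
            "label": [v.label.value for v in variants],
            "maf": [v.maf for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def bundled_variant_table() -> list[Variant]:
    """The 23 curated GLUT10 variants (4 benign-set, 10 pathogenic, 9 VUS)."""
    source = resources.files("tvp.data").joinpath("glut10_variants.tsv")
    with resources.as_file(source) as p:
        return read_variant_table(p)


def validate_variants(variants: Iterable[Variant], structure: Structure) -> pd.DataFrame:
    """Check each variant against the modeled structure; report, do not fail.

    Status is ``ok`` (wild-type letter matches the structure), ``out_of_model``
    (no Cα at that position) or ``mismatch`` (structure holds a different
    residue; both letters reported).
    """
    modeled = {r for (_, r) in structure.ca_residues()}
    rows = []
    for v in variants:
        if v.position not in modeled:
            rows.append({"variant": str(v), "status": "out_of_model", "structure_aa": None})
            continue
        chain = next(c for (c, r) in structure.ca_residues() if r == v.position)
        found = seq1(structure.residue_name_at(chain, v.position))
        status = "ok" if found == v.wt_aa else "mismatch"
        rows.append({"variant": str(v), "status": status, "structure_aa": found})
    return pd.DataFrame(rows)


def delta_property(
    v: Variant,
    table: AminoAcidProperties,
    prop: Literal["pI", "hydropathy"],
) -> float:
    """|property(mut) − property(wt)| for pI or Kyte–Doolittle hydropathy."""
    if prop == "pI":
        lut = table.pi
    elif prop == "hydropathy":
        lut = table.hydropathy
    else:
        raise ParameterError(f"unknown property {prop!r}")
    return abs(lut[v.mut_aa] - lut[v.wt_aa])
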