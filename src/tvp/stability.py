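"""Folding-stability calls from per-conformation ΔΔG tables.

ΔΔG_fold values (kcal/mol, FoldX-style averaged ΔΔG dialect) are consumed as
input, one per (variant, conformation).  A variant's effective destabilization
is the maximum over conformations — destabilizing either endpoint of the
transport cycle can break function — and it is called destabilizing when that
maximum reaches a Boltzmann-scaled cutoff, by default 3 k_BT at the simulation
temperature of 300 K (~1.79 kcal/mol).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError, ParameterError
from .structure import Conformation
from .variants import Variant, VariantLabel, parse_variant

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "DdgRecord",
    "StabilityCall",
    "read_ddg_table",
    "write_ddg_table",
    "stability_calls",
    "compare_groups",
    "kbt_threshold_kcal",
]

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass(frozen=True)
class DdgRecord:
    variant: str
    conformation: Conformation
    ddg: float  # kcal/mol

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise FormatError(f"{self.variant}: non-finite ddg")
        if self.conformation not in (Conformation.IF, Conformation.OF):
            raise ParameterError(f"{self.variant}: conformation must be IF or OF")


@dataclass(frozen=True)
class StabilityCall:
    variant: str
    ddg_if: float | None
    ddg_of: float | None
    ddg_max: float
    destabilizing: bool
    partial: bool  # only one conformation available


def kbt_threshold_kcal(threshold_kbt: float = 3.0, temperature: float = 300.0) -> float:
    """Convert a multiple of k_BT into kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive (K)")
    return threshold_kbt * KB_KCAL_PER_MOL_K * temperature


def read_ddg_table(path: Union[str, Path]) -> list[DdgRecord]:
    """TSV with columns ``variant``, ``conformation`` (IF/OF), ``ddg`` (kcal/mol)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant", "conformation", "ddg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["variant", "conformation"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate record for {row['variant']} ({row['conformation']})"
        )
    records = []
    for _, row in df.iterrows():
        try:
            ddg = float(row["ddg"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: unparseable ddg {row['ddg']!r} for {row['variant']}"
            ) from None
        parse_variant(str(row["variant"]))  # validate nomenclature
        records.append(DdgRecord(str(row["variant"]), Conformation(row["conformation"]), ddg))
    return records


def write_ddg_table(records: Iterable[DdgRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "variant": [r.variant for r in records],
            "conformation": [r.conformation.value for r in records],
            "ddg": [r.ddg for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def stability_calls(
    records: Iterable[DdgRecord],
    threshold_kbt: float = 3.0,
    temperature: float = 300.0,
) -> list[StabilityCall]:
    """Aggregate per-conformation ΔΔG into per-variant destabilization calls.

    ``ddg_max`` is the maximum over available conformations; a variant with a
    single conformation is flagged ``partial`` rather than rejected.
    """
    cutoff = kbt_threshold_kcal(threshold_kbt, temperature)
    per_variant: dict[str, dict[Conformation, float]] = {}
    for r in records:
        per_variant.setdefault(r.variant, {})[r.conformation] = r.ddg
    calls = []
    for variant, ddgs in per_variant.items():
        ddg_max = max(ddgs.values())
        calls.append(
            StabilityCall(
                variant=variant,
                ddg_if=ddgs.get(Conformation.IF),
                ddg_of=ddgs.get(Conformation.OF),
                ddg_max=ddg_max,
                destabilizing=bool(ddg_max >= cutoff),
                partial=len(ddgs) < 2,
            )
        )
    return calls


def calls_frame(calls: Iterable[StabilityCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def compare_groups(
    calls: Iterable[StabilityCall],
    labels: dict[str, Union[VariantLabel, str]],
    column: str = "ddg_max",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Welch t-test on ``ddg_max`` (or a per-conformation column) per class pair.

    ``alternative`` follows scipy ('two-sided', 'greater', 'less'), applied as
    first-listed class vs second; classes are ordered pathogenic, vus, benign
    so 'greater' asks whether the more severe class is more destabilizing.
    """
    df = calls_frame(calls)
    df["label"] = df["variant"].map(
        {k: VariantLabel(v).value for k, v in labels.items()}
    )
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "variant"].tolist()
        raise DataError(f"variants without class labels: {missing[:5]}")
    order = ["pathogenic", "vus", "benign"]
    groups = {
        lab: df.loc[df["label"] == lab, column].dropna().to_numpy()
        for lab in order
        if (df["label"] == lab).any()
    }
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise ParameterError(f"class {lab!r} has < 2 members")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        t, p = stats.ttest_ind(
            groups[a], groups[b], equal_var=False, alternative=alternative
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "column": column,
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
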