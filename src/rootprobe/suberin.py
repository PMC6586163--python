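"""Zone-resolved suberin composition from GC monomer tables.

Suberin is the aliphatic/aromatic polyester deposited on endodermal cell
walls; its monomers released by transesterification fall into four aliphatic
classes — primary alcohols (alc), fatty acids (fa), α,ω-dicarboxylic acids
(diacids) and ω-hydroxy acids (ω-OH acids), chain lengths C16–C26 — plus the
aromatic coumaric and ferulic acids.  Monomer amounts are quantified per
biological replicate and per root zone (relative-length zones A/B/C), then
normalised to the endodermal surface area of the zone, A = 2π·r·L, giving
μg cm⁻² comparable across zones and treatments.

Aromatic amounts are reported but flagged for cautious interpretation: in
grasses, cell-wall-bound hydroxycinnamic acids are not exclusive to suberin.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ALIPHATIC_CLASSES",
    "AROMATIC_CLASSES",
    "CHEMISTRY_ZONES",
    "RNASEQ_ZONES",
    "ZoneSpec",
    "MonomerRecord",
    "ClassificationError",
    "classify_monomer",
    "endodermal_surface_area",
    "assign_zone",
    "aggregate_amounts",
    "group_summary",
    "relative_composition",
]

ALIPHATIC_CLASSES = ("alcohol", "fatty_acid", "diacid", "omega_oh_acid")
AROMATIC_CLASSES = ("coumaric_acid", "ferulic_acid")


class ClassificationError(ValueError):
    """Compound label not recognised by the monomer registry."""


@dataclass(frozen=True)
class ZoneSpec:
    """A relative-root-length zone, half-open on [start, end) of total length.

    Chemistry zones span A [0, 0.25), B [0.25, 0.50), C [0.50, 1.0]; for
    RNA-seq the sampled windows are narrower (A [0, 0.125), B [0.25, 0.375),
    C [0.50, 0.625)) to avoid overloading and to sharpen zone identity.
    """

    label: str
    start_fraction: float
    end_fraction: float
    purpose: str = "chemistry"

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_fraction < self.end_fraction <= 1.0:
            raise ValueError("require 0 ≤ start < end ≤ 1")

    def contains(self, fraction: float) -> bool:
        if self.end_fraction == 1.0:  # basal zone is closed at the root base
            return self.start_fraction <= fraction <= 1.0
        return self.start_fraction <= fraction < self.end_fraction


CHEMISTRY_ZONES = (
    ZoneSpec("A", 0.0, 0.25, "chemistry"),
    ZoneSpec("B", 0.25, 0.50, "chemistry"),
    ZoneSpec("C", 0.50, 1.0, "chemistry"),
)

RNASEQ_ZONES = (
    ZoneSpec("A", 0.0, 0.125, "rnaseq"),
    ZoneSpec("B", 0.25, 0.375, "rnaseq"),
    ZoneSpec("C", 0.50, 0.625, "rnaseq"),
)


@dataclass(frozen=True)
class MonomerRecord:
    """One GC-quantified suberin monomer amount for (zone, treatment, replicate)."""

    compound_label: str
    substance_class: str
    chain_length: int | None
    unsaturation: int | None
    amount: float  # μg per sample
    zone: str
    treatment: str
    replicate: str

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be ≥ 0")
        if self.substance_class in ALIPHATIC_CLASSES:
            if self.chain_length is None:
                raise ValueError(f"aliphatic class {self.substance_class} needs a chain length")
            if not 16 <= self.chain_length <= 26:
                raise ValueError("chain length must lie in C16–C26")
        elif self.substance_class in AROMATIC_CLASSES:
            if self.chain_length is not None:
                raise ValueError("aromatic monomers carry no chain length")
        else:
            raise ValueError(f"unknown substance class {self.substance_class!r}")


# registry grammar: "C<len>[:<unsat>] <class word(s)>", plus named aromatics
_CLASS_WORDS = {
    "alcohol": "alcohol",
    "alc": "alcohol",
    "fatty acid": "fatty_acid",
    "fa": "fatty_acid",
    "acid": "fatty_acid",
    "diacid": "diacid",
    "dicarboxylic acid": "diacid",
    "ω-oh acid": "omega_oh_acid",
    "w-oh acid": "omega_oh_acid",
    "omega-oh acid": "omega_oh_acid",
    "oh acid": "omega_oh_acid",
    "ω-hydroxy acid": "omega_oh_acid",
    "omega-hydroxy acid": "omega_oh_acid",
}
_AROMATICS = {
    "coumaric acid": "coumaric_acid",
    "p-coumaric acid": "coumaric_acid",
    "ferulic acid": "ferulic_acid",
}
_ALIPHATIC_RE = re.compile(r"^c(\d+)(?::(\d+))?\s+(.+)$")


def classify_monomer(compound_label: str) -> tuple[str, int | None, int | None]:
    """Parse a monomer label into (substance_class, chain_length, unsaturation).

    Labels follow the GC reporting convention ``C<len>[:<unsat>] <class>``
    (e.g. ``"C18:1 diacid"``, ``"C24 ω-OH acid"``) or a named aromatic
    (``"ferulic acid"``).  Classification is a pure, deterministic function of
    the label.  Odd chain lengths are accepted with a warning since the
    dominant homologues are even-numbered.
    """
    label = compound_label.strip().lower().replace("‐", "-").replace("–", "-")
    if label in _AROMATICS:
        return _AROMATICS[label], None, None
    m = _ALIPHATIC_RE.match(label)
    if m:
        chain = int(m.group(1))
        unsat = int(m.group(2)) if m.group(2) else 0
        class_word = m.group(3).strip()
        if class_word in _CLASS_WORDS:
            if chain % 2:
                warnings.warn(
                    f"odd chain length C{chain} in {compound_label!r}; dominant "
                    "suberin homologues are even-numbered",
                    stacklevel=2,
                )
            return _CLASS_WORDS[class_word], chain, unsat
    nearest = sorted(set(_CLASS_WORDS) | set(_AROMATICS))
    raise ClassificationError(
        f"unrecognised compound label {compound_label!r}; expected "
        f"'C<len>[:<unsat>] <class>' with class in {nearest} or a named aromatic"
    )


def endodermal_surface_area(endodermis_radius: float, zone_length: float) -> float:
    """Endodermal cylinder area A = 2π·r·L (same length unit squared, e.g. cm²)."""
    if endodermis_radius <= 0:
        raise ValueError("endodermis radius must be > 0")
    if zone_length < 0:
        raise ValueError("zone length must be ≥ 0")
    return 2.0 * math.pi * endodermis_radius * zone_length


def assign_zone(fraction: float, zones: tuple[ZoneSpec, ...] = CHEMISTRY_ZONES) -> str:
    """Zone label for a segment whose midpoint lies at ``fraction`` of root length."""
    for z in zones:
        if z.contains(fraction):
            return z.label
    raise ValueError(f"relative position {fraction} falls in no zone")


def aggregate_amounts(records: pd.DataFrame, areas: dict[str, float]) -> pd.DataFrame:
    """Per-area class totals and replicate-level aggregates.

    Parameters
    ----------
    records :
        Tidy monomer table with columns ``compound_label, amount_ug, zone,
        treatment, replicate`` (a ``substance_class`` column is honoured if
        present, otherwise derived from the label).
    areas :
        Endodermal surface area per zone label, cm².

    Returns
    -------
    DataFrame
        One row per (zone, treatment, replicate) with per-class totals, total
        aliphatic and total aromatic, all in μg cm⁻².  Total aliphatic equals
        the sum of the four aliphatic class columns exactly; likewise the
        aromatic total.
    """
    req = {"compound_label", "amount_ug", "zone", "treatment", "replicate"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"monomer table lacks columns {sorted(missing)}")
    if (records["amount_ug"] < 0).any():
        raise ValueError("negative monomer amounts")
    for zone in records["zone"].unique():
        if zone not in areas:
            raise ValueError(f"no endodermal area configured for zone {zone!r}")

    df = records.copy()
    if "substance_class" not in df.columns:
        df["substance_class"] = [classify_monomer(lbl)[0] for lbl in df["compound_label"]]
    df["per_area"] = df["amount_ug"] / df["zone"].map(areas)

    wide = (
        df.pivot_table(
            index=["zone", "treatment", "replicate"],
            columns="substance_class",
            values="per_area",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(ALIPHATIC_CLASSES) + list(AROMATIC_CLASSES), fill_value=0.0)
        .reset_index()
    )
    wide.columns.name = None
    wide["total_aliphatic"] = wide[list(ALIPHATIC_CLASSES)].sum(axis=1)
    wide["total_aromatic"] = wide[list(AROMATIC_CLASSES)].sum(axis=1)
    wide.attrs["units"] = "ug_per_cm2"
    wide.attrs["aromatic_caveat"] = (
        "cell-wall-bound hydroxycinnamic acids are not suberin-specific in "
        "Graminaceae; interpret aromatic totals cautiously"
    )
    return wide


def group_summary(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD across replicates per (zone, treatment) for every class column."""
    value_cols = [
        c for c in per_replicate.columns if c not in ("zone", "treatment", "replicate")
    ]
    out = (
        per_replicate.groupby(["zone", "treatment"])[value_cols]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in out.columns
    ]
    return out


def relative_composition(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentage of total aliphatic suberin, per row; sums to 100 %."""
    totals = per_replicate["total_aliphatic"]
    if (totals <= 0).any():
        bad = per_replicate.loc[totals <= 0, ["zone", "treatment", "replicate"]]
        raise ValueError(f"relative composition undefined for all-zero groups:\n{bad}")
    out = per_replicate[["zone", "treatment", "replicate"]].copy()
    for cls in ALIPHATIC_CLASSES:
        out[f"{cls}_pct"] = 100.0 * per_replicate[cls] / totals
    return out
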