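"""Fluorescence-probability (pf) estimation from monomer/dimer brightness.

A fluorophore subunit is fluorescent only with probability pf (immature,
photobleached or dark-state proteins do not emit).  For a tandem dimer whose
subunits light up independently, the apparent brightness relative to the
monomer is

    B_dimer / B_monomer = 1 + pf    =>    pf = B_dimer / B_monomer - 1.

Brightness is referenced strictly within one experiment day (and condition
and method): the monomer average of that day divides each dimer cell's
brightness, and only the resulting per-cell pf values are pooled across
days into the final mean +- SEM.  Per-cell pf values outside [0, 1] can
arise from noise; they are kept (dropping them would bias the mean) and
counted in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BrightnessRecord",
    "PfEstimate",
    "GroupSummary",
    "monomer_reference",
    "pf_per_cell",
    "pool_pf",
    "summarize_group",
    "pf_from_records",
]


@dataclass(frozen=True)
class BrightnessRecord:
    """One cell's brightness measurement with its provenance."""

    cell_id: str
    construct: str  # "monomer" or "dimer"
    brightness: float  # counts/s/molecule
    day: str  # session identifier; pf referencing never crosses days
    fluorophore: str = ""
    method: str = "nandb"  # or "sfcs"
    condition: str = ""  # e.g. a pH label

    def __post_init__(self) -> None:
        if self.construct not in ("monomer", "dimer"):
            raise ValueError("construct must be 'monomer' or 'dimer'")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if not self.day:
            raise ValueError("a day/session id is required")


@dataclass
class PfEstimate:
    """Pooled fluorescence probability with per-cell values retained."""

    values: np.ndarray  # per-cell pf
    mean: float
    sem: Optional[float]  # None for a single cell
    n: int
    sessions: tuple[str, ...] = ()
    n_out_of_range: int = 0  # per-cell values outside [0, 1], kept in the mean


@dataclass
class GroupSummary:
    mean: float
    median: float
    sem: Optional[float]
    iqr: float
    q1: float
    q3: float
    n: int


def monomer_reference(records: Sequence[BrightnessRecord]) -> float:
    """Day-level monomer brightness: arithmetic mean over that day's cells.

    All records must be monomers from a single day, condition and method;
    mixing days in one reference defeats the per-day normalisation and is
    an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no monomer records")
    if any(r.construct != "monomer" for r in records):
        raise ValueError("monomer_reference accepts monomer records only")
    for attr in ("day", "condition", "method"):
        if len({getattr(r, attr) for r in records}) > 1:
            raise ValueError(f"records mix more than one {attr}")
    if len(records) < 3:
        warnings.warn(
            f"monomer reference from only {len(records)} cell(s)",
            stacklevel=2,
        )
    return float(np.mean([r.brightness for r in records]))


def pf_per_cell(dimer_brightness: float, monomer_ref: float) -> float:
    """pf = B_dimer / B_monomer - 1 for one dimer cell."""
    if dimer_brightness <= 0 or monomer_ref <= 0:
        raise ValueError("brightness values must be positive")
    return dimer_brightness / monomer_ref - 1.0


def pool_pf(
    values: Iterable[float],
    sessions: Iterable[str] = (),
) -> PfEstimate:
    """Pool per-cell pf values across sessions into mean +- SEM."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no pf values to pool")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    out_of_range = int(((arr < 0) | (arr > 1)).sum())
    return PfEstimate(
        values=arr,
        mean=float(arr.mean()),
        sem=sem,
        n=int(arr.size),
        sessions=tuple(dict.fromkeys(sessions)),
        n_out_of_range=out_of_range,
    )


def pf_from_records(records: Sequence[BrightnessRecord]) -> PfEstimate:
    """Full pf workflow over mixed-day records.

    Groups by (day, condition, method), builds the monomer reference per
    group, computes one pf per dimer cell against its own group's reference
    and pools everything.
    """
    groups: dict[tuple[str, str, str], list[BrightnessRecord]] = {}
    for r in records:
        groups.setdefault((r.day, r.condition, r.method), []).append(r)

    values: list[float] = []
    sessions: list[str] = []
    for key, group in sorted(groups.items()):
        monomers = [r for r in group if r.construct == "monomer"]
        dimers = [r for r in group if r.construct == "dimer"]
        if not monomers or not dimers:
            continue
        ref = monomer_reference(monomers)
        for r in dimers:
            values.append(pf_per_cell(r.brightness, ref))
        sessions.append(key[0])
    if not values:
        raise ValueError("no (monomer, dimer) pair found within any day")
    return pool_pf(values, sessions)


def summarize_group(values: Iterable[float]) -> GroupSummary:
    """Descriptive set shown under group plots: mean, median, SEM, IQR, n.

    Quartiles use linearly interpolated quantiles, e.g. {1,2,3,4} gives
    Q1 = 1.75, Q3 = 3.25, IQR = 1.5.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty group")
    q1, q3 = np.percentile(arr, [25, 75])
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return GroupSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sem=sem,
        iqr=float(q3 - q1),
        q1=float(q1),
        q3=float(q3),
        n=int(arr.size),
    )
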