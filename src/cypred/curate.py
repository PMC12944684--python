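"""Label curation for single-concentration HTS percent-inhibition data.

Raw measurements are clipped or rejected, grouped by canonical structure,
screened for irreproducible replicate groups, and aggregated with a piecewise
interval rule: groups whose replicate mean falls below ``lo`` take the minimum
(guards against spuriously high single reads), groups above ``hi`` take the
maximum (preserves strong-inhibition signal), and intermediate groups take the
arithmetic mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chemio import RawRecord, StandardizationError, murcko_scaffold, standardize_structure

logger = logging.getLogger(__name__)

DEFAULT_LO = 20.0
DEFAULT_HI = 70.0
DEFAULT_MAX_SD = 30.0
DEFAULT_CLIP_WINDOW = (-10.0, 110.0)


class RejectedValue(Exception):
    """A measurement outside the acceptance window or non-numeric."""

    def __init__(self, reason: str):
        self.reason = reason  # out_of_window | non_numeric
        super().__init__(reason)


@dataclass
class MeasurementGroup:
    molecule_key: str
    values: list[float]
    provenance: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CuratedRecord:
    molecule_key: str
    label: float
    n_replicates: int
    branch: str  # min | max | mean | single


@dataclass
class SensitivityReport:
    grid: list[tuple[float, float, int, float]]  # (lo, hi, n_retained, mean_label)


def clip_or_reject(value, clip_window=DEFAULT_CLIP_WINDOW) -> float:
    """Map a raw measurement into [0, 100] or reject it.

    Values already in [0, 100] pass through; mild assay overshoot inside the
    window clips to the nearest bound; anything outside the window (or
    non-numeric) raises :class:`RejectedValue`.
    """
    lo_b, hi_b = clip_window
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise RejectedValue("non_numeric")
    if math.isnan(v):
        raise RejectedValue("non_numeric")
    if v < lo_b or v > hi_b:
        raise RejectedValue("out_of_window")
    return min(100.0, max(0.0, v))


def aggregate_group(values, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI) -> tuple[float, str]:
    """Piecewise replicate aggregation: (label, branch).

    Singletons pass through.  Otherwise the replicate mean routes the group:
    mean < lo -> minimum, mean > hi -> maximum, else the mean itself.  A mean
    exactly equal to lo or hi falls in the mean branch.
    """
    vals = sorted(float(v) for v in values)  # sort: exact permutation invariance
    if not vals:
        raise ValueError("empty replicate group")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if len(vals) == 1:
        return vals[0], "single"
    m = float(np.mean(vals))
    if m < lo:
        return float(min(vals)), "min"
    if m > hi:
        return float(max(vals)), "max"
    return m, "mean"


def flag_outlier_group(values, max_sd: float = DEFAULT_MAX_SD) -> bool:
    """True when replicate spread (sample SD, ddof=1) exceeds ``max_sd``.

    Singleton groups are never flagged.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty replicate group")
    if len(vals) == 1:
        return False
    return float(np.std(vals, ddof=1)) > max_sd


def curate_groups(
    groups: list[MeasurementGroup],
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    max_sd: float = DEFAULT_MAX_SD,
) -> list[CuratedRecord]:
    """Outlier-flag then aggregate each replicate group.

    Flagging runs on the raw replicate values before aggregation so the
    min/max branches cannot hide irreproducible groups.
    """
    out = []
    for g in groups:
        if flag_outlier_group(g.values, max_sd):
            logger.info("excluded %s: replicate SD > %.1f", g.molecule_key, max_sd)
            continue
        label, branch = aggregate_group(g.values, lo, hi)
        out.append(
            CuratedRecord(
                molecule_key=g.molecule_key,
                label=label,
                n_replicates=len(g.values),
                branch=branch,
            )
        )
    return out


def curate_records(
    records: list[RawRecord],
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    max_sd: float = DEFAULT_MAX_SD,
    clip_window=DEFAULT_CLIP_WINDOW,
) -> tuple[list[CuratedRecord], list[dict]]:
    """Full curation pipeline on raw records.

    Standardizes structures, clips/rejects values, groups by canonical
    SMILES, and curates groups.  Returns (curated records, rejection log).
    """
    rejections: list[dict] = []
    grouped: dict[str, MeasurementGroup] = {}
    for rec in records:
        try:
            mol = standardize_structure(rec.structure)
        except StandardizationError as e:
            rejections.append({"source_id": rec.source_id, "stage": "structure", "reason": e.reason})
            continue
        try:
            v = clip_or_reject(rec.value, clip_window)
        except RejectedValue as e:
            rejections.append({"source_id": rec.source_id, "stage": "value", "reason": e.reason})
            continue
        g = grouped.setdefault(mol.canonical, MeasurementGroup(mol.canonical, [], []))
        g.values.append(v)
        g.provenance.append(rec.source_id)
    groups = list(grouped.values())
    n_before = len(groups)
    curated = curate_groups(groups, lo, hi, max_sd)
    if len(curated) < n_before:
        rejections.append(
            {"source_id": "*", "stage": "replicates", "reason": f"{n_before - len(curated)} groups flagged"}
        )
    return curated, rejections


def run_sensitivity(groups: list[MeasurementGroup], lo_grid, hi_grid, max_sd: float = DEFAULT_MAX_SD) -> SensitivityReport:
    """Re-aggregate all groups for each (lo, hi) threshold combination.

    Records retained-group count and mean aggregated label per cell, to show
    how sensitive the curated set is to the interval thresholds.
    """
    lo_grid = list(lo_grid)
    hi_grid = list(hi_grid)
    if any(lo >= hi for lo in lo_grid for hi in hi_grid):
        raise ValueError("every lo must be < every hi")
    grid = []
    for lo in lo_grid:
        for hi in hi_grid:
            recs = curate_groups(groups, lo, hi, max_sd)
            n = len(recs)
            mean_label = float(np.mean([r.label for r in recs])) if n else float("nan")
            grid.append((float(lo), float(hi), n, mean_label))
    return SensitivityReport(grid=grid)


def scaffold_summary(records: list[CuratedRecord]) -> tuple[int, int]:
    """(n_molecules, n_unique_scaffolds) over the curated set.

    Acyclic molecules all fall into one empty-scaffold class.
    """
    if not records:
        raise ValueError("empty curated set")
    keys = set()
    for r in records:
        keys.add(murcko_scaffold(standardize_structure(r.molecule_key)))
    return len(records), len(keys)
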