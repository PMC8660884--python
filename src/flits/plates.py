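"""Plate-reader screening normalisation and magnesium-sensitivity ratios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateRecord",
    "plate_normalize_and_fold_change",
    "average_normalized",
    "magnesium_dynamic_range",
]


@dataclass
class PlateRecord:
    """One screening well: raw intensity series plus the plate references.

    ``eb_reference`` is the intensity of a well with 1 mg/ml Erythrosin B,
    a photostable dye used as a between-plate intensity standard;
    ``background`` is a blank-medium well.
    """

    well_id: str
    raw: np.ndarray
    eb_reference: float
    background: float

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1 or self.raw.size == 0:
            raise ValueError("raw intensity series must be a nonempty 1-D array")


def plate_normalize_and_fold_change(record: PlateRecord) -> tuple[np.ndarray, float]:
    """Normalise a well series and compute its intensity fold-change.

    Normalisation subtracts the background and divides by the Erythrosin B
    reference: (I - background) / I_EB.  The fold-change F_max/F_0 is the
    series maximum divided by its first read.  A well whose first read is
    indistinguishable from background returns NaN for the fold-change
    (flagged undefined) rather than raising.
    """
    if record.eb_reference <= record.background:
        raise ValueError("EB reference intensity must exceed the background")
    normalized = (record.raw - record.background) / record.eb_reference
    first = normalized[0]
    if abs(first) < 1e-9:
        return normalized, float("nan")
    return normalized, float(normalized.max() / first)


def average_normalized(records: list[PlateRecord]) -> tuple[np.ndarray, float]:
    """Average duplicate wells after normalisation, then take the fold-change."""
    if not records:
        raise ValueError("no records to average")
    normed = [plate_normalize_and_fold_change(r)[0] for r in records]
    lengths = {len(n) for n in normed}
    if len(lengths) != 1:
        raise ValueError("duplicate wells have different series lengths")
    mean = np.mean(normed, axis=0)
    first = mean[0]
    fold = float("nan") if abs(first) < 1e-9 else float(mean.max() / first)
    return mean, fold


def magnesium_dynamic_range(table: pd.DataFrame) -> pd.DataFrame:
    """Per-magnesium-level dynamic range mean(bound)/mean(free).

    ``table`` columns: mg_mM, state ("bound"/"free"), intensity.  The SD
    of the ratio is propagated from the per-state sample SDs:
    ratio * sqrt((sd_b/mean_b)^2 + (sd_f/mean_f)^2).
    """
    required = {"mg_mM", "state", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for mg, grp in table.groupby("mg_mM"):
        bound = grp.loc[grp["state"] == "bound", "intensity"].to_numpy(dtype=float)
        free = grp.loc[grp["state"] == "free", "intensity"].to_numpy(dtype=float)
        if bound.size == 0 or free.size == 0:
            raise ValueError(f"magnesium level {mg} mM lacks paired bound/free measurements")
        mb, mf = bound.mean(), free.mean()
        if mf == 0:
            raise ValueError(f"zero free-state mean at {mg} mM")
        ratio = mb / mf
        sdb = bound.std(ddof=1) if bound.size > 1 else 0.0
        sdf = free.std(ddof=1) if free.size > 1 else 0.0
        sd = abs(ratio) * np.sqrt((sdb / mb) ** 2 + (sdf / mf) ** 2) if mb != 0 else np.nan
        rows.append({"mg_mM": float(mg), "ratio": float(ratio), "sd": float(sd)})
    return pd.DataFrame(rows).sort_values("mg_mM", ignore_index=True)
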