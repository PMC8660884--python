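"""In situ calibration: equilibrium extraction, anchor derivation, Hill fits
and the detection range.

The calibration experiment records the view-average phasor of sensor-
expressing cells in a ladder of buffered free-calcium concentrations,
permeabilising the membrane with digitonin during the series so the
intracellular concentration equilibrates with the buffer.  This module
turns such a dataset into:

* the two phasor anchors (calcium-free and saturated states), taken from
  the equilibrium phasors at the extreme concentrations;
* Hill fits of both the intensity-corrected bound fraction F and the raw
  line fraction a against free calcium (the a-parameterised fit allows
  concentration conversion without the brightness-ratio correction);
* the detection range: the concentration interval over which the measured
  fraction is distinguishable from 0 and 1 given the replicate spread at
  the calibration extremes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hill import HillModel, HillParams, HillResults
from .quantify import TwoStateAnchors, fraction_bound, line_fraction

__all__ = [
    "CalibrationDataset",
    "EquilibriumPoint",
    "DetectionRange",
    "CalibrationResult",
    "InSituCalibration",
    "extract_equilibrium",
    "calibrate_in_situ",
    "calibrate_from_phasors",
    "detection_range",
]

#: Default post-digitonin delay before samples count as equilibrated (s).
DEFAULT_MIN_DELAY_S = 360.0


@dataclass
class CalibrationDataset:
    """Calibration time series: one view-average phasor trace per buffer.

    ``df`` columns: conc_nM, replicate, time_s, g, s, intensity,
    digitonin_time_s.  Times must be strictly increasing within each
    (concentration, replicate) series.
    """

    df: pd.DataFrame
    frequency_mhz: float
    frame_interval_s: float = 20.0

    REQUIRED = ("conc_nM", "replicate", "time_s", "g", "s", "intensity", "digitonin_time_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"calibration dataset is missing columns {missing}")
        if self.df["conc_nM"].nunique() < 2:
            raise ValueError("calibration dataset needs at least 2 concentrations")
        for (conc, rep), grp in self.df.groupby(["conc_nM", "replicate"]):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times are not strictly increasing for conc {conc} nM, replicate {rep}"
                )

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.df["conc_nM"].unique())

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "frequency_mhz", self.frequency_mhz)
        out.insert(1, "frame_interval_s", self.frame_interval_s)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        df = pd.read_csv(path)
        freq = float(df.pop("frequency_mhz").iloc[0])
        interval = float(df.pop("frame_interval_s").iloc[0]) if "frame_interval_s" in df else 20.0
        return cls(df=df, frequency_mhz=freq, frame_interval_s=interval)


@dataclass(frozen=True)
class EquilibriumPoint:
    """Post-digitonin equilibrium phasor of one calibration series."""

    g: float
    s: float
    intensity: float
    sd_g: float
    sd_s: float
    n_samples: int


def extract_equilibrium(
    series: pd.DataFrame,
    digitonin_time_s: float | None = None,
    min_delay_s: float = DEFAULT_MIN_DELAY_S,
) -> EquilibriumPoint:
    """Average a calibration series over its post-equilibration window.

    All samples with t >= digitonin time + ``min_delay_s`` are averaged;
    the default delay of 360 s (6 min) lets the digitonin equilibration
    transient decay.  The within-window standard deviation is reported as
    a stability diagnostic.
    """
    if digitonin_time_s is None:
        digitonin_time_s = float(series["digitonin_time_s"].iloc[0])
    window = series[series["time_s"] >= digitonin_time_s + min_delay_s]
    if window.empty:
        raise ValueError(
            f"series ends before the equilibrium window (needs samples at "
            f"t >= {digitonin_time_s + min_delay_s:g} s)"
        )
    return EquilibriumPoint(
        g=float(window["g"].mean()), s=float(window["s"].mean()),
        intensity=float(window["intensity"].mean()),
        sd_g=float(window["g"].std(ddof=1)) if len(window) > 1 else 0.0,
        sd_s=float(window["s"].std(ddof=1)) if len(window) > 1 else 0.0,
        n_samples=int(len(window)),
    )


@dataclass(frozen=True)
class DetectionRange:
    """Concentration interval distinguishable from the calibration extremes."""

    ca_low_nM: float
    ca_high_nM: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not self.ca_low_nM < self.ca_high_nM:
            raise ValueError("detection range must have low < high")


def _ci95(values: np.ndarray) -> float:
    """95% band half-width: Student-t quantile (df = n-1) times the sample SD."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 replicates per extreme")
    return float(stats.t.ppf(0.975, values.size - 1) * values.std(ddof=1))


def detection_range(
    f_replicates_at_zero,
    f_replicates_at_sat,
    hill_on_F: HillParams,
    clamp_eps: float = 1e-4,
) -> DetectionRange:
    """Detection range from replicate spread at the calibration extremes.

    The lowest reliably measurable fraction is mean(F at 0) plus the 95%
    band of those replicates; the highest is mean(F at saturation) minus
    its band.  Both are mapped through the Hill inverse.  Zero-variance
    replicates collapse the range onto the clamp floor/ceiling and are
    flagged ``degenerate``.
    """
    f0 = np.asarray(f_replicates_at_zero, dtype=float)
    f1 = np.asarray(f_replicates_at_sat, dtype=float)
    f_low = float(f0.mean() + _ci95(f0))
    f_high = float(f1.mean() - _ci95(f1))
    span = hill_on_F.fmax - hill_on_F.fmin
    lo_clamp = hill_on_F.fmin + clamp_eps * span
    hi_clamp = hill_on_F.fmax - clamp_eps * span
    degenerate = f_low <= lo_clamp or f_high >= hi_clamp or f_low >= f_high
    f_low = min(max(f_low, lo_clamp), hi_clamp)
    f_high = min(max(f_high, lo_clamp), hi_clamp)
    ca_low = float(hill_on_F.inverse(f_low))
    ca_high = float(hill_on_F.inverse(f_high))
    return DetectionRange(ca_low_nM=ca_low, ca_high_nM=ca_high, degenerate=degenerate)


@dataclass
class CalibrationResult:
    """Everything the quantification pipeline needs from a calibration."""

    anchors: TwoStateAnchors
    hill_on_F: HillResults | HillParams
    hill_on_a: HillResults | HillParams
    detection: DetectionRange | None
    equilibrium_table: pd.DataFrame = field(repr=False, default=None)
    r_ratio: float = np.nan

    def summary(self) -> str:
        lines = [
            "In situ calibration",
            f"  intensity ratio R : {self.r_ratio:.3g}",
            f"  apo anchor        : ({self.anchors.g_min:.4f}, {self.anchors.s_min:.4f})",
            f"  saturated anchor  : ({self.anchors.g_max:.4f}, {self.anchors.s_max:.4f})",
            f"  Kd (on F)         : {self.hill_on_F.kd:.4g} nM  [n = {self.hill_on_F.n:.3g}]",
            f"  Kd (on a)         : {self.hill_on_a.kd:.4g} nM  [n = {self.hill_on_a.n:.3g}]",
        ]
        if self.detection is not None:
            tag = " (degenerate)" if self.detection.degenerate else ""
            lines.append(
                f"  detection range   : {self.detection.ca_low_nM:.3g} - "
                f"{self.detection.ca_high_nM:.3g} nM{tag}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "anchors": self.anchors.to_dict(),
            "hill_on_F": self.hill_on_F.to_dict(),
            "hill_on_a": self.hill_on_a.to_dict(),
            "r_ratio": self.r_ratio,
            "detection_range": None,
        }
        if self.detection is not None:
            d["detection_range"] = {
                "ca_low_nM": self.detection.ca_low_nM,
                "ca_high_nM": self.detection.ca_high_nM,
                "degenerate": self.detection.degenerate,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        det = d.get("detection_range")
        return cls(
            anchors=TwoStateAnchors.from_dict(d["anchors"]),
            hill_on_F=HillParams.from_dict(d["hill_on_F"]),
            hill_on_a=HillParams.from_dict(d["hill_on_a"]),
            detection=None if det is None else DetectionRange(
                ca_low_nM=det["ca_low_nM"], ca_high_nM=det["ca_high_nM"],
                degenerate=det["degenerate"],
            ),
            r_ratio=d.get("r_ratio", np.nan),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def plot_phasor(self, ax=None):
        """Phasor plot: universal semicircle, chord, and equilibrium points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        th = np.linspace(0, np.pi, 200)
        ax.plot(0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th), "k--", lw=0.8,
                label="universal semicircle")
        ax.plot([self.anchors.g_min, self.anchors.g_max],
                [self.anchors.s_min, self.anchors.s_max], "-", color="gray")
        if self.equilibrium_table is not None:
            ax.plot(self.equilibrium_table["g"], self.equilibrium_table["s"], "o",
                    label="equilibrium phasors")
        ax.plot([self.anchors.g_min], [self.anchors.s_min], "s", label="apo anchor")
        ax.plot([self.anchors.g_max], [self.anchors.s_max], "^", label="saturated anchor")
        ax.set_xlabel("G")
        ax.set_ylabel("S")
        ax.set_aspect("equal")
        ax.legend(fontsize="small")
        return ax


class InSituCalibration:
    """Fit an in situ calibration from a :class:`CalibrationDataset`.

    Parameters
    ----------
    dataset : CalibrationDataset
        View-average phasor time series per buffer concentration.
    r_ratio : float
        Bound/unbound brightness ratio R used for the intensity correction
        (determined independently, e.g. from the saturation fold-change).
    """

    def __init__(self, dataset: CalibrationDataset, r_ratio: float):
        if r_ratio <= 0:
            raise ValueError("intensity ratio R must be positive")
        self.dataset = dataset
        self.r_ratio = float(r_ratio)

    def fit(self, min_delay_s: float = DEFAULT_MIN_DELAY_S) -> CalibrationResult:
        eq_rows = []
        for (conc, rep), grp in self.dataset.df.groupby(["conc_nM", "replicate"]):
            pt = extract_equilibrium(grp, min_delay_s=min_delay_s)
            eq_rows.append({"conc_nM": conc, "replicate": rep, "g": pt.g, "s": pt.s,
                            "intensity": pt.intensity, "sd_g": pt.sd_g, "sd_s": pt.sd_s})
        eq = pd.DataFrame(eq_rows)
        if eq["conc_nM"].nunique() < 2:
            raise ValueError("fewer than 2 usable concentrations after equilibrium extraction")
        return calibrate_from_phasors(
            eq["conc_nM"].to_numpy(), eq["g"].to_numpy(), eq["s"].to_numpy(),
            r_ratio=self.r_ratio, frequency_mhz=self.dataset.frequency_mhz,
            equilibrium_table=eq,
        )


def _project_onto_principal_chord(g, s, points):
    """Orthogonal projection of (g, s) onto the total-least-squares line
    through ``points`` (first principal component about the centroid)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    direction = vt[0]
    t = (np.array([g, s]) - centroid) @ direction
    return tuple(centroid + t * direction)


def calibrate_from_phasors(
    conc_nM,
    g,
    s,
    r_ratio: float,
    frequency_mhz: float,
    equilibrium_table: pd.DataFrame | None = None,
    anchor_method: str = "extremes",
) -> CalibrationResult:
    """Calibration from per-well (or per-view) equilibrium phasors.

    Shared by the in situ pipeline (after equilibrium extraction) and the
    in vitro well-plate analysis.  Anchors are the replicate-mean phasors
    at the lowest and highest concentration (``anchor_method="extremes"``,
    the default, appropriate when the ladder spans zero to saturation);
    ``anchor_method="chord_fit"`` instead fits a total-least-squares line
    through all points and projects the extreme means onto it, which
    spreads anchor noise over the whole series.  Each point is projected
    onto the chord (line fraction a), corrected to the bound fraction F
    with the supplied R, and both a and F are fitted with the Hill model.
    The detection range is computed when both extremes carry >= 3
    replicates.
    """
    conc = np.asarray(conc_nM, dtype=float)
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    c_lo, c_hi = conc.min(), conc.max()
    at_lo = conc == c_lo
    at_hi = conc == c_hi
    g_min, s_min = float(g[at_lo].mean()), float(s[at_lo].mean())
    g_max, s_max = float(g[at_hi].mean()), float(s[at_hi].mean())
    if anchor_method == "chord_fit":
        points = np.column_stack([g, s])
        g_min, s_min = _project_onto_principal_chord(g_min, s_min, points)
        g_max, s_max = _project_onto_principal_chord(g_max, s_max, points)
    elif anchor_method != "extremes":
        raise ValueError("anchor_method must be 'extremes' or 'chord_fit'")
    anchors = TwoStateAnchors(
        g_min=g_min, s_min=s_min, g_max=g_max, s_max=s_max,
        intensity_ratio_R=r_ratio, frequency_mhz=frequency_mhz,
    )
    a = line_fraction(g, s, anchors)
    f = fraction_bound(np.clip(a, 0.0, 1.0), r_ratio)
    hill_f = HillModel(conc, f).fit()
    hill_a = HillModel(conc, np.clip(a, 0.0, 1.0)).fit()

    det = None
    if at_lo.sum() >= 3 and at_hi.sum() >= 3:
        det = detection_range(f[at_lo], f[at_hi], hill_f)

    if equilibrium_table is None:
        equilibrium_table = pd.DataFrame({"conc_nM": conc, "g": g, "s": s})
    equilibrium_table = equilibrium_table.assign(line_fraction=a, fraction_bound=f)
    return CalibrationResult(anchors=anchors, hill_on_F=hill_f, hill_on_a=hill_a,
                             detection=det, equilibrium_table=equilibrium_table,
                             r_ratio=r_ratio)


def calibrate_in_situ(dataset: CalibrationDataset, r_ratio: float,
                      min_delay_s: float = DEFAULT_MIN_DELAY_S) -> CalibrationResult:
    """Convenience wrapper: ``InSituCalibration(dataset, r_ratio).fit()``."""
    return InSituCalibration(dataset, r_ratio).fit(min_delay_s=min_delay_s)
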