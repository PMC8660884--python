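"""Henderson-Hasselbalch pH response models and their fits.

Fluorescent-protein biosensors respond sigmoidally to pH.  The one-site
model is

    f(pH) = fmin + (fmax - fmin) / (1 + 10^(n * (pKa - pH)))

and the two-site extension (used when a single transition cannot describe
the data, e.g. a calcium-bound sensor whose chromophore and calcium-binding
domains titrate separately) is

    f(pH) = fmin + (fmed - fmin) / (1 + 10^(n1 * (pKa1 - pH)))
                 + (fmax - fmed) / (1 + 10^(n2 * (pKa2 - pH)))

with ordered transitions pKa1 < pKa2.  ``fmin <= 0`` is allowed, mirroring
the common practice of letting the baseline float below zero when the
acid-quenched intensity is indistinguishable from background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "OneSitePH",
    "TwoSitePH",
    "PHModel",
    "PHResults",
    "fit_ph",
    "dynamic_range_curve",
]


@dataclass(frozen=True)
class OneSitePH:
    """One-site pH model parameters; callable on a pH grid."""

    fmin: float
    fmax: float
    pka: float
    n: float

    def __call__(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.fmin + (self.fmax - self.fmin) / (1.0 + 10.0 ** (self.n * (self.pka - ph)))

    def to_dict(self) -> dict:
        return {"kind": "one", "fmin": self.fmin, "fmax": self.fmax, "pka": self.pka, "n": self.n}


@dataclass(frozen=True)
class TwoSitePH:
    """Two-site pH model parameters; callable on a pH grid."""

    fmin: float
    fmed: float
    fmax: float
    pka1: float
    n1: float
    pka2: float
    n2: float

    def __call__(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        t1 = (self.fmed - self.fmin) / (1.0 + 10.0 ** (self.n1 * (self.pka1 - ph)))
        t2 = (self.fmax - self.fmed) / (1.0 + 10.0 ** (self.n2 * (self.pka2 - ph)))
        return self.fmin + t1 + t2

    def to_dict(self) -> dict:
        return {
            "kind": "two", "fmin": self.fmin, "fmed": self.fmed, "fmax": self.fmax,
            "pka1": self.pka1, "n1": self.n1, "pka2": self.pka2, "n2": self.n2,
        }


class PHModel:
    """Least-squares fit of a one- or two-site pH titration.

    Parameters
    ----------
    ph, response : array_like
        Measured pH values and background-corrected intensities.
    sites : int
        1 or 2 protonation sites.

    The two-site fit multi-starts over a grid of (pKa1, pKa2) pairs with
    the ordering constraint pKa1 < pKa2 to avoid label switching, and
    keeps the best solution.
    """

    N_STARTS = 20

    def __init__(self, ph, response, sites: int = 1):
        ph = np.asarray(ph, dtype=float)
        response = np.asarray(response, dtype=float)
        if ph.shape != response.shape or ph.ndim != 1:
            raise ValueError("ph and response must be 1-D arrays of equal length")
        if sites not in (1, 2):
            raise ValueError("sites must be 1 or 2")
        min_pts = 6 if sites == 1 else 7
        if np.unique(ph).size < min_pts:
            raise ValueError(f"need at least {min_pts} distinct pH points for a {sites}-site fit")
        if np.ptp(response) == 0:
            raise ValueError("degenerate response: all observations identical")
        self.ph = ph
        self.response = response
        self.sites = sites

    # ---- one site ----------------------------------------------------
    def _fit_one(self) -> "PHResults":
        y = self.response
        span = np.ptp(y)
        lo = np.array([min(y.min() - span, 0.0) - span, y.min(), self.ph.min(), 0.05])
        hi = np.array([y.max(), y.max() + span, self.ph.max(), 20.0])
        p0 = np.array([y.min(), y.max(), float(np.median(self.ph)), 1.0])
        p0 = np.clip(p0, lo, hi)

        def resid(p):
            return OneSitePH(*p)(self.ph) - y

        sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"one-site pH fit did not converge: {sol.message}")
        params = OneSitePH(*map(float, sol.x))
        return PHResults(params=params, model=self,
                         residual_norm=float(np.linalg.norm(sol.fun)),
                         converged=True, nobs=self.ph.size)

    # ---- two sites ---------------------------------------------------
    def _fit_two(self) -> "PHResults":
        y = self.response
        span = np.ptp(y)
        lo = np.array([min(y.min() - span, 0.0) - span, y.min() - span, y.min(),
                       self.ph.min(), 0.05, self.ph.min(), 0.05])
        hi = np.array([y.max(), y.max() + span, y.max() + span,
                       self.ph.max(), 20.0, self.ph.max(), 20.0])

        def resid(p):
            return TwoSitePH(*p)(self.ph) - y

        rng = np.random.default_rng(0)  # deterministic multi-start jitter
        grid = np.linspace(self.ph.min() + 0.5, self.ph.max() - 0.5, 5)
        starts = []
        for pka1 in grid:
            for pka2 in grid:
                if pka1 < pka2:
                    starts.append((pka1, pka2))
        starts = starts[: self.N_STARTS] + [
            tuple(sorted(rng.uniform(self.ph.min(), self.ph.max(), 2)))
            for _ in range(max(0, self.N_STARTS - len(starts)))
        ]
        best = None
        for pka1, pka2 in starts:
            p0 = np.clip(np.array([y.min(), 0.5 * (y.min() + y.max()), y.max(),
                                   pka1, 1.0, pka2, 2.0]), lo, hi)
            try:
                sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                             xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("two-site pH fit did not converge from any start")
        p = best.x
        if p[3] > p[5]:  # enforce pKa1 < pKa2 in the reported labels
            p = np.array([p[0], p[0] + p[2] - p[1], p[2], p[5], p[6], p[3], p[4]])
        params = TwoSitePH(*map(float, p))
        return PHResults(params=params, model=self,
                         residual_norm=float(np.linalg.norm(best.fun)),
                         converged=True, nobs=self.ph.size)

    def fit(self) -> "PHResults":
        return self._fit_one() if self.sites == 1 else self._fit_two()


@dataclass(frozen=True)
class PHResults:
    """Fitted pH model with diagnostics; callable on a pH grid."""

    params: OneSitePH | TwoSitePH
    model: PHModel = field(repr=False, default=None)
    residual_norm: float = np.nan
    converged: bool = False
    nobs: int = 0

    def __call__(self, ph) -> np.ndarray:
        return self.params(ph)

    def predict(self, ph) -> np.ndarray:
        return self.params(ph)

    def __getattr__(self, name):
        # expose parameter fields (pka, n, fmin, ...) directly on the results
        try:
            return getattr(self.params, name)
        except AttributeError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        d = self.params.to_dict()
        kind = d.pop("kind")
        lines = [f"{kind}-site Henderson-Hasselbalch fit",
                 f"  observations : {self.nobs}",
                 f"  residual norm: {self.residual_norm:.4g}"]
        for k, v in d.items():
            lines.append(f"  {k:<6} {v:>12.6g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self.model.ph.min(), self.model.ph.max(), 200)
        ax.plot(self.model.ph, self.model.response, "o", label="data")
        ax.plot(grid, self(grid), "-", label="fit")
        ax.set_xlabel("pH")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def fit_ph(ph, response, model_kind: str = "one") -> PHResults:
    """Fit a pH series; ``model_kind`` is ``"one"`` or ``"two"``."""
    sites = {"one": 1, "two": 2}.get(model_kind)
    if sites is None:
        raise ValueError("model_kind must be 'one' or 'two'")
    return PHModel(ph, response, sites=sites).fit()


def dynamic_range_curve(fit_sat, fit_apo, ph_grid) -> np.ndarray:
    """Ratio of the saturated-state model over the calcium-free-state model.

    Both arguments may be fitted results or bare parameter sets (anything
    callable on a pH grid).  The ratio is the sensor's intensity dynamic
    range as a function of pH; for a pH-robust sensor it is flat over the
    physiological range.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    denom = np.asarray(fit_apo(ph_grid), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(fit_sat(ph_grid), dtype=float) / denom
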