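"""Hill binding model: forward curve, inverse, and nonlinear least-squares fit.

Every titration-shaped quantity in this package (fluorescence intensity,
phase/modulation lifetime, phasor line fraction, corrected bound fraction)
is fitted with the same four-parameter Hill curve

    f(L) = fmin + (fmax - fmin) / ((Kd / L)^n + 1)

where L is the free-ligand (calcium) concentration, Kd the apparent
dissociation constant, and n the Hill coefficient.  The L = 0 limit is
f = fmin (the (Kd/L)^n form is singular there and is handled explicitly).

The fit is exposed statsmodels-style: ``HillModel(conc, response).fit()``
returns a :class:`HillResults` carrying the estimates, their standard
errors, diagnostics and a ``summary()`` table.  ``fit_hill`` is a thin
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["HillParams", "HillModel", "HillResults", "fit_hill", "hill_curve", "hill_inverse"]


def hill_curve(conc, fmin: float, fmax: float, kd: float, n: float) -> np.ndarray:
    """Evaluate the Hill curve; exact at L = 0 (returns fmin)."""
    conc = np.asarray(conc, dtype=float)
    safe = np.where(conc > 0, conc, 1.0)
    f = fmin + (fmax - fmin) / ((kd / safe) ** n + 1.0)
    return np.where(conc > 0, f, fmin)


def hill_inverse(f, fmin: float, fmax: float, kd: float, n: float) -> np.ndarray:
    """Invert the Hill curve: concentration at response ``f``.

    Values at or outside (fmin, fmax) map to 0 / inf / NaN; callers that
    work on images apply a clamping policy first (see
    :func:`flits.quantify.concentration_from_fraction`).
    """
    f = np.asarray(f, dtype=float)
    u = (f - fmin) / (fmax - fmin)  # occupancy-like coordinate in (0, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = kd / (1.0 / u - 1.0) ** (1.0 / n)
    conc = np.where(u <= 0, 0.0, conc)
    conc = np.where(u >= 1, np.inf, conc)
    return conc


@dataclass(frozen=True)
class HillParams:
    """A Hill parameter set (ground truth or fitted).

    Callable: ``params(conc)`` evaluates the curve.
    """

    fmin: float
    fmax: float
    kd: float
    n: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")
        if self.fmax == self.fmin:
            raise ValueError("fmax must differ from fmin")

    def __call__(self, conc) -> np.ndarray:
        return hill_curve(conc, self.fmin, self.fmax, self.kd, self.n)

    def inverse(self, f) -> np.ndarray:
        return hill_inverse(f, self.fmin, self.fmax, self.kd, self.n)

    def to_dict(self) -> dict:
        return {"fmin": self.fmin, "fmax": self.fmax, "kd": self.kd, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(fmin=d["fmin"], fmax=d["fmax"], kd=d["kd"], n=d["n"])


class HillModel:
    """Four-parameter Hill fit of a response versus ligand concentration.

    Parameters
    ----------
    conc : array_like
        Ligand concentrations (>= 0, any consistent unit; Kd is returned
        in the same unit).
    response : array_like
        Measured responses, same length as ``conc``.
    """

    def __init__(self, conc, response):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape or conc.ndim != 1:
            raise ValueError("conc and response must be 1-D arrays of equal length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.unique(conc).size < 4:
            raise ValueError("need at least 4 distinct concentrations for a 4-parameter fit")
        if np.ptp(response) == 0:
            raise ValueError("degenerate response: all observations identical")
        self.conc = conc
        self.response = response

    def _default_init(self) -> np.ndarray:
        pos = self.conc[self.conc > 0]
        kd0 = float(np.exp(np.mean(np.log(pos))))
        order = np.argsort(self.conc)
        fmin0 = float(self.response[order[0]])
        fmax0 = float(self.response[order[-1]])
        if fmax0 == fmin0:
            fmax0 = fmin0 + np.ptp(self.response)
        return np.array([fmin0, fmax0, kd0, 1.0])

    def _default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.conc[self.conc > 0]
        span = np.ptp(self.response)
        lo = np.array([self.response.min() - 10 * span, self.response.min() - 10 * span,
                       pos.min() / 100.0, 0.1])
        hi = np.array([self.response.max() + 10 * span, self.response.max() + 10 * span,
                       pos.max() * 100.0, 10.0])
        return lo, hi

    def fit(self, init=None, bounds=None) -> "HillResults":
        """Bounded nonlinear least squares on the Hill curve.

        Non-convergence raises with the optimizer's diagnostic message;
        it is never silent.
        """
        p0 = np.asarray(init, dtype=float) if init is not None else self._default_init()
        lo, hi = bounds if bounds is not None else self._default_bounds()
        p0 = np.clip(p0, lo, hi)

        def residuals(p):
            return hill_curve(self.conc, *p) - self.response

        sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"Hill fit did not converge: {sol.message}")
        resid = sol.fun
        dof = max(self.conc.size - 4, 1)
        s2 = float(resid @ resid) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((4, 4), np.nan)
        return HillResults(
            fmin=float(sol.x[0]), fmax=float(sol.x[1]), kd=float(sol.x[2]), n=float(sol.x[3]),
            model=self, cov=cov, residual_norm=float(np.linalg.norm(resid)),
            converged=bool(sol.success), nobs=int(self.conc.size),
        )


@dataclass(frozen=True)
class HillResults(HillParams):
    """Fitted Hill parameters with uncertainties and diagnostics."""

    model: HillModel = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    residual_norm: float = np.nan
    converged: bool = False
    nobs: int = 0

    @property
    def bse(self) -> dict:
        """Approximate standard errors from the Gauss-Newton covariance."""
        se = np.sqrt(np.diag(self.cov)) if self.cov is not None else np.full(4, np.nan)
        return dict(zip(("fmin", "fmax", "kd", "n"), se))

    def predict(self, conc) -> np.ndarray:
        return self(conc)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Hill model fit",
            f"  observations : {self.nobs}",
            f"  converged    : {self.converged}",
            f"  residual norm: {self.residual_norm:.4g}",
            "  parameter      estimate     std err",
        ]
        for name in ("fmin", "fmax", "kd", "n"):
            lines.append(f"  {name:<9} {getattr(self, name):>12.6g} {se[name]:>11.3g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot data and the fitted curve (log-x, zero shown at the axis edge)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.conc, self.model.response
        pos = x[x > 0]
        floor = pos.min() / 10.0
        grid = np.geomspace(floor, pos.max(), 200)
        ax.semilogx(np.where(x > 0, x, floor), y, "o", label="data")
        ax.semilogx(grid, self(grid), "-", label="Hill fit")
        ax.set_xlabel("free ligand concentration")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def fit_hill(conc, response, init=None, bounds=None) -> HillResults:
    """Convenience wrapper: ``HillModel(conc, response).fit(...)``."""
    return HillModel(conc, response).fit(init=init, bounds=bounds)
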