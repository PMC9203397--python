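"""Per-locus quantile-regression normative reference.

At each of the 37 grid loci, sensitivity is regressed linearly on age at
two quantile levels: the median (tau = 0.5), which supplies the expected
age-matched sensitivity, and the 2.5th percentile (tau = 0.025), which
supplies the lower bound of the 95% prediction band used to flag
below-normal loci.  Fitting minimizes the pinball (check) loss

    L(a, b) = sum_i rho_tau(y_i - (b + a * x_i)),
    rho_tau(u) = u * tau        if u >= 0
               = u * (tau - 1)  otherwise,

which is a linear program; it is solved here directly via the HiGHS LP
solver, in the standard residual-splitting formulation.  An optimal line
of this LP always interpolates two data points, which is what the
brute-force oracle used in the tests enumerates.

Ties between equally good lines are resolved deterministically: among all
loss-minimizing lines, the one with the smallest |slope| is chosen, then
the smallest intercept, by two further LP phases over the optimal face.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .exams import CohortTable
from .grid import N_LOCI, TestGrid, build_maia_grid, grid_hash

#: Quantile levels used by the reference: lower 95% prediction bound and median.
DEFAULT_TAUS: tuple[float, ...] = (0.025, 0.5)

#: Minimum training eyes per locus (warn below _SMALL_N).
DEFAULT_MIN_N = 20
_SMALL_N = 50

_HIGHS_OPTS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


class InsufficientDataError(ValueError):
    """Too few training exams to build a reference."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the training age range."""


def pinball_loss(residual, tau: float):
    """Check loss of a residual at quantile level tau.

    Non-negative, convex, piecewise linear; the tau-quantile minimizes its
    expectation.  Vectorized over ``residual``.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    r = np.asarray(residual, dtype=float)
    out = np.where(r >= 0, r * tau, r * (tau - 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QuantileFit:
    """A fitted quantile line sens = intercept + slope * age."""

    tau: float
    slope: float
    intercept: float
    pinball_loss: float
    n: int

    def predict(self, age) -> float:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def _lp(c, A_eq, b_eq, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=(0, None),
        method="highs",
        options=_HIGHS_OPTS,
    )
    if not res.success:  # pragma: no cover - HiGHS does not fail on these LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res


def fit_quantile_line(ages: Sequence[float], sens: Sequence[float], tau: float,
                      tie_break: bool = True) -> QuantileFit:
    """Fit one quantile line by linear programming.

    Variables are [a+, a-, b+, b-, u_1..n, v_1..n] with residual
    y_i - (b + a x_i) = u_i - v_i and objective tau*sum(u) + (1-tau)*sum(v).
    With ``tie_break`` (default) two more phases select, among optimal
    lines, the smallest |slope| then the smallest intercept.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    x = np.asarray(ages, dtype=float)
    y = np.asarray(sens, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and sens must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("ages are all identical; the slope is unidentified")

    ones = np.ones(n)
    eye = sparse.identity(n, format="csc")
    A_eq = sparse.hstack(
        [
            sparse.csc_matrix(x[:, None]),
            sparse.csc_matrix(-x[:, None]),
            sparse.csc_matrix(ones[:, None]),
            sparse.csc_matrix(-ones[:, None]),
            eye,
            -eye,
        ],
        format="csc",
    )
    c_loss = np.concatenate([[0.0, 0.0, 0.0, 0.0], tau * ones, (1.0 - tau) * ones])

    res = _lp(c_loss, A_eq, y)
    loss_star = res.fun
    sol = res.x

    def _line_loss(s) -> float:
        return float(np.sum(pinball_loss(y - ((s[2] - s[3]) + (s[0] - s[1]) * x), tau)))

    if tie_break:
        # Explore the optimal face within a small relaxation, but accept the
        # tie-break candidate only if its true loss matches the phase-1
        # vertex: on genuinely unique optima this reverts to phase 1 rather
        # than trading loss tolerance for a flatter line.
        tol = 1e-9 * max(1.0, abs(loss_star))
        loss_row = sparse.csr_matrix(c_loss)
        # phase 2: minimal |slope| on the optimal face
        c2 = np.zeros(4 + 2 * n)
        c2[0] = c2[1] = 1.0
        res2 = _lp(c2, A_eq, y, A_ub=loss_row, b_ub=np.array([loss_star + tol]))
        slope_star = res2.fun
        # phase 3: minimal intercept among those
        c3 = np.zeros(4 + 2 * n)
        c3[2], c3[3] = 1.0, -1.0
        A_ub = sparse.vstack([loss_row, sparse.csr_matrix(c2)], format="csr")
        res3 = _lp(c3, A_eq, y, A_ub=A_ub,
                   b_ub=np.array([loss_star + tol, slope_star + tol]))
        if _line_loss(res3.x) <= _line_loss(sol) + 1e-12 * max(1.0, abs(loss_star)):
            sol = res3.x

    slope = float(sol[0] - sol[1])
    intercept = float(sol[2] - sol[3])
    loss = float(np.sum(pinball_loss(y - (intercept + slope * x), tau)))
    return QuantileFit(tau=tau, slope=slope, intercept=intercept, pinball_loss=loss, n=n)


@dataclass
class NormativeReference:
    """Per-locus quantile lines over age, fitted from healthy right-oriented eyes."""

    grid: TestGrid
    fits: dict[int, dict[float, QuantileFit]]
    age_range: tuple[float, float]
    n_training: int

    def taus(self) -> tuple[float, ...]:
        first = self.fits[next(iter(self.fits))]
        return tuple(sorted(first))

    def line_arrays(self, tau: float) -> tuple[np.ndarray, np.ndarray]:
        """(slopes, intercepts) over loci in locus_id order for one tau."""
        slopes = np.empty(N_LOCI)
        intercepts = np.empty(N_LOCI)
        for lid in range(N_LOCI):
            fit = self._fit(lid, tau)
            slopes[lid] = fit.slope
            intercepts[lid] = fit.intercept
        return slopes, intercepts

    def _fit(self, locus_id: int, tau: float) -> QuantileFit:
        try:
            by_tau = self.fits[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus_id {locus_id}") from None
        try:
            return by_tau[tau]
        except KeyError:
            raise KeyError(f"no fit for tau={tau} at locus {locus_id}") from None


def build_reference(healthy: CohortTable, grid: TestGrid,
                    taus: Iterable[float] = DEFAULT_TAUS,
                    min_n: int = DEFAULT_MIN_N) -> NormativeReference:
    """Fit the per-locus reference from a healthy, right-oriented cohort.

    Exams must already be mirrored to right-eye orientation and pass the
    fixation-stability filter; this function fits each locus and tau
    independently and records the training age range and size.
    """
    taus = tuple(taus)
    if any(not 0 < t < 1 for t in taus):
        raise ValueError("all taus must be in (0, 1)")
    n = len(healthy)
    if n < max(2, min_n):
        raise InsufficientDataError(
            f"reference needs at least {max(2, min_n)} healthy eyes, got {n}"
        )
    if n < _SMALL_N:
        warnings.warn(
            f"only {n} training eyes; extreme-quantile lines are unstable below {_SMALL_N}",
            UserWarning,
            stacklevel=2,
        )
    if any(e.laterality != "right" for e in healthy):
        raise ValueError("training exams must be in right-eye orientation (mirror first)")
    ages = healthy.ages()
    S = healthy.sensitivity_matrix()
    fits: dict[int, dict[float, QuantileFit]] = {}
    for lid in range(N_LOCI):
        fits[lid] = {t: fit_quantile_line(ages, S[:, lid], t) for t in taus}
    return NormativeReference(
        grid=grid,
        fits=fits,
        age_range=(float(ages.min()), float(ages.max())),
        n_training=n,
    )


def predict_percentile(ref: NormativeReference, locus_id: int, age: float, tau: float) -> float:
    """Evaluate a reference line at an age, in dB.

    Ages outside the training range are allowed but raise an
    :class:`ExtrapolationWarning`.
    """
    fit = ref._fit(locus_id, tau)
    lo, hi = ref.age_range
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside training range [{lo:.1f}, {hi:.1f}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(fit.intercept + fit.slope * age)


def reference_to_json(ref: NormativeReference) -> str:
    payload = {
        "grid_hash": grid_hash(ref.grid),
        "age_range": list(ref.age_range),
        "n_training": ref.n_training,
        "fits": {
            str(lid): {
                repr(tau): {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "pinball_loss": f.pinball_loss,
                    "n": f.n,
                }
                for tau, f in by_tau.items()
            }
            for lid, by_tau in ref.fits.items()
        },
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def save_reference(ref: NormativeReference, path) -> None:
    with open(path, "w") as fh:
        fh.write(reference_to_json(ref))


def load_reference(path) -> NormativeReference:
    """Load a serialized reference; only the standard 37-locus grid is supported."""
    with open(path) as fh:
        payload = json.load(fh)
    grid = build_maia_grid()
    if payload["grid_hash"] != grid_hash(grid):
        raise ValueError("reference was built on a non-standard grid; cannot load")
    fits: dict[int, dict[float, QuantileFit]] = {}
    for lid_s, by_tau in payload["fits"].items():
        lid = int(lid_s)
        fits[lid] = {}
        for tau_s, f in by_tau.items():
            tau = float(tau_s)
            fits[lid][tau] = QuantileFit(
                tau=tau,
                slope=f["slope"],
                intercept=f["intercept"],
                pinball_loss=f["pinball_loss"],
                n=f["n"],
            )
    return NormativeReference(
        grid=grid,
        fits=fits,
        age_range=tuple(payload["age_range"]),
        n_training=payload["n_training"],
    )
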