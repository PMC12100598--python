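"""Structural-parameter and mixture fitting of SAXS curves.

Two fitting modes mirror how steady-state tubulin-assembly curves are
analyzed:

* :func:`mixture_fit` — non-negative least squares over a library of
  component curves (free dimer, short tubule, bundle, ...), each normalized
  per dimer so the coefficients weight tubulin *mass*; coefficients are
  renormalized to mass fractions summing to one, with the overall intensity
  scale free.
* :func:`scan_structure_params` — grid search over geometric parameters
  (radius, pitch, R_min/R_max, lattice constant ...), rebuilding the model
  assembly and its Debye intensity at every grid point, minimizing weighted
  chi-squared with a free scale factor.  The full objective profile is
  returned for sensitivity reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .scattering import SAXSCurve
from .state_fitting import r_squared

__all__ = [
    "ComponentLibrary",
    "StructureFitResult",
    "mixture_fit",
    "scan_structure_params",
    "chi_squared",
]


@dataclass
class ComponentLibrary:
    """Named component curves on a shared q-grid, with per-component dimer counts."""

    q: np.ndarray
    names: list[str] = field(default_factory=list)
    curves: list[np.ndarray] = field(default_factory=list)
    dimer_counts: list[int] = field(default_factory=list)

    def add(self, name: str, curve: SAXSCurve, n_dimers: int) -> None:
        if curve.q.shape != np.shape(self.q) or not np.allclose(curve.q, self.q):
            raise ValueError(f"component {name!r} is not on the library q-grid")
        if n_dimers < 1:
            raise ValueError("dimer count must be >= 1")
        self.names.append(name)
        self.curves.append(np.asarray(curve.I, dtype=float))
        self.dimer_counts.append(int(n_dimers))

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class StructureFitResult:
    """Best-fit parameters and/or mass fractions with goodness statistics."""

    params: dict
    fractions: dict
    chi2: float
    r2: float
    scale: float
    fitted: SAXSCurve | None = None
    profile: pd.DataFrame | None = None


def _weights(target: SAXSCurve, rel_pseudo_sigma: float = 0.01) -> np.ndarray:
    if target.sigma is not None:
        return 1.0 / target.sigma ** 2
    pseudo = np.maximum(np.abs(target.I) * rel_pseudo_sigma, 1e-300)
    return 1.0 / pseudo ** 2


def chi_squared(target: SAXSCurve, model_I: np.ndarray,
                rel_pseudo_sigma: float = 0.01) -> float:
    """Weighted chi^2 per point; sigma falls back to 1% of |I| when absent."""
    w = _weights(target, rel_pseudo_sigma)
    return float((w * (target.I - model_I) ** 2).sum() / target.I.size)


def mixture_fit(target: SAXSCurve, library: ComponentLibrary) -> StructureFitResult:
    """Decompose a curve into mass fractions of library components.

    Component curves are divided by their dimer counts before the
    non-negative least squares, so each coefficient is proportional to the
    tubulin mass in that component; fractions are the coefficients
    renormalized to sum to one, and the global scale is reported separately.
    """
    if len(library) == 0:
        raise ValueError("empty component library")
    if target.q.shape != np.shape(library.q) or not np.allclose(target.q, library.q):
        raise ValueError("target curve is not on the library q-grid")
    if not np.any(target.I != 0.0):
        raise ValueError("all-zero target curve")

    w = _weights(target)
    sw = np.sqrt(w)
    M = np.column_stack(
        [c / n for c, n in zip(library.curves, library.dimer_counts)]
    )
    coef, _ = nnls(M * sw[:, None], target.I * sw)
    total = coef.sum()
    if total == 0.0:
        raise ValueError("mixture fit collapsed to zero: no component matches")
    fractions = {name: float(c / total) for name, c in zip(library.names, coef)}
    fitted_I = M @ coef
    return StructureFitResult(
        params={},
        fractions=fractions,
        chi2=chi_squared(target, fitted_I),
        r2=r_squared(target.I, fitted_I, w),
        scale=float(total),
        fitted=SAXSCurve(np.asarray(library.q), fitted_I),
    )


def _fit_scale(target_I: np.ndarray, model_I: np.ndarray, w: np.ndarray) -> float:
    denom = (w * model_I * model_I).sum()
    if denom == 0.0:
        return 0.0
    return float((w * model_I * target_I).sum() / denom)


def scan_structure_params(
    target: SAXSCurve,
    recipe: Callable[..., SAXSCurve],
    grid: Mapping[str, Sequence[float]],
    cache: dict | None = None,
    refine: bool = False,
) -> StructureFitResult:
    """Grid-search geometric parameters against a measured/synthetic curve.

    ``recipe(**params)`` must return the model :class:`SAXSCurve` on the
    target's q-grid (typically: build the assembly, Debye-sum a subunit).
    Infeasible grid points may raise; they are skipped.  The objective is
    the weighted chi^2 after fitting a free intensity scale, so it is
    invariant to the target's overall scale.  ``cache`` (parameter tuple ->
    model intensity) persists model curves across repeated scans.
    ``refine=True`` polishes the best grid point with Nelder-Mead (the
    objective is non-smooth in discrete subunit counts, so refinement is
    off by default).
    """
    names = list(grid.keys())
    values = [np.asarray(grid[k], dtype=float) for k in names]
    if any(v.size == 0 for v in values) or not names:
        raise ValueError("empty parameter grid")
    w = _weights(target)
    cache = cache if cache is not None else {}

    rows = []
    best = None
    for combo in itertools.product(*values):
        key = tuple(combo)
        params = dict(zip(names, combo))
        if key in cache:
            model_I = cache[key]
        else:
            try:
                model_I = np.asarray(recipe(**params).I, dtype=float)
            except Exception:
                continue
            cache[key] = model_I
        scale = _fit_scale(target.I, model_I, w)
        chi2 = float((w * (target.I - scale * model_I) ** 2).sum() / target.I.size)
        rows.append({**params, "chi2": chi2, "scale": scale})
        if best is None or chi2 < best[0]:
            best = (chi2, params, scale, model_I)

    if best is None:
        raise ValueError("no feasible grid point: every recipe evaluation failed")

    chi2_best, params_best, scale_best, model_best = best

    if refine:
        from scipy.optimize import minimize

        x0 = np.array([params_best[k] for k in names])

        def objective(x):
            p = dict(zip(names, x))
            try:
                mI = np.asarray(recipe(**p).I, dtype=float)
            except Exception:
                return np.inf
            s = _fit_scale(target.I, mI, w)
            return float((w * (target.I - s * mI) ** 2).sum() / target.I.size)

        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 200})
        if np.isfinite(res.fun) and res.fun < chi2_best:
            params_best = dict(zip(names, res.x))
            model_best = np.asarray(recipe(**params_best).I, dtype=float)
            scale_best = _fit_scale(target.I, model_best, w)
            chi2_best = float(res.fun)

    fitted_I = scale_best * model_best
    return StructureFitResult(
        params=params_best,
        fractions={},
        chi2=chi2_best,
        r2=r_squared(target.I, fitted_I, w),
        scale=scale_best,
        fitted=SAXSCurve(target.q.copy(), fitted_I),
        profile=pd.DataFrame(rows),
    )
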