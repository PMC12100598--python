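"""Spectral decomposition of SAXS curve families.

Tools for the two-state analysis of assembly reactions followed by
scattering: fit each curve of a time or condition series as a linear
combination of two basis states (e.g. the tubulin-dimer-rich initial state
and the microtubule-rich final state), count the independent components by
SVD, and locate isosbestic points — q values where all curves of a
two-component mixing series cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scattering import SAXSCurve

__all__ = [
    "CurveFamily",
    "TwoStateFit",
    "two_state_fit",
    "svd_rank",
    "find_isosbestic",
    "r_squared",
    "subtract_background",
]


@dataclass
class CurveFamily:
    """A set of SAXS curves on one shared q-grid.

    ``intensities`` has shape (n_curves, n_q); ``labels`` are time stamps or
    condition labels; ``sigma`` optional matching uncertainties.
    """

    q: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray | list | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.q.size:
            raise ValueError("intensity matrix must be (n_curves, n_q)")
        if self.sigma is not None:
            self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
            if self.sigma.shape != self.intensities.shape:
                raise ValueError("sigma must match the intensity matrix")
        if self.labels is not None and len(self.labels) != self.intensities.shape[0]:
            raise ValueError("one label per curve required")

    @property
    def n_curves(self) -> int:
        return self.intensities.shape[0]

    def curve(self, i: int) -> SAXSCurve:
        sig = None if self.sigma is None else self.sigma[i]
        return SAXSCurve(self.q, self.intensities[i], sig)


@dataclass
class TwoStateFit:
    """Result of fitting every curve as f_A * A(q) + f_B * B(q)."""

    f_a: np.ndarray
    f_b: np.ndarray
    r2: np.ndarray              # per curve
    r2_global: float
    residuals: np.ndarray       # (n_curves, n_q)
    fitted: np.ndarray          # (n_curves, n_q)
    closure: bool = True


def r_squared(observed, fitted, weights=None) -> float:
    """Weighted coefficient of determination, 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal shapes")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    mean = (w * obs).sum() / w.sum()
    ss_tot = (w * (obs - mean) ** 2).sum()
    if ss_tot == 0.0:
        raise ValueError("zero total variance: R^2 undefined")
    ss_res = (w * (obs - fit) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)


def _check_basis(q: np.ndarray, basis: SAXSCurve, name: str) -> np.ndarray:
    if basis.q.shape != q.shape or not np.allclose(basis.q, q):
        raise ValueError(f"basis {name} is not on the family's q-grid")
    return basis.I


def two_state_fit(
    family: CurveFamily,
    basis_a: SAXSCurve,
    basis_b: SAXSCurve,
    closure: bool = True,
    nonneg: bool = True,
) -> TwoStateFit:
    """Fit every family curve as a linear combination of two basis states.

    Weighted least squares per curve (weights 1/sigma^2 when the family
    carries uncertainties).  With ``closure`` the model is
    ``f * A + (1 - f) * B`` with a single free fraction; ``nonneg`` clips
    (closure) or constrains (NNLS) the fractions to be non-negative.
    """
    A = _check_basis(family.q, basis_a, "A")
    B = _check_basis(family.q, basis_b, "B")

    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0 or np.linalg.norm(A / na - B / nb) < 1e-8:
        raise ValueError("basis curves are collinear: two-state fit is degenerate")

    n = family.n_curves
    f_a = np.empty(n)
    f_b = np.empty(n)
    r2 = np.empty(n)
    fitted = np.empty_like(family.intensities)

    for i in range(n):
        y = family.intensities[i]
        w = (
            1.0 / family.sigma[i] ** 2
            if family.sigma is not None
            else np.ones_like(y)
        )
        if closure:
            d = A - B
            f = float((w * (y - B) * d).sum() / (w * d * d).sum())
            if nonneg:
                f = min(max(f, 0.0), 1.0)
            fa, fb = f, 1.0 - f
        else:
            sw = np.sqrt(w)
            M = np.column_stack([A, B]) * sw[:, None]
            yv = y * sw
            if nonneg:
                from scipy.optimize import nnls

                coef, _ = nnls(M, yv)
            else:
                coef, *_ = np.linalg.lstsq(M, yv, rcond=None)
            fa, fb = float(coef[0]), float(coef[1])
        f_a[i], f_b[i] = fa, fb
        fitted[i] = fa * A + fb * B
        r2[i] = r_squared(y, fitted[i], w)

    w_all = (
        1.0 / family.sigma ** 2 if family.sigma is not None
        else np.ones_like(family.intensities)
    )
    r2_glob = r_squared(family.intensities.ravel(), fitted.ravel(), w_all.ravel())
    return TwoStateFit(
        f_a=f_a, f_b=f_b, r2=r2, r2_global=r2_glob,
        residuals=family.intensities - fitted, fitted=fitted, closure=closure,
    )


def svd_rank(
    family: CurveFamily,
    center: bool = False,
    noise_floor: float | None = None,
) -> tuple[np.ndarray, int]:
    """Singular values of the (curve x q) matrix and the effective rank.

    When the family carries uncertainties, each q column is scaled by the
    rms uncertainty of that column before the decomposition.  A diagonal
    column scaling preserves the matrix rank exactly while flattening the
    noise spectrum (which is otherwise shaped by the orders of magnitude
    spanned by I(q)), so the plateau criterion below is meaningful.  The
    effective rank counts singular values above a noise floor; by default
    the floor is 3x the median of the trailing half of the spectrum, or it
    can be supplied explicitly.  ``center=True`` removes the mean curve
    first (then a two-state family is rank 1 in the centered matrix).
    """
    if family.n_curves < 2:
        raise ValueError("SVD rank analysis needs at least 2 curves")
    M = family.intensities
    scaled_sigma = None
    if family.sigma is not None:
        col_scale = np.maximum(np.sqrt(np.mean(family.sigma**2, axis=0)), 1e-300)
        M = M / col_scale
        scaled_sigma = family.sigma / col_scale
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    s = np.linalg.svd(M, compute_uv=False)
    if noise_floor is None:
        if scaled_sigma is not None:
            # operator-norm bound for a noise matrix with a known variance
            # profile: sqrt(max row variance sum) + sqrt(max column variance
            # sum), with a safety factor
            v = scaled_sigma**2
            bound = math.sqrt(v.sum(axis=1).max()) + math.sqrt(v.sum(axis=0).max())
            noise_floor = 1.5 * bound
        else:
            # plateau estimate from the trailing half of the spectrum
            tail = s[s.size // 2:]
            noise_floor = 3.0 * float(np.median(tail))
        # all-signal guard: tiny spectra (2-3 curves) have no noise plateau
        noise_floor = max(noise_floor, s[0] * 1e-12)
    rank = int((s > noise_floor).sum())
    return s, rank


def find_isosbestic(
    family: CurveFamily, tolerance: float = 0.01
) -> np.ndarray:
    """q positions where all curves of the family cross (isosbestic points).

    A point qualifies when the across-curve relative spread (std/mean) has
    a local minimum below ``tolerance`` (so nearby crossings separated by a
    shallow spread maximum are still resolved).  If every q qualifies
    (identical curves) the whole grid is returned — a degenerate family
    crosses itself everywhere.
    """
    if family.n_curves < 3:
        raise ValueError("isosbestic detection needs at least 3 curves")
    M = family.intensities
    mean = M.mean(axis=0)
    spread = M.std(axis=0) / np.maximum(np.abs(mean), 1e-300)
    below = spread < tolerance
    if below.all():
        return family.q.copy()
    points = []
    n = spread.size
    for i in range(n):
        if not below[i]:
            continue
        left = spread[i - 1] if i > 0 else np.inf
        right = spread[i + 1] if i < n - 1 else np.inf
        if spread[i] <= left and spread[i] < right:
            points.append(family.q[i])
    return np.asarray(points)


def subtract_background(
    sample: SAXSCurve, background: SAXSCurve, scale: float = 1.0
) -> SAXSCurve:
    """Supernatant/buffer subtraction: ``I_sample - scale * I_background``.

    The background is linearly interpolated onto the sample grid; the
    output is restricted to the overlapping q-range.  Uncertainties combine
    in quadrature.
    """
    lo = max(sample.q[0], background.q[0])
    hi = min(sample.q[-1], background.q[-1])
    if lo > hi:
        raise ValueError("sample and background q-ranges do not overlap")
    keep = (sample.q >= lo) & (sample.q <= hi)
    q = sample.q[keep]
    bg = np.interp(q, background.q, background.I)
    I = sample.I[keep] - scale * bg

    sigma = None
    if sample.sigma is not None or background.sigma is not None:
        s_s = sample.sigma[keep] if sample.sigma is not None else np.zeros_like(q)
        s_b = (
            np.interp(q, background.q, background.sigma)
            if background.sigma is not None
            else np.zeros_like(q)
        )
        sigma = np.sqrt(s_s ** 2 + (scale * s_b) ** 2)
        if np.any(sigma <= 0):
            sigma = None
    return SAXSCurve(q, I, sigma)
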