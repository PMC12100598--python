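"""Synthetic inputs with known ground truth.

Everything the fitting pipeline consumes can be generated here: a
two-ellipsoid stand-in for the tubulin dimer (so no PDB download is ever
required), multiplicative-noise scattering curves emulating
supernatant-subtracted steady-state data, and time-resolved families that
are linear mixtures of two basis states following a lag-phase (logistic)
fraction trajectory.

All generators are pure functions of their parameters and a seed; ground
truth is returned (and can be serialized) alongside every data set so
downstream recovery tests are self-validating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .scattering import BeadModel, SAXSCurve, coarse_grain_ellipsoids
from .state_fitting import CurveFamily

__all__ = [
    "NoiseModel",
    "KineticScenario",
    "make_synthetic_dimer",
    "noisy_curve",
    "make_mixture_family",
    "make_kinetic_series",
    "write_ground_truth",
]

PROTEIN_DENSITY = 410.0  # typical protein electron density, e/nm^3


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative relative noise plus an additive floor, seeded.

    ``relative_sd`` is the standard deviation of the multiplicative error
    (0.02 emulates the ~2% error bars of steady-state tubulin curves);
    ``floor`` is an additive absolute noise level.
    """

    relative_sd: float = 0.02
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.floor < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class KineticScenario:
    """A lag-phase two-state assembly time course.

    The fraction of the final (assembled) state follows the logistic
    ``f_B(t) = 1 / (1 + exp(-rate * (t - tau_lag)))``: flat near zero
    during the lag, sigmoidal growth to one.  Times in the same units as
    ``tau_lag`` (seconds for the stopped-flow emulation).
    """

    times: tuple
    tau_lag: float = 60.0
    rate: float = 0.1
    noise: NoiseModel = NoiseModel()

    def fractions(self) -> np.ndarray:
        from scipy.special import expit

        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        return expit(self.rate * (t - self.tau_lag))


def make_synthetic_dimer(
    L_dim: float = 8.0,
    T_dim: float = 5.0,
    bead_radius: float = 0.35,
    protein_density: float = PROTEIN_DENSITY,
    with_shell: bool = False,
) -> BeadModel:
    """Two tangent ellipsoids along z emulating the alpha/beta monomers.

    Each monomer is an ellipsoid with semi-axes (T_dim/2, T_dim/2, L_dim/4);
    the pair is tangent at the origin, spans L_dim in z and T_dim across,
    and is centered so the whole dimer's center of mass sits at the origin.
    Contrast is ``protein_density - 334`` e/nm^3 over the envelope volume.
    """
    if L_dim <= 0 or T_dim <= 0:
        raise ValueError("dimer dimensions must be positive")
    semi = np.array([T_dim / 2.0, T_dim / 2.0, L_dim / 4.0])
    centers = np.array([[0.0, 0.0, -L_dim / 4.0], [0.0, 0.0, L_dim / 4.0]])
    return coarse_grain_ellipsoids(
        centers, np.vstack([semi, semi]), bead_radius=bead_radius,
        protein_density=protein_density, with_shell=with_shell,
        provenance="synthetic-ellipsoid",
    )


def noisy_curve(clean: SAXSCurve, noise: NoiseModel) -> SAXSCurve:
    """Apply the noise model: ``I' = I (1 + eps) + floor * eta`` with seeded draws.

    The sigma column is populated with the nominal per-point uncertainty
    ``sqrt((relative_sd * I)^2 + floor^2)``.
    """
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, 1.0, clean.I.size)
    eta = rng.normal(0.0, 1.0, clean.I.size)
    I = clean.I * (1.0 + noise.relative_sd * eps) + noise.floor * eta
    sigma = np.sqrt((noise.relative_sd * clean.I) ** 2 + noise.floor ** 2)
    if np.all(sigma == 0.0):
        return SAXSCurve(clean.q.copy(), I)
    return SAXSCurve(clean.q.copy(), I, np.maximum(sigma, 1e-300))


def make_mixture_family(
    basis_a: SAXSCurve,
    basis_b: SAXSCurve,
    fractions_a,
    noise: NoiseModel | None = None,
) -> CurveFamily:
    """Steady-state-style family: each curve ``f A + (1 - f) B`` plus noise."""
    if basis_a.q.shape != basis_b.q.shape or not np.allclose(basis_a.q, basis_b.q):
        raise ValueError("basis curves must share a q-grid")
    fr = np.asarray(fractions_a, dtype=float)
    curves, sigmas = [], []
    for i, f in enumerate(fr):
        clean = SAXSCurve(basis_a.q, f * basis_a.I + (1.0 - f) * basis_b.I)
        if noise is not None:
            c = noisy_curve(clean, NoiseModel(noise.relative_sd, noise.floor,
                                              noise.seed + i))
        else:
            c = clean
        curves.append(c.I)
        sigmas.append(c.sigma)
    sigma = None if any(s is None for s in sigmas) else np.vstack(sigmas)
    return CurveFamily(basis_a.q.copy(), np.vstack(curves), labels=fr, sigma=sigma)


def make_kinetic_series(
    scenario: KineticScenario, basis_a: SAXSCurve, basis_b: SAXSCurve
) -> tuple[CurveFamily, np.ndarray]:
    """Time-resolved family following the scenario's lag-phase trajectory.

    Returns the family (labels = time stamps) together with the generating
    fractions of the final state B, the ground truth for recovery tests.
    """
    f_b = scenario.fractions()
    family = make_mixture_family(basis_a, basis_b, 1.0 - f_b, scenario.noise)
    family.labels = np.asarray(scenario.times, dtype=float)
    return family, f_b


def write_ground_truth(path, scenario_or_params, extra: dict | None = None) -> None:
    """Serialize generator parameters next to a generated data set (JSON)."""
    if hasattr(scenario_or_params, "__dataclass_fields__"):
        payload = asdict(scenario_or_params)
    else:
        payload = dict(scenario_or_params)
    if extra:
        payload.update(extra)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
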