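"""File formats: dol pose lists, PDB subunits, 3-column SAXS text, configs.

The *dol* dialect used here is a plain-text pose list, one subunit copy per
row, whitespace-delimited columns ``x y z alpha beta gamma`` (nm, degrees)
with '#' comment headers carrying provenance.  Values survive a
write-then-read round trip to at least 12 significant digits.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

from .geometry import Assembly
from .scattering import SAXSCurve

__all__ = [
    "write_dol",
    "read_dol",
    "write_saxs",
    "read_saxs",
    "read_pdb_subunit",
    "load_config",
    "ConfigError",
]


# --------------------------------------------------------------------------
# dol pose files
# --------------------------------------------------------------------------

def write_dol(path, assembly: Assembly, comments: list[str] | None = None) -> None:
    """Write an assembly's poses as a dol file."""
    lines = [f"# tubulaxs dol pose file: kind={assembly.kind}"]
    if assembly.spec is not None:
        lines.append(f"# spec: {assembly.spec!r}")
    for c in comments or []:
        lines.append(f"# {c}")
    lines.append("# columns: x[nm] y[nm] z[nm] alpha[deg] beta[deg] gamma[deg]")
    for p, a in zip(assembly.positions, assembly.angles):
        lines.append(" ".join(f"{v:.15g}" for v in (*p, *a)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dol(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a dol file; returns (positions (N,3), angles (N,3)).

    Blank lines and '#' comments are tolerated; a malformed row raises with
    its line number.  An empty (header-only) file yields empty arrays.
    """
    positions, angles = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(
                f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
            )
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
        positions.append(vals[:3])
        angles.append(vals[3:])
    if not positions:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.asarray(positions), np.asarray(angles)


# --------------------------------------------------------------------------
# SAXS text files
# --------------------------------------------------------------------------

def write_saxs(path, curve: SAXSCurve, comments: list[str] | None = None) -> None:
    """Write a curve as 3-column text (q I sigma); 2 columns when sigma absent."""
    lines = [f"# {c}" for c in comments or []]
    lines.append("# columns: q[1/nm] I[a.u.]" +
                 (" sigma[a.u.]" if curve.sigma is not None else ""))
    for i in range(len(curve)):
        row = [f"{curve.q[i]:.9g}", f"{curve.I[i]:.9g}"]
        if curve.sigma is not None:
            row.append(f"{curve.sigma[i]:.9g}")
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_saxs(path, angstrom: bool = False) -> SAXSCurve:
    """Read a 2- or 3-column SAXS text file.

    ``angstrom=True`` declares the file's q in 1/Angstrom; it is converted
    to 1/nm at this boundary (q_nm = 10 * q_A).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least q and I columns")
    q = data[:, 0] * (10.0 if angstrom else 1.0)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(q, data[:, 1], sigma)


# --------------------------------------------------------------------------
# PDB subunits
# --------------------------------------------------------------------------

def read_pdb_subunit(
    path, include_hetatm: bool = False, center: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Element-resolved coordinates and electron counts from a PDB file.

    Returns (positions (N,3) in nm, electrons (N,)).  Coordinates are
    converted from Angstrom and, by default, centered at the (electron
    weighted) center of mass, matching how subunits are prepared before
    assembly replication.  Unknown elements warn and fall back to carbon.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    positions, electrons = [], []
    for model in st:
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                if het and not include_hetatm:
                    continue
                for atom in residue:
                    el = atom.element
                    ne = el.atomic_number
                    if ne == 0:
                        warnings.warn(
                            f"unknown element for atom {atom.name!r}; "
                            "using carbon", stacklevel=2,
                        )
                        ne = 6
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    electrons.append(float(ne))
        break  # first model only
    if not positions:
        raise ValueError(f"{path}: no ATOM/HETATM records read")
    pos = np.asarray(positions) / 10.0  # Angstrom -> nm
    ele = np.asarray(electrons)
    if center:
        pos = pos - (pos * ele[:, None]).sum(axis=0) / ele.sum()
    return pos, ele


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


_ALLOWED_KEYS = {
    "model": {"kind", "r", "p", "h", "L_dim", "T_dim", "handedness", "spacing",
              "R_max", "R_min", "n", "V_h", "N_spirals", "N_p", "axial_rise",
              "a", "gamma_lattice", "n1_range", "n2_range", "disc_cutoff",
              "sublattice_j", "mode"},
    "subunit": {"source", "path", "L_dim", "T_dim", "bead_radius",
                "protein_density", "with_shell", "include_hetatm"},
    "q_grid": {"q_min", "q_max", "n"},
    "noise": {"relative_sd", "floor", "seed"},
    "fit": {"closure", "nonneg", "tolerance", "grid", "components"},
    "output": {"dol", "saxs", "results"},
}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for section, content in raw.items():
        if section not in _ALLOWED_KEYS:
            raise ConfigError(f"{path}: unknown section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        unknown = set(content) - _ALLOWED_KEYS[section]
        if unknown:
            raise ConfigError(
                f"{path}: unknown keys in {section!r}: {sorted(unknown)}"
            )
    return raw
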