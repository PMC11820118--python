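"""Energy terms of the Mpipi residue-resolution coarse-grained model.

One bead per amino acid; the total energy decomposes as

    E = E_bond + E_elec + E_pair

with harmonic bonds, Debye-Hueckel screened Coulomb electrostatics, and
Wang-Frenkel short-range pair interactions. Units are fixed package-wide:
Angstrom, Kelvin, kcal/mol, elementary charges. Default globals are the
standard Mpipi values: bond constant k = 19.1 kcal mol^-1 A^-2,
equilibrium bond length r0 = 3.81 A, relative permittivity eps_r = 80,
inverse Debye length kappa = 0.126 A^-1 (150 mM monovalent salt at
~300 K).

Per-pair (eps, sigma, mu, nu) parameters are consumed from a user-supplied
table (documented YAML schema, see :func:`load_params`); none are
hard-coded. This module evaluates energies only — no forces, no sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import constants as sc

__all__ = [
    "COULOMB_CONSTANT_KCAL_A_E2",
    "DEFAULT_BOND_K",
    "DEFAULT_BOND_R0",
    "DEFAULT_EPS_R",
    "DEFAULT_KAPPA",
    "ParamTableError",
    "ResidueParams",
    "PairParams",
    "MpipiParamTable",
    "BeadConfiguration",
    "EnergyBreakdown",
    "load_params",
    "bond_energy",
    "debye_kappa",
    "electrostatic_energy",
    "wang_frenkel_energy",
    "wang_frenkel_alpha",
    "total_energy",
    "read_configuration",
]

#: Coulomb prefactor e^2/(4 pi eps0) in kcal mol^-1 A e^-2 (CODATA-derived,
#: full precision documented: 332.0637 kcal*A/(mol*e^2)).
COULOMB_CONSTANT_KCAL_A_E2 = 332.0637

DEFAULT_BOND_K = 19.1     # kcal mol^-1 A^-2
DEFAULT_BOND_R0 = 3.81    # A
DEFAULT_EPS_R = 80.0      # dimensionless
DEFAULT_KAPPA = 0.126     # A^-1


class ParamTableError(ValueError):
    """Parameter file violates the documented schema."""


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead parameters: mass (amu), charge (e), diameter (A)."""

    mass: float
    charge: float
    sigma: float


@dataclass(frozen=True)
class PairParams:
    """Wang-Frenkel parameters for an unordered residue pair.

    eps in kcal/mol, sigma in A, mu/nu dimensionless shape exponents,
    rc the cutoff in A (defaults to 3*sigma when a table omits it).
    """

    eps: float
    sigma: float
    mu: float
    nu: float
    rc: float


@dataclass(frozen=True)
class MpipiParamTable:
    """Validated residue + pair parameter table with global constants."""

    residues: Mapping[str, ResidueParams]
    pairs: Mapping[frozenset, PairParams]
    bond_k: float = DEFAULT_BOND_K
    bond_r0: float = DEFAULT_BOND_R0
    eps_r: float = DEFAULT_EPS_R
    kappa: float = DEFAULT_KAPPA

    def residue(self, code: str) -> ResidueParams:
        try:
            return self.residues[code]
        except KeyError:
            raise ParamTableError(f"residue {code!r} not in parameter table") from None

    def pair(self, i: str, j: str) -> PairParams:
        key = frozenset((i, j))
        try:
            return self.pairs[key]
        except KeyError:
            raise ParamTableError(f"pair ({i}, {j}) not in parameter table") from None


def load_params(path: str | Path) -> MpipiParamTable:
    """Load and validate a YAML parameter table.

    Schema::

        globals: {bond_k: 19.1, bond_r0: 3.81, eps_r: 80.0, kappa: 0.126}
        residues:
          Y: {mass: 163.18, charge: 0.0, sigma: 6.46}
          ...
        pairs:
          - {i: Y, j: Y, eps: 0.30, sigma: 6.46, mu: 2, nu: 1}   # rc optional
          ...

    A pair listed once covers both orders; a pair listed in both orders
    must agree exactly, otherwise the conflicting keys are reported.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "residues" not in doc or "pairs" not in doc:
        raise ParamTableError(f"{path}: expected mapping with 'residues' and 'pairs'")

    residues: dict[str, ResidueParams] = {}
    for code, block in doc["residues"].items():
        missing = {"mass", "charge", "sigma"} - set(block)
        if missing:
            raise ParamTableError(f"{path}: residue {code}: missing keys {sorted(missing)}")
        residues[code] = ResidueParams(
            mass=float(block["mass"]), charge=float(block["charge"]),
            sigma=float(block["sigma"]),
        )

    pairs: dict[frozenset, PairParams] = {}
    seen_as: dict[frozenset, tuple] = {}
    for entry in doc["pairs"]:
        missing = {"i", "j", "eps", "sigma", "mu", "nu"} - set(entry)
        if missing:
            raise ParamTableError(f"{path}: pair entry {entry}: missing keys {sorted(missing)}")
        i, j = entry["i"], entry["j"]
        for code in (i, j):
            if code not in residues:
                raise ParamTableError(f"{path}: pair ({i}, {j}) references unknown residue {code!r}")
        sigma = float(entry["sigma"])
        params = PairParams(
            eps=float(entry["eps"]), sigma=sigma, mu=float(entry["mu"]),
            nu=float(entry["nu"]), rc=float(entry.get("rc", 3.0 * sigma)),
        )
        key = frozenset((i, j))
        if key in pairs and pairs[key] != params:
            raise ParamTableError(
                f"{path}: conflicting parameters for pair ({i}, {j}): "
                f"{pairs[key]} vs {params} (first seen as {seen_as[key]})"
            )
        pairs[key] = params
        seen_as.setdefault(key, (i, j))

    g = doc.get("globals", {}) or {}
    return MpipiParamTable(
        residues=residues, pairs=pairs,
        bond_k=float(g.get("bond_k", DEFAULT_BOND_K)),
        bond_r0=float(g.get("bond_r0", DEFAULT_BOND_R0)),
        eps_r=float(g.get("eps_r", DEFAULT_EPS_R)),
        kappa=float(g.get("kappa", DEFAULT_KAPPA)),
    )


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------

def bond_energy(r: float, k: float = DEFAULT_BOND_K, r0: float = DEFAULT_BOND_R0) -> float:
    """Harmonic bond energy 0.5*k*(r - r0)^2 in kcal/mol."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    return 0.5 * k * (r - r0) ** 2


def debye_kappa(ionic_strength: float, eps_r: float = DEFAULT_EPS_R, temperature: float = 300.0) -> float:
    """Inverse Debye screening length in A^-1.

    kappa = sqrt(2 e^2 N_A (1000 I) / (eps0 eps_r kB T)) for a monovalent
    salt of molar ionic strength I. 150 mM at eps_r = 80, T = 300 K gives
    0.126 A^-1.
    """
    if ionic_strength < 0 or eps_r <= 0 or temperature <= 0:
        raise ValueError("ionic strength must be >= 0; eps_r and T positive")
    number_density = 1000.0 * ionic_strength * sc.Avogadro  # ions of each sign per m^3
    kappa_sq = (
        2.0 * sc.elementary_charge ** 2 * number_density
        / (sc.epsilon_0 * eps_r * sc.Boltzmann * temperature)
    )
    return math.sqrt(kappa_sq) * 1e-10  # m^-1 -> A^-1


def electrostatic_energy(
    qi: float, qj: float, r: float,
    kappa: float = DEFAULT_KAPPA, eps_r: float = DEFAULT_EPS_R,
) -> float:
    """Screened Coulomb energy qi*qj/(4 pi eps0 eps_r r) * exp(-kappa r), kcal/mol."""
    if r <= 0:
        raise ValueError("electrostatic energy undefined at r <= 0")
    return COULOMB_CONSTANT_KCAL_A_E2 * qi * qj / (eps_r * r) * math.exp(-kappa * r)


def wang_frenkel_alpha(sigma: float, mu: float, nu: float, rc: float) -> float:
    """Normalisation making the Wang-Frenkel minimum depth exactly -eps."""
    ratio = (rc / sigma) ** (2.0 * mu)
    return 2.0 * nu * ratio * ((1.0 + 2.0 * nu) / (2.0 * nu * (ratio - 1.0))) ** (2.0 * nu + 1.0)


def wang_frenkel_energy(
    r: float, eps: float, sigma: float, mu: float, nu: float, rc: float | None = None,
) -> float:
    """Wang-Frenkel pair energy in kcal/mol.

    phi(r) = eps * alpha * [(sigma/r)^(2mu) - 1] * [(rc/r)^(2mu) - 1]^(2nu)

    vanishing identically at and beyond the cutoff rc (default 3*sigma) and
    crossing zero at r = sigma, with minimum depth -eps by the choice of
    alpha.
    """
    if r <= 0:
        raise ValueError("pair energy undefined at r <= 0")
    if rc is None:
        rc = 3.0 * sigma
    if rc <= sigma:
        raise ValueError("cutoff rc must exceed sigma")
    if r >= rc:
        return 0.0
    alpha = wang_frenkel_alpha(sigma, mu, nu, rc)
    return (
        eps * alpha
        * ((sigma / r) ** (2.0 * mu) - 1.0)
        * ((rc / r) ** (2.0 * mu) - 1.0) ** (2.0 * nu)
    )


# ---------------------------------------------------------------------------
# Configurations and totals
# ---------------------------------------------------------------------------

@dataclass
class BeadConfiguration:
    """Bead positions (A) with residue identities and bonded topology."""

    residues: list[str]
    positions: np.ndarray  # (n, 3) float, A
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.residues), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.residues)} beads"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead positions must be finite")
        n = len(self.residues)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ValueError(f"bond ({a}, {b}) references invalid beads")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposed total energy in kcal/mol."""

    bond: float
    electrostatic: float
    pair: float

    @property
    def total(self) -> float:
        return self.bond + self.electrostatic + self.pair


def total_energy(config: BeadConfiguration, params: MpipiParamTable) -> EnergyBreakdown:
    """Sum bond, screened-electrostatic, and Wang-Frenkel terms.

    Bonded (1-2) pairs are excluded from the non-bonded sums; pair terms
    are cut off at each pair's rc.
    """
    for code in config.residues:
        params.residue(code)  # raises for unknown residues
    bonded = {frozenset(b) for b in config.bonds}

    e_bond = 0.0
    for a, b in config.bonds:
        r = float(np.linalg.norm(config.positions[a] - config.positions[b]))
        e_bond += bond_energy(r, params.bond_k, params.bond_r0)

    e_elec = 0.0
    e_pair = 0.0
    n = len(config.residues)
    for a in range(n):
        qa = params.residue(config.residues[a]).charge
        for b in range(a + 1, n):
            if frozenset((a, b)) in bonded:
                continue
            r = float(np.linalg.norm(config.positions[a] - config.positions[b]))
            qb = params.residue(config.residues[b]).charge
            if qa * qb != 0.0:
                e_elec += electrostatic_energy(qa, qb, r, params.kappa, params.eps_r)
            pp = params.pair(config.residues[a], config.residues[b])
            e_pair += wang_frenkel_energy(r, pp.eps, pp.sigma, pp.mu, pp.nu, pp.rc)
    return EnergyBreakdown(bond=e_bond, electrostatic=e_elec, pair=e_pair)


def read_configuration(path: str | Path) -> BeadConfiguration:
    """Read a bead configuration from a whitespace table.

    Format: one ``index residue x y z`` line per bead (A), then an
    optional ``bonds`` line followed by ``i j`` index pairs. ``#`` starts
    a comment.
    """
    residues: list[str] = []
    coords: list[list[float]] = []
    bonds: list[tuple[int, int]] = []
    in_bonds = False
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower() == "bonds":
                in_bonds = True
                continue
            fields = line.split()
            if in_bonds:
                bonds.append((int(fields[0]), int(fields[1])))
            else:
                residues.append(fields[1])
                coords.append([float(x) for x in fields[2:5]])
    return BeadConfiguration(residues=residues, positions=np.array(coords), bonds=bonds)
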