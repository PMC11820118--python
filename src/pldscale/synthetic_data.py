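"""Seed-deterministic generators for every input the pipeline consumes.

The analysis stages were designed for data produced by cluster-scale
direct-coexistence molecular dynamics; these generators emulate the
*statistical shape* of that data — tanh-interface slab density profiles,
binodal point sets obeying the coexistence and rectilinear-diameter laws,
variant families following the scaling ansaetze with additive Gaussian
noise, and PLD-like random sequences with realistic composition — so
every stage is testable without any download or simulation.

Each generator is a pure function of a truth dataclass (which includes
its seed); truths serialise to/from JSON so every synthetic dataset is
self-describing. Noise is i.i.d. Gaussian throughout. What the
generators deliberately do not emulate: MD time-correlation structure,
finite-size effects, and interfacial fluctuations beyond tanh + noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binodal import CoexistencePoint, CriticalPoint, DensityProfile, predict_binodal
from .scaling import Ansatz, VariantObservation, ansatz_x
from .sequence_tools import RESIDUE_CLASSES, PLDSequence, ResidueClass

__all__ = [
    "ProfileTruth",
    "BinodalTruth",
    "FamilyTruth",
    "SequenceTruth",
    "synth_density_profile",
    "synth_coexistence_points",
    "synth_variant_family",
    "synth_pld_sequence",
    "truth_to_json",
    "truth_from_json",
]


@dataclass(frozen=True)
class ProfileTruth:
    """Ground truth for a synthetic slab density profile.

    Plateaus in g/cm^3, geometry in A. Defaults resemble a 64-chain slab
    box: 1000 A long axis with a ~300 A dense slab.
    """

    rho_low: float = 0.05
    rho_high: float = 0.60
    z1: float = 350.0
    z2: float = 650.0
    width: float = 20.0
    box_length: float = 1000.0
    n_bins: int = 200
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rho_high > self.rho_low >= 0):
            raise ValueError("need rho_high > rho_low >= 0")
        if not (0 < self.z1 < self.z2 < self.box_length):
            raise ValueError("need 0 < z1 < z2 < box_length")


def synth_density_profile(truth: ProfileTruth) -> DensityProfile:
    """Double-tanh slab profile plus i.i.d. Gaussian noise."""
    rng = np.random.default_rng(truth.seed)
    dz = truth.box_length / truth.n_bins
    z = dz * (np.arange(truth.n_bins) + 0.5)
    rho = truth.rho_low + 0.5 * (truth.rho_high - truth.rho_low) * (
        np.tanh((z - truth.z1) / truth.width) - np.tanh((z - truth.z2) / truth.width)
    )
    if truth.noise_sd > 0:
        rho = np.clip(rho + rng.normal(0.0, truth.noise_sd, size=rho.shape), 0.0, None)
    err = np.full_like(rho, truth.noise_sd) if truth.noise_sd > 0 else None
    return DensityProfile(z=z, rho=rho, err=err)


@dataclass(frozen=True)
class BinodalTruth:
    """Ground truth critical point plus sampling grid for a binodal.

    The default critical parameters (Tc = 400 K, rho_c = 0.30 g/cm^3,
    d = 0.77, A = -0.001 g cm^-3 K^-1) are arbitrary fixtures shaped like
    typical PLD binodals; they are not measured values.
    """

    Tc: float = 400.0
    rho_c: float = 0.30
    d: float = 0.77
    A: float = -0.001
    temperatures: tuple[float, ...] = tuple(float(t) for t in range(320, 400, 8))
    noise_sd: float = 0.0
    seed: int = 0

    def critical_point(self) -> CriticalPoint:
        return CriticalPoint(Tc=self.Tc, rho_c=self.rho_c, d=self.d, A=self.A)


def synth_coexistence_points(truth: BinodalTruth) -> list[CoexistencePoint]:
    """Closed-form binodal densities plus Gaussian noise.

    The error columns are set to the noise sd (the generating truth), so
    weighted fits downstream see honest weights.
    """
    if any(T >= truth.Tc for T in truth.temperatures):
        raise ValueError("all grid temperatures must lie below Tc")
    clean = predict_binodal(truth.critical_point(), truth.temperatures)
    if truth.noise_sd <= 0:
        return clean
    rng = np.random.default_rng(truth.seed)
    noisy = []
    for p in clean:
        lo = p.rho_low + rng.normal(0.0, truth.noise_sd)
        hi = p.rho_high + rng.normal(0.0, truth.noise_sd)
        lo = max(lo, 1e-6)
        hi = max(hi, lo + 1e-6)
        noisy.append(CoexistencePoint(
            T=p.T, rho_low=lo, rho_high=hi,
            err_low=truth.noise_sd, err_high=truth.noise_sd,
        ))
    return noisy


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for a variant family generated under one ansatz.

    ``lengths`` and ``counts`` are per-observation (recycled to the longer
    of the two); delta_Tc = S_truth * x + Gaussian(0, noise_sd).
    """

    pair: str = "R->K"
    ansatz: Ansatz = Ansatz.FRACTION
    S_truth: float = -1300.0
    lengths: tuple[int, ...] = (100, 150, 200, 250, 300)
    counts: tuple[int, ...] = (2, 4, 6, 8, 10)
    n_obs: int = 20
    noise_sd: float = 2.0
    seed: int = 0


def synth_variant_family(truth: FamilyTruth) -> list[VariantObservation]:
    """Observations with delta_Tc on the generating line plus noise."""
    rng = np.random.default_rng(truth.seed)
    obs = []
    for i in range(truth.n_obs):
        L = truth.lengths[i % len(truth.lengths)]
        N = truth.counts[i % len(truth.counts)]
        if N > L:
            raise ValueError(f"observation {i}: N={N} exceeds L={L}")
        x = ansatz_x(N, L, truth.ansatz)
        noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        obs.append(VariantObservation(
            variant_id=f"synth_{truth.pair}_{i:03d}", pair=truth.pair,
            count=N, length=L, delta_tc=truth.S_truth * x + noise,
            delta_tc_err=truth.noise_sd if truth.noise_sd > 0 else None,
        ))
    return obs


_DEFAULT_CLASS_TARGETS = {
    # Inside the wild-type PLD ranges: aromatic fraction 0.19-0.43, total
    # charged 0.02-0.10.
    ResidueClass.AROMATIC: 0.30,
    ResidueClass.POSITIVE: 0.03,
    ResidueClass.NEGATIVE: 0.01,
    ResidueClass.NEUTRAL_PI: 0.25,
    ResidueClass.GLYCINE: 0.20,
    ResidueClass.NEUTRAL: 0.21,
}


@dataclass(frozen=True)
class SequenceTruth:
    """Ground truth for a random PLD-like sequence: length and per-class
    composition targets (must sum to 1)."""

    length: int = 200
    class_targets: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_TARGETS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("sequence length must be >= 20")
        total = sum(self.class_targets.values())
        if any(v < 0 or v > 1 for v in self.class_targets.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("class targets must be in [0, 1] and sum to 1")


def synth_pld_sequence(truth: SequenceTruth, seq_id: str = "synthetic_pld") -> PLDSequence:
    """Random sequence matching class targets by largest-remainder rounding.

    Within a class, letters are drawn uniformly from the class members;
    the final arrangement is a seeded permutation.
    """
    rng = np.random.default_rng(truth.seed)
    classes = list(ResidueClass)
    raw = {c: truth.length * float(truth.class_targets.get(c, 0.0)) for c in classes}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = truth.length - sum(counts.values())
    for c in sorted(classes, key=lambda c: (-(raw[c] - counts[c]), classes.index(c)))[:short]:
        counts[c] += 1
    letters = []
    for c in classes:
        members = sorted(RESIDUE_CLASSES[c])
        picks = rng.integers(0, len(members), size=counts[c])
        letters.extend(members[i] for i in picks)
    order = rng.permutation(len(letters))
    return PLDSequence(id=seq_id, residues="".join(letters[i] for i in order))


# ---------------------------------------------------------------------------
# Truth serialisation
# ---------------------------------------------------------------------------

_TRUTH_TYPES = {
    "ProfileTruth": ProfileTruth,
    "BinodalTruth": BinodalTruth,
    "FamilyTruth": FamilyTruth,
    "SequenceTruth": SequenceTruth,
}


def truth_to_json(truth) -> str:
    """Serialise any truth dataclass (type-tagged) to JSON."""
    payload = dataclasses.asdict(truth)
    if isinstance(truth, FamilyTruth):
        payload["ansatz"] = truth.ansatz.value
    if isinstance(truth, SequenceTruth):
        payload["class_targets"] = {
            (k.value if isinstance(k, ResidueClass) else str(k)): v
            for k, v in truth.class_targets.items()
        }
    return json.dumps({"type": type(truth).__name__, **payload}, indent=2)


def truth_from_json(text: str):
    """Inverse of :func:`truth_to_json`."""
    doc = json.loads(text)
    kind = doc.pop("type")
    cls = _TRUTH_TYPES[kind]
    for key in ("temperatures", "lengths", "counts"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    if cls is FamilyTruth:
        doc["ansatz"] = Ansatz(doc["ansatz"])
    if cls is SequenceTruth:
        doc["class_targets"] = {ResidueClass(k): v for k, v in doc["class_targets"].items()}
    return cls(**doc)
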