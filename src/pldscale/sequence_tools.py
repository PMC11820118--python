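"""Sequence handling for prion-like domains (PLDs).

Residue-class taxonomy, composition and net-charge-per-residue (NCPR)
statistics, parsing of variant labels in the ``-nX+mZ`` convention, and
composition-preserving in-silico mutagenesis.

Variant families of PLDs are conventionally designed under five
constraints: probe both strong (aromatic, arginine) and subtle (polar,
neutral) modulators of phase separation; mutate one amino-acid type at a
time; distribute mutations homogeneously along the chain; replace deleted
residues with weakly interacting amino acids (Ser, Thr, Gly, Ala) in
wild-type proportions; and span a wide range of critical temperatures.
:func:`design_variant` implements the second through fourth rules
deterministically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CANONICAL_RESIDUES",
    "WEAK_REPLACEMENTS",
    "ResidueClass",
    "RESIDUE_CLASSES",
    "PLDSequence",
    "ChargeModel",
    "CompositionProfile",
    "MutationSpec",
    "SequenceParseError",
    "LabelParseError",
    "read_fasta",
    "write_fasta",
    "classify_residue",
    "composition_profile",
    "parse_variant_label",
    "format_variant_label",
    "infer_mutation",
    "design_variant",
    "read_variant_table",
    "write_variant_table",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Weakly interacting residues used for composition-preserving replacement
#: ("X" targets). The string order is the fixed tie-break order for
#: largest-remainder rounding.
WEAK_REPLACEMENTS = "STGA"


class SequenceParseError(ValueError):
    """A FASTA record or residue string could not be interpreted."""


class LabelParseError(ValueError):
    """A variant label does not follow the -nX+mZ grammar."""


class ResidueClass(str, Enum):
    """Six-way partition of the 20 canonical amino acids.

    ``neutral_pi`` are uncharged residues with pi electrons in the side
    chain (Asn, Gln); ``neutral`` are uncharged without them. Histidine is
    grouped compositionally with the positives even though it carries no
    formal charge in the default :class:`ChargeModel`.
    """

    AROMATIC = "aromatic"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL_PI = "neutral_pi"
    GLYCINE = "glycine"
    NEUTRAL = "neutral"


RESIDUE_CLASSES: dict[ResidueClass, frozenset[str]] = {
    ResidueClass.AROMATIC: frozenset("FWY"),
    ResidueClass.POSITIVE: frozenset("KHR"),
    ResidueClass.NEGATIVE: frozenset("DE"),
    ResidueClass.NEUTRAL_PI: frozenset("NQ"),
    ResidueClass.GLYCINE: frozenset("G"),
    ResidueClass.NEUTRAL: frozenset("ACILMPSTV"),
}

_CLASS_OF: dict[str, ResidueClass] = {
    aa: cls for cls, members in RESIDUE_CLASSES.items() for aa in members
}


def classify_residue(aa: str) -> ResidueClass:
    """Return the unique :class:`ResidueClass` of a one-letter code."""
    try:
        return _CLASS_OF[aa]
    except KeyError:
        raise SequenceParseError(f"not a canonical one-letter residue code: {aa!r}") from None


@dataclass(frozen=True)
class PLDSequence:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id:
        Text label (FASTA header word).
    residues:
        One-letter codes, uppercase, canonical alphabet only.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceParseError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise SequenceParseError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        """Chain length L (number of residues)."""
        return len(self.residues)

    def count(self, residues: Iterable[str]) -> int:
        members = set(residues)
        return sum(1 for aa in self.residues if aa in members)

    def class_count(self, cls: ResidueClass) -> int:
        return self.count(RESIDUE_CLASSES[cls])


@dataclass(frozen=True)
class ChargeModel:
    """Formal charge per residue, in units of the elementary charge.

    Default: Arg and Lys +1, Asp and Glu -1, everything else 0. Histidine
    is neutral by default but configurable (its protonation state depends
    on pH).
    """

    charges: Mapping[str, float] = field(
        default_factory=lambda: {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0}
    )

    @classmethod
    def default(cls, histidine_charge: float = 0.0) -> "ChargeModel":
        base = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0}
        if histidine_charge:
            base["H"] = histidine_charge
        return cls(charges=base)

    def charge_of(self, aa: str) -> float:
        return self.charges.get(aa, 0.0)

    def ncpr(self, seq: PLDSequence) -> float:
        return sum(self.charge_of(aa) for aa in seq.residues) / seq.length


@dataclass(frozen=True)
class CompositionProfile:
    """Per-class fractions (summing to 1) plus net charge per residue."""

    fractions: Mapping[ResidueClass, float]
    ncpr: float


def composition_profile(
    seq: PLDSequence, charge_model: ChargeModel | None = None
) -> CompositionProfile:
    """Class composition and NCPR of a sequence."""
    cm = charge_model or ChargeModel.default()
    fractions = {
        cls: seq.class_count(cls) / seq.length for cls in ResidueClass
    }
    return CompositionProfile(fractions=fractions, ncpr=cm.ncpr(seq))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[PLDSequence]:
    """Read a multi-record FASTA file into :class:`PLDSequence` objects.

    Lowercase input is uppercased; a non-canonical residue raises
    :class:`SequenceParseError` naming the record and 1-based position.
    """
    sequences: list[PLDSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        sequences.append(PLDSequence(id=record.id, residues=str(record.seq).upper()))
    return sequences


def write_fasta(sequences: Iterable[PLDSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variant labels and mutation specs
# ---------------------------------------------------------------------------

# "-nX+mZ": remove n residues of type X, add m of type Z. "-nX" alone means
# composition-biased replacement (target "X"). U+2212 minus accepted.
_LABEL_RE = re.compile(
    r"^-(?P<n>\d+)(?P<src>[A-Z](?:/[A-Z])*)"
    r"(?:\+(?P<m>\d+)(?P<tgt>[A-Z]))?$"
)


@dataclass(frozen=True)
class MutationSpec:
    """One mutation type: source residue set -> target residue.

    ``target == "X"`` denotes composition-biased replacement by weakly
    interacting residues. ``positions`` are 1-based when given.
    ``multi_type`` marks substitution sets spanning more than one
    source->target pair; downstream fitting refuses those.
    """

    source: str
    target: str
    count: int
    positions: tuple[int, ...] | None = None
    multi_type: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("mutation count must be non-negative")
        if self.positions is not None and len(self.positions) != self.count:
            raise ValueError(
                f"count {self.count} does not match {len(self.positions)} positions"
            )
        if not self.multi_type and self.target != "X":
            if set(self.source.split("/")) & {self.target}:
                raise ValueError("source and target residues must be disjoint")

    @property
    def source_set(self) -> frozenset[str]:
        return frozenset(self.source.split("/"))

    @property
    def pair(self) -> str:
        """Canonical mutation-pair label, e.g. ``"R->K"`` or ``"F/Y->X"``."""
        src = "/".join(sorted(self.source_set))
        return f"{src}->{self.target}"

    def fraction(self, length: int) -> float:
        """Mutation fraction f = N / L for a chain of the given length."""
        return self.count / length


def parse_variant_label(label: str) -> MutationSpec:
    """Parse a ``-nX+mZ`` or ``-nX`` variant label into a MutationSpec.

    Both the ASCII hyphen-minus and the typographic minus (U+2212) are
    accepted. In the paired form the removal and addition counts must be
    equal (substitution, not indel).
    """
    text = label.strip().replace("−", "-")
    match = _LABEL_RE.match(text)
    if match is None:
        raise LabelParseError(f"cannot parse variant label {label!r}")
    n = int(match.group("n"))
    source = match.group("src")
    for aa in source.split("/"):
        if aa not in CANONICAL_RESIDUES and aa != "X":
            raise LabelParseError(f"label {label!r}: unknown source residue {aa!r}")
    if match.group("m") is None:
        target = "X"
    else:
        m = int(match.group("m"))
        if m != n:
            raise LabelParseError(
                f"label {label!r}: removal count {n} != addition count {m}; "
                "substitution labels must balance"
            )
        target = match.group("tgt")
        if target not in CANONICAL_RESIDUES:
            raise LabelParseError(f"label {label!r}: unknown target residue {target!r}")
    return MutationSpec(source=source, target=target, count=n)


def format_variant_label(spec: MutationSpec) -> str:
    """Inverse of :func:`parse_variant_label` on well-formed specs."""
    if spec.target == "X":
        return f"-{spec.count}{spec.source}"
    return f"-{spec.count}{spec.source}+{spec.count}{spec.target}"


def infer_mutation(wt: PLDSequence, variant: PLDSequence) -> MutationSpec:
    """Recover the substitution set between equal-length sequences.

    Substitutions collapsing to one source->target pair give a plain spec.
    A single-class source with all targets among the weak replacement set
    is recognised as a composition-biased deletion (target ``"X"``).
    Anything else is returned flagged ``multi_type``.
    """
    if wt.length != variant.length:
        raise ValueError(
            f"length mismatch: {wt.id} has L={wt.length}, {variant.id} has "
            f"L={variant.length} (this dataset substitutes, never inserts/deletes)"
        )
    diffs = [
        (pos, a, b)
        for pos, (a, b) in enumerate(zip(wt.residues, variant.residues), start=1)
        if a != b
    ]
    if not diffs:
        return MutationSpec(source="", target="X", count=0, positions=(), multi_type=False)
    positions = tuple(pos for pos, _, _ in diffs)
    sources = sorted({a for _, a, _ in diffs})
    targets = sorted({b for _, _, b in diffs})
    source = "/".join(sources)
    if len(targets) == 1 and len(sources) == 1:
        return MutationSpec(source=source, target=targets[0], count=len(diffs),
                            positions=positions)
    source_classes = {classify_residue(a) for a in sources}
    if len(source_classes) == 1 and set(targets) <= set(WEAK_REPLACEMENTS):
        return MutationSpec(source=source, target="X", count=len(diffs),
                            positions=positions)
    return MutationSpec(source=source, target="/".join(targets), count=len(diffs),
                        positions=positions, multi_type=True)


# ---------------------------------------------------------------------------
# Variant design
# ---------------------------------------------------------------------------

def _largest_remainder(
    weights: Mapping[str, float], total: int, order: Sequence[str]
) -> dict[str, int]:
    """Apportion ``total`` among keys proportionally to ``weights``.

    Largest-remainder rounding; remainder ties broken by position in
    ``order``.
    """
    wsum = float(sum(weights.values()))
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    raw = {k: total * weights[k] / wsum for k in order if k in weights}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    by_remainder = sorted(
        raw, key=lambda k: (-(raw[k] - counts[k]), order.index(k))
    )
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def _evenly_spaced_indices(m: int, n: int) -> list[int]:
    # Quantiles of the occurrence list: round(j*(M-1)/(N-1)); single pick ->
    # the middle occurrence. Steps >= 1, so rounded picks never collide.
    if n == 0:
        return []
    if n == 1:
        return [round((m - 1) / 2)]
    return [round(j * (m - 1) / (n - 1)) for j in range(n)]


def design_variant(
    wt: PLDSequence, spec: MutationSpec, seed: int = 0
) -> PLDSequence:
    """Apply a mutation spec to a wild-type sequence.

    Exactly ``spec.count`` residues of the source set are replaced, at the
    evenly spaced quantiles of the source-occurrence list. For an ``"X"``
    target, replacement letters are drawn from the weak residues
    (Ser/Thr/Gly/Ala) with multiplicities proportional to their wild-type
    counts by largest-remainder rounding; the seed only shuffles which
    chosen position receives which replacement letter.
    """
    if spec.multi_type:
        raise ValueError("refusing a multi-type mutation spec")
    if spec.count == 0:
        return PLDSequence(id=f"{wt.id}_{format_variant_label(spec)}" if spec.source else wt.id,
                           residues=wt.residues)
    occurrences = [
        i for i, aa in enumerate(wt.residues) if aa in spec.source_set
    ]
    m = len(occurrences)
    if spec.count > m:
        raise ValueError(
            f"{wt.id}: spec asks for {spec.count} {spec.source} mutations but only "
            f"{m} such residues exist (deficit {spec.count - m})"
        )
    if spec.positions is not None:
        chosen = [p - 1 for p in spec.positions]
        for p in chosen:
            if p < 0 or p >= wt.length or wt.residues[p] not in spec.source_set:
                raise ValueError(f"position {p + 1} is not a {spec.source} residue")
    else:
        chosen = [occurrences[i] for i in _evenly_spaced_indices(m, spec.count)]

    if spec.target == "X":
        weights = {aa: wt.residues.count(aa) for aa in WEAK_REPLACEMENTS}
        if sum(weights.values()) == 0:
            weights = {aa: 1 for aa in WEAK_REPLACEMENTS}
        quota = _largest_remainder(weights, spec.count, WEAK_REPLACEMENTS)
        pool = [aa for aa in WEAK_REPLACEMENTS for _ in range(quota.get(aa, 0))]
        rng = np.random.default_rng(seed)
        replacements = [pool[i] for i in rng.permutation(len(pool))]
    else:
        replacements = [spec.target] * spec.count

    residues = list(wt.residues)
    for idx, new_aa in zip(chosen, replacements):
        residues[idx] = new_aa
    return PLDSequence(
        id=f"{wt.id}_{format_variant_label(spec)}", residues="".join(residues)
    )


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["variant_id", "wt_id", "label", "L", "N", "fraction"]


def write_variant_table(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write a variant table CSV (variant_id, wt_id, label, L, N, fraction)."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise ValueError(f"variant table rows missing columns: {missing}")
    df.to_csv(path, index=False, columns=_VARIANT_COLUMNS if len(df) else None)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns: {missing}")
    return df
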