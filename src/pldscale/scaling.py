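"""Mutation scaling laws for PLD critical temperatures.

Three ansaetze relate the critical-temperature shift delta_Tc of a variant
to its mutation count N and chain length L:

    count:     delta_Tc = S * N
    fraction:  delta_Tc = S * N / L
    sqrt:      delta_Tc = S * N / sqrt(L)

Each mutation class (e.g. Y->F, R->K) carries one fitted constant S under
one ansatz. Fits are through the origin — zero mutations force
delta_Tc = 0 — so R^2 is defined against the raw sum of squares,
R^2 = 1 - SS_res / sum(y^2). By the sign convention
delta_Tc = Tc(variant) - Tc(wild type), reversing a mutation pair flips
the sign of S.

The constants fitted on the published 140-variant direct-coexistence
dataset ship as package data (:data:`PUBLISHED_LAWS`) and are never
silently refit. Ansatz assignment there: count for Y->F, F/Y->W, S->T,
G->T, A->S; fraction for R->K, R->X, N->Q; sqrt for F/Y->X.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binodal import DeltaTc
from .sequence_tools import MutationSpec

__all__ = [
    "Ansatz",
    "ScalingLaw",
    "VariantObservation",
    "AnsatzSelection",
    "PUBLISHED_LAWS",
    "ansatz_x",
    "fit_scaling_constant",
    "select_ansatz",
    "normalize_pair",
    "reverse_pair",
    "lookup_law",
    "predict_delta_tc",
    "cumulative_prediction",
    "build_table1",
    "read_observation_csv",
    "write_observation_csv",
]


class Ansatz(str, Enum):
    COUNT = "count"
    FRACTION = "fraction"
    SQRT = "sqrt"


def ansatz_x(count: int, length: int, ansatz: Ansatz) -> float:
    """The ansatz variable x for N mutations in a chain of length L."""
    if length < 1:
        raise ValueError("chain length must be >= 1")
    if ansatz == Ansatz.COUNT:
        return float(count)
    if ansatz == Ansatz.FRACTION:
        return count / length
    if ansatz == Ansatz.SQRT:
        return count / math.sqrt(length)
    raise ValueError(f"unknown ansatz {ansatz!r}")


def normalize_pair(pair: str) -> str:
    """Canonical form of a mutation-pair label.

    Accepts unicode or ASCII arrows and any order of a multi-letter source
    alias: ``"Y/F→X"`` -> ``"F/Y->X"``.
    """
    text = pair.replace("→", "->").replace(" ", "")
    try:
        src, tgt = text.split("->")
    except ValueError:
        raise ValueError(f"cannot parse mutation pair label {pair!r}") from None
    src = "/".join(sorted(src.split("/")))
    tgt = "/".join(sorted(tgt.split("/")))
    return f"{src}->{tgt}"


def reverse_pair(pair: str) -> str:
    src, tgt = normalize_pair(pair).split("->")
    return f"{tgt}->{src}"


@dataclass(frozen=True)
class ScalingLaw:
    """A mutation-class scaling constant S (K per unit x) under one ansatz.

    ``S_err`` may be None for a single-observation fit (slope defined,
    uncertainty not). ``provenance`` is a free-text note on where the
    constant comes from (published fit vs refit on synthetic data).
    """

    pair: str
    ansatz: Ansatz
    S: float
    S_err: float | None = None
    r_squared: float | None = None
    provenance: str = ""

    def reversed(self) -> "ScalingLaw":
        """The antisymmetric law for the reversed mutation direction."""
        return ScalingLaw(
            pair=reverse_pair(self.pair), ansatz=self.ansatz, S=-self.S,
            S_err=self.S_err, r_squared=self.r_squared,
            provenance=self.provenance + " (direction reversed)",
        )


@dataclass(frozen=True)
class VariantObservation:
    """One measured variant: mutation class, N, L, and its delta_Tc."""

    variant_id: str
    pair: str
    count: int
    length: int
    delta_tc: float
    delta_tc_err: float | None = None
    multi_type: bool = False

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("observation must have at least one mutation")
        if self.length < self.count:
            raise ValueError("chain length must be >= mutation count")


def _load_published() -> dict[str, ScalingLaw]:
    text = (
        resources.files("pldscale").joinpath("data/published_scaling_laws.json")
        .read_text()
    )
    doc = json.loads(text)
    laws: dict[str, ScalingLaw] = {}
    for entry in doc["laws"]:
        if entry["S"] is None:
            continue  # represented classes with no constant are refused downstream
        pair = normalize_pair(entry["pair"])
        laws[pair] = ScalingLaw(
            pair=pair, ansatz=Ansatz(entry["ansatz"]), S=float(entry["S"]),
            S_err=float(entry["S_err"]), r_squared=entry["r_squared"],
            provenance=entry.get("note", "published constant"),
        )
    return laws


#: Published per-class constants, keyed by canonical pair label.
PUBLISHED_LAWS: dict[str, ScalingLaw] = _load_published()

#: Classes acknowledged in the source dataset but without a fitted
#: constant; predictions refuse them explicitly.
REPRESENTED_WITHOUT_CONSTANT = frozenset({"G->S"})


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_scaling_constant(
    data: Sequence[VariantObservation], ansatz: Ansatz
) -> ScalingLaw:
    """Through-origin least squares of delta_Tc on the ansatz variable.

    S = sum(x*y) / sum(x^2); the slope standard error uses the residual
    variance with n-1 degrees of freedom (no intercept). R^2 is computed
    against sum(y^2), the correct baseline for a no-intercept model.
    """
    if not data:
        raise ValueError("no observations")
    pairs = {normalize_pair(obs.pair) for obs in data}
    if len(pairs) != 1:
        raise ValueError(f"mixed mutation pairs in one fit: {sorted(pairs)}")
    if any(obs.multi_type for obs in data):
        raise ValueError("refusing observations flagged multi-type")
    pair = pairs.pop()

    x = np.array([ansatz_x(obs.count, obs.length, ansatz) for obs in data])
    y = np.array([obs.delta_tc for obs in data])
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all ansatz variables are zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    n = len(data)
    if n > 1:
        s2 = float(resid @ resid) / (n - 1)
        s_err = math.sqrt(s2 / sxx)
    else:
        s_err = None
    syy = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    return ScalingLaw(pair=pair, ansatz=ansatz, S=slope, S_err=s_err,
                      r_squared=r2, provenance=f"through-origin fit, n={n}")


@dataclass(frozen=True)
class AnsatzSelection:
    """All three candidate fits plus the R^2 maximizer (if identifiable)."""

    laws: Mapping[Ansatz, ScalingLaw]
    best: Ansatz | None
    indistinguishable: bool


def select_ansatz(data: Sequence[VariantObservation]) -> AnsatzSelection:
    """Fit all three ansaetze and flag the R^2 maximizer.

    With a single chain length L in the data the three design vectors are
    exactly proportional and the fits are equivalent up to rescaling of S;
    no winner is declared (``indistinguishable=True``).
    """
    laws = {a: fit_scaling_constant(data, a) for a in Ansatz}
    lengths = {obs.length for obs in data}
    if len(lengths) < 2:
        return AnsatzSelection(laws=laws, best=None, indistinguishable=True)
    best = max(laws, key=lambda a: laws[a].r_squared)
    return AnsatzSelection(laws=laws, best=best, indistinguishable=False)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def lookup_law(pair: str, laws: Mapping[str, ScalingLaw] | None = None) -> ScalingLaw:
    """Find the law for a pair, applying the antisymmetric flip if only
    the reversed direction is on file."""
    table = PUBLISHED_LAWS if laws is None else laws
    key = normalize_pair(pair)
    if key in REPRESENTED_WITHOUT_CONSTANT or reverse_pair(key) in REPRESENTED_WITHOUT_CONSTANT:
        raise ValueError(
            f"mutation class {key} is represented in the dataset but has no "
            "fitted constant; refusing to predict"
        )
    if key in table:
        return table[key]
    rkey = reverse_pair(key)
    if rkey in table:
        return table[rkey].reversed()
    raise ValueError(f"no scaling law on file for mutation pair {key}")


def predict_delta_tc(
    spec: MutationSpec | None,
    length: int,
    law: ScalingLaw | None = None,
    pair: str | None = None,
    count: int | None = None,
) -> DeltaTc:
    """Predicted critical-temperature shift S*x with error |x|*S_err.

    Either pass a bound :class:`MutationSpec` (with ``length``), or pass
    ``pair``/``count`` explicitly. When ``law`` is omitted the published
    constant for the pair is used (reversed direction handled by the
    antisymmetry of S).
    """
    if spec is not None:
        if spec.multi_type:
            raise ValueError("refusing a multi-type mutation spec")
        pair = spec.pair
        count = spec.count
    if pair is None or count is None:
        raise ValueError("need either a MutationSpec or pair and count")
    if count == 0:
        return DeltaTc(value=0.0, error=0.0)
    if law is None:
        law = lookup_law(pair)
    elif normalize_pair(law.pair) != normalize_pair(pair):
        if normalize_pair(reverse_pair(law.pair)) == normalize_pair(pair):
            law = law.reversed()
        else:
            raise ValueError(
                f"law is for pair {law.pair}, spec is {pair}"
            )
    x = ansatz_x(count, length, law.ansatz)
    err = abs(x) * law.S_err if law.S_err is not None else 0.0
    return DeltaTc(value=law.S * x, error=err)


def cumulative_prediction(
    specs: Iterable[MutationSpec],
    length: int,
    laws: Mapping[str, ScalingLaw] | None = None,
) -> DeltaTc:
    """Additive combination of per-class predictions.

    The laws are cumulative: successive mutations of different classes
    contribute the sum of their individual shifts, with errors combined in
    quadrature. Empty input gives 0 +/- 0.
    """
    total = 0.0
    var = 0.0
    for spec in specs:
        law = lookup_law(spec.pair, laws)
        pred = predict_delta_tc(spec, length, law=law)
        total += pred.value
        var += pred.error ** 2
    return DeltaTc(value=total, error=math.sqrt(var))


_TABLE1_PAIRS = (
    "Y->F", "F/Y->W", "F/Y->X", "R->K", "R->X", "N->Q", "S->T", "G->T", "A->S",
)


def build_table1(
    laws: Mapping[str, ScalingLaw] | None = None,
    lengths: Sequence[int] = (100, 200, 300),
) -> pd.DataFrame:
    """Single-point-mutation (N=1) prediction grid over chain lengths.

    Returns a long-form DataFrame with columns pair, L, delta_tc_K,
    err_K — the unrounded values behind the conventional summary table.
    """
    table = PUBLISHED_LAWS if laws is None else laws
    rows = []
    for pair in _TABLE1_PAIRS:
        law = lookup_law(pair, table)
        for L in lengths:
            pred = predict_delta_tc(None, L, law=law, pair=pair, count=1)
            rows.append({"pair": pair, "L": L,
                         "delta_tc_K": pred.value, "err_K": pred.error})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_observation_csv(path) -> list[VariantObservation]:
    """Read observations from CSV: variant_id, pair, N, L, delta_tc[, delta_tc_err]."""
    df = pd.read_csv(path)
    needed = {"variant_id", "pair", "N", "L", "delta_tc"}
    if not needed <= set(df.columns):
        raise ValueError(f"observation CSV {path} missing columns {needed - set(df.columns)}")
    obs = []
    for _, row in df.iterrows():
        err = row.get("delta_tc_err")
        obs.append(VariantObservation(
            variant_id=str(row["variant_id"]), pair=normalize_pair(str(row["pair"])),
            count=int(row["N"]), length=int(row["L"]),
            delta_tc=float(row["delta_tc"]),
            delta_tc_err=None if err is None or pd.isna(err) else float(err),
        ))
    return obs


def write_observation_csv(observations: Iterable[VariantObservation], path) -> None:
    pd.DataFrame(
        [
            {"variant_id": o.variant_id, "pair": o.pair, "N": o.count,
             "L": o.length, "delta_tc": o.delta_tc, "delta_tc_err": o.delta_tc_err}
            for o in observations
        ]
    ).to_csv(path, index=False)
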