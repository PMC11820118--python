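"""End-to-end pipeline: coexistence tables -> critical fits -> delta_Tc ->
scaling fits -> predictions -> report.

The pipeline consumes the same on-disk schemas the individual stages
read: a FASTA of sequences, a variant table CSV (variant_id, wt_id,
label, L, N, fraction), and one coexistence CSV per variant id. It
produces per-variant critical fits, delta_Tc against each wild type,
per-class scaling fits under all three ansaetze with R^2, a sigma_aro
table, and a single-mutation prediction grid from the published
constants, bundled as JSON + CSV with stage timings.

:func:`generate_synthetic_study` writes a complete synthetic input set
(with its generating truths) so the whole chain can be exercised and its
parameter recovery checked without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binodal as bd
from . import scaling as sc
from . import sequence_tools as st
from . import synthetic_data as sd
from .patterning import analyze_patterning

__all__ = ["RunConfig", "run_pipeline", "generate_synthetic_study"]

logger = logging.getLogger("pldscale")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable pipeline configuration.

    For deterministic stages, (config, inputs) determine the outputs
    bit-for-bit; stochastic stages record their seeds in the report.
    """

    fasta: str | None = None
    variant_table: str | None = None
    points_dir: str | None = None
    out_dir: str = "pldscale_out"
    windows: tuple[int, ...] = (5, 6)
    histidine_charge: float = 0.0
    weighted_fits: bool = True
    tmax_frac: float | None = None
    table_lengths: tuple[int, ...] = (100, 200, 300)
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _stage(report: dict, name: str, started: float) -> None:
    elapsed = time.perf_counter() - started
    report.setdefault("stage_timings_s", {})[name] = round(elapsed, 6)
    logger.info("stage %s finished in %.3f s", name, elapsed)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the inputs support and write the report bundle.

    Stages with missing inputs are skipped and recorded as such; any
    stage failure raises with the stage name attached, after partial
    outputs are written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "seed": config.seed}

    sequences: list[st.PLDSequence] = []
    stage = "read_sequences"
    t0 = time.perf_counter()
    try:
        if config.fasta:
            sequences = st.read_fasta(config.fasta)
        _stage(report, stage, t0)

        # sigma_aro table
        stage = "patterning"
        t0 = time.perf_counter()
        pat_rows = []
        for seq in sequences:
            res = analyze_patterning(seq, windows=config.windows)
            for w in res.windows:
                pat_rows.append({
                    "seq_id": seq.id, "l": w.window, "sigma_aro": w.sigma_aro,
                    "n_stickers": w.n_stickers, "n_aro": w.n_aro,
                })
        if pat_rows:
            pd.DataFrame(pat_rows).to_csv(out / "sigma_aro.csv", index=False)
        report["sigma_aro"] = pat_rows
        _stage(report, stage, t0)

        # per-variant critical fits
        stage = "critical_fits"
        t0 = time.perf_counter()
        fits: dict[str, bd.CriticalPoint] = {}
        variants = None
        if config.variant_table and config.points_dir:
            variants = st.read_variant_table(config.variant_table)
            points_dir = Path(config.points_dir)
            ids = list(variants["variant_id"]) + sorted(set(variants["wt_id"]))
            for vid in dict.fromkeys(ids):  # preserve order, unique
                path = points_dir / f"{vid}.csv"
                if not path.exists():
                    raise FileNotFoundError(f"stage {stage}: no coexistence table {path}")
                pts = bd.read_coexistence_csv(path)
                fits[vid] = bd.fit_critical_point(
                    pts, weighted=config.weighted_fits, tmax_frac=config.tmax_frac
                )
            report["critical_fits"] = {
                vid: {"Tc": cp.Tc, "Tc_err": cp.Tc_err, "rho_c": cp.rho_c,
                      "d": cp.d, "A": cp.A}
                for vid, cp in fits.items()
            }
        _stage(report, stage, t0)

        # delta_Tc vs wild type + observation table
        stage = "delta_tc"
        t0 = time.perf_counter()
        observations: list[sc.VariantObservation] = []
        if variants is not None:
            rows = []
            for _, row in variants.iterrows():
                vid, wid = str(row["variant_id"]), str(row["wt_id"])
                shift = bd.delta_tc(fits[vid], fits[wid])
                spec = st.parse_variant_label(str(row["label"]))
                rows.append({
                    "variant_id": vid, "wt_id": wid, "pair": spec.pair,
                    "N": int(row["N"]), "L": int(row["L"]),
                    "delta_tc": shift.value, "delta_tc_err": shift.error,
                })
                observations.append(sc.VariantObservation(
                    variant_id=vid, pair=spec.pair, count=int(row["N"]),
                    length=int(row["L"]), delta_tc=shift.value,
                    delta_tc_err=shift.error,
                ))
            pd.DataFrame(rows).to_csv(out / "delta_tc.csv", index=False)
            report["delta_tc"] = rows
        _stage(report, stage, t0)

        # per-pair scaling fits, all three ansaetze
        stage = "scaling_fits"
        t0 = time.perf_counter()
        scaling_report = {}
        by_pair: dict[str, list[sc.VariantObservation]] = {}
        for obs in observations:
            by_pair.setdefault(obs.pair, []).append(obs)
        for pair, group in by_pair.items():
            if len(group) < 2:
                scaling_report[pair] = {"skipped": "fewer than 2 observations"}
                continue
            sel = sc.select_ansatz(group)
            scaling_report[pair] = {
                "best": sel.best.value if sel.best else None,
                "indistinguishable": sel.indistinguishable,
                "fits": {
                    a.value: {"S": law.S, "S_err": law.S_err, "r_squared": law.r_squared}
                    for a, law in sel.laws.items()
                },
            }
        report["scaling_fits"] = scaling_report
        _stage(report, stage, t0)

        # published-constant prediction grid
        stage = "prediction_grid"
        t0 = time.perf_counter()
        grid = sc.build_table1(lengths=config.table_lengths)
        grid.to_csv(out / "prediction_grid.csv", index=False)
        report["prediction_grid"] = grid.to_dict(orient="records")
        _stage(report, stage, t0)
    except Exception as exc:
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def generate_synthetic_study(
    out_dir: str | Path,
    seed: int = 0,
    n_variants_per_family: int = 4,
    noise_sd_profile: float = 0.01,
    binodal_noise_sd: float = 0.0,
    families: tuple[str, ...] = ("Y->F", "F/Y->X", "N->Q"),
) -> dict:
    """Write a self-contained synthetic study the pipeline can consume.

    One wild-type plus ``n_variants_per_family`` variants per mutation
    class. Each system gets a coexistence CSV generated from a known
    critical point: the wild type at Tc = 400 K, each variant shifted by
    the published scaling law for its class (so downstream recovery can
    be checked against the generating constants). Truth JSONs are written
    beside the data. Returns a manifest dict.
    """
    out = Path(out_dir)
    points = out / "points"
    points.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    wt_truth = sd.SequenceTruth(length=200, seed=seed)
    wt = sd.synth_pld_sequence(wt_truth, seq_id="WT")
    sequences = [wt]
    rows = []
    wt_binodal = sd.BinodalTruth(noise_sd=binodal_noise_sd, seed=seed)
    bd.write_coexistence_csv(sd.synth_coexistence_points(wt_binodal), points / "WT.csv")
    (points / "WT.truth.json").write_text(sd.truth_to_json(wt_binodal))

    for pair in families:
        law = sc.lookup_law(pair)
        src = pair.split("->")[0].split("/")
        available = wt.count(src)
        counts = sorted({max(1, min(available, 2 * k))
                         for k in range(1, n_variants_per_family + 1)})
        for n_mut in counts:
            spec = st.MutationSpec(source="/".join(src), target=pair.split("->")[1],
                                   count=n_mut)
            var = st.design_variant(wt, spec, seed=int(rng.integers(0, 2**31 - 1)))
            # ids become file names; drop the slash of multi-letter aliases
            var = st.PLDSequence(id=var.id.replace("/", ""), residues=var.residues)
            sequences.append(var)
            shift = sc.predict_delta_tc(None, wt.length, law=law, pair=pair, count=n_mut)
            vb = sd.BinodalTruth(
                Tc=wt_binodal.Tc + shift.value,
                temperatures=tuple(t for t in wt_binodal.temperatures
                                   if t < wt_binodal.Tc + shift.value - 5.0),
                noise_sd=binodal_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            bd.write_coexistence_csv(sd.synth_coexistence_points(vb),
                                     points / f"{var.id}.csv")
            (points / f"{var.id}.truth.json").write_text(sd.truth_to_json(vb))
            rows.append({
                "variant_id": var.id, "wt_id": "WT",
                "label": st.format_variant_label(spec), "L": wt.length,
                "N": n_mut, "fraction": n_mut / wt.length,
            })

    st.write_fasta(sequences, out / "sequences.fasta")
    st.write_variant_table(rows, out / "variants.csv")
    manifest = {
        "seed": seed,
        "fasta": str(out / "sequences.fasta"),
        "variant_table": str(out / "variants.csv"),
        "points_dir": str(points),
        "wt_truth": json.loads(sd.truth_to_json(wt_binodal)),
        "families": list(families),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
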