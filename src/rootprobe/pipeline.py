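"""End-to-end orchestration: simulate → analyze → summarise, reproducibly.

`analyze_cohort` turns a set of per-root trace pairs into a per-root
parameter table and a group summary (mean ± SD, n, two-sample t-test between
groups) in the layout of a transport-parameter table: hydrostatic and osmotic
Lpr in 10⁻⁸ m s⁻¹ MPa⁻¹, Psr in 10⁻⁹ m s⁻¹ and σ dimensionless.

`run_pipeline` drives a full synthetic study from one config + seed: probe
cohort, suberin tables with ANOVA/LSD letters, and a TPM demonstration,
writing CSV tables, a versioned results JSON, and a run manifest into the
output directory.  Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import suberin as sub
from .forward import LN2, xylem_volume
from .inverse import (
    NoMinimumError,
    analyze_osmotic_trace,
    fit_exponential_phase,
    hydraulic_conductivity,
)
from .stats import GroupSamples, anova_fisher_lsd, tpm, two_sample_t
from .synth import generate_counts, generate_monomer_table, generate_probe_traces
from .traceio import default_config, geometry_from_config, probe_from_config

__all__ = ["analyze_cohort", "suberin_study", "run_pipeline"]

RESULTS_SCHEMA_VERSION = "1"


def analyze_cohort(cohort: dict, cfg: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse-analyse every root of a simulated (or loaded) probe cohort.

    Returns (per_root, summary): per-root estimates of t½w, hydrostatic and
    osmotic Lpr, Psr and σ, and the per-group mean ± SD with the two-sample
    t-test verdict against the first group.
    """
    cfg = default_config() if cfg is None else cfg
    probe = probe_from_config(cfg)
    geom = geometry_from_config(cfg)
    vx = xylem_volume(geom)

    rows = []
    for root in cohort["roots"]:
        hydro_fit = fit_exponential_phase(root["hydrostatic"])
        lpr_h = hydraulic_conductivity(hydro_fit.half_time, probe.Ar, probe.beta)
        row = {
            "root_id": root["root_id"],
            "group": root["group"],
            "t_half_w_s": hydro_fit.half_time,
            "Lpr_hydrostatic": lpr_h,
            "qc": "pass",
        }
        try:
            osmo = analyze_osmotic_trace(root["osmotic"], probe, geom)
            row.update({
                "t_half_s_s": osmo["decomposition"].solute_fit.half_time,
                "Lpr_osmotic": osmo["Lpr_osmotic"],
                "Psr": osmo["Psr"],
                "sigma": osmo["sigma"],
                "deltaPr_mpa": osmo["deltaPr"],
                "tmin_s": osmo["tmin"],
            })
        except NoMinimumError:
            row.update({"t_half_s_s": np.nan, "Lpr_osmotic": np.nan,
                        "Psr": np.nan, "sigma": np.nan,
                        "deltaPr_mpa": np.nan, "tmin_s": np.nan,
                        "qc": "no_minimum"})
        rows.append(row)
    per_root = pd.DataFrame(rows)

    display = {
        "Lpr_hydrostatic": ("Hydrostatic Lpr (1e-8 m/s/MPa)", 1e8),
        "Lpr_osmotic": ("Osmotic Lpr (1e-8 m/s/MPa)", 1e8),
        "Psr": ("Solute permeability Psr (1e-9 m/s)", 1e9),
        "sigma": ("Reflection coefficient sigma (-)", 1.0),
    }
    groups = list(dict.fromkeys(per_root["group"]))
    ref = groups[0]
    summary_rows = []
    for col, (label, scale) in display.items():
        entry: dict = {"parameter": label}
        for g in groups:
            vals = per_root.loc[per_root["group"] == g, col].dropna().to_numpy() * scale
            entry[f"{g}_mean"] = vals.mean() if vals.size else np.nan
            entry[f"{g}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            entry[f"{g}_n"] = int(vals.size)
        for g in groups[1:]:
            a = per_root.loc[per_root["group"] == ref, col].dropna().to_numpy()
            b = per_root.loc[per_root["group"] == g, col].dropna().to_numpy()
            if a.size >= 2 and b.size >= 2:
                t, df, p, verdict = two_sample_t(a, b)
                entry[f"{g}_vs_{ref}_p"] = p
                entry[f"{g}_vs_{ref}"] = verdict
        summary_rows.append(entry)
    return per_root, pd.DataFrame(summary_rows)


def suberin_study(records: pd.DataFrame, areas: dict[str, float], alpha: float = 0.05):
    """Aggregate a monomer table and letter the treatments within each zone.

    Returns (per_replicate, summary, letters) where ``letters`` maps zone →
    treatment → letter string for the total-aliphatic comparison.
    """
    per_rep = sub.aggregate_amounts(records, areas)
    summary = sub.group_summary(per_rep)
    letters: dict[str, dict[str, str]] = {}
    for zone, zdf in per_rep.groupby("zone"):
        groups = [
            GroupSamples(str(tr), tdf["total_aliphatic"].to_numpy())
            for tr, tdf in zdf.groupby("treatment")
            if len(tdf) >= 2
        ]
        if len(groups) >= 2:
            letters[str(zone)] = anova_fisher_lsd(groups, alpha=alpha).letters
    return per_rep, summary, letters


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(outdir: str | Path, config: dict | None = None, seed: int = 0) -> Path:
    """Run the full synthetic study and write tables + results JSON + manifest.

    Stages: probe cohort simulation and inverse analysis; suberin table
    generation, aggregation and LSD lettering; TPM on a synthetic count
    matrix.  Any stage error propagates after partial outputs are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config() if config is None else config

    # stage 1: probe transport
    cohort = generate_probe_traces(cfg, seed=seed)
    per_root, summary = analyze_cohort(cohort, cfg)
    per_root.to_csv(outdir / "per_root_parameters.csv", index=False)
    summary.to_csv(outdir / "transport_summary.csv", index=False)

    # stage 2: suberin chemistry
    records, sub_manifest = generate_monomer_table(seed=seed + 1)
    per_rep, sub_summary, letters = suberin_study(records, sub_manifest["areas_cm2"])
    records.to_csv(outdir / "suberin_monomers.csv", index=False)
    per_rep.to_csv(outdir / "suberin_per_replicate.csv", index=False)
    sub_summary.to_csv(outdir / "suberin_summary.csv", index=False)

    # stage 3: expression summary
    counts, lengths = generate_counts(seed=seed + 2)
    tpm_table = pd.DataFrame(
        {c: tpm(counts[c].to_numpy(), lengths.to_numpy()) for c in counts.columns},
        index=counts.index,
    )
    tpm_table.to_csv(outdir / "tpm.csv")

    results = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "seed": seed,
        "config_hash": _hash_config(cfg),
        "transport": {
            row["parameter"]: {k: v for k, v in row.items() if k != "parameter"}
            for row in summary.to_dict("records")
        },
        "suberin_letters": letters,
        "tpm_colsums": {c: float(tpm_table[c].sum()) for c in tpm_table.columns},
    }
    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    manifest = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "seed": seed,
        "config_hash": _hash_config(cfg),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "run_manifest.json"),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
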