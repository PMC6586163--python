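"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the three experimental data streams:

* **Probe traces** — per treatment group, each root draws its transport
  triple (Lpr, Psr, σ) from the group mean ± SD (Gaussian, truncated to the
  physical ranges by resampling, never by clipping); a hydrostatic relaxation
  and a biphasic osmotic response are then simulated with the closed-form
  forward model and Gaussian sensor noise is added.  A manifest records the
  ground-truth parameters of every root.

* **Suberin monomer tables** — per (zone, treatment, replicate), class totals
  follow configured per-area means with a strong basipetal gradient (zone C
  ≈ 10-fold zone A for diacids and ω-OH acids, ≈ 2-fold for alcohols and
  fatty acids) and a ≈ 2-fold aliphatic increase under osmotic stress of
  −0.8 MPa or stronger in the mid and basal zones; replicate noise is
  lognormal (multiplicative, mean 1, configurable CV) as befits strictly
  positive amounts.  Class totals are distributed over fixed C16–C26
  homologue weights.

* **Count matrices** — negative-binomial counts over a configurable gene set
  with known transcript lengths, as a fixture for TPM summaries.

All generators are pure functions of (config, seed): a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import (
    PressureTrace,
    ProbeSystem,
    RootGeometry,
    TransportParams,
    simulate_hydrostatic_relaxation,
    simulate_osmotic_response,
)
from .osmoticum import vant_hoff_osmotic_pressure
from .suberin import endodermal_surface_area
from .traceio import (
    default_config,
    geometry_from_config,
    probe_from_config,
    write_trace_csv,
)

__all__ = [
    "truncated_normal",
    "generate_probe_traces",
    "write_probe_cohort",
    "default_suberin_config",
    "generate_monomer_table",
    "generate_counts",
]

TREATMENTS = ("control", "-0.4MPa", "-0.8MPa", "-1.2MPa")


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
    max_tries: int = 10000,
) -> float:
    """Gaussian draw truncated to (low, high) by resampling (no boundary atoms)."""
    if sd == 0:
        if not low < mean < high:
            raise ValueError("degenerate draw outside bounds")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError("truncated sampling failed; bounds too tight for mean/sd")


def _draw_params(rng: np.random.Generator, g: dict) -> TransportParams:
    return TransportParams(
        Lpr=truncated_normal(rng, g["Lpr"], g.get("Lpr_sd", 0.0), low=0.0),
        Psr=truncated_normal(rng, g["Psr"], g.get("Psr_sd", 0.0), low=0.0),
        sigma=truncated_normal(rng, g["sigma"], g.get("sigma_sd", 0.0), low=0.0, high=1.0),
    )


def _add_noise(trace: PressureTrace, rng: np.random.Generator, sd: float) -> PressureTrace:
    if sd == 0:
        return trace
    noisy = trace.pressure + rng.normal(0.0, sd, size=trace.n)
    return PressureTrace(trace.time, noisy, trace.event_kind, trace.event_magnitude,
                         dict(trace.meta))


def generate_probe_traces(config: dict | None = None, seed: int = 0) -> dict:
    """Simulate a pressure-probe cohort for every configured treatment group.

    Returns ``{"roots": [...], "manifest": {...}}`` where each root entry
    holds its id, group, ground-truth :class:`TransportParams`, and the
    simulated hydrostatic and osmotic :class:`PressureTrace` pair.
    """
    cfg = default_config() if config is None else config
    rng = np.random.default_rng(seed)
    probe = probe_from_config(cfg)
    geom = geometry_from_config(cfg)
    exp = cfg["experiment"]
    delta_pi = vant_hoff_osmotic_pressure(
        exp["osmolality_step_mosmol_kg"], exp["temperature_c"]
    )
    noise_sd = float(exp.get("noise_sd_mpa", 0.0))

    roots = []
    for group, gcfg in cfg["groups"].items():
        for i in range(int(exp["n_roots"])):
            params = _draw_params(rng, gcfg)
            hydro = simulate_hydrostatic_relaxation(
                params, probe, exp["P_ss_mpa"], exp["deltaP0_mpa"],
                exp["hydrostatic_duration_s"], exp["hydrostatic_dt_s"],
            )
            osmo = simulate_osmotic_response(
                params, probe, geom, exp["P_ss_mpa"], delta_pi,
                exp["osmotic_duration_s"], exp["osmotic_dt_s"],
            )
            roots.append({
                "root_id": f"{group}_root{i + 1:02d}",
                "group": group,
                "true_params": params,
                "hydrostatic": _add_noise(hydro, rng, noise_sd),
                "osmotic": _add_noise(osmo, rng, noise_sd),
            })
    manifest = {
        "seed": seed,
        "delta_pi_mpa": delta_pi,
        "noise_sd_mpa": noise_sd,
        "probe": {"beta": probe.beta, "Ar": probe.Ar},
        "truth": {
            r["root_id"]: {
                "group": r["group"],
                "Lpr": r["true_params"].Lpr,
                "Psr": r["true_params"].Psr,
                "sigma": r["true_params"].sigma,
            }
            for r in roots
        },
    }
    return {"roots": roots, "manifest": manifest}


def write_probe_cohort(cohort: dict, outdir: str | Path) -> list[Path]:
    """Write every trace as CSV plus a ground-truth manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for root in cohort["roots"]:
        for kind in ("hydrostatic", "osmotic"):
            path = outdir / f"{root['root_id']}_{kind}.csv"
            write_trace_csv(root[kind], path)
            written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(cohort["manifest"], indent=2, sort_keys=True))
    written.append(manifest_path)
    return written


# --- suberin tables ---------------------------------------------------------

#: Fixed homologue weights per aliphatic class (C18:1 diacid and C18:1/C24
#: ω-OH acids dominate their classes, chain lengths span C16–C26).
_HOMOLOGUES: dict[str, list[tuple[str, float]]] = {
    "alcohol": [("C18 alcohol", 0.4), ("C20 alcohol", 0.35), ("C22 alcohol", 0.25)],
    "fatty_acid": [("C16 fatty acid", 0.3), ("C18 fatty acid", 0.25),
                   ("C20 fatty acid", 0.2), ("C22 fatty acid", 0.15),
                   ("C24 fatty acid", 0.1)],
    "diacid": [("C16 diacid", 0.2), ("C18:1 diacid", 0.55), ("C18 diacid", 0.25)],
    "omega_oh_acid": [("C16 ω-OH acid", 0.15), ("C18:1 ω-OH acid", 0.35),
                      ("C22 ω-OH acid", 0.15), ("C24 ω-OH acid", 0.30),
                      ("C26 ω-OH acid", 0.05)],
    "coumaric_acid": [("coumaric acid", 1.0)],
    "ferulic_acid": [("ferulic acid", 1.0)],
}


def default_suberin_config() -> dict:
    """Synthetic suberin study configuration.

    Per-area aliphatic totals rise basipetally (0.6 / 1.5 / 3.3 μg cm⁻² in
    zones A/B/C under control conditions) with zone shares chosen so the
    basipetal fold changes are ≈ 2 for alcohols and fatty acids and ≈ 10 for
    diacids and ω-OH acids; osmotic stress of −0.8 MPa or stronger doubles
    the zone-B aliphatic total, and every stress level doubles zone C (peak
    ≈ 7 μg cm⁻² aliphatic).  Aromatic totals are twice the control aliphatic
    total of the zone and treatment-independent.  Three lognormal replicates
    per cell, CV 0.15.
    """
    return {
        "n_replicates": 3,
        "cv": 0.15,
        "endodermis_radius_cm": 0.02,
        "zone_lengths_cm": {"A": 3.0, "B": 3.0, "C": 6.0},
        "aliphatic_total": {"A": 0.6, "B": 1.5, "C": 3.3},  # μg cm⁻², control
        "class_shares": {
            "A": {"fatty_acid": 0.33, "alcohol": 0.09,
                  "diacid": 0.09, "omega_oh_acid": 0.49},
            "B": {"fatty_acid": 0.20, "alcohol": 0.06,
                  "diacid": 0.14, "omega_oh_acid": 0.60},
            "C": {"fatty_acid": 0.12, "alcohol": 0.04,
                  "diacid": 0.18, "omega_oh_acid": 0.66},
        },
        "stress_multiplier": {
            "A": {"control": 1.0, "-0.4MPa": 1.0, "-0.8MPa": 1.0, "-1.2MPa": 1.0},
            "B": {"control": 1.0, "-0.4MPa": 1.0, "-0.8MPa": 2.0, "-1.2MPa": 2.0},
            "C": {"control": 1.0, "-0.4MPa": 2.0, "-0.8MPa": 2.0, "-1.2MPa": 2.0},
        },
        "aromatic_over_aliphatic": 2.0,  # × control aliphatic total, per zone
        "aromatic_shares": {"coumaric_acid": 0.4, "ferulic_acid": 0.6},
        "treatments": list(TREATMENTS),
    }


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(-0.5 * s2, math.sqrt(s2)))


def generate_monomer_table(
    config: dict | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy monomer table plus its ground-truth manifest.

    Returns (records, manifest): ``records`` has columns ``compound_label,
    amount_ug, zone, treatment, replicate`` (amounts in μg per sample, i.e.
    per-area class mean × zone area × lognormal factor, split over homologue
    weights); ``manifest`` carries the per-zone areas and the true per-area
    class means per (zone, treatment).
    """
    cfg = default_suberin_config() if config is None else config
    rng = np.random.default_rng(seed)
    areas = {
        z: endodermal_surface_area(cfg["endodermis_radius_cm"], length)
        for z, length in cfg["zone_lengths_cm"].items()
    }

    rows = []
    truth: dict[str, dict] = {}
    for zone in ("A", "B", "C"):
        shares = cfg["class_shares"][zone]
        for treatment in cfg["treatments"]:
            mult = cfg["stress_multiplier"][zone][treatment]
            ali_total = cfg["aliphatic_total"][zone] * mult
            aro_total = cfg["aliphatic_total"][zone] * cfg["aromatic_over_aliphatic"]
            class_means = {cls: ali_total * shares[cls] for cls in shares}
            for cls, share in cfg["aromatic_shares"].items():
                class_means[cls] = aro_total * share
            truth[f"{zone}/{treatment}"] = {
                "area_cm2": areas[zone],
                "class_means_ug_cm2": class_means,
                "total_aliphatic_ug_cm2": ali_total,
                "total_aromatic_ug_cm2": aro_total,
            }
            for rep in range(1, int(cfg["n_replicates"]) + 1):
                for cls, mean in class_means.items():
                    factor = _lognormal_factor(rng, cfg["cv"])
                    class_amount_ug = mean * areas[zone] * factor
                    for label, weight in _HOMOLOGUES[cls]:
                        rows.append({
                            "compound_label": label,
                            "amount_ug": class_amount_ug * weight,
                            "zone": zone,
                            "treatment": treatment,
                            "replicate": f"rep{rep}",
                        })
    records = pd.DataFrame(rows)
    manifest = {"seed": seed, "areas_cm2": areas, "truth": truth}
    return records, manifest


def generate_counts(
    n_genes: int = 200,
    n_samples: int = 3,
    seed: int = 0,
    mean_expression: float = 200.0,
    dispersion: float = 0.3,
    boosted_gene: int | None = None,
    boost_factor: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix plus transcript lengths (bp).

    Per-gene expected counts are lognormal around ``mean_expression`` scaled
    by transcript length; ``boosted_gene`` (row index) is set to
    ``boost_factor`` times the largest base concentration, so it ranks first
    in TPM by construction.
    Returns (counts DataFrame genes × samples, lengths Series).
    """
    rng = np.random.default_rng(seed)
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes),
        index=[f"gene{i:04d}" for i in range(n_genes)],
        name="length_bp",
    )
    base_conc = rng.lognormal(0.0, 1.0, size=n_genes)
    if boosted_gene is not None:
        base_conc[boosted_gene] = boost_factor * base_conc.max()
    mu = mean_expression * base_conc / base_conc.mean() * lengths.to_numpy() / 1000.0
    # NB via gamma-Poisson mixture with shape 1/dispersion
    shape = 1.0 / dispersion
    counts = {}
    for j in range(n_samples):
        lam = rng.gamma(shape, mu / shape)
        counts[f"sample{j + 1}"] = rng.poisson(lam)
    return pd.DataFrame(counts, index=lengths.index), lengths
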