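"""File formats: trace CSV, monomer CSV, YAML configuration.

Trace CSV layout: comment lines starting with ``#`` carry ``key=value`` event
metadata (at minimum ``event_kind`` and ``event_magnitude_mpa``; time zero is
defined at the annotated event sample), followed by a header row and the two
columns ``time_s, pressure_mpa``.

The YAML configuration gathers probe constants (β, Ar), root geometry, and
transport parameter sets per treatment group; `load_config` materialises them
into the package's typed objects.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forward import PressureTrace, ProbeSystem, RootGeometry, TransportParams

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "read_monomer_csv",
    "load_config",
    "default_config",
    "probe_from_config",
    "geometry_from_config",
    "params_from_group",
]

_META_KEYS = ("event_kind", "event_magnitude_mpa")


def write_trace_csv(trace: PressureTrace, path: str | Path) -> None:
    """Write a trace with `#` metadata header lines and time/pressure columns."""
    path = Path(path)
    lines = [
        f"# event_kind={trace.event_kind}",
        f"# event_magnitude_mpa={trace.event_magnitude!r}",
        "# time zero at the annotated event sample",
    ]
    for key, val in trace.meta.items():
        lines.append(f"# {key}={val!r}")
    buf = io.StringIO()
    pd.DataFrame({"time_s": trace.time, "pressure_mpa": trace.pressure}).to_csv(
        buf, index=False, float_format="%.10g"
    )
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_trace_csv(path: str | Path) -> PressureTrace:
    """Read a trace CSV, re-basing time to start at the first sample."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = val.strip().strip("'\"")
        elif line.strip():
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    if not {"time_s", "pressure_mpa"} <= set(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns time_s, pressure_mpa")
    kind = meta.get("event_kind", "hydrostatic_step")
    magnitude = float(meta.get("event_magnitude_mpa", "nan"))
    time = df["time_s"].to_numpy(dtype=float)
    extra = {k: v for k, v in meta.items() if k not in _META_KEYS}
    return PressureTrace(
        time - time[0],
        df["pressure_mpa"].to_numpy(dtype=float),
        kind,  # type: ignore[arg-type]
        magnitude,
        meta=extra,
    )


def read_monomer_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy suberin monomer table (compound_label, amount_ug, zone, …)."""
    df = pd.read_csv(path, comment="#")
    required = {"compound_label", "amount_ug", "zone", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: monomer CSV lacks columns {sorted(missing)}")
    return df


def default_config() -> dict:
    """Default synthetic experiment configuration (all overridable).

    Probe and geometry defaults are chosen so that control-condition roots
    show t½w ≈ 5 s and t½s ≈ 10 min, the magnitudes of barley seminal roots
    on a root pressure probe.
    """
    return {
        "probe": {"beta_mpa_per_m3": 1.09e10, "Ar_m2": 1.57e-4},
        "geometry": {
            "conductive_length_m": 0.10,
            "root_diameter_m": 5.0e-4,
            "endodermis_radius_m": 2.0e-4,
            "xylem_fraction": 0.015,
        },
        "experiment": {
            "P_ss_mpa": 0.2,
            "deltaP0_mpa": 0.05,
            "osmolality_step_mosmol_kg": 60.0,
            "temperature_c": 23.0,
            "hydrostatic_duration_s": 60.0,
            "hydrostatic_dt_s": 0.05,
            "osmotic_duration_s": 3000.0,
            "osmotic_dt_s": 0.1,
            "noise_sd_mpa": 0.002,
            "n_roots": 8,
        },
        "groups": {
            "control": {"Lpr": 8.11e-8, "Lpr_sd": 2.37e-8,
                        "Psr": 2.24e-9, "Psr_sd": 1.54e-9,
                        "sigma": 0.38, "sigma_sd": 0.06},
            "stress_-0.8MPa": {"Lpr": 3.19e-8, "Lpr_sd": 1.45e-8,
                               "Psr": 0.61e-9, "Psr_sd": 0.61e-9,
                               "sigma": 0.38, "sigma_sd": 0.17},
        },
    }


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merged over the defaults (shallow per section)."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                merged = dict(cfg[section])
                merged.update(values)
                cfg[section] = merged
            else:
                cfg[section] = values
    return cfg


def probe_from_config(cfg: dict) -> ProbeSystem:
    p = cfg["probe"]
    return ProbeSystem(beta=float(p["beta_mpa_per_m3"]), Ar=float(p["Ar_m2"]))


def geometry_from_config(cfg: dict) -> RootGeometry:
    g = cfg["geometry"]
    return RootGeometry(
        conductive_length=float(g["conductive_length_m"]),
        root_diameter=float(g["root_diameter_m"]),
        endodermis_radius=float(g["endodermis_radius_m"]),
        xylem_fraction=float(g.get("xylem_fraction", 0.015)),
    )


def params_from_group(group_cfg: dict) -> TransportParams:
    return TransportParams(
        Lpr=float(group_cfg["Lpr"]),
        Psr=float(group_cfg["Psr"]),
        sigma=float(group_cfg["sigma"]),
    )
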