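"""Tabular I/O, the bundled design-table fixture, and config parsing.

All tables are comma-separated UTF-8 text with a header row and "." decimal
separator; nested reports are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import HexPoreSpec, pitch, pore_density, porosity_percent
from .mechanics import LoadDeflectionSeries
from .sieve import ParticlePopulation

_FIXTURE_CASES = 6


@dataclass(frozen=True)
class DesignCase:
    """One row of the bundled six-case design table.

    Carries both the mask design values and the measured (post-fabrication)
    values; ``measured_dprime`` is the measured flat-to-flat width, the
    effective sieving cutoff of the case.
    """

    case: int
    design: HexPoreSpec
    measured: HexPoreSpec
    measured_dprime: float
    porosity_pct: float


def load_table2_fixture() -> list[DesignCase]:
    """The six bundled membrane design cases (design + measured values)."""
    with resources.files("hexpore.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    required = {
        "case", "d_design_um", "s_design_um", "d_meas_um", "dprime_meas_um",
        "s_meas_um", "porosity_pct",
    }
    if not required <= set(df.columns) or len(df) != _FIXTURE_CASES:
        raise RuntimeError(
            "bundled design-table fixture is corrupted: expected "
            f"{_FIXTURE_CASES} rows with columns {sorted(required)}"
        )
    cases = []
    for row in df.itertuples(index=False):
        label = f"case{int(row.case)}"
        cases.append(
            DesignCase(
                case=int(row.case),
                design=HexPoreSpec(d=row.d_design_um, s=row.s_design_um, label=label),
                measured=HexPoreSpec(d=row.d_meas_um, s=row.s_meas_um, label=label),
                measured_dprime=float(row.dprime_meas_um),
                porosity_pct=float(row.porosity_pct),
            )
        )
    return cases


def get_case(case_no: int) -> DesignCase:
    for c in load_table2_fixture():
        if c.case == case_no:
            return c
    raise KeyError(f"no design case {case_no} (fixture has 1..{_FIXTURE_CASES})")


def measured_cutoffs(case_numbers: Sequence[int]) -> list[float]:
    """Measured flat-to-flat cutoffs (μm) of the given cases, in order."""
    table = {c.case: c.measured_dprime for c in load_table2_fixture()}
    return [table[n] for n in case_numbers]


def design_frame(cases: Sequence[HexPoreSpec]) -> pd.DataFrame:
    """Derived design-geometry table for a list of specs."""
    rows = []
    for spec in cases:
        rows.append(
            {
                "case": spec.label,
                "d_um": spec.d,
                "dprime_um": round(spec.flat_to_flat, 2),
                "s_um": spec.s,
                "pitch_um": round(pitch(spec), 4),
                "porosity_pct": porosity_percent(spec),
                "density_per_mm2": round(pore_density(spec), 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "case", "d_um", "dprime_um", "s_um", "pitch_um",
            "porosity_pct", "density_per_mm2",
        ],
    )


def render_design_table(cases: Sequence[HexPoreSpec]) -> str:
    """Design table as comma-separated text (header always present)."""
    return design_frame(cases).to_csv(index=False)


def read_membrane_config(path: str | Path) -> HexPoreSpec:
    """Flat key-value membrane config: keys label, d_um, s_um, h_um.

    Accepts ``key = value`` or ``key: value`` lines; '#' starts a comment.
    """
    fields: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = "=" if "=" in line else ":"
        if sep not in line:
            raise ValueError(f"cannot parse config line: {raw!r}")
        key, value = (part.strip() for part in line.split(sep, 1))
        fields[key] = value
    try:
        return HexPoreSpec(
            d=float(fields["d_um"]),
            s=float(fields["s_um"]),
            h=float(fields.get("h_um", 10.0)),
            label=fields.get("label", ""),
        )
    except KeyError as exc:
        raise ValueError(f"membrane config missing key {exc}") from exc


def write_membrane_config(spec: HexPoreSpec, path: str | Path) -> None:
    Path(path).write_text(
        f"label = {spec.label}\nd_um = {spec.d!r}\ns_um = {spec.s!r}\n"
        f"h_um = {spec.h!r}\n"
    )


def read_load_deflection(path: str | Path) -> LoadDeflectionSeries:
    """Two-column CSV with header ``load_N,deflection_m``."""
    df = pd.read_csv(path)
    if not {"load_N", "deflection_m"} <= set(df.columns):
        raise ValueError("load-deflection file needs columns load_N, deflection_m")
    return LoadDeflectionSeries(df["load_N"].to_numpy(), df["deflection_m"].to_numpy())


def write_load_deflection(series: LoadDeflectionSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"load_N": series.loads, "deflection_m": series.deflections}
    ).to_csv(path, index=False)


def read_population(path: str | Path) -> ParticlePopulation:
    """One-column CSV ``diameter_um`` with optional ``label`` column."""
    df = pd.read_csv(path)
    if "diameter_um" not in df.columns:
        raise ValueError("population file needs a diameter_um column")
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
    return ParticlePopulation(df["diameter_um"].to_numpy(), labels)


def write_population(pop: ParticlePopulation, path: str | Path) -> None:
    data = {"diameter_um": pop.diameters}
    if pop.labels is not None:
        data["label"] = pop.labels
    pd.DataFrame(data).to_csv(path, index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
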