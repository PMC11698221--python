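"""Particle-table and configuration readers/writers.

Particle tables are UTF-8 comma-separated text with one header row and
'.' decimal separators::

    id,x_mm,y_mm,L_um,morphology,C_atpct,O_atpct,...,Fe_atpct

Element columns are exactly the ten analyzed elements in fixed order; any
other ``*_atpct`` column is a hard error (the element universe is fixed).
Synthetic ground-truth tables add ``particle_class`` and ``thickness_um``;
classified tables add ``decision`` and ``reject_reasons``.  Real measured
tables omit the ground-truth columns and downstream code never requires
them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .edx_measurement import BeamConfig
from .particle_model import (
    ELEMENTS,
    Composition,
    Decision,
    MeasuredParticle,
    Morphology,
    ParticleClass,
    ParticleRecord,
    ProtocolConfig,
    SampleSummary,
    StopCheck,
    normalize_composition,
)
from .synthetic_dust import SampleConfig, coal_terminal_mixture

__all__ = [
    "ELEMENT_COLUMNS",
    "BASE_COLUMNS",
    "read_particle_table",
    "write_particle_table",
    "write_classified_table",
    "load_config",
    "summary_to_dict",
    "format_summary_table",
    "write_run_manifest",
]

ELEMENT_COLUMNS = [f"{el}_atpct" for el in ELEMENTS]
BASE_COLUMNS = ["id", "x_mm", "y_mm", "L_um", "morphology"]
GROUND_TRUTH_COLUMNS = ["particle_class", "thickness_um"]
DECISION_COLUMNS = ["decision", "reject_reasons"]


class ParticleTableError(ValueError):
    """Schema or value error in a particle table, with row/column context."""


def _check_columns(columns: list[str], path: Path) -> None:
    allowed = set(BASE_COLUMNS + ELEMENT_COLUMNS + GROUND_TRUTH_COLUMNS + DECISION_COLUMNS)
    unknown = [c for c in columns if c not in allowed]
    if unknown:
        atpct = [c for c in unknown if c.endswith("_atpct")]
        if atpct:
            raise ParticleTableError(
                f"{path}: element column(s) {atpct} outside the fixed ten-element "
                f"set {ELEMENTS}; refusing to drop them silently"
            )
        raise ParticleTableError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in BASE_COLUMNS[1:] + ELEMENT_COLUMNS if c not in columns]
    if missing:
        raise ParticleTableError(f"{path}: missing required column(s) {missing}")


def read_particle_table(path: str | Path) -> list[ParticleRecord]:
    """Read and validate a particle table.

    Row numbers (1-based, excluding the header) become ids when the ``id``
    column is absent.  Compositions are closed to 100 At.% on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(list(df.columns), path)
    records: list[ParticleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        rid = rowd.get("id") or f"row{i}"

        def numeric(col: str, row_index: int = i) -> float:
            raw = rowd[col]
            try:
                return float(raw)
            except ValueError:
                raise ParticleTableError(
                    f"{path}: row {row_index}, column {col!r}: "
                    f"non-numeric value {raw!r}"
                ) from None

        try:
            morphology = Morphology(rowd["morphology"])
        except ValueError:
            raise ParticleTableError(
                f"{path}: row {i}, column 'morphology': {rowd['morphology']!r} "
                f"not one of {[m.value for m in Morphology]}"
            ) from None
        comp_raw = {el: numeric(f"{el}_atpct") for el in ELEMENTS}
        try:
            composition = normalize_composition(comp_raw)
        except ValueError as exc:
            raise ParticleTableError(f"{path}: row {i}: {exc}") from None
        particle_class = None
        if "particle_class" in rowd and rowd["particle_class"]:
            try:
                particle_class = ParticleClass(rowd["particle_class"])
            except ValueError:
                raise ParticleTableError(
                    f"{path}: row {i}, column 'particle_class': "
                    f"{rowd['particle_class']!r} is not a known class"
                ) from None
        thickness = (
            numeric("thickness_um")
            if "thickness_um" in rowd and rowd["thickness_um"]
            else None
        )
        try:
            records.append(
                ParticleRecord(
                    id=rid,
                    x_mm=numeric("x_mm"),
                    y_mm=numeric("y_mm"),
                    L_um=numeric("L_um"),
                    morphology=morphology,
                    intrinsic_composition=composition,
                    particle_class=particle_class,
                    thickness_um=thickness,
                )
            )
        except ValueError as exc:
            raise ParticleTableError(f"{path}: row {i}: {exc}") from None
    return records


def _record_row(p: ParticleRecord, ground_truth: bool) -> dict:
    row: dict = {
        "id": p.id,
        "x_mm": repr(p.x_mm),
        "y_mm": repr(p.y_mm),
        "L_um": repr(p.L_um),
        "morphology": p.morphology.value,
    }
    for el, v in p.intrinsic_composition:
        row[f"{el}_atpct"] = repr(v)
    if ground_truth:
        row["particle_class"] = p.particle_class.value if p.particle_class else ""
        row["thickness_um"] = repr(p.thickness_um) if p.thickness_um is not None else ""
    return row


def write_particle_table(
    records: Sequence[ParticleRecord],
    path: str | Path,
    ground_truth: bool | None = None,
) -> None:
    """Write records as CSV; full float precision (``repr``) so that a
    write/read round-trip is exact.  Ground-truth columns are included when
    any record carries them (or per the explicit flag)."""
    if ground_truth is None:
        ground_truth = any(r.thickness_um is not None or r.particle_class is not None
                           for r in records)
    cols = BASE_COLUMNS + ELEMENT_COLUMNS + (GROUND_TRUTH_COLUMNS if ground_truth else [])
    rows = [_record_row(p, ground_truth) for p in records]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_classified_table(
    measured: Sequence[MeasuredParticle], path: str | Path
) -> None:
    """Write measured+classified particles: measured composition, observed
    morphology, decision, and all reject reasons (semicolon-joined)."""
    gt = any(m.particle.particle_class is not None for m in measured)
    rows = []
    for m in measured:
        row = _record_row(
            replace(
                m.particle,
                morphology=m.observed_morphology,
                intrinsic_composition=m.measured_composition,
            ),
            gt,
        )
        row["decision"] = m.decision.value if m.decision is not None else ""
        row["reject_reasons"] = ";".join(sorted(r.value for r in m.reject_reasons))
        rows.append(row)
    cols = (BASE_COLUMNS + ELEMENT_COLUMNS
            + (GROUND_TRUTH_COLUMNS if gt else []) + DECISION_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def _build_section(cls, data: dict, name: str, **extra):
    known = set(cls.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"config section {name!r}: unknown key(s) {unknown}")
    return cls(**{**data, **extra})


def load_config(
    path: str | Path,
) -> tuple[ProtocolConfig, BeamConfig, SampleConfig | None]:
    """Load a YAML run configuration.

    Sections (all optional): ``protocol`` (ProtocolConfig fields), ``beam``
    (BeamConfig fields), and ``sample``.  ``sample`` is either
    ``preset: coal_terminal`` with optional overrides
    (total_above_limit_loading_per_mm2, coal_fraction_above_limit,
    region_width_mm, region_height_mm, seed) or ``preset: blank``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    unknown = sorted(set(data) - {"protocol", "beam", "sample"})
    if unknown:
        raise ValueError(f"unknown config section(s) {unknown}")
    proto_raw = dict(data.get("protocol") or {})
    if "stop_check" in proto_raw:
        proto_raw["stop_check"] = StopCheck(proto_raw["stop_check"])
    if "substrate_composition" in proto_raw:
        proto_raw["substrate_composition"] = normalize_composition(
            proto_raw["substrate_composition"]
        )
    protocol = _build_section(ProtocolConfig, proto_raw, "protocol")
    beam = _build_section(BeamConfig, dict(data.get("beam") or {}), "beam")
    sample_raw = dict(data.get("sample") or {})
    sample: SampleConfig | None = None
    if sample_raw:
        preset = sample_raw.pop("preset", "coal_terminal")
        if preset == "coal_terminal":
            allowed = {
                "total_above_limit_loading_per_mm2",
                "coal_fraction_above_limit",
                "region_width_mm",
                "region_height_mm",
                "seed",
            }
            unknown = sorted(set(sample_raw) - allowed)
            if unknown:
                raise ValueError(f"config section 'sample': unknown key(s) {unknown}")
            sample = coal_terminal_mixture(
                size_limit_um=protocol.size_limit_um, **sample_raw
            )
        elif preset == "blank":
            allowed = {"region_width_mm", "region_height_mm", "seed"}
            unknown = sorted(set(sample_raw) - allowed)
            if unknown:
                raise ValueError(f"config section 'sample': unknown key(s) {unknown}")
            sample = SampleConfig(
                class_specs=[], total_loading_per_mm2=0.0, **sample_raw
            )
        else:
            raise ValueError(f"unknown sample preset {preset!r}")
    return protocol, beam, sample


# ---------------------------------------------------------------------------
# reports and manifests


def summary_to_dict(summary: SampleSummary) -> dict:
    return asdict(summary)


_TABLE_COLUMNS = [
    ("sample", "{}"),
    ("positions", "{:d}"),
    ("area_mm2", "{:.2f}"),
    ("particles", "{:d}"),
    ("total_per_mm2", "{:.0f}"),
    ("coal", "{:d}"),
    ("coal_pct", "{:.0f}"),
    ("coal_per_mm2", "{:.1f}"),
]


def format_summary_table(labeled: Sequence[tuple[str, SampleSummary]]) -> str:
    """Summary-table-shaped delimited text (one row per sample)."""
    lines = ["\t".join(name for name, _ in _TABLE_COLUMNS)]
    for label, s in labeled:
        values = [
            label,
            s.n_area_positions,
            s.area_analyzed_mm2_2dp,
            s.n_particles_analyzed,
            s.total_loading_per_mm2,
            s.n_coal,
            s.coal_fraction_pct,
            s.coal_loading_per_mm2,
        ]
        lines.append(
            "\t".join(fmt.format(v) for (_, fmt), v in zip(_TABLE_COLUMNS, values))
        )
    return "\n".join(lines) + "\n"


def write_run_manifest(
    out_path: str | Path,
    seed: int,
    config_path: str | Path | None,
) -> None:
    """Record what is needed to reproduce a run byte-for-byte."""
    import numpy
    from . import __version__

    manifest = {
        "semdust_version": __version__,
        "numpy_version": numpy.__version__,
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
            if config_path is not None
            else None
        ),
    }
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
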