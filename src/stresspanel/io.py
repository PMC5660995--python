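"""Readers and writers for the package's file dialects.

Instrument-like data (Cq tables, fluorescence traces) travel as CSV with dot
decimals; annotation tables (panel, reference profiles) and stage outputs as
TSV. The JSON run report is serialized deterministically (sorted keys) so
reruns diff cleanly. An empty ``cq`` field in the Cq table means
no-amplification.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, STRESSES, TOLERANT_CONTROL
from .panel import MarkerPanel, PanelGene
from .synthdata import FluorTrace

CQ_COLUMNS = [
    "plate",
    "well",
    "gene_id",
    "sample_id",
    "variety",
    "location",
    "treatment",
    "bio_rep",
    "tech_rep",
    "cq",
]


def read_cq_table(path) -> pd.DataFrame:
    """Read and validate a long-format Cq table CSV.

    Enforces the column contract, numeric (or empty = no-amplification) cq,
    and uniqueness of (gene_id, sample_id, bio_rep, tech_rep).
    """
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "sample_id": str})
    missing = set(CQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["cq"] = pd.to_numeric(df["cq"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cq value ({exc})") from exc
    bad = df["cq"].notna() & (df["cq"] <= 0)
    if bad.any():
        raise ValueError(f"{path}: non-positive cq in rows {df.index[bad].tolist()}")
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    key = ["gene_id", "sample_id", "bio_rep", "tech_rep"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.index[dup][0]
        raise ValueError(
            f"{path}: duplicate (gene_id, sample_id, bio_rep, tech_rep) at row "
            f"{first}: {df.loc[first, key].tolist()}"
        )
    return df[CQ_COLUMNS]


def write_cq_table(wells: pd.DataFrame, path) -> None:
    wells[CQ_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def write_traces(traces: Iterable[FluorTrace], path) -> None:
    frames = [
        pd.DataFrame({"well_id": t.well_id, "cycle": t.cycles, "rn": t.rn})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_traces(path) -> list[FluorTrace]:
    df = pd.read_csv(path)
    out = []
    for well_id, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("cycle")
        out.append(
            FluorTrace(
                well_id=str(well_id),
                cycles=grp["cycle"].to_numpy(),
                rn=grp["rn"].to_numpy(),
            )
        )
    return out


PANEL_COLUMNS = [
    "gene_id",
    "probeset_id",
    "annotation",
    "mapman_bin",
    "expected_direction",
    "stress_assignments",
    "is_reference",
    "direction_source",
]


def read_panel(path) -> MarkerPanel:
    """Read the marker-panel TSV.

    ``stress_assignments`` uses ';' between labels; reference genes leave
    direction and stresses empty. Unknown direction or stress labels raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "expected_direction", "stress_assignments", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for i, row in df.iterrows():
        is_ref = str(row["is_reference"]).strip().lower() in ("1", "true", "yes")
        direction = row["expected_direction"].strip() or None
        if direction is not None and direction not in ("up", "down"):
            raise ValueError(
                f"{path} row {i}: unknown direction {direction!r} "
                f"for {row['gene_id']}"
            )
        stresses = tuple(
            s for s in (x.strip() for x in row["stress_assignments"].split(";")) if s
        )
        unknown = set(stresses) - set(STRESSES)
        if unknown:
            raise ValueError(f"{path} row {i}: unknown stresses {sorted(unknown)}")
        genes.append(
            PanelGene(
                gene_id=row["gene_id"],
                probeset_id=row.get("probeset_id", ""),
                annotation=row.get("annotation", ""),
                mapman_bin=row.get("mapman_bin", "") or "not assigned",
                expected_direction=direction,
                stress_assignments=stresses,
                is_reference=is_ref,
                direction_source=row.get("direction_source", "")
                or TOLERANT_CONTROL,
            )
        )
    return MarkerPanel(genes)


def write_panel(panel: MarkerPanel, path) -> None:
    panel.to_frame()[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ref_profiles(path) -> pd.DataFrame:
    """Reference-genotype profile TSV: gene_id, stress, tolerant, sensitive
    (optionally a location column for location-specific profiles)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "stress", "tolerant", "sensitive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df["stress"]) - set(STRESSES)
    if unknown:
        raise ValueError(f"{path}: unknown stresses {sorted(unknown)}")
    return df


def write_ref_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        clean = obj.replace({np.nan: None})
        return clean.to_dict(orient="records")
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else round(f, 10)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(outputs: Mapping[str, object], config: RunConfig, path) -> None:
    """Serialize all stage outputs plus the config echo as deterministic JSON.

    Stages not run should be passed as None so their keys are present but
    null; floats are rounded to 10 decimals and NaN maps to null.
    """
    if not any(v is not None for v in outputs.values()):
        raise ValueError("need ≥ 1 stage output")
    payload = {
        "software": {"name": "stresspanel", "version": __version__},
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "outputs": _jsonable(dict(outputs)),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
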