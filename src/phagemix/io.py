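"""Tabular readers/writers, packaged fixtures, validation and reporting.

Canonical CSV dialect: UTF-8, comma-separated, header row, '.' decimal;
scientific notation is accepted on input and emitted as e-notation. All
reading and writing goes through pandas.

The packaged fixtures transcribe the development campaign's printed result
tables: the strain collection, the phage panel with receptor annotations,
the per-phage lytic-activity summary, the resistant-variant
cross-sensitivity matrix, the mutant gene tables, the gene->receptor map,
the genome-based receptor predictions and the 24-month storage-stability
series.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    BiofilmMeasurement,
    CellState,
    CrossSensitivityMatrix,
    KineticCurve,
    MilkAssayResult,
    MutationRecord,
    PhageRecord,
    PlaqueCountSeries,
    SpotSeries,
    StabilitySeries,
    VariantRecord,
)

_FIXTURES = {
    "strains": "strains.csv",
    "phages": "phages.csv",
    "lytic_summary": "lytic_summary.csv",
    "cross_matrix": "cross_matrix.csv",
    "mutations": "mutations.csv",
    "stability": "stability.csv",
    "receptor_predictions": "receptor_predictions.csv",
    "gene_receptor_map": "gene_receptor_map.csv",
}

#: printed-table aliases
_ALIASES = {
    "table1": "strains",
    "table2": "phages",
    "table5": "phages",
    "table6": "lytic_summary",
    "table7": "cross_matrix",
    "table8": "mutations",
    "table9": "mutations",
    "table10": "stability",
    "table11": "receptor_predictions",
}


def _fixture_path(name: str):
    key = _ALIASES.get(name, name)
    if key not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES) + sorted(_ALIASES)}"
        )
    return resources.files("phagemix.data") / _FIXTURES[key]


def _split_classes(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def load_fixture(name: str):
    """Load a packaged fixture as its typed object.

    Names: ``strains`` (DataFrame), ``phages`` (list of PhageRecord),
    ``lytic_summary`` (DataFrame), ``cross_matrix``
    (CrossSensitivityMatrix), ``mutations`` (list of MutationRecord),
    ``stability`` (StabilitySeries), ``receptor_predictions``
    (dict phage -> receptor set), ``gene_receptor_map`` (dict gene ->
    class). Printed-table aliases ``table1`` .. ``table11`` resolve to the
    corresponding fixture.
    """
    key = _ALIASES.get(name, name)
    with resources.as_file(_fixture_path(name)) as path:
        df = pd.read_csv(path)
    if key == "strains":
        return df
    if key == "lytic_summary":
        return df
    if key == "phages":
        return [
            PhageRecord(
                phage_id=r.phage_id,
                host_species=r.host_species,
                family=r.family if isinstance(r.family, str) else "",
                genus=r.genus,
                main_receptors=_split_classes(r.main_receptors),
                support_receptors=_split_classes(r.support_receptors),
                short_name=str(r.short_name),
            )
            for r in df.itertuples()
        ]
    if key == "cross_matrix":
        return cross_matrix_from_frame(df)
    if key == "mutations":
        return [
            MutationRecord(
                variant_id=r.variant_id,
                gene=r.gene,
                effect=r.effect,
                product=r.product,
            )
            for r in df.itertuples()
        ]
    if key == "stability":
        return stability_from_frame(df)
    if key == "receptor_predictions":
        return {
            r.phage_id: _split_classes(r.predicted_receptors) for r in df.itertuples()
        }
    if key == "gene_receptor_map":
        return dict(zip(df.gene, df.receptor_class))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# frame <-> typed-object converters (the CSV dialects the CLI consumes)
# ---------------------------------------------------------------------------

_META_COLS = ("variant_id", "species", "parent_strain", "inducing_phage")


def cross_matrix_from_frame(df: pd.DataFrame) -> CrossSensitivityMatrix:
    """Matrix CSV: variant_id, species, parent_strain, inducing_phage, then
    one column per phage with cell codes {+, -, x}."""
    phages = [c for c in df.columns if c not in _META_COLS]
    variants, cells = [], {}
    for _, r in df.iterrows():
        vid = str(r["variant_id"])
        variants.append(
            VariantRecord(
                variant_id=vid,
                parent_strain_id=str(r["parent_strain"]),
                inducing_phage_id=str(r["inducing_phage"]),
                species=str(r["species"]) if "species" in df.columns else "",
            )
        )
        for p in phages:
            cells[(vid, p)] = CellState(r[p])
    return CrossSensitivityMatrix(variants, phages, cells)


def cross_matrix_to_frame(matrix: CrossSensitivityMatrix) -> pd.DataFrame:
    rows = []
    for v in matrix.variants:
        row = {
            "variant_id": v.variant_id,
            "species": v.species,
            "parent_strain": v.parent_strain_id,
            "inducing_phage": v.inducing_phage_id,
        }
        for p in matrix.phages:
            row[p] = matrix.cell(v.variant_id, p).value
        rows.append(row)
    return pd.DataFrame(rows)


def stability_from_frame(df: pd.DataFrame) -> StabilitySeries:
    """Stability CSV: month, species, titer_pfu_ml (long format)."""
    months = sorted(df["month"].unique())
    comp = {}
    for species, grp in df.groupby("species"):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(months):
            raise ValueError(f"component {species!r} missing timepoints")
        comp[str(species)] = tuple(grp["titer_pfu_ml"].astype(float))
    return StabilitySeries(months=tuple(float(m) for m in months), component_titers=comp)


def stability_to_frame(series: StabilitySeries) -> pd.DataFrame:
    rows = [
        {"month": m, "species": sp, "titer_pfu_ml": series.component_titers[sp][i]}
        for i, m in enumerate(series.months)
        for sp in series.component_titers
    ]
    return pd.DataFrame(rows)


def load_phage_row(row) -> PhageRecord:
    """Build a PhageRecord from one row of a phage-panel CSV."""
    return PhageRecord(
        phage_id=str(row["phage_id"]),
        host_species=str(row["host_species"]),
        family=str(row["family"]) if not pd.isna(row.get("family")) else "",
        genus=str(row["genus"]) if not pd.isna(row.get("genus")) else "",
        main_receptors=_split_classes(row.get("main_receptors")),
        support_receptors=_split_classes(row.get("support_receptors")),
        short_name=str(row["short_name"]) if "short_name" in row else "",
    )


def read_plaque_counts(path) -> PlaqueCountSeries:
    """Plaque CSV: columns dilution, plate_id, plaques, volume_ml."""
    return read_plaque_counts_frame(pd.read_csv(path))


def read_plaque_counts_frame(df: pd.DataFrame) -> PlaqueCountSeries:
    vols = df["volume_ml"].unique()
    if len(vols) != 1:
        raise ValueError("mixed plated volumes in one series")
    records = tuple(
        (float(d), tuple(int(c) for c in grp["plaques"]))
        for d, grp in df.groupby("dilution", sort=False)
    )
    return PlaqueCountSeries(records=records, volume_ml=float(vols[0]))


def read_kinetics(path) -> pd.DataFrame:
    """Long-format kinetics CSV: time_min, od, well_role, phage_id,
    strain_id, replicate. Returned as a validated DataFrame; grouping into
    KineticCurve objects is done by :func:`kinetics_curves`."""
    df = pd.read_csv(path)
    required = {"time_min", "od", "well_role", "phage_id", "strain_id", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinetics CSV missing columns: {sorted(missing)}")
    return df


def kinetics_curves(
    df: pd.DataFrame, phage_id: str, strain_id: str
) -> Dict[str, List[KineticCurve]]:
    """Split one phage/strain block into curves keyed by well role."""
    block = df[(df.phage_id == phage_id) & (df.strain_id == strain_id)]
    out: Dict[str, List[KineticCurve]] = {}
    for (role, rep), grp in block.groupby(["well_role", "replicate"]):
        grp = grp.sort_values("time_min")
        out.setdefault(role, []).append(
            KineticCurve(
                grp["time_min"].to_numpy(),
                grp["od"].to_numpy(),
                role=role,
                replicate_id=str(rep),
            )
        )
    return out


def read_spots(path) -> Dict[str, List[SpotSeries]]:
    """Spot CSV: strain_id, replicate, spotted_titer_pfu_ml, observation."""
    df = pd.read_csv(path)
    out: Dict[str, List[SpotSeries]] = {}
    for (strain, rep), grp in df.groupby(["strain_id", "replicate"]):
        grp = grp.sort_values("spotted_titer_pfu_ml", ascending=False)
        out.setdefault(str(strain), []).append(
            SpotSeries(
                strain_id=str(strain),
                spots=tuple(
                    zip(grp["spotted_titer_pfu_ml"].astype(float), grp["observation"])
                ),
                replicate_id=str(rep),
            )
        )
    return out


def read_biofilm(path) -> List[BiofilmMeasurement]:
    """Biofilm CSV: strain_id, assay, arm ('test'|'control_100'), od570,
    replicate."""
    df = pd.read_csv(path)
    out = []
    for (strain, assay), grp in df.groupby(["strain_id", "assay"]):
        a_ts = tuple(grp.loc[grp.arm == "test", "od570"].astype(float))
        a_c100 = tuple(grp.loc[grp.arm == "control_100", "od570"].astype(float))
        out.append(
            BiofilmMeasurement(
                strain_id=str(strain), assay=str(assay), a_ts=a_ts, a_c100=a_c100
            )
        )
    return out


def read_milk(path) -> Dict[Tuple[str, float], Dict[str, MilkAssayResult]]:
    """Milk CSV: strain_id, arm, initial_density, cfu_per_ml, replicate."""
    df = pd.read_csv(path)
    out: Dict[Tuple[str, float], Dict[str, MilkAssayResult]] = {}
    for (strain, dens, arm), grp in df.groupby(
        ["strain_id", "initial_density", "arm"]
    ):
        out.setdefault((str(strain), float(dens)), {})[str(arm)] = MilkAssayResult(
            strain_id=str(strain),
            arm=str(arm),
            endpoint_counts=tuple(grp["cfu_per_ml"].astype(float)),
            initial_density=float(dens),
        )
    return out


def write_csv(df: pd.DataFrame, path) -> None:
    """Write the canonical dialect (UTF-8, comma, header, '.' decimal)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(
    matrix: CrossSensitivityMatrix,
    phage_ids: Sequence[str],
    strain_ids: Optional[Sequence[str]] = None,
) -> List[str]:
    """Referential-integrity report for a cross matrix.

    Returns one message per violation (empty list = clean). Matrix phage
    columns and inducing phages must resolve against ``phage_ids``; parent
    strains must resolve against ``strain_ids`` (when given), where a
    variant id is itself an admissible parent (variants can be re-exposed).
    """
    known_phages = set(phage_ids)
    violations = []
    for j, p in enumerate(matrix.phages):
        if p not in known_phages:
            violations.append(f"column {j}: unknown phage id {p!r}")
    for i, v in enumerate(matrix.variants):
        if v.inducing_phage_id not in known_phages:
            violations.append(
                f"row {i} ({v.variant_id}): unknown inducing phage "
                f"{v.inducing_phage_id!r}"
            )
        if strain_ids is not None:
            admissible = set(strain_ids) | {x.variant_id for x in matrix.variants}
            if v.parent_strain_id not in admissible:
                violations.append(
                    f"row {i} ({v.variant_id}): dangling parent strain "
                    f"{v.parent_strain_id!r}"
                )
    return violations


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value  # enums
    return obj


def _markdown_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def report(results: Mapping[str, Any], out_json=None, out_markdown=None) -> str:
    """Serialize a result bundle to JSON and a markdown summary.

    ``results`` maps section names to DataFrames, dataclasses, mappings or
    scalars. Returns the markdown text; writes the files when paths are
    given.
    """
    payload = _jsonable(results)
    md_parts = []
    for section, value in results.items():
        md_parts.append(f"## {section}\n")
        if isinstance(value, pd.DataFrame):
            md_parts.append(_markdown_table(value.reset_index()) + "\n")
        else:
            md_parts.append(
                "```json\n" + json.dumps(_jsonable(value), indent=2) + "\n```\n"
            )
    md = "\n".join(md_parts)
    if out_json is not None:
        Path(out_json).parent.mkdir(parents=True, exist_ok=True)
        Path(out_json).write_text(json.dumps(payload, indent=2), encoding="utf-8")
    if out_markdown is not None:
        Path(out_markdown).parent.mkdir(parents=True, exist_ok=True)
        Path(out_markdown).write_text(md, encoding="utf-8")
    return md
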