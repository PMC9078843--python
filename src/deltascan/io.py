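"""Readers and writers for the tabular artifacts of the pipeline.

All tables are UTF-8, tab-separated, "." decimal point, with a header row.

PSM table columns (one row per spectrum/site):
    spectrum_id, peptide, protein, site, residue, delta_mass,
    score, delta_mod_score, fdr_2d, sample_id, group

Modification database columns:
    name, composition, class, plausible, source

Site numbering is 1-based over the full protein sequence including the
initiator methionine (UniProt numbering); mature-chain positions used in
some hemoglobin literature are one lower.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import chem
from .errors import CompositionError, TableError

__all__ = [
    "PSM_COLUMNS",
    "STANDARD_AA",
    "CLASS_LABELS",
    "ModificationEntry",
    "read_psm_table",
    "write_psm_table",
    "validate_psm_table",
    "read_modification_db",
    "write_modification_db",
    "modification_db_frame",
    "read_cluster_table",
    "write_cluster_table",
    "read_clinical_table",
    "write_clinical_table",
    "write_annotation_report",
    "preknown_db_path",
    "unimod_db_path",
    "peak_summary_path",
]

PSM_COLUMNS = (
    "spectrum_id", "peptide", "protein", "site", "residue", "delta_mass",
    "score", "delta_mod_score", "fdr_2d", "sample_id", "group",
)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The five final class labels used in peak summaries.
CLASS_LABELS = (
    "Reactive species",
    "AA substitution",
    "Chemical derivative",
    "Artefact",
    "Unknown",
)

CLUSTER_COLUMNS = (
    "cluster_id", "center", "sd", "weight", "window", "n_psms", "r_squared",
)

CLINICAL_COLUMNS = ("patient_id", "time", "event", "marker")

_DATA_DIR = Path(__file__).parent / "data"


def preknown_db_path() -> Path:
    """Path of the packaged 62-entry preknown tryptophan-variant database."""
    return _DATA_DIR / "preknown_trp.tsv"


def unimod_db_path() -> Path:
    """Path of the packaged Unimod-like secondary modification database."""
    return _DATA_DIR / "unimod_like.tsv"


def peak_summary_path() -> Path:
    """Path of the packaged 25-peak published summary table."""
    return _DATA_DIR / "trp_peak_table.tsv"


@dataclass(frozen=True)
class ModificationEntry:
    """One modification database row.

    ``delta`` is derived from ``composition`` at load time and is always
    consistent with it (within 1e-9 Da).
    """

    name: str
    composition: chem.ElementalComposition
    class_label: str
    plausible: bool
    source: str = "preknown"
    delta: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "delta", chem.monoisotopic_mass(self.composition))


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def validate_psm_table(table: pd.DataFrame) -> None:
    """Check PSM-table invariants; raise :class:`TableError` on the first
    violation, naming the offending (1-based, header-inclusive) line."""
    for col in PSM_COLUMNS:
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        if row.site < 1:
            raise TableError(f"site must be >= 1, got {row.site}", line=idx)
        if row.residue not in STANDARD_AA:
            raise TableError(f"invalid residue {row.residue!r}", line=idx)
        if not 0.0 <= row.fdr_2d <= 1.0:
            raise TableError(f"fdr_2d out of [0, 1]: {row.fdr_2d}", line=idx)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a PSM TSV. Never silently drops rows."""
    try:
        table = pd.read_csv(
            path, sep="\t",
            dtype={
                "spectrum_id": str, "peptide": str, "protein": str,
                "residue": str, "sample_id": str, "group": str,
            },
        )
    except ValueError as exc:
        raise TableError(f"unreadable PSM table {path}: {exc}") from exc
    for col in PSM_COLUMNS:
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    for col, kind in (("site", "Int64"), ("delta_mass", float),
                      ("score", float), ("delta_mod_score", float),
                      ("fdr_2d", float)):
        try:
            table[col] = table[col].astype(kind)
        except (TypeError, ValueError) as exc:
            raise TableError(f"column {col!r} is not numeric: {exc}") from exc
    table["site"] = table["site"].astype(int)
    validate_psm_table(table)
    return table[list(PSM_COLUMNS)]


def write_psm_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_psm_table(table)
    table[list(PSM_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Modification databases
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_bool(value, name: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise TableError(f"entry {name!r}: non-boolean plausible flag {value!r}")


def read_modification_db(path: str | Path) -> list[ModificationEntry]:
    """Read a modification database TSV into :class:`ModificationEntry` rows.

    Duplicate names are retained: names are labels, masses are keys.
    Composition parse failures are reported with the entry name.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "composition", "class", "plausible"):
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    if "source" not in table.columns:
        table["source"] = "preknown"
    table = table.rename(columns={"class": "class_label"})
    entries = []
    for row in table.itertuples(index=False):
        try:
            comp = chem.parse_composition(row.composition)
        except CompositionError as exc:
            raise TableError(f"entry {row.name!r}: {exc}") from exc
        entries.append(ModificationEntry(
            name=row.name,
            composition=comp,
            class_label=str(row.class_label),
            plausible=_parse_bool(row.plausible, row.name),
            source=str(row.source),
        ))
    return entries


def modification_db_frame(entries: Iterable[ModificationEntry]) -> pd.DataFrame:
    rows = [{
        "name": e.name,
        "composition": chem.format_composition(e.composition),
        "class": e.class_label,
        "plausible": e.plausible,
        "source": e.source,
        "delta": e.delta,
    } for e in entries]
    return pd.DataFrame(rows, columns=[
        "name", "composition", "class", "plausible", "source", "delta"])


def write_modification_db(entries: Iterable[ModificationEntry],
                          path: str | Path) -> None:
    frame = modification_db_frame(entries).drop(columns=["delta"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cluster, clinical and report tables
# ---------------------------------------------------------------------------

def read_cluster_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in CLUSTER_COLUMNS:
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    return table


def write_cluster_table(table: pd.DataFrame, path: str | Path) -> None:
    for col in CLUSTER_COLUMNS:
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    table.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (patient_id, time, event, marker)."""
    table = pd.read_csv(path, sep="\t")
    for col in CLINICAL_COLUMNS:
        if col not in table.columns:
            raise TableError(f"missing required column {col!r}")
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        if not row.time > 0:
            raise TableError(f"time must be > 0, got {row.time}", line=idx)
        if int(row.event) not in (0, 1):
            raise TableError(f"event must be 0/1, got {row.event}", line=idx)
    table["event"] = table["event"].astype(int)
    return table


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(CLINICAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_annotation_report(rows: list[dict], path: str | Path) -> None:
    """Write the JSON annotation report mirroring the published summary
    columns (classification, delta mass, frequency, annotation, chemical
    formula, monoisotopic mass, error)."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump({"peaks": rows}, handle, indent=2)
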