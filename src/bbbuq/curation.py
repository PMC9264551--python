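"""Molecule curation: standardization, binary labeling and deduplication.

Public BBB-permeability collections are noisy: they mix salts and solvates
with the parent drug, carry unparseable SMILES, and list the same structure
twice (sometimes as enantiomers, which stereo-agnostic 2D models cannot tell
apart; keeping both inflates apparent performance). This module turns a raw
SMILES table into a standardized, deduplicated, binary-labeled dataset and
accounts for every removal in a :class:`CurationReport`.

Standardization order is fixed: strip registered salts/solvents, keep the
largest-molecular-weight fragment, neutralize protonation states, remove
stereochemistry, canonicalize. The canonical SMILES string is the dataset
key.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.SaltRemover import SaltRemover

from .exceptions import (
    EmptyFile,
    MissingColumn,
    MissingEndpoint,
    UnparseableStructure,
    UnrecognizedLabelToken,
)

RDLogger.DisableLog("rdApp.*")

POSITIVE = "positive"
NEGATIVE = "negative"

#: default class boundaries: logBB >= -1 (i.e. Kp >= 0.1) and Kp,uu >= 0.1
DEFAULT_THRESHOLDS = {"logbb": -1.0, "kp": 0.1, "kpuu": 0.1}

_POSITIVE_TOKENS = {"1", "1.0", "p", "+", "bbb+", "positive", "cns", "yes", "true"}
_NEGATIVE_TOKENS = {"0", "0.0", "n", "-", "bbb-", "negative", "non-cns", "noncns", "no", "false"}


@dataclass
class RawEntry:
    """One un-curated input row: a SMILES plus at least one label source."""

    identifier: str
    smiles: str
    label_raw: str | None = None
    logbb: float | None = None
    kp: float | None = None
    kpuu: float | None = None


@dataclass
class MoleculeRecord:
    """A standardized molecule with a binary permeability label."""

    identifier: str
    smiles_raw: str
    smiles_std: str
    label: str
    label_source: str
    endpoint_value: float | None = None


@dataclass
class CurationReport:
    """Audit of a curation run; counts always satisfy
    ``n_output == n_input - n_unparseable - n_duplicates_removed - n_label_conflicts_dropped``.

    ``n_label_conflicts_dropped`` counts dropped *records* (every member of a
    conflicting duplicate group), so the identity above holds exactly.
    """

    n_input: int = 0
    n_unparseable: int = 0
    n_mixtures_resolved: int = 0
    n_duplicates_removed: int = 0
    n_label_conflicts_dropped: int = 0
    n_output: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_output == (
            self.n_input
            - self.n_unparseable
            - self.n_duplicates_removed
            - self.n_label_conflicts_dropped
        ), "curation report counts do not sum"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# --- standardization ---------------------------------------------------------

_SALT_REMOVER: SaltRemover | None = None
_UNCHARGER = rdMolStandardize.Uncharger()


def _get_salt_remover(extra_defn: str | None = None) -> SaltRemover:
    """Default salt dictionary plus water; an extra SMARTS definition block
    (one pattern per line) may be appended by the caller."""
    global _SALT_REMOVER
    if extra_defn is not None:
        return SaltRemover(defnData=extra_defn)
    if _SALT_REMOVER is None:
        _SALT_REMOVER = SaltRemover()
    return _SALT_REMOVER


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Fragment with the largest molecular weight; ties broken by heavy-atom
    count, then lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    return max(
        frags,
        key=lambda f: (
            Descriptors.MolWt(f),
            f.GetNumHeavyAtoms(),
            # invert for "smallest SMILES wins" under max()
            tuple(-ord(c) for c in Chem.MolToSmiles(f)),
        ),
    )


def standardize_structure(smiles_raw: str, salt_defn: str | None = None) -> str:
    """Standardize one SMILES to its canonical, neutral, achiral parent.

    Pipeline: parse → strip salts/solvents (never stripping everything) →
    largest-MW fragment → neutralize common acid/base groups (permanently
    charged centres such as quaternary N are left alone) → remove stereo
    markers → canonical SMILES. Idempotent.

    Raises
    ------
    UnparseableStructure
        If the SMILES cannot be parsed.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise UnparseableStructure("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise UnparseableStructure(f"cannot parse SMILES: {smiles_raw!r}")
    remover = _get_salt_remover(salt_defn)
    mol = remover.StripMol(mol, dontRemoveEverything=True)
    if mol.GetNumAtoms() == 0:
        raise UnparseableStructure(f"nothing left after salt stripping: {smiles_raw!r}")
    mol = _largest_fragment(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise UnparseableStructure(f"sanitization failed: {smiles_raw!r}") from exc
    return Chem.MolToSmiles(mol)


# --- labeling ----------------------------------------------------------------

def assign_label(
    entry: RawEntry,
    mode: str,
    threshold: float | None = None,
    positive_tokens: set[str] | None = None,
    negative_tokens: set[str] | None = None,
) -> str:
    """Binarize one entry.

    Continuous modes (``logbb``, ``kp``, ``kpuu``) call the molecule positive
    iff the endpoint value is >= the threshold (boundary inclusive, so
    logBB = -1 exactly is BBB+). ``annotated`` mode maps CNS/BBB+ style
    tokens to positive and non-CNS/BBB- tokens to negative.
    """
    if mode in ("logbb", "kp", "kpuu"):
        value = getattr(entry, mode)
        if value is None:
            raise MissingEndpoint(f"{entry.identifier}: no {mode} value")
        if threshold is None:
            threshold = DEFAULT_THRESHOLDS[mode]
        return POSITIVE if value >= threshold else NEGATIVE
    if mode == "annotated":
        if entry.label_raw is None:
            raise MissingEndpoint(f"{entry.identifier}: no annotated label")
        token = str(entry.label_raw).strip().lower()
        if token in (positive_tokens or _POSITIVE_TOKENS):
            return POSITIVE
        if token in (negative_tokens or _NEGATIVE_TOKENS):
            return NEGATIVE
        raise UnrecognizedLabelToken(f"{entry.identifier}: {entry.label_raw!r}")
    raise ValueError(f"unknown labeling mode: {mode!r}")


# --- deduplication -----------------------------------------------------------

def deduplicate_dataset(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Collapse records sharing a canonical key.

    Stereoisomers were already collapsed by :func:`standardize_structure`.
    Within a group of identical keys the first-seen record is kept; if the
    group disagrees on the label, *all* of its members are dropped (keeping
    either label would inject annotation noise) and counted as conflicts.
    """
    report = CurationReport(n_input=len(records))
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles_std not in groups:
            groups[rec.smiles_std] = []
            order.append(rec.smiles_std)
        groups[rec.smiles_std].append(rec)

    kept: list[MoleculeRecord] = []
    for key in order:
        group = groups[key]
        labels = {r.label for r in group}
        if len(labels) > 1:
            report.n_label_conflicts_dropped += len(group)
            for r in group:
                report.dropped.append((r.identifier, "label_conflict"))
            continue
        kept.append(group[0])
        report.n_duplicates_removed += len(group) - 1
        for r in group[1:]:
            report.dropped.append((r.identifier, f"duplicate_of:{group[0].identifier}"))
    report.n_output = len(kept)
    report.check()
    return kept, report


# --- pipeline ----------------------------------------------------------------

def curate(
    entries: Iterable[RawEntry],
    mode: str = "logbb",
    threshold: float | None = None,
    salt_defn: str | None = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Full curation: standardize, label, deduplicate, and account.

    Unparseable structures and unlabelable entries are reported, never
    raised; the batch always completes. Re-running on already-curated data
    is a no-op.
    """
    entries = list(entries)
    records: list[MoleculeRecord] = []
    report = CurationReport(n_input=len(entries))
    for entry in entries:
        try:
            smiles_std = standardize_structure(entry.smiles, salt_defn)
        except UnparseableStructure:
            report.n_unparseable += 1
            report.dropped.append((entry.identifier, "unparseable"))
            continue
        try:
            label = assign_label(entry, mode, threshold)
        except (MissingEndpoint, UnrecognizedLabelToken) as exc:
            report.n_unparseable += 1
            report.dropped.append((entry.identifier, f"unlabelable:{exc}"))
            continue
        if "." in entry.smiles:
            report.n_mixtures_resolved += 1
        endpoint = getattr(entry, mode) if mode != "annotated" else None
        records.append(
            MoleculeRecord(
                identifier=entry.identifier,
                smiles_raw=entry.smiles,
                smiles_std=smiles_std,
                label=label,
                label_source=mode if mode != "annotated" else "annotated",
                endpoint_value=endpoint,
            )
        )
    kept, dedup_report = deduplicate_dataset(records)
    report.n_duplicates_removed = dedup_report.n_duplicates_removed
    report.n_label_conflicts_dropped = dedup_report.n_label_conflicts_dropped
    report.dropped.extend(dedup_report.dropped)
    report.n_output = len(kept)
    report.check()
    return kept, report


# --- I/O ---------------------------------------------------------------------

@dataclass
class ColumnMap:
    """Names of the relevant columns in an input table."""

    smiles_col: str = "smiles"
    id_col: str | None = None
    label_col: str | None = None
    logbb_col: str | None = None
    kp_col: str | None = None
    kpuu_col: str | None = None


def _opt_float(row: dict, col: str | None) -> float | None:
    if col is None:
        return None
    v = row.get(col, "")
    if v is None or str(v).strip() == "":
        return None
    return float(v)


def load_table(path: str | Path, columns: ColumnMap | None = None) -> list[RawEntry]:
    """Load raw entries from a CSV (header row) or whitespace .smi file."""
    path = Path(path)
    columns = columns or ColumnMap()
    entries: list[RawEntry] = []
    if path.suffix.lower() == ".smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                ident = parts[1] if len(parts) > 1 else f"mol{i}"
                entries.append(RawEntry(identifier=ident, smiles=parts[0]))
        if not entries:
            raise EmptyFile(str(path))
        return entries
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyFile(str(path))
        if columns.smiles_col not in reader.fieldnames:
            raise MissingColumn(f"{path}: no column {columns.smiles_col!r}")
        for i, row in enumerate(reader):
            ident = row[columns.id_col] if columns.id_col else f"mol{i}"
            entries.append(
                RawEntry(
                    identifier=str(ident),
                    smiles=row[columns.smiles_col],
                    label_raw=row.get(columns.label_col) if columns.label_col else None,
                    logbb=_opt_float(row, columns.logbb_col),
                    kp=_opt_float(row, columns.kp_col),
                    kpuu=_opt_float(row, columns.kpuu_col),
                )
            )
    if not entries:
        raise EmptyFile(str(path))
    return entries


def write_dataset(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write curated records as CSV (round-trip stable with load_dataset)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["identifier", "smiles_raw", "smiles_std", "label", "label_source", "endpoint_value"]
        )
        for r in records:
            writer.writerow(
                [
                    r.identifier,
                    r.smiles_raw,
                    r.smiles_std,
                    r.label,
                    r.label_source,
                    "" if r.endpoint_value is None else repr(r.endpoint_value),
                ]
            )


def load_dataset(path: str | Path) -> list[MoleculeRecord]:
    """Load a curated CSV written by :func:`write_dataset`."""
    records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyFile(str(path))
        required = {"identifier", "smiles_std", "label"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise MissingColumn(f"{path}: missing {sorted(missing)}")
        for row in reader:
            records.append(
                MoleculeRecord(
                    identifier=row["identifier"],
                    smiles_raw=row.get("smiles_raw", row["smiles_std"]),
                    smiles_std=row["smiles_std"],
                    label=row["label"],
                    label_source=row.get("label_source", "annotated"),
                    endpoint_value=(
                        float(row["endpoint_value"])
                        if row.get("endpoint_value", "") not in ("", None)
                        else None
                    ),
                )
            )
    if not records:
        raise EmptyFile(str(path))
    return records
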