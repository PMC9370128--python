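"""CSV readers/writers for cultivar tables, primer panels and registries.

All files are UTF-8 delimited text. The cultivar table schema is

    name,country,origin_class,allele1,allele2,flags[,source,presumed_homozygous,documented_sc]

where ``flags`` is a semicolon-joined subset of {a,b,c,d} mirroring the
compilation-table footnotes; the three trailing columns are optional and
default to ``study``, ``0``, ``0``. Parse failures are reported with the
offending line number; duplicate cultivar names (case- and
accent-insensitive) are rejected listing both lines.
"""

from __future__ import annotations

import csv
import io as _io
import unicodedata
from pathlib import Path
from typing import Iterable, TextIO

from .core import (
    AssayId,
    CultivarRecord,
    GroupRegistry,
    OriginClass,
    PrimerAssayDef,
    SGenotype,
    SizeEntry,
    normalize_name,
    parse_allele,
)

__all__ = [
    "TableParseError",
    "read_cultivar_table",
    "write_cultivar_table",
    "read_panel",
    "write_panel",
    "read_registry",
    "write_registry",
]

CULTIVAR_COLUMNS = ["name", "country", "origin_class", "allele1", "allele2", "flags"]
EXTRA_COLUMNS = ["source", "presumed_homozygous", "documented_sc"]
PANEL_COLUMNS = [
    "assay", "primer_f", "primer_r", "expected_bp", "candidates",
    "tolerance_bp", "verified",
]
REGISTRY_COLUMNS = ["allele1", "allele2", "group"]


class TableParseError(ValueError):
    """A row-level failure, carrying the 1-based file line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _open(path_or_file, mode: str = "r"):
    if hasattr(path_or_file, "read") or hasattr(path_or_file, "write"):
        return path_or_file, False
    return open(Path(path_or_file), mode, encoding="utf-8", newline=""), True


def _bool(token: str) -> bool:
    return token.strip().lower() in ("1", "true", "yes", "y")


def read_cultivar_table(path, delimiter: str = ",") -> list[CultivarRecord]:
    """Parse a cultivar table into records with canonicalized genotypes."""
    fh, close = _open(path)
    try:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError(1, "empty file (missing header)") from None
        header = [h.strip().lower() for h in header]
        if header[: len(CULTIVAR_COLUMNS)] != CULTIVAR_COLUMNS:
            raise TableParseError(
                1,
                f"header mismatch: expected {CULTIVAR_COLUMNS} "
                f"(optionally + {EXTRA_COLUMNS}), got {header}",
            )
        idx = {col: i for i, col in enumerate(header)}
        records: list[CultivarRecord] = []
        seen: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                record = _parse_row(row, idx)
            except ValueError as exc:
                raise TableParseError(lineno, str(exc)) from None
            key = normalize_name(record.name)
            if key in seen:
                raise TableParseError(
                    lineno,
                    f"duplicate cultivar {record.name!r} "
                    f"(first seen on line {seen[key]})",
                )
            seen[key] = lineno
            records.append(record)
        return records
    finally:
        if close:
            fh.close()


def _parse_row(row: list[str], idx: dict[str, int]) -> CultivarRecord:
    def get(col: str, default: str = "") -> str:
        i = idx.get(col)
        return row[i].strip() if i is not None and i < len(row) else default

    name = unicodedata.normalize("NFC", get("name"))
    if not name:
        raise ValueError("missing cultivar name")
    origin_raw = get("origin_class") or "unknown"
    try:
        origin = OriginClass(origin_raw.lower())
    except ValueError:
        raise ValueError(f"unknown origin_class {origin_raw!r}") from None
    flags_raw = get("flags")
    flags = frozenset(f for f in flags_raw.split(";") if f)
    genotype = SGenotype.parse(
        get("allele1"),
        get("allele2"),
        presumed_homozygous=_bool(get("presumed_homozygous", "0")),
    )
    return CultivarRecord(
        name=name,
        genotype=genotype,
        country=get("country") or "?",
        origin_class=origin,
        flags=flags,
        source=get("source", "study") or "study",
        documented_self_compatible=_bool(get("documented_sc", "0")),
    )


def write_cultivar_table(
    records: Iterable[CultivarRecord], path, delimiter: str = ","
) -> None:
    """Write records in canonical form (inverse of :func:`read_cultivar_table`)."""
    fh, close = _open(path, "w")
    try:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CULTIVAR_COLUMNS + EXTRA_COLUMNS)
        for r in records:
            g = r.genotype
            writer.writerow(
                [
                    r.name,
                    r.country,
                    r.origin_class.value,
                    g.a1,
                    "" if g.a2 == "?" else g.a2,
                    ";".join(sorted(r.flags)),
                    r.source,
                    int(g.presumed_homozygous),
                    int(r.documented_self_compatible),
                ]
            )
    finally:
        if close:
            fh.close()


def read_panel(path, delimiter: str = ",") -> list[PrimerAssayDef]:
    """Parse a primer-panel table (one row per diagnostic fragment size)."""
    fh, close = _open(path)
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        rows = list(reader)
    finally:
        if close:
            fh.close()
    grouped: dict[AssayId, dict] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            assay = AssayId(row["assay"].strip())
            entry = SizeEntry(
                expected_bp=int(row["expected_bp"]),
                candidates=frozenset(
                    parse_allele(a) for a in row["candidates"].split("|") if a
                ),
                verified=_bool(row.get("verified") or "1"),
            )
            tol = int(row["tolerance_bp"])
        except (KeyError, ValueError) as exc:
            raise TableParseError(lineno, str(exc)) from None
        g = grouped.setdefault(
            assay,
            {
                "primer_f": row["primer_f"].strip(),
                "primer_r": row["primer_r"].strip(),
                "tolerance_bp": tol,
                "entries": [],
            },
        )
        g["entries"].append(entry)
    return [
        PrimerAssayDef(
            assay_id=assay,
            primer_f=g["primer_f"],
            primer_r=g["primer_r"],
            size_map=tuple(g["entries"]),
            tolerance_bp=g["tolerance_bp"],
        )
        for assay, g in grouped.items()
    ]


def write_panel(panel: Iterable[PrimerAssayDef], path, delimiter: str = ",") -> None:
    fh, close = _open(path, "w")
    try:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for assay in panel:
            for entry in assay.size_map:
                writer.writerow(
                    [
                        assay.assay_id.value,
                        assay.primer_f,
                        assay.primer_r,
                        entry.expected_bp,
                        "|".join(sorted(entry.candidates)),
                        assay.tolerance_bp,
                        int(entry.verified),
                    ]
                )
    finally:
        if close:
            fh.close()


def read_registry(path, delimiter: str = ",") -> GroupRegistry:
    fh, close = _open(path)
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        registry = GroupRegistry()
        for lineno, row in enumerate(reader, start=2):
            try:
                genotype = SGenotype.parse(row["allele1"], row["allele2"])
                registry.register(genotype, row["group"].strip())
            except (KeyError, ValueError) as exc:
                raise TableParseError(lineno, str(exc)) from None
        return registry
    finally:
        if close:
            fh.close()


def write_registry(registry: GroupRegistry, path, delimiter: str = ",") -> None:
    fh, close = _open(path, "w")
    try:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REGISTRY_COLUMNS)
        for genotype, label in sorted(
            registry.items(), key=lambda kv: (kv[1] != "0", kv[0].a1, kv[0].a2)
        ):
            writer.writerow([genotype.a1, genotype.a2, label])
    finally:
        if close:
            fh.close()


def loads_cultivar_table(text: str, delimiter: str = ",") -> list[CultivarRecord]:
    """Parse a cultivar table from an in-memory string (test convenience)."""
    return read_cultivar_table(_io.StringIO(text), delimiter=delimiter)
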