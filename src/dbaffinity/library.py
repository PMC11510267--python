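"""Authentic-standards spectral library: data model, CSV/JSON I/O, isomer
group indexing, and the packaged 41-standard reference library for
*Uvaria macrophylla* leaf constituents.

The packaged library carries, per standard: the neutral and ion formulas,
polarity, retention time, the curated characteristic MS/MS fragments, the
subset of fragments that are diagnostic within an isomer group, and the
reported leaf content used as ground truth by the synthetic-data generator.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import chem
from .chem import ElementalFormula, IonSpec, ion_mz, parse_formula, ppm_error

#: maximum formula-vs-declared-m/z disagreement tolerated at load time
VALIDATION_PPM = 10.0


class LibraryError(ValueError):
    """Raised when a library file violates the schema or its invariants."""


@dataclass(frozen=True)
class StandardRecord:
    """One authentic standard of the library."""

    id: int
    name: str
    neutral_formula: ElementalFormula
    ion: IonSpec
    rt: float  # minutes
    characteristic_fragments: tuple[float, ...]
    diagnostic_fragments: tuple[float, ...] = ()
    content_truth: float | None = None  # mg/g, used only for data synthesis
    bioactivity: str = ""
    declared_mz: float | None = None  # as tabulated; cross-checked vs formula

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.ion)

    @property
    def polarity(self) -> str:
        return self.ion.polarity

    def validate(self) -> None:
        if self.rt < 0:
            raise LibraryError(f"record {self.id}: negative retention time")
        if not set(self.diagnostic_fragments) <= set(self.characteristic_fragments):
            raise LibraryError(
                f"record {self.id}: diagnostic fragments not a subset of "
                "characteristic fragments")
        mz = self.theoretical_mz
        for f in self.characteristic_fragments:
            if f >= mz + 0.01:
                raise LibraryError(
                    f"record {self.id}: fragment {f} above precursor m/z {mz:.4f}")
        if self.declared_mz is not None:
            if ppm_error(self.declared_mz, mz) > VALIDATION_PPM:
                raise LibraryError(
                    f"record {self.id}: declared m/z {self.declared_mz} is "
                    f">{VALIDATION_PPM} ppm from formula m/z {mz:.4f}")


@dataclass(frozen=True)
class IsomerGroup:
    """Standards sharing an identical ion formula and charge."""

    ion_formula_key: str
    member_ids: tuple[int, ...]


@dataclass
class SpectralLibrary:
    records: list[StandardRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryError("empty library")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise LibraryError("duplicate record ids")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise LibraryError("duplicate record names")
        for r in self.records:
            r.validate()
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: int) -> StandardRecord:
        return self._by_id[record_id]

    def by_polarity(self, polarity: str) -> list[StandardRecord]:
        return [r for r in self.records if r.polarity == polarity]


def isomer_groups(lib: SpectralLibrary) -> list[IsomerGroup]:
    """Group records by (ion formula, charge); singletons are excluded."""
    buckets: dict[str, list[int]] = {}
    for r in lib:
        buckets.setdefault(str(r.ion), []).append(r.id)
    return [IsomerGroup(key, tuple(sorted(ids)))
            for key, ids in sorted(buckets.items()) if len(ids) >= 2]


def _parse_mz_list(cell: str) -> tuple[float, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    return tuple(float(x) for x in cell.split(";") if x.strip())


def _record_from_row(row: dict) -> StandardRecord:
    try:
        return StandardRecord(
            id=int(row["id"]),
            name=row["name"].strip(),
            neutral_formula=parse_formula(row["neutral_formula"]),
            ion=IonSpec(parse_formula(row["ion_formula"]), int(row["charge"])),
            rt=float(row["rt_min"]),
            characteristic_fragments=_parse_mz_list(row["fragments"]),
            diagnostic_fragments=_parse_mz_list(row.get("diagnostic", "")),
            content_truth=(float(row["content_mg_per_g"])
                           if row.get("content_mg_per_g", "") not in ("", None)
                           else None),
            bioactivity=(row.get("bioactivity") or "").strip(),
            declared_mz=(float(row["theoretical_mz"])
                         if row.get("theoretical_mz", "") not in ("", None)
                         else None),
        )
    except (KeyError, ValueError, chem.FormulaError) as exc:
        raise LibraryError(f"bad library row {row.get('id', '?')}: {exc}") from exc


def load_library(path: str | Path, format: str | None = None) -> SpectralLibrary:
    """Load a library from CSV or JSON (format inferred from the suffix).

    CSV schema (one header row):
    ``id,name,neutral_formula,ion_formula,charge,rt_min,fragments,diagnostic,
    content_mg_per_g,bioactivity`` with fragment lists semicolon-separated;
    an optional ``theoretical_mz`` column is cross-checked against the ion
    formula at 10 ppm. The JSON schema mirrors it, one object per record.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        rows = payload["records"] if isinstance(payload, dict) else payload
    else:
        raise LibraryError(f"unknown library format {fmt!r}")
    if not rows:
        raise LibraryError(f"empty library file: {path}")
    records = [_record_from_row(dict(row)) for row in rows]
    return SpectralLibrary(records, metadata={"source": str(path)})


def write_library(lib: SpectralLibrary, path: str | Path,
                  format: str | None = None) -> None:
    """Write a library in the CSV or JSON dialect read by :func:`load_library`."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for r in lib:
        rows.append({
            "id": r.id,
            "name": r.name,
            "neutral_formula": r.neutral_formula.hill(),
            "ion_formula": r.ion.formula.hill(),
            "charge": r.ion.charge,
            "rt_min": repr(r.rt),
            "fragments": ";".join(f"{f:.4f}" for f in r.characteristic_fragments),
            "diagnostic": ";".join(f"{f:.4f}" for f in r.diagnostic_fragments),
            "content_mg_per_g": "" if r.content_truth is None else repr(r.content_truth),
            "bioactivity": r.bioactivity,
            "theoretical_mz": "" if r.declared_mz is None else f"{r.declared_mz:.4f}",
        })
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"records": rows}, fh, indent=1)
    else:
        raise LibraryError(f"unknown library format {fmt!r}")


def load_reference_library() -> SpectralLibrary:
    """The packaged 41-standard *U. macrophylla* leaf library.

    36 standards are negative-mode [M-H]- ions and 5 positive-mode [M+H]+;
    four isomer groups (ids {1,2,3}, {4,5,6}, {7,8}, {23,24}) share an ion
    formula and are told apart by diagnostic fragments and retention time.
    """
    ref = resources.files("dbaffinity.data") / "uvaria_leaf_standards.csv"
    with resources.as_file(ref) as path:
        lib = load_library(path, format="csv")
    lib.metadata["source"] = "packaged U. macrophylla leaf standards"
    return lib


# observed m/z and printed delta-ppm of the tabulated reference runs, kept
# alongside the fixture for the mass-arithmetic regression checks
def load_reference_observations() -> list[dict]:
    ref = resources.files("dbaffinity.data") / "uvaria_leaf_standards.csv"
    with resources.as_file(ref) as path:
        with open(path, newline="", encoding="utf-8") as fh:
            return [
                {"id": int(row["id"]),
                 "observed_mz": float(row["observed_mz"]),
                 "theoretical_mz": float(row["theoretical_mz"]),
                 "delta_ppm": float(row["delta_ppm_printed"])}
                for row in csv.DictReader(fh)
            ]
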