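"""Reading and writing LC-MS/MS runs as peak lists.

Two dialects are supported: MGF (via :mod:`pyteomics.mgf`; one BEGIN
IONS block per feature, RT in seconds, precursor area as the second
PEPMASS value, the A/A+1/A+2 envelope in an ENVELOPE line) and a plain
CSV pair (a feature table plus a long-format fragment table).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from pyteomics import mgf

from .matcher import FeatureObservation, Peak


def write_mgf(run, path: str | Path) -> None:
    spectra = []
    for i, f in enumerate(run, start=1):
        spectra.append({
            "m/z array": np.array([p.mz for p in f.msms]),
            "intensity array": np.array([p.intensity for p in f.msms]),
            "params": {
                "title": f"feature_{i}",
                "pepmass": (f.precursor_mz, f.area),
                "rtinseconds": f.rt * 60.0,
                "charge": [1 if f.polarity == "+" else -1],
                "envelope": ",".join(repr(x) for x in f.envelope),
            },
        })
    mgf.write(spectra, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[FeatureObservation]:
    out = []
    with mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            mz, area = params["pepmass"][0], params["pepmass"][1] or 0.0
            charge = int(params["charge"][0])
            env = tuple(float(x) for x in str(params["envelope"]).split(","))
            peaks = tuple(Peak(float(m), float(i)) for m, i in
                          zip(spec["m/z array"], spec["intensity array"]))
            out.append(FeatureObservation(
                rt=float(params["rtinseconds"]) / 60.0, precursor_mz=float(mz),
                area=float(area), envelope=env, msms=peaks,
                polarity="+" if charge > 0 else "-"))
    return out


def write_csv(run, features_path: str | Path, fragments_path: str | Path) -> None:
    with open(features_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["feature_id", "rt_min", "precursor_mz", "area",
                    "polarity", "envelope"])
        for i, f in enumerate(run, start=1):
            w.writerow([i, repr(f.rt), repr(f.precursor_mz), repr(f.area),
                        f.polarity, ";".join(repr(x) for x in f.envelope)])
    with open(fragments_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["feature_id", "mz", "intensity"])
        for i, f in enumerate(run, start=1):
            for p in f.msms:
                w.writerow([i, repr(p.mz), repr(p.intensity)])


def read_csv(features_path: str | Path,
             fragments_path: str | Path | None = None) -> list[FeatureObservation]:
    frags: dict[int, list[Peak]] = {}
    if fragments_path is not None:
        with open(fragments_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                frags.setdefault(int(row["feature_id"]), []).append(
                    Peak(float(row["mz"]), float(row["intensity"])))
    out = []
    with open(features_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            fid = int(row["feature_id"])
            env = tuple(float(x) for x in row["envelope"].split(";"))
            out.append(FeatureObservation(
                rt=float(row["rt_min"]), precursor_mz=float(row["precursor_mz"]),
                area=float(row["area"]), envelope=env,
                msms=tuple(frags.get(fid, ())), polarity=row["polarity"]))
    return out


def read_run(path: str | Path) -> list[FeatureObservation]:
    """Dispatch on suffix: ``.mgf`` or a feature CSV (with a sibling
    ``<stem>_fragments.csv`` if present)."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        return read_mgf(path)
    sibling = path.with_name(path.stem + "_fragments.csv")
    return read_csv(path, sibling if sibling.exists() else None)
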