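"""Pipeline orchestration: identify -> quantify -> antioxidant contribution.

Ties the stages together, reads the documented CSV inputs, writes the
report (CSV + human-readable text) and the reference-style summary table,
and can materialize a complete synthetic study bundle on disk.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import runio
from .antioxidant import (antioxidant_contribution, scavenging_stats,
                          select_qmarker, AbsorbanceReading)
from .chem import ppm_error, truncate
from .library import SpectralLibrary, isomer_groups, load_library, load_reference_library
from .matcher import MatchParams, MatchResult, identify_run
from .quant import (ExtractionFactors, QuantWarning, fit_calibration,
                    quantify, replicate_stats)
from .simulate import (RunSpec, simulate_abts, simulate_calibration,
                       simulate_replicate_runs)


class MissingInputError(FileNotFoundError):
    """A configured input path does not exist."""


@dataclass
class PipelineConfig:
    library_path: str | None = None  # None -> packaged reference library
    run_paths: list[str] = field(default_factory=list)
    calibration_path: str | None = None
    assay_path: str | None = None
    match_params: MatchParams = field(default_factory=MatchParams)
    factors: ExtractionFactors = field(default_factory=ExtractionFactors)
    basis: str = "powder"
    out_dir: str | None = None
    seed: int = 42


@dataclass
class Report:
    rows: list[dict]
    summary: dict
    log: list[str]

    def to_csv(self, path: str | Path) -> None:
        cols = list(self.rows[0]) if self.rows else _ROW_COLUMNS
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerows(self.rows)

    def to_text(self) -> str:
        lines = ["pipeline summary", "----------------"]
        for k, v in self.summary.items():
            lines.append(f"{k}: {v}")
        lines.append("")
        lines.extend(self.log)
        return "\n".join(lines) + "\n"


_ROW_COLUMNS = ["id", "name", "rt", "observed_mz", "theoretical_mz",
                "ppm_nominal", "ppm_theoretical", "matched_fragments",
                "content_mean", "content_sd", "content_n",
                "scavenging_mean", "scavenging_sd", "relative_level",
                "contribution", "rank"]


def read_calibration_csv(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    """CSV schema: standard_id,concentration_ug_per_ml,area,replicate."""
    series: dict[int, list[tuple[float, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            series.setdefault(int(row["standard_id"]), []).append(
                (float(row["concentration_ug_per_ml"]), float(row["area"])))
    return series


def read_assay_csv(path: str | Path) -> dict[int, list[AbsorbanceReading]]:
    """CSV schema: standard_id,replicate,a0,a."""
    readings: dict[int, list[AbsorbanceReading]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            readings.setdefault(int(row["standard_id"]), []).append(
                AbsorbanceReading(float(row["a0"]), float(row["a"])))
    return readings


def simulate_study(out_dir: str | Path, seed: int = 42,
                   run_spec: RunSpec | None = None, n_replicates: int = 3,
                   lib: SpectralLibrary | None = None) -> PipelineConfig:
    """Write a complete synthetic study bundle and return a config for it.

    The bundle holds ``run_rep<i>.mgf`` replicate runs, ``calibration.csv``,
    ``assay.csv`` and a ``truth.json`` ground-truth manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lib = lib or load_reference_library()
    spec = run_spec or RunSpec(seed=seed)
    runs, truth = simulate_replicate_runs(lib, spec, n_replicates)
    run_paths = []
    for i, run in enumerate(runs, start=1):
        p = out_dir / f"run_rep{i}.mgf"
        runio.write_mgf(run, p)
        run_paths.append(str(p))

    with open(out_dir / "calibration.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["standard_id", "concentration_ug_per_ml", "area", "replicate"])
        for rec in lib:
            slope, intercept = truth.calibration[rec.id]
            pts = simulate_calibration(slope, intercept, seed=seed + rec.id)
            for c, a in pts:
                w.writerow([rec.id, repr(c), repr(a), 1])

    with open(out_dir / "assay.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["standard_id", "replicate", "a0", "a"])
        for rec in lib:
            readings = simulate_abts(truth.scavenging[rec.id], n=n_replicates,
                                     seed=seed + 1000 + rec.id)
            for j, r in enumerate(readings, start=1):
                w.writerow([rec.id, j, repr(r.a0), repr(r.a)])

    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump({
            "contents_mg_per_g": truth.contents,
            "calibration": {k: list(v) for k, v in truth.calibration.items()},
            "scavenging_percent": truth.scavenging,
            "n_noise_features_per_run": spec.n_noise_features,
        }, fh, indent=1)

    return PipelineConfig(run_paths=run_paths,
                          calibration_path=str(out_dir / "calibration.csv"),
                          assay_path=str(out_dir / "assay.csv"),
                          out_dir=str(out_dir), seed=seed)


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute identification, quantification and contribution scoring.

    Stages without configured inputs are skipped (their report columns stay
    empty). Every non-obvious decision is logged with the rule that fired.
    """
    log: list[str] = []
    lib = (load_library(config.library_path) if config.library_path
           else load_reference_library())
    log.append(f"library: {len(lib)} standards "
               f"({len(lib.by_polarity('-'))} negative, "
               f"{len(lib.by_polarity('+'))} positive)")

    for p in list(config.run_paths) + [config.calibration_path, config.assay_path]:
        if p is not None and not Path(p).exists():
            raise MissingInputError(p)

    # --- identification -------------------------------------------------
    runs = [runio.read_run(p) for p in config.run_paths]
    per_run_results: list[list[MatchResult]] = []
    for i, run in enumerate(runs, start=1):
        results = identify_run(run, lib, config.match_params)
        per_run_results.append(results)
        for res in results:
            if res.decision != "identified" and res.rule:
                log.append(f"run {i}: feature m/z {res.feature.precursor_mz:.4f} "
                           f"-> {res.decision} ({res.rule})")
    primary = per_run_results[0] if per_run_results else []
    identified = {r.standard_id: r for r in primary if r.decision == "identified"}

    groups = isomer_groups(lib)
    resolved_groups = sum(1 for g in groups
                          if set(g.member_ids) <= set(identified))

    # --- quantification -------------------------------------------------
    contents = {}
    if config.calibration_path and runs:
        curves = {}
        for sid, pts in read_calibration_csv(config.calibration_path).items():
            curves[sid] = fit_calibration(pts, standard_id=sid)
        replicate_contents: dict[int, list[float]] = {}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", QuantWarning)
            for results in per_run_results:
                for res in results:
                    sid = res.standard_id
                    if res.decision == "identified" and sid in curves:
                        c = quantify(res.feature.area, curves[sid],
                                     config.factors, config.basis)
                        replicate_contents.setdefault(sid, []).append(c)
        log.extend(f"quant: {w.message}" for w in caught
                   if issubclass(w.category, QuantWarning))
        for sid, vals in replicate_contents.items():
            contents[sid] = replicate_stats(vals, standard_id=sid)
        log.append(f"quantified {len(contents)} constituents on the "
                   f"{config.basis} basis over {len(runs)} replicate run(s)")

    # --- antioxidant contribution ---------------------------------------
    scav, scores, qmarker = {}, {}, None
    if config.assay_path and contents:
        for sid, readings in read_assay_csv(config.assay_path).items():
            s = scavenging_stats(readings, standard_id=sid)
            scav[sid] = s
            if s.out_of_range:
                log.append(f"standard {sid}: scavenging outside [0,100]% "
                           "(reported, not clipped)")
        common = sorted(set(scav) & set(contents))
        for sid in common:
            scores[sid] = antioxidant_contribution(
                scav[sid].percent, contents[sid].mean, standard_id=sid)
        if scores:
            qmarker = select_qmarker(scores.values())
            log.append(f"Q-marker: id {qmarker.standard_id} "
                       f"(dominance={qmarker.dominance}, tie={qmarker.tie})")

    # --- assemble report -------------------------------------------------
    order = sorted(scores, key=lambda s: -scores[s].contribution)
    ranks = {sid: i + 1 for i, sid in enumerate(order)}
    rows = []
    for sid in sorted(identified):
        rec, res = lib[sid], identified[sid]
        est = contents.get(sid)
        sc = scav.get(sid)
        score = scores.get(sid)
        obs4, theo4 = round(res.feature.precursor_mz, 4), round(rec.theoretical_mz, 4)
        rows.append({
            "id": sid, "name": rec.name, "rt": round(res.feature.rt, 2),
            "observed_mz": obs4,
            "theoretical_mz": theo4,
            # tabulated convention: error of the 4-decimal printed m/z pair
            "ppm_nominal": truncate(ppm_error(obs4, theo4, "nominal_denominator"))
            if obs4 != theo4 else 0.0,
            "ppm_theoretical": truncate(res.ppm_error),
            "matched_fragments": ";".join(f"{f:.4f}" for f in res.matched_fragments),
            "content_mean": "" if est is None else round(est.mean, 3),
            "content_sd": "" if est is None else round(est.sd, 3),
            "content_n": "" if est is None else est.n,
            "scavenging_mean": "" if sc is None else round(sc.percent, 1),
            "scavenging_sd": "" if sc is None else round(sc.sd, 1),
            "relative_level": "" if score is None else round(score.relative_level, 3),
            "contribution": "" if score is None else round(score.contribution, 3),
            "rank": ranks.get(sid, ""),
        })
    n_ambiguous = sum(1 for r in primary if r.decision == "ambiguous")
    summary = {
        "n_features": len(runs[0]) if runs else 0,
        "n_identified": len(identified),
        "n_ambiguous": n_ambiguous,
        "isomer_groups_resolved": f"{resolved_groups}/{len(groups)}",
        "qmarker_id": None if qmarker is None else qmarker.standard_id,
        "qmarker_dominance": None if qmarker is None else qmarker.dominance,
        "content_basis": config.basis,
        "relative_level_definition": "ABTS scavenging percent / 100",
    }
    report = Report(rows, summary, log)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        (out / "report.txt").write_text(report.to_text(), encoding="utf-8")
        emit_table1_emulation(report, out / "constituent_table.csv", lib)
    return report


_TABLE_COLUMNS = ["No.", "RT Min", "Name", "Molecular Ion",
                  "Observed m/z Value", "Theoretical m/z Value",
                  "Error (delta ppm)", "Content (mg/g) n = 3",
                  "Characteristic MS/MS Fragment Peak m/z", "Bioactivity"]


def emit_table1_emulation(report: Report, path: str | Path,
                          lib: SpectralLibrary | None = None) -> None:
    """Write the identified constituents in the reference tabulation layout.

    Follows that table's formatting conventions: 4-decimal m/z, nominal-
    denominator delta ppm truncated at 4 decimals, 3-decimal contents as
    ``mean +/- sd``.
    """
    lib = lib or load_reference_library()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_TABLE_COLUMNS)
        for row in report.rows:
            rec = lib[row["id"]]
            content = ""
            if row["content_mean"] != "":
                content = f"{row['content_mean']:.3f} ± {row['content_sd']:.3f}"
            w.writerow([
                row["id"], row["rt"], rec.name, str(rec.ion),
                f"{row['observed_mz']:.4f}", f"{row['theoretical_mz']:.4f}",
                f"{row['ppm_nominal']:.4f}", content,
                ", ".join(f"{f:.4f}" for f in rec.characteristic_fragments),
                rec.bioactivity,
            ])
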