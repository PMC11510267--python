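"""Database-affinity identification engine.

A detected LC-MS feature is identified against the authentic-standards
library by comparing four parameters: retention time, molecular-ion m/z
(precursor, ppm tolerance), isotope-pattern fit, and the MS/MS profile with
its characteristic fragments. Isobaric candidates (isomer groups) are told
apart first by diagnostic fragments, then by the weight of fragment
evidence, and finally by retention-time proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import isotope_envelope, ppm_error
from .library import SpectralLibrary, StandardRecord

#: |rt_delta| difference below which two RT-decided candidates are a tie
RT_TIE_MIN = 0.01


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")


@dataclass(frozen=True)
class FeatureObservation:
    """One detected precursor with its isotope envelope and MS/MS spectrum."""

    rt: float  # minutes
    precursor_mz: float
    area: float
    envelope: tuple[float, ...]  # A, A+1, A+2 intensities
    msms: tuple[Peak, ...] = ()
    polarity: str = "-"


@dataclass(frozen=True)
class MatchParams:
    """Identification thresholds.

    Defaults follow the acquisition settings of the workflow this package
    models: 10 ppm precursor tolerance, S/N threshold 5, 90% isotope-pattern
    fit, top-5 MS/MS peaks. The RT tolerance (0.2 min) and the absolute
    fragment tolerance (0.01 Da) are this package's defaults.
    """

    precursor_tol: float = 10.0  # ppm
    fragment_tol: float = 0.01  # Da
    rt_tol: float = 0.2  # minutes
    sn_threshold: float = 5.0
    isotopic_fit_threshold: float = 0.90
    top_n_msms: int = 5

    def __post_init__(self) -> None:
        if min(self.precursor_tol, self.fragment_tol, self.rt_tol,
               self.sn_threshold, self.top_n_msms) <= 0:
            raise ValueError("all match parameters must be positive")
        if not 0 < self.isotopic_fit_threshold <= 1:
            raise ValueError("isotopic_fit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class MatchResult:
    feature: FeatureObservation
    standard_id: int | None
    ppm_error: float = float("nan")
    rt_delta: float = float("nan")
    fragment_score: float = 0.0
    matched_fragments: tuple[float, ...] = ()
    diagnostic_hit: bool = False
    isotopic_fit: float = 0.0
    decision: str = "rejected"  # identified | ambiguous | rejected
    rule: str = ""  # the rule that fixed the decision, for the report log


class AmbiguousMatch(Exception):
    """Isomer discrimination could not single out one candidate."""


def filter_peaks(peaks: list[Peak] | tuple[Peak, ...],
                 sn_threshold: float = 5.0) -> list[Peak]:
    """Drop peaks below ``sn_threshold`` times the noise floor.

    The noise floor is estimated as the median intensity of the spectrum;
    order is preserved. An empty spectrum stays empty.
    """
    if not peaks:
        return []
    floor = float(np.median([p.intensity for p in peaks]))
    return [p for p in peaks if p.intensity >= sn_threshold * floor]


def precursor_candidates(feature: FeatureObservation, lib: SpectralLibrary,
                         params: MatchParams = MatchParams()) -> list[StandardRecord]:
    """Library records of matching polarity within the precursor ppm window,
    sorted by |ppm error| (exact-theoretical-denominator convention)."""
    out = []
    for rec in lib:
        if rec.polarity != feature.polarity:
            continue
        err = ppm_error(feature.precursor_mz, rec.theoretical_mz)
        if err <= params.precursor_tol:
            out.append((err, rec))
    out.sort(key=lambda t: (t[0], t[1].id))
    return [rec for _, rec in out]


def isotopic_fit(observed_envelope, theoretical) -> float:
    """Cosine similarity of the observed and theoretical isotope envelopes.

    Both vectors are truncated to their common length and scaled to unit
    sum before the cosine is taken; the result lies in [0, 1] for
    non-negative envelopes.
    """
    obs = np.asarray(observed_envelope, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.ndim != 1 or theo.ndim != 1 or len(obs) < 2 or len(theo) < 2:
        raise ValueError("envelopes must be 1-d with at least two peaks")
    if not obs.any():
        raise ValueError("observed envelope is all zero")
    k = min(len(obs), len(theo))
    obs, theo = obs[:k], theo[:k]
    obs = obs / obs.sum()
    theo = theo / theo.sum()
    return float(obs @ theo / (np.linalg.norm(obs) * np.linalg.norm(theo)))


def fragment_match_score(msms, record: StandardRecord,
                         fragment_tol: float = 0.01):
    """Match the record's characteristic fragments against a spectrum.

    Returns ``(score, matched, diagnostic_hit)``: *score* is the fraction of
    characteristic fragments with an observed peak within ``fragment_tol``;
    *diagnostic_hit* is True iff every diagnostic fragment matched
    (vacuously true for an empty diagnostic set, except that an empty
    spectrum with a non-empty diagnostic set never hits).
    """
    if not record.characteristic_fragments:
        raise ValueError(f"record {record.id} has no characteristic fragments")
    mzs = np.array([p.mz for p in msms]) if msms else np.empty(0)
    matched = tuple(
        f for f in record.characteristic_fragments
        if mzs.size and np.min(np.abs(mzs - f)) <= fragment_tol)
    score = len(matched) / len(record.characteristic_fragments)
    diagnostic_hit = all(f in matched for f in record.diagnostic_fragments)
    return score, matched, diagnostic_hit


def _evidence(feature: FeatureObservation, rec: StandardRecord,
              params: MatchParams, peaks) -> dict:
    score, matched, diag = fragment_match_score(peaks, rec, params.fragment_tol)
    n_diag = sum(1 for f in rec.diagnostic_fragments if f in matched)
    return {
        "record": rec,
        "ppm": ppm_error(feature.precursor_mz, rec.theoretical_mz),
        "rt_delta": feature.rt - rec.rt,
        "score": score,
        "matched": matched,
        "diag_hit": diag,
        "n_diag": n_diag,
    }


def discriminate_isomers(candidates: list[StandardRecord],
                         feature: FeatureObservation,
                         params: MatchParams = MatchParams()) -> StandardRecord:
    """Pick one record out of isobaric candidates.

    Order of evidence: (1) keep candidates whose diagnostic fragments all
    matched, when any candidate's did; (2) prefer more matched diagnostic
    fragments, then more matched fragments, then a higher fragment score;
    (3) break remaining ties by retention-time proximity, requiring
    |rt delta| <= rt_tol. Raises :class:`AmbiguousMatch` when the best two
    candidates remain tied within 0.01 min of RT proximity.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if len(candidates) == 1:
        return candidates[0]
    peaks = sorted(filter_peaks(feature.msms, params.sn_threshold),
                   key=lambda p: -p.intensity)[: params.top_n_msms]
    ev = [_evidence(feature, rec, params, peaks) for rec in candidates]
    hits = [e for e in ev if e["diag_hit"] and e["record"].diagnostic_fragments]
    if hits:
        ev = hits
    best_key = max((e["n_diag"], len(e["matched"]), e["score"]) for e in ev)
    ev = [e for e in ev
          if (e["n_diag"], len(e["matched"]), e["score"]) == best_key]
    if len(ev) == 1:
        return ev[0]["record"]
    ev = [e for e in ev if abs(e["rt_delta"]) <= params.rt_tol]
    if not ev:
        raise AmbiguousMatch("no tied candidate within the RT tolerance")
    ev.sort(key=lambda e: (abs(e["rt_delta"]), e["record"].id))
    if len(ev) > 1 and abs(abs(ev[0]["rt_delta"]) - abs(ev[1]["rt_delta"])) < RT_TIE_MIN:
        raise AmbiguousMatch("RT proximity tie within 0.01 min")
    return ev[0]["record"]


def _match_feature(feature: FeatureObservation, lib: SpectralLibrary,
                   params: MatchParams) -> MatchResult:
    cands = precursor_candidates(feature, lib, params)
    if not cands:
        return MatchResult(feature, None, rule="10 ppm gate")
    peaks = sorted(filter_peaks(feature.msms, params.sn_threshold),
                   key=lambda p: -p.intensity)[: params.top_n_msms]
    survivors = []
    for rec in cands:
        fit = isotopic_fit(feature.envelope, _theoretical_envelope(rec))
        if fit < params.isotopic_fit_threshold:
            continue
        e = _evidence(feature, rec, params, peaks)
        if abs(e["rt_delta"]) > params.rt_tol:
            continue
        if peaks and e["score"] == 0:
            continue  # MS/MS present but no characteristic fragment matched
        e["fit"] = fit
        survivors.append(e)
    if not survivors:
        return MatchResult(feature, None, rule="isotopic fit 0.90 gate / RT / MS2")
    if len(survivors) == 1:
        chosen, rule = survivors[0], "single candidate"
    else:
        try:
            rec = discriminate_isomers([e["record"] for e in survivors],
                                       feature, params)
        except AmbiguousMatch as exc:
            e0 = min(survivors, key=lambda e: e["ppm"])
            return MatchResult(feature, None, ppm_error=e0["ppm"],
                               rt_delta=e0["rt_delta"], isotopic_fit=e0["fit"],
                               decision="ambiguous", rule=str(exc))
        chosen = next(e for e in survivors if e["record"].id == rec.id)
        rule = ("diagnostic fragments" if chosen["record"].diagnostic_fragments
                else "RT proximity")
    return MatchResult(
        feature, chosen["record"].id, ppm_error=chosen["ppm"],
        rt_delta=chosen["rt_delta"], fragment_score=chosen["score"],
        matched_fragments=chosen["matched"], diagnostic_hit=chosen["diag_hit"],
        isotopic_fit=chosen["fit"], decision="identified", rule=rule)


_ENVELOPE_CACHE: dict[str, tuple[float, ...]] = {}


def _theoretical_envelope(rec: StandardRecord, n_peaks: int = 3):
    key = str(rec.ion)
    if key not in _ENVELOPE_CACHE:
        _ENVELOPE_CACHE[key] = tuple(a for _, a in isotope_envelope(rec.ion, n_peaks))
    return _ENVELOPE_CACHE[key]


def identify_run(run, lib: SpectralLibrary,
                 params: MatchParams = MatchParams()) -> list[MatchResult]:
    """Identify every feature of a run against the library.

    Each feature passes the precursor, isotope-fit, RT and MS/MS gates and,
    when several candidates survive, isomer discrimination. A standard may
    be claimed by at most one feature: on conflict the feature with the
    smaller |ppm error| keeps the identification and the others are demoted
    to ambiguous.
    """
    results = [_match_feature(f, lib, params) for f in run]
    # one-to-one assignment: best ppm wins, losers demoted
    claims: dict[int, list[int]] = {}
    for i, res in enumerate(results):
        if res.decision == "identified":
            claims.setdefault(res.standard_id, []).append(i)
    for sid, idxs in claims.items():
        if len(idxs) > 1:
            idxs.sort(key=lambda i: (results[i].ppm_error, i))
            for i in idxs[1:]:
                results[i] = replace(results[i], standard_id=None,
                                     decision="ambiguous",
                                     rule="standard already claimed (best ppm wins)")
    return results
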