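"""Ground-truth generator emulating the study design of the modeled assay.

Produces every input the pipeline consumes: LC-MS/MS feature runs (one
feature per library standard plus decoy noise features), calibration
series, and ABTS plate-reader absorbances. All generators are pure
functions of their inputs and a seed.

The defaults mirror the acquisition they emulate: precursor m/z jitter
well inside the 10 ppm window (sd 1 ppm), RT jitter sd 0.05 min, no
fragment dropout, 20 noise features in the scanned m/z 100-1500 range,
relative area noise 1%, and ABTS control absorbance 0.65 +/- 0.01.

The default scavenging profile is a reconstruction of the modeled study's
qualitative statements (six constituents at 100%, ids 34-41 negligible,
the rest mid-range), not measured data; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .antioxidant import AbsorbanceReading
from .chem import isotope_envelope, ppm_error
from .library import SpectralLibrary
from .matcher import FeatureObservation, Peak

#: ids reported to quench the ABTS radical completely at the assay dose
FULL_SCAVENGER_IDS = frozenset({18, 22, 24, 29, 32, 33})
#: ids reported to have negligible scavenging (steroids, fatty acids, ...)
NEGLIGIBLE_SCAVENGER_IDS = frozenset(range(34, 42))

MZ_RANGE = (100.0, 1500.0)  # scanned mass range, Da
NOISE_EXCLUSION_PPM = 50.0  # noise features keep clear of library ions


@dataclass(frozen=True)
class RunSpec:
    """Noise model of one synthetic LC-MS/MS run."""

    seed: int = 42
    ppm_jitter_sd: float = 1.0  # ppm, precursor and fragment m/z
    rt_jitter_sd: float = 0.05  # minutes
    fragment_dropout_p: float = 0.0  # per non-diagnostic fragment
    n_noise_features: int = 20
    noise_intensity_scale: float = 1e4
    envelope_noise_rel: float = 0.05
    area_noise_rel: float = 0.01
    fragment_sigma: float = 0.5  # log-normal intensity spread
    #: weak chemical-noise peaks per MS/MS spectrum; they form the noise
    #: floor the matcher's S/N filter estimates (a spectrum holding only
    #: strong real fragments has no floor to measure)
    msms_noise_peaks: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.fragment_dropout_p <= 1:
            raise ValueError("fragment_dropout_p must be in [0, 1]")
        if min(self.ppm_jitter_sd, self.rt_jitter_sd, self.envelope_noise_rel,
               self.area_noise_rel) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic run."""

    feature_ids: list[int | None]  # per feature: true standard id or None
    contents: dict[int, float]  # mg/g powder
    calibration: dict[int, tuple[float, float]]  # id -> (slope, intercept)
    scavenging: dict[int, float]  # id -> true percent


def default_scavenging_profile(lib: SpectralLibrary) -> dict[int, float]:
    """Reconstructed true scavenging percentages for the packaged library."""
    out = {}
    for rec in lib:
        if rec.id in FULL_SCAVENGER_IDS:
            out[rec.id] = 100.0
        elif rec.id in NEGLIGIBLE_SCAVENGER_IDS:
            out[rec.id] = 0.0
        else:
            out[rec.id] = 50.0
    return out


def true_calibration_params(lib: SpectralLibrary, seed: int):
    """Per-standard true calibration lines (slope in area per ug/mL).

    Slopes are log-uniform over 200-2000 (instrument response spans about
    an order of magnitude between constituents); intercepts are small and
    positive so that low-content constituents stay quantifiable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    params = {}
    for rec in lib:
        slope = float(np.exp(rng.uniform(math.log(200.0), math.log(2000.0))))
        intercept = float(rng.uniform(0.0, 20.0))
        params[rec.id] = (slope, intercept)
    return params


def _true_area(content: float, slope: float, intercept: float,
               solution_conc: float = 30.0) -> float:
    conc = content * solution_conc  # mg/g x mg/mL -> ug/mL
    return slope * conc + intercept


def simulate_run(lib: SpectralLibrary, spec: RunSpec = RunSpec(),
                 calibration_params: dict | None = None):
    """One synthetic run: a feature per library record plus noise features.

    Returns ``(features, truth)``. Precursor and fragment m/z get relative
    Gaussian jitter (ppm), RT gets absolute Gaussian jitter, the isotope
    envelope gets relative noise, fragment intensities are log-normal with
    the true record's diagnostic fragments always the most intense, and
    areas follow the true calibration lines with relative noise. Noise
    features sit at uniform random m/z avoiding +/-50 ppm of every library
    ion and never match any standard.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    contents = {r.id: (r.content_truth if r.content_truth is not None else 0.1)
                for r in lib}
    calib = calibration_params or true_calibration_params(lib, spec.seed)
    scav = default_scavenging_profile(lib)
    features: list[FeatureObservation] = []
    truth_ids: list[int | None] = []

    for rec in lib:
        theo = rec.theoretical_mz
        mz = theo * (1.0 + rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6)
        rt = max(rec.rt + rng.normal(0.0, spec.rt_jitter_sd), 0.0)
        env = np.array([a for _, a in isotope_envelope(rec.ion, 3)])
        env = np.clip(env * (1.0 + rng.normal(0.0, spec.envelope_noise_rel,
                                              env.shape)), 0.0, None)
        slope, intercept = calib[rec.id]
        area = _true_area(contents[rec.id], slope, intercept)
        area *= max(1.0 + rng.normal(0.0, spec.area_noise_rel), 0.0)

        peaks = []
        intensities = {}
        for f in rec.characteristic_fragments:
            is_diag = f in rec.diagnostic_fragments
            if not is_diag and rng.random() < spec.fragment_dropout_p:
                continue
            intensities[f] = rng.lognormal(math.log(spec.noise_intensity_scale),
                                           spec.fragment_sigma)
        if intensities:
            top = max(intensities.values())
            for f in rec.diagnostic_fragments:
                if f in intensities:  # diagnostics outshine the rest
                    intensities[f] = top * rng.uniform(1.2, 2.0)
            for f, inten in intensities.items():
                fmz = f * (1.0 + rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6)
                peaks.append(Peak(fmz, float(inten)))
        # chemical-noise floor: weak peaks clear of the real fragments,
        # at ~1/50 of the real-fragment intensity scale
        noise_scale = spec.noise_intensity_scale / 50.0
        for _ in range(spec.msms_noise_peaks):
            nmz = rng.uniform(50.0, max(theo, 60.0))
            if any(abs(nmz - f) < 0.02 for f in rec.characteristic_fragments):
                continue
            peaks.append(Peak(float(nmz),
                              float(rng.lognormal(math.log(noise_scale), 1.0))))
        features.append(FeatureObservation(
            rt=rt, precursor_mz=float(mz), area=float(area),
            envelope=tuple(float(x) for x in env),
            msms=tuple(peaks), polarity=rec.polarity))
        truth_ids.append(rec.id)

    library_mzs = np.array([r.theoretical_mz for r in lib])
    n_neg = len(lib.by_polarity("-"))
    p_neg = n_neg / len(lib)
    made = 0
    while made < spec.n_noise_features:
        mz = rng.uniform(*MZ_RANGE)
        if np.min(np.abs(mz - library_mzs) / library_mzs) * 1e6 < NOISE_EXCLUSION_PPM:
            continue
        assert all(ppm_error(mz, t) >= NOISE_EXCLUSION_PPM for t in library_mzs)
        rt = rng.uniform(0.3, 17.0)
        env = rng.dirichlet(np.ones(3))
        n_peaks = rng.integers(2, 6)
        msms = tuple(Peak(float(rng.uniform(50.0, mz)),
                          float(rng.lognormal(math.log(spec.noise_intensity_scale),
                                              spec.fragment_sigma)))
                     for _ in range(n_peaks))
        features.append(FeatureObservation(
            rt=float(rt), precursor_mz=float(mz),
            area=float(rng.lognormal(math.log(1e4), 1.0)),
            envelope=tuple(float(x) for x in env), msms=msms,
            polarity="-" if rng.random() < p_neg else "+"))
        truth_ids.append(None)
        made += 1

    truth = GroundTruth(truth_ids, contents, calib, scav)
    return features, truth


def simulate_replicate_runs(lib: SpectralLibrary, spec: RunSpec = RunSpec(),
                            n_replicates: int = 3):
    """Independent replicate runs sharing one ground truth (seeds derived
    from ``spec.seed``)."""
    calib = true_calibration_params(lib, spec.seed)
    runs = []
    truth = None
    for i in range(n_replicates):
        rep_spec = replace(spec, seed=spec.seed + 7919 * i)
        feats, t = simulate_run(lib, rep_spec, calibration_params=calib)
        truth = truth or t
        runs.append(feats)
    return runs, truth


#: default calibration levels in ug/mL (a design choice of this package;
#: the modeled protocol only documents a 30 ug/mL standard solution)
DEFAULT_LEVELS = (0.5, 1.0, 5.0, 10.0, 50.0, 100.0)


def simulate_calibration(truth_slope: float, truth_intercept: float,
                         levels=DEFAULT_LEVELS, noise_rel: float = 0.01,
                         seed: int = 0):
    """(concentration, area) pairs on a true line with relative area noise."""
    if len(levels) < 2:
        raise ValueError("need at least two calibration levels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    pts = []
    for c in levels:
        area = (truth_slope * c + truth_intercept)
        area *= 1.0 + rng.normal(0.0, noise_rel)
        pts.append((float(c), float(area)))
    return pts


def simulate_abts(true_percent: float, a0_mean: float = 0.65,
                  a0_sd: float = 0.01, n: int = 3, seed: int = 0):
    """Replicate ABTS absorbance readings for a true scavenging percent.

    A0 is Gaussian around 0.65 (truncated positive); A is the unquenched
    fraction of A0 plus read noise at half the A0 spread.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = []
    for _ in range(n):
        a0 = 0.0
        while a0 <= 0:
            a0 = rng.normal(a0_mean, a0_sd)
        a = a0 * (1.0 - true_percent / 100.0) + rng.normal(0.0, a0_sd / 2.0)
        out.append(AbsorbanceReading(float(a0), float(a)))
    return out
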