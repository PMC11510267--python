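"""ABTS radical-cation scavenging and antioxidant-contribution scoring.

The ABTS assay reads absorbance at 734 nm: A0 for the radical solution
alone (0.65 +/- 0.01 in the modeled protocol) and A after adding the
constituent. Scavenging% = (A0 - A) / A0 x 100. A constituent's
antioxidant contribution is its relative antioxidant level (scavenging
fraction) times its chemical content in mg/g; the constituent with the
largest contribution is the antioxidant quality marker (Q-marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AbsorbanceReading:
    a0: float  # control absorbance at 734 nm
    a: float  # sample absorbance at 734 nm
    blank_corrected: bool = True

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("control absorbance A0 must be positive")


@dataclass(frozen=True)
class ScavengingResult:
    standard_id: int
    percent: float  # mean over replicates
    sd: float = 0.0
    n: int = 1
    out_of_range: bool = False  # any replicate outside [0, 100]


@dataclass(frozen=True)
class ContributionScore:
    standard_id: int
    relative_level: float  # scavenging fraction, percent / 100
    content: float  # mg/g
    contribution: float  # mg/g-equivalent


@dataclass(frozen=True)
class QMarkerSelection:
    standard_id: int
    dominance: bool  # contribution exceeds the sum of all others
    tie: bool = False


def scavenging_percent(r: AbsorbanceReading) -> float:
    """(A0 - A)/A0 x 100. Values outside [0, 100] pass through unclipped;
    callers flag them (assay drift is information, not an error)."""
    return (r.a0 - r.a) / r.a0 * 100.0


def scavenging_stats(readings, standard_id: int = 0) -> ScavengingResult:
    """Replicate mean +/- sample SD of scavenging percentages."""
    vals = [scavenging_percent(r) for r in readings]
    if not vals:
        raise ValueError("no absorbance readings")
    sd = 0.0 if len(vals) == 1 else float(np.std(vals, ddof=1))
    oor = any(v < 0 or v > 100 for v in vals)
    return ScavengingResult(standard_id, float(np.mean(vals)), sd, len(vals),
                            out_of_range=oor)


def antioxidant_contribution(percent: float, content: float,
                             standard_id: int = 0) -> ContributionScore:
    """Contribution = relative antioxidant level x chemical content."""
    if content < 0:
        raise ValueError("content must be non-negative")
    level = percent / 100.0
    return ContributionScore(standard_id, level, content, level * content)


def select_qmarker(scores) -> QMarkerSelection:
    """Pick the maximal-contribution constituent.

    ``dominance`` is True when the winner's contribution exceeds the sum of
    all other contributions. Ties on the maximum are broken by the lower
    standard id and flagged.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no contribution scores")
    best = max(s.contribution for s in scores)
    winners = sorted(s.standard_id for s in scores if s.contribution == best)
    rest = sum(s.contribution for s in scores if s.standard_id != winners[0])
    return QMarkerSelection(winners[0], dominance=best > rest,
                            tie=len(winners) > 1)
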