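"""Candidate enumeration and filtered siRNA design on a target mRNA.

Slides a 23-nt window along the mRNA (one candidate per start position),
derives guide and passenger strands, evaluates every candidate against the
five selection conditions, and emits an ordered report.  Passing rows are
ordered by seed-duplex Tm ascending (weakest off-target inducer first),
then A/U count in guide positions 1-7 descending, then window start; the
ordering is presentation only and never changes the pass set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import pandas as pd

from .core_seq import (
    NucleotideSequence,
    SequenceValidationError,
    SiRNACandidate,
    TARGET_WINDOW_LENGTH,
    normalize,
)
from .rules import MAX_GC_STRETCH_ALLOWED, MIN_AU_1TO7, RuleReport, evaluate
from .thermo import DESIGN_TM_THRESHOLD_C, NNParameterSet

logger = logging.getLogger("sirnaselect")

#: Column order of the design report TSV.
DESIGN_REPORT_COLUMNS = (
    "target_id",
    "window_start",
    "target_window",
    "guide",
    "passenger",
    "pos1_au",
    "au_count_1to7",
    "pos19_gc",
    "max_gc_stretch",
    "seed",
    "seed_tm_celsius",
    "all_pass",
    "rank",
)


@dataclass(frozen=True)
class DesignConfig:
    """Tunable thresholds and policies for a design run."""

    tm_threshold: float = DESIGN_TM_THRESHOLD_C
    min_au_1to7: int = MIN_AU_1TO7
    max_gc_stretch_allowed: int = MAX_GC_STRETCH_ALLOWED
    require_all_rules: bool = True
    skip_ambiguous_windows: bool = False
    restrict_to_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.tm_threshold):
            raise ValueError("tm_threshold must be finite")
        if self.min_au_1to7 < 0 or self.max_gc_stretch_allowed < 0:
            raise ValueError("rule thresholds must be non-negative")
        if self.restrict_to_region is not None:
            start, end = self.restrict_to_region
            if not (1 <= start <= end):
                raise ValueError(f"invalid region {self.restrict_to_region}")


@dataclass(frozen=True)
class DesignReportRow:
    """One evaluated candidate with its rank in the ordered report."""

    candidate: SiRNACandidate
    report: RuleReport
    rank: int

    def to_row(self) -> dict:
        c, r = self.candidate, self.report
        return {
            "target_id": c.target_id,
            "window_start": c.window_start,
            "target_window": c.target_window.residues,
            "guide": c.guide.residues,
            "passenger": c.passenger.residues,
            "pos1_au": r.pos1_au,
            "au_count_1to7": r.au_count_1to7,
            "pos19_gc": r.pos19_gc,
            "max_gc_stretch": r.max_gc_stretch,
            "seed": r.seed,
            "seed_tm_celsius": r.seed_tm_celsius,
            "all_pass": r.all_pass,
            "rank": self.rank,
        }


def enumerate_candidates(
    mrna: NucleotideSequence, region: tuple[int, int] | None = None
) -> list[SiRNACandidate]:
    """All 23-nt windows of the mRNA as siRNA candidates, 5'->3' order.

    ``region`` restricts window starts to a 1-based inclusive interval on
    the mRNA (windows must lie entirely inside it).  An mRNA shorter than
    23 nt yields an empty list with a warning.
    """
    n = len(mrna)
    if n < TARGET_WINDOW_LENGTH:
        logger.warning(
            "mRNA %r is %d nt, shorter than the %d-nt window; no candidates",
            mrna.id, n, TARGET_WINDOW_LENGTH,
        )
        return []
    lo, hi = 1, n - TARGET_WINDOW_LENGTH + 1
    if region is not None:
        start, end = region
        if not (1 <= start <= end <= n):
            raise ValueError(f"region {region} outside sequence 1..{n}")
        lo = max(lo, start)
        hi = min(hi, end - TARGET_WINDOW_LENGTH + 1)
    return [
        SiRNACandidate.from_window(
            mrna.region(i, i + TARGET_WINDOW_LENGTH - 1), target_id=mrna.id, window_start=i
        )
        for i in range(lo, hi + 1)
    ]


def _windows_from_raw(
    raw: str, id: str, config: DesignConfig
) -> tuple[NucleotideSequence | None, list[int]]:
    """Normalize raw text, optionally tolerating ambiguous characters.

    Returns the normalized sequence (with ambiguous characters replaced by
    a placeholder handled at window level) and the list of bad 1-based
    positions.  Without ``skip_ambiguous_windows`` a bad character aborts.
    """
    stripped = "".join(raw.split()).upper()
    bad_positions = [i for i, c in enumerate(stripped, start=1) if c not in "ACGTU"]
    if bad_positions and not config.skip_ambiguous_windows:
        raise SequenceValidationError(
            f"invalid character {stripped[bad_positions[0] - 1]!r} at position "
            f"{bad_positions[0]} in sequence {id!r} (set skip_ambiguous_windows to tolerate)"
        )
    # Substitute bad residues with A so a NucleotideSequence can be built;
    # every window overlapping a bad position is excluded afterwards.
    chars = list(stripped.replace("T", "U"))
    for p in bad_positions:
        chars[p - 1] = "A"
    alphabet = "DNA" if "T" in stripped else "RNA"
    return NucleotideSequence("".join(chars), id=id, original_alphabet=alphabet), bad_positions


def design(
    mrna: Union[str, NucleotideSequence],
    config: DesignConfig | None = None,
    params: NNParameterSet | None = None,
    target_id: str = "",
) -> list[DesignReportRow]:
    """Evaluate every candidate window and return the ordered design report.

    With ``config.require_all_rules`` (default) only candidates passing
    all five conditions are returned; otherwise every window is returned.
    Rows are ordered by (seed Tm ascending, A/U count 1-7 descending,
    window start ascending) and ranked 1..N.
    """
    if config is None:
        config = DesignConfig()

    skipped: set[int] = set()
    if isinstance(mrna, str):
        seq, bad_positions = _windows_from_raw(mrna, target_id, config)
        if bad_positions:
            bad = set(bad_positions)
            n = len(seq)
            for start in range(1, max(0, n - TARGET_WINDOW_LENGTH + 1) + 1):
                if any(p in bad for p in range(start, start + TARGET_WINDOW_LENGTH)):
                    skipped.add(start)
            logger.warning(
                "skipping %d windows overlapping %d ambiguous positions in %r",
                len(skipped), len(bad_positions), target_id,
            )
    else:
        seq = mrna

    candidates = enumerate_candidates(seq, region=config.restrict_to_region)
    if skipped:
        candidates = [c for c in candidates if c.window_start not in skipped]

    evaluated = [(c, evaluate(c, params, config)) for c in candidates]
    if config.require_all_rules:
        evaluated = [(c, r) for c, r in evaluated if r.all_pass]
    evaluated.sort(key=lambda cr: (cr[1].seed_tm_celsius, -cr[1].au_count_1to7, cr[0].window_start))
    return [
        DesignReportRow(candidate=c, report=r, rank=i)
        for i, (c, r) in enumerate(evaluated, start=1)
    ]


def report_to_dataframe(rows: list[DesignReportRow]) -> pd.DataFrame:
    """Design report as a DataFrame with the documented column order."""
    return pd.DataFrame([r.to_row() for r in rows], columns=list(DESIGN_REPORT_COLUMNS))


def write_design_tsv(rows: list[DesignReportRow], path: Union[str, Path]) -> None:
    """Write the design report as TSV."""
    report_to_dataframe(rows).to_csv(path, sep="\t", index=False)
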