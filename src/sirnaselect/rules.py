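"""The functional-siRNA sequence rules, evaluated on a 21-nt guide strand.

Five conditions define a good candidate (positions 1-based from the guide
5' end):

1. A or U at position 1 — favors guide-strand retention in the RISC and
   anchoring of the guide 5' nucleotide in the Argonaute MID pocket.
2. Four to seven A/U residues at positions 1-7 (>= 57% A/U) — a
   thermodynamically unstable guide 5' terminus drives asymmetric
   unwinding.
3. G or C at position 19 — a stable passenger 5' terminus, the other half
   of the asymmetry.
4. No G/C stretch longer than 9 nt anywhere in the strand — long GC runs
   trap the cleaved passenger fragments on the guide.
5. Seed-duplex Tm at or below the threshold (default 21.5 degC) — a weak
   seed-target helix makes the guide a poor inducer of off-target
   repression.

Rules 1-4 are pure sequence predicates on the guide; rule 5 delegates to
:mod:`sirnaselect.thermo`.  Literature variants (Reynolds: A specifically
preferred at position 1; Amarzguioui: G/C but not U at position 19) are
reported as informational annotations and never enter the overall verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Union

from .core_seq import NucleotideSequence, SequenceValidationError, SiRNACandidate
from .thermo import DESIGN_TM_THRESHOLD_C, NNParameterSet, seed_tm

if TYPE_CHECKING:  # pragma: no cover
    from .designer import DesignConfig

GUIDE_LENGTH = 21
MIN_AU_1TO7 = 4
MAX_GC_STRETCH_ALLOWED = 9

#: Column order of a serialized rule report (TSV).
RULE_REPORT_COLUMNS = (
    "pos1_au",
    "au_count_1to7",
    "au_rule_pass",
    "pos19_gc",
    "max_gc_stretch",
    "gc_stretch_pass",
    "seed",
    "seed_tm_celsius",
    "seed_tm_pass",
    "all_pass",
    "annotations",
)


@dataclass(frozen=True)
class RuleReport:
    """Per-rule outcomes for one candidate guide strand."""

    pos1_au: bool
    au_count_1to7: int
    au_rule_pass: bool
    pos19_gc: bool
    max_gc_stretch: int
    gc_stretch_pass: bool
    seed: str
    seed_tm_celsius: float
    seed_tm_pass: bool
    all_pass: bool
    annotations: frozenset[str] = frozenset()

    def to_row(self) -> dict:
        """One TSV row, columns as in :data:`RULE_REPORT_COLUMNS`."""
        d = {c: getattr(self, c) for c in RULE_REPORT_COLUMNS}
        d["annotations"] = ",".join(sorted(self.annotations))
        return d


def _coerce_guide(guide: Union[str, NucleotideSequence]) -> str:
    s = guide.residues if isinstance(guide, NucleotideSequence) else guide
    if len(s) != GUIDE_LENGTH:
        raise SequenceValidationError(f"guide must be {GUIDE_LENGTH} nt, got {len(s)}")
    return s


def rule_position1(guide: Union[str, NucleotideSequence]) -> bool:
    """A or U at guide position 1 (5' end)."""
    return _coerce_guide(guide)[0] in "AU"


def rule_au_1to7(guide: Union[str, NucleotideSequence]) -> tuple[int, bool]:
    """A/U count over guide positions 1-7; passes with four or more."""
    s = _coerce_guide(guide)
    count = sum(1 for c in s[:7] if c in "AU")
    return count, count >= MIN_AU_1TO7


def rule_position19(guide: Union[str, NucleotideSequence]) -> bool:
    """G or C at guide position 19."""
    return _coerce_guide(guide)[18] in "GC"


def max_gc_stretch(seq: Union[str, NucleotideSequence]) -> int:
    """Length of the longest run of consecutive G/C residues (0 if none)."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    best = run = 0
    for c in s:
        run = run + 1 if c in "GC" else 0
        if run > best:
            best = run
    return best


def evaluate(
    candidate: SiRNACandidate,
    params: NNParameterSet | None = None,
    config: "DesignConfig | None" = None,
) -> RuleReport:
    """Evaluate all five conditions on a candidate, returning a full report.

    ``config`` may be any object carrying ``tm_threshold``,
    ``min_au_1to7`` and ``max_gc_stretch_allowed`` (a
    :class:`~sirnaselect.designer.DesignConfig` qualifies); defaults are
    the standard thresholds.  The GC-stretch rule is evaluated on the
    21-nt guide strand: within the 19-bp duplex core any G/C run in the
    guide implies an equal-length run in the passenger.
    """
    tm_threshold = getattr(config, "tm_threshold", DESIGN_TM_THRESHOLD_C)
    min_au = getattr(config, "min_au_1to7", MIN_AU_1TO7)
    max_gc_allowed = getattr(config, "max_gc_stretch_allowed", MAX_GC_STRETCH_ALLOWED)

    guide = candidate.guide.residues
    pos1 = rule_position1(guide)
    au_count, _ = rule_au_1to7(guide)
    au_pass = au_count >= min_au
    pos19 = rule_position19(guide)
    stretch = max_gc_stretch(guide)
    stretch_pass = stretch <= max_gc_allowed
    seed = candidate.seed
    tm = seed_tm(seed, params)
    tm_pass = tm <= tm_threshold

    annotations = set()
    if guide[0] == "A":
        annotations.add("reynolds_pos1_A")
    if pos19:  # G/C at 19 necessarily excludes U
        annotations.add("amarzguioui_pos19_not_U")

    return RuleReport(
        pos1_au=pos1,
        au_count_1to7=au_count,
        au_rule_pass=au_pass,
        pos19_gc=pos19,
        max_gc_stretch=stretch,
        gc_stretch_pass=stretch_pass,
        seed=seed,
        seed_tm_celsius=tm,
        seed_tm_pass=tm_pass,
        all_pass=pos1 and au_pass and pos19 and stretch_pass and tm_pass,
        annotations=frozenset(annotations),
    )
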