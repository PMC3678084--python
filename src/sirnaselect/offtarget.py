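"""Seed-complementary site scanning in 3'-UTR collections.

Seed-dependent off-target repression needs only a perfect Watson-Crick
match between the guide seed (positions 2-8) and a 7-nt site on a
transcript, so auditing a guide amounts to locating every occurrence of
the seed's reverse complement in the supplied UTR sequences.  Whether the
guide is a good or poor off-target inducer is decided not by how many
sites exist but by the seed-duplex stability: guides whose seed-target Tm
reaches the benchmark (default 21.5 degC) are classed ``strong`` inducers,
those below it ``weak``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .core_seq import NucleotideSequence, SequenceValidationError, revcomp
from .thermo import DESIGN_TM_THRESHOLD_C, NNParameterSet, seed_tm

SEED_SITE_LENGTH = 7


@dataclass(frozen=True)
class SeedMatch:
    """One seed-complementary heptamer site on a UTR (sense strand)."""

    utr_id: str
    position: int  # 1-based start of the 7-nt site
    matched_heptamer: str
    guide_seed: str

    def __post_init__(self) -> None:
        if self.matched_heptamer != revcomp(self.guide_seed):
            raise ValueError("matched heptamer is not the reverse complement of the seed")


@dataclass(frozen=True)
class OffTargetSummary:
    """Aggregate audit of one guide against a UTR collection."""

    guide_seed: str
    seed_tm_celsius: float
    inducer_class: str  # "strong" or "weak"
    matches_per_utr: dict[str, int]
    total_matches: int


def _guide_seed(guide: Union[str, NucleotideSequence]) -> str:
    s = guide.residues if isinstance(guide, NucleotideSequence) else guide
    if len(s) != 21:
        raise SequenceValidationError(f"guide must be 21 nt, got {len(s)}")
    return s[1:8]  # positions 2-8, 1-based


def find_seed_matches(
    guide: Union[str, NucleotideSequence],
    utrs: Iterable[NucleotideSequence],
) -> list[SeedMatch]:
    """Every seed-complementary site of a guide across a UTR collection.

    Sites are exact reverse complements of guide positions 2-8 (no G:U
    wobble); overlapping occurrences are all reported, ordered by UTR
    input order then position.
    """
    seed = _guide_seed(guide)
    target = revcomp(seed)
    matches: list[SeedMatch] = []
    for utr in utrs:
        hay = utr.residues
        start = hay.find(target)
        while start != -1:
            matches.append(
                SeedMatch(
                    utr_id=utr.id,
                    position=start + 1,
                    matched_heptamer=target,
                    guide_seed=seed,
                )
            )
            start = hay.find(target, start + 1)  # shift-by-one: overlap-inclusive
    return matches


def summarize(
    guide: Union[str, NucleotideSequence],
    utrs: Iterable[NucleotideSequence],
    params: NNParameterSet | None = None,
    benchmark_tm: float = DESIGN_TM_THRESHOLD_C,
) -> OffTargetSummary:
    """Audit one guide: per-UTR site counts plus the Tm-based inducer class.

    ``inducer_class`` is ``strong`` when the seed-duplex Tm is at or above
    the benchmark and ``weak`` otherwise; it depends only on the seed and
    the thermodynamic parameters, never on the UTR set.
    """
    utrs = list(utrs)
    seed = _guide_seed(guide)
    tm = seed_tm(seed, params)
    counts: dict[str, int] = {u.id: 0 for u in utrs}
    for m in find_seed_matches(guide, utrs):
        counts[m.utr_id] += 1
    return OffTargetSummary(
        guide_seed=seed,
        seed_tm_celsius=tm,
        inducer_class="strong" if tm >= benchmark_tm else "weak",
        matches_per_utr=counts,
        total_matches=sum(counts.values()),
    )


def matches_to_dataframe(matches: list[SeedMatch]) -> pd.DataFrame:
    cols = ["utr_id", "position", "matched_heptamer", "guide_seed"]
    return pd.DataFrame(
        [{c: getattr(m, c) for c in cols} for m in matches], columns=cols
    )


def write_matches_tsv(matches: list[SeedMatch], path: Union[str, Path]) -> None:
    """Write seed-match sites as TSV, one row per site."""
    matches_to_dataframe(matches).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summary: OffTargetSummary, path: Union[str, Path]) -> None:
    """Write the per-guide audit summary as a one-row TSV."""
    pd.DataFrame(
        [
            {
                "guide_seed": summary.guide_seed,
                "seed_tm_celsius": summary.seed_tm_celsius,
                "inducer_class": summary.inducer_class,
                "total_matches": summary.total_matches,
                "n_utrs": len(summary.matches_per_utr),
            }
        ]
    ).to_csv(path, sep="\t", index=False)
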