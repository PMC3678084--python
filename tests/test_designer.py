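import random

import pytest

from sirnaselect import (
    DesignConfig,
    NucleotideSequence,
    SequenceValidationError,
    design,
    enumerate_candidates,
    generate_synthetic_mrna,
    report_to_dataframe,
    seed_tm,
)
from sirnaselect.core_seq import revcomp
from sirnaselect.designer import DESIGN_REPORT_COLUMNS, write_design_tsv


def _naive_all_pass(window: str, tm_threshold: float = 21.5) -> bool:
    """Re-derive the five conditions for a 23-nt window from scratch."""
    guide = revcomp(window[:21])
    if guide[0] not in "AU":
        return False
    if sum(c in "AU" for c in guide[:7]) < 4:
        return False
    if guide[18] not in "GC":
        return False
    run = best = 0
    for c in guide:
        run = run + 1 if c in "GC" else 0
        best = max(best, run)
    if best > 9:
        return False
    return seed_tm(guide[1:8]) <= tm_threshold


@pytest.mark.parametrize("length, expected", [(30, 8), (23, 1), (24, 2)])
def test_candidate_counts(length, expected):
    mrna = generate_synthetic_mrna(length, 0.5, 3)
    assert len(enumerate_candidates(mrna)) == expected


def test_short_mrna_yields_no_candidates(caplog):
    mrna = NucleotideSequence("A" * 22, id="short")
    with caplog.at_level("WARNING", logger="sirnaselect"):
        assert enumerate_candidates(mrna) == []
    assert "shorter" in caplog.text


def test_candidate_strands_recomputed_independently():
    mrna = generate_synthetic_mrna(60, 0.5, 9)
    for cand in enumerate_candidates(mrna):
        w = mrna.residues[cand.window_start - 1 : cand.window_start + 22]
        assert cand.target_window.residues == w
        assert cand.guide.residues == revcomp(w[:21])
        assert cand.passenger.residues == w[2:]


def test_poly_a_mrna_has_zero_passing_designs():
    mrna = NucleotideSequence("A" * 40, id="polyA")
    assert design(mrna) == []


def test_planted_window_is_the_unique_passing_design(planted_mrna):
    rows = design(planted_mrna)
    assert len(rows) == 1
    assert rows[0].candidate.window_start == 31
    assert rows[0].rank == 1
    assert rows[0].report.all_pass


def test_no_filter_reports_every_window():
    mrna = generate_synthetic_mrna(80, 0.5, 5)
    rows = design(mrna, DesignConfig(require_all_rules=False))
    assert len(rows) == len(enumerate_candidates(mrna))


def test_design_matches_exhaustive_naive_reevaluation():
    """Pass set identical to a from-scratch evaluation of all windows (<=200 nt)."""
    for seed in (1, 2, 3):
        mrna = generate_synthetic_mrna(200, 0.45, seed)
        got = {r.candidate.window_start for r in design(mrna)}
        expected = {
            i
            for i in range(1, len(mrna) - 22 + 1)
            if _naive_all_pass(mrna.residues[i - 1 : i + 22])
        }
        assert got == expected


def test_design_invariant_to_case_and_t_u_spelling():
    mrna = generate_synthetic_mrna(120, 0.5, 8, id="m")
    as_dna = mrna.residues.replace("U", "t").lower()
    rows_rna = design(mrna)
    rows_dna = design(as_dna, target_id="m")
    assert [(r.candidate.window_start, r.rank) for r in rows_rna] == [
        (r.candidate.window_start, r.rank) for r in rows_dna
    ]


def test_ordering_is_total_and_reproducible():
    mrna = generate_synthetic_mrna(300, 0.4, 13)
    rows1 = design(mrna, DesignConfig(require_all_rules=False))
    rows2 = design(mrna, DesignConfig(require_all_rules=False))
    assert [r.rank for r in rows1] == list(range(1, len(rows1) + 1))
    assert [
        (r.candidate.window_start, r.rank) for r in rows1
    ] == [(r.candidate.window_start, r.rank) for r in rows2]
    # primary key: seed Tm ascending
    tms = [r.report.seed_tm_celsius for r in rows1]
    assert tms == sorted(tms)


def test_lowering_tm_threshold_never_adds_designs():
    mrna = generate_synthetic_mrna(400, 0.45, 21)
    counts = [
        len(design(mrna, DesignConfig(tm_threshold=t))) for t in (30.0, 21.5, 15.0, 5.0, -20.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_region_restriction_bounds_window_starts(planted_mrna):
    rows = design(planted_mrna, DesignConfig(require_all_rules=False,
                                             restrict_to_region=(31, 60)))
    starts = {r.candidate.window_start for r in rows}
    assert starts == set(range(31, 60 - 23 + 2))
    with pytest.raises(ValueError):
        design(planted_mrna, DesignConfig(restrict_to_region=(0, 10)))


def test_ambiguous_characters_abort_unless_skipped(caplog):
    raw = "A" * 30 + "N" + "A" * 30
    with pytest.raises(SequenceValidationError):
        design(raw, target_id="amb")
    with caplog.at_level("WARNING", logger="sirnaselect"):
        rows = design(raw, DesignConfig(require_all_rules=False,
                                        skip_ambiguous_windows=True), target_id="amb")
    assert "skipping" in caplog.text
    starts = {r.candidate.window_start for r in rows}
    # windows overlapping position 31 (starts 9..31) are excluded
    assert starts == set(range(1, 9)) | set(range(32, 40))


def test_report_dataframe_and_tsv(tmp_path, planted_mrna):
    rows = design(planted_mrna)
    df = report_to_dataframe(rows)
    assert list(df.columns) == list(DESIGN_REPORT_COLUMNS)
    out = tmp_path / "design.tsv"
    write_design_tsv(rows, out)
    header = out.read_text().splitlines()[0]
    assert header.split("\t") == list(DESIGN_REPORT_COLUMNS)
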