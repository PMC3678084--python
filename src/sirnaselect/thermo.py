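"""Nearest-neighbor melting temperature of the 7-bp seed-target duplex.

The guide-strand seed (positions 2-8) pairing its perfect Watson-Crick
complement on a target mRNA forms a 7-bp RNA/RNA helix.  Its melting
temperature under the two-state nearest-neighbor model is

    Tm(degC) = 1000 * dH / (dS + R * ln(CT / 4)) - 273.15 + 16.6 * log10([Na+])

where dH (kcal/mol) and dS (cal/(mol*K)) sum the six interior dinucleotide
stacks plus helix initiation, R is the gas constant, CT the total strand
concentration of a non-self-complementary duplex, and the last term the
standard sodium correction.  The shipped stack table is the RNA/RNA set of
Freier et al. (1986); defaults are R = 1.987 cal/(mol*K), CT = 100 uM,
[Na+] = 100 mM.  Seeds with Tm at or below ~21.5 degC form duplexes too
unstable to trigger seed-dependent off-target repression, which is what
makes this quantity the design filter.

This module also enumerates the complete 7-mer seed space (4^7 = 16,384
sequences) to quantify how much of it is available below a threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .core_seq import NucleotideSequence, SequenceValidationError, revcomp

#: Tm threshold used when selecting siRNAs for design (degC, inclusive).
DESIGN_TM_THRESHOLD_C = 21.5
#: Tm threshold used when summarizing the seed space (degC, inclusive).
SEED_SPACE_TM_THRESHOLD_C = 21.0

SEED_LENGTH = 7
SEED_SPACE_SIZE = 4**SEED_LENGTH  # 16,384

_ALL_STACKS = tuple("".join(p) for p in itertools.product("ACGU", repeat=2))


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stack parameters plus solution conditions.

    ``stack_dH``/``stack_dS`` map all 16 dinucleotide stacks (read 5'->3'
    on either strand of a Watson-Crick duplex) to enthalpy (kcal/mol) and
    entropy (cal/(mol*K)); the table must be duplex-symmetric, i.e. a stack
    and its reverse complement carry identical parameters.
    """

    stack_dH: Mapping[str, float]
    stack_dS: Mapping[str, float]
    init_dH: float = 0.0
    init_dS: float = -10.8
    gas_constant_R: float = 1.987  # cal/(mol*K)
    total_strand_conc_CT: float = 100e-6  # mol/L
    sodium_conc: float = 0.1  # mol/L
    name: str = ""

    def __post_init__(self) -> None:
        for table, label in ((self.stack_dH, "dH"), (self.stack_dS, "dS")):
            missing = [s for s in _ALL_STACKS if s not in table]
            if missing:
                raise ValueError(f"{label} table missing stacks: {missing}")
            asym = [s for s in _ALL_STACKS if table[s] != table[revcomp(s)]]
            if asym:
                raise ValueError(f"{label} table not duplex-symmetric at stacks: {asym}")
        if self.total_strand_conc_CT <= 0:
            raise ValueError("total strand concentration must be positive")
        if self.sodium_conc <= 0:
            raise ValueError("sodium concentration must be positive")


@dataclass(frozen=True)
class SeedTmResult:
    """Tm of one 7-nt seed and its relation to a threshold."""

    seed: str
    tm_celsius: float
    below_threshold: bool


def _parse_nn_table(path: Path) -> tuple[dict[str, float], dict[str, float], float, float]:
    stack_dH: dict[str, float] = {}
    stack_dS: dict[str, float] = {}
    init_dH = 0.0
    init_dS = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("stack\t"):
                continue
            stack, dh, ds = line.split("\t")
            if stack == "init":
                init_dH, init_dS = float(dh), float(ds)
            else:
                stack_dH[stack] = float(dh)
                stack_dS[stack] = float(ds)
    return stack_dH, stack_dS, init_dH, init_dS


def load_nn_parameters(path: Union[str, Path, None] = None, **overrides) -> NNParameterSet:
    """Load a nearest-neighbor parameter table from a TSV file.

    With no ``path`` the packaged Freier et al. (1986) RNA/RNA table is
    loaded.  Solution conditions (``gas_constant_R``,
    ``total_strand_conc_CT``, ``sodium_conc``) may be overridden by
    keyword.
    """
    if path is None:
        with resources.as_file(
            resources.files("sirnaselect.data") / "freier1986_rna_nn.tsv"
        ) as p:
            stack_dH, stack_dS, init_dH, init_dS = _parse_nn_table(p)
        name = overrides.pop("name", "freier1986_rna_nn")
    else:
        stack_dH, stack_dS, init_dH, init_dS = _parse_nn_table(Path(path))
        name = overrides.pop("name", Path(path).stem)
    return NNParameterSet(
        stack_dH=stack_dH,
        stack_dS=stack_dS,
        init_dH=init_dH,
        init_dS=init_dS,
        name=name,
        **overrides,
    )


@lru_cache(maxsize=1)
def default_parameters() -> NNParameterSet:
    """The packaged Freier 1986 RNA/RNA parameter set (cached)."""
    return load_nn_parameters()


def _coerce_seed(seed: Union[str, NucleotideSequence]) -> str:
    s = seed.residues if isinstance(seed, NucleotideSequence) else seed
    if len(s) != SEED_LENGTH:
        raise SequenceValidationError(f"seed must be {SEED_LENGTH} nt, got {len(s)}")
    bad = next((i for i, c in enumerate(s, start=1) if c not in "ACGU"), None)
    if bad is not None:
        raise SequenceValidationError(f"invalid residue {s[bad - 1]!r} at seed position {bad}")
    return s


def seed_tm(
    seed: Union[str, NucleotideSequence], params: NNParameterSet | None = None
) -> float:
    """Melting temperature (degC) of the fully complementary 7-bp seed duplex.

    Sums the six interior stacks of the helix plus initiation and applies
    the non-self-complementary two-state formula with sodium correction.
    Because the stack table is duplex-symmetric,
    ``seed_tm(x) == seed_tm(reverse_complement(x))`` exactly.
    """
    s = _coerce_seed(seed)
    if params is None:
        params = default_parameters()
    # Canonicalize each stack to its duplex-symmetric representative and sum
    # in sorted order so that a seed and its reverse complement accumulate
    # identical floating-point totals (exact strand symmetry).
    stacks = sorted(min(st, revcomp(st)) for st in (s[i : i + 2] for i in range(SEED_LENGTH - 1)))
    dh = params.init_dH
    ds = params.init_dS
    for st in stacks:
        dh += params.stack_dH[st]
        ds += params.stack_dS[st]
    denom = ds + params.gas_constant_R * math.log(params.total_strand_conc_CT / 4.0)
    return (
        (dh * 1000.0) / denom
        - 273.15
        + 16.6 * math.log10(params.sodium_conc)
    )


def seed_tm_result(
    seed: Union[str, NucleotideSequence],
    params: NNParameterSet | None = None,
    threshold_celsius: float = DESIGN_TM_THRESHOLD_C,
) -> SeedTmResult:
    """Tm of one seed classified against an inclusive threshold."""
    s = _coerce_seed(seed)
    tm = seed_tm(s, params)
    return SeedTmResult(seed=s, tm_celsius=tm, below_threshold=tm <= threshold_celsius)


def all_seeds() -> list[str]:
    """All 4^7 seed 7-mers in lexicographic (A < C < G < U) order."""
    return ["".join(p) for p in itertools.product("ACGU", repeat=SEED_LENGTH)]


def enumerate_seed_space(
    params: NNParameterSet | None = None,
    threshold_celsius: float = SEED_SPACE_TM_THRESHOLD_C,
) -> pd.DataFrame:
    """Tm of every possible 7-nt seed, one row per 7-mer.

    Returns a DataFrame with columns ``seed``, ``tm_celsius`` and
    ``below_threshold`` (Tm <= ``threshold_celsius``), 16,384 rows in
    deterministic lexicographic order.
    """
    if params is None:
        params = default_parameters()
    seeds = all_seeds()
    tms = [seed_tm(s, params) for s in seeds]
    df = pd.DataFrame({"seed": seeds, "tm_celsius": tms})
    df["below_threshold"] = df["tm_celsius"] <= threshold_celsius
    return df


def fraction_below(
    threshold_celsius: float, params: NNParameterSet | None = None
) -> float:
    """Fraction of the 16,384-seed space with Tm <= ``threshold_celsius``."""
    if params is None:
        params = default_parameters()
    n = sum(1 for s in all_seeds() if seed_tm(s, params) <= threshold_celsius)
    return n / SEED_SPACE_SIZE


def write_seed_space_tsv(
    path: Union[str, Path],
    params: NNParameterSet | None = None,
    threshold_celsius: float = SEED_SPACE_TM_THRESHOLD_C,
) -> None:
    """Export the full seed-space table as TSV."""
    enumerate_seed_space(params, threshold_celsius).to_csv(path, sep="\t", index=False)
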