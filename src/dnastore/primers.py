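"""Primer library design.

Primers double as file indexes: a pair of 20-nt sequences flanks every
fragment of a file and is what an in-silico PCR selection matches on.
Design therefore has two goals: each primer must look like a usable oligo
(GC content, no long homopolymer), and any two primers in a library must be
mutually distinguishable, operationalised here as a minimum pairwise
Hamming distance.

The generator is seeded rejection sampling: draw uniform random L_p-mers,
reject any that violate the single-sequence constraints or come too close
to an already accepted primer. This is exact, reproducible, and fast at
the library sizes a storage pool needs (tens to hundreds of pairs).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .errors import AlphabetError, PrimerDesignError

ALPHABET = frozenset("ACGT")
NUCLEOTIDE_ORDER = "ACGT"

ROLE_FILE_F = "file-forward"
ROLE_FILE_R = "file-reverse"
ROLE_UNI_F = "universal-forward"
ROLE_UNI_R = "universal-reverse"


@dataclass(frozen=True)
class Primer:
    sequence: str
    role: str = ROLE_FILE_F

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse pair; the integer id is the library label."""

    id: int
    forward: Primer
    reverse: Primer

    def as_universal(self) -> "PrimerPair":
        return PrimerPair(
            self.id,
            Primer(self.forward.sequence, ROLE_UNI_F),
            Primer(self.reverse.sequence, ROLE_UNI_R),
        )


@dataclass(frozen=True)
class PrimerConstraints:
    gc_min: float = 0.4
    gc_max: float = 0.6
    max_homopolymer: int = 3
    min_pairwise_distance: int = 8
    max_attempts: int = 20_000

    def __post_init__(self):
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.min_pairwise_distance < 1:
            raise ValueError("min_pairwise_distance must be >= 1")


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(sequence: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(sequence))


def gc_fraction(sequence: str) -> float:
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def check_primer_constraints(sequence: str,
                             constraints: PrimerConstraints
                             ) -> ValidationReport:
    """Validate one sequence against the single-primer rules.

    Returns a report whose ``violations`` names each failed rule
    (``"gc_content"``, ``"homopolymer"``). Pairwise distance is a library
    property and is not checked here. Non-ACGT characters raise
    :class:`AlphabetError`.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    foreign = set(sequence) - ALPHABET
    if foreign:
        raise AlphabetError(
            f"non-ACGT characters in primer: {sorted(foreign)}")
    violations = []
    if not (constraints.gc_min <= gc_fraction(sequence)
            <= constraints.gc_max):
        violations.append("gc_content")
    if max_homopolymer_run(sequence) > constraints.max_homopolymer:
        violations.append("homopolymer")
    return ValidationReport(not violations, violations)


def generate_primer_library(count: int,
                            L_p: int = 20,
                            constraints: PrimerConstraints | None = None,
                            seed: int = 0) -> list[PrimerPair]:
    """Generate *count* mutually distant primer pairs of length *L_p*.

    All ``2 * count`` primers satisfy the single-sequence constraints and
    every unordered pair is at Hamming distance >=
    ``constraints.min_pairwise_distance``. Identical (count, L_p,
    constraints, seed) inputs give byte-identical libraries. Raises
    :class:`PrimerDesignError` once ``max_attempts`` consecutive draws fail
    for a single slot, which signals that the constraint set cannot yield a
    library of the requested size.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if L_p < 4:
        raise ValueError("L_p must be >= 4")
    constraints = constraints or PrimerConstraints()
    rng = random.Random(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < 2 * count:
        if attempts >= constraints.max_attempts:
            raise PrimerDesignError(
                f"gave up after {attempts} rejected candidates while "
                f"filling primer {len(accepted) + 1} of {2 * count}; "
                f"relax constraints or shorten the library")
        candidate = "".join(rng.choice(NUCLEOTIDE_ORDER)
                            for _ in range(L_p))
        attempts += 1
        if not check_primer_constraints(candidate, constraints).passed:
            continue
        if any(hamming_distance(candidate, prev)
               < constraints.min_pairwise_distance for prev in accepted):
            continue
        accepted.append(candidate)
        attempts = 0
    return [
        PrimerPair(i + 1,
                   Primer(accepted[2 * i], ROLE_FILE_F),
                   Primer(accepted[2 * i + 1], ROLE_FILE_R))
        for i in range(count)
    ]
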