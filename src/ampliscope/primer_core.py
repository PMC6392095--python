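"""IUPAC degenerate-sequence algebra and primer definitions.

A degenerate PCR primer is a mixture of concrete oligonucleotides written as a
single string over the 15-letter IUPAC DNA alphabet (A, C, G, T plus the eleven
ambiguity codes). This module provides the primitive operations every other
module builds on: code-set lookup, degeneracy, expansion into concrete
sequences, IUPAC-aware reverse complement, and mismatch counting between two
(possibly degenerate) equal-length sequences.

Mismatch semantics: two positions *match* whenever the IUPAC code sets of the
two characters intersect. For a concrete site this equals the minimum Hamming
distance over all expansions of the degenerate sequence — the interpretation
used when asking how far a binding site lies from the best-matching primer
formulation. A reference `N` therefore never counts as a mismatch: it denotes
an unknown base, not a different one.

The primer presets for the V1-V2, V3-V4 and V4 hypervariable-region pairs
(27F-YM/338R, 341F/806RB, 515F/806RB) ship as a packaged tab-separated table
and can be overridden by a user file in the same format.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import DegeneracyCapError, DataError, InvalidAlphabetError

#: IUPAC code -> set of concrete bases. DNA only; U and gap characters are invalid.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: frozenset of bases -> IUPAC code.
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: IUPAC complement table (complement of the code's base set).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: SETS_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}

DEFAULT_EXPANSION_CAP = 4096


def validate_iupac(seq: str, context: str = "") -> str:
    """Uppercase ``seq`` and verify every character is a valid IUPAC DNA code.

    Raises :class:`InvalidAlphabetError` naming the first offending character
    and its 0-based position. U is rejected (DNA only), as are gaps.
    """
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise InvalidAlphabetError(ch, i, context)
    return up


def iupac_set(code: str) -> frozenset[str]:
    """Return the set of concrete bases denoted by a single IUPAC letter."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise InvalidAlphabetError(code, 0) from None


def degeneracy(seq: str) -> int:
    """Number of concrete sequences encoded by ``seq``.

    Product over positions of the code-set cardinality; equals
    ``len(expand(seq))`` whenever expansion is permitted.
    """
    up = validate_iupac(seq)
    d = 1
    for ch in up:
        d *= len(IUPAC_SETS[ch])
    return d


def expand(seq: str, cap: int = DEFAULT_EXPANSION_CAP) -> list[str]:
    """All concrete DNA sequences consistent with ``seq``, lexicographically sorted.

    Refuses (``DegeneracyCapError``) when the degeneracy exceeds ``cap`` — an
    N-rich input would otherwise explode combinatorially.
    """
    up = validate_iupac(seq)
    d = degeneracy(up)
    if d > cap:
        raise DegeneracyCapError(
            f"degeneracy {d} of {seq!r} exceeds expansion cap {cap}"
        )
    choices = [sorted(IUPAC_SETS[ch]) for ch in up]
    return ["".join(t) for t in itertools.product(*choices)]


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution: Y<->R, W<->W, N<->N)."""
    up = validate_iupac(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(up))


def mismatches(a: str, b: str) -> int:
    """Count positions where the IUPAC code sets of ``a`` and ``b`` are disjoint.

    Symmetric in its arguments. When one side is concrete this equals the
    minimum Hamming distance over expansions of the other. Raises on unequal
    lengths.
    """
    ua = validate_iupac(a)
    ub = validate_iupac(b)
    if len(ua) != len(ub):
        raise ValueError(
            f"length mismatch: {len(ua)} vs {len(ub)} (ungapped comparison only)"
        )
    return sum(
        1 for x, y in zip(ua, ub) if not (IUPAC_SETS[x] & IUPAC_SETS[y])
    )


def merge_codes(a: str, b: str) -> str:
    """Position-wise IUPAC union of two equal-length sequences.

    The result is the minimal-degeneracy IUPAC sequence whose expansion set
    contains every expansion of both inputs (used in primer-pool merging).
    """
    ua = validate_iupac(a)
    ub = validate_iupac(b)
    if len(ua) != len(ub):
        raise ValueError(f"length mismatch: {len(ua)} vs {len(ub)}")
    return "".join(
        SETS_TO_CODE[IUPAC_SETS[x] | IUPAC_SETS[y]] for x, y in zip(ua, ub)
    )


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named degenerate primer, written 5'->3' as synthesized.

    ``direction`` is ``"forward"`` (anneals to the minus strand; its sequence
    reads along the plus strand) or ``"reverse"`` (anneals to the plus strand;
    its plus-strand binding site is the reverse complement of the sequence).
    """

    name: str
    sequence: str
    direction: str

    def __post_init__(self):
        seq = validate_iupac(self.sequence, context=f"primer {self.name}")
        object.__setattr__(self, "sequence", seq)
        if not 10 <= len(seq) <= 50:
            raise ValueError(
                f"primer {self.name}: length {len(seq)} outside [10, 50]"
            )
        if self.direction not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name}: direction must be 'forward' or 'reverse', "
                f"got {self.direction!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    def expansions(self, cap: int = DEFAULT_EXPANSION_CAP) -> list[str]:
        return expand(self.sequence, cap=cap)

    def plus_strand_query(self) -> str:
        """Sequence to compare against plus-strand template windows."""
        return self.sequence if self.direction == "forward" else revcomp(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair amplifying one hypervariable region."""

    region_name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    expected_mean_size: int | None = None

    def __post_init__(self):
        if self.forward.direction != "forward":
            raise ValueError(f"pair {self.region_name}: forward primer has direction "
                             f"{self.forward.direction!r}")
        if self.reverse.direction != "reverse":
            raise ValueError(f"pair {self.region_name}: reverse primer has direction "
                             f"{self.reverse.direction!r}")
        if self.expected_mean_size is not None:
            floor = len(self.forward) + len(self.reverse)
            if self.expected_mean_size <= floor:
                raise ValueError(
                    f"pair {self.region_name}: expected_mean_size "
                    f"{self.expected_mean_size} <= combined primer length {floor}"
                )


#: Mean amplicon sizes (bp, region plus both primer footprints) per region.
PRESET_MEAN_SIZES = {"V1-V2": 349, "V3-V4": 466, "V4": 292}


def _read_primer_table(lines: Iterable[str], source: str) -> list[dict[str, str]]:
    rows = []
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            missing = {"name", "direction", "sequence", "region"} - set(header)
            if missing:
                raise DataError(
                    f"{source}: missing column(s) {sorted(missing)} in header"
                )
            continue
        if len(fields) != len(header):
            raise DataError(f"{source} line {lineno}: expected {len(header)} "
                            f"tab-separated fields, got {len(fields)}")
        rows.append(dict(zip(header, fields)))
    if header is None:
        raise DataError(f"{source}: empty primer table")
    return rows


def load_primers(path: str | Path | None = None) -> dict[str, DegeneratePrimer]:
    """Load primers from a Table-2-style TSV (columns name, direction, sequence, region).

    With no path, the packaged preset table is used. Returns a dict keyed by
    primer name; a name listed under several regions must carry one sequence.
    """
    if path is None:
        text = resources.files("ampliscope.data").joinpath("primers_16s.tsv").read_text()
        rows = _read_primer_table(text.splitlines(), "packaged primer table")
    else:
        rows = _read_primer_table(Path(path).read_text().splitlines(), str(path))
    primers: dict[str, DegeneratePrimer] = {}
    for row in rows:
        p = DegeneratePrimer(
            name=row["name"].strip(),
            sequence=row["sequence"].strip(),
            direction=row["direction"].strip().lower(),
        )
        prev = primers.get(p.name)
        if prev is not None and prev != p:
            raise DataError(f"primer {p.name!r} defined twice with different fields")
        primers[p.name] = p
    return primers


def load_pairs(path: str | Path | None = None,
               mean_sizes: dict[str, int] | None = None) -> dict[str, PrimerPair]:
    """Build region -> PrimerPair from a primer table (packaged presets by default)."""
    if path is None:
        text = resources.files("ampliscope.data").joinpath("primers_16s.tsv").read_text()
        rows = _read_primer_table(text.splitlines(), "packaged primer table")
        if mean_sizes is None:
            mean_sizes = PRESET_MEAN_SIZES
    else:
        rows = _read_primer_table(Path(path).read_text().splitlines(), str(path))
    mean_sizes = mean_sizes or {}
    by_region: dict[str, dict[str, DegeneratePrimer]] = {}
    for row in rows:
        p = DegeneratePrimer(row["name"].strip(), row["sequence"].strip(),
                             row["direction"].strip().lower())
        slot = by_region.setdefault(row["region"].strip(), {})
        if p.direction in slot:
            raise DataError(f"region {row['region']!r}: two {p.direction} primers")
        slot[p.direction] = p
    pairs = {}
    for region, slot in by_region.items():
        if set(slot) != {"forward", "reverse"}:
            raise DataError(f"region {region!r}: needs one forward and one reverse primer")
        pairs[region] = PrimerPair(
            region_name=region,
            forward=slot["forward"],
            reverse=slot["reverse"],
            expected_mean_size=mean_sizes.get(region),
        )
    return pairs


def preset_primers() -> dict[str, DegeneratePrimer]:
    """The five study primers (27F-YM, 338R, 341F, 806RB, 515F)."""
    return load_primers(None)


def preset_pairs() -> list[PrimerPair]:
    """The three study primer pairs (V1-V2, V3-V4, V4) with mean amplicon sizes."""
    pairs = load_pairs(None)
    return [pairs[r] for r in ("V1-V2", "V3-V4", "V4")]
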