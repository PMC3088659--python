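"""Domain types for hammerhead ribozyme detection and annotation.

The hammerhead motif is a three-helix junction whose catalytic core consists
of 13 strictly constrained nucleotides: box 1 (C3 U4 G5 A6 N7 G8 A9) between
stems I and II, box 2 (G12 A13 A14) between stems II and III, the conserved
closing pair of stem III (A15.1-U16.1), and the cleavage-site residue H17.
Strand scission occurs at the phosphodiester immediately 3' of residue 17.

Going 5'->3' around the conceptual circle the elements are::

    stemI 1.x half - loop I - stemI 2.x half - box1 -
    stemII 10.x half - loop II - stemII 11.x half - box2 -
    stemIII 15.x half - loop III - stemIII 16.x half - residue 17 - (back to 1.1)

Natural hammerheads occur as the three circular permutations of this circle,
named for the stem that is opened (lacks a terminal loop and carries the
molecule's termini): type I, type II and type III.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

# --------------------------------------------------------------------------
# Nucleotide alphabet
# --------------------------------------------------------------------------

RNA_BASES = ("A", "C", "G", "U")

#: IUPAC nucleotide ambiguity codes mapped to the set of RNA bases they admit.
IUPAC: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class AlphabetError(ValueError):
    """Raised for characters outside the IUPAC nucleotide alphabet."""


def complement(base: str) -> str:
    """Watson-Crick complement of an unambiguous RNA base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"not an unambiguous RNA base: {base!r}") from None


_IUPAC_COMPLEMENT = {
    "A": "U", "U": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement, defined for the full IUPAC alphabet."""
    try:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise AlphabetError(f"not a nucleotide symbol: {exc.args[0]!r}") from None


def is_pair(x: str, y: str, allow_wobble: bool = True) -> bool:
    """True if x/y form a Watson-Crick pair, or a G-U wobble when allowed.

    Ambiguity codes are legal input but never count as paired: a stem is only
    as good as the unambiguous evidence for it.
    """
    for b in (x, y):
        if b not in IUPAC:
            raise AlphabetError(f"not a nucleotide symbol: {b!r}")
    if (x, y) in _WC_PAIRS:
        return True
    return allow_wobble and (x, y) in _WOBBLE_PAIRS


def normalize_sequence(seq: str, record_id: str = "<seq>") -> str:
    """Uppercase, convert T to U, and validate against the IUPAC alphabet.

    Raises :class:`AlphabetError` naming the record and 0-based offset of the
    first illegal character.
    """
    out = seq.upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in IUPAC:
            raise AlphabetError(
                f"record {record_id}: illegal character {ch!r} at offset {i}"
            )
    return out


# --------------------------------------------------------------------------
# Core consensus
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NucSet:
    """A consensus position: an IUPAC symbol and the base set it allows."""

    symbol: str
    allowed: frozenset

    def __post_init__(self):
        if not self.allowed:
            raise ValueError("empty nucleotide set")

    @classmethod
    def from_symbol(cls, symbol: str) -> "NucSet":
        if symbol not in IUPAC:
            raise AlphabetError(f"unknown IUPAC code: {symbol!r}")
        return cls(symbol, IUPAC[symbol])

    def matches(self, letter: str) -> bool:
        """Subset rule: an input letter matches iff its IUPAC set is a
        subset of the allowed set (so an input N only matches consensus N)."""
        if letter not in IUPAC:
            raise AlphabetError(f"not a nucleotide symbol: {letter!r}")
        return IUPAC[letter] <= self.allowed


#: Labels of the 13 constrained core positions, in strand order within
#: their elements.  Box 1 = 3..9, box 2 = 12..14, stem III closing pair
#: 15.1/16.1, cleavage-site residue 17.
CORE_LABELS = (
    "3", "4", "5", "6", "7", "8", "9",
    "12", "13", "14",
    "15.1", "16.1",
    "17",
)

_DEFAULT_CORE = {
    "3": "C", "4": "U", "5": "G", "6": "A", "7": "N", "8": "G", "9": "A",
    "12": "G", "13": "A", "14": "A",
    "15.1": "A", "16.1": "U",
    "17": "H",
}


@dataclass(frozen=True)
class CoreConsensus:
    """The 13 constrained core positions and their allowed nucleotide sets."""

    positions: Dict[str, NucSet]

    @classmethod
    def default(cls) -> "CoreConsensus":
        return cls({lbl: NucSet.from_symbol(sym) for lbl, sym in _DEFAULT_CORE.items()})

    def __post_init__(self):
        missing = set(CORE_LABELS) - set(self.positions)
        if missing:
            raise ValueError(f"core consensus missing positions: {sorted(missing)}")

    def allowed(self, label: str) -> NucSet:
        return self.positions[label]


# --------------------------------------------------------------------------
# Topology
# --------------------------------------------------------------------------


class Topology(enum.Enum):
    """Circular permutation of the motif, named for the open (loop-less) stem."""

    I = "I"
    II = "II"
    III = "III"

    @property
    def open_stem(self) -> str:
        return self.value


#: Canonical cyclic element order (5'->3' around the closed circle).
CYCLE = (
    "stem1_a", "loop1", "stem1_b", "box1",
    "stem2_a", "loop2", "stem2_b", "box2",
    "stem3_a", "loop3", "stem3_b", "res17",
)

_OPEN_LOOP = {Topology.I: "loop1", Topology.II: "loop2", Topology.III: "loop3"}


def topology_layout(topology: Topology) -> List[str]:
    """Linear 5'->3' element order for a topology.

    The circle is opened at the terminal loop of the open stem, so that
    stem's two halves sit at the molecule's termini and it carries no loop.
    E.g. type II (stem II open)::

        stem2_b box2 stem3_a loop3 stem3_b res17 stem1_a loop1 stem1_b box1 stem2_a
    """
    if not isinstance(topology, Topology):
        raise ValueError(f"unknown topology: {topology!r}")
    cut = CYCLE.index(_OPEN_LOOP[topology])
    rotated = CYCLE[cut + 1:] + CYCLE[:cut]
    return list(rotated)


# --------------------------------------------------------------------------
# Structural elements
# --------------------------------------------------------------------------


@dataclass
class Stem:
    """A folded helix: paired columns plus defect bookkeeping.

    ``pairs`` lists (5'-index, 3'-index) of actually paired columns, ordered
    from the core junction outward; mispaired columns inside the stem are
    counted in ``n_mispairs`` but carry no entry in ``pairs``.  Intervals are
    0-based half-open on the scanned strand.
    """

    id: str                      # "I", "II" or "III"
    pairs: List[Tuple[int, int]]
    n_wobble: int = 0
    n_mispairs: int = 0
    n_bulges: int = 0
    five_interval: Tuple[int, int] = (0, 0)
    three_interval: Tuple[int, int] = (0, 0)
    #: indices of the core-adjacent column (e.g. 10.1 and 11.1 for stem II),
    #: recorded whether or not that column actually pairs
    innermost: Tuple[int, int] = (-1, -1)
    innermost_paired: bool = True

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def n_defects(self) -> int:
        return self.n_mispairs + self.n_bulges


@dataclass
class Pseudoknot:
    """A contiguous antiparallel duplex between a terminal loop and a
    single-stranded flank beyond the partner stem (the tertiary contact that
    stabilizes the parallel stem I/II arrangement)."""

    loop_region: Tuple[int, int]
    tail_region: Tuple[int, int]
    n_bp: int
    n_wobble: int
    geometry: str                # "loopI-3'tail", "loopI-5'flank", "loopII-flank"
    pairs: List[Tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class CoreVariant:
    """A catalogued, experimentally characterized deviation from the core
    consensus (substitution, covariation, insertion, or closing-pair change)."""

    name: str
    kind: str  # substitution | covariation | insertion | closing-pair-swap | closing-pair-mismatch
    substitutions: Tuple[Tuple[str, str], ...] = ()   # (label, replacement)
    insertions: Tuple[Tuple[str, str, str], ...] = () # (after_label, new_label, nucleotide)
    activity_note: str = "active"


# --------------------------------------------------------------------------
# Hits
# --------------------------------------------------------------------------


@dataclass
class FilterVerdict:
    """Outcome of the disqualification rules for one hit."""

    status: str                 # pass-strict | pass-variant | rejected
    reason: str = "none"        # core_mutation | adjacent_mispair | short_stem_defects | none
    details: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.status == "rejected" and self.reason == "none":
            raise ValueError("rejected verdict requires a reason")


@dataclass
class HammerheadHit:
    """A located, typed, filtered motif match.

    ``interval`` is 0-based half-open on the forward (input) strand and spans
    the structured motif (stems + core); pseudoknot flanks lie outside it.
    ``core`` maps core-position labels (plus any inserted labels such as "6a")
    to indices on the *scanned* strand; for minus-strand hits the scanned
    strand is the reverse complement of the record.  ``cleavage_site`` is the
    0-based boundary on the forward strand of the scissile phosphodiester
    (immediately 3' of residue 17 along the scanned strand).
    """

    record_id: str
    strand: str                              # "+" or "-"
    interval: Tuple[int, int]
    topology: Topology
    core: Dict[str, int]
    stems: Dict[str, Stem]
    loops: Dict[str, Tuple[int, int]]
    cleavage_site: int
    verdict: Optional[FilterVerdict] = None
    variants: List[CoreVariant] = field(default_factory=list)
    pseudoknot: Optional[Pseudoknot] = None
    score: float = 0.0
    deviations: Dict[str, str] = field(default_factory=dict)  # core label -> observed letter
    scanned_length: int = 0
    scanned_seq: str = ""

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def res17_index(self) -> int:
        return self.core["17"]

    def stem_span_on_scanned(self) -> Tuple[int, int]:
        """Span of all structured elements on the scanned strand."""
        idxs = list(self.core.values())
        for stem in self.stems.values():
            idxs.extend([stem.five_interval[0], stem.five_interval[1] - 1,
                         stem.three_interval[0], stem.three_interval[1] - 1])
        return min(idxs), max(idxs) + 1


def forward_interval(start: int, end: int, strand: str, length: int) -> Tuple[int, int]:
    """Map a scanned-strand interval back onto the forward reference."""
    if strand == "+":
        return (start, end)
    return (length - end, length - start)


# --------------------------------------------------------------------------
# Kinetics containers
# --------------------------------------------------------------------------


@dataclass
class KineticsTrace:
    """A self-cleavage time course: times in minutes, fraction cleaved in [0, 1]."""

    times: Sequence[float]
    fraction_cleaved: Sequence[float]

    def __post_init__(self):
        t = list(self.times)
        f = list(self.fraction_cleaved)
        if len(t) != len(f):
            raise ValueError("times and fractions differ in length")
        if len(t) < 3:
            raise ValueError("a kinetics trace needs at least 3 points")
        if any(x < 0 for x in t):
            raise ValueError("times must be non-negative")
        if any(not (t[i] < t[i + 1]) for i in range(len(t) - 1)):
            raise ValueError("times must be strictly increasing")
        if any(not (0.0 <= x <= 1.0) for x in f):
            raise ValueError("fractions cleaved must lie in [0, 1]")

    def __len__(self) -> int:
        return len(list(self.times))
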