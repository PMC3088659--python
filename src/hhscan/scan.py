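"""Descriptor-based enumeration of hammerhead placements in a sequence.

The scanner anchors on the two conserved core boxes (box 1 ``CUGANGA`` and
box 2 ``GAA`` followed by the A15.1 closing-pair nucleotide), then, for each
of the three circularly permuted topologies, tries to fold the three stems
around the anchors under the configured length and pairing constraints.  The
candidate residue-17 position is enumerated between the anchors (it is fixed
relative to the stem III 16.1 half), cheap one-letter checks (H17, U16.1)
prune most positions, and the surviving geometries are folded.

Stem folding extends from the core junction outward, counts G-U wobbles as
paired, tolerates a bounded number of mispairs, and considers at most one
single-nucleotide bulge per stem half (bulges strictly internal to the
stem).  The objective is lexicographic: most paired columns, then fewest
defects, then fewest bulges, then innermost bulge placement.  Hairpin stems
fold inside a fixed region and must leave a terminal loop within the
configured bounds; the open stem's halves extend toward the molecule's
termini.

Alternative foldings of the same core placement (same strand, topology and
box anchors) are collapsed to the single best-scoring hit; verdicts come
from the filter module, pseudoknots from the pseudoknot module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml

from . import filters as _filters
from . import pseudoknot as _pk
from .model import (
    CORE_LABELS,
    CoreConsensus,
    CoreVariant,
    HammerheadHit,
    NucSet,
    Stem,
    Topology,
    forward_interval,
    is_pair,
    normalize_sequence,
    reverse_complement,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class ScanConfig:
    """Tunable scanner parameters.

    Stem length ranges count paired columns (base pairs); defaults cover the
    stem lengths depicted across known natural hammerheads, including the
    one-base-pair stem II.  Terminal loops are bounded; open-stem flanks are
    unbounded up to the window span.
    """

    stem_bp: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"I": (2, 12), "II": (1, 10), "III": (2, 12)}
    )
    loop_len: Tuple[int, int] = (3, 30)
    max_span: int = 200
    allow_wobble: bool = True
    both_strands: bool = True
    mode: str = "strict"                 # "strict" or "variant"
    pk_min_bp: int = 4
    pk_tail_window: int = 30
    short_stem_threshold: int = 4
    max_defects_per_stem: int = 2
    max_bulges_per_half: int = 1

    def __post_init__(self):
        for stem_id, (lo, hi) in self.stem_bp.items():
            if lo < 1 or lo > hi:
                raise ValueError(f"bad stem {stem_id} bp range: {(lo, hi)}")
        if self.loop_len[0] < 1 or self.loop_len[0] > self.loop_len[1]:
            raise ValueError(f"bad loop length range: {self.loop_len}")
        if self.mode not in ("strict", "variant"):
            raise ValueError(f"mode must be 'strict' or 'variant', not {self.mode!r}")
        min_span = (
            sum(2 * lo for lo, _ in self.stem_bp.values())
            + 2 * self.loop_len[0] + 7 + 3 + 1 + 2
        )
        if self.max_span < min_span:
            raise ValueError(
                f"max_span {self.max_span} below minimal motif length {min_span}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        """Load a flat key-value config document (YAML)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for stem_id in ("I", "II", "III"):
            lo = data.pop(f"stem_{stem_id}_min_bp", None)
            hi = data.pop(f"stem_{stem_id}_max_bp", None)
            if lo is not None or hi is not None:
                kwargs.setdefault("stem_bp", dict(cls().stem_bp))
                old = kwargs["stem_bp"][stem_id]
                kwargs["stem_bp"][stem_id] = (
                    lo if lo is not None else old[0],
                    hi if hi is not None else old[1],
                )
        if "loop_min" in data or "loop_max" in data:
            base = cls().loop_len
            kwargs["loop_len"] = (data.pop("loop_min", base[0]), data.pop("loop_max", base[1]))
        for key in (
            "max_span", "allow_wobble", "both_strands", "mode",
            "pk_min_bp", "pk_tail_window", "short_stem_threshold",
            "max_defects_per_stem", "max_bulges_per_half",
        ):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)


# --------------------------------------------------------------------------
# Stem folding
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """One candidate stem alignment of two core->outward half sequences."""

    n_cols: int
    paired: Tuple[bool, ...]
    wobble: Tuple[bool, ...]
    bulge_a: Optional[int]       # a-side skips one nt before this column
    bulge_b: Optional[int]

    @property
    def n_bp(self) -> int:
        return sum(self.paired)

    @property
    def n_mispairs(self) -> int:
        return self.n_cols - self.n_bp

    @property
    def n_bulges(self) -> int:
        return (self.bulge_a is not None) + (self.bulge_b is not None)

    @property
    def n_defects(self) -> int:
        return self.n_mispairs + self.n_bulges

    @property
    def consumed_a(self) -> int:
        return self.n_cols + (self.bulge_a is not None)

    @property
    def consumed_b(self) -> int:
        return self.n_cols + (self.bulge_b is not None)

    def a_index(self, col: int) -> int:
        return col + (1 if self.bulge_a is not None and col >= self.bulge_a else 0)

    def b_index(self, col: int) -> int:
        return col + (1 if self.bulge_b is not None and col >= self.bulge_b else 0)

    def sort_key(self):
        big = 10 ** 6
        return (
            self.n_bp,
            -self.n_defects,
            -self.n_bulges,
            -(self.bulge_a if self.bulge_a is not None else big),
            -(self.bulge_b if self.bulge_b is not None else big),
        )


def _evaluate(
    a: str,
    b: str,
    n: int,
    bulge_a: Optional[int],
    bulge_b: Optional[int],
    allow_wobble: bool,
    max_defects: int,
) -> Optional[Alignment]:
    if n + (bulge_a is not None) > len(a) or n + (bulge_b is not None) > len(b):
        return None
    paired = []
    wobble = []
    for c in range(n):
        ia = c + (1 if bulge_a is not None and c >= bulge_a else 0)
        ib = c + (1 if bulge_b is not None and c >= bulge_b else 0)
        x, y = a[ia], b[ib]
        p = is_pair(x, y, allow_wobble)
        paired.append(p)
        wobble.append(p and (x, y) in (("G", "U"), ("U", "G")))
    if not paired or not paired[-1]:
        return None
    aln = Alignment(n, tuple(paired), tuple(wobble), bulge_a, bulge_b)
    if aln.n_defects > max_defects:
        return None
    return aln


def _bulge_options(n: int, cap: int) -> List[Optional[int]]:
    # bulges only strictly internal to the stem
    opts: List[Optional[int]] = [None]
    if cap >= 1:
        opts.extend(range(1, n))
    return opts


def _search_alignments(
    a: str,
    b: str,
    *,
    allow_wobble: bool,
    min_bp: int,
    max_bp: int,
    max_defects: int,
    max_bulges_per_half: int,
    pair_budget=None,
) -> Optional[Alignment]:
    """Best alignment of outward halves ``a`` and ``b`` under the caps.

    ``pair_budget(consumed_a, consumed_b) -> bool`` optionally restricts the
    combined consumption (used by the hairpin fold to preserve its loop).
    """
    best: Optional[Alignment] = None
    n_hi = min(len(a), len(b), max_bp + max_defects)
    for n in range(n_hi, 0, -1):
        # candidates at n columns have n_bp <= n, but a smaller-n candidate
        # can still beat an equal-n_bp best on defects — only break when no
        # candidate at this n can tie the best
        if best is not None and best.n_bp > n:
            break
        for ba in _bulge_options(n, max_bulges_per_half):
            for bb in _bulge_options(n, max_bulges_per_half):
                if (ba is not None) + (bb is not None) > max_defects:
                    continue
                if pair_budget is not None:
                    ca = n + (ba is not None)
                    cb = n + (bb is not None)
                    if not pair_budget(ca, cb):
                        continue
                aln = _evaluate(a, b, n, ba, bb, allow_wobble, max_defects)
                if aln is None or aln.n_bp > max_bp:
                    continue
                if best is None or aln.sort_key() > best.sort_key():
                    best = aln
    if best is None or best.n_bp < min_bp:
        return None
    return best


def fold_open(
    a_out: str,
    b_out: str,
    *,
    allow_wobble: bool = True,
    min_bp: int = 1,
    max_bp: int = 12,
    max_defects: int = 2,
    max_bulges_per_half: int = 1,
) -> Optional[Alignment]:
    """Fold an open stem whose halves extend toward the molecule's termini."""
    return _search_alignments(
        a_out, b_out,
        allow_wobble=allow_wobble, min_bp=min_bp, max_bp=max_bp,
        max_defects=max_defects, max_bulges_per_half=max_bulges_per_half,
    )


def fold_hairpin(
    region: str,
    *,
    allow_wobble: bool = True,
    min_bp: int = 1,
    max_bp: int = 12,
    min_loop: int = 3,
    max_loop: int = 30,
    max_defects: int = 2,
    max_bulges_per_half: int = 1,
) -> Optional[Tuple[Alignment, Tuple[int, int]]]:
    """Fold a hairpin stem inside a fixed region.

    Returns the best alignment and the terminal-loop interval relative to the
    region, or None if no folding satisfies the limits.
    """
    L = len(region)
    if L < 2 * min_bp + min_loop:
        return None

    def budget(ca: int, cb: int) -> bool:
        loop = L - ca - cb
        return min_loop <= loop <= max_loop

    aln = _search_alignments(
        region, region[::-1],
        allow_wobble=allow_wobble, min_bp=min_bp, max_bp=max_bp,
        max_defects=max_defects, max_bulges_per_half=max_bulges_per_half,
        pair_budget=budget,
    )
    if aln is None:
        return None
    return aln, (aln.consumed_a, L - aln.consumed_b)


def fold_stem(
    five_half: str,
    three_half: str,
    allow_wobble: bool = True,
    limits: Optional[Dict[str, int]] = None,
    stem_id: str = "I",
) -> Optional[Stem]:
    """Fold two explicit stem halves (5'->3' each; the core junction sits at
    the start of ``five_half`` and the end of ``three_half``).

    Returns the maximal stem as a :class:`Stem` with half-local indices, or
    None if no arrangement satisfies the limits.
    """
    lim = {"min_bp": 1, "max_bp": 12, "max_defects": 2, "max_bulges_per_half": 1}
    lim.update(limits or {})
    aln = _search_alignments(
        five_half, three_half[::-1],
        allow_wobble=allow_wobble, **lim,
    )
    if aln is None:
        return None
    nb = len(three_half)
    pairs = []
    wob = 0
    for c in range(aln.n_cols):
        if aln.paired[c]:
            pairs.append((aln.a_index(c), nb - 1 - aln.b_index(c)))
            wob += aln.wobble[c]
    return Stem(
        id=stem_id,
        pairs=pairs,
        n_wobble=wob,
        n_mispairs=aln.n_mispairs,
        n_bulges=aln.n_bulges,
        five_interval=(0, aln.consumed_a),
        three_interval=(nb - aln.consumed_b, nb),
        innermost=(0, nb - 1),
        innermost_paired=aln.paired[0],
    )


# --------------------------------------------------------------------------
# Box anchor patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxPattern:
    """A box anchor: IUPAC symbols plus the core labels they place."""

    symbols: Tuple[str, ...]
    labels: Tuple[str, ...]
    pre_insert: Tuple[Tuple[str, str], ...] = ()   # (label, symbol) just 5' of the box
    variant: Optional[CoreVariant] = None
    p15_symbol: str = ""                           # box 2 only
    p16_symbol: str = ""                           # box 2 only

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def pre_length(self) -> int:
        return len(self.pre_insert)


_BOX1_LABELS = ("3", "4", "5", "6", "7", "8", "9")
_BOX2_LABELS = ("12", "13", "14")


def _canonical_box1(consensus: CoreConsensus) -> BoxPattern:
    return BoxPattern(
        symbols=tuple(consensus.allowed(l).symbol for l in _BOX1_LABELS),
        labels=_BOX1_LABELS,
    )


def _canonical_box2(consensus: CoreConsensus) -> BoxPattern:
    return BoxPattern(
        symbols=tuple(consensus.allowed(l).symbol for l in _BOX2_LABELS),
        labels=_BOX2_LABELS,
        p15_symbol=consensus.allowed("15.1").symbol,
        p16_symbol=consensus.allowed("16.1").symbol,
    )


def build_anchor_patterns(
    consensus: CoreConsensus,
    catalog: Sequence[CoreVariant],
    mode: str,
) -> Tuple[List[BoxPattern], List[BoxPattern]]:
    """Box 1 and box 2 anchor patterns for the given mode.

    Strict mode anchors only on the consensus; variant mode adds one pattern
    per catalogued variant that alters the anchored letters (one catalogued
    variant per hit).  Structural variants (the closing-pair mismatch) need
    no anchor change.
    """
    box1 = [_canonical_box1(consensus)]
    box2 = [_canonical_box2(consensus)]
    if mode != "variant":
        return box1, box2

    for entry in catalog:
        subs = dict(entry.substitutions)
        b1_labels = [l for l in subs if l in _BOX1_LABELS]
        b2_labels = [l for l in subs if l in _BOX2_LABELS or l in ("15.1", "16.1")]
        ins_box1 = [ins for ins in entry.insertions if ins[0] in _BOX1_LABELS]
        ins_box2 = [ins for ins in entry.insertions if ins[0] in _BOX2_LABELS]
        ins_pre = [ins for ins in entry.insertions if ins[0] in ("2.1",)]

        if b1_labels or ins_box1 or ins_pre:
            symbols = list(_canonical_box1(consensus).symbols)
            labels = list(_BOX1_LABELS)
            for lbl in b1_labels:
                symbols[labels.index(lbl)] = subs[lbl]
            for after, new_label, nt in ins_box1:
                pos = labels.index(after) + 1
                labels.insert(pos, new_label)
                symbols.insert(pos, nt)
            pre = tuple((new_label, nt) for _, new_label, nt in ins_pre)
            box1.append(BoxPattern(tuple(symbols), tuple(labels), pre, entry))
        if b2_labels or ins_box2:
            symbols = list(_canonical_box2(consensus).symbols)
            labels = list(_BOX2_LABELS)
            for lbl in b2_labels:
                if lbl in labels:
                    symbols[labels.index(lbl)] = subs[lbl]
            for after, new_label, nt in ins_box2:
                pos = labels.index(after) + 1
                labels.insert(pos, new_label)
                symbols.insert(pos, nt)
            p15 = subs.get("15.1", consensus.allowed("15.1").symbol)
            p16 = subs.get("16.1", consensus.allowed("16.1").symbol)
            box2.append(BoxPattern(tuple(symbols), tuple(labels), (), entry, p15, p16))
    return box1, box2


def _symbol_matches(symbol: str, letter: str) -> bool:
    return NucSet.from_symbol(symbol).matches(letter)


def _find_box(seq: str, pattern: BoxPattern, extra_3p: int = 0) -> List[int]:
    """Start offsets (of the box proper, after any pre-insert) where the
    pattern matches under the subset rule; requires ``extra_3p`` additional
    nt of sequence after the box (for the 15.1 check)."""
    out = []
    pre = pattern.pre_length
    for p in range(pre, len(seq) - pattern.length - extra_3p + 1):
        ok = all(
            _symbol_matches(sym, seq[p + k]) for k, sym in enumerate(pattern.symbols)
        )
        if ok and pre:
            ok = all(
                _symbol_matches(sym, seq[p - pre + k])
                for k, (_, sym) in enumerate(pattern.pre_insert)
            )
        if ok:
            out.append(p)
    return out


# --------------------------------------------------------------------------
# Core matching and scoring
# --------------------------------------------------------------------------


def match_core(
    seq: str,
    placement: Dict[str, int],
    consensus: Optional[CoreConsensus] = None,
) -> Tuple[bool, Dict[str, str]]:
    """Check the 13 consensus positions of a placement against a sequence.

    Returns ``(ok, deviations)`` where deviations maps the deviating core
    labels to the observed letter (consumed by variant mode).  Inserted
    labels in the placement are ignored here; they are scored as core
    insertions by the filters.
    """
    consensus = consensus or CoreConsensus.default()
    missing = [l for l in CORE_LABELS if l not in placement]
    if missing:
        raise ValueError(f"placement lacks core positions: {missing}")
    for group in (_BOX1_LABELS, _BOX2_LABELS):
        idxs = [placement[l] for l in group]
        if any(b <= a for a, b in zip(idxs, idxs[1:])):
            raise ValueError(f"placement indices out of order in {group}")
    devs = {}
    for label in CORE_LABELS:
        idx = placement[label]
        if not (0 <= idx < len(seq)):
            raise ValueError(f"placement index {idx} for {label} out of range")
        letter = seq[idx]
        if not consensus.allowed(label).matches(letter):
            devs[label] = letter
    return (not devs, devs)


def score_hit(hit: HammerheadHit) -> float:
    """Deterministic ranking score: total paired columns minus defects, plus
    twice the pseudoknot length.  Never used for accept/reject decisions."""
    total = sum(s.n_bp for s in hit.stems.values())
    defects = sum(s.n_defects for s in hit.stems.values())
    pk = hit.pseudoknot.n_bp if hit.pseudoknot is not None else 0
    return float(total - defects + 2 * pk)


# --------------------------------------------------------------------------
# Scan driver
# --------------------------------------------------------------------------


def _hairpin_len_bounds(stem_id: str, config: ScanConfig) -> Tuple[int, int]:
    lo, hi = config.stem_bp[stem_id]
    lmin, lmax = config.loop_len
    consumed_max = hi + config.max_defects_per_stem + 1
    return 2 * lo + lmin, 2 * consumed_max + lmax


def _open_cap(stem_id: str, config: ScanConfig) -> int:
    hi = config.stem_bp[stem_id][1]
    return hi + config.max_defects_per_stem + 1


def _stem_from_hairpin(
    stem_id: str, region0: int, region1: int, aln: Alignment, seq: str
) -> Stem:
    pairs = []
    wob = 0
    for c in range(aln.n_cols):
        if aln.paired[c]:
            pairs.append((region0 + aln.a_index(c), region1 - 1 - aln.b_index(c)))
            wob += aln.wobble[c]
    return Stem(
        id=stem_id,
        pairs=pairs,
        n_wobble=wob,
        n_mispairs=aln.n_mispairs,
        n_bulges=aln.n_bulges,
        five_interval=(region0, region0 + aln.consumed_a),
        three_interval=(region1 - aln.consumed_b, region1),
        innermost=(region0, region1 - 1),
        innermost_paired=aln.paired[0],
    )


def _stem_from_open(
    stem_id: str, a0: int, b0: int, aln: Alignment
) -> Stem:
    """Open stem: a-half extends 3' from a0, b-half extends 5' from b0."""
    pairs = []
    wob = 0
    for c in range(aln.n_cols):
        if aln.paired[c]:
            pairs.append((b0 - aln.b_index(c), a0 + aln.a_index(c)))
            wob += aln.wobble[c]
    return Stem(
        id=stem_id,
        pairs=pairs,
        n_wobble=wob,
        n_mispairs=aln.n_mispairs,
        n_bulges=aln.n_bulges,
        five_interval=(b0 - aln.consumed_b + 1, b0 + 1),
        three_interval=(a0, a0 + aln.consumed_a),
        innermost=(b0, a0),
        innermost_paired=aln.paired[0],
    )


def _hairpin_kwargs(stem_id: str, config: ScanConfig) -> Dict:
    lo, hi = config.stem_bp[stem_id]
    return dict(
        allow_wobble=config.allow_wobble,
        min_bp=lo, max_bp=hi,
        min_loop=config.loop_len[0], max_loop=config.loop_len[1],
        max_defects=config.max_defects_per_stem,
        max_bulges_per_half=config.max_bulges_per_half,
    )


def _open_kwargs(stem_id: str, config: ScanConfig) -> Dict:
    lo, hi = config.stem_bp[stem_id]
    return dict(
        allow_wobble=config.allow_wobble,
        min_bp=lo, max_bp=hi,
        max_defects=config.max_defects_per_stem,
        max_bulges_per_half=config.max_bulges_per_half,
    )


def _try_candidate(
    seq: str,
    topo: Topology,
    p: int,
    b1: BoxPattern,
    q: int,
    b2: BoxPattern,
    t: int,
    config: ScanConfig,
    consensus: CoreConsensus,
) -> Optional[dict]:
    """Attempt folding one (topology, box1, box2, residue-17) geometry.

    Returns the raw structural pieces or None if infeasible.
    """
    pre = b1.pre_length
    b1len, b2len = b1.length, b2.length
    stems: Dict[str, Stem] = {}
    loops: Dict[str, Tuple[int, int]] = {}

    if topo is Topology.I:
        r2 = (p + b1len, q)
        h2 = fold_hairpin(seq[r2[0]:r2[1]], **_hairpin_kwargs("II", config))
        if h2 is None:
            return None
        r3 = (q + b2len, t)
        h3 = fold_hairpin(seq[r3[0]:r3[1]], **_hairpin_kwargs("III", config))
        if h3 is None:
            return None
        cap = _open_cap("I", config)
        a_out = seq[t + 1:t + 1 + cap]
        b_start = p - pre
        b_out = seq[max(0, b_start - cap):b_start][::-1]
        o1 = fold_open(a_out, b_out, **_open_kwargs("I", config))
        if o1 is None:
            return None
        stems["II"] = _stem_from_hairpin("II", r2[0], r2[1], h2[0], seq)
        loops["II"] = (r2[0] + h2[1][0], r2[0] + h2[1][1])
        stems["III"] = _stem_from_hairpin("III", r3[0], r3[1], h3[0], seq)
        loops["III"] = (r3[0] + h3[1][0], r3[0] + h3[1][1])
        stems["I"] = _stem_from_open("I", t + 1, b_start - 1, o1)
    elif topo is Topology.II:
        r3 = (q + b2len, t)
        h3 = fold_hairpin(seq[r3[0]:r3[1]], **_hairpin_kwargs("III", config))
        if h3 is None:
            return None
        r1 = (t + 1, p - pre)
        h1 = fold_hairpin(seq[r1[0]:r1[1]], **_hairpin_kwargs("I", config))
        if h1 is None:
            return None
        cap = _open_cap("II", config)
        a_out = seq[p + b1len:p + b1len + cap]
        b_out = seq[max(0, q - cap):q][::-1]
        o2 = fold_open(a_out, b_out, **_open_kwargs("II", config))
        if o2 is None:
            return None
        stems["III"] = _stem_from_hairpin("III", r3[0], r3[1], h3[0], seq)
        loops["III"] = (r3[0] + h3[1][0], r3[0] + h3[1][1])
        stems["I"] = _stem_from_hairpin("I", r1[0], r1[1], h1[0], seq)
        loops["I"] = (r1[0] + h1[1][0], r1[0] + h1[1][1])
        stems["II"] = _stem_from_open("II", p + b1len, q - 1, o2)
    else:  # Topology.III
        r1 = (t + 1, p - pre)
        h1 = fold_hairpin(seq[r1[0]:r1[1]], **_hairpin_kwargs("I", config))
        if h1 is None:
            return None
        r2 = (p + b1len, q)
        h2 = fold_hairpin(seq[r2[0]:r2[1]], **_hairpin_kwargs("II", config))
        if h2 is None:
            return None
        cap = _open_cap("III", config)
        a_out = seq[q + b2len:q + b2len + cap]
        b_out = seq[max(0, t - cap):t][::-1]
        o3 = fold_open(a_out, b_out, **_open_kwargs("III", config))
        if o3 is None:
            return None
        stems["I"] = _stem_from_hairpin("I", r1[0], r1[1], h1[0], seq)
        loops["I"] = (r1[0] + h1[1][0], r1[0] + h1[1][1])
        stems["II"] = _stem_from_hairpin("II", r2[0], r2[1], h2[0], seq)
        loops["II"] = (r2[0] + h2[1][0], r2[0] + h2[1][1])
        stems["III"] = _stem_from_open("III", q + b2len, t - 1, o3)

    # core placement
    core: Dict[str, int] = {}
    for k, (lbl, _) in enumerate(b1.pre_insert):
        core[lbl] = p - pre + k
    for k, lbl in enumerate(b1.labels):
        core[lbl] = p + k
    for k, lbl in enumerate(b2.labels):
        core[lbl] = q + k
    core["15.1"] = q + b2len
    core["16.1"] = t - 1
    core["17"] = t
    return {"stems": stems, "loops": loops, "core": core}


def scan(
    sequence: str,
    config: Optional[ScanConfig] = None,
    record_id: str = "seq",
    consensus: Optional[CoreConsensus] = None,
    catalog: Sequence[CoreVariant] = _filters.DEFAULT_VARIANT_CATALOG,
) -> List[HammerheadHit]:
    """Scan one nucleotide sequence for hammerhead motifs.

    Returns deduplicated hits (both strands when configured) ordered by
    start coordinate then descending score.  Verdicts are assigned by the
    filter module; pseudoknots are annotated on every hit.
    """
    config = config or ScanConfig()
    consensus = consensus or CoreConsensus.default()
    seq = normalize_sequence(sequence, record_id)
    if not seq:
        return []
    length = len(seq)

    strands = [("+", seq)]
    if config.both_strands:
        strands.append(("-", reverse_complement(seq)))

    hits: List[HammerheadHit] = []
    for strand, s in strands:
        hits.extend(
            _scan_strand(s, strand, length, record_id, config, consensus, catalog)
        )
    hits.sort(key=lambda h: (h.start, -h.score, h.strand, h.topology.value))
    return hits


def _scan_strand(
    seq: str,
    strand: str,
    length: int,
    record_id: str,
    config: ScanConfig,
    consensus: CoreConsensus,
    catalog: Sequence[CoreVariant],
) -> List[HammerheadHit]:
    box1_pats, box2_pats = build_anchor_patterns(consensus, catalog, config.mode)
    h17 = consensus.allowed("17")

    b1occ = [(p, pat) for pat in box1_pats for p in _find_box(seq, pat)]
    b2occ = [(q, pat) for pat in box2_pats for q in _find_box(seq, pat, extra_3p=1)
             if _symbol_matches(pat.p15_symbol, seq[q + pat.length])]
    if not b1occ or not b2occ:
        return []

    h1_lo, h1_hi = _hairpin_len_bounds("I", config)
    h2_lo, h2_hi = _hairpin_len_bounds("II", config)
    h3_lo, h3_hi = _hairpin_len_bounds("III", config)

    # per (strand, topology, box1, box2): every accepted folding (these have
    # distinct residue-17 placements, hence distinct cleavage sites and are
    # genuinely different ribozyme calls), plus the single best rejected
    # folding when none is accepted
    passing: Dict[tuple, Dict[int, HammerheadHit]] = {}
    best_rejected: Dict[tuple, HammerheadHit] = {}

    def consider(topo, p, b1, q, b2, t):
        # one catalogued variant per hit
        if b1.variant is not None and b2.variant is not None:
            return
        if not (0 < t < len(seq)):
            return
        if not h17.matches(seq[t]):
            return
        if not _symbol_matches(b2.p16_symbol, seq[t - 1]):
            return
        raw = _try_candidate(seq, topo, p, b1, q, b2, t, config, consensus)
        if raw is None:
            return
        hit = _assemble_hit(
            seq, strand, length, record_id, topo, raw, config, consensus, catalog
        )
        if hit is None:
            return
        key = (strand, topo.value, p, q)
        if hit.verdict.status != "rejected":
            passing.setdefault(key, {})[t] = hit
        else:
            old = best_rejected.get(key)
            if old is None or _hit_rank(hit) > _hit_rank(old):
                best_rejected[key] = hit

    for p, b1 in b1occ:
        b1len = b1.length
        pre = b1.pre_length
        for q, b2 in b2occ:
            b2len = b2.length
            # type I: box1 ... stemII hairpin ... box2 ... stemIII hairpin ... 17
            if h2_lo <= q - (p + b1len) <= h2_hi:
                for t in range(q + b2len + h3_lo, min(q + b2len + h3_hi, len(seq) - 1) + 1):
                    consider(Topology.I, p, b1, q, b2, t)
            # type III: 17 ... stemI hairpin ... box1 ... stemII hairpin ... box2
            if h2_lo <= q - (p + b1len) <= h2_hi:
                for reg1 in range(h1_lo, h1_hi + 1):
                    t = p - pre - reg1 - 1
                    if t >= 1:
                        consider(Topology.III, p, b1, q, b2, t)
            # type II: box2 ... stemIII hairpin ... 17 ... stemI hairpin ... box1
            if q + b2len < p - pre:
                for t in range(q + b2len + h3_lo, q + b2len + h3_hi + 1):
                    if h1_lo <= (p - pre) - (t + 1) <= h1_hi:
                        consider(Topology.II, p, b1, q, b2, t)

    out: List[HammerheadHit] = []
    for key, by_t in passing.items():
        out.extend(by_t.values())
    for key, hit in best_rejected.items():
        if key not in passing:
            out.append(hit)
    return out


def _hit_rank(hit: HammerheadHit):
    # among alternative foldings of one core placement, an accepted folding
    # beats a rejected one regardless of score; among accepted foldings the
    # better-structured parse wins
    return (
        0 if hit.verdict.status == "rejected" else 1,
        hit.score,
        hit.stems["II"].n_bp,
        hit.stems["I"].n_bp,
        -hit.start,
        -hit.core["17"],
    )


def _assemble_hit(
    seq: str,
    strand: str,
    length: int,
    record_id: str,
    topo: Topology,
    raw: dict,
    config: ScanConfig,
    consensus: CoreConsensus,
    catalog: Sequence[CoreVariant],
) -> Optional[HammerheadHit]:
    stems: Dict[str, Stem] = raw["stems"]
    core: Dict[str, int] = raw["core"]

    idxs = list(core.values())
    for st in stems.values():
        idxs.extend([st.five_interval[0], st.five_interval[1] - 1,
                     st.three_interval[0], st.three_interval[1] - 1])
    span0, span1 = min(idxs), max(idxs) + 1
    if span1 - span0 > config.max_span:
        return None

    _, deviations = match_core(seq, core, consensus)
    t = core["17"]
    hit = HammerheadHit(
        record_id=record_id,
        strand=strand,
        interval=forward_interval(span0, span1, strand, length),
        topology=topo,
        core=core,
        stems=stems,
        loops=raw["loops"],
        cleavage_site=(t + 1) if strand == "+" else (length - (t + 1)),
        deviations=deviations,
        scanned_length=length,
        scanned_seq=seq,
    )
    verdict = _filters.apply_strict_filters(hit, config.short_stem_threshold)
    if verdict.status == "rejected" and config.mode == "variant":
        verdict = _filters.apply_variant_catalog(
            hit, catalog, config.short_stem_threshold
        )
    hit.verdict = verdict
    hit.pseudoknot = _pk.detect_pseudoknot(
        hit, seq,
        min_bp=config.pk_min_bp,
        tail_window=config.pk_tail_window,
        allow_wobble=config.allow_wobble,
    )
    hit.score = score_hit(hit)
    return hit


def scan_records(
    records: Iterable[Tuple[str, str]],
    config: Optional[ScanConfig] = None,
    **kwargs,
) -> List[HammerheadHit]:
    """Scan an iterable of (record_id, sequence) pairs."""
    hits: List[HammerheadHit] = []
    for rec_id, seq in records:
        hits.extend(scan(seq, config, record_id=rec_id, **kwargs))
    return hits
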