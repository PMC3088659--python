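"""Ground-truthed synthetic hammerheads, decoys and benchmarks.

The generator instantiates the consensus architecture directly: it samples
stem base pairs (10% G-U wobble), terminal loops and flanks, installs the
requested pseudoknot complementarity and (optionally) exactly one catalogued
core variant, and then verifies by re-folding each region that the planted
structure is the unique maximal folding under the scanner's own pairing
rules — resampling unconstrained loop/flank letters until it is.  Flanks are
long enough that stem folding can never read past them, so constructs stay
well-behaved when embedded in arbitrary background.

Everything is deterministic per seed.  The background model is uniform
i.i.d. nucleotides: this is test scaffolding, not a genome model.
"""

from __future__ import annotations

import copy
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import filters as _filters
from . import pseudoknot as _pk
from .model import (
    CORE_LABELS,
    CoreConsensus,
    CoreVariant,
    HammerheadHit,
    Stem,
    Topology,
    complement,
    is_pair,
    topology_layout,
)
from .scan import ScanConfig, fold_hairpin, fold_open, match_core

_BASES = ("A", "C", "G", "U")
_WOBBLE_PROB = 0.10
_MAX_FIXUP_TRIES = 800

#: flank lengths long enough that open-stem folding (max bp + defect + bulge
#: columns) can never extend past them into foreign sequence
_FLANK5_LEN = 16
_MIN_TAIL_LEN = 16


class GenerationError(ValueError):
    """Raised for infeasible length/variant combinations."""


def _rand_base(rng) -> str:
    return _BASES[int(rng.integers(0, 4))]


def _sample_pair(rng, wobble_prob: float = _WOBBLE_PROB) -> Tuple[str, str]:
    x = _rand_base(rng)
    y = complement(x)
    if x in ("G", "U") and rng.random() < wobble_prob:
        y = "U" if x == "G" else "G"
    return x, y


def _stem_columns(rng, n_bp: int, inner: Optional[Tuple[str, str]] = None,
                  inner_paired: bool = True) -> List[Tuple[str, str]]:
    """Columns core->outward; an explicit unpaired inner column is prepended
    without counting toward ``n_bp``."""
    cols = []
    if inner is not None:
        cols.append(inner)
    while len(cols) < n_bp + (0 if inner is None or inner_paired else 1):
        cols.append(_sample_pair(rng))
    return cols


def generate_hammerhead(
    topology: Topology | str,
    stem_lens: Tuple[int, int, int] = (6, 4, 6),
    loop_lens: Tuple[int, int, int] = (6, 6, 6),
    pk_len: int = 0,
    variant: Optional[str | CoreVariant] = None,
    seed: Optional[int] = 0,
    rng=None,
    consensus: Optional[CoreConsensus] = None,
    config: Optional[ScanConfig] = None,
) -> Tuple[str, dict]:
    """Generate one hammerhead-positive sequence with its truth annotation.

    ``stem_lens`` are paired base pairs for stems I/II/III; ``loop_lens`` are
    terminal loop lengths in the same order (the open stem's entry is
    ignored).  ``pk_len`` of 0 means no pseudoknot; otherwise at least 4.
    ``variant`` names a catalogued core variant to install, or None for a
    strict-consensus positive.

    Returns ``(sequence, truth)`` where truth records the coordinates of
    every element including the cleavage site (all 0-based, plus strand).
    """
    topo = Topology(topology) if not isinstance(topology, Topology) else topology
    rng = rng if rng is not None else np.random.default_rng(seed)
    consensus = consensus or CoreConsensus.default()
    config = config or ScanConfig()

    n1, n2, n3 = stem_lens
    loops_req = {"I": loop_lens[0], "II": loop_lens[1], "III": loop_lens[2]}
    open_stem = topo.open_stem
    hairpins = [s for s in ("I", "II", "III") if s != open_stem]

    for sid, n in zip(("I", "II", "III"), (n1, n2, n3)):
        lo, hi = config.stem_bp[sid]
        if not (lo <= n <= hi):
            raise GenerationError(f"stem {sid} length {n} outside range {(lo, hi)}")
    for sid in hairpins:
        if not (config.loop_len[0] <= loops_req[sid] <= config.loop_len[1]):
            raise GenerationError(f"loop {sid} length {loops_req[sid]} out of range")
    if pk_len != 0 and pk_len < 4:
        raise GenerationError("pseudoknots are defined as >= 4 bp (or 0 for none)")

    entry: Optional[CoreVariant] = None
    if variant is not None:
        entry = variant if isinstance(variant, CoreVariant) else _filters.catalog_by_name(variant)

    # --- core letters -----------------------------------------------------
    box1_labels = ["3", "4", "5", "6", "7", "8", "9"]
    box1 = ["C", "U", "G", "A", _rand_base(rng), "G", "A"]
    box2_labels = ["12", "13", "14"]
    box2 = ["G", "A", "A"]
    p15, p16 = "A", "U"
    h17 = ("A", "C", "U")[int(rng.integers(0, 3))]
    pre_ins_labels: List[str] = []
    pre_ins: List[str] = []
    mismatch_inner = None

    if entry is not None:
        subs = dict(entry.substitutions)
        if entry.kind == "closing-pair-mismatch":
            mismatch_inner = tuple(subs[l] for l in ("10.1", "11.1"))
        else:
            for lbl, nt in subs.items():
                if lbl in box1_labels:
                    box1[box1_labels.index(lbl)] = nt
                elif lbl in box2_labels:
                    box2[box2_labels.index(lbl)] = nt
                elif lbl == "15.1":
                    p15 = nt
                elif lbl == "16.1":
                    p16 = nt
                else:
                    raise GenerationError(f"cannot install substitution at {lbl}")
        for after, new_label, nt in entry.insertions:
            if after in box1_labels:
                k = box1_labels.index(after) + 1
                box1_labels.insert(k, new_label)
                box1.insert(k, nt)
            elif after in box2_labels:
                k = box2_labels.index(after) + 1
                box2_labels.insert(k, new_label)
                box2.insert(k, nt)
            elif after == "2.1":
                pre_ins_labels.append(new_label)
                pre_ins.append(nt)
            else:
                raise GenerationError(f"cannot install insertion after {after}")

    # --- stems ------------------------------------------------------------
    cols: Dict[str, List[Tuple[str, str]]] = {
        "I": _stem_columns(rng, n1),
        "II": _stem_columns(
            rng, n2, inner=mismatch_inner, inner_paired=mismatch_inner is None
        ),
        "III": None,  # set below: the closing pair is part of the core
    }
    stem3 = [(p15, p16)]
    stem3.extend(_sample_pair(rng) for _ in range(n3 - 1))
    cols["III"] = stem3

    # --- loops and flanks ---------------------------------------------------
    pk_loop_stem = "II" if topo is Topology.I else "I"
    if pk_len and pk_loop_stem == open_stem:  # pragma: no cover - impossible by layout
        raise GenerationError("pseudoknot loop cannot sit on the open stem")
    if pk_len and loops_req[pk_loop_stem] < pk_len:
        raise GenerationError(
            f"loop {pk_loop_stem} ({loops_req[pk_loop_stem]} nt) shorter than the "
            f"requested {pk_len} bp pseudoknot"
        )
    loop_letters = {
        sid: [_rand_base(rng) for _ in range(loops_req[sid])] for sid in hairpins
    }
    tail_len = max(_MIN_TAIL_LEN, 3 + pk_len + 8)
    flank5 = [_rand_base(rng) for _ in range(_FLANK5_LEN)]
    tail3 = [_rand_base(rng) for _ in range(tail_len)]

    pk_offset = 0
    if pk_len:
        pk_offset = (loops_req[pk_loop_stem] - pk_len) // 2

    def refresh_pk_partner():
        if not pk_len:
            return
        seg = loop_letters[pk_loop_stem][pk_offset:pk_offset + pk_len]
        partner = [complement(seg[pk_len - 1 - j]) for j in range(pk_len)]
        tail3[3:3 + pk_len] = partner

    refresh_pk_partner()

    # --- assembly ---------------------------------------------------------
    def build() -> Tuple[List[str], dict]:
        parts: List[Tuple[str, List[str]]] = [("flank5", flank5)]
        for element in topology_layout(topo):
            sid = element[4] if element.startswith("stem") else None
            if element == "box1":
                if pre_ins:
                    parts.append(("pre_ins", pre_ins))
                parts.append(("box1", box1))
            elif element == "box2":
                parts.append(("box2", box2))
            elif element == "res17":
                parts.append(("res17", [h17]))
            elif element.startswith("loop"):
                sid = {"loop1": "I", "loop2": "II", "loop3": "III"}[element]
                parts.append((f"loop{sid}", loop_letters[sid]))
            elif element.endswith("_a"):
                parts.append((element, [c[0] for c in cols[sid_of(element)]]))
            else:  # *_b half, written outer -> inner
                parts.append((element, [c[1] for c in cols[sid_of(element)]][::-1]))
        parts.append(("tail3", tail3))

        chars: List[str] = []
        offsets: Dict[str, int] = {}
        for name, letters in parts:
            offsets[name] = len(chars)
            chars.extend(letters)

        stems_truth = {}
        for sid, num in (("I", "1"), ("II", "2"), ("III", "3")):
            a0 = offsets[f"stem{num}_a"]
            b0 = offsets[f"stem{num}_b"]
            nc = len(cols[sid])
            columns = [
                tuple(sorted((a0 + c, b0 + nc - 1 - c))) for c in range(nc)
            ]
            lo_int = (min(a0, b0), min(a0, b0) + nc)
            hi_int = (max(a0, b0), max(a0, b0) + nc)
            stems_truth[sid] = {
                "columns": columns,
                "five_interval": lo_int,
                "three_interval": hi_int,
            }

        core = {}
        for k, lbl in enumerate(box1_labels):
            core[lbl] = offsets["box1"] + k
        for k, lbl in enumerate(box2_labels):
            core[lbl] = offsets["box2"] + k
        for k, lbl in enumerate(pre_ins_labels):
            core[lbl] = offsets["pre_ins"] + k
        core["15.1"] = offsets["stem3_a"]
        core["16.1"] = offsets["stem3_b"] + len(cols["III"]) - 1
        core["17"] = offsets["res17"]

        loops_truth = {
            sid: (offsets[f"loop{sid}"], offsets[f"loop{sid}"] + loops_req[sid])
            for sid in hairpins
        }

        span = (len(flank5), len(chars) - len(tail3))
        pk_truth = None
        if pk_len:
            l0 = loops_truth[pk_loop_stem][0]
            pk_truth = {
                "loop": (l0 + pk_offset, l0 + pk_offset + pk_len),
                "tail": (span[1] + 3, span[1] + 3 + pk_len),
                "n_bp": pk_len,
            }
        truth = {
            "record_id": "synthetic",
            "strand": "+",
            "topology": topo.value,
            "interval": span,
            "core": core,
            "cleavage_site": core["17"] + 1,
            "stems": stems_truth,
            "loops": loops_truth,
            "pseudoknot": pk_truth,
            "variant": entry.name if entry is not None else None,
        }
        return chars, truth

    def sid_of(element: str) -> str:
        return {"1": "I", "2": "II", "3": "III"}[element[4]]

    # --- verification / rejection sampling --------------------------------
    def check(chars: List[str], truth: dict) -> Optional[str]:
        seq = "".join(chars)
        exp_defects = {"I": 0, "II": 1 if mismatch_inner else 0, "III": 0}
        for sid in hairpins:
            st = truth["stems"][sid]
            r0, r1 = st["five_interval"][0], st["three_interval"][1]
            nc = len(st["columns"])
            lo, hi = config.stem_bp[sid]
            res = fold_hairpin(
                seq[r0:r1], allow_wobble=config.allow_wobble,
                min_bp=lo, max_bp=hi,
                min_loop=config.loop_len[0], max_loop=config.loop_len[1],
                max_defects=config.max_defects_per_stem,
                max_bulges_per_half=config.max_bulges_per_half,
            )
            if (
                res is None
                or res[0].consumed_a != nc
                or res[0].consumed_b != nc
                or res[0].n_bp != nc - exp_defects[sid]
                or res[0].n_bulges != 0
            ):
                return f"loop{sid}"
        st = truth["stems"][open_stem]
        nc = len(st["columns"])
        lo, hi = config.stem_bp[open_stem]
        cap = hi + config.max_defects_per_stem + 1
        a0 = st["three_interval"][0]
        b0 = st["five_interval"][1] - 1
        res = fold_open(
            seq[a0:a0 + cap], seq[max(0, b0 + 1 - cap):b0 + 1][::-1],
            allow_wobble=config.allow_wobble, min_bp=lo, max_bp=hi,
            max_defects=config.max_defects_per_stem,
            max_bulges_per_half=config.max_bulges_per_half,
        )
        if (
            res is None
            or res.consumed_a != nc
            or res.consumed_b != nc
            or res.n_bp != nc - exp_defects[open_stem]
            or res.n_bulges != 0
        ):
            return "insulators"

        # pseudoknot windows
        span0, span1 = truth["interval"]
        loop_sid = pk_loop_stem
        if loop_sid in truth["loops"]:
            l0, l1 = truth["loops"][loop_sid]
            loop_seq = seq[l0:l1]
            w = config.pk_tail_window
            k3 = _pk.best_duplex(loop_seq, seq[span1:span1 + w], config.allow_wobble)[0]
            k5 = _pk.best_duplex(loop_seq, seq[max(0, span0 - w):span0], config.allow_wobble)[0]
            if pk_len:
                if k3 != pk_len or k5 > pk_len:
                    return "pk_window"
            else:
                if max(k3, k5) >= config.pk_min_bp:
                    return "pk_window"
        return None

    chars, truth = build()
    for _ in range(_MAX_FIXUP_TRIES):
        problem = check(chars, truth)
        if problem is None:
            break
        if problem.startswith("loop"):
            sid = problem[4:]
            loop_letters[sid][:] = [_rand_base(rng) for _ in range(loops_req[sid])]
            if sid == pk_loop_stem:
                refresh_pk_partner()
        elif problem == "insulators":
            for k in range(3):
                tail3[k] = _rand_base(rng)
                flank5[-1 - k] = _rand_base(rng)
        else:  # pk_window
            for k in range(3 + pk_len, len(tail3)):
                tail3[k] = _rand_base(rng)
            for k in range(len(flank5) - 3):
                flank5[k] = _rand_base(rng)
            if pk_loop_stem in loop_letters:
                free = [
                    k for k in range(loops_req[pk_loop_stem])
                    if not (pk_len and pk_offset <= k < pk_offset + pk_len)
                ]
                for k in free:
                    loop_letters[pk_loop_stem][k] = _rand_base(rng)
        chars, truth = build()
    else:
        raise GenerationError(
            "could not realize the requested structure "
            f"(topology {topo.value}, stems {stem_lens}, loops {loop_lens}, pk {pk_len})"
        )
    return "".join(chars), truth


# --------------------------------------------------------------------------
# Truth -> hit (used by the filter machinery and tests)
# --------------------------------------------------------------------------


def hit_from_truth(
    seq: str,
    truth: dict,
    consensus: Optional[CoreConsensus] = None,
    allow_wobble: bool = True,
) -> HammerheadHit:
    """Construct a HammerheadHit directly from a truth annotation.

    Stem pairing statistics are recomputed from the (possibly mutated)
    sequence, so decoys derived from a positive show up with the defects
    their mutations introduce.
    """
    consensus = consensus or CoreConsensus.default()
    stems = {}
    for sid, st in truth["stems"].items():
        pairs, wob, mis = [], 0, 0
        for (i, j) in st["columns"]:
            if is_pair(seq[i], seq[j], allow_wobble):
                pairs.append((i, j))
                wob += (seq[i], seq[j]) in (("G", "U"), ("U", "G"))
            else:
                mis += 1
        stems[sid] = Stem(
            id=sid,
            pairs=pairs,
            n_wobble=wob,
            n_mispairs=mis,
            n_bulges=0,
            five_interval=st["five_interval"],
            three_interval=st["three_interval"],
            innermost=st["columns"][0],
            innermost_paired=is_pair(
                seq[st["columns"][0][0]], seq[st["columns"][0][1]], allow_wobble
            ),
        )
    _, deviations = match_core(seq, truth["core"], consensus)
    return HammerheadHit(
        record_id=truth.get("record_id", "truth"),
        strand=truth.get("strand", "+"),
        interval=tuple(truth["interval"]),
        topology=Topology(truth["topology"]),
        core=dict(truth["core"]),
        stems=stems,
        loops={k: tuple(v) for k, v in truth.get("loops", {}).items()},
        cleavage_site=truth["cleavage_site"],
        deviations=deviations,
        scanned_length=len(seq),
        scanned_seq=seq,
    )


# --------------------------------------------------------------------------
# Decoys
# --------------------------------------------------------------------------


def enumerate_core_mutants(
    consensus: Optional[CoreConsensus] = None,
) -> List[Tuple[str, str]]:
    """All (core label, disallowed nucleotide) single substitutions.

    N7 admits every base and H17 admits all but G, so the exhaustive decoy
    set has 34 members, not 13 x 3.
    """
    consensus = consensus or CoreConsensus.default()
    out = []
    for label in CORE_LABELS:
        allowed = consensus.allowed(label).allowed
        for base in _BASES:
            if base not in allowed:
                out.append((label, base))
    return out


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Dinucleotide-composition-preserving shuffle (Altschul-Erickson).

    Builds the dinucleotide transition multigraph and walks a random Eulerian
    path from the original first letter to the original last letter.
    """
    if len(seq) < 3:
        return seq
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(edges)

    for _ in range(2000):
        # choose a candidate final edge for every non-terminal vertex
        final = {}
        for v in vertices:
            if v == last:
                continue
            final[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        # the chosen final edges must form a tree pointing at `last`
        ok = True
        for v in final:
            seen = {v}
            w = v
            while w != last:
                w = final.get(w)
                if w is None or w in seen:
                    ok = False
                    break
                seen.add(w)
            if not ok:
                break
        if not ok:
            continue
        shuffled_edges = {}
        for v in vertices:
            rest = list(edges[v])
            if v in final:
                rest.remove(final[v])
            order = list(rng.permutation(len(rest))) if rest else []
            lst = [rest[i] for i in order]
            if v in final:
                lst.append(final[v])
            shuffled_edges[v] = lst
        out = [seq[0]]
        v = seq[0]
        counters = {u: 0 for u in vertices}
        for _ in range(len(seq) - 1):
            nxt = shuffled_edges[v][counters[v]]
            counters[v] += 1
            out.append(nxt)
            v = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")


DECOY_KINDS = ("core-mutant", "adjacent-mispair", "stem-broken", "shuffled")


def generate_decoy(
    base: Tuple[str, dict],
    kind: str,
    seed: Optional[int] = 0,
    rng=None,
    target: Optional[Tuple[str, str]] = None,
) -> Tuple[str, dict]:
    """Derive a negative control from a positive (sequence, truth) pair.

    ``core-mutant`` introduces one disallowed core substitution (``target``
    may pin the (label, base)); ``adjacent-mispair`` breaks one core-adjacent
    closing pair; ``stem-broken`` introduces disqualifying mispairs inside a
    stem; ``shuffled`` applies a dinucleotide-preserving shuffle.  Exactly
    one targeted defect is introduced and recorded in the returned truth.
    """
    seq, truth = base
    rng = rng if rng is not None else np.random.default_rng(seed)
    truth = copy.deepcopy(truth)
    chars = list(seq)

    if kind == "core-mutant":
        options = enumerate_core_mutants()
        label, base_nt = target or options[int(rng.integers(0, len(options)))]
        idx = truth["core"][label]
        if chars[idx] == base_nt:
            raise GenerationError(f"decoy base equals the original at {label}")
        chars[idx] = base_nt
        truth["defect"] = {"kind": kind, "label": label, "base": base_nt}
        truth["expected_reason"] = "core_mutation"
    elif kind == "adjacent-mispair":
        sid = ("I", "II")[int(rng.integers(0, 2))]
        i, j = truth["stems"][sid]["columns"][0]
        partner = chars[i]
        bad = [
            b for b in _BASES
            if not is_pair(partner, b) and not (partner == "U" and b == "U")
        ]
        chars[j] = bad[int(rng.integers(0, len(bad)))]
        truth["defect"] = {"kind": kind, "stem": sid, "index": j}
        truth["expected_reason"] = "adjacent_mispair"
    elif kind == "stem-broken":
        candidates = [
            sid for sid, st in truth["stems"].items() if len(st["columns"]) >= 4
        ]
        if not candidates:
            raise GenerationError("no stem long enough to break")
        sid = candidates[int(rng.integers(0, len(candidates)))]
        columns = truth["stems"][sid]["columns"]
        n_break = 1 if len(columns) <= 4 else 2
        mid = list(range(1, len(columns) - 1))
        picks = [mid[int(k)] for k in rng.choice(len(mid), size=n_break, replace=False)]
        for c in picks:
            i, j = columns[c]
            bad = [b for b in _BASES if not is_pair(chars[i], b)]
            chars[j] = bad[int(rng.integers(0, len(bad)))]
        truth["defect"] = {"kind": kind, "stem": sid, "columns": picks}
        truth["expected_reason"] = "short_stem_defects"
    elif kind == "shuffled":
        shuffled = dinucleotide_shuffle(seq, rng)
        return shuffled, {
            "record_id": truth.get("record_id", "decoy"),
            "negative": True,
            "defect": {"kind": kind},
        }
    else:
        raise GenerationError(f"unknown decoy kind: {kind!r}")
    truth["negative"] = True
    return "".join(chars), truth


# --------------------------------------------------------------------------
# Benchmark
# --------------------------------------------------------------------------


def _sample_positive(rng, pk_prob: float, variant_prob: float,
                     catalog=_filters.DEFAULT_VARIANT_CATALOG) -> Tuple[str, dict]:
    topo = Topology(("I", "II", "III")[int(rng.integers(0, 3))])
    n1 = int(rng.integers(2, 11))
    n2 = int(rng.integers(1, 9))
    n3 = int(rng.integers(2, 11))
    pk = 0
    if rng.random() < pk_prob:
        pk = int(rng.integers(4, 9))
    loops = [int(rng.integers(4, 11)) for _ in range(3)]
    pk_loop = 1 if topo is Topology.I else 0
    loops[pk_loop] = max(loops[pk_loop], pk)
    variant = None
    if variant_prob and rng.random() < variant_prob:
        variant = catalog[int(rng.integers(0, len(catalog)))].name
    return generate_hammerhead(
        topo, (n1, n2, n3), tuple(loops), pk_len=pk, variant=variant, rng=rng
    )


def _enforce_pk_window(chars: List[str], truth: dict, rng, config: ScanConfig) -> None:
    """Resample embedded background letters so the pseudoknot annotation of an
    embedded positive stays exactly as planted."""
    pk_loop = "II" if truth["topology"] == "I" else "I"
    if pk_loop not in truth["loops"]:
        return
    planted = truth["pseudoknot"]["n_bp"] if truth["pseudoknot"] else 0
    l0, l1 = truth["loops"][pk_loop]
    span0, span1 = truth["interval"]
    w = config.pk_tail_window
    c0, c1 = truth["_construct"]
    for _ in range(200):
        seq = "".join(chars)
        loop_seq = seq[l0:l1]
        k3 = _pk.best_duplex(loop_seq, seq[span1:min(len(seq), span1 + w)], config.allow_wobble)[0]
        k5 = _pk.best_duplex(loop_seq, seq[max(0, span0 - w):span0], config.allow_wobble)[0]
        if planted:
            ok = k3 == planted and k5 <= planted
        else:
            ok = max(k3, k5) < config.pk_min_bp
        if ok:
            return
        # only background letters outside the construct may be resampled
        for k in range(span1, min(len(chars), span1 + w)):
            if not (c0 <= k < c1):
                chars[k] = _rand_base(rng)
        for k in range(max(0, span0 - w), span0):
            if not (c0 <= k < c1):
                chars[k] = _rand_base(rng)
    raise GenerationError("could not insulate an embedded pseudoknot window")


def _shift_truth(truth: dict, off: int) -> dict:
    t = copy.deepcopy(truth)
    t["interval"] = (truth["interval"][0] + off, truth["interval"][1] + off)
    t["cleavage_site"] = truth["cleavage_site"] + off
    t["core"] = {k: v + off for k, v in truth["core"].items()}
    t["loops"] = {k: (a + off, b + off) for k, (a, b) in truth["loops"].items()}
    for sid, st in t["stems"].items():
        st["columns"] = [(i + off, j + off) for i, j in st["columns"]]
        st["five_interval"] = tuple(x + off for x in st["five_interval"])
        st["three_interval"] = tuple(x + off for x in st["three_interval"])
    if t.get("pseudoknot"):
        pk = t["pseudoknot"]
        pk["loop"] = tuple(x + off for x in pk["loop"])
        pk["tail"] = tuple(x + off for x in pk["tail"])
    return t


def generate_benchmark(
    n_pos: int,
    n_neg: int,
    bg_len: int = 500,
    seed: int = 0,
    pk_prob: float = 0.4,
    variant_prob: float = 0.0,
    config: Optional[ScanConfig] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """A benchmark of embedded positives and matched shuffled negatives.

    Returns ``(records, truth_table)``: records are (id, sequence) pairs —
    ``n_pos`` positives each embedded at a random offset in uniform random
    background of roughly ``bg_len`` nt, and ``n_neg`` dinucleotide-shuffled
    negatives of the same construction.  The truth table is BED-like
    (0-based half-open, strand column) with one row per planted positive.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    rng = np.random.default_rng(seed)
    config = config or ScanConfig()
    records: List[Tuple[str, str]] = []
    rows = []

    for i in range(n_pos):
        seq, truth = _sample_positive(rng, pk_prob, variant_prob)
        total = max(bg_len, len(seq) + 20)
        pad = total - len(seq)
        off = int(rng.integers(0, pad + 1))
        bg = [_rand_base(rng) for _ in range(pad)]
        chars = bg[:off] + list(seq) + bg[off:]
        truth = _shift_truth(truth, off)
        truth["_construct"] = (off, off + len(seq))
        _enforce_pk_window(chars, truth, rng, config)
        rec_id = f"pos_{i:04d}"
        truth["record_id"] = rec_id
        records.append((rec_id, "".join(chars)))
        rows.append({
            "record": rec_id,
            "start": truth["interval"][0],
            "end": truth["interval"][1],
            "strand": "+",
            "topology": truth["topology"],
            "cleavage_site": truth["cleavage_site"],
            "pk_len": truth["pseudoknot"]["n_bp"] if truth["pseudoknot"] else 0,
            "variant": truth["variant"] or ".",
        })

    for i in range(n_neg):
        seq, truth = _sample_positive(rng, pk_prob, variant_prob)
        total = max(bg_len, len(seq) + 20)
        pad = total - len(seq)
        off = int(rng.integers(0, pad + 1))
        bg = [_rand_base(rng) for _ in range(pad)]
        rec = "".join(bg[:off]) + seq + "".join(bg[off:])
        records.append((f"neg_{i:04d}", dinucleotide_shuffle(rec, rng)))

    truth_table = pd.DataFrame(
        rows,
        columns=["record", "start", "end", "strand", "topology",
                 "cleavage_site", "pk_len", "variant"],
    )
    return records, truth_table
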