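"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the scanner's semantics by exhaustive
enumeration — every box placement, every residue-17 position, every stem
alignment (all column counts and all internal bulge placements) — without
using the scanner's search code.  They share only the primitive domain
types (pairing predicate, consensus sets, the hit container) and the filter
/pseudoknot annotators, which have their own dedicated tests.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from hhscan import filters as hh_filters
from hhscan import pseudoknot as hh_pk
from hhscan.model import (
    CoreConsensus,
    HammerheadHit,
    Stem,
    Topology,
    forward_interval,
    is_pair,
    reverse_complement,
)
from hhscan.scan import ScanConfig

BIG = 10 ** 6


# -- exhaustive stem alignment search --------------------------------------

def _alignments(a: str, b: str, max_bp: int, max_defects: int, allow_wobble: bool):
    """Yield (n_bp, mispairs, bulges, ba, bb, paired, wobbles, ca, cb)."""
    n_max = min(len(a), len(b), max_bp + max_defects)
    for n in range(1, n_max + 1):
        for ba in [None] + list(range(1, n)):
            for bb in [None] + list(range(1, n)):
                ca = n + (ba is not None)
                cb = n + (bb is not None)
                if ca > len(a) or cb > len(b):
                    continue
                paired, wob = [], []
                for c in range(n):
                    ia = c + (1 if ba is not None and c >= ba else 0)
                    ib = c + (1 if bb is not None and c >= bb else 0)
                    p = is_pair(a[ia], b[ib], allow_wobble)
                    paired.append(p)
                    wob.append(p and (a[ia], b[ib]) in (("G", "U"), ("U", "G")))
                if not paired[-1]:
                    continue
                n_bp = sum(paired)
                mis = n - n_bp
                bulges = (ba is not None) + (bb is not None)
                if mis + bulges > max_defects or n_bp > max_bp:
                    continue
                yield (n_bp, mis, bulges, ba, bb, paired, wob, ca, cb)


def _aln_key(t):
    n_bp, mis, bulges, ba, bb = t[0], t[1], t[2], t[3], t[4]
    return (n_bp, -(mis + bulges), -bulges,
            -(ba if ba is not None else BIG), -(bb if bb is not None else BIG))


def brute_fold_open(a: str, b: str, min_bp: int, max_bp: int,
                    max_defects: int, allow_wobble: bool):
    cands = [t for t in _alignments(a, b, max_bp, max_defects, allow_wobble)]
    cands = [t for t in cands if t[0] >= min_bp]
    return max(cands, key=_aln_key) if cands else None


def brute_fold_hairpin(region: str, min_bp: int, max_bp: int, min_loop: int,
                       max_loop: int, max_defects: int, allow_wobble: bool):
    cands = []
    for t in _alignments(region, region[::-1], max_bp, max_defects, allow_wobble):
        loop = len(region) - t[7] - t[8]
        if t[0] >= min_bp and min_loop <= loop <= max_loop:
            cands.append(t)
    return max(cands, key=_aln_key) if cands else None


# -- exhaustive duplex search (pseudoknot oracle) --------------------------

def brute_best_duplex(loop: str, flank: str, allow_wobble: bool = True) -> int:
    """Length of the longest contiguous antiparallel duplex, O(n^2) runs."""
    best = 0
    for i in range(len(loop)):
        for j in range(len(flank)):
            k = 0
            while (i + k < len(loop) and j - k >= 0
                   and is_pair(loop[i + k], flank[j - k], allow_wobble)):
                k += 1
            best = max(best, k)
    return best


# -- whole-scan oracle -----------------------------------------------------

def _stem_from_brute_hairpin(sid, r0, r1, t):
    n_bp, mis, bulges, ba, bb, paired, wob, ca, cb = t
    pairs, nw = [], 0
    for c in range(len(paired)):
        ia = c + (1 if ba is not None and c >= ba else 0)
        ib = c + (1 if bb is not None and c >= bb else 0)
        if paired[c]:
            pairs.append((r0 + ia, r1 - 1 - ib))
            nw += wob[c]
    return Stem(id=sid, pairs=pairs, n_wobble=nw, n_mispairs=mis, n_bulges=bulges,
                five_interval=(r0, r0 + ca), three_interval=(r1 - cb, r1),
                innermost=(r0, r1 - 1), innermost_paired=paired[0])


def _stem_from_brute_open(sid, a0, b0, t):
    n_bp, mis, bulges, ba, bb, paired, wob, ca, cb = t
    pairs, nw = [], 0
    for c in range(len(paired)):
        ia = c + (1 if ba is not None and c >= ba else 0)
        ib = c + (1 if bb is not None and c >= bb else 0)
        if paired[c]:
            pairs.append((b0 - ib, a0 + ia))
            nw += wob[c]
    return Stem(id=sid, pairs=pairs, n_wobble=nw, n_mispairs=mis, n_bulges=bulges,
                five_interval=(b0 - cb + 1, b0 + 1), three_interval=(a0, a0 + ca),
                innermost=(b0, a0), innermost_paired=paired[0])


def oracle_scan(sequence: str, config: Optional[ScanConfig] = None,
                record_id: str = "seq") -> List[HammerheadHit]:
    """Exhaustive strict-mode scan: every (box1, box2, topology, residue-17,
    stem alignment) combination, the same constraints, the same collapsing
    rule, enumerated naively."""
    config = config or ScanConfig()
    assert config.mode == "strict", "the oracle covers strict mode"
    consensus = CoreConsensus.default()
    seq0 = sequence.upper().replace("T", "U")
    length = len(seq0)
    strands = [("+", seq0)]
    if config.both_strands:
        strands.append(("-", reverse_complement(seq0)))

    md = config.max_defects_per_stem
    wob = config.allow_wobble
    lmin, lmax = config.loop_len
    passing: Dict[tuple, Dict[int, HammerheadHit]] = {}
    rejected: Dict[tuple, HammerheadHit] = {}

    for strand, seq in strands:
        box1 = [p for p in range(0, len(seq) - 6)
                if seq[p] == "C" and seq[p + 1] == "U" and seq[p + 2] == "G"
                and seq[p + 3] == "A" and seq[p + 5] == "G" and seq[p + 6] == "A"]
        box2 = [q for q in range(0, len(seq) - 3)
                if seq[q:q + 3] == "GAA" and seq[q + 3] == "A"]

        _hp_memo: Dict[tuple, object] = {}

        def hairpin(sid, r0, r1):
            if r1 <= r0:
                return None
            key = (sid, r0, r1)
            if key not in _hp_memo:
                lo, hi = config.stem_bp[sid]
                _hp_memo[key] = brute_fold_hairpin(
                    seq[r0:r1], lo, hi, lmin, lmax, md, wob)
            return _hp_memo[key]

        def openstem(sid, a0, b0):
            lo, hi = config.stem_bp[sid]
            cap = hi + md + 1
            a = seq[a0:a0 + cap]
            b = seq[max(0, b0 + 1 - cap):b0 + 1][::-1]
            if not a or not b:
                return None
            return brute_fold_open(a, b, lo, hi, md, wob)

        def emit(topo, p, q, t, stems, loops):
            core = {str(k): p + k - 3 for k in range(3, 10)}
            core.update({str(k): q + k - 12 for k in range(12, 15)})
            core["15.1"] = q + 3
            core["16.1"] = t - 1
            core["17"] = t
            idxs = list(core.values())
            for st in stems.values():
                idxs += [st.five_interval[0], st.five_interval[1] - 1,
                         st.three_interval[0], st.three_interval[1] - 1]
            s0, s1 = min(idxs), max(idxs) + 1
            if s1 - s0 > config.max_span:
                return
            devs = {}
            for label, idx in core.items():
                if not consensus.allowed(label).matches(seq[idx]):
                    devs[label] = seq[idx]
            hit = HammerheadHit(
                record_id=record_id, strand=strand,
                interval=forward_interval(s0, s1, strand, length),
                topology=topo, core=core, stems=stems, loops=loops,
                cleavage_site=(t + 1) if strand == "+" else (length - (t + 1)),
                deviations=devs, scanned_length=length, scanned_seq=seq,
            )
            hit.verdict = hh_filters.apply_strict_filters(hit, config.short_stem_threshold)
            hit.pseudoknot = hh_pk.detect_pseudoknot(
                hit, seq, min_bp=config.pk_min_bp,
                tail_window=config.pk_tail_window, allow_wobble=wob)
            pk = hit.pseudoknot.n_bp if hit.pseudoknot else 0
            hit.score = float(
                sum(s.n_bp for s in stems.values())
                - sum(s.n_defects for s in stems.values()) + 2 * pk)
            key = (strand, topo.value, p, q)
            if hit.verdict.status != "rejected":
                passing.setdefault(key, {})[t] = hit
            else:
                rank = (hit.score, stems["II"].n_bp, stems["I"].n_bp,
                        -hit.start, -t)
                old = rejected.get(key)
                if old is None or rank > old._oracle_rank:
                    hit._oracle_rank = rank
                    rejected[key] = hit

        for p in box1:
            for q in box2:
                for t in range(1, len(seq)):
                    if seq[t] not in "ACU" or seq[t - 1] != "U":
                        continue
                    # type I: p < q < t, stems II and III hairpinned, I open
                    if p + 7 <= q and q + 3 < t:
                        h2 = hairpin("II", p + 7, q)
                        h3 = hairpin("III", q + 3, t)
                        if h2 and h3:
                            o1 = openstem("I", t + 1, p - 1)
                            if o1:
                                emit(Topology.I, p, q, t, {
                                    "II": _stem_from_brute_hairpin("II", p + 7, q, h2),
                                    "III": _stem_from_brute_hairpin("III", q + 3, t, h3),
                                    "I": _stem_from_brute_open("I", t + 1, p - 1, o1),
                                }, {
                                    "II": _loop_of(p + 7, q, h2),
                                    "III": _loop_of(q + 3, t, h3),
                                })
                    # type II: q < t < p, stems III and I hairpinned, II open
                    if q + 3 < t and t + 1 < p:
                        h3 = hairpin("III", q + 3, t)
                        h1 = hairpin("I", t + 1, p)
                        if h3 and h1:
                            o2 = openstem("II", p + 7, q - 1)
                            if o2:
                                emit(Topology.II, p, q, t, {
                                    "III": _stem_from_brute_hairpin("III", q + 3, t, h3),
                                    "I": _stem_from_brute_hairpin("I", t + 1, p, h1),
                                    "II": _stem_from_brute_open("II", p + 7, q - 1, o2),
                                }, {
                                    "III": _loop_of(q + 3, t, h3),
                                    "I": _loop_of(t + 1, p, h1),
                                })
                    # type III: t < p, p + 7 <= q, stems I and II hairpinned, III open
                    if t + 1 < p and p + 7 <= q:
                        h1 = hairpin("I", t + 1, p)
                        h2 = hairpin("II", p + 7, q)
                        if h1 and h2:
                            o3 = openstem("III", q + 3, t - 1)
                            if o3:
                                emit(Topology.III, p, q, t, {
                                    "I": _stem_from_brute_hairpin("I", t + 1, p, h1),
                                    "II": _stem_from_brute_hairpin("II", p + 7, q, h2),
                                    "III": _stem_from_brute_open("III", q + 3, t - 1, o3),
                                }, {
                                    "I": _loop_of(t + 1, p, h1),
                                    "II": _loop_of(p + 7, q, h2),
                                })
    out = []
    for key, by_t in passing.items():
        out.extend(by_t.values())
    for key, hit in rejected.items():
        if key not in passing:
            out.append(hit)
    return out


def _loop_of(r0: int, r1: int, t) -> Tuple[int, int]:
    ca, cb = t[7], t[8]
    return (r0 + ca, r1 - cb)


def hit_signature(h: HammerheadHit) -> tuple:
    """Comparable summary of a hit for equivalence checks."""
    return (
        h.record_id, h.strand, h.topology.value,
        h.core["3"], h.core["12"], h.core["17"],
        tuple(h.interval), h.cleavage_site,
        h.verdict.status, h.verdict.reason,
        h.stems["I"].n_bp, h.stems["II"].n_bp, h.stems["III"].n_bp,
        sum(s.n_defects for s in h.stems.values()),
        h.pseudoknot.n_bp if h.pseudoknot else 0,
        h.score,
    )
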