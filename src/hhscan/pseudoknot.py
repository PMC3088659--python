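"""Annotation of the stem I/stem II tertiary contact.

Many natural hammerheads stabilize the catalytically required parallel
arrangement of stems I and II with a pseudoknot: a contiguous antiparallel
duplex of at least four base pairs between the terminal loop of stem I and
the single-stranded flank just beyond stem II (for type I hits, whose stem I
carries the termini, the mirrored geometry is searched: loop II against the
flank beyond stem I).  A weaker, explicitly heuristic screen classifies the
remaining hits by loop-loop complementarity.
"""

from __future__ import annotations

from typing import Optional, Tuple

from .model import HammerheadHit, Pseudoknot, Topology, is_pair

#: Minimum duplex length for a pseudoknot call.
DEFAULT_MIN_BP = 4
#: How far beyond the motif the single-stranded flank is searched, in nt.
DEFAULT_TAIL_WINDOW = 30


def best_duplex(
    loop: str,
    flank: str,
    allow_wobble: bool = True,
) -> Tuple[int, int, int, int]:
    """Longest contiguous antiparallel duplex between two strands.

    Returns ``(k, i, j, n_wobble)`` where ``loop[i + m]`` pairs
    ``flank[j + k - 1 - m]`` for ``m in range(k)``.  Ties broken by smaller
    ``i``, then smaller ``j``.  Returns ``(0, -1, -1, 0)`` if nothing pairs.
    """
    best = (0, -1, -1, 0)
    nl, nf = len(loop), len(flank)
    for i in range(nl):
        for jend in range(nf - 1, -1, -1):  # flank index paired with loop[i]
            k = 0
            wob = 0
            while i + k < nl and jend - k >= 0 and is_pair(
                loop[i + k], flank[jend - k], allow_wobble
            ):
                if (loop[i + k], flank[jend - k]) in (("G", "U"), ("U", "G")):
                    wob += 1
                k += 1
            if k > best[0]:
                best = (k, i, jend - k + 1, wob)
    return best


def _designated_loop(hit: HammerheadHit) -> Tuple[str, Tuple[int, int]]:
    """The loop eligible for the pseudoknot: loop I for types II/III,
    loop II (mirrored geometry) for type I."""
    if hit.topology is Topology.I:
        label = "II"
    else:
        label = "I"
    if label not in hit.loops:
        raise ValueError(
            f"topology {hit.topology.value} hit provides no eligible terminal loop"
        )
    return label, hit.loops[label]


def detect_pseudoknot(
    hit: HammerheadHit,
    sequence: Optional[str] = None,
    min_bp: int = DEFAULT_MIN_BP,
    tail_window: int = DEFAULT_TAIL_WINDOW,
    allow_wobble: bool = True,
) -> Optional[Pseudoknot]:
    """Find the pseudoknot duplex for a hit, or None.

    ``sequence`` is the scanned-strand sequence (defaults to the one stored
    on the hit).  Both single-stranded flanks of the motif are searched
    within ``tail_window`` nt; the longest duplex wins, with the 3' tail
    preferred on ties (the geometry the type II consensus uses).  The duplex
    never consumes nucleotides assigned to stems or core boxes because the
    flanks lie entirely outside the structured span.
    """
    seq = sequence if sequence is not None else hit.scanned_seq
    if not seq:
        raise ValueError("no sequence available for pseudoknot detection")
    loop_label, (l0, l1) = _designated_loop(hit)
    span0, span1 = hit.stem_span_on_scanned()
    loop_seq = seq[l0:l1]

    tail0, tail1 = span1, min(len(seq), span1 + tail_window)
    head0, head1 = max(0, span0 - tail_window), span0

    candidates = []
    for flank0, flank1, side in ((tail0, tail1, "3'"), (head0, head1, "5'")):
        if flank1 <= flank0:
            continue
        k, i, j, wob = best_duplex(loop_seq, seq[flank0:flank1], allow_wobble)
        if k >= max(min_bp, 1):
            candidates.append((k, 1 if side == "3'" else 0, side, i, j, wob, flank0))
    if not candidates:
        return None
    k, _, side, i, j, wob, flank0 = max(candidates, key=lambda c: (c[0], c[1], -c[3], -c[4]))

    if hit.topology is Topology.I:
        geometry = "loopII-flank"
    else:
        geometry = "loopI-3'tail" if side == "3'" else "loopI-5'flank"
    loop_abs = (l0 + i, l0 + i + k)
    tail_abs = (flank0 + j, flank0 + j + k)
    pairs = [(loop_abs[0] + m, tail_abs[1] - 1 - m) for m in range(k)]
    return Pseudoknot(
        loop_region=loop_abs,
        tail_region=tail_abs,
        n_bp=k,
        n_wobble=wob,
        geometry=geometry,
        pairs=pairs,
    )


def screen_loop_interaction(
    hit: HammerheadHit,
    sequence: Optional[str] = None,
    min_patch: int = 2,
    tail_window: int = DEFAULT_TAIL_WINDOW,
    allow_wobble: bool = True,
) -> str:
    """Heuristic classification of the stem I/II tertiary contact.

    Returns ``"pseudoknot"`` if a pseudoknot was (or can be) detected,
    ``"putative loop-loop"`` if the stem I side and stem II side share at
    least ``min_patch`` bp of contiguous complementarity, else ``"none"``.
    This is a deliberately reduced complementarity screen, not a motif
    taxonomy: treat the loop-loop call as a flag for inspection.
    """
    seq = sequence if sequence is not None else hit.scanned_seq
    pk = hit.pseudoknot
    if pk is None and seq:
        pk = detect_pseudoknot(hit, seq, tail_window=tail_window, allow_wobble=allow_wobble)
    if pk is not None:
        return "pseudoknot"
    if not seq:
        raise ValueError("no sequence available for the loop-interaction screen")

    span0, span1 = hit.stem_span_on_scanned()

    def region(label: str) -> str:
        if label in hit.loops:
            a, b = hit.loops[label]
            return seq[a:b]
        # open stem: use the 3' tail as that side's single-stranded segment
        return seq[span1:min(len(seq), span1 + tail_window)]

    side_one = region("I")
    side_two = region("II")
    k, _, _, _ = best_duplex(side_one, side_two, allow_wobble)
    if k >= min_patch:
        return "putative loop-loop"
    return "none"
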