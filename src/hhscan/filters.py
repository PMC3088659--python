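"""Final-alignment disqualification rules and the tolerated-variant catalog.

Strict mode applies three rules to every structurally feasible hit:

1. any deviation at the 13 core consensus positions (including an insertion
   into the core) disqualifies the hit;
2. a mispair at any of the three core-adjacent stem columns
   (1.1-2.1, 10.1-11.1, 15.1-16.1) disqualifies the hit;
3. defective stems disqualify the hit: one or more mispairs/bulges in a
   short stem (<= ``short_stem_threshold`` bp), or two or more in a longer
   stem.

Variant mode re-examines hits rejected by rules 1 or 2: if every core
deviation, core insertion, and core-adjacent mismatch is covered by a
catalogued, experimentally characterized natural variant, the hit passes
as ``pass-variant`` and is annotated with the matched variants.  Covariations
require all of their co-changes to be present.  Rule 3 is never relaxed.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

from .model import CORE_LABELS, CoreVariant, FilterVerdict, HammerheadHit

#: Default stem-length threshold (in paired columns) below which a single
#: mispair or bulge is disqualifying.
SHORT_STEM_THRESHOLD = 4

#: Maximum defects tolerated in a stem longer than the short-stem threshold.
MAX_LONG_STEM_DEFECTS = 1


#: Catalogued natural core variants with their measured activity behaviour.
#: Each entry lists *all* co-required changes; a partial match never rescues.
DEFAULT_VARIANT_CATALOG: Tuple[CoreVariant, ...] = (
    CoreVariant(
        name="C3U/G8A",
        kind="covariation",
        substitutions=(("3", "U"), ("8", "A")),
        activity_note="active (C3-G8 base pair maintained by covariation)",
    ),
    CoreVariant(
        name="A6C",
        kind="substitution",
        substitutions=(("6", "C"),),
        activity_note="low-activity (kobs below 0.1 min-1)",
    ),
    CoreVariant(
        name="A6a",
        kind="insertion",
        insertions=(("6", "6a", "A"),),
        activity_note="low-activity (backbone insertion next to the U4 contact)",
    ),
    CoreVariant(
        name="U13a",
        kind="insertion",
        insertions=(("13", "13a", "U"),),
        activity_note="active (insertion points out of the core)",
    ),
    CoreVariant(
        name="U15.1-A16.1",
        kind="closing-pair-swap",
        substitutions=(("15.1", "U"), ("16.1", "A")),
        activity_note="low-activity (self-cleaves less efficiently than consensus)",
    ),
    CoreVariant(
        name="U10.1-U11.1",
        kind="closing-pair-mismatch",
        substitutions=(("10.1", "U"), ("11.1", "U")),
        activity_note="active (best-tolerated mispair at the stem II closing pair)",
    ),
    CoreVariant(
        name="2a/2b",
        kind="insertion",
        insertions=(("2.1", "2a", "G"), ("2.1", "2b", "C")),
        activity_note="salt-dependent (requires very high ionic strength)",
    ),
)


def catalog_by_name(name: str, catalog: Iterable[CoreVariant] = DEFAULT_VARIANT_CATALOG) -> CoreVariant:
    for entry in catalog:
        if entry.name == name:
            return entry
    raise KeyError(f"no catalogued variant named {name!r}")


def _core_insertions(hit: HammerheadHit) -> Dict[str, str]:
    """Inserted core labels (e.g. '6a', '2a') -> observed nucleotide."""
    out = {}
    for label, idx in hit.core.items():
        if label not in CORE_LABELS:
            out[label] = hit.scanned_seq[idx] if hit.scanned_seq else "?"
    return out


def apply_strict_filters(
    hit: HammerheadHit,
    short_stem_threshold: int = SHORT_STEM_THRESHOLD,
) -> FilterVerdict:
    """Apply the three strict disqualification rules to a hit.

    The hit must carry a core-match report (``deviations``); rejected hits
    get exactly one primary reason, evaluated in rule order.
    """
    if hit.deviations is None:
        raise ValueError("hit lacks a core match report")

    insertions = _core_insertions(hit)
    if hit.deviations or insertions:
        return FilterVerdict(
            status="rejected",
            reason="core_mutation",
            details={"deviations": dict(hit.deviations), "insertions": insertions},
        )

    mispaired = [
        stem_id for stem_id, stem in sorted(hit.stems.items())
        if not stem.innermost_paired
    ]
    if mispaired:
        return FilterVerdict(
            status="rejected",
            reason="adjacent_mispair",
            details={"stems": mispaired},
        )

    for stem_id, stem in sorted(hit.stems.items()):
        # a stem's length is its physical extent in columns (paired + mispaired)
        length = stem.n_bp + stem.n_mispairs
        limit = 0 if length <= short_stem_threshold else MAX_LONG_STEM_DEFECTS
        if stem.n_defects > limit:
            return FilterVerdict(
                status="rejected",
                reason="short_stem_defects",
                details={"stem": stem_id, "n_bp": stem.n_bp, "defects": stem.n_defects},
            )

    return FilterVerdict(status="pass-strict")


def apply_variant_catalog(
    hit: HammerheadHit,
    catalog: Iterable[CoreVariant] = DEFAULT_VARIANT_CATALOG,
    short_stem_threshold: int = SHORT_STEM_THRESHOLD,
) -> FilterVerdict:
    """Re-examine a rejected hit against the tolerated-variant catalog.

    Passes as ``pass-variant`` iff every core deviation, core insertion and
    core-adjacent mismatch is covered by catalog entries (all co-changes of a
    covariation must be present) and the stem-defect rule still holds.  A
    hit that strict mode passes is returned unchanged (monotonicity).
    """
    strict = apply_strict_filters(hit, short_stem_threshold)
    if strict.status == "pass-strict":
        return strict
    if strict.reason == "short_stem_defects":
        return strict

    for entry in catalog:
        for label, _ in tuple(entry.substitutions) + tuple(
            (lbl, nt) for lbl, _, nt in entry.insertions
        ):
            if label not in CORE_LABELS and label not in ("10.1", "11.1", "2.1", "1.1", "2a", "2b"):
                raise ValueError(f"catalog entry {entry.name!r} references unknown position {label!r}")

    remaining_devs = dict(hit.deviations)
    remaining_ins = dict(_core_insertions(hit))
    remaining_mispairs = {
        stem_id for stem_id, stem in hit.stems.items() if not stem.innermost_paired
    }
    matched: List[CoreVariant] = []

    for entry in catalog:
        if entry.kind == "closing-pair-mismatch":
            # covers a mismatch at the stem II closing pair with the
            # catalogued nucleotides on both sides
            if "II" not in remaining_mispairs:
                continue
            stem = hit.stems["II"]
            want = dict(entry.substitutions)
            i, j = stem.innermost
            if not hit.scanned_seq:
                continue
            letters = {hit.scanned_seq[i], hit.scanned_seq[j]}
            if letters == set(want.values()):
                remaining_mispairs.discard("II")
                matched.append(entry)
            continue

        subs_ok = all(
            remaining_devs.get(label) == nt for label, nt in entry.substitutions
        )
        ins_ok = all(
            remaining_ins.get(new_label) == nt for _, new_label, nt in entry.insertions
        )
        if not entry.substitutions and not entry.insertions:
            continue
        if subs_ok and ins_ok:
            for label, _ in entry.substitutions:
                remaining_devs.pop(label, None)
            for _, new_label, _ in entry.insertions:
                remaining_ins.pop(new_label, None)
            matched.append(entry)

    if remaining_devs or remaining_ins or remaining_mispairs:
        return strict  # the original rejection stands

    # rule 3 still applies in variant mode, but a catalogued closing-pair
    # mismatch is no longer double-counted as a stem defect
    rescued_mispair = any(e.kind == "closing-pair-mismatch" for e in matched)
    for stem_id, stem in sorted(hit.stems.items()):
        defects = stem.n_defects
        length = stem.n_bp + stem.n_mispairs
        if stem_id == "II" and rescued_mispair and not stem.innermost_paired:
            defects -= 1
        limit = 0 if length <= short_stem_threshold else MAX_LONG_STEM_DEFECTS
        if defects > limit:
            return FilterVerdict(
                status="rejected",
                reason="short_stem_defects",
                details={"stem": stem_id, "n_bp": stem.n_bp, "defects": stem.n_defects},
            )

    hit.variants = matched
    return FilterVerdict(
        status="pass-variant",
        details={"variants": [v.name for v in matched]},
    )
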