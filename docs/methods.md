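# Methods

This note documents the models and procedures implemented in `hhscan`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the package's known limitations.

## The motif model

The hammerhead motif is represented as a circular architecture opened at
one terminal loop.  Going 5′→3′ around the circle:

```
stem I (1.x half) – loop I – stem I (2.x half) – box 1 (C3 U4 G5 A6 N7 G8 A9) –
stem II (10.x) – loop II – stem II (11.x) – box 2 (G12 A13 A14) –
stem III (15.x) – loop III – stem III (16.x) – residue 17 – [cleavage] – back to 1.1
```

The three natural topologies are the three ways of opening this circle:
type I opens at loop I (termini in stem I), type II at loop II, type III at
loop III.  `topology_layout` returns the resulting linear element orders;
they are bijective with the topologies and re-close to the same cyclic
order.  The 13-position core consensus and the closing pair A15.1–U16.1
are held in `CoreConsensus`; input letters match a consensus position only
if their IUPAC set is a *subset* of the allowed set, so masked (N) input
never satisfies a fixed consensus letter.

Coordinates are 0-based half-open on the scanned strand; minus-strand hits
are found on the reverse complement and reported with forward coordinates.
The cleavage site is reported as the boundary 3′ of residue 17.  A hit's
interval spans the structured motif (stems + core); pseudoknot flanks are
annotated separately.

## Scanning

The scanner anchors on box 1 (`CUGANGA`) and box 2 (`GAA` plus the A15.1
nucleotide).  For each anchor pair, topology and candidate residue-17
position (pinned between the anchors by the architecture; cheap letter
checks on H17 and U16.1 prune most positions), the three stems are folded:

* folding proceeds from the core junction outward, column by column;
* Watson–Crick and (by default) G–U wobble pairs count as paired;
* a bounded number of defects is tolerated per stem (default 2 =
  mispairs + bulges, matching the filter threshold beyond which a stem can
  never pass), with at most one single-nucleotide bulge per half, bulges
  strictly internal to the stem;
* the outermost column must pair; the objective is lexicographic —
  most paired columns, fewest defects, fewest bulges, innermost bulge
  placement — which makes folding deterministic;
* hairpin stems fold inside the fixed region between their anchors and
  must leave a terminal loop of 3–30 nt; the open stem's halves extend
  toward the molecule's termini, capped so a hit never exceeds the
  200 nt window.

Default stem ranges (stem I 2–12 bp, stem II 1–10 bp, stem III 2–12 bp)
cover the range of depicted natural structures, including the known
one-base-pair stem II; all ranges are configurable (`ScanConfig`, flat
YAML config file, CLI flags).

**Collapsing.** A core placement is the full label→index map including
residue 17.  For one (strand, topology, box 1, box 2) anchor group, every
*accepted* folding is reported — different residue-17 placements have
different cleavage sites and are genuinely different ribozyme calls — while
rejected foldings are collapsed to the single best-scoring one (score =
total bp − defects + 2·pseudoknot bp; ties broken by longer stem II, longer
stem I, smaller start, smaller residue-17).  An accepted folding always
outranks a rejected one: if a core placement admits a consensus-conforming
structure, that structure is the call, and a defect-stretched alternative
with a nominally higher score is noise.

## Filtering

Strict mode applies three rules in order; a rejected hit carries exactly
one primary reason:

1. **core_mutation** — any deviation at the 13 core positions, or any
   insertion into the core;
2. **adjacent_mispair** — a mispair at 1.1–2.1, 10.1–11.1 or 15.1–16.1
   (wobble counts as paired, not as a defect);
3. **short_stem_defects** — ≥ 1 mispair/bulge in a short stem, or ≥ 2 in a
   longer stem.  "Short" means physical stem length (paired + mispaired
   columns) at or below the threshold (default 4), so breaking one pair of
   a 5-column stem does not reclassify it as short.  The quantification of
   "short" and "multiple" is a package choice; both knobs are configurable.

Variant mode re-examines hits rejected by rules 1–2 against a catalog of
experimentally characterized natural variants: C3U/G8A (active
covariation; both changes required), A6C (low activity, kobs < 0.1 min⁻¹),
A6a and U13a insertions, the U15.1–A16.1 closing-pair swap (reduced
activity), the U10.1–U11.1 closing-pair mismatch (the best-tolerated
mispair; once catalog-matched it no longer counts as a stem defect), and
the 2a/2b GC insertion between stem I and C3 (active only at very high
ionic strength).  Every deviation must be covered; rule 3 is never
relaxed.  The catalog is data (`CoreVariant` entries) and user-extensible.

In variant mode the scanner finds catalogued variants by adding one anchor
pattern per catalog entry; one catalogued variant per hit.  Uncatalogued
core mutants are deliberately not anchored — they are the false-positive
class the filters exist to remove — but hits can be constructed from truth
annotations (`hit_from_truth`) to exercise the filters directly.

## Pseudoknot annotation

For types II/III the terminal loop of stem I, and for type I (mirrored
geometry) the loop of stem II, is searched against both single-stranded
flanks of the motif within a 30 nt window (configurable); the annotation is
the longest contiguous antiparallel duplex of ≥ 4 bp (wobble allowed), with
the 3′ tail preferred on ties.  Interior (bulged) pairings are not
considered: the criterion is a contiguous run.  The loop-interaction screen
is deliberately reduced — pseudoknot if one is detected, else "putative
loop–loop" if the stem I and stem II loops share ≥ 2 bp of contiguous
complementarity, else none — and is flagged as heuristic.

## Kinetics

* `fit_kobs_linear`: kobs = −slope of the least-squares line of
  ln(1 − F/endpoint) versus time, restricted to points whose cleaved
  fraction lies in the first 5–30 % of the reaction *amplitude* (not clock
  time), the standard pseudo-first-order practice.  The endpoint defaults
  to 1.0 (reaction goes to completion) and may be set to a known plateau or
  to the observed maximum.  Fewer than two in-window points is an error
  that advises a full-range or biphasic fit.
* `fit_biphasic`: bounded non-linear least squares on
  F = a(1−e^(−bt)) + c(1−e^(−dt)), with 10 deterministic multistart
  initializations (amplitudes from the trace plateaus, slow rate at b/20,
  log-normal jitter from a fixed seed).  b ≥ d is enforced by relabeling;
  amplitudes are bounded to [0, 1.05] with a + c ≤ 1.05 as fit slack (the
  amplitude sum is intentionally not constrained to the endpoint).
  Non-convergence raises an explicit error with diagnostics.
* All rates are min⁻¹.  `fold_change` returns the exact ratio (so the
  reciprocal product is exactly 1) and is formatted to 3 significant
  figures for display.

## Synthetic data

The generator instantiates the consensus directly: random paired stems
(10 % wobble probability, matching the scanner's pairing rules), random
loops and flanks, an exact-complement pseudoknot when requested, and at
most one catalogued variant.  Two design points matter:

* **insulation** — flanks are ≥ 16 nt so open-stem folding can never read
  past them, and loop/flank letters are rejection-sampled (deterministically
  from the seed) until each planted region is the unique maximal folding
  and the pseudoknot windows contain exactly the planted complementarity.
  The checks use the scanner's fold primitives on local regions only; the
  generator never runs the full scanner on its output.
* **benchmarks** — positives are embedded at random offsets in uniform
  i.i.d. background (a deliberate choice: the studies the defaults mirror
  have no background model, and uniform background makes false-positive
  counts interpretable); negatives are dinucleotide-preserving shuffles
  (Altschul–Erickson Eulerian-path shuffle) of matched constructs.
  Defaults: topologies uniform over I/II/III, stem lengths sampled across
  the configured ranges, pseudoknots on 40 % of positives with lengths
  4–8 bp — the fraction reported for natural hammerhead collections.

What passing tests on this data do *not* show: behaviour on real genomic
background (repeats, skewed composition, ORFs), on bulged natural stems, or
on hammerheads outside the configured length ranges.  The benchmark
measures the machinery, not genome-scale specificity.

The exhaustive core-mutant decoy set contains 34 members, not 13 × 3:
N7 admits every nucleotide (no decoys) and H17 admits all but G (one
decoy).

## Numerical and degenerate-input choices

* Folding, collapsing and tie-breaks are fully deterministic (documented
  lexicographic keys); outputs are byte-identical across runs for fixed
  inputs, config and seeds.
* Ambiguity codes never pair in stems or pseudoknots; they can satisfy
  consensus positions only under the subset rule.
* Empty or sub-minimal sequences scan to an empty hit list; illegal
  characters raise an error naming the record and offset.
* Scan problem sizes used by the shipped test suite and acceptance script
  (200-record benchmarks of ~500 nt, 200-sequence oracle suites of ≤ 80 nt,
  500-replicate kinetics simulations) were chosen as the smallest sizes at
  which the recovery, specificity and calibration claims are statistically
  meaningful.

## Known limitations

* The 2a/2b insertion sits between stem I and C3, so a strict-mode scan can
  always reinterpret the two inserted nucleotides as loop/stem context and
  report a consensus-conforming parse at the same cleavage site; the
  insertion is only identified as such by the variant catalog applied to
  the true placement.  This is an inherent ambiguity of descriptor
  scanning, not a filter defect.
* Overlapping passing calls at distinct core placements are all reported;
  downstream deduplication (e.g. one call per locus) is left to the user.
* The scanner is a descriptor engine, not a covariance model: it assigns no
  E-values and does no alignment-based homology search.
* The loop-interaction screen is a complementarity heuristic and does not
  reproduce any specific tertiary-contact taxonomy.
* Kinetics fitting assumes complete (or known-amplitude) single- or
  two-phase first-order reactions; Mg²⁺-binding isotherms are out of scope
  beyond tabulating user-supplied kobs values.
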