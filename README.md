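# hhscan — hammerhead ribozyme scanning, annotation and kinetics

Hammerhead ribozymes are small self-cleaving RNAs that cut their own
backbone by internal phosphoester transfer.  The motif is a three-helix
junction whose catalytic core comprises 13 strictly constrained
nucleotides — box 1 (C3 U4 G5 A6 N7 G8 A9), box 2 (G12 A13 A14), the
conserved stem III closing pair A15.1–U16.1, and the cleavage-site residue
H17 (H = A, C or U; scission occurs 3′ of residue 17).  The motif occurs in
nature as three circular permutations ("types" I, II and III, named for the
stem that carries the molecule's termini instead of a terminal loop), and
many representatives stabilize the catalytically required parallel
arrangement of stems I and II with a pseudoknot: a contiguous duplex of
≥ 4 bp between the loop of stem I and the single-stranded flank just beyond
stem II.

`hhscan` is a descriptor-based scanner and annotator for this motif, for
people who want to find hammerheads in genomes, phage genomes or metagenome
contigs and characterize what they find:

* **scanning** — anchors on the two conserved boxes, folds the three stems
  around them (G–U wobbles count as paired; bounded mispairs/bulges) for
  all three topologies on both strands;
* **filtering** — the strict disqualification rules used for final
  curation: any core mutation rejects the hit; any mispair at the
  core-adjacent closing pairs (N1.1–N2.1, N10.1–N11.1, A15.1–U16.1)
  rejects it; multiple mispairs or bulges in short stems reject it.  A
  *variant mode* additionally admits a catalog of experimentally
  characterized natural core variants (C3U/G8A covariation, A6C, A6a,
  U13a, U15.1–A16.1, U10.1–U11.1, 2a/2b) with their activity notes;
* **pseudoknot annotation** and a heuristic loop–loop interaction screen;
* **census statistics** (counts per topology, pseudoknot fractions
  stratified by stem II length and by stem I − stem II length difference);
* **self-cleavage kinetics** — kobs from the slope of ln(fraction
  remaining) vs time over the first 5–30 % of the reaction, and biphasic
  fits to F = a(1−e^(−bt)) + c(1−e^(−dt)) with b ≥ d, all in min⁻¹;
* **synthetic benchmarks** — ground-truthed positives of all three
  topologies (with pseudoknots and catalogued variants), targeted decoys,
  and dinucleotide-shuffled negatives, so every component is testable
  without external data.

## Worked example

Generate a small planted benchmark, scan it, and fit a cleavage trace:

```bash
hhscan simulate --n-pos 3 --n-neg 2 --bg-len 400 --seed 11 \
       --out-fasta bench.fa --out-truth truth.tsv
hhscan scan --fasta bench.fa --out-tsv hits.tsv --passing-only
cat hits.tsv
```

```text
record    strand  start  end  topology  verdict      reason  score  cleavage_site  stem1_bp  stem2_bp  stem3_bp  mispairs  bulges  pk_len  pk_geometry   variants
pos_0000  +       131    185  I         pass-strict  none    16.0   182            3         7         6         0         0       0       .             .
pos_0001  +       21     75   I         pass-strict  none    23.0   67             8         1         4         0         0       5       loopII-flank  .
pos_0002  +       289    328  III       pass-strict  none    7.0    294            2         1         4         0         0       0       .             .
```

Each row is one motif call: 0-based half-open coordinates on the forward
strand, the topology, the filter verdict, the per-stem base-pair counts,
and — for `pos_0001` — a 5 bp pseudoknot in the mirrored type I geometry
(loop II paired with the flank beyond stem I).  `cleavage_site` is the
coordinate of the scissile phosphodiester 3′ of residue 17; all three calls
match the planted truth table exactly, and the two shuffled negatives
produce no passing hit.

```bash
hhscan kinetics-sim --kobs 0.17 --t-max 8 --n-points 12 --noise-sd 0.01 \
       --seed 2 --out trace.tsv
hhscan kinetics-fit --trace trace.tsv --model mono
```

```text
kinetics fit: monophasic (12 points)
  kobs = 0.1641 min^-1
  window = 5%-30% of reaction (3 points used)
  residual sum of squares = 4.968e-05
```

The fitted kobs (0.164 min⁻¹) recovers the simulated truth (0.17 min⁻¹)
from a noisy 12-point time course.  As a reference point for rate
comparisons, `hhscan.fold_change(0.17, 4e-4)` — a consensus hammerhead
versus the salt-dependent HHmeta variant under molar monovalent salt —
prints as a 425-fold difference.

The same functionality is available as a library (`hhscan.scan`,
`hhscan.generate_benchmark`, `hhscan.fit_kobs_linear`, …); GFF3 and
Stockholm output (with `<>`/`Aa` structure layers) are supported alongside
TSV.

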