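"""File formats: FASTA input, GFF3/TSV/Stockholm hit output, trace files."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import pandas as pd
from Bio import AlignIO, SeqIO

from .model import AlphabetError, HammerheadHit, KineticsTrace, normalize_sequence


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a multi-record FASTA (wrapped lines, mixed case, T or U).

    Returns (record id, normalized RNA sequence) pairs; raises
    :class:`AlphabetError` naming the record and offset of the first illegal
    character, or ValueError for files that are not FASTA at all.
    """
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: not FASTA (line 1 does not start with '>')")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_sequence(str(rec.seq), rec.id)))
    return records


def read_stockholm(path) -> List[Tuple[str, str]]:
    """Read sequences from a Stockholm alignment, stripping gap characters."""
    out = []
    for aln in AlignIO.parse(str(path), "stockholm"):
        for rec in aln:
            seq = str(rec.seq).replace("-", "").replace(".", "")
            out.append((rec.id, normalize_sequence(seq, rec.id)))
    return out


# --------------------------------------------------------------------------
# Hit tables
# --------------------------------------------------------------------------

TSV_COLUMNS = [
    "record", "strand", "start", "end", "topology", "verdict", "reason",
    "score", "cleavage_site", "stem1_bp", "stem2_bp", "stem3_bp",
    "mispairs", "bulges", "pk_len", "pk_geometry", "variants",
]


def hits_to_frame(hits: Sequence[HammerheadHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append({
            "record": h.record_id,
            "strand": h.strand,
            "start": h.start,
            "end": h.end,
            "topology": h.topology.value,
            "verdict": h.verdict.status if h.verdict else ".",
            "reason": h.verdict.reason if h.verdict else ".",
            "score": h.score,
            "cleavage_site": h.cleavage_site,
            "stem1_bp": h.stems["I"].n_bp,
            "stem2_bp": h.stems["II"].n_bp,
            "stem3_bp": h.stems["III"].n_bp,
            "mispairs": sum(s.n_mispairs for s in h.stems.values()),
            "bulges": sum(s.n_bulges for s in h.stems.values()),
            "pk_len": h.pseudoknot.n_bp if h.pseudoknot else 0,
            "pk_geometry": h.pseudoknot.geometry if h.pseudoknot else ".",
            "variants": ",".join(v.name for v in h.variants) or ".",
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_tsv(hits: Sequence[HammerheadHit], path) -> None:
    """Write hits as a stable, documented TSV (0-based half-open coords)."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gff3(hits: Sequence[HammerheadHit], path, source: str = "hhscan") -> None:
    """GFF3 output: 1-based inclusive coordinates, feature type 'ribozyme'.

    The ``cleavage_site`` attribute is the 1-based coordinate, on the
    forward reference, of the nucleotide immediately 5' of the scissile
    phosphodiester.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, start=1):
            attrs = [
                f"ID=hammerhead{i}",
                f"topology={h.topology.value}",
                f"verdict={h.verdict.status if h.verdict else '.'}",
                f"variants={','.join(v.name for v in h.variants) or '.'}",
                f"pk_len={h.pseudoknot.n_bp if h.pseudoknot else 0}",
                f"cleavage_site={h.cleavage_site}",
                f"score={h.score:g}",
            ]
            fh.write("\t".join([
                h.record_id, source, "ribozyme",
                str(h.start + 1), str(h.end),
                f"{h.score:g}", h.strand, ".",
                ";".join(attrs),
            ]) + "\n")


def write_stockholm(hits: Sequence[HammerheadHit], path) -> None:
    """One Stockholm block per hit with an SS_cons line carrying the stem
    layer (``<``/``>``) and the pseudoknot layer (``A``/``a``)."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            if not h.scanned_seq:
                continue
            span0, span1 = h.stem_span_on_scanned()
            lo = span0
            hi = span1
            if h.pseudoknot:
                lo = min(lo, h.pseudoknot.tail_region[0], h.pseudoknot.loop_region[0])
                hi = max(hi, h.pseudoknot.tail_region[1], h.pseudoknot.loop_region[1])
            seq = h.scanned_seq[lo:hi]
            ss = ["."] * (hi - lo)
            for stem in h.stems.values():
                for (p5, p3) in stem.pairs:
                    ss[p5 - lo] = "<"
                    ss[p3 - lo] = ">"
            if h.pseudoknot:
                for (p5, p3) in h.pseudoknot.pairs:
                    ss[p5 - lo] = "A"
                    ss[p3 - lo] = "a"
            name = f"{h.record_id}/{h.start + 1}-{h.end}({h.strand})"
            fh.write("# STOCKHOLM 1.0\n")
            fh.write(f"#=GF ID hammerhead{i}\n")
            fh.write(f"{name} {seq}\n")
            fh.write(f"#=GC SS_cons {''.join(ss)}\n")
            fh.write("//\n")


# --------------------------------------------------------------------------
# Kinetics traces
# --------------------------------------------------------------------------


def read_trace(path) -> KineticsTrace:
    """Read a two-column TSV time course (time_min, fraction_cleaved);
    a header line is required."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns with a header")
    times = frame.iloc[:, 0].astype(float).tolist()
    fracs = frame.iloc[:, 1].astype(float).tolist()
    return KineticsTrace(times=times, fraction_cleaved=fracs)


def write_trace(trace: KineticsTrace, path) -> None:
    pd.DataFrame(
        {"time_min": list(trace.times), "fraction_cleaved": list(trace.fraction_cleaved)}
    ).to_csv(path, sep="\t", index=False)
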