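"""Census statistics over a hit collection.

Summarizes a set of annotated hits the way a motif census is usually
reported: counts per topology, the fraction of hits carrying a pseudoknot
(overall, per topology, and stratified by stem II length and by the stem
length difference stem I minus stem II), and tallies of catalogued core
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import HammerheadHit
from .scan import ScanConfig, scan


@dataclass
class CensusSummary:
    """Tabulated census over a hit collection."""

    n_hits: int
    overall: pd.DataFrame          # one row: count, pk_count, pk_fraction
    by_topology: pd.DataFrame      # index topology
    by_stem2_len: pd.DataFrame     # index stem II bp
    by_stem_diff: pd.DataFrame     # index stem I bp - stem II bp
    variant_counts: pd.DataFrame   # index variant name

    @property
    def pk_fraction(self) -> float:
        return float(self.overall["pk_fraction"].iloc[0])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for title, frame in (
                ("overall", self.overall),
                ("by_topology", self.by_topology),
                ("by_stem2_len", self.by_stem2_len),
                ("by_stem_diff", self.by_stem_diff),
                ("variants", self.variant_counts),
            ):
                fh.write(f"# {title}\n")
                frame.to_csv(fh, sep="\t")
                fh.write("\n")


def _stratify(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    grp = frame.groupby(key).agg(
        count=("pk", "size"), pk_count=("pk", "sum")
    )
    grp["pk_fraction"] = grp["pk_count"] / grp["count"]
    return grp


def tabulate(
    hits: Sequence[HammerheadHit],
    exclude_records: Optional[Iterable[str]] = None,
) -> CensusSummary:
    """Census statistics for a list of annotated hits.

    ``exclude_records`` optionally drops hits from the named records before
    tabulating (e.g. to exclude a known highly repetitive family); nothing is
    excluded automatically.  With no hits, fractions are reported as NaN.
    """
    excluded = set(exclude_records or ())
    kept = [h for h in hits if h.record_id not in excluded]
    rows = [
        {
            "topology": h.topology.value,
            "pk": h.pseudoknot is not None,
            "stem2": h.stems["II"].n_bp,
            "diff": h.stems["I"].n_bp - h.stems["II"].n_bp,
            "variants": ",".join(v.name for v in h.variants),
        }
        for h in kept
    ]
    frame = pd.DataFrame(rows, columns=["topology", "pk", "stem2", "diff", "variants"])
    n = len(frame)
    pk_count = int(frame["pk"].sum()) if n else 0
    overall = pd.DataFrame(
        [{
            "count": n,
            "pk_count": pk_count,
            "pk_fraction": (pk_count / n) if n else float("nan"),
        }]
    )
    if n:
        by_topology = _stratify(frame, "topology")
        by_stem2 = _stratify(frame, "stem2")
        by_diff = _stratify(frame, "diff")
        vnames = [v for names in frame["variants"] if names for v in names.split(",")]
        variant_counts = (
            pd.Series(vnames, dtype=object).value_counts().rename("count").to_frame()
            if vnames
            else pd.DataFrame(columns=["count"])
        )
    else:
        empty = pd.DataFrame(columns=["count", "pk_count", "pk_fraction"])
        by_topology = by_stem2 = by_diff = empty
        variant_counts = pd.DataFrame(columns=["count"])
    return CensusSummary(
        n_hits=n,
        overall=overall,
        by_topology=by_topology,
        by_stem2_len=by_stem2,
        by_stem_diff=by_diff,
        variant_counts=variant_counts,
    )


@dataclass
class CollectionScan:
    """Result of scanning a sequence collection: the best hit per record."""

    hits: List[HammerheadHit]
    n_records: int
    unmatched: List[str] = field(default_factory=list)
    n_duplicates: int = 0


_STATUS_RANK = {"pass-strict": 2, "pass-variant": 1, "rejected": 0}


def load_collection(
    records: Iterable[Tuple[str, str]],
    config: Optional[ScanConfig] = None,
) -> CollectionScan:
    """Scan a collection of hammerhead candidate sequences.

    Each record is scanned in variant mode and its single best hit retained
    (passing status preferred, then score).  Records yielding no passing hit
    are counted and listed as unmatched, never silently dropped; exact
    duplicate sequences are deduplicated and counted.
    """
    if config is None:
        config = ScanConfig(mode="variant")
    hits: List[HammerheadHit] = []
    unmatched: List[str] = []
    seen = {}
    n_records = 0
    n_dup = 0
    for rec_id, seq in records:
        n_records += 1
        key = seq.upper().replace("T", "U")
        if key in seen:
            n_dup += 1
            continue
        seen[key] = rec_id
        rec_hits = scan(seq, config, record_id=rec_id)
        passing = [h for h in rec_hits if h.verdict.status != "rejected"]
        if not passing:
            unmatched.append(rec_id)
            continue
        passing.sort(key=lambda h: (_STATUS_RANK[h.verdict.status], h.score), reverse=True)
        hits.append(passing[0])
    return CollectionScan(
        hits=hits, n_records=n_records, unmatched=unmatched, n_duplicates=n_dup
    )
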