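"""Small-RNA read-stack profiling of precursor processing accuracy.

Reads are mapped to a single hairpin by exact, sense-strand substring
matching (a deliberate precision-over-sensitivity choice for hairpin-space
mapping; an optional one-mismatch mode exists).  Counts are indexed by
(5' start position on the hairpin, read length) for lengths 18-26 — the
"read stack" behind stacked-bar processing plots.  Processing accuracy is
the fraction of mapped reads identical to the intended mature species:
exact 5' end, exact 3' end, exact length.  The star arm is summarised the
same way.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

from ._seq import to_rna
from .foldback_model import Precursor

SIZE_RANGE = (18, 26)


@dataclass
class ReadStackMatrix:
    """Fractional read counts per (1-based 5' start, read length)."""

    counts: dict[tuple[int, int], float] = field(default_factory=dict)
    total_mapped: float = 0.0
    total_input: int = 0
    precursor_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "length": length, "count": count}
            for (pos, length), count in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["position", "length", "count"])


@dataclass(frozen=True)
class ProcessingSummary:
    """Accuracy summary of one library on one precursor.

    Fractions are ``None`` when nothing mapped (undefined, not zero).
    """

    accurate_fraction: float | None
    other_fraction: float | None
    star_fraction: float | None
    size_histogram: Mapping[int, float]
    total_mapped: float
    total_input: int


def _iter_reads(
    reads: Union[str, Path, Iterable[str]],
) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq)
    else:
        yield from reads


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (overlapping) 0-based match positions of needle in haystack."""
    out, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def _occurrences_1mm(needle: str, haystack: str) -> list[int]:
    out = []
    n = len(needle)
    for idx in range(len(haystack) - n + 1):
        mism = 0
        window = haystack[idx : idx + n]
        for a, b in zip(needle, window):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            out.append(idx)
    return out


def map_reads(
    reads: Union[str, Path, Iterable[str]],
    p: Precursor,
    mismatches: int = 0,
    multimap: str = "fractional",
) -> ReadStackMatrix:
    """Map reads onto a hairpin by exact sense-strand substring matching.

    A read matching at k loci credits 1/k to each locus (``multimap=
    "fractional"``) or 1 to the first locus (``"first"``).  Reads with
    length outside 18-26 count toward ``total_input`` only.
    """
    if multimap not in ("fractional", "first"):
        raise ValueError("multimap must be 'fractional' or 'first'")
    if mismatches not in (0, 1):
        raise ValueError("mismatches must be 0 or 1")
    finder = _occurrences if mismatches == 0 else _occurrences_1mm
    lo, hi = SIZE_RANGE
    m = ReadStackMatrix(precursor_id=p.id)
    hairpin = p.sequence
    for raw in _iter_reads(reads):
        m.total_input += 1
        read = to_rna(raw)
        if not (lo <= len(read) <= hi):
            continue
        loci = finder(read, hairpin)
        if not loci:
            continue
        m.total_mapped += 1.0
        if multimap == "first":
            loci = loci[:1]
        weight = 1.0 / len(loci)
        for idx in loci:
            key = (idx + 1, len(read))
            m.counts[key] = m.counts.get(key, 0.0) + weight
    return m


def processing_summary(m: ReadStackMatrix, p: Precursor) -> ProcessingSummary:
    """Accuracy fractions of a read-stack matrix for one precursor."""
    if m.precursor_id and m.precursor_id != p.id:
        raise ValueError(
            f"matrix was built on {m.precursor_id!r}, not {p.id!r}"
        )
    size_hist: dict[int, float] = {}
    for (_, length), count in m.counts.items():
        size_hist[length] = size_hist.get(length, 0.0) + count
    if m.total_mapped == 0:
        return ProcessingSummary(
            accurate_fraction=None,
            other_fraction=None,
            star_fraction=None,
            size_histogram=size_hist,
            total_mapped=0.0,
            total_input=m.total_input,
        )
    ms, me = p.mature_span
    ss, se = p.star_span
    accurate = m.counts.get((ms, me - ms + 1), 0.0) / m.total_mapped
    star = m.counts.get((ss, se - ss + 1), 0.0) / m.total_mapped
    return ProcessingSummary(
        accurate_fraction=accurate,
        other_fraction=1.0 - accurate,
        star_fraction=star,
        size_histogram=size_hist,
        total_mapped=m.total_mapped,
        total_input=m.total_input,
    )


def compare_precursors(
    summaries: Sequence[tuple[str, ProcessingSummary]],
) -> pd.DataFrame:
    """Rank named processing summaries by accuracy (descending; ties by
    name).  Undefined fractions sort last as NaN."""
    if len(summaries) < 2:
        raise ValueError("compare_precursors requires at least two summaries")
    names = [name for name, _ in summaries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate precursor names: {dupes}")
    df = pd.DataFrame(
        {
            "name": names,
            "accurate_fraction": [
                s.accurate_fraction if s.accurate_fraction is not None else math.nan
                for _, s in summaries
            ],
            "star_fraction": [
                s.star_fraction if s.star_fraction is not None else math.nan
                for _, s in summaries
            ],
            "total_mapped": [s.total_mapped for _, s in summaries],
        }
    )
    df = df.sort_values(
        ["accurate_fraction", "name"],
        ascending=[False, True],
        kind="stable",
        na_position="last",
        ignore_index=True,
    )
    return df


def stack_long_table(m: ReadStackMatrix) -> pd.DataFrame:
    """Long-format table for stacked-bar plotting, with a reads-per-million
    column."""
    df = m.to_frame()
    rpm = (
        df["count"] / m.total_mapped * 1e6 if m.total_mapped else float("nan")
    )
    df["rpm"] = rpm
    return df
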