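"""MIRNA foldback anatomy from mature/star annotations.

A plant MIRNA precursor (hairpin) carries the miRNA guide strand on one arm
and the miRNA* (passenger) strand on the other.  The *distal stem-loop* is
the segment strictly between the two annotated arms — the region a synthetic
amiRNA insert must reproduce, whose length therefore sets oligonucleotide
synthesis cost.  This module represents annotated hairpins, computes the
inter-arm loop deterministically from coordinates (no structure prediction),
and summarises loop lengths over a cohort.

Coordinates are 1-based inclusive throughout (miRBase convention); 0-based
half-open conversions exist only at I/O edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from ._seq import validate_rna

Span = tuple[int, int]

ARM_LENGTH_RANGE = (19, 24)

ANNOTATION_COLUMNS = [
    "hairpin_id",
    "mature_start",
    "mature_end",
    "star_start",
    "star_end",
]


@dataclass(frozen=True)
class Precursor:
    """An annotated MIRNA hairpin.

    ``sequence`` is stored as uppercase RNA; ``mature_span`` and
    ``star_span`` are 1-based inclusive intervals on it.
    """

    id: str
    sequence: str
    mature_span: Span
    star_span: Span

    def __post_init__(self) -> None:
        seq = validate_rna(self.sequence, context=f"hairpin {self.id!r}")
        object.__setattr__(self, "sequence", seq)
        for name, (s, e) in (("mature", self.mature_span), ("star", self.star_span)):
            if not (1 <= s <= e <= len(seq)):
                raise ValueError(
                    f"hairpin {self.id!r}: {name} span {s}..{e} outside "
                    f"sequence of length {len(seq)}"
                )
            arm_len = e - s + 1
            lo, hi = ARM_LENGTH_RANGE
            if not (lo <= arm_len <= hi):
                raise ValueError(
                    f"hairpin {self.id!r}: {name} arm length {arm_len} "
                    f"outside [{lo}, {hi}]"
                )
            arm = seq[s - 1 : e]
            if "N" in arm:
                raise ValueError(
                    f"hairpin {self.id!r}: N base inside {name} span {s}..{e}"
                )
        a, b = sorted([self.mature_span, self.star_span])
        if a[1] >= b[0]:
            raise ValueError(
                f"hairpin {self.id!r}: mature and star spans overlap "
                f"({self.mature_span} vs {self.star_span})"
            )

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_span
        return self.sequence[s - 1 : e]

    @property
    def star_sequence(self) -> str:
        s, e = self.star_span
        return self.sequence[s - 1 : e]


@dataclass(frozen=True)
class FoldbackAnatomy:
    """Inter-arm (distal stem-loop) segment of a precursor.

    ``loop_span`` is the 1-based inclusive interval strictly between the two
    arms, or ``None`` when the arms are adjacent (zero-length loop).
    ``arm_order`` is ``"mature_first"`` or ``"star_first"`` depending on
    which arm is 5'-proximal.
    """

    loop_span: Span | None
    loop_length: int
    arm_order: str

    def __post_init__(self) -> None:
        if self.loop_span is None:
            if self.loop_length != 0:
                raise ValueError("empty loop_span with non-zero loop_length")
        else:
            s, e = self.loop_span
            if e - s + 1 != self.loop_length:
                raise ValueError("loop_span width disagrees with loop_length")


def load_precursors(
    hairpin_records: Union[str, Path, Iterable[SeqRecord]],
    annotations: Union[str, Path, pd.DataFrame],
) -> list[Precursor]:
    """Build :class:`Precursor` objects from hairpins plus a coordinate table.

    Parameters
    ----------
    hairpin_records
        FASTA path or iterable of Bio.SeqRecord objects.
    annotations
        TSV path or DataFrame with columns ``hairpin_id, mature_start,
        mature_end, star_start, star_end`` (1-based inclusive).

    Raises
    ------
    ValueError
        If an annotation row names an absent hairpin, a span falls outside
        its sequence, or the mature/star spans overlap.
    """
    if isinstance(hairpin_records, (str, Path)):
        records = list(SeqIO.parse(str(hairpin_records), "fasta"))
    else:
        records = list(hairpin_records)
    seqs = {rec.id: str(rec.seq) for rec in records}

    if isinstance(annotations, (str, Path)):
        table = pd.read_csv(annotations, sep="\t")
    else:
        table = annotations.copy()
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {missing_cols}")

    precursors: list[Precursor] = []
    for row in table.itertuples(index=False):
        hid = str(row.hairpin_id)
        if hid not in seqs:
            raise ValueError(f"annotation references absent hairpin id {hid!r}")
        precursors.append(
            Precursor(
                id=hid,
                sequence=seqs[hid],
                mature_span=(int(row.mature_start), int(row.mature_end)),
                star_span=(int(row.star_start), int(row.star_end)),
            )
        )
    return precursors


def distal_loop(p: Precursor) -> FoldbackAnatomy:
    """Distal stem-loop of ``p``: the residues strictly between the arms."""
    first, second = sorted([p.mature_span, p.star_span])
    arm_order = "mature_first" if first == p.mature_span else "star_first"
    loop_start = first[1] + 1
    loop_end = second[0] - 1
    length = loop_end - loop_start + 1
    if length <= 0:
        return FoldbackAnatomy(loop_span=None, loop_length=0, arm_order=arm_order)
    return FoldbackAnatomy(
        loop_span=(loop_start, loop_end), loop_length=length, arm_order=arm_order
    )


def anatomy_survey(
    ps: Sequence[Precursor],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Loop-length survey over a cohort of precursors.

    Returns a table (``id, loop_length``; sorted by id) and a summary dict
    with ``median``, ``q1``, ``q3``, ``min``, ``max`` and ``n``.
    """
    if len(ps) == 0:
        raise ValueError("anatomy_survey requires a non-empty precursor list")
    table = pd.DataFrame(
        {
            "id": [p.id for p in ps],
            "loop_length": [distal_loop(p).loop_length for p in ps],
        }
    ).sort_values("id", kind="stable", ignore_index=True)
    lengths = table["loop_length"].to_numpy(dtype=float)
    summary = {
        "n": int(lengths.size),
        "median": float(np.median(lengths)),
        "q1": float(np.percentile(lengths, 25)),
        "q3": float(np.percentile(lengths, 75)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
    }
    return table, summary


def write_survey(
    table: pd.DataFrame, summary: dict[str, float], out_tsv: Union[str, Path]
) -> None:
    """Write the survey table as TSV plus a JSON summary next to it."""
    out_tsv = Path(out_tsv)
    table.to_csv(out_tsv, sep="\t", index=False)
    out_tsv.with_suffix(".summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
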