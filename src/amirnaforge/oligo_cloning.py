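"""Cloning-oligo assembly for B/c (BsaI/ccdB) amiRNA vectors.

The amiRNA insert — amiRNA guide / precursor distal stem-loop / amiRNA*
top-to-bottom — is synthesised as two overlapping, partially complementary
oligonucleotides carrying fixed 5' overhangs (forward 5'-CTTG, reverse
5'-CATG) that direct ligation into the BsaI-linearised vector without any
enzymatic modification of the oligos.  For the OsMIR390 template (16-nt
distal loop, 58-nt core) both oligos are exactly 60 bases.

Template layouts (loop sequence, declared oligo length) are data, loaded
from the packaged ``templates.synthetic.json``; the loop sequences there are
synthetic stand-ins of the documented lengths, and every template is
validated at load time against its declared geometry.  Layout partition:
forward = CTTG + core[1..L-2]; reverse = CATG + revcomp(core[3..L]); the two
oligos overlap over core[3..L-2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from ._seq import revcomp_dna, to_dna
from .tps_scoring import AMIRNA_LENGTH

FORWARD_OVERHANG = "CTTG"
REVERSE_OVERHANG = "CATG"
BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"

TEMPLATE_NAMES = ("OsMIR390", "OsMIR390-AtL", "AtMIR390a-OsL", "AtMIR390a")


@dataclass(frozen=True)
class PrecursorTemplate:
    """Insert geometry of one precursor backbone."""

    name: str
    loop_sequence: str
    oligo_length: int
    forward_overhang: str = FORWARD_OVERHANG
    reverse_overhang: str = REVERSE_OVERHANG

    @property
    def core_length(self) -> int:
        return 2 * AMIRNA_LENGTH + len(self.loop_sequence)

    def validate(self) -> None:
        expected = self.core_length + 2  # 4-nt overhang, core minus 2 each side
        if self.oligo_length != expected:
            raise ValueError(
                f"template {self.name!r}: declared oligo length "
                f"{self.oligo_length} != layout-implied {expected} "
                "(template fixture corrupt)"
            )
        if self.name in ("OsMIR390", "AtMIR390a-OsL") and len(self.loop_sequence) != 16:
            raise ValueError(
                f"template {self.name!r} must use the 16-nt Os distal loop"
            )


def load_templates(path: Union[str, Path, None] = None) -> dict[str, PrecursorTemplate]:
    """Load and validate the packaged (or a user-supplied) template file."""
    if path is None:
        raw = (
            resources.files("amirnaforge.data")
            .joinpath("templates.synthetic.json")
            .read_text()
        )
    else:
        raw = Path(path).read_text()
    doc = json.loads(raw)
    templates: dict[str, PrecursorTemplate] = {}
    for name, entry in doc["templates"].items():
        t = PrecursorTemplate(
            name=name,
            loop_sequence=to_dna(entry["loop"]),
            oligo_length=int(entry["oligo_length"]),
            forward_overhang=doc.get("forward_overhang", FORWARD_OVERHANG),
            reverse_overhang=doc.get("reverse_overhang", REVERSE_OVERHANG),
        )
        t.validate()
        templates[name] = t
    return templates


def get_template(name: str) -> PrecursorTemplate:
    templates = load_templates()
    if name not in templates:
        raise ValueError(f"unknown template {name!r}; known: {sorted(templates)}")
    return templates[name]


@dataclass(frozen=True)
class Insert:
    """Assembled insert duplex (DNA, top strand 5'->3')."""

    top: str
    bottom: str  # reverse complement of top
    template_name: str
    amirna_span: tuple[int, int]  # 1-based inclusive on top
    loop_span: tuple[int, int]
    star_span: tuple[int, int]


@dataclass(frozen=True)
class OligoPair:
    forward: str
    reverse: str
    insert_top: str
    insert_bottom: str

    def __post_init__(self) -> None:
        if not self.forward.startswith(FORWARD_OVERHANG):
            raise ValueError("forward oligo must start with CTTG")
        if not self.reverse.startswith(REVERSE_OVERHANG):
            raise ValueError("reverse oligo must start with CATG")


def assemble_insert(amirna: str, star: str, template: PrecursorTemplate) -> Insert:
    """Concatenate amiRNA + distal loop + amiRNA* as a DNA duplex."""
    amirna = to_dna(amirna)
    star = to_dna(star)
    if len(amirna) != AMIRNA_LENGTH or len(star) != AMIRNA_LENGTH:
        raise ValueError("amiRNA and amiRNA* must both be 21 nt")
    loop = template.loop_sequence
    if not loop and template.core_length != 2 * AMIRNA_LENGTH:
        raise ValueError("template layout placeholder unfilled")
    top = amirna + loop + star
    a = len(amirna)
    return Insert(
        top=top,
        bottom=revcomp_dna(top),
        template_name=template.name,
        amirna_span=(1, a),
        loop_span=(a + 1, a + len(loop)) if loop else (a + 1, a),
        star_span=(a + len(loop) + 1, len(top)),
    )


def emit_oligos(insert: Insert, template: PrecursorTemplate) -> OligoPair:
    """Split the insert into the two overhang-bearing synthesis oligos."""
    if insert.template_name != template.name:
        raise ValueError(
            f"insert was assembled with template {insert.template_name!r}, "
            f"not {template.name!r}"
        )
    core = insert.top
    L = len(core)
    forward = template.forward_overhang + core[: L - 2]
    reverse = template.reverse_overhang + revcomp_dna(core[2:])
    for name, oligo in (("forward", forward), ("reverse", reverse)):
        if len(oligo) != template.oligo_length:
            raise ValueError(
                f"{name} oligo length {len(oligo)} != declared "
                f"{template.oligo_length} (template fixture corrupt)"
            )
    # annealing check: the two oligos must agree over the shared core region
    if revcomp_dna(reverse[len(template.reverse_overhang):]) != core[2:]:
        raise ValueError("oligos fail the annealing identity check")
    return OligoPair(
        forward=forward,
        reverse=reverse,
        insert_top=core,
        insert_bottom=insert.bottom,
    )


def parse_oligos(pair: OligoPair, template: PrecursorTemplate) -> tuple[str, str]:
    """Recover (amiRNA, amiRNA*) in DNA alphabet from an oligo pair."""
    head = pair.forward[len(template.forward_overhang):]
    tail = revcomp_dna(pair.reverse[len(template.reverse_overhang):])
    core = head + tail[-2:]
    if len(core) != template.core_length:
        raise ValueError("oligo pair does not reconstruct the template core")
    if core[2 : len(head)] != head[2:]:
        raise ValueError("forward/reverse overlap disagrees")
    amirna = core[:AMIRNA_LENGTH]
    star = core[AMIRNA_LENGTH + len(template.loop_sequence):]
    return amirna, star


def screen_bsai(seq: str) -> list[dict]:
    """Report every BsaI recognition site on either strand of a DNA string.

    Returns one warning per occurrence: ``{"position": 1-based start,
    "strand": "+"|"-"}``; an empty list means the sequence is clean for
    B/c cloning.
    """
    seq = to_dna(seq)
    warnings: list[dict] = []
    for motif, strand in ((BSAI_SITE, "+"), (BSAI_SITE_RC, "-")):
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            warnings.append({"position": idx + 1, "strand": strand})
            start = idx + 1
    warnings.sort(key=lambda w: (w["position"], w["strand"]))
    return warnings


def oligos_report(
    amirna: str, star: str, template: PrecursorTemplate
) -> pd.DataFrame:
    """One-row TSV-ready report: template, oligos, lengths, BsaI warnings."""
    insert = assemble_insert(amirna, star, template)
    pair = emit_oligos(insert, template)
    warnings = screen_bsai(insert.top)
    return pd.DataFrame(
        [
            {
                "template": template.name,
                "forward": pair.forward,
                "reverse": pair.reverse,
                "forward_length": len(pair.forward),
                "reverse_length": len(pair.reverse),
                "bsai_warnings": ";".join(
                    f"{w['position']}{w['strand']}" for w in warnings
                ),
            }
        ]
    )
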