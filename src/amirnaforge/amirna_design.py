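"""P-SAMS-style amiRNA candidate generation and vetting.

For every 21-nt window of the intended target transcript the raw candidate
is the window's reverse complement (perfect antiparallel complementarity).
Two fixed substitutions are then applied where needed: position 1 is forced
to U (the 5'-terminal nucleotide AGO1 prefers to load) and position 19 to C
— which, under the canonical miRNA/miRNA* duplex register with 2-nt 3'
overhangs, places an AGO-non-preferred G at position 1 of the amiRNA* strand
and thereby biases loading toward the guide.  Both forced positions fall
outside the doubled 5' core, so each costs at most one unit of on-target
TPS.

A candidate is *optimal* when its best on-target interaction has TPS <= 1
and no transcript other than the intended one carries a site with TPS < 4;
off-target silencing can then only arise through interactions in the
[4, 11] TPS interval, which empirically do not direct cleavage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import complement_rna, revcomp_rna, validate_rna
from .tps_scoring import (
    AMIRNA_LENGTH,
    DEFAULT_SCHEME,
    ScoringScheme,
    TargetHit,
    find_sites,
)

logger = logging.getLogger(__name__)

#: amiRNA position i (1-based) pairs star position STAR_REGISTER_OFFSET - i
#: under the 2-nt 3'-overhang duplex register (amiRNA 1..19 <-> star 19..1;
#: positions 20-21 of both strands are the unpaired overhangs).
STAR_REGISTER_OFFSET = 20

#: default duplex template: star position 1 fixed to G (coincides with the
#: complement of the forced amiRNA C19), positions 2..19 pair their amiRNA
#: partners, positions 20-21 are the fixed unpaired 3'-overhang dinucleotide.
DEFAULT_STAR_TEMPLATE: tuple[str, ...] = ("G",) + ("pair",) * 18 + ("C", "U")

FORCED_5P = "U"  # amiRNA position 1
FORCED_19 = "C"  # amiRNA position 19


@dataclass(frozen=True)
class DesignCandidate:
    amirna: str
    star: str
    source_window: tuple[int, int]  # 1-based inclusive span on the target
    substitutions: tuple[tuple[int, str, str], ...]
    on_target_tps: float
    flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.amirna) != AMIRNA_LENGTH or len(self.star) != AMIRNA_LENGTH:
            raise ValueError("amiRNA and star must both be 21 nt")
        if self.amirna[0] != FORCED_5P:
            raise ValueError("amiRNA position 1 must be U")
        if self.amirna[18] != FORCED_19:
            raise ValueError("amiRNA position 19 must be C")
        if self.star[0] != "G":
            raise ValueError("star position 1 must be G")
        if any(pos not in (1, 19) for pos, _, _ in self.substitutions):
            raise ValueError("substitutions only allowed at positions 1 and 19")


@dataclass(frozen=True)
class DesignReport:
    candidate: DesignCandidate
    off_target_hits: tuple[TargetHit, ...]
    optimal: bool
    rejection_reasons: tuple[str, ...]


def build_star(
    amirna: str, duplex_template: Sequence[str] = DEFAULT_STAR_TEMPLATE
) -> str:
    """Construct the 21-nt amiRNA* strand from a per-position template.

    Each template entry is either ``"pair"`` (complement the amiRNA partner
    under the 2-nt 3'-overhang register) or a literal base.  Star positions
    20-21 have no partner under that register, so ``"pair"`` there is an
    error.
    """
    amirna = validate_rna(amirna, context="amiRNA")
    if len(amirna) != AMIRNA_LENGTH:
        raise ValueError("amiRNA must be 21 nt")
    if len(duplex_template) != AMIRNA_LENGTH:
        raise ValueError(
            f"duplex template length {len(duplex_template)} != {AMIRNA_LENGTH}"
        )
    star: list[str] = []
    for j0, entry in enumerate(duplex_template):
        j = j0 + 1
        if entry == "pair":
            partner = STAR_REGISTER_OFFSET - j
            if not (1 <= partner <= AMIRNA_LENGTH):
                raise ValueError(
                    f"star position {j} has no amiRNA partner under the "
                    "2-nt 3'-overhang register; template must give a literal"
                )
            star.append(complement_rna(amirna[partner - 1]))
        else:
            star.append(validate_rna(entry, context=f"template base at {j}"))
    return "".join(star)


def star_partner(star_position: int) -> int | None:
    """amiRNA position paired with a star position, or None (3' overhang)."""
    partner = STAR_REGISTER_OFFSET - star_position
    return partner if 1 <= partner <= AMIRNA_LENGTH else None


def candidates_from_target(
    target_transcript: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    duplex_template: Sequence[str] = DEFAULT_STAR_TEMPLATE,
) -> list[DesignCandidate]:
    """One candidate per N-free 21-nt window of the target, in window order."""
    target = validate_rna(target_transcript, context="target transcript")
    if len(target) < AMIRNA_LENGTH:
        raise ValueError("target transcript shorter than 21 nt")
    candidates: list[DesignCandidate] = []
    for s0 in range(len(target) - AMIRNA_LENGTH + 1):
        window = target[s0 : s0 + AMIRNA_LENGTH]
        if "N" in window:
            logger.info("skipping window at %d: contains N", s0 + 1)
            continue
        raw = revcomp_rna(window)
        subs: list[tuple[int, str, str]] = []
        amirna = list(raw)
        if amirna[0] != FORCED_5P:
            subs.append((1, amirna[0], FORCED_5P))
            amirna[0] = FORCED_5P
        if amirna[18] != FORCED_19:
            subs.append((19, amirna[18], FORCED_19))
            amirna[18] = FORCED_19
        amirna_s = "".join(amirna)
        span = (s0 + 1, s0 + AMIRNA_LENGTH)
        hits = find_sites(amirna_s, window, scheme)
        on_tps = min(h.tps for h in hits) if hits else float("inf")
        star = build_star(amirna_s, duplex_template)
        candidates.append(
            DesignCandidate(
                amirna=amirna_s,
                star=star,
                source_window=span,
                substitutions=tuple(subs),
                on_target_tps=on_tps,
                flags={
                    "five_prime_U": amirna_s[0] == FORCED_5P,
                    "c19": amirna_s[18] == FORCED_19,
                    "star_5G": star[0] == "G",
                },
            )
        )
    return candidates


def assess_candidate(
    c: DesignCandidate,
    intended_transcript_id: str,
    transcriptome: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    on_target_max: float = 1.0,
    offtarget_floor: float = 4.0,
) -> DesignReport:
    """Vet a candidate against the intended transcript and the background.

    ``optimal`` iff the best on-target TPS is <= ``on_target_max`` (default 1)
    and no other transcript has a site with TPS strictly below
    ``offtarget_floor`` (default 4).  All off-target hits up to the scheme's
    report cap are listed.
    """
    if intended_transcript_id not in transcriptome:
        raise ValueError(
            f"intended transcript {intended_transcript_id!r} absent from transcriptome"
        )
    reasons: list[str] = []
    on_hits = find_sites(
        c.amirna,
        transcriptome[intended_transcript_id],
        scheme,
        transcript_id=intended_transcript_id,
    )
    on_tps = min((h.tps for h in on_hits), default=float("inf"))
    if on_tps > on_target_max:
        reasons.append(f"on_target_tps={on_tps} exceeds {on_target_max}")

    off_hits: list[TargetHit] = []
    for tid, seq in transcriptome.items():
        if tid == intended_transcript_id:
            continue
        off_hits.extend(find_sites(c.amirna, seq, scheme, transcript_id=tid))
    off_hits.sort(key=lambda h: (h.tps, h.transcript_id, h.start))
    for h in off_hits:
        if h.tps < offtarget_floor:
            reasons.append(
                f"off_target:{h.transcript_id}:tps={h.tps} below {offtarget_floor}"
            )
    return DesignReport(
        candidate=c,
        off_target_hits=tuple(off_hits),
        optimal=not reasons,
        rejection_reasons=tuple(reasons),
    )


def rank_reports(reports: Iterable[DesignReport]) -> list[DesignReport]:
    """Optimal candidates first, sorted by (on-target TPS, distance of the
    worst off-target TPS from 4 descending, window position)."""

    def key(r: DesignReport):
        worst = min((h.tps for h in r.off_target_hits), default=float("inf"))
        margin = worst - 4.0
        return (
            not r.optimal,
            r.candidate.on_target_tps,
            -margin,
            r.candidate.source_window[0],
        )

    return sorted(reports, key=key)
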