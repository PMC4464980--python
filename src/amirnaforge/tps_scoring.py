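"""Allen/TargetFinder-style scoring of amiRNA-target complementarity.

A 21-nt small RNA is aligned antiparallel to a candidate target site:
amiRNA position 1 (its 5' end) pairs the 3'-most base of the site.  Each
amiRNA position receives a state — Watson-Crick pair, G:U wobble, mismatch,
or a single-nucleotide bulge on either strand — and the Target Prediction
Score (TPS) is the penalty sum: mismatch and bulge cost 1, G:U wobble 0.5,
all doubled when the amiRNA position falls in the 5' core (positions 2-13).
Lower TPS means higher complementarity; perfect complementarity scores 0.

Sites are found by scanning every transcript window with up to ``max_gaps``
single-nucleotide bulges; hits above ``report_cap`` (default 11) are never
emitted.  The predicted slicer cleavage site is the phosphodiester bond
opposite amiRNA positions 10/11.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from ._seq import validate_rna


class PairState(Enum):
    WATSON_CRICK = "WC"
    GU_WOBBLE = "GU"
    MISMATCH = "MM"
    TARGET_BULGE = "TB"
    AMIRNA_BULGE = "AB"


BULGE_STATES = (PairState.TARGET_BULGE, PairState.AMIRNA_BULGE)

#: one display character per state for the TSV alignment string
STATE_CHARS = {
    PairState.WATSON_CRICK: ":",
    PairState.GU_WOBBLE: ".",
    PairState.MISMATCH: "x",
    PairState.TARGET_BULGE: "^",
    PairState.AMIRNA_BULGE: "-",
}

AMIRNA_LENGTH = 21

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty constants of the TPS scheme (TargetFinder defaults)."""

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty: float = 1.0
    core_window: tuple[int, int] = (2, 13)
    core_multiplier: float = 2.0
    report_cap: float = 11.0
    max_gaps: int = 1

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.bulge_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        lo, hi = self.core_window
        if not (1 <= lo <= hi <= AMIRNA_LENGTH):
            raise ValueError("core_window must lie within 1..21")

    def in_core(self, position: int) -> bool:
        lo, hi = self.core_window
        return lo <= position <= hi


DEFAULT_SCHEME = ScoringScheme()


def pair_class(amirna_nt: str, target_nt: str) -> PairState:
    """Classify one amiRNA/target base opposition (U/T-insensitive).

    N on either side is a mismatch; non-nucleotide characters raise.
    """
    a = validate_rna(amirna_nt, context="amiRNA base")
    t = validate_rna(target_nt, context="target base")
    if len(a) != 1 or len(t) != 1:
        raise ValueError("pair_class takes single nucleotides")
    if (a, t) in _WC_PAIRS:
        return PairState.WATSON_CRICK
    if (a, t) in _GU_PAIRS:
        return PairState.GU_WOBBLE
    return PairState.MISMATCH


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position states over amiRNA positions 1..21.

    ``target_partners`` maps each amiRNA position (1-based) to the 1-based
    transcript coordinate of its paired target base, or ``None`` for an
    amiRNA-bulged position.  A TARGET_BULGE state at position *i* records an
    extra unpaired target nucleotide inserted immediately 3'-of-site between
    the partners of positions *i-1* and *i*; only the bulge penalty is
    scored for that column.
    """

    states: tuple[PairState, ...]
    target_partners: tuple[int | None, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.states) != AMIRNA_LENGTH:
            raise ValueError("alignment must cover all 21 amiRNA positions")
        if self.target_partners and len(self.target_partners) != AMIRNA_LENGTH:
            raise ValueError("target_partners must cover all 21 amiRNA positions")

    @property
    def gap_count(self) -> int:
        return sum(s in BULGE_STATES for s in self.states)

    def notation(self) -> str:
        """Compact alignment string (``:`` WC, ``.`` G:U, ``x`` mismatch,
        ``^`` target bulge, ``-`` amiRNA bulge), amiRNA 5'->3'."""
        return "".join(STATE_CHARS[s] for s in self.states)


def score_alignment(
    aln: DuplexAlignment, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """TPS of an alignment: penalty sum, doubled inside the 5' core."""
    if aln.gap_count > scheme.max_gaps:
        raise ValueError(
            f"alignment has {aln.gap_count} bulges; scheme allows {scheme.max_gaps}"
        )
    penalty = {
        PairState.WATSON_CRICK: 0.0,
        PairState.GU_WOBBLE: scheme.gu_penalty,
        PairState.MISMATCH: scheme.mismatch_penalty,
        PairState.TARGET_BULGE: scheme.bulge_penalty,
        PairState.AMIRNA_BULGE: scheme.bulge_penalty,
    }
    total = 0.0
    for pos0, state in enumerate(aln.states):
        p = penalty[state]
        if scheme.in_core(pos0 + 1):
            p *= scheme.core_multiplier
        total += p
    return total


@dataclass(frozen=True)
class TargetHit:
    """A scored amiRNA site on a transcript (1-based inclusive span)."""

    transcript_id: str
    start: int
    end: int
    alignment: DuplexAlignment
    tps: float


def _align_ungapped(amirna: str, site: str, start: int) -> DuplexAlignment:
    states, partners = [], []
    n = len(site)
    for i in range(AMIRNA_LENGTH):
        j = n - 1 - i  # amiRNA position 1 pairs the 3'-most site base
        states.append(pair_class(amirna[i], site[j]))
        partners.append(start + j)
    return DuplexAlignment(tuple(states), tuple(partners))


def _align_target_bulge(
    amirna: str, site: str, start: int, bulge_site_idx: int
) -> DuplexAlignment:
    """Site length 22 with the base at ``bulge_site_idx`` (0-based, interior)
    unpaired; the bulge column is attributed to the amiRNA position whose
    partner lies immediately 5' (site-wise) of the bulged base."""
    kept = [j for j in range(len(site)) if j != bulge_site_idx]
    states: list[PairState] = []
    partners: list[int | None] = []
    for i in range(AMIRNA_LENGTH):
        j = kept[len(kept) - 1 - i]
        if j == bulge_site_idx - 1:
            # partner just 5' of the bulge: this column carries the bulge
            states.append(PairState.TARGET_BULGE)
        else:
            states.append(pair_class(amirna[i], site[j]))
        partners.append(start + j)
    return DuplexAlignment(tuple(states), tuple(partners))


def _align_amirna_bulge(
    amirna: str, site: str, start: int, bulge_pos0: int
) -> DuplexAlignment:
    """Site length 20 with amiRNA position ``bulge_pos0`` (0-based, interior)
    unpaired."""
    n = len(site)
    states: list[PairState] = []
    partners: list[int | None] = []
    j = n  # next partner index (walking 3'->5' on the site)
    for i in range(AMIRNA_LENGTH):
        if i == bulge_pos0:
            states.append(PairState.AMIRNA_BULGE)
            partners.append(None)
        else:
            j -= 1
            states.append(pair_class(amirna[i], site[j]))
            partners.append(start + j)
    return DuplexAlignment(tuple(states), tuple(partners))


def find_sites(
    amirna: str,
    transcript: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    transcript_id: str = "transcript",
) -> list[TargetHit]:
    """Scan a transcript (sense strand) for amiRNA sites with TPS <= cap.

    Every window — ungapped (21 nt) and, when ``scheme.max_gaps >= 1``, with
    one single-nucleotide bulge on either strand (22/20 nt) — is aligned and
    scored; for each distinct (start, end) span only the best-scoring
    alignment is kept.  Hits are sorted by ascending TPS, ties by start.
    """
    amirna = validate_rna(amirna, context="amiRNA")
    if len(amirna) != AMIRNA_LENGTH:
        raise ValueError(f"amiRNA must be 21 nt, got {len(amirna)}")
    if "N" in amirna:
        raise ValueError("amiRNA contains N")
    transcript = validate_rna(transcript, context="transcript")
    L = len(transcript)

    best: dict[tuple[int, int], tuple[float, DuplexAlignment]] = {}

    def consider(start0: int, aln: DuplexAlignment, span_len: int) -> None:
        tps = score_alignment(aln, scheme)
        if tps > scheme.report_cap:
            return
        key = (start0 + 1, start0 + span_len)
        if key not in best or tps < best[key][0]:
            best[key] = (tps, aln)

    for s0 in range(L - AMIRNA_LENGTH + 1):
        site = transcript[s0 : s0 + AMIRNA_LENGTH]
        consider(s0, _align_ungapped(amirna, site, s0 + 1), AMIRNA_LENGTH)

    if scheme.max_gaps >= 1:
        for s0 in range(L - (AMIRNA_LENGTH + 1) + 1):
            site = transcript[s0 : s0 + AMIRNA_LENGTH + 1]
            for b in range(1, AMIRNA_LENGTH):  # interior site positions
                consider(
                    s0,
                    _align_target_bulge(amirna, site, s0 + 1, b),
                    AMIRNA_LENGTH + 1,
                )
        if L >= AMIRNA_LENGTH - 1:
            for s0 in range(L - (AMIRNA_LENGTH - 1) + 1):
                site = transcript[s0 : s0 + AMIRNA_LENGTH - 1]
                for i in range(1, AMIRNA_LENGTH - 1):  # interior amiRNA positions
                    consider(
                        s0,
                        _align_amirna_bulge(amirna, site, s0 + 1, i),
                        AMIRNA_LENGTH - 1,
                    )

    hits = [
        TargetHit(transcript_id, start, end, aln, tps)
        for (start, end), (tps, aln) in best.items()
    ]
    hits.sort(key=lambda h: (h.tps, h.start, h.end))
    return hits


def scan_transcriptome(
    amirna: str,
    transcripts: Iterable[tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[TargetHit]:
    """find_sites over (id, sequence) pairs, concatenated and re-sorted."""
    hits: list[TargetHit] = []
    for tid, seq in transcripts:
        hits.extend(find_sites(amirna, seq, scheme, transcript_id=tid))
    hits.sort(key=lambda h: (h.tps, h.transcript_id, h.start))
    return hits


def predict_cleavage(hit: TargetHit) -> int:
    """Transcript coordinate of the base paired to amiRNA position 10.

    Slicer cleavage occurs in the phosphodiester bond opposite amiRNA
    positions 10/11, i.e. between the returned coordinate and the one just
    5' of it; the returned base is the 5'-terminal nucleotide of the 3'
    cleavage fragment (the species 5'-RLM-RACE captures).  A bulge falling
    between positions 10 and 11 makes the site ambiguous and raises.
    """
    partners = hit.alignment.target_partners
    if not partners:
        raise ValueError("hit alignment lacks target coordinates")
    p10, p11 = partners[9], partners[10]
    if p10 is None or p11 is None:
        raise ValueError("amiRNA position 10 or 11 is bulged; cleavage ambiguous")
    if abs(p10 - p11) != 1:
        raise ValueError("target bulge between amiRNA positions 10 and 11")
    return p10


def hits_to_frame(hits: Sequence[TargetHit], amirna_id: str = "amiRNA") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "amirna_id": amirna_id,
            "transcript_id": [h.transcript_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "tps": [h.tps for h in hits],
            "alignment": [h.alignment.notation() for h in hits],
        }
    )


def write_hits(
    hits: Sequence[TargetHit], out: Union[str, Path], amirna_id: str = "amiRNA"
) -> None:
    hits_to_frame(hits, amirna_id).to_csv(out, sep="\t", index=False)
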