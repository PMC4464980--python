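"""Seed-deterministic synthetic data generators.

Every analysis module in the package is testable without downloads: this
module fabricates small-RNA libraries with a controlled accurate-processing
fraction, transcriptomes with target sites planted at exact TPS values
(plus background transcripts rejection-sampled to carry no reportable
site), and differential-expression tables with a planted under-expressed
gene set.  All generators derive their random streams from a single seed
through fixed per-generator offsets, so adding a generator never perturbs
existing fixtures, and every declared generating parameter is recoverable
by the corresponding analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from ._seq import complement_rna, revcomp_rna, validate_rna
from .foldback_model import Precursor
from .tps_scoring import (
    AMIRNA_LENGTH,
    DEFAULT_SCHEME,
    ScoringScheme,
    find_sites,
)

# fixed substream offsets off the user seed (one per generator)
_STREAM_READS = 11
_STREAM_TRANSCRIPTOME = 23
_STREAM_DE = 37
_STREAM_HAIRPIN = 53

SIZE_RANGE = (18, 26)
SHIFT_RANGE = (-3, 3)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the read simulator.

    ``fidelity`` is the probability a read is the exact mature species;
    non-accurate reads draw a 5' shift in [-3, 3] and a length in [18, 26]
    (uniformly, excluding the exact mature coordinates), emulating the
    off-register and off-size species around an imprecisely processed
    hairpin.
    """

    seed: int = 0
    depth: int = 10_000
    fidelity: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 <= self.fidelity <= 1.0):
            raise ValueError("fidelity must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


def simulate_reads(p: Precursor, cfg: SimConfig) -> list[str]:
    """Simulate ``cfg.depth`` hairpin-derived reads.

    Exact-mature reads occur with probability ``fidelity``; the rest are
    drawn at shifted starts/other lengths and resampled while they fall
    outside the hairpin or coincide with the exact mature species, so the
    expected accurate fraction equals ``fidelity`` exactly.
    """
    rng = _rng(cfg.seed, _STREAM_READS)
    ms, me = p.mature_span
    mature_len = me - ms + 1
    hairpin = p.sequence
    reads: list[str] = []
    resamples = 0
    lo, hi = SIZE_RANGE
    for _ in range(cfg.depth):
        if rng.random() < cfg.fidelity:
            reads.append(p.mature_sequence)
            continue
        while True:
            shift = int(rng.integers(SHIFT_RANGE[0], SHIFT_RANGE[1] + 1))
            length = int(rng.integers(lo, hi + 1))
            start = ms + shift
            if shift == 0 and length == mature_len:
                resamples += 1
                continue  # would be the exact mature species
            if start < 1 or start + length - 1 > len(hairpin):
                resamples += 1
                continue
            reads.append(hairpin[start - 1 : start - 1 + length])
            break
    simulate_reads.last_resample_count = resamples  # type: ignore[attr-defined]
    return reads


def write_fastq(reads: Sequence[str], out: Union[str, Path]) -> None:
    """Write reads as FASTQ (constant quality; byte-identical per input)."""
    with open(out, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read.replace('U', 'T')}\n+\n{'I' * len(read)}\n")


def random_hairpin(
    seed: int,
    arm_length: int = 21,
    loop_length: int = 16,
    flank_length: int = 10,
) -> Precursor:
    """A synthetic, annotation-consistent hairpin: 5' flank, mature arm,
    loop, star arm (revcomp of mature, 2-nt offset register ignored for
    simplicity), 3' flank."""
    rng = _rng(seed, _STREAM_HAIRPIN)
    bases = np.array(list("ACGU"))
    flank5 = "".join(rng.choice(bases, flank_length))
    mature = "".join(rng.choice(bases, arm_length))
    loop = "".join(rng.choice(bases, loop_length))
    star = revcomp_rna(mature)
    flank3 = "".join(rng.choice(bases, flank_length))
    seq = flank5 + mature + loop + star + flank3
    ms = flank_length + 1
    ss = flank_length + arm_length + loop_length + 1
    return Precursor(
        id=f"synthetic-hairpin-{seed}",
        sequence=seq,
        mature_span=(ms, ms + arm_length - 1),
        star_span=(ss, ss + arm_length - 1),
    )


# ---------------------------------------------------------------------------
# transcriptome with planted target sites


def _plant_site(
    amirna: str, tps: float, rng: np.random.Generator, scheme: ScoringScheme
) -> str:
    """Edit the perfect-complement site of ``amirna`` so its TPS equals
    ``tps`` exactly: non-core G:U (+0.5), core G:U or non-core mismatch
    (+1), core mismatch (+2); positions chosen at random among those whose
    amiRNA base supports the edit."""
    halves = round(tps * 2)
    if abs(tps * 2 - halves) > 1e-9 or tps < 0:
        raise ValueError(f"TPS {tps} is not a non-negative multiple of 0.5")

    lo, hi = scheme.core_window
    core = [i for i in range(1, AMIRNA_LENGTH + 1) if lo <= i <= hi]
    noncore = [i for i in range(1, AMIRNA_LENGTH + 1) if i not in core]

    # choose a composition: core mismatches (4 halves), core GU / non-core
    # mismatches (2 halves), non-core GU (1 half)
    site = list(revcomp_rna(amirna))  # site 5'->3'; amiRNA i pairs site 21-i

    def partner_index(pos: int) -> int:
        return AMIRNA_LENGTH - pos  # 0-based index into site

    def can_gu(pos: int) -> bool:
        return amirna[pos - 1] in "GU"

    def apply_gu(pos: int) -> None:
        site[partner_index(pos)] = "U" if amirna[pos - 1] == "G" else "G"

    def apply_mismatch(pos: int) -> None:
        a = amirna[pos - 1]
        comp = complement_rna(a)
        gu = {"G": "U", "U": "G"}.get(a)
        choices = [b for b in "ACGU" if b != comp and b != gu]
        site[partner_index(pos)] = str(rng.choice(choices))

    core_pool = list(core)
    noncore_pool = list(noncore)
    rng.shuffle(core_pool)
    rng.shuffle(noncore_pool)

    remaining = halves
    # 4-half units: core mismatches
    while remaining >= 4 and core_pool:
        apply_mismatch(core_pool.pop())
        remaining -= 4
    # 2-half units: non-core mismatches, else core G:U
    while remaining >= 2:
        if noncore_pool:
            apply_mismatch(noncore_pool.pop())
        elif core_pool and can_gu(core_pool[-1]):
            apply_gu(core_pool.pop())
        elif core_pool:
            core_pool.pop()
            continue
        else:
            raise ValueError(f"cannot compose TPS {tps} on this amiRNA")
        remaining -= 2
    # 1-half unit: a non-core G:U
    if remaining == 1:
        gu_pool = [i for i in noncore_pool if can_gu(i)]
        if not gu_pool:
            raise ValueError(
                f"TPS {tps} needs a non-core G:U but no non-core position "
                "of this amiRNA is G or U"
            )
        apply_gu(gu_pool[int(rng.integers(len(gu_pool)))])
        remaining = 0
    if remaining:
        raise ValueError(f"cannot compose TPS {tps} on this amiRNA")
    return "".join(site)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


def simulate_transcriptome(
    amirna: str,
    planted: Sequence[float],
    background_n: int = 5,
    length: int = 500,
    seed: int = 0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_tries: int = 200,
) -> list[tuple[str, str]]:
    """Synthetic transcriptome as (id, sequence) pairs.

    One transcript per requested TPS in ``planted``, each containing
    exactly one site whose ``find_sites`` minimum TPS equals the request
    (verified; edit placements are re-drawn on failure), plus
    ``background_n`` transcripts rejection-sampled to carry no site with
    TPS <= the report cap.
    """
    amirna = validate_rna(amirna, context="amiRNA")
    if len(amirna) != AMIRNA_LENGTH:
        raise ValueError("amiRNA must be 21 nt")
    rng = _rng(seed, _STREAM_TRANSCRIPTOME)
    records: list[tuple[str, str]] = []
    for k, tps in enumerate(planted):
        for attempt in range(max_tries):
            site = _plant_site(amirna, tps, rng, scheme)
            backbone = _random_seq(rng, length)
            pos = int(rng.integers(0, length - AMIRNA_LENGTH + 1))
            seq = backbone[:pos] + site + backbone[pos + len(site):]
            hits = find_sites(amirna, seq, scheme)
            if hits and min(h.tps for h in hits) == tps:
                records.append((f"planted_tps{tps:g}_{k}", seq))
                break
        else:
            raise RuntimeError(
                f"failed to plant a TPS={tps} site in {max_tries} attempts"
            )
    for k in range(background_n):
        for attempt in range(max_tries):
            seq = _random_seq(rng, length)
            if not find_sites(amirna, seq, scheme):
                records.append((f"background_{k}", seq))
                break
        else:
            raise RuntimeError("failed to sample a clean background transcript")
    return records


def write_fasta(records: Sequence[tuple[str, str]], out: Union[str, Path]) -> None:
    with open(out, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# differential-expression tables


def simulate_de(
    genes: Sequence[str],
    planted_under: Iterable[str],
    seed: int = 0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """DESeq2-dialect DE table with a planted under-expressed gene set.

    Planted genes draw q uniformly in (0, threshold) with negative log2FC;
    all others draw q uniformly in (threshold, 1], so classification at the
    same threshold recovers the planted set exactly.
    """
    planted = set(planted_under)
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)[:5]}")
    rng = _rng(seed, _STREAM_DE)
    n = len(genes)
    base_mean = np.exp(rng.normal(4.0, 1.5, n))
    is_planted = np.array([g in planted for g in genes])
    q = np.where(
        is_planted,
        rng.uniform(0.0, q_threshold, n) * (1 - 1e-9) + 1e-12,
        rng.uniform(q_threshold, 1.0, n) + 1e-12,
    )
    q = np.minimum(q, 1.0)
    fc = np.where(
        is_planted,
        -np.abs(rng.normal(2.0, 0.8, n)) - 0.1,
        rng.normal(0.0, 0.5, n),
    )
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "baseMean": base_mean,
            "log2FoldChange": fc,
            "padj": q,
        }
    )
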