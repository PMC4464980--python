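"""Off-target specificity audit of amiRNA lines.

Consumes an externally produced differential-expression table (DESeq2
results dialect), classifies genes as under-/over-/non-differentially
expressed at a q-value threshold (default 0.01), bins genes by the minimum
TPS of their predicted amiRNA sites (0.5-wide bins from 0 to the report
cap, plus a "no predicted site" stratum), tests whether predicted targets
in the [4, 11] interval are preferentially under-expressed (two-sided
Fisher exact test), and tallies 5'-RLM-RACE clone 5' ends against the
predicted slicer cleavage position.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .tps_scoring import TargetHit, predict_cleavage

Q_THRESHOLD = 0.01
TPS_INTERVAL = (4.0, 11.0)  # closed bounds, as printed
RACE_MAX_TPS = 7.0  # predicted targets above this are not expected to be cleaved

STATUS_UNDER = "UNDER"
STATUS_OVER = "OVER"
STATUS_NS = "NS"

#: accepted column aliases (DESeq2 results dialect -> canonical)
_COLUMN_ALIASES = {
    "log2FoldChange": "log2fc",
    "padj": "qvalue",
    "baseMean": "base_mean",
    "baseMean_": "base_mean",
}


def _canonicalize(table: pd.DataFrame) -> pd.DataFrame:
    df = table.rename(columns=_COLUMN_ALIASES).copy()
    required = ["gene_id", "log2fc", "qvalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DE table lacks columns: {missing}")
    return df


def classify_de(
    table: Union[str, Path, pd.DataFrame],
    q_threshold: float = Q_THRESHOLD,
    zero_counts: Mapping[str, int] | None = None,
    max_zero_samples: int = 5,
    n_samples: int = 8,
) -> pd.DataFrame:
    """Classify DE status per gene.

    UNDER iff q < threshold and log2FC < 0; OVER iff q < threshold and
    log2FC > 0; otherwise (including missing q) NS.  When per-gene
    zero-sample counts are supplied, genes with zero counts in at least
    ``max_zero_samples`` of ``n_samples`` samples are dropped before
    classification (the pre-filter applied ahead of DE testing).
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t")
    df = _canonicalize(table)
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate gene_id in DE table: {dupes[:5]}")
    if zero_counts is not None:
        keep = df["gene_id"].map(
            lambda g: zero_counts.get(g, 0) < max_zero_samples
        )
        df = df.loc[keep].reset_index(drop=True)

    q = pd.to_numeric(df["qvalue"], errors="coerce")
    fc = pd.to_numeric(df["log2fc"], errors="coerce")
    sig = q.notna() & (q < q_threshold)
    status = np.where(
        sig & (fc < 0), STATUS_UNDER, np.where(sig & (fc > 0), STATUS_OVER, STATUS_NS)
    )
    out = df.copy()
    out["status"] = status
    return out


@dataclass(frozen=True)
class TPSBinReport:
    """Per-bin DE-status counts plus the closed-interval summary."""

    bins: pd.DataFrame  # columns: tps_bin, n_total, n_under, n_over, n_ns
    no_site: dict[str, int]
    interval: tuple[float, float]
    interval_counts: dict[str, int]

    @property
    def contingency(self) -> np.ndarray:
        """2x2 table {predicted in interval, not predicted} x {UNDER, not}."""
        a = self.interval_counts["n_under"]
        b = self.interval_counts["n_total"] - a
        c = self.no_site["n_under"]
        d = self.no_site["n_total"] - c
        return np.array([[a, b], [c, d]])


def bin_by_tps(
    records: pd.DataFrame,
    gene_tps: Mapping[str, float],
    bin_width: float = 0.5,
    cap: float = 11.0,
    interval: tuple[float, float] = TPS_INTERVAL,
) -> TPSBinReport:
    """Assign each classified gene to its minimum-TPS bin.

    ``gene_tps`` maps gene_id -> minimum TPS over that gene's predicted
    sites; genes absent from it fall into the "no predicted site" stratum.
    TPS values keyed to genes missing from ``records`` are skipped.
    Bin label is the lower edge of the 0.5-wide bin; a TPS value that is an
    exact multiple of the width is its own bin (TPS granularity is 0.5, so
    with the default width each score is its own bin).
    """
    known = set(records["gene_id"])
    orphans = set(gene_tps) - known
    if orphans:
        warnings.warn(
            f"{len(orphans)} TPS-scored gene(s) absent from the DE records "
            "were skipped",
            stacklevel=2,
        )
    edges = np.round(np.arange(0.0, cap + bin_width, bin_width), 10)
    per_bin = {
        e: {"n_total": 0, "n_under": 0, "n_over": 0, "n_ns": 0} for e in edges
    }
    no_site = {"n_total": 0, "n_under": 0, "n_over": 0, "n_ns": 0}
    lo, hi = interval
    interval_counts = {"n_total": 0, "n_under": 0, "n_over": 0, "n_ns": 0}

    status_key = {STATUS_UNDER: "n_under", STATUS_OVER: "n_over", STATUS_NS: "n_ns"}
    for row in records.itertuples(index=False):
        gene = row.gene_id
        skey = status_key[row.status]
        tps = gene_tps.get(gene)
        if tps is None:
            no_site["n_total"] += 1
            no_site[skey] += 1
            continue
        edge = np.round(math.floor(round(tps / bin_width, 10)) * bin_width, 10)
        edge = min(edge, edges[-1])
        per_bin[edge]["n_total"] += 1
        per_bin[edge][skey] += 1
        if lo <= tps <= hi:
            interval_counts["n_total"] += 1
            interval_counts[skey] += 1

    bins_df = pd.DataFrame(
        [
            {"tps_bin": e, **counts}
            for e, counts in sorted(per_bin.items())
        ]
    )
    return TPSBinReport(
        bins=bins_df,
        no_site=no_site,
        interval=interval,
        interval_counts=interval_counts,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    note: str = ""


def enrichment_test(
    report_or_table: Union[TPSBinReport, Sequence[Sequence[int]], np.ndarray],
) -> EnrichmentResult:
    """Two-sided Fisher exact test of the 2x2 contingency
    {predicted target in [4, 11] vs not predicted} x {UNDER vs not}.

    The two-sided p sums all tables (at fixed margins) whose hypergeometric
    probability does not exceed the observed table's — the standard
    definition, distinct from mid-p variants.  Any zero margin makes the
    table degenerate: p = 1.0 with a note.
    """
    if isinstance(report_or_table, TPSBinReport):
        table = report_or_table.contingency
    else:
        table = np.asarray(report_or_table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("enrichment_test needs a non-negative 2x2 table")
    (a, b), (c, d) = table
    tup = ((int(a), int(b)), (int(c), int(d)))
    row_margins = (a + b, c + d)
    col_margins = (a + c, b + d)
    if 0 in row_margins or 0 in col_margins:
        return EnrichmentResult(
            odds_ratio=math.nan,
            p_value=1.0,
            table=tup,
            note="degenerate table: a zero margin fixes all cell counts",
        )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(odds_ratio=float(odds), p_value=float(p), table=tup)


@dataclass(frozen=True)
class RaceTally:
    """5'-RLM-RACE clone 5' ends versus the predicted cleavage position."""

    position_counts: Mapping[int, int]
    canonical_position: int
    canonical_fraction: float | None
    total_clones: int


def race_tally(
    clone_positions: Iterable[int],
    hit: TargetHit,
    max_tps: float | None = RACE_MAX_TPS,
) -> RaceTally:
    """Tally clone 5'-end positions against the canonical cleavage site.

    ``max_tps`` enforces the eligibility preset (predicted targets with
    TPS above it are not expected to be cleaved); pass ``None`` to tally
    regardless of score.
    """
    if max_tps is not None and hit.tps > max_tps:
        raise ValueError(
            f"hit TPS {hit.tps} exceeds the RACE eligibility cap {max_tps}"
        )
    canonical = predict_cleavage(hit)
    counts = Counter(int(p) for p in clone_positions)
    total = sum(counts.values())
    fraction = counts.get(canonical, 0) / total if total else None
    return RaceTally(
        position_counts=dict(sorted(counts.items())),
        canonical_position=canonical,
        canonical_fraction=fraction,
        total_clones=total,
    )


def min_tps_per_gene(
    hits: Iterable[TargetHit], transcript_to_gene: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Per-gene minimum TPS over all sites (ties toward the 5'-most site
    are irrelevant for the minimum itself).  Transcript ids are mapped to
    gene ids when a mapping is given, else used verbatim."""
    out: dict[str, float] = {}
    for h in hits:
        gene = (
            transcript_to_gene.get(h.transcript_id, h.transcript_id)
            if transcript_to_gene
            else h.transcript_id
        )
        if gene not in out or h.tps < out[gene]:
            out[gene] = h.tps
    return out
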