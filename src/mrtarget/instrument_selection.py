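"""Cis-instrument selection for a drug-target locus.

Candidate variants are restricted to the target gene's cis region (gene
body, promoter, enhancers), filtered at genome-wide significance
(p <= 5e-8) and MAF > 0.01, and greedily clumped to approximate pairwise
independence at r^2 < 0.1 against a reference LD panel. When fewer than
three independent instruments survive, two relaxations are tried — a
looser association threshold (p <= 1e-4) or a looser clumping threshold
(r^2 < 0.6) — and the one retaining more variants is adopted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_io import LDMatrix, RegionSet, SummaryStatTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    r2_clump: float = 0.1
    fallback_p: float = 1e-4
    fallback_r2: float = 0.6
    min_snps_before_fallback: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= self.fallback_p <= 1):
            raise ValueError("require 0 < p_threshold <= fallback_p <= 1")
        if not (0 < self.r2_clump <= self.fallback_r2 <= 1):
            raise ValueError("require 0 < r2_clump <= fallback_r2 <= 1")


@dataclass
class SelectionResult:
    retained: list[str]
    candidate_count: int
    fallback_used: str  # "none" | "relaxed_p" | "relaxed_r2"
    config_effective: SelectionConfig
    dropped_no_ld: list[str] = field(default_factory=list)


def cis_filter(table: SummaryStatTable, regions: RegionSet) -> SummaryStatTable:
    """Keep records whose (chrom, pos) falls in the union of cis intervals.

    Interval ends are inclusive; an empty result is returned as an empty
    table, not an error.
    """
    rec = table.records
    keep = [
        regions.contains(chrom, pos)
        for chrom, pos in zip(rec["chrom"], rec["pos"])
    ]
    return SummaryStatTable(
        trait_name=table.trait_name,
        trait_kind=table.trait_kind,
        trait_units=table.trait_units,
        records=rec[keep].reset_index(drop=True),
    )


def maf_of(eaf: float) -> float:
    """Minor-allele frequency: min(eaf, 1 - eaf)."""
    return float(min(eaf, 1.0 - eaf))


def _rank_order(rec: pd.DataFrame) -> pd.DataFrame:
    # smallest p first; ties broken by position then variant id for determinism
    return rec.sort_values(
        ["pvalue", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)


def greedy_clump(
    candidates: SummaryStatTable, ld: LDMatrix, r2_threshold: float
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly retain the remaining candidate with the smallest p-value
    and discard all others correlated with it at ``r^2 >= r2_threshold``,
    until the pool is empty. Candidates absent from the LD reference are
    dropped with a warning rather than assumed independent. Returns
    variant ids in retention order.
    """
    rec = candidates.records
    in_ld = rec["variant_id"].map(ld.contains)
    if not in_ld.all():
        missing = list(rec.loc[~in_ld, "variant_id"])
        logger.warning("greedy_clump: dropping %d variants absent from LD: %s",
                       len(missing), missing)
        rec = rec[in_ld]
    if rec.empty:
        return []
    rec = _rank_order(rec)
    ids = list(rec["variant_id"])
    r2 = ld.submatrix(ids).r2
    retained: list[str] = []
    alive = np.ones(len(ids), dtype=bool)
    while alive.any():
        i = int(np.flatnonzero(alive)[0])  # best remaining p
        retained.append(ids[i])
        alive &= r2[i] < r2_threshold
        alive[i] = False
    return retained


def select_instruments(
    table: SummaryStatTable,
    regions: RegionSet,
    ld: LDMatrix,
    config: SelectionConfig | None = None,
    snp_allowlist: Sequence[str] | None = None,
) -> SelectionResult:
    """Run the full selection pipeline with fallback relaxations.

    Pipeline: cis filter -> p threshold -> MAF threshold -> greedy clump.
    If fewer than ``min_snps_before_fallback`` variants survive, both
    relaxations (looser p, looser r^2) are rerun and the one retaining
    more variants is used, ties going to the relaxed-p rule; the choice is
    recorded in ``fallback_used``. ``snp_allowlist`` optionally restricts
    candidates to a curated id list (e.g. variant-to-gene vetting).
    """
    if config is None:
        config = SelectionConfig()
    cis = cis_filter(table, regions)
    rec = cis.records
    if snp_allowlist is not None:
        rec = rec[rec["variant_id"].isin(set(snp_allowlist))]
    mafs = rec["eaf"].map(maf_of)
    rec = rec[mafs > config.maf_min]

    def attempt(p_thr: float, r2_thr: float) -> tuple[list[str], int]:
        cand = rec[rec["pvalue"] <= p_thr]
        sub = SummaryStatTable(
            trait_name=table.trait_name,
            trait_kind=table.trait_kind,
            trait_units=table.trait_units,
            records=cand.reset_index(drop=True),
        )
        return greedy_clump(sub, ld, r2_thr), len(cand)

    retained, n_cand = attempt(config.p_threshold, config.r2_clump)
    fallback_used = "none"
    eff = config
    if len(retained) < config.min_snps_before_fallback:
        ret_p, n_p = attempt(config.fallback_p, config.r2_clump)
        ret_r2, n_r2 = attempt(config.p_threshold, config.fallback_r2)
        if len(ret_p) >= len(ret_r2):
            retained, n_cand, fallback_used = ret_p, n_p, "relaxed_p"
            eff = replace(config, p_threshold=config.fallback_p)
        else:
            retained, n_cand, fallback_used = ret_r2, n_r2, "relaxed_r2"
            eff = replace(config, r2_clump=config.fallback_r2)

    result = SelectionResult(
        retained=retained,
        candidate_count=n_cand,
        fallback_used=fallback_used,
        config_effective=eff,
    )
    _assert_independent(result, ld)
    return result


def _assert_independent(result: SelectionResult, ld: LDMatrix) -> None:
    # invariant checked on every run: no retained pair at/above the threshold
    if len(result.retained) < 2:
        return
    r2 = ld.submatrix(result.retained).r2
    thr = result.config_effective.r2_clump
    off = r2[~np.eye(len(result.retained), dtype=bool)]
    if np.any(off >= thr):
        raise AssertionError(
            f"retained pair violates r2 < {thr}: max off-diagonal {off.max():.4f}"
        )
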