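"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS may report the same SNP with effect/other alleles swapped or on
opposite strands. Before any causal estimation the outcome estimates must
be expressed per copy of the *exposure's* effect allele: swapped alleles
negate the outcome beta (and flip its EAF), strand differences are
resolved by complementing the outcome alleles, and ambiguous variants are
excluded — palindromic SNPs (A/T or C/G, identical on both strands) and
SNPs with both allele frequencies near 50% (MAF > 0.42), for which strand
cannot be inferred from frequency.

The product is an :class:`InstrumentSet`: aligned exposure/outcome effect
vectors with their SEs and the signed LD submatrix, the object every
estimator consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .instrument_selection import maf_of
from .summary_io import LDMatrix, SummaryStatTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Watson–Crick complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is its own reverse complement ({A,T} or {C,G})."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class InstrumentSet:
    """Harmonized, MR-ready instrument data for one exposure/outcome pair."""

    variant_ids: list[str]
    gamma: np.ndarray        # exposure betas, per effect-allele copy
    sigma_x: np.ndarray      # exposure SEs
    Gamma: np.ndarray        # outcome betas, aligned to the exposure effect allele
    sigma_y: np.ndarray      # outcome SEs
    rho: np.ndarray          # signed LD correlation submatrix
    exposure_units: str = ""
    outcome_kind: str = "binary"  # "quantitative" | "binary"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("gamma", "sigma_x", "Gamma", "sigma_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        m = len(self.variant_ids)
        if m < 1:
            raise ValueError("InstrumentSet needs at least one variant")
        for name in ("gamma", "sigma_x", "Gamma", "sigma_y"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
        if self.rho.shape != (m, m):
            raise ValueError(f"rho must have shape ({m}, {m})")
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise ValueError("all SEs must be strictly positive")
        if not np.allclose(self.rho, self.rho.T, atol=1e-8) or not np.allclose(
            np.diag(self.rho), 1.0
        ):
            raise ValueError("rho must be symmetric with unit diagonal")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: Sequence[int]) -> "InstrumentSet":
        keep = list(keep)
        return InstrumentSet(
            variant_ids=[self.variant_ids[i] for i in keep],
            gamma=self.gamma[keep],
            sigma_x=self.sigma_x[keep],
            Gamma=self.Gamma[keep],
            sigma_y=self.sigma_y[keep],
            rho=self.rho[np.ix_(keep, keep)],
            exposure_units=self.exposure_units,
            outcome_kind=self.outcome_kind,
            provenance=dict(self.provenance),
        )


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_matched_direct: int = 0
    n_flipped: int = 0
    n_strand_complemented: int = 0
    n_excluded_palindromic: int = 0
    n_excluded_maf: int = 0
    n_excluded_unmatched: int = 0
    eaf_source: str = "exposure"

    @property
    def n_output(self) -> int:
        return self.n_matched_direct + self.n_flipped + self.n_strand_complemented

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_output
            + self.n_excluded_palindromic
            + self.n_excluded_maf
            + self.n_excluded_unmatched
        )


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    ld: LDMatrix,
    selected: Sequence[str],
    maf_exclusion: float = 0.42,
    maf_exclusion_palindromic_only: bool = False,
) -> tuple[InstrumentSet, HarmonizationReport]:
    """Align outcome estimates to the exposure's effect alleles.

    Per selected variant, in order: (1) exclude palindromic SNPs;
    (2) exclude SNPs whose exposure-study MAF exceeds ``maf_exclusion``
    (set ``maf_exclusion_palindromic_only`` for the stricter reading that
    frequency ambiguity only matters when strand is ambiguous — with
    palindromic SNPs excluded outright this disables the rule);
    (3) match outcome alleles directly, as a swap (negating the outcome
    beta), or after strand complementing, else exclude as unmatched.

    Selected ids must exist in the exposure table (KeyError otherwise);
    ids absent from the outcome are counted ``n_excluded_unmatched``.
    Raises ``ValueError`` if no variant survives, naming the last
    exclusion applied.
    """
    report = HarmonizationReport(n_input=len(selected))
    exp_idx = exposure.records.set_index("variant_id", drop=False)
    out_idx = outcome.records.set_index("variant_id", drop=False)
    missing_exp = [v for v in selected if v not in exp_idx.index]
    if missing_exp:
        raise KeyError(f"selected variants missing from exposure table: {missing_exp}")

    kept: list[str] = []
    gamma, sigma_x, Gamma, sigma_y = [], [], [], []
    last_exclusion = "no variants selected"
    log: list[str] = []

    for vid in selected:
        e = exp_idx.loc[vid]
        if vid not in out_idx.index:
            report.n_excluded_unmatched += 1
            last_exclusion = "unmatched (absent from outcome)"
            log.append(f"{vid}: excluded, absent from outcome")
            continue
        o = out_idx.loc[vid]
        ea, oa = e["effect_allele"], e["other_allele"]
        if is_palindromic(ea, oa):
            report.n_excluded_palindromic += 1
            last_exclusion = "palindromic"
            log.append(f"{vid}: excluded, palindromic {ea}/{oa}")
            continue
        if not maf_exclusion_palindromic_only and maf_of(e["eaf"]) > maf_exclusion:
            report.n_excluded_maf += 1
            last_exclusion = f"MAF > {maf_exclusion}"
            log.append(f"{vid}: excluded, MAF {maf_of(e['eaf']):.3f} > {maf_exclusion}")
            continue

        o_ea, o_oa, o_beta = o["effect_allele"], o["other_allele"], float(o["beta"])
        strand = False
        if {o_ea, o_oa} != {ea, oa} and {complement(o_ea), complement(o_oa)} == {ea, oa}:
            o_ea, o_oa = complement(o_ea), complement(o_oa)
            strand = True
        if (o_ea, o_oa) == (ea, oa):
            if strand:
                report.n_strand_complemented += 1
                log.append(f"{vid}: strand-complemented, direct match")
            else:
                report.n_matched_direct += 1
        elif (o_ea, o_oa) == (oa, ea):
            o_beta = -o_beta
            if strand:
                report.n_strand_complemented += 1
                log.append(f"{vid}: strand-complemented, then flipped")
            else:
                report.n_flipped += 1
                log.append(f"{vid}: alleles swapped, outcome beta negated")
        else:
            report.n_excluded_unmatched += 1
            last_exclusion = "unmatched alleles"
            log.append(f"{vid}: excluded, alleles {o_ea}/{o_oa} do not match {ea}/{oa}")
            continue

        kept.append(vid)
        gamma.append(float(e["beta"]))
        sigma_x.append(float(e["se"]))
        Gamma.append(o_beta)
        sigma_y.append(float(o["se"]))

    if not kept:
        raise ValueError(
            f"no variants survived harmonization; last exclusion applied: {last_exclusion}"
        )

    instr = InstrumentSet(
        variant_ids=kept,
        gamma=np.array(gamma),
        sigma_x=np.array(sigma_x),
        Gamma=np.array(Gamma),
        sigma_y=np.array(sigma_y),
        rho=ld.submatrix(kept).r,
        exposure_units=exposure.trait_units,
        outcome_kind=outcome.trait_kind,
        provenance={
            "exposure": exposure.trait_name,
            "outcome": outcome.trait_name,
            "eaf_source_for_maf_rule": "exposure",
            "log": log,
        },
    )
    assert report.reconciles()
    return instr, report


def orient_positive(instr: InstrumentSet) -> InstrumentSet:
    """Recode alleles so every exposure beta is non-negative.

    Flipping a variant's coded allele negates its exposure and outcome
    betas and the sign of its LD correlation with every other variant.
    Wald ratios and the IVW estimate are invariant; MR-Egger requires this
    orientation because its intercept is defined in the
    exposure-increasing allele frame.
    """
    s = np.where(instr.gamma < 0, -1.0, 1.0)
    rho = instr.rho * np.outer(s, s)
    np.fill_diagonal(rho, 1.0)
    return replace(
        instr,
        gamma=instr.gamma * s,
        Gamma=instr.Gamma * s,
        rho=rho,
    )
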