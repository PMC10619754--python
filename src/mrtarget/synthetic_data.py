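"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the pipeline's real
inputs at a single cis locus: LD-correlated marginal effect estimates for
a quantitative exposure (a standardized blood-pressure-like trait) and a
binary (log-odds) or quantitative outcome, estimated in two
non-overlapping samples. Summary statistics are drawn directly from their
asymptotic sampling distribution —

    gamma_hat ~ MVN(R b,        S_x R S_x),
    Gamma_hat ~ MVN(theta*gamma + pleiotropy, S_y R S_y),

where b are the joint (conditional) exposure effects of the causal
variants, R the signed LD matrix, and S_x, S_y the diagonal per-variant
standard errors implied by allele frequency and sample size:
sigma_x = 1/sqrt(2 f (1-f) n) for a unit-variance quantitative trait and
sigma_y = 1/sqrt(2 f (1-f) n c (1-c)) on the log-odds scale for a binary
outcome with case fraction c. Exposure and outcome draws use independent
random streams, enforcing the two-sample independence assumption.

Directional pleiotropy is planted in the exposure-increasing allele
frame: Gamma_j = theta*gamma_j + sign(gamma_j)*alpha_j with
alpha_j ~ N(alpha_mu, alpha_sd^2) independent of gamma (InSIDE). A
mediated fraction of theta can be routed through a mediator trait; the
"adjusted" outcome GWAS then carries only the direct path, emulating the
output of a conditional-GWAS method without implementing one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .harmonization import InstrumentSet
from .summary_io import (
    LDMatrix,
    SummaryStatTable,
    write_ld_matrix,
    write_summary_stats,
)

LDSpec = Union[str, tuple]

#: ordered (effect, other) allele pairs that are not palindromic
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters and study dimensions for one synthetic locus.

    Defaults describe the reference scenario used throughout the test
    suite: an 8-variant cis locus with AR(1) LD (r = 0.3 between
    neighbours), explaining 1% of the variance of a standardized
    exposure measured in ~10^5 individuals, against a binary outcome
    GWAS of 50,000 individuals at a 7% case fraction — consortium-scale
    designs scaled down to desk runtimes. ``theta`` is the causal effect
    in outcome units per unit of exposure (log-odds per exposure unit
    for binary outcomes).
    """

    n_variants: int = 8
    ld_structure: LDSpec = ("ar1", 0.3)
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_exposure: int = 100_000
    n_outcome: int = 50_000
    case_fraction: float = 0.07
    outcome_kind: str = "binary"
    theta: float = 0.05
    alpha_mu: float = 0.0
    alpha_sd: float = 0.0
    mediated_fraction: float = 0.0
    prop_causal: float = 1.0
    exposure_h2_locus: float = 0.01
    plant_harmonization_cases: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_fraction", "mediated_fraction", "prop_causal",
                     "exposure_h2_locus"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValueError("n_exposure and n_outcome must be >= 100")
        if self.outcome_kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")


@dataclass
class SimTruth:
    """Ground truth paired with one simulated dataset."""

    joint_effects: np.ndarray      # conditional exposure effects b
    marginal_effects: np.ndarray   # R @ b, what GWAS estimates target
    theta: float
    alpha_vec: np.ndarray          # planted per-variant direct effects (signed frame applied)
    mediated_fraction: float


@dataclass
class LocusDraw:
    """One realisation of the locus as raw arrays (fast path for Monte Carlo)."""

    variant_ids: list[str]
    mafs: np.ndarray
    gamma_hat: np.ndarray
    sigma_x: np.ndarray
    Gamma_hat: np.ndarray
    Gamma_adj_hat: np.ndarray
    sigma_y: np.ndarray
    ld: LDMatrix
    truth: SimTruth
    outcome_kind: str = "binary"


def make_ld(config: SimulationConfig) -> LDMatrix:
    """Build the locus LD matrix from the configured structure.

    ``"identity"`` gives independent variants; ``("ar1", r)`` gives
    r^|i-j| decay; ``("block", sizes, within_r)`` gives constant
    correlation inside blocks and zero between. All forms are symmetric
    PSD.
    """
    m = config.n_variants
    spec = config.ld_structure
    if isinstance(spec, str):
        spec = (spec,)
    kind = spec[0]
    if kind == "identity":
        r = np.eye(m)
    elif kind == "ar1":
        base = float(spec[1])
        if not -1 < base < 1:
            raise ValueError("ar1 base correlation must be in (-1, 1)")
        idx = np.arange(m)
        r = base ** np.abs(idx[:, None] - idx[None, :])
    elif kind == "block":
        sizes, within = list(spec[1]), float(spec[2])
        if not -1 < within < 1:
            raise ValueError("block within-correlation must be in (-1, 1)")
        if sum(sizes) != m:
            raise ValueError(f"block sizes {sizes} do not sum to n_variants={m}")
        r = np.zeros((m, m))
        start = 0
        for s in sizes:
            if within < -1.0 / max(s - 1, 1):
                raise ValueError("block correlation makes the matrix non-PSD")
            r[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown ld_structure {config.ld_structure!r}")
    ids = [f"rs{1000 + i}" for i in range(m)]
    return LDMatrix(ids, r)


def _mvn_draw(mean: np.ndarray, sd: np.ndarray, chol_r: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(len(mean))
    return mean + sd * (chol_r @ z)


def draw_locus(config: SimulationConfig) -> LocusDraw:
    """Draw one locus realisation as arrays (no table/allele decoration).

    Deterministic in ``config.seed``; exposure, outcome and adjusted-
    outcome noise come from independent child streams of the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_locus, rng_exp, rng_out, rng_adj = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    m = config.n_variants
    ld = make_ld(config)
    r = ld.r
    # LD matrices here are PSD by construction; jitter-free Cholesky may
    # still fail for exactly singular blocks, so fall back to eigh.
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(r)
        chol = v * np.sqrt(np.maximum(w, 0.0))

    mafs = rng_locus.uniform(config.maf_low, config.maf_high, m)
    n_causal = max(1, int(round(config.prop_causal * m)))
    causal = rng_locus.choice(m, size=n_causal, replace=False)
    # One shared effect direction per locus (variants in a single gene
    # region perturb the target the same way — the premise of the
    # fixed-effect model), with magnitudes bounded away from zero:
    # instruments only enter an analysis after passing a significance
    # screen, so the generator emulates instrument-grade variants.
    shared_sign = rng_locus.choice([-1.0, 1.0])
    b = np.zeros(m)
    b[causal] = shared_sign * (0.5 + np.abs(rng_locus.standard_normal(n_causal)))
    quad = float(b @ r @ b)
    if quad > 0 and config.exposure_h2_locus > 0:
        b *= np.sqrt(config.exposure_h2_locus / quad)
    gamma = r @ b

    sigma_x = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * config.n_exposure)
    gamma_hat = _mvn_draw(gamma, sigma_x, chol, rng_exp)

    alpha = np.zeros(m)
    if config.alpha_mu != 0 or config.alpha_sd != 0:
        raw = rng_locus.normal(config.alpha_mu, config.alpha_sd, m)
        # plant directional pleiotropy relative to the exposure-increasing allele
        alpha = np.where(gamma < 0, -raw, raw)

    theta_direct = (1.0 - config.mediated_fraction) * config.theta
    Gamma = config.theta * gamma + alpha
    Gamma_adj = theta_direct * gamma + alpha

    if config.outcome_kind == "binary":
        eff_n = config.n_outcome * config.case_fraction * (1 - config.case_fraction)
    else:
        eff_n = config.n_outcome
    sigma_y = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * eff_n)
    Gamma_hat = _mvn_draw(Gamma, sigma_y, chol, rng_out)
    Gamma_adj_hat = _mvn_draw(Gamma_adj, sigma_y, chol, rng_adj)

    truth = SimTruth(
        joint_effects=b,
        marginal_effects=gamma,
        theta=config.theta,
        alpha_vec=alpha,
        mediated_fraction=config.mediated_fraction,
    )
    return LocusDraw(
        variant_ids=list(ld.variant_ids),
        mafs=mafs,
        gamma_hat=gamma_hat,
        sigma_x=sigma_x,
        Gamma_hat=Gamma_hat,
        Gamma_adj_hat=Gamma_adj_hat,
        sigma_y=sigma_y,
        ld=ld,
        truth=truth,
        outcome_kind=config.outcome_kind,
    )


def instrument_set(draw: LocusDraw, adjusted: bool = False) -> InstrumentSet:
    """Assemble an MR-ready instrument set straight from a locus draw.

    Bypasses harmonization: the simulator reports both studies on
    identical effect alleles, so there is nothing to align or exclude.
    Intended for estimator calibration studies where selection and QC are
    not under test.
    """
    return InstrumentSet(
        variant_ids=list(draw.variant_ids),
        gamma=draw.gamma_hat,
        sigma_x=draw.sigma_x,
        Gamma=draw.Gamma_adj_hat if adjusted else draw.Gamma_hat,
        sigma_y=draw.sigma_y,
        rho=draw.ld.r,
        exposure_units="mmHg",
        outcome_kind=draw.outcome_kind,
        provenance={"source": "synthetic", "adjusted": adjusted},
    )


def _table_from_arrays(
    name: str,
    kind: str,
    units: str,
    draw: LocusDraw,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    chrom: str = "8",
) -> SummaryStatTable:
    z = np.abs(beta) / se
    pvals = np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": draw.variant_ids,
            "chrom": chrom,
            "pos": 1000 + 500 * np.arange(len(beta)),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pvals,
            "n": n,
        }
    )
    return SummaryStatTable(trait_name=name, trait_kind=kind, trait_units=units,
                            records=df)


def simulate_locus(
    config: SimulationConfig,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, LDMatrix, SimTruth]:
    """Simulate exposure, outcome and adjusted-outcome summary statistics.

    Returns ``(exposure, outcome, outcome_adjusted, ld, truth)``. Alleles
    are drawn uniformly from non-palindromic pairs and shared between the
    two studies; with ``plant_harmonization_cases`` the first three
    variants are rewritten to exercise harmonization edge cases: variant
    0 becomes palindromic (A/T), variant 1 gets an exposure EAF of 0.45
    (MAF > 0.42), and variant 2's outcome record has its alleles swapped
    with beta negated and EAF flipped (a pure coding difference).
    Identical configs (including seed) give bit-identical outputs.
    """
    draw = draw_locus(config)
    m = config.n_variants
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11E1E)))
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)
    alleles = [_NONPALINDROMIC_PAIRS[i] for i in pair_idx]
    eaf = draw.mafs.copy()  # report the minor allele as effect allele

    exp_alleles = list(alleles)
    out_alleles = list(alleles)
    exp_eaf = eaf.copy()
    out_eaf = eaf.copy()
    out_beta = draw.Gamma_hat.copy()
    adj_alleles = list(alleles)
    adj_eaf = eaf.copy()

    if config.plant_harmonization_cases:
        if m < 3:
            raise ValueError("plant_harmonization_cases needs n_variants >= 3")
        exp_alleles[0] = out_alleles[0] = adj_alleles[0] = ("A", "T")
        exp_eaf[1] = 0.45
        ea, oa = out_alleles[2]
        out_alleles[2] = (oa, ea)
        out_beta[2] = -out_beta[2]
        out_eaf[2] = 1 - out_eaf[2]

    exposure = _table_from_arrays(
        "synthetic_dbp", "quantitative", "mmHg", draw,
        draw.gamma_hat, draw.sigma_x, config.n_exposure, exp_alleles, exp_eaf,
    )
    kind = config.outcome_kind
    units = "log-odds" if kind == "binary" else "unit"
    outcome = _table_from_arrays(
        "synthetic_hf", kind, units, draw,
        out_beta, draw.sigma_y, config.n_outcome, out_alleles, out_eaf,
    )
    outcome_adj = _table_from_arrays(
        "synthetic_hf_adjusted", kind, units, draw,
        draw.Gamma_adj_hat, draw.sigma_y, config.n_outcome, adj_alleles, adj_eaf,
    )
    return exposure, outcome, outcome_adj, draw.ld, draw.truth


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate a locus and write all artefacts as plain text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, outcome_adj, ld, truth = simulate_locus(config)
    paths = {
        "exposure": out / "exposure.tsv",
        "outcome": out / "outcome.tsv",
        "outcome_adjusted": out / "outcome_adjusted.tsv",
        "ld_matrix": out / "ld.txt",
        "ld_ids": out / "ld_ids.txt",
        "truth": out / "truth.json",
    }
    write_summary_stats(exposure, paths["exposure"])
    write_summary_stats(outcome, paths["outcome"])
    write_summary_stats(outcome_adj, paths["outcome_adjusted"])
    write_ld_matrix(ld, paths["ld_matrix"], paths["ld_ids"])
    paths["truth"].write_text(
        json.dumps(
            {
                "theta": truth.theta,
                "mediated_fraction": truth.mediated_fraction,
                "joint_effects": truth.joint_effects.tolist(),
                "marginal_effects": truth.marginal_effects.tolist(),
                "alpha_vec": truth.alpha_vec.tolist(),
            },
            indent=2,
        )
        + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# deterministic toy fixtures


def _toy_table(name, kind, units, rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ],
    )
    return SummaryStatTable(trait_name=name, trait_kind=kind, trait_units=units,
                            records=df)


def make_fixture(kind: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small deterministic fixture bundle for one edge case.

    Kinds:

    * ``harmonization_toy`` — 6 variants: one palindromic, one with
      exposure MAF 0.45, one with swapped outcome alleles, one reported on
      the opposite strand; harmonization must exclude exactly two, flip
      exactly one sign, and keep four.
    * ``clump_toy`` — 6 variants in LD blocks (3 + 2 + 1 at r = 0.9)
      whose greedy clump at r^2 < 0.1 retains rs1, rs4, rs6.
    * ``pleiotropy_toy`` — 5 independent variants constructed with
      Gamma = 0.05 + 0.2*gamma exactly (Egger recovers both terms).
    * ``outlier_toy`` — 5 independent variants sharing Wald ratio 0.2
      except one planted 5 outcome-SEs away.

    ``seed`` is accepted for interface uniformity; the bundles are fully
    deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if kind == "harmonization_toy":
        exp_rows = [
            ("rs1", "8", 1000, "A", "G", 0.30, 0.030, 0.004, 1e-13, 100000),
            ("rs2", "8", 1500, "A", "T", 0.30, 0.028, 0.004, 1e-12, 100000),  # palindromic
            ("rs3", "8", 2000, "A", "C", 0.45, 0.026, 0.004, 1e-10, 100000),  # MAF 0.45
            ("rs4", "8", 2500, "C", "T", 0.20, 0.024, 0.004, 1e-9, 100000),   # swapped in outcome
            ("rs5", "8", 3000, "A", "G", 0.25, 0.022, 0.004, 1e-8, 100000),   # strand-complemented
            ("rs6", "8", 3500, "G", "T", 0.40, 0.020, 0.004, 2e-8, 100000),
        ]
        out_rows = [
            ("rs1", "8", 1000, "A", "G", 0.30, 0.010, 0.008, 0.21, 50000),
            ("rs2", "8", 1500, "A", "T", 0.30, 0.009, 0.008, 0.26, 50000),
            ("rs3", "8", 2000, "A", "C", 0.45, 0.008, 0.008, 0.32, 50000),
            ("rs4", "8", 2500, "T", "C", 0.80, -0.007, 0.008, 0.38, 50000),
            ("rs5", "8", 3000, "T", "C", 0.25, 0.006, 0.008, 0.45, 50000),
            ("rs6", "8", 3500, "G", "T", 0.40, 0.005, 0.008, 0.53, 50000),
        ]
        exposure = _toy_table("toy_dbp", "quantitative", "mmHg", exp_rows)
        outcome = _toy_table("toy_hf", "binary", "log-odds", out_rows)
        ld = LDMatrix([r[0] for r in exp_rows], np.eye(6))
        meta = {
            "selected": [r[0] for r in exp_rows],
            "expected": {
                "n_excluded_palindromic": 1,
                "n_excluded_maf": 1,
                "n_flipped": 1,
                "n_strand_complemented": 1,
                "n_kept": 4,
            },
        }
    elif kind == "clump_toy":
        rows = [
            ("rs1", "8", 1000, "A", "G", 0.30, 0.040, 0.004, 1e-12, 100000),
            ("rs2", "8", 1400, "A", "C", 0.28, 0.036, 0.004, 1e-10, 100000),
            ("rs3", "8", 1800, "G", "T", 0.32, 0.034, 0.004, 1e-9, 100000),
            ("rs4", "8", 2200, "C", "T", 0.22, 0.038, 0.004, 1e-11, 100000),
            ("rs5", "8", 2600, "A", "G", 0.26, 0.030, 0.004, 1e-8, 100000),
            ("rs6", "8", 3000, "T", "C", 0.35, 0.028, 0.004, 5e-8, 100000),
        ]
        exposure = _toy_table("toy_dbp", "quantitative", "mmHg", rows)
        outcome = None
        r = np.eye(6)
        for i, j in [(0, 1), (0, 2), (1, 2)]:  # block rs1-rs3
            r[i, j] = r[j, i] = 0.9
        r[3, 4] = r[4, 3] = 0.9          # block rs4-rs5
        ld = LDMatrix([row[0] for row in rows], r)
        meta = {"expected": {"retained": ["rs1", "rs4", "rs6"]}}
    elif kind == "pleiotropy_toy":
        gammas = [0.02, 0.03, 0.04, 0.05, 0.06]
        rows, out_rows = [], []
        for i, g in enumerate(gammas):
            vid, pos = f"rs{i + 1}", 1000 + 400 * i
            rows.append((vid, "8", pos, "A", "G", 0.30, g, 0.002, 1e-9, 100000))
            out_rows.append(
                (vid, "8", pos, "A", "G", 0.30, 0.05 + 0.2 * g, 0.01, 0.5, 50000)
            )
        exposure = _toy_table("toy_dbp", "quantitative", "mmHg", rows)
        outcome = _toy_table("toy_hf", "binary", "log-odds", out_rows)
        ld = LDMatrix([r[0] for r in rows], np.eye(5))
        meta = {"expected": {"egger_intercept": 0.05, "egger_slope": 0.2}}
    elif kind == "outlier_toy":
        rows, out_rows = [], []
        for i in range(5):
            vid, pos = f"rs{i + 1}", 1000 + 400 * i
            gamma, sy = 0.05, 0.01
            Gamma = 0.2 * gamma + (5 * sy if i == 2 else 0.0)
            rows.append((vid, "8", pos, "A", "G", 0.30, gamma, 0.002, 1e-9, 100000))
            out_rows.append((vid, "8", pos, "A", "G", 0.30, Gamma, sy, 0.3, 50000))
        exposure = _toy_table("toy_dbp", "quantitative", "mmHg", rows)
        outcome = _toy_table("toy_hf", "binary", "log-odds", out_rows)
        ld = LDMatrix([r[0] for r in rows], np.eye(5))
        meta = {"expected": {"outlier": "rs3"}}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    paths = {
        "exposure": out / "exposure.tsv",
        "ld_matrix": out / "ld.txt",
        "ld_ids": out / "ld_ids.txt",
        "meta": out / "meta.json",
    }
    write_summary_stats(exposure, paths["exposure"])
    if outcome is not None:
        paths["outcome"] = out / "outcome.tsv"
        write_summary_stats(outcome, paths["outcome"])
    write_ld_matrix(ld, paths["ld_matrix"], paths["ld_ids"])
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths
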