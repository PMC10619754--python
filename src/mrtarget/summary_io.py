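"""Readers, writers and the in-memory data model for GWAS summary statistics.

The pipeline works on three kinds of inputs, all plain delimited text:

* per-variant marginal association estimates for one trait
  (:class:`SummaryStatTable`),
* cis-region interval definitions for a target gene (:class:`RegionSet`),
* a signed LD correlation matrix from a reference panel (:class:`LDMatrix`).

Coordinates are 1-based inclusive everywhere inside the package; only the
BED reader converts from 0-based half-open. Strand is not stored: summary
statistics are assumed forward-strand reported and strand discrepancies are
resolved downstream by allele complementing during harmonization.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

REGION_CLASSES = ("gene_body", "promoter", "enhancer")

#: canonical record field -> default source column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

RECORD_COLUMNS = list(DEFAULT_COLUMN_MAP)

#: fields that must be present and valid in every retained row
_REQUIRED_FIELDS = [c for c in RECORD_COLUMNS if c != "n"]

RESULT_COLUMNS = [
    "target",
    "exposure_trait",
    "outcome_trait",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "or",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
    "direction",
]


@dataclass
class SummaryStatTable:
    """Marginal association estimates for one trait.

    ``records`` is a DataFrame with the canonical columns
    ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pvalue, n`` (``n`` may be missing). Betas are in trait units per copy
    of the effect allele.
    """

    trait_name: str
    trait_kind: str  # "quantitative" | "binary"
    trait_units: str
    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing == ["n"]:
            self.records = self.records.assign(n=np.nan)
        elif missing:
            raise ValueError(f"records missing columns {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records["variant_id"])

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatTable":
        """Rows restricted to ``variant_ids``, in the given order."""
        idx = self.records.set_index("variant_id", drop=False)
        present = [v for v in variant_ids if v in idx.index]
        return SummaryStatTable(
            trait_name=self.trait_name,
            trait_kind=self.trait_kind,
            trait_units=self.trait_units,
            records=idx.loc[present].reset_index(drop=True),
        )

    def record_for(self, variant_id: str) -> pd.Series:
        rows = self.records[self.records["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return rows.iloc[0]


@dataclass
class RegionSet:
    """Union of cis intervals (gene body, promoter, enhancers) for one gene.

    Intervals are (chrom, start, end, region_class), 1-based inclusive;
    overlaps are allowed and membership tests use the union.
    """

    gene_symbol: str
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, cls in self.intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end} on {chrom}")
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region_class {cls!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            c == str(chrom) and start <= pos <= end
            for c, start, end, _ in self.intervals
        )


@dataclass
class LDMatrix:
    """Signed pairwise correlations ``r`` between variants of one locus."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric within 1e-8")
        if np.any(np.abs(self.r) > 1 + 1e-6):
            raise ValueError("LD matrix has |r| > 1")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index_of(self, variant_ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in LD reference") from None

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = self.index_of(variant_ids)
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)].copy())

    def contains(self, variant_id: str) -> bool:
        return variant_id in set(self.variant_ids)


# ---------------------------------------------------------------------------
# summary statistics


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) == 1 and a in VALID_BASES


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_meta: Mapping[str, str] | None = None,
) -> SummaryStatTable:
    """Load a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical field names to source column names
    (defaults to :data:`DEFAULT_COLUMN_MAP`). Rows violating record
    invariants (non-SNP alleles, se <= 0, p outside (0, 1], eaf outside
    (0, 1), pos < 1, duplicate ids, identical alleles) are dropped and
    counted in ``n_dropped``.

    Raises ``ValueError`` if a mapped column for a required field is
    absent, or if no valid rows remain.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    meta = {"trait_name": str(path), "trait_kind": "quantitative", "trait_units": ""}
    if trait_meta:
        meta.update(trait_meta)

    df = pd.read_csv(path, sep=None, engine="python", dtype={cmap["chrom"]: str})
    for fld in _REQUIRED_FIELDS:
        if cmap[fld] not in df.columns:
            raise ValueError(
                f"column {cmap[fld]!r} (mapped to field {fld!r}) not found in {path}"
            )
    rename = {src: fld for fld, src in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    if "n" not in df.columns:
        df["n"] = np.nan
    df = df[RECORD_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for a in ("effect_allele", "other_allele"):
        df[a] = df[a].astype(str).str.upper()

    n_input = len(df)
    num = df[["pos", "eaf", "beta", "se", "pvalue"]].apply(
        pd.to_numeric, errors="coerce"
    )
    df[num.columns] = num
    ok = (
        df["variant_id"].notna()
        & num.notna().all(axis=1)
        & df["effect_allele"].map(_valid_allele)
        & df["other_allele"].map(_valid_allele)
        & (df["effect_allele"] != df["other_allele"])
        & (df["pos"] >= 1)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
    )
    df = df[ok]
    df = df[~df["variant_id"].duplicated(keep="first")]
    n_dropped = n_input - len(df)
    if n_dropped:
        logger.info("read_summary_stats(%s): dropped %d invalid rows", path, n_dropped)
    if df.empty:
        raise ValueError(f"no valid rows in {path}")
    df["pos"] = df["pos"].astype(int)
    df = df.reset_index(drop=True)
    return SummaryStatTable(records=df, n_dropped=n_dropped, **meta)


def write_summary_stats(table: SummaryStatTable, path: str | Path) -> None:
    """Write a table back to TSV using the default column names."""
    out = table.records.rename(columns=DEFAULT_COLUMN_MAP)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# regions


def read_regions(
    path: str | Path,
    dialect: str = "bed",
    gene_symbol: str = "",
) -> RegionSet:
    """Read cis-region intervals from BED or a 1-based TSV.

    BED input is 0-based half-open and is converted to 1-based inclusive:
    ``(start=99, end=200)`` becomes ``(100, 200)``. The optional BED name
    column supplies the region class when it matches one of
    ``gene_body/promoter/enhancer``; otherwise ``gene_body`` is assumed.
    The ``one_based_tsv`` dialect expects a header with columns
    ``chrom, start, end, region_class`` already 1-based inclusive.
    """
    intervals: list[tuple[str, int, int, str]] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                start, end = start0 + 1, end0
                if start > end:
                    raise ValueError(f"{path}:{lineno}: start > end after conversion")
                cls = "gene_body"
                if len(parts) > 3 and parts[3] in REGION_CLASSES:
                    cls = parts[3]
                intervals.append((chrom, start, end, cls))
    elif dialect == "one_based_tsv":
        df = pd.read_csv(path, sep=None, engine="python", dtype={"chrom": str})
        for col in ("chrom", "start", "end", "region_class"):
            if col not in df.columns:
                raise ValueError(f"regions file {path} missing column {col!r}")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            start, end = int(row.start), int(row.end)
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            intervals.append((str(row.chrom), start, end, str(row.region_class)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RegionSet(gene_symbol=gene_symbol, intervals=intervals)


def interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """Inverse of the BED reader's coordinate conversion."""
    return start - 1, end


# ---------------------------------------------------------------------------
# LD


def read_ld_matrix(matrix_path: str | Path, ids_path: str | Path) -> LDMatrix:
    """Load a dense LD correlation matrix and its variant-id sidecar.

    The matrix file holds whitespace- or comma-delimited floats; the ids
    file holds one variant id per line. The matrix is symmetrized as
    ``(M + M.T) / 2`` with the diagonal set to 1; asymmetry beyond 1e-6 is
    logged as a warning. Dimension mismatch or ``|r| > 1 + 1e-6`` is a
    hard error.
    """
    text = Path(matrix_path).read_text()
    m = np.loadtxt(io.StringIO(text.replace(",", " ")), ndmin=2)
    ids = [
        line.strip()
        for line in Path(ids_path).read_text().splitlines()
        if line.strip()
    ]
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"LD matrix is not square: {m.shape}")
    if m.shape[0] != len(ids):
        raise ValueError(
            f"LD matrix dimension {m.shape[0]} != number of ids {len(ids)}"
        )
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > 1e-6:
        logger.warning(
            "read_ld_matrix(%s): asymmetry %.3g > 1e-6; symmetrizing", matrix_path, asym
        )
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    if np.any(np.abs(m) > 1 + 1e-6):
        raise ValueError("LD matrix has |r| > 1 + 1e-6")
    np.clip(m, -1.0, 1.0, out=m)
    return LDMatrix(ids, m)


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, ids_path: str | Path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g")
    Path(ids_path).write_text("".join(f"{v}\n" for v in ld.variant_ids))


# ---------------------------------------------------------------------------
# results


def _fmt(x: object) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write MR estimates as a results TSV.

    Each row is a mapping with keys ``target``, ``exposure_trait``,
    ``outcome_trait`` and ``estimate`` (an ``MREstimate``). OR columns are
    left empty for quantitative outcomes, where an odds ratio is
    undefined.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for row in rows:
        est = row["estimate"]
        or_vals = est.or_scale if est.or_scale is not None else (None, None, None)
        values = [
            row.get("target", ""),
            row.get("exposure_trait", ""),
            row.get("outcome_trait", ""),
            est.method,
            est.n_snps,
            est.theta,
            est.se,
            est.ci_low,
            est.ci_high,
            or_vals[0],
            or_vals[1],
            or_vals[2],
            est.pvalue,
            est.direction,
        ]
        lines.append("\t".join(_fmt(v) for v in values))
    Path(path).write_text("".join(f"{line}\n" for line in lines))
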