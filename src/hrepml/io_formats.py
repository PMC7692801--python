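"""Plain-CSV readers and writers for the four-file association run contract.

The tool consumes four comma-separated inputs:

* a genotype file, one row per SNP marker, whose first two columns carry the
  chromosome label and base-pair position, followed by one column per
  individual with calls coded 0/1/2 for aa/Aa/AA;
* a phenotype file holding a single numeric column (one value per individual);
* an n-by-n genomic relatedness (kinship) file;
* a covariate (fixed-effect design) file whose first column is all ones.

It writes a results file (one row per declared marker) and a timing file.
All readers auto-detect an optional header row and raise :class:`FormatError`
with row/column coordinates on malformed content.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "GenotypeTable",
    "PhenotypeVector",
    "CovariateTable",
    "KinshipTable",
    "ResultRecord",
    "read_genotype",
    "read_phenotype",
    "read_kinship",
    "read_covariates",
    "write_results",
    "read_results",
    "write_timings",
]

#: Tokens treated as a missing genotype call.
_NA_TOKENS = {"", "NA", "N/A", "NAN", "NULL", "."}

_VALID_CALLS = (0.0, 1.0, 2.0)


class FormatError(ValueError):
    """An input file violates the declared CSV contract."""


class DimensionError(ValueError):
    """Input files are individually valid but mutually inconsistent."""


@dataclass
class GenotypeTable:
    """Marker-major genotype matrix with per-marker chromosome/position.

    ``calls`` is an m-by-n float matrix; observed entries are exactly 0, 1 or
    2, while imputed entries may be fractional marker means (imputation keeps
    the allele frequency of the observed calls).
    """

    chromosome: np.ndarray
    position: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise FormatError("genotype calls must form a 2-D matrix")
        m, n = self.calls.shape
        if m < 1 or n < 2:
            raise FormatError(
                f"need at least 1 marker and 2 individuals, got {m} markers, {n} individuals"
            )
        if len(self.chromosome) != m or len(self.position) != m:
            raise FormatError("chromosome/position metadata length mismatch")
        if np.any(self.position < 0):
            raise FormatError("marker positions must be non-negative")
        if not np.all(np.isfinite(self.calls)):
            raise FormatError("genotype calls must be finite after imputation")

    @property
    def marker_count(self) -> int:
        return self.calls.shape[0]

    @property
    def sample_count(self) -> int:
        return self.calls.shape[1]

    def sample_major(self) -> np.ndarray:
        """n-by-m view (individuals in rows) used by the model stages."""
        return self.calls.T

    def marker_vector(self, i: int) -> np.ndarray:
        """Length-n genotype vector of marker ``i``."""
        return self.calls[i]


@dataclass
class PhenotypeVector:
    """Length-n trait vector; missing phenotypes are not supported."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size == 0:
            raise FormatError("phenotype file is empty")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("phenotype values must all be finite (missingness unsupported)")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CovariateTable:
    """n-by-c fixed-effect design whose first column is the unit vector."""

    design: np.ndarray

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        n, c = self.design.shape
        if not np.allclose(self.design[:, 0], 1.0, atol=1e-12):
            raise FormatError("first covariate column must be identically 1")
        if c >= n:
            raise FormatError(f"need fewer covariates than individuals (c={c}, n={n})")
        if np.linalg.matrix_rank(self.design) < c:
            raise FormatError("covariate design matrix is rank deficient")

    @property
    def sample_count(self) -> int:
        return self.design.shape[0]

    @property
    def count(self) -> int:
        return self.design.shape[1]


@dataclass
class KinshipTable:
    """n-by-n symmetric genomic relatedness matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise FormatError(f"kinship matrix must be square, got shape {self.matrix.shape}")
        scale = max(1.0, float(np.abs(self.matrix).max(initial=0.0)))
        if np.abs(self.matrix - self.matrix.T).max(initial=0.0) > 1e-8 * scale:
            raise FormatError("kinship matrix is not symmetric within tolerance")
        if np.any(np.diag(self.matrix) < -1e-12):
            raise FormatError("kinship diagonal must be non-negative")

    @property
    def sample_count(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ResultRecord:
    """One finally declared marker: location, effect, scaled SE and LOD."""

    chromosome: int
    position: int
    effect: float
    std_error: float
    lod: float


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="") as handle:
        rows = [row for row in csv.reader(handle) if row and any(f.strip() for f in row)]
    return [[f.strip() for f in row] for row in rows]


def _is_numeric_or_na(token: str) -> bool:
    if token.upper() in _NA_TOKENS:
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def _strip_header(rows: list[list[str]]) -> list[list[str]]:
    """Drop the first row when it contains any non-numeric, non-missing token."""
    if rows and not all(_is_numeric_or_na(tok) for tok in rows[0]):
        return rows[1:]
    return rows


def _parse_cell(token: str, row: int, col: int, what: str) -> float:
    if token.upper() in _NA_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric {what} value {token!r} at row {row + 1}, column {col + 1}")


def read_genotype(path) -> GenotypeTable:
    """Parse a marker-major genotype CSV (chromosome, position, calls...).

    Observed calls must be exactly 0, 1 or 2; missing cells (empty or NA) are
    imputed with the marker mean of the observed calls, kept real-valued so
    the marker's allele frequency is preserved.
    """
    rows = _strip_header(_read_rows(path))
    if not rows:
        raise FormatError(f"genotype file {path} contains no data rows")
    width = len(rows[0])
    if width < 3:
        raise FormatError("genotype rows need at least 3 columns (chrom, position, calls...)")
    chrom, pos, calls = [], [], []
    for r, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(f"ragged genotype row {r + 1}: {len(row)} fields, expected {width}")
        c = _parse_cell(row[0], r, 0, "chromosome")
        p = _parse_cell(row[1], r, 1, "position")
        if math.isnan(c) or math.isnan(p) or c != int(c) or p != int(p):
            raise FormatError(f"chromosome/position must be integers at row {r + 1}")
        marker = np.empty(width - 2)
        for j, tok in enumerate(row[2:]):
            val = _parse_cell(tok, r, j + 2, "genotype")
            if not math.isnan(val) and val not in _VALID_CALLS:
                raise FormatError(
                    f"genotype call {val!r} at row {r + 1}, column {j + 3} is not in {{0, 1, 2}}"
                )
            marker[j] = val
        missing = np.isnan(marker)
        if missing.all():
            raise FormatError(f"marker at row {r + 1} has no observed calls")
        if missing.any():
            marker[missing] = marker[~missing].mean()
        chrom.append(int(c))
        pos.append(int(p))
        calls.append(marker)
    return GenotypeTable(np.array(chrom), np.array(pos), np.array(calls))


def read_phenotype(path) -> PhenotypeVector:
    """Parse the single-column phenotype CSV."""
    rows = _strip_header(_read_rows(path))
    if not rows:
        raise FormatError(f"phenotype file {path} is empty")
    values = []
    for r, row in enumerate(rows):
        if len(row) != 1:
            raise FormatError(f"phenotype row {r + 1} must hold exactly one value, got {len(row)}")
        val = _parse_cell(row[0], r, 0, "phenotype")
        if math.isnan(val):
            raise FormatError(f"missing phenotype at row {r + 1}: missingness is unsupported")
        values.append(val)
    return PhenotypeVector(np.array(values))


def _read_matrix(path, what: str) -> np.ndarray:
    rows = _strip_header(_read_rows(path))
    if not rows:
        raise FormatError(f"{what} file {path} is empty")
    width = len(rows[0])
    out = np.empty((len(rows), width))
    for r, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(f"ragged {what} row {r + 1}: {len(row)} fields, expected {width}")
        for j, tok in enumerate(row):
            val = _parse_cell(tok, r, j, what)
            if math.isnan(val):
                raise FormatError(f"missing {what} value at row {r + 1}, column {j + 1}")
            out[r, j] = val
    return out


def read_kinship(path) -> KinshipTable:
    """Parse the n-by-n kinship CSV and validate symmetry."""
    return KinshipTable(_read_matrix(path, "kinship"))


def read_covariates(path) -> CovariateTable:
    """Parse the fixed-effect design CSV (first column all ones)."""
    return CovariateTable(_read_matrix(path, "covariate"))


_RESULT_HEADER = ("chromosome", "position", "effect", "std_error", "lod")


def write_results(records: Sequence[ResultRecord], path) -> None:
    """Write the declared markers to ``path`` (header always present)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_RESULT_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.chromosome,
                    rec.position,
                    format(rec.effect, ".17g"),
                    format(rec.std_error, ".17g"),
                    format(rec.lod, ".17g"),
                ]
            )


def read_results(path) -> list[ResultRecord]:
    """Re-parse a results file written by :func:`write_results`."""
    rows = _read_rows(path)
    if not rows or tuple(rows[0]) != _RESULT_HEADER:
        raise FormatError(f"results file {path} is missing the expected header")
    out = []
    for r, row in enumerate(rows[1:]):
        if len(row) != 5:
            raise FormatError(f"results row {r + 2} must have 5 fields, got {len(row)}")
        out.append(
            ResultRecord(
                chromosome=int(row[0]),
                position=int(row[1]),
                effect=float(row[2]),
                std_error=float(row[3]),
                lod=float(row[4]),
            )
        )
    return out


def write_timings(timings: dict[str, float], path) -> None:
    """Write per-stage wall times (seconds) as a two-column CSV."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(("stage", "seconds"))
        for stage, seconds in timings.items():
            writer.writerow((stage, format(seconds, ".6f")))
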