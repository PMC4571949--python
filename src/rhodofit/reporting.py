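"""Spectral-shift computation and pigment summary tables.

A mutant pigment is *red shifted* when its λmax moves to longer
wavelengths than the reference (wild-type) pigment and *blue shifted*
when it moves shorter.  Shifts are reported as mutant − reference, so
positive = red.  The table renderer produces one row per genotype with
the R- and M-form λmax, fit correlations, sample counts, and shifts
versus the reference, mirroring the layout of a pigment summary table;
missing quantities render as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PigmentRecord",
    "compute_shift",
    "classify_shift",
    "pigment_table",
    "render_pigment_table",
    "table_from_tsv",
]

TABLE_COLUMNS = [
    "genotype",
    "R",
    "M",
    "corr_SS",
    "corr_MSP",
    "n_SS",
    "n_MSP",
    "shift_R",
    "shift_M",
]


@dataclass(frozen=True)
class PigmentRecord:
    """One genotype's fitted quantities (one summary-table row)."""

    genotype: str
    lambda_max_R: float | None = None
    lambda_max_M: float | None = None
    corr_SS: float | None = None
    corr_MSP: float | None = None
    n_SS: int = 0
    n_MSP: int = 0

    def __post_init__(self) -> None:
        if not self.genotype:
            raise ValueError("genotype must be nonempty")
        for name in ("corr_SS", "corr_MSP"):
            v = getattr(self, name)
            if v is not None and not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")


def compute_shift(mutant_lambda_max: float, reference_lambda_max: float) -> float:
    """Signed λmax shift in nm: mutant − reference (positive = red shift)."""
    if mutant_lambda_max is None or reference_lambda_max is None:
        raise ValueError("missing λmax: shift requires both values")
    m, r = float(mutant_lambda_max), float(reference_lambda_max)
    if not (math.isfinite(m) and math.isfinite(r)):
        raise ValueError("missing λmax: shift requires finite values")
    return m - r


def classify_shift(shift: float) -> str:
    """'red' for a positive shift, 'blue' for negative, 'none' for zero."""
    if shift > 0:
        return "red"
    if shift < 0:
        return "blue"
    return "none"


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def pigment_table(records: list[PigmentRecord], reference: str) -> pd.DataFrame:
    """Assemble the machine-readable pigment report (full precision).

    One row per record, with shift columns computed against the reference
    genotype's λmax values; NaN marks unavailable quantities.  Use
    :func:`render_pigment_table` for the rendered (1-nm precision, "NA")
    text form.
    """
    names = [r.genotype for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate genotype in report")
    by_name = {r.genotype: r for r in records}
    if reference not in by_name:
        raise ValueError(f"reference genotype {reference!r} absent from records")
    ref = by_name[reference]
    if ref.lambda_max_R is None:
        raise ValueError(f"reference genotype {reference!r} has no R-form λmax")
    rows = []
    for rec in records:
        shift_r = (
            compute_shift(rec.lambda_max_R, ref.lambda_max_R)
            if rec.lambda_max_R is not None
            else None
        )
        shift_m = (
            compute_shift(rec.lambda_max_M, ref.lambda_max_M)
            if rec.lambda_max_M is not None and ref.lambda_max_M is not None
            else None
        )
        rows.append(
            {
                "genotype": rec.genotype,
                "R": rec.lambda_max_R,
                "M": rec.lambda_max_M,
                "corr_SS": rec.corr_SS,
                "corr_MSP": rec.corr_MSP,
                "n_SS": rec.n_SS,
                "n_MSP": rec.n_MSP,
                "shift_R": shift_r,
                "shift_M": shift_m,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def render_pigment_table(table: pd.DataFrame) -> str:
    """Render the report as TSV text: λmax and shifts at 1-nm precision
    (rounding half away from zero), correlations to 3 decimals, NA for
    missing values."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for _, row in table.iterrows():
        cells = [str(row["genotype"])]
        for col in ("R", "M"):
            v = row[col]
            cells.append("NA" if pd.isna(v) else str(_round_half_away(v)))
        for col in ("corr_SS", "corr_MSP"):
            v = row[col]
            cells.append("NA" if pd.isna(v) else f"{v:.3f}")
        for col in ("n_SS", "n_MSP"):
            cells.append(str(int(row[col])))
        for col in ("shift_R", "shift_M"):
            v = row[col]
            cells.append("NA" if pd.isna(v) else f"{_round_half_away(v):+d}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def table_from_tsv(text: str) -> pd.DataFrame:
    """Parse a rendered table back to a DataFrame (NA → NaN)."""
    from io import StringIO

    return pd.read_csv(StringIO(text), sep="\t", na_values=["NA"])
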