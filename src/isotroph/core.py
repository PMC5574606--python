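"""Isotope-ratio / δ-notation arithmetic and preservation corrections.

Stable-isotope abundances are reported in δ notation: the per-mil deviation
of a sample's heavy-to-light isotope ratio from an international reference,

    δX (‰) = (R_sample / R_reference − 1) × 1000,

with R_reference the ¹³C/¹²C ratio of Vienna Pee Dee Belemnite for carbon
and the ¹⁵N/¹⁴N ratio of atmospheric N₂ for nitrogen.  This module houses
the reference constants, the δ ↔ ratio conversions, the record type used by
the rest of the package, the +1‰ δ¹³C correction for formalin-preserved
tissue, and delimited-text ingestion of consumer isotope tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_VPDB",
    "R_AIR_N2",
    "GUILDS",
    "LAYERS",
    "IsotopeConstants",
    "IsotopeRecord",
    "PreservationCorrection",
    "TableDialect",
    "delta_from_ratios",
    "ratio_from_delta",
    "formalin_correct",
    "read_isotope_table",
    "write_isotope_table",
    "records_to_frame",
]

#: 13C/12C of the Vienna Pee Dee Belemnite carbonate standard.
R_VPDB = 0.0112372
#: 15N/14N of atmospheric N2.
R_AIR_N2 = 0.0036765

#: Closed feeding-guild vocabulary: facultative filter/surface deposit
#: feeder, obligate filter feeder, predator/scavenger, subsurface deposit
#: feeder, obligate surface deposit feeder, plus an explicit unknown.
GUILDS = ("FF/SDF", "FF", "P/S", "SSDF", "SDF", "unknown")

#: Sediment horizons used in the sampling design.
LAYERS = ("0-5 cm", "5-10 cm", "pooled")

_R_REFERENCE = {"C": R_VPDB, "N": R_AIR_N2}

#: Required columns of a delimited consumer isotope table.
ISOTOPE_TABLE_COLUMNS = (
    "taxon",
    "site",
    "guild",
    "layer",
    "d13c",
    "d15n",
    "n_pooled",
    "preserved_formalin",
)


@dataclass(frozen=True)
class IsotopeConstants:
    """Fixed reference-standard isotope ratios (not configurable)."""

    r_vpdb: float = R_VPDB
    r_atm_n2: float = R_AIR_N2


@dataclass(frozen=True)
class TableDialect:
    """Dialect of delimited isotope/core tables (UTF-8, '.' decimals)."""

    delimiter: str = ","


@dataclass(frozen=True)
class PreservationCorrection:
    """Offsets added to formalin-preserved tissue signatures.

    Formalin preservation depletes tissue δ¹³C by about 1‰ while leaving
    δ¹⁵N unchanged, hence the defaults.
    """

    d13c_offset: float = 1.0
    d15n_offset: float = 0.0


@dataclass(frozen=True)
class IsotopeRecord:
    """One pooled-sample measurement of consumer tissue.

    Several individuals of the same taxon from one core are typically
    homogenised into a single sample (``n_pooled``).  ``corrected`` guards
    against applying the preservation correction twice.
    """

    taxon: str
    site: str
    d13c: float
    d15n: float
    guild: str = "unknown"
    layer: str = "pooled"
    n_pooled: int = 1
    preserved_formalin: bool = False
    corrected: bool = False
    row: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ValueError(
                f"non-finite isotope value for {self.taxon!r}: "
                f"d13c={self.d13c}, d15n={self.d15n}"
            )
        if self.n_pooled < 1:
            raise ValueError(f"n_pooled must be >= 1, got {self.n_pooled}")
        if self.guild not in GUILDS:
            raise ValueError(
                f"unknown guild {self.guild!r}; expected one of {GUILDS}"
            )


def delta_from_ratios(r_sample, element: str):
    """Convert an absolute isotope ratio to per-mil δ notation.

    Parameters
    ----------
    r_sample : float or array-like
        Heavy/light isotope ratio of the sample; must be positive.
    element : {"C", "N"}
        Which reference standard to use (VPDB or atmospheric N2).
    """
    r_ref = _r_reference(element)
    r = np.asarray(r_sample, dtype=float)
    if np.any(~(r > 0)):
        bad = r[~(r > 0)]
        raise ValueError(f"isotope ratio must be positive, got {bad.tolist()}")
    out = (r / r_ref - 1.0) * 1000.0
    return float(out) if np.isscalar(r_sample) else out


def ratio_from_delta(delta, element: str):
    """Inverse of :func:`delta_from_ratios`: per-mil δ back to a ratio."""
    r_ref = _r_reference(element)
    d = np.asarray(delta, dtype=float)
    out = (d / 1000.0 + 1.0) * r_ref
    return float(out) if np.isscalar(delta) else out


def _r_reference(element: str) -> float:
    try:
        return _R_REFERENCE[element]
    except KeyError:
        raise ValueError(f"element must be 'C' or 'N', got {element!r}") from None


def formalin_correct(
    records: Iterable[IsotopeRecord],
    correction: PreservationCorrection = PreservationCorrection(),
) -> list[IsotopeRecord]:
    """Apply the preservation correction to formalin-preserved records.

    Returns new records with δ¹³C shifted by ``d13c_offset`` (default +1‰)
    and δ¹⁵N by ``d15n_offset`` (default 0), marked ``corrected``.  Inputs
    are unchanged.  Raises if a record is not flagged as preserved or was
    already corrected, so the correction can never be applied twice or to
    unpreserved material (e.g. sediment samples).
    """
    out = []
    for rec in records:
        if not rec.preserved_formalin:
            raise ValueError(
                f"record for {rec.taxon!r} is not formalin-preserved; "
                "refusing to apply the preservation correction"
            )
        if rec.corrected:
            raise ValueError(
                f"record for {rec.taxon!r} is already corrected; "
                "the preservation correction is applied at most once"
            )
        out.append(
            replace(
                rec,
                d13c=rec.d13c + correction.d13c_offset,
                d15n=rec.d15n + correction.d15n_offset,
                corrected=True,
            )
        )
    return out


def read_isotope_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
) -> list[IsotopeRecord]:
    """Read a delimited consumer isotope table into records.

    The file must be UTF-8 with a header naming the required columns
    (``taxon, site, guild, layer, d13c, d15n, n_pooled,
    preserved_formalin``).  Unknown guild strings are mapped to
    ``"unknown"`` with a warning; row numbers are preserved for error
    reporting.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ISOTOPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")

    records: list[IsotopeRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, after the header line
        d13c = _parse_float(row["d13c"], path, rowno, "d13c")
        d15n = _parse_float(row["d15n"], path, rowno, "d15n")
        n_pooled = int(_parse_float(row["n_pooled"], path, rowno, "n_pooled"))
        guild = str(row["guild"]).strip()
        if guild not in GUILDS:
            warnings.warn(
                f"{path} row {rowno}: unknown guild {guild!r} mapped to 'unknown'",
                stacklevel=2,
            )
            guild = "unknown"
        records.append(
            IsotopeRecord(
                taxon=str(row["taxon"]).strip(),
                site=str(row["site"]).strip(),
                guild=guild,
                layer=str(row["layer"]).strip(),
                d13c=d13c,
                d15n=d15n,
                n_pooled=n_pooled,
                preserved_formalin=_parse_bool(row["preserved_formalin"]),
                row=rowno,
            )
        )
    return records


def _parse_float(cell, path, rowno: int, column: str) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ValueError(
            f"{path} row {rowno}, column {column!r}: "
            f"unparseable numeric value {cell!r}"
        ) from None


def _parse_bool(cell) -> bool:
    s = str(cell).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", "nan", ""}:
        return False
    raise ValueError(f"unparseable boolean value {cell!r}")


def records_to_frame(records: Sequence[IsotopeRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in the file-schema column order."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "site": r.site,
                "guild": r.guild,
                "layer": r.layer,
                "d13c": r.d13c,
                "d15n": r.d15n,
                "n_pooled": r.n_pooled,
                "preserved_formalin": r.preserved_formalin,
            }
            for r in records
        ],
        columns=list(ISOTOPE_TABLE_COLUMNS),
    )


def write_isotope_table(
    records: Sequence[IsotopeRecord],
    path: str | Path,
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write records back to the delimited schema of :func:`read_isotope_table`."""
    records_to_frame(records).to_csv(path, sep=dialect.delimiter, index=False)
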