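"""Reading, writing and matrix-level filtering of genotype data.

Supported formats:

* VCF v4.x (read, via :mod:`cyvcf2`): only the GT field is used, phased and
  unphased calls are treated identically, half-calls become missing, and
  multiallelic records are dropped with a logged count.
* tab-delimited 0/1/2 dosage matrix (read/write): header row of locus ids,
  first column of sample ids. ``NA``, ``.`` and ``-9`` are accepted as
  missing on read; ``NA`` is written.
* sample metadata CSV with headers ``sample,site,lat,lon,ecoregion``.
* occurrence-record CSV with headers ``year,lat,lon``.
"""

from __future__ import annotations

import datetime
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Missing-data tokens accepted in 0/1/2 matrices (common dialects).
MISSING_TOKENS = {"NA", ".", "-9", ""}

REQUIRED_METADATA_COLUMNS = ("sample", "site", "lat", "lon", "ecoregion")
REQUIRED_OCCURRENCE_COLUMNS = ("year", "lat", "lon")


class FileFormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


# --------------------------------------------------------------------- reads
def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format`` is ``"vcf"``, ``"matrix012"`` or ``"auto"`` (decided from the
    file suffix; ``.vcf``/``.vcf.gz`` means VCF, anything else the 0/1/2
    matrix dialect).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "matrix012"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix012":
        return _read_matrix012(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix012(path: Path) -> GenotypeMatrix:
    if os.path.getsize(path) == 0:
        raise FileFormatError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FileFormatError(f"{path}: could not parse 0/1/2 matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise FileFormatError(f"{path}: matrix has no locus columns")
    tokens = df.to_numpy()
    calls = np.full(tokens.shape, MISSING, dtype=np.int8)
    for tok, code in (("0", 0), ("1", 1), ("2", 2)):
        calls[tokens == tok] = code
    known = np.isin(tokens, ["0", "1", "2", *MISSING_TOKENS])
    if not known.all():
        bad = sorted(set(tokens[~known].tolist()))[:5]
        raise FileFormatError(f"{path}: unknown genotype tokens {bad}")
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if os.path.getsize(path) == 0:
        raise FileFormatError(f"{path}: empty file")
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FileFormatError(f"{path}: could not open VCF: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[str] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise FileFormatError(
                    f"{path}: non-diploid genotype at {var.CHROM}:{var.POS} sample "
                    f"{samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:  # half-calls / missing -> MISSING
                continue
            col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(name)
        columns.append(col)
    if n_multi:
        logger.info("dropped %d multiallelic VCF record(s)", n_multi)
    if not loci:
        raise FileFormatError(f"{path}: no biallelic records found")
    calls = np.column_stack(columns)
    return GenotypeMatrix(samples, loci, calls)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write ``g`` as a tab-delimited 0/1/2 matrix (missing written as NA)."""
    tokens = g.calls.astype(object)
    out = np.where(g.calls == MISSING, "NA", tokens.astype(str))
    df = pd.DataFrame(out, index=g.samples, columns=g.loci)
    df.to_csv(path, sep="\t", index_label="sample")


# ------------------------------------------------------------------- filters
def filter_individuals_by_missingness(
    g: GenotypeMatrix, max_missing_fraction: float = 0.75
) -> GenotypeMatrix:
    """Drop samples whose missing-call fraction is *strictly greater* than
    ``max_missing_fraction`` (a sample at exactly the threshold is retained).
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = g.missing_fraction()
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError(
            f"all {g.n_samples} samples exceed the missingness threshold "
            f"{max_missing_fraction}"
        )
    removed = [g.samples[i] for i in np.flatnonzero(~keep)]
    if removed:
        logger.info(
            "removed %d individual(s) with >%d%% missing data: %s",
            len(removed), round(100 * max_missing_fraction), ", ".join(removed),
        )
    return g.take_samples(keep)


def filter_loci_by_presence(
    g: GenotypeMatrix, min_presence_fraction: float = 0.10
) -> GenotypeMatrix:
    """Retain loci genotyped in *at least* ``min_presence_fraction`` of samples."""
    if not 0 < min_presence_fraction <= 1:
        raise ValueError("min_presence_fraction must be in (0, 1]")
    keep = g.locus_presence() >= min_presence_fraction
    if not keep.any():
        raise ValueError(
            f"all {g.n_loci} loci fall below the presence threshold "
            f"{min_presence_fraction}"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d locus/loci present in <%d%% of samples",
                    n_removed, round(100 * min_presence_fraction))
    return g.take_loci(keep)


def apply_matrix_filters(
    g: GenotypeMatrix,
    max_missing_fraction: float = 0.75,
    min_presence_fraction: float = 0.10,
) -> GenotypeMatrix:
    """Standard matrix-level cleanup: individuals first, then loci.

    The order is fixed (and matters): high-missingness individuals are removed
    before locus presence is assessed, so a locus's presence fraction is
    computed over the retained individuals only.
    """
    g = filter_individuals_by_missingness(g, max_missing_fraction)
    return filter_loci_by_presence(g, min_presence_fraction)


# ------------------------------------------------------------------ metadata
def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (sample, site, lat, lon, ecoregion).

    Rows with unparseable or out-of-range coordinates are rejected with their
    line numbers logged. Duplicate sample ids are an error.
    """
    df = pd.read_csv(path, dtype={"sample": str, "site": str, "ecoregion": str})
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FileFormatError(f"{path}: missing required column(s) {missing_cols}")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    ok = lat.between(-90, 90) & lon.between(-180, 180)
    if not ok.all():
        bad_lines = (df.index[~ok] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: rejected %d metadata row(s) with bad coordinates "
                       "(lines %s)", path, len(bad_lines), bad_lines)
    df = df.loc[ok].copy()
    df["lat"] = lat[ok]
    df["lon"] = lon[ok]
    dup = df["sample"].duplicated()
    if dup.any():
        raise FileFormatError(
            f"{path}: duplicate sample id(s) {sorted(df['sample'][dup].unique())}"
        )
    return df.reset_index(drop=True)[list(REQUIRED_METADATA_COLUMNS)]


def read_occurrences(path, year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read dated occurrence records (year, lat, lon).

    Rows with unparseable years/coordinates or a year outside ``year_range``
    (default 1800..current year) are rejected with logged line numbers.
    """
    if year_range is None:
        year_range = (1800, datetime.date.today().year)
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_OCCURRENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FileFormatError(f"{path}: missing required column(s) {missing_cols}")
    year = pd.to_numeric(df["year"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    ok = (
        year.notna() & (year == year.round()) & year.between(*year_range)
        & lat.between(-90, 90) & lon.between(-180, 180)
    )
    if not ok.all():
        bad_lines = (df.index[~ok] + 2).tolist()
        logger.warning("%s: rejected %d occurrence row(s) (lines %s)",
                       path, len(bad_lines), bad_lines)
    out = pd.DataFrame({
        "year": year[ok].astype(int),
        "lat": lat[ok],
        "lon": lon[ok],
    })
    return out.reset_index(drop=True)
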