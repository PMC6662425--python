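"""Per-locus and per-group diversity statistics for selfing populations.

Quantities
----------
Ho
    Observed heterozygosity: the fraction of non-missing calls that are
    heterozygous (dosage 1), averaged over loci.
He
    Expected (Hardy-Weinberg) heterozygosity ``2 p (1 - p)`` from the
    alternate-allele frequency ``p``, averaged over loci. No small-sample
    correction is applied by default (togglable).
Fis
    Multilocus inbreeding coefficient ``1 - mean(Ho) / mean(He)``.
S, T
    Selfing and outcrossing rates under equilibrium partial selfing:
    ``S = 2 Fis / (1 + Fis)`` and ``T = 1 - S``. The inverse relation is
    ``Fis = S / (2 - S)``.
private alleles
    Alleles (reference or alternate at a locus) observed in exactly one
    cluster and in no other, counted over non-missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LocusFrequencies:
    """Per-locus alternate-allele frequency, MAF and call counts.

    ``p`` is ``nan`` at loci with no non-missing call in the subset; such
    loci are flagged by ``defined``.
    """

    p: np.ndarray
    n_called: np.ndarray

    @property
    def maf(self) -> np.ndarray:
        return np.fmin(self.p, 1.0 - self.p)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.p)


@dataclass
class MeanSE:
    """Mean over loci with its standard error (sd / sqrt(#loci))."""

    mean: float
    se: float
    n_loci: int


def _subset_calls(g: GenotypeMatrix, samples) -> np.ndarray:
    if samples is None:
        return g.calls
    samples = np.asarray(samples)
    if samples.dtype == bool:
        samples = np.flatnonzero(samples)
    if samples.size == 0:
        raise ValueError("empty sample subset")
    return g.calls[samples, :]


def allele_frequencies(g: GenotypeMatrix, samples=None) -> LocusFrequencies:
    """Alternate-allele frequency per locus over non-missing calls.

    ``p = (sum of dosages) / (2 * number of non-missing calls)``.
    """
    calls = _subset_calls(g, samples)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    dose = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose / (2.0 * n_called), np.nan)
    if (n_called == 0).any():
        logger.warning("%d locus/loci with no calls in subset; frequency undefined",
                       int((n_called == 0).sum()))
    return LocusFrequencies(p=p, n_called=n_called)


def flag_rare_variants(freqs: LocusFrequencies, threshold: float = 0.10) -> np.ndarray:
    """Boolean per-locus flag: ``0 < MAF < threshold``.

    Monomorphic loci (MAF = 0) and loci with undefined frequency are never
    flagged as rare.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    maf = freqs.maf
    with np.errstate(invalid="ignore"):
        return np.where(freqs.defined, (maf > 0) & (maf < threshold), False)


def _mean_se(values: np.ndarray) -> MeanSE:
    defined = ~np.isnan(values)
    n = int(defined.sum())
    if n == 0:
        return MeanSE(np.nan, np.nan, 0)
    v = values[defined]
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return MeanSE(float(v.mean()), se, n)


def observed_heterozygosity(
    g: GenotypeMatrix, samples=None, include_monomorphic: bool = True
) -> tuple[np.ndarray, MeanSE]:
    """Per-locus observed heterozygosity and its mean (+/- SE) over loci."""
    calls = _subset_calls(g, samples)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het / n_called, np.nan)
    if not include_monomorphic:
        freqs = LocusFrequencies(
            p=np.where(n_called > 0,
                       np.where(called, calls, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1)),
                       np.nan),
            n_called=n_called,
        )
        ho = np.where(freqs.maf > 0, ho, np.nan)
    return ho, _mean_se(ho)


def expected_heterozygosity(
    freqs: LocusFrequencies,
    unbiased: bool = False,
    include_monomorphic: bool = True,
) -> tuple[np.ndarray, MeanSE]:
    """Per-locus expected heterozygosity ``2 p (1 - p)`` and mean (+/- SE).

    With ``unbiased=True`` the ``2n / (2n - 1)`` small-sample correction is
    applied (``n`` = diploid call count per locus).
    """
    he = 2.0 * freqs.p * (1.0 - freqs.p)
    if unbiased:
        two_n = 2.0 * freqs.n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(two_n > 1, he * two_n / (two_n - 1.0), np.nan)
    if not include_monomorphic:
        he = np.where(freqs.maf > 0, he, np.nan)
    return he, _mean_se(he)


def inbreeding_coefficient(ho_mean: float, he_mean: float) -> float:
    """Multilocus Fis = 1 - mean(Ho) / mean(He), clamped to [-1, 1].

    Returns ``nan`` (flagged via a warning) when mean He is 0.
    """
    if not np.isfinite(he_mean) or he_mean == 0:
        logger.warning("mean He is zero or undefined; Fis undefined")
        return np.nan
    fis = 1.0 - ho_mean / he_mean
    if fis < -1 or fis > 1:
        logger.warning("Fis %.4f outside [-1, 1]; clamped", fis)
        fis = float(np.clip(fis, -1.0, 1.0))
    return float(fis)


def selfing_rate(fis):
    """Equilibrium selfing rate S = 2 Fis / (1 + Fis); requires Fis > -1.

    Negative Fis yields a negative S, which is reported with a warning
    (heterozygote excess is incompatible with equilibrium selfing).
    """
    fis = np.asarray(fis, dtype=float)
    if np.any(fis <= -1):
        raise ValueError("selfing rate undefined at Fis <= -1")
    s = 2.0 * fis / (1.0 + fis)
    if np.any(s < 0):
        logger.warning("negative Fis yields negative selfing rate")
    return float(s) if s.ndim == 0 else s


def outcrossing_rate(fis):
    """Outcrossing rate T = 1 - S = (1 - Fis) / (1 + Fis)."""
    s = selfing_rate(fis)
    return 1.0 - s


def fis_from_selfing(s):
    """Inverse of :func:`selfing_rate`: equilibrium Fis = S / (2 - S)."""
    s = np.asarray(s, dtype=float)
    fis = s / (2.0 - s)
    return float(fis) if fis.ndim == 0 else fis


def private_alleles(g: GenotypeMatrix, assignment) -> dict[str, int]:
    """Count alleles private to each cluster.

    An allele (ref or alt at a locus) is private to cluster ``c`` iff it is
    observed among ``c``'s non-missing calls and unobserved in every other
    cluster. With a single cluster every observed allele is vacuously private.

    ``assignment`` maps every sample to exactly one cluster label (array-like
    of length ``n_samples``); unassigned samples are an error.
    """
    labels = np.asarray(assignment, dtype=object)
    if labels.shape != (g.n_samples,):
        raise ValueError("assignment must give one label per sample")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValueError("every sample must be assigned to a cluster")
    clusters = sorted(set(labels.tolist()), key=str)
    called = g.called
    alt_obs = np.zeros((len(clusters), g.n_loci), dtype=bool)
    ref_obs = np.zeros((len(clusters), g.n_loci), dtype=bool)
    for ci, c in enumerate(clusters):
        rows = labels == c
        sub = g.calls[rows, :]
        sub_called = called[rows, :]
        alt_obs[ci] = ((sub >= 1) & sub_called).any(axis=0)
        ref_obs[ci] = ((sub <= 1) & sub_called).any(axis=0)
    counts: dict[str, int] = {}
    for ci, c in enumerate(clusters):
        others = np.ones(len(clusters), dtype=bool)
        others[ci] = False
        alt_private = alt_obs[ci] & ~alt_obs[others].any(axis=0)
        ref_private = ref_obs[ci] & ~ref_obs[others].any(axis=0)
        counts[c] = int(alt_private.sum() + ref_private.sum())
    return counts


def diversity_summary(
    g: GenotypeMatrix,
    assignment,
    include_monomorphic: bool = True,
    unbiased_he: bool = False,
) -> pd.DataFrame:
    """Per-group summary table: n, Ho, He (with SEs), Fis, S, T, private alleles.

    One row per group label in ``assignment``, mirroring the classic
    per-cluster diversity table layout.
    """
    labels = np.asarray(assignment, dtype=object)
    privates = private_alleles(g, labels)
    rows = []
    for group in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == group)
        freqs = allele_frequencies(g, idx)
        _, ho = observed_heterozygosity(g, idx, include_monomorphic=include_monomorphic)
        _, he = expected_heterozygosity(
            freqs, unbiased=unbiased_he, include_monomorphic=include_monomorphic
        )
        fis = inbreeding_coefficient(ho.mean, he.mean)
        s = selfing_rate(fis) if np.isfinite(fis) else np.nan
        rows.append({
            "group": group,
            "n": len(idx),
            "Ho": ho.mean, "Ho_se": ho.se,
            "He": he.mean, "He_se": he.se,
            "Fis": fis,
            "S": s,
            "T": 1.0 - s if np.isfinite(s) else np.nan,
            "private": privates[group],
        })
    return pd.DataFrame(rows).set_index("group")
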