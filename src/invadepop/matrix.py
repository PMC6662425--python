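"""Core genotype container.

Genotypes are biallelic diploid calls coded as the dosage of the alternate
allele (0, 1 or 2); missing calls are coded with :data:`MISSING` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing diploid call.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass(eq=False)
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers (length ``n``).
    loci
        Ordered, unique locus identifiers (length ``L``).
    calls
        ``(n, L)`` integer array with entries in ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.loci = [str(l) for l in self.loci]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus ids must be unique")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; expected 0/1/2/{MISSING}")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    # ----------------------------------------------------------------- access
    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, shape ``(n, L)``."""
        return self.calls != MISSING

    def dosages(self) -> np.ndarray:
        """Float copy of the calls with missing entries as ``nan``."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def locus_presence(self) -> np.ndarray:
        """Per-locus fraction of samples with a non-missing call."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.calls != MISSING).mean(axis=0)

    # --------------------------------------------------------------- subsets
    def take_samples(self, index) -> "GenotypeMatrix":
        """New matrix restricted to samples at integer or boolean ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], list(self.loci), self.calls[index, :]
        )

    def take_loci(self, index) -> "GenotypeMatrix":
        """New matrix restricted to loci at integer or boolean ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.samples), [self.loci[j] for j in index], self.calls[:, index]
        )

    def sample_index(self, ids) -> np.ndarray:
        """Integer positions of the given sample ids (order preserved)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[str(s)] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc}") from None

    # -------------------------------------------------------------- equality
    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )
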