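"""Allele-dosage genotype container shared by all pipeline stages.

Genotypes are biallelic SNPs stored as counts (0, 1, 2) of the counted
allele per individual, with ``NaN`` marking a missing call.  The counted
allele is, by convention, the second most frequent one, so a dosage of 0
is the common homozygote and 2 the rare homozygote; :mod:`cloneval.relmat`
re-anchors the coding when frequencies say otherwise.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["GenotypeMatrix"]


class GenotypeMatrix:
    """Individuals x markers dosage matrix with a missingness mask.

    Parameters
    ----------
    dosages:
        Array of shape ``(n_samples, n_markers)`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing calls.
    samples, markers:
        Identifier sequences for rows and columns.
    alleles:
        Optional ``(n_markers, 2)`` array of allele labels ordered as
        (counted allele, other allele).  Used to harmonise panels typed
        on opposite reference alleles.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: Sequence[str],
        markers: Sequence[str],
        alleles: Optional[np.ndarray] = None,
    ) -> None:
        dosages = np.array(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array (samples x markers)")
        samples = np.asarray(list(samples), dtype=object)
        markers = np.asarray(list(markers), dtype=object)
        if dosages.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker identifiers")
        if alleles is not None:
            alleles = np.asarray(alleles, dtype=object)
            if alleles.shape != (len(markers), 2):
                raise ValueError("alleles must have shape (n_markers, 2)")
        self.dosages = dosages
        self.samples = samples
        self.markers = markers
        self.alleles = alleles
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._marker_index = {m: j for j, m in enumerate(markers)}

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample identifier {exc.args[0]!r}") from None

    def marker_indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._marker_index[m] for m in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown marker identifier {exc.args[0]!r}") from None

    # ------------------------------------------------------------------
    def marker_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return np.isfinite(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return np.isfinite(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return freq

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with per-marker mean imputation of missing calls."""
        out = self.dosages.copy()
        miss = ~np.isfinite(out)
        if miss.any():
            col_mean = np.where(
                np.isfinite(self.allele_freq()), 2.0 * self.allele_freq(), 0.0
            )
            out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out

    # ------------------------------------------------------------------
    def subset(
        self,
        samples: Optional[Sequence[str]] = None,
        markers: Optional[Sequence[str]] = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given samples/markers, preserving the order asked for."""
        si = self.sample_indices(samples) if samples is not None else np.arange(self.n_samples)
        mi = self.marker_indices(markers) if markers is not None else np.arange(self.n_markers)
        alleles = self.alleles[mi] if self.alleles is not None else None
        return GenotypeMatrix(
            self.dosages[np.ix_(si, mi)], self.samples[si], self.markers[mi], alleles
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            self.samples.copy(),
            self.markers.copy(),
            None if self.alleles is None else self.alleles.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"
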