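"""Allele-frequency inference for dominant markers under inbreeding.

A dominant band masks the heterozygote: only the band-absent (00) phenotype
identifies a genotype unambiguously.  Writing ``p`` for the frequency of the
recessive '0' allele and ``F`` for the inbreeding coefficient, the
band-absence phenotype frequency is

    f00 = (1 - F) p**2 + F p

which is inverted per population and marker by taking the admissible root of
the quadratic.  The default ``F = -0.14`` reflects heterozygote excess
(negative inbreeding) typical of outcrossing trees; it must be supplied from
independent codominant data, it is not estimable from the bands themselves.

Absolute allele counts (``count0 + count1 = 2n``) are obtained by rounding
``2 n p`` to the nearest integer (half up) and are the currency of all
downstream F-statistics and outlier scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BandMatrix, MISSING

#: default inbreeding coefficient (heterozygote excess)
DEFAULT_FIS = -0.14


@dataclass
class FreqTable:
    """Per-population, per-marker inferred allele frequencies and counts.

    Arrays are shaped ``(n_populations, n_markers)``.  ``f00`` and ``p`` are
    NaN where a population has no non-missing call for a marker; ``count0``
    and ``count1`` are -1 there.
    """

    populations: list
    markers: list
    n: np.ndarray        # diploid sample size with non-missing calls
    f00: np.ndarray
    p: np.ndarray        # recessive '0' allele frequency
    count0: np.ndarray
    count1: np.ndarray
    fis: float = DEFAULT_FIS

    @property
    def n_alleles(self) -> np.ndarray:
        """Gene copies per population/marker (2n)."""
        return 2 * self.n

    def restrict(self, populations) -> "FreqTable":
        idx = [self.populations.index(p) for p in populations]
        return FreqTable(list(populations), list(self.markers),
                         self.n[idx], self.f00[idx], self.p[idx],
                         self.count0[idx], self.count1[idx], self.fis)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pop in enumerate(self.populations):
            rows.append(pd.DataFrame({
                "population": pop,
                "marker": self.markers,
                "f00": self.f00[i],
                "n": self.n[i],
                "p": self.p[i],
                "count0": self.count0[i],
                "count1": self.count1[i],
            }))
        return pd.concat(rows, ignore_index=True)


def band_absence_freq(bands: BandMatrix, samples: pd.DataFrame,
                      by=("site", "habitat")):
    """Band-absence phenotype frequency and sample size per population.

    Populations are the cells of the ``by`` grouping of the sample table
    (default site x habitat).  Returns ``(populations, f00, n)`` where both
    arrays are (n_pops, n_markers); ``f00`` is NaN for all-missing cells.
    """
    samples = samples.set_index("sample_id").loc[bands.sample_ids]
    if isinstance(by, str):
        by = (by,)
    keys = samples[list(by)].astype(str).agg(":".join, axis=1).to_numpy()
    populations = sorted(set(keys))
    f00 = np.empty((len(populations), bands.n_markers))
    n = np.zeros((len(populations), bands.n_markers), dtype=int)
    absent, scored = bands.absent, bands.scored
    for i, pop in enumerate(populations):
        rows = keys == pop
        if not rows.any():
            raise ValueError(f"empty population cell {pop!r}")
        n[i] = scored[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f00[i] = absent[rows].sum(axis=0) / n[i]
    return populations, f00, n


def infer_null_allele_freq(f00, fis: float = DEFAULT_FIS):
    """Invert f00 = (1-F) p^2 + F p for the '0' allele frequency p.

    Takes the larger quadratic root, the unique root compatible with a
    nonnegative genotype frequency when F < 0:

        p = (-F + sqrt(F^2 + 4 (1-F) f00)) / (2 (1-F))

    clamped into [0, 1].  NaN entries propagate.
    """
    if fis >= 1.0:
        raise ValueError("F_IS = 1 makes the genotype equation degenerate")
    f00 = np.asarray(f00, dtype=float)
    disc = fis * fis + 4.0 * (1.0 - fis) * f00
    with np.errstate(invalid="ignore"):
        assert not (disc < 0).any(), "negative discriminant for f00 >= 0"
        p = (-fis + np.sqrt(disc)) / (2.0 * (1.0 - fis))
    return np.clip(p, 0.0, 1.0)


def band_phenotype_freq(p, fis: float = DEFAULT_FIS):
    """Forward map: band-absence phenotype frequency from allele frequency."""
    p = np.asarray(p, dtype=float)
    return (1.0 - fis) * p * p + fis * p


def allele_counts(p, n):
    """Absolute allele counts from relative frequency and diploid sample size.

    ``count0 = round(2 n p)`` with half-up rounding; ``count1 = 2n - count0``.
    NaN frequencies give counts of -1.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n)
    total = 2 * n
    with np.errstate(invalid="ignore"):
        c0 = np.floor(total * p + 0.5)
    c0 = np.where(np.isnan(p) | (total == 0), -1, c0).astype(int)
    c1 = np.where(c0 >= 0, total - c0, -1).astype(int)
    return c0, c1


def compute_freq_table(bands: BandMatrix, samples: pd.DataFrame,
                       fis: float = DEFAULT_FIS, by=("site", "habitat")
                       ) -> FreqTable:
    """Full inference path: bands -> f00 -> p -> absolute counts per population."""
    populations, f00, n = band_absence_freq(bands, samples, by=by)
    p = infer_null_allele_freq(f00, fis)
    c0, c1 = allele_counts(p, n)
    return FreqTable(populations, list(bands.marker_ids), n, f00, p, c0, c1, fis)


def freq_table_from_counts(populations, markers, count0, n, fis=DEFAULT_FIS
                           ) -> FreqTable:
    """Build a FreqTable directly from '0'-allele counts (e.g. simulated)."""
    count0 = np.asarray(count0, dtype=int)
    n = np.asarray(n, dtype=int)
    total = 2 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, count0 / total, np.nan)
    return FreqTable(list(populations), list(markers), n,
                     band_phenotype_freq(p, fis), p, count0, total - count0, fis)
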