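"""Spatial genetic structure: kinship, autocorrelograms, Sp and gene dispersal.

Pairwise kinship for dominant markers uses a conditional-dosage plug-in: for
each individual and locus the expected dosage of the band-presence allele is
computed given the phenotype, the population allele frequency and a prior
inbreeding coefficient, and plugged into a Loiselle-type ratio estimator

    F_ij = sum_l (x_il/2 - q_l)(x_jl/2 - q_l) / sum_l q_l (1 - q_l)

with sums over loci co-scored in both individuals and q_l the band-presence
allele frequency of the reference population.  Kinship is then summarised as
a distance-class autocorrelogram with permutation envelopes, the regression
slope b of F_ij on (log) distance with a delete-one-locus jackknife SE, the
SGS intensity Sp = b / (F(1) - 1), and an iterative neighborhood-size /
dispersal estimate in the Wright framework Nb = 4 pi De sigma^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqs import FreqTable
from .io import BandMatrix, PairwiseMatrix


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipDecomposition:
    """Per-locus building blocks of the multilocus kinship ratio estimator.

    ``centered`` holds ``x_il/2 - q_l`` (0 where missing), ``mask`` the
    non-missing indicator and ``weights`` the per-locus denominator term
    ``q_l (1 - q_l)``.  The pairwise numerator is ``centered @ centered.T``;
    keeping the per-locus factorisation allows exact delete-one-locus
    jackknifing without recomputation.
    """

    sample_ids: list
    centered: np.ndarray   # (n_samples, n_loci)
    mask: np.ndarray       # (n_samples, n_loci) bool
    weights: np.ndarray    # (n_loci,)

    def matrix(self) -> PairwiseMatrix:
        num = self.centered @ self.centered.T
        mw = self.mask * self.weights
        den = mw @ self.mask.T
        with np.errstate(invalid="ignore", divide="ignore"):
            f = num / den
        f[den <= 0] = np.nan
        np.fill_diagonal(f, np.nan)
        return PairwiseMatrix(list(self.sample_ids), f, metric="kinship")


def dominant_kinship(bands: BandMatrix, freqs: FreqTable,
                     fis: float | None = None) -> KinshipDecomposition:
    """Conditional-dosage kinship components for dominant band phenotypes.

    ``freqs`` must contain a single reference population (typically the whole
    site the samples come from).  Band-absent individuals carry dosage 0 of
    the band allele; band-present individuals carry the conditional
    expectation (2 f11 + f10) / (f11 + f10) under inbreeding coefficient
    ``fis`` (defaults to the one stored in ``freqs``).  Monomorphic loci get
    zero weight and drop out of the ratio.
    """
    if len(freqs.populations) != 1:
        raise ValueError("kinship needs a single reference population; "
                         "compute the FreqTable with by='site' or restrict it")
    if fis is None:
        fis = freqs.fis
    if list(freqs.markers) != list(bands.marker_ids):
        raise ValueError("freqs and bands disagree on markers")
    p = freqs.p[0]
    q = 1.0 - p
    f11 = np.clip((1.0 - fis) * q * q + fis * q, 0.0, None)
    f10 = np.clip(2.0 * (1.0 - fis) * p * q, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_present = (2.0 * f11 + f10) / (f11 + f10)
    w = q * (1.0 - q)
    poly = np.isfinite(w) & (w > 0) & np.isfinite(x_present)
    mask = bands.scored & poly
    dosage = np.where(bands.present, x_present, 0.0)
    centered = np.where(mask, dosage / 2.0 - q, 0.0)
    return KinshipDecomposition(list(bands.sample_ids), centered, mask,
                                np.where(poly, w, 0.0))


def dominant_kinship_matrix(bands: BandMatrix, freqs: FreqTable,
                            fis: float | None = None) -> PairwiseMatrix:
    """Multilocus pairwise kinship F_ij (see :func:`dominant_kinship`)."""
    return dominant_kinship(bands, freqs, fis).matrix()


# ---------------------------------------------------------------------------
# distances and classes
# ---------------------------------------------------------------------------

def pair_distances(coords: np.ndarray, jitter: float = 0.1, rng=None):
    """Euclidean distances for all unordered pairs; duplicate coordinates are
    jittered by ``jitter`` meters with a warning (zero distances break the
    log-distance regression)."""
    coords = np.asarray(coords, dtype=float)
    iu, ju = np.triu_indices(len(coords), k=1)
    d = np.hypot(*(coords[iu] - coords[ju]).T)
    if (d == 0).any():
        warnings.warn(f"{int((d == 0).sum())} coincident pair(s); "
                      f"jittering coordinates by {jitter} m")
        rng = np.random.default_rng(rng)
        coords = coords + rng.uniform(-jitter, jitter, coords.shape)
        d = np.hypot(*(coords[iu] - coords[ju]).T)
    return iu, ju, d


def build_distance_classes(coords, n_classes: int = 20, dmax: float = 500.0):
    """Evenly spaced distance-class bounds 0..dmax (left-open, right-closed)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 samples")
    _, _, d = pair_distances(coords)
    if (d == 0).all():
        raise ValueError("all pairwise distances are zero")
    return np.linspace(0.0, dmax, n_classes + 1)


def assign_classes(d, bounds):
    """Class index per pair (0-based); -1 for pairs beyond the last bound.

    Classes are left-open right-closed: a pair at exactly a bound belongs to
    the class ending there.
    """
    idx = np.searchsorted(bounds, d, side="left") - 1
    idx[d > bounds[-1]] = -1
    idx[d <= bounds[0]] = 0
    return idx


# ---------------------------------------------------------------------------
# correlogram
# ---------------------------------------------------------------------------

@dataclass
class SGSCorrelogram:
    bounds: np.ndarray
    mean_f: np.ndarray          # per class
    pair_count: np.ndarray
    envelope_lo: np.ndarray | None
    envelope_hi: np.ndarray | None
    f1: float
    b: float = np.nan
    b_se: float = np.nan
    sp: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "d_lo": self.bounds[:-1], "d_hi": self.bounds[1:],
            "mean_fij": self.mean_f, "n_pairs": self.pair_count})
        if self.envelope_lo is not None:
            df["env_lo"] = self.envelope_lo
            df["env_hi"] = self.envelope_hi
        return df


def autocorrelogram(kinship: PairwiseMatrix, coords, bounds,
                    n_perm: int = 1000, seed=None) -> SGSCorrelogram:
    """Distance-class kinship means with permutation envelopes.

    The null envelope (2.5% / 97.5% quantiles of per-class means) is built by
    permuting individuals among geographical locations, i.e. shuffling the
    coordinate assignment while keeping the kinship matrix fixed.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(kinship.sample_ids)
    if len(coords) != n:
        raise ValueError("kinship and coordinates not aligned")
    iu, ju, d = pair_distances(coords)
    fvals = kinship.values[iu, ju]
    cls = assign_classes(d, bounds)
    n_classes = len(bounds) - 1

    def class_means(class_idx):
        ok = (class_idx >= 0) & np.isfinite(fvals)
        cnt = np.bincount(class_idx[ok], minlength=n_classes)
        s = np.bincount(class_idx[ok], weights=fvals[ok], minlength=n_classes)
        with np.errstate(invalid="ignore", divide="ignore"):
            return s / cnt, cnt

    mean_f, cnt = class_means(cls)
    lo = hi = None
    if n_perm:
        rng = np.random.default_rng(seed)
        # precompute class matrix once; permuting locations == permuting the
        # rows/cols of the pair->class lookup
        cmat = np.full((n, n), -1, dtype=np.int32)
        cmat[iu, ju] = cls
        cmat[ju, iu] = cls
        perm_means = np.empty((n_perm, n_classes))
        for k in range(n_perm):
            perm = rng.permutation(n)
            pcls = cmat[np.ix_(perm, perm)][iu, ju]
            perm_means[k], _ = class_means(pcls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(perm_means, 2.5, axis=0)
            hi = np.nanpercentile(perm_means, 97.5, axis=0)
    f1 = float(mean_f[0]) if cnt[0] else float("nan")
    return SGSCorrelogram(np.asarray(bounds, float), mean_f, cnt, lo, hi, f1)


# ---------------------------------------------------------------------------
# regression slope, Sp, dispersal
# ---------------------------------------------------------------------------

def _ols_slope(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def kinship_distance_slope(decomp: KinshipDecomposition, coords,
                           scale: str = "linear", dmin: float = 1e-9,
                           dmax: float | None = None,
                           distance_range: tuple | None = None):
    """OLS slope b of pairwise kinship on (log) distance, jackknife SE.

    The SE deletes one locus at a time, recomputes the multilocus F_ij and the
    slope exactly (using the per-locus factorisation), and applies the usual
    jackknife variance ((L-1)/L) * sum (b_(l) - mean)^2.

    ``distance_range = (lo, hi)`` restricts the regression to pairs with
    lo < d <= hi (used by the iterative dispersal estimator).
    """
    coords = np.asarray(coords, dtype=float)
    iu, ju, d = pair_distances(coords)
    num = (decomp.centered @ decomp.centered.T)[iu, ju]
    mw = decomp.mask * decomp.weights
    den = (mw @ decomp.mask.T)[iu, ju]
    sel = den > 0
    if dmax is not None:
        sel &= d <= dmax
    if distance_range is not None:
        sel &= (d > distance_range[0]) & (d <= distance_range[1])
    if scale == "log":
        sel &= d > dmin
    if sel.sum() < 3:
        raise ValueError("fewer than 3 pairs available for the regression")
    x = np.log(d[sel]) if scale == "log" else d[sel]
    f = num[sel] / den[sel]
    b = _ols_slope(x, f)

    loci = np.where(decomp.weights > 0)[0]
    if len(loci) < 2:
        raise ValueError("jackknife needs at least 2 polymorphic loci")
    C = decomp.centered[:, loci]
    M = decomp.mask[:, loci]
    w = decomp.weights[loci]
    ii, jj = iu[sel], ju[sel]
    b_loo = np.empty(len(loci))
    for k in range(len(loci)):
        num_l = C[ii, k] * C[jj, k]
        den_l = w[k] * (M[ii, k] & M[jj, k])
        dden = den[sel] - den_l
        with np.errstate(invalid="ignore", divide="ignore"):
            f_l = (num[sel] - num_l) / dden
        ok = dden > 0
        b_loo[k] = _ols_slope(x[ok], f_l[ok])
    L = len(loci)
    se = float(np.sqrt((L - 1) / L * ((b_loo - b_loo.mean()) ** 2).sum()))
    return b, se


def sp_statistic(b: float, f1: float) -> float:
    """SGS intensity Sp = b / (F(1) - 1)."""
    if f1 == 1:
        raise ValueError("F(1) = 1 makes Sp undefined")
    return b / (f1 - 1.0)


@dataclass
class DispersalEstimate:
    D: float
    De: float
    Nb: float
    sigma_g: float
    iterations: int
    converged: bool
    b_restricted: float = np.nan


def neighborhood_size(b: float, f1: float) -> float:
    """First-iterate neighborhood size Nb = -(1 - F1) / b (log-scale slope)."""
    return -(1.0 - f1) / b


def sigma_from_nb(nb: float, de: float) -> float:
    """Gene dispersal sigma = sqrt(Nb / (4 pi De))."""
    return float(np.sqrt(nb / (4.0 * np.pi * de)))


def dispersal_estimate(decomp: KinshipDecomposition, coords, b: float,
                       f1: float, D: float, ratio_de: float = 0.5,
                       max_iter: int = 20, tol: float = 1e-3
                       ) -> DispersalEstimate:
    """Iterative SPAGeDi-style neighborhood-size / dispersal estimate.

    Starting from Nb0 = -(1 - F1)/b (b the log-distance slope), sigma is
    solved from Nb = 4 pi De sigma^2 with effective density De = ratio_de * D,
    then b is re-estimated restricting pairs to distances in (sigma, 20 sigma)
    and the cycle repeats until sigma moves less than ``tol`` meters.  A
    nonnegative slope at any stage flags non-convergence.
    """
    if D <= 0:
        raise ValueError("census density must be positive")
    de = ratio_de * D
    if b >= 0 or f1 >= 1:
        return DispersalEstimate(D, de, np.nan, np.nan, 0, False)
    nb = neighborhood_size(b, f1)
    sigma = sigma_from_nb(nb, de)
    b_r = b
    for it in range(1, max_iter + 1):
        try:
            b_r, _ = kinship_distance_slope(decomp, coords, scale="log",
                                            distance_range=(sigma, 20.0 * sigma))
        except ValueError:
            return DispersalEstimate(D, de, nb, sigma, it, False, b_r)
        if b_r >= 0:
            return DispersalEstimate(D, de, nb, sigma, it, False, b_r)
        nb = neighborhood_size(b_r, f1)
        new_sigma = sigma_from_nb(nb, de)
        if abs(new_sigma - sigma) < tol:
            return DispersalEstimate(D, de, nb, new_sigma, it, True, b_r)
        sigma = new_sigma
    return DispersalEstimate(D, de, nb, sigma, max_iter, False, b_r)


def sgs_analysis(bands: BandMatrix, freqs: FreqTable, coords,
                 n_classes: int = 20, dmax: float = 500.0,
                 n_perm: int = 1000, slope_scale: str = "linear",
                 seed=None) -> SGSCorrelogram:
    """Correlogram + slope + Sp in one pass for a single site."""
    decomp = dominant_kinship(bands, freqs)
    bounds = build_distance_classes(coords, n_classes=n_classes, dmax=dmax)
    corr = autocorrelogram(decomp.matrix(), coords, bounds, n_perm=n_perm,
                           seed=seed)
    corr.b, corr.b_se = kinship_distance_slope(decomp, coords, scale=slope_scale)
    corr.sp = sp_statistic(corr.b, corr.f1)
    return corr
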