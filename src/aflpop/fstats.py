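"""F-statistics from inferred allele counts.

All estimators work on absolute allele counts per population (two allelic
states), the quantity the dominant-marker inference path produces.  The
two-level estimator is the classical AMOVA variance decomposition with
pairwise-difference distance between alleles, equivalent to a
Weir-Cockerham-type theta on biallelic gene copies; the hierarchical version
adds an among-groups level (F_CT, F_SC, F_ST) with the usual nested ANOVA
coefficients for unbalanced designs.

Permutation significance follows the standard schemes: gene copies shuffled
between populations (F_ST), populations shuffled across groups (F_CT), and
gene copies shuffled across populations within groups (F_SC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .freqs import FreqTable
from .io import BandMatrix


# ---------------------------------------------------------------------------
# two-level decomposition
# ---------------------------------------------------------------------------

def amova_components(count0: np.ndarray, n_alleles: np.ndarray):
    """Two-level AMOVA variance components per locus.

    Parameters
    ----------
    count0 : (n_pops, n_loci) '0'-allele counts (-1 = missing).
    n_alleles : (n_pops, n_loci) gene copies per population (2n).

    Returns
    -------
    sigma_a, sigma_w : (n_loci,) among- and within-population components.
    Loci monomorphic over all populations (or with < 2 scored populations)
    are NaN.
    """
    count0 = np.asarray(count0, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    ok = count0 >= 0
    n = np.where(ok, n, 0.0)
    count0 = np.where(ok, count0, 0.0)
    K = ok.sum(axis=0)
    N = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, count0 / n, 0.0)
        pbar = count0.sum(axis=0) / N
        ss_within = (n * p * (1.0 - p)).sum(axis=0)
        ss_total = N * pbar * (1.0 - pbar)
        ss_among = ss_total - ss_within
        ms_within = ss_within / (N - K)
        ms_among = ss_among / (K - 1)
        n_c = (N - (n * n).sum(axis=0) / N) / (K - 1)
        sigma_a = (ms_among - ms_within) / n_c
    bad = (K < 2) | (ss_total <= 0) | (N <= K)
    sigma_a = np.where(bad, np.nan, sigma_a)
    sigma_w = np.where(bad, np.nan, ms_within)
    return sigma_a, sigma_w


def fst_from_components(sigma_a, sigma_w):
    with np.errstate(invalid="ignore", divide="ignore"):
        return sigma_a / (sigma_a + sigma_w)


def multilocus_fst(sigma_a, sigma_w) -> float:
    """Ratio-of-sums multilocus F_ST over loci with defined components."""
    ok = np.isfinite(sigma_a) & np.isfinite(sigma_w)
    if not ok.any():
        return float("nan")
    return float(sigma_a[ok].sum() / (sigma_a[ok] + sigma_w[ok]).sum())


@dataclass
class PairwiseFstResult:
    markers: list
    fst: np.ndarray          # per locus
    fst_multilocus: float
    p_values: np.ndarray | None = None
    p_multilocus: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker": self.markers, "fst": self.fst})
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df


def pairwise_fst(freqs: FreqTable, n_perm: int = 1000, seed=None
                 ) -> PairwiseFstResult:
    """Per-locus and multilocus F_ST between exactly two populations.

    P-values come from shuffling gene copies between the two populations
    (conditioning on per-locus allele totals, a hypergeometric redraw), with
    the add-one rule so p is never exactly 0.
    """
    if len(freqs.populations) != 2:
        raise ValueError("pairwise_fst needs a FreqTable with exactly 2 populations")
    c0, n2 = freqs.count0, freqs.n_alleles
    sigma_a, sigma_w = amova_components(c0, n2)
    fst = fst_from_components(sigma_a, sigma_w)
    ml = multilocus_fst(sigma_a, sigma_w)
    pvals = pml = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ok = (c0 >= 0).all(axis=0)
        tot0 = c0[:, ok].sum(axis=0)
        n1, ntot = n2[0, ok], n2[:, ok].sum(axis=0)
        obs = fst[ok]
        exceed = np.zeros(ok.sum())
        ml_exceed = 0
        for _ in range(n_perm):
            c0p = rng.hypergeometric(tot0, ntot - tot0, n1)
            perm0 = np.vstack([c0p, tot0 - c0p])
            sa, sw = amova_components(perm0, n2[:, ok])
            f = fst_from_components(sa, sw)
            with np.errstate(invalid="ignore"):
                exceed += (f >= obs) | np.isnan(obs)
            if multilocus_fst(sa, sw) >= ml:
                ml_exceed += 1
        p_ok = (exceed + 1.0) / (n_perm + 1.0)
        pvals = np.full(len(freqs.markers), np.nan)
        pvals[ok] = p_ok
        pvals[np.isnan(fst)] = np.nan
        pml = (ml_exceed + 1.0) / (n_perm + 1.0)
    return PairwiseFstResult(list(freqs.markers), fst, ml, pvals, pml)


# ---------------------------------------------------------------------------
# hierarchical (three-level) decomposition
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    markers: list
    fct: np.ndarray
    fsc: np.ndarray
    fst: np.ndarray
    fct_multilocus: float
    fsc_multilocus: float
    fst_multilocus: float
    sd: dict                      # per-statistic SD across loci
    p_values: dict | None = None  # {"fct": float, "fsc": float}
    components: tuple | None = None  # multilocus (sigma_a, sigma_b, sigma_c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.markers, "fct": self.fct,
                             "fsc": self.fsc, "fst": self.fst})


def _hier_components(count0, n_alleles, group_idx, n_groups):
    """Three-level nested ANOVA components per locus (vectorized over loci)."""
    count0 = np.asarray(count0, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    ok = count0 >= 0
    n = np.where(ok, n, 0.0)
    count0 = np.where(ok, count0, 0.0)
    P = ok.sum(axis=0)
    N = n.sum(axis=0)
    G = n_groups
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, count0 / n, 0.0)
        # group and grand totals
        Ng = np.zeros((G, n.shape[1]))
        c0g = np.zeros((G, n.shape[1]))
        sum_n2_g = np.zeros((G, n.shape[1]))
        for g in range(G):
            sel = group_idx == g
            Ng[g] = n[sel].sum(axis=0)
            c0g[g] = count0[sel].sum(axis=0)
            sum_n2_g[g] = (n[sel] ** 2).sum(axis=0)
        pg = np.where(Ng > 0, c0g / Ng, 0.0)
        pbar = count0.sum(axis=0) / N
        ss_wp = (n * p * (1.0 - p)).sum(axis=0)
        ss_ap = (n * (p - pg[group_idx]) ** 2).sum(axis=0)
        ss_ag = (Ng * (pg - pbar) ** 2).sum(axis=0)
        ms_wp = ss_wp / (N - P)
        ms_ap = ss_ap / (P - G)
        ms_ag = ss_ag / (G - 1)
        ratio = np.where(Ng > 0, sum_n2_g / Ng, 0.0).sum(axis=0)
        a = (N - ratio) / (P - G)
        b = (ratio - (n * n).sum(axis=0) / N) / (G - 1)
        c = (N - (Ng * Ng).sum(axis=0) / N) / (G - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / a
        sigma_a = (ms_ag - sigma_c - b * sigma_b) / c
    ss_total = N * pbar * (1.0 - pbar)
    bad = (ss_total <= 0) | (P <= G) | (N <= P)
    for arr in (sigma_a, sigma_b, sigma_c):
        arr[bad] = np.nan
    return sigma_a, sigma_b, sigma_c


def _hier_f(sigma_a, sigma_b, sigma_c):
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = sigma_a + sigma_b + sigma_c
        fct = sigma_a / tot
        fsc = sigma_b / (sigma_b + sigma_c)
        fst = (sigma_a + sigma_b) / tot
    return fct, fsc, fst


def hierarchical_amova(freqs: FreqTable, groups: dict, n_perm: int = 1000,
                       seed=None) -> AmovaResult:
    """Hierarchical AMOVA on allele counts: groups / populations / gene copies.

    ``groups`` maps population name -> group name.  F_CT is among-group
    differentiation relative to total, F_SC among populations within groups,
    F_ST their combination; the identity (1-F_ST) = (1-F_CT)(1-F_SC) holds by
    construction of the variance components.
    """
    pops = freqs.populations
    names = sorted(set(groups[p] for p in pops))
    if len(names) < 2:
        raise ValueError("hierarchical AMOVA needs >= 2 groups")
    gidx = np.array([names.index(groups[p]) for p in pops])
    for g in range(len(names)):
        if (gidx == g).sum() < 2:
            raise ValueError(f"group {names[g]!r} has a single population; "
                             "F_SC is undefined for it")
    c0, n2 = freqs.count0, freqs.n_alleles
    sa, sb, sc = _hier_components(c0, n2, gidx, len(names))
    fct, fsc, fst = _hier_f(sa, sb, sc)

    def _ml(x, y):
        ok = np.isfinite(sa)
        return float(x[ok].sum() / y[ok].sum()) if ok.any() else float("nan")

    ml_fct = _ml(sa, sa + sb + sc)
    ml_fsc = _ml(sb, sb + sc)
    ml_fst = _ml(sa + sb, sa + sb + sc)
    sd = {"fct": float(np.nanstd(fct)), "fsc": float(np.nanstd(fsc)),
          "fst": float(np.nanstd(fst))}

    p_values = None
    if n_perm:
        rng = np.random.default_rng(seed)
        # F_CT: permute populations across groups
        exceed_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(gidx)
            psa, psb, psc = _hier_components(c0, n2, perm, len(names))
            if _ml_stat(psa, psa + psb + psc) >= ml_fct:
                exceed_ct += 1
        # F_SC: shuffle gene copies across populations within each group
        exceed_sc = 0
        ok = (c0 >= 0).all(axis=0)
        for _ in range(n_perm):
            c0p = c0.copy().astype(float)
            for g in range(len(names)):
                sel = np.where(gidx == g)[0]
                tot0 = c0[sel][:, ok].sum(axis=0)
                rem0 = tot0.copy()
                remN = n2[sel][:, ok].sum(axis=0)
                for i in sel[:-1]:
                    draw = rng.hypergeometric(rem0, remN - rem0, n2[i, ok])
                    c0p[i, ok] = draw
                    rem0 -= draw
                    remN -= n2[i, ok]
                c0p[sel[-1], ok] = rem0
            psa, psb, psc = _hier_components(c0p, n2, gidx, len(names))
            if _ml_stat(psb, psb + psc) >= ml_fsc:
                exceed_sc += 1
        p_values = {"fct": (exceed_ct + 1.0) / (n_perm + 1.0),
                    "fsc": (exceed_sc + 1.0) / (n_perm + 1.0)}

    return AmovaResult(list(freqs.markers), fct, fsc, fst,
                       ml_fct, ml_fsc, ml_fst, sd, p_values,
                       components=(np.nansum(sa), np.nansum(sb), np.nansum(sc)))


def _ml_stat(num, den):
    ok = np.isfinite(num) & np.isfinite(den)
    return num[ok].sum() / den[ok].sum() if ok.any() else float("nan")


# ---------------------------------------------------------------------------
# band-frequency contingency tests
# ---------------------------------------------------------------------------

def band_frequency_chi2(bands: BandMatrix, samples: pd.DataFrame,
                        partition: str = "habitat") -> pd.DataFrame:
    """Per-locus 2x2 chi-square tests of band frequency between two habitats.

    Uses the uncorrected chi-square statistic; when any expected count is
    below 5 the test switches to Fisher's exact test (``exact`` flag).
    Monomorphic loci, or loci without calls in one cell, are NaN.
    """
    meta = samples.set_index("sample_id").loc[bands.sample_ids]
    levels = sorted(meta[partition].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"partition {partition!r} must have exactly 2 levels, "
                         f"got {levels}")
    g1 = (meta[partition].astype(str) == levels[0]).to_numpy()
    pres, scrd = bands.present, bands.scored
    rows = []
    for j, m in enumerate(bands.marker_ids):
        table = np.array([
            [pres[g1, j].sum(), (scrd[g1, j] & ~pres[g1, j]).sum()],
            [pres[~g1, j].sum(), (scrd[~g1, j] & ~pres[~g1, j]).sum()]],
            dtype=float)
        n1, n2c = table.sum(axis=1)
        exact = False
        if n1 == 0 or n2c == 0 or table.sum(axis=0).min() == 0:
            chi2 = p = np.nan  # monomorphic or empty cell
        else:
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            if (expected < 5).any():
                exact = True
                _, p = stats.fisher_exact(table.astype(int))
                chi2 = np.nan
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append((m, chi2, p, exact))
    return pd.DataFrame(rows, columns=["marker", "chi2", "p_value", "exact"])
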