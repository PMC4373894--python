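"""Detection of loci with excess differentiation (outlier scans).

Two complementary scans are provided, both consuming the allele counts the
dominant-marker inference path produces:

* a coalescent-free FDIST-style test: neutral loci are simulated under the
  Balding-Nichols island model (beta-distributed subpopulation frequencies,
  the stationary approximation of the island model), pushed through the same
  dominance + inbreeding + frequency-inference path as the observed data, and
  the observed per-locus (He, F_ST) is compared with the simulated cloud
  conditional on heterozygosity.  P-values are one-sided toward divergent
  selection and converted to q-values (Strimmer-style local FDR by default,
  Benjamini-Hochberg as fallback), with flags at FDR 0.10.

* a Bayesian logistic F_ST decomposition: logit(F_ST(i,j)) = alpha_j + beta_i
  with a spike-and-slab prior on the locus effect alpha_j (prior inclusion
  odds 1:10).  Allele counts are beta-binomial after integrating the
  island-model frequency distribution analytically; a Metropolis-within-Gibbs
  sampler with model-indicator jumps yields posterior inclusion probabilities
  and posterior-error-probability-derived q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln

from .fstats import amova_components, fst_from_components, multilocus_fst, \
    _hier_components, _hier_f
from .freqs import DEFAULT_FIS, FreqTable, allele_counts, infer_null_allele_freq

FDR_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# neutral envelope simulation
# ---------------------------------------------------------------------------

@dataclass
class NeutralCloud:
    he: np.ndarray
    fst: np.ndarray
    model: str                      # "island" | "hierarchical"
    mean_fst: float                 # realized multilocus F_ST of the cloud
    target_fst: float
    param_fst: float                # calibrated BN parameter actually used
    sample_sizes: tuple
    f_ct: float | None = None


def bn_freqs(p_anc, fst, n_pops, rng):
    """Balding-Nichols subpopulation frequencies.

    Beta with mean ``p_anc`` and variance ``p_anc (1 - p_anc) fst``:
    shape parameters ``p_anc (1-fst)/fst`` and ``(1-p_anc)(1-fst)/fst``.
    ``fst = 0`` returns the ancestral frequency for every population.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if fst == 0:
        return np.broadcast_to(p_anc, (n_pops,) + p_anc.shape).copy()
    if not 0 < fst < 1:
        raise ValueError("fst must be in [0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale,
                    size=(n_pops,) + p_anc.shape)


def _phenotype_absent_prob(p0, fis):
    """P(band absent) for '0'-allele frequency p0 under inbreeding fis.

    Genotype frequencies with negative fis can go negative at extreme
    frequencies; they are truncated at zero and renormalized.
    """
    q = 1.0 - p0
    g00 = np.clip((1.0 - fis) * p0 * p0 + fis * p0, 0.0, None)
    g11 = np.clip((1.0 - fis) * q * q + fis * q, 0.0, None)
    g10 = np.clip(2.0 * (1.0 - fis) * p0 * q, 0.0, None)
    return g00 / (g00 + g10 + g11)


def _simulate_observed_counts(pop_p0, n_dip, fis, rng):
    """Sample band phenotypes and re-infer allele counts, per pop x locus."""
    absent_prob = _phenotype_absent_prob(pop_p0, fis)
    n_absent = rng.binomial(n_dip[:, None], absent_prob)
    f00 = n_absent / n_dip[:, None]
    p_hat = infer_null_allele_freq(f00, fis)
    c0, _ = allele_counts(p_hat, n_dip[:, None])
    return c0


def _island_cloud(param_fst, sample_sizes, n_loci, fis, rng,
                  anc_bounds=(0.01, 0.99)):
    n_dip = np.asarray(sample_sizes, dtype=int)
    he = np.empty(0)
    fst = np.empty(0)
    sa_all = np.empty(0)
    sw_all = np.empty(0)
    while len(he) < n_loci:
        batch = max(n_loci - len(he), 1000)
        p_anc = rng.uniform(*anc_bounds, size=batch)
        pop_p0 = bn_freqs(p_anc, param_fst, len(n_dip), rng)
        c0 = _simulate_observed_counts(pop_p0, n_dip, fis, rng)
        ntot = np.broadcast_to(2 * n_dip[:, None], c0.shape)
        sa, sw = amova_components(c0, ntot)
        f = fst_from_components(sa, sw)
        pbar = c0.sum(axis=0) / ntot.sum(axis=0)
        h = 2.0 * pbar * (1.0 - pbar)
        ok = np.isfinite(f)
        he = np.append(he, h[ok])
        fst = np.append(fst, f[ok])
        sa_all = np.append(sa_all, sa[ok])
        sw_all = np.append(sw_all, sw[ok])
    he, fst = he[:n_loci], fst[:n_loci]
    ml = multilocus_fst(sa_all[:n_loci], sw_all[:n_loci])
    return he, fst, ml


def _hierarchical_cloud(param_fsc, f_ct, sample_sizes, n_loci, fis, rng,
                        anc_bounds=(0.01, 0.99)):
    """Two groups of populations; F_ST measured by hierarchical AMOVA."""
    n_dip = np.asarray(sample_sizes, dtype=int)   # pops within one group
    n_groups = 2
    all_n = np.concatenate([n_dip] * n_groups)
    gidx = np.repeat(np.arange(n_groups), len(n_dip))
    he = np.empty(0)
    fst = np.empty(0)
    num = np.empty(0)
    den = np.empty(0)
    while len(he) < n_loci:
        batch = max(n_loci - len(he), 1000)
        p_anc = rng.uniform(*anc_bounds, size=batch)
        group_p = bn_freqs(p_anc, f_ct, n_groups, rng)
        pop_p0 = np.concatenate(
            [bn_freqs(group_p[g], param_fsc, len(n_dip), rng)
             for g in range(n_groups)], axis=0)
        c0 = _simulate_observed_counts(pop_p0, all_n, fis, rng)
        ntot = np.broadcast_to(2 * all_n[:, None], c0.shape)
        sa, sb, sc = _hier_components(c0, ntot, gidx, n_groups)
        _, _, f = _hier_f(sa, sb, sc)
        pbar = c0.sum(axis=0) / ntot.sum(axis=0)
        h = 2.0 * pbar * (1.0 - pbar)
        ok = np.isfinite(f)
        he = np.append(he, h[ok])
        fst = np.append(fst, f[ok])
        num = np.append(num, (sa + sb)[ok])
        den = np.append(den, (sa + sb + sc)[ok])
    he, fst = he[:n_loci], fst[:n_loci]
    ml = float(num[:n_loci].sum() / den[:n_loci].sum())
    return he, fst, ml


def neutral_envelope(model: str, mean_fst: float, sample_sizes,
                     f_ct: float | None = None, n_sim: int = 20000,
                     fis: float = DEFAULT_FIS, seed=None, calibrate: bool = True,
                     pilot: int = 4000, anc_bounds=(0.01, 0.99)) -> NeutralCloud:
    """Simulate the neutral (He, F_ST) cloud matching an observed mean F_ST.

    The Balding-Nichols parameter is calibrated (as FDIST does) so that the
    realized multilocus F_ST of the simulated cloud matches ``mean_fst``
    within 2%, then the full cloud of ``n_sim`` polymorphic loci is drawn.
    For the hierarchical model, ``f_ct`` fixes the between-group level and the
    within-group parameter is calibrated on total F_ST; requires
    ``f_ct < mean_fst``.
    """
    if not 0 < mean_fst < 1:
        raise ValueError("mean_fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if model == "island":
        def run(par, n):
            return _island_cloud(par, sample_sizes, n, fis, rng, anc_bounds)
        param = mean_fst
    elif model == "hierarchical":
        if f_ct is None or f_ct >= mean_fst:
            raise ValueError("hierarchical model needs f_ct < mean_fst")
        # split total F_ST via (1 - fst) = (1 - fct)(1 - fsc)
        param = 1.0 - (1.0 - mean_fst) / (1.0 - f_ct)

        def run(par, n):
            return _hierarchical_cloud(par, f_ct, sample_sizes, n, fis, rng,
                                       anc_bounds)
    else:
        raise ValueError(f"unknown model {model!r}")

    if calibrate:
        for _ in range(6):
            _, _, est = run(param, pilot)
            if est <= 0 or abs(est - mean_fst) <= 0.02 * mean_fst:
                break
            param = float(np.clip(param * mean_fst / est, 1e-6, 0.98))
    he, fst, ml = run(param, n_sim)
    return NeutralCloud(he, fst, model, ml, mean_fst, param,
                        tuple(sample_sizes), f_ct)


# ---------------------------------------------------------------------------
# envelope p-values
# ---------------------------------------------------------------------------

def envelope_pvalues(he_obs, fst_obs, cloud: NeutralCloud,
                     he_bins: int = 20, min_bin: int = 100,
                     tie: str = "midp", rng=None) -> np.ndarray:
    """One-sided (divergent-selection) empirical p-values conditional on He.

    Simulated loci are binned by heterozygosity (equal-width bins over the
    simulated range; bins with fewer than ``min_bin`` loci are merged with a
    neighbor).  For an observed locus, p is the upper-tail probability of a
    simulated F_ST at least as large, with the add-one rule so p is never 0.
    Observed He outside the simulated range uses the nearest bin.

    The per-locus F_ST of dominant data is a coarsely discrete statistic
    (phenotype counts take <= n+1 values), so the strict ">=" p-value is
    markedly super-uniform.  ``tie`` selects the correction:

    - ``"midp"`` (default): ties contribute half weight; deterministic and
      nearly calibrated.
    - ``"randomized"``: fuzzy p-value, exactly uniform under the null;
      requires ``rng`` (or a seed) and is what the scans use.
    - ``"upper"``: classic strict rule, conservative.
    """
    he_obs = np.asarray(he_obs, dtype=float)
    fst_obs = np.asarray(fst_obs, dtype=float)
    edges = np.linspace(cloud.he.min(), cloud.he.max(), he_bins + 1)
    idx = np.clip(np.digitize(cloud.he, edges[1:-1]), 0, he_bins - 1)
    # merge small bins with their left neighbor (leftmost merges right)
    counts = np.bincount(idx, minlength=he_bins)
    remap = np.arange(he_bins)
    merged = False
    for b in range(he_bins):
        if 0 < counts[b] < min_bin or counts[b] == 0:
            tgt = b - 1 if b > 0 else b + 1
            while tgt < he_bins and counts[tgt] == 0:
                tgt += 1
            if 0 <= tgt < he_bins:
                remap[remap == b] = tgt
                counts[tgt] += counts[b]
                counts[b] = 0
                merged = True
    if merged:
        warnings.warn("merged heterozygosity bins with insufficient "
                      "simulated loci")
    idx = remap[idx]
    sorted_fst = {b: np.sort(cloud.fst[idx == b]) for b in np.unique(idx)}
    bins_used = np.array(sorted(sorted_fst))
    # representative He per bin for nearest-bin lookup
    bin_he = np.array([cloud.he[idx == b].mean() for b in bins_used])

    if tie == "randomized":
        rng = np.random.default_rng(rng)
        u = rng.random(len(fst_obs))
    elif tie not in ("midp", "upper"):
        raise ValueError(f"unknown tie rule {tie!r}")

    obs_idx = remap[np.clip(np.digitize(he_obs, edges[1:-1]), 0, he_bins - 1)]
    p = np.full(len(fst_obs), np.nan)
    for k, (b, h) in enumerate(zip(obs_idx, he_obs)):
        if not np.isfinite(fst_obs[k]) or not np.isfinite(h):
            continue
        if b not in sorted_fst:
            b = bins_used[np.argmin(np.abs(bin_he - h))]
        sims = sorted_fst[b]
        n = len(sims)
        n_gt = n - np.searchsorted(sims, fst_obs[k], side="right")
        n_ge = n - np.searchsorted(sims, fst_obs[k], side="left")
        if tie == "upper":
            p[k] = (n_ge + 1.0) / (n + 1.0)
        elif tie == "midp":
            p[k] = (n_gt + 0.5 * (n_ge - n_gt) + 1.0) / (n + 1.0)
        else:
            p[k] = (n_gt + u[k] * (n_ge - n_gt + 1.0)) / (n + 1.0)
    return p


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def _grenander_cdf(p_sorted):
    """Least concave majorant of the p-value ECDF (upper convex hull)."""
    n = len(p_sorted)
    xs = np.concatenate([[0.0], p_sorted, [1.0]])
    ys = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    hull_x = [xs[0]]
    hull_y = [ys[0]]
    for x, y in zip(xs[1:], ys[1:]):
        while len(hull_x) >= 2:
            cross = ((hull_x[-1] - hull_x[-2]) * (y - hull_y[-2])
                     - (hull_y[-1] - hull_y[-2]) * (x - hull_x[-2]))
            if cross >= 0:
                hull_x.pop()
                hull_y.pop()
            else:
                break
        hull_x.append(x)
        hull_y.append(y)
    return np.asarray(hull_x), np.asarray(hull_y)


def fdr_qvalues(p_values, method: str = "local_fdr",
                threshold: float = FDR_THRESHOLD):
    """Convert p-values to q-values and flag loci at the FDR threshold.

    ``local_fdr`` follows the Strimmer empirical-null construction: the
    p-value distribution is modelled as a mixture of a uniform null (weight
    eta0, estimated from the right-hand slope of the Grenander/least-concave-
    majorant fit of the ECDF) and a left-leaning alternative; the reported
    q-value is the tail-area false discovery rate eta0 * p / F(p).  ``bh`` is
    plain Benjamini-Hochberg.  NaN p-values give NaN q-values and no flag.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        pv = p[ok]
        if method == "bh":
            order = np.argsort(pv, kind="stable")
            m = len(pv)
            ranked = pv[order] * m / np.arange(1, m + 1)
            qs = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(qs, 1.0)
            q[ok] = out
        elif method == "local_fdr":
            order = np.argsort(pv, kind="stable")
            ps = pv[order]
            hx, hy = _grenander_cdf(ps)
            # null proportion from the right-hand tail (Storey, lambda = 0.5);
            # the literal rightmost LCM segment is a degenerate corner when
            # max(p) < 1, so it cannot serve as the density at 1
            lam = 0.5
            eta0 = float(min((ps > lam).mean() / (1.0 - lam), 1.0))
            fhat = np.interp(ps, hx, hy)
            with np.errstate(invalid="ignore", divide="ignore"):
                qs = np.where(fhat > 0, eta0 * ps / fhat, 0.0)
            qs = np.clip(qs, 0.0, 1.0)
            out = np.empty(len(ps))
            out[order] = qs
            q[ok] = out
        else:
            raise ValueError(f"unknown FDR method {method!r}")
    flags = np.where(ok, q <= threshold, False)
    return q, flags


# ---------------------------------------------------------------------------
# Bayesian scan
# ---------------------------------------------------------------------------

@dataclass
class BayesScanResult:
    markers: list
    posterior_prob: np.ndarray
    alpha_mean: np.ndarray
    beta_mean: np.ndarray
    q_values: np.ndarray
    flags: np.ndarray
    acceptance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.markers,
                             "posterior_prob": self.posterior_prob,
                             "alpha": self.alpha_mean,
                             "q_value": self.q_values,
                             "flag": self.flags})


def _betabin_loglik(k, n, a, b):
    """Beta-binomial log likelihood without the binomial coefficient."""
    return betaln(k + a, n - k + b) - betaln(a, b)


def bayesian_scan(freqs: FreqTable, n_iter: int = 50000, burn_in: int = 10000,
                  thin: int = 10, prior_odds: float = 10.0,
                  fdr: float = FDR_THRESHOLD, seed=None,
                  alpha_sd: float = 3.0, beta_prior=(-2.0, 1.8),
                  rw_scales=(0.06, 0.6, 0.25)) -> BayesScanResult:
    """Bayesian F_ST decomposition scan over loci.

    Locus-by-population differentiation is logit(F_ST(i,j)) = alpha_j + beta_i;
    integrating the Balding-Nichols frequency prior gives a beta-binomial
    likelihood for the allele counts.  alpha_j carries a spike-and-slab prior
    (point mass at 0 with odds ``prior_odds`` : 1 against inclusion, slab
    N(0, alpha_sd^2)); beta_i a N(beta_prior) prior.  Posterior inclusion
    frequencies give per-locus q-values as cumulative mean posterior error
    probabilities, flagged at ``fdr``.
    """
    rng = np.random.default_rng(seed)
    k = np.asarray(freqs.count0, dtype=float)
    ntot = np.asarray(freqs.n_alleles, dtype=float)
    K, L = k.shape
    if K < 2:
        raise ValueError("bayesian scan needs >= 2 populations")
    obs = k >= 0
    k = np.where(obs, k, 0.0)
    ntot = np.where(obs, ntot, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = k.sum(axis=0) / ntot.sum(axis=0)
    pbar = np.clip(np.where(np.isfinite(pooled), pooled, 0.5), 1e-3, 1 - 1e-3)
    sa, sw = amova_components(np.where(obs, k, -1), ntot)
    fst0 = np.clip(multilocus_fst(sa, sw), 0.005, 0.5)
    beta = np.full(K, np.log(fst0 / (1 - fst0)))
    alpha = np.zeros(L)
    included = np.zeros(L, dtype=bool)
    pi1 = 1.0 / (1.0 + prior_odds)
    log_odds_incl = np.log(pi1 / (1.0 - pi1))

    def loglik_rows(alpha_v, pbar_v, beta_v):
        theta = np.exp(-(alpha_v[None, :] + beta_v[:, None]))
        a = theta * pbar_v[None, :]
        b = theta * (1.0 - pbar_v[None, :])
        ll = _betabin_loglik(k, ntot, a, b)
        return np.where(obs, ll, 0.0)

    ll_rows = loglik_rows(alpha, pbar, beta)
    ll_loc = ll_rows.sum(axis=0)

    s_pbar, s_alpha, s_beta = rw_scales
    acc = {"pbar": 0, "alpha": 0, "alpha_n": 0, "beta": 0, "rj": 0}
    n_samples = 0
    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    beta_sum = np.zeros(K)

    for it in range(n_iter):
        # ancestral frequencies (uniform prior, reflected random walk)
        prop = pbar + rng.normal(0.0, s_pbar, L)
        prop = np.abs(prop)
        prop = np.where(prop > 1, 2 - prop, prop)
        prop = np.clip(prop, 1e-4, 1 - 1e-4)
        ll_prop_rows = loglik_rows(alpha, prop, beta)
        ll_prop = ll_prop_rows.sum(axis=0)
        accept = np.log(rng.random(L)) < ll_prop - ll_loc
        pbar = np.where(accept, prop, pbar)
        ll_rows = np.where(accept[None, :], ll_prop_rows, ll_rows)
        ll_loc = np.where(accept, ll_prop, ll_loc)
        acc["pbar"] += accept.mean()

        # alpha random walk for included loci
        if included.any():
            prop_a = np.where(included, alpha + rng.normal(0, s_alpha, L), alpha)
            ll_prop_rows = loglik_rows(prop_a, pbar, beta)
            ll_prop = ll_prop_rows.sum(axis=0)
            dprior = (alpha ** 2 - prop_a ** 2) / (2 * alpha_sd ** 2)
            accept = included & (np.log(rng.random(L)) < ll_prop - ll_loc + dprior)
            alpha = np.where(accept, prop_a, alpha)
            ll_rows = np.where(accept[None, :], ll_prop_rows, ll_rows)
            ll_loc = np.where(accept, ll_prop, ll_loc)
            acc["alpha"] += accept[included].mean()
            acc["alpha_n"] += 1

        # model-indicator jumps (propose from the slab so densities cancel)
        draw = rng.normal(0.0, alpha_sd, L)
        prop_a = np.where(included, 0.0, draw)
        ll_prop_rows = loglik_rows(prop_a, pbar, beta)
        ll_prop = ll_prop_rows.sum(axis=0)
        logr = np.where(included,
                        ll_prop - ll_loc - log_odds_incl,
                        ll_prop - ll_loc + log_odds_incl)
        accept = np.log(rng.random(L)) < logr
        alpha = np.where(accept, prop_a, alpha)
        included = np.where(accept, ~included, included)
        ll_rows = np.where(accept[None, :], ll_prop_rows, ll_rows)
        ll_loc = np.where(accept, ll_prop, ll_loc)
        acc["rj"] += accept.mean()

        # population effects
        for i in range(K):
            bprop = beta.copy()
            bprop[i] += rng.normal(0.0, s_beta)
            theta = np.exp(-(alpha + bprop[i]))
            a = theta * pbar
            bb = theta * (1.0 - pbar)
            row = np.where(obs[i], _betabin_loglik(k[i], ntot[i], a, bb), 0.0)
            dprior = ((beta[i] - beta_prior[0]) ** 2
                      - (bprop[i] - beta_prior[0]) ** 2) / (2 * beta_prior[1] ** 2)
            if np.log(rng.random()) < row.sum() - ll_rows[i].sum() + dprior:
                beta = bprop
                ll_rows[i] = row
                ll_loc = ll_rows.sum(axis=0)
                acc["beta"] += 1

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            incl_sum += included
            alpha_sum += np.where(included, alpha, 0.0)
            beta_sum += beta

    pip = incl_sum / n_samples
    rates = {"pbar": acc["pbar"] / n_iter,
             "alpha": acc["alpha"] / max(acc["alpha_n"], 1),
             "rj": acc["rj"] / n_iter,
             "beta": acc["beta"] / (n_iter * K)}
    warns = [f"{name} acceptance rate {r:.3f} outside (0.05, 0.95)"
             for name, r in rates.items() if not 0.05 < r < 0.95 and name != "rj"]
    for w in warns:
        warnings.warn(w)

    q = _pip_qvalues(pip)
    return BayesScanResult(list(freqs.markers), pip, alpha_sum / n_samples,
                           beta_sum / n_samples, q, q <= fdr, rates, warns)


def _pip_qvalues(pip):
    """q(j) = mean posterior error probability among loci at least as extreme."""
    order = np.argsort(-pip, kind="stable")
    pep = 1.0 - pip[order]
    q_sorted = np.cumsum(pep) / np.arange(1, len(pep) + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full scans and reporting
# ---------------------------------------------------------------------------

def coalescent_scan(freqs: FreqTable, model: str = "island",
                    f_ct: float | None = None, n_sim: int = 20000,
                    he_bins: int = 20, fdr: float = FDR_THRESHOLD,
                    fdr_method: str = "local_fdr", seed=None,
                    groups: dict | None = None) -> pd.DataFrame:
    """Observed per-locus (He, F_ST) against a matched neutral envelope.

    For ``model='island'`` the FreqTable must hold the two populations of one
    group; for ``model='hierarchical'`` supply ``groups`` mapping population
    -> group (2 groups) and the envelope fixes F_CT at the observed value.
    Envelope p-values use the randomized tie rule (exactly calibrated for
    the discrete dominant-marker statistic), seeded by ``seed``.
    """
    rng = np.random.default_rng(seed)
    c0, ntot = freqs.count0, freqs.n_alleles
    if model == "island":
        sa, sw = amova_components(c0, ntot)
        fst = fst_from_components(sa, sw)
        ml = multilocus_fst(sa, sw)
        sizes = [int(np.median(freqs.n[i][freqs.n[i] > 0]))
                 for i in range(len(freqs.populations))]
        cloud = neutral_envelope("island", ml, sizes, n_sim=n_sim,
                                 fis=freqs.fis, seed=rng)
    else:
        names = sorted(set(groups.values()))
        gidx = np.array([names.index(groups[p]) for p in freqs.populations])
        sa, sb, sc = _hier_components(c0, ntot, gidx, len(names))
        _, _, fst = _hier_f(sa, sb, sc)
        ok = np.isfinite(sa)
        ml = float((sa + sb)[ok].sum() / (sa + sb + sc)[ok].sum())
        fct = float(sa[ok].sum() / (sa + sb + sc)[ok].sum())
        fct = min(max(fct, 1e-4), 0.9 * ml)
        sizes = [int(np.median(freqs.n[i][freqs.n[i] > 0]))
                 for i in range(len(freqs.populations))][:2]
        cloud = neutral_envelope("hierarchical", ml, sizes, f_ct=fct,
                                 n_sim=n_sim, fis=freqs.fis, seed=rng)
    mask = (c0 >= 0).any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(c0 >= 0, c0, 0).sum(axis=0) / \
            np.where(c0 >= 0, ntot, 0).sum(axis=0)
    he = 2.0 * pbar * (1.0 - pbar)
    p = envelope_pvalues(he, fst, cloud, he_bins=he_bins, tie="randomized",
                         rng=rng)
    q, flags = fdr_qvalues(p, method=fdr_method, threshold=fdr)
    return pd.DataFrame({"marker": freqs.markers, "he": he, "fst": fst,
                         "p_value": p, "q_value": q, "flag_coalescent": flags})


def outlier_report(coalescent: pd.DataFrame | None = None,
                   bayesian: BayesScanResult | None = None,
                   chi2: pd.DataFrame | None = None,
                   truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge per-method outlier tables into one row per locus (outer join)."""
    parts = []
    if coalescent is not None:
        parts.append(coalescent.set_index("marker"))
    if bayesian is not None:
        df = bayesian.to_frame().rename(columns={
            "q_value": "q_bayesian", "flag": "flag_bayesian"})
        parts.append(df.set_index("marker"))
    if chi2 is not None:
        df = chi2.rename(columns={"p_value": "p_chi2"})
        parts.append(df.set_index("marker"))
    if truth is not None:
        parts.append(truth.set_index("marker"))
    if not parts:
        return pd.DataFrame(columns=["marker"])
    out = parts[0]
    for df in parts[1:]:
        out = out.join(df, how="outer")
    return out.reset_index().rename(columns={"index": "marker"})
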