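"""Bayesian landscape model of pairwise genetic distance.

Pairwise Jaccard genetic distance between individual trees is partitioned
into neutral and putatively adaptive components through the linear model

    GENET = mu + t1*SITE + (1 - SITE)(t2*GEO + t3*ELEV)
               + t4*DROUGHT + t5*WATERLOG + t6*SOILTYPE + eps,
    eps ~ Normal(0, sigma2_R)

where SITE is 0 for a same-site pair and 1 otherwise, GEO and ELEV are
within-site Euclidean xy and elevation distances (zeroed between sites by the
(1 - SITE) factor), and the environmental distances are absolute differences
of the ordinal habitat codes (soil type is a 0/1 mismatch indicator).
Environmental distances apply to every pair, including between-site ones.

The posterior is sampled by conjugate Gibbs with weakly-informative priors
(Normal(0, 1000) on each coefficient, inverse-gamma(0.001, 0.001) on the
residual variance).  Pairs are treated as exchangeable observations, exactly
as in the original formulation; no correction for their non-independence is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PairwiseMatrix, check_env_covers

logger = logging.getLogger(__name__)

PARAM_NAMES = ["mu", "theta1_site", "theta2_geo", "theta3_elev",
               "theta4_drought", "theta5_waterlog", "theta6_soil", "sigma2_R"]
DESIGN_COLUMNS = ["GENET", "SITE", "GEO", "ELEV", "DROUGHT", "WATERLOG",
                  "SOILTYPE"]


def build_pair_design(samples: pd.DataFrame, env: pd.DataFrame,
                      genet: PairwiseMatrix) -> pd.DataFrame:
    """Design table with one row per unordered sample pair."""
    check_env_covers(samples, env)
    meta = samples.set_index("sample_id").loc[genet.sample_ids]
    if meta[["x", "y", "elevation"]].isna().any().any():
        raise ValueError("sample without coordinates")
    envi = env.set_index(["site", "habitat"])
    cells = list(zip(meta["site"], meta["habitat"]))
    drought = np.array([envi.loc[c, "drought"] for c in cells], dtype=float)
    waterlog = np.array([envi.loc[c, "waterlog"] for c in cells], dtype=float)
    soil = np.array([envi.loc[c, "soil_type"] for c in cells], dtype=object)
    xy = meta[["x", "y"]].to_numpy(dtype=float)
    elev = meta["elevation"].to_numpy(dtype=float)
    site = meta["site"].to_numpy()

    iu, ju, g = genet.condensed()
    same = site[iu] == site[ju]
    geo = np.where(same, np.hypot(*(xy[iu] - xy[ju]).T), 0.0)
    delev = np.where(same, np.abs(elev[iu] - elev[ju]), 0.0)
    return pd.DataFrame({
        "id1": np.asarray(genet.sample_ids)[iu],
        "id2": np.asarray(genet.sample_ids)[ju],
        "GENET": g,
        "SITE": (~same).astype(float),
        "GEO": geo,
        "ELEV": delev,
        "DROUGHT": np.abs(drought[iu] - drought[ju]),
        "WATERLOG": np.abs(waterlog[iu] - waterlog[ju]),
        "SOILTYPE": (soil[iu] != soil[ju]).astype(float),
    })


@dataclass
class PosteriorSummary:
    summary: pd.DataFrame          # per parameter: mean sd 2.5% median 97.5%
    draws: np.ndarray              # (n_chains, n_draws, n_params)
    ess: pd.Series | None = None

    def __getitem__(self, name):
        return self.summary.loc[name]

    def to_frame(self) -> pd.DataFrame:
        return self.summary.reset_index(names="parameter")


def _design_matrix(design: pd.DataFrame, include=None):
    d = design.dropna(subset=["GENET"])
    dropped = len(design) - len(d)
    if dropped:
        logger.info("dropped %d pair(s) with missing genetic distance", dropped)
    columns = {
        "mu": np.ones(len(d)),
        "theta1_site": d["SITE"].to_numpy(float),
        "theta2_geo": ((1.0 - d["SITE"]) * d["GEO"]).to_numpy(float),
        "theta3_elev": ((1.0 - d["SITE"]) * d["ELEV"]).to_numpy(float),
        "theta4_drought": d["DROUGHT"].to_numpy(float),
        "theta5_waterlog": d["WATERLOG"].to_numpy(float),
        "theta6_soil": d["SOILTYPE"].to_numpy(float),
    }
    names = ["mu"] + list(include) if include is not None else PARAM_NAMES[:-1]
    X = np.column_stack([columns[n] for n in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the user
        keep = []
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    return X, d["GENET"].to_numpy(dtype=float), names


def fit_distance_model(design: pd.DataFrame, n_iter: int = 10000,
                       burn_in: int = 1000, seed=None, n_chains: int = 1,
                       coef_var: float = 1000.0, ig_a: float = 0.001,
                       ig_b: float = 0.001, include=None) -> PosteriorSummary:
    """Gibbs sampler for the pairwise-distance linear model.

    Returns posterior summaries (mean, sd, 2.5%, median, 97.5%) for mu,
    theta1..theta6 and sigma2_R.  ``include`` may name a subset of the theta
    predictors (e.g. for designs where a term is constant); default all.
    """
    X, y, names = _design_matrix(design, include=include)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / coef_var
    rng = np.random.default_rng(seed)
    chains = []
    for _ in range(n_chains):
        beta = np.linalg.solve(XtX + prior_prec, Xty)
        sigma2 = float(np.var(y - X @ beta)) or 1e-6
        draws = np.empty((n_iter - burn_in, p + 1))
        for it in range(n_iter):
            prec = XtX / sigma2 + prior_prec
            chol = np.linalg.cholesky(np.linalg.inv(prec))
            mean = np.linalg.solve(prec, Xty / sigma2)
            beta = mean + chol @ rng.standard_normal(p)
            resid = y - X @ beta
            sigma2 = 1.0 / rng.gamma(ig_a + n / 2.0,
                                     1.0 / (ig_b + 0.5 * resid @ resid))
            if it >= burn_in:
                draws[it - burn_in, :p] = beta
                draws[it - burn_in, p] = sigma2
        chains.append(draws)
    draws = np.stack(chains)
    flat = draws.reshape(-1, p + 1)
    summary = pd.DataFrame({
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1),
        "q2.5": np.percentile(flat, 2.5, axis=0),
        "median": np.median(flat, axis=0),
        "q97.5": np.percentile(flat, 97.5, axis=0),
    }, index=names + ["sigma2_R"])
    ess = None
    try:  # effective sample size when arviz is available
        import arviz as az
        ess = pd.Series(
            az.ess(az.convert_to_dataset(draws)).to_array().values.ravel()[:p + 1],
            index=names + ["sigma2_R"])
    except Exception:
        pass
    return PosteriorSummary(summary, draws, ess)


def gelman_rubin(post: PosteriorSummary) -> pd.Series:
    """Split-free potential scale reduction factor across chains."""
    draws = post.draws
    m, n_d, _ = draws.shape
    if m < 2:
        raise ValueError("R-hat needs >= 2 chains")
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B = n_d * chain_means.var(axis=0, ddof=1)
    var_hat = (n_d - 1) / n_d * W + B / n_d
    return pd.Series(np.sqrt(var_hat / W), index=post.summary.index)


def summarize_effects(post: PosteriorSummary, unit_scale: dict | float = 1.0
                      ) -> pd.DataFrame:
    """Rescale posterior summaries (e.g. a per-meter slope x1000 -> per km)."""
    df = post.summary.copy()
    if np.isscalar(unit_scale):
        unit_scale = {name: unit_scale for name in df.index}
    for name, s in unit_scale.items():
        if name not in df.index:
            raise KeyError(f"unknown parameter {name!r}")
        cols = ["mean", "sd", "q2.5", "median", "q97.5"]
        df.loc[name, cols] = df.loc[name, cols] * s
    return df.reset_index(names="parameter")
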