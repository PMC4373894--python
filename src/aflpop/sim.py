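"""Synthetic dominant-marker data with the structure the analyses assume.

The generator realises a two-level island model via Balding-Nichols sampling:
ancestral allele frequencies are drawn uniformly, group frequencies around
them with variance set by F_CT, and population frequencies around those with
per-locus-class within-group F_ST targets.  Diploid genotypes are drawn with
inbreeding coefficient F_IS (negative values allowed; impossible genotype
frequencies are truncated at zero and renormalised, with truncations
counted), then dominance collapses genotypes to band phenotypes so synthetic
data traverse exactly the same inference path as real data.

The default configuration is the study design this package targets: 2 sites
x 2 habitats x 30 trees, 1196 markers of which 1146 are neutral (within-group
F_ST 0.039 in group 1 and 0.026 in group 2), 25 under moderate divergent
selection (F_ST 0.11) and 25 under strong selection (F_ST 0.23), with
F_CT = 0.01 between sites and F_IS = -0.14.

`error_rate_evaluation` runs the 100-dataset Type I / Type II calibration:
each dataset is scanned per group at FDR 0.10 and the flagged-neutral and
missed-selected fractions are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqs import DEFAULT_FIS, compute_freq_table, freq_table_from_counts
from .io import ABSENT, MISSING, PRESENT, BandMatrix
from .outliers import FDR_THRESHOLD, bayesian_scan, coalescent_scan

logger = logging.getLogger(__name__)


@dataclass
class LocusClass:
    n_loci: int
    target_fst: float | tuple     # scalar, or one value per group
    label: str


@dataclass
class SimConfig:
    n_groups: int = 2
    pops_per_group: int = 2
    n_per_pop: int = 30
    f_ct: float = 0.01
    classes: list = field(default_factory=lambda: [
        LocusClass(1146, (0.039, 0.026), "neutral"),
        LocusClass(25, 0.11, "moderate"),
        LocusClass(25, 0.23, "strong"),
    ])
    fis: float = DEFAULT_FIS
    anc_bounds: tuple = (0.1, 0.9)
    replicate_error: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.n_groups < 1 or self.pops_per_group < 1 or self.n_per_pop < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.f_ct < 1:
            raise ValueError("F_CT must be in [0, 1)")
        for c in self.classes:
            for f in np.atleast_1d(c.target_fst):
                if not 0 <= f < 1:
                    raise ValueError("class F_ST must be in [0, 1)")

    @property
    def n_loci(self) -> int:
        return sum(c.n_loci for c in self.classes)


def calibration_design() -> SimConfig:
    """The published calibration design (120 trees x 1196 markers)."""
    return SimConfig()


def bn_subpop_freqs(p_anc, fst, n_pops, rng):
    """Balding-Nichols island-model frequencies (beta around the ancestral).

    Variance is ``p_anc (1 - p_anc) fst``; ``fst = 0`` returns the ancestral
    frequency exactly for every population.
    """
    from .outliers import bn_freqs
    return bn_freqs(p_anc, fst, n_pops, rng)


def _genotype_probs(p0, fis):
    """(g00, g10, g11) genotype probabilities, truncated-renormalised.

    Returns the probability stack and the number of loci whose raw
    frequencies were negative (possible when fis < 0 at extreme p).
    """
    q = 1.0 - p0
    g00 = (1.0 - fis) * p0 * p0 + fis * p0
    g10 = 2.0 * (1.0 - fis) * p0 * q
    g11 = (1.0 - fis) * q * q + fis * q
    raw = np.stack([g00, g10, g11])
    truncated = int((raw < 0).any(axis=0).sum())
    raw = np.clip(raw, 0.0, None)
    return raw / raw.sum(axis=0), truncated


def sample_band_phenotypes(pop_p0, n_per_pop, fis, rng):
    """Draw per-individual band phenotypes for each population x locus.

    ``pop_p0`` is (n_pops, n_loci) '0'-allele frequencies.  Returns an
    (n_pops * n_per_pop, n_loci) 0/1 array (individuals blocked by
    population) and the truncation count.
    """
    n_pops, n_loci = pop_p0.shape
    probs, truncated = _genotype_probs(pop_p0, fis)
    absent_prob = probs[0]
    u = rng.random((n_pops, n_per_pop, n_loci))
    bands = (u >= absent_prob[:, None, :]).astype(np.int8)
    return bands.reshape(n_pops * n_per_pop, n_loci), truncated


def simulate_dataset(cfg: SimConfig, rng=None):
    """Simulate (BandMatrix, SampleTable, TruthTable) under ``cfg``.

    Sites are groups (separated by ~300 km in the generated coordinates),
    habitats are populations within sites (bottomland low / hilltop high
    elevation, ~200 m apart, individuals jittered within 50 m).
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    L = cfg.n_loci
    G, P, n = cfg.n_groups, cfg.pops_per_group, cfg.n_per_pop
    p_anc = rng.uniform(*cfg.anc_bounds, size=L)
    group_p = bn_subpop_freqs(p_anc, cfg.f_ct, G, rng)

    pop_p0 = np.empty((G * P, L))
    labels = np.empty(L, dtype=object)
    targets = np.empty((G, L))
    start = 0
    for c in cfg.classes:
        sl = slice(start, start + c.n_loci)
        fsts = np.atleast_1d(np.asarray(c.target_fst, dtype=float))
        if len(fsts) == 1:
            fsts = np.repeat(fsts, G)
        elif len(fsts) != G:
            raise ValueError(f"class {c.label!r}: need 1 or {G} F_ST targets")
        for g in range(G):
            pop_p0[g * P:(g + 1) * P, sl] = bn_subpop_freqs(
                group_p[g, sl], float(fsts[g]), P, rng)
            targets[g, sl] = fsts[g]
        labels[sl] = c.label
        start += c.n_loci
    if start != L:
        raise AssertionError("locus classes do not tile the marker set")

    bands_arr, truncated = sample_band_phenotypes(pop_p0, n, cfg.fis, rng)
    if truncated:
        logger.info("truncated genotype law at %d / %d pop-locus draws",
                    truncated, pop_p0.size)

    sample_ids, rows = [], []
    habitats = ["bottomland", "hilltop"]
    for g in range(G):
        site = f"site{g + 1}"
        for p in range(P):
            hab = habitats[p % 2] if P <= 2 else f"hab{p + 1}"
            cx, cy = 300000.0 * g, 200.0 * p
            for i in range(n):
                sid = f"{site}_{hab}_{i + 1:02d}"
                sample_ids.append(sid)
                rows.append((sid, site, hab,
                             cx + rng.uniform(-50, 50),
                             cy + rng.uniform(-50, 50),
                             (20.0 if hab == "bottomland" else 60.0)
                             + rng.uniform(-5, 5)))
    markers = [f"L{j + 1:04d}" for j in range(L)]
    bands = BandMatrix(sample_ids, markers, bands_arr)
    samples = pd.DataFrame(rows, columns=["sample_id", "site", "habitat",
                                          "x", "y", "elevation"])
    truth = pd.DataFrame({"marker": markers, "label": labels,
                          "target_fst_group1": targets[0],
                          "target_fst_group2": targets[min(1, G - 1)]})
    return bands, samples, truth


def simulate_spatial_population(grid: int = 10, deme_size: int = 50,
                                migration: float = 0.1,
                                n_generations: int = 200, n_loci: int = 100,
                                fis: float = 0.0, sampled_per_deme: int = 2,
                                deme_spacing: float = 50.0, rng=None):
    """Stepping-stone forward simulation on a grid (isolation by distance).

    Allele frequencies evolve by nearest-neighbor migration (rate
    ``migration`` split among the 4 neighbors) and binomial drift over
    ``n_generations``; sampled individuals sit at deme centers plus uniform
    jitter, and dominant band phenotypes are emitted.
    """
    if not 0 < migration <= 0.5:
        raise ValueError("migration rate must be in (0, 0.5]")
    if grid < 3:
        raise ValueError("grid must be at least 3x3")
    if n_generations < 10 / migration:
        logger.warning("only %d generations for m=%.3g; quasi-equilibrium "
                       "needs roughly >= %d", n_generations, migration,
                       int(10 / migration))
    rng = np.random.default_rng(rng)
    freq = np.broadcast_to(rng.uniform(0.2, 0.8, n_loci),
                           (grid, grid, n_loci)).copy()
    for _ in range(n_generations):
        # torus topology: np.roll wraps the grid edges
        neigh = (np.roll(freq, 1, 0) + np.roll(freq, -1, 0)
                 + np.roll(freq, 1, 1) + np.roll(freq, -1, 1)) / 4.0
        freq = (1 - migration) * freq + migration * neigh
        freq = rng.binomial(2 * deme_size, freq) / (2.0 * deme_size)

    sample_ids, rows, profiles = [], [], []
    for ix in range(grid):
        for iy in range(grid):
            pop_p0 = freq[ix, iy][None, :]
            bands_arr, _ = sample_band_phenotypes(pop_p0, sampled_per_deme,
                                                  fis, rng)
            for s in range(sampled_per_deme):
                sid = f"d{ix}_{iy}_{s}"
                sample_ids.append(sid)
                rows.append((sid, "site1", "hab1",
                             ix * deme_spacing + rng.uniform(-5, 5),
                             iy * deme_spacing + rng.uniform(-5, 5), 0.0))
                profiles.append(bands_arr[s])
    markers = [f"L{j + 1:04d}" for j in range(n_loci)]
    bands = BandMatrix(sample_ids, markers, np.asarray(profiles, dtype=np.int8))
    samples = pd.DataFrame(rows, columns=["sample_id", "site", "habitat",
                                          "x", "y", "elevation"])
    return bands, samples


def replicate_pair(bands: BandMatrix, error_rate: float = 0.02,
                   missing_rate: float = 0.02, rng=None,
                   n_controls: int = 2):
    """Two noisy replicate copies plus synthetic negative-control peaks.

    Each replicate flips every 0/1 cell independently with probability
    ``error_rate`` and blanks it with probability ``missing_rate``; the
    control peak table mimics low-fluorescence noise below any real signal.
    """
    if not (0 <= error_rate < 0.5 and 0 <= missing_rate < 0.5):
        raise ValueError("error_rate and missing_rate must be in [0, 0.5)")
    rng = np.random.default_rng(rng)

    def noisy():
        v = bands.values.copy()
        scored = v != MISSING
        flip = scored & (rng.random(v.shape) < error_rate)
        v[flip] = 1 - v[flip]
        v[scored & (rng.random(v.shape) < missing_rate)] = MISSING
        return BandMatrix(list(bands.sample_ids), list(bands.marker_ids), v)

    controls = pd.DataFrame({
        "sample_id": [f"neg_ctrl_{i + 1}" for i in range(n_controls)],
        "combo": "combo1",
        "bin": 0,
        "height": rng.uniform(20, 50, n_controls),
        "is_control": True,
    })
    return noisy(), noisy(), controls


@dataclass
class ErrorRateReport:
    method: str
    alpha_pct: float              # flagged neutral / total neutral, %
    beta_pct: float               # missed selected / total selected, %
    alpha_by_group: dict
    beta_by_group: dict
    n_datasets: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": self.method, "group": "all",
                 "alpha_pct": self.alpha_pct, "beta_pct": self.beta_pct}]
        for g in self.alpha_by_group:
            rows.append({"method": self.method, "group": g,
                         "alpha_pct": self.alpha_by_group[g],
                         "beta_pct": self.beta_by_group[g]})
        return pd.DataFrame(rows)


def _scan_group_flags(freqs_pair, method, scan, rng):
    if method == "coalescent":
        res = coalescent_scan(
            freqs_pair, model="island",
            n_sim=scan.get("n_sim", 20000),
            he_bins=scan.get("he_bins", 20),
            fdr=scan.get("fdr", FDR_THRESHOLD),
            fdr_method=scan.get("fdr_method", "local_fdr"),
            seed=rng)
        return res["flag_coalescent"].to_numpy(dtype=bool)
    if method == "bayesian":
        res = bayesian_scan(
            freqs_pair,
            n_iter=scan.get("n_iter", 50000),
            burn_in=scan.get("burn_in", 10000),
            thin=scan.get("thin", 10),
            prior_odds=scan.get("prior_odds", 10.0),
            fdr=scan.get("fdr", FDR_THRESHOLD),
            seed=rng)
        return res.flags
    raise ValueError(f"unknown scan method {method!r}")


def error_rate_evaluation(cfg: SimConfig, n_datasets: int = 100,
                          methods=("coalescent",), scan_settings=None,
                          seed=None) -> dict:
    """Type I / Type II error rates of the outlier scans on simulated data.

    Each dataset is simulated under ``cfg`` and scanned separately within
    each group (site) at the configured FDR threshold.  Type I error is the
    fraction of neutral loci flagged, Type II the fraction of selected loci
    not flagged (loci untestable in a group, e.g. monomorphic, count as not
    flagged), both relative to the full simulated class sizes and averaged
    over datasets and groups.  Returns ``{method: ErrorRateReport}``.
    """
    scan_settings = scan_settings or {}
    master = np.random.default_rng(seed)
    group_names = [f"site{g + 1}" for g in range(cfg.n_groups)]
    tallies = {m: {g: dict(fp=0, tn=0, fn=0, tp=0) for g in group_names}
               for m in methods}
    failed = 0
    for d in range(n_datasets):
        rng = np.random.default_rng(master.integers(2 ** 31))
        bands, samples, truth = simulate_dataset(cfg, rng)
        neutral = (truth["label"] == "neutral").to_numpy()
        freqs = compute_freq_table(bands, samples, fis=cfg.fis)
        try:
            for g, gname in enumerate(group_names):
                pops = [p for p in freqs.populations if p.startswith(gname + ":")]
                fpair = freqs.restrict(pops)
                for m in methods:
                    flags = _scan_group_flags(
                        fpair, m, scan_settings.get(m, scan_settings),
                        np.random.default_rng(master.integers(2 ** 31)))
                    t = tallies[m][gname]
                    t["fp"] += int(flags[neutral].sum())
                    t["tn"] += int(neutral.sum()) - int(flags[neutral].sum())
                    t["tp"] += int(flags[~neutral].sum())
                    t["fn"] += int((~neutral).sum()) - int(flags[~neutral].sum())
        except Exception:
            failed += 1
            logger.exception("dataset %d failed; excluded", d)
    out = {}
    for m in methods:
        a_by = {g: 100.0 * t["fp"] / max(t["fp"] + t["tn"], 1)
                for g, t in tallies[m].items()}
        b_by = {g: 100.0 * t["fn"] / max(t["fn"] + t["tp"], 1)
                for g, t in tallies[m].items()}
        fp = sum(t["fp"] for t in tallies[m].values())
        tn = sum(t["tn"] for t in tallies[m].values())
        fn = sum(t["fn"] for t in tallies[m].values())
        tp = sum(t["tp"] for t in tallies[m].values())
        out[m] = ErrorRateReport(
            m, 100.0 * fp / max(fp + tn, 1), 100.0 * fn / max(fn + tp, 1),
            a_by, b_by, n_datasets - failed, failed)
    return out
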