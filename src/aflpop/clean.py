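"""Replicate-based cleaning of AFLP band calls.

The full genotyping protocol is run twice independently per sample; cleaning
proceeds in three steps: (i) peak-detection thresholds are set from negative
controls per primer combination, (ii) the two replicate band matrices are
collapsed to a consensus profile in which only replicated genotypes are kept
(disagreements become missing), and (iii) markers without sufficient coverage
in every site x habitat cell are dropped.

Peak binning / electrophoregram alignment is done upstream by dedicated
scoring software; this module starts from peak/bin tables and 0/1 matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ABSENT, MISSING, PRESENT, BandMatrix

PEAK_COLUMNS = ["sample_id", "combo", "bin", "height", "is_control"]

#: reason codes recorded by filter_markers
REASON_LOW_COVERAGE = "low-coverage cell"
REASON_MONOMORPHIC = "monomorphic-after-clean"


@dataclass
class CleaningReport:
    markers_in: int
    markers_out: int
    reasons: dict = field(default_factory=dict)       # marker -> reason code
    monomorphic: list = field(default_factory=list)   # flagged, not dropped
    mismatch_rate: dict = field(default_factory=dict) # sample -> replicate mismatch

    @property
    def retained_fraction(self) -> float:
        return self.markers_out / self.markers_in if self.markers_in else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": list(self.reasons), "reason": list(self.reasons.values())})


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing required column(s): {missing}")
    if (df["height"] < 0).any():
        raise ValueError("negative peak height")
    return df


def detection_threshold(peaks: pd.DataFrame, multiplier: float = 1.0,
                        fallback: float | None = None) -> dict:
    """Peak-detection threshold per primer combination from negative controls.

    The threshold is the maximum control peak height times ``multiplier``
    (peaks at or below it are treated as absent).  A combination with no
    control peaks uses ``fallback`` or raises.
    """
    out = {}
    ctrl = peaks[peaks["is_control"].astype(bool)]
    for combo in peaks["combo"].unique():
        h = ctrl.loc[ctrl["combo"] == combo, "height"]
        if len(h):
            out[combo] = float(h.max()) * multiplier
        elif fallback is not None:
            out[combo] = float(fallback)
        else:
            raise ValueError(f"no negative controls for combination {combo!r} "
                             "and no fallback threshold configured")
    return out


def bands_from_peaks(peaks: pd.DataFrame, thresholds: dict) -> BandMatrix:
    """Call bands from a peak table: present iff a peak exceeds its threshold.

    Markers are named ``combo:bin``; samples without any peak at a bin are
    scored absent (AFLP absence of amplification), control rows are dropped.
    """
    obs = peaks[~peaks["is_control"].astype(bool)].copy()
    obs["marker"] = obs["combo"].astype(str) + ":" + obs["bin"].astype(str)
    obs["thr"] = obs["combo"].map(thresholds)
    if obs["thr"].isna().any():
        raise ValueError("peak table contains a combination without a threshold")
    samples = sorted(obs["sample_id"].astype(str).unique())
    markers = sorted(obs["marker"].unique())
    vals = np.full((len(samples), len(markers)), ABSENT, dtype=np.int8)
    hit = obs[obs["height"] > obs["thr"]]
    si = pd.Index(samples)
    mi = pd.Index(markers)
    vals[si.get_indexer(hit["sample_id"].astype(str)),
         mi.get_indexer(hit["marker"])] = PRESENT
    return BandMatrix(samples, markers, vals)


def replicate_mismatch_rate(rep_a: BandMatrix, rep_b: BandMatrix) -> dict:
    """Per-sample fraction of markers scored 0/1 in both replicates that disagree."""
    a, b = _align(rep_a, rep_b)
    both = a.scored & b.scored
    dis = both & (a.values != b.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = dis.sum(axis=1) / both.sum(axis=1)
    return dict(zip(a.sample_ids, rate))


def _align(rep_a: BandMatrix, rep_b: BandMatrix):
    samples = [s for s in rep_a.sample_ids if s in set(rep_b.sample_ids)]
    markers = [m for m in rep_a.marker_ids if m in set(rep_b.marker_ids)]
    if not samples or not markers:
        raise ValueError("replicates share no samples or no markers")
    if len(samples) < rep_a.n_samples or len(samples) < rep_b.n_samples \
            or len(markers) < rep_a.n_markers or len(markers) < rep_b.n_markers:
        warnings.warn("replicates differ in samples/markers; using intersection")
        rep_a = rep_a.subset(samples, markers)
        rep_b = rep_b.subset(samples, markers)
    else:
        rep_b = rep_b.subset(samples, markers)
    return rep_a, rep_b


def consensus_profiles(rep_a: BandMatrix, rep_b: BandMatrix) -> BandMatrix:
    """Keep only replicated genotypes; disagreeing or missing calls -> missing."""
    a, b = _align(rep_a, rep_b)
    agree = (a.values == b.values) & a.scored
    vals = np.where(agree, a.values, MISSING).astype(np.int8)
    return BandMatrix(list(a.sample_ids), list(a.marker_ids), vals)


def filter_markers(bands: BandMatrix, samples: pd.DataFrame,
                   min_per_cell: int = 15) -> tuple[BandMatrix, CleaningReport]:
    """Keep markers genotyped in >= ``min_per_cell`` samples per site/habitat cell.

    Markers that are monomorphic across all retained samples after cleaning
    are flagged in the report but not dropped (they become 'na' in per-site
    statistics downstream).
    """
    meta = samples.set_index("sample_id").loc[bands.sample_ids]
    keys = meta["site"].astype(str) + ":" + meta["habitat"].astype(str)
    scored = bands.scored
    reasons = {}
    keep = np.ones(bands.n_markers, dtype=bool)
    for cell, rows in keys.groupby(keys).groups.items():
        mask = keys.index.isin(rows)
        if mask.sum() < min_per_cell:
            raise ValueError(
                f"cell {cell!r} has only {int(mask.sum())} samples; the "
                f">= {min_per_cell} per-cell coverage filter is unsatisfiable")
        low = scored[mask].sum(axis=0) < min_per_cell
        keep &= ~low
        for j in np.where(low)[0]:
            reasons.setdefault(bands.marker_ids[j], REASON_LOW_COVERAGE)
    kept = bands.subset(markers=[m for m, k in zip(bands.marker_ids, keep) if k])
    mono = []
    for j, m in enumerate(kept.marker_ids):
        col = kept.values[:, j]
        col = col[col != MISSING]
        if col.size and (col == col[0]).all():
            mono.append(m)
            reasons.setdefault(m, REASON_MONOMORPHIC)
    report = CleaningReport(markers_in=bands.n_markers, markers_out=kept.n_markers,
                            reasons=reasons, monomorphic=mono)
    return kept, report


def clean_pipeline(rep_a: BandMatrix, rep_b: BandMatrix, samples: pd.DataFrame,
                   min_per_cell: int = 15) -> tuple[BandMatrix, CleaningReport]:
    """Consensus + coverage filter, with replicate mismatch rates in the report."""
    consensus = consensus_profiles(rep_a, rep_b)
    kept, report = filter_markers(consensus, samples, min_per_cell=min_per_cell)
    report.mismatch_rate = replicate_mismatch_rate(rep_a, rep_b)
    return kept, report
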