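"""Tabular I/O and pairwise genetic distances for dominant-marker data.

The central container is :class:`BandMatrix`, a samples x markers matrix of
dominant band phenotypes (1 = band present, 0 = band absent, missing allowed).
Sample metadata (site, habitat, planar coordinates in meters, elevation) live
in a :class:`SampleTable`; per (site, habitat) environmental descriptors in an
:class:`EnvTable`.  All files are plain delimited text (tab or comma,
auto-detected) so matrices exported from standard AFLP scoring tools can be
read directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: integer codes used inside BandMatrix.values
PRESENT = 1
ABSENT = 0
MISSING = -1

#: string labels accepted for ordinal environment codes
WATERLOG_LABELS = {"none": 0, "no": 0, "seasonal": 1, "permanent": 2}
DROUGHT_LABELS = {"low": 0, "intermediate": 1, "strong": 2, "very strong": 3,
                  "very_strong": 3}


class BandMatrixError(ValueError):
    """Raised when a band matrix violates its invariants."""


@dataclass
class BandMatrix:
    """Dominant band phenotypes for a set of samples at a set of markers.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered, unique identifiers.
    values
        ``(n_samples, n_markers)`` int8 array with entries in
        ``{PRESENT, ABSENT, MISSING}``.
    """

    sample_ids: list
    marker_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.marker_ids)
        if n < 1 or m < 1:
            raise BandMatrixError("band matrix needs at least 1 sample and 1 marker")
        if len(set(self.sample_ids)) != n:
            raise BandMatrixError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise BandMatrixError("duplicate marker ids")
        if self.values.shape != (n, m):
            raise BandMatrixError(
                f"values shape {self.values.shape} does not match ids ({n}, {m})")
        bad = ~np.isin(self.values, (PRESENT, ABSENT, MISSING))
        if bad.any():
            raise BandMatrixError(
                f"{bad.sum()} cell(s) outside {{0, 1, missing}}")

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def present(self) -> np.ndarray:
        return self.values == PRESENT

    @property
    def absent(self) -> np.ndarray:
        return self.values == ABSENT

    @property
    def scored(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.values != MISSING

    def to_frame(self, missing_token: str = "NA") -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(object), index=self.sample_ids,
                          columns=self.marker_ids)
        return df.where(self.values != MISSING, missing_token)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, missing_token: str = "NA") -> "BandMatrix":
        raw = df.astype(str).to_numpy()
        vals = np.full(raw.shape, MISSING, dtype=np.int8)
        vals[raw == "0"] = ABSENT
        vals[raw == "1"] = PRESENT
        unknown = ~np.isin(raw, ("0", "1", missing_token, "nan", ""))
        if unknown.any():
            i, j = np.argwhere(unknown)[0]
            raise BandMatrixError(
                f"cell ({df.index[i]}, {df.columns[j]}) = {raw[i, j]!r} "
                f"is not 0/1/{missing_token}")
        return cls(list(df.index), list(df.columns), vals)

    def subset(self, samples=None, markers=None) -> "BandMatrix":
        si = (np.arange(self.n_samples) if samples is None else
              np.asarray([self.sample_ids.index(s) for s in samples]))
        mi = (np.arange(self.n_markers) if markers is None else
              np.asarray([self.marker_ids.index(m) for m in markers]))
        return BandMatrix([self.sample_ids[i] for i in si],
                          [self.marker_ids[j] for j in mi],
                          self.values[np.ix_(si, mi)])


@dataclass
class PairwiseMatrix:
    """Symmetric per-pair values (genetic distance or kinship)."""

    sample_ids: list
    values: np.ndarray            # (n, n) float, NaN = undefined pair
    metric: str = "jaccard"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("pairwise matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("pairwise matrix not symmetric")

    def condensed(self):
        """Upper-triangle (i<j) values and index pairs."""
        iu, ju = np.triu_indices(len(self.sample_ids), k=1)
        return iu, ju, self.values[iu, ju]


SAMPLE_COLUMNS = ["sample_id", "site", "habitat", "x", "y", "elevation"]
ENV_COLUMNS = ["site", "habitat", "soil_type", "waterlog", "drought"]


def _read_delimited(path, **kw) -> pd.DataFrame:
    """Read tab- or comma-delimited text, auto-detecting the separator."""
    return pd.read_csv(path, sep=None, engine="python", **kw)


def read_band_matrix(path, missing_token: str = "NA") -> BandMatrix:
    """Read a band matrix: first row marker ids, first column sample ids."""
    with open(path) as fh:
        header = fh.readline().strip()
    sep = "\t" if "\t" in header else ","
    markers = header.split(sep)[1:]
    if len(markers) != len(set(markers)):
        raise BandMatrixError("duplicate marker ids in file")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise BandMatrixError(f"empty band matrix file: {path}")
    if df.index.has_duplicates:
        raise BandMatrixError("duplicate sample ids in file")
    return BandMatrix.from_frame(df, missing_token=missing_token)


def write_band_matrix(bands: BandMatrix, path, sep="\t", missing_token="NA"):
    bands.to_frame(missing_token).to_csv(path, sep=sep, index_label="sample_id")


def read_sample_table(path) -> pd.DataFrame:
    """Read the per-sample table (sample_id, site, habitat, x, y, elevation)."""
    df = _read_delimited(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if extra:
        logger.warning("sample table: ignoring unknown column(s) %s", extra)
    df = df[SAMPLE_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    for c in ("x", "y", "elevation"):
        df[c] = pd.to_numeric(df[c], errors="raise")
        if not np.isfinite(df[c].to_numpy()).all():
            raise ValueError(f"non-finite values in sample table column {c!r}")
    return df


def read_env_table(path, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the per (site, habitat) environment table.

    ``waterlog`` accepts codes 0-2 or labels none/seasonal/permanent;
    ``drought`` codes 0-3 or labels low/intermediate/strong/very strong.
    When ``samples`` is given, every (site, habitat) cell present there must
    have a row.
    """
    df = _read_delimited(path)
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"environment table missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in ENV_COLUMNS]
    if extra:
        logger.warning("environment table: ignoring unknown column(s) %s", extra)
    df = df[ENV_COLUMNS].copy()

    def _ordinal(col, labels, hi):
        out = []
        for v in df[col]:
            sv = str(v).strip().lower()
            if sv in labels:
                out.append(labels[sv])
            else:
                iv = int(v)
                if not 0 <= iv <= hi:
                    raise ValueError(f"{col} code {iv} outside 0..{hi}")
                out.append(iv)
        df[col] = out

    _ordinal("waterlog", WATERLOG_LABELS, 2)
    _ordinal("drought", DROUGHT_LABELS, 3)
    if df.duplicated(["site", "habitat"]).any():
        raise ValueError("duplicate (site, habitat) row in environment table")
    if samples is not None:
        check_env_covers(samples, df)
    return df


def check_env_covers(samples: pd.DataFrame, env: pd.DataFrame):
    have = set(zip(env["site"], env["habitat"]))
    need = set(zip(samples["site"], samples["habitat"]))
    lacking = need - have
    if lacking:
        raise ValueError(f"environment table missing (site, habitat) cell(s): "
                         f"{sorted(lacking)}")


def write_table(df: pd.DataFrame, path, sep="\t"):
    df.to_csv(path, sep=sep, index=False)


def jaccard_distance_matrix(bands: BandMatrix, min_shared: int = 50) -> PairwiseMatrix:
    """Pairwise Jaccard genetic distance between band profiles.

    For each pair, over markers scored in both samples,
    ``d = 1 - M11 / (M11 + M10 + M01)``; double absences (both 0) carry no
    information about shared bands and are excluded.  Pairs sharing fewer than
    ``min_shared`` co-scored markers (or with an empty band union) are NaN.
    """
    P = bands.present.astype(np.float64)
    A = bands.absent.astype(np.float64)
    S = bands.scored.astype(np.float64)
    m11 = P @ P.T
    m10 = P @ A.T
    m01 = A @ P.T
    union = m11 + m10 + m01
    co_scored = S @ S.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - m11 / union
    bad = (union == 0) | (co_scored < min_shared)
    n_bad = int(np.triu(bad, 1).sum())
    if n_bad:
        warnings.warn(f"{n_bad} pair(s) with no shared band information or "
                      f"< {min_shared} co-scored markers set to missing")
    d[bad] = np.nan
    np.fill_diagonal(d, 0.0)
    # restore the diagonal NaN for samples that are entirely missing
    return PairwiseMatrix(list(bands.sample_ids), d, metric="jaccard")
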