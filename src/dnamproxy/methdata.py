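"""Data model, I/O and quality-control filters for methylation beta matrices.

The central container is :class:`BetaMatrix`: a probes × samples matrix of
methylation fractions (beta values in [0, 1]) with optional per-cell
detection p-values and per-sample batch labels.  Filters mirror the standard
array QC steps: dropping probes with a poor detection rate, dropping samples
with a low call rate, and restricting to a probe set shared between array
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeSet",
    "load_beta_matrix",
    "write_beta_matrix",
    "filter_probes_by_detection",
    "filter_samples_by_callrate",
    "intersect_probes",
    # documented QC presets (two cohort conventions; neither privileged)
    "DETECTION_PRESET_STRICT",
    "DETECTION_PRESET_LENIENT",
]

# Two common detection-filter conventions: (p_threshold, max_fail_fraction).
DETECTION_PRESET_STRICT = (0.01, 0.0)     # probe fails if any sample has p > .01
DETECTION_PRESET_LENIENT = (0.05, 0.05)   # probe fails if >5% of samples have p > .05


class BetaMatrixError(ValueError):
    """Raised for malformed or out-of-range beta matrices."""


@dataclass(frozen=True)
class ProbeSet:
    """A set of probe identifiers (e.g. the 450K ∩ EPIC intersection)."""

    ids: frozenset[str]

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "ProbeSet":
        ids = list(ids)
        fs = frozenset(ids)
        if len(fs) != len(ids):
            raise BetaMatrixError("ProbeSet ids must be unique")
        return cls(fs)

    def __contains__(self, probe: str) -> bool:
        return probe in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class BetaMatrix:
    """Probes × samples methylation fractions with optional QC side-tables.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns; entries are
        beta values in [0, 1] or NaN for missing.
    detection_p
        Optional DataFrame of the same shape holding per-cell detection
        p-values.
    batch
        Optional per-sample batch/plate labels (index = sample ids).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise BetaMatrixError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if self.detection_p is not None:
            dp = self.detection_p
            if dp.shape != v.shape:
                raise BetaMatrixError(
                    f"detection_p shape {dp.shape} != beta shape {v.shape}"
                )
            if not dp.index.equals(v.index) or not dp.columns.equals(v.columns):
                raise BetaMatrixError("detection_p ids do not match beta ids")
        if self.batch is not None:
            if not self.batch.index.equals(v.columns):
                raise BetaMatrixError("batch index does not match sample ids")

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        """Restrict to the given probe/sample ids, preserving original order."""
        v = self.values
        if probes is not None:
            keep = [p for p in v.index if p in set(probes)]
            v = v.loc[keep]
        if samples is not None:
            keep_s = [s for s in v.columns if s in set(samples)]
            v = v[keep_s]
        dp = None
        if self.detection_p is not None:
            dp = self.detection_p.loc[v.index, v.columns]
        b = None
        if self.batch is not None:
            b = self.batch.loc[v.columns]
        return BetaMatrix(values=v, detection_p=dp, batch=b)


# -- I/O ---------------------------------------------------------------------

Layout = Literal["probes-by-samples", "samples-by-probes"]


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_beta_matrix(
    path,
    layout: Layout = "probes-by-samples",
    detection_p_path=None,
    sep: str | None = None,
) -> BetaMatrix:
    """Load a beta matrix from delimited text (gzip-transparent).

    ``layout`` says how the file is oriented; the in-memory object is always
    probes × samples.  Values outside [0, 1] are rejected with the offending
    probe and sample named; missing cells (empty/NA) are preserved as NaN.
    """
    df = _read_table(path, sep)
    if layout == "samples-by-probes":
        df = df.T
    elif layout != "probes-by-samples":
        raise ValueError(f"unknown layout {layout!r}")
    dp = None
    if detection_p_path is not None:
        dp = _read_table(detection_p_path, sep)
        if layout == "samples-by-probes":
            dp = dp.T
    return BetaMatrix(values=df.astype(float), detection_p=dp)


def write_beta_matrix(
    m: BetaMatrix,
    path,
    detection_p_path=None,
    sep: str = "\t",
    float_precision: int = 6,
) -> None:
    """Write probes-as-rows delimited text; round-trips with ``load_beta_matrix``
    to the configured decimal precision (default 6 places)."""
    fmt = f"%.{float_precision}g"
    m.values.to_csv(path, sep=sep, float_format=fmt)
    if detection_p_path is not None:
        if m.detection_p is None:
            raise BetaMatrixError("matrix has no detection_p to write")
        m.detection_p.to_csv(detection_p_path, sep=sep, float_format=fmt)


# -- QC filters ---------------------------------------------------------------


def _require_detection(m: BetaMatrix) -> pd.DataFrame:
    if m.detection_p is None:
        raise BetaMatrixError("operation requires detection p-values")
    return m.detection_p


def filter_probes_by_detection(
    m: BetaMatrix, p_threshold: float, max_fail_fraction: float
) -> BetaMatrix:
    """Drop probes whose fraction of samples with detection p > ``p_threshold``
    exceeds ``max_fail_fraction``.  Samples are untouched; retained probe order
    is preserved, so the filter is idempotent."""
    dp = _require_detection(m)
    fail_frac = (dp.to_numpy() > p_threshold).mean(axis=1)
    keep = m.values.index[fail_frac <= max_fail_fraction]
    return m.subset(probes=keep)


def filter_samples_by_callrate(
    m: BetaMatrix, p_threshold: float, min_detected: int
) -> BetaMatrix:
    """Drop samples with fewer than ``min_detected`` probes detected at
    p < ``p_threshold``."""
    dp = _require_detection(m)
    n_det = (dp.to_numpy() < p_threshold).sum(axis=0)
    keep = m.values.columns[n_det >= min_detected]
    return m.subset(samples=keep)


def intersect_probes(m: BetaMatrix, keep: ProbeSet) -> BetaMatrix:
    """Restrict to probes present in ``keep``, preserving matrix order.

    Raises if the intersection is empty (no probes left to train or score on).
    """
    inter = [p for p in m.values.index if p in keep]
    if not inter:
        raise BetaMatrixError("probe intersection is empty")
    return m.subset(probes=inter)
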