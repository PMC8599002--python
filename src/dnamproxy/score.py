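"""Sparse probe-weight scores: representation, serialization and projection.

An *episcore* is a sparse map from probe ids to real weights.  Projecting it
into a beta matrix computes, per sample, the weighted sum of beta values over
the score's probes — the standard poly-epigenetic score construction.  No
intercept enters the projected score by default: downstream uses
(correlations, regressions) are location/scale free.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .methdata import BetaMatrix

__all__ = ["ProbeWeights", "project_score", "read_weights", "write_weights"]


class ScoreError(ValueError):
    pass


@dataclass
class ProbeWeights:
    """Probe id → weight map with optional intercept and training metadata."""

    weights: pd.Series
    intercept: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weights
        if not isinstance(w, pd.Series):
            w = pd.Series(dict(w), dtype=float)
        w = w.astype(float)
        if w.index.has_duplicates:
            dups = w.index[w.index.duplicated()].unique().tolist()
            raise ScoreError(f"duplicate probe ids in weights: {dups[:5]}")
        if not np.all(np.isfinite(w.to_numpy())):
            raise ScoreError("weights must be finite")
        # zeros are dropped: the score is defined by its nonzero support
        self.weights = w[w != 0.0]

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def probe_ids(self) -> list[str]:
        return self.weights.index.tolist()


def project_score(
    m: BetaMatrix,
    w: ProbeWeights,
    missing_policy: Literal["error", "mean_impute"] = "mean_impute",
    max_missing_weight_fraction: float = 0.2,
) -> pd.Series:
    """Per-sample weighted sum of beta values: scoreₛ = Σₚ wₚ · betaₚₛ.

    Probes absent from the matrix contribute 0 and are reported via a
    warning; if their absolute-weight mass exceeds
    ``max_missing_weight_fraction`` of the total, projection fails.  Under
    ``mean_impute``, per-sample missing cells of present probes are imputed
    with that probe's mean over the samples where it is observed; under
    ``error`` any absence raises.
    """
    if missing_policy not in ("error", "mean_impute"):
        raise ScoreError(f"unknown missing_policy {missing_policy!r}")
    if len(w) == 0:
        return pd.Series(0.0, index=m.values.columns, name="score")

    present = [p for p in w.probe_ids if p in m.values.index]
    absent = [p for p in w.probe_ids if p not in m.values.index]
    if absent:
        if missing_policy == "error":
            raise ScoreError(f"probes absent from matrix: {absent[:10]}")
        total_mass = float(np.abs(w.weights).sum())
        absent_mass = float(np.abs(w.weights[absent]).sum())
        if total_mass > 0 and absent_mass / total_mass > max_missing_weight_fraction:
            raise ScoreError(
                f"absent probes carry {absent_mass / total_mass:.1%} of weight "
                f"mass (limit {max_missing_weight_fraction:.1%}): {absent[:10]}"
            )
        warnings.warn(
            f"{len(absent)} score probes absent from matrix contribute 0: "
            f"{absent[:5]}"
        )
    if not present:
        return pd.Series(0.0, index=m.values.columns, name="score")

    B = m.values.loc[present]
    if B.isna().any().any():
        if missing_policy == "error":
            bad = B.index[B.isna().any(axis=1)].tolist()
            raise ScoreError(f"missing beta values at score probes: {bad[:10]}")
        B = B.apply(lambda row: row.fillna(row.mean()), axis=1)
        if B.isna().any().any():
            raise ScoreError("score probe with no observed values in any sample")
    wv = w.weights[present].to_numpy()
    scores = wv @ B.to_numpy(dtype=float)
    return pd.Series(scores, index=m.values.columns, name="score")


def write_weights(w: ProbeWeights, path) -> None:
    """Two-column TSV (probe, weight) with '#'-prefixed metadata lines;
    floats at full precision so the round-trip is lossless."""
    with open(path, "w") as fh:
        meta = dict(w.metadata)
        if w.intercept is not None:
            meta["intercept"] = w.intercept
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("probe\tweight\n")
        for probe, weight in w.weights.items():
            fh.write(f"{probe}\t{float(weight)!r}\n")


def read_weights(path) -> ProbeWeights:
    """Inverse of :func:`write_weights`; rejects duplicate probes and
    non-numeric weights."""
    metadata: dict = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                payload = line.lstrip("# ")
                if payload:
                    try:
                        metadata.update(json.loads(payload))
                    except json.JSONDecodeError:
                        metadata.setdefault("comments", []).append(payload)
                continue
            if not header_seen:
                header_seen = True  # "probe\tweight" header row
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ScoreError(f"line {lineno}: expected 2 columns")
            try:
                weight = float(parts[1])
            except ValueError as exc:
                raise ScoreError(
                    f"line {lineno}: non-numeric weight {parts[1]!r}"
                ) from exc
            if not math.isfinite(weight):
                raise ScoreError(f"line {lineno}: non-finite weight")
            rows.append((parts[0], weight))
    probes = [p for p, _ in rows]
    if len(set(probes)) != len(probes):
        seen, dups = set(), []
        for p in probes:
            if p in seen:
                dups.append(p)
            seen.add(p)
        raise ScoreError(f"duplicate probe rows: {dups[:5]}")
    intercept = metadata.pop("intercept", None)
    return ProbeWeights(
        weights=pd.Series(dict(rows), dtype=float).loc[probes],
        intercept=intercept,
        metadata=metadata,
    )
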