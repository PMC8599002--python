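"""Reference-based leukocyte deconvolution by constrained projection.

Each sample's methylome (over probes shared with the reference) is projected
onto the cell-type mean methylomes by solving the quadratic program

    min_w ‖b − R w‖²   subject to   w ≥ 0,  Σ w ≤ 1,

the constrained-projection formulation of reference-based cell-mixture
estimation.  With only six cell types the program is solved *exactly* by
enumerating every support subset (with and without the Σw = 1 boundary) and
taking the feasible candidate with the lowest objective — deterministic and
free of iterative-solver tolerance issues.

Estimated fractions are returned as a samples × cell-types DataFrame; the
optional ``renormalize`` flag rescales each row to sum exactly to 1.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .methdata import BetaMatrix
from .simulate import CellReference

__all__ = ["estimate_proportions", "DeconvError"]

_FEAS_EPS = 1e-9


class DeconvError(ValueError):
    pass


def _solve_one(G: np.ndarray, c: np.ndarray, bb: float) -> np.ndarray:
    """Exact minimizer of ‖b−Rw‖² over {w ≥ 0, Σw ≤ 1} given G=RᵀR, c=Rᵀb."""
    t = G.shape[0]
    best_obj = bb  # empty support: w = 0
    best_w = np.zeros(t)
    idx = np.arange(t)
    for k in range(1, t + 1):
        for S in combinations(idx, k):
            S = np.array(S)
            Gss = G[np.ix_(S, S)]
            cs = c[S]
            # interior candidate: unconstrained on S
            try:
                ws = np.linalg.solve(Gss, cs)
            except np.linalg.LinAlgError:
                ws = None
            if ws is not None and np.all(ws >= -_FEAS_EPS) and ws.sum() <= 1 + _FEAS_EPS:
                obj = bb - 2 * cs @ ws + ws @ Gss @ ws
                if obj < best_obj - 1e-15 * max(1.0, bb):
                    best_obj = obj
                    best_w = np.zeros(t)
                    best_w[S] = ws
            # boundary candidate: Σw = 1 on S (KKT with one multiplier)
            K = np.zeros((k + 1, k + 1))
            K[:k, :k] = Gss
            K[:k, k] = 1.0
            K[k, :k] = 1.0
            rhs = np.concatenate([cs, [1.0]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            ws = sol[:k]
            if np.all(ws >= -_FEAS_EPS):
                obj = bb - 2 * cs @ ws + ws @ Gss @ ws
                if obj < best_obj - 1e-15 * max(1.0, bb):
                    best_obj = obj
                    best_w = np.zeros(t)
                    best_w[S] = ws
    return np.clip(best_w, 0.0, None)


def estimate_proportions(
    m: BetaMatrix, ref: CellReference, renormalize: bool = False
) -> pd.DataFrame:
    """Estimate per-sample leukocyte fractions from shared probes.

    Probes are matched by id between matrix and reference; samples with
    missing beta at shared probes are solved on their observed subset.
    """
    ref_index = pd.Index(ref.probe_ids)
    shared = [p for p in ref_index if p in m.values.index]
    if not shared:
        raise DeconvError("no probes shared between matrix and reference")
    if len(shared) < 50:
        warnings.warn(
            f"only {len(shared)} probes shared with reference; "
            "estimates may be unstable"
        )
    ref_df = ref.to_frame().loc[shared]
    R = ref_df.to_numpy(dtype=float)
    B = m.values.loc[shared].to_numpy(dtype=float)  # shared probes × samples

    t = R.shape[1]
    n = B.shape[1]
    out = np.empty((n, t))
    G_full = R.T @ R
    for s in range(n):
        b = B[:, s]
        obs = ~np.isnan(b)
        if not obs.any():
            raise DeconvError(f"sample {m.values.columns[s]!r} has no observed "
                              "values at shared probes")
        if obs.all():
            G, c, bb = G_full, R.T @ b, float(b @ b)
        else:
            Ro, bo = R[obs], b[obs]
            G, c, bb = Ro.T @ Ro, Ro.T @ bo, float(bo @ bo)
        out[s] = _solve_one(G, c, bb)

    props = pd.DataFrame(out, index=m.values.columns, columns=ref_df.columns)
    if renormalize:
        sums = props.sum(axis=1)
        nonzero = sums > 0
        props.loc[nonzero] = props.loc[nonzero].div(sums[nonzero], axis=0)
    return props
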