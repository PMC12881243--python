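"""ABS Hebbian plasticity: discretised LTP/LTD with weight clipping.

A synapse from presynaptic neuron i to postsynaptic neuron j changes by
a fixed increment each step:

* ``+delta`` (LTP) when the presynaptic rate estimate omega_E(i) is at
  or above ``theta_pre`` and the postsynaptic potential V(j) is at or
  above ``theta_plus``;
* ``-delta`` (homosynaptic LTD) when the presynaptic rate is above
  threshold but V(j) sits in the band ``[theta_minus, theta_plus)``;
* ``-delta`` (heterosynaptic LTD) when the presynaptic rate is below
  threshold while V(j) is at or above ``theta_plus``;
* ``0`` otherwise.

All thresholds are inclusive; at the ambiguous boundary V == theta_plus
the LTP branch wins (branches evaluated in the order printed above).
Weights are clipped to ``[w_min, w_max]`` after every update.  Only E-E
connections are plastic.
"""

from __future__ import annotations

import numpy as np

from .params import PlasticityParameters

__all__ = ["hebbian_delta", "apply_plasticity", "abs_update_indexed"]


def hebbian_delta(omega_E_pre, V_post, p: PlasticityParameters):
    """Per-synapse weight change of the ABS rule (scalar or elementwise)."""
    pre = np.asarray(omega_E_pre, dtype=float)
    post = np.asarray(V_post, dtype=float)
    active = pre >= p.theta_pre
    hi = post >= p.theta_plus
    mid = (post >= p.theta_minus) & ~hi
    dw = np.where(active & hi, p.delta,
                  np.where(active & mid, -p.delta,
                           np.where(~active & hi, -p.delta, 0.0)))
    return float(dw) if dw.ndim == 0 else dw


def apply_plasticity(projection, pre_rates, post_potentials,
                     p: PlasticityParameters):
    """Update every edge of a plastic projection in place and clip.

    ``pre_rates`` / ``post_potentials`` are indexed by the projection's
    local source/target numbering.  Calling this on a non-plastic
    projection is a contract violation.
    """
    if not projection.spec.plastic:
        raise ValueError(
            f"projection {projection.spec.source_area}->"
            f"{projection.spec.target_area} ({projection.spec.synapse_class}) "
            "is not plastic")
    dw = hebbian_delta(np.asarray(pre_rates)[projection.pre],
                       np.asarray(post_potentials)[projection.post], p)
    np.clip(projection.weight + dw, p.w_min, p.w_max, out=projection.weight)
    return projection


def _take_rows(indptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    counts = indptr[rows + 1] - indptr[rows]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.repeat(indptr[rows] - cum, counts) + np.arange(total)


def abs_update_indexed(indptr, order, post, cptr, corder, pre, w,
                       om_r, V, p: PlasticityParameters) -> None:
    """One plasticity step over the shared E-E edge store (vectorised).

    Exploits the sparsity of change: only edges whose presynaptic rate is
    above ``theta_pre`` (LTP / homosynaptic LTD) or whose postsynaptic
    potential is above ``theta_plus`` (heterosynaptic LTD) can move.
    Equivalent branch-for-branch to :func:`hebbian_delta` applied to all
    edges, but linear in the number of affected edges.
    """
    active_pre = np.flatnonzero(om_r >= p.theta_pre)
    if active_pre.size:
        sel = order[_take_rows(indptr, active_pre)]
        v = V[post[sel]]
        up = v >= p.theta_plus
        down = (v >= p.theta_minus) & ~up
        touched = sel[up | down]
        if touched.size:
            w[touched] = np.clip(
                w[touched] + np.where(up[up | down], p.delta, -p.delta),
                p.w_min, p.w_max)
    hot_post = np.flatnonzero(V >= p.theta_plus)
    if hot_post.size:
        sel = corder[_take_rows(cptr, hot_post)]
        sel = sel[om_r[pre[sel]] < p.theta_pre]
        if sel.size:
            w[sel] = np.maximum(w[sel] - p.delta, p.w_min)
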