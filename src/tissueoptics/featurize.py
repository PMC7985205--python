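"""Compression of a photon exit log into spatio-temporal moments.

The reflected (or transmitted) photon cloud I(r, t) is summarized by its
weighted statistical moments up to a total order K (default 5):

* order 0: the total detected weight ``W = sum_i w_i``;
* order 1: the weighted means ``<r>`` and ``<t>``;
* order >= 2: the weighted central cross-moments
  ``<r^a t^b> = sum_i w_i (r_i - <r>)^a (t_i - <t>)^b / W``
  for all a + b <= K.

With K = 5 this yields 21 numbers, ordered canonically by ascending total
order and, within an order, by descending radial exponent. The moment set
is a dense, binning-free representation of the slab's spatio-temporal
impulse response and is the input of the neural inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .montecarlo import (
    REFLECTION,
    TRANSMISSION,
    ExitRecord,
    InvalidParameterError,
    SimulationResult,
)

__all__ = [
    "MomentIndex",
    "FeatureVector",
    "moment_indices",
    "moment_labels",
    "compute_moments",
    "N_FEATURES_DEFAULT",
]

#: Length of the default (max_order = 5) feature vector.
N_FEATURES_DEFAULT = 21


@dataclass(frozen=True)
class MomentIndex:
    """Exponent pair (alpha: radial order, beta: temporal order)."""

    alpha: int
    beta: int

    @property
    def order(self) -> int:
        return self.alpha + self.beta


def moment_indices(max_order: int = 5) -> List[MomentIndex]:
    """Enumerate all (alpha, beta) with alpha + beta <= max_order.

    Canonical order: ascending total order; within an order, descending
    alpha. The count is (K+1)(K+2)/2 — 21 for K = 5.
    """
    if max_order < 0:
        raise InvalidParameterError("max_order must be non-negative")
    return [
        MomentIndex(alpha=k - b, beta=b)
        for k in range(max_order + 1)
        for b in range(k + 1)
    ]


def moment_labels(max_order: int = 5) -> List[str]:
    """Column labels matching :func:`moment_indices`.

    The three sub-second-order slots carry their conventional names ``W``,
    ``r_mean`` and ``t_mean``; higher slots are ``m_<alpha>_<beta>``.
    """
    special = {(0, 0): "W", (1, 0): "r_mean", (0, 1): "t_mean"}
    return [
        special.get((ix.alpha, ix.beta), f"m_{ix.alpha}_{ix.beta}")
        for ix in moment_indices(max_order)
    ]


@dataclass
class FeatureVector:
    """Ordered moment values of one detector side of one run."""

    values: np.ndarray
    labels: List[str]
    max_order: int
    source_side: str
    valid: bool

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])


def _extract_arrays(records, side: str, include_specular: bool):
    """Pull (r, t, w) arrays for one detector side from any supported input."""
    if isinstance(records, SimulationResult):
        mask = records.reflected if side == REFLECTION else ~records.reflected
        r = records.r[mask]
        t = records.time[mask]
        w = records.weight[mask]
        if include_specular and side == REFLECTION and records.specular_weight > 0.0:
            r = np.concatenate([[0.0], r])
            t = np.concatenate([[0.0], t])
            w = np.concatenate([[records.specular_weight], w])
        return r, t, w
    if isinstance(records, pd.DataFrame):
        sub = records[records["side"] == side]
        if "r" in sub.columns:
            r = sub["r"].to_numpy(dtype=float)
        else:
            r = np.hypot(sub["x"].to_numpy(dtype=float), sub["y"].to_numpy(dtype=float))
        return r, sub["time"].to_numpy(dtype=float), sub["weight"].to_numpy(dtype=float)
    recs = [rec for rec in records if rec.side == side]
    r = np.array([rec.r for rec in recs], dtype=float)
    t = np.array([rec.time for rec in recs], dtype=float)
    w = np.array([rec.weight for rec in recs], dtype=float)
    return r, t, w


def compute_moments(
    records: Union[SimulationResult, pd.DataFrame, Sequence[ExitRecord]],
    max_order: int = 5,
    side: str = REFLECTION,
    include_specular: bool = True,
) -> FeatureVector:
    """Compute the ordered moment vector of one detector side.

    Accepts a :class:`SimulationResult`, an exit-log table (columns ``side``,
    ``weight``, ``time`` and ``r`` or ``x``/``y``) or a sequence of
    :class:`ExitRecord`. An empty detector (total weight 0) yields a vector
    flagged ``valid=False`` with NaN entries rather than silent zeros.

    Records are summed in a fixed (time, r) sort order so the result is
    independent of the input ordering, bit for bit.
    """
    if side not in (REFLECTION, TRANSMISSION):
        raise InvalidParameterError(f"side must be reflection|transmission, got {side!r}")
    indices = moment_indices(max_order)
    labels = moment_labels(max_order)
    r, t, w = _extract_arrays(records, side, include_specular)

    total_w = float(w.sum())
    if not total_w > 0.0:
        return FeatureVector(
            values=np.full(len(indices), np.nan),
            labels=labels,
            max_order=max_order,
            source_side=side,
            valid=False,
        )

    order = np.lexsort((r, t))
    r, t, w = r[order], t[order], w[order]

    r_mean = float((w * r).sum() / total_w)
    t_mean = float((w * t).sum() / total_w)
    dr = r - r_mean
    dt = t - t_mean
    # powers dr^a, dt^b for a, b in 0..max_order
    r_pow = np.ones((max_order + 1, r.size))
    t_pow = np.ones((max_order + 1, t.size))
    for k in range(1, max_order + 1):
        r_pow[k] = r_pow[k - 1] * dr
        t_pow[k] = t_pow[k - 1] * dt

    values = np.empty(len(indices))
    for i, ix in enumerate(indices):
        if ix.order == 0:
            values[i] = total_w
        elif (ix.alpha, ix.beta) == (1, 0):
            values[i] = r_mean
        elif (ix.alpha, ix.beta) == (0, 1):
            values[i] = t_mean
        else:
            values[i] = float((w * r_pow[ix.alpha] * t_pow[ix.beta]).sum() / total_w)
    return FeatureVector(
        values=values,
        labels=labels,
        max_order=max_order,
        source_side=side,
        valid=True,
    )
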