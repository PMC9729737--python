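"""Simplex geometry for 24-h time-use compositions.

A day is represented as a 4-part composition — minutes spent in sleep,
sedentary behaviour (SB), light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA) — closed to 1440 min.
Because the parts carry only relative information, regression modelling
works in isometric log-ratio (ilr) coordinates: three orthonormal
log-contrasts built from a sequential binary partition (SBP) of the parts.
With the default part order (sleep, SB, LPA, MVPA) the first "pivot"
coordinate contrasts sleep against the geometric mean of the remaining
behaviours, the second contrasts SB against {LPA, MVPA}, and the third is
the LPA:MVPA balance.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: canonical part order: sleep, sedentary behaviour, light PA, moderate-vigorous PA
PARTS: tuple[str, ...] = ("sleep", "sb", "lpa", "mvpa")

#: minutes in a day; every closed composition sums to this
DAY_MINUTES: float = 1440.0


def _as_parts(comp: Iterable[float]) -> np.ndarray:
    arr = np.asarray(comp, dtype=float)
    if arr.shape[-1] != len(PARTS):
        raise ValueError(f"expected {len(PARTS)} parts, got shape {arr.shape}")
    return arr


def closure(parts: Iterable[float], total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale strictly positive parts to sum to ``total`` (ratio-preserving).

    Raises ``ValueError`` for any nonpositive part: zero minutes in a
    device-derived daily average is treated as an input error, and no
    zero-replacement is performed.
    """
    arr = _as_parts(parts)
    if np.any(arr <= 0):
        raise ValueError("all composition parts must be strictly positive")
    return arr * (total / arr.sum(axis=-1, keepdims=True))


def sbp_order(first: str | None = None) -> tuple[str, ...]:
    """Part order for a pivot SBP placing ``first`` in the leading position.

    The remaining parts keep their canonical relative order; the leading
    ilr coordinate under this order is the pivot log-ratio of ``first``
    against the geometric mean of the rest.
    """
    if first is None:
        return PARTS
    if first not in PARTS:
        raise ValueError(f"unknown behaviour {first!r}; expected one of {PARTS}")
    return (first,) + tuple(p for p in PARTS if p != first)


def contrast_matrix(order: Sequence[str] = PARTS) -> np.ndarray:
    """(D-1, D) orthonormal log-contrast matrix of the pivot-coordinate SBP.

    Row k (0-based) encodes
    ``z_k = sqrt((D-k-1)/(D-k)) * ln(x_k / gmean(x_{k+1}..x_{D-1}))``
    on the parts arranged in ``order``, with columns mapped back to the
    canonical :data:`PARTS` positions.  Rows are orthonormal and sum to zero.
    """
    if sorted(order) != sorted(PARTS):
        raise ValueError(f"order must be a permutation of {PARTS}")
    d = len(order)
    psi = np.zeros((d - 1, d))
    for k in range(d - 1):
        r = d - k - 1  # number of parts after the pivot
        a = np.sqrt(r / (r + 1.0))
        psi[k, k] = a
        psi[k, k + 1 :] = -a / r
    # reorder columns: psi acts on log(x) in `order`; map to canonical order
    perm = [order.index(p) for p in PARTS]
    return psi[:, perm]


def ilr_transform(comp: Iterable[float], order: Sequence[str] = PARTS) -> np.ndarray:
    """Map compositions (…, 4) to ilr coordinates (…, 3); scale-invariant."""
    arr = _as_parts(comp)
    if np.any(arr <= 0):
        raise ValueError("ilr requires strictly positive parts")
    return np.log(arr) @ contrast_matrix(order).T


def ilr_inverse(
    z: Iterable[float], order: Sequence[str] = PARTS, total: float = DAY_MINUTES
) -> np.ndarray:
    """Unique strictly positive composition closed to ``total`` with the given ilr."""
    zarr = np.asarray(z, dtype=float)
    if zarr.shape[-1] != len(PARTS) - 1:
        raise ValueError(f"expected {len(PARTS) - 1} ilr coordinates")
    clr = zarr @ contrast_matrix(order)
    expd = np.exp(clr)
    return expd * (total / expd.sum(axis=-1, keepdims=True))


def compositional_mean(comps: Iterable[Iterable[float]], total: float = DAY_MINUTES) -> np.ndarray:
    """Centre of a compositional sample: part-wise geometric means, closed.

    Coincides with ``ilr_inverse(mean(ilr_transform(comps)))`` — the geometric
    mean is the Fréchet mean of the Aitchison geometry.
    """
    arr = np.atleast_2d(np.asarray(list(comps), dtype=float))
    if arr.size == 0:
        raise ValueError("compositional_mean of an empty sample")
    if np.any(arr <= 0):
        raise ValueError("compositional_mean requires strictly positive parts")
    gm = np.exp(np.mean(np.log(arr), axis=0))
    return closure(gm, total=total)


def aitchison_distance(a: Iterable[float], b: Iterable[float]) -> float:
    """Aitchison distance: Euclidean distance between clr (equivalently ilr) images."""
    za = ilr_transform(a)
    zb = ilr_transform(b)
    return float(np.linalg.norm(za - zb))


# vertices of the plotting triangle: sleep top, SB bottom-left, PA bottom-right
_TRIANGLE = np.array([[0.5, np.sqrt(3.0) / 2.0], [0.0, 0.0], [1.0, 0.0]])


def amalgamate_to_ternary(comp: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Amalgamate LPA+MVPA into a single PA part and map to the 2-simplex.

    Returns ``(percentages, xy)`` where ``percentages`` is (sleep%, SB%, PA%)
    summing to 100 and ``xy`` the barycentric point in the plotting triangle.
    Closure-invariant: scaling all parts leaves the output unchanged.
    """
    arr = _as_parts(comp)
    if np.any(arr <= 0):
        raise ValueError("ternary amalgamation requires strictly positive parts")
    three = np.array([arr[..., 0], arr[..., 1], arr[..., 2] + arr[..., 3]])
    frac = three / three.sum(axis=0)
    xy = np.tensordot(frac, _TRIANGLE, axes=(0, 0))
    return 100.0 * frac, xy
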