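"""Leaf angles in the stem's principal-axis frame and phyllotaxy statistics.

Each leaf direction is expressed in an orthonormal frame built from the stem
skeleton: ``e1`` is the first principal axis of the stem voxels (oriented
upward), ``e2`` the second (oriented toward +x), and ``e3 = e1 x e2``.  A
leaf's inclination ``theta`` is measured from ``e1`` and its azimuth ``phi``
in the ``e2``-``e3`` plane.  Sequential-leaf azimuth differences give the
phyllotaxic angles ``phi_i = (phi_{i+1} - phi_i) mod 360``; grasses are
expected to alternate at 180 degrees, so the deviation ``Phi_i =
|phi_i - 180|`` measures departure from perfect alternation.

Because the side of the plant on which measurement begins is arbitrary, an
angle ``phi`` and its conjugate ``360 - phi`` describe the same leaf pair.
Two measurement series of one plant are aligned by the sign of their Pearson
correlation: a negative correlation indicates opposite measuring sides and
the second series is replaced by its conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

Array = np.ndarray

__all__ = [
    "StemFrame", "LeafAngle", "PhyllotaxySeries", "DeviationSeries",
    "AlignResult", "stem_frame", "leaf_axis", "leaf_angles", "phyllo_series",
    "deviation", "filter_angles", "conjugate", "align_pair",
    "repeatability_r2", "PHI_KEEP_LOW", "PHI_KEEP_HIGH",
]

# retention window: angles below a right angle (or its conjugate image) are
# more likely to be reconstruction errors than real sorghum phyllotaxy
PHI_KEEP_LOW = 90.0
PHI_KEEP_HIGH = 270.0

_EPS = 1e-12


@dataclass(frozen=True)
class StemFrame:
    """Right-handed orthonormal frame (e1 up, e2 toward +x) at the stem centroid."""

    origin: Array
    e1: Array
    e2: Array
    e3: Array


@dataclass(frozen=True)
class LeafAngle:
    """Inclination ``theta`` (from e1, degrees) and azimuth ``phi`` (degrees)."""

    rank: int | None
    theta: float
    phi: float


@dataclass
class PhyllotaxySeries:
    """Per-leaf azimuths, derived phyllotaxic angles, and retention flags."""

    phi_values: Array           # leaf azimuths, ordered by rank
    phyllo: Array               # phi_i = (phi_{i+1} - phi_i) mod 360
    kept: Array                 # True where 90 <= phyllo <= 270

    @property
    def deviation(self) -> Array:
        return np.abs(self.phyllo - 180.0)


@dataclass(frozen=True)
class DeviationSeries:
    """Absolute departures from 180-degree alternation for kept angles."""

    Phi: Array
    kept: Array


@dataclass(frozen=True)
class AlignResult:
    a: Array
    b_aligned: Array
    transformed: bool
    r: float
    degenerate: bool
    shared: Array  # indices used for the correlation


def _principal_axes(points: Array) -> tuple[Array, Array]:
    x = np.asarray(points, dtype=float)
    c = x - x.mean(axis=0)
    cov = c.T @ c / len(x)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def stem_frame(stem_xyz: Array) -> StemFrame:
    """Principal-axis frame of the stem nodes with fixed sign conventions.

    ``e1`` points upward (positive z component; for an exactly horizontal
    first axis the sign is fixed toward +x then +y).  ``e2`` is chosen with a
    non-negative x component (tie: non-negative y).  Collinear stems are
    allowed: ``e2`` is then taken as the projection of x-hat onto the plane
    orthogonal to ``e1``.
    """
    x = np.atleast_2d(np.asarray(stem_xyz, dtype=float))
    if len(x) < 2:
        raise ValueError("stem frame requires at least two nodes")
    w, v = _principal_axes(x)
    e1 = v[:, 0]
    if e1[2] < 0 or (e1[2] == 0 and (e1[0] < 0 or (e1[0] == 0 and e1[1] < 0))):
        e1 = -e1
    if len(x) >= 3 and w[1] > max(w[0] * 1e-10, _EPS):
        e2 = v[:, 1]
    else:
        for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
            cand = ref - (ref @ e1) * e1
            if np.linalg.norm(cand) > 1e-8:
                e2 = cand / np.linalg.norm(cand)
                break
    if e2[0] < 0 or (e2[0] == 0 and e2[1] < 0):
        e2 = -e2
    e3 = np.cross(e1, e2)
    return StemFrame(origin=x.mean(axis=0), e1=e1, e2=e2, e3=e3)


def leaf_axis(path_xyz: Array, n_vox: int = 20) -> Array:
    """First principal axis of the first ``n_vox`` leaf path nodes.

    The window starts at the junction end, so the axis reflects the tangent
    at the insertion point rather than the chord to the drooping tip.  The
    sign is fixed to point away from the junction.
    """
    x = np.atleast_2d(np.asarray(path_xyz, dtype=float))
    if len(x) < 2:
        raise ValueError("leaf axis requires at least two path nodes")
    head = x[:min(n_vox, len(x))]
    _, v = _principal_axes(head)
    axis = v[:, 0]
    chord = head[-1] - head[0]
    if axis @ chord < 0:
        axis = -axis
    return axis


def leaf_angles(frame: StemFrame, axis: Array, rank: int | None = None) -> LeafAngle:
    """Inclination/azimuth of a unit leaf axis in the stem frame."""
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < _EPS:
        raise ValueError("leaf axis has zero length")
    a = a / norm
    theta = float(np.degrees(np.arccos(np.clip(a @ frame.e1, -1.0, 1.0))))
    theta = theta % 180.0 if theta >= 180.0 else theta
    phi = float(np.degrees(np.arctan2(a @ frame.e3, a @ frame.e2)) % 360.0)
    return LeafAngle(rank=rank, theta=theta, phi=phi)


def phyllo_series(phis: Array) -> PhyllotaxySeries:
    """Sequential azimuth differences normalized to [0, 360).

    A single azimuth is rejected: phyllotaxy is a property of a leaf pair, so
    one-leaf reconstructions carry no information and are excluded.
    """
    phis = np.asarray(phis, dtype=float)
    if phis.ndim != 1 or len(phis) < 2:
        raise ValueError("phyllotaxy requires at least two leaf azimuths")
    phyllo = np.mod(np.diff(phis), 360.0)
    kept = (phyllo >= PHI_KEEP_LOW) & (phyllo <= PHI_KEEP_HIGH)
    return PhyllotaxySeries(phi_values=phis, phyllo=phyllo, kept=kept)


def deviation(series: PhyllotaxySeries) -> DeviationSeries:
    """``Phi_i = |phi_i - 180|``: deviation from perfect alternation."""
    return DeviationSeries(Phi=np.abs(series.phyllo - 180.0), kept=series.kept.copy())


def filter_angles(series: PhyllotaxySeries) -> PhyllotaxySeries:
    """Recompute retention flags: keep iff 90 <= phi <= 270.

    Equivalent to dropping deviations ``Phi > 90``; the boundary itself is
    kept on both formulations.
    """
    kept = (series.phyllo >= PHI_KEEP_LOW) & (series.phyllo <= PHI_KEEP_HIGH)
    return PhyllotaxySeries(phi_values=series.phi_values.copy(),
                            phyllo=series.phyllo.copy(), kept=kept)


def conjugate(phi):
    """The same leaf pair measured from the other side: ``(360 - phi) mod 360``."""
    out = np.mod(360.0 - np.asarray(phi, dtype=float), 360.0)
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(out)
    return out


def align_pair(a: Array, b: Array, prefilter: bool = True) -> AlignResult:
    """Resolve the measuring-side ambiguity between two series of one plant.

    Pairs are compared on indices where both values pass the retention window
    (when ``prefilter``).  A non-negative Pearson correlation means both
    series were measured from the same side and ``b`` is returned unchanged;
    a negative correlation flips ``b`` to its conjugate.  Fewer than two
    shared angles, or zero variance in either vector, is degenerate: no
    transform is applied and the result is flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal lengths")
    ok = np.isfinite(a) & np.isfinite(b)
    if prefilter:
        ok &= (a >= PHI_KEEP_LOW) & (a <= PHI_KEEP_HIGH)
        ok &= (b >= PHI_KEEP_LOW) & (b <= PHI_KEEP_HIGH)
    shared = np.flatnonzero(ok)
    if len(shared) < 2 or np.std(a[shared]) < _EPS or np.std(b[shared]) < _EPS:
        return AlignResult(a=a, b_aligned=b.copy(), transformed=False,
                           r=np.nan, degenerate=True, shared=shared)
    r = float(np.corrcoef(a[shared], b[shared])[0, 1])
    if r >= 0:
        return AlignResult(a=a, b_aligned=b.copy(), transformed=False,
                           r=r, degenerate=False, shared=shared)
    return AlignResult(a=a, b_aligned=conjugate(b), transformed=True,
                       r=r, degenerate=False, shared=shared)


def repeatability_r2(plant_pairs, align: bool = True) -> float:
    """Squared Pearson correlation over pooled per-plant-aligned angle pairs.

    ``plant_pairs`` is an iterable of ``(a, b)`` series, one pair per plant.
    Each plant is aligned (conjugated if measured from opposite sides) and
    range-filtered before pooling.  Returns NaN when the pooled set is
    degenerate.

    Note that per-plant sign alignment is a selection step: under the null of
    independent measurements it inflates the pooled R^2 by roughly the
    squared expected magnitude of a length-k sample correlation (about 0.1
    for five angles per plant).  ``align=False`` pools the range-filtered
    pairs as-is, which is the unbiased null reference.
    """
    xs, ys = [], []
    for a, b in plant_pairs:
        res = align_pair(np.asarray(a, float), np.asarray(b, float))
        if len(res.shared) == 0:
            continue
        xs.append(res.a[res.shared])
        ys.append((res.b_aligned if align else np.asarray(b, float))[res.shared])
    if not xs:
        return float("nan")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2 or np.std(x) < _EPS or np.std(y) < _EPS:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
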