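"""Procedural sorghum-like plants with known ground-truth leaf angles.

The generator builds a plant as a union of capsules (line segments swept by a
sphere): a vertical stem plus, at each node, a leaf that rises at its
insertion inclination and then droops along a planar arc at a fixed azimuth.
Because every leaf arc is planar, its true azimuth is constant along the leaf,
so the recorded ground truth is exact regardless of droop.

Binary silhouettes of the model are rendered analytically: under orthographic
projection a capsule projects to a 2-D stadium (segment with a radius), and a
pixel is foreground iff its centre lies inside the union of the projected
stadiums.  Rendering is therefore exact at pixel-centre sampling and fully
deterministic.

The module also simulates genotype/phenotype populations with known variance
components for exercising the quantitative-genetics tail of the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CalibratedView, CameraRig

Array = np.ndarray

__all__ = [
    "PlantSpec", "TillerSpec", "PlantModel", "SilhouetteSet",
    "make_plant", "render_silhouettes", "Population", "make_population",
    "save_silhouettes", "load_silhouettes",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class TillerSpec:
    """A secondary shoot: a slanted stem rising from near the base."""

    azimuth: float = 45.0          # degrees
    inclination: float = 25.0      # degrees from vertical
    length: float = 300.0          # mm
    radius: float = 8.0            # mm
    attach_height: float = 30.0    # mm above ground


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic plant.

    Azimuths are degrees in [0, 360); inclinations are degrees from the
    vertical stem axis in [0, 90].  ``leaf_droop`` in [0, 1] scales how far
    the leaf tip bends down along its arc.  The derived true phyllotaxy
    series is ``(azimuth[i+1] - azimuth[i]) mod 360``.
    """

    n_leaves: int
    internode_lengths: tuple[float, ...]
    true_azimuths: tuple[float, ...]
    true_inclinations: tuple[float, ...]
    leaf_length: float = 280.0
    leaf_droop: float = 0.4
    stem_radius: float = 12.0
    leaf_radius: float = 10.0
    apex_length: float = 120.0
    base_offset: tuple[float, float] = (5.0, -3.0)  # pot never perfectly centred
    tiller: TillerSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be non-negative")
        for name in ("internode_lengths", "true_azimuths", "true_inclinations"):
            if len(getattr(self, name)) != self.n_leaves:
                raise ValueError(f"{name} must have length n_leaves={self.n_leaves}")
        if any(l <= 0 for l in self.internode_lengths):
            raise ValueError("internode lengths must be positive")
        if any(not (0 <= a < 360) for a in self.true_azimuths):
            raise ValueError("azimuths must lie in [0, 360)")
        if any(not (0 <= t <= 90) for t in self.true_inclinations):
            raise ValueError("inclinations must lie in [0, 90]")
        if self.leaf_length <= 0 or self.stem_radius <= 0 or self.leaf_radius <= 0:
            raise ValueError("lengths and radii must be positive")
        if not (0 <= self.leaf_droop <= 1):
            raise ValueError("leaf_droop must lie in [0, 1]")

    @property
    def true_phyllotaxy(self) -> Array:
        """phi[i] = (azimuth[i+1] - azimuth[i]) mod 360, one value per leaf pair."""
        az = np.asarray(self.true_azimuths, dtype=float)
        return np.mod(np.diff(az), 360.0)

    @property
    def true_deviation(self) -> Array:
        """Absolute departure from perfect 180-degree alternation."""
        return np.abs(self.true_phyllotaxy - 180.0)

    @classmethod
    def random(cls, seed: int, n_leaves: int | None = None,
               max_deviation: float = 60.0, **overrides) -> "PlantSpec":
        """Sample a plant with alternating phyllotaxy perturbed by at most
        ``max_deviation`` degrees per step.

        Sizes emulate a juvenile sorghum plant around 7 weeks after planting:
        70-110 mm internodes, 220-320 mm leaves inserted 20-60 degrees from
        vertical.
        """
        rng = np.random.default_rng(seed)
        k = int(n_leaves if n_leaves is not None else rng.integers(5, 9))
        az0 = rng.uniform(0, 360)
        azimuths, a = [], az0
        for _ in range(k):
            azimuths.append(a % 360.0)
            a += 180.0 + rng.uniform(-max_deviation, max_deviation)
        fields = dict(
            n_leaves=k,
            internode_lengths=tuple(rng.uniform(70, 110, k).round(2)),
            true_azimuths=tuple(np.round(azimuths, 3)),
            true_inclinations=tuple(rng.uniform(20, 60, k).round(2)),
            leaf_length=float(rng.uniform(220, 320)),
            leaf_droop=float(rng.uniform(0.2, 0.6)),
            base_offset=tuple(rng.uniform(-15, 15, 2).round(2)),
            seed=seed,
        )
        fields.update(overrides)
        return cls(**fields)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlantSpec":
        d = json.loads(text)
        if d.get("tiller") is not None:
            d["tiller"] = TillerSpec(**d["tiller"])
        for name in ("internode_lengths", "true_azimuths", "true_inclinations"):
            d[name] = tuple(d[name])
        d["base_offset"] = tuple(d.get("base_offset", (5.0, -3.0)))
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry


def _leaf_arc(junction: Array, azimuth_deg: float, inclination_deg: float,
              length: float, droop: float, n_seg: int = 24) -> Array:
    """Polyline of a planar leaf arc starting at the stem junction.

    The tangent starts ``inclination`` degrees from vertical and tips over by
    an extra ``droop * 120`` degrees along the arc (capped short of pointing
    straight down), so the direction over the first few centimetres reflects
    the insertion angle while the tip droops.
    """
    az = np.deg2rad(azimuth_deg)
    radial = np.array([np.cos(az), np.sin(az), 0.0])
    total_droop = np.deg2rad(droop * 120.0)
    alpha0 = np.deg2rad(inclination_deg)
    ds = length / n_seg
    pts = [np.asarray(junction, dtype=float)]
    for i in range(n_seg):
        s_mid = (i + 0.5) / n_seg
        alpha = min(alpha0 + total_droop * s_mid, np.deg2rad(165.0))
        d = radial * np.sin(alpha) + np.array([0.0, 0.0, np.cos(alpha)])
        pts.append(pts[-1] + d * ds)
    return np.asarray(pts)


def _polyline_capsules(poly: Array, radius: float) -> list[tuple[Array, Array, float]]:
    return [(poly[i], poly[i + 1], radius) for i in range(len(poly) - 1)]


@dataclass
class PlantModel:
    """Capsule-swept geometry plus the ground-truth angle table."""

    spec: PlantSpec
    capsules: list[tuple[Array, Array, float]]
    stem_polyline: Array
    leaf_polylines: list[Array]
    ground_truth: pd.DataFrame

    @property
    def bounds(self) -> tuple[Array, Array]:
        los, his = [], []
        for p0, p1, r in self.capsules:
            lo = np.minimum(p0, p1) - r
            hi = np.maximum(p0, p1) + r
            los.append(lo)
            his.append(hi)
        return np.min(los, axis=0), np.max(his, axis=0)

    def distance(self, points: Array) -> Array:
        """Signed distance from points to the plant surface (negative inside)."""
        pts = np.atleast_2d(points)
        best = np.full(len(pts), np.inf)
        for p0, p1, r in self.capsules:
            best = np.minimum(best, _segment_distance(pts, p0, p1) - r)
        return best

    def contains(self, points: Array, margin: float = 0.0) -> Array:
        """True for points at least ``margin`` mm inside the surface."""
        return self.distance(points) <= -margin

    def centerline_distance(self, points: Array) -> Array:
        """Distance from points to the union of stem and leaf centrelines."""
        pts = np.atleast_2d(points)
        best = _segment_distance(pts, self.stem_polyline[0], self.stem_polyline[-1])
        for poly in self.leaf_polylines:
            for i in range(len(poly) - 1):
                best = np.minimum(best, _segment_distance(pts, poly[i], poly[i + 1]))
        return best


def _segment_distance(pts: Array, p0: Array, p1: Array) -> Array:
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip((pts - p0) @ d / dd, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def make_plant(spec: PlantSpec) -> PlantModel:
    """Build the capsule geometry and ground-truth table for a plant spec."""
    heights = np.cumsum(spec.internode_lengths) if spec.n_leaves else np.array([])
    top = (heights[-1] if spec.n_leaves else 0.0) + spec.apex_length
    dx, dy = spec.base_offset
    # start at z = radius so the bottom spherical cap rests on the ground plane
    stem = np.array([[dx, dy, spec.stem_radius], [dx, dy, top]])
    capsules = _polyline_capsules(stem, spec.stem_radius)
    leaf_polys = []
    rows = []
    for i in range(spec.n_leaves):
        junction = np.array([dx, dy, heights[i]])
        poly = _leaf_arc(junction, spec.true_azimuths[i], spec.true_inclinations[i],
                         spec.leaf_length, spec.leaf_droop)
        leaf_polys.append(poly)
        capsules.extend(_polyline_capsules(poly, spec.leaf_radius))
        rows.append({
            "leaf_rank": i + 1,
            "attach_height_mm": float(heights[i]),
            "azimuth_deg": float(spec.true_azimuths[i]),
            "inclination_deg": float(spec.true_inclinations[i]),
        })
    if spec.tiller is not None:
        t = spec.tiller
        az = np.deg2rad(t.azimuth)
        d = np.array([np.cos(az) * np.sin(np.deg2rad(t.inclination)),
                      np.sin(az) * np.sin(np.deg2rad(t.inclination)),
                      np.cos(np.deg2rad(t.inclination))])
        p0 = np.array([dx, dy, t.attach_height])
        capsules.append((p0, p0 + d * t.length, t.radius))
    truth = pd.DataFrame(rows, columns=["leaf_rank", "attach_height_mm",
                                        "azimuth_deg", "inclination_deg"])
    truth.attrs["true_phyllotaxy"] = spec.true_phyllotaxy
    return PlantModel(spec=spec, capsules=capsules, stem_polyline=stem,
                      leaf_polylines=leaf_polys, ground_truth=truth)


# ---------------------------------------------------------------------------
# silhouette rendering


@dataclass
class SilhouetteSet:
    """One strictly binary mask per calibrated view."""

    masks: list[Array]
    views: list[CalibratedView]
    rig: CameraRig | None = None

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.views):
            raise ValueError("mask count must equal view count")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]

    def __len__(self) -> int:
        return len(self.masks)


def render_silhouettes(model: PlantModel, rig: CameraRig) -> SilhouetteSet:
    """Render exact binary silhouettes of the model for every view of the rig.

    Raises if the model does not fit inside the rig's world extent; the error
    names the first view whose image the model would overflow.
    """
    lo, hi = model.bounds
    e = rig.world_extent
    box_lo = np.array([-e / 2, -e / 2, 0.0])
    box_hi = np.array([e / 2, e / 2, e])
    views = rig.views()
    if np.any(lo < box_lo) or np.any(hi > box_hi):
        # identify a view whose image would clip the model
        corners = np.array(np.meshgrid(*zip(lo, hi), indexing="ij")).reshape(3, -1).T
        for v in views:
            r, c = v.project(corners)
            h, w = v.image_shape
            if r.min() < 0 or c.min() < 0 or r.max() > h - 1 or c.max() > w - 1:
                raise ValueError(
                    f"model exceeds world extent and clips view {v.label!r}")
        raise ValueError("model exceeds the rig's world extent")
    masks = [_render_view(model, v) for v in views]
    return SilhouetteSet(masks=masks, views=views, rig=rig)


def _render_view(model: PlantModel, view: CalibratedView) -> Array:
    h, w = view.image_shape
    mask = np.zeros((h, w), dtype=bool)
    for p0, p1, r in model.capsules:
        (r0, r1), (c0, c1) = view.project(np.stack([p0, p1]))
        if view.kind == "orthographic":
            rpx = r / view.px_size
        else:
            depth = np.mean(((np.stack([p0, p1]) - view.origin) @ view.forward))
            rpx = r * view.focal_px / depth
        rmin = max(int(np.floor(min(r0, r1) - rpx - 1)), 0)
        rmax = min(int(np.ceil(max(r0, r1) + rpx + 1)), h - 1)
        cmin = max(int(np.floor(min(c0, c1) - rpx - 1)), 0)
        cmax = min(int(np.ceil(max(c0, c1) + rpx + 1)), w - 1)
        if rmin > rmax or cmin > cmax:
            continue
        rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1),
                             indexing="ij")
        d = _segment_distance_2d(rr.ravel(), cc.ravel(), r0, c0, r1, c1)
        sub = (d <= rpx).reshape(rr.shape)
        mask[rmin:rmax + 1, cmin:cmax + 1] |= sub
    return mask


def _segment_distance_2d(rr, cc, r0, c0, r1, c1):
    dr, dc = r1 - r0, c1 - c0
    dd = dr * dr + dc * dc
    if dd == 0:
        return np.hypot(rr - r0, cc - c0)
    t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / dd, 0.0, 1.0)
    return np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))


def save_silhouettes(silh: SilhouetteSet, out_dir: str | Path) -> None:
    """Write masks as 8-bit PNGs (0/255) plus the rig description as JSON."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mask, view in zip(silh.masks, silh.views):
        img = Image.fromarray((mask.astype(np.uint8)) * 255)
        img.save(out / f"{view.label}.png")
    if silh.rig is not None:
        (out / "rig.json").write_text(silh.rig.to_json())


def load_silhouettes(in_dir: str | Path) -> SilhouetteSet:
    from PIL import Image

    src = Path(in_dir)
    rig = CameraRig.from_json((src / "rig.json").read_text())
    views = rig.views()
    masks = []
    for view in views:
        img = np.asarray(Image.open(src / f"{view.label}.png"))
        masks.append(img > 127)
    return SilhouetteSet(masks=masks, views=views, rig=rig)


# ---------------------------------------------------------------------------
# genotype / phenotype population simulation


@dataclass
class Population:
    """Simulated mapping population with recorded ground truth.

    ``truth`` holds the realized genotypic values and variance components so
    estimator recovery can be checked against known quantities.
    """

    genotypes: "GenotypeMatrix"  # noqa: F821 - imported lazily below
    phenotypes: pd.DataFrame
    truth: dict


def make_population(n_geno: int, reps: int, n_markers: int,
                    causal: list[tuple[int, float]] | None = None,
                    h2_target: float = 0.5, seed: int = 0,
                    maf_range: tuple[float, float] = (0.05, 0.5),
                    inbreeding: float = 0.95,
                    n_timepoints: int = 1) -> Population:
    """Simulate genotypes in inbred Hardy-Weinberg proportions and replicated
    phenotypes.

    Genotype frequencies follow Hardy-Weinberg with inbreeding coefficient
    ``inbreeding`` (F); the default 0.95 reflects a predominantly selfing
    panel, where heterozygous calls are rare (F = 0 recovers a fully outbred
    population).  ``h2_target`` is the plot-level genotypic fraction of
    variance sigma_G^2 / (sigma_G^2 + sigma_R^2).  ``causal`` lists
    ``(marker_index, variance_fraction)`` pairs; each causal marker
    contributes that fraction of the total phenotypic variance, carved out of
    the genotypic share.  Total phenotypic variance is scaled to 1.
    """
    from .quantgen import GenotypeMatrix

    if not (0 <= h2_target < 1):
        # h2_target = 1 with a single replicate would make genotype and
        # residual indistinguishable; full determinism is disallowed outright
        raise ValueError("h2_target must lie in [0, 1)")
    causal = list(causal or [])
    if any(j >= n_markers or j < 0 for j, _ in causal):
        raise ValueError("causal marker index out of range")
    causal_var = sum(f for _, f in causal)
    if causal_var > h2_target + 1e-12:
        raise ValueError("causal variance fractions exceed h2_target")

    if not (0 <= inbreeding <= 1):
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, n_markers)[:, None]
    f = inbreeding
    p_hom_alt = p ** 2 + p * (1 - p) * f
    p_het = 2 * p * (1 - p) * (1 - f)
    u = rng.random((n_markers, n_geno))
    dosages = np.where(u < p_hom_alt, 2.0,
                       np.where(u < p_hom_alt + p_het, 1.0, 0.0))

    gv = np.zeros(n_geno)
    if h2_target > 0:
        for j, frac in causal:
            z = _standardize(dosages[j])
            gv += np.sqrt(frac) * z
        poly_var = h2_target - causal_var
        if poly_var > 0:
            gv += np.sqrt(poly_var) * _standardize(rng.normal(size=n_geno))
    resid_sd = np.sqrt(1.0 - h2_target)

    rows = []
    for g in range(n_geno):
        for t in range(1, n_timepoints + 1):
            for j in range(reps):
                rows.append({
                    "plant_id": f"g{g:04d}_r{j}",
                    "genotype_id": f"g{g:04d}",
                    "timepoint": t,
                    "value": gv[g] + rng.normal(0.0, resid_sd),
                })
    pheno = pd.DataFrame(rows)

    gm = GenotypeMatrix(
        dosages=dosages,
        chrom=np.array(["1"] * n_markers),
        pos=np.arange(1, n_markers + 1) * 100,
        ids=np.array([f"m{j}" for j in range(n_markers)]),
        ref=np.array(["A"] * n_markers),
        alt=np.array(["T"] * n_markers),
        samples=[f"g{g:04d}" for g in range(n_geno)],
    )
    sigma_g = float(np.var(gv))
    truth = {
        "sigma2_g": sigma_g,
        "sigma2_r": float(resid_sd ** 2),
        "h2_plot": sigma_g / (sigma_g + resid_sd ** 2) if (sigma_g + resid_sd ** 2) else 0.0,
        "genotypic_values": gv,
        "causal": causal,
        "allele_freq": p,
    }
    return Population(genotypes=gm, phenotypes=pheno, truth=truth)


def _standardize(x: Array) -> Array:
    s = np.std(x)
    if s == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / s


def h2_for_target_H(H: float, n: int = 2) -> float:
    """Plot-level genotypic fraction that yields broad-sense heritability ``H``
    when residual variance is divided by ``n`` replicates."""
    if not (0 <= H < 1):
        raise ValueError("H must lie in [0, 1)")
    return H / (n - (n - 1) * H)
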