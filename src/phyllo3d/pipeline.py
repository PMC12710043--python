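"""End-to-end measurement: silhouettes -> hull -> skeleton -> leaf angles.

``measure_plant`` runs the full reconstruction chain on a synthetic plant (or
pre-rendered silhouettes) and returns a :class:`PhyllotaxyRecord` holding the
reconstruction score, topology verdict, segmented organ count and the derived
phyllotaxy series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .camera import CameraRig
from .carving import (VoxelGrid, accept_reconstruction, carve,
                      score_reconstruction)
from .phyllotaxy import (LeafAngle, PhyllotaxySeries, align_pair, leaf_angles,
                         leaf_axis, phyllo_series, stem_frame)
from .segmentation import SegmentedPlant, segment
from .skeleton import (BranchClassifier, RuleBasedBranchClassifier,
                       SkeletonGraph, is_tree, join_gaps, largest_component,
                       prune_spurious, thin)
from .synthetic_plant import (PlantModel, PlantSpec, SilhouetteSet, make_plant,
                              render_silhouettes)

__all__ = ["PhyllotaxyRecord", "measure_plant", "measure_silhouettes",
           "phi_errors_vs_truth"]


@dataclass
class PhyllotaxyRecord:
    """Measurement outcome for one plant at one timepoint."""

    score: "object"
    topology_ok: bool
    accepted: bool
    n_leaves: int
    angles: list[LeafAngle]
    series: PhyllotaxySeries | None
    segmented: SegmentedPlant | None
    skeleton: SkeletonGraph | None
    grid: VoxelGrid | None = None
    used_fallback: bool = False


def measure_silhouettes(silhouettes: SilhouetteSet, *, resolution: int = 128,
                        max_bridge: float = 15.0,
                        classifier: BranchClassifier | None = None,
                        n_axis_voxels: int = 20,
                        dice_threshold: float = 0.70,
                        enforce_tree: bool = True,
                        keep_grid: bool = False) -> PhyllotaxyRecord:
    """Measure leaf angles from calibrated silhouettes.

    When the pruned skeleton still contains cycles (phantom hull volume can
    fuse neighbouring organs), ``enforce_tree`` extracts a minimum spanning
    tree by edge length so the plant remains measurable; the topology verdict
    reported alongside is that of the unmodified skeleton, and drives the
    accept/reject flag exactly as a non-tree skeleton would.
    """
    grid = carve(silhouettes, resolution=resolution)
    score = score_reconstruction(grid, silhouettes, threshold=dice_threshold)
    if grid.n_occupied == 0:
        return PhyllotaxyRecord(score=score, topology_ok=False, accepted=False,
                                n_leaves=0, angles=[], series=None,
                                segmented=None, skeleton=None,
                                grid=grid if keep_grid else None)
    skel = thin(grid)
    skel = join_gaps(skel, max_bridge=max_bridge)
    skel = largest_component(skel)
    skel = prune_spurious(skel, classifier=classifier)
    topology_ok = is_tree(skel)
    if not topology_ok and enforce_tree and skel.n_nodes > 0:
        mst = nx.minimum_spanning_tree(skel.graph, weight="length")
        skel = SkeletonGraph(graph=mst, voxel_size=skel.voxel_size,
                             origin=skel.origin)
        # cycle-breaking exposes new terminal branches; prune once more
        skel = prune_spurious(skel, classifier=classifier)
    accepted = accept_reconstruction(score, topology_ok)
    seg = segment(skel) if is_tree(skel) else None
    angles: list[LeafAngle] = []
    series = None
    if seg is not None and seg.leaves:
        frame = stem_frame(seg.stem_xyz)
        for leaf in seg.leaves:
            path_xyz = seg.leaf_xyz(leaf)
            if len(path_xyz) < 2:
                continue
            axis = leaf_axis(path_xyz, n_vox=n_axis_voxels)
            angles.append(leaf_angles(frame, axis, rank=leaf.rank))
        if len(angles) >= 2:
            series = phyllo_series(np.array([a.phi for a in angles]))
    return PhyllotaxyRecord(score=score, topology_ok=topology_ok,
                            accepted=accepted,
                            n_leaves=len(seg.leaves) if seg else 0,
                            angles=angles, series=series, segmented=seg,
                            skeleton=skel, grid=grid if keep_grid else None,
                            used_fallback=bool(seg.used_fallback) if seg else False)


def measure_plant(spec: PlantSpec | PlantModel, rig: CameraRig | None = None,
                  *, resolution: int = 128, voxel_matched_rig: bool = True,
                  **kwargs) -> PhyllotaxyRecord:
    """Render a synthetic plant and measure it end to end.

    By default the rendering raster is matched to the voxel pitch of the
    requested grid so reprojection scores compare commensurate rasters.
    """
    model = spec if isinstance(spec, PlantModel) else make_plant(spec)
    if rig is None:
        rig = CameraRig()
    if voxel_matched_rig:
        rig = rig.voxel_matched(resolution)
    silh = render_silhouettes(model, rig)
    return measure_silhouettes(silh, resolution=resolution, **kwargs)


def phi_errors_vs_truth(record: PhyllotaxyRecord, spec: PlantSpec,
                        n_lower: int = 4) -> np.ndarray:
    """Absolute errors of the lower recovered phyllotaxic angles against the
    generator's ground truth, after measuring-side alignment.

    Truth and recovery are compared on the first ``n_lower`` angle indices
    present in both; the recovered series is conjugate-aligned to the truth
    before differencing, and differences are taken on the circle.
    """
    if record.series is None:
        return np.array([])
    truth = spec.true_phyllotaxy
    rec = record.series.phyllo
    k = min(len(truth), len(rec), n_lower)
    if k == 0:
        return np.array([])
    res = align_pair(truth[:k], rec[:k], prefilter=True)
    if res.degenerate and len(res.shared) == 0:
        return np.array([])
    idx = res.shared if len(res.shared) else np.arange(k)
    diff = np.abs(res.a[idx] - res.b_aligned[idx])
    return np.minimum(diff, 360.0 - diff)
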