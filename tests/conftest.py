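import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_spec():
    from phyllo3d.synthetic_plant import PlantSpec

    return PlantSpec.random(42, n_leaves=6)


@pytest.fixture(scope="session")
def fixture_record(fixture_spec):
    """One plant measured end to end at 128^3; shared across tests."""
    from phyllo3d.pipeline import measure_plant

    return measure_plant(fixture_spec, resolution=128, keep_grid=True)


@pytest.fixture(scope="session")
def sphere_scene():
    """A centred sphere rendered by the default five-side-plus-top rig."""
    from phyllo3d.camera import CameraRig
    from phyllo3d.synthetic_plant import (PlantSpec, make_plant,
                                          render_silhouettes)

    rig = CameraRig().voxel_matched(64)
    spec = PlantSpec(n_leaves=0, internode_lengths=(), true_azimuths=(),
                     true_inclinations=(), stem_radius=1.0)
    model = make_plant(spec)
    center = np.array([0.0, 0.0, 500.0])
    radius = 200.0
    model.capsules = [(center, center, radius)]
    model.stem_polyline = np.array([center, center])
    silh = render_silhouettes(model, rig)
    return silh, center, radius


def skeleton_from_edges(coords, edges, voxel_size=10.0):
    """Build a skeleton graph from integer coordinates and an edge list."""
    import networkx as nx
    from phyllo3d.skeleton import SkeletonGraph

    g = nx.Graph()
    for c in coords:
        c = tuple(c)
        g.add_node(c, xyz=np.asarray(c, float) * voxel_size, radius=5.0)
    for a, b in edges:
        a, b = tuple(a), tuple(b)
        length = float(np.linalg.norm(np.subtract(a, b)) * voxel_size)
        g.add_edge(a, b, length=length, is_bridge=False)
    return SkeletonGraph(graph=g, voxel_size=voxel_size, origin=np.zeros(3))


def random_tree_skeleton(rng, n_nodes):
    """Random tree embedded on a 3-D integer lattice with distinct coords."""
    coords = [(0, 0, 0)]
    edges = []
    seen = {(0, 0, 0)}
    while len(coords) < n_nodes:
        parent = coords[rng.integers(len(coords))]
        step = tuple(rng.integers(-1, 2, 3))
        child = tuple(np.add(parent, step) + np.array([0, 0, 1]))
        if child in seen:
            continue
        seen.add(child)
        coords.append(child)
        edges.append((parent, child))
    return skeleton_from_edges(coords, edges)
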