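import numpy as np
import pytest

import sogseg as sg


@pytest.fixture(scope="session")
def small_mito():
    """A small mitochondria phantom shared across unit tests."""
    spec = sg.mito_sbem_spec(grid_shape=(96, 96, 96), rng_seed=1)
    vol, truth = sg.make_mitochondria_phantom(
        spec, n_objects=8, n_speckle=30, n_membrane_fragments=5
    )
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_neurite():
    """A small neurite phantom (default drop-off, crossovers, trachiole)."""
    spec = sg.neurite_sbem_spec(grid_shape=(96, 224, 224), rng_seed=3)
    vol, truth = sg.make_neurite_phantom(spec)
    return spec, vol, truth


def soma_seed(spec, truth, object_id=1):
    """Voxel index of a cell's soma centre."""
    info = next(
        o for o in truth.catalogue
        if o.class_name == "cell" and o.object_id == object_id
    )
    c = np.asarray(info.params["soma_center_nm"]) / np.asarray(spec.voxel_size)
    return tuple(int(v) for v in c)


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def neighbor_offsets(connectivity):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                s = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and s != 1:
                    continue
                if connectivity == 18 and s > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def bfs_components(mask, connectivity):
    """Exhaustive BFS flood fill: returns a set of frozensets of voxel tuples."""
    mask = np.asarray(mask, dtype=bool)
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = set()
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.add(frozenset(comp))
    return comps


def label_partition(labels):
    """Partition of a label array as a set of frozensets of voxel tuples."""
    comps = set()
    for oid in range(1, int(labels.max(initial=0)) + 1):
        comps.add(frozenset(zip(*np.nonzero(labels == oid))))
    return comps
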