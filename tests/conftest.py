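"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mito3d import VoxelSpacing
from mito3d.skeleton import build_centerline_tree, extract_skeleton
from mito3d.synthetic import NetworkSpec, generate_network_phantom

ISO10 = VoxelSpacing(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def iso10() -> VoxelSpacing:
    return ISO10


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Straight tube, radius 100 nm, axis length 2000 nm, 10 nm voxels."""
    spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 2000)], edges=[(0, 1, 100.0)])
    density, labels, truth = generate_network_phantom(spec, ISO10, seed=1)
    return spec, density, labels, truth


@pytest.fixture(scope="session")
def cylinder_tree(cylinder_phantom):
    _, _, labels, _ = cylinder_phantom
    sk = extract_skeleton(labels.mask(1), ISO10)
    return build_centerline_tree(sk, mito_label=1), sk


@pytest.fixture(scope="session")
def y_junction_phantom():
    """Three 600 nm arms of radius 60 nm meeting at one node."""
    dirs = np.array([[0, 0, 1.0], [0, 0.94, -0.342], [0, -0.94, -0.342]])
    nodes = [(0.0, 0.0, 0.0)] + [tuple(d * 600) for d in dirs]
    spec = NetworkSpec(nodes=nodes, edges=[(0, k + 1, 60.0) for k in range(3)])
    density, labels, truth = generate_network_phantom(spec, ISO10, seed=2)
    return spec, density, labels, truth


@pytest.fixture(scope="session")
def sphere_phantom():
    """Single ball of radius 300 nm."""
    spec = NetworkSpec(nodes=[(0.0, 0.0, 0.0)], edges=[], spheres=[(0, 300.0)])
    density, labels, truth = generate_network_phantom(spec, ISO10, seed=3)
    return spec, density, labels, truth


def analytic_capsule_volume(radius: float, length: float) -> float:
    """Closed-form cylinder + two hemispherical caps."""
    return math.pi * radius**2 * length + (4.0 / 3.0) * math.pi * radius**3


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS connected-component oracle for small volumes."""
    from collections import deque

    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    out = np.zeros(mask.shape, dtype=np.int32)
    label = 0
    for start in zip(*np.nonzero(mask)):
        if out[start]:
            continue
        label += 1
        queue = deque([start])
        out[start] = label
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not out[nz, ny, nx]
                ):
                    out[nz, ny, nx] = label
                    queue.append((nz, ny, nx))
    return out
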