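"""Independent test oracles, deliberately naive.

These re-derive reference answers by exhaustive enumeration and via scipy's
rotation alignment, sharing no code with the package's mapping/superposition
implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def align_oracle(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Displacements and RMSD of the optimal rigid alignment of a onto b,
    via scipy (>=3 points) or plain translation (<3 points)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    if len(a) < 3:
        moved = a - ca + cb
    else:
        rot, _ = Rotation.align_vectors(b - cb, a - ca)
        moved = rot.apply(a - ca) + cb
    disp = np.linalg.norm(moved - b, axis=1)
    return disp, float(np.sqrt(np.mean(disp**2)))


def grid_superpose_rmsd(a: np.ndarray, b: np.ndarray, coarse: int = 24) -> float:
    """Minimum RMSD by brute-force search over rotations (coarse Euler grid
    followed by local refinement), fully independent of any SVD solver."""
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)

    def rmsd_of(angles):
        moved = Rotation.from_euler("zyx", angles).apply(a)
        return np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    best_angles, best = None, np.inf
    for angles in itertools.product(grid, repeat=3):
        r = rmsd_of(angles)
        if r < best:
            best, best_angles = r, np.array(angles)
    step = 2 * np.pi / coarse
    while step > 1e-5:
        improved = False
        for axis in range(3):
            for sign in (-1.0, 1.0):
                trial = best_angles.copy()
                trial[axis] += sign * step
                r = rmsd_of(trial)
                if r < best:
                    best, best_angles, improved = r, trial, True
        if not improved:
            step /= 2
    return float(best)


def mapping_oracle(clouds, hypothesis, max_omitted: int):
    """Exhaustive best-fit mapping over (conformer x subset x assignment).

    ``clouds`` is a list of lists of (ftype, xyz) tuples; ``hypothesis`` a
    list of (ftype, xyz, tolerance, weight).  Returns (fit, correspondence)
    with correspondence as a sorted tuple of (hyp index, cloud index),
    ties broken by lower rmsd then lexicographic correspondence then lower
    conformer index.
    """
    k = len(hypothesis)
    centroids = np.array([f[1] for f in hypothesis])
    best_key, best = None, (0.0, ())
    for ci, cloud in enumerate(clouds):
        pos = np.array([f[1] for f in cloud]) if cloud else np.zeros((0, 3))
        for m in range(max(1, k - max_omitted), k + 1):
            for subset in itertools.combinations(range(k), m):
                for perm in itertools.permutations(range(len(cloud)), m):
                    if any(cloud[c][0] != hypothesis[s][0]
                           for s, c in zip(subset, perm)):
                        continue
                    disp, rmsd = align_oracle(pos[list(perm)], centroids[list(subset)])
                    fit = sum(
                        hypothesis[s][3]
                        * max(0.0, 1.0 - (d / hypothesis[s][2]) ** 2)
                        for s, d in zip(subset, disp)
                    )
                    corr = tuple(zip(subset, perm))
                    key = (-fit, rmsd, corr, ci)
                    if best_key is None or key < best_key:
                        best_key, best = key, (fit, corr)
    return best
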