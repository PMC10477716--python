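"""Small shared helpers: seeding, Gaussian spectral shapes, triangle vectors."""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(base_seed: int, tag: str) -> int:
    """Derive a stage-specific seed from a global seed and a stage name.

    Deterministic across platforms and Python processes (no use of hash()).
    """
    digest = hashlib.sha256(f"{int(base_seed)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def gaussian_profile(grid: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Non-negative Gaussian bump on a wavelength grid, unit Euclidean norm."""
    g = np.exp(-0.5 * ((np.asarray(grid, dtype=float) - peak) / width) ** 2)
    g = np.clip(g, 0.0, None)
    nrm = np.linalg.norm(g)
    if nrm == 0:
        raise ValueError(f"Gaussian profile at {peak} nm has no support on the grid")
    return g / nrm


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle entries of a square matrix as a vector."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]
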