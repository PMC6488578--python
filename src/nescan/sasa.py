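"""Rolling-probe-style solvent accessibility on coarse sphere models.

Accessibility is estimated in the Shrake–Rupley manner: each atom is a
sphere; test points are distributed quasi-uniformly on the probe-expanded
surface (radius + probe) with a Fibonacci lattice, and a point is
accessible when it lies outside every other atom's probe-expanded sphere.
A cavity narrower than the probe diameter is therefore inaccessible, which
is exactly the rolling-probe behaviour the accessibility correction needs.
"""

from __future__ import annotations

import numpy as np

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 146


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def accessible_fractions(
    centers: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Accessible surface fraction of each sphere in ``subset``.

    Parameters
    ----------
    centers : (n, 3) sphere centres in Å.
    radii : (n,) sphere radii in Å.
    subset : indices of the spheres to evaluate (default: all).

    Returns
    -------
    (len(subset),) fractions in [0, 1].
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers must be (n, 3)")
    if len(radii) != len(centers):
        raise ValueError("radii/centers length mismatch")
    if subset is None:
        subset = np.arange(len(centers))
    unit = fibonacci_sphere(n_points)
    expanded = radii + probe
    out = np.empty(len(subset))
    for j, i in enumerate(subset):
        pts = centers[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        # neighbours that could occlude any test point
        d = np.linalg.norm(centers - centers[i], axis=1)
        nbr = np.where((d < expanded + expanded[i]) & (np.arange(len(centers)) != i))[0]
        for k in nbr:
            accessible &= (
                np.linalg.norm(pts - centers[k], axis=1) >= expanded[k]
            )
            if not accessible.any():
                break
        out[j] = accessible.mean()
    return out


def sphere_area(radius: float, probe: float = DEFAULT_PROBE) -> float:
    """Probe-expanded surface area of an isolated sphere (Å²)."""
    r = radius + probe
    return 4.0 * np.pi * r * r
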