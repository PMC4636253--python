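"""Superimposition machinery: centroid size, reflection, generalized
Procrustes analysis (GPA), tangent projection and Procrustes distance.

Matching symmetry is handled by reflecting one designated side *before*
superimposition; the rotation fit itself never reflects, so chirality is
preserved where it exists.  All shapes are scaled to unit centroid size
(full Procrustes), keeping size as a separate variable analyzed on the
pre-scaling centroid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import LandmarkConfiguration, SpecimenRecord

# The iteration is run to near machine precision so that GPA is idempotent
# (re-running on aligned output moves the consensus by < 1e-10).
GPA_TOL = 1e-13
GPA_MAX_ITER = 100


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances from the barycentre.

    Accepts a :class:`LandmarkConfiguration` or an (LM, 2) array.
    Translation- and rotation-invariant; scales linearly with the
    coordinates.
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def reflect(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration about the y axis (x negated, order kept)."""
    pts = config.points.copy()
    pts[:, 0] = -pts[:, 0]
    return LandmarkConfiguration(pts, config.point_roles)


def _center_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs <= 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return centered / cs, float(cs)


def _rotate_to(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (det=+1, no reflection) of x onto target."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    return x @ rot


@dataclass
class AlignedShapes:
    """Result of a GPA run.

    Attributes
    ----------
    consensus : (LM, 2) array at unit centroid size, centered at the origin.
    aligned : (n, LM, 2) array of superimposed configurations.
    centroid_sizes : (n,) pre-scaling centroid sizes.
    records : the input records, in the row order of ``aligned``
        (reflected side already mirrored).
    n_iterations : GPA iterations to convergence.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    records: list[SpecimenRecord]
    n_iterations: int

    @property
    def n_points(self) -> int:
        return self.consensus.shape[0]

    @property
    def shape_dim(self) -> int:
        """Intrinsic dimension of shape space: 2*LM - 4 for 2D data."""
        return 2 * self.n_points - 4

    def flat_aligned(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2*LM) matrix."""
        return self.aligned.reshape(self.aligned.shape[0], -1)

    def flat_consensus(self) -> np.ndarray:
        return self.consensus.ravel()


def gpa(records, reflect_side: str | None = "left") -> AlignedShapes:
    """Generalized Procrustes analysis of a set of specimen records.

    The configurations of *reflect_side* (``"left"``, ``"right"`` or
    ``None``/``"none"``) are mirrored first so both sides are directly
    comparable.  All configurations are then centered, scaled to unit
    centroid size, and iteratively rotated to the running consensus until
    the consensus moves by less than ``GPA_TOL`` (full Procrustes, rotation
    only).  Also accepts raw ``LandmarkConfiguration`` objects.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    configs, out_records = [], []
    for rec in records:
        if isinstance(rec, LandmarkConfiguration):
            cfg, out = rec, rec
        else:
            cfg = rec.config
            out = rec
            if reflect_side not in (None, "none") and rec.side == reflect_side:
                cfg = reflect(cfg)
                out = replace(rec, config=cfg)
        configs.append(cfg)
        out_records.append(out)
    lms = {c.n_points for c in configs}
    if len(lms) != 1:
        raise ValueError(f"configurations disagree on point count: {sorted(lms)}")

    shapes = np.empty((len(configs), configs[0].n_points, 2))
    sizes = np.empty(len(configs))
    for i, c in enumerate(configs):
        shapes[i], sizes[i] = _center_scale(c.points)

    consensus = shapes[0]
    delta = np.inf
    for it in range(1, GPA_MAX_ITER + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = _rotate_to(shapes[i], consensus)
        new = shapes.mean(axis=0)
        new, _ = _center_scale(new)
        delta = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if delta < GPA_TOL:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {GPA_MAX_ITER} iterations (last delta {delta:.3e})"
        )
    # final re-fit so every shape is optimally rotated to the converged consensus
    for i in range(shapes.shape[0]):
        shapes[i] = _rotate_to(shapes[i], consensus)
    return AlignedShapes(
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=sizes,
        records=out_records,
        n_iterations=it,
    )


def procrustes_distance(a, b) -> float:
    """Euclidean distance between two commonly-aligned coordinate vectors.

    Both arguments must come from the same GPA alignment (no per-pair
    re-superimposition); this is exactly the quantity whose squares the
    ANOVA decomposition sums.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"mismatched lengths: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def tangent_project(aligned: AlignedShapes) -> np.ndarray:
    """Per-record tangent-space coordinates, an (n, 2*LM) matrix.

    Each record's deviation from the consensus is projected orthogonally
    to the consensus direction.  Together with centering (2 constraints)
    and the rotation alignment (1), this leaves vectors of intrinsic
    dimension 2*LM - 4.
    """
    c = aligned.flat_consensus()
    c = c / np.linalg.norm(c)
    x = aligned.flat_aligned()
    dev = x - aligned.flat_consensus()
    return dev - np.outer(dev @ c, c)
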