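"""PCA of the variance-component strata of the symmetry design, lollipop
displacement exports, and angular comparison of principal components
against a random-vector null.

Each ANOVA stratum (individual, individual x side interaction, replicate
error) yields a matrix of tangent-space deviation vectors; its PCA gives
the dominant displacement fields of that variance source.  Whether two
sources share morphological structure is tested by the angle between
index-matched PCs, compared with the distribution of angles between
independent uniformly random unit vectors in d = 2*LM - 4 dimensions
(one-sided: smaller-than-random angles indicate shared structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .anova import Design, design_from_records, _cell_means
from .procrustes import AlignedShapes, tangent_project

STRATA = ("individual", "interaction", "error")


@dataclass
class EffectPCA:
    effect: str
    eigenvectors: np.ndarray  # (k, 2*LM), rows orthonormal, sign-fixed
    eigenvalues: np.ndarray  # descending, >= 0
    pct_variance: np.ndarray  # sums to 100 over all PCs

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class AngularTestResult:
    pc_pair: tuple[int, int]
    angle_deg: float
    dimension: int
    p: float

    @property
    def stars(self) -> str:
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p <= thr:
                return s
        return ""


def effect_deviations(
    aligned: AlignedShapes, design: Design | None = None, effect: str = "individual"
) -> np.ndarray:
    """Deviation matrix of one variance stratum (rows sum to zero).

    individual: individual means minus the grand mean (one row per
    individual); interaction: cell means minus individual, side and grand
    corrections (one row per individual x side); error: observations minus
    their cell mean (one row per record).
    """
    if effect not in STRATA:
        raise ValueError(f"effect must be one of {STRATA}, got {effect!r}")
    if design is None:
        design = design_from_records(aligned.records)
    y = tangent_project(aligned)
    grand, m_ind, m_side, m_cell = _cell_means(y, design)
    if effect == "individual":
        return m_ind - grand
    if effect == "interaction":
        dev = m_cell - m_ind[:, None, :] - m_side[None, :, :] + grand
        return dev.reshape(-1, dev.shape[-1])
    return y - m_cell[design.ind_idx, design.side_idx]


def pca_effect(deviations: np.ndarray, effect: str = "") -> EffectPCA:
    """PCA of a deviation matrix via SVD of the column-centred rows.

    Eigenvector signs are fixed so each PC's largest-magnitude loading is
    positive; percentages of variance are over all retained (nonzero)
    eigenvalues.
    """
    dev = np.asarray(deviations, float)
    if dev.ndim != 2 or dev.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    if not np.any(dev):
        raise ValueError("zero deviation matrix")
    centered = dev - dev.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (dev.shape[0] - 1)
    keep = eigvals > eigvals[0] * 1e-12
    eigvals = eigvals[keep]
    vecs = vt[keep]
    for i in range(vecs.shape[0]):
        j = np.argmax(np.abs(vecs[i]))
        if vecs[i, j] < 0:
            vecs[i] = -vecs[i]
    return EffectPCA(
        effect=effect,
        eigenvectors=vecs,
        eigenvalues=eigvals,
        pct_variance=100 * eigvals / eigvals.sum(),
    )


def vector_angle(u, v) -> float:
    """Angle between two directions in degrees, folded to [0, 90].

    The fold (via |cos|) makes the result invariant to the sign ambiguity
    of eigenvectors.
    """
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(u @ v)) / (nu * nv)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def random_angle_test(angle_deg: float, d: int) -> float:
    """P(angle between two independent random unit vectors in d dimensions,
    folded to [0, 90], <= observed angle).

    For uniform unit vectors, cos^2 of the angle is Beta(1/2, (d-1)/2)
    distributed, so the p-value is an upper tail of the regularized
    incomplete beta function.  Small p means the two directions are more
    parallel than chance.
    """
    if d < 2:
        raise ValueError("dimension must be >= 2")
    if not 0 <= angle_deg <= 90:
        raise ValueError("angle must be in [0, 90] degrees")
    c2 = np.cos(np.radians(angle_deg)) ** 2
    # P(|cos| >= c) = 1 - I_{c^2}(1/2, (d-1)/2)
    return float(1.0 - special.betainc(0.5, (d - 1) / 2.0, c2))


def random_angle_test_mc(angle_deg: float, d: int, n_draws: int = 100_000,
                         seed: int = 0) -> float:
    """Monte-Carlo version of :func:`random_angle_test` (simulation oracle)."""
    if d < 2:
        raise ValueError("dimension must be >= 2")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_draws, d))
    v = rng.standard_normal((n_draws, d))
    c = np.abs((u * v).sum(axis=1)) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return float((c >= np.cos(np.radians(angle_deg))).mean())


def compare_pcs(
    pca_a: EffectPCA, pca_b: EffectPCA, k: int = 3, d: int | None = None
) -> list[AngularTestResult]:
    """Angles and random-vector p-values for index-matched PC pairs.

    *d* is the null dimension (2*LM - 4); when omitted it is derived from
    the eigenvector length.
    """
    if pca_a.eigenvectors.shape[1] != pca_b.eigenvectors.shape[1]:
        raise ValueError("PCAs are over different landmark schemes")
    if k > min(pca_a.n_components, pca_b.n_components):
        raise ValueError(
            f"k={k} exceeds available PCs "
            f"({pca_a.n_components}, {pca_b.n_components})"
        )
    if d is None:
        d = pca_a.eigenvectors.shape[1] - 4
    out = []
    for i in range(k):
        ang = vector_angle(pca_a.eigenvectors[i], pca_b.eigenvectors[i])
        out.append(
            AngularTestResult(
                pc_pair=(i + 1, i + 1),
                angle_deg=ang,
                dimension=d,
                p=random_angle_test(ang, d),
            )
        )
    return out


def angle_table(results: dict[str, list[AngularTestResult]]) -> pd.DataFrame:
    """Assemble angular test results into a PC x comparison table with stars."""
    rows = {}
    for label, res in results.items():
        for r in res:
            rows.setdefault(r.pc_pair[0], {})[label] = f"{r.angle_deg:.2f}{r.stars}"
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "PC"
    return df


def lollipop_export(
    pca: EffectPCA, consensus: np.ndarray, pc_index: int = 1
) -> pd.DataFrame:
    """Per-landmark displacement table for one PC (lollipop graph data).

    Columns: landmark (1-based), consensus x/y, displacement dx/dy.  The
    dx/dy columns re-flatten to the eigenvector exactly.
    """
    if not 1 <= pc_index <= pca.n_components:
        raise ValueError(f"pc_index {pc_index} out of range")
    cons = np.asarray(consensus, float).reshape(-1, 2)
    disp = pca.eigenvectors[pc_index - 1].reshape(-1, 2)
    if disp.shape != cons.shape:
        raise ValueError("consensus and eigenvector disagree on landmark count")
    return pd.DataFrame(
        {
            "landmark": np.arange(1, cons.shape[0] + 1),
            "x": cons[:, 0],
            "y": cons[:, 1],
            "dx": disp[:, 0],
            "dy": disp[:, 1],
        }
    )


def lollipop_figure(pca: EffectPCA, consensus: np.ndarray, pc_index: int = 1,
                    scale: float = 0.3, ax=None):
    """Optional matplotlib rendering of a lollipop graph."""
    import matplotlib.pyplot as plt

    tab = lollipop_export(pca, consensus, pc_index)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(tab.x, tab.y, "o", ms=3, color="k")
    for _, row in tab.iterrows():
        ax.plot([row.x, row.x + scale * row.dx], [row.y, row.y + scale * row.dy],
                "-", color="tab:red", lw=1)
    ax.set_aspect("equal")
    ax.set_title(f"{pca.effect} PC{pc_index}")
    return ax
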