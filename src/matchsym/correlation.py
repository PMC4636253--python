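"""Buffering-hypothesis correlation battery, standardized major axis (SMA)
trend lines, and the multivariate allometric regression of shape on size.

The battery asks three questions of the per-individual variation scores:
(a) do inter-individual variation (canalization's inverse) and FA
(developmental stability's inverse) correlate, per trait and anchor type;
(b) do shape and size variation correlate within the intra- and
inter-individual levels; and (c) do the four scores correlate across the
two anchor types.  Significant correlations are flagged for SMA trend
lines, which treat both variables symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fa import FARecord, fa_records_to_frame
from .procrustes import AlignedShapes, tangent_project


def pearson_test(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (t transform, n-2 df).

    ``method`` may be "pearson" (default) or "spearman".
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def sma_fit(x, y) -> tuple[float, float]:
    """Standardized major axis fit: slope = sign(r) * sd(y)/sd(x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


@dataclass
class CorrelationResult:
    question: str  # "a" | "b" | "c"
    pair: str
    anchor: str  # dorsal | ventral | cross
    n: int
    r: float
    p: float
    sma_slope: float
    sma_intercept: float
    plot_trend: bool


#: The frozen comparison set of the buffering battery:
#: (question, pair label, anchor, x column, y column)
BATTERY_SCHEMA = [
    ("a", "inter_shape~fa_shape", "dorsal", "inter_shape", "fa_shape"),
    ("a", "inter_shape~fa_shape", "ventral", "inter_shape", "fa_shape"),
    ("a", "inter_size~fa_size", "dorsal", "inter_size", "fa_size"),
    ("a", "inter_size~fa_size", "ventral", "inter_size", "fa_size"),
    ("b", "fa_shape~fa_size", "dorsal", "fa_shape", "fa_size"),
    ("b", "fa_shape~fa_size", "ventral", "fa_shape", "fa_size"),
    ("b", "inter_shape~inter_size", "dorsal", "inter_shape", "inter_size"),
    ("b", "inter_shape~inter_size", "ventral", "inter_shape", "inter_size"),
    ("c", "fa_shape_D~fa_shape_V", "cross", "fa_shape", "fa_shape"),
    ("c", "fa_size_D~fa_size_V", "cross", "fa_size", "fa_size"),
    ("c", "inter_shape_D~inter_shape_V", "cross", "inter_shape", "inter_shape"),
    ("c", "inter_size_D~inter_size_V", "cross", "inter_size", "inter_size"),
]


def run_buffering_battery(
    dorsal: list[FARecord],
    ventral: list[FARecord],
    alpha: float = 0.05,
    method: str = "pearson",
    holm: bool = False,
) -> pd.DataFrame:
    """The 12-test buffering battery over per-individual variation scores.

    Cross-anchor rows use the individuals present in both anchor datasets.
    ``plot_trend`` is set where p <= alpha (SMA trend lines are drawn only
    for significant correlations).  With ``holm=True`` a Holm correction is
    applied across the 12 tests before flagging.
    """
    frames = {
        "dorsal": fa_records_to_frame(dorsal).set_index("individual_id"),
        "ventral": fa_records_to_frame(ventral).set_index("individual_id"),
    }
    shared = frames["dorsal"].index.intersection(frames["ventral"].index)
    results = []
    for question, pair, anchor, xcol, ycol in BATTERY_SCHEMA:
        if anchor == "cross":
            if len(shared) < 3:
                raise ValueError(
                    f"only {len(shared)} individuals shared across anchors; "
                    "cross-anchor correlations need >= 3"
                )
            x = frames["dorsal"].loc[shared, xcol].to_numpy()
            y = frames["ventral"].loc[shared, ycol].to_numpy()
        else:
            x = frames[anchor][xcol].to_numpy()
            y = frames[anchor][ycol].to_numpy()
        r, p = pearson_test(x, y, method=method)
        slope, intercept = sma_fit(x, y)
        results.append(
            CorrelationResult(question, pair, anchor, x.size, r, p, slope,
                              intercept, False)
        )
    pvals = np.array([res.p for res in results])
    if holm:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        flagged = adj <= alpha
    else:
        flagged = pvals <= alpha
    for res, fl in zip(results, flagged):
        res.plot_trend = bool(fl)
    return pd.DataFrame(
        {
            "question": [r.question for r in results],
            "pair": [r.pair for r in results],
            "anchor": [r.anchor for r in results],
            "n": [r.n for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "sma_slope": [r.sma_slope for r in results],
            "sma_intercept": [r.sma_intercept for r in results],
            "plot_trend": [r.plot_trend for r in results],
        }
    )


@dataclass
class AllometryResult:
    pct_shape_variance_explained: float
    p: float
    n: int
    predictor: str


def allometry_test(
    aligned: AlignedShapes,
    sizes: np.ndarray | None = None,
    predictor: str = "cs",
    n_perm: int = 10_000,
    seed: int = 0,
) -> AllometryResult:
    """Multivariate regression of tangent shape coordinates on size.

    Reports the percentage of total shape variation explained by the size
    predictor (centroid size, or its log with ``predictor="log_cs"``) and a
    permutation p-value obtained by shuffling the size values against the
    shape rows.
    """
    y = tangent_project(aligned)
    x = np.asarray(
        aligned.centroid_sizes if sizes is None else sizes, float
    )
    if predictor == "log_cs":
        x = np.log(x)
    elif predictor != "cs":
        raise ValueError("predictor must be 'cs' or 'log_cs'")
    if x.size != y.shape[0]:
        raise ValueError("size vector length must match number of shapes")
    if x.size < 5:
        raise ValueError("need >= 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant size predictor")

    def pct_explained(xv):
        xc = xv - xv.mean()
        yc = y - y.mean(axis=0)
        beta = (xc @ yc) / (xc @ xc)  # per-coordinate slope
        ss_pred = float((xc**2).sum() * (beta**2).sum())
        ss_tot = float((yc**2).sum())
        return 100.0 * ss_pred / ss_tot

    obs = pct_explained(x)
    rng = np.random.default_rng(seed)
    ge = 1
    for _ in range(n_perm):
        if pct_explained(rng.permutation(x)) >= obs:
            ge += 1
    return AllometryResult(
        pct_shape_variance_explained=obs,
        p=ge / (n_perm + 1),
        n=int(x.size),
        predictor=predictor,
    )
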