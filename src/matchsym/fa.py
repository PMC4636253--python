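"""Per-individual fluctuating-asymmetry (FA) and inter-individual variation
scores for shape and size, with FA-vs-antisymmetry diagnostics.

FA indices are raw (uncorrected for measurement error): size FA is the
replicate-averaged absolute left-right centroid-size difference; shape FA
is the Procrustes distance between an individual's replicate-averaged left
and right shapes in a common superimposition with one side reflected.
Inter-individual scores are deviations of individual means from the sample
consensus.  Antisymmetry — systematic asymmetry of random direction, which
would invalidate reading the individual x side variance as FA — is screened
via the signed R-L size distribution (skewness, kurtosis and a dip-statistic
unimodality test) and via side overlap in a PCA of the aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import Design, design_from_records
from .procrustes import AlignedShapes, procrustes_distance, tangent_project


@dataclass
class FARecord:
    """Intra- (FA) and inter-individual variation scores for one individual."""

    individual_id: str
    anchor_type: str
    fa_shape: float
    fa_size: float
    inter_shape: float
    inter_size: float


def size_fa(cs_left, cs_right) -> float:
    """Size FA: mean over replicates of |CS_left - CS_right|."""
    left = np.asarray(cs_left, float)
    right = np.asarray(cs_right, float)
    if left.size == 0 or left.shape != right.shape:
        raise ValueError("need matching replicate centroid sizes for both sides")
    return float(np.abs(left - right).mean())


def shape_fa(left_vecs, right_vecs, average_first: bool = True) -> float:
    """Shape FA: Procrustes distance between left and right mean shapes.

    *left_vecs* / *right_vecs* are (R, 2*LM) aligned coordinate (or tangent)
    matrices from a common GPA with one side reflected.  With
    ``average_first`` (default) replicates are averaged before the distance
    is taken; otherwise per-replicate distances are averaged.
    """
    left = np.atleast_2d(np.asarray(left_vecs, float))
    right = np.atleast_2d(np.asarray(right_vecs, float))
    if left.shape != right.shape:
        raise ValueError("left and right replicate matrices must match")
    if average_first:
        return procrustes_distance(left.mean(axis=0), right.mean(axis=0))
    return float(
        np.mean([procrustes_distance(a, b) for a, b in zip(left, right)])
    )


def compute_fa_records(
    aligned: AlignedShapes,
    design: Design | None = None,
    average_first: bool = True,
) -> list[FARecord]:
    """All four variation scores for every individual in a GPA result."""
    if design is None:
        design = design_from_records(aligned.records)
    y = tangent_project(aligned)
    sizes = aligned.centroid_sizes
    anchor = aligned.records[0].anchor_type
    grand_cs = float(sizes.mean())
    out = []
    for i, ind in enumerate(design.individuals):
        mask = design.ind_idx == i
        lmask = mask & (design.side_idx == 0)
        rmask = mask & (design.side_idx == 1)
        order_l = np.argsort(design.rep_idx[lmask])
        order_r = np.argsort(design.rep_idx[rmask])
        fa_sh = shape_fa(y[lmask][order_l], y[rmask][order_r], average_first)
        fa_sz = size_fa(sizes[lmask][order_l], sizes[rmask][order_r])
        inter_sh = float(np.linalg.norm(y[mask].mean(axis=0)))
        inter_sz = abs(float(sizes[mask].mean()) - grand_cs)
        out.append(FARecord(ind, anchor, fa_sh, fa_sz, inter_sh, inter_sz))
    return out


def inter_individual_scores(
    aligned: AlignedShapes, design: Design | None = None
) -> pd.DataFrame:
    """Per-individual deviations of mean shape / mean size from the consensus."""
    recs = compute_fa_records(aligned, design)
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in recs],
            "inter_shape": [r.inter_shape for r in recs],
            "inter_size": [r.inter_size for r in recs],
        }
    )


def fa_records_to_frame(records: list[FARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "anchor_type": [r.anchor_type for r in records],
            "fa_shape": [r.fa_shape for r in records],
            "fa_size": [r.fa_size for r in records],
            "inter_shape": [r.inter_shape for r in records],
            "inter_size": [r.inter_size for r in records],
        }
    )


def fa_summary(records: list[FARecord]) -> pd.DataFrame:
    """Mean +/- SD of FA per anchor type and trait.

    Rows (for the anchor types present, in this order): ``Dorsal (shape)``,
    ``Ventral (shape)``, ``Dorsal (size)``, ``Ventral (size)``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 individuals")
    df = fa_records_to_frame(records)
    rows = []
    for trait, col in (("shape", "fa_shape"), ("size", "fa_size")):
        for anchor in ("dorsal", "ventral"):
            sub = df[df.anchor_type == anchor]
            if len(sub):
                rows.append(
                    {
                        "anchor": f"{anchor.capitalize()} ({trait})",
                        "mean": float(sub[col].mean()),
                        "sd": float(sub[col].std(ddof=1)),
                        "n": int(len(sub)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Antisymmetry diagnostics
# ---------------------------------------------------------------------------


def dip_statistic(x) -> float:
    """Hartigan & Hartigan's dip statistic of unimodality.

    The dip is the largest sup-norm distance between the empirical CDF and
    the closest unimodal CDF; it lies in [1/(2n), 1/4], reaching 1/4 for a
    balanced two-point distribution.  Implementation follows the classical
    greatest-convex-minorant / least-concave-majorant algorithm.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n < 4 or x[0] == x[-1]:
        # degenerate: the classical convention returns the lower bound
        return 0.0 if n < 2 else 1.0 / (2 * n)

    # All bookkeeping below is in ECDF *count* units (0..n); the statistic
    # is divided by 2n at the end.
    low, high = 0, n - 1
    dip_val = 1.0

    # predecessor links of the greatest convex minorant (mn) and successor
    # links of the least concave majorant (mj) over the whole sample
    mn = np.empty(n, dtype=int)
    mj = np.empty(n, dtype=int)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    while True:
        # GCM touch points within [low, high], from high down to low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        # LCM touch points within [low, high], from low up to high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)

        ig, ih = l_gcm - 1, l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            # largest vertical distance between the GCM and LCM curves
            d = 0.0
            ix, iv = l_gcm - 2, 1
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # distance measured at the LCM point against the GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # distance measured at the GCM point against the LCM chord
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip_val:
            break

        # max ECDF deviation above the GCM between low and the critical point
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            je, jb = gcm[j], gcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # max ECDF deviation below the LCM between the critical point and high
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip_val = max(dip_val, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return float(dip_val / (2.0 * n))


def dip_test(x, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Dip statistic with a Monte-Carlo p-value under the uniform null.

    The uniform distribution is the standard calibration null for the dip
    (it is the hardest unimodal case); p is the fraction of uniform samples
    of the same size with a dip at least as large.
    """
    x = np.asarray(x, float)
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boots = np.array(
        [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
    )
    p = (1 + (boots >= d).sum()) / (n_boot + 1)
    return d, float(p)


@dataclass
class AntisymmetrySizeReport:
    n: int
    mean: float
    skewness: float
    excess_kurtosis: float
    dip: float
    dip_p: float
    histogram: pd.DataFrame
    verdict: str
    warning: str | None = None


def antisymmetry_size_check(
    signed_diffs, n_bins: int = 10, seed: int = 0, n_boot: int = 500
) -> AntisymmetrySizeReport:
    """Screen the signed R-L size differences for antisymmetry.

    A unimodal, roughly mesokurtic distribution of signed differences is
    consistent with FA; a strongly platykurtic (excess kurtosis < -1) or
    bimodal (dip test rejecting at 0.05) distribution suggests antisymmetry.
    """
    d = np.asarray(signed_diffs, float)
    if d.size < 10:
        raise ValueError("need at least 10 individuals")
    if np.ptp(d) == 0:
        hist = pd.DataFrame({"bin_left": [d[0]], "bin_right": [d[0]], "count": [d.size]})
        return AntisymmetrySizeReport(
            n=d.size, mean=float(d[0]), skewness=0.0, excess_kurtosis=0.0,
            dip=0.0, dip_p=1.0, histogram=hist, verdict="FA-consistent",
            warning="all signed differences identical; distribution degenerate",
        )
    counts, edges = np.histogram(d, bins=n_bins)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    kurt = float(stats.kurtosis(d, fisher=True, bias=False))
    skew = float(stats.skew(d, bias=False))
    dip, dip_p = dip_test(d, n_boot=n_boot, seed=seed)
    suspected = kurt < -1.0 or dip_p < 0.05
    return AntisymmetrySizeReport(
        n=d.size,
        mean=float(d.mean()),
        skewness=skew,
        excess_kurtosis=kurt,
        dip=dip,
        dip_p=dip_p,
        histogram=hist,
        verdict="antisymmetry-suspected" if suspected else "FA-consistent",
    )


def signed_size_differences(
    aligned: AlignedShapes, design: Design | None = None
) -> np.ndarray:
    """Per-individual replicate-averaged signed right-minus-left centroid sizes."""
    if design is None:
        design = design_from_records(aligned.records)
    sizes = aligned.centroid_sizes
    out = np.empty(design.n_individuals)
    for i in range(design.n_individuals):
        mask = design.ind_idx == i
        out[i] = (
            sizes[mask & (design.side_idx == 1)].mean()
            - sizes[mask & (design.side_idx == 0)].mean()
        )
    return out


@dataclass
class AntisymmetryShapeReport:
    scores: pd.DataFrame  # PC1, PC2, side per record
    pct_variance: np.ndarray
    side_accuracy: float
    verdict: str


def antisymmetry_shape_check(
    aligned: AlignedShapes, design: Design | None = None
) -> AntisymmetryShapeReport:
    """PCA of aligned coordinates labeled by side; quantifies side overlap.

    The overlap statistic is the side-classification accuracy of a
    nearest-centroid rule on PC1-2: accuracy near 0.5 means a single mixed
    cluster (FA); accuracy near 1 means the two sides separate (directional
    asymmetry / antisymmetry signal).  Deterministic.
    """
    if design is None:
        design = design_from_records(aligned.records)
    y = tangent_project(aligned)
    yc = y - y.mean(axis=0)
    _, s, vt = np.linalg.svd(yc, full_matrices=False)
    scores = yc @ vt[:2].T
    var = s**2
    pct = 100 * var / var.sum() if var.sum() > 0 else var
    sides = design.side_idx
    cen = np.array([scores[sides == g].mean(axis=0) for g in (0, 1)])
    pred = np.argmin(
        ((scores[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    acc = float((pred == sides).mean())
    df = pd.DataFrame(
        {
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
            "side": ["left" if s_ == 0 else "right" for s_ in sides],
        }
    )
    verdict = "FA-consistent" if acc < 0.75 else "side-separation-suspected"
    return AntisymmetryShapeReport(df, pct[:2], acc, verdict)
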