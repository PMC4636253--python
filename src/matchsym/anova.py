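"""Procrustes ANOVA for shape and two-way ANOVA for centroid size under a
balanced individual x side design with digitization replicates, plus the
interaction-free submodels and assumption diagnostics.

The shape analysis sums, over all 2*LM tangent coordinates, the classical
balanced two-factor sums of squares; degrees of freedom are the univariate
df multiplied by the shape-space dimension d = 2*LM - 4.  F ratios follow
the mixed-model ladder: individual and side are tested over the
individual x side interaction, and the interaction (the fluctuating-
asymmetry stratum) over replicate measurement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SIDES, SpecimenRecord
from .procrustes import AlignedShapes, tangent_project

EFFECTS = ("individual", "side", "interaction", "replicate")


@dataclass
class AnovaRow:
    effect: str
    SS: float
    pct_SS: float
    df: int
    MS: float
    F: float | None = None
    p: float | None = None
    denominator: str | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    trait: str  # "shape" | "size"
    anchor_type: str | None
    N: int
    R: int
    LM: int

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": [r.effect for r in self.rows],
                "SS": [r.SS for r in self.rows],
                "pct_SS": [round(r.pct_SS, 1) for r in self.rows],
                "MS": [r.MS for r in self.rows],
                "df": [r.df for r in self.rows],
                "F": [r.F for r in self.rows],
                "p": [r.p for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class Design:
    """Integer-coded balanced design extracted from specimen records."""

    individuals: list[str]
    ind_idx: np.ndarray
    side_idx: np.ndarray  # 0 = left, 1 = right
    rep_idx: np.ndarray  # 0-based
    n_replicates: int

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def design_from_records(records: list[SpecimenRecord]) -> Design:
    individuals = sorted({r.individual_id for r in records})
    ind_map = {v: i for i, v in enumerate(individuals)}
    reps = sorted({r.replicate for r in records})
    if reps != list(range(1, len(reps) + 1)):
        raise ValueError(f"replicate labels must be 1..R, got {reps}")
    n, nr = len(individuals), len(reps)
    seen = set()
    for r in records:
        seen.add((r.individual_id, r.side, r.replicate))
    if len(seen) != len(records) or len(records) != n * 2 * nr:
        raise ValueError(
            "unbalanced design: every individual needs both sides x all "
            "replicates exactly once (run filter_complete_pairs first)"
        )
    return Design(
        individuals=individuals,
        ind_idx=np.array([ind_map[r.individual_id] for r in records]),
        side_idx=np.array([SIDES.index(r.side) for r in records]),
        rep_idx=np.array([r.replicate - 1 for r in records]),
        n_replicates=nr,
    )


def _cell_means(y: np.ndarray, design: Design):
    """Grand, individual, side and cell means of an (n_obs, q) matrix."""
    n, nr = design.n_individuals, design.n_replicates
    q = y.shape[1]
    grand = y.mean(axis=0)
    m_ind = np.zeros((n, q))
    m_side = np.zeros((2, q))
    m_cell = np.zeros((n, 2, q))
    np.add.at(m_ind, design.ind_idx, y)
    np.add.at(m_side, design.side_idx, y)
    np.add.at(m_cell, (design.ind_idx, design.side_idx), y)
    m_ind /= 2 * nr
    m_side /= n * nr
    m_cell /= nr
    return grand, m_ind, m_side, m_cell


def _two_factor_ss(y: np.ndarray, design: Design):
    """Balanced two-factor SS decomposition summed over columns."""
    n, nr = design.n_individuals, design.n_replicates
    grand, m_ind, m_side, m_cell = _cell_means(y, design)
    ss_ind = 2 * nr * float(((m_ind - grand) ** 2).sum())
    ss_side = n * nr * float(((m_side - grand) ** 2).sum())
    inter = m_cell - m_ind[:, None, :] - m_side[None, :, :] + grand
    ss_int = nr * float((inter**2).sum())
    resid = y - m_cell[design.ind_idx, design.side_idx]
    ss_rep = float((resid**2).sum())
    return ss_ind, ss_side, ss_int, ss_rep


def _assemble_table(ss, d, design, trait, anchor_type, lm) -> AnovaTable:
    n, nr = design.n_individuals, design.n_replicates
    dfs = ((n - 1) * d, d, (n - 1) * d, n * 2 * (nr - 1) * d)
    total = sum(ss)
    rows = []
    ms = [s / df if df > 0 else math.nan for s, df in zip(ss, dfs)]
    denom = {"individual": 2, "side": 2, "interaction": 3}
    for k, effect in enumerate(EFFECTS):
        f = p = None
        den_name = None
        if effect in denom and dfs[denom[effect]] > 0:
            ms_den = ms[denom[effect]]
            den_name = EFFECTS[denom[effect]]
            if ms_den > 0:
                f = ms[k] / ms_den
                p = float(stats.f.sf(f, dfs[k], dfs[denom[effect]]))
        rows.append(
            AnovaRow(
                effect=effect,
                SS=ss[k],
                pct_SS=100 * ss[k] / total if total > 0 else math.nan,
                df=dfs[k],
                MS=ms[k],
                F=f,
                p=p,
                denominator=den_name,
            )
        )
    return AnovaTable(rows=rows, trait=trait, anchor_type=anchor_type, N=n, R=nr, LM=lm)


def procrustes_anova(aligned: AlignedShapes, design: Design | None = None) -> AnovaTable:
    """Procrustes ANOVA of shape under the individual x side design.

    Requires a GPA run on a balanced dataset with one side reflected.  SS
    are summed over all 2*LM tangent coordinates; df use the shape-space
    dimension d = 2*LM - 4.
    """
    if design is None:
        design = design_from_records(aligned.records)
    if design.n_replicates < 2:
        raise ValueError("Procrustes ANOVA needs >= 2 replicates for the error stratum")
    y = tangent_project(aligned)
    ss = _two_factor_ss(y, design)
    anchor = aligned.records[0].anchor_type if aligned.records else None
    return _assemble_table(
        ss, aligned.shape_dim, design, "shape", anchor, aligned.n_points
    )


def size_anova(
    centroid_sizes: np.ndarray,
    design: Design | list[SpecimenRecord],
    anchor_type: str | None = None,
    lm: int = 0,
) -> AnovaTable:
    """Two-way ANOVA of centroid size (individual, side, interaction, replicate)."""
    if not isinstance(design, Design):
        design = design_from_records(list(design))
    sizes = np.asarray(centroid_sizes, float).reshape(-1, 1)
    if design.n_replicates < 2:
        raise ValueError("size ANOVA needs >= 2 replicates for the error stratum")
    ss = _two_factor_ss(sizes, design)
    table = _assemble_table(ss, 1, design, "size", anchor_type, lm)
    if all(s == 0 for s in ss):
        import warnings

        warnings.warn("all centroid sizes identical; F ratios are undefined")
        for row in table.rows:
            row.F = None
            row.p = None
    return table


def size_anova_from_aligned(aligned: AlignedShapes) -> AnovaTable:
    anchor = aligned.records[0].anchor_type if aligned.records else None
    return size_anova(
        aligned.centroid_sizes,
        design_from_records(aligned.records),
        anchor_type=anchor,
        lm=aligned.n_points,
    )


def anova_table_from_summary(
    mean_squares: dict[str, float],
    n_individuals: int,
    n_replicates: int,
    lm: int,
    trait: str = "shape",
    anchor_type: str | None = None,
) -> AnovaTable:
    """Rebuild an ANOVA table (df, F ratios, p) from published mean squares.

    Useful for checking the F-ratio structure against a printed table when
    the raw data are unavailable: *mean_squares* maps each of the four
    effects to its MS, and the df ladder is reconstructed from the design.
    """
    missing = set(EFFECTS) - set(mean_squares)
    if missing:
        raise ValueError(f"missing mean squares for {sorted(missing)}")
    d = 2 * lm - 4 if trait == "shape" else 1
    n = n_individuals
    design = Design(
        individuals=[f"i{k}" for k in range(n)],
        ind_idx=np.repeat(np.arange(n), 2 * n_replicates),
        side_idx=np.tile(np.repeat([0, 1], n_replicates), n),
        rep_idx=np.tile(np.arange(n_replicates), 2 * n),
        n_replicates=n_replicates,
    )
    dfs = ((n - 1) * d, d, (n - 1) * d, n * 2 * (n_replicates - 1) * d)
    ss = tuple(mean_squares[e] * df for e, df in zip(EFFECTS, dfs))
    return _assemble_table(ss, d, design, trait, anchor_type, lm)


# ---------------------------------------------------------------------------
# Interaction-free submodels
# ---------------------------------------------------------------------------


def _additive_ss(y: np.ndarray, design: Design):
    """Sequential SS for the additive model (individual first, then side).

    Under balance the sequential SS coincide with the full-model main-effect
    SS; the residual pools interaction and replicate variation.
    """
    ss_ind, ss_side, ss_int, ss_rep = _two_factor_ss(y, design)
    grand = y.mean(axis=0)
    ss_tot = float(((y - grand) ** 2).sum())
    ss_res = ss_tot - ss_ind - ss_side
    return ss_ind, ss_side, ss_res, ss_tot


def submodel_anova_shape(
    aligned: AlignedShapes,
    design: Design | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AnovaTable:
    """Distance-based permutational MANOVA of tangent coordinates with
    factors individual and side (no interaction).

    Pseudo-F ratios use sequential SS (individual entered first) over the
    pooled residual; p-values come from ``n_perm`` seeded permutations of
    raw observation rows.
    """
    if design is None:
        design = design_from_records(aligned.records)
    y = tangent_project(aligned)
    n_obs = y.shape[0]
    n = design.n_individuals
    df_ind, df_side, df_res = n - 1, 1, n_obs - n - 1
    ss_ind, ss_side, ss_res, ss_tot = _additive_ss(y, design)
    ms_res = ss_res / df_res
    f_ind = (ss_ind / df_ind) / ms_res
    f_side = (ss_side / df_side) / ms_res

    rng = np.random.default_rng(seed)
    ge_ind = ge_side = 1  # observed counts as one of its own permutations
    for _ in range(n_perm):
        perm = rng.permutation(n_obs)
        pi, ps, pr, _ = _additive_ss(y[perm], design)
        if (pi / df_ind) / (pr / df_res) >= f_ind:
            ge_ind += 1
        if (ps / df_side) / (pr / df_res) >= f_side:
            ge_side += 1
    p_ind = ge_ind / (n_perm + 1)
    p_side = ge_side / (n_perm + 1)

    rows = [
        AnovaRow("individual", ss_ind, 100 * ss_ind / ss_tot, df_ind,
                 ss_ind / df_ind, f_ind, p_ind, "residual"),
        AnovaRow("side", ss_side, 100 * ss_side / ss_tot, df_side,
                 ss_side / df_side, f_side, p_side, "residual"),
        AnovaRow("residual", ss_res, 100 * ss_res / ss_tot, df_res, ms_res),
    ]
    anchor = aligned.records[0].anchor_type if aligned.records else None
    return AnovaTable(rows, "shape", anchor, n, design.n_replicates, aligned.n_points)


def submodel_anova_size(
    centroid_sizes: np.ndarray, design: Design | list[SpecimenRecord]
) -> AnovaTable:
    """Classical additive two-way ANOVA of size (no interaction), parametric p."""
    if not isinstance(design, Design):
        design = design_from_records(list(design))
    y = np.asarray(centroid_sizes, float).reshape(-1, 1)
    n_obs = y.shape[0]
    n = design.n_individuals
    df_ind, df_side, df_res = n - 1, 1, n_obs - n - 1
    ss_ind, ss_side, ss_res, ss_tot = _additive_ss(y, design)
    if ss_tot == 0:
        import warnings

        warnings.warn("all centroid sizes identical; F ratios are undefined")
        rows = [
            AnovaRow("individual", 0.0, math.nan, df_ind, 0.0),
            AnovaRow("side", 0.0, math.nan, df_side, 0.0),
            AnovaRow("residual", 0.0, math.nan, df_res, 0.0),
        ]
        return AnovaTable(rows, "size", None, n, design.n_replicates, 0)
    ms_res = ss_res / df_res
    f_ind = (ss_ind / df_ind) / ms_res
    f_side = (ss_side / df_side) / ms_res
    rows = [
        AnovaRow("individual", ss_ind, 100 * ss_ind / ss_tot, df_ind,
                 ss_ind / df_ind, f_ind, float(stats.f.sf(f_ind, df_ind, df_res)),
                 "residual"),
        AnovaRow("side", ss_side, 100 * ss_side / ss_tot, df_side,
                 ss_side / df_side, f_side, float(stats.f.sf(f_side, df_side, df_res)),
                 "residual"),
        AnovaRow("residual", ss_res, 100 * ss_res / ss_tot, df_res, ms_res),
    ]
    return AnovaTable(rows, "size", None, n, design.n_replicates, 0)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def replicate_residuals(values: np.ndarray, design: Design) -> np.ndarray:
    """Replicate-stratum residuals: observation minus its individual x side
    cell mean."""
    y = np.asarray(values, float).reshape(-1, 1)
    _, _, _, m_cell = _cell_means(y, design)
    return (y - m_cell[design.ind_idx, design.side_idx]).ravel()


def residual_normality(residuals: np.ndarray):
    """Shapiro-Wilk test of the replicate-stratum residuals."""
    res = np.asarray(residuals, float)
    if res.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(res) == 0:
        raise ValueError("residuals are constant; normality test undefined")
    w, p = stats.shapiro(res)
    return float(w), float(p)


def dispersion_homogeneity_shape(
    aligned: AlignedShapes,
    design: Design | None = None,
    n_perm: int = 999,
    seed: int = 0,
):
    """Multivariate dispersion homogeneity across sides.

    Each record's tangent vector is reduced to its distance from its own
    side's spatial centroid; group differences in those distances are
    tested by a one-way F with a seeded permutation p-value.
    """
    if design is None:
        design = design_from_records(aligned.records)
    y = tangent_project(aligned)
    groups = design.side_idx
    dists = _centroid_distances(y, groups)
    f_obs = _oneway_f(dists, groups)
    rng = np.random.default_rng(seed)
    ge = 1
    for _ in range(n_perm):
        gp = rng.permutation(groups)
        dp = _centroid_distances(y, gp)
        if _oneway_f(dp, gp) >= f_obs:
            ge += 1
    return float(f_obs), ge / (n_perm + 1)


def _centroid_distances(y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    d = np.empty(y.shape[0])
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError("each group needs >= 2 members")
        cen = y[mask].mean(axis=0)
        d[mask] = np.sqrt(((y[mask] - cen) ** 2).sum(axis=1))
    return d


def _oneway_f(d: np.ndarray, groups: np.ndarray) -> float:
    grand = d.mean()
    ss_b = ss_w = 0.0
    k = 0
    for g in np.unique(groups):
        dg = d[groups == g]
        ss_b += dg.size * (dg.mean() - grand) ** 2
        ss_w += ((dg - dg.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, d.size - k
    if ss_w == 0:
        return 0.0 if ss_b == 0 else math.inf
    return (ss_b / df_b) / (ss_w / df_w)


def levene_size(centroid_sizes: np.ndarray, design: Design | list[SpecimenRecord]):
    """Brown-Forsythe (median-centred Levene) test of size variance across sides."""
    if not isinstance(design, Design):
        design = design_from_records(list(design))
    sizes = np.asarray(centroid_sizes, float)
    groups = [sizes[design.side_idx == s] for s in (0, 1)]
    if any(g.size < 2 for g in groups):
        raise ValueError("each side needs >= 2 observations")
    f, p = stats.levene(*groups, center="median")
    return float(f), float(p)
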