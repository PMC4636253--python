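"""Seeded generator of bilateral landmark datasets with known ground truth.

The generator emulates a two-factor morphometric study design: every
individual contributes a left and a right copy of a paired structure, and
every copy is digitized R times.  Variation enters at four levels, for
shape and size independently:

* individual (inter-individual variation; the inverse of canalization),
* side (directional asymmetry, a fixed offset applied to right copies),
* individual x side (fluctuating asymmetry; the inverse of developmental
  stability),
* replicate (digitization / measurement error).

Shape effects are i.i.d. Gaussian displacement fields added per coordinate
in the tangent space at a fixed template held at unit centroid size; the
small-variation regime of geometric morphometrics is preserved by keeping
the SDs well below the template size.  Raw configurations are then scaled
to their drawn centroid size, given a random rotation and translation (so
downstream superimposition is exercised), and left-side copies are mirrored
to mimic raw digitized bilateral pairs.

Default variance components reproduce the magnitude ladder of a real
monogenean-anchor study (per-coordinate shape SDs of a few parts per
thousand with measurement error exceeding the FA signal; size components
of a few percent of mean centroid size); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import LandmarkConfiguration, LandmarkDataset, SpecimenRecord, SIDES
from .procrustes import centroid_size

#: Fixed template landmarks tracing an anchor-like closed outline:
#: inner root (1), root inflexion (2), outer root (3), outer shaft base (4),
#: outer point base (5), tip of point (6), inner point base (7),
#: inner shaft base (8).  Deliberately chiral.
_ANCHOR_LANDMARKS = np.array(
    [
        [0.00, 1.00],
        [0.35, 0.72],
        [0.80, 0.90],
        [0.75, 0.45],
        [0.52, -0.70],
        [-0.20, -0.75],
        [0.05, -0.45],
        [0.10, 0.30],
    ]
)

DEFAULT_SEMI_COUNTS = (4, 4, 4, 4, 4, 4, 4, 4)


def make_anchor_template(
    n_semis_per_segment: Sequence[int] = DEFAULT_SEMI_COUNTS,
) -> LandmarkConfiguration:
    """Anchor-like template: 8 landmarks plus equidistant semilandmarks.

    Semilandmark group *i* (3 to 6 points) is placed equidistantly on the
    straight segment between consecutive landmarks i and i+1 of the closed
    outline.  The default counts (4 per segment) give 8 + 32 = 40 points.
    Point order: the 8 landmarks first, then the semilandmark groups.
    """
    counts = list(n_semis_per_segment)
    if len(counts) != 8:
        raise ValueError("need exactly 8 semilandmark counts (one per segment)")
    if any(not (3 <= int(c) <= 6) for c in counts):
        raise ValueError(f"semilandmark counts must be in 3..6, got {counts}")
    pts = [row for row in _ANCHOR_LANDMARKS]
    roles = ["landmark"] * 8
    for seg, c in enumerate(counts):
        a = _ANCHOR_LANDMARKS[seg]
        b = _ANCHOR_LANDMARKS[(seg + 1) % 8]
        for k in range(1, int(c) + 1):
            t = k / (int(c) + 1)
            pts.append((1 - t) * a + t * b)
            roles.append("semilandmark")
    return LandmarkConfiguration(np.array(pts), tuple(roles))


@dataclass
class SimulationParams:
    """Parameters of the two-factor bilateral simulation.

    Shape SDs are tangent-space SDs per coordinate at unit centroid size;
    size parameters are in centroid-size units.  ``da_magnitude`` is the
    norm of the fixed directional-asymmetry displacement field added to
    right-side shapes.  ``allometry_vector`` (length 2*LM) shifts shape by
    that field per unit of centroid-size deviation from ``cs_mean``.
    ``buffering_sd`` plants a per-individual lognormal factor that scales
    the individual AND the FA effects together (a shared buffering
    capacity); 0 disables it.
    """

    template: LandmarkConfiguration = field(default_factory=make_anchor_template)
    n_individuals: int = 25
    n_replicates: int = 2
    sd_individual: float = 0.0035
    sd_fa: float = 0.0021
    da_magnitude: float = 0.0
    sd_error: float = 0.0049
    cs_mean: float = 100.0
    cs_sd_individual: float = 2.5
    cs_sd_fa: float = 1.9
    cs_sd_error: float = 1.7
    allometry_vector: np.ndarray | None = None
    buffering_sd: float = 0.0
    anchor_type: str = "dorsal"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("sd_individual", "sd_fa", "da_magnitude", "sd_error",
                     "cs_sd_individual", "cs_sd_fa", "cs_sd_error", "buffering_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.template.n_points < 3:
            raise ValueError("template needs >= 3 points")


#: Variance ladders emulating the reference study's two anchor types.
#: Shape values are per-coordinate tangent SDs back-solved from the
#: Procrustes ANOVA mean squares (sd_error = sqrt(MS_rep),
#: sd_fa = sqrt((MS_int - MS_rep)/R), sd_individual =
#: sqrt((MS_ind - MS_int)/(2R))); size values likewise from the size ANOVA.
STUDY_LADDERS = {
    "dorsal": dict(
        n_individuals=25,
        sd_individual=0.0035,
        sd_fa=0.0021,
        sd_error=0.0049,
        cs_sd_individual=2.5,
        cs_sd_fa=1.9,
        cs_sd_error=1.7,
    ),
    "ventral": dict(
        n_individuals=30,
        sd_individual=0.0030,
        sd_fa=0.0039,
        sd_error=0.0045,
        cs_sd_individual=2.56,
        cs_sd_fa=2.5,
        cs_sd_error=1.34,
    ),
}


def study_params(anchor_type: str = "dorsal", **overrides) -> SimulationParams:
    """Simulation parameters emulating the study design for one anchor type.

    Dorsal: N = 25 individuals; ventral: N = 30; both with R = 2 replicates,
    40 points, no directional asymmetry, and the anchor type's variance
    ladder.  Keyword arguments override individual fields.
    """
    if anchor_type not in STUDY_LADDERS:
        raise ValueError(f"anchor_type must be one of {sorted(STUDY_LADDERS)}")
    kwargs = dict(STUDY_LADDERS[anchor_type], anchor_type=anchor_type)
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


class SimulatedDataset(LandmarkDataset):
    """A landmark dataset carrying its generating ground truth."""

    def __init__(self, records, truth: dict):
        super().__init__(records)
        self.truth = truth


def _unit_displacement_field(rng: np.random.Generator, template_flat: np.ndarray) -> np.ndarray:
    """A random unit field orthogonal to translation and scaling of the template."""
    q = template_flat.size
    v = rng.standard_normal(q)
    # remove translation components (per-axis means) and the template direction
    v = v.reshape(-1, 2)
    v -= v.mean(axis=0)
    v = v.ravel()
    t = template_flat / np.linalg.norm(template_flat)
    v -= (v @ t) * t
    return v / np.linalg.norm(v)


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate a balanced individual x side x replicate landmark dataset.

    Fully reproducible for a fixed seed.  The returned dataset passes
    ``filter_complete_pairs`` unchanged and carries a ``truth`` dict with
    every generating parameter, the DA field and the per-individual
    buffering factors.
    """
    tpl = params.template.points
    tpl = tpl - tpl.mean(axis=0)
    cs0 = np.sqrt((tpl**2).sum())
    if cs0 <= 1e-12 or np.linalg.matrix_rank(tpl) < 2:
        raise ValueError("degenerate template (zero spread or collinear)")
    tpl = tpl / cs0
    tpl_flat = tpl.ravel()
    q = tpl_flat.size
    n, r = params.n_individuals, params.n_replicates
    rng = np.random.default_rng(params.seed)

    da_field = np.zeros(q)
    if params.da_magnitude > 0:
        da_field = params.da_magnitude * _unit_displacement_field(rng, tpl_flat)

    g = np.ones(n)
    if params.buffering_sd > 0:
        g = np.exp(rng.normal(0.0, params.buffering_sd, size=n))

    allo = np.zeros(q)
    if params.allometry_vector is not None:
        allo = np.asarray(params.allometry_vector, float)
        if allo.shape != (q,):
            raise ValueError(f"allometry_vector must have length {q}")

    ind_eff = rng.standard_normal((n, q)) * params.sd_individual * g[:, None]
    fa_eff = rng.standard_normal((n, 2, q)) * params.sd_fa * g[:, None, None]
    err_eff = rng.standard_normal((n, 2, r, q)) * params.sd_error

    cs_ind = rng.normal(0.0, params.cs_sd_individual, size=n) * g
    cs_fa = rng.normal(0.0, params.cs_sd_fa, size=(n, 2)) * g[:, None]
    cs_err = rng.normal(0.0, params.cs_sd_error, size=(n, 2, r))

    width = len(str(n))
    records = []
    for i in range(n):
        ind_id = f"ind{i + 1:0{width}d}"
        for si, side in enumerate(SIDES):
            for rep in range(1, r + 1):
                cs = params.cs_mean + cs_ind[i] + cs_fa[i, si] + cs_err[i, si, rep - 1]
                if cs <= 0:
                    raise ValueError(
                        "drawn centroid size <= 0; reduce size SDs or raise cs_mean"
                    )
                shape = (
                    tpl_flat
                    + ind_eff[i]
                    + (da_field if side == "right" else 0.0)
                    + fa_eff[i, si]
                    + err_eff[i, si, rep - 1]
                    + allo * (cs - params.cs_mean)
                )
                pts = shape.reshape(-1, 2)
                pts = pts - pts.mean(axis=0)
                pts = pts * (cs / np.sqrt((pts**2).sum()))
                # random digitization pose
                theta = rng.uniform(0, 2 * np.pi)
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                pts = pts @ rot.T + rng.uniform(-5, 5, size=2) * params.cs_mean / 100.0
                if side == "left":
                    pts = pts.copy()
                    pts[:, 0] = -pts[:, 0]
                records.append(
                    SpecimenRecord(
                        individual_id=ind_id,
                        anchor_type=params.anchor_type,
                        side=side,
                        replicate=rep,
                        config=LandmarkConfiguration(pts, params.template.point_roles),
                    )
                )

    truth = {
        "n_individuals": n,
        "n_replicates": r,
        "n_points": params.template.n_points,
        "sd_individual": params.sd_individual,
        "sd_fa": params.sd_fa,
        "da_magnitude": params.da_magnitude,
        "sd_error": params.sd_error,
        "cs_mean": params.cs_mean,
        "cs_sd_individual": params.cs_sd_individual,
        "cs_sd_fa": params.cs_sd_fa,
        "cs_sd_error": params.cs_sd_error,
        "da_field": da_field.tolist(),
        "allometry_vector": allo.tolist(),
        "buffering_sd": params.buffering_sd,
        "buffering_factors": g.tolist(),
        "anchor_type": params.anchor_type,
        "seed": params.seed,
    }
    return SimulatedDataset(records, truth)
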