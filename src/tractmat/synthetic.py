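"""Synthetic cohorts, growth fields, and embedded tensor volumes.

The study design being emulated is a single-site cross-sectional cohort of
178 healthy participants (83 male / 95 female) aged 6-30 years, measured
at every vertex of medial tract surfaces.  Ground truth at each vertex is
one of three age models:

* exponential maturation  y = C + A exp(-age/t)  (A < 0 for rising FA,
  A > 0 for falling MD; t in years, regionally varying),
* linear drift            y = b + a age,
* no age effect           y = b.

Measurements add Gaussian noise (defaults: FA 0.03, MD 0.05e-3 mm²/s —
chosen so fit correlations land in the 0.4-0.7 band typical of vertexwise
maturation fits at ~90 subjects per sex).  Every generator is a pure
function of its parameters and seed, and each ground-truth field is kept
so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import LN10
from .projection import VertexMeasureSet
from .surface import MedialSurface, heat_smooth
from .tensors import DiffusionTensorVolume, tensor_from_fa_md

__all__ = [
    "GrowthField",
    "Region",
    "gen_surface",
    "gen_cohort",
    "gen_growth_field",
    "gen_vertex_measures",
    "gen_tensor_volume",
]

#: default measurement noise SD (FA dimensionless, MD mm²/s)
NOISE_SD_FA = 0.03
NOISE_SD_MD = 0.05e-3

#: study-cohort constants
STUDY_N = 178
STUDY_FEMALE_FRACTION = 95 / 178
STUDY_AGE_RANGE = (6.0, 30.0)
#: empirical age moments (mean, sd) per sex for the truncated-normal preset
STUDY_AGE_MOMENTS = {"M": (15.6, 6.1), "F": (16.0, 6.4)}


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def _grid_mesh(nu: int, nv: int) -> np.ndarray:
    """Triangulate an nu x nv vertex grid with alternating diagonals."""
    tris = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = a + 1
            c = a + nv
            d = c + 1
            if (i + j) % 2 == 0:
                tris += [[a, b, d], [a, d, c]]
            else:
                tris += [[a, b, c], [b, d, c]]
    return np.array(tris, dtype=np.int64)


def gen_surface(
    kind: str = "flat_sheet",
    nu: int = 20,
    nv: int = 10,
    extent: tuple[float, float] = (40.0, 20.0),
    radius_spec: dict | None = None,
    tract_name: str = "synthetic",
    hemisphere: str = "midline",
) -> MedialSurface:
    """Deterministic fixture surface standing in for a template tract.

    ``kind`` is one of ``flat_sheet`` (plane z=0), ``curved_sheet`` (gentle
    sinusoidal bulge) or ``arch`` (half-cylinder segment with arc length
    ``extent[0]``, so its analytic area is ``extent[0] * extent[1]``).
    ``radius_spec`` selects the medial
    radius field: ``{"kind": "constant", "r0": 2.0}``,
    ``{"kind": "linear", "r0": ..., "slope": ...}`` (gradient along u, per
    mm), or ``{"kind": "bump", "r0": ..., "amp": ..., "width_mm": ...}``.
    """
    if nu < 2 or nv < 2:
        raise ValueError("nu and nv must be at least 2")
    lu, lv = extent
    if lu <= 0 or lv <= 0:
        raise ValueError("extent must be positive")
    u = np.linspace(0.0, lu, nu)
    v = np.linspace(0.0, lv, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uu = uu.ravel()
    vv = vv.ravel()
    if kind == "flat_sheet":
        pts = np.column_stack([uu, vv, np.zeros_like(uu)])
    elif kind == "curved_sheet":
        pts = np.column_stack([uu, vv, 2.0 * np.sin(np.pi * uu / lu)])
    elif kind == "arch":
        # half cylinder: u parameter sweeps the arc (angle 0..pi), v the axis
        r_arch = lu / np.pi  # so the arc length equals lu
        theta = np.pi * uu / lu
        pts = np.column_stack([r_arch * np.cos(theta), vv, r_arch * np.sin(theta)])
    else:
        raise ValueError(f"unknown surface kind {kind!r}")
    spec = radius_spec or {"kind": "constant", "r0": 2.0}
    r0 = spec.get("r0", 2.0)
    if spec["kind"] == "constant":
        radius = np.full(uu.size, float(r0))
    elif spec["kind"] == "linear":
        radius = r0 + spec.get("slope", 0.0) * uu
    elif spec["kind"] == "bump":
        w = spec.get("width_mm", lu / 4.0)
        radius = r0 + spec.get("amp", 0.5) * np.exp(-((uu - lu / 2.0) ** 2) / (2.0 * w**2))
    else:
        raise ValueError(f"unknown radius_spec kind {spec['kind']!r}")
    if np.any(radius <= 0):
        raise ValueError("radius_spec yields non-positive radius")
    return MedialSurface(pts, _grid_mesh(nu, nv), radius, tract_name, hemisphere)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _truncnorm_parent_params(
    target_mu: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sd) so that truncation to [lo, hi] matches the targets."""
    from scipy import optimize, stats

    def gap(p):
        mu, sd = p
        a, b = (lo - mu) / sd, (hi - mu) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sd, moments="mv")
        return [m - target_mu, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(gap, [target_mu, target_sd], full_output=False)
    return float(sol[0]), float(sol[1])


def gen_cohort(
    n: int = STUDY_N,
    age_min: float = STUDY_AGE_RANGE[0],
    age_max: float = STUDY_AGE_RANGE[1],
    female_fraction: float = STUDY_FEMALE_FRACTION,
    seed: int = 0,
    age_distribution: str = "uniform",
) -> pd.DataFrame:
    """Subject table (id, age, sex), reproducible under ``seed``.

    Sexes are assigned by rounding ``n * female_fraction`` (the study split
    178 → 83 M / 95 F).  Ages are uniform on [age_min, age_max] by default;
    ``age_distribution="empirical"`` draws truncated normals matching the
    study's per-sex age moments instead.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= female_fraction <= 1.0:
        raise ValueError("female_fraction must be in [0, 1]")
    if age_min > age_max:
        raise ValueError("age bounds are inverted")
    rng = np.random.default_rng(seed)
    n_f = int(round(n * female_fraction))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    if age_distribution == "uniform":
        ages = rng.uniform(age_min, age_max, size=n)
    elif age_distribution == "empirical":
        from scipy import stats

        ages = np.empty(n)
        for s in ("F", "M"):
            mask = sex == s
            mu, sd = _truncnorm_parent_params(*STUDY_AGE_MOMENTS[s], age_min, age_max)
            a, b = (age_min - mu) / sd, (age_max - mu) / sd
            ages[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                             size=mask.sum(), random_state=rng)
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")
    return pd.DataFrame(
        {"id": [f"s{i:04d}" for i in range(n)], "age": ages, "sex": sex}
    )


# ---------------------------------------------------------------------------
# growth fields
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """A labeled vertex patch with its ground-truth parameter ranges.

    ``model`` ∈ {"exponential", "linear", "none"}.  Ranges are (lo, hi)
    tuples sampled uniformly per vertex before spatial smoothing.
    """

    name: str
    vertices: np.ndarray
    model: str = "exponential"
    C: tuple[float, float] = (0.45, 0.60)
    A: tuple[float, float] = (-0.45, -0.25)
    t: tuple[float, float] = (3.0, 6.0)
    slope: tuple[float, float] = (0.002, 0.004)
    intercept: tuple[float, float] = (0.35, 0.50)

    @classmethod
    def md(cls, name: str, vertices: np.ndarray, model: str = "exponential", **ranges) -> "Region":
        """Region with mean-diffusivity-scaled defaults (mm²/s).

        Asymptotes ~0.7-0.8e-3, falling amplitudes 0.25-0.5e-3, and
        negative linear slopes, mirroring adult white-matter MD levels and
        the amplitude range implied by published tract-level rates.
        """
        defaults: dict = dict(
            C=(0.70e-3, 0.80e-3),
            A=(0.25e-3, 0.50e-3),
            t=(3.0, 6.0),
            slope=(-0.004e-3, -0.002e-3),
            intercept=(0.85e-3, 0.95e-3),
        )
        defaults.update(ranges)
        return cls(name, vertices, model, **defaults)


@dataclass
class GrowthField:
    """Per-vertex ground-truth age model for one measure.

    ``model`` holds "exponential"/"linear"/"none" per vertex; exponential
    vertices use (C, A, t), linear ones (intercept, slope).  ``sex_effect``
    scales the male time constant (``t_scale``) and offsets the male
    asymptote (``C_offset``), emulating later male maturation.
    """

    model: np.ndarray
    C: np.ndarray
    A: np.ndarray
    t: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    noise_sd: float
    sex_effect: dict = field(default_factory=lambda: {"t_scale": 1.0, "C_offset": 0.0})

    def __post_init__(self) -> None:
        exp = self.model == "exponential"
        if np.any(self.t[exp] <= 0):
            raise ValueError("time constants must be positive on exponential vertices")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def params_for_sex(self, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(C, A, t) maps for one sex with the sex effect applied (males)."""
        if sex == "M":
            return (
                self.C + self.sex_effect.get("C_offset", 0.0),
                self.A,
                self.t * self.sex_effect.get("t_scale", 1.0),
            )
        return self.C, self.A, self.t

    def curve(self, ages: np.ndarray, sex: str) -> np.ndarray:
        """Noiseless measure values, shape (n_subjects, n_vertices)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))[:, None]
        C, A, t = self.params_for_sex(sex)
        exp_curve = C + A * np.exp(-ages / np.where(self.t > 0, t, 1.0))
        lin_curve = self.intercept + self.slope * ages
        flat = np.broadcast_to(self.intercept, exp_curve.shape)
        out = np.where(self.model == "exponential", exp_curve,
                       np.where(self.model == "linear", lin_curve, flat))
        return out

    def plateau_ages(self, sex: str = "F", age_min: float = 6.0) -> np.ndarray:
        """Ground-truth plateau ages ``age_min + t ln 10`` (NaN off-model)."""
        _, _, t = self.params_for_sex(sex)
        return np.where(self.model == "exponential", age_min + t * LN10, np.nan)


def gen_growth_field(
    surface: MedialSurface,
    regions: list[Region],
    seed: int = 0,
    noise_sd: float = NOISE_SD_FA,
    smooth_fwhm: float = 8.0,
    sex_effect: dict | None = None,
) -> GrowthField:
    """Draw a regionally varying ground-truth field on the surface.

    ``regions`` must partition the vertices.  Parameters are drawn
    uniformly within each region's ranges, then spatially smoothed at
    ``smooth_fwhm`` within the whole surface so parameter maps are smooth
    at the analysis smoothing scale.
    """
    n = surface.n_vertices
    covered = np.zeros(n, dtype=int)
    for reg in regions:
        if len(reg.vertices) == 0:
            raise ValueError(f"region {reg.name!r} is empty")
        covered[np.asarray(reg.vertices, dtype=int)] += 1
    if not np.all(covered == 1):
        raise ValueError("regions must partition the vertices exactly")
    rng = np.random.default_rng(seed)
    model = np.empty(n, dtype=object)
    C = np.zeros(n)
    A = np.zeros(n)
    t = np.ones(n)
    slope = np.zeros(n)
    intercept = np.zeros(n)
    for reg in regions:
        idx = np.asarray(reg.vertices, dtype=int)
        model[idx] = reg.model
        C[idx] = rng.uniform(*reg.C, size=idx.size)
        A[idx] = rng.uniform(*reg.A, size=idx.size)
        t[idx] = rng.uniform(*reg.t, size=idx.size)
        slope[idx] = rng.uniform(*reg.slope, size=idx.size)
        intercept[idx] = rng.uniform(*reg.intercept, size=idx.size)
    if smooth_fwhm > 0:
        C = heat_smooth(surface, C, smooth_fwhm)
        A = heat_smooth(surface, A, smooth_fwhm)
        t = np.clip(heat_smooth(surface, t, smooth_fwhm), 1e-3, None)
        slope = heat_smooth(surface, slope, smooth_fwhm)
        intercept = heat_smooth(surface, intercept, smooth_fwhm)
    return GrowthField(
        model=model.astype(str), C=C, A=A, t=t, slope=slope, intercept=intercept,
        noise_sd=noise_sd,
        sex_effect=sex_effect or {"t_scale": 1.0, "C_offset": 0.0},
    )


def gen_vertex_measures(
    surface: MedialSurface,
    growth: GrowthField,
    subjects: pd.DataFrame,
    seed: int = 0,
    missing_rate: float = 0.0,
    clip_fa: bool = True,
) -> VertexMeasureSet:
    """Simulate the projected per-vertex measures for a cohort.

    Each value is the ground-truth curve at the subject's age plus
    ``Normal(0, noise_sd)``; FA-scaled fields are clipped to [0, 1].
    ``missing_rate`` knocks out (subject, vertex) pairs at random the way
    sub-threshold projections would.  The same array is stored in both the
    ``fa`` and ``md`` slots scaled appropriately only when used as such by
    the caller; here a single measure is produced and duplicated, with MD
    mirroring FA so the invariant "missing together" holds.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ages = subjects["age"].to_numpy(dtype=float)
    values = np.empty((len(subjects), surface.n_vertices))
    for sex in ("F", "M"):
        mask = (subjects["sex"] == sex).to_numpy()
        if mask.any():
            values[mask] = growth.curve(ages[mask], sex)
    values = values + rng.normal(0.0, growth.noise_sd, size=values.shape)
    if clip_fa:
        values = np.clip(values, 0.0, 1.0)
    if missing_rate > 0:
        miss = rng.random(values.shape) < missing_rate
        values = np.where(miss, np.nan, values)
    return VertexMeasureSet(
        subject_ids=[str(s) for s in subjects["id"]], fa=values, md=values.copy(),
        fa_min=0.0,
    )


# ---------------------------------------------------------------------------
# embedded tensor volumes
# ---------------------------------------------------------------------------


def gen_tensor_volume(
    surface: MedialSurface,
    growth: GrowthField,
    subject: pd.Series,
    voxel_size: float = 1.0,
    background_md: float = 0.9e-3,
    md_field: GrowthField | None = None,
    margin: float | None = None,
) -> DiffusionTensorVolume:
    """Embed the tract in an isotropic background volume for one subject.

    Voxels within the spoke envelope (distance to the nearest skeleton
    vertex at most its radius) get a prolate tensor whose principal axis
    follows the local surface tangent and whose FA/MD equal the growth
    curves at the subject's age; everything else is isotropic with
    ``MD = background_md`` (FA = 0, far below the 0.2 projection
    threshold).  ``md_field`` supplies the MD ground truth; when omitted,
    MD is held at ``background_md`` inside the tract too.
    """
    from scipy.spatial import cKDTree

    r_max = float(surface.radius.max())
    margin = 2.0 * r_max if margin is None else margin
    if margin < r_max:
        raise ValueError("margin must cover the maximum radius")
    lo = surface.vertices.min(axis=0) - margin
    hi = surface.vertices.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * voxel_size + lo

    age = float(subject["age"])
    sex = str(subject["sex"])
    fa_vals = growth.curve(np.array([age]), sex)[0]
    md_vals = (
        md_field.curve(np.array([age]), sex)[0]
        if md_field is not None
        else np.full(surface.n_vertices, background_md)
    )

    tree = cKDTree(surface.vertices)
    dist, nearest = tree.query(centers)
    inside = dist <= surface.radius[nearest]

    # local tangent direction: dominant mesh direction around each vertex
    normals = surface.vertex_normals
    ref = np.where(np.abs(normals[:, :1]) < 0.9, np.eye(3)[0], np.eye(3)[1])
    tangents = np.cross(normals, np.cross(ref, normals))
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    tensors = np.zeros(centers.shape[0:1] + (3, 3))
    iso = background_md * np.eye(3)
    tensors[:] = iso
    for vox in np.flatnonzero(inside):
        v = nearest[vox]
        tensors[vox] = tensor_from_fa_md(
            float(np.clip(fa_vals[v], 0.0, 1.0)), float(md_vals[v]), tangents[v]
        )
    return DiffusionTensorVolume(tensors.reshape(*shape, 3, 3), affine)
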