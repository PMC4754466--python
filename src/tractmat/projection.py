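"""Project subject tensor volumes onto the medial surface.

For every skeleton vertex, tensors are sampled along the chord
``b_minus -> m -> b_plus`` (both spokes pooled, skeleton point included)
and the sample with the largest FA is selected, mirroring the TBSS-style
max-FA projection; its FA and MD are recorded for that subject and vertex.
Vertices whose best FA falls below ``fa_min`` (default 0.2) are treated as
missing — the tract is assumed not to pass reliably through them for that
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface import MedialSurface, SpokeSet, heat_smooth
from .tensors import DiffusionTensorVolume, compute_fa, compute_md

__all__ = ["VertexMeasureSet", "sample_max_fa", "project_cohort", "smooth_measures"]

DEFAULT_FA_MIN = 0.2
DEFAULT_SAMPLES_PER_SPOKE = 11


@dataclass
class VertexMeasureSet:
    """Per-subject, per-vertex FA and MD after projection.

    ``fa`` and ``md`` are (n_subjects, n_vertices) float arrays; NaN marks a
    missing (subject, vertex) pair and always occurs in both arrays at once.
    """

    subject_ids: list[str]
    fa: np.ndarray
    md: np.ndarray
    fa_min: float = DEFAULT_FA_MIN
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.md = np.asarray(self.md, dtype=float)
        if self.fa.shape != self.md.shape:
            raise ValueError("fa and md must have the same shape")
        if self.fa.shape[0] != len(self.subject_ids):
            raise ValueError("one row per subject required")
        if not np.array_equal(np.isnan(self.fa), np.isnan(self.md)):
            raise ValueError("fa and md must be missing together")

    @property
    def n_subjects(self) -> int:
        return self.fa.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.fa.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-subject fraction of missing vertices."""
        return np.isnan(self.fa).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject_id, vertex_id, fa, md); missing dropped."""
        subj = np.repeat(self.subject_ids, self.n_vertices)
        vert = np.tile(np.arange(self.n_vertices), self.n_subjects)
        df = pd.DataFrame(
            {"subject_id": subj, "vertex_id": vert, "fa": self.fa.ravel(), "md": self.md.ravel()}
        )
        return df.dropna(subset=["fa"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_vertices: int | None = None) -> "VertexMeasureSet":
        subjects = list(pd.unique(df["subject_id"]))
        if n_vertices is None:
            n_vertices = int(df["vertex_id"].max()) + 1
        fa = np.full((len(subjects), n_vertices), np.nan)
        md = np.full((len(subjects), n_vertices), np.nan)
        idx = {s: k for k, s in enumerate(subjects)}
        rows = df["subject_id"].map(idx).to_numpy()
        cols = df["vertex_id"].to_numpy()
        fa[rows, cols] = df["fa"].to_numpy()
        md[rows, cols] = df["md"].to_numpy()
        return cls([str(s) for s in subjects], fa, md)


def _spoke_samples(
    m: np.ndarray, u: np.ndarray, r: float, k: int, min_voxel: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points along one half-spoke m -> m + r*u, densified so the
    step never exceeds half the smallest voxel edge.  Returns (points,
    distance-from-skeleton)."""
    k = max(k, int(np.ceil(2.0 * r / min_voxel)) + 1)
    s = np.linspace(0.0, r, k + 1)
    return m + s[:, None] * u, s


def sample_max_fa(
    surface: MedialSurface,
    spokes: SpokeSet,
    volume: DiffusionTensorVolume,
    samples_per_spoke: int = DEFAULT_SAMPLES_PER_SPOKE,
    fa_min: float = DEFAULT_FA_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-FA projection of one subject's tensor volume onto the surface.

    Returns per-vertex ``(fa, md)`` arrays with NaN where the vertex is
    missing: invalid spoke, all samples out of volume bounds, or maximum
    FA below ``fa_min``.  The MD returned is the MD of the max-FA sample,
    not the maximal MD.  Ties in FA are broken toward the sample nearest
    the skeleton.
    """
    if samples_per_spoke < 3:
        raise ValueError("samples_per_spoke must be at least 3")
    n = surface.n_vertices
    fa_out = np.full(n, np.nan)
    md_out = np.full(n, np.nan)
    min_voxel = float(volume.voxel_size.min())
    for v in range(n):
        if not spokes.valid[v]:
            continue
        m = surface.vertices[v]
        r = surface.radius[v]
        pts_p, s_p = _spoke_samples(m, spokes.u_plus[v], r, samples_per_spoke, min_voxel)
        pts_m, s_m = _spoke_samples(m, spokes.u_minus[v], r, samples_per_spoke, min_voxel)
        pts = np.vstack([pts_p, pts_m[1:]])  # skeleton point included once
        dist = np.concatenate([s_p, s_m[1:]])
        tensors, inside = volume.interpolate(pts)
        if not inside.any():
            continue
        fa = compute_fa(tensors[inside])
        d = dist[inside]
        best_fa = fa.max()
        if best_fa < fa_min:
            continue
        # tie-break: among samples within float tolerance of the max FA,
        # prefer the one closest to the skeleton
        near = np.flatnonzero(fa >= best_fa - 1e-12)
        pick = near[np.argmin(d[near])]
        fa_out[v] = fa[pick]
        md_out[v] = compute_md(tensors[inside][pick])
    return fa_out, md_out


def project_cohort(
    surface: MedialSurface,
    spokes: SpokeSet,
    volumes: dict[str, DiffusionTensorVolume],
    subjects: pd.DataFrame,
    samples_per_spoke: int = DEFAULT_SAMPLES_PER_SPOKE,
    fa_min: float = DEFAULT_FA_MIN,
) -> VertexMeasureSet:
    """Apply :func:`sample_max_fa` to every subject in template space.

    ``subjects`` must carry an ``id`` column; every id needs a tensor volume
    in ``volumes``.  The per-subject missing-vertex fraction is recorded in
    the result's ``log``.
    """
    ids = [str(s) for s in subjects["id"]]
    missing = set(ids) - set(volumes)
    if missing:
        raise ValueError(f"no tensor volume for subject(s): {sorted(missing)}")
    fa = np.full((len(ids), surface.n_vertices), np.nan)
    md = np.full((len(ids), surface.n_vertices), np.nan)
    for k, sid in enumerate(ids):
        fa[k], md[k] = sample_max_fa(
            surface, spokes, volumes[sid], samples_per_spoke, fa_min
        )
    out = VertexMeasureSet(ids, fa, md, fa_min=fa_min)
    out.log["missing_fraction"] = dict(zip(ids, out.missing_fraction()))
    out.log["invalid_spokes"] = spokes.n_invalid
    return out


def smooth_measures(
    surface: MedialSurface, measures: VertexMeasureSet, fwhm: float = 8.0
) -> VertexMeasureSet:
    """Surface-smooth each subject's FA and MD maps (default 8 mm FWHM).

    Applied after projection and before curve fitting, matching the
    pipeline order; missing vertices stay missing.
    """
    fa = np.vstack([heat_smooth(surface, row, fwhm) for row in measures.fa])
    md = np.vstack([heat_smooth(surface, row, fwhm) for row in measures.md])
    out = VertexMeasureSet(measures.subject_ids, fa, md, fa_min=measures.fa_min)
    out.log = dict(measures.log, smoothing_fwhm=fwhm)
    return out
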