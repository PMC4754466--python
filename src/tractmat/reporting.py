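"""Tract-level summaries, hemisphere pooling, and mean trajectories.

Vertexwise results are condensed per (tract, sex, measure) into the
summary statistics used for between-tract and between-sex comparison:
the percentage of vertices with each significant model, mean fit
correlations, mean time constant and plateau age with their standard
errors, and mean annual rates.  Bilateral tracts are pooled across
hemispheres (the significant-vertex sets of the two sides are unioned
before averaging; fitting itself stays per side).

The module also ships the published tract-level reference fits (14 rows
per measure: 7 tracts x 2 sexes, left+right combined) as package data,
used for worked examples and cross-checks of the summary arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .inference import LN10, sex_overlap_test

__all__ = [
    "TractSummary",
    "tract_summary",
    "combine_hemispheres",
    "mean_trajectory",
    "load_reference_fits",
    "round_half_away",
    "sex_significant_tracts",
]


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (0.5 -> 1, -0.5 -> -1), element-wise.

    Used for table output so that reported integers/decimals are
    deterministic across platforms (numpy's default rounds half to even).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def load_reference_fits() -> pd.DataFrame:
    """Published tract-level fit summaries (FA and MD, both sexes).

    Columns: measure, tract, sex, p_exp/p_lin (%), r_exp/r_lin, t/se_t
    (years), rate_exp/rate_lin (units per year), T/se_T (years), sex_sig
    (1 where the printed tables mark the sex difference significant).
    """
    with resources.files("tractmat.data").joinpath("reference_tract_fits.csv").open() as f:
        return pd.read_csv(f)


@dataclass
class TractSummary:
    """Aggregate fit statistics for one (tract, sex, measure)."""

    tract: str
    sex: str
    measure: str
    n_vertices: int
    p_exp: float
    p_lin: float
    mean_r_exp: float
    mean_r_lin: float
    mean_t: float
    mean_se_t: float
    mean_rate_exp: float
    mean_rate_lin: float
    mean_T: float
    mean_se_T: float
    empty: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def tract_summary(
    results: pd.DataFrame, tract: str = "tract", age_min: float = 6.0
) -> list[TractSummary]:
    """Summarize an ``analyze_vertices`` table per (sex, measure).

    Percentages are relative to all valid vertices (those with at least one
    fit attempted); exponential means (t, T, SEs, rate) are taken over the
    significant-exponential mask and the linear rate over the significant-
    linear mask.  Zero valid vertices yields an explicitly flagged empty
    summary.  ``mean_T`` always equals ``age_min + ln10 * mean_t`` since
    the plateau age is linear in t.
    """
    out = []
    for (sex, measure), grp in results.groupby(["sex", "measure"], sort=True):
        valid = grp[~(grp["lin_p"].isna() & grp["exp_p"].isna())]
        n_valid = len(valid)
        if n_valid == 0:
            out.append(
                TractSummary(tract, sex, measure, 0, *([np.nan] * 10), empty=True)
            )
            continue
        exp_mask = valid["model"] == "exponential"
        lin_mask = valid["model"] == "linear"
        e = valid[exp_mask]
        l = valid[lin_mask]
        out.append(
            TractSummary(
                tract=tract,
                sex=sex,
                measure=measure,
                n_vertices=n_valid,
                p_exp=100.0 * exp_mask.mean(),
                p_lin=100.0 * lin_mask.mean(),
                mean_r_exp=e["exp_r"].mean() if len(e) else np.nan,
                mean_r_lin=l["lin_r"].mean() if len(l) else np.nan,
                mean_t=e["exp_t"].mean() if len(e) else np.nan,
                mean_se_t=e["exp_se_t"].mean() if len(e) else np.nan,
                mean_rate_exp=e["rate"].mean() if len(e) else np.nan,
                mean_rate_lin=l["rate"].mean() if len(l) else np.nan,
                mean_T=age_min + LN10 * e["exp_t"].mean() if len(e) else np.nan,
                mean_se_T=LN10 * e["exp_se_t"].mean() if len(e) else np.nan,
            )
        )
    return out


def combine_hemispheres(results_left: pd.DataFrame, results_right: pd.DataFrame) -> pd.DataFrame:
    """Pool vertex results of the two hemispheres of a bilateral tract.

    Fitting stays per side; this simply concatenates the per-vertex rows
    (re-indexing the right side's vertices) so that the summary statistics
    run over the union of the two significant-vertex sets.  Both sides must
    carry the same (sex, measure) combinations.
    """
    keys_l = set(map(tuple, results_left[["sex", "measure"]].drop_duplicates().values))
    keys_r = set(map(tuple, results_right[["sex", "measure"]].drop_duplicates().values))
    if results_left.empty:
        return results_right.copy()
    if results_right.empty:
        return results_left.copy()
    if keys_l != keys_r:
        raise ValueError("hemisphere results have mismatched sex/measure groups")
    right = results_right.copy()
    offset = results_left["vertex_id"].max() + 1
    right["vertex_id"] = right["vertex_id"] + offset
    return pd.concat([results_left, right], ignore_index=True)


def mean_trajectory(
    measures,
    mask: np.ndarray,
    subjects: pd.DataFrame,
    model: str = "exponential",
) -> pd.DataFrame:
    """Per-subject mean over masked vertices, with a per-sex group fit.

    Emulates whole-tract trajectory plots: each subject contributes the
    mean of the measure over the masked (significant) vertices, and an
    exponential (or linear) curve is fitted to those subject means per sex.
    Returns the per-subject series with columns ``id, age, sex, mean_value,
    fitted``; the per-sex fit parameters live in ``DataFrame.attrs["fits"]``.

    Raises ``ValueError`` on an empty mask.
    """
    from .fitting import fit_exponential, fit_linear

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty vertex mask")
    vals = measures.fa[:, mask]
    series = pd.DataFrame(
        {
            "id": measures.subject_ids,
            "mean_value": np.nanmean(vals, axis=1),
        }
    )
    subj = subjects.copy()
    subj["id"] = subj["id"].astype(str)
    series = series.merge(subj[["id", "age", "sex"]], on="id")
    fits = {}
    series["fitted"] = np.nan
    for sex, grp in series.groupby("sex"):
        if model == "exponential":
            fit = fit_exponential(grp["age"].to_numpy(), grp["mean_value"].to_numpy())
        else:
            fit = fit_linear(grp["age"].to_numpy(), grp["mean_value"].to_numpy())
        fits[sex] = fit
        if fit is not None:
            series.loc[grp.index, "fitted"] = fit.predict(grp["age"].to_numpy())
    series.attrs["fits"] = fits
    series.attrs["model"] = model
    return series


def sex_significant_tracts(reference: pd.DataFrame, measure: str) -> set[str]:
    """Tracts whose female/male plateau-age intervals do not overlap.

    Applies the interval-overlap rule to tract-level (T, se_T) pairs in a
    reference table (as produced by :func:`load_reference_fits`).
    """
    sig = set()
    sub = reference[reference["measure"] == measure]
    for tract, grp in sub.groupby("tract"):
        f = grp[grp["sex"] == "F"].iloc[0]
        m = grp[grp["sex"] == "M"].iloc[0]
        significant, _ = sex_overlap_test(f["T"], f["se_T"], m["T"], m["se_T"])
        if significant:
            sig.add(tract)
    return sig
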