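"""Growth-rate parcellation and atlas-based region statistics.

Fast-maturing (transient) compartments are delineated from the mean
absolute Gompertz rate over selected channels: the resulting map is
thresholded and decomposed into connected components.  Region statistics
use the same 1.5-SD robust averaging rule as template construction, and
associations between regional metrics and gestational age at birth are
assessed with an ordinary linear model (age at scan as covariate) with
Bonferroni correction across all (region, channel) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
import statsmodels.api as sm

from .errors import GridMismatchError, InsufficientDataError
from .images import ScalarImage, require_same_grid

logger = logging.getLogger(__name__)


@dataclass
class ParcellationMap:
    """Integer label volume (0 = background) with a label table."""

    labels: np.ndarray
    label_table: dict[int, str]
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> list[int]:
        return sorted(self.label_table)


ROI_STATS_COLUMNS = [
    "subject_id", "age_at_scan", "ga_at_birth", "group", "roi",
    "channel", "robust_mean", "n_retained",
]


def average_growth_rate_map(gamma_maps: dict[str, ScalarImage]) -> ScalarImage:
    """Voxelwise mean of the absolute growth rates of selected channels.

    Standard inputs are the T1w-like, T2w-like, RD and FISO rate maps;
    any non-empty set of grid-shared maps is accepted.
    """
    if not gamma_maps:
        raise InsufficientDataError("no gamma maps given")
    maps = list(gamma_maps.values())
    require_same_grid(*maps)
    acc = np.mean([np.abs(m.values) for m in maps], axis=0)
    return ScalarImage(acc, maps[0].voxel_to_world.copy())


def threshold_parcellation(
    gamma_av: ScalarImage, threshold: float = 0.25, min_region_voxels: int = 27
) -> ParcellationMap:
    """Supra-threshold connected components of the mean-rate map.

    Components are 26-connected; those smaller than ``min_region_voxels``
    are dropped; surviving labels are renumbered by descending size.
    """
    binary = gamma_av.values >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labelled, n = ndimage.label(binary, structure=structure)
    out = np.zeros_like(labelled)
    table: dict[int, str] = {}
    if n == 0:
        logger.warning("no voxels at or above threshold %.3g; empty parcellation", threshold)
        return ParcellationMap(out, table, gamma_av.voxel_to_world.copy())
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    new_id = 0
    for idx in order:
        if sizes[idx] < min_region_voxels:
            continue
        new_id += 1
        out[labelled == idx + 1] = new_id
        table[new_id] = f"region_{new_id:02d}"
    if not table:
        logger.warning("all components below %d voxels; empty parcellation", min_region_voxels)
    return ParcellationMap(out, table, gamma_av.voxel_to_world.copy())


def robust_mean(values: np.ndarray, sd_threshold: float = 1.5) -> tuple[float, int]:
    """Mean after excluding values deviating more than ``sd_threshold``
    population SDs from the plain mean; returns (mean, n retained)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sd = values.std()
    keep = np.abs(values - mean) <= sd_threshold * sd
    if sd == 0 or not keep.any():
        keep = np.ones_like(values, dtype=bool)
    return float(values[keep].mean()), int(keep.sum())


def roi_robust_stats(
    subject_map: ScalarImage,
    parcellation: ParcellationMap,
    sd_threshold: float = 1.5,
    subject_id: str = "",
    channel: str = "",
    age_at_scan: float = np.nan,
    ga_at_birth: float = np.nan,
    group: str = "",
) -> pd.DataFrame:
    """Robust per-region means of one subject map in atlas space."""
    if subject_map.grid_shape != parcellation.grid_shape:
        raise GridMismatchError("subject map and parcellation grids differ")
    rows = []
    for roi in parcellation.ids:
        inside = parcellation.labels == roi
        if not inside.any():
            logger.info("ROI %d absent from the label volume; skipped", roi)
            continue
        mean, n_kept = robust_mean(subject_map.values[inside], sd_threshold)
        rows.append(
            {
                "subject_id": subject_id,
                "age_at_scan": age_at_scan,
                "ga_at_birth": ga_at_birth,
                "group": group,
                "roi": roi,
                "channel": channel,
                "robust_mean": mean,
                "n_retained": n_kept,
            }
        )
    return pd.DataFrame(rows, columns=ROI_STATS_COLUMNS)


@dataclass
class AssociationResult:
    roi: int
    channel: str
    coefficient: float
    p_raw: float
    p_corrected: float
    n: int
    estimable: bool = True


def association_analysis(
    table: pd.DataFrame,
    outcome: str = "robust_mean",
    predictor: str = "ga_at_birth",
    covariates: tuple[str, ...] = ("age_at_scan",),
    min_subjects: int = 10,
) -> list[AssociationResult]:
    """Per-(ROI, channel) linear-model association with Bonferroni
    correction.

    Fits ``outcome ~ predictor + covariates`` by OLS within each (roi,
    channel) group, reports the predictor's coefficient and p-value, and
    multiplies p by the number of tests (capped at 1).  Rank-deficient
    designs are flagged not estimable.
    """
    groups = list(table.groupby(["roi", "channel"], sort=True))
    n_tests = len(groups)
    results: list[AssociationResult] = []
    for (roi, channel), df in groups:
        n = len(df)
        if n < min_subjects:
            raise InsufficientDataError(
                f"ROI {roi}/{channel}: {n} subjects < required {min_subjects}"
            )
        design = sm.add_constant(df[[predictor, *covariates]].to_numpy())
        if np.linalg.matrix_rank(design) < design.shape[1]:
            results.append(
                AssociationResult(int(roi), str(channel), np.nan, np.nan, np.nan, n, False)
            )
            continue
        fit = sm.OLS(df[outcome].to_numpy(), design).fit()
        coef = float(fit.params[1])
        p = float(fit.pvalues[1])
        results.append(AssociationResult(int(roi), str(channel), coef, p, min(1.0, p * n_tests), n))
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": r.roi, "channel": r.channel, "coefficient": r.coefficient,
                "p_raw": r.p_raw, "p_corrected": r.p_corrected, "n": r.n,
                "estimable": r.estimable,
            }
            for r in results
        ]
    )
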