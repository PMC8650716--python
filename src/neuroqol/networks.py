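"""Latent neural-network extraction from regional CBF and differential activity.

The unit of analysis is the per-region mean cerebral blood flow (CBF, in
ml/100 g/min) of each participant during one fMRI stage (baseline 1, stress,
baseline 2).  The front end of the analysis is:

1.  ``region_means`` -- average the voxel CBF of a participant within each
    atlas region intersected with the gray-matter group mask;
2.  ``gm_center`` -- subtract each participant's global GM mean (the average
    over their regional means) from their row, per stage;
3.  ``fit_networks`` -- singular value decomposition of the centered *stress*
    matrix.  Each right singular vector is the loading pattern of one latent
    network; the participant scores are the matrix projected on the loadings.
    No region-wise (column) centering is applied, so a full-rank matrix of
    n participants yields exactly n components (28 in the motivating design);
4.  ``project_stage`` -- activity of the same networks during the baseline
    stages, by projecting their centered matrices on the stress loadings;
5.  ``differential_activity`` -- stress exposure = stress - baseline 1 scores,
    stress cessation (relaxation) = baseline 2 - stress scores;
6.  ``winner_takes_all`` -- assign each region to the network with maximal
    absolute loading.

Sign convention: each loading column is oriented so that its largest-magnitude
entry is positive, making outputs reproducible across platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("baseline1", "stress", "baseline2")
PROCESSES: tuple[str, ...] = ("exposure", "cessation")


class RegionAlignmentError(ValueError):
    """Raised when region sets/orders differ between inputs."""


class RankConfigurationError(ValueError):
    """Raised when fewer regions than participants are supplied."""


@dataclass
class RegionalActivityMatrix:
    """Participants x regions mean CBF for one fMRI stage."""

    data: pd.DataFrame  # index: participant_id, columns: region names
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def participants(self) -> pd.Index:
        return self.data.index

    @property
    def regions(self) -> pd.Index:
        return self.data.columns


@dataclass
class CenteredMatrix:
    """Row-centered regional matrix plus the per-participant subtracted mean."""

    data: pd.DataFrame
    stage: str
    row_means: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class NetworkModel:
    """Stress-stage principal-component network model.

    ``loadings`` (regions x components) has orthonormal columns; components
    are ordered by singular value, descending.  ``stress_scores``
    (participants x components) times ``loadings``' transpose reconstructs
    the centered stress matrix.
    """

    loadings: pd.DataFrame
    stress_scores: pd.DataFrame
    singular_values: np.ndarray
    explained_variation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sv2 = np.asarray(self.singular_values, dtype=float) ** 2
        total = sv2.sum()
        self.explained_variation = sv2 / total if total > 0 else sv2

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def regions(self) -> pd.Index:
        return self.loadings.index


@dataclass
class DifferentialActivity:
    """Per participant x network differential scores for the two processes.

    ``exposure`` = stress - baseline1 scores; ``cessation`` = baseline2 -
    stress scores.  Participants lacking the baseline-2 stage carry NaN in
    the cessation plane and are dropped listwise downstream.
    """

    exposure: pd.DataFrame
    cessation: pd.DataFrame

    def plane(self, process: str) -> pd.DataFrame:
        if process not in PROCESSES:
            raise ValueError(f"unknown process {process!r}")
        return self.exposure if process == "exposure" else self.cessation


def region_means(
    voxel_map: np.ndarray, parcellation: np.ndarray, mask: np.ndarray
) -> pd.Series:
    """Mean in-mask voxel CBF per atlas region.

    ``parcellation`` holds integer region labels (0 = background).  Regions
    whose intersection with the mask is empty are dropped with a warning.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    parcellation = np.asarray(parcellation)
    mask = np.asarray(mask, dtype=bool)
    if not (voxel_map.shape == parcellation.shape == mask.shape):
        raise RegionAlignmentError("voxel map, parcellation and mask grids differ")
    labels = parcellation[mask]
    values = voxel_map[mask]
    out: dict[int, float] = {}
    all_regions = np.unique(parcellation)
    all_regions = all_regions[all_regions != 0]
    sums = np.bincount(labels, weights=values, minlength=int(all_regions.max()) + 1 if all_regions.size else 1)
    counts = np.bincount(labels, minlength=sums.size)
    for region in all_regions:
        r = int(region)
        if r < counts.size and counts[r] > 0:
            out[r] = sums[r] / counts[r]
        else:
            logger.warning("region %d has empty intersection with mask; dropped", r)
    return pd.Series(out, name="mean_cbf")


def gm_center(matrix: RegionalActivityMatrix) -> CenteredMatrix:
    """Subtract each participant's average overall GM CBF from their row."""
    df = matrix.data
    if df.isna().any().any():
        raise ValueError(f"stage {matrix.stage!r} matrix has missing cells")
    row_means = df.mean(axis=1)
    centered = df.sub(row_means, axis=0)
    return CenteredMatrix(data=centered, stage=matrix.stage, row_means=row_means)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Orient each loading vector so its largest-magnitude entry is positive.
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs, scores * signs


def fit_networks(centered_stress: CenteredMatrix) -> NetworkModel:
    """SVD of the row-centered stress matrix, keeping all n_participants
    components.

    Column (region-wise) means are deliberately *not* removed: only the
    per-participant global GM centering is applied, so the decomposition of a
    full-rank n x r matrix (r >= n) has exactly n components rather than the
    n-1 a column-centered PCA would leave.
    """
    X = centered_stress.values
    n, r = X.shape
    if r < n:
        raise RankConfigurationError(
            f"need at least as many regions ({r}) as participants ({n})"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt.T  # regions x n
    scores = U * s  # participants x n
    loadings, scores = _fix_signs(loadings, scores)
    comp_names = [f"network_{i + 1}" for i in range(n)]
    return NetworkModel(
        loadings=pd.DataFrame(loadings, index=centered_stress.data.columns, columns=comp_names),
        stress_scores=pd.DataFrame(scores, index=centered_stress.data.index, columns=comp_names),
        singular_values=s,
    )


def project_stage(centered_stage: CenteredMatrix, model: NetworkModel) -> pd.DataFrame:
    """Network activity scores of a (baseline) stage: centered matrix times
    the stress-stage loadings."""
    if not centered_stage.data.columns.equals(model.regions):
        raise RegionAlignmentError("stage regions do not match the network model")
    scores = centered_stage.values @ model.loadings.to_numpy()
    return pd.DataFrame(
        scores, index=centered_stage.data.index, columns=model.loadings.columns
    )


def differential_activity(
    scores_b1: pd.DataFrame,
    scores_stress: pd.DataFrame,
    scores_b2: pd.DataFrame | None,
) -> DifferentialActivity:
    """Stress-exposure and stress-cessation differential network activity.

    ``scores_b2`` may cover only a subset of participants (a participant can
    lack the baseline-2 scan); their cessation rows are NaN.
    """
    if not scores_b1.index.equals(scores_stress.index) or not scores_b1.columns.equals(
        scores_stress.columns
    ):
        raise RegionAlignmentError("baseline-1 and stress score shapes differ")
    exposure = scores_stress - scores_b1
    if scores_b2 is None:
        cessation = pd.DataFrame(
            np.nan, index=scores_stress.index, columns=scores_stress.columns
        )
    else:
        if not scores_b2.columns.equals(scores_stress.columns):
            raise RegionAlignmentError("baseline-2 networks do not match")
        extra = scores_b2.index.difference(scores_stress.index)
        if len(extra):
            raise RegionAlignmentError(f"unknown baseline-2 participants {list(extra)}")
        cessation = scores_b2.reindex(scores_stress.index) - scores_stress
    return DifferentialActivity(exposure=exposure, cessation=cessation)


def winner_takes_all(loadings: pd.DataFrame) -> pd.Series:
    """Assign each region to the network with maximal absolute loading.

    Ties are broken in favor of the lower component index.
    """
    arr = np.abs(loadings.to_numpy())
    if not np.isfinite(arr).all():
        raise ValueError("non-finite loadings")
    idx = np.argmax(arr, axis=1)  # first max -> lower component wins ties
    return pd.Series(
        [loadings.columns[i] for i in idx], index=loadings.index, name="network"
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.loadings.to_csv(out / "loadings.csv")
    model.stress_scores.to_csv(out / "stress_scores.csv")
    pd.DataFrame(
        {
            "singular_value": model.singular_values,
            "explained_variation": model.explained_variation,
        },
        index=model.loadings.columns,
    ).to_csv(out / "singular_values.csv")
    meta = {
        "n_components": model.n_components,
        "n_regions": len(model.regions),
        "n_participants": model.stress_scores.shape[0],
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(in_dir) -> NetworkModel:
    p = Path(in_dir)
    loadings = pd.read_csv(p / "loadings.csv", index_col=0)
    scores = pd.read_csv(p / "stress_scores.csv", index_col=0)
    sv = pd.read_csv(p / "singular_values.csv", index_col=0)["singular_value"].to_numpy()
    return NetworkModel(loadings=loadings, stress_scores=scores, singular_values=sv)


def read_stage_csv(path, stage: str) -> RegionalActivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return RegionalActivityMatrix(data=df, stage=stage)
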