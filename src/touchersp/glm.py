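"""Mass-univariate GLM on scalp-time voxels with cluster-extent inference.

First level: per subject, single-trial scalp-time images are modelled with
six condition dummies (texture x estimation cells HH, SH, NH, HS, SS, NS)
plus six parametric regressors carrying the mean-centred friction+load
summation within each cell; OLS betas give per-subject contrast images for
the texture main effect, two estimation contrasts and two interaction
contrasts.  Second level: a one-sample F-test (F = t^2) for the texture
effect, and a two-column group design with F-contrast [1 0; 0 1] jointly
testing the two estimation (or interaction) contrast means.  Voxels above
the cluster-forming threshold (inverse upper-tail F quantile at p < .001)
are grouped into connected components under 18-connectivity (faces + edges)
in (x, y, t); components of fewer than 35 voxels are discarded.  Power in
surviving clusters is extracted per subject and condition for post-hoc
tests.  No random-field or permutation correction is applied: the decision
rule is exactly "p < .001 uncorrected + extent >= k_min".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

from touchersp.config import CELL_OF, CELLS

#: contrast vectors over the six dummy columns, in CELLS order
#: (HH, SH, NH, HS, SS, NS); weights scaled so each contrast estimates a
#: mean dB difference
CONTRASTS: dict[str, np.ndarray] = {
    # hessian (SH+HH+NH) vs silk (SS+HS+NS)
    "texture": np.array([1, 1, 1, -1, -1, -1]) / 3.0,
    # sensory (SH+SS) vs hedonic (HH+HS)
    "est_sensory_vs_hedonic": np.array([-1, 1, 0, -1, 1, 0]) / 2.0,
    # hedonic (HH+HS) vs no estimation (NH+NS)
    "est_hedonic_vs_none": np.array([1, 0, -1, 1, 0, -1]) / 2.0,
    # sensory hessian + hedonic silk (SH+HS) vs hedonic hessian + sensory silk
    "interaction_1": np.array([-1, 1, 0, 1, -1, 0]) / 2.0,
    # hedonic hessian + no-est silk (HH+NS) vs no-est hessian + hedonic silk
    "interaction_2": np.array([1, 0, -1, -1, 0, 1]) / 2.0,
}

EFFECT_CONTRASTS = {
    "texture": ["texture"],
    "estimation": ["est_sensory_vs_hedonic", "est_hedonic_vs_none"],
    "interaction": ["interaction_1", "interaction_2"],
}


class GlmError(ValueError):
    """Labelled error from the GLM stage."""


@dataclass
class DesignMatrix:
    """Trials x (6 dummies + covariate columns); full column rank for valid
    inputs, covariates mean-centred per the centring policy."""

    X: pd.DataFrame
    centring: str = "column"

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def contrast_vector(self, name: str) -> np.ndarray:
        c6 = CONTRASTS[name]
        c = np.zeros(self.X.shape[1])
        c[: len(CELLS)] = c6
        return c


@dataclass
class ClusterResult:
    """One supra-threshold connected component of the F map."""

    cluster_id: int
    effect: str
    band: str
    voxels: np.ndarray  # k x 3 (ix, iy, it)
    k: int
    peak_value: float
    peak_ix: int
    peak_iy: int
    peak_it: int
    peak_x_mm: float
    peak_y_mm: float
    peak_latency_ms: float
    df: tuple[float, float]
    threshold: float
    power: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Design and first level
# ---------------------------------------------------------------------------


def build_design(
    trials: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("median_friction", "median_load"),
    centring: str = "column",
    standardise: bool = False,
) -> DesignMatrix:
    """Six one-hot cell dummies plus per-cell mean-centred covariate columns.

    The covariate value is the plain summation of the listed behaviours
    (friction in N plus load in g, following the source convention), placed
    in the trial's cell column and mean-centred over the whole column
    (default) or over the cell's nonzero entries (``centring='cell'``).
    ``standardise=True`` z-scores each behaviour over trials before summing
    (the recommended commensurate-units mode: the raw N + g sum makes the
    modulator columns nearly collinear with their cell dummies, inflating
    first-level variance roughly with the covariate's mean/SD ratio).
    """
    if centring not in ("column", "cell"):
        raise GlmError("centring must be 'column' or 'cell'")
    n = len(trials)
    if n == 0:
        raise GlmError("empty trial table")
    cells = np.array([CELL_OF[(t, c)] for t, c in zip(trials["texture"], trials["condition"])])
    X = pd.DataFrame(0.0, index=np.arange(n), columns=list(CELLS))
    for cell in CELLS:
        X.loc[cells == cell, cell] = 1.0
    empty = [cell for cell in CELLS if X[cell].sum() == 0]
    if empty:
        raise GlmError(f"design has empty condition cells: {empty}")
    if covariates:
        for col in covariates:
            if col not in trials.columns:
                raise GlmError(f"trials table lacks covariate column {col!r}")
            if trials[col].isna().any():
                raise GlmError(f"covariate {col!r} contains undefined values")
        cols = trials[list(covariates)].to_numpy(dtype=float)
        if standardise:
            sd = cols.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            cols = (cols - cols.mean(axis=0)) / sd
        cv = cols.sum(axis=1)
        for cell in CELLS:
            sel = cells == cell
            if sel.sum() < 2 or np.isclose(cv[sel].std(), 0.0):
                # no within-cell variance: the modulator column would be
                # collinear with the cell dummy; omit it
                continue
            col = np.where(sel, cv, 0.0)
            if centring == "column":
                col = col - col.mean()
            else:
                col = col.copy()
                col[sel] = col[sel] - col[sel].mean()
            X[f"CV_{cell}"] = col
    return DesignMatrix(X, centring)


def fit_first_level(
    Y: np.ndarray,
    design: DesignMatrix,
    contrasts: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """OLS fit per voxel; returns contrast images c^T beta.

    ``Y``: trials x (any voxel shape).  Raises on rank-deficient designs,
    naming the dependent columns.
    """
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise GlmError(f"{Y.shape[0]} images for {X.shape[0]} design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by leave-one-out rank
        bad = [
            col
            for i, col in enumerate(design.X.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise GlmError(f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                       f"dependent columns: {bad}")
    shape = Y.shape[1:]
    yf = Y.reshape(Y.shape[0], -1)
    finite = np.isfinite(yf).all(axis=0)
    beta = np.full((X.shape[1], yf.shape[1]), np.nan)
    beta[:, finite] = np.linalg.pinv(X) @ yf[:, finite]
    names = contrasts if contrasts is not None else list(CONTRASTS)
    return {name: (design.contrast_vector(name) @ beta).reshape(shape) for name in names}


# ---------------------------------------------------------------------------
# Second level
# ---------------------------------------------------------------------------


def second_level_F(
    images: np.ndarray | list[np.ndarray],
    design: str = "one_sample",
) -> tuple[np.ndarray, tuple[float, float]]:
    """Group-level voxelwise F map.

    ``one_sample``: input n subject images; F = t^2 with t = mean/(SD/sqrt n),
    df = (1, n-1).  ``paired_two_contrast``: input a list/array of two blocks
    of n images (one per contrast type, subjects aligned); a two-column group
    design (one mean per type) is fitted and F jointly tests both means = 0,
    df = (2, N-2) with N = 2n total images.
    """
    if design == "one_sample":
        Y = np.asarray(images, dtype=float)
        n = Y.shape[0]
        if n < 2:
            raise GlmError("one-sample design needs >= 2 subjects")
        mean = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        return t**2, (1.0, float(n - 1))
    if design == "paired_two_contrast":
        blocks = [np.asarray(b, dtype=float) for b in images]
        if len(blocks) != 2:
            raise GlmError("paired_two_contrast needs exactly two image blocks")
        if blocks[0].shape != blocks[1].shape:
            raise GlmError("mismatched subject sets between the two contrast blocks")
        n = blocks[0].shape[0]
        N = 2 * n
        if N <= 2:
            raise GlmError("not enough images for the two-contrast design")
        m1 = blocks[0].mean(axis=0)
        m2 = blocks[1].mean(axis=0)
        rss1 = ((blocks[0] - m1) ** 2).sum(axis=0) + ((blocks[1] - m2) ** 2).sum(axis=0)
        rss0 = (blocks[0] ** 2).sum(axis=0) + (blocks[1] ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ((rss0 - rss1) / 2.0) / (rss1 / (N - 2))
        return F, (2.0, float(N - 2))
    raise GlmError(f"unknown second-level design {design!r}")


# ---------------------------------------------------------------------------
# Cluster inference
# ---------------------------------------------------------------------------

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_threshold(
    F: np.ndarray,
    df: tuple[float, float],
    *,
    p_form: float = 0.001,
    k_min: int = 35,
    connectivity: int = 18,
    x_mm: np.ndarray | None = None,
    y_mm: np.ndarray | None = None,
    t_ms: np.ndarray | None = None,
    effect: str = "",
    band: str = "",
) -> list[ClusterResult]:
    """Threshold the F map and keep connected components of extent >= k_min.

    The voxel threshold is the upper-tail F quantile at ``p_form`` for
    ``df``; components are connected under the declared 3D connectivity
    (18 = faces + edges by default).  NaN voxels (outside the scalp mask)
    never enter a cluster.  Survivors are reported with peak value, location
    and latency (ties: earliest latency, then lowest y, then lowest x).
    """
    if not 0 < p_form < 1:
        raise GlmError("p_form must lie in (0, 1)")
    if connectivity not in _STRUCTURES:
        raise GlmError("connectivity must be one of 6, 18, 26")
    thr = float(sp_stats.f.isf(p_form, df[0], df[1]))
    supra = np.isfinite(F) & (F > thr)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n_comp = ndimage.label(supra, structure=structure)
    results: list[ClusterResult] = []
    cid = 0
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labels == comp)
        if len(vox) < k_min:
            continue
        vals = F[vox[:, 0], vox[:, 1], vox[:, 2]]
        vmax = vals.max()
        at_max = vox[vals == vmax]
        # tie-break: earliest latency, lowest y, lowest x
        order = np.lexsort((at_max[:, 0], at_max[:, 1], at_max[:, 2]))
        ix, iy, it = (int(v) for v in at_max[order[0]])
        cid += 1
        results.append(
            ClusterResult(
                cluster_id=cid,
                effect=effect,
                band=band,
                voxels=vox,
                k=len(vox),
                peak_value=float(vmax),
                peak_ix=ix,
                peak_iy=iy,
                peak_it=it,
                peak_x_mm=float(x_mm[ix]) if x_mm is not None else float(ix),
                peak_y_mm=float(y_mm[iy]) if y_mm is not None else float(iy),
                peak_latency_ms=float(t_ms[it]) if t_ms is not None else float(it),
                df=df,
                threshold=thr,
            )
        )
    results.sort(key=lambda c: -c.k)
    for i, c in enumerate(results):
        c.cluster_id = i + 1
    return results


def extract_cluster_power(
    clusters: list[ClusterResult],
    condition_images: dict[tuple[str, str], np.ndarray],
) -> pd.DataFrame:
    """Mean dB over each cluster's voxels, per (subject, condition) image.

    ``condition_images`` maps (subject, condition-label) to a scalp-time
    array of the cluster's grid shape.  Returns a tidy table with columns
    ``cluster, subject, condition, mean_db`` ready for post-hoc testing.
    """
    rows = []
    for cl in clusters:
        ix, iy, it = cl.voxels[:, 0], cl.voxels[:, 1], cl.voxels[:, 2]
        for (subject, condition), img in condition_images.items():
            rows.append(
                {
                    "cluster": cl.cluster_id,
                    "effect": cl.effect,
                    "band": cl.band,
                    "subject": subject,
                    "condition": condition,
                    "mean_db": float(np.nanmean(img[ix, iy, it])),
                }
            )
    df = pd.DataFrame(rows, columns=["cluster", "effect", "band", "subject", "condition", "mean_db"])
    for cl in clusters:
        cl.power = df[df["cluster"] == cl.cluster_id].reset_index(drop=True)
    return df


def clusters_to_frame(clusters: list[ClusterResult]) -> pd.DataFrame:
    rows = [
        {
            "cluster": c.cluster_id,
            "band": c.band,
            "effect": c.effect,
            "peak_F": c.peak_value,
            "df1": c.df[0],
            "df2": c.df[1],
            "k": c.k,
            "peak_x_mm": c.peak_x_mm,
            "peak_y_mm": c.peak_y_mm,
            "peak_latency_ms": c.peak_latency_ms,
            "threshold_F": c.threshold,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster", "band", "effect", "peak_F", "df1", "df2", "k",
                 "peak_x_mm", "peak_y_mm", "peak_latency_ms", "threshold_F"],
    )
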