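"""Plate normalization: positivity calling, Tukey median polish, B-scores, NPA.

High-throughput RNAi screens carry strong row/column artifacts (edge
evaporation, dispenser gradients) and plate-to-plate offsets.  The B score
removes the additive plate structure with a two-way median polish,

    x[i, j] = overall + row_effect[i] + col_effect[j] + residual[i, j],

then scales residuals by the plate's median absolute deviation (MAD, with
the Gaussian-consistency constant 1.4826), so scores are comparable across
plates and robust to outlying wells — which is essential, because the hits
one is screening for *are* the outliers.

Normalized percent activation (NPA) instead anchors a raw readout between
the plate's control means,

    NPA = (x - mean_neg) / (mean_pos - mean_neg),

so 0 corresponds to the non-targeting negative controls and 1 to the
positive-control siRNAs.  Values outside [0, 1] are meaningful (stronger
than the positive control) and are never clipped by default.

The module exposes the primitives as functions and wraps them in two
scikit-learn transformers, :class:`BScoreNormalizer` and :class:`NPAScorer`,
that operate on the tidy well table of :mod:`stagescreen.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import PlateMeasurementSet

__all__ = [
    "MAD_GAUSSIAN",
    "MedianPolishDecomposition",
    "BScoreResult",
    "ControlSummary",
    "call_percent_positive",
    "median_polish",
    "bscore_plate",
    "aggregate_bscores",
    "npa",
    "control_summary",
    "BScoreNormalizer",
    "NPAScorer",
]

#: Gaussian-consistency constant: MAD * 1.4826 estimates sigma for normal data.
MAD_GAUSSIAN = 1.4826


@dataclass
class MedianPolishDecomposition:
    """Additive decomposition of a plate matrix from Tukey's median polish."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations_run: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        """overall + row + col + residual; NaN where the input was missing."""
        return (self.overall
                + self.row_effects[:, None]
                + self.col_effects[None, :]
                + self.residuals)


@dataclass
class BScoreResult:
    """Per-well B-scores for one (plate, channel, replicate) slice."""

    decomposition: MedianPolishDecomposition
    mad_scale: float
    bscores: np.ndarray  # NaN at non-sample wells
    plate_id: str
    channel: str
    replicate: int = 1
    degenerate: bool = False  # MAD was 0; all B-scores forced to 0


@dataclass
class ControlSummary:
    """Per-plate/channel control statistics anchoring thresholds and NPA."""

    channel: str
    neg_mean: float
    neg_sd: float
    n_neg: int
    pos_mean: float | None = None
    pos_sd: float | None = None
    n_pos: int = 0
    plate_id: str | None = None


def call_percent_positive(cell_values, negative_control_values) -> float:
    """Percent of cells whose intensity exceeds the negative-control mean.

    The positivity threshold is the mean per-cell intensity of an internal
    negative control; a cell counts as positive only if strictly above it.
    """
    cells = np.asarray(cell_values, dtype=float)
    controls = np.asarray(negative_control_values, dtype=float)
    if cells.size == 0 or controls.size == 0:
        raise ValueError("cell and control intensity vectors must be non-empty")
    if not (np.isfinite(cells).all() and np.isfinite(controls).all()):
        raise ValueError("non-finite intensity values")
    threshold = controls.mean()
    return 100.0 * float(np.mean(cells > threshold))


def median_polish(
    matrix, max_iter: int = 100, tol: float = 1e-6
) -> MedianPolishDecomposition:
    """Two-way median polish of a plate matrix with optional missing cells.

    Alternately sweeps row medians and column medians out of the residual
    matrix (even-count medians use the midpoint), recentring the effect
    vectors by their own medians into the overall term, until the summed
    absolute adjustment of one full sweep drops below ``tol`` or
    ``max_iter`` sweeps have run.  Missing cells (NaN) are ignored by the
    medians and stay missing in the residuals.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("median polish needs a matrix with >= 2 rows and columns")
    present = ~np.isnan(z)
    for i in np.flatnonzero(~present.any(axis=1)):
        raise ValueError(f"row {i} is entirely missing")
    for j in np.flatnonzero(~present.any(axis=0)):
        raise ValueError(f"column {j} is entirely missing")

    n_rows, n_cols = z.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rdelta = np.nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row_eff += rdelta
        cshift = np.median(col_eff)
        col_eff -= cshift
        overall += cshift

        cdelta = np.nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col_eff += cdelta
        rshift = np.median(row_eff)
        row_eff -= rshift
        overall += rshift

        adjustment = (np.abs(rdelta).sum() + np.abs(cdelta).sum()
                      + abs(cshift) + abs(rshift))
        if adjustment < tol:
            converged = True
            break

    return MedianPolishDecomposition(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=z,
        iterations_run=iterations,
        converged=converged,
    )


def _plate_matrix(df: pd.DataFrame, n_rows: int, n_cols: int) -> np.ndarray:
    """Sample-well value matrix; control/mock/empty wells left missing."""
    mat = np.full((n_rows, n_cols), np.nan)
    samples = df[df["role"] == "sample"]
    mat[samples["row"].to_numpy(), samples["col"].to_numpy()] = samples["value"].to_numpy()
    return mat


def bscore_plate(
    plate: PlateMeasurementSet | pd.DataFrame,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    mad_constant: float = MAD_GAUSSIAN,
) -> BScoreResult:
    """B-score one (plate, channel, replicate) slice.

    Control/mock/empty wells are treated as missing so they cannot distort
    the row/column effects; the MAD scale is computed over sample-well
    residuals only.  A plate whose residual MAD is 0 yields all-zero
    B-scores with ``degenerate=True`` rather than an error.
    """
    if isinstance(plate, PlateMeasurementSet):
        df, n_rows, n_cols = plate.data, plate.n_rows, plate.n_cols
    else:
        df, n_rows, n_cols = plate, 8, 12

    for key in ("plate_id", "channel", "replicate"):
        if df[key].nunique() > 1:
            raise ValueError(f"bscore_plate expects a single {key}, got {df[key].unique()}")

    samples = df[df["role"] == "sample"]
    if len(samples) < 4:
        raise ValueError(f"plate has {len(samples)} sample wells; need >= 4")
    if (df["row"].max() >= n_rows) or (df["col"].max() >= n_cols):
        raise ValueError("well coordinates exceed the declared plate geometry")

    mat = _plate_matrix(df, n_rows, n_cols)
    # a partially filled last plate can leave whole rows/columns without
    # sample wells; polish the occupied submatrix and re-embed
    occ_rows = np.flatnonzero(~np.isnan(mat).all(axis=1))
    occ_cols = np.flatnonzero(~np.isnan(mat).all(axis=0))
    sub = median_polish(mat[np.ix_(occ_rows, occ_cols)], max_iter=max_iter, tol=tol)
    row_eff = np.full(n_rows, np.nan)
    col_eff = np.full(n_cols, np.nan)
    resid = np.full((n_rows, n_cols), np.nan)
    row_eff[occ_rows] = sub.row_effects
    col_eff[occ_cols] = sub.col_effects
    resid[np.ix_(occ_rows, occ_cols)] = sub.residuals
    dec = MedianPolishDecomposition(
        overall=sub.overall, row_effects=row_eff, col_effects=col_eff,
        residuals=resid, iterations_run=sub.iterations_run, converged=sub.converged)

    sample_resid = dec.residuals[~np.isnan(dec.residuals)]
    mad_scale = float(mad_constant * np.median(np.abs(sample_resid)))

    if mad_scale > 0:
        bscores = dec.residuals / mad_scale
        degenerate = False
    else:
        bscores = np.where(np.isnan(dec.residuals), np.nan, 0.0)
        degenerate = True

    return BScoreResult(
        decomposition=dec,
        mad_scale=mad_scale,
        bscores=bscores,
        plate_id=str(df["plate_id"].iloc[0]),
        channel=str(df["channel"].iloc[0]),
        replicate=int(df["replicate"].iloc[0]),
        degenerate=degenerate,
    )


def aggregate_bscores(well_scores: pd.DataFrame) -> pd.DataFrame:
    """Average well-level B-scores into one score per (siRNA, replicate).

    ``well_scores`` is a tidy frame with columns batch_id, gene, sirna_id,
    replicate, channel, bscore (sample wells only).  Within each
    transfection batch the B-scores of all wells carrying a given siRNA in
    a given replicate are averaged arithmetically.  An siRNA absent from a
    replicate appears with a missing score, never zero.
    """
    agg = (
        well_scores.groupby(["batch_id", "gene", "sirna_id", "replicate", "channel"],
                            dropna=False)["bscore"]
        .mean()
        .reset_index()
        .rename(columns={"bscore": "score"})
    )
    # complete the (siRNA, replicate) grid per channel so absences are explicit
    full = (
        agg.set_index(["gene", "sirna_id", "channel", "replicate"])
        .unstack("replicate")
        .stack("replicate", future_stack=True)
        .reset_index()
    )
    return full[["batch_id", "gene", "sirna_id", "replicate", "channel", "score"]]


def npa(x: float, controls: ControlSummary) -> float:
    """Normalized percent activation: (x − neg_mean) / (pos_mean − neg_mean).

    0 at the negative-control mean, 1 at the positive-control mean; values
    outside [0, 1] are legal and are not clipped.
    """
    if controls.pos_mean is None:
        raise ValueError("NPA needs a positive-control mean")
    denom = controls.pos_mean - controls.neg_mean
    if denom == 0:
        raise ValueError(
            f"degenerate controls (pos_mean == neg_mean == {controls.neg_mean})"
            + (f" on plate {controls.plate_id}" if controls.plate_id else "")
        )
    return (x - controls.neg_mean) / denom


def control_summary(
    df: pd.DataFrame, channel: str, plate_id: str | None = None
) -> ControlSummary:
    """Summarize negative/positive control wells of one plate/channel slice."""
    neg = df.loc[df["role"] == "negative_control", "value"].dropna()
    pos = df.loc[df["role"] == "positive_control", "value"].dropna()
    if len(neg) < 2:
        raise ValueError(
            f"need >= 2 negative-control wells, found {len(neg)}"
            + (f" on plate {plate_id}" if plate_id else "")
        )
    return ControlSummary(
        channel=channel,
        neg_mean=float(neg.mean()),
        neg_sd=float(neg.std(ddof=1)),
        n_neg=len(neg),
        pos_mean=float(pos.mean()) if len(pos) else None,
        pos_sd=float(pos.std(ddof=1)) if len(pos) > 1 else None,
        n_pos=len(pos),
        plate_id=plate_id,
    )


class BScoreNormalizer(TransformerMixin, BaseEstimator):
    """B-score every (plate, channel, replicate) slice of a tidy well table.

    fit(X) runs the median polish per slice and stores the decompositions;
    transform(X) returns X with a ``bscore`` column for sample wells
    (NaN elsewhere).  X is the ``data`` frame of a
    :class:`~stagescreen.io.PlateMeasurementSet` (or the set itself).

    Parameters
    ----------
    max_iter, tol
        Median-polish sweep limit and convergence tolerance on the summed
        absolute median adjustment.
    mad_constant
        Scale factor applied to the median absolute residual; 1.4826 makes
        the scale estimate Gaussian-consistent.

    Attributes
    ----------
    results_ : dict[(plate_id, channel, replicate), BScoreResult]
    degenerate_plates_ : list of keys whose residual MAD was 0.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6,
                 mad_constant: float = MAD_GAUSSIAN):
        self.max_iter = max_iter
        self.tol = tol
        self.mad_constant = mad_constant

    @staticmethod
    def _frame(X) -> tuple[pd.DataFrame, int, int]:
        if isinstance(X, PlateMeasurementSet):
            return X.data, X.n_rows, X.n_cols
        return X, 8, 12

    def fit(self, X, y=None):
        df, n_rows, n_cols = self._frame(X)
        self.results_ = {}
        self.degenerate_plates_ = []
        for (plate, channel, rep), block in df.groupby(
                ["plate_id", "channel", "replicate"]):
            res = bscore_plate(
                PlateMeasurementSet(block.reset_index(drop=True), n_rows, n_cols),
                max_iter=self.max_iter, tol=self.tol, mad_constant=self.mad_constant,
            )
            key = (plate, channel, int(rep))
            self.results_[key] = res
            if res.degenerate:
                self.degenerate_plates_.append(key)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Attach a ``bscore`` column.

        Sample wells take the polished residual / MAD.  Control and mock
        wells are excluded from the polish, so their score is computed
        against the fitted decomposition:
        (value - overall - row_effect - col_effect) / MAD.
        """
        check_is_fitted(self, "results_")
        df, _, _ = self._frame(X)
        out = df.copy()
        scores = np.full(len(out), np.nan)
        for idx, (plate, channel, rep, row, col, role, value) in enumerate(
                zip(out["plate_id"], out["channel"], out["replicate"],
                    out["row"], out["col"], out["role"], out["value"])):
            key = (plate, channel, int(rep))
            if key not in self.results_:
                raise KeyError(f"plate slice {key} was not seen during fit")
            res = self.results_[key]
            b = res.bscores[row, col]
            if np.isnan(b) and role != "empty" and np.isfinite(value):
                dec = res.decomposition
                resid = value - dec.overall - dec.row_effects[row] - dec.col_effects[col]
                b = 0.0 if res.degenerate else resid / res.mad_scale
            scores[idx] = b
        out["bscore"] = scores
        return out


class NPAScorer(TransformerMixin, BaseEstimator):
    """Score wells as normalized percent activation against plate controls.

    fit(X) computes each grouping unit's negative/positive control summary;
    transform(X) adds an ``npa`` column.  ``per_plate=True`` anchors every
    plate on its own controls (required for the killing screen, where NPA
    absorbs plate/batch/replicate offsets); ``per_plate=False`` pools the
    controls of each channel across the whole set.
    """

    def __init__(self, per_plate: bool = True, clip: bool = False):
        self.per_plate = per_plate
        self.clip = clip

    def fit(self, X, y=None):
        df, _, _ = BScoreNormalizer._frame(X)
        self.controls_ = {}
        if self.per_plate:
            for (plate, channel, rep), block in df.groupby(
                    ["plate_id", "channel", "replicate"]):
                cs = control_summary(block, channel, plate_id=str(plate))
                self._check(cs)
                self.controls_[(plate, channel, int(rep))] = cs
        else:
            for channel, block in df.groupby("channel"):
                cs = control_summary(block, channel)
                self._check(cs)
                self.controls_[channel] = cs
        return self

    @staticmethod
    def _check(cs: ControlSummary) -> None:
        if cs.pos_mean is None:
            raise ValueError(
                f"no positive-control wells for channel {cs.channel}"
                + (f" on plate {cs.plate_id}" if cs.plate_id else "")
            )
        if cs.pos_mean == cs.neg_mean:
            raise ValueError(
                f"degenerate controls for channel {cs.channel}"
                + (f" on plate {cs.plate_id}" if cs.plate_id else "")
            )

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "controls_")
        df, _, _ = BScoreNormalizer._frame(X)
        out = df.copy()
        scores = np.empty(len(out))
        for idx, (plate, channel, rep, value) in enumerate(
                zip(out["plate_id"], out["channel"], out["replicate"], out["value"])):
            key = (plate, channel, int(rep)) if self.per_plate else channel
            if key not in self.controls_:
                raise KeyError(f"control summary for {key} was not seen during fit")
            scores[idx] = npa(value, self.controls_[key])
        if self.clip:
            scores = np.clip(scores, 0.0, 1.0)
        out["npa"] = scores
        return out
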