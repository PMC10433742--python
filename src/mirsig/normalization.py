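"""Preprocessing chain: LOWESS correction against the median profile,
log2 transform, gene-median centering.

Intensity-dependent bias (background, saturation) shows up as a smooth trend of
each sample's deviation from a common reference as a function of signal level —
the single-channel analogue of an MA-plot trend. LOWESS estimates that trend
per sample and subtracts it. The reference is the per-gene median profile
across all samples, and the correction runs on log2 intensities by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .matrix import ExpressionMatrix

#: LOWESS evaluates the local fit on a subsample and linearly interpolates
#: within windows of this fraction of the abscissa range; equivalent to an
#: anchor grid of roughly 1/DELTA_FRACTION points and within 0.01 of the full
#: fit on smooth trends.
DELTA_FRACTION = 0.005


def median_reference(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene median across all samples (even counts use the central-pair mean)."""
    if matrix.n_samples < 2:
        raise ValueError("median reference needs at least 2 samples")
    return matrix.values.median(axis=1)


def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.4,
    iterations: int = 3,
) -> np.ndarray:
    """Robust locally-weighted linear regression of y on x, evaluated at x.

    ``span`` is the fraction of points in each local window; ``iterations``
    robustifying reweighting passes guard against outliers. Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("lowess needs at least 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if span * len(x) < 2:
        raise ValueError(f"span {span} gives a window of <2 points for n={len(x)}")
    delta = DELTA_FRACTION * (x.max() - x.min())
    fitted = _sm_lowess(
        y, x, frac=span, it=iterations, delta=delta, return_sorted=False
    )
    return np.asarray(fitted, dtype=float)


def normalize_to_reference(
    matrix: ExpressionMatrix,
    span: float = 0.4,
    iterations: int = 3,
) -> ExpressionMatrix:
    """Remove each sample's intensity-dependent trend against the median profile.

    For every sample j the deviation ``x_j − reference`` is regressed on the
    reference with :func:`lowess_fit` and the fitted trend subtracted, so that
    affine per-sample biases vanish exactly and smooth nonlinear ones to within
    the fit tolerance. Expects log2-scale input (the default convention for
    this correction); linear intensities should be log-transformed first.
    """
    if matrix.n_genes < 3:
        raise ValueError("normalization needs at least 3 genes")
    reference = median_reference(matrix).to_numpy()
    corrected = matrix.values.to_numpy().copy()
    for j in range(matrix.n_samples):
        deviation = corrected[:, j] - reference
        trend = lowess_fit(reference, deviation, span=span, iterations=iterations)
        corrected[:, j] -= trend
    return ExpressionMatrix(
        pd.DataFrame(corrected, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups,
    )


def trend_amplitude(
    matrix: ExpressionMatrix, span: float = 0.4, iterations: int = 3
) -> pd.Series:
    """Max |LOWESS trend vs the median profile| per sample; a QC diagnostic."""
    reference = median_reference(matrix).to_numpy()
    amplitudes = {}
    for j, sample in enumerate(matrix.sample_ids):
        deviation = matrix.values.iloc[:, j].to_numpy() - reference
        trend = lowess_fit(reference, deviation, span=span, iterations=iterations)
        amplitudes[sample] = float(np.abs(trend).max())
    return pd.Series(amplitudes, name="trend_amplitude")


def log2_and_center(
    matrix: ExpressionMatrix, log: bool = True, center: str = "median"
) -> ExpressionMatrix:
    """log2-transform (optional) then center every gene at its median (or mean).

    Non-positive values abort the log step with the offending genes listed,
    rather than silently producing −inf/NaN.
    """
    values = matrix.values
    if log:
        bad = values.index[(values <= 0).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"log2 of non-positive values for {len(bad)} genes, e.g. "
                f"{list(bad[:5])}"
            )
        values = np.log2(values)
    if center == "median":
        values = values.sub(values.median(axis=1), axis=0)
    elif center == "mean":
        values = values.sub(values.mean(axis=1), axis=0)
    elif center != "none":
        raise ValueError(f"unknown centering {center!r}")
    return ExpressionMatrix(values, matrix.groups)
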