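"""Scikit-learn style estimator wrapping Tsallis threshold selection.

``TsallisThresholder`` follows the fit/predict/transform protocol: ``fit``
learns the maximum-entropy threshold(s) from an image (or a precomputed
histogram), ``predict`` applies them to produce a binary lesion mask, and
``transform`` aliases ``predict`` so the estimator composes with sklearn
pipelines.  All tunables are constructor parameters exposed through
``get_params``/``set_params``; fitted state lives in trailing-underscore
attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .errors import ContractError
from .histograms import Histogram1D, Histogram2D, histogram_1d, histogram_2d, neighborhood_mean
from .image_model import BinaryMask, GrayImage
from .segmentation import apply_threshold_1d, apply_threshold_2d
from .tsallis import TsallisParams, _sweep_2d, select_threshold_1d

__all__ = ["TsallisThresholder"]


class TsallisThresholder(TransformerMixin, BaseEstimator):
    """Maximum-Tsallis-entropy threshold selection as a transformer.

    Parameters
    ----------
    q : float, default 0.8
        Entropic index of the Tsallis entropy (q -> 1 recovers Shannon).
    method : {"1d", "2d"}
        "1d" thresholds the gray-level histogram; "2d" thresholds the joint
        (gray, neighborhood-mean) histogram, which is markedly more robust
        to voxelwise noise.
    levels : int, default 256
        Gray-level count used when quantizing raw floating-point input.
    window : int, default 3
        Odd neighborhood size for the local-mean channel (2d method).
    combination : {"pseudo_additive", "plain_sum"}
        Rule combining the two class entropies into the objective.
    quadrant_policy : {"ignore", "joint"}
        Treatment of the off-diagonal quadrants of the joint histogram.
    invert : bool, default False
        If True the below-threshold class is the foreground (hypointense
        lesions); default keeps hyperintense foreground.

    Attributes
    ----------
    threshold_ : int
        Selected gray-level threshold (the s of the pair for method="2d").
    mean_threshold_ : int or None
        Neighborhood-mean threshold t (method="2d" only).
    objective_ : float
        Combined Tsallis entropy at the optimum.
    curve_ : ndarray or None
        Objective over all admissible thresholds (method="1d" only).
    """

    def __init__(
        self,
        q: float = 0.8,
        method: str = "1d",
        levels: int = 256,
        window: int = 3,
        combination: str = "pseudo_additive",
        quadrant_policy: str = "ignore",
        invert: bool = False,
    ):
        self.q = q
        self.method = method
        self.levels = levels
        self.window = window
        self.combination = combination
        self.quadrant_policy = quadrant_policy
        self.invert = invert

    # -- helpers ----------------------------------------------------------

    def _as_image(self, X) -> GrayImage:
        if isinstance(X, GrayImage):
            return X
        arr = np.asarray(X)
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= self.levels - 1:
            return GrayImage(arr.astype(np.int64), levels=self.levels)
        from .image_model import quantize

        return quantize(arr, levels=self.levels)

    def _params(self) -> TsallisParams:
        return TsallisParams(q=self.q, combination=self.combination)

    # -- sklearn protocol --------------------------------------------------

    def fit(self, X, y=None):
        """Select the optimal threshold(s) from an image, raster, or histogram.

        ``X`` may be a 2D/3D array, a :class:`GrayImage`, or a precomputed
        :class:`Histogram1D` / :class:`Histogram2D` matching ``method``.
        """
        if self.method not in ("1d", "2d"):
            raise ContractError(f"method must be '1d' or '2d', got {self.method!r}")
        params = self._params()
        if self.method == "1d":
            if isinstance(X, Histogram2D):
                raise ContractError("method='1d' cannot fit a joint histogram")
            h = X if isinstance(X, Histogram1D) else histogram_1d(self._as_image(X))
            res = select_threshold_1d(h, params)
            self.threshold_ = res.t
            self.mean_threshold_ = None
            self.objective_ = res.objective
            self.curve_ = res.curve
            self.result_ = res
        else:
            if isinstance(X, Histogram1D):
                raise ContractError("method='2d' cannot fit a marginal histogram")
            if isinstance(X, Histogram2D):
                h2 = X
            else:
                h2 = histogram_2d(self._as_image(X), window=self.window)
            res = _sweep_2d(h2.p, params, quadrant_policy=self.quadrant_policy)
            self.threshold_ = res.s
            self.mean_threshold_ = res.t
            self.objective_ = res.objective
            self.curve_ = None
            self.result_ = res
        return self

    def predict(self, X) -> BinaryMask:
        """Apply the fitted threshold(s) to an image and return a binary mask."""
        if not hasattr(self, "threshold_"):
            raise NotFittedError("TsallisThresholder must be fitted before predict")
        img = self._as_image(X)
        if self.method == "1d":
            return apply_threshold_1d(img, self.threshold_, invert=self.invert)
        mean_img = neighborhood_mean(img, window=self.window)
        return apply_threshold_2d(
            img, mean_img, self.threshold_, self.mean_threshold_, invert=self.invert
        )

    def transform(self, X) -> BinaryMask:
        """Alias of :meth:`predict` for pipeline composition."""
        return self.predict(X)

    def fit_predict(self, X, y=None) -> BinaryMask:
        return self.fit(X).predict(X)
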