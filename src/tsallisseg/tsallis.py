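"""Tsallis (non-extensive) entropy and maximum-entropy threshold selection.

The Tsallis entropy of a discrete distribution p with entropic index q > 0 is

    S_q(p) = (1 - sum_i p_i^q) / (q - 1),

a one-parameter generalization of Shannon entropy, which it recovers in the
limit q -> 1.  Thresholding an image at level t splits its gray-level
histogram into a target class A (levels <= t) and background class B
(levels > t); each class is renormalized by its total probability and the
selected threshold is the one maximizing the combined entropy of the two
classes.  For independent systems Tsallis entropy composes
pseudo-additively, S(A+B) = S(A) + S(B) + (1-q) S(A) S(B), which is the
default combination rule here; a plain sum is available as an option.

The 2D variant thresholds the joint (gray level, neighborhood mean)
histogram at a pair (s, t): class A is the lower-left quadrant
{i <= s, j <= t}, class B the upper-right {i > s, j > t}.  The two
off-diagonal quadrants hold mostly noise and edge pixels; under the default
policy their mass is ignored and each class is renormalized within its own
quadrant.  Cumulative-sum tables make the full (s, t) sweep O(L^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, NoThresholdError, ParameterError
from .histograms import Histogram1D, Histogram2D

__all__ = [
    "TsallisParams",
    "ThresholdResult1D",
    "ThresholdResult2D",
    "shannon_entropy",
    "tsallis_entropy",
    "class_probabilities",
    "partition_entropies",
    "combine_entropy",
    "select_threshold_1d",
    "select_threshold_2d",
]

#: |q - 1| below which the Shannon limit is used instead of the power form.
_Q_SHANNON_TOL = 1e-9


@dataclass
class TsallisParams:
    """Entropic index q and class-combination rule.

    q is the free non-extensiveness parameter of the method; 0.8 is the
    package default.  ``combination`` is ``"pseudo_additive"`` (default) or
    ``"plain_sum"``.
    """

    q: float = 0.8
    combination: str = "pseudo_additive"

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ParameterError(f"q must be positive, got {self.q}")
        if self.combination not in ("pseudo_additive", "plain_sum"):
            raise ParameterError(f"unknown combination rule: {self.combination!r}")


@dataclass
class ThresholdResult1D:
    """Selected 1D threshold with the full objective curve.

    ``curve[t]`` is the combined entropy at threshold t (NaN where t is
    inadmissible because one class would be empty); ``admissible`` marks
    the valid entries.
    """

    t: int
    objective: float
    curve: np.ndarray = field(repr=False)
    admissible: np.ndarray = field(repr=False)

    def curve_tsv(self, path) -> None:
        """Export (t, objective) rows, admissible thresholds only."""
        ts = np.nonzero(self.admissible)[0]
        np.savetxt(
            path,
            np.column_stack([ts, self.curve[ts]]),
            fmt=("%d", "%.12g"),
            delimiter="\t",
            header="t\tobjective",
            comments="",
        )


@dataclass
class ThresholdResult2D:
    """Selected (gray, neighborhood-mean) threshold pair."""

    s: int
    t: int
    objective: float
    quadrant_policy: str = "ignore"


def _check_prob(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ContractError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > tol:
        raise ContractError(f"probabilities must sum to 1, got {p.sum()!r}")
    return p


def shannon_entropy(p) -> float:
    """Shannon entropy -sum p_i ln p_i in nats, with 0 ln 0 = 0."""
    p = _check_prob(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def tsallis_entropy(p, q: float) -> float:
    """Tsallis entropy (1 - sum p_i^q)/(q - 1); Shannon limit at |q-1| < 1e-9.

    Zero-probability entries contribute nothing for every q > 0.
    """
    if q <= 0:
        raise ParameterError(f"q must be positive, got {q}")
    p = _check_prob(p)
    if abs(q - 1.0) < _Q_SHANNON_TOL:
        return shannon_entropy(p)
    nz = p[p > 0]
    return float((1.0 - (nz**q).sum()) / (q - 1.0))


def class_probabilities(h: Histogram1D, t: int) -> tuple[float, float]:
    """Total probability of class A (levels 0..t) and class B (levels t+1..L-1)."""
    if not 0 <= t < h.levels - 1:
        raise ContractError(f"threshold t={t} outside [0, {h.levels - 2}]")
    p_a = float(h.p[: t + 1].sum())
    return p_a, float(1.0 - p_a)


def partition_entropies(h: Histogram1D, t: int, q: float) -> tuple[float, float] | None:
    """Tsallis entropies of the renormalized class distributions at threshold t.

    Returns None when either class is empty — an inadmissible threshold the
    caller should skip, not an error.
    """
    head, tail = h.p[: t + 1], h.p[t + 1 :]
    # slice sums, not 1 - cumulative, so an empty class is exactly zero
    p_a, p_b = float(head.sum()), float(tail.sum())
    if p_a <= 0.0 or p_b <= 0.0:
        return None
    s_a = tsallis_entropy(head / p_a, q)
    s_b = tsallis_entropy(tail / p_b, q)
    return s_a, s_b


def combine_entropy(s_a: float, s_b: float, q: float, rule: str = "pseudo_additive") -> float:
    """Combine class entropies: pseudo-additive S_A + S_B + (1-q) S_A S_B, or plain sum."""
    if rule == "pseudo_additive":
        return s_a + s_b + (1.0 - q) * s_a * s_b
    if rule == "plain_sum":
        return s_a + s_b
    raise ParameterError(f"unknown combination rule: {rule!r}")


def _class_entropies_from_sums(
    p_cls: np.ndarray, pq_cls: np.ndarray, plogp_cls: np.ndarray, q: float
) -> np.ndarray:
    """Vectorized within-class Tsallis entropy from class mass and power sums.

    For class mass P and raw power sum sum(p_i^q) over the class, the
    renormalized entropy is (1 - sum(p_i^q)/P^q)/(q-1); in the Shannon
    limit it is ln P - sum(p_i ln p_i)/P.  Entries with P <= 0 yield NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(q - 1.0) < _Q_SHANNON_TOL:
            out = np.log(p_cls) - plogp_cls / p_cls
        else:
            out = (1.0 - pq_cls / p_cls**q) / (q - 1.0)
    out[~(p_cls > 0)] = np.nan
    return out


def _plogp(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def select_threshold_1d(h: Histogram1D, params: TsallisParams | None = None) -> ThresholdResult1D:
    """Exhaustive maximum-Tsallis-entropy threshold search over a 1D histogram.

    Sweeps every t with both classes non-empty and returns the argmax of the
    combined entropy; exact ties break toward the smallest t.
    """
    params = params or TsallisParams()
    p = h.p
    if np.count_nonzero(p) < 2:
        raise NoThresholdError("histogram has fewer than 2 occupied levels")
    q = params.q

    def head_tail(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # forward and reverse cumulative sums so an empty class is exactly 0
        return np.cumsum(v)[:-1], np.cumsum(v[::-1])[::-1][1:]

    p_a, p_b = head_tail(p)
    pq = p**q if abs(q - 1.0) >= _Q_SHANNON_TOL else np.zeros_like(p)
    pq_a, pq_b = head_tail(pq)
    plogp_a, plogp_b = head_tail(_plogp(p))
    occ_a, occ_b = head_tail((p > 0).astype(np.int64))
    admissible = (occ_a >= 1) & (occ_b >= 1)

    s_a = _class_entropies_from_sums(p_a, pq_a, plogp_a, q)
    s_b = _class_entropies_from_sums(p_b, pq_b, plogp_b, q)
    curve = np.full(h.levels - 1, np.nan)
    curve[admissible] = combine_entropy(s_a[admissible], s_b[admissible], q, params.combination)
    if not admissible.any():
        raise NoThresholdError("no threshold leaves both classes non-empty")
    objective = np.nanmax(curve)
    # smallest t among near-ties, robust to cumulative-sum rounding
    tie_tol = 1e-12 * max(1.0, abs(objective))
    t = int(np.nonzero(curve >= objective - tie_tol)[0][0])
    objective = curve[t]
    return ThresholdResult1D(t=t, objective=float(objective), curve=curve, admissible=admissible)


def select_threshold_2d(
    h2: Histogram2D,
    params: TsallisParams | None = None,
    quadrant_policy: str = "ignore",
) -> ThresholdResult2D:
    """Maximum-Tsallis-entropy search over (gray, neighborhood-mean) pairs.

    Class A is the quadrant {i <= s, j <= t}, class B is {i > s, j > t}.
    The default ``quadrant_policy="ignore"`` drops the mass of the two
    off-diagonal quadrants (mostly edge and noise pixels) and renormalizes
    each class within its own quadrant; ``"joint"`` renormalizes both
    classes by the total retained mass P_A + P_B instead.  2D cumulative
    sums make the sweep O(L^2); exact ties break to the lexicographically
    smallest (s, t).
    """
    params = params or TsallisParams()
    return _sweep_2d(h2.p, params, quadrant_policy=quadrant_policy)


def _sweep_2d(p2: np.ndarray, params: TsallisParams, quadrant_policy: str = "ignore") -> ThresholdResult2D:
    if quadrant_policy not in ("ignore", "joint"):
        raise ParameterError(f"unknown quadrant policy: {quadrant_policy!r}")
    q = params.q
    L = p2.shape[0]
    shannon = abs(q - 1.0) < _Q_SHANNON_TOL

    def corner_sums(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # C[s, t] = sum over {i <= s, j <= t}; B via inclusion-exclusion
        c = mat.cumsum(axis=0).cumsum(axis=1)
        a = c[:-1, :-1]
        total = c[-1, -1]
        b = total - c[:-1, -1][:, None] - c[-1, :-1][None, :] + a
        return a, b

    pa, pb = corner_sums(p2)
    pb = np.maximum(pb, 0.0)  # inclusion-exclusion rounding
    if shannon:
        pqa = pqb = np.zeros_like(pa)
        la, lb = corner_sums(_plogp(p2))
    else:
        pqa, pqb = corner_sums(p2**q)
        la = lb = np.zeros_like(pa)

    # admissibility from occupancy counts (exact), not float mass
    occ_a, occ_b = corner_sums((p2 > 0).astype(np.float64))
    admissible = (occ_a >= 0.5) & (occ_b >= 0.5)
    if not admissible.any():
        raise NoThresholdError("no (s, t) pair leaves both quadrant classes non-empty")

    if quadrant_policy == "ignore":
        s_a = _class_entropies_from_sums(pa, pqa, la, q)
        s_b = _class_entropies_from_sums(pb, pqb, lb, q)
    else:
        # renormalize by the jointly retained mass; class sums stay per-quadrant
        m = pa + pb
        with np.errstate(divide="ignore", invalid="ignore"):
            if shannon:
                s_a = (pa / m) * np.log(m) - la / m
                s_b = (pb / m) * np.log(m) - lb / m
            else:
                s_a = (pa / m - pqa / m**q) / (q - 1.0)
                s_b = (pb / m - pqb / m**q) / (q - 1.0)
        s_a[~admissible] = np.nan
        s_b[~admissible] = np.nan

    obj = combine_entropy(s_a, s_b, q, params.combination)
    obj[~admissible] = -np.inf
    best = obj.max()
    tie_tol = 1e-12 * max(1.0, abs(best))
    # row-major first near-tie -> lexicographically smallest (s, t)
    flat = int(np.argmax(obj.ravel() >= best - tie_tol))
    s, t = divmod(flat, L - 1)
    return ThresholdResult2D(
        s=int(s), t=int(t), objective=float(obj[s, t]), quadrant_policy=quadrant_policy
    )
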