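"""Quantal analysis: equidistant Gaussian sums fitted to amplitude histograms.

Under the quantal hypothesis, postsynaptic amplitudes cluster at multiples of
the elementary (quantal) size q, so a histogram of amplitudes can be
described by a sum of Gaussians with equidistant means

    mu_k = offset + (k - 1) q,   k = 1..K.

Amplitudes between 5 and 150 pA are binned at 2 pA increments and the sum is
fitted by least squares with q and the offset shared across components
(component weights solved by non-negative least squares given the shape
parameters — a variable-projection scheme).  The number of components is
selected by the Bayesian information criterion on the Poisson likelihood of
the binned counts, an objective stand-in for by-eye confirmation of fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.special import gammaln
from scipy.stats import norm


@dataclass
class AmplitudeHistogram:
    counts: np.ndarray
    edges: np.ndarray
    n_excluded: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class QuantalFit:
    n_components: int
    quantal_size_pA: float
    offset_pA: float
    sigmas_pA: np.ndarray
    weights: np.ndarray  # per-component event counts
    rss: float
    criterion_value: float
    converged: bool = True
    means_pA: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sigmas_pA = np.asarray(self.sigmas_pA, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means_pA = self.offset_pA + np.arange(self.n_components) * self.quantal_size_pA


def bin_amplitudes(
    amplitudes: np.ndarray,
    lo: float = 5.0,
    hi: float = 150.0,
    width: float = 2.0,
) -> AmplitudeHistogram:
    """Histogram amplitudes over half-open bins [lo + k*w, lo + (k+1)*w).

    Values outside [lo, hi) are excluded and counted; the last bin is
    truncated at ``hi`` when the range is not a multiple of the width.
    """
    if width <= 0 or lo >= hi:
        raise ValueError("need width > 0 and lo < hi")
    amps = np.asarray(amplitudes, dtype=float)
    inside = (amps >= lo) & (amps < hi)
    edges = np.arange(lo, hi, width)
    edges = np.r_[edges, hi] if edges[-1] < hi else edges
    counts, edges = np.histogram(amps[inside], bins=edges)
    return AmplitudeHistogram(counts=counts, edges=edges,
                              n_excluded=int((~inside).sum()))


def _component_matrix(edges: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Expected per-bin probability mass of each unit-weight component."""
    z = (edges[:, None] - means[None, :]) / sigmas[None, :]
    cdf = norm.cdf(z)
    return cdf[1:, :] - cdf[:-1, :]


def _sigmas(sigma: float, k: int, mode: str) -> np.ndarray:
    if mode == "common":
        return np.full(k, sigma)
    if mode == "sqrt_k":
        return sigma * np.sqrt(np.arange(1, k + 1))
    raise ValueError("sigma_mode must be 'common' or 'sqrt_k'")


def _poisson_bic(counts: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    mu = np.clip(mu, 1e-9, None)
    loglik = float(np.sum(counts * np.log(mu) - mu - gammaln(counts + 1)))
    n = max(int(counts.sum()), 2)
    return -2 * loglik + n_params * np.log(n)


_Q_GRID = (6.0, 10.0, 14.0, 18.0, 22.0, 26.0)


def fit_gaussian_sum(
    hist: AmplitudeHistogram,
    k: int,
    sigma_mode: str = "common",
    force_offset_equal_q: bool = False,
) -> QuantalFit:
    """Least-squares fit of a k-component equidistant Gaussian sum.

    The shared spacing q, the first mean (offset) and the width are optimized
    nonlinearly from a grid of starting spacings; component weights are
    solved by non-negative least squares at each step, so the equidistance
    of the means is a hard constraint of the parameterization.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = hist.counts.astype(float)
    nonzero = int((counts > 0).sum())
    if counts.sum() == 0:
        raise ValueError("cannot fit an all-zero histogram")
    if k > max(1, hist.counts.size // 3):
        raise ValueError(f"k={k} exceeds a third of the bin count")
    edges = hist.edges
    width = float(np.median(np.diff(edges)))

    def unpack(theta):
        if force_offset_equal_q:
            q, sigma = theta
            offset = q
        else:
            q, offset, sigma = theta
        return q, offset, sigma

    def resid(theta):
        q, offset, sigma = unpack(theta)
        means = offset + np.arange(k) * q
        phi = _component_matrix(edges, means, _sigmas(sigma, k, sigma_mode))
        w, _ = nnls(phi, counts)
        return phi @ w - counts

    lo_edge, hi_edge = edges[0], edges[-1]
    if force_offset_equal_q:
        lb = [1.0, 0.3]
        ub = [hi_edge, (hi_edge - lo_edge) / 2]
    else:
        lb = [1.0, lo_edge - width, 0.3]
        ub = [hi_edge, hi_edge, (hi_edge - lo_edge) / 2]

    # starting offset near the first substantial mode of the histogram
    centers = hist.centers
    mode_c = float(centers[np.argmax(counts)])
    best = None
    for q0 in _Q_GRID:
        offsets0 = {q0, mode_c} if not force_offset_equal_q else {q0}
        for off0 in offsets0:
            sigma0 = max(1.0, width)
            if force_offset_equal_q:
                x0 = np.clip([q0, sigma0], lb, ub)
            else:
                x0 = np.clip([q0, off0, sigma0], lb, ub)
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
    q, offset, sigma = unpack(best.x)
    means = offset + np.arange(k) * q
    sigmas = _sigmas(sigma, k, sigma_mode)
    phi = _component_matrix(edges, means, sigmas)
    w, _ = nnls(phi, counts)
    mu = phi @ w
    rss = float(np.sum((mu - counts) ** 2))
    n_params = (2 if force_offset_equal_q else 3) + k
    bic = _poisson_bic(counts, mu, n_params)
    converged = bool(best.success) and nonzero >= 2
    return QuantalFit(
        n_components=k,
        quantal_size_pA=float(q),
        offset_pA=float(offset),
        sigmas_pA=sigmas,
        weights=w,
        rss=rss,
        criterion_value=bic,
        converged=converged,
    )


def select_component_count(
    hist: AmplitudeHistogram,
    k_min: int = 1,
    k_max: int = 10,
    sigma_mode: str = "common",
    force_offset_equal_q: bool = False,
) -> tuple[int, dict[int, QuantalFit]]:
    """Fit all component counts in range and pick the best by criterion.

    The full fit list is returned for audit.  Ties go to the lower k.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    k_cap = max(1, hist.counts.size // 3)
    fits: dict[int, QuantalFit] = {}
    for k in range(k_min, min(k_max, k_cap) + 1):
        fits[k] = fit_gaussian_sum(hist, k, sigma_mode=sigma_mode,
                                   force_offset_equal_q=force_offset_equal_q)
    best_k = min(fits, key=lambda k: (fits[k].criterion_value, k))
    return best_k, fits
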