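"""Pairwise synchronization indices for multichannel time series.

Three estimators, covering the linear/nonlinear and symmetric/directed
corners of functional-connectivity practice:

* **MSC** — magnitude squared coherence, the Welch-averaged cross-spectral
  density normalized by the auto-spectra:
  ``gamma_xy(f) = |<S_xy>|^2 / (<S_xx><S_yy>)``, in [0, 1] per frequency.
* **RIM** — a robust nonlinear interdependence measure on delay-embedded
  signals.  With ``R_t(Y)`` the mean squared distance of the embedded point
  ``y(t)`` to all other points and ``R_t^(k)(Y|X)`` the mean squared distance
  to the points at the time indices of ``x(t)``'s k nearest neighbours,
  ``N(Y|X) = mean_t (R_t(Y) - R_t^(k)(Y|X)) / R_t(Y)``.  A Theiler window of
  ``m * tau`` samples excludes temporally correlated neighbours.  The
  symmetric index is ``(N(X|Y) + N(Y|X)) / 2``.
* **PDC** — partial directed coherence from a fitted VAR(p) model.  With
  ``Abar(w) = I - sum_r A(r) e^(-i w r)``, the influence of channel j on
  channel i at frequency w is ``|Abar_ij(w)|`` normalized over the source
  column j.  The ``standard`` variant divides by
  ``sqrt(sum_l |Abar_lj|^2)`` so that the squared entries of each column sum
  to one; the ``as_printed`` variant divides by the un-rooted sum of squares.

``connectivity_matrix`` assembles a full channel-by-channel synchronization
matrix for any of the three methods, reduced to a frequency band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist

from .errors import ComputationError, ConfigError, InputFormatError
from .network import default_labels

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSet",
    "WelchParams",
    "EmbeddingParams",
    "VARModel",
    "RIMResult",
    "ConnectivityResult",
    "msc",
    "rim",
    "estimate_tau",
    "fit_var",
    "pdc",
    "band_reduce",
    "connectivity_matrix",
]

#: EEG frequency bands (Hz) conventionally used for band reduction.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class TimeSeriesSet:
    """Samples-by-channels signal block with a sampling rate in Hz."""

    data: np.ndarray
    fs: float = 1.0
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InputFormatError("time series data must be 2-D (samples x channels)")
        if data.shape[1] < 2:
            raise InputFormatError("a time series set needs at least 2 channels")
        if not np.all(np.isfinite(data)):
            raise InputFormatError("time series contains non-finite values")
        if self.fs <= 0:
            raise InputFormatError(f"sampling rate must be positive, got {self.fs}")
        labels = tuple(self.labels) if self.labels else default_labels(data.shape[1])
        if len(labels) != data.shape[1]:
            raise InputFormatError("channel label count does not match data columns")
        data = data.copy()
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, i: int) -> np.ndarray:
        return self.data[:, i]


@dataclass(frozen=True)
class WelchParams:
    """Welch spectral-estimation parameters (Hann window, 50% overlap)."""

    nperseg: int = 256
    noverlap: int | None = None
    window: str = "hann"
    detrend: str = "constant"

    def resolved_noverlap(self) -> int:
        return self.nperseg // 2 if self.noverlap is None else self.noverlap


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters for the nonlinear interdependence measure.

    ``m`` is the embedding dimension, ``tau`` the delay in samples, ``k`` the
    neighbour count.  The Theiler window is ``m * tau`` samples.
    """

    m: int = 5
    tau: int = 1
    k: int = 10

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ConfigError(f"delay tau must be >= 1, got {self.tau}")
        if self.k < 1:
            raise ConfigError(f"neighbour count k must be >= 1, got {self.k}")

    @property
    def theiler(self) -> int:
        return self.m * self.tau

    def n_embedded(self, n_samples: int) -> int:
        return n_samples - (self.m - 1) * self.tau


@dataclass(frozen=True)
class VARModel:
    """Vector autoregressive model x(t) = sum_r A(r) x(t-r) + eps(t)."""

    order: int
    coefs: np.ndarray  # shape (p, n, n); coefs[r-1] = A(r)
    sigma: np.ndarray  # noise covariance, n x n
    nobs: int = 0
    residual_rms: float = float("nan")
    aic: float = float("nan")

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefs, dtype=float)
        if coefs.ndim != 3 or coefs.shape[1] != coefs.shape[2]:
            raise InputFormatError("coefs must have shape (p, n, n)")
        if coefs.shape[0] != self.order or self.order < 1:
            raise InputFormatError("order must match the number of coefficient matrices")
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != coefs.shape[1:]:
            raise InputFormatError("sigma must be n x n")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise InputFormatError("noise covariance must be symmetric")
        if not self.is_stable():
            logger.warning(
                "VAR companion matrix has spectral radius >= 1; model is unstable"
            )
        object.__setattr__(self, "coefs", coefs)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    def companion(self) -> np.ndarray:
        p, n, _ = np.asarray(self.coefs).shape
        C = np.zeros((n * p, n * p))
        C[:n, :] = np.concatenate(list(np.asarray(self.coefs)), axis=1)
        if p > 1:
            C[n:, :-n] = np.eye(n * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass(frozen=True)
class RIMResult:
    """Raw and clipped nonlinear interdependence values for one channel pair."""

    n_yx: float  # N(Y|X): how well X's neighbourhoods predict Y
    n_xy: float  # N(X|Y)
    params: EmbeddingParams

    @property
    def symmetric(self) -> float:
        return 0.5 * (self.n_xy + self.n_yx)

    @property
    def synchronization(self) -> float:
        """Symmetric index clipped to [0, 1] for use as an edge value."""
        return float(min(max(self.symmetric, 0.0), 1.0))


@dataclass(frozen=True)
class ConnectivityResult:
    """Per-band synchronization matrix together with the parameters used."""

    method: str  # msc | rim | pdc
    matrix: np.ndarray
    band: tuple[float, float] | None
    directed: bool
    labels: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise InputFormatError("connectivity matrix must be square")
        if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
            raise ComputationError("connectivity values left [0, 1]")
        M = np.clip(M, 0.0, 1.0)
        np.fill_diagonal(M, 0.0)
        M.setflags(write=False)
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "labels", tuple(self.labels))


# -- magnitude squared coherence ------------------------------------------


def _check_channel(x: np.ndarray, name: str) -> None:
    if np.ptp(x) == 0:
        raise ComputationError(
            f"channel {name} is constant; coherence is undefined for "
            "zero-variance signals"
        )


def msc(
    ts: TimeSeriesSet,
    i: int,
    j: int,
    welch: WelchParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude squared coherence between channels i and j.

    Returns ``(frequencies_hz, gamma)`` with gamma in [0, 1] at every
    frequency.  Symmetric in (i, j); the self-coherence (i == j) is
    identically 1.
    """
    welch = welch or WelchParams()
    x = ts.channel(i)
    y = x if i == j else ts.channel(j)  # identical object => exact self-coherence
    _check_channel(x, ts.labels[i])
    _check_channel(y, ts.labels[j])
    if welch.nperseg > ts.n_samples:
        raise ConfigError(
            f"Welch segment length {welch.nperseg} exceeds series length "
            f"{ts.n_samples}"
        )
    kw = dict(
        fs=ts.fs,
        window=welch.window,
        nperseg=welch.nperseg,
        noverlap=welch.resolved_noverlap(),
        detrend=welch.detrend,
    )
    f, s_xy = signal.csd(x, y, **kw)
    _, s_xx = signal.welch(x, **kw)
    _, s_yy = signal.welch(y, **kw)
    # |<S_xy>|^2 computed as re^2 + im^2 (not abs()**2) so the self-coherence
    # is exactly 1: for i == j the averaged cross-spectrum is real and equal
    # to the auto-spectrum float-for-float
    gamma = (s_xy.real**2 + s_xy.imag**2) / (s_xx * s_yy)
    return f, gamma


# -- nonlinear interdependence --------------------------------------------


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Forward delay embedding: row t is [x(t), x(t+tau), ..., x(t+(m-1)tau)]."""
    n_emb = len(x) - (m - 1) * tau
    if n_emb < 2:
        raise ComputationError("series too short for the requested embedding")
    idx = np.arange(n_emb)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _theiler_knn(sq_dist: np.ndarray, k: int, theiler: int) -> np.ndarray:
    """Indices of the k nearest neighbours per row, excluding the Theiler band."""
    n = sq_dist.shape[0]
    masked = sq_dist.copy()
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    masked[offsets <= theiler] = np.inf
    if np.isfinite(masked).sum(axis=1).min() < k:
        raise ComputationError(
            "not enough Theiler-admissible points for the requested k neighbours"
        )
    return np.argpartition(masked, k - 1, axis=1)[:, :k]


def rim(
    ts: TimeSeriesSet,
    i: int,
    j: int,
    emb: EmbeddingParams | None = None,
) -> RIMResult:
    """Nonlinear interdependence between channels i (X) and j (Y).

    Computes both conditional measures N(Y|X) and N(X|Y) on delay-embedded
    signals, with temporally adjacent points (|index - t| <= m*tau) excluded
    from the neighbour search.  Raw values can be slightly negative for
    independent signals; the :class:`RIMResult` exposes both the raw values
    and a [0, 1]-clipped synchronization value.
    """
    emb = emb or EmbeddingParams()
    n_emb = emb.n_embedded(ts.n_samples)
    if n_emb <= emb.k + 2 * emb.theiler:
        raise ComputationError(
            f"series too short for embedding: N' = {n_emb} must exceed "
            f"k + 2*m*tau = {emb.k + 2 * emb.theiler}"
        )
    ex = _embed(ts.channel(i), emb.m, emb.tau)
    ey = _embed(ts.channel(j), emb.m, emb.tau)
    dx = cdist(ex, ex, "sqeuclidean")
    dy = cdist(ey, ey, "sqeuclidean")
    nn_x = _theiler_knn(dx, emb.k, emb.theiler)
    nn_y = _theiler_knn(dy, emb.k, emb.theiler)

    def conditional(d_self: np.ndarray, nn_other: np.ndarray) -> float:
        n = d_self.shape[0]
        # mean squared distance to all other points (the self term is 0,
        # so the row sum over n-1 divisors is exact)
        r_all = d_self.sum(axis=1) / (n - 1)
        r_cond = np.take_along_axis(d_self, nn_other, axis=1).mean(axis=1)
        return float(np.mean((r_all - r_cond) / r_all))

    n_yx = conditional(dy, nn_x)  # N(Y|X)
    n_xy = conditional(dx, nn_y)  # N(X|Y)
    return RIMResult(n_yx=n_yx, n_xy=n_xy, params=emb)


def estimate_tau(
    x: np.ndarray, max_lag: int | None = None, zero_tol: float | None = None
) -> int:
    """Embedding delay: first zero crossing of the autocorrelation function.

    A finite-sample autocorrelation estimate never hits zero exactly, so the
    crossing is declared at the first lag where the estimate falls below
    ``zero_tol`` (default ``2 / sqrt(N)``, the Bartlett standard error of the
    estimate for an uncorrelated series).  Falls back to the first lag where
    the autocorrelation drops below 1/e when no crossing occurs within
    max_lag (default N // 2).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InputFormatError("estimate_tau expects a single channel")
    if np.ptp(x) == 0:
        raise ComputationError("autocorrelation undefined for a constant series")
    n = len(x)
    max_lag = max_lag or n // 2
    if zero_tol is None:
        zero_tol = 2.0 / np.sqrt(n)
    xc = x - x.mean()
    denom = float(xc @ xc)
    first_below_1e = None
    for lag in range(1, max_lag + 1):
        acf = float(xc[:-lag] @ xc[lag:]) / denom
        if acf <= zero_tol:
            return lag
        if first_below_1e is None and acf < 1.0 / np.e:
            first_below_1e = lag
    if first_below_1e is not None:
        logger.info(
            "autocorrelation has no zero crossing within %d lags; "
            "using 1/e decay lag %d", max_lag, first_below_1e,
        )
        return first_below_1e
    raise ComputationError(
        f"autocorrelation neither crosses zero nor decays below 1/e within "
        f"{max_lag} lags; choose tau manually"
    )


# -- VAR estimation and partial directed coherence -------------------------


def _fit_var_fixed(data: np.ndarray, p: int) -> VARModel:
    n_samples, n = data.shape
    if n_samples <= n * p + 1:
        raise ComputationError(
            f"need more than n*p + 1 = {n * p + 1} samples to fit VAR({p})"
        )
    x = data - data.mean(axis=0)
    # lagged design: row t-p holds [x(t-1), ..., x(t-p)] flattened
    T = n_samples - p
    X = np.empty((T, n * p))
    for r in range(1, p + 1):
        X[:, (r - 1) * n : r * n] = x[p - r : n_samples - r]
    Y = x[p:]
    rank = np.linalg.matrix_rank(X)
    if rank < n * p:
        raise ComputationError(
            "lagged design matrix is rank deficient (collinear channels?); "
            "cannot estimate VAR coefficients"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    # B has shape (n*p, n); A(r) = B[(r-1)n : rn].T
    coefs = np.stack([B[(r - 1) * n : r * n].T for r in range(1, p + 1)])
    resid = Y - X @ B
    dof = max(T - n * p, 1)
    sigma = resid.T @ resid / dof
    sigma = 0.5 * (sigma + sigma.T)
    sign, logdet = np.linalg.slogdet(sigma + 1e-300 * np.eye(n))
    aic = logdet + 2.0 * p * n * n / T
    return VARModel(
        order=p,
        coefs=coefs,
        sigma=sigma,
        nobs=T,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        aic=float(aic),
    )


def fit_var(ts: TimeSeriesSet, p: int | str = 1, p_max: int | None = None) -> VARModel:
    """Least-squares VAR fit on the lagged design (data centred first).

    ``p="aic"`` selects the order in [1, p_max] minimizing the Akaike
    criterion; p_max defaults to min(10, N // (5 n)).
    """
    data = np.asarray(ts.data, dtype=float)
    if p == "aic":
        n_samples, n = data.shape
        cap = p_max or max(1, min(10, n_samples // (5 * n)))
        fits = [_fit_var_fixed(data, order) for order in range(1, cap + 1)]
        best = min(fits, key=lambda m: m.aic)
        logger.info("AIC selected VAR order %d of max %d", best.order, cap)
        return best
    if not isinstance(p, (int, np.integer)) or p < 1:
        raise ConfigError(f"VAR order must be a positive integer or 'aic', got {p!r}")
    return _fit_var_fixed(data, int(p))


def pdc(
    model: VARModel,
    freqs: np.ndarray,
    variant: str = "standard",
) -> np.ndarray:
    """Partial directed coherence over a frequency grid.

    ``freqs`` are in cycles/sample (0 to 0.5 = Nyquist).  Returns an array of
    shape ``(len(freqs), n, n)`` whose entry ``[f, i, j]`` is the influence
    of channel j on channel i at that frequency.

    The ``standard`` variant normalizes each source column j by the root
    sum of squares, so ``sum_i pdc[f, i, j]**2 == 1``; the ``as_printed``
    variant normalizes by the un-rooted sum of squares instead.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > 0.5):
        raise ConfigError("PDC frequencies must lie in [0, 0.5] cycles/sample")
    if variant not in ("standard", "as_printed"):
        raise ConfigError(f"unknown PDC variant {variant!r}")
    p, n, _ = model.coefs.shape
    r = np.arange(1, p + 1)
    # Abar(w) = I - sum_r A(r) exp(-i 2 pi f r), per frequency
    phases = np.exp(-2j * np.pi * freqs[:, None] * r[None, :])  # (F, p)
    abar = np.eye(n)[None, :, :] - np.einsum("fr,rij->fij", phases, model.coefs)
    mag = np.abs(abar)
    col_ssq = np.sum(mag**2, axis=1, keepdims=True)  # (F, 1, n)
    if np.any(col_ssq <= 0):
        raise ComputationError("PDC denominator vanished for an entire source column")
    if variant == "standard":
        return mag / np.sqrt(col_ssq)
    return mag / col_ssq


# -- band reduction and matrix assembly ------------------------------------


def band_reduce(
    freqs: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] | None = None,
    reducer: str = "mean",
):
    """Reduce a spectral index to a scalar over a frequency band.

    ``values`` may be any array whose first axis runs over ``freqs``; the
    reduction (arithmetic mean by default, median optionally) is taken over
    the grid frequencies with ``f_lo <= f <= f_hi``.  ``band=None`` averages
    over the whole grid (broadband).
    """
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=float)
    if band is None:
        mask = np.ones(len(freqs), dtype=bool)
    else:
        f_lo, f_hi = band
        mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ComputationError(
            f"band {band} does not intersect the frequency grid "
            f"[{freqs.min():g}, {freqs.max():g}]"
        )
    if reducer == "mean":
        return values[mask].mean(axis=0)
    if reducer == "median":
        return np.median(values[mask], axis=0)
    raise ConfigError(f"unknown band reducer {reducer!r}")


def connectivity_matrix(
    ts: TimeSeriesSet,
    method: str = "msc",
    band: tuple[float, float] | None = None,
    welch: WelchParams | None = None,
    emb: EmbeddingParams | None = None,
    order: int | str = 1,
    pdc_variant: str = "standard",
    n_freqs: int = 64,
    reducer: str = "mean",
) -> ConnectivityResult:
    """Full channel-pair synchronization matrix for one method and band.

    MSC and RIM iterate the n(n-1)/2 unordered channel pairs and produce a
    symmetric matrix; PDC fits one VAR model over all channels and fills the
    ordered pairs, so the matrix may be asymmetric (entry (i, j) is the
    band-reduced influence of channel j on channel i).
    """
    n = ts.n_channels
    matrix = np.zeros((n, n))
    params: dict = {"method": method, "band": band, "fs": ts.fs, "reducer": reducer}

    if method == "msc":
        welch = welch or WelchParams()
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                f, gamma = msc(ts, i, j, welch)
                matrix[i, j] = matrix[j, i] = band_reduce(f, gamma, band, reducer)
                count += 1
        params.update(
            nperseg=welch.nperseg,
            noverlap=welch.resolved_noverlap(),
            window=welch.window,
            n_pair_evaluations=count,
        )
        directed = False
    elif method == "rim":
        emb = emb or EmbeddingParams()
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                res = rim(ts, i, j, emb)
                matrix[i, j] = matrix[j, i] = res.synchronization
                count += 1
        params.update(m=emb.m, tau=emb.tau, k=emb.k, n_pair_evaluations=count)
        directed = False
    elif method == "pdc":
        model = fit_var(ts, order)
        freqs = np.linspace(0.0, 0.5, n_freqs)
        values = pdc(model, freqs, pdc_variant)
        band_cps = None
        if band is not None:
            band_cps = (band[0] / ts.fs, band[1] / ts.fs)
        reduced = band_reduce(freqs, values, band_cps, reducer)
        matrix = reduced.copy()
        np.fill_diagonal(matrix, 0.0)
        params.update(
            order=model.order,
            variant=pdc_variant,
            n_freqs=n_freqs,
            n_pair_evaluations=n * (n - 1),
        )
        directed = True
    else:
        raise ConfigError(f"unknown connectivity method {method!r}")

    logger.info(
        "connectivity %s: %d channels, %d pair evaluations",
        method, n, params["n_pair_evaluations"],
    )
    return ConnectivityResult(
        method=method,
        matrix=matrix,
        band=band,
        directed=directed,
        labels=ts.labels,
        params=params,
    )
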