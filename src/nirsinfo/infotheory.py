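"""Continuous-variable information estimators and the transfer-entropy lag scan.

Two estimator families are provided, selected by ``EstimatorConfig.method``:

``gaussian``
    Closed forms on the sample covariance: ``H = 1/2 ln((2*pi*e)^d det S)``,
    mutual information and conditional mutual information as log-ratios of
    conditional variances.  Exact for Gaussian data given its covariance, and
    used as the oracle family in tests.

``ksg``
    Nonparametric k-nearest-neighbour estimators with the Chebyshev metric:
    Kozachenko-Leonenko for differential entropy, Kraskov-Stoegbauer-
    Grassberger algorithm 1 for mutual information, and the Frenzel-Pompe
    construction for conditional mutual information (hence transfer entropy).
    A tiny seeded jitter (1e-8 of each variable's standard deviation by
    default) breaks ties, the standard precaution for data with repeated
    values.

All quantities are reported in nats.  Differential entropies may be
negative; slightly negative mutual-information or transfer-entropy estimates
are reported as-is with a flag rather than clamped, so downstream
comparisons of before/after attenuation remain unbiased.

Transfer entropy follows the convention that lag ``L`` means the source
sample ``y[t+1-L]`` predicts the target's next state ``x[t+1]`` given the
target's own history ``x[t], ..., x[t-m+1]``:

    T(Y -> X; L) = I(y[t+1-L]; x[t+1] | x[t], ..., x[t-m+1])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .config import EstimatorConfig

__all__ = [
    "InfoQuantity",
    "LagScan",
    "EstimatorError",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "transfer_entropy",
    "scan_lags",
    "grand_average_lag",
]

_DEFAULT_JITTER = 1e-8
#: KSG accuracy degrades quickly with dimension; warn above this.
_KSG_DIM_GUARD = 3


class EstimatorError(ValueError):
    """Raised for degenerate estimator input (singular covariance, ties...)."""


@dataclass
class InfoQuantity:
    """One estimated information quantity, in nats."""

    value: float
    estimator: str
    n_samples: int
    parameters: dict = field(default_factory=dict)
    #: set when a non-negative quantity (MI/TE) was estimated slightly below 0
    nonneg_violation: bool = False

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class LagScan:
    """Transfer entropy over a lag grid; argmax ties break to the smallest lag."""

    lags: np.ndarray
    te_values: np.ndarray
    argmax_lag: int

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=int)
        self.te_values = np.asarray(self.te_values, dtype=float)
        if len(self.lags) != len(self.te_values):
            raise EstimatorError("lags and te_values lengths differ")
        if self.argmax_lag not in self.lags:
            raise EstimatorError("argmax_lag not on the lag grid")


# ---------------------------------------------------------------------------
# helpers

def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise EstimatorError("samples must be a vector or a samples x dims matrix")
    return x


def _check_n(*arrays, minimum=10):
    n = len(arrays[0])
    for a in arrays[1:]:
        if len(a) != n:
            raise EstimatorError(f"sample lengths differ: {n} vs {len(a)}")
    if n < minimum:
        raise EstimatorError(f"need at least {minimum} samples, got {n}")
    return n


def _jitter(x: np.ndarray, cfg: EstimatorConfig, rng) -> np.ndarray:
    scale = _DEFAULT_JITTER if cfg.jitter_sd is None else cfg.jitter_sd
    if scale == 0:
        return x
    rng = np.random.default_rng(0) if rng is None else rng
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x + rng.normal(0.0, scale, size=x.shape) * sd


def _cov(X: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.cov(X.T, ddof=1))


def _logdet(S: np.ndarray, what: str) -> float:
    sign, ld = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(ld):
        raise EstimatorError(
            f"singular sample covariance in {what}; variables are (nearly) "
            "linearly dependent — consider the ksg method with jitter"
        )
    return ld


# ---------------------------------------------------------------------------
# gaussian family

def _h_gauss(X: np.ndarray) -> float:
    d = X.shape[1]
    return 0.5 * (d * np.log(2 * np.pi * np.e) + _logdet(_cov(X), "entropy"))


def _cmi_gauss(s, t, z) -> float:
    # I(s;t|z) = 1/2 ln( det S_sz det S_tz / (det S_z det S_stz) )
    def ld(*blocks):
        return _logdet(_cov(np.hstack(blocks)), "conditional MI")

    return 0.5 * (ld(s, z) + ld(t, z) - ld(z) - ld(s, t, z))


# ---------------------------------------------------------------------------
# ksg family

def _knn_radius(X: np.ndarray, k: int) -> np.ndarray:
    n = len(X)
    if k >= n:
        raise EstimatorError(f"k_neighbors={k} must be below n_samples={n}")
    tree = cKDTree(X)
    dist, _ = tree.query(X, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    if np.any(eps == 0):
        raise EstimatorError(
            "duplicate points saturate the k-NN search even after jitter; "
            "increase jitter_sd"
        )
    return eps


def _count_within(X: np.ndarray, radii: np.ndarray) -> np.ndarray:
    # strictly-less-than counts, excluding the point itself
    tree = cKDTree(X)
    r = np.nextafter(radii, 0)
    return tree.query_ball_point(X, r=r, p=np.inf, return_length=True) - 1


def _h_kl(X: np.ndarray, k: int) -> float:
    n, d = X.shape
    if d > _KSG_DIM_GUARD:
        warnings.warn(
            f"Kozachenko-Leonenko entropy in {d} dimensions is unreliable",
            stacklevel=3,
        )
    eps = _knn_radius(X, k)
    return float(digamma(n) - digamma(k) + d * np.mean(np.log(2 * eps)))


def _mi_ksg(x: np.ndarray, y: np.ndarray, k: int) -> float:
    n = len(x)
    eps = _knn_radius(np.hstack([x, y]), k)
    n_x = _count_within(x, eps)
    n_y = _count_within(y, eps)
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
    )


def _cmi_ksg(s: np.ndarray, t: np.ndarray, z: np.ndarray, k: int) -> float:
    eps = _knn_radius(np.hstack([s, t, z]), k)
    n_sz = _count_within(np.hstack([s, z]), eps)
    n_tz = _count_within(np.hstack([t, z]), eps)
    n_z = _count_within(z, eps)
    return float(
        digamma(k)
        - np.mean(digamma(n_sz + 1) + digamma(n_tz + 1) - digamma(n_z + 1))
    )


# ---------------------------------------------------------------------------
# public operations

def _make(value, cfg, n, *, nonneg=False, **params) -> InfoQuantity:
    return InfoQuantity(
        value=float(value),
        estimator=cfg.method,
        n_samples=int(n),
        parameters=params,
        nonneg_violation=bool(nonneg and value < 0),
    )


def entropy(x, cfg: EstimatorConfig | None = None, rng=None) -> InfoQuantity:
    """Differential entropy H(x) of a vector or low-dimensional matrix."""
    cfg = cfg or EstimatorConfig()
    X = _as_matrix(x)
    n = _check_n(X)
    if cfg.method == "gaussian":
        value = _h_gauss(X)
    else:
        value = _h_kl(_jitter(X, cfg, rng), cfg.k_neighbors)
    return _make(value, cfg, n, k=cfg.k_neighbors if cfg.method == "ksg" else None)


def conditional_entropy(x, y, cfg=None, rng=None) -> InfoQuantity:
    """H(X|Y) = H(X, Y) - H(Y), both terms from the same estimator family."""
    cfg = cfg or EstimatorConfig()
    X, Y = _as_matrix(x), _as_matrix(y)
    n = _check_n(X, Y)
    if cfg.method == "gaussian":
        value = _h_gauss(np.hstack([X, Y])) - _h_gauss(Y)
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        Xj, Yj = _jitter(X, cfg, rng), _jitter(Y, cfg, rng)
        value = _h_kl(np.hstack([Xj, Yj]), cfg.k_neighbors) - _h_kl(
            Yj, cfg.k_neighbors
        )
    return _make(value, cfg, n)


def mutual_information(x, y, cfg=None, rng=None) -> InfoQuantity:
    """I(X;Y): Kraskov algorithm 1 (ksg) or the covariance closed form."""
    cfg = cfg or EstimatorConfig()
    X, Y = _as_matrix(x), _as_matrix(y)
    n = _check_n(X, Y)
    if cfg.method == "gaussian":
        if X.shape[1] == 1 and Y.shape[1] == 1:
            rho = np.corrcoef(X[:, 0], Y[:, 0])[0, 1]
            if abs(rho) >= 1.0 - 1e-15:
                raise EstimatorError(
                    "|correlation| = 1 makes Gaussian MI diverge; add jitter "
                    "or use the ksg method"
                )
            value = -0.5 * np.log1p(-rho**2)
        else:
            value = (
                _h_gauss(X) + _h_gauss(Y) - _h_gauss(np.hstack([X, Y]))
            )
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        value = _mi_ksg(
            _jitter(X, cfg, rng), _jitter(Y, cfg, rng), cfg.k_neighbors
        )
    return _make(value, cfg, n, nonneg=True)


def conditional_mutual_information(s, t, z, cfg=None, rng=None) -> InfoQuantity:
    """I(s;t|z) via Frenzel-Pompe (ksg) or Gaussian conditional variances."""
    cfg = cfg or EstimatorConfig()
    S, T, Z = _as_matrix(s), _as_matrix(t), _as_matrix(z)
    n = _check_n(S, T, Z)
    if cfg.method == "gaussian":
        value = _cmi_gauss(S, T, Z)
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        value = _cmi_ksg(
            _jitter(S, cfg, rng),
            _jitter(T, cfg, rng),
            _jitter(Z, cfg, rng),
            cfg.k_neighbors,
        )
    return _make(value, cfg, n, nonneg=True)


def _te_embed(source, target, lag: int, cfg: EstimatorConfig):
    x = np.asarray(target, dtype=float).ravel()
    y = np.asarray(source, dtype=float).ravel()
    _check_n(x, y, minimum=3)
    n = len(x)
    m, l = cfg.target_history, cfg.source_history
    if lag < 1:
        raise EstimatorError(f"lag must be >= 1, got {lag}")
    if lag >= n - 2:
        raise EstimatorError(f"lag {lag} too large for series of length {n}")
    # next-state index t+1 runs over [t0+1, n); all embeddings must fit
    t0 = max(m - 1, lag + l - 2)
    idx = np.arange(t0 + 1, n)
    if len(idx) < 10 + cfg.k_neighbors:
        raise EstimatorError(
            f"series too short for lag {lag} with histories ({m}, {l})"
        )
    tgt = x[idx][:, None]
    cond = np.column_stack([x[idx - 1 - j] for j in range(m)])
    src = np.column_stack([y[idx - lag - j] for j in range(l)])
    return src, tgt, cond


def transfer_entropy(source, target, lag: int, cfg=None, rng=None) -> InfoQuantity:
    """T(source -> target) at the given lag, as a conditional MI."""
    cfg = cfg or EstimatorConfig()
    src, tgt, cond = _te_embed(source, target, lag, cfg)
    q = conditional_mutual_information(src, tgt, cond, cfg, rng)
    q.parameters.update(
        lag=lag,
        target_history=cfg.target_history,
        source_history=cfg.source_history,
    )
    return q


def scan_lags(source, target, cfg=None, rng=None) -> LagScan:
    """Transfer entropy at every lag in [lag_min, lag_max].

    The same jitter realisation is reused across lags so the scan is a
    deterministic function of (data, cfg, rng state at entry).
    """
    cfg = cfg or EstimatorConfig()
    if cfg.lag_max + 2 >= len(np.asarray(target).ravel()):
        raise EstimatorError("lag_max too large for this series")
    rng = np.random.default_rng(0) if rng is None else rng
    lags = np.arange(cfg.lag_min, cfg.lag_max + 1)
    values = np.array(
        [transfer_entropy(source, target, int(L), cfg, rng).value for L in lags]
    )
    best = int(lags[int(np.argmax(values))])  # argmax returns first == smallest lag
    return LagScan(lags=lags, te_values=values, argmax_lag=best)


def grand_average_lag(scans: list[LagScan]) -> int:
    """Argmax of the mean transfer-entropy curve across scans.

    This single study-level lag is used for every subsequent criterion
    evaluation; ties break to the smallest lag.
    """
    if not scans:
        raise EstimatorError("no scans given")
    grid = scans[0].lags
    for s in scans[1:]:
        if not np.array_equal(s.lags, grid):
            raise EstimatorError("lag grids differ across scans")
    mean_curve = np.mean([s.te_values for s in scans], axis=0)
    return int(grid[int(np.argmax(mean_curve))])
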