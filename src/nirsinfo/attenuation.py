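"""Skin-blood-flow attenuation: resting-baseline PCA filtering and ICA removal.

Two algorithms from the comparative literature on scalp-hemodynamics
removal:

* **PCA spatial filtering** (Zhang-style): channel-space eigenvectors are
  computed from the covariance of the column-centred resting prefix; the
  task rows are projected onto the orthogonal complement of the first *r*
  eigenvectors (*r* in {1, 2, 3}).  Because scalp hemodynamics are more
  global than cortical activity, the leading resting eigenvector captures
  the common-mode interference.

* **ICA uniform-component removal** (Kohno-style): the full multichannel
  series is decomposed into as many independent components as channels
  (symmetric FastICA, log-cosh contrast); the component whose mixing
  weights are most spatially uniform — highest coefficient of spatial
  uniformity, |mean(weights)| / sd(weights) — is subtracted from every
  channel.

The pipeline orderings of the source methods are honoured by
:func:`attenuate`: preprocess-then-filter for PCA, filter-raw-then-
preprocess for ICA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .config import AttenuationConfig, ConfigError, PreprocessConfig, rng_for
from .io import Recording, SBFTrace
from .preprocess import preprocess_trace, run_pipeline

__all__ = [
    "AttenuationResult",
    "AttenuationError",
    "pca_spatial_filter",
    "ica_uniform_removal",
    "attenuate",
]


class AttenuationError(ValueError):
    """Raised for degenerate attenuation input (rank deficiency etc.)."""


@dataclass
class AttenuationResult:
    """Filtered recording plus removed-component diagnostics.

    ``filtered`` always has the same shape, sampling rate and resting-prefix
    length as the input.  For PCA, ``removed_spatial_vectors`` are the
    removed eigenvectors (unit norm, mutually orthogonal) and
    ``variance_explained`` the per-eigenvector fraction of total resting
    variance, reported for *all* eigenvectors.  For ICA, ``csu_scores``
    holds the spatial-uniformity score of every component,
    ``selected_component`` the removed one, ``removed_timecourse`` its
    source signal and ``attributed_channel`` the channel with the largest
    absolute mixing weight on it.
    """

    filtered: Recording
    algorithm: str
    removed_spatial_vectors: list = field(default_factory=list)
    variance_explained: np.ndarray | None = None
    csu_scores: np.ndarray | None = None
    selected_component: int | None = None
    attributed_channel: int | None = None
    removed_timecourse: np.ndarray | None = None
    #: for attenuate(): the input recording run through the same
    #: preprocessing as `filtered`, for like-for-like criterion evaluation
    reference: Recording | None = None
    sbf_processed: SBFTrace | None = None
    diagnostics: dict = field(default_factory=dict)


def _rest_eigendecomposition(rec: Recording, normalize_variance: bool):
    if rec.n_channels < 2:
        raise AttenuationError("PCA spatial filtering needs >= 2 channels")
    if rec.rest_len < rec.n_channels + 2:
        raise AttenuationError(
            f"resting prefix ({rec.rest_len}) too short for "
            f"{rec.n_channels}-channel covariance"
        )
    rest = rec.rest - rec.rest.mean(axis=0)
    if normalize_variance:
        sd = rest.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise AttenuationError("constant resting channel cannot be normalised")
        rest = rest / sd
    cov = np.cov(rest.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-15 * max(evals[0], 1e-300):
        corr = np.corrcoef(rest.T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise AttenuationError(
            "rank-deficient resting covariance; channels "
            f"{rec.channel_labels[i]!r} and {rec.channel_labels[j]!r} are "
            "collinear"
        )
    # deterministic sign: largest-magnitude element of each vector positive
    for c in range(evecs.shape[1]):
        piv = np.argmax(np.abs(evecs[:, c]))
        if evecs[piv, c] < 0:
            evecs[:, c] = -evecs[:, c]
    return evals, evecs


def pca_spatial_filter(
    rec: Recording,
    components=(1, 2),
    normalize_baseline_variance: bool = False,
) -> AttenuationResult:
    """Remove the first *r* resting-baseline eigenvectors from the task rows.

    ``components`` is a prefix set {1}, {1, 2} or {1, 2, 3} (the empty set
    is allowed and gives the identity, exposed for testing).  The resting
    prefix is carried through unmodified — it exists to fit the filter, not
    to be analysed.
    """
    components = tuple(int(c) for c in components)
    if components and (
        components != tuple(range(1, len(components) + 1)) or len(components) > 3
    ):
        raise ConfigError(
            "component set must be a prefix {1},{1,2},{1,2,3}; "
            f"got {set(components)}"
        )
    evals, evecs = _rest_eigendecomposition(rec, normalize_baseline_variance)
    r = len(components)
    U = evecs[:, :r]
    out = rec.data.copy()
    if r:
        proj = rec.task @ U
        out[rec.rest_len :] = rec.task - proj @ U.T
    return AttenuationResult(
        filtered=rec.replace(data=out),
        algorithm="pca",
        removed_spatial_vectors=[U[:, i].copy() for i in range(r)],
        variance_explained=evals / evals.sum(),
        diagnostics={"eigenvalues": evals, "eigenvectors": evecs},
    )


def _csu(weights: np.ndarray, mode: str) -> float:
    sd = weights.std(ddof=1)
    mean = abs(weights.mean())
    if mode == "inverse_cv":
        return np.inf if sd == 0 else mean / sd
    # literal |coefficient of variation| reading, selectable for comparison
    return np.inf if mean == 0 else sd / mean


def ica_uniform_removal(
    rec: Recording,
    seed: int = 0,
    csu_mode: str = "inverse_cv",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> AttenuationResult:
    """Subtract the most spatially uniform independent component.

    The full series (rest and task) is decomposed into ``n_channels``
    components with symmetric fixed-point ICA (log-cosh contrast, whitening
    included).  For each component *j* with mixing weights ``a_j`` across
    channels, the coefficient of spatial uniformity is
    ``|mean(a_j)| / sd(a_j)``; the maximiser's contribution
    ``a_j s_j(t)`` is removed from every channel.  Non-convergence within
    ``max_iter`` iterations is recorded in ``diagnostics`` rather than
    raised: exactly-Gaussian sources never satisfy the fixed-point
    tolerance, yet the decomposition they yield is the one this algorithm
    family uses in practice.
    """
    if rec.n_channels < 2:
        raise AttenuationError("ICA removal needs >= 2 channels")
    if rec.n_samples < 10 * rec.n_channels:
        raise AttenuationError(
            f"need >= {10 * rec.n_channels} samples for "
            f"{rec.n_channels}-channel ICA, got {rec.n_samples}"
        )
    ica = FastICA(
        n_components=rec.n_channels,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(rec.data)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=rec.n_channels,
                    algorithm="parallel",
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=int(seed) % (2**31),
                )
                sources = ica.fit_transform(rec.data)
        except Exception as exc:  # numerical failure inside the solver
            raise AttenuationError(f"ICA decomposition failed: {exc}") from exc
    mixing = ica.mixing_  # channels x components
    csu = np.array([_csu(mixing[:, j], csu_mode) for j in range(mixing.shape[1])])
    selected = int(np.argmax(csu))
    contribution = np.outer(sources[:, selected], mixing[:, selected])
    return AttenuationResult(
        filtered=rec.replace(data=rec.data - contribution),
        algorithm="ica",
        csu_scores=csu,
        selected_component=selected,
        attributed_channel=int(np.argmax(np.abs(mixing[:, selected]))),
        removed_timecourse=sources[:, selected].copy(),
        diagnostics={
            "mixing": mixing,
            "sources": sources,
            "converged": converged,
            "n_iter": int(ica.n_iter_),
        },
    )


def attenuate(
    rec: Recording,
    sbf: SBFTrace | None = None,
    atten_cfg: AttenuationConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    seed: int = 0,
) -> AttenuationResult:
    """Run one attenuation setting with its conventional pipeline ordering.

    PCA filters the *preprocessed* series; ICA filters the raw series and
    preprocesses afterwards.  The result carries both the fully processed
    filtered recording and the identically preprocessed unfiltered
    recording (``reference``), plus the preprocessed SBF trace when one is
    supplied, so criterion differences downstream reflect attenuation only.
    """
    atten_cfg = atten_cfg or AttenuationConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    reference = run_pipeline(rec, pre_cfg)
    if atten_cfg.algorithm == "pca":
        res = pca_spatial_filter(
            reference,
            atten_cfg.components,
            atten_cfg.normalize_baseline_variance,
        )
    elif atten_cfg.algorithm == "ica":
        ica_seed = int(rng_for(seed, "ica").integers(2**31))
        raw = ica_uniform_removal(
            rec,
            seed=ica_seed,
            csu_mode=atten_cfg.csu_mode,
            max_iter=atten_cfg.max_iter,
            tol=atten_cfg.tol,
        )
        res = raw
        res.filtered = run_pipeline(raw.filtered, pre_cfg)
    else:  # pragma: no cover - AttenuationConfig already validates
        raise ConfigError(f"unknown algorithm {atten_cfg.algorithm!r}")
    res.reference = reference
    if sbf is not None:
        res.sbf_processed = preprocess_trace(sbf, rec.rest_len, pre_cfg)
    res.diagnostics["pipeline_order"] = (
        ("preprocess", "pca") if atten_cfg.algorithm == "pca" else ("ica", "preprocess")
    )
    res.diagnostics["preprocess_steps"] = tuple(
        res.filtered.meta.get("steps", ())
    )
    return res
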