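"""The information-preservation criteria for an (X, X', Y) triple.

For a recording X before attenuation, X' after, and the interfering
skin-blood-flow trace Y, five inequalities separate "the attenuation
reduced the interference" from "the attenuation preserved the cortical
signal" (all quantities in nats, at one study-level lag):

    c1:  T(Y -> X') <= T(Y -> X)        interference transfer reduced
    c2:  H(Y | X)   <= H(Y | X')        X' tells less about Y
    c3:  H(X | Y)   <= H(X' | Y)        Y tells less about X'
    c4:  H(X | X')  <= H(X | Y)         X' explains X better than Y does
    c5:  H(X | X')  <= H(X')            preservation margin non-negative

c1-c3 are necessary-and-sufficient conditions for interference reduction;
c4 guards against "attenuation" that simply replaces the signal with the
interferer; the c5 margin H(X') - H(X|X') is the study-level preservation
score compared across attenuation settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EstimatorConfig
from .infotheory import (
    conditional_entropy,
    entropy,
    transfer_entropy,
)
from .io import Recording, SBFTrace

__all__ = ["InfoReport", "evaluate_recording", "evaluate_channels", "c5_margin"]


@dataclass
class InfoReport:
    """All eight information quantities and the five criterion outcomes."""

    lag_used: int
    te_before: float
    te_after: float
    h_y_given_x: float
    h_y_given_xp: float
    h_x_given_y: float
    h_xp_given_y: float
    h_x_given_xp: float
    h_xp: float
    criteria_flags: dict = field(init=False)
    c5_margin: float = field(init=False)
    channel: int | None = None
    estimator: str | None = None
    n_samples: int | None = None

    def __post_init__(self):
        self.criteria_flags = {
            "c1": self.te_after <= self.te_before,
            "c2": self.h_y_given_x <= self.h_y_given_xp,
            "c3": self.h_x_given_y <= self.h_xp_given_y,
            "c4": self.h_x_given_xp <= self.h_x_given_y,
            "c5": self.h_x_given_xp <= self.h_xp,
        }
        self.c5_margin = self.h_xp - self.h_x_given_xp

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "lag_used",
                "te_before",
                "te_after",
                "h_y_given_x",
                "h_y_given_xp",
                "h_x_given_y",
                "h_xp_given_y",
                "h_x_given_xp",
                "h_xp",
                "c5_margin",
                "channel",
                "estimator",
                "n_samples",
            )
        }
        d.update(self.criteria_flags)
        return d


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def evaluate_recording(
    x,
    xp,
    y,
    lag: int,
    cfg: EstimatorConfig | None = None,
    rng=None,
    standardize: bool = True,
) -> InfoReport:
    """Evaluate all five criteria for one channel triple at one lag.

    ``x``, ``xp`` and ``y`` are equal-length sample vectors (task portion
    only; the resting prefix is reserved for filter fitting).  Every
    quantity is computed with the same estimator configuration so the
    criterion comparisons are like-for-like.

    By default each series is z-scored first (``standardize=True``).
    Mutual information and transfer entropy are invariant to this, but the
    conditional entropies are not: attenuation shrinks signal amplitude,
    and in raw units that amplitude change — not the change in dependence
    structure — would dominate every entropy comparison.  Standardised
    units make the criteria compare information content; they also match
    the default normalisation of the JIDT estimators this field commonly
    uses.
    """
    cfg = cfg or EstimatorConfig()
    x = np.asarray(x, dtype=float).ravel()
    xp = np.asarray(xp, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not len(x) == len(xp) == len(y):
        raise ValueError(
            f"length mismatch: x={len(x)}, xp={len(xp)}, y={len(y)}"
        )
    if standardize:
        x, xp, y = _zscore(x), _zscore(xp), _zscore(y)
    rng = np.random.default_rng(0) if rng is None else rng
    report = InfoReport(
        lag_used=int(lag),
        te_before=transfer_entropy(y, x, lag, cfg, rng).value,
        te_after=transfer_entropy(y, xp, lag, cfg, rng).value,
        h_y_given_x=conditional_entropy(y, x, cfg, rng).value,
        h_y_given_xp=conditional_entropy(y, xp, cfg, rng).value,
        h_x_given_y=conditional_entropy(x, y, cfg, rng).value,
        h_xp_given_y=conditional_entropy(xp, y, cfg, rng).value,
        h_x_given_xp=conditional_entropy(x, xp, cfg, rng).value,
        h_xp=entropy(xp, cfg, rng).value,
    )
    report.estimator = cfg.method
    report.n_samples = len(x)
    return report


def evaluate_channels(
    rec: Recording,
    rec_after: Recording,
    y: SBFTrace,
    lag: int,
    cfg: EstimatorConfig | None = None,
    analysis_channels=(0,),
    rng=None,
) -> list[InfoReport]:
    """One :class:`InfoReport` per selected channel, task portion only."""
    channels = tuple(analysis_channels)
    if not channels:
        raise ValueError("analysis channel set is empty")
    for c in channels:
        if not 0 <= c < rec.n_channels:
            raise ValueError(
                f"channel index {c} outside [0, {rec.n_channels})"
            )
    if rec.data.shape != rec_after.data.shape:
        raise ValueError("before/after recordings differ in shape")
    y_task = y.values[rec.rest_len :]
    reports = []
    for c in channels:
        rep = evaluate_recording(
            rec.task[:, c], rec_after.task[:, c], y_task, lag, cfg, rng
        )
        rep.channel = int(c)
        reports.append(rep)
    return reports


def c5_margin(report: InfoReport) -> float:
    """Preservation score H(X') - H(X|X') of a report."""
    return float(report.c5_margin)
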