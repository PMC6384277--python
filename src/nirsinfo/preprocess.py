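"""Signal conditioning: baseline normalisation, zero-phase band-pass, detrend.

The chain mirrors standard fNIRS practice: subtract the mean of the resting
prefix per channel, apply a first-order Butterworth band-pass (0.01-0.6 Hz)
forward and backward for zero phase, then remove a least-squares line.  All
steps preserve shape, sampling rate and resting-prefix length, and the
applied steps are recorded in the output recording's ``meta`` so pipeline
orderings can be audited downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .config import ConfigError, PreprocessConfig
from .io import Recording, SBFTrace

__all__ = [
    "baseline_normalize",
    "bandpass",
    "detrend_linear",
    "run_pipeline",
    "preprocess_trace",
]


def _with_step(rec: Recording, data: np.ndarray, step: str) -> Recording:
    meta = dict(rec.meta)
    meta["steps"] = tuple(meta.get("steps", ())) + (step,)
    return rec.replace(data=data, meta=meta)


def baseline_normalize(rec: Recording) -> Recording:
    """Subtract each channel's resting-prefix mean from the whole series."""
    if rec.rest_len < 2:
        raise ValueError(
            f"baseline normalisation needs rest_len >= 2, got {rec.rest_len}"
        )
    baseline = rec.rest.mean(axis=0)
    return _with_step(rec, rec.data - baseline, "baseline")


def _settle_len(cfg: PreprocessConfig, fs: float) -> int:
    # dominant time constant of the band-pass is set by the low edge
    return int(np.ceil(fs / (2.0 * np.pi * cfg.band_low)))


def _design(cfg: PreprocessConfig, fs: float):
    if not 0 < cfg.band_low < cfg.band_high < fs / 2:
        raise ValueError(
            f"band edges ({cfg.band_low}, {cfg.band_high}) Hz outside (0, {fs / 2})"
        )
    return _signal.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high], btype="band", fs=fs
    )


def bandpass(
    rec: Recording, cfg: PreprocessConfig | None = None, zero_phase: bool = True
) -> Recording:
    """Band-pass filter every channel.

    By default the filter runs forward and backward (``filtfilt``) so the
    output is zero-phase and transfer-entropy lag semantics are not shifted;
    ``zero_phase=False`` gives the causal single pass.  Edges are handled by
    reflect-padding with three dominant time constants of the low band edge.
    """
    cfg = cfg or PreprocessConfig()
    b, a = _design(cfg, rec.fs)
    n = rec.n_samples
    if zero_phase:
        padlen = min(3 * _settle_len(cfg, rec.fs), n - 1)
        out = _signal.filtfilt(b, a, rec.data, axis=0, padtype="even", padlen=padlen)
    else:
        out = _signal.lfilter(b, a, rec.data, axis=0)
    return _with_step(rec, out, "bandpass")


def detrend_linear(rec: Recording) -> Recording:
    """Remove the full-series least-squares line from every channel."""
    if rec.n_samples < 3:
        raise ValueError(f"detrend needs >= 3 samples, got {rec.n_samples}")
    out = _signal.detrend(rec.data, axis=0, type="linear")
    return _with_step(rec, out, "detrend")


_STEP_FUNCS = {
    "baseline": baseline_normalize,
    "bandpass": bandpass,
    "detrend": detrend_linear,
}


def run_pipeline(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply the configured steps in order; the order is recorded in meta."""
    cfg = cfg or PreprocessConfig()
    if not cfg.steps:
        raise ConfigError("preprocessing pipeline has no steps")
    out = rec
    for step in cfg.steps:
        if step not in _STEP_FUNCS:
            raise ConfigError(f"unknown preprocessing step {step!r}")
        out = bandpass(out, cfg) if step == "bandpass" else _STEP_FUNCS[step](out)
    return out


def preprocess_trace(
    trace: SBFTrace, rest_len: int, cfg: PreprocessConfig | None = None
) -> SBFTrace:
    """Run the same chain over a scalar trace (wrapped as a one-channel
    recording) so the interfering process is conditioned identically."""
    rec = Recording(
        data=trace.values[:, None],
        fs=trace.fs,
        channel_labels=["sbf"],
        rest_len=rest_len,
    )
    return SBFTrace(values=run_pipeline(rec, cfg).data[:, 0], fs=trace.fs)
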