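"""Fiber-photometry preprocessing, transient quantification, and amplitude model.

Pipeline: Butterworth high-pass detrending of both channels (470 nm signal
and 405 nm isosbestic), 200 ms moving-average denoising, regression-based
scaling of the isosbestic onto the signal channel and subtraction (motion
correction), then conversion to ΔF/F0 with a centered 10 s moving-mean
baseline. Detrending is applied with the channel's DC level restored
afterwards, so F0 stays in raw fluorescence units and ΔF/F0 is a meaningful
fractional change.

Per-reward transient amplitude is peak minus local baseline within a 0.5 s
post-reward window, and the amplitudes are modeled with a linear
mixed-effects model

    amplitude ~ z(log NRI) + context + z(log IRI),  random intercept ~ session

where NRI is the entry-to-reward interval and IRI the inter-reward interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

log = logging.getLogger(__name__)

__all__ = [
    "PhotometryTrace",
    "RewardTransient",
    "AmplitudeModelFit",
    "preprocess_trace",
    "quantify_transient",
    "quantify_session",
    "fit_amplitude_model",
]


@dataclass
class PhotometryTrace:
    """Two-channel sampled fluorescence plus derived corrected and ΔF/F0 traces."""

    time: np.ndarray
    raw_470: np.ndarray
    raw_405: np.ndarray
    sampling_rate: float
    session_id: str = "session"
    corrected: np.ndarray | None = None
    dff: np.ndarray | None = None
    edge_mask: np.ndarray | None = None  # True where the F0 window is truncated

    def __post_init__(self):
        if not (len(self.time) == len(self.raw_470) == len(self.raw_405)):
            raise ValueError("all channels must have the same length")


@dataclass(frozen=True)
class RewardTransient:
    """Quantified dopamine transient for one reward."""

    reward_time: float
    nri: float
    iri: float
    context: str
    peak_value: float
    baseline_value: float
    amplitude: float


@dataclass(frozen=True)
class AmplitudeModelFit:
    """Fixed effects of the amplitude model with 95% CIs.

    ``method`` is "mixedlm" normally, "ols" when the mixed fit is singular or
    fails to converge (random-intercept variance is then NaN).
    """

    beta_log_nri: float
    beta_context_low: float
    beta_log_iri: float
    ci_log_nri: tuple
    ci_context_low: tuple
    ci_log_iri: tuple
    random_intercept_var: float
    n_observations: int
    method: str


def _moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return x.copy()
    return uniform_filter1d(x, size=window_samples, mode="nearest")


def preprocess_trace(
    raw: PhotometryTrace,
    highpass_cutoff: float = 0.01,
    ma_window: float = 0.2,
    baseline_window: float = 10.0,
    filter_order: int = 2,
    f0_floor: float = 1e-6,
) -> PhotometryTrace:
    """Detrend, denoise, motion-correct, and normalize a two-channel trace.

    Order of operations: zero-phase Butterworth high-pass on both channels
    (each channel's mean is added back so fluorescence stays on its raw
    scale), moving-average denoising of both, OLS scaling of the isosbestic
    onto the signal channel and subtraction, then ΔF/F0 where ΔF is the
    corrected trace and F0 is the centered ``baseline_window`` moving mean of
    the processed 470 channel. Deterministic.
    """
    fs = raw.sampling_rate
    n = len(raw.time)
    if n <= baseline_window * fs:
        raise ValueError("trace shorter than the baseline window")

    sos = butter(filter_order, highpass_cutoff, btype="high", fs=fs, output="sos")
    f470 = sosfiltfilt(sos, raw.raw_470) + raw.raw_470.mean()
    f405 = sosfiltfilt(sos, raw.raw_405) + raw.raw_405.mean()

    w = max(1, int(round(ma_window * fs)))
    f470 = _moving_average(f470, w)
    f405 = _moving_average(f405, w)

    design = np.column_stack([np.ones(n), f405])
    beta, *_ = np.linalg.lstsq(design, f470, rcond=None)
    corrected = f470 - design @ beta

    bw = max(1, int(round(baseline_window * fs)))
    f0 = _moving_average(f470, bw)
    if np.any(f0 <= 0):
        log.warning("F0 <= 0 at %d samples; flooring at %g", int((f0 <= 0).sum()), f0_floor)
        f0 = np.maximum(f0, f0_floor)
    dff = corrected / f0

    half = bw // 2
    edge = np.zeros(n, dtype=bool)
    edge[:half] = True
    edge[n - half :] = True
    return replace(raw, corrected=corrected, dff=dff, edge_mask=edge)


def quantify_transient(
    trace: PhotometryTrace,
    reward_time: float,
    nri: float = math.nan,
    iri: float = math.nan,
    context: str = "",
    window: float = 0.5,
) -> RewardTransient | None:
    """Peak-minus-baseline transient amplitude for one reward.

    Peak = maximum ΔF/F0 in the ``window`` after the reward; baseline =
    minimum ΔF/F0 after the reward but before the peak (equal to the peak,
    hence amplitude 0, when the peak is the first post-reward sample).
    Returns None when fewer than ``window`` seconds of trailing data exist.
    """
    if trace.dff is None:
        raise ValueError("trace has no dff; run preprocess_trace first")
    fs = trace.sampling_rate
    i0 = int(np.floor(reward_time * fs)) + 1  # first sample strictly after reward
    i1 = int(np.floor((reward_time + window) * fs)) + 1
    if i1 > len(trace.dff) or i0 >= len(trace.dff):
        return None
    seg = trace.dff[i0:i1]
    ipk = int(np.argmax(seg))
    peak = float(seg[ipk])
    baseline = peak if ipk == 0 else float(seg[:ipk].min())
    return RewardTransient(
        reward_time=reward_time, nri=nri, iri=iri, context=context,
        peak_value=peak, baseline_value=baseline, amplitude=peak - baseline,
    )


def quantify_session(trace: PhotometryTrace, events, window: float = 0.5) -> pd.DataFrame:
    """Quantify every patch-reward transient of a session.

    Rewards without sufficient trailing data are dropped. Returns a frame
    with reward covariates (NRI, IRI, context) and the measured amplitude.
    """
    from .synthetic_data import patch_reward_covariates

    cov = patch_reward_covariates(events)
    rows = []
    for r in cov.itertuples(index=False):
        tr = quantify_transient(trace, r.reward_time, r.nri, r.iri, r.context, window)
        if tr is None:
            continue
        rows.append(
            dict(session=trace.session_id, reward_time=r.reward_time, nri=r.nri,
                 iri=r.iri, context=r.context, peak=tr.peak_value,
                 baseline=tr.baseline_value, amplitude=tr.amplitude)
        )
    return pd.DataFrame(
        rows,
        columns=["session", "reward_time", "nri", "iri", "context",
                 "peak", "baseline", "amplitude"],
    )


def fit_amplitude_model(transients: pd.DataFrame, min_observations: int = 50) -> AmplitudeModelFit:
    """Mixed-effects model of transient amplitude on reward-timing covariates.

    amplitude ~ standardized log(NRI) + low-context indicator + standardized
    log(IRI), with a random intercept per session. Falls back to OLS (with a
    logged downgrade) when the mixed fit is singular or does not converge.
    Requires ``min_observations`` transients and both contexts present.
    """
    import statsmodels.formula.api as smf

    df = transients.dropna(subset=["amplitude", "nri", "iri"]).copy()
    if len(df) < min_observations:
        raise ValueError(f"need >= {min_observations} transients, got {len(df)}")
    if df["context"].nunique() < 2:
        raise ValueError("both contexts must be represented")
    for col, src in (("log_nri_z", "nri"), ("log_iri_z", "iri")):
        v = np.log(df[src].to_numpy())
        df[col] = (v - v.mean()) / (v.std() or 1.0)
    df["context_low"] = (df["context"] == "low").astype(float)
    if "session" not in df.columns:
        df["session"] = "session"

    formula = "amplitude ~ log_nri_z + context_low + log_iri_z"
    method = "mixedlm"
    re_var = math.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, df, groups=df["session"]).fit(reml=True)
        if not np.all(np.isfinite(res.bse_fe)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        re_var = float(np.asarray(res.cov_re)[0, 0])
        params, ci = res.fe_params, res.conf_int()
    except Exception as err:  # singular / non-convergent mixed fit
        log.warning("mixed model downgraded to OLS: %s", err)
        method = "ols"
        res = smf.ols(formula, df).fit()
        params, ci = res.params, res.conf_int()

    def pick(name):
        return float(params[name]), (float(ci.loc[name, 0]), float(ci.loc[name, 1]))

    b_nri, ci_nri = pick("log_nri_z")
    b_ctx, ci_ctx = pick("context_low")
    b_iri, ci_iri = pick("log_iri_z")
    return AmplitudeModelFit(
        beta_log_nri=b_nri, beta_context_low=b_ctx, beta_log_iri=b_iri,
        ci_log_nri=ci_nri, ci_context_low=ci_ctx, ci_log_iri=ci_iri,
        random_intercept_var=re_var, n_observations=len(df), method=method,
    )
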