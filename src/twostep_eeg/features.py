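"""Quantification of feedback-locked EEG components.

Measurement pipeline, applied identically at averaged and single-trial
level:

* artifact rejection: drop epochs deviating more than +/-300 uV from the
  epoch's channel mean (configurable exemption list for blink channels);
* baseline correction: subtract the mean of the 200 ms before feedback;
* FRN: peak-to-peak at FCz after a zero-phase 15 Hz second-order
  Butterworth low-pass — most negative local peak in 200-350 ms minus the
  mean of the most positive deflections in 100 ms flanking windows, with
  outward 10 ms widening (up to 300 ms) when a flank maximum sits on the
  window edge;
* P3: mean amplitude 300-500 ms at Pz;
* theta / delta: mean dB power 4-8 Hz in 200-400 ms at FCz and 1-4 Hz in
  300-500 ms at Pz, from a Morlet wavelet transform (50 log-spaced
  frequencies 1-50 Hz, wavelet width sigma = 4 / (2 pi f)), dB-normalized
  by the across-trial mean baseline power in -300..-200 ms;
* cell-mean repeated-measures ANOVA over condition x expectancy x valence.

Windows are closed intervals in ms relative to feedback onset, mapped to
samples by rounding half-up.  The measurement path contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.fft import fft, ifft, next_fast_len

from .eeg_sim import EpochSet

#: channels exempt from the deviation criterion by default (blink-prone
#: frontal sites, when present)
BLINK_CHANNELS = ("Fp1", "Fpz", "Fp2", "AF7", "AF8")

FRN_SEARCH_MS = (200.0, 350.0)
P3_WINDOW_MS = (300.0, 500.0)
THETA_BAND = (4.0, 8.0)
THETA_WINDOW_MS = (200.0, 400.0)
DELTA_BAND = (1.0, 4.0)
DELTA_WINDOW_MS = (300.0, 500.0)


def _ms_to_idx(times_ms: np.ndarray, ms: float) -> int:
    """Index of the sample at `ms`, rounding half-up on the sample grid."""
    dt = times_ms[1] - times_ms[0]
    i = int(np.floor((ms - times_ms[0]) / dt + 0.5))
    return int(np.clip(i, 0, len(times_ms) - 1))


def reject_artifacts(epochs: EpochSet, threshold: float = 300.0,
                     exempt_channels: tuple = BLINK_CHANNELS) -> EpochSet:
    """Remove epochs where any non-exempt channel deviates more than
    +/- threshold uV from that epoch's channel mean."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    chans = [i for i, c in enumerate(epochs.ch_names)
             if c not in exempt_channels]
    x = epochs.data[:, chans, :]
    dev = np.abs(x - x.mean(axis=2, keepdims=True)).max(axis=(1, 2))
    return epochs.select(dev <= threshold)


def baseline_correct(epochs: EpochSet,
                     window=(-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the baseline window."""
    t = epochs.times
    lo, hi = _ms_to_idx(t, window[0]), _ms_to_idx(t, window[1])
    if hi <= lo:
        raise ValueError("empty baseline window")
    out = epochs.copy()
    out.data -= out.data[:, :, lo:hi + 1].mean(axis=2, keepdims=True)
    return out


def lowpass_filter(x: np.ndarray, srate: float, cutoff: float = 15.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along the last
    axis; zero-phase filtering protects peak latencies."""
    b, a = signal.butter(order, cutoff, fs=srate)
    return signal.filtfilt(b, a, x, axis=-1)


class FRNMeasure(NamedTuple):
    p2p: float
    latency_pre_ms: float
    latency_frn_ms: float
    latency_post_ms: float
    fallback: bool


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Interior local minima; plateaus resolve to their earliest sample."""
    idx = []
    for i in range(1, len(x) - 1):
        if x[i] < x[i - 1] and x[i] <= x[i + 1]:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def _flank_max(x: np.ndarray, times: np.ndarray, peak_idx: int,
               direction: int, start_ms: float = 100.0,
               step_ms: float = 10.0, max_ms: float = 300.0) -> int:
    """Most positive deflection in the flanking window.

    ``direction`` -1 for the preceding window, +1 for the succeeding one.
    The window grows outward in ``step_ms`` increments (to ``max_ms``
    total) while its maximum lies on the outer edge.
    """
    w = start_ms
    while True:
        if direction < 0:
            lo = _ms_to_idx(times, times[peak_idx] - w)
            hi = peak_idx
        else:
            lo = peak_idx
            hi = _ms_to_idx(times, times[peak_idx] + w)
        seg = x[lo:hi + 1]
        rel = int(np.argmax(seg))
        idx = lo + rel
        outer = lo if direction < 0 else hi
        at_bound = (direction < 0 and lo == 0) or \
            (direction > 0 and hi == len(x) - 1)
        if idx != outer or w >= max_ms or at_bound:
            return idx
        w = min(w + step_ms, max_ms)


def frn_peak_to_peak(waveform: np.ndarray, times_ms: np.ndarray,
                     search=FRN_SEARCH_MS) -> FRNMeasure:
    """Peak-to-peak FRN of a single (already low-passed) waveform.

    Most negative local peak within the search window, minus the mean of
    the preceding and succeeding positive peaks.  Falls back (flagged) to
    the window minimum when the search window contains no local minimum.
    """
    x = np.asarray(waveform, dtype=float)
    lo = _ms_to_idx(times_ms, search[0])
    hi = _ms_to_idx(times_ms, search[1])
    cand = _local_minima(x[lo:hi + 1]) + lo
    if len(cand):
        peak = cand[np.argmin(x[cand])]
        fallback = False
    else:
        peak = lo + int(np.argmin(x[lo:hi + 1]))
        fallback = True
    pre = _flank_max(x, times_ms, peak, -1)
    post = _flank_max(x, times_ms, peak, +1)
    p2p = x[peak] - 0.5 * (x[pre] + x[post])
    return FRNMeasure(p2p=float(p2p),
                      latency_pre_ms=float(times_ms[pre]),
                      latency_frn_ms=float(times_ms[peak]),
                      latency_post_ms=float(times_ms[post]),
                      fallback=fallback)


def p3_mean_amplitude(waveform: np.ndarray, times_ms: np.ndarray,
                      window=P3_WINDOW_MS) -> float:
    """Arithmetic mean over the 300-500 ms window."""
    lo = _ms_to_idx(times_ms, window[0])
    hi = _ms_to_idx(times_ms, window[1])
    return float(np.mean(waveform[lo:hi + 1]))


@dataclass
class TFRepresentation:
    """dB-scale Morlet power: trials x frequencies x samples."""

    power_db: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    channel: str
    edge_mask: np.ndarray  # freqs x samples, True where edge-contaminated

    def __post_init__(self):
        if len(self.freqs) != self.power_db.shape[1]:
            raise ValueError("frequency vector mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency vector must be strictly increasing")


def morlet_wavelet(freq: float, srate: float) -> np.ndarray:
    """Complex Morlet carrier exp(-i 2 pi f t) under a Gaussian envelope
    of width sigma = 4 / (2 pi f), sampled over +/- 5 sigma (the envelope
    is ~4e-6 of its peak at the ends)."""
    sigma = 4.0 / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma * srate))
    t = np.arange(-half, half + 1) / srate
    w = np.exp(-1j * 2 * np.pi * freq * t) * np.exp(-t**2 / (2 * sigma**2))
    return w / np.sum(np.abs(w))


def morlet_power(epochs: EpochSet, channel: str = "FCz",
                 baseline=(-300.0, -200.0), fmin: float = 1.0,
                 fmax: float = 50.0, n_freqs: int = 50,
                 return_raw: bool = False):
    """Single-trial Morlet power, dB-normalized to the pre-feedback
    baseline.

    Power is |FFT-convolution of the signal with each wavelet|^2; the dB
    baseline is the across-trial average baseline power per frequency
    (condition-blind), so single-trial estimates at low frequencies stay
    stable.  Samples closer than 2 sigma_t to the epoch edge are flagged
    in ``edge_mask``.
    """
    freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
    ch = epochs.channel(channel)
    x = epochs.data[:, ch, :]
    n_trials, n = x.shape
    times = epochs.times
    b_lo = _ms_to_idx(times, baseline[0])
    b_hi = _ms_to_idx(times, baseline[1])
    if b_hi <= b_lo:
        raise ValueError("empty baseline window")

    wavelets = [morlet_wavelet(f, epochs.srate) for f in freqs]
    max_m = max(len(w) for w in wavelets)
    nfft = next_fast_len(n + max_m - 1)
    X = fft(x, n=nfft, axis=1)

    power = np.empty((n_trials, n_freqs, n))
    edge = np.zeros((n_freqs, n), dtype=bool)
    for k, w in enumerate(wavelets):
        m = len(w)
        W = fft(w, n=nfft)
        conv = ifft(X * W[None, :], axis=1)
        start = (m - 1) // 2
        seg = conv[:, start:start + n]
        power[:, k, :] = np.abs(seg) ** 2
        sigma_t = 4.0 / (2.0 * np.pi * freqs[k])
        guard = int(np.ceil(2.0 * sigma_t * epochs.srate))
        if guard > 0:
            edge[k, :min(guard, n)] = True
            edge[k, max(n - guard, 0):] = True

    base = power[:, :, b_lo:b_hi + 1].mean(axis=(0, 2))  # per frequency
    db = 10.0 * np.log10(power / base[None, :, None])
    tfr = TFRepresentation(power_db=db, freqs=freqs, times_ms=times,
                           channel=channel, edge_mask=edge)
    if return_raw:
        return tfr, power
    return tfr


def band_window_average(tfr: TFRepresentation, band, window) -> np.ndarray:
    """Mean dB over the frequency band x time window, per trial."""
    fmask = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tmask = (tfr.times_ms >= window[0]) & (tfr.times_ms <= window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("empty band/window selection")
    return tfr.power_db[:, fmask, :][:, :, tmask].mean(axis=(1, 2))


def trial_features(epochs: EpochSet, frn_channel: str = "FCz",
                   p3_channel: str = "Pz") -> pd.DataFrame:
    """Single-trial FRN, P3, theta and delta measures with trial metadata.

    Expects preprocessed (artifact-free, baseline-corrected) epochs; the
    15 Hz low-pass for the FRN is applied internally to a copy.
    """
    times = epochs.times
    fcz = lowpass_filter(epochs.data[:, epochs.channel(frn_channel), :],
                         epochs.srate)
    pz = epochs.data[:, epochs.channel(p3_channel), :]

    frn = np.empty(epochs.n_trials)
    frn_fallback = np.zeros(epochs.n_trials, dtype=bool)
    p3 = np.empty(epochs.n_trials)
    for i in range(epochs.n_trials):
        m = frn_peak_to_peak(fcz[i], times)
        frn[i] = m.p2p
        frn_fallback[i] = m.fallback
        p3[i] = p3_mean_amplitude(pz[i], times)

    tfr_f = morlet_power(epochs, channel=frn_channel)
    tfr_p = morlet_power(epochs, channel=p3_channel)
    theta = band_window_average(tfr_f, THETA_BAND, THETA_WINDOW_MS)
    delta = band_window_average(tfr_p, DELTA_BAND, DELTA_WINDOW_MS)

    out = epochs.trial_meta.copy()
    out["frn_p2p"] = frn
    out["frn_fallback"] = frn_fallback
    out["p3_mean"] = p3
    out["theta_db"] = theta
    out["delta_db"] = delta
    return out


def _rm_anova_sums(cells: np.ndarray, levels: tuple) -> list[dict]:
    """Within-subject factorial ANOVA by direct sums-of-squares
    decomposition.

    ``cells``: subjects x cell array, cells in row-major order over
    ``levels``.  Every effect is tested against its interaction with the
    subject factor.  A zero numerator (identical cell means) yields F = 0.
    """
    n_subj = cells.shape[0]
    k = len(levels)
    y = cells.reshape((n_subj, *levels))
    factors = list(range(k))
    results = []
    for r in range(1, k + 1):
        for eff in combinations(factors, r):
            # u-terms by inclusion-exclusion over sub-effects
            def marginal(sub, with_subject):
                axes = tuple(1 + f for f in factors if f not in sub)
                m = y.mean(axis=axes, keepdims=True)
                if not with_subject:
                    m = m.mean(axis=0, keepdims=True)
                return m

            u_eff = np.zeros((1, *[levels[f] if f in eff else 1
                                   for f in factors]))
            u_err = np.zeros((n_subj, *[levels[f] if f in eff else 1
                                        for f in factors]))
            for rr in range(0, len(eff) + 1):
                for sub in combinations(eff, rr):
                    sign = (-1) ** (len(eff) - len(sub))
                    u_eff = u_eff + sign * marginal(sub, False)
                    # error term: same expansion including the subject
                    # factor (inclusion-exclusion over sub x {subject})
                    u_err = u_err + sign * (marginal(sub, True)
                                            - marginal(sub, False))
            rep = n_subj * int(np.prod([levels[f] for f in factors
                                        if f not in eff]))
            ss_eff = float(np.sum(u_eff**2)) * rep
            rep_err = int(np.prod([levels[f] for f in factors
                                   if f not in eff]))
            ss_err = float(np.sum(u_err**2)) * rep_err
            df_eff = int(np.prod([levels[f] - 1 for f in eff]))
            df_err = df_eff * (n_subj - 1)
            if ss_eff < 1e-12:
                f_val, p = 0.0, 1.0
            elif ss_err < 1e-12:
                f_val, p = np.inf, 0.0
            else:
                f_val = (ss_eff / df_eff) / (ss_err / df_err)
                p = float(stats.f.sf(f_val, df_eff, df_err))
            results.append({"effect": eff, "ss": ss_eff, "ss_err": ss_err,
                            "df": df_eff, "df_err": df_err,
                            "F": float(f_val), "p": p})
    return results


def cell_anova(features: pd.DataFrame, measure: str,
               factors=("condition", "expectancy", "valence")) -> \
        pd.DataFrame:
    """Repeated-measures ANOVA on per-subject cell means.

    Subjects missing any design cell are dropped with a warning.  Returns
    a tidy table with one row per main effect and interaction.
    """
    import warnings

    levels = [sorted(features[f].unique()) for f in factors]
    n_cells = int(np.prod([len(l) for l in levels]))
    cell_means = features.groupby(["subject", *factors], observed=True)[
        measure].mean().reset_index()
    counts = cell_means.groupby("subject").size()
    complete = counts[counts == n_cells].index
    dropped = counts[counts != n_cells].index
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} subject(s) with missing "
                      f"design cells: {list(dropped)}")
    if len(complete) < 2:
        raise ValueError("need >= 2 subjects with complete design cells")
    sub = cell_means[cell_means["subject"].isin(complete)]
    wide = sub.pivot_table(index="subject", columns=list(factors),
                           values=measure)
    # row-major cell order over the factor levels
    order = list(product(*levels))
    wide = wide[order]
    res = _rm_anova_sums(wide.to_numpy(), tuple(len(l) for l in levels))
    rows = []
    for r in res:
        name = " x ".join(factors[f] for f in r["effect"])
        rows.append({"effect": name, "F": r["F"], "df_num": r["df"],
                     "df_den": r["df_err"], "p": r["p"]})
    return pd.DataFrame(rows)
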