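"""Action-potential metrics and voltage-clamp current analysis.

Current measures follow the whole-cell K⁺-current conventions for rodent
ventricular myocytes: I_to is peak minus end-of-pulse current, I_K the mean
current at the end of the pulse, I_K1 the Ba²⁺-sensitive end-of-pulse
difference current; all are normalised to cell capacitance (pA/pF).  Model
fits: Boltzmann activation/inactivation, bi-exponential I_to decay, and
bi-phasic recovery from inactivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AnalysisError, ProtocolError
from .io import SweepSet, TimeSeriesRecording

__all__ = [
    "ApMetrics",
    "BoltzmannFit",
    "BiexpFit",
    "RecoveryFit",
    "measure_ap",
    "extract_ito",
    "extract_ik",
    "extract_ik1",
    "fit_boltzmann",
    "fit_biexponential",
    "fit_recovery",
    "activation_curve",
    "availability_curve",
    "recovery_curve",
]

END_WINDOW_FRAC = 0.05


@dataclass
class ApMetrics:
    rmp_mv: float
    dvdt_max_mv_ms: float
    overshoot_mv: float
    apd20_ms: float
    apd50_ms: float
    apd90_ms: float
    apd_0mv_ms: float
    beat_index: int


@dataclass
class BoltzmannFit:
    v50_mv: float
    slope_mv: float
    direction: str  # "activation" | "inactivation"
    residual: float


@dataclass
class BiexpFit:
    tau_fast_ms: float
    tau_slow_ms: float
    c1: float
    c2: float
    amp_fast: float
    amp_slow: float
    offset: float
    residual: float


@dataclass
class RecoveryFit:
    k_fast_ms: float
    k_slow_ms: float
    frac_fast: float
    frac_slow: float
    residual: float


# ---------------------------------------------------------------------------
# action potentials


def measure_ap(
    rec: TimeSeriesRecording,
    beat_index: int = 30,
    channel: str = "membrane_potential",
    dvdt_threshold_mv_ms: float = 20.0,
    refractory_s: float = 0.1,
    rmp_window_s: tuple[float, float] = (0.05, 0.005),
) -> ApMetrics:
    """Metrics of the ``beat_index``-th action potential (1-based, default 30).

    Upstrokes are located where dV/dt exceeds the threshold for at least two
    consecutive samples (events separated by at least ``refractory_s``); the
    effective threshold is the larger of ``dvdt_threshold_mv_ms`` and a
    quarter of the trace's maximum dV/dt, so isolated noise excursions during
    diastole cannot masquerade as beats.  The upstroke onset — the first
    sample of the supra-threshold run, ties toward the earliest sample — is
    time zero for all APD measures.  RMP is the mean over a pre-upstroke window,
    dV/dt_max the maximum discrete derivative of the upstroke, overshoot the
    peak above 0 mV.  APD_x is the time to x% repolarisation between peak and
    RMP (linear interpolation); APD_0mV the time to the first downward 0 mV
    crossing.
    """
    v = rec.channel(channel)
    dt = rec.dt
    dvdt = np.diff(v) / (dt * 1000.0)  # mV/ms
    threshold = max(dvdt_threshold_mv_ms, 0.25 * float(dvdt.max()))
    supra = dvdt > threshold
    supra = supra & (np.roll(supra, -1) | np.roll(supra, 1))  # 2-sample persistence
    if not supra.any():
        raise AnalysisError("no upstroke found (dV/dt never exceeds threshold)")
    idx = np.nonzero(supra)[0]
    onsets = [int(idx[0])]
    for i in idx[1:]:
        if (i - onsets[-1]) * dt > refractory_s:
            onsets.append(int(i))
    if len(onsets) < beat_index:
        raise AnalysisError(
            f"only {len(onsets)} paced beats detected but beat {beat_index} was "
            "requested (analysis uses the 30th AP by default)"
        )
    k0 = onsets[beat_index - 1]
    k_end = onsets[beat_index] if beat_index < len(onsets) else v.size

    w0 = max(0, k0 - int(round(rmp_window_s[0] / dt)))
    w1 = max(w0 + 1, k0 - int(round(rmp_window_s[1] / dt)))
    rmp = float(v[w0:w1].mean())

    seg = v[k0:k_end]
    kp = int(np.argmax(seg))
    peak = float(seg[kp])
    # dV/dt_max over the upstroke (onset to peak)
    up = dvdt[k0 : k0 + max(kp, 1)]
    dvdt_max = float(up.max()) if up.size else float(dvdt[k0])

    def crossing(level: float) -> float:
        below = np.nonzero(seg[kp:] <= level)[0]
        if below.size == 0:
            return float("nan")
        j = kp + int(below[0])
        if j == 0 or seg[j - 1] == seg[j]:
            return j * dt * 1000.0
        frac = (seg[j - 1] - level) / (seg[j - 1] - seg[j])
        return (j - 1 + frac) * dt * 1000.0

    amp = peak - rmp
    return ApMetrics(
        rmp_mv=rmp,
        dvdt_max_mv_ms=dvdt_max,
        overshoot_mv=peak,
        apd20_ms=crossing(peak - 0.20 * amp),
        apd50_ms=crossing(peak - 0.50 * amp),
        apd90_ms=crossing(peak - 0.90 * amp),
        apd_0mv_ms=crossing(0.0),
        beat_index=beat_index,
    )


# ---------------------------------------------------------------------------
# current extraction


def _pulse_slice(sw_time: np.ndarray, row) -> tuple[int, int]:
    i0 = int(np.searchsorted(sw_time, row.pulse_start_s))
    i1 = int(np.searchsorted(sw_time, row.pulse_end_s))
    if i1 <= i0:
        raise ProtocolError("empty pulse window in protocol")
    return i0, i1


def _end_mean(signal: np.ndarray, i0: int, i1: int, end_frac: float) -> float:
    n_end = max(1, int(round(end_frac * (i1 - i0))))
    return float(signal[i1 - n_end : i1].mean())


def extract_ito(
    ss: SweepSet,
    end_window_frac: float = END_WINDOW_FRAC,
    peak_smooth_s: float = 0.001,
) -> pd.DataFrame:
    """Per-sweep I_to: (pulse peak − end-of-pulse mean) / capacitance.

    The end-of-pulse window defaults to the last 5% of the commanded step.
    The peak is read from a lightly smoothed copy of the pulse (boxcar of
    ``peak_smooth_s``, default 1 ms): the raw maximum of a noisy trace is
    biased by the noise ceiling, and the smoothing bias cancels exactly in
    normalized quantities (activation, availability, paired-pulse ratios).
    """
    rows = []
    for sw, row in zip(ss.sweeps, ss.protocol.itertuples()):
        i0, i1 = _pulse_slice(sw.time, row)
        seg = sw.signal[i0:i1]
        if peak_smooth_s > 0 and seg.size > 3:
            dt = float(np.mean(np.diff(sw.time[: min(50, sw.time.size)])))
            w = max(1, int(round(peak_smooth_s / dt)))
            kernel = np.ones(w) / w
            seg = np.convolve(seg, kernel, mode="same")
        peak = float(seg.max())
        end = _end_mean(sw.signal, i0, i1, end_window_frac)
        rec = {c: getattr(row, c) for c in ss.protocol.columns}
        rec.update(
            peak_pa=peak,
            end_pa=end,
            ito_pa_pf=(peak - end) / ss.capacitance_pf,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def extract_ik(ss: SweepSet, end_window_frac: float = END_WINDOW_FRAC) -> pd.DataFrame:
    """Per-sweep I_K: mean current over the end-of-pulse window / capacitance."""
    rows = []
    for sw, row in zip(ss.sweeps, ss.protocol.itertuples()):
        i0, i1 = _pulse_slice(sw.time, row)
        end = _end_mean(sw.signal, i0, i1, end_window_frac)
        rec = {c: getattr(row, c) for c in ss.protocol.columns}
        rec.update(ik_pa_pf=end / ss.capacitance_pf)
        rows.append(rec)
    return pd.DataFrame(rows)


def extract_ik1(
    control: SweepSet, blocked: SweepSet, end_window_frac: float = END_WINDOW_FRAC
) -> pd.DataFrame:
    """I_K1 as the Ba²⁺-sensitive end-of-pulse difference current, per potential.

    ``control`` and ``blocked`` must share the commanded potentials; inward
    currents come out negative (e.g. at −120 mV).
    """
    vc = np.asarray(control.protocol["v_test_mv"], float)
    vb = np.asarray(blocked.protocol["v_test_mv"], float)
    if vc.shape != vb.shape or not np.allclose(vc, vb):
        raise ProtocolError("control and blocked protocols do not match")
    if control.capacitance_pf != blocked.capacitance_pf:
        warnings.warn("capacitance differs between control and blocked sets", stacklevel=2)
    ctrl = extract_ik(control, end_window_frac)
    blk = extract_ik(blocked, end_window_frac)
    return pd.DataFrame(
        {
            "v_test_mv": vc,
            "ik1_pa_pf": ctrl["ik_pa_pf"].to_numpy() - blk["ik_pa_pf"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# derived normalized curves


def activation_curve(ss: SweepSet, reference_mv: float = 60.0) -> pd.DataFrame:
    """Normalized conductivity vs potential: I_to(V) / I_to(reference).

    Under a linear driving-force assumption the reversal potential cancels in
    the normalisation, so no E_rev correction is applied by default.
    """
    ito = extract_ito(ss)
    ref = ito.loc[np.isclose(ito["v_test_mv"], reference_mv), "ito_pa_pf"]
    if ref.empty or float(ref.iloc[0]) == 0:
        raise ProtocolError(f"no usable reference sweep at {reference_mv} mV")
    return pd.DataFrame(
        {
            "v_mv": ito["v_test_mv"],
            "g_norm": ito["ito_pa_pf"] / float(ref.iloc[0]),
        }
    )


def availability_curve(ss: SweepSet, reference_cond_mv: float = -80.0) -> pd.DataFrame:
    """Steady-state inactivation: test-pulse I_to normalised to the most
    negative conditioning potential."""
    if "v_cond_mv" not in ss.protocol.columns:
        raise ProtocolError("inactivation protocol requires a v_cond_mv column")
    ito = extract_ito(ss)
    ref = ito.loc[np.isclose(ito["v_cond_mv"], reference_cond_mv), "ito_pa_pf"]
    if ref.empty or float(ref.iloc[0]) == 0:
        raise ProtocolError(f"no usable reference at conditioning {reference_cond_mv} mV")
    return pd.DataFrame(
        {
            "v_mv": ito["v_cond_mv"],
            "g_norm": ito["ito_pa_pf"] / float(ref.iloc[0]),
        }
    )


def recovery_curve(ss: SweepSet) -> pd.DataFrame:
    """Paired-pulse recovery: I_to(P2)/I_to(P1) vs inter-pulse interval (ms)."""
    if "role" not in ss.protocol.columns or "interval_s" not in ss.protocol.columns:
        raise ProtocolError("recovery protocol requires role and interval_s columns")
    ito = extract_ito(ss)
    rows = []
    for interval, grp in ito.groupby("interval_s"):
        p1 = grp.loc[grp["role"] == "p1", "ito_pa_pf"]
        p2 = grp.loc[grp["role"] == "p2", "ito_pa_pf"]
        if p1.empty or p2.empty:
            raise ProtocolError(f"interval {interval}: missing p1 or p2 sweep")
        rows.append(
            {"interval_ms": 1000.0 * float(interval), "ratio": float(p2.iloc[0]) / float(p1.iloc[0])}
        )
    return pd.DataFrame(rows).sort_values("interval_ms", ignore_index=True)


# ---------------------------------------------------------------------------
# model fits


def _boltzmann(v, v50, k, sign):
    return 1.0 / (1.0 + np.exp(sign * (v - v50) / k))


def fit_boltzmann(v_mv: np.ndarray, y: np.ndarray, direction: str) -> BoltzmannFit:
    """Least-squares Boltzmann fit y = 1/(1+exp(±(V50−V)/k)).

    ``direction='activation'`` rises with depolarisation,
    ``'inactivation'`` falls.  The slope factor k is reported positive; the
    direction flag carries the sign convention.
    """
    v = np.asarray(v_mv, float)
    y = np.asarray(y, float)
    if v.size < 4:
        raise AnalysisError("need at least 4 points spanning the transition")
    if direction not in ("activation", "inactivation"):
        raise AnalysisError(f"unknown direction {direction!r}")
    if np.ptp(y) < 0.2:
        raise AnalysisError("no transition in the data: Boltzmann fit is undefined")
    sign = -1.0 if direction == "activation" else 1.0
    v50_init = float(v[np.argmin(np.abs(y - 0.5))])
    best = None
    for k_init in (2.0, 5.0, 10.0, 20.0):
        try:
            popt, _ = curve_fit(
                lambda vv, v50, k: _boltzmann(vv, v50, k, sign),
                v,
                y,
                p0=[v50_init, k_init],
                bounds=([-200.0, 0.1], [200.0, 200.0]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        res = float(np.sum((y - _boltzmann(v, *popt, sign)) ** 2))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise AnalysisError("Boltzmann fit did not converge")
    (v50, k), res = best
    return BoltzmannFit(v50_mv=float(v50), slope_mv=float(k), direction=direction, residual=res)


def _biexp(t, af, tf, as_, ts, c):
    return af * np.exp(-t / tf) + as_ * np.exp(-t / ts) + c


def _lin_amps(t: np.ndarray, y: np.ndarray, tf: float, ts: float) -> tuple[np.ndarray, float]:
    """Linear least squares for (A_f, A_s, C) at fixed time constants."""
    X = np.column_stack([np.exp(-t / tf), np.exp(-t / ts), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = float(np.sum((y - X @ coef) ** 2))
    return coef, res


def fit_biexponential(t_s: np.ndarray, current: np.ndarray) -> BiexpFit:
    """Fit I(t) = A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) + C to a decay.

    Initialisation scans a log-spaced τ grid with amplitudes solved linearly;
    the best grid point seeds a full nonlinear refinement.  τ_fast < τ_slow is
    enforced by post-fit ordering and c1 = A_f/(A_f+A_s).  A τ ratio below 2
    triggers a poorly-separable-components warning.
    """
    t = np.asarray(t_s, float)
    y = np.asarray(current, float)
    if t.size < 6:
        raise AnalysisError("too few samples for a bi-exponential fit")
    t = t - t[0]
    span = t[-1]
    taus = np.geomspace(max(span * 1e-3, np.diff(t).min()), span, 12)
    best = None
    for i, tf in enumerate(taus):
        for ts in taus[i + 1 :]:
            if ts < 2.0 * tf:
                continue
            coef, res = _lin_amps(t, y, tf, ts)
            if best is None or res < best[2]:
                best = ((coef[0], tf, coef[1], ts, coef[2]), res, res)
    if best is None:
        raise AnalysisError("no valid initialisation for the bi-exponential fit")
    p0 = best[0]
    try:
        popt, _ = curve_fit(_biexp, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise AnalysisError(f"bi-exponential fit did not converge: {exc}") from exc
    af, tf, as_, ts, c = popt
    if tf > ts:
        af, tf, as_, ts = as_, ts, af, tf
    if ts / tf < 2.0:
        warnings.warn(
            f"tau ratio {ts / tf:.2f} < 2: fast and slow components are poorly separable",
            stacklevel=2,
        )
    total = af + as_
    c1 = af / total if total != 0 else float("nan")
    res = float(np.sum((y - _biexp(t, af, tf, as_, ts, c)) ** 2))
    return BiexpFit(
        tau_fast_ms=1000.0 * float(tf),
        tau_slow_ms=1000.0 * float(ts),
        c1=float(c1),
        c2=float(1.0 - c1),
        amp_fast=float(af),
        amp_slow=float(as_),
        offset=float(c),
        residual=res,
    )


def _biphasic(t, a, kf, b, ks):
    return 1.0 - a * np.exp(-t / kf) - b * np.exp(-t / ks)


def fit_recovery(interval_ms: np.ndarray, ratio: np.ndarray) -> RecoveryFit:
    """Fit the bi-phasic association y(t) = 1 − a·e^(−t/K_f) − b·e^(−t/K_s).

    a, b ≥ 0; K_fast < K_slow enforced by post-fit ordering; fractions are
    reported as a/(a+b) and b/(a+b).
    """
    t = np.asarray(interval_ms, float)
    y = np.asarray(ratio, float)
    if t.size < 5:
        raise AnalysisError("too few interval points for a bi-phasic recovery fit")
    span = t.max()
    taus = np.geomspace(max(t.min() / 2.0, 1e-3), span * 2.0, 10)
    best = None
    for i, kf in enumerate(taus):
        for ks in taus[i + 1 :]:
            if ks < 2.0 * kf:
                continue
            X = np.column_stack([np.exp(-t / kf), np.exp(-t / ks)])
            coef, *_ = np.linalg.lstsq(X, 1.0 - y, rcond=None)
            res = float(np.sum((1.0 - y - X @ coef) ** 2))
            if best is None or res < best[1]:
                best = ((max(coef[0], 1e-6), kf, max(coef[1], 1e-6), ks), res)
    p0 = best[0]
    try:
        popt, _ = curve_fit(
            _biphasic,
            t,
            y,
            p0=p0,
            bounds=([0.0, 1e-6, 0.0, 1e-6], [2.0, 1e7, 2.0, 1e7]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise AnalysisError(f"recovery fit did not converge: {exc}") from exc
    a, kf, b, ks = popt
    if kf > ks:
        a, kf, b, ks = b, ks, a, kf
    total = a + b
    res = float(np.sum((y - _biphasic(t, a, kf, b, ks)) ** 2))
    return RecoveryFit(
        k_fast_ms=float(kf),
        k_slow_ms=float(ks),
        frac_fast=float(a / total) if total else float("nan"),
        frac_slow=float(b / total) if total else float("nan"),
        residual=res,
    )
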