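"""Synthetic-data generators with known ground truth.

Every downstream stage of the package (beat analysis, TATS and mitochondrial
imaging, patch-clamp metric extraction, equivalence statistics) is validated
by parameter recovery against the generators in this module.  Each generator
is deterministic under a fixed seed and returns machine-readable ground truth
sufficient to compute the expected analysis output.

Conventions
-----------
* Seeds are explicit parameters; no global random state is touched.
* The Ca²⁺-transient / contraction pulse is a peak-normalised difference of
  exponentials ``(1 - exp(-t/rise_tau)) * exp(-t/decay_tau)``, which rises and
  decays monotonically and has the closed-form peak time
  ``t_peak = rise_tau * ln(1 + decay_tau/rise_tau)``.
* Stimulus impulses are rendered as 2-sample rectangles of fixed amplitude so
  that threshold detection is unambiguous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import SpecError
from .io import Sweep, SweepSet, TimeSeriesRecording, VolumeImage

__all__ = [
    "TransientSimSpec",
    "TatsPhantomSpec",
    "MitoPhantomSpec",
    "EphysSimSpec",
    "GroupSimSpec",
    "pulse_peak_time",
    "pulse_shape",
    "gen_transient_trace",
    "gen_sarcomere_trace",
    "gen_striation_profile",
    "gen_tats_volume",
    "gen_mito_volume",
    "gen_vclamp_sweeps",
    "gen_ap_trace",
    "gen_group_samples",
]

PAPER_LADDER_HZ = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
STIMULUS_AMPLITUDE_V = 5.0


# ---------------------------------------------------------------------------
# pulse primitives


def pulse_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Peak time of the difference-of-exponentials pulse (s)."""
    return rise_tau * math.log(1.0 + decay_tau / rise_tau)


def pulse_shape(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalised pulse, zero for t < 0, unit maximum."""
    t = np.asarray(t, dtype=float)
    tp = pulse_peak_time(rise_tau, decay_tau)
    peak = (1.0 - math.exp(-tp / rise_tau)) * math.exp(-tp / decay_tau)
    out = np.zeros_like(t)
    pos = t > 0
    tv = t[pos]
    out[pos] = (1.0 - np.exp(-tv / rise_tau)) * np.exp(-tv / decay_tau) / peak
    return out


# ---------------------------------------------------------------------------
# transient / sarcomere traces


@dataclass
class TransientSimSpec:
    """Stimulus-locked transient simulation.

    The default ladder and interval rule follow the experimental pacing
    protocol: frequencies 0.5–4 Hz, each interval lasting at least 24
    stimulations or at least 12 s, whichever is longer.

    The default sampling rate (2 kHz) is chosen so that the 21-sample moving
    median used downstream spans ~10 ms, short against the pulse rise time;
    the default kinetics (rise 15 ms, decay 65 ms) give TTP90 ≈ 24 ms and
    TTBL90 ≈ 165 ms, so the transient resolves within the 250 ms period at
    4 Hz pacing.
    """

    pacing_frequencies: tuple[float, ...] = PAPER_LADDER_HZ
    min_stimuli: int = 24
    min_duration_s: float = 12.0
    diastolic_level: float = 1.0
    amplitude: float = 0.5
    rise_tau: float = 0.015
    decay_tau: float = 0.065
    noise_sd: float = 0.025
    missed_beat_prob: float = 0.05
    sampling_rate: float = 2000.0
    lead_in_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.pacing_frequencies, dtype=float)
        if f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise SpecError("pacing_frequencies must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if not 0.0 <= self.missed_beat_prob <= 1.0:
            raise SpecError("missed_beat_prob must be in [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise SpecError("time constants must be positive")
        # Beats must be resolvable at the fastest pacing rate: the pulse peak
        # has to fall inside one stimulation period.
        tp = pulse_peak_time(self.rise_tau, self.decay_tau)
        if tp >= 1.0 / float(f.max()):
            raise SpecError(
                f"pulse peak time {tp * 1e3:.1f} ms exceeds the stimulation period at "
                f"{f.max():g} Hz; beats would overlap unresolvably — shorten rise/decay "
                "time constants or lower the maximum pacing frequency"
            )

    def interval_plan(self) -> pd.DataFrame:
        """Per-frequency stimulus counts and durations under the interval rule."""
        rows = []
        t0 = self.lead_in_s
        for f in self.pacing_frequencies:
            n = max(self.min_stimuli, math.ceil(self.min_duration_s * f))
            dur = n / f
            rows.append(
                {"frequency_hz": f, "n_stimuli": n, "duration_s": dur, "start_s": t0}
            )
            t0 += dur
        return pd.DataFrame(rows)


def _pulse_train(
    spec: TransientSimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clean (noise-free, unit-amplitude) pulse sum plus stimulus bookkeeping.

    Returns (time, clean, stim_times, stim_freqs, captured).
    """
    plan = spec.interval_plan()
    stim_times, stim_freqs = [], []
    for row in plan.itertuples():
        stim_times.append(row.start_s + np.arange(row.n_stimuli) / row.frequency_hz)
        stim_freqs.append(np.full(row.n_stimuli, row.frequency_hz))
    stim_times = np.concatenate(stim_times)
    stim_freqs = np.concatenate(stim_freqs)

    total_s = plan["start_s"].iloc[-1] + plan["duration_s"].iloc[-1]
    n = int(round(total_s * spec.sampling_rate))
    time = np.arange(n) / spec.sampling_rate

    captured = rng.random(stim_times.size) >= spec.missed_beat_prob

    clean = np.zeros(n)
    # pulse support: ignore contributions below 1e-4 of the peak
    tp = pulse_peak_time(spec.rise_tau, spec.decay_tau)
    t_cut = tp + spec.decay_tau * math.log(1e4)
    for ts in stim_times[captured]:
        i0 = int(math.ceil(ts * spec.sampling_rate))
        i1 = min(n, int(math.ceil((ts + t_cut) * spec.sampling_rate)))
        if i0 >= n:
            continue
        clean[i0:i1] += pulse_shape(time[i0:i1] - ts, spec.rise_tau, spec.decay_tau)
    return time, clean, stim_times, stim_freqs, captured


def _eval_clean(
    t: np.ndarray, stim_times: np.ndarray, captured: np.ndarray, spec: TransientSimSpec
) -> np.ndarray:
    """Continuous noise-free unit-amplitude pulse sum at arbitrary times."""
    tp = pulse_peak_time(spec.rise_tau, spec.decay_tau)
    t_cut = tp + spec.decay_tau * math.log(1e4)
    out = np.zeros_like(t, dtype=float)
    cap_times = stim_times[captured]
    lo = np.searchsorted(cap_times, t.min() - t_cut)
    hi = np.searchsorted(cap_times, t.max())
    for ts in cap_times[lo:hi]:
        out += pulse_shape(t - ts, spec.rise_tau, spec.decay_tau)
    return out


def _beat_truth_table(
    spec: TransientSimSpec,
    stim_times: np.ndarray,
    stim_freqs: np.ndarray,
    captured: np.ndarray,
    total_s: float,
    oversample: int = 5,
) -> pd.DataFrame:
    """Per-beat ground truth evaluated on the noise-free continuous model.

    Metric definitions mirror the analysis contract: the beat window runs from
    its stimulus to the next stimulus (or trace end); the diastolic level is
    the mean of the 200 ms pre-stimulus segment; TTP90 runs from the
    10%-of-amplitude upstroke crossing to the peak; TTBL90 from the peak to
    the 10% crossing on the decay.  Superposed tails of earlier beats are part
    of the signal and therefore part of the truth.
    """
    dt = 1.0 / (spec.sampling_rate * oversample)
    rows = []
    for i, ts in enumerate(stim_times):
        t_next = stim_times[i + 1] if i + 1 < stim_times.size else total_s
        row: dict = {
            "stimulus_time_s": ts,
            "frequency_hz": stim_freqs[i],
            "captured": bool(captured[i]),
            "nominal_amplitude": spec.amplitude,
        }
        if not captured[i]:
            rows.append(row)
            continue
        tw = np.arange(ts, t_next, dt)
        sig = spec.amplitude * _eval_clean(tw, stim_times, captured, spec)
        pre = np.arange(max(0.0, ts - 0.2), ts, dt)
        if pre.size:
            dia = spec.amplitude * _eval_clean(pre, stim_times, captured, spec).mean()
        else:
            dia = sig[0]
        k = int(np.argmax(sig))
        amp = sig[k] - dia
        level = dia + 0.1 * amp
        up = np.nonzero(sig[: k + 1] < level)[0]
        ttp90 = np.nan
        if up.size:
            j = up[-1]
            frac = (level - sig[j]) / (sig[j + 1] - sig[j])
            ttp90 = (k - j - frac) * dt
        down = np.nonzero(sig[k:] < level)[0]
        ttbl90 = np.nan
        if down.size:
            j = k + down[0]
            frac = (sig[j - 1] - level) / (sig[j - 1] - sig[j])
            ttbl90 = (j - 1 + frac - k) * dt
        row.update(
            diastolic=dia + spec.diastolic_level,
            amplitude=amp,
            ttp90=ttp90,
            ttbl90=ttbl90,
            catd90=ttp90 + ttbl90,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _stimulus_channel(
    time: np.ndarray, stim_times: np.ndarray, sampling_rate: float
) -> np.ndarray:
    stim = np.zeros_like(time)
    idx = np.round(stim_times * sampling_rate).astype(int)
    for j in idx:
        stim[j : j + 2] = STIMULUS_AMPLITUDE_V
    return stim


def gen_transient_trace(
    spec: TransientSimSpec, with_truth: bool = True
) -> tuple[TimeSeriesRecording, pd.DataFrame]:
    """Simulate a paced Fura-2 ratio recording.

    Returns the recording (channels ``fura_ratio`` and ``stimulus``) and the
    per-beat ground-truth table.
    """
    rng = np.random.default_rng(spec.seed)
    time, clean, stim_times, stim_freqs, captured = _pulse_train(spec, rng)
    signal = spec.diastolic_level + spec.amplitude * clean
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.size)
    rec = TimeSeriesRecording(
        time=time,
        channels={
            "fura_ratio": signal,
            "stimulus": _stimulus_channel(time, stim_times, spec.sampling_rate),
        },
        sampling_rate=spec.sampling_rate,
    )
    truth = (
        _beat_truth_table(spec, stim_times, stim_freqs, captured, time[-1] + rec.dt)
        if with_truth
        else pd.DataFrame()
    )
    return rec, truth


def gen_sarcomere_trace(
    spec: TransientSimSpec,
    resting_sl_um: float = 1.8,
    shortening_um: float = 0.1,
    with_truth: bool = True,
) -> tuple[TimeSeriesRecording, pd.DataFrame]:
    """Simulate a sarcomere-length trace: downward deflections from rest.

    The pulse machinery is shared with :func:`gen_transient_trace`; ground
    truth reports the (positive) shortening amplitude and kinetics of the
    negated signal.
    """
    if shortening_um >= resting_sl_um:
        raise SpecError("shortening must be smaller than the resting sarcomere length")
    if shortening_um < 0:
        raise SpecError("shortening must be non-negative")
    inner = TransientSimSpec(
        **{
            **spec.__dict__,
            "diastolic_level": 0.0,
            "amplitude": shortening_um,
        }
    )
    rng = np.random.default_rng(inner.seed)
    time, clean, stim_times, stim_freqs, captured = _pulse_train(inner, rng)
    signal = resting_sl_um - shortening_um * clean
    if inner.noise_sd > 0:
        signal = signal + rng.normal(0.0, inner.noise_sd, size=signal.size)
    rec = TimeSeriesRecording(
        time=time,
        channels={
            "sarcomere_length": signal,
            "stimulus": _stimulus_channel(time, stim_times, inner.sampling_rate),
        },
        sampling_rate=inner.sampling_rate,
    )
    if with_truth:
        truth = _beat_truth_table(
            inner, stim_times, stim_freqs, captured, time[-1] + rec.dt
        )
        if "diastolic" in truth:
            # diastolic of the SL channel itself (µm), not of the negated signal
            truth["diastolic_sl_um"] = resting_sl_um - truth["diastolic"]
    else:
        truth = pd.DataFrame()
    return rec, truth


def gen_striation_profile(
    sl_um: float,
    pixel_size_um: float = 0.05,
    length_um: float = 30.0,
    noise_sd: float = 0.0,
    contrast: float = 1.0,
    offset: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Brightfield striation intensity profile with spatial period ``sl_um``.

    Returns (positions µm, intensities).
    """
    if length_um <= 0:
        raise SpecError("profile length must be positive")
    if sl_um <= 0 or pixel_size_um <= 0:
        raise SpecError("sarcomere length and pixel size must be positive")
    if pixel_size_um >= sl_um / 2:
        raise SpecError("pixel size must resolve the striation period (Nyquist)")
    x = np.arange(0.0, length_um, pixel_size_um)
    profile = offset + contrast * np.sin(2.0 * np.pi * x / sl_um)
    if noise_sd > 0:
        profile = profile + np.random.default_rng(seed).normal(0, noise_sd, x.size)
    return x, profile


# ---------------------------------------------------------------------------
# TATS phantom


@dataclass
class TatsPhantomSpec:
    """Tubule-lattice phantom emulating membrane-dye confocal stacks.

    Transverse tubules are cylinders along y placed on an (x, z) grid with
    longitudinal spacing ``transverse_spacing_um`` (x, the cell long axis) and
    depth spacing ``z_spacing_um``; axial connectors along x appear with
    ``axial_element_prob``.  The analytic volume fraction of the transverse
    lattice is pi r^2 / (spacing_x * spacing_z).
    """

    cell_extent_um: tuple[float, float, float] = (8.0, 16.0, 32.0)  # (z, y, x)
    margin_um: float = 1.0
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1)
    transverse_spacing_um: float = 1.8
    z_spacing_um: float = 1.8
    tubule_radius_um: float = 0.25
    axial_element_prob: float = 0.1
    dropout_prob: float = 0.0
    position_jitter_sd_um: float = 0.05
    psf_sigma_um: tuple[float, float, float] = (0.2, 0.1, 0.1)
    noise_sd: float = 0.02
    interior_intensity: float = 0.08
    surface_intensity: float = 2.0  # sarcolemma outshines tubules in surface dyes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transverse_spacing_um <= 2 * self.tubule_radius_um:
            raise SpecError("transverse spacing must exceed the tubule diameter")
        for p in (self.axial_element_prob, self.dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise SpecError("probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size_um):
            raise SpecError("voxel sizes must be positive")

    @property
    def analytic_volume_fraction(self) -> float:
        """Pre-blur transverse-lattice tubule volume fraction (of cell volume)."""
        return (
            math.pi
            * self.tubule_radius_um**2
            / (self.transverse_spacing_um * self.z_spacing_um)
            * (1.0 - self.dropout_prob)
        )


def gen_tats_volume(spec: TatsPhantomSpec) -> tuple[VolumeImage, dict]:
    """Render a tubule-lattice phantom.

    Returns the image and a truth dict with keys ``cell_mask``, ``tats_mask``
    (both pre-blur, voxelised) and ``analytic_volume_fraction_pct``.
    """
    rng = np.random.default_rng(spec.seed)
    ez, ey, ex = spec.cell_extent_um
    dz, dy, dx = spec.voxel_size_um
    m = spec.margin_um
    shape = (
        int(round((ez + 2 * m) / dz)),
        int(round((ey + 2 * m) / dy)),
        int(round((ex + 2 * m) / dx)),
    )
    zc = (np.arange(shape[0]) + 0.5) * dz
    yc = (np.arange(shape[1]) + 0.5) * dy
    xc = (np.arange(shape[2]) + 0.5) * dx

    cell = (
        (zc[:, None, None] >= m)
        & (zc[:, None, None] < m + ez)
        & (yc[None, :, None] >= m)
        & (yc[None, :, None] < m + ey)
        & (xc[None, None, :] >= m)
        & (xc[None, None, :] < m + ex)
    )

    r = spec.tubule_radius_um
    tats = np.zeros(shape, dtype=bool)
    xs = np.arange(m + spec.transverse_spacing_um / 2, m + ex, spec.transverse_spacing_um)
    zs = np.arange(m + spec.z_spacing_um / 2, m + ez, spec.z_spacing_um)
    y_in = (yc >= m) & (yc < m + ey)
    # transverse tubules: axes parallel to y at (x_i, z_j)
    for x0 in xs:
        for z0 in zs:
            if rng.random() < spec.dropout_prob:
                continue
            xj = x0 + rng.normal(0, spec.position_jitter_sd_um)
            zj = z0 + rng.normal(0, spec.position_jitter_sd_um)
            d2 = (zc[:, None] - zj) ** 2 + (xc[None, :] - xj) ** 2
            disk = d2 <= r * r
            if disk.any():
                tats |= disk[:, None, :] & y_in[None, :, None]
    # axial connectors: segments along x between adjacent transverse planes
    for i in range(len(xs) - 1):
        for z0 in zs:
            if rng.random() >= spec.axial_element_prob:
                continue
            y0 = rng.uniform(m + r, m + ey - r)
            z0j = z0 + rng.normal(0, spec.position_jitter_sd_um)
            d2 = (zc[:, None] - z0j) ** 2 + (yc[None, :] - y0) ** 2
            disk = d2 <= r * r
            x_in = (xc >= xs[i]) & (xc <= xs[i + 1])
            tats |= disk[:, :, None] & x_in[None, None, :]
    tats &= cell

    surface = cell & ~ndi.binary_erosion(cell)  # 1-voxel sarcolemmal shell
    img = (
        spec.interior_intensity * cell.astype(float)
        + (1.0 - spec.interior_intensity) * tats.astype(float)
        + spec.surface_intensity * surface.astype(float)
    )
    sigma = tuple(s / v for s, v in zip(spec.psf_sigma_um, spec.voxel_size_um))
    if any(s > 0 for s in sigma):
        img = ndi.gaussian_filter(img, sigma=sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    vol = VolumeImage(voxels=img, voxel_size_um=spec.voxel_size_um, channel="membrane")
    truth = {
        "cell_mask": cell,
        "tats_mask": tats,
        "analytic_volume_fraction_pct": 100.0 * spec.analytic_volume_fraction,
    }
    return vol, truth


# ---------------------------------------------------------------------------
# mitochondrial phantom


@dataclass
class MitoPhantomSpec:
    """Dual-channel mitochondrial phantom (MTG structure, TMRM potential dye).

    The MTG channel is a near-binary mitochondrial mask plus additive noise.
    Channel decorrelation down to ``target_channel_correlation`` is produced
    by a smooth multiplicative texture on the TMRM channel only, mimicking
    membrane-potential heterogeneity between mitochondria; the texture
    amplitude is solved analytically from the requested Pearson r.
    """

    cell_extent_um: tuple[float, float, float] = (5.0, 12.0, 24.0)  # (z, y, x)
    margin_um: float = 1.5
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1)
    mito_volume_fraction: float = 0.30
    cortex_um: float = 0.3  # organelle-free rim below the sarcolemma
    target_channel_correlation: float = 0.7
    mtg_contrast: float = 300.0
    tmrm_contrast: float = 200.0
    background: float = 100.0
    noise_sd: float = 15.0
    structure_sigma_um: float = 0.4
    texture_sigma_um: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mito_volume_fraction < 1.0:
            raise SpecError("mito_volume_fraction must lie in (0, 1)")
        if not -1.0 <= self.target_channel_correlation <= 1.0:
            raise SpecError("target correlation must lie in [-1, 1]")


def gen_mito_volume(
    spec: MitoPhantomSpec,
) -> tuple[VolumeImage, VolumeImage, dict]:
    """Render MTG and TMRM phantom channels.

    Returns (mtg, tmrm, truth) where truth carries ``cell_mask``,
    ``mito_mask``, ``volume_fraction`` and the realised within-cell Pearson
    correlation of the noise-free channels plus the target.
    """
    rng = np.random.default_rng(spec.seed)
    ez, ey, ex = spec.cell_extent_um
    dz, dy, dx = spec.voxel_size_um
    m = spec.margin_um
    shape = (
        int(round((ez + 2 * m) / dz)),
        int(round((ey + 2 * m) / dy)),
        int(round((ex + 2 * m) / dx)),
    )
    zc = (np.arange(shape[0]) + 0.5) * dz
    yc = (np.arange(shape[1]) + 0.5) * dy
    xc = (np.arange(shape[2]) + 0.5) * dx
    cell = (
        (zc[:, None, None] >= m)
        & (zc[:, None, None] < m + ez)
        & (yc[None, :, None] >= m)
        & (yc[None, :, None] < m + ey)
        & (xc[None, None, :] >= m)
        & (xc[None, None, :] < m + ex)
    )

    # blobby mitochondrial structure: smoothed noise thresholded at the
    # quantile that realises the requested volume fraction inside the cell.
    # Mitochondria stay out of a thin cortical rim below the sarcolemma
    # (myofilament/sarcolemma exclusion), so the quantile is taken over the
    # eligible interior at a correspondingly higher occupancy.
    sigma = tuple(spec.structure_sigma_um / v for v in spec.voxel_size_um)
    fieldv = ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    eligible = cell
    if spec.cortex_um > 0:
        depth = ndi.distance_transform_edt(cell, sampling=spec.voxel_size_um)
        eligible = cell & (depth > spec.cortex_um)
    occupancy = spec.mito_volume_fraction * cell.sum() / max(eligible.sum(), 1)
    if occupancy >= 1.0:
        raise SpecError(
            "mito_volume_fraction unreachable with this cortex width: the "
            "eligible interior is smaller than the requested mitochondrial volume"
        )
    thr = np.quantile(fieldv[eligible], 1.0 - occupancy)
    mito = (fieldv > thr) & eligible
    M = mito.astype(float)

    r = spec.target_channel_correlation
    exact = r >= 0.999
    noise_sd = 0.0 if exact else spec.noise_sd

    p = M[cell].mean()

    tsig = tuple(spec.texture_sigma_um / v for v in spec.voxel_size_um)
    tex = ndi.gaussian_filter(rng.standard_normal(shape), sigma=tsig)
    tex = np.clip(tex / tex.std(), -1.2, 1.2)
    tex = tex / tex[cell].std()

    # Solve the texture amplitude u from the realised sample moments so the
    # within-cell Pearson r of (MTG = bg + cm·M + n1, TMRM = bg + ct·M·(1+u·tex)
    # + n2) hits the target exactly up to the noise draw:
    #   r(u) = (A + u·C) / sqrt((A + s1)(A + u²·X + 2u·C + s2))
    # with A = var(M), X = var(M·tex), C = cov(M, M·tex) over the cell and
    # s_i the noise variances scaled by the channel contrasts.
    u = 0.0
    if not exact and 0 < r < 1:
        a = M[cell]
        x = (M * tex)[cell]
        A = float(a.var())
        X = float(x.var())
        C = float(np.cov(a, x)[0, 1])
        s1 = (noise_sd / spec.mtg_contrast) ** 2
        s2 = (noise_sd / spec.tmrm_contrast) ** 2
        r2 = r * r
        qa = C * C - r2 * (A + s1) * X
        qb = 2 * A * C - 2 * r2 * (A + s1) * C
        qc = A * A - r2 * (A + s1) * (A + s2)
        roots = np.roots([qa, qb, qc]) if qa != 0 else np.array([-qc / qb] if qb else [])
        cands = [float(z.real) for z in roots if abs(z.imag) < 1e-9 and z.real > 0]
        u = min(cands) if cands else 0.0

    mtg_clean = spec.background * cell + spec.mtg_contrast * M
    tmrm_clean = spec.background * cell + spec.tmrm_contrast * M * (1.0 + u * tex)
    mtg = mtg_clean + (rng.normal(0, noise_sd, shape) if noise_sd else 0.0)
    tmrm = tmrm_clean + (rng.normal(0, noise_sd, shape) if noise_sd else 0.0)
    mtg = np.clip(mtg, 0, None)
    tmrm = np.clip(tmrm, 0, None)

    a, b = mtg_clean[cell], tmrm_clean[cell]
    realized_r = float(
        np.corrcoef(a, b)[0, 1]
    ) if a.std() > 0 and b.std() > 0 else float("nan")

    truth = {
        "cell_mask": cell,
        "mito_mask": mito,
        "volume_fraction": float(p),
        "target_r": r,
        "realized_clean_r": realized_r,
        "texture_amplitude": u,
    }
    return (
        VolumeImage(mtg, spec.voxel_size_um, channel="mtg"),
        VolumeImage(tmrm, spec.voxel_size_um, channel="tmrm"),
        truth,
    )


# ---------------------------------------------------------------------------
# electrophysiology


@dataclass
class ItoParams:
    """Bi-exponential transient-outward current, density units (pA/pF).

    Defaults anchor to measured adult-rat values: tau_fast 48.7 ms, tau_slow
    322 ms, fast-component contribution 55.2%, peak-minus-end density
    ~42.3 pA/pF on top of a steady delayed-rectifier level of 18.9 pA/pF.
    """

    amp_fast: float = 25.1
    amp_slow: float = 20.4
    tau_fast_s: float = 0.0487
    tau_slow_s: float = 0.322
    steady: float = 18.9

    def __post_init__(self) -> None:
        if self.tau_fast_s >= self.tau_slow_s:
            raise SpecError("tau_fast must be smaller than tau_slow")

    def density(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amp_fast * np.exp(-t / self.tau_fast_s)
            + self.amp_slow * np.exp(-t / self.tau_slow_s)
            + self.steady
        )


@dataclass
class BoltzmannParams:
    v50_mv: float = -34.0
    slope_mv: float = 5.0

    def availability(self, v_mv: np.ndarray) -> np.ndarray:
        """Steady-state inactivation curve (1 at very negative potentials)."""
        return 1.0 / (1.0 + np.exp((np.asarray(v_mv, float) - self.v50_mv) / self.slope_mv))

    def activation(self, v_mv: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v50_mv - np.asarray(v_mv, float)) / self.slope_mv))


@dataclass
class RecoveryParams:
    """Bi-phasic recovery from inactivation: y(t) = 1 - a e^(-t/Kf) - b e^(-t/Ks)."""

    k_fast_s: float = 0.0505
    k_slow_s: float = 1.319
    frac_fast: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_fast <= 1.0:
            raise SpecError("frac_fast must lie in [0, 1]")
        if self.k_fast_s >= self.k_slow_s:
            raise SpecError("K_fast must be smaller than K_slow")

    def fraction_recovered(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, float)
        return (
            1.0
            - self.frac_fast * np.exp(-t / self.k_fast_s)
            - (1.0 - self.frac_fast) * np.exp(-t / self.k_slow_s)
        )


@dataclass
class EphysSimSpec:
    holding_mv: float = -90.0
    step_potentials_mv: tuple[float, ...] = (60, 40, 20, 0, -20, -40, -60, -80)
    step_duration_s: float = 0.6
    pre_s: float = 0.05
    post_s: float = 0.05
    sampling_rate: float = 5000.0
    ito: ItoParams = field(default_factory=ItoParams)
    activation: BoltzmannParams = field(
        default_factory=lambda: BoltzmannParams(v50_mv=5.0, slope_mv=12.0)
    )
    inactivation: BoltzmannParams = field(default_factory=BoltzmannParams)
    recovery: RecoveryParams = field(default_factory=RecoveryParams)
    recovery_first_interval_s: float = 0.005
    recovery_n_intervals: int = 14
    recovery_interval_factor: float = 1.5
    ik1_conductance_pa_pf_mv: float = 0.1716
    ik1_ek_mv: float = -85.0
    leak_pa_pf_mv: float = 0.02
    capacitance_pf: float = 172.6
    noise_sd_pa: float = 0.0
    seed: int = 0


def _make_sweep(
    spec: EphysSimSpec,
    density_of_t: np.ndarray,
    rng: np.random.Generator,
) -> Sweep:
    """Assemble a sweep: zero-ish holding current, pulse, tail; adds noise."""
    n_pre = int(round(spec.pre_s * spec.sampling_rate))
    n_pulse = int(round(spec.step_duration_s * spec.sampling_rate))
    n_post = int(round(spec.post_s * spec.sampling_rate))
    current = np.concatenate(
        [np.zeros(n_pre), density_of_t * spec.capacitance_pf, np.zeros(n_post)]
    )
    if spec.noise_sd_pa > 0:
        current = current + rng.normal(0, spec.noise_sd_pa, current.size)
    time = np.arange(current.size) / spec.sampling_rate
    assert n_pulse == len(density_of_t)
    return Sweep(time=time, signal=current)


def _pulse_time(spec: EphysSimSpec) -> np.ndarray:
    n_pulse = int(round(spec.step_duration_s * spec.sampling_rate))
    return np.arange(n_pulse) / spec.sampling_rate


def gen_vclamp_sweeps(spec: EphysSimSpec, protocol: str = "iv") -> tuple[SweepSet, dict]:
    """Simulate voltage-clamp sweep families.

    protocol:
      ``iv``           — steps +60..−80 mV: Boltzmann-gated bi-exponential decay.
      ``inactivation`` — two-pulse availability protocol; emits the +60 mV test
                         pulses scaled by the conditioning-potential availability.
      ``recovery``     — paired-pulse protocol; inter-pulse intervals grow
                         geometrically by ``recovery_interval_factor``.
      ``ik1``          — control and Ba²⁺-blocked sweep pairs; the difference at
                         end of pulse is the inward-rectifier current.
    """
    rng = np.random.default_rng(spec.seed)
    t = _pulse_time(spec)
    pulse_start = spec.pre_s
    pulse_end = spec.pre_s + spec.step_duration_s

    if protocol == "iv":
        sweeps, rows = [], []
        gate60 = spec.activation.activation(np.array([60.0]))[0]
        for v in spec.step_potentials_mv:
            gate = spec.activation.activation(np.array([float(v)]))[0]
            dens = gate * spec.ito.density(t)
            sweeps.append(_make_sweep(spec, dens, rng))
            rows.append(
                {
                    "v_test_mv": float(v),
                    "pulse_start_s": pulse_start,
                    "pulse_end_s": pulse_end,
                }
            )
        truth = {
            "ito": spec.ito,
            "activation": spec.activation,
            "gate_at_60": gate60,
            "peak_minus_end_density": _analytic_ito_density(spec),
        }
        ss = SweepSet(sweeps, pd.DataFrame(rows), spec.capacitance_pf, kind="iv")
        return ss, truth

    if protocol == "inactivation":
        v_cond = np.arange(-80.0, 10.0 + 1e-9, 10.0)
        avail = spec.inactivation.availability(v_cond)
        sweeps, rows = [], []
        gate60 = spec.activation.activation(np.array([60.0]))[0]
        for v, h in zip(v_cond, avail):
            dens = h * gate60 * spec.ito.density(t)
            sweeps.append(_make_sweep(spec, dens, rng))
            rows.append(
                {
                    "v_test_mv": 60.0,
                    "v_cond_mv": float(v),
                    "pulse_start_s": pulse_start,
                    "pulse_end_s": pulse_end,
                }
            )
        truth = {"availability": dict(zip(v_cond, avail)), "inactivation": spec.inactivation}
        ss = SweepSet(sweeps, pd.DataFrame(rows), spec.capacitance_pf, kind="inactivation")
        return ss, truth

    if protocol == "recovery":
        intervals = spec.recovery_first_interval_s * spec.recovery_interval_factor ** np.arange(
            spec.recovery_n_intervals
        )
        gate60 = spec.activation.activation(np.array([60.0]))[0]
        sweeps, rows = [], []
        for iv in intervals:
            frac = spec.recovery.fraction_recovered(np.array([iv]))[0]
            for role, scale in (("p1", 1.0), ("p2", frac)):
                dens = scale * gate60 * spec.ito.density(t)
                sweeps.append(_make_sweep(spec, dens, rng))
                rows.append(
                    {
                        "v_test_mv": 60.0,
                        "role": role,
                        "interval_s": float(iv),
                        "pulse_start_s": pulse_start,
                        "pulse_end_s": pulse_end,
                    }
                )
        truth = {"recovery": spec.recovery, "intervals_s": intervals}
        ss = SweepSet(sweeps, pd.DataFrame(rows), spec.capacitance_pf, kind="recovery")
        return ss, truth

    if protocol == "ik1":
        potentials = spec.step_potentials_mv
        sweeps, rows = [], []
        for blocked in (False, True):
            for v in potentials:
                leak = spec.leak_pa_pf_mv * (v - spec.holding_mv)
                dens_end = leak
                if not blocked:
                    rect = 1.0 / (1.0 + math.exp((v + 60.0) / 15.0))
                    dens_end = leak + spec.ik1_conductance_pa_pf_mv * (v - spec.ik1_ek_mv) * rect
                dens = np.full_like(t, dens_end)
                sweeps.append(_make_sweep(spec, dens, rng))
                rows.append(
                    {
                        "v_test_mv": float(v),
                        "condition": "blocked" if blocked else "control",
                        "pulse_start_s": pulse_start,
                        "pulse_end_s": pulse_end,
                    }
                )
        ik1_true = {
            float(v): spec.ik1_conductance_pa_pf_mv
            * (v - spec.ik1_ek_mv)
            / (1.0 + math.exp((v + 60.0) / 15.0))
            for v in potentials
        }
        truth = {"ik1_density": ik1_true}
        ss = SweepSet(sweeps, pd.DataFrame(rows), spec.capacitance_pf, kind="ik1")
        return ss, truth

    raise SpecError(f"unknown protocol {protocol!r}")


def _analytic_ito_density(spec: EphysSimSpec) -> float:
    """Closed-form peak-minus-end density at +60 mV (gating included)."""
    gate = spec.activation.activation(np.array([60.0]))[0]
    p = spec.ito
    peak = p.amp_fast + p.amp_slow + p.steady
    end = (
        p.amp_fast * math.exp(-spec.step_duration_s / p.tau_fast_s)
        + p.amp_slow * math.exp(-spec.step_duration_s / p.tau_slow_s)
        + p.steady
    )
    return gate * (peak - end)


@dataclass
class ApSimSpec:
    """Current-clamp action-potential train template.

    The repolarisation is a single exponential whose time constant is set by
    ``apd50_ms`` (τ = APD50/ln 2, measured from the upstroke onset); the
    upstroke is a linear ramp of ``rise_time_ms``.  This is a measurement
    template, not a biophysical membrane model.
    """

    rmp_mv: float = -85.0
    overshoot_mv: float = 30.0
    apd50_ms: float = 40.0
    n_beats: int = 35
    pacing_hz: float = 1.0
    noise_sd_mv: float = 0.3
    sampling_rate: float = 10000.0
    rise_time_ms: float = 1.0
    lead_in_s: float = 0.1
    seed: int = 0


def gen_ap_trace(spec: ApSimSpec) -> tuple[TimeSeriesRecording, dict]:
    """Simulate a paced AP train; truth gives all per-beat metrics in closed form."""
    if spec.n_beats < 30:
        warnings.warn(
            "fewer than 30 paced beats: the 30th-AP analysis rule cannot be applied",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate
    total = spec.lead_in_s + spec.n_beats / spec.pacing_hz
    n = int(round(total * spec.sampling_rate))
    time = np.arange(n) / spec.sampling_rate
    v = np.full(n, spec.rmp_mv)

    peak = spec.overshoot_mv
    amp = peak - spec.rmp_mv
    tau = spec.apd50_ms / 1000.0 / math.log(2.0)
    rise_s = spec.rise_time_ms / 1000.0
    beat_times = spec.lead_in_s + np.arange(spec.n_beats) / spec.pacing_hz
    seg = np.arange(0.0, 0.95 / spec.pacing_hz, dt)
    ramp_n = max(1, int(round(rise_s / dt)))
    template = np.where(
        seg < rise_s,
        spec.rmp_mv + amp * seg / rise_s,
        spec.rmp_mv + amp * np.exp(-(seg - rise_s) / tau),
    )
    for bt in beat_times:
        i0 = int(round(bt * spec.sampling_rate))
        i1 = min(n, i0 + template.size)
        v[i0:i1] = template[: i1 - i0]
    if spec.noise_sd_mv > 0:
        v = v + rng.normal(0, spec.noise_sd_mv, n)

    def apd(frac: float) -> float:
        return 1000.0 * (rise_s + tau * math.log(1.0 / (1.0 - frac)))

    truth = {
        "rmp_mv": spec.rmp_mv,
        "overshoot_mv": peak,
        "dvdt_max_mv_ms": amp / spec.rise_time_ms,
        "apd20_ms": apd(0.20),
        "apd50_ms": apd(0.50),
        "apd90_ms": apd(0.90),
        "apd_0mv_ms": 1000.0 * (rise_s + tau * math.log(amp / (0.0 - spec.rmp_mv))),
        "beat_times_s": beat_times,
        "ramp_samples": ramp_n,
    }
    rec = TimeSeriesRecording(
        time=time, channels={"membrane_potential": v}, sampling_rate=spec.sampling_rate
    )
    return rec, truth


# ---------------------------------------------------------------------------
# group samples for the statistics layer


@dataclass
class GroupSimSpec:
    """Two-group per-cell metric harness with a controllable relative effect."""

    n_per_group: int = 30
    control_mean: float = 1.0
    relative_effect: float = 0.0
    coefficient_of_variation: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SpecError("need at least two cells per group")
        if self.coefficient_of_variation < 0:
            raise SpecError("coefficient of variation must be >= 0")


def gen_group_samples(spec: GroupSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (control, treated) samples; treated mean = (1+effect)·control mean.

    Both groups share the coefficient of variation, so the treated SD scales
    with its mean.
    """
    rng = np.random.default_rng(spec.seed)
    mu_a = spec.control_mean
    mu_b = spec.control_mean * (1.0 + spec.relative_effect)
    cv = spec.coefficient_of_variation
    a = rng.normal(mu_a, abs(mu_a) * cv, spec.n_per_group)
    b = rng.normal(mu_b, abs(mu_b) * cv, spec.n_per_group)
    return a, b
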