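"""Synthetic generators for arterial-pressure recordings, tachograms, ITT
curves and group cohorts.

Every downstream stage of the pipeline (beat detection, variability
spectra, KITT estimation, group statistics) is validated against data
produced here, where the ground truth is known by construction: the
pulse-interval oscillation amplitudes, the glucose decay constant, the
cohort means/SDs and pairwise correlations are all inputs.

The tachogram model is additive: PI(t) = base + A_LF sin(2*pi*f_LF*t)
+ A_HF sin(2*pi*f_HF*t) + white noise, turned into a beat train by the
integrate-and-fire rule t[k+1] = t[k] + PI(t[k]).  Defaults describe a
conscious rat: base PI 150 ms (400 bpm), a low-frequency (Mayer-wave)
rhythm near 0.4 Hz and a respiratory rhythm near 1.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import PressureWaveform

__all__ = [
    "TachogramSpec",
    "PulseShapeSpec",
    "CohortSpec",
    "Tachogram",
    "simulate_tachogram",
    "render_waveform",
    "simulate_itt",
    "simulate_cohort",
]

ITT_SAMPLE_TIMES_MIN = (0.0, 4.0, 8.0, 12.0, 16.0)


@dataclass(frozen=True)
class TachogramSpec:
    """Parameters of a modulated pulse-interval (tachogram) simulation.

    Amplitudes and the noise SD are in milliseconds; frequencies in Hz;
    duration in seconds.  The constraint ``amp_lf + amp_hf + 3*noise_sd
    < base_pi`` keeps every generated interval positive.
    """

    base_pi: float = 150.0
    amp_lf: float = 0.0
    freq_lf: float = 0.4
    amp_hf: float = 0.0
    freq_hf: float = 1.5
    noise_sd: float = 0.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_pi <= 0:
            raise ValueError("base_pi must be positive")
        if self.amp_lf < 0 or self.amp_hf < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not 0 < self.freq_lf < self.freq_hf:
            raise ValueError("need 0 < freq_lf < freq_hf")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amp_lf + self.amp_hf + 3.0 * self.noise_sd >= self.base_pi:
            raise ValueError(
                "amp_lf + amp_hf + 3*noise_sd must be < base_pi "
                "(risk of non-positive pulse intervals)"
            )


@dataclass(frozen=True)
class PulseShapeSpec:
    """Shape of one rendered arterial pulse.

    A raised-cosine systolic upstroke from DAP to SAP over
    ``upstroke_fraction`` of the median beat, followed by an exponential
    diastolic decay back to DAP; gives unambiguous per-beat extrema for
    detector testing.
    """

    sap: float = 180.0
    dap: float = 120.0
    upstroke_fraction: float = 0.25
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        if not self.sap > self.dap > 0:
            raise ValueError("need sap > dap > 0")
        if not 0 < self.upstroke_fraction < 1:
            raise ValueError("upstroke_fraction must be in (0, 1)")
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated treatment group: per-variable normal marginals with
    optional pairwise correlation targets.

    ``means``/``sds`` map variable name -> value. ``correlations`` is a
    list of (var_a, var_b, r) constraints; the implied correlation
    matrix must be positive semi-definite.
    """

    group_name: str
    means: dict[str, float]
    sds: dict[str, float]
    n: int
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same variables")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SDs must be non-negative")
        for a, b, r in self.correlations:
            if a not in self.means or b not in self.means:
                raise ValueError(f"correlation names unknown variable: {a!r}/{b!r}")
            if abs(r) > 1:
                raise ValueError("|r| must be <= 1")

    def correlation_matrix(self) -> tuple[list[str], np.ndarray]:
        names = list(self.means)
        idx = {v: i for i, v in enumerate(names)}
        corr = np.eye(len(names))
        for a, b, r in self.correlations:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("requested correlation matrix is not positive semi-definite")
        return names, corr


@dataclass(frozen=True)
class Tachogram:
    """A beat train: systolic times (s) and the pulse interval (ms)
    starting at each beat. ``pi[k] = 1000*(times[k+1] - times[k])`` for
    all but the final beat, whose PI is the modulation value at its time."""

    times: np.ndarray
    pi: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def _modulation(spec: TachogramSpec, t: np.ndarray | float) -> np.ndarray | float:
    return (
        spec.base_pi
        + spec.amp_lf * np.sin(2.0 * np.pi * spec.freq_lf * t)
        + spec.amp_hf * np.sin(2.0 * np.pi * spec.freq_hf * t)
    )


def simulate_tachogram(spec: TachogramSpec) -> Tachogram:
    """Generate a beat train by integrate-and-fire on the modulated PI.

    Beat times start at 0 and advance by the instantaneous PI evaluated
    at the current beat, plus per-beat Gaussian noise.  Deterministic
    for a fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    # worst-case beat count bound for preallocation
    min_pi_s = (spec.base_pi - spec.amp_lf - spec.amp_hf - 5 * spec.noise_sd) / 1000.0
    cap = int(spec.duration / max(min_pi_s, 1e-6)) + 8
    times = np.empty(cap)
    pis = np.empty(cap)
    t = 0.0
    k = 0
    while t <= spec.duration:
        pi = float(_modulation(spec, t))
        if spec.noise_sd > 0:
            pi += spec.noise_sd * rng.standard_normal()
        if pi <= 0:
            raise ValueError("spec produced a non-positive pulse interval")
        times[k] = t
        pis[k] = pi
        t += pi / 1000.0
        k += 1
    return Tachogram(times=times[:k].copy(), pi=pis[:k].copy())


def render_waveform(beats: np.ndarray | Tachogram, shape: PulseShapeSpec) -> PressureWaveform:
    """Render a beat train into a uniformly sampled pressure waveform.

    ``beats`` are systolic-peak times (s), strictly increasing.  Each
    inter-beat interval is an exponential diastolic decay from SAP that
    reaches DAP exactly when the next upstroke begins, then a
    raised-cosine rise back to SAP at the next peak time.  The upstroke
    duration is fixed (upstroke_fraction of the median interval) so
    peak-to-peak spacing reproduces the input intervals exactly.
    """
    if isinstance(beats, Tachogram):
        beats = beats.times
    beats = np.asarray(beats, dtype=float)
    if beats.ndim != 1 or len(beats) < 1:
        raise ValueError("need at least one beat time")
    if len(beats) > 1 and np.any(np.diff(beats) <= 0):
        raise ValueError("beat times must be strictly increasing")

    fs = shape.sampling_rate
    med_pi = float(np.median(np.diff(beats))) if len(beats) > 1 else 0.15
    if med_pi * fs < 10:
        raise ValueError(
            f"sampling_rate {fs} Hz resolves fewer than 10 samples per beat "
            f"(median interval {med_pi:.4f} s)"
        )
    u_dur = shape.upstroke_fraction * med_pi
    if len(beats) > 1:
        u_dur = min(u_dur, 0.9 * float(np.min(np.diff(beats))))

    start = beats[0] - u_dur
    stop = beats[-1] + med_pi - u_dur
    n = int(np.floor((stop - start) * fs)) + 1
    t = start + np.arange(n) / fs

    sap, dap = shape.sap, shape.dap
    # peak index for each sample: beat whose peak is the next at/after
    # the sample's upstroke, i.e. segment k covers [beats[k], beats[k+1])
    seg = np.searchsorted(beats, t, side="right") - 1
    seg = np.clip(seg, 0, len(beats) - 1)
    t_peak = beats[seg]
    if len(beats) > 1:
        next_peak = np.append(beats[1:], beats[-1] + med_pi)
    else:
        next_peak = np.array([beats[0] + med_pi])
    decay_len = next_peak[seg] - t_peak - u_dur
    tau = (t - t_peak) / np.maximum(decay_len, 1e-9)

    # decay: sap -> dap over decay_len, hitting dap exactly at the end
    e3 = np.exp(-3.0)
    b = (sap - dap) / (1.0 - e3)
    a = sap - b
    pressure = a + b * np.exp(-3.0 * np.clip(tau, 0.0, 1.0))
    # upstroke region: tau > 1 (within u_dur of the next peak) or before
    # the first peak
    phase = (t - (t_peak + decay_len)) / u_dur
    rising = tau > 1.0
    pressure[rising] = dap + (sap - dap) * 0.5 * (
        1.0 - np.cos(np.pi * np.clip(phase[rising], 0.0, 1.0))
    )
    pre = t < beats[0]
    if np.any(pre):
        ph = 1.0 + (t[pre] - beats[0]) / u_dur
        pressure[pre] = dap + (sap - dap) * 0.5 * (1.0 - np.cos(np.pi * np.clip(ph, 0.0, 1.0)))
    return PressureWaveform(samples=pressure, sampling_rate=fs, start_time=float(start))


def simulate_itt(
    g0: float,
    k: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    times: tuple[float, ...] = ITT_SAMPLE_TIMES_MIN,
):
    """Simulate an insulin-tolerance-test glucose curve.

    Expected value G(t) = g0*exp(-k*t) sampled at ``times`` minutes
    (default 0/4/8/12/16 after the insulin bolus), with additive
    Gaussian measurement noise in mg/dL.
    """
    from .metabolic import ITTCurve

    if g0 <= 0:
        raise ValueError("g0 must be positive")
    if k < 0:
        raise ValueError("decay constant k must be non-negative")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    glucose = g0 * np.exp(-k * t)
    if noise_sd > 0:
        glucose = glucose + noise_sd * rng.standard_normal(t.shape)
    return ITTCurve(times=t, glucose=glucose)


def simulate_cohort(spec: CohortSpec):
    """Draw a cohort table (animal, variable, value) in long format.

    Values come from a multivariate normal with the requested marginal
    means/SDs and pairwise correlations; at large n the sample moments
    converge to the spec.  Matches the mean +/- SEM reporting convention
    of summary tables (normality is this module's assumption).
    """
    import pandas as pd

    names, corr = spec.correlation_matrix()
    sd = np.array([spec.sds[v] for v in names])
    mean = np.array([spec.means[v] for v in names])
    cov = corr * np.outer(sd, sd)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(mean, cov, size=spec.n, method="svd")
    frames = pd.DataFrame(draws, columns=names)
    frames.insert(0, "animal", [f"{spec.group_name}-{i + 1}" for i in range(spec.n)])
    long = frames.melt(id_vars="animal", var_name="variable", value_name="value")
    long.insert(1, "group", spec.group_name)
    return long.sort_values(["variable", "animal"], kind="stable").reset_index(drop=True)
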