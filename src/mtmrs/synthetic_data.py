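"""Synthetic ³¹P MT-MRS data with known ground-truth exchange rates.

Forward model of the magnetisation-transfer experiment: a pulse train of
``n`` selective saturation pulses applied on the γ-ATP resonance drives an
exchange-mediated signal loss in Pi(i) (ATP synthase pathway) and PCr
(creatine kinase pathway).  Each acquisition is a complex free induction
decay (FID) built from damped complex exponentials — one per metabolite
resonance — plus a broad short-T2* phospholipid component, additive complex
Gaussian noise, and 0th/1st-order phase errors.

The saturation-transfer signal fraction follows the Forsén–Hoffman two-site
result

    S(τ)/S0 = R_inf + (1 − R_inf) · exp(−τ/T_app),

with R_inf = 1/(1 + k_f·T1) and 1/T_app = 1/T1 + k_f.  This steady-state
form is algebraically identical to the k_f·T_app·e^(−τ/T_app) + T_app/T1
expression used by the fitting side (:mod:`mtmrs.exchange_kinetics`) but is
implemented independently so that round-trip tests exercise two distinct
code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AcquisitionConfig",
    "GroundTruth",
    "Condition",
    "FidSeries",
    "Peak",
    "DEFAULT_PEAKS",
    "decay_fraction",
    "bloch_mcconnell_decay",
    "simulate_fid",
    "simulate_session",
    "make_phantom_cohort",
    "Cohort",
    "SubjectPhantom",
]


# --------------------------------------------------------------------------
# configuration / ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of the MT ³¹P FID experiment.

    Defaults follow a 3 T clinical protocol: 32 averages, TR 12 s, 3000 Hz
    bandwidth, 2048 complex points, MT trains of 0/3/6/12/18/30/44 pulses of
    114.29 ms interleaved with a 5 ms spoiler and 50 ms delay, and an
    off-resonance control at +15 ppm.  The ³¹P spectrometer frequency
    defaults to 49.9 MHz (nominal 3 T).
    """

    spectrometer_frequency: float = 49.9      # MHz
    bandwidth: float = 3000.0                 # Hz
    n_points: int = 2048
    n_averages: int = 32
    tr: float = 12.0                          # s
    pulse_duration: float = 0.11429           # s
    spoiler_duration: float = 0.005           # s
    inter_pulse_delay: float = 0.050          # s
    pulse_counts: tuple[int, ...] = (0, 3, 6, 12, 18, 30, 44)
    control_offset: float = 15.0              # ppm
    control_pulses: int = 30

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_points < 2 or (self.n_points & (self.n_points - 1)) != 0:
            raise ValueError("n_points must be a power of two")
        if self.spectrometer_frequency <= 0:
            raise ValueError("spectrometer_frequency must be positive")
        counts = self.pulse_counts
        if any(c < 0 for c in counts):
            raise ValueError("pulse_counts must be nonnegative")
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("pulse_counts must be strictly increasing")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds (1/bandwidth)."""
        return 1.0 / self.bandwidth

    @property
    def acquisition_duration(self) -> float:
        """FID read-out duration, n_points/bandwidth."""
        return self.n_points / self.bandwidth

    @property
    def pulse_unit_duration(self) -> float:
        """Length of one MT train element: pulse + spoiler + delay."""
        return self.pulse_duration + self.spoiler_duration + self.inter_pulse_delay

    def tau(self, n_pulses: int) -> float:
        """Saturation-transfer time for an ``n_pulses`` MT train."""
        if n_pulses < 0:
            raise ValueError("n_pulses must be nonnegative")
        return n_pulses * self.pulse_unit_duration

    @property
    def tau_grid(self) -> np.ndarray:
        return np.array([self.tau(n) for n in self.pulse_counts])

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time


@dataclass(frozen=True)
class Peak:
    """One resonance: label, chemical shift (ppm, PCr = 0), amplitude, FWHM (Hz)."""

    label: str
    shift: float
    amplitude: float
    linewidth: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"peak {self.label}: amplitude must be nonnegative")
        if self.linewidth <= 0:
            raise ValueError(f"peak {self.label}: linewidth must be positive")


#: Default brain ³¹P peak table (shifts per standard assignments, amplitudes
#: in arbitrary units with PCr dominant and Pi small, linewidths in Hz).
DEFAULT_PEAKS: tuple[Peak, ...] = (
    Peak("PME", 6.8, 0.9, 28.0),
    Peak("Pi_e", 5.2, 0.45, 11.0),
    Peak("Pi_i", 4.9, 1.1, 11.0),
    Peak("PDE", 2.9, 1.4, 32.0),
    Peak("PCr", 0.0, 5.0, 8.0),
    Peak("gATP", -2.5, 2.2, 13.0),
    Peak("aATP", -7.5, 2.2, 15.0),
    Peak("bATP", -16.0, 1.9, 17.0),
)


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters of one synthetic session.

    ``kf_pi``/``kf_pcr`` are the forward exchange rates seen by Pi(i)
    (ATP synthase) and PCr (creatine kinase); ``t1_pi``/``t1_pcr`` the
    intrinsic longitudinal relaxation times.  ``delta_pi_i`` is the Pi(i)
    chemical shift, which encodes intracellular pH.
    """

    kf_pi: float = 0.2            # s^-1
    kf_pcr: float = 0.35          # s^-1
    t1_pi: float = 3.1            # s
    t1_pcr: float = 5.1           # s
    peak_table: tuple[Peak, ...] = DEFAULT_PEAKS
    baseline_amplitude: float = 2.0   # broad phospholipid component, a.u.
    baseline_linewidth: float = 500.0  # Hz
    noise_sd: float = 0.0         # complex noise sd per FID point, a.u.
    phase0: float = 0.0           # rad
    phase1: float = 0.0           # rad/ppm
    delta_pi_i: float = 4.9       # ppm
    gamma_sat_tau: float = 0.05   # s, γ-ATP saturation onset constant

    def __post_init__(self) -> None:
        for name in ("kf_pi", "kf_pcr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("t1_pi", "t1_pcr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (4.0 < self.delta_pi_i < 6.0):
            raise ValueError("delta_pi_i must lie within (4, 6) ppm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def peaks_with_pi_shift(self) -> tuple[Peak, ...]:
        """Peak table with the Pi(i) shift replaced by ``delta_pi_i``."""
        return tuple(
            replace(p, shift=self.delta_pi_i) if p.label == "Pi_i" else p
            for p in self.peak_table
        )


@dataclass(frozen=True)
class Condition:
    """Saturation condition of one scan.

    ``kind`` is ``saturation`` (MT train on γ-ATP at −2.5 ppm), ``control``
    (+15 ppm off-resonance) or ``selectivity`` (+2.5 ppm check).
    """

    kind: str
    n_pulses: int
    offset: float  # ppm

    KINDS = ("saturation", "control", "selectivity")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be nonnegative")

    @classmethod
    def saturation(cls, n_pulses: int, offset: float = -2.5) -> "Condition":
        return cls("saturation", n_pulses, offset)

    @classmethod
    def control(cls, n_pulses: int = 30, offset: float = 15.0) -> "Condition":
        return cls("control", n_pulses, offset)

    @classmethod
    def selectivity(cls, n_pulses: int = 30, offset: float = 2.5) -> "Condition":
        return cls("selectivity", n_pulses, offset)

    @property
    def id(self) -> str:
        return f"{self.kind}_n{self.n_pulses}_at{self.offset:+g}ppm"


@dataclass
class FidSeries:
    """One complex FID with its saturation condition and acquisition metadata."""

    samples: np.ndarray
    condition: Condition
    tau: float
    acquisition: AcquisitionConfig
    subject_id: str = "sim"
    session_label: str = "pre"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if len(self.samples) != self.acquisition.n_points:
            raise ValueError(
                f"FID has {len(self.samples)} samples, expected "
                f"{self.acquisition.n_points}"
            )

    def copy_with(self, samples: np.ndarray, step: dict | None = None) -> "FidSeries":
        new = FidSeries(
            samples=samples,
            condition=self.condition,
            tau=self.tau,
            acquisition=self.acquisition,
            subject_id=self.subject_id,
            session_label=self.session_label,
            history=list(self.history),
        )
        if step is not None:
            new.history.append(step)
        return new


# --------------------------------------------------------------------------
# exchange model
# --------------------------------------------------------------------------

def decay_fraction(kf: float, t1: float, tau) -> np.ndarray | float:
    """Forsén–Hoffman saturation-transfer signal fraction S(τ)/S0.

    Steady-state/transient decomposition: the observed pool relaxes from 1
    toward R_inf = 1/(1 + kf·T1) with apparent time constant
    T_app = 1/(1/T1 + kf).  Monotonically nonincreasing in τ and kf,
    bounded in (0, 1].

    Parameters
    ----------
    kf : forward exchange rate, s^-1 (≥ 0)
    t1 : intrinsic longitudinal relaxation time, s (> 0)
    tau : saturation time(s), s (≥ 0); scalar or array
    """
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    if kf < 0:
        raise ValueError("kf must be nonnegative")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    t_app = 1.0 / (1.0 / t1 + kf)
    r_inf = 1.0 / (1.0 + kf * t1)
    out = r_inf + (1.0 - r_inf) * np.exp(-tau / t_app)
    return float(out) if out.ndim == 0 else out


def bloch_mcconnell_decay(
    kf: float,
    t1: float,
    tau_grid,
    saturation_efficiency: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Two-pool Bloch–McConnell longitudinal-exchange oracle.

    Integrates dM/dt = (M0 − M)/T1 − kf·M + kr·M_sat for the observed pool,
    with the saturated partner pool clamped at (1 − efficiency)·M_sat0 and
    detailed balance kr·M_sat0 = kf·M0.  At ``saturation_efficiency = 1``
    this reproduces the closed-form :func:`decay_fraction`; at lower
    efficiency the decay is shallower.  Numerical ODE integration — kept
    deliberately independent of any closed-form expression so it can act as
    an oracle for the analytic model.
    """
    if not 0.0 <= saturation_efficiency <= 1.0:
        raise ValueError("saturation_efficiency must be in [0, 1]")
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    if kf < 0:
        raise ValueError("kf must be nonnegative")
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if tau_grid.size == 0:
        raise ValueError("tau_grid must not be empty")
    if np.any(tau_grid < 0):
        raise ValueError("tau values must be nonnegative")

    m0 = 1.0
    reverse_influx = (1.0 - saturation_efficiency) * kf * m0

    def rhs(_t, y):
        return [(m0 - y[0]) / t1 - kf * y[0] + reverse_influx]

    t_end = float(tau_grid.max())
    out = np.empty_like(tau_grid)
    if t_end == 0.0:
        out[:] = m0
        return out
    positive = tau_grid > 0
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [m0],
        t_eval=np.sort(np.unique(tau_grid[positive])),
        rtol=rtol,
        atol=atol,
        method="RK45",
        max_step=t_end / 50.0,
    )
    lookup = dict(zip(sol.t, sol.y[0]))
    out[~positive] = m0
    out[positive] = [lookup[t] for t in tau_grid[positive]]
    return out


# --------------------------------------------------------------------------
# FID synthesis
# --------------------------------------------------------------------------

def _peak_scale(truth: GroundTruth, peak: Peak, condition: Condition, tau: float) -> float:
    """Amplitude scale factor applied to ``peak`` under ``condition``."""
    if condition.kind != "saturation" or tau == 0.0:
        return 1.0
    if peak.label == "Pi_i":
        return decay_fraction(truth.kf_pi, truth.t1_pi, tau)
    if peak.label == "PCr":
        return decay_fraction(truth.kf_pcr, truth.t1_pcr, tau)
    if peak.label == "gATP":
        # near-instant full saturation of the irradiated resonance
        return math.exp(-tau / truth.gamma_sat_tau)
    return 1.0


def simulate_fid(
    truth: GroundTruth,
    condition: Condition,
    acq: AcquisitionConfig | None = None,
    seed: int | None = 0,
    subject_id: str = "sim",
    session_label: str = "pre",
) -> FidSeries:
    """Simulate one complex FID for a saturation condition.

    Each resonance contributes A·exp(i·2π·f·t − t/T2*) with f = shift·f0
    (f0 in MHz gives Hz per ppm) and T2* = 1/(π·FWHM).  Pi(i) and PCr are
    attenuated by the exchange decay fraction at the condition's τ; γ-ATP is
    suppressed under on-resonance saturation.  A broad short-T2* component
    models the phospholipid baseline.  Phase errors are applied in the
    frequency domain; complex Gaussian noise is added last.  Deterministic
    for a given seed.
    """
    acq = acq or AcquisitionConfig()
    tau = acq.tau(condition.n_pulses)
    f0 = acq.spectrometer_frequency  # MHz -> Hz per ppm
    half_bw_ppm = acq.bandwidth / 2.0 / f0

    t = acq.time_axis()
    fid = np.zeros(acq.n_points, dtype=complex)
    for peak in truth.peaks_with_pi_shift():
        if abs(peak.shift) >= half_bw_ppm:
            raise ValueError(
                f"peak {peak.label} at {peak.shift} ppm falls outside the "
                f"±{half_bw_ppm:.1f} ppm spectral window"
            )
        scale = _peak_scale(truth, peak, condition, tau)
        freq_hz = peak.shift * f0
        t2_star = 1.0 / (math.pi * peak.linewidth)
        fid += (peak.amplitude * scale) * np.exp(
            (2j * math.pi * freq_hz - 1.0 / t2_star) * t
        )
    if truth.baseline_amplitude > 0:
        t2_broad = 1.0 / (math.pi * truth.baseline_linewidth)
        fid += truth.baseline_amplitude * np.exp(-t / t2_broad)

    if truth.phase0 != 0.0 or truth.phase1 != 0.0:
        freqs = np.fft.fftfreq(acq.n_points, d=acq.dwell_time)
        ppm = freqs / f0
        spec = np.fft.fft(fid)
        spec *= np.exp(1j * (truth.phase0 + truth.phase1 * ppm))
        fid = np.fft.ifft(spec)

    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + truth.noise_sd * (
            rng.standard_normal(acq.n_points)
            + 1j * rng.standard_normal(acq.n_points)
        )

    return FidSeries(
        samples=fid,
        condition=condition,
        tau=tau,
        acquisition=acq,
        subject_id=subject_id,
        session_label=session_label,
    )


def simulate_session(
    truth: GroundTruth,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    session_label: str = "pre",
) -> list[FidSeries]:
    """All saturation conditions of one session plus the +15 ppm control."""
    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    fids = []
    conditions = [Condition.saturation(n) for n in acq.pulse_counts]
    conditions.append(Condition.control(acq.control_pulses, acq.control_offset))
    for cond in conditions:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fids.append(
            simulate_fid(truth, cond, acq, seed=sub_seed,
                         subject_id=subject_id, session_label=session_label)
        )
    return fids


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class SubjectPhantom:
    subject_id: str
    age: float
    truth_pre: GroundTruth
    truth_post: GroundTruth
    sessions: dict  # session label -> list[FidSeries]


@dataclass
class Cohort:
    subjects: list
    acquisition: AcquisitionConfig
    seed: int

    def ground_truth_table(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            for label, truth in (("pre", s.truth_pre), ("post", s.truth_post)):
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "session": label,
                        "age": s.age,
                        "kf_pi": truth.kf_pi,
                        "kf_pcr": truth.kf_pcr,
                        "t1_pi": truth.t1_pi,
                        "t1_pcr": truth.t1_pcr,
                        "delta_pi_i": truth.delta_pi_i,
                        "noise_sd": truth.noise_sd,
                        "phase0": truth.phase0,
                        "phase1": truth.phase1,
                    }
                )
        return pd.DataFrame(rows)


def _sample_positive(rng, mean: float, sd: float, floor: float = 1e-3) -> float:
    """Normal draw rejected to the positive axis."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    raise RuntimeError("could not draw a positive rate; check the distribution")


#: Default per-session measurement-independent cohort parameters: paired
#: design where each subject's post rate is pre + effect, with the effect
#: itself varying across subjects.
DEFAULT_EFFECT_SD = 0.03
DEFAULT_NOISE_SD = 0.025


def make_phantom_cohort(
    n_subjects: int = 7,
    pre_kf_distribution: tuple[float, float] = (0.2, 0.05),
    post_kf_distribution: tuple[float, float] = (0.3, 0.05),
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    effect_sd: float = DEFAULT_EFFECT_SD,
    paired: bool = True,
    phase0_sd: float = 0.15,
    phase1_sd: float = 0.02,
    base_truth: GroundTruth | None = None,
) -> Cohort:
    """Simulate a pre/post cohort with subject-level rate variability.

    ``pre_kf_distribution``/``post_kf_distribution`` are (mean, sd) of the
    subject-level ATP-synthase rates.  With ``paired=True`` (default) each
    subject's post-treatment rate is its pre rate plus a normal effect of
    mean ``post_mean − pre_mean`` and sd ``effect_sd``, mimicking a
    within-subject treatment response; with ``paired=False`` pre and post
    are drawn independently.  All sampling derives from ``seed``; a fixed
    seed yields a byte-identical serialised cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for name, (mean, sd) in (
        ("pre_kf_distribution", pre_kf_distribution),
        ("post_kf_distribution", post_kf_distribution),
    ):
        if mean <= 0:
            raise ValueError(f"{name}: mean rate must be positive")
        if sd < 0:
            raise ValueError(f"{name}: sd must be nonnegative")

    acq = acq or AcquisitionConfig()
    base = base_truth or GroundTruth(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    pre_mean, pre_sd = pre_kf_distribution
    post_mean, post_sd = post_kf_distribution

    subjects = []
    for i in range(n_subjects):
        kf_pre = _sample_positive(rng, pre_mean, pre_sd)
        if paired:
            kf_post = kf_pre + rng.normal(post_mean - pre_mean, effect_sd)
            kf_post = max(kf_post, 1e-3)
        else:
            kf_post = _sample_positive(rng, post_mean, post_sd)
        age = float(rng.uniform(60, 85))
        phases = {
            label: (rng.normal(0.0, phase0_sd), rng.normal(0.0, phase1_sd))
            for label in ("pre", "post")
        }
        truth_pre = replace(
            base, kf_pi=kf_pre, noise_sd=noise_sd,
            phase0=phases["pre"][0], phase1=phases["pre"][1],
        )
        truth_post = replace(
            base, kf_pi=kf_post, noise_sd=noise_sd,
            phase0=phases["post"][0], phase1=phases["post"][1],
        )
        sid = f"S{i + 1:02d}"
        sessions = {}
        for label, truth in (("pre", truth_pre), ("post", truth_post)):
            session_seed = int(rng.integers(0, 2**31 - 1))
            sessions[label] = simulate_session(
                truth, acq, seed=session_seed, subject_id=sid, session_label=label
            )
        subjects.append(
            SubjectPhantom(sid, age, truth_pre, truth_post, sessions)
        )
    return Cohort(subjects=subjects, acquisition=acq, seed=seed)
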