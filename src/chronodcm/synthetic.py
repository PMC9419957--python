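"""Seeded synthetic resting-state cohorts from the generative model.

The generator emulates the study design the analysis expects: six two-hour
timespan groups between 09:00 and 21:00, two sessions (LR/RL phase encoding)
per subject, and multi-ROI BOLD series produced by power-law endogenous
fluctuations filtered through stable linear neuronal dynamics and the
nonlinear Balloon model, plus power-law observation noise and motion/WM/CSF
confound regressors.  Group-level time-of-day effects follow any of the 18
design-space models and are injected on a configurable subset of parameters
(hemodynamic, spectral, or connectivity), so the full pipeline can be scored
against a known ground truth.

Defaults mirror the study conditions: TR 0.72 s, 1200 volumes (14.4 min),
6 timespans x 2 sessions, 96 subjects per timespan, and a model-7 effect (a
deviation over the two morning timespans) of 0.1 on the log scale of the
decay and CSD-amplitude parameters, against a between-subject SD of 0.1.
Everything scales down for desk-sized runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .forward import (
    BALLOON,
    DCMParams,
    HemoConstants,
    bold_observer,
    innovation_spectrum,
)
from .model_space import N_TIMESPANS, SESSIONS, default_scheme, time_effect_column

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SubjectRecord",
    "make_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

BURN_IN_VOLUMES = 64
OVERSAMPLE = 16  # integration steps per TR
N_CONFOUNDS = 14  # 12 motion-like + WM-like + CSF-like
MAX_STABILITY_DRAWS = 64

#: required damping margin (Hz) on the neuronal eigenvalues of simulated
#: systems: poles slower than this produce near-critical excursions that the
#: nonlinear Balloon model cannot absorb, and a <10 s relaxation time is the
#: physiological regime for resting dynamics
STABILITY_MARGIN = 0.1

#: the Balloon model is integrated with the endogenous drive attenuated by
#: this factor and the BOLD deviation rescaled by its inverse.  The linearized
#: response -- and hence the model cross-spectrum -- is invariant under this
#: joint rescaling; it only pins the flow/volume excursions to the few-percent
#: regime where the Balloon nonlinearity is mild, mirroring resting BOLD.
DRIVE_ATTENUATION = 1.0 / 32.0

#: map from effect-target names to DCMParams attributes
EFFECT_TARGETS = {
    "decay": "decay",
    "csd_amplitude": "alpha_v",
    "transit": "transit",
    "epsilon": "epsilon",
    "A_offdiag": "a_offdiag",
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_rois: int = 8
    n_subjects_per_timespan: int = 96
    n_volumes: int = 1200
    tr: float = 0.72
    sessions: tuple[str, ...] = SESSIONS
    effect_model_id: int = 7
    effect_targets: tuple[str, ...] = ("decay", "csd_amplitude")
    effect_size: float = 0.1
    between_subject_sd: float = 0.1
    noise_alpha: float = 0.0
    noise_beta: float = 0.0
    confound_leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least two ROIs")
        if self.n_volumes < 128:
            raise ValueError("need at least 128 volumes")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        unknown = set(self.effect_targets) - set(EFFECT_TARGETS)
        if unknown:
            raise ValueError(f"unknown effect targets: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Base parameters, per-timespan parameters, and the injected effect."""

    base_params: DCMParams
    per_timespan_params: list[DCMParams]
    effect_column: np.ndarray
    config: CohortConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": {**asdict(self.config), "sessions": list(self.config.sessions),
                           "effect_targets": list(self.config.effect_targets)},
                "base_params": json.loads(self.base_params.to_json()),
                "per_timespan_params": [json.loads(p.to_json()) for p in self.per_timespan_params],
                "effect_column": self.effect_column.tolist(),
            }
        )


@dataclass
class SubjectRecord:
    """One subject-session: ROI series, confounds, and group assignment."""

    subject_id: str
    timespan: int
    session: str
    series: np.ndarray  # volumes x ROIs
    confounds: np.ndarray  # volumes x 14
    mid_scan_time: float
    true_params: DCMParams | None = None

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.series)):
            raise ValueError("subject series contains non-finite values")
        if self.confounds.shape[1] != N_CONFOUNDS:
            raise ValueError(f"confounds must have {N_CONFOUNDS} columns")


# -- ground truth -------------------------------------------------------------


def _draw_stable_base(n_rois: int, rng: np.random.Generator) -> DCMParams:
    for _ in range(MAX_STABILITY_DRAWS):
        p = DCMParams.zeros(n_rois)
        p.a_offdiag = rng.uniform(-0.25, 0.25, (n_rois, n_rois))
        np.fill_diagonal(p.a_offdiag, 0.0)
        if p.is_stable(STABILITY_MARGIN):
            return p
    raise RuntimeError(
        f"could not draw a stable base connectivity in {MAX_STABILITY_DRAWS} attempts"
    )


def _apply_effect(base: DCMParams, targets: tuple[str, ...], delta: float) -> DCMParams:
    p = base.copy()
    for t in targets:
        attr = EFFECT_TARGETS[t]
        val = getattr(p, attr)
        if isinstance(val, np.ndarray):
            if t == "A_offdiag":
                mask = ~np.eye(p.n_rois, dtype=bool)
                val = val.copy()
                val[mask] += delta
            else:
                val = val + delta
            setattr(p, attr, val)
        else:
            setattr(p, attr, val + delta)
    return p


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw stable base parameters and inject the configured group effect."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6721]))
    base = _draw_stable_base(config.n_rois, rng)
    base.alpha_e = config.noise_alpha
    base.beta_e = config.noise_beta
    col = time_effect_column(config.effect_model_id)
    per_ts = []
    for t in range(N_TIMESPANS):
        p = _apply_effect(base, config.effect_targets, config.effect_size * col[t])
        if not p.is_stable(STABILITY_MARGIN):
            raise RuntimeError(
                f"injected effect destabilizes the system in timespan {t + 1}"
            )
        per_ts.append(p)
    return GroundTruth(base_params=base, per_timespan_params=per_ts,
                       effect_column=col, config=config)


# -- noise synthesis ----------------------------------------------------------


def _powerlaw_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                    dt: float, alpha: float, beta: float) -> np.ndarray:
    """Gaussian series with two-sided PSD exp(alpha)/64 * f**(-exp(beta)).

    Synthesized in the frequency domain (amplitude set per rfft bin, Gaussian
    complex coefficients) and inverse-transformed; the DC and Nyquist bins
    carry no power, so every realization is exactly mean-free.
    """
    freqs = np.fft.rfftfreq(n_samples, dt)
    spec = np.zeros_like(freqs)
    spec[1:] = innovation_spectrum(alpha, beta, freqs[1:])
    if n_samples % 2 == 0:
        spec[-1] = 0.0
    scale = np.sqrt(spec * n_samples / (2.0 * dt))
    coeff = scale * (
        rng.standard_normal((n_series, freqs.size))
        + 1j * rng.standard_normal((n_series, freqs.size))
    )
    coeff[:, 0] = 0.0
    return np.fft.irfft(coeff, n=n_samples, axis=1)


# -- integrator ---------------------------------------------------------------


def _integrate_core(a, kappa, gamma, tau, alpha_g, e0, u, dt, oversample, n_out):
    """Heun integration of the coupled neuronal-Balloon system (one subject).

    ``a`` is (n, n); ``u`` is the endogenous input sampled at dt, (n, T_dt);
    returns the hemodynamic states at volume times: (2, n, n_out) holding
    (v, q).
    """
    n = a.shape[0]
    t_dt = u.shape[1]
    x = np.zeros(n)
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    out = np.empty((2, n, n_out))
    k = 0
    for t in range(t_dt):
        if t % oversample == 0:
            if k < n_out:
                for i in range(n):
                    out[0, i, k] = v[i]
                    out[1, i, k] = q[i]
                k += 1
        # stage 1
        dx1 = np.empty(n); ds1 = np.empty(n); df1 = np.empty(n)
        dv1 = np.empty(n); dq1 = np.empty(n)
        for i in range(n):
            acc = u[i, t]
            for j in range(n):
                acc += a[i, j] * x[j]
            dx1[i] = acc
            ds1[i] = x[i] - kappa * s[i] - gamma * (f[i] - 1.0)
            df1[i] = s[i]
            fv = v[i] ** (1.0 / alpha_g)
            ef = 1.0 - (1.0 - e0) ** (1.0 / f[i])
            dv1[i] = (f[i] - fv) / tau[i]
            dq1[i] = (f[i] * ef / e0 - fv * q[i] / v[i]) / tau[i]
        # stage 2 at the predictor state with the next input sample
        t2 = t + 1 if t + 1 < t_dt else t
        x2 = x + dt * dx1
        s2 = s + dt * ds1
        f2 = f + dt * df1
        v2 = v + dt * dv1
        q2 = q + dt * dq1
        for i in range(n):
            acc = u[i, t2]
            for j in range(n):
                acc += a[i, j] * x2[j]
            dx2 = acc
            ds2 = x2[i] - kappa * s2[i] - gamma * (f2[i] - 1.0)
            df2 = s2[i]
            fv = v2[i] ** (1.0 / alpha_g)
            ef = 1.0 - (1.0 - e0) ** (1.0 / f2[i])
            dv2 = (f2[i] - fv) / tau[i]
            dq2 = (f2[i] * ef / e0 - fv * q2[i] / v2[i]) / tau[i]
            x[i] += 0.5 * dt * (dx1[i] + dx2)
            s[i] += 0.5 * dt * (ds1[i] + ds2)
            f[i] += 0.5 * dt * (df1[i] + df2)
            v[i] += 0.5 * dt * (dv1[i] + dv2)
            q[i] += 0.5 * dt * (dq1[i] + dq2)
    return out


try:  # numba gives a ~100x faster integrator; the pure-Python path is identical
    from numba import njit

    _integrate = njit(cache=True)(_integrate_core)
except ImportError:  # pragma: no cover
    _integrate = _integrate_core


# -- subject and cohort simulation -------------------------------------------


def _draw_subject_params(group: DCMParams, sd: float,
                         rng: np.random.Generator) -> DCMParams:
    if sd == 0.0:
        return group.copy()
    n = group.n_rois
    for _ in range(MAX_STABILITY_DRAWS):
        vec = group.to_vector() + sd * rng.standard_normal(DCMParams.n_params(n))
        p = DCMParams.from_vector(vec, n)
        if p.is_stable(STABILITY_MARGIN):
            return p
    raise RuntimeError(
        f"no stable subject-level draw around the group parameters in "
        f"{MAX_STABILITY_DRAWS} attempts (sd={sd})"
    )


def _make_confounds(rng: np.random.Generator, n_volumes: int, tr: float) -> np.ndarray:
    """12 motion-like smoothed random walks plus WM/CSF-like slow noise."""
    from scipy.ndimage import gaussian_filter1d

    motion = np.cumsum(rng.standard_normal((n_volumes, 12)) * 0.02, axis=0)
    motion = gaussian_filter1d(motion, sigma=4.0, axis=0)
    slow = _powerlaw_noise(rng, 2, n_volumes, tr, alpha=0.0, beta=math.log(2.0)).T
    return np.hstack([motion, slow])


def simulate_subject(
    truth: GroundTruth,
    timespan: int,
    session: str,
    subject_seed: int,
    subject_id: str | None = None,
    mid_scan_time: float | None = None,
    const: HemoConstants = BALLOON,
) -> SubjectRecord:
    """Simulate one subject-session record.

    The subject-level parameter draw depends only on ``subject_seed``, so the
    two sessions of a subject share parameters; session-specific innovation
    and noise streams are keyed by (subject_seed, session).  Identical seeds
    reproduce the series bit for bit.
    """
    cfg = truth.config
    if not 1 <= timespan <= N_TIMESPANS:
        raise ValueError("timespan must be in 1..6")
    if session not in cfg.sessions:
        raise ValueError(f"unknown session {session!r}")
    group = truth.per_timespan_params[timespan - 1]
    param_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_seed, 1]))
    params = _draw_subject_params(group, cfg.between_subject_sd, param_rng)

    sess_idx = cfg.sessions.index(session)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject_seed, 2 + sess_idx])
    )
    n = cfg.n_rois
    dt = cfg.tr / OVERSAMPLE
    t_vol = cfg.n_volumes + BURN_IN_VOLUMES
    t_dt = t_vol * OVERSAMPLE
    u = DRIVE_ATTENUATION * _powerlaw_noise(rng, n, t_dt, dt, params.alpha_v, params.beta_v)

    kappa = const.kappa0 * math.exp(params.decay)
    tau = const.tau0 * np.exp(params.transit)
    states = _integrate(
        params.effective_a(), kappa, const.gamma, tau, const.alpha_g, const.e0,
        u, dt, OVERSAMPLE, t_vol,
    )
    if np.any(~np.isfinite(states)):
        raise RuntimeError(
            f"integration diverged for subject_seed={subject_seed}, "
            f"timespan={timespan}; parameters: {params.to_json()}"
        )
    v_state = states[0, :, BURN_IN_VOLUMES:]
    q_state = states[1, :, BURN_IN_VOLUMES:]
    bold = bold_observer(v_state, q_state, params.epsilon, const).T / DRIVE_ATTENUATION

    noise = _powerlaw_noise(rng, n, cfg.n_volumes, cfg.tr, params.alpha_e, params.beta_e).T
    confounds = _make_confounds(rng, cfg.n_volumes, cfg.tr)
    series = bold + noise
    if cfg.confound_leakage:
        weights = rng.standard_normal((N_CONFOUNDS, n))
        series = series + cfg.confound_leakage * confounds @ weights

    if mid_scan_time is None:
        lo, hi = default_scheme().boundaries[timespan - 1]
        mid_scan_time = float(lo + (hi - lo) * rng.uniform())
    return SubjectRecord(
        subject_id=subject_id or f"sub-{subject_seed:05d}",
        timespan=timespan,
        session=session,
        series=series,
        confounds=confounds,
        mid_scan_time=mid_scan_time,
        true_params=params,
    )


def simulate_cohort(config: CohortConfig):
    """Simulate the full cohort: subjects x 6 timespans x sessions.

    Returns ``(records, truth)``; records are ordered timespan-major, then
    subject, then session, so the hierarchy downstream is reproducible.
    """
    truth = make_ground_truth(config)
    records: list[SubjectRecord] = []
    idx = 0
    for t in range(1, N_TIMESPANS + 1):
        for s in range(config.n_subjects_per_timespan):
            subject_seed = idx
            subject_id = f"sub-t{t}-{s:04d}"
            mid = None
            for session in config.sessions:
                rec = simulate_subject(
                    truth, t, session, subject_seed, subject_id=subject_id,
                    mid_scan_time=mid,
                )
                mid = rec.mid_scan_time  # shared across the subject's sessions
                records.append(rec)
            idx += 1
    return records, truth


# -- on-disk interchange ------------------------------------------------------


def write_cohort(records: list[SubjectRecord], truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write per-record TSV series + confounds and a JSON manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        stem = f"{rec.subject_id}_{rec.session}"
        n = rec.series.shape[1]
        pd.DataFrame(rec.series, columns=[f"roi{i + 1}" for i in range(n)]).to_csv(
            out / f"{stem}_series.tsv", sep="\t", index=False
        )
        cols = [f"motion{i + 1}" for i in range(12)] + ["wm", "csf"]
        pd.DataFrame(rec.confounds, columns=cols).to_csv(
            out / f"{stem}_confounds.tsv", sep="\t", index=False
        )
        manifest.append(
            {
                "subject_id": rec.subject_id,
                "timespan": rec.timespan,
                "session": rec.session,
                "mid_scan_time": rec.mid_scan_time,
                "series": f"{stem}_series.tsv",
                "confounds": f"{stem}_confounds.tsv",
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "ground_truth.json").write_text(truth.to_json())
    return out


def load_cohort(out_dir: str | Path) -> list[SubjectRecord]:
    import pandas as pd

    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    records = []
    for entry in manifest:
        series = pd.read_csv(out / entry["series"], sep="\t").to_numpy()
        confounds = pd.read_csv(out / entry["confounds"], sep="\t").to_numpy()
        records.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                timespan=entry["timespan"],
                session=entry["session"],
                series=series,
                confounds=confounds,
                mid_scan_time=entry["mid_scan_time"],
            )
        )
    return records
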