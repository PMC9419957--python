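"""Generative model: linear neuronal dynamics, Balloon hemodynamics, and the
cross-spectral density they predict.

The neuronal states obey ``dx/dt = A x + v`` where ``A`` is the effective
connectivity matrix (off-diagonal entries in Hz, self-connections given by a
log-scale parameter through ``self_connection_rate``) and ``v`` is an
endogenous fluctuation process with a power-law spectrum.  Each region's
neuronal activity drives a Balloon model (vasodilatory signal ``s``, inflow
``f``, venous volume ``v``, deoxyhemoglobin ``q``) whose linearization about
the resting fixpoint, composed with the BOLD observer, yields the transfer
function ``G(w) = L (iwI - J)^-1 B`` and the model cross-spectrum

    S(f) = G(2 pi f) g_v(f) G(2 pi f)* + g_e(f) I

with ``g_v``/``g_e`` the endogenous-fluctuation and observation-noise spectra.
All hemodynamic and observer constants live in one auditable table
(:class:`HemoConstants`); none of them are fitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HemoConstants",
    "BALLOON",
    "DCMParams",
    "FrequencyGrid",
    "CrossSpectrum",
    "self_connection_rate",
    "innovation_spectrum",
    "full_jacobian",
    "transfer_function",
    "predict_csd",
    "csd_with_jacobian",
    "default_grid",
    "nonlinear_drift",
    "bold_observer",
]

#: prior mean of the self-connection rate (Hz); a zero log-parameter maps here
SELF_CONNECTION_PRIOR_HZ = -0.5

#: scale of the innovation amplitude: g(f) = exp(alpha)/64 * f**(-exp(beta))
AMPLITUDE_SCALE = 1.0 / 64.0

#: prior mean of the power-law exponent (beta is a log-deviation about it)
EXPONENT_PRIOR = 1.0


@dataclass(frozen=True)
class HemoConstants:
    """Balloon-model and 3T BOLD-observer constants (one frozen table).

    kappa0   rate of vasodilatory signal decay at zero log-deviation (1/s)
    gamma    rate of flow-dependent elimination (1/s)
    tau0     venous transit time at zero log-deviation (s)
    alpha_g  Grubb's vessel stiffness exponent
    e0       resting oxygen extraction fraction
    v0       resting venous blood volume fraction (percent)
    theta0   frequency offset at the outer surface of magnetized vessels (1/s)
    r0       slope of intravascular relaxation rate with extraction (1/s)
    te       echo time (s)
    """

    kappa0: float = 0.64
    gamma: float = 0.32
    tau0: float = 2.0
    alpha_g: float = 0.32
    e0: float = 0.4
    v0: float = 4.0
    theta0: float = 40.3
    r0: float = 25.0
    te: float = 0.0331

    @property
    def k1(self) -> float:
        return 6.93 * self.theta0 * self.e0 * self.te

    def k2(self, epsilon_lin: float) -> float:
        return epsilon_lin * self.r0 * self.e0 * self.te

    def k3(self, epsilon_lin: float) -> float:
        return 1.0 - epsilon_lin


BALLOON = HemoConstants()


def self_connection_rate(a_self: float | np.ndarray) -> float | np.ndarray:
    """Effective self-connection rate in Hz for a log-scale parameter.

    Zero maps to the prior mean of -0.5 Hz; the result is always negative,
    which keeps each region self-inhibiting.
    """
    return SELF_CONNECTION_PRIOR_HZ * np.exp(a_self)


def innovation_spectrum(
    alpha: float, beta: float, freq: float | np.ndarray
) -> float | np.ndarray:
    """Power-law spectrum ``exp(alpha)/64 * f**(-exp(beta))`` (two-sided, per Hz).

    ``alpha`` and ``beta`` are log-deviations about the documented prior
    means (amplitude 1/64, exponent 1).  Frequencies must be positive.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("innovation_spectrum requires strictly positive frequencies")
    out = AMPLITUDE_SCALE * math.exp(alpha) * f ** (-EXPONENT_PRIOR * math.exp(beta))
    return float(out) if np.isscalar(freq) else out


@dataclass
class DCMParams:
    """All free parameters of one subject's generative model.

    ``a_offdiag`` is in Hz with a structurally zero diagonal; ``a_self``,
    ``transit``, ``decay`` and ``epsilon`` are log-deviations about the prior
    means baked into :class:`HemoConstants`; the four spectral parameters are
    log-deviations about the documented amplitude/exponent priors.  ``decay``,
    ``epsilon`` and the spectral parameters are global; ``transit`` is per ROI.
    """

    a_offdiag: np.ndarray
    a_self: np.ndarray
    transit: np.ndarray
    decay: float = 0.0
    epsilon: float = 0.0
    alpha_v: float = 0.0
    beta_v: float = 0.0
    alpha_e: float = 0.0
    beta_e: float = 0.0

    def __post_init__(self) -> None:
        self.a_offdiag = np.array(self.a_offdiag, dtype=float)
        self.a_self = np.array(self.a_self, dtype=float)
        self.transit = np.array(self.transit, dtype=float)
        n = self.a_offdiag.shape[0]
        if self.a_offdiag.shape != (n, n):
            raise ValueError("a_offdiag must be square")
        if self.a_self.shape != (n,) or self.transit.shape != (n,):
            raise ValueError("a_self and transit must have one entry per ROI")
        np.fill_diagonal(self.a_offdiag, 0.0)

    @property
    def n_rois(self) -> int:
        return self.a_offdiag.shape[0]

    @classmethod
    def zeros(cls, n_rois: int) -> "DCMParams":
        return cls(
            a_offdiag=np.zeros((n_rois, n_rois)),
            a_self=np.zeros(n_rois),
            transit=np.zeros(n_rois),
        )

    def effective_a(self) -> np.ndarray:
        """The full neuronal coupling matrix A (Hz), diagonal included."""
        a = self.a_offdiag.copy()
        np.fill_diagonal(a, self_connection_rate(self.a_self))
        return a

    def is_stable(self, margin: float = 0.0) -> bool:
        """True when every neuronal eigenvalue has real part < -margin (Hz)."""
        return bool(np.max(np.linalg.eigvals(self.effective_a()).real) < -margin)

    # -- canonical flat-vector representation ---------------------------------

    @staticmethod
    def names(n_rois: int) -> list[str]:
        """Canonical parameter ordering shared by priors, posteriors and PEB."""
        out = [
            f"a_{i + 1}_{j + 1}"
            for i in range(n_rois)
            for j in range(n_rois)
            if i != j
        ]
        out += [f"a_self_{i + 1}" for i in range(n_rois)]
        out += [f"transit_{i + 1}" for i in range(n_rois)]
        out += ["decay", "epsilon", "alpha_v", "beta_v", "alpha_e", "beta_e"]
        return out

    @staticmethod
    def n_params(n_rois: int) -> int:
        return n_rois * n_rois + n_rois + 6

    def to_vector(self) -> np.ndarray:
        n = self.n_rois
        off = self.a_offdiag[~np.eye(n, dtype=bool)]
        return np.concatenate(
            [
                off,
                self.a_self,
                self.transit,
                [self.decay, self.epsilon, self.alpha_v, self.beta_v, self.alpha_e, self.beta_e],
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_rois: int) -> "DCMParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != cls.n_params(n_rois):
            raise ValueError(
                f"expected {cls.n_params(n_rois)} parameters for {n_rois} ROIs, got {vec.size}"
            )
        n = n_rois
        k = n * (n - 1)
        a = np.zeros((n, n))
        a[~np.eye(n, dtype=bool)] = vec[:k]
        a_self = vec[k : k + n]
        transit = vec[k + n : k + 2 * n]
        decay, epsilon, av, bv, ae, be = vec[k + 2 * n :]
        return cls(a, a_self, transit, decay, epsilon, av, bv, ae, be)

    def copy(self) -> "DCMParams":
        return replace(
            self,
            a_offdiag=self.a_offdiag.copy(),
            a_self=self.a_self.copy(),
            transit=self.transit.copy(),
        )

    def to_json(self) -> str:
        return json.dumps(
            {"n_rois": self.n_rois, "names": self.names(self.n_rois), "values": self.to_vector().tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "DCMParams":
        d = json.loads(text)
        return cls.from_vector(np.asarray(d["values"]), d["n_rois"])


@dataclass(frozen=True)
class FrequencyGrid:
    """Ascending positive frequencies (Hz) on which spectra are evaluated."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly ascending")
        object.__setattr__(self, "freqs", f)

    def __len__(self) -> int:
        return self.freqs.size


def default_grid(n_volumes: int, tr: float, n_freq: int = 32, f_max: float = 0.1) -> FrequencyGrid:
    """Linearly spaced grid from the fundamental 1/(N*TR) up to ``f_max`` Hz.

    The 0.1 Hz ceiling keeps the fit inside the band where resting-state
    fluctuations carry the signal of interest.
    """
    f_min = 1.0 / (n_volumes * tr)
    nyquist = 0.5 / tr
    f_max = min(f_max, nyquist)
    if f_min >= f_max:
        raise ValueError("series too short to resolve the analysis band")
    return FrequencyGrid(np.linspace(f_min, f_max, n_freq))


@dataclass
class CrossSpectrum:
    """Complex Hermitian ROI x ROI spectral matrices on a frequency grid."""

    grid: FrequencyGrid
    S: np.ndarray  # (n_freq, n_rois, n_rois) complex

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[0] != len(self.grid) or self.S.shape[1] != self.S.shape[2]:
            raise ValueError("S must be (n_freq, n_rois, n_rois)")

    @property
    def n_rois(self) -> int:
        return self.S.shape[1]

    def is_hermitian(self, atol: float = 1e-10) -> bool:
        return bool(np.allclose(self.S, np.conj(np.transpose(self.S, (0, 2, 1))), atol=atol))


# -- linearized system --------------------------------------------------------

STATES_PER_ROI = 5  # x, s, f, v, q


def _hemo_rates(params: DCMParams, const: HemoConstants):
    kappa = const.kappa0 * math.exp(params.decay)
    tau = const.tau0 * np.exp(params.transit)
    return kappa, tau


def _observer_gain(params: DCMParams, const: HemoConstants):
    """d(BOLD)/d(v, q) at the resting fixpoint, per ROI (shared values)."""
    eps = math.exp(params.epsilon)
    dv = const.v0 * (const.k2(eps) - const.k3(eps))
    dq = -const.v0 * (const.k1 + const.k2(eps))
    return dv, dq


def full_jacobian(params: DCMParams, const: HemoConstants = BALLOON):
    """Linearization (J, B, L) of the coupled neuronal-hemodynamic system.

    State ordering is block-wise ``[x, s, f, v, q]`` with ``n`` entries per
    block.  ``B`` injects the endogenous fluctuation into the neuronal block;
    ``L`` is the gradient of the BOLD observer at the fixpoint.
    """
    vec = np.concatenate([params.a_offdiag.ravel(), params.a_self, params.transit,
                          [params.decay, params.epsilon]])
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite parameters passed to full_jacobian")
    n = params.n_rois
    m = STATES_PER_ROI * n
    kappa, tau = _hemo_rates(params, const)
    e0, ag = const.e0, const.alpha_g
    # d/df [f*E(f)/E0] at f=1, with E(f) = 1 - (1-E0)**(1/f)
    c_f = 1.0 + (1.0 - e0) * math.log(1.0 - e0) / e0

    x, s, f, v, q = (slice(k * n, (k + 1) * n) for k in range(STATES_PER_ROI))
    J = np.zeros((m, m))
    J[x, x] = params.effective_a()
    J[s, x] = np.eye(n)
    J[s, s] = -kappa * np.eye(n)
    J[s, f] = -const.gamma * np.eye(n)
    J[f, s] = np.eye(n)
    J[v, f] = np.diag(1.0 / tau)
    J[v, v] = np.diag(-1.0 / (ag * tau))
    J[q, f] = np.diag(c_f / tau)
    J[q, v] = np.diag(-(1.0 / ag - 1.0) / tau)
    J[q, q] = np.diag(-1.0 / tau)

    B = np.zeros((m, n))
    B[x, :] = np.eye(n)

    dv, dq = _observer_gain(params, const)
    L = np.zeros((n, m))
    L[:, v] = dv * np.eye(n)
    L[:, q] = dq * np.eye(n)
    return J, B, L


def nonlinear_drift(state: np.ndarray, u: np.ndarray, params: DCMParams,
                    const: HemoConstants = BALLOON) -> np.ndarray:
    """Drift of the full nonlinear system; states as deviations, f/v/q absolute.

    ``state`` is ``[x, s, f, v, q]`` stacked (length 5n) with the hemodynamic
    states on their natural (positive) scale; the resting fixpoint is
    ``x = s = 0, f = v = q = 1``.  Used by the simulator and as the oracle the
    linearization is checked against.
    """
    n = params.n_rois
    x, s, f, v, q = (state[k * n : (k + 1) * n] for k in range(STATES_PER_ROI))
    kappa, tau = _hemo_rates(params, const)
    e0, ag = const.e0, const.alpha_g
    a = params.effective_a()
    ef = 1.0 - (1.0 - e0) ** (1.0 / f)
    fv = v ** (1.0 / ag)
    dx = a @ x + u
    ds = x - kappa * s - const.gamma * (f - 1.0)
    df = s
    dv = (f - fv) / tau
    dq = (f * ef / e0 - fv * q / v) / tau
    return np.concatenate([dx, ds, df, dv, dq])


def bold_observer(v: np.ndarray, q: np.ndarray, epsilon: float,
                  const: HemoConstants = BALLOON) -> np.ndarray:
    """Nonlinear BOLD signal for venous volume/deoxyhemoglobin states."""
    eps = math.exp(epsilon)
    k1, k2, k3 = const.k1, const.k2(eps), const.k3(eps)
    return const.v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _resolvent_factors(J: np.ndarray, B: np.ndarray, L: np.ndarray,
                       omegas: np.ndarray):
    """L (iwI - J)^-1 and (iwI - J)^-1 B for every angular frequency."""
    m = J.shape[0]
    eye = np.eye(m)
    M = 1j * omegas[:, None, None] * eye - J  # (F, m, m)
    RB = np.linalg.solve(M, np.broadcast_to(B, (omegas.size, m, B.shape[1])))
    LR = np.transpose(
        np.linalg.solve(np.transpose(M, (0, 2, 1)), np.broadcast_to(L.T, (omegas.size, m, L.shape[0]))),
        (0, 2, 1),
    )
    return LR, RB


def transfer_function(params: DCMParams, grid: FrequencyGrid,
                      observer: str = "bold", const: HemoConstants = BALLOON) -> np.ndarray:
    """``G(w) = L (iwI - J)^-1 B`` at each grid frequency, shape (F, n, n).

    ``observer="neuronal"`` replaces the BOLD gain with a direct read-out of
    the neuronal states (a test hook for closed-form checks).
    """
    J, B, L = full_jacobian(params, const)
    if observer == "neuronal":
        L = B.T.copy()
    elif observer != "bold":
        raise ValueError("observer must be 'bold' or 'neuronal'")
    omegas = 2.0 * np.pi * grid.freqs
    LR, RB = _resolvent_factors(J, B, L, omegas)
    return LR @ B


def predict_csd(params: DCMParams, grid: FrequencyGrid,
                const: HemoConstants = BALLOON, observer: str = "bold") -> CrossSpectrum:
    """Model cross-spectrum ``S(f) = G g_v G* + g_e I`` on the grid."""
    G = transfer_function(params, grid, observer=observer, const=const)
    gv = innovation_spectrum(params.alpha_v, params.beta_v, grid.freqs)
    ge = innovation_spectrum(params.alpha_e, params.beta_e, grid.freqs)
    GH = np.conj(np.transpose(G, (0, 2, 1)))
    S = gv[:, None, None] * (G @ GH) + ge[:, None, None] * np.eye(params.n_rois)
    return CrossSpectrum(grid=grid, S=S)


def csd_with_jacobian(params: DCMParams, grid: FrequencyGrid,
                      const: HemoConstants = BALLOON):
    """Model cross-spectrum plus its analytic parameter Jacobian.

    Returns ``(S, dS)`` with ``S`` of shape (F, n, n) and ``dS`` of shape
    (P, F, n, n), parameters in the canonical :meth:`DCMParams.names` order.
    Derivatives follow from ``dG = L R (dJ) R B`` for parameters entering the
    state Jacobian, ``dG = dL R B`` for epsilon, and direct differentiation of
    the power-law innovation spectra for the four spectral parameters.
    """
    n = params.n_rois
    m = STATES_PER_ROI * n
    J, B, L = full_jacobian(params, const)
    omegas = 2.0 * np.pi * grid.freqs
    LR, RB = _resolvent_factors(J, B, L, omegas)  # (F,n,m), (F,m,n)
    G = LR @ B
    GH = np.conj(np.transpose(G, (0, 2, 1)))
    gv = innovation_spectrum(params.alpha_v, params.beta_v, grid.freqs)
    ge = innovation_spectrum(params.alpha_e, params.beta_e, grid.freqs)
    eye = np.eye(n)
    S = gv[:, None, None] * (G @ GH) + ge[:, None, None] * eye

    x, s, f, v, q = (slice(k * n, (k + 1) * n) for k in range(STATES_PER_ROI))
    kappa, tau = _hemo_rates(params, const)

    # dG = L R (dJ) R B; each parameter family touches few entries of J, so
    # the products reduce to small outer products / matmuls per family
    LRx = LR[:, :, x]  # (F, n, n): columns of L R hitting the neuronal block
    RBx = RB[:, x, :]  # (F, n, n)

    # a_offdiag (i, j): dJ has a single 1 at (x_i, x_j)
    off_i, off_j = np.nonzero(~np.eye(n, dtype=bool))
    dG_off = np.einsum("fap,fpb->pfab", LRx[:, :, off_i], RBx[:, off_j, :])

    # a_self i: single entry at (x_i, x_i), value -0.5 exp(a_self_i)
    dself = SELF_CONNECTION_PRIOR_HZ * np.exp(params.a_self)
    dG_self = np.einsum(
        "p,fap,fpb->pfab", dself, LRx, RBx
    )

    # transit_i: the v_i and q_i rows of J scale by 1/tau_i, so dJ rows = -J rows
    vq = np.r_[np.arange(3 * n, 4 * n), np.arange(4 * n, 5 * n)]
    JR = np.einsum("rm,fmb->frb", J[vq, :], RB)  # (F, 2n, n)
    dG_tr = -(
        np.einsum("fap,fpb->pfab", LR[:, :, vq[:n]], JR[:, :n, :])
        + np.einsum("fap,fpb->pfab", LR[:, :, vq[n:]], JR[:, n:, :])
    )

    # decay: dJ[s, s] = -kappa I
    dG_dec = (-kappa * (LR[:, :, s] @ RB[:, s, :]))[None]

    dG_J = np.concatenate([dG_off, dG_self, dG_tr, dG_dec], axis=0)

    # epsilon enters only the observer gain L
    eps = math.exp(params.epsilon)
    dL = np.zeros((n, m))
    dL[:, v] = const.v0 * (const.k2(eps) + eps) * eye
    dL[:, q] = -const.v0 * const.k2(eps) * eye
    dG_eps = np.einsum("ir,frj->fij", dL, RB)[None]

    dG = np.concatenate([dG_J, dG_eps], axis=0)  # (nj+1, F, n, n)
    dGH = np.conj(np.transpose(dG, (0, 1, 3, 2)))
    dS_G = gv[None, :, None, None] * (dG @ GH[None] + G[None] @ dGH)

    GGH = G @ GH
    lnf = np.log(grid.freqs)
    bv = EXPONENT_PRIOR * math.exp(params.beta_v)
    be = EXPONENT_PRIOR * math.exp(params.beta_e)
    dS_alpha_v = (gv[:, None, None] * GGH)[None]
    dS_beta_v = ((-bv * lnf * gv)[:, None, None] * GGH)[None]
    dS_alpha_e = (ge[:, None, None] * np.broadcast_to(eye, GGH.shape))[None]
    dS_beta_e = ((-be * lnf * ge)[:, None, None] * np.broadcast_to(eye, GGH.shape))[None]

    dS = np.concatenate([dS_G, dS_alpha_v, dS_beta_v, dS_alpha_e, dS_beta_e], axis=0)
    return S, dS
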