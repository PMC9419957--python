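"""Hierarchical parametric empirical Bayes over first-level posteriors.

The second-level model places a general linear model over subjects' posterior
parameter vectors: ``theta_i = X_i beta + eps_i`` with ``eps_i`` Gaussian
between-subject variability.  Estimation uses only the first-level posterior
summaries: replacing subject ``i``'s prior with the implied group prior
``N(X_i beta, Gamma)`` changes its log evidence by a closed-form Gaussian
expression (Bayesian model reduction), and because that expression is
quadratic in ``beta`` the group posterior and the model evidence follow
analytically for a fixed between-subject scale.  A single scalar ``gamma``
scales the between-subject covariance ``Gamma = gamma * prior_cov / 16`` and
is optimized by free energy on a deterministic grid with golden-section
refinement.

In the hierarchical analysis one mean-only PEB is fitted per (timespan,
session) cell, and a single second-level PEB whose contrast block spans every
timespan pattern is then scored against all 18 time-of-day designs by
Bayesian model reduction: each design's prior concentrates the contrast
space along its own time-effect direction, so all models are evaluated
against the same fitted between-cell variance.  Model probabilities are the
softmax of the free energies (uniform model prior); Bayesian model averaging
moment-matches the probability-weighted mixture of group posteriors, and
per-parameter posterior probabilities of a nonzero effect come from
BMR-style pruning (prior variance of the effect driven to zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inversion import GaussianDensity
from .model_space import N_SESSIONS, N_TIMESPANS, DesignMatrix, ModelSpace, SESSIONS

__all__ = [
    "PebConfig",
    "PebResult",
    "BmcResult",
    "BmaResult",
    "bmr",
    "peb_fit",
    "hierarchical_peb",
    "bmc",
    "bma",
    "effect_size",
]


@dataclass
class PebConfig:
    """Hyperparameters of the empirical-Bayes scheme."""

    #: between-subject covariance = gamma_f * (first-level prior cov) / 16,
    #: with one scale gamma_f per parameter family (see
    #: :func:`_parameter_families`) because the families disperse very
    #: differently and a shared scale lets the noisiest block inflate the rest
    component_scale: float = 1.0 / 16.0
    #: prior on each log gamma: N(0, gamma_prior_var)
    gamma_prior_var: float = 16.0
    #: search range and coarse resolution for log gamma
    gamma_log_bounds: tuple[float, float] = (-8.0, 12.0)
    gamma_coarse_points: int = 13
    gamma_refine_iters: int = 12
    gamma_sweeps: int = 2
    #: drop cross-parameter covariances of the cell posteriors before the
    #: second level (test timespan patterns per parameter)
    diagonal_second_level: bool = True
    #: deconvolution guard: a direction of a posterior's data precision is
    #: used only when it exceeds this fraction of the prior precision;
    #: deconvolving near-flat ridges only amplifies approximation error
    deconvolution_guard: float = 0.05
    #: hyperprior variance for the second level of a hierarchical analysis.
    #: The 12 (timespan, session) cells are exchangeable replicates once
    #: first-level uncertainty is propagated, so their residual dispersion is
    #: pinned near the reference scale; a loose second-level variance would
    #: absorb any systematic time-of-day pattern as "cell noise" and flatten
    #: the model comparison.
    second_level_gamma_prior_var: float = 1.0 / 16.0
    #: group-level prior variance scale per design column; the nuisance
    #: timespan codes are shrunk so a genuine time effect is cheaper to
    #: express through a model's dedicated time-effect column than through
    #: the nuisance block (which exists to absorb idiosyncratic group means)
    mean_column_scale: float = 1.0
    effect_column_scale: float = 4.0
    nuisance_column_scale: float = 1.0 / 16.0


@dataclass
class PebResult:
    """Posterior over group effects (design columns x parameters)."""

    group_posterior: GaussianDensity
    free_energy: float
    design: np.ndarray
    column_names: list[str]
    param_names: list[str]
    gamma: dict
    between_subject_sd: np.ndarray
    prior: GaussianDensity | None = None
    level: int = 1
    model_id: int | None = None
    #: for second-level results scored by model reduction: the 6-vector of
    #: per-timespan predictions this design's prior concentrates on
    time_column: np.ndarray | None = None

    def effect_block(self, column: str) -> GaussianDensity:
        """Marginal posterior of one design column's effects."""
        names = [f"{column}:{p}" for p in self.param_names]
        return self.group_posterior.select(names)


@dataclass
class BmcResult:
    free_energies: np.ndarray
    posterior_probs: np.ndarray
    winning_id: int


@dataclass
class BmaResult:
    averaged_posterior: GaussianDensity
    per_timespan_means: np.ndarray  # 6 x parameters
    pp_per_parameter: dict = field(default_factory=dict)
    param_names: list[str] = field(default_factory=list)
    threshold: float = 0.95


def _inv_psd(a: np.ndarray, name: str) -> np.ndarray:
    a = 0.5 * (a + a.T)
    w, V = np.linalg.eigh(a)
    if np.any(w <= 0):
        if np.any(w < -1e-8 * max(w.max(), 1.0)):
            raise np.linalg.LinAlgError(
                f"{name} is not positive definite (eigenvalue range "
                f"[{w.min():.3e}, {w.max():.3e}])"
            )
        w = np.clip(w, 1e-12 * max(w.max(), 1.0), None)
    return (V / w) @ V.T


def _logdet_psd(a: np.ndarray) -> float:
    w = np.linalg.eigvalsh(0.5 * (a + a.T))
    w = np.clip(w, 1e-300, None)
    return float(np.sum(np.log(w)))


def bmr(
    full_posterior: GaussianDensity,
    full_prior: GaussianDensity,
    reduced_prior: GaussianDensity,
):
    """Evidence change and posterior under a reduced prior, without re-fitting.

    Closed-form Gaussian identity: with posterior precision ``P``, prior
    precision ``P0`` and reduced-prior precision ``P0r``, the reduced
    posterior has precision ``Pr = P - P0 + P0r`` and the log-evidence change
    is assembled from the corresponding determinants and quadratic forms.
    Returns ``(delta_F, reduced_posterior)`` where ``delta_F`` is the reduced
    minus the full log evidence.
    """
    P = _inv_psd(full_posterior.cov, "full posterior covariance")
    P0 = _inv_psd(full_prior.cov, "full prior covariance")
    P0r = _inv_psd(reduced_prior.cov, "reduced prior covariance")
    Pr = P - P0 + P0r
    w = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is singular; conditioning report: "
            f"eigenvalues in [{w.min():.3e}, {w.max():.3e}]"
        )
    mu, m0, m0r = full_posterior.mean, full_prior.mean, reduced_prior.mean
    Sr = _inv_psd(Pr, "reduced posterior precision")
    mur = Sr @ (P @ mu - P0 @ m0 + P0r @ m0r)
    delta_F = 0.5 * (
        _logdet_psd(P)
        - _logdet_psd(Pr)
        + _logdet_psd(P0r)
        - _logdet_psd(P0)
        + float(mur @ Pr @ mur)
        - float(mu @ P @ mu)
        + float(m0 @ P0 @ m0)
        - float(m0r @ P0r @ m0r)
    )
    reduced = GaussianDensity(names=list(full_posterior.names), mean=mur, cov=Sr)
    return float(delta_F), reduced


def _design_array(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, DesignMatrix):
        return design.matrix, list(design.column_names)
    if isinstance(design, tuple) and len(design) == 2:
        return np.atleast_2d(np.asarray(design[0], dtype=float)), list(design[1])
    arr = np.atleast_2d(np.asarray(design, dtype=float))
    return arr, [f"col{c + 1}" for c in range(arr.shape[1])]


def _session_factor_codes_rows() -> np.ndarray:
    """Sum-to-zero timespan effects codes replicated over the two sessions."""
    from .model_space import _session_factor_codes

    return np.repeat(_session_factor_codes(), N_SESSIONS, axis=0)


def _column_scales(column_names: list[str], cfg: PebConfig) -> np.ndarray:
    scales = np.ones(len(column_names))
    for c, name in enumerate(column_names):
        if name == "mean" or c == 0:
            scales[c] = cfg.mean_column_scale
        elif name == "time_effect":
            scales[c] = cfg.effect_column_scale
        else:
            scales[c] = cfg.nuisance_column_scale
    return scales


def _parameter_families(names: list[str]):
    """Group parameter names into dispersion families.

    Parameters whose estimates disperse very differently get separate
    between-subject scales: lumping, say, decay with epsilon would let the
    noisier parameter inflate the other's between-subject variance.
    Exchangeable blocks (off-diagonal connectivity, self-connections,
    regional transit times, the observation-noise pair) share one scale.
    """
    labels: list[str] = []
    fam = np.zeros(len(names), dtype=int)

    def fid(label: str) -> int:
        if label not in labels:
            labels.append(label)
        return labels.index(label)

    for j, n in enumerate(names):
        if n.startswith("a_self"):
            fam[j] = fid("self")
        elif n.startswith("a_"):
            fam[j] = fid("connectivity")
        elif n.startswith("transit"):
            fam[j] = fid("transit")
        elif n in ("decay", "epsilon"):
            fam[j] = fid(n)
        elif n in ("alpha_v", "beta_v"):
            fam[j] = fid(n)
        else:
            fam[j] = fid("noise")
    return fam, labels


class _PebObjective:
    """Free energy of the group model as a function of the log gammas."""

    def __init__(self, posteriors, design, prior, cfg: PebConfig, column_names):
        self.X = design  # (n_subj, C)
        self.C = design.shape[1]
        self.p = prior.dim
        self.cfg = cfg
        self.m0 = prior.mean
        self.S0 = prior.cov
        self.P0 = _inv_psd(prior.cov, "first-level prior covariance")
        self.fam, self.fam_labels = _parameter_families(prior.names)
        # each subject's data precision P_i - P0 is floored at PSD so the
        # group precision stays well defined even when a marginal posterior
        # is locally less precise than the prior; the information vector c is
        # projected onto the range of the floored precision (the deconvolved
        # data only exist along directions the data actually inform)
        P_list, c_list = [], []
        for g in posteriors:
            Pi = _inv_psd(g.cov, "subject posterior covariance")
            D = Pi - self.P0
            w, V = np.linalg.eigh(0.5 * (D + D.T))
            # directions where the data add less than 5% of the prior
            # precision are treated as uninformative: deconvolving along such
            # near-flat ridges only amplifies approximation error
            q = np.einsum("up,uv,vp->p", V, self.P0, V)
            keep = w > cfg.deconvolution_guard * q
            D_f = (V[:, keep] * w[keep]) @ V[:, keep].T
            P_list.append(D_f + self.P0)
            c_raw = Pi @ g.mean - self.P0 @ self.m0
            c_list.append(V[:, keep] @ (V[:, keep].T @ c_raw))
        self.P = np.stack(P_list)  # (N, p, p)
        self.c = np.stack(c_list)
        mus = np.stack([g.mean for g in posteriors])
        sign, logdets = np.linalg.slogdet(self.P)
        self.const = float(
            np.sum(
                -0.5 * np.einsum("iu,iuv,iv->i", mus, self.P, mus)
                + 0.5 * logdets
            )
            + len(posteriors)
            * (0.5 * float(self.m0 @ self.P0 @ self.m0) - 0.5 * _logdet_psd(self.P0))
        )
        # group-level prior over beta: block diagonal, per-column scaled prior
        scales = _column_scales(column_names, cfg)
        d = self.C * self.p
        self.b0 = np.zeros(d)
        self.b0[: self.p] = self.m0  # the mean column is centred on the prior mean
        self.Sb_inv = np.zeros((d, d))
        self.Sb_logdet = 0.0
        for c in range(self.C):
            sl = slice(c * self.p, (c + 1) * self.p)
            self.Sb_inv[sl, sl] = self.P0 / scales[c]
            self.Sb_logdet += _logdet_psd(self.S0 * scales[c])

    @property
    def n_families(self) -> int:
        return len(self.fam_labels)

    def evaluate(self, log_gammas: np.ndarray):
        cfg = self.cfg
        s = np.sqrt(np.exp(np.asarray(log_gammas, dtype=float)))[self.fam]
        # Gamma = diag(s) (S0 * scale) diag(s)  =>  Q = diag(1/s) P0 diag(1/s) / scale
        Q = self.P0 / (np.outer(s, s) * cfg.component_scale)
        logdet_Q = _logdet_psd(Q)
        n_subj = self.P.shape[0]
        Pr = self.P - self.P0[None] + Q[None]
        Sr = np.linalg.inv(Pr)
        sign, logdet_Pr = np.linalg.slogdet(Pr)
        QSr = np.einsum("uv,ivw->iuw", Q, Sr)
        W = Q[None] - np.einsum("iuw,wz->iuz", QSr, Q)
        q_sc = np.einsum("iuw,iw->iu", QSr, self.c)
        d = self.C * self.p
        M = np.einsum("ia,ib,iuv->aubv", self.X, self.X, W).reshape(d, d)
        v = np.einsum("ia,iu->au", self.X, q_sc).reshape(d)
        A_const = (
            self.const
            + 0.5 * (n_subj * logdet_Q - float(logdet_Pr.sum()))
            + 0.5 * float(np.einsum("iu,iuv,iv->", self.c, Sr, self.c))
        )
        Pb = M + self.Sb_inv
        h = v + self.Sb_inv @ self.b0
        Sb_post = _inv_psd(Pb, "group posterior precision")
        mu_b = Sb_post @ h
        logZ = (
            0.5 * float(h @ mu_b)
            - 0.5 * float(self.b0 @ self.Sb_inv @ self.b0)
            - 0.5 * (self.Sb_logdet + _logdet_psd(Pb))
        )
        F = A_const + logZ - 0.5 * float(np.sum(np.asarray(log_gammas) ** 2)) / cfg.gamma_prior_var
        return F, mu_b, Sb_post


def peb_fit(
    posteriors: list[GaussianDensity],
    design,
    prior: GaussianDensity,
    config: PebConfig | None = None,
    parameter_selection: list[str] | None = None,
    level: int = 1,
    model_id: int | None = None,
) -> PebResult:
    """Empirical-Bayes estimate of group effects from posterior summaries.

    ``design`` is an (n_subjects x C) matrix (or a :class:`DesignMatrix`);
    ``prior`` is the first-level prior the posteriors were estimated under.
    ``parameter_selection`` restricts the analysis to a named subset (the
    marginal posteriors are used).
    """
    cfg = config or PebConfig()
    X, column_names = _design_array(design)
    if parameter_selection is not None:
        posteriors = [g.select(parameter_selection) for g in posteriors]
        prior = prior.select(parameter_selection)
    if X.shape[0] != len(posteriors):
        raise ValueError(
            f"design has {X.shape[0]} rows but {len(posteriors)} posteriors were given"
        )
    names0 = posteriors[0].names
    for g in posteriors[1:]:
        if g.names != names0:
            raise ValueError("all posteriors must share parameter names")
    if prior.names != names0:
        raise ValueError("prior parameter names must match the posteriors")
    for c in range(X.shape[1]):
        for c2 in range(c + 1, X.shape[1]):
            if np.array_equal(X[:, c], X[:, c2]):
                raise ValueError(
                    f"design columns {column_names[c]!r} and {column_names[c2]!r} "
                    "are identical; the group model is degenerate"
                )

    obj = _PebObjective(posteriors, X, prior, cfg, column_names)

    nf = obj.n_families
    lgs = np.zeros(nf)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0

    def coord_value(f, val):
        trial = lgs.copy()
        trial[f] = val
        return obj.evaluate(trial)[0]

    lo, hi = cfg.gamma_log_bounds
    for sweep in range(cfg.gamma_sweeps):
        for f in range(nf):
            if sweep == 0:
                grid = np.linspace(lo, hi, cfg.gamma_coarse_points)
                vals = [coord_value(f, g) for g in grid]
                k = int(np.argmax(vals))
                a = grid[max(k - 1, 0)]
                b = grid[min(k + 1, grid.size - 1)]
            else:
                a = max(lgs[f] - 2.0, lo)
                b = min(lgs[f] + 2.0, hi)
            x1 = b - invphi * (b - a)
            x2 = a + invphi * (b - a)
            f1 = coord_value(f, x1)
            f2 = coord_value(f, x2)
            for _ in range(cfg.gamma_refine_iters):
                if f1 < f2:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + invphi * (b - a)
                    f2 = coord_value(f, x2)
                else:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - invphi * (b - a)
                    f1 = coord_value(f, x1)
            lgs[f] = x1 if f1 >= f2 else x2

    F, mu_b, Sb_post = obj.evaluate(lgs)

    # Laplace correction over each log gamma from the local curvature
    F_total = F
    h = 0.25
    for f in range(nf):
        f_plus = coord_value(f, lgs[f] + h)
        f_minus = coord_value(f, lgs[f] - h)
        curv = (f_plus - 2.0 * F + f_minus) / h**2
        var_lg = -1.0 / curv if curv < 0 else cfg.gamma_prior_var
        F_total += 0.5 * math.log(2.0 * math.pi * var_lg)

    beta_names = [f"{c}:{p}" for c in column_names for p in names0]
    gammas = np.exp(lgs)
    gamma = {label: float(g) for label, g in zip(obj.fam_labels, gammas)}
    bs_var = gammas[obj.fam] * cfg.component_scale * np.diag(prior.cov)
    return PebResult(
        group_posterior=GaussianDensity(names=beta_names, mean=mu_b, cov=Sb_post),
        free_energy=float(F_total),
        design=X,
        column_names=column_names,
        param_names=list(names0),
        gamma=gamma,
        between_subject_sd=np.sqrt(bs_var),
        prior=prior,
        level=level,
        model_id=model_id,
    )


def hierarchical_peb(
    cohort_results: dict,
    model_space: ModelSpace,
    prior: GaussianDensity,
    config: PebConfig | None = None,
    parameter_selection: list[str] | None = None,
):
    """Two-level PEB: one mean-only PEB per (timespan, session) cell, then one
    second-level PEB per design over the 12 first-level group posteriors.

    ``cohort_results`` maps ``(timespan, session)`` to the list of that cell's
    subject posteriors.  Returns ``(first_level, second_level)`` where
    ``first_level`` is the list of 12 cell results in timespan-major order and
    ``second_level`` holds one result per design.
    """
    cfg = config or PebConfig()
    if parameter_selection is not None:
        prior_sel = prior.select(parameter_selection)
    else:
        prior_sel = prior

    first_level = []
    for t in range(1, N_TIMESPANS + 1):
        for session in SESSIONS:
            key = (t, session)
            if key not in cohort_results or not cohort_results[key]:
                raise ValueError(f"missing first-level cell (timespan={t}, session={session!r})")
            cell = cohort_results[key]
            res = peb_fit(
                cell,
                np.ones((len(cell), 1)),
                prior,
                cfg,
                parameter_selection=parameter_selection,
                level=1,
            )
            first_level.append(res)
    assert len(first_level) == N_TIMESPANS * N_SESSIONS

    # The LR and RL cells of a timespan hold the same subjects, so their
    # means share the subject-level deviations; treating the 12 cells as
    # independent would understate the timespan-mean variance.  Adding the
    # estimated between-subject covariance once more (divided by cell size)
    # to each cell exactly compensates when the two sessions are averaged
    # through the common design.
    # The LR and RL cells of a timespan hold the same subjects, so their
    # means share the subjects' parameter deviations; each cell posterior is
    # therefore inflated by the session-shared part of the between-subject
    # variance (divided by cell size), which exactly compensates when the two
    # sessions are averaged through the common design.  The session-shared
    # part is isolated by subtracting the estimation-noise variance measured
    # from within-subject across-session differences (subject parameters
    # cancel in those differences).  Cell covariances are also diagonalized:
    # the approximate cross-parameter correlations of first-level posteriors
    # (amplitude/exponent/transit trade-offs) would otherwise be deconvolved
    # into spurious joint "effects".
    psel_names = first_level[0].param_names
    p_sel = len(psel_names)

    # The LR and RL cells of a timespan hold the same subjects, so their
    # means share every session-stable component of the subject estimates:
    # true parameter deviations and subject-specific estimation bias alike,
    # including their cross-parameter (ridge) correlations.  The pooled
    # cross-session covariance of subject estimates isolates exactly that
    # shared component (session-independent noise cancels); adding it, scaled
    # by cell size, to each cell posterior makes the 12 cells exchangeable
    # inputs for the second level.
    shared_cov = None
    if len(SESSIONS) == 2:
        blocks = []
        for t in range(1, N_TIMESPANS + 1):
            a = cohort_results[(t, SESSIONS[0])]
            b = cohort_results[(t, SESSIONS[1])]
            if len(a) != len(b) or len(a) < 3:
                continue
            ma = np.stack([g.select(psel_names).mean for g in a])
            mb = np.stack([g.select(psel_names).mean for g in b])
            ma = ma - ma.mean(axis=0)
            mb = mb - mb.mean(axis=0)
            blocks.append(ma.T @ mb / (len(a) - 1))
        if blocks:
            C = np.mean(blocks, axis=0)
            C = 0.5 * (C + C.T)
            w, V = np.linalg.eigh(C)
            shared_cov = (V * np.clip(w, 0.0, None)) @ V.T
    if shared_cov is None:
        shared_cov = np.diag(first_level[0].between_subject_sd**2)

    cell_posteriors = []
    for r, key in zip(
        first_level,
        [(t, s) for t in range(1, N_TIMESPANS + 1) for s in SESSIONS],
    ):
        n_cell = len(cohort_results[key])
        cov = r.group_posterior.cov
        if cfg.diagonal_second_level:
            cov = np.diag(np.diag(cov))
        cov = cov + shared_cov / n_cell
        cell_posteriors.append(
            GaussianDensity(
                names=r.param_names,
                mean=r.group_posterior.mean,
                cov=cov,
            )
        )
    subject_sd = np.mean([r.between_subject_sd for r in first_level], axis=0)

    from dataclasses import replace as _replace

    # Second level: one full fit whose contrast block spans every timespan
    # pattern, then one analytic model reduction per design.  Scoring all 18
    # designs against the same fitted between-cell variance keeps their
    # evidences commensurable; fitting each design separately would let the
    # free variance component absorb the very pattern under test.
    cfg2 = _replace(
        cfg,
        gamma_prior_var=cfg.second_level_gamma_prior_var,
        nuisance_column_scale=1.0,
    )
    codes = _session_factor_codes_rows()
    X_full = np.column_stack([np.ones(N_TIMESPANS * N_SESSIONS), codes])
    full = peb_fit(
        cell_posteriors,
        (X_full, ["mean", "c1", "c2", "c3", "c4", "c5"]),
        prior_sel,
        cfg2,
        level=2,
    )
    full.between_subject_sd = subject_sd

    p = prior_sel.dim
    d = 6 * p
    S0 = prior_sel.cov
    b0 = np.zeros(d)
    b0[:p] = prior_sel.mean
    full_cov = np.zeros((d, d))
    full_cov[:p, :p] = S0
    for k in range(5):
        sl = slice((k + 1) * p, (k + 2) * p)
        full_cov[sl, sl] = S0
    full_prior = GaussianDensity(
        names=list(full.group_posterior.names), mean=b0, cov=full_cov
    )
    ridge = 1e-8 * np.kron(np.eye(5), np.diag(np.diag(S0)))

    second_level = []
    for design in model_space:
        col = design.matrix[::N_SESSIONS, design.column_names.index("time_effect")]
        w = col[:5]  # effects-code coordinates of the time-effect pattern
        red_cov = np.zeros((d, d))
        red_cov[:p, :p] = S0
        red_cov[p:, p:] = (
            cfg.effect_column_scale * np.kron(np.outer(w, w), S0) + ridge
        )
        red_prior = GaussianDensity(
            names=list(full.group_posterior.names), mean=b0, cov=red_cov
        )
        dF, red_post = bmr(full.group_posterior, full_prior, red_prior)
        second_level.append(
            PebResult(
                group_posterior=red_post,
                free_energy=full.free_energy + dF,
                design=X_full,
                column_names=list(full.column_names),
                param_names=list(full.param_names),
                gamma=full.gamma,
                between_subject_sd=subject_sd,
                prior=prior_sel,
                level=2,
                model_id=design.model_id,
                time_column=col,
            )
        )
    return first_level, second_level


def bmc(second_level_results: list[PebResult]) -> BmcResult:
    """Softmax of free energies under a uniform model prior."""
    F = np.array([r.free_energy for r in second_level_results], dtype=float)
    ids = np.array([r.model_id or (i + 1) for i, r in enumerate(second_level_results)])
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("no finite free energies to compare")
    probs = np.zeros_like(F)
    Ff = F[finite]
    w = np.exp(Ff - Ff.max())
    probs[finite] = w / w.sum()
    return BmcResult(
        free_energies=F,
        posterior_probs=probs,
        winning_id=int(ids[int(np.argmax(np.where(finite, F, -np.inf)))]),
    )


def bma(
    second_level_results: list[PebResult],
    probs: np.ndarray | BmcResult,
    threshold_pp: float = 0.95,
    config: PebConfig | None = None,
) -> BmaResult:
    """Probability-weighted average of group posteriors across the designs.

    The mixture is moment-matched to one Gaussian; per-parameter posterior
    probabilities of a nonzero effect come from BMR pruning on the averaged
    posterior (prior variance of each effect parameter driven to zero), so an
    entry with ``pp < threshold`` is reported as not significant.
    """
    cfg = config or PebConfig()
    if isinstance(probs, BmcResult):
        probs = probs.posterior_probs
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    ref = second_level_results[0]
    d = ref.group_posterior.dim
    mean = np.zeros(d)
    second_moment = np.zeros((d, d))
    for w, r in zip(probs, second_level_results):
        if w <= 0:
            continue
        mu = r.group_posterior.mean
        mean += w * mu
        second_moment += w * (r.group_posterior.cov + np.outer(mu, mu))
    cov = second_moment - np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T)
    averaged = GaussianDensity(names=list(ref.group_posterior.names), mean=mean, cov=cov)

    # per-timespan parameter means: apply each design to its own effects
    p = len(ref.param_names)
    per_ts = np.zeros((N_TIMESPANS, p))
    for w, r in zip(probs, second_level_results):
        if w <= 0:
            continue
        beta = r.group_posterior.mean.reshape(len(r.column_names), p)
        rows = r.design[::N_SESSIONS]  # one row per timespan (sessions identical)
        per_ts += w * (rows @ beta)

    # BMR-based pruning of each parameter's time effect against the group
    # prior the designs were scored under
    pp: dict[str, float] = {}
    if ref.prior is not None:
        prior_mean = np.zeros(d)
        prior_mean[:p] = ref.prior.mean
        full_prior_cov = np.zeros((d, d))
        if ref.time_column is not None:
            for c in range(len(ref.column_names)):
                sl = slice(c * p, (c + 1) * p)
                full_prior_cov[sl, sl] = ref.prior.cov
            effect_cols = list(range(1, len(ref.column_names)))
        elif "time_effect" in ref.column_names:
            scales = _column_scales(ref.column_names, cfg)
            for c in range(len(ref.column_names)):
                sl = slice(c * p, (c + 1) * p)
                full_prior_cov[sl, sl] = ref.prior.cov * scales[c]
            effect_cols = [ref.column_names.index("time_effect")]
        else:
            effect_cols = []
        if effect_cols:
            full_prior = GaussianDensity(
                names=list(averaged.names), mean=prior_mean, cov=full_prior_cov
            )
            for j, pname in enumerate(ref.param_names):
                idx = [c * p + j for c in effect_cols]
                red_cov = full_prior_cov.copy()
                red_cov[idx, :] = 0.0
                red_cov[:, idx] = 0.0
                red_cov[idx, idx] = 1e-8
                reduced_prior = GaussianDensity(
                    names=list(averaged.names), mean=prior_mean, cov=red_cov
                )
                try:
                    dF, _ = bmr(averaged, full_prior, reduced_prior)
                except np.linalg.LinAlgError:
                    pp[pname] = float("nan")
                    continue
                # dF = log evidence(pruned) - log evidence(kept)
                pp[pname] = float(1.0 / (1.0 + math.exp(min(max(dF, -500.0), 500.0))))
    return BmaResult(
        averaged_posterior=averaged,
        per_timespan_means=per_ts,
        pp_per_parameter=pp,
        param_names=list(ref.param_names),
        threshold=threshold_pp,
    )


def effect_size(peb_result: PebResult, parameter: str) -> float:
    """Cohen's d: |time-effect posterior mean| / between-subject SD."""
    if parameter not in peb_result.param_names:
        raise KeyError(f"unknown parameter {parameter!r}")
    j = peb_result.param_names.index(parameter)
    p = len(peb_result.param_names)
    sd = float(peb_result.between_subject_sd[j])
    if sd <= 0:
        raise ValueError(f"between-subject SD for {parameter!r} is zero; d undefined")
    if "time_effect" in peb_result.column_names:
        c = peb_result.column_names.index("time_effect")
        mu = float(peb_result.group_posterior.mean[c * p + j])
    elif peb_result.time_column is not None:
        w = peb_result.time_column[:5]
        wn = float(w @ w)
        if wn == 0.0:  # the null design predicts no effect anywhere
            return 0.0
        u = np.array(
            [peb_result.group_posterior.mean[(k + 1) * p + j] for k in range(5)]
        )
        mu = float(w @ u) / wn
    else:
        raise ValueError("result carries no time-effect structure")
    return abs(mu) / sd
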