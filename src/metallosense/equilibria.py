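"""Mass-action speciation and chelator-competition affinity fitting.

The central objects are an :class:`EquilibriumModel` (named free components,
complexes with integer stoichiometries and log10 formation constants) and a
:class:`TitrationExperiment` (a schedule of total concentrations with an
observed signal).  The speciation solver works in log free-concentration
space with a damped Newton iteration, which keeps every concentration
positive even when formation constants span twenty orders of magnitude, as
they do for the Cu(i)-bis(bathocuproine disulfonate) complex
(log beta2 = 19.8).

Affinity fitting follows the chelator-competition strategy used for
copper(I) and zinc(II) sensor proteins: the protein's metal sites compete
with a chromophoric chelator of known affinity, and one or more titrations
are fit globally with shared thermodynamic constants and per-experiment
optical nuisance parameters (baseline and response scale).  When binding is
stoichiometric relative to the chelator, the affinity is unresolvable and
only a lower bound can be reported; the fitter detects this from the
likelihood profile and reports the bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EquilibriumModel",
    "TitrationExperiment",
    "AffinityFitResult",
    "SpeciationError",
    "solve_speciation",
    "simulate_titration",
    "fit_global_affinity",
    "detect_stoichiometry_breakpoint",
    "cu_bcs_model",
    "zn_mf2_model",
]

logger = logging.getLogger(__name__)


class SpeciationError(RuntimeError):
    """Raised when the speciation solver fails to converge."""


@dataclass(frozen=True)
class Complex:
    name: str
    stoich: tuple[int, ...]
    log_beta: float


@dataclass
class EquilibriumModel:
    """A set of components and complexes governed by mass action.

    Parameters
    ----------
    components
        Names of the free species (metal, chelator, protein site, ...).
    complexes
        Triples ``(name, stoich, log_beta)`` where ``stoich`` maps component
        names to non-negative integer coefficients and ``log_beta`` is the
        log10 cumulative formation constant in M^(1 - sum(stoich)).
    temperature
        Kelvin; carried for bookkeeping only.
    """

    components: list[str]
    complexes: list[Complex] = field(default_factory=list)
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if len(set(self.components)) != len(self.components):
            raise ValueError("component names must be unique")
        norm = []
        for cx in self.complexes:
            if not isinstance(cx, Complex):
                name, stoich, log_beta = cx
                if isinstance(stoich, dict):
                    vec = tuple(int(stoich.get(c, 0)) for c in self.components)
                else:
                    vec = tuple(int(s) for s in stoich)
                cx = Complex(name, vec, float(log_beta))
            if len(cx.stoich) != len(self.components):
                raise ValueError(f"stoichiometry length mismatch for {cx.name}")
            if any(s < 0 for s in cx.stoich) or not any(s > 0 for s in cx.stoich):
                raise ValueError(f"invalid stoichiometry for {cx.name}")
            if not np.isfinite(cx.log_beta):
                raise ValueError(f"non-finite log beta for {cx.name}")
            norm.append(cx)
        self.complexes = norm

    @property
    def stoich_matrix(self) -> np.ndarray:
        """(n_complexes, n_components) integer matrix."""
        return np.array([cx.stoich for cx in self.complexes], dtype=float).reshape(
            len(self.complexes), len(self.components)
        )

    def with_log_beta(self, name: str, log_beta: float) -> "EquilibriumModel":
        """Copy of the model with one complex's log beta replaced."""
        new = [
            Complex(cx.name, cx.stoich, log_beta if cx.name == name else cx.log_beta)
            for cx in self.complexes
        ]
        return EquilibriumModel(list(self.components), new, self.temperature)


@dataclass
class TitrationExperiment:
    """Totals schedule and observed signal for one titration.

    ``totals`` is a mapping component name -> array of per-point total
    concentrations (M).  ``signal`` is the observed optical signal (AU).
    ``observable`` maps species names (components or complexes) to molar
    response coefficients; a ``baseline`` offset completes the optical model.
    """

    totals: dict[str, np.ndarray]
    signal: np.ndarray
    titrant: str
    observable: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.totals = {k: np.asarray(v, dtype=float) for k, v in self.totals.items()}
        self.signal = np.asarray(self.signal, dtype=float)
        n = len(self.signal)
        for k, v in self.totals.items():
            if len(v) != n:
                raise ValueError(f"length mismatch for totals[{k!r}]")
            if np.any(v < 0):
                raise ValueError(f"negative totals for {k!r}")
        if self.titrant not in self.totals:
            raise ValueError(f"titrant {self.titrant!r} missing from totals")

    @property
    def n_points(self) -> int:
        return len(self.signal)


def _solve_point(
    S: np.ndarray,
    log10_beta: np.ndarray,
    totals: np.ndarray,
    *,
    max_iter: int = 200,
    rtol: float = 1e-12,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton solve for free concentrations at one titration point.

    Unknowns are ln(free) of components with positive totals; components with
    zero total are pinned at zero concentration and every complex containing
    them vanishes.
    """
    nc = len(totals)
    active = totals > 0
    free = np.zeros(nc)
    if not active.any():
        return free, np.zeros(len(log10_beta))

    # restrict to complexes formable from active components
    usable = np.array(
        [all(active[k] or S[j, k] == 0 for k in range(nc)) for j in range(len(log10_beta))]
    )
    Sa = S[np.ix_(usable, active)] if usable.any() else np.zeros((0, active.sum()))
    ln_beta = np.log(10.0) * log10_beta[usable] if usable.any() else np.zeros(0)
    ta = totals[active]

    x = np.log(ta) if x0 is None else x0.copy()
    scale = np.maximum(ta, 1e-300)
    conc = np.zeros(len(ln_beta))
    for it in range(max_iter):
        conc = np.exp(ln_beta + Sa @ x) if len(ln_beta) else conc
        f = np.exp(x)
        tot_calc = f + (Sa.T @ conc if len(conc) else 0.0)
        r = (tot_calc - ta) / scale
        if np.max(np.abs(r)) < rtol:
            break
        # J[i,k] = d tot_calc_i / d x_k, divided by scale_i
        J = np.diag(f) + (Sa.T @ (Sa * conc[:, None]) if len(conc) else 0.0)
        J = J / scale[:, None]
        try:
            dx = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -r, rcond=None)[0]
        # damping: cap the log step, then backtrack on the residual norm
        step = np.clip(dx, -3.0, 3.0)
        r0 = np.linalg.norm(r)
        lam = 1.0
        for _ in range(40):
            xt = x + lam * step
            ct = np.exp(ln_beta + Sa @ xt) if len(ln_beta) else conc
            rt = (np.exp(xt) + (Sa.T @ ct if len(ct) else 0.0) - ta) / scale
            if np.linalg.norm(rt) < r0:
                break
            lam *= 0.5
        x = x + lam * step
    else:
        # damped Newton stalled (pathological conditioning at extreme
        # formation constants): fall back to trust-region least squares on
        # the same log-free parameterization
        from scipy.optimize import least_squares as _lsq

        def _res(xv: np.ndarray) -> np.ndarray:
            cv = np.exp(ln_beta + Sa @ xv) if len(ln_beta) else np.zeros(0)
            return (np.exp(xv) + (Sa.T @ cv if len(cv) else 0.0) - ta) / scale

        sol = _lsq(_res, np.minimum(x, np.log(ta)), method="trf",
                   xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=2000)
        if np.max(np.abs(sol.fun)) > 1e-9:
            raise SpeciationError(
                f"speciation did not converge after {max_iter} iterations "
                f"(totals={totals.tolist()})"
            )
        x = sol.x

    free[active] = np.exp(x)
    all_conc = np.zeros(len(log10_beta))
    if usable.any():
        all_conc[usable] = np.exp(ln_beta + Sa @ x)
    return free, all_conc


def solve_speciation(
    model: EquilibriumModel, totals: dict[str, float]
) -> dict[str, float]:
    """Solve equilibrium speciation for one set of total concentrations.

    Returns a dict with the free concentration of every component (keyed by
    component name) and the concentration of every complex (keyed by complex
    name), all in molar.  Mass balance is satisfied to 1e-9 relative.
    """
    t = np.array([float(totals.get(c, 0.0)) for c in model.components])
    if np.any(t < 0):
        raise ValueError("totals must be non-negative")
    S = model.stoich_matrix
    lb = np.array([cx.log_beta for cx in model.complexes])
    free, conc = _solve_point(S, lb, t)
    out = {c: free[i] for i, c in enumerate(model.components)}
    out.update({cx.name: conc[j] for j, cx in enumerate(model.complexes)})
    return out


def _speciate_schedule(
    model: EquilibriumModel, totals: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Vectorized-by-loop speciation over a titration schedule.

    Consecutive points warm-start from the previous solution, which makes
    titration curves cheap despite the per-point Newton solve.
    """
    names = model.components
    arrs = [np.asarray(totals.get(c, 0.0), dtype=float) for c in names]
    npts = max((len(a) for a in arrs if a.ndim), default=1)
    T = np.column_stack([np.broadcast_to(a, npts) for a in arrs])
    S = model.stoich_matrix
    lb = np.array([cx.log_beta for cx in model.complexes])
    free = np.zeros((npts, len(names)))
    conc = np.zeros((npts, len(model.complexes)))
    x_prev: np.ndarray | None = None
    prev_active: np.ndarray | None = None
    for i in range(npts):
        act = T[i] > 0
        x0 = x_prev if (prev_active is not None and np.array_equal(act, prev_active)) else None
        try:
            free[i], conc[i] = _solve_point(S, lb, T[i], x0=x0)
        except SpeciationError:
            free[i], conc[i] = _solve_point(S, lb, T[i])  # cold restart
        x_prev = np.log(np.maximum(free[i][act], 1e-300)) if act.any() else None
        prev_active = act
    out = {c: free[:, j] for j, c in enumerate(names)}
    out.update({cx.name: conc[:, j] for j, cx in enumerate(model.complexes)})
    return out


def simulate_titration(
    model: EquilibriumModel,
    totals: dict[str, np.ndarray],
    observable: dict[str, float],
    baseline: float = 0.0,
) -> np.ndarray:
    """Predicted signal = baseline + sum(eps_i * conc_i) along a schedule."""
    known = set(model.components) | {cx.name for cx in model.complexes}
    for sp in observable:
        if sp not in known:
            raise ValueError(f"observable species {sp!r} not in model")
    spec = _speciate_schedule(model, totals)
    npts = len(next(iter(spec.values())))
    sig = np.full(npts, float(baseline))
    for sp, eps in observable.items():
        sig = sig + eps * spec[sp]
    return sig


@dataclass
class AffinityFitResult:
    """Result of a global competition fit.

    ``log10_K`` maps each floated complex name to its fitted log10 constant;
    ``stderr`` and ``ci95`` carry the Jacobian-based standard errors and
    +/-1.96 SE intervals.  ``nuisance`` holds per-experiment (baseline,
    scale).  When the objective profile is flat above the estimate
    (stoichiometric binding) ``lower_bound_only`` is set and
    ``lower_bound_log10K`` holds the largest log10 K at which the objective
    rises by four residual variances (about two sigma).
    """

    log10_K: dict[str, float]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    nuisance: list[dict[str, float]]
    residuals: np.ndarray
    rss: float
    lower_bound_only: bool = False
    lower_bound_log10K: float | None = None

    def __post_init__(self) -> None:
        for k, est in self.log10_K.items():
            lo, hi = self.ci95.get(k, (est, est))
            if not (lo <= est <= hi):
                raise ValueError("confidence interval does not bracket estimate")


def _profiled_residuals(
    model: EquilibriumModel,
    experiments: list[TitrationExperiment],
    free_names: list[str],
    log_k: np.ndarray,
    fixed: dict[str, float],
) -> tuple[np.ndarray, list[dict[str, float]]]:
    """Residuals with per-experiment baseline/scale solved by linear LS.

    The optical model ``signal = b + s * m(point)`` is linear in (b, s) for a
    fixed thermodynamic parameter vector, so the nuisances are profiled out
    exactly (variable projection).
    """
    m = model
    for name, v in fixed.items():
        m = m.with_log_beta(name, v)
    for name, v in zip(free_names, log_k):
        m = m.with_log_beta(name, v)
    res_all = []
    nuis = []
    for exp in experiments:
        pred = simulate_titration(m, exp.totals, exp.observable, baseline=0.0)
        A = np.column_stack([np.ones_like(pred), pred])
        coef, *_ = np.linalg.lstsq(A, exp.signal, rcond=None)
        b, s = coef
        res_all.append(A @ coef - exp.signal)
        nuis.append({"baseline": b, "scale": s})
    return np.concatenate(res_all), nuis


def fit_global_affinity(
    experiments: list[TitrationExperiment],
    model: EquilibriumModel,
    free_parameters: dict[str, float],
    fixed_parameters: dict[str, float] | None = None,
    *,
    bound_scan_width: float = 4.0,
) -> AffinityFitResult:
    """Global least-squares fit of shared formation constants.

    Parameters
    ----------
    experiments
        One or more titrations sharing the thermodynamic model.
    model
        Template model; the constants named in ``free_parameters`` and
        ``fixed_parameters`` refer to its complexes.
    free_parameters
        Mapping complex name -> initial log10 constant for the floated
        constants.
    fixed_parameters
        Mapping complex name -> log10 constant held fixed.
    bound_scan_width
        Width (log10 units) of the profile scans used to detect a
        stoichiometric (lower-bound-only) regime.
    """
    if not experiments:
        raise ValueError("at least one experiment required")
    fixed = dict(fixed_parameters or {})
    free_names = list(free_parameters)
    n_obs = sum(e.n_points for e in experiments)
    n_par = len(free_names) + 2 * len(experiments)
    if n_obs < n_par:
        raise ValueError(
            f"underdetermined: {n_obs} points for {n_par} parameters"
        )

    x0 = np.array([free_parameters[n] for n in free_names], dtype=float)

    def fun(x: np.ndarray) -> np.ndarray:
        return _profiled_residuals(model, experiments, free_names, x, fixed)[0]

    sol = least_squares(fun, x0, diff_step=1e-4, xtol=1e-12, ftol=1e-12)
    res, nuis = _profiled_residuals(model, experiments, free_names, sol.x, fixed)
    rss = float(res @ res)
    dof = max(n_obs - n_par, 1)
    s2 = rss / dof

    # SEs from the Jacobian of the profiled objective at the optimum
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(free_names), np.inf)

    est = {n: float(v) for n, v in zip(free_names, sol.x)}
    stderr = {n: float(s) for n, s in zip(free_names, se)}
    ci = {n: (est[n] - 1.96 * stderr[n], est[n] + 1.96 * stderr[n]) for n in free_names}

    result = AffinityFitResult(
        log10_K=est, stderr=stderr, ci95=ci, nuisance=nuis, residuals=res, rss=rss
    )

    # Lower-bound detection by a 1-D likelihood profile of the first floated
    # constant: flat above the optimum means only a bound is resolvable.
    if len(free_names) == 1:
        name = free_names[0]
        khat = est[name]
        threshold = 4.0 * s2  # ~2 sigma on the objective

        def rss_at(lk: float) -> float:
            r, _ = _profiled_residuals(model, experiments, free_names, np.array([lk]), fixed)
            return float(r @ r)

        if rss_at(khat + bound_scan_width) - rss < threshold:
            result.lower_bound_only = True
            # scan downward for the largest logK whose objective exceeds the
            # threshold, then bisect the crossing
            lo, hi = khat - 12.0, khat
            grid = np.linspace(lo, hi, 49)
            rss_grid = np.array([rss_at(g) for g in grid])
            above = rss_grid - rss > threshold
            if above.any():
                i = int(np.nonzero(above)[0].max())
                a, b = grid[i], grid[min(i + 1, len(grid) - 1)]
                for _ in range(30):
                    mid = 0.5 * (a + b)
                    if rss_at(mid) - rss > threshold:
                        a = mid
                    else:
                        b = mid
                result.lower_bound_log10K = float(0.5 * (a + b))
            else:
                result.lower_bound_log10K = float(lo)
            logger.debug(
                "lower-bound regime: logK >= %.2f", result.lower_bound_log10K
            )
    return result


def detect_stoichiometry_breakpoint(
    titration: TitrationExperiment,
    protein_concentration: float,
    *,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Equivalence point of a stoichiometric titration by bilinear fit.

    Fits a continuous two-segment piecewise-linear model to signal vs
    titrant total and returns the intersection abscissa divided by
    ``protein_concentration`` (mol titrant per mol protein unit), with a
    residual-bootstrap 95% CI.

    Raises ``ValueError`` when the schedule has no post-saturation plateau
    (fewer than 3 points on either side of the best break).
    """
    x = titration.totals[titration.titrant]
    y = titration.signal

    def fit_break(yv: np.ndarray) -> tuple[float, float]:
        best = (np.inf, np.nan)
        for xb in np.linspace(x[1], x[-2], 201):
            A = np.column_stack(
                [np.ones_like(x), x, np.maximum(x - xb, 0.0)]
            )
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            r = A @ coef - yv
            sse = float(r @ r)
            if sse < best[0]:
                best = (sse, xb)
        return best[1], best[0]

    xb, _ = fit_break(y)
    n_pre = int(np.sum(x < xb))
    n_post = int(np.sum(x > xb))
    if n_pre < 3 or n_post < 3:
        raise ValueError("breakpoint undefined: need >=3 points on each side")
    # reject if the post-break segment is not a plateau relative to pre-break
    A = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope_pre, slope_post = coef[1], coef[1] + coef[2]
    if abs(slope_pre) > 0 and abs(slope_post) > 0.5 * abs(slope_pre):
        raise ValueError("breakpoint undefined: no post-saturation plateau")

    resid = A @ coef - y
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        yb = A @ coef + rng.choice(resid, size=len(resid), replace=True)
        xb_b, _ = fit_break(yb)
        boots.append(xb_b / protein_concentration)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "equivalence": float(xb / protein_concentration),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "break_total": float(xb),
    }


def cu_bcs_model(
    log_beta2: float = 19.8, log_k_cu: float = 16.0
) -> EquilibriumModel:
    """Cu(i)/BCS competition model with two identical independent protein
    sites per dimer (site concentration = 2 x dimer).

    Components: Cu, BCS, P (protein site).  Complexes: CuL2 (the A483
    chromophore) and CuP (per-site association constant K_Cu).
    """
    return EquilibriumModel(
        components=["Cu", "BCS", "P"],
        complexes=[
            ("CuL2", {"Cu": 1, "BCS": 2}, log_beta2),
            ("CuP", {"Cu": 1, "P": 1}, log_k_cu),
        ],
    )


def zn_mf2_model(
    log_k_mf2: float = np.log10(5.0e7), log_k_zn: float = 9.0
) -> EquilibriumModel:
    """Zn(ii)/mag-fura-2 competition model with one Zn site per dimer.

    Components: Zn, mf2, P (dimer site).  The Zn-mf2 complex is the A325
    chromophore.
    """
    return EquilibriumModel(
        components=["Zn", "mf2", "P"],
        complexes=[
            ("Znmf2", {"Zn": 1, "mf2": 1}, log_k_mf2),
            ("ZnP", {"Zn": 1, "P": 1}, log_k_zn),
        ],
    )
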