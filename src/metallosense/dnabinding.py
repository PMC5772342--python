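"""Protein-DNA binding isotherms and allosteric coupling free energy.

The repressor dimer is treated as non-dissociable, so binding of dimer (P)
to operator duplex (D) is a simple 1:1 equilibrium with association constant
Ka.  The exact bound fraction of DNA follows from the quadratic mass-balance
solution, with no ligand-excess approximation, which matters because
fluorescence-anisotropy titrations are run with DNA near the Kd.

The allosteric coupling free energy between two metal-occupancy states is

    dG_c = -R T ln(Ka_state / Ka_ref)

so a *negative* dG_c means the queried state binds DNA more tightly than
the reference (allosteric activation); a positive value means inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import R_KCAL, T_DEFAULT

__all__ = [
    "BindingIsotherm",
    "CouplingResult",
    "fraction_bound_1to1",
    "fit_anisotropy_isotherm",
    "coupling_free_energy",
    "estimate_ka_from_band_fractions",
]

logger = logging.getLogger(__name__)


@dataclass
class BindingIsotherm:
    """One anisotropy (or bound-fraction) titration at fixed DNA."""

    protein_dimer: np.ndarray  # M, per point
    dna_total: float  # M
    anisotropy: np.ndarray  # dimensionless
    metallostate: str = "apo"
    temperature: float = T_DEFAULT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_dimer = np.asarray(self.protein_dimer, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if len(self.protein_dimer) != len(self.anisotropy):
            raise ValueError("length mismatch")
        if np.any(self.protein_dimer < 0) or self.dna_total < 0:
            raise ValueError("totals must be non-negative")
        if np.any((self.anisotropy < 0) | (self.anisotropy > 0.4)):
            raise ValueError("anisotropy outside [0, 0.4]")


@dataclass
class CouplingResult:
    dG_c: float  # kcal/mol
    dG_c_se: float
    ka_ref: float
    ka_state: float
    temperature: float


def fraction_bound_1to1(Ka: float, Ptot, Dtot) -> np.ndarray | float:
    """Exact bound fraction of DNA for 1:1 dimer-DNA binding.

    fb = [(KaP + KaD + 1) - sqrt((KaP + KaD + 1)^2 - 4 Ka^2 P D)] / (2 Ka D)

    Continuous in all arguments; the Dtot -> 0 limit is Ka P / (1 + Ka P).
    """
    Ka = float(Ka)
    if Ka < 0:
        raise ValueError("Ka must be non-negative")
    P = np.asarray(Ptot, dtype=float)
    D = np.asarray(Dtot, dtype=float)
    if np.any(P < 0) or np.any(D < 0):
        raise ValueError("totals must be non-negative")
    if Ka == 0:
        out = np.zeros(np.broadcast(P, D).shape)
        return float(out) if out.ndim == 0 else out
    b = Ka * P + Ka * D + 1.0
    disc = b * b - 4.0 * Ka * Ka * P * D
    # rationalized root 2KaP/(b + sqrt(disc)) avoids the catastrophic
    # cancellation of (b - sqrt(disc)) when Ka*P and Ka*D are small; it also
    # gives the correct Dtot -> 0 limit KaP/(1 + KaP) without branching
    fb = 2.0 * Ka * P / (b + np.sqrt(np.maximum(disc, 0.0)))
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def fit_anisotropy_isotherm(isotherm: BindingIsotherm) -> dict:
    """Nonlinear LS fit of r = r_free + dr * fb(Ka, P, D).

    Ka is parameterized as log10 so its uncertainty is symmetric on the
    scale binding constants live on.  Returns point estimates, standard
    errors, and the residual vector.

    Raises ``ValueError`` when the data show no curvature (all points at
    one end of the transition), in which case only a bound on Ka could be
    reported.
    """
    P, D, r = isotherm.protein_dimer, isotherm.dna_total, isotherm.anisotropy
    if len(r) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    span = r.max() - r.min()
    if span <= 0:
        raise ValueError("unresolvable Ka: flat isotherm; report a bound instead")

    params = lmfit.Parameters()
    # seed logKa at the half-saturation protein concentration
    mid = r.min() + 0.5 * span
    i_mid = int(np.argmin(np.abs(r - mid)))
    p_mid = max(P[i_mid], 1e-12)
    params.add("log_ka", value=-np.log10(p_mid), min=0, max=15)
    params.add("r_free", value=float(r.min()), min=0, max=0.4)
    params.add("dr", value=float(span))

    def resid(p):
        fb = fraction_bound_1to1(10.0 ** p["log_ka"].value, P, D)
        return p["r_free"].value + p["dr"].value * fb - r

    out = lmfit.minimize(resid, params)
    fb_hat = fraction_bound_1to1(10.0 ** out.params["log_ka"].value, P, D)
    if fb_hat.max() - fb_hat.min() < 0.2:
        raise ValueError(
            "unresolvable Ka: no curvature in data; report a bound instead"
        )
    ka = 10.0 ** out.params["log_ka"].value
    log_se = out.params["log_ka"].stderr
    return {
        "Ka": float(ka),
        "Ka_se": float(ka * np.log(10) * log_se) if log_se else np.nan,
        "log10_Ka": float(out.params["log_ka"].value),
        "log10_Ka_se": float(log_se) if log_se else np.nan,
        "r_free": float(out.params["r_free"].value),
        "r_free_se": float(out.params["r_free"].stderr or np.nan),
        "dr": float(out.params["dr"].value),
        "dr_se": float(out.params["dr"].stderr or np.nan),
        "residuals": np.asarray(resid(out.params)),
        "rss": float(np.sum(np.asarray(resid(out.params)) ** 2)),
    }


def coupling_free_energy(
    ka_ref: float,
    ka_state: float,
    T: float = T_DEFAULT,
    *,
    ka_ref_se: float = 0.0,
    ka_state_se: float = 0.0,
) -> CouplingResult:
    """Allosteric coupling free energy dG_c = -RT ln(Ka_state/Ka_ref).

    Negative dG_c = activation (the state binds DNA more tightly than the
    reference); positive = inhibition.  The SE is propagated from the two
    Ka standard errors assuming independence.
    """
    if ka_ref <= 0 or ka_state <= 0:
        raise ValueError("association constants must be positive")
    dg = -R_KCAL * T * np.log(ka_state / ka_ref)
    se = R_KCAL * T * np.hypot(
        ka_ref_se / ka_ref if ka_ref_se else 0.0,
        ka_state_se / ka_state if ka_state_se else 0.0,
    )
    return CouplingResult(float(dg), float(se), ka_ref, ka_state, T)


def estimate_ka_from_band_fractions(
    bound: np.ndarray,
    free: np.ndarray,
    protein_dimer: np.ndarray,
    dna_total: float,
) -> dict:
    """Ka estimate from gel-shift band intensities.

    Per lane, fb = B / (B + F); lanes with zero total intensity are
    excluded with a logged warning.  Ka is then the least-squares match of
    the 1:1 closed-form isotherm to the lane fractions.
    """
    B = np.asarray(bound, dtype=float)
    F = np.asarray(free, dtype=float)
    P = np.asarray(protein_dimer, dtype=float)
    if np.any(B < 0) or np.any(F < 0):
        raise ValueError("intensities must be non-negative")
    tot = B + F
    keep = tot > 0
    if not keep.all():
        logger.warning("excluding %d zero-intensity lane(s)", int((~keep).sum()))
    B, F, P, tot = B[keep], F[keep], P[keep], tot[keep]
    fb = B / tot
    mid = (fb > 0) & (fb < 1)
    if not mid.any():
        logger.warning("all-or-nothing lanes: Ka estimate is a bound only")
        if fb.max() == 0:
            return {"Ka": 0.0, "bound_only": True}

    def resid(p):
        return fraction_bound_1to1(10.0 ** p["log_ka"].value, P, dna_total) - fb

    params = lmfit.Parameters()
    p_mid = max(P[int(np.argmin(np.abs(fb - 0.5)))], 1e-12)
    params.add("log_ka", value=-np.log10(p_mid), min=0, max=15)
    out = lmfit.minimize(resid, params)
    return {
        "Ka": float(10.0 ** out.params["log_ka"].value),
        "log10_Ka": float(out.params["log_ka"].value),
        "bound_only": not mid.any(),
        "residuals": np.asarray(resid(out.params)),
        "n_lanes": int(keep.sum()),
    }
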