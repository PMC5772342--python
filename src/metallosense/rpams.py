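"""Ratiometric pulsed-alkylation mass spectrometry (rPA-MS) analysis.

A pulse of pentadeuterated N-ethylmaleimide (d5-NEM) followed by a chase
with protiated NEM (H5-NEM) under denaturing conditions converts the
kinetics of cysteine alkylation into a 5.0 Da isotope shift readable by
MALDI-TOF.  This module computes the isotopologue peptide and fragment
masses, the pulse-time forward model for species fractions, per-cysteine
rate fitting, and the MS/MS partitioning of a singly-deuterated two-Cys
peptide into per-site occupancies.

Masses are monoisotopic by default (an average-mass mode is available);
residue masses come from pyteomics.  The kinetic model treats sites as
independent pseudo-first-order reactions with an ideal instantaneous chase,
so the per-site deuteration probability is 1 - exp(-k t) and species
fractions are products over sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from pyteomics import mass as _pmass
from scipy.optimize import least_squares

from .constants import D5_NEM_MASS, NEM_MASS, PROTON, WATER

__all__ = [
    "Peptide",
    "AdductLibrary",
    "AlkylationTimeCourse",
    "peptide_mh_mass",
    "modified_peptide_masses",
    "fragment_ion_masses",
    "alkylation_forward_model",
    "fit_alkylation_rates",
    "protection_factor",
    "site_occupancy_from_fragments",
]

logger = logging.getLogger(__name__)

_MONO = dict(_pmass.std_aa_mass)  # monoisotopic residue masses, 1-letter
_AVG = {aa: _pmass.calculate_mass(sequence=aa, average=True) - 18.0153 for aa in _MONO}


@dataclass
class AdductLibrary:
    """Named alkylation adducts and the mass each Michael addition adds."""

    adducts: dict[str, float] = field(
        default_factory=lambda: {"h5": NEM_MASS, "d5": D5_NEM_MASS}
    )

    def mass(self, name: str) -> float:
        key = name.lower().replace("-nem", "").replace("nem", "") or name.lower()
        key = {"": "h5", "h5": "h5", "d5": "d5"}.get(key, name.lower())
        if key not in self.adducts:
            raise KeyError(f"unknown adduct {name!r}")
        m = self.adducts[key]
        if m <= 0:
            raise ValueError("adduct masses must be positive")
        return m


@dataclass
class Peptide:
    """A peptide with free termini and optional per-residue adducts.

    ``modifications`` is a list of (0-based residue index, adduct name);
    alkylation adducts are only accepted on cysteine.
    """

    sequence: str
    modifications: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(_MONO)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        for idx, _name in self.modifications:
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"modification index {idx} out of range")
            if self.sequence[idx] != "C":
                raise ValueError(
                    f"alkylation adduct on non-Cys residue {self.sequence[idx]}{idx}"
                )

    @property
    def cys_indices(self) -> list[int]:
        return [i for i, aa in enumerate(self.sequence) if aa == "C"]


def peptide_mh_mass(
    peptide: Peptide | str,
    *,
    adducts: AdductLibrary | None = None,
    average: bool = False,
) -> float:
    """Monoisotopic [M+H]+ of a peptide, including its adducts (Da)."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    table = _AVG if average else _MONO
    lib = adducts or AdductLibrary()
    m = sum(table[aa] for aa in peptide.sequence) + WATER + PROTON
    m += sum(lib.mass(name) for _idx, name in peptide.modifications)
    return m


def modified_peptide_masses(
    peptide: Peptide | str,
    labeling: dict[int, str] | list[str] | None = None,
    *,
    adducts: AdductLibrary | None = None,
) -> dict[str, float]:
    """[M+H]+ for isotopologue species of an alkylated peptide.

    ``labeling`` assigns each Cys an adduct ('h5', 'd5') or None for
    unmodified; given as a dict keyed by residue index or a list in Cys
    order.  When omitted, all fully-alkylated combinations are enumerated —
    for n Cys these collapse into n+1 ratio-distinguishable mass classes
    keyed like 'd5/h5'.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    lib = adducts or AdductLibrary()
    cys = peptide.cys_indices
    if labeling is not None:
        if isinstance(labeling, dict):
            pattern = [labeling.get(i) for i in cys]
        else:
            if len(labeling) != len(cys):
                raise ValueError("one label per Cys required")
            pattern = list(labeling)
        mods = [(i, lab) for i, lab in zip(cys, pattern) if lab]
        key = "/".join(lab if lab else "-" for lab in pattern) or "unmodified"
        return {key: peptide_mh_mass(Peptide(peptide.sequence, mods), adducts=lib)}
    out: dict[str, float] = {}
    for combo in product(["d5", "h5"], repeat=len(cys)):
        # mass classes only: site permutations of the same label multiset
        # are isobaric, so sort labels into a canonical key (d5 first)
        key = "/".join(sorted(combo)) if cys else "unmodified"
        mods = [(i, lab) for i, lab in zip(cys, combo)]
        out[key] = peptide_mh_mass(Peptide(peptide.sequence, mods), adducts=lib)
    return dict(sorted(out.items(), key=lambda kv: kv[1]))


def fragment_ion_masses(
    peptide: Peptide | str,
    series: str = "by",
    max_charge: int = 1,
    *,
    adducts: AdductLibrary | None = None,
) -> dict[str, float]:
    """b- and/or y-ion m/z values, modifications carried by the fragment
    containing the modified site.

    b_i = sum(residues 1..i) + z*proton; y_j = sum(residues n-j+1..n) +
    water + z*proton, reported as m/z.  The complementarity identity
    b_i + y_{n-i} = [M+H]+ + proton holds exactly at charge 1.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if max_charge < 1:
        raise ValueError("charge must be >= 1")
    lib = adducts or AdductLibrary()
    n = len(peptide.sequence)
    res = np.array([_MONO[aa] for aa in peptide.sequence])
    add = np.zeros(n)
    for idx, name in peptide.modifications:
        add[idx] += lib.mass(name)
    res = res + add
    out: dict[str, float] = {}
    for z in range(1, max_charge + 1):
        zs = "" if z == 1 else f"^{z}+"
        if "b" in series:
            csum = np.cumsum(res[:-1])
            for i, m in enumerate(csum, start=1):
                out[f"b{i}{zs}"] = (m + z * PROTON) / z
        if "y" in series:
            csum = np.cumsum(res[::-1][:-1])
            for j, m in enumerate(csum, start=1):
                out[f"y{j}{zs}"] = (m + WATER + z * PROTON) / z
    return out


@dataclass
class AlkylationTimeCourse:
    """Pulse-time series of isotopologue species intensities.

    ``intensities`` maps species key (e.g. 'd5/h5') to an array over pulse
    times.  Keys use sorted adduct labels so 'd5/h5' covers both site
    permutations of a singly-deuterated two-Cys peptide.
    """

    times: np.ndarray  # s
    intensities: dict[str, np.ndarray]
    sites: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.intensities = {
            k: np.asarray(v, dtype=float) for k, v in self.intensities.items()
        }
        for k, v in self.intensities.items():
            if len(v) != len(self.times):
                raise ValueError(f"length mismatch for {k}")
            if np.any(v < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def n_sites(self) -> int:
        if self.sites:
            return len(self.sites)
        return max(k.count("/") for k in self.intensities) + 1


def _species_keys(n_sites: int) -> list[str]:
    """Mass-class keys for n sites: number of d5 labels 0..n."""
    return ["/".join(["d5"] * k + ["h5"] * (n_sites - k)) for k in range(n_sites + 1)]


def alkylation_forward_model(times, k_per_site) -> dict[str, np.ndarray]:
    """Expected species fractions under independent pseudo-first-order
    labeling.

    Per-site d5 probability f_i(t) = 1 - exp(-k_i t); a species fraction is
    the product of its sites' probabilities summed over site permutations
    within a mass class.  Fractions sum to 1 at every time.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    k = np.asarray(k_per_site, dtype=float)
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    f = 1.0 - np.exp(-np.outer(k, t))  # (n_sites, n_times)
    n = len(k)
    out = {key: np.zeros_like(t) for key in _species_keys(n)}
    for combo in product([True, False], repeat=n):
        p = np.ones_like(t)
        for i, is_d5 in enumerate(combo):
            p = p * (f[i] if is_d5 else (1.0 - f[i]))
        key = "/".join(["d5"] * sum(combo) + ["h5"] * (n - sum(combo)))
        out[key] += p
    return out


def fit_alkylation_rates(tc: AlkylationTimeCourse) -> dict:
    """Per-site alkylation rate constants from a species time course.

    Intensities are normalized to fractions at each pulse time; time points
    with zero total intensity are excluded with a warning.  Rates are fit by
    least squares against the independent-sites forward model in log space.
    A site whose labeling is undetectable is reported as k = 0 with a finite
    upper bound from the objective profile.

    For multi-Cys peptides the MS-level species cannot say *which* site is
    fast; rates are returned sorted ascending and site assignment requires
    the MS/MS partitioning (see :func:`site_occupancy_from_fragments`).
    """
    t = tc.times
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    n = tc.n_sites
    keys = _species_keys(n)
    I = np.vstack([tc.intensities[k] for k in keys])
    tot = I.sum(axis=0)
    keep = tot > 0
    if not keep.all():
        warnings.warn("excluding time point(s) with zero total intensity")
    t, I, tot = t[keep], I[:, keep], tot[keep]
    frac = I / tot

    def resid(logk):
        model = alkylation_forward_model(t, np.exp(logk))
        return np.concatenate([model[k] - frac[i] for i, k in enumerate(keys)])

    # staggered start values break the permutation symmetry deterministically
    k0 = np.log(np.array([10.0 ** (-2 - 0.5 * i) for i in range(n)]))
    sol = least_squares(resid, k0, xtol=1e-14, ftol=1e-14)
    k_hat = np.sort(np.exp(sol.x))
    rss = float(sol.fun @ sol.fun)
    dof = max(frac.size - n, 1)
    s2 = rss / dof

    results = []
    for i, k in enumerate(k_hat):
        entry = {"k": float(k), "upper_bound": None}
        # undetectable labeling: predicted d5 conversion below noise at t_max
        if k * t.max() < 0.02:
            entry["k"] = 0.0
            # largest k whose objective stays within ~2 sigma of the optimum
            grid = np.logspace(-8, 1, 120)
            others = np.delete(k_hat, i)
            for g in grid[::-1]:
                trial = np.sort(np.append(others, g))
                r = resid(np.log(np.maximum(trial, 1e-300)))
                if float(r @ r) - rss <= 4.0 * s2:
                    entry["upper_bound"] = float(g)
                    break
        results.append(entry)
    return {
        "k": [r["k"] for r in results],
        "upper_bounds": [r["upper_bound"] for r in results],
        "rss": rss,
        "n_times": int(keep.sum()),
    }


def protection_factor(k_ref: float, k_state: float) -> float:
    """Protection factor = k_reference / k_state (>= 0; inf when fully
    quenched)."""
    if k_ref < 0 or k_state < 0:
        raise ValueError("rates must be non-negative")
    if k_state == 0:
        return np.inf if k_ref > 0 else 1.0
    return k_ref / k_state


def site_occupancy_from_fragments(
    fragment_intensities: dict[str, tuple[float, float]],
    diagnostic_ions: dict[str, list[str]],
) -> dict[str, float]:
    """Relative d5 occupancy per Cys from MS/MS of the singly-deuterated
    peptide.

    ``fragment_intensities`` maps ion label -> (d5 intensity, h5 intensity);
    ``diagnostic_ions`` maps site name -> ion labels diagnostic for that
    site alone (e.g. y2/y3 for the C-terminal Cys, b9/b10 for the internal
    one).  Raw occupancy per site is sum(d5)/sum(d5+h5) over its ions; the
    two sites of a singly-labeled peptide are then normalized to sum to 1.
    """
    raw: dict[str, float] = {}
    for site, ions in diagnostic_ions.items():
        d5 = h5 = 0.0
        for ion in ions:
            if ion in fragment_intensities:
                a, b = fragment_intensities[ion]
                d5 += a
                h5 += b
        if d5 + h5 == 0:
            raise ValueError(f"no diagnostic ions observed for site {site}")
        raw[site] = d5 / (d5 + h5)
    total = sum(raw.values())
    if total == 0:
        return {s: 0.0 for s in raw}
    return {s: v / total for s, v in raw.items()}
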