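"""Equilibrium thermodynamics of one protein binding a two-site DNA.

The model is the standard two-site lattice: a DNA duplex carries two
protein-binding sites with microscopic association constants K1 and K2
(per molar) and a cooperativity factor omega multiplying the statistical
weight of the doubly-bound state.  At free protein concentration ``p`` the
partition function over the four microstates {empty, site1, site2, both} is

    Z = 1 + (K1 + K2) p + omega K1 K2 p**2

and the species fractions observable on a gel (free DNA, monomer shift,
dimer shift) are f0 = 1/Z, f1 = (K1 + K2) p / Z, f2 = omega K1 K2 p**2 / Z.
omega > 1 is positive cooperativity, omega = 1 independent sites, omega < 1
negative cooperativity.

EMSA lanes run at micromolar DNA, where bound protein is a large share of
total protein, so the free concentration is solved from conservation
(ligand depletion) rather than approximated by the total.

Identifiability: the observable fractions depend on the parameters only
through K1 + K2 and omega * K1 * K2, so a single titration cannot separate
K1 from K2.  ``fit_affinities`` therefore ties K1 = K2 by default; the
``fix`` mask lets callers pin any parameter from outside information
(e.g. an ITC-derived K) and untie the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "SiteAffinities",
    "SpeciesFractions",
    "TitrationLane",
    "CooperativityEstimate",
    "StoichiometryResult",
    "AffinityFit",
    "LaneUnusableError",
    "partition_fractions",
    "solve_free_protein",
    "simulate_series",
    "omega_from_lane",
    "estimate_omega",
    "classify_cooperativity",
    "fit_affinities",
    "macroscopic_constants",
    "infer_stoichiometry",
    "duplex_mass",
]

#: Lanes with a monomer-shift fraction below this are excluded from the
#: ratio estimator: its variance explodes as f1 -> 0.
EPSILON_F1 = 0.05


class LaneUnusableError(ValueError):
    """Raised when a lane's monomer fraction is too small for the ratio estimator."""


@dataclass(frozen=True)
class SiteAffinities:
    """Microscopic association constants (per molar) and cooperativity factor."""

    k1: float
    k2: float
    omega: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("association constants must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    def canonical(self) -> "SiteAffinities":
        """Break the K1<->K2 exchange symmetry: K1 >= K2."""
        if self.k1 >= self.k2:
            return self
        return SiteAffinities(self.k2, self.k1, self.omega)

    @property
    def kd1_uM(self) -> float:
        return 1e6 / self.k1

    @property
    def kd2_uM(self) -> float:
        return 1e6 / self.k2


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of free (f0), singly-bound (f1) and doubly-bound (f2) DNA."""

    f0: float
    f1: float
    f2: float

    def __post_init__(self) -> None:
        for name, val in (("f0", self.f0), ("f1", self.f1), ("f2", self.f2)):
            if not -1e-9 <= val <= 1 + 1e-9:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if abs(self.f0 + self.f1 + self.f2 - 1.0) > 1e-6:
            raise ValueError(
                f"fractions sum to {self.f0 + self.f1 + self.f2}, expected 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2])


@dataclass(frozen=True)
class TitrationLane:
    """One EMSA lane: totals (molar) plus the observed species fractions."""

    p_total: float
    d_total: float
    fractions: SpeciesFractions
    label: str = ""

    def __post_init__(self) -> None:
        if self.p_total < 0:
            raise ValueError("p_total must be >= 0")
        if self.d_total <= 0:
            raise ValueError("d_total must be > 0")


@dataclass(frozen=True)
class CooperativityEstimate:
    omega_hat: float
    se: float
    n_used: int
    classification: str

    def __post_init__(self) -> None:
        if self.n_used < 1:
            raise ValueError("need at least one usable lane")


@dataclass(frozen=True)
class StoichiometryResult:
    """Protomers per duplex inferred from a light-scattering complex mass."""

    n_protein: int
    residual_mass: float


@dataclass(frozen=True)
class AffinityFit:
    params: SiteAffinities
    rss: float
    param_se: dict[str, float]
    converged: bool
    n_lanes: int
    message: str = ""


def partition_fractions(params: SiteAffinities, p_free: float) -> SpeciesFractions:
    """Species fractions of the two-site lattice at free protein ``p_free`` (M)."""
    if p_free < 0:
        raise ValueError(f"p_free must be >= 0, got {p_free}")
    w1 = (params.k1 + params.k2) * p_free
    w2 = params.omega * params.k1 * params.k2 * p_free * p_free
    z = 1.0 + w1 + w2
    return SpeciesFractions(1.0 / z, w1 / z, w2 / z)


def _bound_protein(params: SiteAffinities, p_free: float, d_total: float) -> float:
    f = partition_fractions(params, p_free)
    return d_total * (f.f1 + 2.0 * f.f2)


def solve_free_protein(
    params: SiteAffinities, p_total: float, d_total: float
) -> float:
    """Free protein concentration satisfying mass conservation.

    Solves p_total = p_free + d_total * (f1 + 2 f2) by bracketed root
    finding on [0, p_total]; the bound term is strictly increasing in
    p_free, so the root is unique.
    """
    if p_total < 0 or d_total < 0:
        raise ValueError("totals must be non-negative")
    if p_total == 0.0:
        return 0.0
    if d_total == 0.0:
        return p_total

    def residual(p: float) -> float:
        return p + _bound_protein(params, p, d_total) - p_total

    lo, hi = 0.0, p_total
    if residual(hi) < 0:  # cannot happen mathematically; guard numerics
        raise RuntimeError("free-protein bracket failed")
    root = brentq(residual, lo, hi, xtol=1e-30, rtol=4 * np.finfo(float).eps)
    return float(root)


def simulate_series(
    params: SiteAffinities,
    p_totals: Iterable[float],
    d_total: float,
) -> list[TitrationLane]:
    """Noiseless model twin of an EMSA titration (one lane per p_total)."""
    lanes = []
    for i, p_tot in enumerate(p_totals):
        p_free = solve_free_protein(params, p_tot, d_total)
        lanes.append(
            TitrationLane(
                p_total=float(p_tot),
                d_total=float(d_total),
                fractions=partition_fractions(params, p_free),
                label=f"lane{i + 1}",
            )
        )
    return lanes


def omega_from_lane(lane: TitrationLane, epsilon_f1: float = EPSILON_F1) -> float:
    """Statistical-factor-corrected lane estimator 4 f0 f2 / f1**2.

    Exact when K1 = K2; for unequal sites it reads low by the fixed factor
    4 K1 K2 / (K1 + K2)**2 <= 1 (documented bias, independent of protein
    concentration).
    """
    f = lane.fractions
    if f.f1 <= epsilon_f1:
        raise LaneUnusableError(
            f"monomer fraction {f.f1:.4f} <= {epsilon_f1}; lane excluded "
            "(use mid-titration lanes)"
        )
    return 4.0 * f.f0 * f.f2 / (f.f1 * f.f1)


def classify_cooperativity(omega_hat: float, se: float) -> str:
    """'positive', 'none' or 'negative' with a 2*SE (min 0.05) band around 1."""
    band = max(2.0 * se, 0.05)
    if abs(omega_hat - 1.0) <= band:
        return "none"
    return "positive" if omega_hat > 1.0 else "negative"


def estimate_omega(
    series: Sequence[TitrationLane],
    epsilon_f1: float = EPSILON_F1,
    epsilon_bands: float = EPSILON_F1,
) -> CooperativityEstimate:
    """Mean of the lane estimator over usable lanes, with SEM across lanes.

    A lane is usable when every band fraction exceeds the quantifiability
    threshold: all three bands enter the ratio, and a band near zero is
    dominated by densitometry noise (clipping at zero makes the estimator's
    bias unbounded, not just its variance).  Pass ``epsilon_bands=0`` to
    recover the f1-only rule.
    """
    values = []
    for lane in series:
        f = lane.fractions
        if min(f.f0, f.f2) <= epsilon_bands:
            continue
        try:
            values.append(omega_from_lane(lane, epsilon_f1=epsilon_f1))
        except LaneUnusableError:
            continue
    if not values:
        raise LaneUnusableError(
            "no usable lane (all monomer fractions below threshold); "
            "include mid-titration lanes where the monomer shift is populated"
        )
    arr = np.asarray(values)
    omega_hat = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return CooperativityEstimate(
        omega_hat=omega_hat,
        se=se,
        n_used=arr.size,
        classification=classify_cooperativity(omega_hat, se),
    )


_FIT_PARAM_NAMES = ("k1", "k2", "omega")
_MULTISTART_SEEDS = (101, 211, 307, 401, 503)


def fit_affinities(
    series: Sequence[TitrationLane],
    fix: Mapping[str, float] | None = None,
    tie_sites: bool = True,
    weights: Sequence[float] | None = None,
) -> AffinityFit:
    """Least-squares fit of the two-site model to observed lane fractions.

    Parameters are optimised in log space; the free protein concentration is
    re-solved per lane inside the objective (full depletion treatment).
    Five fixed-seed multi-starts guard against local minima.  ``fix`` maps
    parameter names ('k1', 'k2', 'omega') to pinned values; ``tie_sites``
    constrains K1 = K2 (the identifiable default, see module docstring).
    ``weights`` are per-lane weights (default 1).
    """
    if len(series) < 4:
        raise ValueError("need at least 4 lanes spanning the titration")
    fix = dict(fix or {})
    for name in fix:
        if name not in _FIT_PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r} in fix mask")
    if weights is None:
        w = np.ones(len(series))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(series),):
            raise ValueError("weights must have one entry per lane")

    free_names = [n for n in _FIT_PARAM_NAMES if n not in fix]
    if tie_sites and "k1" in free_names and "k2" in free_names:
        free_names.remove("k2")  # k2 mirrors k1

    obs = np.concatenate([lane.fractions.as_array() for lane in series])
    lane_w = np.repeat(w, 3)

    def unpack(theta: np.ndarray) -> SiteAffinities:
        vals = dict(fix)
        for name, t in zip(free_names, theta):
            vals[name] = math.exp(t)
        if "k2" not in vals:
            vals["k2"] = vals["k1"]
        return SiteAffinities(vals["k1"], vals["k2"], max(vals["omega"], 1e-300))

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = unpack(theta)
        pred = []
        for lane in series:
            p_free = solve_free_protein(params, lane.p_total, lane.d_total)
            pred.append(partition_fractions(params, p_free).as_array())
        return lane_w * (np.concatenate(pred) - obs)

    # Heuristic initial guess: K ~ 1/median(p_total), omega from usable lanes.
    p_med = float(np.median([ln.p_total for ln in series if ln.p_total > 0]))
    k_init = 1.0 / max(p_med, 1e-12)
    omega_vals = []
    for lane in series:
        try:
            omega_vals.append(omega_from_lane(lane))
        except LaneUnusableError:
            pass
    omega_init = float(np.median(omega_vals)) if omega_vals else 1.0
    omega_init = max(omega_init, 1e-3)
    base = {"k1": k_init, "k2": k_init, "omega": omega_init}
    theta0 = np.array([math.log(base[n]) for n in free_names])

    best = None
    for trial, seed in enumerate((None,) + _MULTISTART_SEEDS[: 4]):
        if seed is None:
            start = theta0
        else:
            rng = np.random.default_rng(seed)
            start = theta0 + rng.normal(0.0, 1.0, size=theta0.shape)
        try:
            sol = least_squares(
                residuals, start, xtol=1e-14, ftol=1e-14, gtol=1e-14, method="trf"
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    params = unpack(best.x).canonical()
    rss = float(2.0 * best.cost)
    # Approximate SEs of the log-parameters from the Jacobian.
    param_se: dict[str, float] = {}
    m, k = best.fun.size, best.x.size
    if m > k:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (m - k)
            for name, var in zip(free_names, np.diag(cov)):
                param_se[name] = float(math.sqrt(max(var, 0.0)))
        except np.linalg.LinAlgError:
            pass
    converged = bool(best.status > 0)
    return AffinityFit(
        params=params,
        rss=rss,
        param_se=param_se,
        converged=converged,
        n_lanes=len(series),
        message="" if converged else "did not converge; best-so-far returned",
    )


def macroscopic_constants(params: SiteAffinities) -> tuple[float, float]:
    """Macroscopic stepwise constants (Ka1, Ka2) for sequential site filling.

    Ka1 = K1 + K2 and Ka2 = omega K1 K2 / (K1 + K2); for equal independent
    sites Ka1/Ka2 = 4, the pure statistical factor.
    """
    ka1 = params.k1 + params.k2
    ka2 = params.omega * params.k1 * params.k2 / ka1
    return ka1, ka2


# Average masses (Da) of 2'-deoxynucleoside 5'-monophosphate residues and water.
_DNMP_MASS = {"A": 331.2218, "C": 307.1971, "G": 347.2212, "T": 322.2085}
_WATER_MASS = 18.0153


def duplex_mass(seq) -> float:
    """Average mass of a blunt double-stranded DNA in kDa.

    Convention: each strand is a chain of dNMP residues losing one water per
    phosphodiester bond (n - 1 waters for n nucleotides); both strands
    (complement included) are summed.  Symmetric under reverse complement.
    """
    bases = seq.bases if hasattr(seq, "bases") else str(seq).upper()
    if not bases:
        raise ValueError("empty sequence")
    if "N" in bases:
        raise ValueError("cannot compute mass of sequence containing N")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    total = 0.0
    for strand in (bases, "".join(comp[b] for b in bases)):
        total += sum(_DNMP_MASS[b] for b in strand) - (len(strand) - 1) * _WATER_MASS
    return total / 1000.0


def infer_stoichiometry(
    complex_mass: float, protein_mass: float, dna_mass: float
) -> StoichiometryResult:
    """Integer protomer count per duplex from SEC-MALS masses (kDa)."""
    if complex_mass <= 0 or protein_mass <= 0 or dna_mass <= 0:
        raise ValueError("all masses must be positive")
    if complex_mass < dna_mass - protein_mass / 2.0:
        raise ValueError(
            f"complex mass {complex_mass} kDa below DNA mass {dna_mass} kDa "
            "by more than half a protomer"
        )
    n = round((complex_mass - dna_mass) / protein_mass)
    if n < 0:
        n = 0
    residual = complex_mass - (dna_mass + n * protein_mass)
    return StoichiometryResult(n_protein=int(n), residual_mass=float(residual))
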