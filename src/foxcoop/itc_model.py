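"""Isothermal titration calorimetry: simulation and fitting.

Simulates per-injection heats for a protein titrated into DNA held in a
perfusion cell, for two equilibrium models:

* ``one_site`` — n identical independent sites per duplex with association
  constant Ka and molar enthalpy dH1 (kcal/mol);
* ``two_site_sequential`` — sequential filling of two sites with macroscopic
  stepwise constants Ka1, Ka2 and stepwise enthalpies dH1, dH2.  Internally
  the sequential model is mapped onto the microscopic two-site lattice of
  :mod:`foxcoop.binding_model` (equal microscopic sites K = Ka1/2 with
  cooperativity omega = 4 Ka2 / Ka1 reproduce any admissible Ka1 >= 4 Ka2
  ... including the cooperative regime Ka2 > Ka1/4).

A biphasic isotherm — normalized heats that change direction, produced by
opposing-sign stepwise enthalpies — is the calorimetric signature of two
thermodynamically distinct binding events on the same duplex.

Cell bookkeeping uses the standard constant-volume displacement convention:
an injection of volume v dilutes existing cell contents by (1 - v/V0) and
delivers syringe material at concentration c_syr * (v/V0) * (1 - v/(2 V0)),
i.e. half of the incoming slug is itself subject to displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.signal import medfilt

from .binding_model import SiteAffinities, partition_fractions, solve_free_protein

__all__ = [
    "ONE_SITE",
    "TWO_SITE",
    "ITCProtocol",
    "ThermoParams",
    "ITCTrace",
    "ITCFit",
    "ModelComparison",
    "concentrations_after_injection",
    "dilution_ledger",
    "simulate_itc",
    "fit_itc",
    "compare_models",
    "biphasic_index",
    "wiseman_isotherm",
]

KCAL_TO_UCAL = 1.0e9

ONE_SITE = "one_site"
TWO_SITE = "two_site_sequential"


@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule: volumes in liters, concentrations in molar."""

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes", tuple(float(v) for v in self.injection_volumes)
        )
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("need at least 2 injections")
        for v in self.injection_volumes:
            if not 0 < v < self.cell_volume:
                raise ValueError(
                    f"injection volume {v} must be in (0, cell_volume)"
                )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of a binding model.

    ``ka1``/``ka2`` in per molar, ``dh1``/``dh2`` in kcal/mol (stepwise for
    the sequential model), ``n`` the site multiplicity (one-site only),
    ``dilution_offset`` a constant normalized-heat nuisance (kcal/mol).
    """

    model: str
    ka1: float
    dh1: float
    ka2: float | None = None
    dh2: float | None = None
    n: float = 1.0
    dilution_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in (ONE_SITE, TWO_SITE):
            raise ValueError(f"unknown model {self.model!r}")
        if self.ka1 <= 0:
            raise ValueError("ka1 must be positive")
        if self.model == TWO_SITE:
            if self.ka2 is None or self.dh2 is None:
                raise ValueError("two-site model requires ka2 and dh2")
            if self.ka2 <= 0:
                raise ValueError("ka2 must be positive")
        else:
            if self.n <= 0:
                raise ValueError("site multiplicity n must be positive")


@dataclass(frozen=True)
class ITCTrace:
    """Per-injection observables; all arrays have one entry per injection."""

    injectant_moles: np.ndarray
    heats_ucal: np.ndarray
    normalized_kcal_per_mol: np.ndarray
    molar_ratio: np.ndarray
    cumulative_kcal: np.ndarray

    def __post_init__(self) -> None:
        lengths = {
            len(self.injectant_moles),
            len(self.heats_ucal),
            len(self.normalized_kcal_per_mol),
            len(self.molar_ratio),
            len(self.cumulative_kcal),
        }
        if len(lengths) != 1:
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")

    @property
    def n_injections(self) -> int:
        return len(self.heats_ucal)


@dataclass(frozen=True)
class ITCFit:
    params: ThermoParams
    rss: float
    aicc: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class ModelComparison:
    selected_model: str
    delta_aicc: float
    biphasic_index: int
    indeterminate: bool
    fits: dict


def dilution_ledger(protocol: ITCProtocol) -> dict[str, np.ndarray]:
    """Cell concentrations and mole bookkeeping after each injection.

    Returns arrays (index i = state after injection i+1) of total DNA and
    protein concentrations in the cell, plus cumulative injected, in-cell and
    expelled protein moles; injected = in-cell + expelled holds to machine
    precision (conservation across the displacement convention).
    """
    v0 = protocol.cell_volume
    d, p = protocol.cell_conc, 0.0
    d_list, p_list = [], []
    injected = expelled = 0.0
    injected_list, incell_list, expelled_list = [], [], []
    for v in protocol.injection_volumes:
        frac = v / v0
        expelled += p * v + protocol.syringe_conc * v * frac / 2.0
        p = p * (1.0 - frac) + protocol.syringe_conc * frac * (1.0 - frac / 2.0)
        d = d * (1.0 - frac)
        injected += protocol.syringe_conc * v
        d_list.append(d)
        p_list.append(p)
        injected_list.append(injected)
        incell_list.append(p * v0)
        expelled_list.append(expelled)
    return {
        "d_total": np.array(d_list),
        "p_total": np.array(p_list),
        "injected_moles": np.array(injected_list),
        "in_cell_moles": np.array(incell_list),
        "expelled_moles": np.array(expelled_list),
    }


def concentrations_after_injection(
    protocol: ITCProtocol, i: int
) -> tuple[float, float]:
    """(d_total, p_total) in the cell after injection ``i`` (0-based)."""
    if not 0 <= i < protocol.n_injections:
        raise ValueError(f"injection index {i} out of range")
    ledger = dilution_ledger(protocol)
    return float(ledger["d_total"][i]), float(ledger["p_total"][i])


def _one_site_free_protein(ka: float, n: float, p_tot: float, d_tot: float) -> float:
    """Free protein for n identical independent sites per duplex."""
    if p_tot == 0.0:
        return 0.0

    def resid(p: float) -> float:
        return p + n * d_tot * ka * p / (1.0 + ka * p) - p_tot

    return brentq(resid, 0.0, p_tot, xtol=1e-30, rtol=4 * np.finfo(float).eps)


def _micro_from_sequential(ka1: float, ka2: float) -> SiteAffinities:
    """Equal-site microscopic parameters reproducing macroscopic (Ka1, Ka2)."""
    k = ka1 / 2.0
    omega = 4.0 * ka2 / ka1
    return SiteAffinities(k, k, omega)


def _cumulative_heats(
    protocol: ITCProtocol, params: ThermoParams
) -> np.ndarray:
    """Cumulative cell heat content Q_i (kcal) after each injection."""
    ledger = dilution_ledger(protocol)
    v0 = protocol.cell_volume
    q = np.empty(protocol.n_injections)
    if params.model == ONE_SITE:
        for i, (d, p) in enumerate(zip(ledger["d_total"], ledger["p_total"])):
            p_free = _one_site_free_protein(params.ka1, params.n, p, d)
            theta = params.ka1 * p_free / (1.0 + params.ka1 * p_free)
            q[i] = v0 * d * params.n * theta * params.dh1
    else:
        micro = _micro_from_sequential(params.ka1, params.ka2)
        for i, (d, p) in enumerate(zip(ledger["d_total"], ledger["p_total"])):
            p_free = solve_free_protein(micro, p, d)
            f = partition_fractions(micro, p_free)
            q[i] = v0 * d * (
                f.f1 * params.dh1 + f.f2 * (params.dh1 + params.dh2)
            )
    return q


def simulate_itc(protocol: ITCProtocol, params: ThermoParams) -> ITCTrace:
    """Noiseless per-injection heats for a protocol and parameter set."""
    q_cum = _cumulative_heats(protocol, params)
    v0 = protocol.cell_volume
    vols = np.asarray(protocol.injection_volumes)
    q_prev = np.concatenate(([0.0], q_cum[:-1]))
    # Displacement correction: material expelled mid-injection carries the
    # average of the before/after heat content.
    q_inj = q_cum - q_prev + (vols / v0) * (q_cum + q_prev) / 2.0
    inj_moles = protocol.syringe_conc * vols
    ledger = dilution_ledger(protocol)
    normalized = q_inj / inj_moles + params.dilution_offset
    return ITCTrace(
        injectant_moles=inj_moles,
        heats_ucal=q_inj * KCAL_TO_UCAL,
        normalized_kcal_per_mol=normalized,
        molar_ratio=ledger["p_total"] / ledger["d_total"],
        cumulative_kcal=q_cum,
    )


def wiseman_isotherm(
    ka: float, n: float, dh: float, v0: float, d_tot: float, p_tot: np.ndarray
) -> np.ndarray:
    """Closed-form cumulative heat (kcal) for n identical sites, no dilution.

    Q = (n d V0 dH / 2) [1 + P/(n d) + 1/(n Ka d)
        - sqrt((1 + P/(n d) + 1/(n Ka d))**2 - 4 P/(n d))]
    """
    p = np.asarray(p_tot, dtype=float)
    x = p / (n * d_tot)
    r = 1.0 / (n * ka * d_tot)
    s = 1.0 + x + r
    return n * d_tot * v0 * dh / 2.0 * (s - np.sqrt(s * s - 4.0 * x))


def biphasic_index(trace: ITCTrace) -> int:
    """Sign changes in the first differences of the normalized heats after
    3-point median smoothing; >= 1 flags a non-monotone (biphasic) isotherm."""
    q = np.asarray(trace.normalized_kcal_per_mol, dtype=float)
    if q.size < 3:
        return 0
    smoothed = medfilt(q, kernel_size=3)
    diffs = np.diff(smoothed)
    scale = np.max(np.abs(q)) if np.max(np.abs(q)) > 0 else 1.0
    signs = np.sign(diffs[np.abs(diffs) > 1e-9 * scale])
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


_MULTISTART_SEEDS = (17, 23, 31, 47)


def _aicc(rss: float, m: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = m * math.log(rss / m) + 2 * k
    if m - k - 1 > 0:
        aic += 2 * k * (k + 1) / (m - k - 1)
    return aic


def fit_itc(
    trace: ITCTrace,
    protocol: ITCProtocol,
    model: str,
) -> ITCFit:
    """Least-squares fit of normalized heats; multi-start, Ka in log space.

    One-site free parameters: (log Ka, dH1, log n, offset); sequential
    two-site: (log Ka1, dH1, log Ka2, dH2, offset).  Model comparison uses
    AICc on the residual sum of squares.
    """
    if trace.n_injections < 8:
        raise ValueError("need at least 8 injections to fit")
    if model not in (ONE_SITE, TWO_SITE):
        raise ValueError(f"unknown model {model!r}")
    obs = np.asarray(trace.normalized_kcal_per_mol, dtype=float)

    def unpack(theta: np.ndarray) -> ThermoParams:
        if model == ONE_SITE:
            return ThermoParams(
                ONE_SITE,
                ka1=math.exp(theta[0]),
                dh1=theta[1],
                n=math.exp(theta[2]),
                dilution_offset=theta[3],
            )
        return ThermoParams(
            TWO_SITE,
            ka1=math.exp(theta[0]),
            dh1=theta[1],
            ka2=math.exp(theta[2]),
            dh2=theta[3],
            dilution_offset=theta[4],
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            sim = simulate_itc(protocol, unpack(theta))
        except (ValueError, RuntimeError, OverflowError):
            return np.full_like(obs, 1e6)
        return sim.normalized_kcal_per_mol - obs

    ka_init = 1.0 / protocol.cell_conc
    dh_init = float(obs[0])
    if model == ONE_SITE:
        theta0 = np.array([math.log(ka_init), dh_init, 0.0, 0.0])
    else:
        dh2_init = float(obs[len(obs) // 2] - dh_init)
        theta0 = np.array(
            [math.log(ka_init * 4.0), dh_init, math.log(ka_init), dh2_init, 0.0]
        )

    best = None
    for seed in (None,) + _MULTISTART_SEEDS:
        if seed is None:
            start = theta0
        else:
            rng = np.random.default_rng(seed)
            start = theta0 + rng.normal(0.0, 1.0, size=theta0.shape)
        try:
            sol = least_squares(
                residuals, start, xtol=1e-12, ftol=1e-12, gtol=1e-12, method="trf"
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    rss = float(2.0 * best.cost)
    k = best.x.size
    m = obs.size
    converged = bool(best.status > 0)
    flat = float(np.ptp(obs)) < 1e-12
    msg = ""
    if flat:
        msg = "flat trace: Ka unidentifiable"
    elif not converged:
        msg = "did not converge; best-so-far returned"
    return ITCFit(
        params=unpack(best.x),
        rss=rss,
        aicc=_aicc(rss, m, k),
        converged=converged and not flat,
        message=msg,
    )


def compare_models(trace: ITCTrace, protocol: ITCProtocol) -> ModelComparison:
    """Fit both binding models and select by AICc.

    ``delta_aicc`` is AICc(one_site) - AICc(two_site): positive favours the
    sequential two-site model.  |delta| < 2 is flagged indeterminate.
    """
    fit_one = fit_itc(trace, protocol, ONE_SITE)
    fit_two = fit_itc(trace, protocol, TWO_SITE)
    delta = fit_one.aicc - fit_two.aicc
    selected = TWO_SITE if delta > 0 else ONE_SITE
    # Null baseline: a constant heat (pure dilution / noise).  If neither
    # binding model beats it, the comparison is meaningless.
    obs = np.asarray(trace.normalized_kcal_per_mol, dtype=float)
    rss_null = float(np.sum((obs - obs.mean()) ** 2))
    aicc_null = _aicc(rss_null, obs.size, 1)
    indeterminate = bool(
        abs(delta) < 2.0 or aicc_null <= min(fit_one.aicc, fit_two.aicc)
    )
    return ModelComparison(
        selected_model=selected,
        delta_aicc=float(delta),
        biphasic_index=biphasic_index(trace),
        indeterminate=indeterminate,
        fits={ONE_SITE: fit_one, TWO_SITE: fit_two},
    )
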