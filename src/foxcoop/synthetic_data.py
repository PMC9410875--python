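"""Seeded generators emulating every experimental input the pipeline reads.

The generators are pure functions of (parameters, seed): identical inputs
give byte-identical outputs.  They emulate

* quantitative EMSA titration tables (species fractions with Gaussian
  densitometry noise, renormalized),
* ITC injection heat tables (Gaussian heat noise),
* promoter-like background sequences with implanted motif instances,
* ideal fiber B-DNA coordinates (via :mod:`foxcoop.structure_groove`).

Named scenarios map the wild-type two-site parameters onto the mutant and
perturbation probes (FBE1/FBE2 knockouts, spacer insertions, Mg depletion)
as documented parameter conventions reproducing the qualitative outcomes of
those experiments; they are not structure-based predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binding_model import SiteAffinities, TitrationLane, simulate_series
from .itc_model import ITCProtocol, ITCTrace, ThermoParams, simulate_itc
from .sequence_motif import DnaSequence, reverse_complement

__all__ = [
    "EmsaNoiseModel",
    "Scenario",
    "SCENARIOS",
    "apply_scenario",
    "gen_emsa_series",
    "gen_itc_trace",
    "gen_promoter",
]

#: Association-constant factor standing in for an "abolished" site that
#: still binds weakly (consensus replaced by a C-run).
WEAK_SITE_FACTOR = 0.02
#: Factor for a fully dead site (no occupancy at assay concentrations).
DEAD_SITE_FACTOR = 0.002


@dataclass(frozen=True)
class EmsaNoiseModel:
    """Gaussian densitometry noise added to fractions before renormalization."""

    sigma_frac: float = 0.03
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_frac < 0:
            raise ValueError("sigma_frac must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """Parameter overrides emulating a probe variant.

    ``k1_factor``/``k2_factor`` scale the microscopic constants;
    ``omega_value`` pins the cooperativity factor; ``omega_residual``
    moves it toward 1 keeping that fraction of the excess
    (omega' = 1 + residual * (omega - 1)).
    """

    name: str
    k1_factor: float = 1.0
    k2_factor: float = 1.0
    omega_value: Optional[float] = None
    omega_residual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k1_factor <= 0 or self.k2_factor <= 0:
            raise ValueError("scale factors must be positive")


SCENARIOS: dict[str, Scenario] = {
    # Wild-type probe: identity.
    "WT": Scenario("WT"),
    # FBE1 consensus replaced: the anchoring site is dead and the second
    # site keeps only its weak intrinsic affinity (no allosteric boost), so
    # the dimer shift is lost and only a weak monomer shift remains.
    "mut1": Scenario(
        "mut1", k1_factor=DEAD_SITE_FACTOR, k2_factor=WEAK_SITE_FACTOR,
        omega_value=1.0,
    ),
    # FBE2 replaced: cooperativity vanishes, second site weakened.  The
    # weakening factor is calibrated so the noiseless lane estimator reads
    # ~0.96 (4f/(1+f)^2 at f=2/3), the residual value reported for this probe.
    "mut2": Scenario("mut2", k2_factor=2.0 / 3.0, omega_value=1.0),
    # Both sites replaced: essentially no occupancy at assay concentrations.
    "mut3": Scenario(
        "mut3", k1_factor=DEAD_SITE_FACTOR, k2_factor=DEAD_SITE_FACTOR,
        omega_value=1.0,
    ),
    # Spacer insertions between the half sites break the allosteric register.
    "spacer_S1": Scenario("spacer_S1", omega_residual=0.25),
    "spacer_S2": Scenario("spacer_S2", omega_residual=0.05),
    # Mg depletion weakens the protein-protein dimer contribution.
    "Mg_depleted": Scenario("Mg_depleted", omega_residual=0.1),
}


def apply_scenario(base: SiteAffinities, scenario: Scenario | str) -> SiteAffinities:
    """Apply a named scenario's overrides to a base parameter set."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
            ) from None
    omega = base.omega
    if scenario.omega_value is not None:
        omega = scenario.omega_value
    if scenario.omega_residual is not None:
        omega = 1.0 + scenario.omega_residual * (omega - 1.0)
    return SiteAffinities(
        k1=base.k1 * scenario.k1_factor,
        k2=base.k2 * scenario.k2_factor,
        omega=omega,
    )


def _perturb_fractions(
    fractions: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    noisy = fractions + rng.normal(0.0, sigma, size=3)
    noisy = np.clip(noisy, 0.0, None)
    total = noisy.sum()
    if total == 0.0:
        return fractions
    return noisy / total


def gen_emsa_series(
    params: SiteAffinities,
    p_totals: Sequence[float],
    d_total: float,
    noise: EmsaNoiseModel,
) -> list[TitrationLane]:
    """Noisy synthetic EMSA titration; replicates are concatenated lanes.

    With ``sigma_frac = 0`` the output equals the noiseless simulation.
    """
    rng = np.random.default_rng(noise.seed)
    clean = simulate_series(params, p_totals, d_total)
    lanes: list[TitrationLane] = []
    for rep in range(1, noise.n_replicates + 1):
        for lane in clean:
            if noise.sigma_frac == 0.0:
                frac = lane.fractions
            else:
                arr = _perturb_fractions(
                    lane.fractions.as_array(), noise.sigma_frac, rng
                )
                from .binding_model import SpeciesFractions

                frac = SpeciesFractions(*arr)
            lanes.append(
                TitrationLane(
                    p_total=lane.p_total,
                    d_total=lane.d_total,
                    fractions=frac,
                    label=f"rep{rep}:{lane.label}",
                )
            )
    return lanes


def gen_itc_trace(
    protocol: ITCProtocol,
    params: ThermoParams,
    sigma_heat: Optional[float] = None,
    seed: int = 0,
) -> ITCTrace:
    """Simulated ITC trace with Gaussian noise on the normalized heats.

    ``sigma_heat`` is in kcal/mol of injectant; None means 2% of the largest
    absolute normalized heat.  Zero noise returns the simulator output.
    """
    trace = simulate_itc(protocol, params)
    if sigma_heat is None:
        sigma_heat = 0.02 * float(np.max(np.abs(trace.normalized_kcal_per_mol)))
    if sigma_heat == 0.0:
        return trace
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_heat, size=trace.n_injections)
    normalized = trace.normalized_kcal_per_mol + noise
    heats = normalized * trace.injectant_moles * 1.0e9
    return ITCTrace(
        injectant_moles=trace.injectant_moles,
        heats_ucal=heats,
        normalized_kcal_per_mol=normalized,
        molar_ratio=trace.molar_ratio,
        cumulative_kcal=trace.cumulative_kcal,
    )


def gen_promoter(
    length: int,
    implants: Sequence[tuple[str, int, str]] = (),
    seed: int = 0,
) -> DnaSequence:
    """Uniform-background sequence with motif instances written in verbatim.

    ``implants`` are (instance, position, strand) triples; minus-strand
    instances are written as their reverse complement on the plus strand.
    Implants must fit and must not overlap each other.
    """
    rng = np.random.default_rng(seed)
    bases = list(rng.choice(list("ACGT"), size=length))
    occupied: list[tuple[int, int]] = []
    for instance, pos, strand in implants:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+'/'-', got {strand!r}")
        written = instance.upper() if strand == "+" else reverse_complement(instance)
        end = pos + len(written)
        if pos < 0 or end > length:
            raise ValueError(f"implant {instance!r} at {pos} does not fit")
        for s, e in occupied:
            if pos < e and s < end:
                raise ValueError(f"implant {instance!r} at {pos} overlaps another")
        occupied.append((pos, end))
        bases[pos:end] = list(written)
    return DnaSequence(f"synthetic-promoter-{seed}", "".join(bases))
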