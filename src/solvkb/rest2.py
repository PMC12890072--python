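"""Replica exchange with solute tempering (REST2) scaling arithmetic.

In REST2 all replicas run at one physical temperature T0, but replica m
sees a softened potential in which the intra-solute energy is scaled by
lambda_m = beta_m / beta_0 and the solute-solvent energy by
sqrt(lambda_m), while the solvent-solvent energy is never scaled:

    E_m(X) = lambda_m * E_pp(X) + sqrt(lambda_m) * E_ps(X) + E_ss(X)

This module builds the lambda ladder, evaluates scaled energies, and
computes the Metropolis probability for a pairwise replica swap.  It
performs no molecular dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KJ_PER_MOL_K


@dataclass(frozen=True)
class EnergyComponents:
    """Decomposed potential energy of one configuration, kJ/mol."""

    E_pp: float  # intra-solute
    E_ps: float  # solute-solvent
    E_ss: float  # solvent-solvent

    def __post_init__(self) -> None:
        for name in ("E_pp", "E_ps", "E_ss"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ReplicaLadder:
    """Scaling factors lambda_m = beta_m / beta_0, descending from 1."""

    lambdas: tuple[float, ...]
    base_temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        lam = self.lambdas
        if len(lam) < 2:
            raise ValueError("a ladder needs at least 2 replicas")
        if abs(lam[0] - 1.0) > 1e-12:
            raise ValueError("lambda_0 must be exactly 1")
        if any(b >= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambdas must be strictly decreasing")
        if self.base_temperature <= 0:
            raise ValueError("base temperature must be positive")

    @property
    def n_replicas(self) -> int:
        return len(self.lambdas)

    @property
    def lambda_min(self) -> float:
        return self.lambdas[-1]


def build_ladder(
    n_replicas: int,
    lambda_min: float,
    spacing: str = "geometric",
    base_temperature: float = 300.0,
) -> ReplicaLadder:
    """Lambda ladder with exact endpoints lambda_0 = 1, lambda_{M-1} = lambda_min.

    Geometric spacing (constant ratio lambda_min^(1/(M-1))) is the
    default; linear spacing (constant difference) is available for
    comparison.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if not 0 < lambda_min < 1:
        raise ValueError("lambda_min must lie strictly between 0 and 1")
    m = np.arange(n_replicas)
    if spacing == "geometric":
        lam = lambda_min ** (m / (n_replicas - 1))
    elif spacing == "linear":
        lam = 1.0 + m * (lambda_min - 1.0) / (n_replicas - 1)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    lam[0], lam[-1] = 1.0, lambda_min  # exact endpoints
    return ReplicaLadder(tuple(float(x) for x in lam),
                         base_temperature=base_temperature)


def scaled_energy(components: EnergyComponents, lam: float) -> float:
    """REST2 replica energy: lam * E_pp + sqrt(lam) * E_ps + E_ss (kJ/mol)."""
    if not 0 < lam <= 1:
        raise ValueError("lambda must lie in (0, 1]")
    return lam * components.E_pp + np.sqrt(lam) * components.E_ps + components.E_ss


def swap_delta(
    components_i: EnergyComponents,
    components_j: EnergyComponents,
    lambda_i: float,
    lambda_j: float,
    base_temperature: float = 300.0,
) -> float:
    """Dimensionless Metropolis exponent for swapping configurations i and j.

    Delta = beta_0 [ (E_i(lambda_j) + E_j(lambda_i))
                     - (E_i(lambda_i) + E_j(lambda_j)) ]
    Antisymmetric under exchanging the replica labels.
    """
    if base_temperature <= 0:
        raise ValueError("base temperature must be positive")
    beta0 = 1.0 / (KB_KJ_PER_MOL_K * base_temperature)
    after = scaled_energy(components_i, lambda_j) + scaled_energy(components_j, lambda_i)
    before = scaled_energy(components_i, lambda_i) + scaled_energy(components_j, lambda_j)
    return beta0 * (after - before)


def swap_acceptance(
    components_i: EnergyComponents,
    components_j: EnergyComponents,
    lambda_i: float,
    lambda_j: float,
    base_temperature: float = 300.0,
) -> float:
    """Metropolis swap probability min(1, exp(-Delta)); symmetric in (i, j)."""
    delta = swap_delta(components_i, components_j, lambda_i, lambda_j,
                       base_temperature)
    return float(min(1.0, np.exp(-delta)))
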