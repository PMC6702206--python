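"""Simulated biological communities: biomass, DNA shedding, and ambient eDNA.

A community is a set of ``n_taxa`` taxa with proportional biomass ``B``
(summing to one), per-taxon DNA shedding rates ``s``, and the resulting
equilibrium environmental-DNA concentration ``D = B * s``.  Collection and
extraction are assumed unbiased (DNA is collected in proportion to its
ambient abundance and extracted with equal efficiency), so ``D`` is the
template pool that enters PCR directly.

Biomass is either exactly uniform (``B_i = 1/N``) or drawn from a symmetric
Dirichlet with concentration ``gamma``; smaller ``gamma`` means more
among-taxon variation.  Shedding rates are lognormal: ``LogNormal(0.5, 0.5)``
by default, parameterized by the mean and standard deviation of the
underlying normal on the natural-log scale.  eDNA concentrations are point
values: production and loss are assumed to be at equilibrium, with loss
constant among taxa, so no decay dynamics are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomassModel",
    "SheddingModel",
    "CommunityState",
    "draw_biomass",
    "draw_shedding",
    "edna_concentration",
    "simulate_community",
]

_BIOMASS_KINDS = ("uniform", "dirichlet")


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BiomassModel:
    """Distribution of proportional biomass among taxa.

    Parameters
    ----------
    kind : {"uniform", "dirichlet"}
        ``uniform`` gives every taxon exactly ``1/N``; ``dirichlet`` draws
        from a symmetric Dirichlet.
    gamma : float
        Dirichlet concentration (> 0); ignored for the uniform model.
        ``gamma=5`` is a moderately variable community, ``gamma=1`` a
        highly variable one.
    """

    kind: str = "dirichlet"
    gamma: float = 5.0

    def __post_init__(self):
        if self.kind not in _BIOMASS_KINDS:
            raise ValueError(f"kind must be one of {_BIOMASS_KINDS}, got {self.kind!r}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class SheddingModel:
    """Lognormal distribution of per-taxon DNA shedding rates.

    ``log_mean`` and ``log_sd`` are the mean and standard deviation of the
    underlying normal on the natural-log scale (numpy's parameterization),
    so the median shedding rate is ``exp(log_mean)``.
    """

    log_mean: float = 0.5
    log_sd: float = 0.5

    def __post_init__(self):
        if not self.log_sd > 0:
            raise ValueError(f"log_sd must be > 0, got {self.log_sd}")


@dataclass(frozen=True)
class CommunityState:
    """One community realization: biomass proportions, shedding rates, eDNA."""

    biomass: np.ndarray
    shedding: np.ndarray
    edna: np.ndarray = field(default=None)

    def __post_init__(self):
        biomass = np.asarray(self.biomass, dtype=float)
        shedding = np.asarray(self.shedding, dtype=float)
        if biomass.shape != shedding.shape:
            raise ValueError("biomass and shedding must have the same shape")
        if not np.isclose(biomass.sum(), 1.0, atol=1e-9):
            raise ValueError(f"biomass must sum to 1, got {biomass.sum()}")
        if np.any(shedding <= 0):
            raise ValueError("all shedding rates must be strictly positive")
        edna = self.edna
        if edna is None:
            edna = biomass * shedding
        else:
            edna = np.asarray(edna, dtype=float)
            if not np.allclose(edna, biomass * shedding):
                raise ValueError("edna must equal biomass * shedding")
        object.__setattr__(self, "biomass", biomass)
        object.__setattr__(self, "shedding", shedding)
        object.__setattr__(self, "edna", edna)

    @property
    def n_taxa(self) -> int:
        return self.biomass.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": [f"taxon_{i:04d}" for i in range(self.n_taxa)],
                "biomass": self.biomass,
                "shedding": self.shedding,
                "edna": self.edna,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CommunityState":
        df = pd.read_csv(path)
        return cls(
            biomass=df["biomass"].to_numpy(),
            shedding=df["shedding"].to_numpy(),
            edna=df["edna"].to_numpy(),
        )


def draw_biomass(n_taxa: int, model: BiomassModel = BiomassModel(), rng_seed=None) -> np.ndarray:
    """Draw a vector of proportional biomasses for ``n_taxa`` taxa.

    Returns a non-negative vector summing to one.  The uniform model returns
    exactly ``1/n_taxa`` per taxon; the Dirichlet model draws from a
    symmetric Dirichlet with concentration ``model.gamma``.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if model.kind == "uniform":
        return np.full(n_taxa, 1.0 / n_taxa)
    rng = _as_rng(rng_seed)
    return rng.dirichlet(np.full(n_taxa, model.gamma))


def draw_shedding(n_taxa: int, model: SheddingModel = SheddingModel(), rng_seed=None) -> np.ndarray:
    """Draw strictly positive lognormal shedding rates for ``n_taxa`` taxa."""
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    rng = _as_rng(rng_seed)
    return rng.lognormal(mean=model.log_mean, sigma=model.log_sd, size=n_taxa)


def edna_concentration(biomass: np.ndarray, shedding: np.ndarray) -> np.ndarray:
    """Equilibrium eDNA concentration ``D_i = B_i * s_i``.

    No normalization is applied: PCR is a competitive reaction, so only the
    relative magnitudes of ``D`` matter downstream.
    """
    biomass = np.asarray(biomass, dtype=float)
    shedding = np.asarray(shedding, dtype=float)
    if biomass.shape != shedding.shape:
        raise ValueError(
            f"shape mismatch: biomass {biomass.shape} vs shedding {shedding.shape}"
        )
    return biomass * shedding


def simulate_community(
    n_taxa: int,
    biomass_model: BiomassModel = BiomassModel(),
    shedding_model: SheddingModel = SheddingModel(),
    rng_seed=None,
) -> CommunityState:
    """Draw biomass and shedding and assemble a :class:`CommunityState`."""
    rng = _as_rng(rng_seed)
    biomass = draw_biomass(n_taxa, biomass_model, rng)
    shedding = draw_shedding(n_taxa, shedding_model, rng)
    return CommunityState(biomass=biomass, shedding=shedding)
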