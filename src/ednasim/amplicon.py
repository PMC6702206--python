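"""PCR amplification and sequencing of an eDNA template pool.

Each taxon has a fixed amplification efficiency ``a`` in [0, 1] (a = 1 is
perfect doubling every cycle), drawn from a Beta distribution or a
two-component Beta mixture.  After ``N`` cycles the amplicon abundance is

    A_i = D_i * (1 + a_i)**N * eps_i,

where ``eps_i ~ LogNormal(0, sigma)`` is a small multiplicative process
error applied once per taxon per amplification event (not per cycle).
Sequencing draws a read depth ``round(Beta(30, 30) * 1e6)`` and then a
multinomial sample of that many reads with probabilities ``A / sum(A)`` —
amplicon data are compositional, so only relative abundances survive.

Three case presets describe primer-efficiency distributions observed in
practice:

* ``case_a`` — Beta(5, 5): broad-spectrum primers, most taxa amplify
  moderately well (mean 0.5, sd 0.15).
* ``case_b`` — Beta(0.5, 1.5): right-skewed, few taxa amplify well
  (mean 0.25, sd 0.26).
* ``case_c`` — 0.1*Beta(2.1, 0.58) + 0.9*Beta(0.01, 10): taxon-specific
  primers that amplify a small target group very well and everything else
  essentially not at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityState, _as_rng, edna_concentration

__all__ = [
    "EfficiencyModel",
    "PCRParams",
    "SequencingParams",
    "ReadTable",
    "CASE_PRESETS",
    "get_case",
    "draw_efficiencies",
    "amplify",
    "sequence",
    "simulate_sample",
]


@dataclass(frozen=True)
class EfficiencyModel:
    """Beta or two-component Beta-mixture model of amplification efficiency.

    ``components`` is a tuple of ``(weight, alpha, beta)`` triples; weights
    must be positive and sum to one.  Draws lie in [0, 1] by Beta support.
    """

    components: tuple = ((1.0, 5.0, 5.0),)

    def __post_init__(self):
        comps = tuple(tuple(float(x) for x in c) for c in self.components)
        if len(comps) == 0:
            raise ValueError("at least one mixture component required")
        weights = np.array([c[0] for c in comps])
        if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"component weights must be positive and sum to 1, got {weights}")
        for _, a, b in comps:
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters must be > 0, got alpha={a}, beta={b}")
        object.__setattr__(self, "components", comps)

    @classmethod
    def beta(cls, alpha: float, beta: float) -> "EfficiencyModel":
        return cls(components=((1.0, alpha, beta),))

    @classmethod
    def mixture(cls, pi1, alpha1, beta1, alpha2, beta2) -> "EfficiencyModel":
        return cls(components=((pi1, alpha1, beta1), (1.0 - pi1, alpha2, beta2)))

    def mean(self) -> float:
        """Closed-form mixture mean sum_k pi_k * alpha_k / (alpha_k + beta_k)."""
        return sum(w * a / (a + b) for w, a, b in self.components)


#: Primer-efficiency presets for the three simulated use-cases.
CASE_PRESETS = {
    "A": EfficiencyModel.beta(5.0, 5.0),
    "B": EfficiencyModel.beta(0.5, 1.5),
    "C": EfficiencyModel.mixture(0.10, 2.1, 0.58, 0.01, 10.0),
}


def get_case(case) -> EfficiencyModel:
    """Resolve a case label ("A"/"B"/"C") or pass through an EfficiencyModel."""
    if isinstance(case, EfficiencyModel):
        return case
    try:
        return CASE_PRESETS[str(case).upper()]
    except KeyError:
        raise ValueError(f"unknown efficiency case {case!r}; expected one of {sorted(CASE_PRESETS)}")


@dataclass(frozen=True)
class PCRParams:
    """PCR cycle count and multiplicative process noise.

    ``noise_log_sd`` is the log-scale standard deviation of the lognormal
    process error; 0 makes the amplification deterministic.
    """

    n_cycles: int = 35
    noise_log_mean: float = 0.0
    noise_log_sd: float = 0.05

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError(f"n_cycles must be >= 0, got {self.n_cycles}")
        if self.noise_log_sd < 0:
            raise ValueError(f"noise_log_sd must be >= 0, got {self.noise_log_sd}")


@dataclass(frozen=True)
class SequencingParams:
    """Read-depth model: depth = round(Beta(a, b) * scale), at least 1."""

    depth_beta_alpha: float = 30.0
    depth_beta_beta: float = 30.0
    depth_scale: int = 1_000_000

    def __post_init__(self):
        if self.depth_beta_alpha <= 0 or self.depth_beta_beta <= 0:
            raise ValueError("depth Beta parameters must be > 0")
        if self.depth_scale < 1:
            raise ValueError(f"depth_scale must be >= 1, got {self.depth_scale}")


@dataclass(frozen=True)
class ReadTable:
    """Taxa x samples matrix of non-negative integer amplicon read counts."""

    counts: np.ndarray
    taxon_ids: tuple = None
    sample_ids: tuple = None

    def __post_init__(self):
        counts = np.atleast_2d(np.asarray(self.counts))
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("read counts must be integers")
            counts = rounded.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("read counts must be non-negative")
        n_taxa, n_samples = counts.shape
        taxon_ids = self.taxon_ids
        if taxon_ids is None:
            taxon_ids = tuple(f"taxon_{i:04d}" for i in range(n_taxa))
        else:
            taxon_ids = tuple(str(t) for t in taxon_ids)
            if len(taxon_ids) != n_taxa:
                raise ValueError("taxon_ids length does not match counts")
        sample_ids = self.sample_ids
        if sample_ids is None:
            sample_ids = tuple(f"sample_{j:03d}" for j in range(n_samples))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
            if len(sample_ids) != n_samples:
                raise ValueError("sample_ids length does not match counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "taxon_ids", taxon_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depths (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.sample_ids))
        df.insert(0, "taxon_id", list(self.taxon_ids))
        return df

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadTable":
        taxon_col = df.columns[0]
        return cls(
            counts=df.drop(columns=taxon_col).to_numpy(),
            taxon_ids=df[taxon_col].astype(str).tolist(),
            sample_ids=[str(c) for c in df.columns[1:]],
        )

    @classmethod
    def from_csv(cls, path, sep=None) -> "ReadTable":
        # sep=None lets pandas sniff comma vs tab
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        return cls.from_frame(df)


def draw_efficiencies(n_taxa: int, model: EfficiencyModel, rng_seed=None) -> np.ndarray:
    """Draw one fixed amplification efficiency in [0, 1] per taxon.

    Mixture draws first pick a component by weight, then draw from that
    component's Beta.  Efficiencies are a property of the primer-template
    pairing, so one value per taxon is held constant across samples and
    timepoints.
    """
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    rng = _as_rng(rng_seed)
    comps = model.components
    if len(comps) == 1:
        _, a, b = comps[0]
        return rng.beta(a, b, size=n_taxa)
    weights = np.array([c[0] for c in comps])
    which = rng.choice(len(comps), size=n_taxa, p=weights)
    out = np.empty(n_taxa)
    for k, (_, a, b) in enumerate(comps):
        mask = which == k
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return out


def amplify(
    edna: np.ndarray,
    efficiencies: np.ndarray,
    pcr: PCRParams = PCRParams(),
    rng_seed=None,
) -> np.ndarray:
    """Exponential PCR: ``A_i = D_i * (1 + a_i)**n_cycles * eps_i``.

    ``eps_i`` is lognormal multiplicative noise drawn independently per
    taxon for this amplification event; with ``noise_log_sd=0`` the result
    is deterministic.  Abundances are kept real-valued — only sequencing
    produces integer counts.
    """
    edna = np.asarray(edna, dtype=float)
    efficiencies = np.asarray(efficiencies, dtype=float)
    if edna.shape != efficiencies.shape:
        raise ValueError(
            f"shape mismatch: edna {edna.shape} vs efficiencies {efficiencies.shape}"
        )
    amplicons = edna * (1.0 + efficiencies) ** pcr.n_cycles
    if pcr.noise_log_sd > 0 or pcr.noise_log_mean != 0:
        rng = _as_rng(rng_seed)
        eps = rng.lognormal(pcr.noise_log_mean, pcr.noise_log_sd, size=edna.shape)
        amplicons = amplicons * eps
    return amplicons


def sequence(
    amplicons: np.ndarray,
    seq: SequencingParams = SequencingParams(),
    rng_seed=None,
) -> tuple[np.ndarray, int]:
    """Multinomial read sampling from the amplicon pool.

    Returns ``(counts, depth)`` where ``depth = round(Beta(a, b) * scale)``
    and ``counts`` sums exactly to ``depth``.
    """
    amplicons = np.asarray(amplicons, dtype=float)
    if np.any(amplicons < 0):
        raise ValueError("amplicon abundances must be non-negative")
    total = amplicons.sum()
    if total <= 0:
        raise ValueError("degenerate input: all amplicon abundances are zero")
    rng = _as_rng(rng_seed)
    p_samp = rng.beta(seq.depth_beta_alpha, seq.depth_beta_beta)
    depth = max(1, int(np.rint(p_samp * seq.depth_scale)))
    counts = rng.multinomial(depth, amplicons / total)
    return counts, depth


def simulate_sample(
    community: CommunityState,
    efficiencies: np.ndarray,
    pcr: PCRParams = PCRParams(),
    seq: SequencingParams = SequencingParams(),
    rng_seed=None,
) -> np.ndarray:
    """Template pool -> PCR -> sequencing for one sample; returns read counts."""
    rng = _as_rng(rng_seed)
    edna = edna_concentration(community.biomass, community.shedding)
    amplicons = amplify(edna, efficiencies, pcr, rng)
    counts, _ = sequence(amplicons, seq, rng)
    return counts
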