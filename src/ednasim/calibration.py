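"""Mock-community calibration of amplification efficiencies.

A mock community pairs known input template proportions with observed read
counts after a known number of PCR cycles.  Inverting the exponential
amplification model gives each taxon's per-cycle fold change

    g_i = (Y_i / D0_i) ** (1 / n_cycles),

and because the overall sequencing scale is unknown, only the max-anchored
relative efficiency ``r_i = g_i / max_i g_i`` is identifiable; ``r_i``
equals ``(1 + a_i) / (1 + a_max)`` under the amplification model.  A Beta
distribution (method of moments, optionally refined by maximum likelihood)
can then be fitted to a set of observed efficiencies to parameterize the
simulator for a given primer set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import EfficiencyModel

__all__ = [
    "MockCommunity",
    "estimate_relative_efficiencies",
    "fit_beta",
    "efficiency_tail_probability",
]

_CLAMP = 1e-6


@dataclass(frozen=True)
class MockCommunity:
    """Known input proportions and observed read counts for one primer set."""

    taxon_ids: tuple
    input_proportions: np.ndarray
    read_counts: np.ndarray
    n_cycles: int

    def __post_init__(self):
        props = np.asarray(self.input_proportions, dtype=float)
        counts = np.asarray(self.read_counts)
        if np.any(props <= 0):
            raise ValueError("input proportions must be strictly positive")
        if not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise ValueError(f"input proportions must sum to 1, got {props.sum()}")
        if np.any(counts < 0) or not np.allclose(counts, np.rint(counts)):
            raise ValueError("read counts must be non-negative integers")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "input_proportions", props)
        object.__setattr__(self, "read_counts", counts.astype(np.int64))

    @classmethod
    def from_csv(cls, path, n_cycles: int) -> "MockCommunity":
        df = pd.read_csv(path)
        return cls(
            taxon_ids=df["taxon_id"].tolist(),
            input_proportions=df["input_proportion"].to_numpy(),
            read_counts=df["read_count"].to_numpy(),
            n_cycles=n_cycles,
        )


def estimate_relative_efficiencies(mock: MockCommunity) -> pd.DataFrame:
    """Per-taxon fold change and max-anchored relative amplification efficiency.

    Taxa with zero reads are detection-limited and get fold change 0.  The
    max-normalization cancels the unknown total sequencing scale, so the
    estimates are invariant to read depth.
    """
    counts = mock.read_counts.astype(float)
    if not np.any(counts > 0):
        raise ValueError("at least one taxon must have a positive read count")
    with np.errstate(divide="ignore"):
        fold = np.where(counts > 0, (counts / mock.input_proportions) ** (1.0 / mock.n_cycles), 0.0)
    rel = fold / fold.max()
    return pd.DataFrame(
        {
            "taxon_id": list(mock.taxon_ids),
            "fold_change": fold,
            "relative_efficiency": rel,
        }
    )


def fit_beta(efficiencies: np.ndarray, method: str = "moments") -> tuple[float, float]:
    """Fit a Beta distribution to efficiencies in [0, 1].

    Method of moments (default, deterministic):

        c = m(1-m)/v - 1;  alpha = m*c;  beta = (1-m)*c

    ``method="mle"`` refines by maximum likelihood with the support fixed
    to [0, 1].  Boundary values are clamped into (0, 1) before fitting.
    """
    x = np.asarray(efficiencies, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("efficiencies must lie in [0, 1]")
    x = np.clip(x, _CLAMP, 1.0 - _CLAMP)
    if np.count_nonzero((x > _CLAMP) & (x < 1 - _CLAMP)) < 3 and x.size < 3:
        raise ValueError("need at least 3 efficiency values to fit")
    m = x.mean()
    v = x.var(ddof=0)
    if v <= 0:
        raise ValueError("zero variance: cannot fit a Beta distribution")
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        raise ValueError("variance too large for a Beta distribution with this mean")
    alpha, beta = m * common, (1.0 - m) * common
    if method == "moments":
        return float(alpha), float(beta)
    if method == "mle":
        a_hat, b_hat, _, _ = stats.beta.fit(x, alpha, beta, floc=0.0, fscale=1.0)
        return float(a_hat), float(b_hat)
    raise ValueError(f"method must be 'moments' or 'mle', got {method!r}")


def efficiency_tail_probability(model: EfficiencyModel, threshold: float) -> float:
    """P(a > threshold) under a Beta or Beta-mixture efficiency model."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return float(
        sum(w * stats.beta.sf(threshold, a, b) for w, a, b in model.components)
    )
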