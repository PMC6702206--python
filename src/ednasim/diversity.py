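"""Diversity metrics and cycle-number / primer-bias experiments.

Richness is the number of taxa with at least one read; Shannon diversity is
``H = -sum(p * ln p)`` over detected-taxon read proportions (natural log by
default).  The experiment drivers sweep PCR cycle number across primer
cases, build sample-based species-accumulation curves, estimate per-taxon
detection probability as a function of amplification efficiency, and
partition variance in a diversity response between primer case and biomass
distribution with a balanced two-factor ANOVA.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community import BiomassModel, SheddingModel, _as_rng, draw_biomass, draw_shedding
from .amplicon import ReadTable, SequencingParams, draw_efficiencies, get_case, sequence

__all__ = [
    "richness",
    "shannon",
    "cycle_sweep",
    "species_accumulation",
    "detection_probability",
    "efficiency_decile_variance",
    "variance_partition",
]

DEFAULT_CYCLE_GRID = tuple(range(5, 51, 5))


def richness(counts, threshold: int = 1) -> int:
    """Number of detected taxa: entries with at least ``threshold`` reads."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    return int(np.count_nonzero(counts >= threshold))


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity ``H = -sum(p ln p)`` over nonzero read proportions.

    ``base`` rescales to another logarithm base (e.g. 2); the default is the
    natural log, the usual ecological convention.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("degenerate input: all counts are zero")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def cycle_sweep(
    n_replicates: int = 100,
    n_taxa: int = 1000,
    biomass_model: BiomassModel = BiomassModel(kind="dirichlet", gamma=5.0),
    cases: Sequence = ("A", "B", "C"),
    cycle_grid: Sequence[int] = DEFAULT_CYCLE_GRID,
    shedding_model: SheddingModel = SheddingModel(),
    pcr_noise_log_sd: float = 0.05,
    seq: SequencingParams = SequencingParams(),
    rng_seed=None,
) -> pd.DataFrame:
    """Sweep PCR cycle number for replicate communities under each primer case.

    For every replicate a community (biomass + shedding) is drawn once and,
    per case, a single efficiency vector is drawn and held fixed across the
    whole cycle grid; each grid point is an independent PCR + sequencing
    event.  Returns a tidy frame with one row per
    (replicate, case, n_cycles) carrying richness and Shannon diversity.
    """
    if len(cycle_grid) == 0:
        raise ValueError("cycle_grid must be non-empty")
    rng = _as_rng(rng_seed)
    case_models = {str(c): get_case(c) for c in cases}
    rows = []
    for rep in range(n_replicates):
        biomass = draw_biomass(n_taxa, biomass_model, rng)
        shedding = draw_shedding(n_taxa, shedding_model, rng)
        edna = biomass * shedding
        for label, model in case_models.items():
            eff = draw_efficiencies(n_taxa, model, rng)
            growth = np.log1p(eff)
            for n_cycles in cycle_grid:
                # log-space amplification avoids overflow at high cycle counts
                log_amp = np.log(edna) + n_cycles * growth
                if pcr_noise_log_sd > 0:
                    log_amp = log_amp + rng.normal(0.0, pcr_noise_log_sd, size=n_taxa)
                amplicons = np.exp(log_amp - log_amp.max())
                counts, _ = sequence(amplicons, seq, rng)
                rows.append(
                    {
                        "replicate": rep,
                        "case": label,
                        "biomass_model": biomass_model.kind
                        if biomass_model.kind == "uniform"
                        else f"dirichlet_gamma{biomass_model.gamma:g}",
                        "n_cycles": n_cycles,
                        "richness": richness(counts),
                        "shannon": shannon(counts),
                    }
                )
    return pd.DataFrame(rows)


def species_accumulation(
    read_table: ReadTable,
    n_permutations: int = 100,
    rng_seed=None,
    method: str = "random",
) -> pd.DataFrame:
    """Sample-based species-accumulation curve.

    ``method="random"`` averages cumulative richness over random orderings
    of the sample columns; ``method="exact"`` computes the expectation
    analytically (the mean over all orderings, via the hypergeometric
    inclusion probability for each taxon).  Returns a frame with columns
    ``n_samples`` and ``mean_richness``; the curve is non-decreasing and
    ends at the pooled richness.
    """
    counts = read_table.counts if isinstance(read_table, ReadTable) else np.atleast_2d(read_table)
    n_taxa, n_samples = counts.shape
    if n_samples < 1:
        raise ValueError("read table must have at least one sample")
    detected = counts > 0  # taxa x samples incidence
    if method == "exact":
        m = detected.sum(axis=1)  # number of samples in which each taxon occurs
        ks = np.arange(1, n_samples + 1)
        # P(taxon absent from k random samples) = C(M-m, k)/C(M, k)
        curve = np.empty(n_samples)
        for idx, k in enumerate(ks):
            with np.errstate(divide="ignore"):
                log_absent = (
                    _log_comb(n_samples - m, k) - _log_comb(np.full_like(m, n_samples), k)
                )
            p_absent = np.where(n_samples - m >= k, np.exp(log_absent), 0.0)
            curve[idx] = float((1.0 - p_absent).sum())
        return pd.DataFrame({"n_samples": ks, "mean_richness": curve})
    if method != "random":
        raise ValueError(f"method must be 'random' or 'exact', got {method!r}")
    rng = _as_rng(rng_seed)
    acc = np.zeros(n_samples)
    for _ in range(n_permutations):
        order = rng.permutation(n_samples)
        seen = np.logical_or.accumulate(detected[:, order], axis=1)
        acc += seen.sum(axis=0)
    return pd.DataFrame(
        {"n_samples": np.arange(1, n_samples + 1), "mean_richness": acc / n_permutations}
    )


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)
    return np.where(n >= k, out, -np.inf)


def detection_probability(
    replicate_counts: Iterable,
    efficiencies: np.ndarray,
    biomass: np.ndarray | None = None,
    threshold: int = 1,
) -> pd.DataFrame:
    """Per-taxon detection frequency across replicate sequencing datasets.

    ``replicate_counts`` is an iterable of per-replicate count vectors (or a
    taxa x replicates matrix) sharing one taxon set and one efficiency
    draw.  Returns a frame with columns ``taxon``, ``efficiency``,
    ``detection_frequency`` and (if biomass is given) ``mean_biomass``.
    """
    mat = np.column_stack([np.asarray(c).ravel() for c in replicate_counts]) if not isinstance(
        replicate_counts, np.ndarray
    ) else np.atleast_2d(replicate_counts)
    efficiencies = np.asarray(efficiencies, dtype=float)
    if mat.shape[0] != efficiencies.size:
        raise ValueError(
            f"replicate tables have {mat.shape[0]} taxa but {efficiencies.size} efficiencies given"
        )
    freq = (mat >= threshold).mean(axis=1)
    out = pd.DataFrame(
        {
            "taxon": np.arange(efficiencies.size),
            "efficiency": efficiencies,
            "detection_frequency": freq,
        }
    )
    if biomass is not None:
        biomass = np.asarray(biomass, dtype=float)
        if biomass.size != efficiencies.size:
            raise ValueError("biomass length does not match taxon set")
        out["mean_biomass"] = biomass
    return out


def efficiency_decile_variance(profile: pd.DataFrame) -> pd.DataFrame:
    """Variance of detection frequency within each amplification-efficiency decile.

    Deciles are equal-count bins of the ranked efficiencies (decile 1 =
    least efficient tenth).  Useful for comparing detection noise across
    biomass distributions at matched efficiency.
    """
    df = profile.copy()
    df["decile"] = pd.qcut(df["efficiency"].rank(method="first"), 10, labels=np.arange(1, 11))
    out = (
        df.groupby("decile", observed=True)["detection_frequency"]
        .agg(["mean", "var", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_detection", "var": "var_detection", "count": "n_taxa"})
    )
    return out


def variance_partition(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("case", "biomass_model"),
) -> pd.DataFrame:
    """Partition variance in a diversity response with a balanced two-factor ANOVA.

    Fits a fixed-effects main-effects model (no interaction) and reports
    ``R^2 = SS_factor / SS_total`` per factor plus the residual fraction.
    The design must be balanced (equal replicate counts in every factor
    combination) so that sequential and marginal sums of squares coincide.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level; cannot partition variance")
    sizes = data.groupby(list(factors), observed=True).size()
    if sizes.nunique() != 1:
        raise ValueError("design is unbalanced: unequal replicates per factor combination")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ss_total = table["sum_sq"].sum()
    rows = []
    for f in factors:
        rows.append({"factor": f, "r_squared": table.loc[f"C({f})", "sum_sq"] / ss_total})
    rows.append({"factor": "residual", "r_squared": table.loc["Residual", "sum_sq"] / ss_total})
    return pd.DataFrame(rows)
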