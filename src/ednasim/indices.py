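"""Quantitative amplicon-abundance indices and the biomass-correlation benchmark.

Amplicon counts are compositional: the sequencer imposes an arbitrary
total, so raw counts carry only relative information.  Seven per-sample
transformations of a taxa x samples read table are provided:

* ``raw`` — untransformed counts;
* ``edna_index`` — within-sample read proportions rescaled by each taxon's
  maximum proportion across samples (a double standardization; values in
  [0, 1], every observed taxon attains 1 somewhere);
* ``frequency`` — proportions scaled so the mean over a sample's nonzero
  taxa is 1 (vegan's "frequency" standardization);
* ``normalized`` — columns scaled to unit Euclidean norm;
* ``rank`` — within-sample ascending ranks of nonzero counts (average-rank
  ties), zeros stay 0;
* ``hellinger`` — square root of within-sample proportions;
* ``log`` — log2(count) + 1 for positive counts, else 0.

Every index maps a zero count to a zero index value, so all indices agree
on incidence.  The benchmark correlates each taxon's index series with its
true biomass series across timepoints (Spearman's rho, average-rank ties),
keeping taxa detected in at least ``min_incidence`` timepoints; a
permutation null shuffles the count matrix cells jointly before indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import BiomassModel, SheddingModel, _as_rng, draw_biomass, draw_shedding
from .amplicon import (
    PCRParams,
    ReadTable,
    SequencingParams,
    amplify,
    draw_efficiencies,
    get_case,
    sequence,
)

__all__ = [
    "IndexMatrix",
    "INDEX_NAMES",
    "compute_index",
    "raw_index",
    "edna_index",
    "frequency_index",
    "normalized_counts",
    "rank_index",
    "hellinger_index",
    "log_index",
    "spearman_by_taxon",
    "correlate_series",
    "null_correlations",
    "stratify_performance",
    "TimeseriesResult",
    "timeseries_experiment",
]


@dataclass(frozen=True)
class IndexMatrix:
    """A transformed taxa x samples abundance matrix."""

    values: np.ndarray
    index_name: str
    taxon_ids: tuple = None
    sample_ids: tuple = None

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        if self.taxon_ids is not None:
            object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        if self.sample_ids is not None:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        n_taxa, n_samples = self.values.shape
        taxa = self.taxon_ids or [f"taxon_{i:04d}" for i in range(n_taxa)]
        samples = self.sample_ids or [f"sample_{j:03d}" for j in range(n_samples)]
        df = pd.DataFrame(self.values, columns=list(samples))
        df.insert(0, "taxon_id", list(taxa))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _counts_of(table) -> np.ndarray:
    if isinstance(table, ReadTable):
        return table.counts.astype(float)
    return np.atleast_2d(np.asarray(table, dtype=float))


def _ids_of(table):
    if isinstance(table, ReadTable):
        return table.taxon_ids, table.sample_ids
    return None, None


def _proportions(counts: np.ndarray) -> np.ndarray:
    depths = counts.sum(axis=0)
    if np.any(depths <= 0):
        raise ValueError("degenerate input: zero-depth sample")
    return counts / depths


def _wrap(values, name, table) -> IndexMatrix:
    taxa, samples = _ids_of(table)
    return IndexMatrix(values=values, index_name=name, taxon_ids=taxa, sample_ids=samples)


def raw_index(table) -> IndexMatrix:
    """Untransformed read counts (as floats)."""
    return _wrap(_counts_of(table), "raw", table)


def edna_index(table) -> IndexMatrix:
    """Read proportions rescaled to each taxon's maximum proportion across samples.

    ``index_ij = p_ij / max_j p_ij`` with ``p_ij = Y_ij / sum_i Y_ij``.
    Taxa never observed get all zeros (0/0 := 0).  Equivalent to the
    Wisconsin double standardization with proportion then row-max margins.
    """
    p = _proportions(_counts_of(table))
    row_max = p.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(row_max > 0, p / np.where(row_max > 0, row_max, 1.0), 0.0)
    return _wrap(values, "edna_index", table)


def frequency_index(table) -> IndexMatrix:
    """Proportions scaled so each sample's nonzero taxa average to 1.

    ``Freq_ij = p_ij * N_j`` where ``N_j`` is the number of detected taxa
    in sample j.
    """
    counts = _counts_of(table)
    p = _proportions(counts)
    n_detected = (counts > 0).sum(axis=0)
    return _wrap(p * n_detected, "frequency", table)


def normalized_counts(table) -> IndexMatrix:
    """Counts scaled to unit sum-of-squares per sample (chord normalization)."""
    counts = _counts_of(table)
    norms = np.sqrt((counts**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("degenerate input: zero-depth sample")
    return _wrap(counts / norms, "normalized", table)


def rank_index(table) -> IndexMatrix:
    """Within-sample ascending ranks of nonzero counts; ties take average rank.

    1 is the rarest detected taxon, so the index increases with abundance
    and correlation signs line up with the other indices; zeros stay 0.
    """
    counts = _counts_of(table)
    values = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nz = col > 0
        if nz.any():
            values[nz, j] = stats.rankdata(col[nz], method="average")
    return _wrap(values, "rank", table)


def hellinger_index(table) -> IndexMatrix:
    """Square root of within-sample read proportions (Hellinger transformation)."""
    return _wrap(np.sqrt(_proportions(_counts_of(table))), "hellinger", table)


def log_index(table) -> IndexMatrix:
    """``log2(count) + 1`` for positive counts, 0 for zeros."""
    counts = _counts_of(table)
    values = np.zeros_like(counts)
    pos = counts > 0
    values[pos] = np.log2(counts[pos]) + 1.0
    return _wrap(values, "log", table)


_INDEX_FUNCS = {
    "raw": raw_index,
    "edna_index": edna_index,
    "frequency": frequency_index,
    "normalized": normalized_counts,
    "rank": rank_index,
    "hellinger": hellinger_index,
    "log": log_index,
}

#: Names of the seven supported abundance indices.
INDEX_NAMES = tuple(_INDEX_FUNCS)


def compute_index(table, name: str) -> IndexMatrix:
    """Apply one of the named index transformations to a read table."""
    try:
        fn = _INDEX_FUNCS[name]
    except KeyError:
        raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    return fn(table)


def spearman_by_taxon(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman's rho between two taxa x samples matrices.

    Average ranks for ties; rows where either series has zero variance get
    NaN (the correlation is undefined there).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    rx = np.apply_along_axis(stats.rankdata, 1, x)
    ry = np.apply_along_axis(stats.rankdata, 1, y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    rho[den == 0] = np.nan
    return rho


def correlate_series(
    index: IndexMatrix,
    biomass: np.ndarray,
    min_incidence: int = 5,
    counts: np.ndarray | ReadTable | None = None,
    efficiencies: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-taxon Spearman correlation between an index series and biomass.

    ``biomass`` is the true taxa x timepoints biomass matrix.  Taxa are
    eligible if detected (index value > 0, equivalently count > 0) in at
    least ``min_incidence`` timepoints; others get NaN rho.  Annotations:

    * ``incidence`` — number of timepoints detected;
    * ``mean_log_abundance`` — log10 of the mean within-sample read
      proportion over the timepoints where the taxon was detected;
    * ``abundance_quartile`` — quartile (1-4) of that abundance among
      eligible taxa;
    * ``efficiency`` — the taxon's amplification efficiency, if supplied.
    """
    values = index.values if isinstance(index, IndexMatrix) else np.atleast_2d(index)
    biomass = np.atleast_2d(np.asarray(biomass, dtype=float))
    if values.shape != biomass.shape:
        raise ValueError(
            f"index {values.shape} and biomass {biomass.shape} shapes do not match"
        )
    n_taxa, n_time = values.shape
    if n_time < 3:
        raise ValueError(f"need at least 3 timepoints, got {n_time}")
    if counts is None:
        count_mat = values
    else:
        count_mat = _counts_of(counts)
    detected = count_mat > 0
    incidence = detected.sum(axis=1)
    eligible = incidence >= min_incidence

    rho = np.full(n_taxa, np.nan)
    if eligible.any():
        rho[eligible] = spearman_by_taxon(values[eligible], biomass[eligible])

    # mean within-sample read proportion over detected timepoints only
    p = count_mat / np.maximum(count_mat.sum(axis=0, keepdims=True), 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_p = np.where(incidence > 0, (p * detected).sum(axis=1) / np.maximum(incidence, 1), np.nan)
        mean_log_abundance = np.log10(mean_p)

    taxa = (
        list(index.taxon_ids)
        if isinstance(index, IndexMatrix) and index.taxon_ids
        else [f"taxon_{i:04d}" for i in range(n_taxa)]
    )
    out = pd.DataFrame(
        {
            "taxon_id": taxa,
            "rho": rho,
            "incidence": incidence,
            "mean_log_abundance": mean_log_abundance,
            "eligible": eligible,
        }
    )
    quart = pd.Series(np.nan, index=out.index)
    mask = eligible & np.isfinite(mean_log_abundance)
    if mask.sum() >= 4:
        quart[mask] = pd.qcut(out.loc[mask, "mean_log_abundance"], 4, labels=[1, 2, 3, 4]).astype(
            float
        )
    out["abundance_quartile"] = quart
    if efficiencies is not None:
        out["efficiency"] = np.asarray(efficiencies, dtype=float)
    return out


def null_correlations(
    table: ReadTable | np.ndarray,
    biomass: np.ndarray,
    min_incidence: int = 5,
    rng_seed=None,
    index_name: str = "edna_index",
    mode: str = "matrix",
    efficiencies: np.ndarray | None = None,
) -> pd.DataFrame:
    """Permutation null: shuffle the count matrix, index it, and correlate.

    ``mode="matrix"`` shuffles all cells jointly (preserving the multiset
    of counts); ``mode="columns"`` shuffles within each sample instead.
    The resulting rho distribution is symmetric with median near zero.
    """
    counts = _counts_of(table).astype(np.int64)
    rng = _as_rng(rng_seed)
    if mode == "matrix":
        flat = counts.ravel().copy()
        rng.shuffle(flat)
        shuffled = flat.reshape(counts.shape)
    elif mode == "columns":
        shuffled = np.column_stack([rng.permutation(counts[:, j]) for j in range(counts.shape[1])])
    else:
        raise ValueError(f"mode must be 'matrix' or 'columns', got {mode!r}")
    idx = compute_index(ReadTable(shuffled), index_name)
    return correlate_series(idx, biomass, min_incidence, counts=shuffled, efficiencies=efficiencies)


def stratify_performance(
    result: pd.DataFrame,
    by: str = "abundance_quartile",
    efficiency_bins: Sequence[float] = (0.35, 0.6),
) -> pd.DataFrame:
    """Median rho per stratum of abundance quartile or efficiency bin.

    ``by="abundance_quartile"`` uses the quartile annotation from
    :func:`correlate_series`; ``by="efficiency_bins"`` cuts the efficiency
    annotation at the given thresholds (defaults 0.35 and 0.6, separating
    poorly-, moderately- and well-amplifying taxa).  Undefined correlations
    are excluded; empty strata are reported with NaN medians.
    """
    df = result[result["eligible"] & result["rho"].notna()].copy()
    if by == "abundance_quartile":
        df["stratum"] = df["abundance_quartile"]
        strata = [1.0, 2.0, 3.0, 4.0]
    elif by == "efficiency_bins":
        if "efficiency" not in df.columns:
            raise ValueError("correlation result carries no efficiency annotation")
        edges = [-np.inf, *sorted(efficiency_bins), np.inf]
        labels = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            lo_s = "0" if lo == -np.inf else f"{lo:g}"
            labels.append(f">={lo_s}" if hi == np.inf else f"[{lo_s},{hi:g})")
        df["stratum"] = pd.cut(df["efficiency"], bins=edges, labels=labels, right=False)
        strata = labels
    else:
        raise ValueError(f"unknown stratification {by!r}")
    grouped = df.groupby("stratum", observed=False)["rho"]
    out = grouped.agg(median_rho="median", n="size").reindex(strata).reset_index()
    out["n"] = out["n"].fillna(0).astype(int)
    return out


@dataclass
class TimeseriesResult:
    """Everything produced by one time-series benchmark run."""

    biomass: np.ndarray
    shedding: np.ndarray
    efficiencies: np.ndarray
    read_table: ReadTable
    indices: dict
    correlations: dict
    null: pd.DataFrame
    single_timepoint_rho: pd.DataFrame

    def median_rho(self, index_name: str = "edna_index") -> float:
        df = self.correlations[index_name]
        return float(df.loc[df["eligible"], "rho"].median())


def timeseries_experiment(
    n_taxa: int = 1000,
    n_timepoints: int = 25,
    biomass_model: BiomassModel = BiomassModel(kind="dirichlet", gamma=5.0),
    case="A",
    pcr: PCRParams = PCRParams(n_cycles=35),
    seq: SequencingParams = SequencingParams(),
    shedding_model: SheddingModel = SheddingModel(),
    min_incidence: int = 5,
    rng_seed=None,
) -> TimeseriesResult:
    """Simulate a temporal series of samples and benchmark all seven indices.

    Biomass is redrawn independently per timepoint (taxa fluctuate around a
    stable expectation); shedding rates and amplification efficiencies are
    fixed per taxon across the series.  Each timepoint is an independent
    PCR + sequencing event.  Also computes, per index, the median
    single-timepoint correlation (across taxa within one sample) for
    contrast with the time-series correlations.
    """
    rng = _as_rng(rng_seed)
    model = get_case(case)
    shedding = draw_shedding(n_taxa, shedding_model, rng)
    efficiencies = draw_efficiencies(n_taxa, model, rng)
    biomass = np.column_stack(
        [draw_biomass(n_taxa, biomass_model, rng) for _ in range(n_timepoints)]
    )
    counts = np.empty((n_taxa, n_timepoints), dtype=np.int64)
    for t in range(n_timepoints):
        amplicons = amplify(biomass[:, t] * shedding, efficiencies, pcr, rng)
        counts[:, t], _ = sequence(amplicons, seq, rng)
    table = ReadTable(counts, sample_ids=[f"t{t:02d}" for t in range(n_timepoints)])

    indices = {name: compute_index(table, name) for name in INDEX_NAMES}
    correlations = {
        name: correlate_series(idx, biomass, min_incidence, counts=counts, efficiencies=efficiencies)
        for name, idx in indices.items()
    }
    null = null_correlations(
        table, biomass, min_incidence, rng_seed=rng, efficiencies=efficiencies
    )

    # single-timepoint correlation: across taxa, within each sample
    rows = []
    for name, idx in indices.items():
        rhos = spearman_by_taxon(idx.values.T, biomass.T)
        rows.append({"index": name, "median_single_timepoint_rho": float(np.nanmedian(rhos))})
    single = pd.DataFrame(rows)

    return TimeseriesResult(
        biomass=biomass,
        shedding=shedding,
        efficiencies=efficiencies,
        read_table=table,
        indices=indices,
        correlations=correlations,
        null=null,
        single_timepoint_rho=single,
    )
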