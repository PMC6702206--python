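"""End-to-end experiment drivers: cycle sweeps, bias comparisons, detection
profiles, and the time-series index benchmark.

Every driver is deterministic given ``ExperimentConfig.master_seed``:
independent substreams are derived per (experiment, stage) with
:func:`substream`, so changing one experiment's replicate count never
perturbs another experiment's draws.  Outputs are tidy long-format CSVs
with a comment-line metadata header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import BiomassModel, SheddingModel, draw_biomass, draw_shedding
from .amplicon import (
    PCRParams,
    SequencingParams,
    amplify,
    draw_efficiencies,
    get_case,
    sequence,
)
from .diversity import (
    cycle_sweep,
    detection_probability,
    efficiency_decile_variance,
    variance_partition,
)
from .indices import TimeseriesResult, stratify_performance, timeseries_experiment

__all__ = [
    "ExperimentConfig",
    "substream",
    "write_csv",
    "run_cycle_sweep",
    "run_bias_experiment",
    "run_detection_experiment",
    "run_index_benchmark",
]

#: The three community biomass distributions compared throughout.
BIOMASS_SCENARIOS = {
    "uniform": BiomassModel(kind="uniform"),
    "dirichlet_gamma5": BiomassModel(kind="dirichlet", gamma=5.0),
    "dirichlet_gamma1": BiomassModel(kind="dirichlet", gamma=1.0),
}


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Derive an independent RNG stream from a master seed and a key path.

    String keys are hashed with CRC-32 (stable across platforms and runs),
    integer keys pass through, so ``substream(seed, "sweep", rep)`` gives
    every (experiment, replicate) its own reproducible stream.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters shared by all experiment drivers.

    Defaults describe the standard setup: 100 replicate communities of 1000
    taxa, moderately variable biomass (Dirichlet gamma=5), 35 PCR cycles
    with lognormal process noise sigma=0.05, read depth Beta(30,30)*1e6,
    and a 25-timepoint series for the index benchmark.
    """

    n_taxa: int = 1000
    n_replicates: int = 100
    n_timepoints: int = 25
    biomass_kind: str = "dirichlet"
    gamma: float = 5.0
    case: str = "A"
    n_cycles: int = 35
    noise_log_sd: float = 0.05
    shedding_log_mean: float = 0.5
    shedding_log_sd: float = 0.5
    depth_beta_alpha: float = 30.0
    depth_beta_beta: float = 30.0
    depth_scale: int = 1_000_000
    min_incidence: int = 5
    cycle_grid: tuple = tuple(range(5, 51, 5))
    master_seed: int = 0
    out_dir: str = "results"

    @property
    def biomass_model(self) -> BiomassModel:
        return BiomassModel(kind=self.biomass_kind, gamma=self.gamma)

    @property
    def shedding_model(self) -> SheddingModel:
        return SheddingModel(log_mean=self.shedding_log_mean, log_sd=self.shedding_log_sd)

    @property
    def pcr(self) -> PCRParams:
        return PCRParams(n_cycles=self.n_cycles, noise_log_sd=self.noise_log_sd)

    @property
    def seq(self) -> SequencingParams:
        return SequencingParams(
            depth_beta_alpha=self.depth_beta_alpha,
            depth_beta_beta=self.depth_beta_beta,
            depth_scale=self.depth_scale,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cycle_grid"] = list(d["cycle_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cycle_grid" in d:
            d["cycle_grid"] = tuple(d["cycle_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["cycle_grid"] = list(d["cycle_grid"])
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, config: ExperimentConfig | None = None) -> Path:
    """Write a tidy CSV with a comment-line metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ednasim {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash: {config.config_hash()}\n")
            fh.write(f"# master_seed: {config.master_seed}\n")
        df.to_csv(fh, index=False)
    return path


def run_cycle_sweep(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Richness/Shannon across the PCR cycle grid for all three primer cases."""
    df = cycle_sweep(
        n_replicates=config.n_replicates,
        n_taxa=config.n_taxa,
        biomass_model=config.biomass_model,
        cases=("A", "B", "C"),
        cycle_grid=config.cycle_grid,
        shedding_model=config.shedding_model,
        pcr_noise_log_sd=config.noise_log_sd,
        seq=config.seq,
        rng_seed=substream(config.master_seed, "cycle_sweep"),
    )
    if out_dir is not None:
        write_csv(df, Path(out_dir) / "cycle_sweep.csv", config)
    return df


def run_bias_experiment(config: ExperimentConfig, out_dir=None):
    """Richness/Shannon at a fixed cycle count across 3 cases x 3 biomass models.

    Each taxon is assigned one fixed amplification efficiency per primer
    case, shared across all replicates and biomass scenarios, so the
    variance partition isolates primer identity from community structure;
    biomass and shedding are redrawn per replicate, and each case amplifies
    the same community draw.  Returns ``(data, anova)``: the per-replicate
    diversity table and the per-response variance partition between primer
    case and biomass distribution.
    """
    from .diversity import richness as _richness, shannon as _shannon

    rng_eff = substream(config.master_seed, "bias", "efficiencies")
    eff_by_case = {c: draw_efficiencies(config.n_taxa, get_case(c), rng_eff) for c in ("A", "B", "C")}
    rows = []
    for label, bm in BIOMASS_SCENARIOS.items():
        rng = substream(config.master_seed, "bias", label)
        for rep in range(config.n_replicates):
            biomass = draw_biomass(config.n_taxa, bm, rng)
            shedding = draw_shedding(config.n_taxa, config.shedding_model, rng)
            for case, eff in eff_by_case.items():
                amplicons = amplify(biomass * shedding, eff, config.pcr, rng)
                counts, _ = sequence(amplicons, config.seq, rng)
                rows.append(
                    {
                        "replicate": rep,
                        "case": case,
                        "biomass_model": label,
                        "n_cycles": config.n_cycles,
                        "richness": _richness(counts),
                        "shannon": _shannon(counts),
                    }
                )
    data = pd.DataFrame(rows)
    anova_rows = []
    for response in ("richness", "shannon"):
        part = variance_partition(data, response, factors=("case", "biomass_model"))
        part.insert(0, "response", response)
        anova_rows.append(part)
    anova = pd.concat(anova_rows, ignore_index=True)
    if out_dir is not None:
        write_csv(data, Path(out_dir) / "bias_diversity.csv", config)
        write_csv(anova, Path(out_dir) / "bias_anova.csv", config)
    return data, anova


def run_detection_experiment(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Per-taxon detection probability vs amplification efficiency.

    One efficiency draw (default Case A) is held constant across all
    replicate datasets and biomass scenarios; each replicate redraws the
    community and re-runs PCR + sequencing.  Returns the per-taxon
    detection profile stacked over biomass scenarios, with the
    per-efficiency-decile variance of detection frequency alongside.
    """
    rng_eff = substream(config.master_seed, "detection", "efficiencies")
    efficiencies = draw_efficiencies(config.n_taxa, get_case(config.case), rng_eff)
    profiles = []
    for label, bm in BIOMASS_SCENARIOS.items():
        rng = substream(config.master_seed, "detection", label)
        counts = np.empty((config.n_taxa, config.n_replicates), dtype=np.int64)
        biomass_acc = np.zeros(config.n_taxa)
        for rep in range(config.n_replicates):
            biomass = draw_biomass(config.n_taxa, bm, rng)
            shedding = draw_shedding(config.n_taxa, config.shedding_model, rng)
            amplicons = amplify(biomass * shedding, efficiencies, config.pcr, rng)
            counts[:, rep], _ = sequence(amplicons, config.seq, rng)
            biomass_acc += biomass
        profile = detection_probability(counts, efficiencies, biomass=biomass_acc / config.n_replicates)
        profile.insert(0, "biomass_model", label)
        profiles.append(profile)
    out = pd.concat(profiles, ignore_index=True)
    if out_dir is not None:
        write_csv(out, Path(out_dir) / "detection_profile.csv", config)
        deciles = (
            out.groupby("biomass_model", group_keys=False)[["efficiency", "detection_frequency"]]
            .apply(efficiency_decile_variance)
            .reset_index()
        )
        write_csv(deciles, Path(out_dir) / "detection_decile_variance.csv", config)
    return out


def run_index_benchmark(config: ExperimentConfig, out_dir=None) -> TimeseriesResult:
    """The 25-timepoint index benchmark: all seven indices plus the null."""
    result = timeseries_experiment(
        n_taxa=config.n_taxa,
        n_timepoints=config.n_timepoints,
        biomass_model=config.biomass_model,
        case=config.case,
        pcr=config.pcr,
        seq=config.seq,
        shedding_model=config.shedding_model,
        min_incidence=config.min_incidence,
        rng_seed=substream(config.master_seed, "timeseries"),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for name, corr in result.correlations.items():
            write_csv(corr, out_dir / f"correlations_{name}.csv", config)
        write_csv(result.null, out_dir / "correlations_null.csv", config)
        write_csv(result.single_timepoint_rho, out_dir / "single_timepoint_rho.csv", config)
        strata = []
        s = stratify_performance(result.correlations["edna_index"], by="abundance_quartile")
        s.insert(0, "by", "abundance_quartile")
        strata.append(s)
        # efficiency strata cover every detected (correlatable) taxon, not
        # only those passing the incidence filter
        from .indices import correlate_series

        corr_all = correlate_series(
            result.indices["edna_index"],
            result.biomass,
            min_incidence=1,
            counts=result.read_table.counts,
            efficiencies=result.efficiencies,
        )
        s = stratify_performance(corr_all, by="efficiency_bins")
        s.insert(0, "by", "efficiency_bins")
        strata.append(s)
        write_csv(pd.concat(strata, ignore_index=True), out_dir / "edna_index_strata.csv", config)
        summary = pd.DataFrame(
            [
                {"index": name, "median_rho": result.median_rho(name)}
                for name in result.correlations
            ]
            + [{"index": "null", "median_rho": float(result.null.loc[result.null["eligible"], "rho"].median())}]
        )
        write_csv(summary, out_dir / "index_median_rho.csv", config)
    return result
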