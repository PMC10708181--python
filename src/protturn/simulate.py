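"""Synthetic pulsed-SILAM peptide abundance time courses with known ground truth.

Emulates a whole-animal pulse-labeling study: at day 0 the diet switches to a
heavy-isotope (15N) source, so the light (14N) fraction of each protein decays
as ``exp(-kd * t)`` under first-order degradation at steady-state abundance.
The generator produces the light-channel peptide intensities a DIA instrument
would report, with per-peptide ionization offsets, per-sample loading factors,
multiplicative lognormal noise, and missingness — plus a panel of long-lived
"housekeeping" proteins used downstream as normalization standards.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class ConfigError(ValueError):
    """Invalid simulation or run configuration."""


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the simulator.

    Defaults mirror a three-organ (lung/heart/brain), three-oxygen-tension
    (8/21/60% FiO2) design with harvests at days 1, 2, 4, 8, 16 and 32 plus
    explicit day-0 baselines, 4 animals per point, and organ median
    half-lives of 3.9 / 7.3 / 8.0 days.

    Parameters
    ----------
    organs : sequence of str
        Tissue labels.
    oxygen_levels : sequence of str
        FiO2 labels (percent); ``reference_oxygen`` is the normoxic reference.
    timepoints_days : sequence of float
        Harvest times in days. Day 0 is always included (baseline samples).
    replicates_per_point : int
        Animals per organ x oxygen x timepoint cell.
    n_proteins : int
        Number of regular (non-panel) proteins per organ.
    peptides_per_protein : (int, int)
        Inclusive range of detected peptides per protein. The typical peptide
        count per protein in tissue DIA is not well pinned down; the 2-8
        default is a plausible guess and easily overridden.
    median_half_life_days : mapping organ -> float
        Median half-life of the per-organ lognormal half-life distribution.
    half_life_sigma : float
        Lognormal sigma (natural-log scale) of half-lives around the median.
    frac_affected : float
        Fraction of proteins whose kd shifts in non-reference oxygen tensions.
    effect_fc_range : (float, float)
        Fold-change interval (both >= 1) for affected proteins; direction
        (faster/slower) is random per protein x condition.
    n_longlived : int
        Size of the long-lived normalization panel.
    longlived_min_half_life_days : float
        Half-life floor for panel proteins.
    longlived_half_life_days : float or None
        If None (default) panel proteins have kd = 0 — idealized fixed
        abundance, matching the assumption under which the panel is used for
        normalization. If a float, panel half-lives are drawn uniformly in
        [max(floor, value/2), 2*value].
    noise_cv : float
        Coefficient of variation of multiplicative lognormal measurement noise.
    missing_rate : float
        Probability a post-baseline measurement is dropped.
    missing_mode : {"mcar", "intensity"}
        MCAR drops uniformly at random; "intensity" makes low-intensity
        observations more likely to be censored (DIA-like), with the same
        marginal rate.
    loading_factor_sigma : float
        Lognormal sigma of per-sample loading factors.
    peptide_intercept_sigma : float
        Lognormal sigma of per-peptide ionization-efficiency offsets (random
        intercepts on the log scale).
    peptide_slope_sigma : float
        Optional per-peptide random slope deviation (per day); default 0.
    seed : int
        RNG seed; identical config + seed gives byte-identical tables.
    """

    organs: Sequence[str] = ("lung", "heart", "brain")
    oxygen_levels: Sequence[str] = ("8", "21", "60")
    reference_oxygen: str = "21"
    timepoints_days: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    replicates_per_point: int = 4
    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (2, 8)
    median_half_life_days: Mapping[str, float] = field(
        default_factory=lambda: {"lung": 3.9, "heart": 7.3, "brain": 8.0}
    )
    half_life_sigma: float = 0.4
    frac_affected: float = 0.1
    effect_fc_range: tuple[float, float] = (1.5, 3.0)
    n_longlived: int = 10
    longlived_min_half_life_days: float = 60.0
    longlived_half_life_days: float | None = None
    noise_cv: float = 0.1
    missing_rate: float = 0.05
    missing_mode: str = "mcar"
    loading_factor_sigma: float = 0.1
    peptide_intercept_sigma: float = 0.3
    peptide_slope_sigma: float = 0.0
    baseline_abundance_log_mean: float = float(np.log(1e6))
    baseline_abundance_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tps = sorted(float(t) for t in self.timepoints_days)
        if 0.0 not in tps:
            tps = [0.0] + tps
        self.timepoints_days = tuple(tps)
        self.validate()

    def validate(self) -> None:
        if not self.organs:
            raise ConfigError("organs must be non-empty")
        if not self.oxygen_levels:
            raise ConfigError("oxygen_levels must be non-empty")
        if self.reference_oxygen not in self.oxygen_levels:
            raise ConfigError(
                f"reference_oxygen {self.reference_oxygen!r} not in oxygen_levels"
            )
        if any(t < 0 for t in self.timepoints_days):
            raise ConfigError("timepoints_days must be non-negative")
        if self.replicates_per_point < 1:
            raise ConfigError("replicates_per_point must be a positive integer")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein must satisfy 1 <= min <= max")
        for organ in self.organs:
            if organ not in self.median_half_life_days:
                raise ConfigError(f"median_half_life_days missing organ {organ!r}")
            if self.median_half_life_days[organ] <= 0:
                raise ConfigError("median half-lives must be positive")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ConfigError("frac_affected must lie in [0, 1]")
        flo, fhi = self.effect_fc_range
        if flo < 1.0 or fhi < flo:
            raise ConfigError("effect_fc_range must satisfy 1 <= low <= high")
        if self.n_longlived < 0:
            raise ConfigError("n_longlived must be non-negative")
        if self.longlived_min_half_life_days <= 0:
            raise ConfigError("longlived_min_half_life_days must be positive")
        if (
            self.longlived_half_life_days is not None
            and self.longlived_half_life_days < self.longlived_min_half_life_days
        ):
            raise ConfigError(
                "longlived_half_life_days must be >= longlived_min_half_life_days"
            )
        if self.noise_cv < 0 or self.loading_factor_sigma < 0:
            raise ConfigError("noise_cv and loading_factor_sigma must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.missing_mode not in ("mcar", "intensity"):
            raise ConfigError("missing_mode must be 'mcar' or 'intensity'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("peptides_per_protein", "effect_fc_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["organs"] = list(self.organs)
        d["oxygen_levels"] = list(self.oxygen_levels)
        d["timepoints_days"] = list(self.timepoints_days)
        d["peptides_per_protein"] = list(self.peptides_per_protein)
        d["effect_fc_range"] = list(self.effect_fc_range)
        d["median_half_life_days"] = dict(self.median_half_life_days)
        return d


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the sample table: one row per organ x oxygen x timepoint x replicate.

    Day-0 baseline samples are emitted for every condition so that the 14N
    fraction (abundance relative to baseline) is always computable.
    """
    rows = []
    for organ in config.organs:
        for oxy in config.oxygen_levels:
            for t in config.timepoints_days:
                for rep in range(1, config.replicates_per_point + 1):
                    t_label = f"{t:g}".replace(".", "p")
                    rows.append(
                        {
                            "sample_id": f"{organ}_o{oxy}_d{t_label}_r{rep}",
                            "organ": organ,
                            "oxygen": str(oxy),
                            "time_days": float(t),
                            "replicate": rep,
                        }
                    )
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():  # pragma: no cover - by construction
        raise ConfigError("duplicate sample ids generated")
    return design


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ground-truth degradation rates per protein x organ x oxygen.

    Half-lives are lognormal around the organ median; for ``frac_affected``
    proteins the kd in each non-reference oxygen tension is multiplied or
    divided (random direction) by a factor drawn uniformly from
    ``effect_fc_range``. Long-lived panel proteins are appended with kd = 0
    (fixed abundance) unless a finite panel half-life is configured.

    Returns a long table with columns protein_id, organ, oxygen, condition,
    true_kd, is_longlived, affected, effect_fc.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    affected = rng.random(n) < config.frac_affected

    rows = []
    for organ in config.organs:
        median_hl = config.median_half_life_days[organ]
        half_lives = np.exp(rng.normal(np.log(median_hl), config.half_life_sigma, n))
        base_kd = LN2 / half_lives
        for oxy in config.oxygen_levels:
            is_ref = oxy == config.reference_oxygen
            fc = np.ones(n)
            if not is_ref:
                flo, fhi = config.effect_fc_range
                magnitude = rng.uniform(flo, fhi, n)
                direction = rng.choice([1.0, -1.0], n)
                shift = np.where(direction > 0, magnitude, 1.0 / magnitude)
                fc = np.where(affected, shift, 1.0)
            kd = base_kd * fc
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": protein_ids,
                        "organ": organ,
                        "oxygen": str(oxy),
                        "true_kd": kd,
                        "is_longlived": False,
                        "affected": affected if not is_ref else np.zeros(n, bool),
                        "effect_fc": fc,
                    }
                )
            )

    # Long-lived normalization panel: same truth in every condition.
    if config.n_longlived > 0:
        panel_ids = [f"LL{i:03d}" for i in range(1, config.n_longlived + 1)]
        if config.longlived_half_life_days is None:
            panel_kd = np.zeros(config.n_longlived)
        else:
            lo = max(config.longlived_min_half_life_days, config.longlived_half_life_days / 2)
            hi = 2 * config.longlived_half_life_days
            panel_kd = LN2 / rng.uniform(lo, hi, config.n_longlived)
        for organ in config.organs:
            for oxy in config.oxygen_levels:
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": panel_ids,
                            "organ": organ,
                            "oxygen": str(oxy),
                            "true_kd": panel_kd,
                            "is_longlived": True,
                            "affected": False,
                            "effect_fc": 1.0,
                        }
                    )
                )

    truth = pd.concat(rows, ignore_index=True)
    truth["condition"] = truth["organ"] + ":" + truth["oxygen"]
    return truth


def _peptide_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign peptides, baseline intensities and random effects per protein."""
    lo, hi = config.peptides_per_protein
    proteins = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    proteins += [f"LL{i:03d}" for i in range(1, config.n_longlived + 1)]
    counts = rng.integers(lo, hi + 1, len(proteins))
    prot_col = np.repeat(proteins, counts)
    pep_idx = np.concatenate([np.arange(1, c + 1) for c in counts])
    pep_ids = [f"{p}_pep{j}" for p, j in zip(prot_col, pep_idx)]
    base_log = rng.normal(
        config.baseline_abundance_log_mean,
        config.baseline_abundance_log_sigma,
        len(proteins),
    )
    peptides = pd.DataFrame(
        {
            "peptide_id": pep_ids,
            "protein_id": prot_col,
            "log_baseline": np.repeat(base_log, counts)
            + rng.normal(0.0, config.peptide_intercept_sigma, len(pep_ids)),
            "slope_dev": rng.normal(0.0, config.peptide_slope_sigma, len(pep_ids))
            if config.peptide_slope_sigma > 0
            else 0.0,
        }
    )
    return peptides


def simulate_abundances(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-model light-channel peptide intensities for every design sample.

    abundance = baseline_peptide * loading_sample * exp(-kd * t) * exp(eps),
    with eps ~ Normal(0, sigma) and sigma chosen so the multiplicative noise
    has coefficient of variation ``noise_cv``. Post-baseline entries are
    dropped at ``missing_rate``; day-0 rows are never dropped so every emitted
    peptide has a baseline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    peptides = _peptide_table(config, rng)
    loading = pd.Series(
        np.exp(rng.normal(0.0, config.loading_factor_sigma, len(design)))
        if config.loading_factor_sigma > 0
        else np.ones(len(design)),
        index=design["sample_id"].to_numpy(),
    )

    # Cross peptides with samples condition-by-condition to keep kd lookups flat.
    kd_map = truth.set_index(["protein_id", "organ", "oxygen"])["true_kd"]
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2))) if config.noise_cv > 0 else 0.0

    blocks = []
    for (organ, oxy), cond_samples in design.groupby(["organ", "oxygen"], sort=True):
        kd = kd_map.loc[
            pd.MultiIndex.from_arrays(
                [
                    peptides["protein_id"],
                    np.repeat(organ, len(peptides)),
                    np.repeat(oxy, len(peptides)),
                ]
            )
        ].to_numpy()
        n_pep, n_smp = len(peptides), len(cond_samples)
        t = cond_samples["time_days"].to_numpy()
        slope = -(kd[:, None] + np.asarray(peptides["slope_dev"])[:, None])
        log_ab = (
            peptides["log_baseline"].to_numpy()[:, None]
            + slope * t[None, :]
            + np.log(loading.loc[cond_samples["sample_id"]].to_numpy())[None, :]
        )
        if sigma > 0:
            log_ab = log_ab + rng.normal(0.0, sigma, (n_pep, n_smp))
        block = pd.DataFrame(
            {
                "peptide_id": np.repeat(peptides["peptide_id"].to_numpy(), n_smp),
                "protein_id": np.repeat(peptides["protein_id"].to_numpy(), n_smp),
                "sample_id": np.tile(cond_samples["sample_id"].to_numpy(), n_pep),
                "abundance": np.exp(log_ab).ravel(),
                "_time": np.tile(t, n_pep),
            }
        )
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)

    if config.missing_rate > 0:
        droppable = table["_time"] > 0
        if config.missing_mode == "mcar":
            p_drop = np.full(len(table), config.missing_rate)
        else:
            # Intensity-dependent censoring: drop probability decreasing with
            # within-table abundance rank, rescaled to the marginal rate.
            rank = table["abundance"].rank(pct=True).to_numpy()
            p_drop = config.missing_rate * 2.0 * (1.0 - rank)
            p_drop = np.clip(p_drop, 0.0, 0.95)
        drop = (rng.random(len(table)) < p_drop) & droppable.to_numpy()
        n_dropped = int(drop.sum())
        table = table.loc[~drop]
        logger.info("missingness: dropped %d of %d measurements", n_dropped, len(drop))
    table = table.drop(columns="_time").reset_index(drop=True)
    return table


def simulate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator: design, truth, abundances and the panel list.

    A single seeded RNG drives all draws, so identical config (including seed)
    yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    truth = simulate_truth(config, rng)
    abundance = simulate_abundances(truth, design, config, rng)
    panel = truth.loc[truth["is_longlived"], "protein_id"].drop_duplicates().tolist()
    logger.info(
        "simulated %d proteins (+%d panel), %d samples, %d abundance rows",
        config.n_proteins,
        config.n_longlived,
        len(design),
        len(abundance),
    )
    return {
        "design": design,
        "truth": truth,
        "abundance": abundance,
        "panel": pd.DataFrame({"protein_id": panel}),
    }


def write_dataset(dataset: Mapping[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write the simulated tables as TSVs (+ one protein id per line for the panel)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in dataset.items():
        if name == "panel":
            path = os.path.join(out_dir, "panel.txt")
            df["protein_id"].to_csv(path, index=False, header=False)
        else:
            path = os.path.join(out_dir, f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
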