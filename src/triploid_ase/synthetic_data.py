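"""Synthetic allele-pair count generator with known ASE and DE truth.

The generator emulates the statistical structure the downstream analysis
assumes for an ABB-type triploid ripening series:

* one collapsed B gene per pair carrying the combined expression of the two
  B haplotypes, so a balanced pair has an expected B:A ratio equal to the
  dosage ratio (2 by default);
* negative-binomial counts with a common dispersion;
* stage-wise ripening trajectories: a configurable fraction of pairs is
  differentially expressed, ramping linearly to its full log2 fold change at
  the last stage;
* injected allelic imbalance: B-dominant pairs sit a configurable multiplier
  beyond the upper calling threshold, A-dominant pairs the same factor below
  the lower threshold, so recovery can be scored against truth.

Counts are the primitive; RPKM is always derived from counts, gene length
and the configured sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ase_calling import ASEClass, PloidyModel
from .core_io import AllelePairSet, ExpressionMatrix, counts_to_rpkm
from .errors import ConfigError, DomainError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic ripening experiment.

    Defaults describe a desk-scale version of a triploid ripening study:
    2,000 allele pairs (scalable to genome size), stages 0/3/6 days
    post-harvest, three biological replicates, a 1:2 A:B dosage baseline and
    moderate negative-binomial noise.
    """

    n_pairs: int = 2000
    stages_dph: Sequence[int] = (0, 3, 6)
    replicates: int = 3
    cultivar: str = "FJ"
    copies_a: int = 1
    copies_b: int = 2
    fold_factor_k: float = 2.0
    frac_b_dominant: float = 0.10
    frac_a_dominant: float = 0.10
    ase_effect_multiplier: float = 2.0
    frac_deg_up: float = 0.10
    frac_deg_down: float = 0.10
    deg_log2fc_mean: float = 2.5
    deg_log2fc_sd: float = 0.5
    nb_dispersion: float = 0.1
    baseline_mean_log_mu: float = float(np.log(100.0))
    baseline_mean_log_sigma: float = 1.0
    library_size: int = 10_000_000
    gene_length_range_bp: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_b_dominant", "frac_a_dominant", "frac_deg_up", "frac_deg_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_b_dominant + self.frac_a_dominant > 1:
            raise ConfigError("frac_b_dominant + frac_a_dominant must be <= 1")
        if self.frac_deg_up + self.frac_deg_down > 1:
            raise ConfigError("frac_deg_up + frac_deg_down must be <= 1")
        if self.ase_effect_multiplier <= 1:
            raise ConfigError("ase_effect_multiplier must be > 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        lo, hi = self.gene_length_range_bp
        if not (0 < lo <= hi):
            raise ConfigError("gene_length_range_bp must satisfy 0 < lo <= hi")

    def ploidy_model(self) -> PloidyModel:
        return PloidyModel(self.copies_a, self.copies_b, self.fold_factor_k)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``ase`` has one row per (pair, stage) with the true class and true B/A
    expression ratio; ``deg`` has one row per gene with its DE status and
    the log2 fold change reached at the final stage.
    """

    ase: pd.DataFrame
    deg: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_dataset(config: SimulationConfig):
    """Draw one synthetic dataset.

    Returns
    -------
    (ExpressionMatrix, AllelePairSet, TruthTable)
        The matrix carries counts and derived RPKM; truth records the
        injected ASE class per (pair, stage) and DE status per gene.
    """
    rng = np.random.default_rng(config.seed)
    model = config.ploidy_model()
    n = config.n_pairs
    stages = list(config.stages_dph)
    n_stage = len(stages)

    pair_ids = np.array([f"pair{i:05d}" for i in range(n)])
    genes_a = np.array([f"geneA{i:05d}" for i in range(n)])
    genes_b = np.array([f"geneB{i:05d}" for i in range(n)])
    lo, hi = config.gene_length_range_bp
    len_a = rng.integers(lo, hi + 1, size=n)
    len_b = rng.integers(lo, hi + 1, size=n)

    # expression level in reads per kb; counts scale with transcript length
    base_expr_a = rng.lognormal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, n)

    # --- injected allelic imbalance -------------------------------------
    classes = np.full(n, ASEClass.BALANCED, dtype=object)
    n_b_dom = int(round(config.frac_b_dominant * n))
    n_a_dom = int(round(config.frac_a_dominant * n))
    idx = rng.permutation(n)
    classes[idx[:n_b_dom]] = ASEClass.B_DOMINANT
    classes[idx[n_b_dom : n_b_dom + n_a_dom]] = ASEClass.A_DOMINANT

    true_ratio = np.full(n, model.dosage_ratio)
    true_ratio[classes == ASEClass.B_DOMINANT] = (
        model.upper_threshold * config.ase_effect_multiplier
    )
    true_ratio[classes == ASEClass.A_DOMINANT] = (
        model.lower_threshold / config.ase_effect_multiplier
    )

    # --- DE trajectories (per pair, both members move together) ---------
    deg_status = np.full(n, "NULL", dtype=object)
    n_up = int(round(config.frac_deg_up * n))
    n_down = int(round(config.frac_deg_down * n))
    idx = rng.permutation(n)
    deg_status[idx[:n_up]] = "UP"
    deg_status[idx[n_up : n_up + n_down]] = "DOWN"
    lfc = np.zeros(n)
    mags = np.abs(rng.normal(config.deg_log2fc_mean, config.deg_log2fc_sd, n))
    lfc[deg_status == "UP"] = mags[deg_status == "UP"]
    lfc[deg_status == "DOWN"] = -mags[deg_status == "DOWN"]

    # stage ramp: 0 at baseline, 1 at the final stage
    ramp = (
        np.linspace(0.0, 1.0, n_stage)
        if n_stage > 1
        else np.array([0.0])
    )

    # --- draw counts -----------------------------------------------------
    sample_ids, design_rows = [], []
    counts = {}
    for si, stage in enumerate(stages):
        mu_a = base_expr_a * (len_a / 1000.0) * 2.0 ** (lfc * ramp[si])
        mu_b = base_expr_a * true_ratio * (len_b / 1000.0) * 2.0 ** (lfc * ramp[si])
        for rep in range(1, config.replicates + 1):
            sid = f"{config.cultivar}_{stage}dph_r{rep}"
            sample_ids.append(sid)
            design_rows.append((sid, config.cultivar, stage, rep))
            counts[sid] = np.concatenate(
                [
                    _nb_draw(rng, mu_a, config.nb_dispersion),
                    _nb_draw(rng, mu_b, config.nb_dispersion),
                ]
            )

    genes = pd.DataFrame(
        {
            "subgenome": ["A"] * n + ["B"] * n,
            "length_bp": np.concatenate([len_a, len_b]),
        },
        index=pd.Index(np.concatenate([genes_a, genes_b]), name="gene_id"),
    )
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "cultivar", "stage_dph", "replicate"]
    ).set_index("sample_id")
    counts_df = pd.DataFrame(counts, index=genes.index)
    matrix = ExpressionMatrix(genes, design, counts=counts_df)
    matrix.compute_rpkm(total_mapped=config.library_size)

    pairs = AllelePairSet(
        pd.DataFrame({"pair_id": pair_ids, "gene_a": genes_a, "gene_b": genes_b})
    )

    truth_ase = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, n_stage),
            "stage_dph": np.tile(stages, n),
            "true_class": np.repeat(classes, n_stage),
            "true_b_over_a": np.repeat(true_ratio, n_stage),
        }
    )
    truth_deg = pd.DataFrame(
        {
            "gene_id": np.concatenate([genes_a, genes_b]),
            "true_deg": np.concatenate([deg_status, deg_status]),
            "true_log2fc": np.concatenate([lfc, lfc]),
        }
    )
    return matrix, pairs, TruthTable(ase=truth_ase, deg=truth_deg)
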