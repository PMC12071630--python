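"""Negative-binomial differential-expression gate for DEG-allele screening.

This is a self-contained re-implementation of the classic count-based DE
scheme used for small replicated RNA-seq designs:

1. **median-of-ratios size factors** — each sample's factor is the median,
   over genes positive in every sample, of its count divided by the gene's
   geometric mean across samples;
2. **method-of-moments dispersion** with shrinkage toward a fitted
   mean–dispersion trend ``alpha(mu) = a0 + a1/mu``;
3. **NB exact test** — conditioning on the two group totals, the two-sided
   p-value sums the probabilities of all (total_1, total_2) splits no more
   likely than the observed one, each group total modelled as negative
   binomial with moment-matched parameters;
4. **Benjamini–Hochberg** step-up FDR.

A pair of subgenome homologs is a *DEG allele* when either member passes
the gate (fold change >= threshold and q below alpha) at any non-baseline
stage.  For inputs that ship only RPKM a fold-change-only fallback is
provided.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom

from .core_io import AllelePairSet, ExpressionMatrix, PipelineConfig
from .errors import ConfigError, DomainError, NormalizationError

logger = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"

    def __str__(self) -> str:
        return self.value


def size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    Only genes with a positive count in every sample contribute to the
    reference (their geometric mean is positive); raises if no such gene
    exists.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise DomainError("counts must be non-negative")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in all samples")
    ref = arr[positive]
    log_geomean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(factors, index=counts.columns, name="size_factor")
    return factors


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# dispersion estimation


def _fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit alpha ~ a0 + a1/mu by iteratively reweighted least squares.

    Gamma-style weighting (weight 1/fitted^2) with two refinement passes;
    falls back to the median dispersion when the fit degenerates.
    """
    ok = (base_mean > 0) & np.isfinite(disp) & (disp > 0)
    if ok.sum() < 10:
        med = float(np.median(disp[ok])) if ok.any() else 0.01
        return max(med, 1e-8), 0.0
    x = 1.0 / base_mean[ok]
    y = disp[ok]
    X = np.column_stack([np.ones_like(x), x])
    w = np.ones_like(y)
    coef = np.array([np.median(y), 0.0])
    for _ in range(3):
        W = w[:, None]
        try:
            coef, *_ = np.linalg.lstsq(X * W, y * w, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        fitted = np.clip(X @ coef, 1e-8, None)
        w = 1.0 / fitted
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    counts: np.ndarray,
    factors: np.ndarray,
    groups: np.ndarray,
    mode: str = "shrink",
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-gene NB dispersion on normalized counts.

    Method-of-moments gene-wise estimates (pooled within-group variance,
    shot-noise corrected) combined with a fitted a0 + a1/mu trend according
    to ``mode``:

    - ``"shrink"`` (default): log-scale blend weighted by residual degrees
      of freedom against ``prior_df`` — gene estimates dominate with many
      replicates, the trend dominates at 2–3;
    - ``"fit"``: trend only;
    - ``"gene"``: gene-wise only;
    - ``"max"``: elementwise max of gene and trend (the conservative
      sharing mode of early NB-test implementations).
    """
    counts = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    q = counts / factors[None, :]
    base_mean = q.mean(axis=1)

    labels = np.unique(groups)
    resid_ss = np.zeros(counts.shape[0])
    df = 0
    for g in labels:
        cols = groups == g
        if cols.sum() >= 2:
            grp = q[:, cols]
            resid_ss += ((grp - grp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += cols.sum() - 1
    if df < 1:
        # no replication anywhere: fall back to treating all samples as one
        # group (blind estimation), the standard recourse without replicates
        resid_ss = ((q - q.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df = counts.shape[1] - 1
        logger.warning("no replicated group; dispersion estimated blind")

    var = resid_ss / df
    xi = np.mean(1.0 / factors)  # shot-noise term on the normalized scale
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_gene = (var - base_mean * xi) / base_mean**2
    disp_gene = np.where(np.isfinite(disp_gene), disp_gene, 0.0)
    disp_gene_floored = np.clip(disp_gene, 1e-8, None)

    if mode == "gene":
        return disp_gene_floored
    a0, a1 = _fit_dispersion_trend(base_mean, disp_gene)
    with np.errstate(divide="ignore"):
        disp_fit = np.clip(a0 + a1 / np.clip(base_mean, 1e-12, None), 1e-8, None)
    if mode == "fit":
        return disp_fit
    if mode == "max":
        return np.maximum(disp_gene_floored, disp_fit)
    if mode == "shrink":
        w = df / (df + prior_df)
        return np.exp(w * np.log(disp_gene_floored) + (1 - w) * np.log(disp_fit))
    raise ConfigError(f"unknown dispersion mode {mode!r}")


# ---------------------------------------------------------------------------
# NB exact test


def _exact_nb_p(k1: int, k2: int, mu1: float, mu2: float, var1: float, var2: float) -> float:
    """Two-sided exact p for the split (k1, k2) of the total k1 + k2.

    The group totals are NB with moment-matched (mean, variance); the
    p-value is the probability, conditional on the observed grand total, of
    all splits at most as likely as the observed one.
    """
    ks = k1 + k2
    if ks == 0:
        return 1.0

    def _params(mu, var):
        var = max(var, mu * (1 + 1e-8))  # guard: NB needs var > mean
        r = mu * mu / (var - mu)
        return r, r / (r + mu)

    r1, p1 = _params(mu1, var1)
    r2, p2 = _params(mu2, var2)
    a = np.arange(ks + 1)
    logp = nbinom.logpmf(a, r1, p1) + nbinom.logpmf(ks - a, r2, p2)
    obs = logp[k1]
    denom = logsumexp(logp)
    num = logsumexp(logp[logp <= obs + 1e-12])
    return float(min(1.0, np.exp(num - denom)))


def nb_test(
    counts_group1: np.ndarray,
    counts_group2: np.ndarray,
    factors_group1: np.ndarray,
    factors_group2: np.ndarray,
    dispersion_mode: str = "shrink",
    dispersions: np.ndarray | None = None,
    max_exact_total: int = 1_000_000,
) -> np.ndarray:
    """Per-gene two-sided NB exact test between two replicate groups.

    ``counts_group*`` are genes x replicates arrays of raw counts with the
    matching per-sample size factors.  Dispersions are estimated across both
    groups unless supplied.  All-zero genes get p = 1 by convention.  Genes
    whose grand total exceeds ``max_exact_total`` use a normal approximation
    to the conditional distribution.
    """
    c1 = np.atleast_2d(np.asarray(counts_group1, dtype=int))
    c2 = np.atleast_2d(np.asarray(counts_group2, dtype=int))
    f1 = np.asarray(factors_group1, dtype=float)
    f2 = np.asarray(factors_group2, dtype=float)
    n_genes = c1.shape[0]

    counts = np.hstack([c1, c2])
    factors = np.concatenate([f1, f2])
    groups = np.array([0] * c1.shape[1] + [1] * c2.shape[1])
    if dispersions is None:
        dispersions = estimate_dispersions(counts, factors, groups, mode=dispersion_mode)

    q = counts / factors[None, :]
    q_hat = q.mean(axis=1)  # pooled mean of normalized counts

    s1, s2 = f1.sum(), f2.sum()
    ss1, ss2 = (f1**2).sum(), (f2**2).sum()
    k1 = c1.sum(axis=1)
    k2 = c2.sum(axis=1)

    mu1 = q_hat * s1
    mu2 = q_hat * s2
    var1 = mu1 + dispersions * q_hat**2 * ss1
    var2 = mu2 + dispersions * q_hat**2 * ss2

    p = np.ones(n_genes)
    for i in range(n_genes):
        tot = int(k1[i] + k2[i])
        if tot == 0:
            continue
        if tot <= max_exact_total:
            p[i] = _exact_nb_p(int(k1[i]), int(k2[i]), mu1[i], mu2[i], var1[i], var2[i])
        else:  # normal approximation on the observed split
            z = (k1[i] - mu1[i]) / np.sqrt(var1[i] + var2[i] * (s1 / s2) ** 2)
            from scipy.stats import norm

            p[i] = float(2 * norm.sf(abs(z)))
    return p


# ---------------------------------------------------------------------------
# DEG-allele screening


@dataclass
class DEGAlleleSet:
    """DEG records plus the allele pairs they pull in.

    ``records`` holds one row per (gene, contrast); ``pair_members`` one row
    per included pair stating which member(s) triggered inclusion; ``pairs``
    is the corresponding subset of the input AllelePairSet.
    """

    records: pd.DataFrame
    pair_members: pd.DataFrame
    pairs: AllelePairSet

    @property
    def pair_ids(self) -> list[str]:
        return self.pairs.pairs["pair_id"].tolist()

    def __len__(self) -> int:
        return len(self.pairs)


def deg_table(
    expression: ExpressionMatrix,
    config: PipelineConfig,
    cultivar: str | None = None,
    dispersion_mode: str = "shrink",
) -> pd.DataFrame:
    """Per-gene DEG records for every non-baseline stage vs the baseline.

    With counts present the NB exact test runs per contrast with BH across
    genes; direction is UP/DOWN only when both the fold-change and the FDR
    condition hold (fold change >= threshold is inclusive).  Without counts
    a fold-change-only screen on stage-mean RPKM is applied (p and q are
    NaN and only the fold-change condition gates direction).
    """
    design = expression.design
    if cultivar is not None:
        design = design[design["cultivar"] == cultivar]
    elif design["cultivar"].nunique() > 1:
        raise ConfigError("design mixes cultivars; pass cultivar=")
    baseline = config.baseline_stage_dph
    stages = sorted(design["stage_dph"].unique())
    if baseline not in stages:
        raise ConfigError(f"baseline stage {baseline} absent from design")
    test_stages = [s for s in stages if s != baseline]
    log2_thr = np.log2(config.deg_fc_threshold)

    gene_ids = expression.genes.index
    frames = []
    if expression.counts is not None:
        counts = expression.counts[list(design.index)]
        factors = size_factors(counts)
        norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
        base_cols = (design["stage_dph"] == baseline).to_numpy()
        for stage in test_stages:
            test_cols = (design["stage_dph"] == stage).to_numpy()
            p = nb_test(
                counts.to_numpy()[:, base_cols],
                counts.to_numpy()[:, test_cols],
                factors.to_numpy()[base_cols],
                factors.to_numpy()[test_cols],
                dispersion_mode=dispersion_mode,
            )
            q = bh_adjust(p)
            mean_base = norm[:, base_cols].mean(axis=1)
            mean_test = norm[:, test_cols].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc = np.log2(mean_test) - np.log2(mean_base)
            frames.append(
                _records_frame(gene_ids, baseline, stage, log2fc, p, q,
                               log2_thr, config.deg_alpha, use_q=True)
            )
    else:
        stage_rpkm = expression.stage_mean_rpkm(
            cultivar=cultivar if cultivar is not None else None
        )
        logger.warning("no raw counts: fold-change-only DEG screen on RPKM")
        for stage in test_stages:
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc = np.log2(stage_rpkm[stage].to_numpy()) - np.log2(
                    stage_rpkm[baseline].to_numpy()
                )
            nan = np.full(len(gene_ids), np.nan)
            frames.append(
                _records_frame(gene_ids, baseline, stage, log2fc, nan, nan,
                               log2_thr, config.deg_alpha, use_q=False)
            )
    return pd.concat(frames, ignore_index=True)


def _records_frame(gene_ids, baseline, stage, log2fc, p, q, log2_thr, alpha, use_q):
    fc_ok = np.abs(log2fc) >= log2_thr - 1e-12  # inclusive >= threshold
    fc_ok &= np.isfinite(log2fc) | np.isposinf(log2fc) | np.isneginf(log2fc)
    sig = (q < alpha) if use_q else np.ones_like(fc_ok, dtype=bool)
    direction = np.where(
        fc_ok & sig & (log2fc > 0), Direction.UP,
        np.where(fc_ok & sig & (log2fc < 0), Direction.DOWN, Direction.NS),
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_dph": baseline,
            "stage_dph": stage,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )


def call_deg_alleles(
    expression: ExpressionMatrix,
    pairs: AllelePairSet,
    config: PipelineConfig,
    cultivar: str | None = None,
    dispersion_mode: str = "shrink",
) -> DEGAlleleSet:
    """Screen allele pairs for differential expression across ripening.

    A pair is a DEG allele when its A and/or B member is UP or DOWN at any
    non-baseline stage in the focal cultivar.  When
    ``config.require_both_cultivars_deg`` is set and the design holds two
    cultivars, a gene must pass the gate in both for its call to count.
    """
    cultivars = expression.design["cultivar"].unique().tolist()
    focal = cultivar or cultivars[0]
    records = deg_table(expression, config, cultivar=focal, dispersion_mode=dispersion_mode)

    hit = records[records["direction"] != Direction.NS]
    hit_genes = set(hit["gene_id"])

    if config.require_both_cultivars_deg and len(cultivars) > 1:
        for other in cultivars:
            if other == focal:
                continue
            other_rec = deg_table(expression, config, cultivar=other,
                                  dispersion_mode=dispersion_mode)
            other_hits = set(
                other_rec.loc[other_rec["direction"] != Direction.NS, "gene_id"]
            )
            hit_genes &= other_hits

    ptab = pairs.pairs
    a_hit = ptab["gene_a"].isin(hit_genes)
    b_hit = ptab["gene_b"].isin(hit_genes)
    included = ptab[a_hit | b_hit]
    members = pd.DataFrame(
        {
            "pair_id": included["pair_id"].to_numpy(),
            "a_member_deg": a_hit[included.index].to_numpy(),
            "b_member_deg": b_hit[included.index].to_numpy(),
        }
    )
    return DEGAlleleSet(
        records=records,
        pair_members=members,
        pairs=AllelePairSet(included),
    )
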