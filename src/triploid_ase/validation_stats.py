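"""qPCR quantification and physiology association statistics.

Relative expression from allele-specific RT-qPCR uses the 2^-dCt convention
against a reference assay (e.g. a ribosomal-protein gene): expression =
2^-(Ct_target - Ct_reference).  Associations between stage-mean expression
and physiological series (ethylene evolution, starch content) are Spearman
rank correlations, with an exact permutation p-value at small n (<= 8
stages) and the usual t approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError


def delta_ct_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference); strictly decreasing in Ct_target."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise DomainError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


def expression_table(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Add a ``relative_expression`` column to a qPCR record table.

    Expects columns sample_id, target_id, ct_target, ct_reference.
    """
    required = {"sample_id", "target_id", "ct_target", "ct_reference"}
    missing = required - set(qpcr.columns)
    if missing:
        raise DomainError(f"qPCR table missing column(s): {sorted(missing)}")
    out = qpcr.copy()
    ct_t = out["ct_target"].to_numpy(dtype=float)
    ct_r = out["ct_reference"].to_numpy(dtype=float)
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise DomainError("Ct values must be finite")
    out["relative_expression"] = 2.0 ** -(ct_t - ct_r)
    return out


def expression_ratio(delta_ct_1: float, delta_ct_2: float) -> float:
    """Expression ratio between two samples: 2^-(dCt_1 - dCt_2)."""
    return 2.0 ** -(delta_ct_1 - delta_ct_2)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_assoc(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8):
    """Spearman correlation with permutation-exact p at small n.

    Returns (rho, p_value).  The two-sided p-value enumerates all n!
    permutations of y's ranks for n <= ``exact_max_n`` and counts those with
    |rho| at least as extreme as observed; larger n uses the t
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise DomainError("need at least 3 observations")
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan")
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        count = 0
        total = 0
        obs = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = _spearman_rho(x, np.asarray(perm))
            total += 1
            if abs(r) >= obs:
                count += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def physiology_correlations(
    expression: pd.DataFrame,
    physio: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate each target's stage profile with each physiology variable.

    ``expression``: columns target_id, stage_dph, value (stage means).
    ``physio``: columns variable, stage_dph, value (stage means).
    Stages are matched on stage_dph; one (target, variable) row per
    combination with at least 3 shared stages.
    """
    rows = []
    for target, expr_grp in expression.groupby("target_id"):
        e = expr_grp.set_index("stage_dph")["value"]
        for var, phys_grp in physio.groupby("variable"):
            ph = phys_grp.set_index("stage_dph")["value"]
            shared = e.index.intersection(ph.index)
            if len(shared) < 3:
                continue
            rho, p = spearman_assoc(e.loc[shared].to_numpy(), ph.loc[shared].to_numpy())
            rows.append(
                {"target_id": target, "variable": var, "n_stages": len(shared),
                 "rho": rho, "p_value": p}
            )
    return pd.DataFrame(rows, columns=["target_id", "variable", "n_stages", "rho", "p_value"])
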