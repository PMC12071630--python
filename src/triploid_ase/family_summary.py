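"""Per-gene-family ASE-ratio tables.

For each annotated family (ACO, AMY, XTH, ...) and ripening stage the table
reports how many of the family's DEG allele pairs are A-dominant ("A > B"),
how many are B-dominant ("B > 4A" under the ABB thresholds), and the ASE
ratio 100 * (A-dominant + B-dominant) / n_DEGs, to two decimals.  The
denominator is the family's full DEG-pair count, not just the expressed
subset, matching how such tables are conventionally reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ase_calling import ASEClass
from .core_io import AnnotationMap
from .errors import DomainError

logger = logging.getLogger(__name__)


def ase_ratio_percent(n_a_dominant: int, n_b_dominant: int, n_degs: int) -> float:
    """100 * (A-dominant + B-dominant) / n_DEGs, rounded to two decimals."""
    if n_degs <= 0:
        raise DomainError("n_degs must be positive")
    if n_a_dominant + n_b_dominant > n_degs:
        raise DomainError("dominant calls exceed the family's DEG count")
    return round(100.0 * (n_a_dominant + n_b_dominant) / n_degs, 2)


def family_table(
    calls: pd.DataFrame,
    annotations: AnnotationMap,
    stage: int,
) -> pd.DataFrame:
    """One row per annotated family at ``stage``.

    ``annotations`` maps pair_id -> family label(s).  Families with no
    called pair at the stage are omitted with a warning.  Columns:
    family, stage_dph, n_degs, n_a_gt_b, n_b_gt_4a, ase_ratio_percent.
    """
    stage_calls = calls[calls["stage_dph"] == stage]
    call_by_pair = stage_calls.set_index("pair_id")["call"]

    rows = []
    for family in sorted(annotations.terms()):
        members = annotations.members_of(family)
        present = [p for p in members if p in call_by_pair.index]
        if not present:
            logger.warning("family %s: no called DEG pair at stage %s; row omitted",
                           family, stage)
            continue
        fam_calls = call_by_pair.loc[present]
        n_a = int((fam_calls == ASEClass.A_DOMINANT).sum())
        n_b = int((fam_calls == ASEClass.B_DOMINANT).sum())
        n = len(present)
        rows.append(
            {
                "family": family,
                "stage_dph": stage,
                "n_degs": n,
                "n_a_gt_b": n_a,
                "n_b_gt_4a": n_b,
                "ase_ratio_percent": ase_ratio_percent(n_a, n_b, n),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "stage_dph", "n_degs", "n_a_gt_b", "n_b_gt_4a",
                 "ase_ratio_percent"],
    )


def range_summary(rows: pd.DataFrame, families: set[str] | None = None) -> tuple[float, float]:
    """(min, max) ASE ratio over the named families at all stages, one decimal."""
    sel = rows
    if families is not None:
        sel = rows[rows["family"].isin(set(families))]
    if sel.empty:
        raise DomainError("empty family selection")
    ratios = sel["ase_ratio_percent"].to_numpy(dtype=float)
    return round(float(ratios.min()), 1), round(float(ratios.max()), 1)
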