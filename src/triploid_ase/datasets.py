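"""Published summary counts from the Fen Jiao (ABB) ripening ASE study.

These are the reported per-stage category counts for the genome-wide ASE
screen and the per-family DEG/ASE count columns for the ethylene
biosynthesis, starch degradation and cell-wall degradation pathways in Fen
Jiao (FJ) banana at 3 and 6 days post-harvest.  They serve as worked-example
inputs: the summary machinery recomputes percentages and ranges from these
counts.

Only counts are stored — every ratio and range is derived at run time.
"""

from __future__ import annotations

import pandas as pd

#: Allele pairs identified genome-wide in FJ (ABB).
FJ_N_ALLELE_PAIRS = 25_716

#: Allele pairs with at least one differentially expressed member.
FJ_N_DEG_ALLELES = 15_415

#: Genome-wide ASE category counts per stage (days post-harvest):
#: (n_b_dominant ["B > 4A"], n_a_dominant ["B < A"]).
FJ_GENOME_ASE_COUNTS: dict[int, tuple[int, int]] = {
    3: (1722, 2469),
    6: (1512, 1900),
}

#: Pathway membership of the reported gene families.
FJ_FAMILY_PATHWAYS: dict[str, list[str]] = {
    "ethylene_biosynthesis": ["SAMS", "ACS", "ACO"],
    "starch_degradation": ["AMY", "BMY", "DPE"],
    "cell_wall_degradation": ["EXPANSIN", "XTH", "PL", "PE", "PG"],
}

_FAMILY_ROWS = [
    # family, stage_dph, n_degs, n_a_gt_b, n_b_gt_4a
    ("SAMS", 3, 6, 5, 0),
    ("SAMS", 6, 6, 5, 0),
    ("ACS", 3, 3, 0, 2),
    ("ACS", 6, 3, 0, 2),
    ("ACO", 3, 8, 2, 3),
    ("ACO", 6, 8, 1, 4),
    ("AMY", 3, 4, 0, 2),
    ("AMY", 6, 4, 1, 2),
    ("BMY", 3, 8, 0, 1),
    ("BMY", 6, 8, 0, 1),
    ("DPE", 3, 2, 0, 0),
    ("DPE", 6, 2, 1, 0),
    ("EXPANSIN", 3, 26, 5, 4),
    ("EXPANSIN", 6, 26, 6, 8),
    ("XTH", 3, 34, 12, 14),
    ("XTH", 6, 34, 7, 12),
    ("PL", 3, 11, 7, 3),
    ("PL", 6, 11, 3, 2),
    ("PE", 3, 26, 7, 9),
    ("PE", 6, 26, 9, 5),
    ("PG", 3, 22, 5, 4),
    ("PG", 6, 22, 4, 8),
]


def family_ase_counts() -> pd.DataFrame:
    """Reported per-family DEG and dominant-call counts, one row per
    (family, stage) across the three pathways."""
    return pd.DataFrame(
        _FAMILY_ROWS,
        columns=["family", "stage_dph", "n_degs", "n_a_gt_b", "n_b_gt_4a"],
    )


def genome_ase_calls() -> pd.DataFrame:
    """Reconstructed genome-wide call table from the reported counts.

    Each stage's B-dominant and A-dominant counts are expanded into a call
    list over the reported DEG-allele total, the remainder balanced.
    """
    from .ase_calling import calls_from_counts

    frames = []
    for stage, (n_b, n_a) in FJ_GENOME_ASE_COUNTS.items():
        frames.append(
            calls_from_counts(
                stage_dph=stage,
                n_b_dominant=n_b,
                n_a_dominant=n_a,
                n_balanced=FJ_N_DEG_ALLELES - n_b - n_a,
            )
        )
    return pd.concat(frames, ignore_index=True)
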