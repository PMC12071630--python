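"""Domain types, tab-separated readers/writers and pipeline configuration.

All on-disk tables are plain TSV with a single header row; lines starting
with ``#`` are comments.  Gene and pair identifiers are opaque strings — the
subgenome of a gene comes from an explicit column, never from parsing its
name.

Expression schema: ``gene_id  subgenome  length_bp`` followed by one column
per sample holding raw counts and/or ``rpkm:``-prefixed columns holding RPKM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    DomainError,
    DuplicationError,
    OrientationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", comment="#")


def counts_to_rpkm(counts, length_bp, total_mapped):
    """RPKM = 1e9 * count / (total_mapped * length_bp); linear in count."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise DomainError("length_bp must be > 0")
    if total_mapped <= 0:
        raise DomainError("total_mapped must be > 0")
    return 1e9 * np.asarray(counts, dtype=float) / (float(total_mapped) * length_bp)


@dataclass(frozen=True)
class SampleDesign:
    """One RNA-seq library: cultivar, ripening stage and replicate."""

    sample_id: str
    cultivar: str
    stage_dph: int
    replicate: int

    def __post_init__(self) -> None:
        if self.stage_dph < 0:
            raise SchemaError(f"sample {self.sample_id}: stage_dph must be >= 0")
        if self.replicate < 1:
            raise SchemaError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    """A gene on one subgenome with its transcript length."""

    gene_id: str
    subgenome: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.subgenome not in ("A", "B"):
            raise SchemaError(
                f"gene {self.gene_id}: subgenome must be 'A' or 'B', "
                f"got {self.subgenome!r}"
            )
        if self.length_bp <= 0:
            raise SchemaError(f"gene {self.gene_id}: length_bp must be > 0")


class ExpressionMatrix:
    """Genes x samples expression with gene metadata.

    Parameters
    ----------
    genes
        DataFrame indexed by gene_id with columns ``subgenome`` and
        ``length_bp`` (or an iterable of :class:`GeneRecord`).
    design
        DataFrame indexed by sample_id with columns ``cultivar``,
        ``stage_dph``, ``replicate`` (or an iterable of
        :class:`SampleDesign`).
    counts, rpkm
        genes x samples DataFrames; at least one must be given.
    """

    def __init__(self, genes, design, counts=None, rpkm=None):
        self.genes = _genes_frame(genes)
        self.design = _design_frame(design)
        if counts is None and rpkm is None:
            raise SchemaError("at least one of counts/rpkm must be provided")
        self.counts = self._check_values(counts, "counts", integer=True)
        self.rpkm = self._check_values(rpkm, "rpkm", integer=False)

    def _check_values(self, values, name, integer):
        if values is None:
            return None
        values = values.copy()
        if list(values.index) != list(self.genes.index):
            values = values.reindex(self.genes.index)
            if values.isna().any().any():
                raise SchemaError(f"{name}: rows do not match the gene table")
        missing = set(values.columns) - set(self.design.index)
        if missing:
            raise SchemaError(f"{name}: samples absent from design: {sorted(missing)}")
        values = values[list(self.design.index)]
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise SchemaError(f"{name}: non-finite values present")
        if (arr < 0).any():
            raise SchemaError(f"{name}: negative values present")
        if integer and not np.allclose(arr, np.round(arr)):
            raise SchemaError("counts: non-integer values present")
        return values.astype(int if integer else float)

    # -- derived quantities ------------------------------------------------

    def compute_rpkm(self, total_mapped: Mapping[str, int] | int | None = None):
        """Derive the RPKM table from counts.

        ``total_mapped`` may be a single library size applied to every
        sample, a per-sample mapping, or None to use each sample's column
        sum.  Stored on the matrix and returned.
        """
        if self.counts is None:
            raise SchemaError("cannot compute RPKM without counts")
        lengths = self.genes["length_bp"].to_numpy(dtype=float)
        rpkm = {}
        for s in self.counts.columns:
            if total_mapped is None:
                total = int(self.counts[s].sum())
            elif isinstance(total_mapped, Mapping):
                total = int(total_mapped[s])
            else:
                total = int(total_mapped)
            rpkm[s] = counts_to_rpkm(self.counts[s].to_numpy(), lengths, total)
        self.rpkm = pd.DataFrame(rpkm, index=self.counts.index)
        return self.rpkm

    def stage_mean_rpkm(self, cultivar: str | None = None) -> pd.DataFrame:
        """Replicate-mean RPKM per stage; columns are stage_dph values."""
        if self.rpkm is None:
            self.compute_rpkm()
        design = self.design
        if cultivar is not None:
            design = design[design["cultivar"] == cultivar]
            if design.empty:
                raise SchemaError(f"no samples for cultivar {cultivar!r}")
        elif design["cultivar"].nunique() > 1:
            raise SchemaError(
                "design mixes cultivars; pass cultivar= to select one"
            )
        groups = design.groupby("stage_dph").groups
        return pd.DataFrame(
            {stage: self.rpkm[list(samples)].mean(axis=1) for stage, samples in groups.items()}
        ).sort_index(axis=1)

    def __repr__(self) -> str:
        have = [n for n, v in (("counts", self.counts), ("rpkm", self.rpkm)) if v is not None]
        return (
            f"ExpressionMatrix({len(self.genes)} genes x {len(self.design)} "
            f"samples; {'+'.join(have)})"
        )


def _genes_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
    else:
        recs = list(genes)
        df = pd.DataFrame(
            {
                "subgenome": [g.subgenome for g in recs],
                "length_bp": [g.length_bp for g in recs],
            },
            index=pd.Index([g.gene_id for g in recs], name="gene_id"),
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicationError(f"duplicate gene_id: {dup[:5]}")
    bad = ~df["subgenome"].isin(["A", "B"])
    if bad.any():
        raise SchemaError(
            f"invalid subgenome label for gene(s) {df.index[bad].tolist()[:5]}"
        )
    if df["length_bp"].isna().any() or (df["length_bp"] <= 0).any():
        raise SchemaError("every gene needs a positive length_bp")
    df["length_bp"] = df["length_bp"].astype(int)
    return df[["subgenome", "length_bp"]]


def _design_frame(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        df = design.copy()
    else:
        recs = list(design)
        df = pd.DataFrame(
            {
                "cultivar": [s.cultivar for s in recs],
                "stage_dph": [s.stage_dph for s in recs],
                "replicate": [s.replicate for s in recs],
            },
            index=pd.Index([s.sample_id for s in recs], name="sample_id"),
        )
    if df.index.has_duplicates:
        raise DuplicationError("duplicate sample_id in design")
    if df.duplicated(["cultivar", "stage_dph", "replicate"]).any():
        raise SchemaError("duplicate (cultivar, stage, replicate) combination")
    if (df["stage_dph"].astype(int) < 0).any():
        raise SchemaError("stage_dph must be >= 0")
    if (df["replicate"].astype(int) < 1).any():
        raise SchemaError("replicate must be >= 1")
    df["stage_dph"] = df["stage_dph"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df[["cultivar", "stage_dph", "replicate"]]


class AllelePairSet:
    """Mapping of A-subgenome genes to their B-subgenome counterparts."""

    def __init__(self, pairs: pd.DataFrame):
        pairs = pairs.copy().reset_index(drop=True)
        for col in ("pair_id", "gene_a", "gene_b"):
            if col not in pairs.columns:
                raise SchemaError(f"pair table missing column {col!r}")
        if pairs["pair_id"].duplicated().any():
            raise DuplicationError("duplicate pair_id")
        members = pd.concat([pairs["gene_a"], pairs["gene_b"]])
        if members.duplicated().any():
            dup = members[members.duplicated()].unique().tolist()
            raise DuplicationError(f"gene(s) in more than one pair: {dup[:5]}")
        self.pairs = pairs[["pair_id", "gene_a", "gene_b"]]

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, pair_ids: Iterable[str]) -> "AllelePairSet":
        keep = self.pairs["pair_id"].isin(set(pair_ids))
        return AllelePairSet(self.pairs[keep])

    def gene_to_pair(self) -> pd.Series:
        """Series mapping each member gene_id to its pair_id."""
        return pd.concat(
            [
                pd.Series(self.pairs["pair_id"].values, index=self.pairs["gene_a"]),
                pd.Series(self.pairs["pair_id"].values, index=self.pairs["gene_b"]),
            ]
        )


class AnnotationMap:
    """gene/pair id -> set of term ids, with optional term labels.

    Ids that do not resolve against the supplied universe are retained in
    ``unresolved`` and logged, never silently dropped.
    """

    def __init__(
        self,
        entries: Mapping[str, set],
        term_names: Mapping[str, str] | None = None,
        known_ids: Iterable[str] | None = None,
    ):
        entries = {k: set(v) for k, v in entries.items()}
        empty = [k for k, v in entries.items() if not v]
        if empty:
            raise SchemaError(f"empty term set for id(s): {empty[:5]}")
        self.unresolved: set[str] = set()
        if known_ids is not None:
            known = set(known_ids)
            self.unresolved = set(entries) - known
            if self.unresolved:
                logger.warning(
                    "%d annotated id(s) not resolvable against the pair set: %s",
                    len(self.unresolved),
                    sorted(self.unresolved)[:5],
                )
            entries = {k: v for k, v in entries.items() if k in known}
        self.entries = entries
        self.term_names = dict(term_names or {})

    def terms(self) -> set[str]:
        out: set[str] = set()
        for v in self.entries.values():
            out |= v
        return out

    def members_of(self, term_id: str) -> set[str]:
        return {k for k, v in self.entries.items() if term_id in v}


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis.

    ``copies_a``/``copies_b``/``fold_factor_k`` generate the dosage-adjusted
    ASE thresholds (ABB defaults give B > 4A / B < A); the DEG gate is
    fold-change >= ``deg_fc_threshold`` at BH FDR < ``deg_alpha`` against the
    ``baseline_stage_dph`` reference.
    """

    copies_a: int = 1
    copies_b: int = 2
    fold_factor_k: float = 2.0
    deg_fc_threshold: float = 2.0
    deg_alpha: float = 0.05
    min_expression_rpkm: float = 1.0
    baseline_stage_dph: int = 0
    require_both_cultivars_deg: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_a < 1 or self.copies_b < 1:
            raise ConfigError("copy numbers must be >= 1")
        if not self.fold_factor_k > 1:
            raise ConfigError("fold_factor_k must be > 1")
        if self.deg_fc_threshold < 1:
            raise ConfigError("deg_fc_threshold must be >= 1")
        if not 0 < self.deg_alpha < 1:
            raise ConfigError("deg_alpha must lie in (0, 1)")
        if self.min_expression_rpkm < 0:
            raise ConfigError("min_expression_rpkm must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def ploidy_model(self):
        from .ase_calling import PloidyModel

        return PloidyModel(self.copies_a, self.copies_b, self.fold_factor_k)


# ---------------------------------------------------------------------------
# readers / writers


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    required = {"sample_id", "cultivar", "stage_dph", "replicate"}
    if not required <= set(df.columns):
        raise SchemaError(f"design missing column(s): {sorted(required - set(df.columns))}")
    return _design_frame(df.set_index("sample_id"))


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV against its sample design."""
    design = read_design(design_path)
    df = pd.read_csv(path, **_READ_KW)
    meta_cols = ["gene_id", "subgenome", "length_bp"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise SchemaError(f"expression table missing column(s): {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise DuplicationError(f"duplicate gene_id in expression table: {dup[:5]}")
    if df["subgenome"].isna().any() or df["length_bp"].isna().any():
        raise SchemaError("genes missing subgenome or length_bp are rejected")

    value_cols = [c for c in df.columns if c not in meta_cols]
    count_cols = [c for c in value_cols if not c.startswith("rpkm:")]
    rpkm_cols = [c for c in value_cols if c.startswith("rpkm:")]
    for c in count_cols:
        if c not in design.index:
            raise SchemaError(f"sample column {c!r} absent from design")
    for c in rpkm_cols:
        if c[len("rpkm:"):] not in design.index:
            raise SchemaError(f"sample column {c!r} absent from design")

    genes = df[meta_cols].set_index("gene_id")
    idx = genes.index
    counts = df[count_cols].set_index(idx) if count_cols else None
    rpkm = None
    if rpkm_cols:
        rpkm = df[rpkm_cols].set_index(idx)
        rpkm.columns = [c[len("rpkm:"):] for c in rpkm_cols]
    return ExpressionMatrix(genes, design, counts=counts, rpkm=rpkm)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.genes.reset_index()
    out = out.rename(columns={out.columns[0]: "gene_id"})
    if matrix.counts is not None:
        out = pd.concat([out, matrix.counts.reset_index(drop=True)], axis=1)
    if matrix.rpkm is not None:
        rpkm = matrix.rpkm.rename(columns=lambda c: f"rpkm:{c}")
        out = pd.concat([out, rpkm.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path, genes: pd.DataFrame) -> AllelePairSet:
    """Read an allele-pair table and validate orientation against subgenomes.

    ``genes`` is the gene metadata frame of the expression matrix (indexed
    by gene_id with a ``subgenome`` column).
    """
    df = pd.read_csv(path, **_READ_KW)
    if df.empty:
        logger.warning("pair table %s is empty", path)
        return AllelePairSet(pd.DataFrame(columns=["pair_id", "gene_a", "gene_b"]))
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise SchemaError("pair table needs columns gene_a and gene_b")
    if "pair_id" not in df.columns:
        df.insert(0, "pair_id", [f"pair{i:06d}" for i in range(len(df))])
    sub = genes["subgenome"]
    for col, want in (("gene_a", "A"), ("gene_b", "B")):
        unknown = ~df[col].isin(sub.index)
        if unknown.any():
            raise SchemaError(
                f"pair member(s) absent from gene table: {df.loc[unknown, col].tolist()[:5]}"
            )
        wrong = sub.loc[df[col]].to_numpy() != want
        if wrong.any():
            bad = df.loc[wrong, col].tolist()
            raise OrientationError(
                f"column {col} must hold subgenome-{want} genes; offending: {bad[:5]}"
            )
    return AllelePairSet(df)


def write_pairs(pairs: AllelePairSet, path: str | Path) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path, known_ids: Iterable[str] | None = None) -> AnnotationMap:
    """Read a ``id TAB term_id [TAB term_label]`` long-format map."""
    df = pd.read_csv(path, **_READ_KW)
    cols = list(df.columns)
    if len(cols) < 2:
        raise SchemaError("annotation table needs at least id and term_id columns")
    id_col, term_col = cols[0], cols[1]
    label_col = cols[2] if len(cols) > 2 else None
    entries: dict[str, set] = {}
    for _, row in df.iterrows():
        entries.setdefault(str(row[id_col]), set()).add(str(row[term_col]))
    names = {}
    if label_col is not None:
        names = {
            str(t): str(l)
            for t, l in zip(df[term_col], df[label_col])
            if pd.notna(l)
        }
    return AnnotationMap(entries, names, known_ids=known_ids)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
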