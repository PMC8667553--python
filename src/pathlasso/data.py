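"""Domain types and I/O: survival datasets, pathway collections, and the
latent (gene-duplication) design used by the overlapping group lasso.

The central trick lives in :func:`build_latent_design`: overlapping pathways
are made disjoint by giving every (pathway, gene) incidence its own column in
an expanded design matrix.  A gene sitting in k pathways contributes k latent
columns, each an exact copy of its standardized expression column, so the
group partition over latent columns is disjoint by construction and a latent
coefficient vector collapses back to gene space by summing the copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "PathwayCollection",
    "LatentDesign",
    "CoefficientVector",
    "StandardizationStats",
    "load_survival_dataset",
    "standardize",
    "read_gene_sets",
    "build_latent_design",
]


@dataclass
class SurvivalDataset:
    """Expression matrix with right-censored survival outcomes.

    Parameters
    ----------
    expression : (n_samples, n_genes) float array
    gene_ids : list of unique gene identifiers, one per column
    time : (n_samples,) non-negative event/censoring times
    event : (n_samples,) indicators, 1 = deceased, 0 = right-censored
    sample_ids : list of unique sample identifiers
    """

    expression: np.ndarray
    gene_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n, m = self.expression.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} expression columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} expression rows")
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event length does not match the number of samples")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValueError(f"event indicator must be 0/1, found values {ev}")
        self.event = self.event.astype(int)
        if not np.isfinite(self.time).all() or (self.time < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not np.isfinite(self.expression).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset (e.g. a train or test split), preserving order of `idx`."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            expression=self.expression[idx],
            gene_ids=list(self.gene_ids),
            time=self.time[idx],
            event=self.event[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PathwayCollection:
    """Named, possibly overlapping gene groups (insertion-ordered)."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.groups.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if len(set(genes)) != len(genes):
                # dedup preserving order
                seen: set[str] = set()
                self.groups[name] = [g for g in genes if not (g in seen or seen.add(g))]

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, name: str) -> list[str]:
        return self.groups[name]


@dataclass
class LatentDesign:
    """Duplicated-column expansion of an expression matrix by pathway.

    ``latent_matrix`` has one column per (retained pathway, measured gene)
    incidence; ``group_slices`` gives the contiguous block of latent columns
    owned by each retained pathway, so the blocks partition the columns.
    """

    latent_matrix: np.ndarray
    group_names: list[str]
    group_slices: list[tuple[int, int]]
    group_sizes: np.ndarray
    column_origin: list[tuple[str, str]]  # (pathway name, gene id) per latent column
    gene_ids: list[str]                   # gene universe of the source matrix
    column_gene_index: np.ndarray         # latent column -> index into gene_ids
    dropped_pathways: list[str] = field(default_factory=list)

    @property
    def n_latent(self) -> int:
        return self.latent_matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def blocks(self, beta: np.ndarray) -> list[np.ndarray]:
        """Views of ``beta`` per group block."""
        return [beta[a:b] for a, b in self.group_slices]

    def collapse(self, beta_latent: np.ndarray) -> np.ndarray:
        """Sum latent copies per gene, returning a gene-space vector.

        By linearity, hazard scores of the latent design with ``beta_latent``
        equal hazard scores of the original matrix with the collapsed vector.
        """
        beta_latent = np.asarray(beta_latent, dtype=float)
        if beta_latent.shape != (self.n_latent,):
            raise ValueError("coefficient vector does not match the latent design")
        out = np.zeros(len(self.gene_ids))
        np.add.at(out, self.column_gene_index, beta_latent)
        return out

    def project(self, expression: np.ndarray) -> np.ndarray:
        """Expand a (n, n_genes) matrix into latent space via column copies."""
        if expression.shape[1] != len(self.gene_ids):
            raise ValueError("expression matrix does not match the design gene universe")
        return expression[:, self.column_gene_index]


@dataclass
class CoefficientVector:
    """Model weights, tagged by the space they live in.

    ``space='latent'`` means one weight per duplicated column of a
    LatentDesign; ``space='gene'`` means one weight per gene of the original
    matrix (plain lasso, or a collapsed latent vector).
    """

    values: np.ndarray
    space: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in ("latent", "gene"):
            raise ValueError(f"unknown coefficient space {self.space!r}")

    def collapse(self, design: LatentDesign) -> "CoefficientVector":
        if self.space != "latent":
            raise ValueError("only latent-space vectors can be collapsed")
        return CoefficientVector(design.collapse(self.values), space="gene")


@dataclass
class StandardizationStats:
    """Per-gene mean and (sample) sd used to z-score a dataset."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean flag per gene


def _read_table(path, orientation: str = "samples_by_genes") -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def load_survival_dataset(
    expression_path,
    clinical_path,
    *,
    orientation: str = "samples_by_genes",
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalDataset:
    """Load expression + clinical tables and align them by sample id.

    Both files are delimited text (tab or comma, auto-detected).  The
    expression table needs a header row and an id column; the clinical table
    needs sample id, time and event columns (names configurable).  Samples
    present in only one file are dropped with a logged count; zero overlap is
    an error.
    """
    expr = _read_table(expression_path, orientation)
    clin = pd.read_csv(clinical_path, sep=None, engine="python")
    for col in (sample_col, time_col, event_col):
        if col not in clin.columns:
            raise ValueError(f"clinical file lacks required column {col!r}")
    clin = clin.set_index(clin[sample_col].astype(str))
    expr.index = expr.index.astype(str)

    common = [s for s in expr.index if s in clin.index]
    if not common:
        raise ValueError("no overlapping sample ids between expression and clinical files")
    dropped = (len(expr) - len(common)) + (len(clin) - len(common))
    if dropped:
        logger.warning("dropped %d samples present in only one of the two files", dropped)

    expr = expr.loc[common]
    clin = clin.loc[common]
    event = clin[event_col].to_numpy()
    if not np.isin(np.unique(event), [0, 1]).all():
        raise ValueError(f"non-binary event codes in column {event_col!r}")
    time = clin[time_col].to_numpy(dtype=float)
    if (time < 0).any():
        raise ValueError("negative survival times")
    if expr.isna().any().any():
        raise ValueError("missing expression values")

    return SurvivalDataset(
        expression=expr.to_numpy(dtype=float),
        gene_ids=[str(g) for g in expr.columns],
        time=time,
        event=event.astype(int),
        sample_ids=list(expr.index),
    )


def standardize(
    data: SurvivalDataset,
    reference: SurvivalDataset | None = None,
) -> tuple[SurvivalDataset, StandardizationStats]:
    """Z-score each gene column (sample sd, ddof=1).

    If ``reference`` is given its per-gene statistics are used instead — the
    honest protocol for held-out data is to standardize the test set with
    training-set moments, so test columns need not come out centred.
    Zero-variance genes map to all-zero columns and are flagged rather than
    dropped, keeping gene indexing stable across resampling.
    """
    src = reference if reference is not None else data
    if reference is not None and reference.gene_ids != data.gene_ids:
        raise ValueError("reference gene set must match the data gene set")
    mean = src.expression.mean(axis=0)
    sd = src.expression.std(axis=0, ddof=1) if src.n_samples > 1 else np.zeros(src.n_genes)
    zero_var = ~(sd > 0)
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (data.expression - mean) / safe_sd
    z[:, zero_var] = 0.0
    out = SurvivalDataset(
        expression=z,
        gene_ids=list(data.gene_ids),
        time=data.time.copy(),
        event=data.event.copy(),
        sample_ids=list(data.sample_ids),
    )
    return out, StandardizationStats(mean=mean, sd=sd, zero_variance=zero_var)


def read_gene_sets(path) -> PathwayCollection:
    """Read a GMT gene-set file: ``name <tab> description <tab> gene...``.

    Duplicate genes within one record are deduplicated; duplicate pathway
    names and empty records are errors.
    """
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"line {lineno}: gene-set record with no genes")
            name = parts[0].strip()
            if name in groups:
                raise ValueError(f"line {lineno}: duplicate pathway name {name!r}")
            seen: set[str] = set()
            genes = [g for g in (p.strip() for p in parts[2:]) if g and not (g in seen or seen.add(g))]
            groups[name] = genes
    if not groups:
        raise ValueError("gene-set file contains no records")
    return PathwayCollection(groups)


def write_gene_sets(pathways: PathwayCollection, path, description: str = "na") -> None:
    """Write a PathwayCollection in GMT format."""
    with open(path, "w") as fh:
        for name, genes in pathways.groups.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def build_latent_design(
    data: SurvivalDataset,
    pathways: PathwayCollection,
) -> LatentDesign:
    """Expand a (standardized) expression matrix into the latent group space.

    Each retained pathway owns a contiguous block of columns, one per
    measured member gene; genes absent from the expression matrix are
    excluded from their groups (logged), and pathways left with no measured
    genes are dropped and reported in ``dropped_pathways``.
    """
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}
    col_gene_idx: list[int] = []
    origins: list[tuple[str, str]] = []
    names: list[str] = []
    slices: list[tuple[int, int]] = []
    dropped: list[str] = []
    n_missing = 0
    for name, genes in pathways.groups.items():
        measured = [g for g in genes if g in gene_pos]
        n_missing += len(genes) - len(measured)
        if not measured:
            dropped.append(name)
            continue
        start = len(col_gene_idx)
        col_gene_idx.extend(gene_pos[g] for g in measured)
        origins.extend((name, g) for g in measured)
        names.append(name)
        slices.append((start, len(col_gene_idx)))
    if not names:
        raise ValueError("no pathway has any measured gene in the expression matrix")
    if n_missing:
        logger.info("excluded %d unmeasured genes from pathway groups", n_missing)
    if dropped:
        logger.info("dropped %d pathways with no measured genes: %s", len(dropped), dropped)
    idx = np.asarray(col_gene_idx, dtype=int)
    return LatentDesign(
        latent_matrix=data.expression[:, idx],
        group_names=names,
        group_slices=slices,
        group_sizes=np.asarray([b - a for a, b in slices]),
        column_origin=origins,
        gene_ids=list(data.gene_ids),
        column_gene_index=idx,
        dropped_pathways=dropped,
    )
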