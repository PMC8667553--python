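"""Paired toy-cancer generator for end-to-end testing of the models.

Emulates the structure of a two-cohort gene-expression survival study:
multivariate-normal expression with strong within-pathway collinearity,
hazard fully determined by a small set of "true" pathways whose loadings are
first-principal-component coefficients computed on the pooled cohorts, ~70%
events / ~30% right-censoring, and censored times stochastically reduced
below the latent death time.  Defaults give two cohorts of 300 and 200
patients with two true pathways each, one shared — the regime where a
cross-cohort coupling penalty has something to transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import CoefficientVector, PathwayCollection, SurvivalDataset

__all__ = [
    "SyntheticSpec",
    "scaled_pathways",
    "synthetic_pathways",
    "generate_expression",
    "true_beta",
    "generate_survival",
    "generate_pair",
    "write_pair",
]


def synthetic_pathways(
    n_pathways: int = 20,
    genes_per_pathway: int = 25,
    overlap: int = 5,
    n_genes: int = 2000,
) -> PathwayCollection:
    """Synthetic pathway collection over gene ids G0000, G0001, ...

    Consecutive pathways share ``overlap`` genes so the latent expansion
    exercises gene duplication; genes beyond the pathway-covered prefix
    belong to no pathway (they exist only in the plain-lasso universe).
    """
    stride = genes_per_pathway - overlap
    needed = (n_pathways - 1) * stride + genes_per_pathway
    if needed > n_genes:
        raise ValueError(f"need at least {needed} genes for {n_pathways} pathways")
    gene = lambda i: f"G{i:04d}"
    groups = {
        f"P{p + 1}": [gene(i) for i in range(p * stride, p * stride + genes_per_pathway)]
        for p in range(n_pathways)
    }
    return PathwayCollection(groups)


def scaled_pathways(n_genes: int, n_pathways: int = 20, genes_per_pathway: int = 25,
                    overlap: int = 5) -> PathwayCollection:
    """Like :func:`synthetic_pathways` but shrunk to fit a small gene universe.

    Pathway sizes are reduced first, then the pathway count, until the
    collection fits ``n_genes``; at desk scale and above this returns the
    default 20 × 25 collection unchanged.
    """
    while (n_pathways - 1) * (genes_per_pathway - overlap) + genes_per_pathway > n_genes:
        if genes_per_pathway > 6:
            genes_per_pathway -= 1
            overlap = max(1, genes_per_pathway // 5)
        elif n_pathways > 3:
            n_pathways -= 1
        else:
            raise ValueError(f"gene universe of {n_genes} is too small for any "
                             "synthetic pathway collection")
    return synthetic_pathways(n_pathways, genes_per_pathway, overlap, n_genes)


@dataclass
class SyntheticSpec:
    """Study conditions for the paired toy cohorts.

    n_samples : cohort sizes, default (300, 200)
    n_genes : gene universe size; 2,000 is the desk-scale default (the
        full-scale regime of ~10,000 genes is available by config)
    true_pathways : per-cohort predictive pathways, default ({P1, P2} and
        {P1, P3}) — two each, one shared
    event_probability : P(C_i = 1), default 0.7
    correlation_model : 'independent', 'block' (equicorrelation ρ within a
        gene's first pathway, default) or 'factor' (shared low-rank factors)
    rho : within-pathway correlation for the block model, default 0.5
    n_factors : rank of the factor model
    censor_shrink : exponent multiplier for the censored-time reduction
        time ← time·U^(shrink·q_i); q_i is the fraction of patients with a
        strictly higher hazard score, so low-risk censored patients are
        shrunk hardest
    mean, cov : optional user-supplied moments (per cohort or shared) that
        replace the parametric correlation model
    """

    n_samples: tuple[int, int] = (300, 200)
    n_genes: int = 2000
    pathways: PathwayCollection | None = None
    true_pathways: tuple[tuple[str, ...], tuple[str, ...]] = (("P1", "P2"), ("P1", "P3"))
    event_probability: float = 0.7
    correlation_model: str = "block"
    rho: float = 0.5
    n_factors: int = 10
    censor_shrink: float = 1.0
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_probability <= 1.0:
            raise ValueError("event_probability must be in [0, 1]")
        if self.correlation_model not in ("independent", "block", "factor"):
            raise ValueError(f"unknown correlation model {self.correlation_model!r}")
        if self.pathways is None:
            self.pathways = synthetic_pathways(n_genes=self.n_genes)
        names = set(self.pathways.names)
        for cohort in self.true_pathways:
            missing = set(cohort) - names
            if missing:
                raise ValueError(f"true pathways {missing} not in the collection")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _gene_block_index(spec: SyntheticSpec) -> np.ndarray:
    """Gene -> correlation-block id (its first pathway), -1 = independent."""
    block = np.full(spec.n_genes, -1, dtype=int)
    pos = {g: i for i, g in enumerate(spec.gene_ids)}
    for b, (_, genes) in enumerate(spec.pathways.groups.items()):
        for g in genes:
            if g in pos and block[pos[g]] < 0:
                block[pos[g]] = b
    return block


def _draw_cohort(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.cov is not None:
        try:
            chol = np.linalg.cholesky(np.asarray(spec.cov, dtype=float))
        except np.linalg.LinAlgError as e:
            raise ValueError("user-supplied covariance is not positive definite") from e
        z = rng.standard_normal((n, spec.n_genes))
        x = z @ chol.T
        if spec.mean is not None:
            x = x + np.asarray(spec.mean, dtype=float)
        return x
    if spec.correlation_model == "independent":
        return rng.standard_normal((n, spec.n_genes))
    if spec.correlation_model == "factor":
        load = rng.standard_normal((spec.n_genes, spec.n_factors)) / np.sqrt(spec.n_factors)
        f = rng.standard_normal((n, spec.n_factors))
        return (f @ load.T + rng.standard_normal((n, spec.n_genes))) / np.sqrt(2.0)
    # block: x_g = √ρ·z_block + √(1−ρ)·ε, unit variance, within-block corr ρ
    block = _gene_block_index(spec)
    n_blocks = block.max() + 1
    z = rng.standard_normal((n, n_blocks)) if n_blocks > 0 else np.zeros((n, 0))
    eps = rng.standard_normal((n, spec.n_genes))
    x = eps.copy()
    in_block = block >= 0
    x[:, in_block] = (np.sqrt(spec.rho) * z[:, block[in_block]]
                      + np.sqrt(1.0 - spec.rho) * eps[:, in_block])
    return x


def generate_expression(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two cohorts' expression matrices (not yet standardized)."""
    rng = np.random.default_rng(spec.seed)
    x1 = _draw_cohort(spec, spec.n_samples[0], rng)
    x2 = _draw_cohort(spec, spec.n_samples[1], rng)
    return x1, x2


def _pc1(columns: np.ndarray) -> np.ndarray:
    """Unit-norm first principal component loadings, largest-|entry| positive."""
    centered = columns - columns.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def true_beta(
    spec: SyntheticSpec,
    expr1: np.ndarray,
    expr2: np.ndarray,
) -> tuple[CoefficientVector, CoefficientVector]:
    """Per-cohort ground-truth gene-space coefficients.

    For each true pathway, the loadings are the first principal component of
    that pathway's gene columns over the pooled cohorts (so the shared
    pathway gets identical loadings in both cohorts); all other genes are
    exactly zero.  Genes in two true pathways sum their loadings.
    """
    pooled = np.vstack([expr1, expr2])
    pos = {g: i for i, g in enumerate(spec.gene_ids)}
    betas = []
    for cohort_truth in spec.true_pathways:
        beta = np.zeros(spec.n_genes)
        for name in cohort_truth:
            genes = spec.pathways[name]
            if len(genes) < 2:
                raise ValueError(f"true pathway {name!r} has fewer than 2 genes")
            idx = np.asarray([pos[g] for g in genes])
            beta[idx] += _pc1(pooled[:, idx])
        betas.append(CoefficientVector(beta, space="gene"))
    return betas[0], betas[1]


def generate_survival(
    expression: np.ndarray,
    beta: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (time, event) from hazard scores x_i·β.

    Events are i.i.d. Bernoulli(event_probability).  The base time is the
    rank-preserving positive transform exp(−score/scale) of the negated
    score (only the ordering matters to a Cox model), so higher scores die
    earlier.  Censored subjects then have their time multiplied by
    U^(shrink·q_i) with U ~ Uniform(0,1) and q_i the fraction of patients
    with a strictly higher score: the recorded censoring time drops below
    the latent death time, and low-risk patients are reduced the most.
    """
    score = expression @ np.asarray(beta, dtype=float)
    n = len(score)
    scale = score.std() or 1.0
    base_time = np.exp(-score / scale)
    event = (rng.random(n) < spec.event_probability).astype(int)
    q = (score[None, :] > score[:, None]).mean(axis=1)
    u = rng.random(n)
    time = base_time.copy()
    censored = event == 0
    time[censored] *= u[censored] ** (spec.censor_shrink * q[censored])
    return time, event


def generate_pair(
    spec: SyntheticSpec | None = None,
) -> tuple[SurvivalDataset, SurvivalDataset, tuple[CoefficientVector, CoefficientVector], dict]:
    """Generate the full paired study: two datasets, true βs, and truth labels."""
    spec = spec or SyntheticSpec()
    x1, x2 = generate_expression(spec)
    b1, b2 = true_beta(spec, x1, x2)
    rng = np.random.default_rng(spec.seed + 1)
    t1, e1 = generate_survival(x1, b1.values, spec, rng)
    t2, e2 = generate_survival(x2, b2.values, spec, rng)
    genes = spec.gene_ids
    ds1 = SurvivalDataset(x1, genes, t1, e1, [f"T1-S{i:04d}" for i in range(spec.n_samples[0])])
    ds2 = SurvivalDataset(x2, genes, t2, e2, [f"T2-S{i:04d}" for i in range(spec.n_samples[1])])
    shared = sorted(set(spec.true_pathways[0]) & set(spec.true_pathways[1]))
    truth = {
        "true_pathways": [list(c) for c in spec.true_pathways],
        "shared_pathways": shared,
        "seed": spec.seed,
        "n_samples": list(spec.n_samples),
        "n_genes": spec.n_genes,
        "event_probability": spec.event_probability,
        "correlation_model": spec.correlation_model,
    }
    return ds1, ds2, (b1, b2), truth


def write_pair(outdir, spec: SyntheticSpec | None = None) -> list[str]:
    """Write a generated pair as delimited text + a ground-truth JSON sidecar."""
    import pandas as pd
    from pathlib import Path

    spec = spec or SyntheticSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds1, ds2, (b1, b2), truth = generate_pair(spec)
    paths = []
    for tag, ds in (("T1", ds1), ("T2", ds2)):
        ep = outdir / f"{tag}_expression.tsv"
        pd.DataFrame(ds.expression, index=ds.sample_ids, columns=ds.gene_ids)\
            .rename_axis("sample").to_csv(ep, sep="\t")
        cp = outdir / f"{tag}_clinical.tsv"
        pd.DataFrame({"sample": ds.sample_ids, "time": ds.time, "event": ds.event})\
            .to_csv(cp, sep="\t", index=False)
        paths += [str(ep), str(cp)]
    truth_out = dict(truth)
    truth_out["true_beta"] = {"T1": b1.values.tolist(), "T2": b2.values.tolist()}
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(truth_out))
    paths.append(str(tp))
    return paths
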