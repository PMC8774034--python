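"""Planted low-rank synthetic datasets for end-to-end testing.

The generator plants community structure: a subset of rows and columns is
assigned to one of ``latent_rank`` communities (one-hot factor plus Gaussian
spread; inactive entities get spread only), with the active fraction sized
so that the aligned-community mass slightly exceeds the requested density.
The factor product is squashed through a logistic into ground-truth
probabilities, thresholded at the quantile that hits the density exactly,
and optionally corrupted by symmetric label flips. Curated side information
is derived from the same latent factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .errors import DataError
from .types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = ["SyntheticSpec", "SyntheticDataset", "simulate_dataset", "planted_benchmark"]

# Gaussian spread around the one-hot community centers of the latent factors;
# smaller values plant sharper block structure.
LATENT_SPREAD = 0.4

# aligned-community mass relative to the target density; values just above 1
# leave few near-threshold negatives, keeping the planted structure recoverable
ACTIVE_SLACK = 1.05


@dataclass(frozen=True)
class SyntheticSpec:
    m: int = 200
    n: int = 150
    latent_rank: int = 3
    density: float = 0.027
    noise: float = 0.0
    curated_coverage: float = 0.0
    dag_coverage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.m, self.n):
            raise DataError("latent rank exceeds matrix dimensions")
        if not (0.0 < self.density < 1.0):
            raise DataError("density must lie in (0, 1)")
        if self.density * self.m * self.n < 5:
            raise DataError("density too low: fewer than 5 expected positives")
        if not (0.0 <= self.noise < 1.0):
            raise DataError("noise must lie in [0, 1)")
        for name in ("curated_coverage", "dag_coverage"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise DataError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    associations: AssociationMatrix
    truth: np.ndarray  # ground-truth probabilities, pre-noise
    mirna_functional: SimilarityMatrix | None
    disease_dag: DiseaseDAG | None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    m, n, r = spec.m, spec.n, spec.latent_rank
    U = LATENT_SPREAD * rng.standard_normal((m, r))
    V = LATENT_SPREAD * rng.standard_normal((n, r))
    # active fraction sized so aligned-community mass ~ ACTIVE_SLACK * density
    rho = min(1.0, float(np.sqrt(ACTIVE_SLACK * spec.density * r)))
    active_rows = rng.choice(m, round(rho * m), replace=False)
    active_cols = rng.choice(n, round(rho * n), replace=False)
    U[active_rows] += np.eye(r)[rng.integers(0, r, size=len(active_rows))]
    V[active_cols] += np.eye(r)[rng.integers(0, r, size=len(active_cols))]
    raw = U @ V.T
    standardized = (raw - raw.mean()) / raw.std()
    truth = _logistic(standardized)

    n_pos = int(round(spec.density * m * n))
    order = np.argsort(truth.ravel(), kind="stable")
    Y = np.zeros(m * n)
    Y[order[-n_pos:]] = 1.0
    Y = Y.reshape(m, n)

    if spec.noise > 0:
        k = int(round(spec.noise * n_pos))
        ones = np.flatnonzero(Y.ravel() == 1)
        zeros = np.flatnonzero(Y.ravel() == 0)
        flip_off = rng.choice(ones, size=min(k, len(ones)), replace=False)
        flip_on = rng.choice(zeros, size=min(k, len(zeros)), replace=False)
        flat = Y.ravel()
        flat[flip_off] = 0.0
        flat[flip_on] = 1.0
        Y = flat.reshape(m, n)

    width_m = len(str(m - 1))
    width_n = len(str(n - 1))
    mirna_ids = [f"mir-{i:0{width_m}d}" for i in range(m)]
    disease_ids = [f"dis-{j:0{width_n}d}" for j in range(n)]
    assoc = AssociationMatrix(Y, mirna_ids, disease_ids)

    curated = None
    n_cov = int(round(spec.curated_coverage * m))
    if n_cov >= 2:
        chosen = np.sort(rng.choice(m, size=n_cov, replace=False))
        Uc = U[chosen]
        norms = np.linalg.norm(Uc, axis=1, keepdims=True)
        cosine = (Uc / norms) @ (Uc / norms).T
        values = np.clip((cosine + 1.0) / 2.0, 0.0, 1.0)
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
        curated = SimilarityMatrix(values, [mirna_ids[i] for i in chosen])

    dag = None
    n_dag = int(round(spec.dag_coverage * n))
    if n_dag >= 1:
        dag = _random_dag(rng, [disease_ids[j] for j in np.sort(rng.choice(n, n_dag, replace=False))])

    return SyntheticDataset(assoc, truth, curated, dag)


def _random_dag(rng: np.random.Generator, diseases: list[str]) -> DiseaseDAG:
    """Forest plus sparse cross links; edges only point to lower indices,
    which guarantees acyclicity by construction."""
    n_internal = max(3, len(diseases) // 2)
    terms = [f"term-{t:03d}" for t in range(n_internal)]
    edges: set[tuple[str, str]] = set()
    for t in range(1, n_internal):
        parent = int(rng.integers(0, t))
        edges.add((terms[t], terms[parent]))
        if t > 1 and rng.random() < 0.3:  # extra cross edge
            extra = int(rng.integers(0, t))
            if extra != parent:
                edges.add((terms[t], terms[extra]))
    nodes = list(terms)
    roots: dict[str, str] = {}
    for k, disease in enumerate(diseases):
        leaf = f"leaf-{k:03d}"
        nodes.append(leaf)
        edges.add((leaf, terms[int(rng.integers(0, n_internal))]))
        roots[disease] = leaf
    return DiseaseDAG(nodes, edges, roots)


def planted_benchmark(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write one simulated dataset to disk in the package's TSV dialects.

    The edge list only names entities with at least one association, so the
    curated similarity and DAG membership tables are restricted to those
    entities to keep the file set mutually consistent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(spec)
    Y = data.associations
    live_m = {Y.mirna_ids[i] for i in np.nonzero(Y.values.any(axis=1))[0]}
    live_n = {Y.disease_ids[j] for j in np.nonzero(Y.values.any(axis=0))[0]}
    paths = {"associations": outdir / "associations.tsv"}
    gio.write_association_edges(paths["associations"], Y)
    if data.mirna_functional is not None:
        curated = data.mirna_functional
        keep = [k for k, name in enumerate(curated.ids) if name in live_m]
        if len(keep) >= 2:
            sub = SimilarityMatrix(
                curated.values[np.ix_(keep, keep)], [curated.ids[k] for k in keep]
            )
            paths["mirna_similarity"] = outdir / "mirna_similarity.tsv"
            gio.write_similarity_tsv(paths["mirna_similarity"], sub)
    if data.disease_dag is not None:
        dag = data.disease_dag
        roots = {d: node for d, node in dag.disease_roots.items() if d in live_n}
        if roots:
            sub_dag = DiseaseDAG(list(dag.nodes), set(dag.parent_edges), roots)
            paths["dag_edges"] = outdir / "dag_edges.tsv"
            paths["dag_membership"] = outdir / "dag_membership.tsv"
            gio.write_dag(paths["dag_edges"], paths["dag_membership"], sub_dag)
    return paths
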