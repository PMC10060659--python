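"""Taxonomy-function concordance: Bray-Curtis NMDS and Procrustes/protest.

The question answered here is whether the sample-to-sample structure of
taxonomic composition (species within functional groups) matches the structure
of functional-category composition.  Both tables are ordinated by non-metric
multidimensional scaling on Bray-Curtis dissimilarities, and the two
configurations are compared by symmetric Procrustes superimposition; the
residual sum of squares M^2 (0 = identical shapes) is tested by the protest
permutation scheme (row-permuting one configuration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .abundance import BROAD, SPECIALIZED, AbundanceTable, GeneCatalog, aggregate, top_features

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "ProcrustesResult",
    "bray_curtis",
    "nmds",
    "procrustes_protest",
    "concordance_pipeline",
]


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity:
    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1]."""
    X = table.data.values
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero = table.data.index[X.sum(axis=1) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.data.index, columns=table.data.index)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame     # samples x k, column-centered
    stress: float            # Kruskal stress-1
    converged: bool
    restarts_used: int


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS (SMACOF with monotone regression) on a dissimilarity
    matrix; the best of ``restarts`` random initializations is returned and the
    reported stress is Kruskal stress-1."""
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples for a {k}-D ordination")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        random_state=None if seed is None else int(seed) & 0x7FFFFFFF,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(d.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    converged = model.n_iter_ < max_iter
    if not converged:
        logger.warning("nmds: no restart converged within %d iterations", max_iter)
    return OrdinationResult(
        coords=pd.DataFrame(coords, index=d.index, columns=[f"NMDS{i+1}" for i in range(k)]),
        stress=float(model.stress_),
        converged=bool(converged),
        restarts_used=restarts,
    )


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float       # sqrt(1 - m2)
    p_value: float
    permutations: int
    seed: int | None


def _unit_configuration(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(X)
    if norm == 0:
        raise ValueError("degenerate configuration: all points identical")
    return X / norm


def _procrustes_m2(Xu: np.ndarray, Yu: np.ndarray) -> float:
    # symmetric Procrustes: both configurations centered and unit-scaled,
    # optimal rotation from the SVD of X^T Y; m2 = 1 - (sum singular values)^2
    sv = np.linalg.svd(Xu.T @ Yu, compute_uv=False)
    return float(max(0.0, 1.0 - sv.sum() ** 2))


def procrustes_protest(
    X: OrdinationResult | pd.DataFrame,
    Y: OrdinationResult | pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes M^2 with the protest permutation test.

    The null distribution row-permutes the second configuration;
    p = (1 + #{m2_perm <= m2_obs}) / (permutations + 1).
    """
    Xc = X.coords if isinstance(X, OrdinationResult) else X
    Yc = Y.coords if isinstance(Y, OrdinationResult) else Y
    if list(Xc.index) != list(Yc.index):
        raise ValueError("configurations must share identical sample row order")
    if Xc.shape[1] != Yc.shape[1]:
        raise ValueError("configurations must share dimensionality")
    Xu = _unit_configuration(Xc.values.astype(float))
    Yu = _unit_configuration(Yc.values.astype(float))
    m2_obs = _procrustes_m2(Xu, Yu)
    rng = np.random.default_rng(seed)
    n = Xu.shape[0]
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if _procrustes_m2(Xu, Yu[perm]) <= m2_obs:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return ProcrustesResult(
        m2=m2_obs,
        correlation=float(np.sqrt(max(0.0, 1.0 - m2_obs))),
        p_value=float(p),
        permutations=permutations,
        seed=seed,
    )


def concordance_pipeline(
    gene_table: AbundanceTable,
    catalog: GeneCatalog,
    func_classes: tuple[str, ...] = (BROAD, SPECIALIZED),
    top_species: int = 20,
    functional_level: str = "gene",
    k: int = 2,
    restarts: int = 20,
    permutations: int = 999,
    seed: int | None = None,
) -> dict[str, ProcrustesResult]:
    """Per functional class: ordinate species-within-functional-groups
    composition against functional composition, then protest them.

    The functional side is the abundance profile of the class's functional
    genes (``functional_level="gene"``, the study's "metabolic functions"
    table); ``"category"`` instead uses per-category totals — note that when
    functional totals are conserved across treatments the category profile
    carries no treatment signal, only replicate noise.  Species tables are
    restricted to the ``top_species`` most abundant species within the class;
    both tables enter the ordination as relative abundance.
    """
    if functional_level not in ("gene", "category"):
        raise ValueError(f"unknown functional_level: {functional_level!r}")
    results: dict[str, ProcrustesResult] = {}
    for fc in func_classes:
        species_tab = aggregate(gene_table, catalog, by="species", func_class=fc)
        ks = min(top_species, len(species_tab.features))
        species_tab, coverage = top_features(species_tab, ks)
        logger.info("concordance[%s]: top-%d species cover %.1f%% of abundance",
                    fc, ks, 100 * coverage)
        if functional_level == "gene":
            in_class = set(catalog.frame.index[catalog.frame["func_class"] == fc])
            genes = [g for g in gene_table.features if g in in_class]
            if not genes:
                raise ValueError(f"no genes in func_class {fc!r}")
            func_tab = AbundanceTable(gene_table.data[genes].copy(), "gene",
                                      gene_table.unit)
        else:
            func_tab = aggregate(gene_table, catalog, by="category", func_class=fc)
        d_sp = bray_curtis(species_tab.relative())
        d_cat = bray_curtis(func_tab.relative())
        base = 0 if seed is None else int(seed)
        ord_sp = nmds(d_sp, k=k, restarts=restarts, seed=base + 11)
        ord_cat = nmds(d_cat, k=k, restarts=restarts, seed=base + 23)
        results[fc] = procrustes_protest(ord_sp, ord_cat, permutations=permutations,
                                         seed=base + 37)
    return results
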