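"""Synthetic soil-metagenome community generator.

Emulates the statistical structure of a 2x2 grazing x phosphorus factorial
experiment on grassland soil: two reciprocal dominant species (a
grazing/P-sensitive "A" and a complementary "R") that together hold ~50% of
relative abundance and carry genes in *every* functional category, plus a tail
of noise species.  Treatment shifts move abundance from A to R (delta per
treatment) while — with conservation enabled — per-category functional totals
stay constant in expectation: A and R share an identical category allocation
profile, so whatever A loses in a category R gains.

The generated tables are the ground-truth test bed for every downstream stage
(profiles, ANOVA letters, networks, robustness, concordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .abundance import (
    BROAD,
    SPECIALIZED,
    TREATMENTS,
    AbundanceTable,
    FunctionalCatalogConfig,
    GeneCatalog,
    make_metadata,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticDesign", "GroundTruth", "generate", "ground_truth_check"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the stated synthetic world.

    Defaults reproduce the study's printed facts: 4 treatments x 4 replicates,
    190 species of which the two dominants hold ``dominant_share`` = 50% of
    relative abundance, reciprocal shift strongest under G+P+, top-12 species
    covering >95% of abundance, 15 broad + 4 specialized categories, noise
    species carrying each specialized category with probability 0.2.
    """

    n_noise_species: int = 188
    genes_per_species_broad: int = 2
    genes_per_species_specialized: int = 2
    dominant_share: float = 0.50
    reciprocal_shift: Mapping[str, float] = field(
        default_factory=lambda: {"G-P-": 0.0, "G-P+": 0.04, "G+P-": 0.04, "G+P+": 0.10}
    )
    replicates: int = 4
    sigma: float = 0.1                      # iid per-gene lognormal noise sd (log scale)
    species_sigma: float = 0.02             # per-species replicate fluctuation, shared by a species' genes
    community_sigma: float = 0.05           # residual per-sample factor sd (RPKM is depth-normalized)
    pathway_sigma: float = 0.15             # per-pathway (functional guild) per-sample factor sd
    pathways_per_category: int = 6          # pathways drawn within each category
    pathway_size_decay: float = 0.6         # geometric skew of pathway sizes (KEGG-like heavy tail)
    sensitivity_spread: float = 0.1         # sd of per-species/per-gene deviations from unit sensitivity
    conservation: bool = True
    specialized_carriage: float = 0.2       # fraction of noise species per specialized category
    noise_decay: float = 0.75               # geometric decay of noise-species shares
    noise_tail_rank: int = 30               # decay flattens past this rank (rare-but-present tail)
    noise_concentration: float = 50.0       # Dirichlet concentration scale
    total_abundance: float = 1e5            # per-sample total (RPKM-like scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reciprocal_shift.get("G-P-", None) != 0.0:
            raise ValueError("control treatment G-P- must have delta = 0")
        half = self.dominant_share / 2
        for t, d in self.reciprocal_shift.items():
            if not (0 <= d <= half):
                raise ValueError(f"delta for {t} must lie in [0, dominant_share/2]")
            if not (0 < half - d and half + d < 1):
                raise ValueError(f"delta for {t} pushes a dominant share outside (0, 1)")
        if not 0 < self.dominant_share < 1:
            raise ValueError("dominant_share must be in (0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    species_a: str
    species_r: str
    delta: dict[str, float]
    dominant_share: float
    sigma: float
    conservation: bool
    expected_species_share: pd.DataFrame   # treatments x species
    expected_category_total: pd.DataFrame  # treatments x categories
    seed: int


def _species_names(n_noise: int) -> tuple[str, str, list[str]]:
    a = "Actinobacteria_bacterium_A"
    r = "Rubrobacter_sp_R"
    noise = [f"noise_species_{i:03d}" for i in range(1, n_noise + 1)]
    return a, r, noise


def generate(
    design: SyntheticDesign,
    config: FunctionalCatalogConfig | None = None,
) -> tuple[AbundanceTable, GeneCatalog, pd.DataFrame, GroundTruth]:
    """Generate (gene AbundanceTable, GeneCatalog, metadata, GroundTruth).

    Construction order (each step draws from its own named substream of the
    design seed, so stages are independently regenerable):

    1. species shares per treatment — A = share/2 - delta(t), R = share/2 +
       delta(t); noise species get fixed Dirichlet(geometric decay) shares;
    2. category carriage — dominants carry all categories, noise species all
       broad categories and a random ``specialized_carriage`` subset of each
       specialized one;
    3. per-species category allocation profiles (A and R share one profile
       when ``conservation`` is on) and per-gene weights within a
       species-category block;
    4. expected gene abundance = total x species share x category allocation x
       gene weight, then multiplicative lognormal noise applied last.

    The noise model has four layers, mirroring replicate soil metagenomes:
    a per-pathway, per-sample functional-guild factor (sd ``pathway_sigma``)
    with gene-level sensitivities, which makes genes of one pathway co-occur
    more tightly than genes of different pathways — the modular structure of
    real functional co-occurrence networks; a small residual per-sample
    factor (sd ``community_sigma``; RPKM units are depth-normalized, so no
    strong global factor survives) with species sensitivities 1 + eps_s; a
    per-species, per-sample fluctuation (sd ``species_sigma``) shared by a
    species' genes; and iid per-gene noise (sd ``sigma``).  All four are
    treatment-independent and move relative shares by well under 1%, so
    functional conservation and the null ANOVA behaviour are preserved.
    """
    cfg = config or FunctionalCatalogConfig.default()
    broad_cats = sorted(c for c, k in cfg.category_class.items() if k == BROAD)
    spec_cats = sorted(c for c, k in cfg.category_class.items() if k == SPECIALIZED)
    all_cats = broad_cats + spec_cats

    a_name, r_name, noise_names = _species_names(design.n_noise_species)
    species = [a_name, r_name] + noise_names
    treatments = list(TREATMENTS)
    half = design.dominant_share / 2

    # -- 1. species shares ---------------------------------------------------
    rng_shares = substream(design.seed, "species_shares")
    ranks = np.minimum(np.arange(design.n_noise_species), design.noise_tail_rank)
    decay = design.noise_decay ** ranks
    alpha = design.noise_concentration * decay / decay.sum() * design.n_noise_species
    noise_rel = rng_shares.dirichlet(alpha)  # shares within the noise pool, fixed across treatments
    noise_share = (1 - design.dominant_share) * noise_rel

    share = pd.DataFrame(index=treatments, columns=species, dtype=float)
    for t in treatments:
        d = design.reciprocal_shift[t]
        share.loc[t, a_name] = half - d
        share.loc[t, r_name] = half + d
        share.loc[t, noise_names] = noise_share

    # -- 2. category carriage ------------------------------------------------
    rng_carry = substream(design.seed, "carriage")
    carried: dict[str, list[str]] = {a_name: all_cats, r_name: all_cats}
    spec_carriers: dict[str, list[str]] = {c: [] for c in spec_cats}
    for s in noise_names:
        cats = list(broad_cats)
        for c in spec_cats:
            if rng_carry.random() < design.specialized_carriage:
                cats.append(c)
                spec_carriers[c].append(s)
        carried[s] = cats

    # -- 3. allocation profiles and gene weights ------------------------------
    rng_prof = substream(design.seed, "profiles")
    profiles: dict[str, pd.Series] = {}
    dom_profile = pd.Series(rng_prof.dirichlet(np.full(len(all_cats), 5.0)), index=all_cats)
    if design.conservation:
        profiles[a_name] = dom_profile
        profiles[r_name] = dom_profile.copy()
    else:
        profiles[a_name] = dom_profile
        profiles[r_name] = pd.Series(
            rng_prof.dirichlet(np.full(len(all_cats), 5.0)), index=all_cats
        )
    for s in noise_names:
        cats = carried[s]
        profiles[s] = pd.Series(rng_prof.dirichlet(np.full(len(cats), 5.0)), index=cats)

    rng_genes = substream(design.seed, "genes")
    gene_rows = []
    expected_rel = []  # expected relative abundance per gene, per treatment
    gid = 0
    for s in species:
        for c in carried[s]:
            n_g = (design.genes_per_species_specialized if c in spec_cats
                   else design.genes_per_species_broad)
            w = rng_genes.dirichlet(np.full(n_g, 2.0))
            for j in range(n_g):
                gid += 1
                pw_w = design.pathway_size_decay ** np.arange(design.pathways_per_category)
                pw = int(rng_genes.choice(design.pathways_per_category, p=pw_w / pw_w.sum()))
                gene_rows.append({
                    "gene_id": f"g{gid:06d}",
                    "species": s,
                    "category": c,
                    "pathway": f"ko{all_cats.index(c):02d}{pw:02d}",
                    "length_bp": int(rng_genes.integers(100, 3001)),
                })
                expected_rel.append(share[s].values * profiles[s][c] * w[j])

    catalog_frame = pd.DataFrame(gene_rows).set_index("gene_id")
    catalog_frame["func_class"] = catalog_frame["category"].map(cfg.category_class)
    catalog = GeneCatalog(catalog_frame)

    # treatments x genes expected relative abundance (rows sum to 1 exactly)
    exp_rel = pd.DataFrame(
        np.column_stack(expected_rel), index=treatments, columns=catalog_frame.index
    )
    exp_rel = exp_rel.div(exp_rel.sum(axis=1), axis=0)  # numerical tidy-up

    # -- 4. samples + noise ----------------------------------------------------
    meta = make_metadata(treatments, replicates=design.replicates)
    rng_noise = substream(design.seed, "sampling_noise")
    species_idx = np.asarray([species.index(s) for s in catalog_frame["species"]])
    pathways = sorted(catalog_frame["pathway"].unique())
    pw_idx = np.asarray([pathways.index(p) for p in catalog_frame["pathway"]])
    sens_species = 1.0 + rng_noise.normal(0.0, design.sensitivity_spread, size=len(species))
    sens_gene = 1.0 + rng_noise.normal(0.0, design.sensitivity_spread, size=len(catalog_frame))
    rows = []
    for sid in meta.index:
        t = meta.loc[sid, "treatment"]
        log_noise = np.zeros(exp_rel.shape[1])
        if design.community_sigma > 0:
            u = rng_noise.normal(0.0, design.community_sigma)
            log_noise += sens_species[species_idx] * u
        if design.pathway_sigma > 0:
            v = rng_noise.normal(0.0, design.pathway_sigma, size=len(pathways))
            log_noise += sens_gene * v[pw_idx]
        if design.species_sigma > 0:
            fluct = rng_noise.normal(0.0, design.species_sigma, size=len(species))
            log_noise += fluct[species_idx]
        if design.sigma > 0:
            log_noise += rng_noise.normal(0.0, design.sigma, size=log_noise.shape)
        rows.append(design.total_abundance * exp_rel.loc[t].values * np.exp(log_noise))
    table = AbundanceTable(
        pd.DataFrame(np.vstack(rows), index=meta.index, columns=catalog_frame.index),
        feature_kind="gene", unit="rpkm",
    )

    cat_tot = pd.DataFrame(
        {c: exp_rel.loc[:, catalog_frame.index[catalog_frame["category"] == c]].sum(axis=1)
         for c in all_cats}
    ) * design.total_abundance
    truth = GroundTruth(
        species_a=a_name, species_r=r_name,
        delta=dict(design.reciprocal_shift),
        dominant_share=design.dominant_share,
        sigma=design.sigma, conservation=design.conservation,
        expected_species_share=share,
        expected_category_total=cat_tot,
        seed=design.seed,
    )
    n_spec_genes = int((catalog_frame["func_class"] == SPECIALIZED).sum())
    logger.info("generated %d genes (%d specialized) across %d species, %d samples",
                len(catalog_frame), n_spec_genes, len(species), len(meta))
    return table, catalog, meta, truth


def ground_truth_check(
    recovered_delta: Mapping[str, float],
    truth: GroundTruth,
    anova_pvalues: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Compare downstream estimates against the planted ground truth.

    Returns per-treatment bias of the recovered reciprocal shift delta, the
    RMSE over treatments, and (if ANOVA p-values are supplied) the realized
    fraction of functional categories with p > alpha.
    """
    missing = set(truth.delta) - set(recovered_delta)
    if missing:
        raise ValueError(f"recovered deltas missing treatment(s): {sorted(missing)}")
    bias = {t: float(recovered_delta[t] - truth.delta[t]) for t in truth.delta}
    rmse = float(np.sqrt(np.mean([b ** 2 for b in bias.values()])))
    report = {"bias": bias, "rmse": rmse}
    if anova_pvalues is not None:
        ps = np.asarray(list(anova_pvalues.values()), dtype=float)
        report["fraction_nonsignificant"] = float(np.mean(ps > alpha))
    return report
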