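"""End-to-end orchestration: simulate/load -> profiles -> treatment stats ->
networks -> robustness -> concordance, with a reproducibility manifest.

One global seed feeds named per-stage substreams, so any stage rerun in
isolation reproduces the values it produced inside the full run.  Every run
writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import base64
import dataclasses
import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .abundance import (
    BROAD,
    SPECIALIZED,
    AbundanceTable,
    FunctionalCatalogConfig,
    classify_functions,
    aggregate,
    load_abundance_tsv,
    load_catalog_tsv,
    load_metadata_tsv,
    top_features,
    write_table_tsv,
)
from .network import (
    build_network,
    correlation_matrix,
    index_panel,
    prevalence_filter,
    rmt_threshold,
    write_edge_list_tsv,
    write_node_attributes_tsv,
)
from .ordination import concordance_pipeline
from .robustness import classify_trend, removal_experiment
from .simulate import SyntheticDesign, generate
from .stats import anova_tukey, reciprocal_shift

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_html"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Either ``design`` (synthetic input) or the three input paths must be set.
    """

    out_dir: str = "redunet_out"
    seed: int = 0
    design: SyntheticDesign | None = field(default_factory=SyntheticDesign)
    abundance_path: str | None = None
    catalog_path: str | None = None
    metadata_path: str | None = None
    # stage parameters
    network_top_genes: int = 300
    scan_step: float = 0.01
    min_prevalence: float = 0.5
    m_max: int = 200
    removal_replicates: int = 100
    permutations: int = 999
    nmds_restarts: int = 20
    k: int = 2
    top_species: int = 20
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"]["reciprocal_shift"] = dict(self.design.reciprocal_shift)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("design") is not None:
            d["design"] = SyntheticDesign(**d["design"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a dict of in-memory stage results.  Identical config + seed
    produce byte-identical outputs (the manifest's timing block aside).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    bundle: dict = {}
    t_all = time.perf_counter()

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return wrap

    # -- input ---------------------------------------------------------------
    @stage("input")
    def _input():
        if config.design is not None:
            design = dataclasses.replace(config.design, seed=config.seed)
            table, catalog, meta, truth = generate(design)
            bundle["truth"] = truth
        else:
            table = load_abundance_tsv(config.abundance_path)
            catalog = load_catalog_tsv(config.catalog_path)
            meta = load_metadata_tsv(config.metadata_path)
            catalog = classify_functions(catalog, FunctionalCatalogConfig.default())
            for key, p in (("abundance", config.abundance_path),
                           ("catalog", config.catalog_path),
                           ("metadata", config.metadata_path)):
                manifest["inputs"][key] = _sha256(Path(p))
        bundle["gene_table"], bundle["catalog"], bundle["metadata"] = table, catalog, meta

    # -- functional profiles + treatment stats --------------------------------
    @stage("profiles_stats")
    def _profiles():
        table, catalog, meta = bundle["gene_table"], bundle["catalog"], bundle["metadata"]
        cat_tab = aggregate(table, catalog, by="category")
        write_table_tsv(cat_tab, out / "category_abundance.tsv")
        tests = anova_tukey(cat_tab, meta, alpha=config.alpha)
        fclass = {r.category: catalog.frame.loc[
            catalog.frame["category"] == r.category, "func_class"].iloc[0] for r in tests}
        rows = []
        for r in tests:
            row = {"category": r.category, "func_class": fclass[r.category],
                   "F": r.F, "p": r.p}
            row.update({f"letter_{t}": l for t, l in sorted(r.letters.items())})
            rows.append(row)
        stats_df = pd.DataFrame(rows).set_index("category").sort_index()
        stats_df.to_csv(out / "category_tests.tsv", sep="\t")
        bundle["category_tests"] = tests

        sp_tab = aggregate(table, catalog, by="species")
        shift = reciprocal_shift(sp_tab, meta)
        _json_dump({
            "decreasing_species": shift.decreasing_species,
            "increasing_species": shift.increasing_species,
            "complementarity": shift.complementarity,
            "dominance": shift.dominance,
            "max_shift_treatment": shift.max_shift_treatment,
            "delta": {t: shift.delta.loc[t].to_dict() for t in shift.delta.index},
        }, out / "reciprocal_shift.json")
        bundle["reciprocal_shift"] = shift

    # -- per-treatment networks ------------------------------------------------
    @stage("networks")
    def _networks():
        table, catalog, meta = bundle["gene_table"], bundle["catalog"], bundle["metadata"]
        top_tab, cov = top_features(table, min(config.network_top_genes,
                                               len(table.features)))
        panels = {}
        networks = {}
        for t in sorted(meta["treatment"].unique()):
            samples = list(meta.index[meta["treatment"] == t])
            if len(samples) < 6:
                logger.warning("networks: treatment %s has %d samples (< 6); "
                               "correlations are fragile", t, len(samples))
            sub = prevalence_filter(top_tab.subset_samples(samples), config.min_prevalence)
            corr = correlation_matrix(sub)
            thr = rmt_threshold(corr, step=config.scan_step)
            net = build_network(corr, thr, treatment=t)
            panel = index_panel(net)
            panels[t] = {"threshold": thr, **panel.as_dict()}
            networks[t] = net
            safe = t.replace("+", "p").replace("-", "m")
            write_edge_list_tsv(net, out / f"network_{safe}_edges.tsv")
            write_node_attributes_tsv(net, catalog, out / f"network_{safe}_nodes.tsv")
        _json_dump(panels, out / "network_index_panels.json")
        bundle["networks"], bundle["index_panels"] = networks, panels

    # -- robustness (specialized-function network, pooled samples) -------------
    @stage("robustness")
    def _robustness():
        table, catalog = bundle["gene_table"], bundle["catalog"]
        spec_genes = catalog.frame.index[catalog.frame["func_class"] == SPECIALIZED]
        spec_tab = AbundanceTable(table.data[list(spec_genes)].copy(), "gene", table.unit)
        spec_tab = prevalence_filter(spec_tab, config.min_prevalence)
        corr = correlation_matrix(spec_tab)
        thr = rmt_threshold(corr, step=config.scan_step)
        net = build_network(corr, thr)
        rng = substream(config.seed, "robustness")
        traj = removal_experiment(net, m_max=config.m_max,
                                  replicates=config.removal_replicates,
                                  seed=int(rng.integers(2 ** 31)))
        trend, fit = classify_trend(traj)
        pd.DataFrame({"removed": traj.removed, "mean_lambda": traj.mean,
                      "sd_lambda": traj.sd}).to_csv(out / "robustness_trajectory.tsv",
                                                    sep="\t", index=False)
        _json_dump({"threshold": thr, "n_nodes": net.n_nodes, "n_links": net.n_links,
                    "trend": trend, "fit_stats": fit}, out / "robustness_fit.json")
        bundle["trajectory"], bundle["trend"] = traj, trend
        bundle["specialized_network"] = net

    # -- concordance -----------------------------------------------------------
    @stage("concordance")
    def _concordance():
        table, catalog = bundle["gene_table"], bundle["catalog"]
        rng = substream(config.seed, "concordance")
        res = concordance_pipeline(
            table, catalog, top_species=config.top_species, k=config.k,
            restarts=config.nmds_restarts, permutations=config.permutations,
            seed=int(rng.integers(2 ** 31)),
        )
        _json_dump({fc: {"m2": r.m2, "correlation": r.correlation,
                         "p_value": r.p_value, "permutations": r.permutations}
                    for fc, r in res.items()}, out / "concordance.json")
        bundle["concordance"] = res

    t_total = time.perf_counter() - t_all
    manifest["total_seconds"] = round(t_total, 3)
    _json_dump(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    bundle["out_dir"] = str(out)
    return bundle


# ---------------------------------------------------------------------------
# single-file HTML report
# ---------------------------------------------------------------------------

def _traj_png_b64(bundle) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = bundle["trajectory"]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(traj.removed, traj.mean, lw=1.5)
    ax.fill_between(traj.removed, traj.mean - traj.sd, traj.mean + traj.sd, alpha=0.3)
    ax.set_xlabel("nodes removed")
    ax.set_ylabel("natural connectivity")
    ax.set_title(f"invulnerability: trend = {bundle['trend']}")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def report_html(bundle: dict, path=None) -> str:
    """Render the bundle to a single self-contained HTML report.

    Sections with missing stages render a notice instead of failing.
    """
    parts = ["<html><head><meta charset='utf-8'><title>redunet report</title>",
             "<style>body{font-family:sans-serif;margin:2em} table{border-collapse:"
             "collapse} td,th{border:1px solid #999;padding:3px 8px}</style></head><body>",
             "<h1>Functional-redundancy analysis report</h1>"]

    def section(title, render):
        parts.append(f"<h2>{title}</h2>")
        try:
            parts.append(render())
        except KeyError:
            parts.append("<p><em>stage output not available in this bundle</em></p>")

    def _letters():
        rows = []
        for r in bundle["category_tests"]:
            rows.append({"category": r.category, "F": round(r.F, 3), "p": round(r.p, 4),
                         **{t: l for t, l in sorted(r.letters.items())}})
        return pd.DataFrame(rows).to_html(index=False)

    def _traj():
        return f"<img src='data:image/png;base64,{_traj_png_b64(bundle)}'/>"

    def _panels():
        return pd.DataFrame(bundle["index_panels"]).T.to_html()

    def _shift():
        s = bundle["reciprocal_shift"]
        df = s.delta.copy()
        head = (f"<p>decreasing: {s.decreasing_species} | increasing: "
                f"{s.increasing_species} | complementarity: "
                f"{ {t: round(v, 3) for t, v in s.complementarity.items()} } | "
                f"dominance of top-2 species: {s.dominance:.3f}</p>")
        return head + df.round(4).to_html()

    def _concord():
        rows = [{"func_class": fc, "M2": round(r.m2, 4),
                 "correlation": round(r.correlation, 4), "p": r.p_value}
                for fc, r in bundle["concordance"].items()]
        return pd.DataFrame(rows).to_html(index=False)

    section("Functional-category treatment tests (ANOVA + Tukey letters)", _letters)
    section("Network invulnerability (natural connectivity)", _traj)
    section("Network index panels", _panels)
    section("Dominant-species reciprocal shifts", _shift)
    section("Taxonomy-function concordance (Procrustes)", _concord)
    parts.append("</body></html>")
    html = "\n".join(parts)
    if path is not None:
        Path(path).write_text(html)
    return html
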