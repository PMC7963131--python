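"""End-to-end pipeline: synthesize/ingest -> process -> SRV -> scan ->
MWSL -> sentinels -> replication -> downstream, under one configuration,
with a hashed run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .downstream import cox_association, stepwise_bootstrap
from .mwas import (
    MWAS,
    ModelSpec,
    estimate_mwsl,
    mwas_scan,
    replicate_hits,
    select_sentinels,
    transform_outcomes,
)
from .network import export_graph, shortest_path_subnetwork
from .spectra import SpectrumSet
from .srv import SRVParams, merge_superclusters, srv_cluster
from .stocsy import stocsy
from .synthetic import (
    CohortSpec,
    GridSpec,
    generate_cohort,
    generate_reaction_graph,
)
from .templates import default_template_library

log = logging.getLogger("nmrmwas")

STAGES = ("synthesize", "cluster", "scan", "mwsl", "sentinels",
          "replicate", "downstream")


@dataclass
class PipelineConfig:
    """One discovery cohort plus at least one replication cohort."""

    discovery: CohortSpec
    replication: list[CohortSpec]
    assay: str = "standard1d"
    outcome: str = "ln_cac1"
    alpha: float = 0.05
    n_perm: int = 2000
    srv: SRVParams = field(default_factory=SRVParams)
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0
    n_boot: int = 200
    reaction_graph: dict = field(default_factory=lambda: {
        "n_compounds": 40, "edge_density": 0.08})

    def __post_init__(self) -> None:
        if not self.replication:
            raise ValueError("at least one replication cohort is required")
        names = [self.discovery.cohort_name] + [c.cohort_name for c in self.replication]
        if len(set(names)) != len(names):
            raise ValueError("cohort names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = raw.pop("cohorts")
        discovery = [c for c in cohorts if c.pop("role", "replication") == "discovery"]
        if len(discovery) != 1:
            raise ValueError("config must mark exactly one discovery cohort")
        replication = [c for c in cohorts if c is not discovery[0]]
        kw = {}
        if "srv" in raw:
            kw["srv"] = SRVParams(**raw.pop("srv"))
        if "grid" in raw:
            kw["grid"] = GridSpec(**raw.pop("grid"))
        return cls(
            discovery=CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in discovery[0].items()}),
            replication=[CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in c.items()}) for c in replication],
            **kw, **raw,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write results plus a manifest to ``out_dir``.

    Reruns with the same configuration and seeds reproduce all outputs
    bit-identically.  A stage failure aborts with the stage name; outputs
    of earlier stages are kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, "seed": config.seed,
                "stages": {}, "outputs": {}}
    templates = default_template_library()
    current = "synthesize"
    try:
        # ---- synthesize ------------------------------------------------
        spectra, pheno, truth = generate_cohort(
            config.discovery, templates, config.assay, config.grid)
        rep_sets = []
        for spec in config.replication:
            rep_sets.append(generate_cohort(spec, templates, config.assay,
                                            config.grid))
        spectra.to_tsv(out / "discovery_spectra.tsv")
        pheno.to_csv(out / "discovery_phenotypes.tsv", sep="\t", index=False)
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        summary = summarize_phenotypes(
            pd.concat([pheno] + [p for _, p, _ in rep_sets], ignore_index=True))
        summary.to_csv(out / "phenotype_summary.tsv", sep="\t")
        manifest["stages"][current] = {
            "n_discovery": spectra.n_samples,
            "n_replication": [s.n_samples for s, _, _ in rep_sets],
            "n_features": spectra.n_features,
        }

        # ---- SRV clustering --------------------------------------------
        current = "cluster"
        cmap = merge_superclusters(srv_cluster(spectra, config.srv),
                                   spectra, config.srv)
        cmap.to_tsv(out / "clusters.tsv", spectra.ppm)
        manifest["stages"][current] = {"n_clusters": cmap.n_clusters}

        # ---- discovery scan --------------------------------------------
        current = "scan"
        model1 = ModelSpec.model1(config.outcome)
        disc_model = MWAS(spectra, pheno, model1)
        disc = disc_model.fit()
        disc.to_tsv(out / "discovery_scan.tsv")
        manifest["stages"][current] = {"n_used": disc.n_used}

        # ---- MWSL ------------------------------------------------------
        current = "mwsl"
        mwsl = disc_model.estimate_mwsl(config.alpha, config.n_perm,
                                        seed=config.seed)
        pd.DataFrame({"min_p": mwsl.permutation_min_p}).to_csv(
            out / "mwsl_min_p.tsv", sep="\t", index=False)
        manifest["stages"][current] = {
            "alpha": mwsl.alpha, "n_perm": mwsl.n_perm, "k": mwsl.k,
            "alpha_prime": mwsl.alpha_prime, "ent": mwsl.ent}

        # ---- sentinels -------------------------------------------------
        current = "sentinels"
        cmap = select_sentinels(disc, cmap)
        cmap.to_tsv(out / "clusters_with_sentinels.tsv", spectra.ppm)
        manifest["stages"][current] = {
            "n_sentinels": sum(c.sentinel_feature is not None
                               for c in cmap.clusters)}

        # ---- replication -----------------------------------------------
        current = "replicate"
        rep_spectra = rep_sets[0][0]
        rep_pheno = pd.concat([p for _, p, _ in rep_sets], ignore_index=True)
        if len(rep_sets) > 1:
            inten = np.vstack([s.intensities for s, _, _ in rep_sets])
            rep_spectra = SpectrumSet(
                inten, spectra.ppm, config.assay,
                [sid for s, _, _ in rep_sets for sid in s.sample_ids],
                [c for s, _, _ in rep_sets for c in s.cohort],
                [ph for s, _, _ in rep_sets for ph in s.phase])
        rep_model = ModelSpec.model1(config.outcome,
                                     pooled=len(rep_sets) > 1)
        rep = mwas_scan(rep_spectra, rep_pheno, rep_model)
        repl = replicate_hits(disc, rep, mwsl)
        repl.to_csv(out / "replication.tsv", sep="\t", index=False)
        manifest["stages"][current] = {
            "n_discovery_hits": len(repl),
            "n_replicated": int(repl["replicated"].sum())}

        # ---- downstream ------------------------------------------------
        current = "downstream"
        down: dict = {}
        sentinels = [c.sentinel_feature for c in cmap.clusters
                     if c.sentinel_feature is not None]
        sig_sent = [s for s in sentinels
                    if disc.table.loc[s, "p_value"] < mwsl.alpha_prime]
        pooled_pheno = pd.concat(
            [pheno] + [p for _, p, _ in rep_sets], ignore_index=True)
        pooled_inten = np.vstack([spectra.intensities]
                                 + [s.intensities for s, _, _ in rep_sets])
        if len(sig_sent) >= 2:
            met = pd.DataFrame(
                pooled_inten[:, sig_sent],
                columns=[f"feat_{s}" for s in sig_sent])
            step = stepwise_bootstrap(
                pooled_pheno, met, config.outcome,
                ModelSpec.model2(config.outcome, pooled=True).covariates,
                n_boot=config.n_boot, seed=config.seed)
            step.to_csv(out / "stepwise_bootstrap.tsv", sep="\t", index=False)
            down["stepwise_candidates"] = len(sig_sent)
            top = sig_sent[0]
            cox = cox_association(
                pooled_pheno, pooled_inten[:, top],
                ModelSpec.model2(config.outcome, pooled=True).covariates)
            down["cox_top_sentinel"] = {
                "hazard_ratio": cox.hazard_ratio, "p": cox.p_value,
                "ph_test_p": cox.ph_test_p, "n_events": cox.n_events}
            trace = stocsy(spectra, float(spectra.ppm[top]))
            trace.to_tsv(out / "stocsy_top_sentinel.tsv")
        # reaction network over hit templates
        hit_blocks = []
        for _, row in truth.iterrows():
            blocks = [tuple(map(int, b.split("-")))
                      for b in row["feature_blocks"].split(";")]
            if any(disc.table.loc[lo:hi, "p_value"].min() < mwsl.alpha_prime
                   for lo, hi in blocks) and row["kegg_id"]:
                direction = "direct" if disc.table.loc[
                    blocks[0][0]:blocks[0][1], "beta_per_sd"].mean() > 0 else "inverse"
                hit_blocks.append((row["kegg_id"], direction))
        graph = generate_reaction_graph(seed=config.seed,
                                        **config.reaction_graph)
        # graft hit compounds into the toy graph so paths exist
        labels = sorted(graph.nodes)
        rng = np.random.default_rng(config.seed)
        for kegg, _ in hit_blocks:
            if kegg not in graph:
                graph.add_edge(kegg, labels[int(rng.integers(len(labels)))])
        if len(hit_blocks) >= 2:
            net = shortest_path_subnetwork(
                graph, [k for k, _ in hit_blocks], dict(hit_blocks))
            export_graph(net, out / "metabonetwork.graphml", "graphml")
            export_graph(net, out / "metabonetwork.dot", "dot")
            down["subnetwork"] = net.summary()
        manifest["stages"][current] = down
    except Exception as err:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    manifest["completed_stages"] = list(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    log.info("pipeline complete: %d stages, outputs in %s",
             len(manifest["stages"]), out)
    return out


def summarize_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort and pooled descriptive table.

    Continuous variables as mean (SD); binaries as n (%), including the
    CAC>0 percentage.
    """
    if pheno.empty:
        raise ValueError("empty phenotype table")
    continuous = [c for c in ("age", "cac_agatston", "imt_mm", "ldl", "hdl",
                              "sbp") if c in pheno.columns]
    binary = [c for c in ("diabetes", "lipid_treatment", "bp_treatment",
                          "event_status") if c in pheno.columns]

    def col_summary(df: pd.DataFrame) -> dict:
        row = {"N": len(df)}
        for c in continuous:
            row[c] = f"{df[c].mean():.1f} ({df[c].std():.1f})"
        if "cac_agatston" in df:
            npos = int((df["cac_agatston"] > 0).sum())
            row["cac_positive"] = f"{npos} ({100 * npos / len(df):.1f})"
        if "sex" in df:
            nm = int((df["sex"] == "M").sum())
            row["male"] = f"{nm} ({100 * nm / len(df):.1f})"
        for c in binary:
            nb = int(df[c].sum())
            row[c] = f"{nb} ({100 * nb / len(df):.1f})"
        return row

    cohorts = (pheno.groupby("cohort") if "cohort" in pheno.columns
               else [("all", pheno)])
    rows = {name: col_summary(df) for name, df in cohorts}
    rows["pooled"] = col_summary(pheno)
    return pd.DataFrame(rows)


def pooled_positive_share(counts: dict[str, tuple[int, int]]) -> float:
    """Pooled percentage of positives from per-cohort (positives, N)."""
    pos = sum(p for p, _ in counts.values())
    total = sum(n for _, n in counts.values())
    if total == 0:
        raise ValueError("no individuals")
    return 100.0 * pos / total
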