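"""End-to-end orchestration: simulate/ingest -> diversity -> ICC ->
classify -> differential -> networks -> ML, from one configuration.

Every stage writes TSV/JSON artifacts into a run directory and records a
SHA-256 digest per file in the run manifest; with a fixed master seed the
deterministic stages reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import differential as da
from . import diversity as dv
from . import ml as mlmod
from . import networks as net
from . import response as resp
from . import simulate as sim
from . import stability as st
from .profiles import AbundanceTable

log = logging.getLogger("microresist")

SIM_KEYS = set(sim.SimulationConfig.__dataclass_fields__)
STAGE_KEYS = {"seed", "outdir", "control", "intervention", "icc", "ml", "network",
              "differential"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: str = ""
    finished: str = ""
    version: str = __version__
    files: dict = field(default_factory=dict)

    def add(self, name: str, path: str) -> None:
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        self.files[name] = {"path": os.path.relpath(path), "sha256": digest}

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - STAGE_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for block in ("control", "intervention"):
        extra = set(cfg.get(block, {})) - SIM_KEYS
        if extra:
            raise ValueError(f"unknown keys in {block!r} block: {sorted(extra)}")
    return cfg


def _sim_config(block: dict, seed: int, **overrides) -> sim.SimulationConfig:
    params = dict(block or {})
    params.setdefault("seed", seed)
    for key, val in overrides.items():
        params.setdefault(key, val)
    if "timepoints" in params:
        params["timepoints"] = tuple(params["timepoints"])
    return sim.SimulationConfig(**params)


def _seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master).spawn(n)]


# ---------------------------------------------------------------------------
# stability pipeline
# ---------------------------------------------------------------------------

def run_stability_analysis(config: dict, outdir: str | None = None) -> RunManifest:
    """Per-cohort diversity and per-species ICCs with stability calls.

    Computes the three alpha indexes and the top-5 PCoA axes of
    Bray–Curtis (plus UniFrac when a tree is present), estimates their
    ICC across the first two visits of every subject, then the
    per-species ICC profile and the cross-cohort comparison table.
    """
    outdir = outdir or config.get("outdir", "run_stability")
    os.makedirs(outdir, exist_ok=True)
    master = int(config.get("seed", 0))
    s_ctl, s_int, s_icc = _seeds(master, 3)
    manifest = RunManifest(config, master, started=_now())

    icc_cfg = config.get("icc", {})
    n_boot = int(icc_cfg.get("n_boot", 1000))
    cohorts = {
        "control": sim.simulate_control_cohort(
            _sim_config(config.get("control"), s_ctl)),
        "intervention": sim.simulate_intervention_cohort(
            _sim_config(config.get("intervention"), s_int, timepoints=(0, 28))),
    }
    rng = np.random.default_rng(s_icc)
    icc_sets: dict[str, pd.Series] = {}
    for name, study in cohorts.items():
        if len(study.metadata.subjects) < 2:
            raise ValueError(f"cohort {name!r} has fewer than 2 subjects")
        rel = study.relative()
        log.info("cohort %s: %d features x %d samples", name, rel.n_features,
                 rel.n_samples)
        div_rows = []
        for index in dv.ALPHA_INDICES:
            table = study.counts if index == "chao1" else rel
            series = dv.alpha_diversity(table, index)
            r = st.diversity_icc(series, study.metadata, n_boot=n_boot,
                                 seed=int(rng.integers(2 ** 31)), target=index)
            div_rows.append(r)
        pco = dv.pcoa(dv.bray_curtis(rel), n_axes=5)
        for axis in pco.coordinates.columns:
            r = st.diversity_icc(pco.coordinates[axis], study.metadata,
                                 n_boot=n_boot, seed=int(rng.integers(2 ** 31)),
                                 target=f"braycurtis_{axis}")
            div_rows.append(r)
        div_table = st.icc_table(div_rows)
        path = os.path.join(outdir, f"icc_diversity_{name}.tsv")
        div_table.to_csv(path, sep="\t", index=False)
        manifest.add(f"icc_diversity_{name}", path)

        feats = st.feature_icc_profile(rel, study.metadata, n_boot=n_boot,
                                       seed=int(rng.integers(2 ** 31)))
        feat_table = st.icc_table(feats)
        path = os.path.join(outdir, f"icc_species_{name}.tsv")
        feat_table.to_csv(path, sep="\t", index=False)
        manifest.add(f"icc_species_{name}", path)
        icc_sets[name] = feat_table.set_index("target")["icc"]

    comparison = st.compare_icc_groups(icc_sets, paired=False)
    path = os.path.join(outdir, "icc_cohort_comparison.tsv")
    comparison.to_csv(path, sep="\t", index=False)
    manifest.add("icc_cohort_comparison", path)

    manifest.finished = _now()
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest


# ---------------------------------------------------------------------------
# response pipeline
# ---------------------------------------------------------------------------

def run_response_pipeline(config: dict, outdir: str | None = None) -> RunManifest:
    """Fluctuation baseline -> labels -> PERMANOVA/ordinal DA -> links ->
    networks -> ML report."""
    outdir = outdir or config.get("outdir", "run_response")
    os.makedirs(outdir, exist_ok=True)
    master = int(config.get("seed", 0))
    s_ctl, s_int, s_stat, s_net, s_ml = _seeds(master, 5)
    manifest = RunManifest(config, master, started=_now())

    control = sim.simulate_control_cohort(_sim_config(config.get("control"), s_ctl))
    intervention = sim.simulate_intervention_cohort(
        _sim_config(config.get("intervention"), s_int, timepoints=(0, 28)))

    baseline = resp.estimate_daily_fluctuation(control.relative(), control.metadata)
    _write_json(os.path.join(outdir, "fluctuation_baseline.json"), {
        "mean": baseline.mean, "sd": baseline.sd, "cutoff1": baseline.cutoff1,
        "cutoff2": baseline.cutoff2, "n_pairs": baseline.n_pairs,
        "max_gap_days": baseline.max_gap_days,
    })
    manifest.add("fluctuation_baseline", os.path.join(outdir, "fluctuation_baseline.json"))

    assessments = resp.assess_cohort(intervention.relative(), intervention.metadata,
                                     baseline)
    path = os.path.join(outdir, "response_assessments.tsv")
    assessments.to_csv(path, sep="\t", index=False)
    manifest.add("response_assessments", path)
    log.info("labels: %s", assessments["label"].value_counts().to_dict())

    # baseline-only analyses
    rel = intervention.relative()
    meta = intervention.metadata.frame
    base_samples = meta.loc[meta["phase"] == "baseline"]
    subj_label = assessments.set_index("subject_id")["label"]
    base_samples = base_samples[base_samples["subject_id"].isin(subj_label.index)]
    sample_labels = pd.Series(
        subj_label.loc[base_samples["subject_id"]].to_numpy(),
        index=base_samples["sample_id"].to_numpy())
    base_rel = rel.subset_samples(list(sample_labels.index))

    # PERMANOVA needs >= 2 samples per group; drop sparse label groups
    group_sizes = sample_labels.value_counts()
    usable = sample_labels[sample_labels.isin(group_sizes[group_sizes >= 2].index)]
    if usable.nunique() >= 2:
        perm = da.permanova(dv.bray_curtis(base_rel.subset_samples(list(usable.index))),
                            usable.to_list(), n_perm=999, seed=s_stat)
    else:
        log.warning("PERMANOVA skipped: fewer than 2 usable groups")
        perm = {"pseudo_F": None, "R2": None, "p": None, "n_perm": 0}
    _write_json(os.path.join(outdir, "permanova.json"), perm)
    manifest.add("permanova", os.path.join(outdir, "permanova.json"))

    q_species = float(config.get("differential", {}).get("q_species",
                                                         da.DEFAULT_Q_SPECIES))
    ordinal = da.ordinal_da(base_rel, sample_labels)
    path = os.path.join(outdir, "ordinal_species.tsv")
    ordinal.to_csv(path, sep="\t", index=False)
    manifest.add("ordinal_species", path)

    func = sim.simulate_stratified_functions(intervention)
    func_base = func.subset_samples(list(sample_labels.index))
    sig_species = ordinal.loc[ordinal["q"] < q_species, "feature"].tolist()
    links = da.links_table(da.link_contributions(
        func_base, sig_species, sorted(intervention.contribution_map)))
    path = os.path.join(outdir, "contribution_links.tsv")
    links.to_csv(path, sep="\t", index=False)
    manifest.add("contribution_links", path)

    # per-group networks
    counts_base = intervention.counts.subset_samples(list(sample_labels.index))
    net_cfg = config.get("network", {})
    nets = {}
    for group in ("responder", "non_responder"):
        ids = sample_labels.index[sample_labels == group].tolist()
        if len(ids) < 10:
            log.info("skipping %s network: only %d baseline samples", group, len(ids))
            continue
        sub = counts_base.subset_samples(ids)
        keep = sub.data.index[(sub.data > 0).mean(axis=1) >= 0.2]
        sub = AbundanceTable(sub.data.loc[keep], sub.unit, sub.level)
        rho, p = net.sparcc_correlations(
            sub, n_boot=int(net_cfg.get("n_boot", 100)), seed=s_net)
        network = net.build_network(rho, p, group=group)
        path = os.path.join(outdir, f"network_{group}.tsv")
        net.write_edge_list(network, path)
        manifest.add(f"network_{group}", path)
        nets[group] = network
    if len(nets) == 2:
        cent = net.compare_centrality(nets["responder"], nets["non_responder"])
        path = os.path.join(outdir, "centrality_comparison.tsv")
        cent.to_csv(path, sep="\t", index=False)
        manifest.add("centrality_comparison", path)

    # ML stage on baseline samples of responders vs non-responders
    binary = sample_labels[sample_labels != "partial_responder"]
    classes = binary.value_counts()
    if len(classes) < 2 or classes.min() < 5:
        log.warning("ML stage skipped: need >= 5 responders and non-responders, "
                    "got %s", classes.to_dict())
    else:
        ml_cfg = dict(config.get("ml", {}))
        ml_cfg.setdefault("cv", 3)
        ml_cfg.setdefault("grid", {k: list(v) for k, v in mlmod.SMALL_GRID.items()})
        cfg = mlmod.ModelConfig(seed=s_ml, **ml_cfg)
        feats = base_rel.subset_samples(list(binary.index)).unstratified().T
        report = mlmod.repeated_split_eval(feats, binary, cfg)
        path = os.path.join(outdir, "ml_report.tsv")
        report.per_split.to_csv(path, sep="\t", index=False)
        manifest.add("ml_per_split", path)
        path = os.path.join(outdir, "ml_summary.json")
        _write_json(path, report.summary.to_dict())
        manifest.add("ml_summary", path)
        path = os.path.join(outdir, "ml_selection_frequency.tsv")
        report.selection_frequency.sort_values(ascending=False).to_csv(
            path, sep="\t", header=["frequency"])
        manifest.add("ml_selection_frequency", path)

    manifest.finished = _now()
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest


def _write_json(path: str, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump({k: (v if not isinstance(v, float) else float(v))
                   for k, v in obj.items()}, fh, indent=2, default=str)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")
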