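"""Synthetic longitudinal microbiome studies with known ground truth.

The generative law is logistic-normal + multinomial: each subject i and
species j has a latent log-abundance baseline m_ij ~ N(mu_j, sigma_b2),
each visit adds independent N(0, sigma_w2) noise, a softmax across
species yields the composition and counts are multinomial at a fixed
read depth.  Between- and within-subject variance therefore decompose
additively on the log scale and the true intra-visit correlation of a
species' latent log-abundance is

    rho = sigma_b2 / (sigma_b2 + sigma_w2),

recorded per feature as ground truth.  Intervention cohorts plant a
responder label: flagged subjects receive a log-scale shift of magnitude
``effect_size`` on a random subset of taxa in their post-intervention
visits, and ``n_informative`` species carry baseline mean offsets between
responder and non-responder subjects so the prediction stage has
recoverable signal.  Pathway tables are stratified sums of contributing
species with known weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, SampleMetadata

__all__ = [
    "SimulationConfig", "SimulatedStudy", "simulate_control_cohort",
    "simulate_intervention_cohort", "simulate_stratified_functions",
    "genus_table", "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the generator (one arm).

    ``sigma_b2``/``sigma_w2`` are between- and within-subject variances of
    latent log-abundance; ``mu_spread`` is the SD of the per-species mean
    log-abundances (abundances span several orders of magnitude, as in
    real gut profiles); ``effect_size`` is the post-intervention log-scale
    shift applied to ``shift_taxa_fraction`` of taxa in responders;
    ``informative_effect`` is the baseline log-scale offset of the
    ``n_informative`` planted discriminative species.
    """

    n_subjects: int = 50
    n_species: int = 150
    n_genera: int = 30
    n_pathways: int = 40
    timepoints: tuple[int, ...] = (0, 1)
    sigma_b2: float = 1.0
    sigma_w2: float = 0.2
    depth: int = 50_000
    responder_fraction: float = 0.5
    effect_size: float = 5.0
    n_informative: int = 8
    informative_effect: float = 2.0
    shift_taxa_fraction: float = 0.3
    mu_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "n_subjects": self.n_subjects, "n_species": self.n_species,
            "n_genera": self.n_genera, "n_pathways": self.n_pathways,
            "sigma_b2": self.sigma_b2, "sigma_w2": self.sigma_w2,
            "depth": self.depth, "responder_fraction": self.responder_fraction,
            "effect_size": self.effect_size, "n_informative": self.n_informative,
            "informative_effect": self.informative_effect,
            "shift_taxa_fraction": self.shift_taxa_fraction,
            "mu_spread": self.mu_spread,
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"non-finite config value: {name}={value!r}")
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be >= 0")
        if self.sigma_w2 <= 0:
            raise ValueError("sigma_w2 must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not 0.0 <= self.shift_taxa_fraction <= 1.0:
            raise ValueError("shift_taxa_fraction must be in [0, 1]")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints per subject")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_informative > self.n_species:
            raise ValueError("n_informative exceeds n_species")

    @property
    def true_rho(self) -> float:
        return self.sigma_b2 / (self.sigma_b2 + self.sigma_w2)


@dataclass
class SimulatedStudy:
    counts: AbundanceTable
    metadata: SampleMetadata
    truth_rho: pd.Series
    config: SimulationConfig
    responder_labels: pd.Series | None = None       # subject -> bool, planted
    informative_features: list[str] = field(default_factory=list)
    contribution_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    genus_map: dict[str, str] = field(default_factory=dict)
    tree_newick: str = ""
    baseline: object = None                          # FluctuationBaseline, if supplied

    def relative(self) -> AbundanceTable:
        return self.counts.relative()


# ---------------------------------------------------------------------------
# naming helpers
# ---------------------------------------------------------------------------

def _species_lineages(n_species: int, n_genera: int) -> tuple[list[str], dict[str, str]]:
    lineages, genus_map = [], {}
    for j in range(n_species):
        g = j * n_genera // n_species
        p = g % 4
        genus = (f"k__Bacteria|p__P{p + 1:02d}|c__C{p + 1:02d}|o__O{p + 1:02d}"
                 f"|f__F{g + 1:02d}|g__G{g + 1:02d}")
        sp = f"{genus}|s__G{g + 1:02d}_sp{j + 1:03d}"
        lineages.append(sp)
        genus_map[sp] = genus
    return lineages, genus_map


def _random_tree(leaf_names: list[str], rng: np.random.Generator) -> str:
    """Random coalescent-like binary newick over the given leaves."""
    nodes = [f"{name}:{rng.exponential(0.5) + 0.01:.4f}" for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.5) + 0.01:.4f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


def _contribution_map(lineages: list[str], n_pathways: int,
                      rng: np.random.Generator) -> dict[str, list[tuple[str, float]]]:
    cmap = {}
    for p in range(n_pathways):
        k = int(rng.integers(1, 5))
        members = rng.choice(len(lineages), size=min(k, len(lineages)), replace=False)
        weights = rng.uniform(0.5, 3.0, size=len(members))
        cmap[f"PWY-{p + 1:04d}"] = [(lineages[m], float(w))
                                    for m, w in zip(members, weights)]
    return cmap


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _simulate(config: SimulationConfig, cohort_id: str, cohort_type: str,
              responders: np.ndarray | None) -> SimulatedStudy:
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_subj, rng_visit, rng_counts, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5))
    n, s, t = config.n_subjects, config.n_species, len(config.timepoints)
    lineages, genus_map = _species_lineages(s, config.n_genera)
    mu = rng_struct.normal(0.0, config.mu_spread, size=s)
    cmap = _contribution_map(lineages, config.n_pathways, rng_struct)
    tree = _random_tree([l.rsplit("|", 1)[-1] for l in lineages], rng_struct)

    m = mu[None, :] + rng_subj.normal(0.0, math.sqrt(config.sigma_b2), size=(n, s))
    informative: list[str] = []
    if responders is not None and config.n_informative > 0:
        informative = lineages[:config.n_informative]
        signs = np.where(np.arange(config.n_informative) % 2 == 0, 1.0, -1.0)
        m[responders, :config.n_informative] += config.informative_effect * signs

    z = m[:, :, None] + rng_visit.normal(0.0, math.sqrt(config.sigma_w2), size=(n, s, t))
    if responders is not None and config.effect_size != 0.0:
        n_shift = int(round(config.shift_taxa_fraction * s))
        for i in np.flatnonzero(responders):
            taxa = rng_misc.choice(s, size=n_shift, replace=False)
            z[i, taxa, 1:] += config.effect_size  # post-intervention visits only

    z = z - z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)

    sample_ids, meta_rows = [], []
    counts = np.empty((s, n * t), dtype=np.int64)
    col = 0
    for i in range(n):
        subject = f"{cohort_id}_S{i + 1:03d}"
        for ti, day in enumerate(config.timepoints):
            sid = f"{subject}_D{day:03d}"
            counts[:, col] = rng_counts.multinomial(config.depth, comp[i, :, ti])
            phase = "baseline" if (cohort_type == "control" or ti == 0) else "post"
            meta_rows.append({"sample_id": sid, "subject_id": subject,
                              "cohort_id": cohort_id, "cohort_type": cohort_type,
                              "day": int(day), "phase": phase})
            sample_ids.append(sid)
            col += 1

    table = AbundanceTable(pd.DataFrame(counts, index=lineages, columns=sample_ids),
                           "counts", "species")
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = pd.Series(config.true_rho, index=lineages, name="true_rho")
    labels = None
    if responders is not None:
        labels = pd.Series(responders, index=[f"{cohort_id}_S{i + 1:03d}" for i in range(n)],
                           name="planted_responder")
    return SimulatedStudy(table, metadata, truth, config, labels, informative,
                          cmap, genus_map, tree)


def simulate_control_cohort(config: SimulationConfig,
                            cohort_id: str = "CTL") -> SimulatedStudy:
    """A no-intervention cohort: pure baseline fluctuation, no planted labels."""
    return _simulate(config, cohort_id, "control", None)


def simulate_intervention_cohort(config: SimulationConfig, baseline=None,
                                 cohort_id: str = "INT",
                                 cohort_type: str = "lifestyle") -> SimulatedStudy:
    """An intervention cohort with planted responders.

    A fraction ``responder_fraction`` of subjects (chosen at random,
    deterministically per seed) receives the post-intervention shift; the
    optional control ``baseline`` is carried along for downstream
    classification.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA5)))
    n_resp = int(round(config.responder_fraction * config.n_subjects))
    responders = np.zeros(config.n_subjects, dtype=bool)
    responders[rng.choice(config.n_subjects, size=n_resp, replace=False)] = True
    study = _simulate(config, cohort_id, cohort_type, responders)
    study.baseline = baseline
    return study


# ---------------------------------------------------------------------------
# stratified functional table
# ---------------------------------------------------------------------------

UNMAPPED_FRACTION = 0.15
UNINTEGRATED_FRACTION = 0.05


def simulate_stratified_functions(study: SimulatedStudy,
                                  config: SimulationConfig | None = None,
                                  ) -> AbundanceTable:
    """Pathway CPM table as stratified sums of contributing species.

    Each pathway's community abundance is sum(weight * species relative
    abundance) over its contributors, columns rescaled to CPM with fixed
    UNMAPPED / UNINTEGRATED mass; one stratified row is emitted per
    contributor, so the unstratified row equals the sum of its stratified
    rows exactly.
    """
    if not study.contribution_map:
        raise ValueError("study has no contribution map")
    for pwy, members in study.contribution_map.items():
        for sp, w in members:
            if w < 0:
                raise ValueError(f"negative contribution weight for {pwy}/{sp}")
    rel = study.relative().data
    raw_rows: dict[str, np.ndarray] = {}
    order: list[str] = []
    for pwy, members in study.contribution_map.items():
        strat = {}
        for sp, w in members:
            genus = study.genus_map[sp].rsplit("|", 1)[-1]
            terminal = sp.rsplit("|", 1)[-1]
            strat[f"{pwy}|{genus}.{terminal}"] = w * rel.loc[sp].to_numpy()
        total = np.sum(list(strat.values()), axis=0)
        raw_rows[pwy] = total
        order.append(pwy)
        for rid, vals in strat.items():
            raw_rows[rid] = vals
            order.append(rid)
    totals = np.sum([raw_rows[p] for p in study.contribution_map], axis=0)
    biological = (1.0 - UNMAPPED_FRACTION - UNINTEGRATED_FRACTION) * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(totals > 0, biological / totals, 0.0)
    data = {rid: raw_rows[rid] * scale for rid in order}
    data["UNMAPPED"] = np.full(rel.shape[1], UNMAPPED_FRACTION * 1e6)
    data["UNINTEGRATED"] = np.full(rel.shape[1], UNINTEGRATED_FRACTION * 1e6)
    frame = pd.DataFrame(data, index=rel.columns).T
    return AbundanceTable(frame, "cpm", "pathway")


# ---------------------------------------------------------------------------
# aggregation and export
# ---------------------------------------------------------------------------

def genus_table(table: AbundanceTable, genus_map: dict[str, str]) -> AbundanceTable:
    """Genus table derived by summing species sharing a genus label."""
    df = table.unstratified().copy()
    genera = [genus_map[f] for f in df.index]
    out = df.groupby(genera, sort=True).sum()
    return AbundanceTable(out, table.unit, "genus")


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write a study in the file dialects the readers consume."""
    import os
    from . import profiles as pio

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    rel = study.relative()
    species_pct = rel.data * 100.0
    gen = genus_table(rel, study.genus_map)
    merged = pd.concat([gen.data * 100.0, species_pct])
    merged.index.name = "clade_name"
    paths["taxonomy"] = os.path.join(outdir, "taxonomic_profiles.tsv")
    merged.to_csv(paths["taxonomy"], sep="\t")

    paths["metadata"] = os.path.join(outdir, "metadata.tsv")
    pio.write_metadata(study.metadata, paths["metadata"])

    func = simulate_stratified_functions(study)
    paths["pathways"] = os.path.join(outdir, "pathway_profiles.tsv")
    pio.write_stratified_function_profile(func, paths["pathways"])

    paths["tree"] = os.path.join(outdir, "species_tree.nwk")
    with open(paths["tree"], "w") as fh:
        fh.write(study.tree_newick + "\n")

    truth = pd.DataFrame({"true_rho": study.truth_rho})
    truth["informative"] = [f in set(study.informative_features) for f in truth.index]
    paths["truth"] = os.path.join(outdir, "truth_features.tsv")
    truth.to_csv(paths["truth"], sep="\t", index_label="feature")
    if study.responder_labels is not None:
        paths["labels"] = os.path.join(outdir, "truth_labels.tsv")
        study.responder_labels.to_frame().to_csv(paths["labels"], sep="\t",
                                                 index_label="subject_id")
    return paths


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
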