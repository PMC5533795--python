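"""Synthetic interaction graphs and multi-cohort expression with ground truth.

The generator emulates the ingredients of a multi-cohort diagnostic-network
study: a hub-dominated (preferential-attachment) protein-interaction graph, a
connected "diagnostic module" planted in it whose members carry tumor-vs-normal
expression shifts, a small set of pivotal genes inside the module with high
within-module connectivity but modest global degree and subtype-specific mean
shifts, and one case/control expression cohort per study with its own batch
offset.  Every planted quantity is recorded in a :class:`GroundTruth` object
so downstream stages can be validated against known answers.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from diagnet.datasets import SUBTYPE_CLASSES, ExpressionDataset
from diagnet.network import write_edge_list

#: shift patterns cycled over pivotal genes; each pattern names the subtype
#: classes receiving the per-subtype shift, so that ER-splitting, TNG-splitting
#: and HER2-splitting markers all exist and the four classes are separable.
_PIVOTAL_PATTERNS = (
    ("ER", ("HR+HER2-", "HR+HER2+")),
    ("TNG", ("TNG",)),
    ("HER2", ("HR+HER2+", "HR-HER2+")),
)


@dataclass
class SimConfig:
    """Study-design parameters of the simulator.

    Defaults describe one realistic multi-cohort instance: 400 genes in a
    preferential-attachment graph (m = 2), a planted connected module of 40
    genes, 4 pivotal genes, 6 cohorts of 30 tumor + 30 normal samples, a
    tumor-vs-normal shift of 2 noise SD for differential genes and a
    3-noise-SD subtype shift for pivotal genes.
    """

    n_genes: int = 400
    attachment: int = 2
    module_size: int = 40
    n_pivotal: int = 4
    n_cohorts: int = 6
    n_tumor: int = 30
    n_normal: int = 30
    effect_size: float = 2.0
    subtype_shift: float = 3.0
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    outside_diff_fraction: float = 0.05
    subtype_probs: tuple = (0.45, 0.20, 0.15, 0.20)
    pivotal_within_degree: int = 8
    rng_seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "attachment": self.attachment,
            "module_size": self.module_size,
            "n_pivotal": self.n_pivotal,
            "n_cohorts": self.n_cohorts,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.module_size > self.n_genes:
            raise ValueError("module size exceeds n_genes")
        if self.n_pivotal > self.module_size:
            raise ValueError("n_pivotal exceeds module_size")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.subtype_probs) != 4 or abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype_probs must be 4 probabilities summing to 1")


@dataclass
class GroundTruth:
    """Planted structure: which genes shift, where the module is, which genes
    are pivotal, and the per-gene effect table (shifts in noise-SD units)."""

    diff_genes: set
    planted_module: set
    pivotal_genes: set
    effect_table: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "diff_genes": sorted(self.diff_genes),
            "planted_module": sorted(self.planted_module),
            "pivotal_genes": sorted(self.pivotal_genes),
            "effect_table": self.effect_table,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            diff_genes=set(payload["diff_genes"]),
            planted_module=set(payload["planted_module"]),
            pivotal_genes=set(payload["pivotal_genes"]),
            effect_table=payload["effect_table"],
        )


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _random_bfs_module(graph: nx.Graph, start, size: int, rng) -> set:
    """Grow a connected module by breadth-first search with randomly shuffled
    neighbor order."""
    visited = [start]
    seen = {start}
    queue = [start]
    while queue and len(visited) < size:
        node = queue.pop(0)
        neigh = sorted(set(graph.neighbors(node)) - seen)
        rng.shuffle(neigh)
        for nb in neigh:
            seen.add(nb)
            visited.append(nb)
            queue.append(nb)
            if len(visited) >= size:
                break
    return set(visited[:size])


def generate_network(config: SimConfig):
    """Build the background interaction graph and its planted ground truth.

    The graph is a Barabási–Albert preferential-attachment graph (heavy-tailed
    degrees, as in curated interactomes).  A connected module of
    ``module_size`` genes is grown by random BFS; its members, plus
    ``outside_diff_fraction`` of the remaining genes, are the differential
    genes.  ``n_pivotal`` low-degree module members become pivotal genes: each
    gains extra edges to other module members (high within-module
    connectivity), while every other differential gene is padded with edges to
    non-differential genes until at most half of its interactions stay inside
    the differential set, so pivotal genes are the ones whose connectivity
    concentrates in the diagnostic module.

    Returns ``(network, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(config.n_genes, config.attachment, seed=ba_seed)
    names = _gene_names(config.n_genes)
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))

    start = names[int(rng.integers(0, config.n_genes))]
    module = _random_bfs_module(graph, start, config.module_size, rng)
    if len(module) < config.module_size:
        raise ValueError("graph component too small for requested module")

    # outside differential genes model unrelated differential biology: they
    # are sampled away from the module's direct neighborhood (distance >= 2)
    # so the planted module stays identifiable as one connected signal region
    adjacent = set().union(*(set(graph.neighbors(g)) for g in module)) - module
    outside_pool = sorted(set(names) - module - adjacent)
    n_outside = int(round(config.outside_diff_fraction * (config.n_genes - len(module))))
    rng.shuffle(outside_pool)
    chosen_outside = outside_pool[:n_outside]
    if len(chosen_outside) < n_outside:  # tiny graphs: fall back to neighbors
        spill = sorted(adjacent)
        rng.shuffle(spill)
        chosen_outside += spill[: n_outside - len(chosen_outside)]
    diff_genes = set(module) | set(chosen_outside)
    nondiff_pool = sorted(set(names) - diff_genes)

    # pivotal genes: module members of modest global degree
    members = sorted(module)
    degs = np.array([graph.degree(g) for g in members])
    modest = [g for g, d in zip(members, degs) if d <= np.median(degs)]
    rng.shuffle(modest)
    pivotal = set(modest[: config.n_pivotal])
    if len(pivotal) < config.n_pivotal:
        extra = [g for g in members if g not in pivotal]
        rng.shuffle(extra)
        pivotal |= set(extra[: config.n_pivotal - len(pivotal)])

    # concentrate pivotal connectivity inside the module
    for gene in sorted(pivotal):
        partners = [g for g in members if g != gene and not graph.has_edge(gene, g)]
        rng.shuffle(partners)
        need = config.pivotal_within_degree - sum(
            1 for nb in graph.neighbors(gene) if nb in module
        )
        graph.add_edges_from((gene, p) for p in partners[: max(0, need)])

    # dilute every other differential gene: at most half of its edges may stay
    # inside the differential set, so only pivotal genes concentrate there
    for gene in sorted(diff_genes - pivotal):
        within = sum(1 for nb in graph.neighbors(gene) if nb in diff_genes)
        deficit = 2 * within - graph.degree(gene)
        if deficit > 0:
            partners = [g for g in nondiff_pool if not graph.has_edge(gene, g)]
            rng.shuffle(partners)
            graph.add_edges_from((gene, p) for p in partners[:deficit])

    effect_table = {}
    signs = rng.choice([-1.0, 1.0], size=len(diff_genes))
    for sign, gene in zip(signs, sorted(diff_genes)):
        effect_table[gene] = {
            "tumor_shift": float(sign * config.effect_size),
            "subtype_shift": {},
        }
    # per-subtype shifts are mean-centered over the tumor subtype mix, so they
    # add heterogeneity without changing the tumor-vs-normal contrast
    probs = dict(zip(SUBTYPE_CLASSES, config.subtype_probs))
    for i, gene in enumerate(sorted(pivotal)):
        _, classes = _PIVOTAL_PATTERNS[i % len(_PIVOTAL_PATTERNS)]
        sign = 1.0 if (i // len(_PIVOTAL_PATTERNS)) % 2 == 0 else -1.0
        p_in = sum(probs[c] for c in classes)
        effect_table[gene]["subtype_shift"] = {
            cls: float(
                sign * config.subtype_shift * ((1.0 - p_in) if cls in classes else -p_in)
            )
            for cls in SUBTYPE_CLASSES
        }

    truth = GroundTruth(
        diff_genes=diff_genes,
        planted_module=module,
        pivotal_genes=pivotal,
        effect_table=effect_table,
    )
    return graph, truth


def generate_expression(network: nx.Graph, truth: GroundTruth, config: SimConfig):
    """Simulate one expression cohort per study.

    Each matrix entry is gene baseline + per-cohort batch offset + planted
    group/subtype shift + i.i.d. Gaussian noise.  Tumor samples carry ER, PR
    and HER2 calls drawn from ``subtype_probs``; normals are labeled
    ``normal``.  Shifts in :class:`GroundTruth` are in noise-SD units and are
    multiplied by ``noise_sd`` here.
    """
    config.validate()
    missing = (truth.diff_genes | truth.planted_module) - set(network.nodes())
    if missing:
        raise ValueError(f"truth genes absent from network: {sorted(missing)[:5]}")
    genes = sorted(network.nodes())
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(genes)), index=genes
    )
    class_shift = pd.DataFrame(0.0, index=genes, columns=list(SUBTYPE_CLASSES))
    tumor_shift = pd.Series(0.0, index=genes)
    for gene, eff in truth.effect_table.items():
        tumor_shift[gene] = eff["tumor_shift"] * config.noise_sd
        for cls, sh in eff.get("subtype_shift", {}).items():
            class_shift.loc[gene, cls] = sh * config.noise_sd

    receptor = {
        "HR+HER2-": ("+", "+", "-"),
        "HR+HER2+": ("+", "+", "+"),
        "HR-HER2+": ("-", "-", "+"),
        "TNG": ("-", "-", "-"),
    }
    datasets = []
    for c in range(config.n_cohorts):
        crng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2, c]))
        name = f"cohort{c + 1:02d}"
        batch = crng.normal(0.0, config.batch_sd, len(genes))
        classes = crng.choice(
            len(SUBTYPE_CLASSES), size=config.n_tumor, p=list(config.subtype_probs)
        )
        tumor_ids = [f"{name}_T{j + 1:03d}" for j in range(config.n_tumor)]
        normal_ids = [f"{name}_N{j + 1:03d}" for j in range(config.n_normal)]
        n_samples = config.n_tumor + config.n_normal
        noise = crng.normal(0.0, config.noise_sd, (len(genes), n_samples))
        values = np.tile((baseline.to_numpy() + batch)[:, None], (1, n_samples)) + noise
        for j, cls_idx in enumerate(classes):
            cls = SUBTYPE_CLASSES[cls_idx]
            values[:, j] += tumor_shift.to_numpy() + class_shift[cls].to_numpy()
        matrix = pd.DataFrame(values, index=genes, columns=tumor_ids + normal_ids)
        rows = []
        for j, cls_idx in enumerate(classes):
            er, pr, her2 = receptor[SUBTYPE_CLASSES[cls_idx]]
            rows.append((tumor_ids[j], "tumor", er, pr, her2))
        rows.extend((s, "normal", "NA", "NA", "NA") for s in normal_ids)
        annot = pd.DataFrame(
            rows, columns=["sample", "group", "ER", "PR", "HER2"]
        ).set_index("sample")
        datasets.append(ExpressionDataset(name=name, values=matrix, annotations=annot))
    return datasets


def generate_genesets(
    network: nx.Graph,
    truth: GroundTruth,
    n_terms: int = 20,
    term_size: int = 25,
    seed: int = 0,
):
    """A small synthetic gene-set library: random terms plus one term equal to
    the planted module (so an enrichment run has a known positive)."""
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes())
    library = {"PLANTED_MODULE": set(truth.planted_module)}
    for i in range(n_terms - 1):
        size = min(term_size, len(genes))
        library[f"RANDOM_SET_{i + 1:02d}"] = set(
            rng.choice(genes, size=size, replace=False)
        )
    return library


def write_simulation(outdir: str, config: SimConfig):
    """Run the full simulation and write all artifacts under ``outdir``.

    Writes the network edge list, the ground truth JSON, the simulation config
    JSON and one expression/annotation TSV pair per cohort; returns
    ``(network, truth, datasets, paths)``.
    """
    from diagnet.datasets import write_dataset

    os.makedirs(outdir, exist_ok=True)
    network, truth = generate_network(config)
    datasets = generate_expression(network, truth, config)
    paths = {}
    net_path = os.path.join(outdir, "network.tsv")
    write_edge_list(network, net_path)
    paths["network"] = net_path
    truth_path = os.path.join(outdir, "truth.json")
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    config_path = os.path.join(outdir, "sim_config.json")
    with open(config_path, "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    paths["config"] = config_path
    for ds in datasets:
        paths.update(
            {f"{ds.name}_{k}": v for k, v in write_dataset(ds, outdir).items()}
        )
    return network, truth, datasets, paths
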