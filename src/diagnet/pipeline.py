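"""End-to-end pipeline: score → induce → search → integrate → pivotal →
enrich → evaluate, with a manifest recording every output and its checksum.

The pipeline is driven by a configuration mapping (usually loaded from YAML).
Either real inputs are given (expression/annotation TSV pairs, a network edge
list, optionally a GMT library and a candidate-gene list) or a ``simulate``
block requests synthetic inputs, which are generated first and then flow
through the same stages.  All randomness derives from one master seed split
per stage, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from diagnet.enrich import enrich as enrich_genes, read_gmt, write_enrichment, write_gmt
import diagnet.evaluate as eval_mod
import diagnet.integrate as integ_mod
import diagnet.pivotal as pivot_mod
import diagnet.scoring as scoring_mod
import diagnet.search as search_mod
import diagnet.synthetic as synth_mod
from diagnet.datasets import read_dataset
from diagnet.network import degree_table, induce_subnetwork, read_edge_list, write_edge_list

STAGES = ("simulate", "score", "search", "integrate", "pivotal", "enrich", "evaluate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    outdir: str
    status: str  # 'ok' or 'no_signal'
    manifest: dict
    consensus: object = None
    diagnostic_networks: dict = field(default_factory=dict)
    breakpoints: object = None
    cv_reports: list = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 0 if self.status == "ok" else 3


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_demo_config(seed: int = 0) -> dict:
    """Configuration of the bundled synthetic demonstration run."""
    return {
        "seed": seed,
        "simulate": {},  # SimConfig defaults; rng_seed is derived from seed
        "score": {"alpha": 0.05},
        "search": {"method": "norm_agg", "top_k": 10, "stop_size": 50, "stop_slack": 5},
        "integrate": {"k": 3},
        "pivotal": {"B": 1000},
        "enrich": {"n_random": 200},
        "evaluate": {"scheme": "kfold10", "knn_k": 10, "repeats": 50},
    }


def run_pipeline(config: dict, outdir: str) -> PipelineResult:
    """Run all stages; outputs land under ``outdir`` and are listed with
    checksums in ``manifest.json``.

    Returns a :class:`PipelineResult` whose ``status`` distinguishes a clean
    run with signal (``ok``) from a clean run whose consensus network is too
    small for pivotal-gene analysis (``no_signal``); stage failures raise
    :class:`StageError`.
    """
    os.makedirs(outdir, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    stage_seeds = {
        stage: int(s)
        for stage, s in zip(
            STAGES,
            np.random.SeedSequence(master_seed).generate_state(len(STAGES)) % (2**31),
        )
    }
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": master_seed,
        "stage_seeds": stage_seeds,
        "stages": [],
        "files": {},
    }
    files = manifest["files"]

    def record(stage: str, name: str, path: str):
        files[name] = {"path": os.path.relpath(path, outdir), "sha256": _sha256(path)}

    def done(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})

    # ---- inputs: simulate or load -------------------------------------
    truth = None
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("rng_seed", stage_seeds["simulate"])
            sim = synth_mod.SimConfig(**sim_kwargs)
            indir = os.path.join(outdir, "inputs")
            network, truth, datasets, paths = synth_mod.write_simulation(indir, sim)
            for name, path in paths.items():
                record("simulate", f"input_{name}", path)
            library = synth_mod.generate_genesets(
                network, truth, seed=stage_seeds["simulate"]
            )
            gmt_path = os.path.join(indir, "library.gmt")
            write_gmt(library, gmt_path)
            record("simulate", "input_library", gmt_path)
            candidates = sorted(network.nodes())
            done("simulate", n_genes=network.number_of_nodes(), n_cohorts=len(datasets))
        else:
            inputs = config["inputs"]
            network = read_edge_list(
                inputs["network"], dialect=inputs.get("network_dialect", "plain")
            )
            datasets = [
                read_dataset(c["expression"], c["annotations"], c.get("name"))
                for c in inputs["cohorts"]
            ]
            library = (
                read_gmt(inputs["gmt"]) if inputs.get("gmt") else None
            )
            if inputs.get("candidates"):
                with open(inputs["candidates"]) as fh:
                    candidates = [line.strip().upper() for line in fh if line.strip()]
            else:
                candidates = sorted(network.nodes())
            done("simulate", skipped=True)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrapped with stage context
        raise StageError("simulate", exc) from exc

    # ---- score --------------------------------------------------------
    try:
        alpha = float(config.get("score", {}).get("alpha", 0.05))
        tables, selections = {}, {}
        for ds in datasets:
            table = scoring_mod.score_genes(ds, candidates)
            tables[ds.name] = table
            selections[ds.name] = scoring_mod.select_diagnostic_genes(table, alpha)
            path = os.path.join(outdir, f"scores_{ds.name}.tsv")
            scoring_mod.write_score_table(table, path)
            record("score", f"scores_{ds.name}", path)
        done("score", alpha=alpha, selected={k: len(v) for k, v in selections.items()})
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", exc) from exc

    # ---- search (per cohort) ------------------------------------------
    try:
        scfg = search_mod.SearchConfig(**(config.get("search") or {}))
        diag_nets = {}
        round_rows = []
        for ds in datasets:
            selected = selections[ds.name]
            sub = induce_subnetwork(network, selected, drop_isolated=True)
            scores = tables[ds.name]["t"].dropna().to_dict()
            if sub.number_of_nodes() == 0:
                diag_nets[ds.name] = sub
                continue
            result = search_mod.iterate_search(sub, scores, scfg)
            diag_nets[ds.name] = result.graph
            for row in result.rounds.to_dict("records"):
                round_rows.append({"cohort": ds.name, **row})
            path = os.path.join(outdir, f"diagnostic_{ds.name}.tsv")
            write_edge_list(result.graph, path)
            record("search", f"diagnostic_{ds.name}", path)
        rounds_path = os.path.join(outdir, "search_rounds.tsv")
        pd.DataFrame(
            round_rows, columns=["cohort", "round", "n_nodes", "score"]
        ).to_csv(rounds_path, sep="\t", index=False)
        record("search", "search_rounds", rounds_path)
        done("search", sizes={k: v.number_of_nodes() for k, v in diag_nets.items()})
    except Exception as exc:  # noqa: BLE001
        raise StageError("search", exc) from exc

    # ---- integrate ----------------------------------------------------
    try:
        k = int(config.get("integrate", {}).get("k", 3))
        nonempty = [g for g in diag_nets.values() if g.number_of_nodes() > 0]
        profile = (
            integ_mod.overlap_profile(nonempty) if len(nonempty) >= 2 else pd.DataFrame()
        )
        profile_path = os.path.join(outdir, "overlap_profile.tsv")
        profile.to_csv(profile_path, sep="\t")
        record("integrate", "overlap_profile", profile_path)
        consensus = integ_mod.consensus_network(list(diag_nets.values()), k=k)
        cons_path = os.path.join(outdir, "consensus.tsv")
        integ_mod.write_consensus(consensus, cons_path)
        record("integrate", "consensus", cons_path)
        done(
            "integrate",
            k=k,
            n_nodes=consensus.number_of_nodes(),
            n_edges=consensus.number_of_edges(),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("integrate", exc) from exc

    result = PipelineResult(
        outdir=outdir,
        status="ok",
        manifest=manifest,
        consensus=consensus,
        diagnostic_networks=diag_nets,
    )

    # ---- pivotal ------------------------------------------------------
    no_signal = consensus.number_of_nodes() < 4
    if no_signal:
        done("pivotal", skipped=True, reason="consensus network too small")
        done("enrich", skipped=True, reason="no signal")
        done("evaluate", skipped=True, reason="no signal")
        result.status = "no_signal"
        _write_manifest(manifest, outdir)
        return result
    try:
        pcfg = config.get("pivotal") or {}
        bg_degrees = degree_table(network)
        genes = sorted(consensus.nodes())
        intervals = pivot_mod.degree_quantile_cutoffs(genes, bg_degrees)
        per = pivot_mod.per_level_representation(genes, bg_degrees, intervals)
        per_path = os.path.join(outdir, "per_levels.tsv")
        per.to_csv(per_path, sep="\t")
        record("pivotal", "per_levels", per_path)
        perm_p = pivot_mod.permutation_test_top_level(
            genes,
            bg_degrees,
            intervals,
            B=int(pcfg.get("B", 1000)),
            seed=stage_seeds["pivotal"],
        )
        ec = pivot_mod.connectivity_enrichment(degree_table(consensus), bg_degrees)
        ec_path = os.path.join(outdir, "ec_table.tsv")
        ec.to_frame().to_csv(ec_path, sep="\t", index_label="gene")
        record("pivotal", "ec_table", ec_path)
        breakpoints = pivot_mod.rank_breakpoints(ec)
        panels_path = os.path.join(outdir, "panels.json")
        with open(panels_path, "w") as fh:
            json.dump(
                {
                    "permutation_p_top_level": perm_p,
                    "breakpoints": breakpoints.breakpoints,
                    "candidates": [
                        {
                            "panel_size": s,
                            "genes": breakpoints.panel(s),
                            "drop_score": float(breakpoints.drop_scores.get(s, np.nan)),
                        }
                        for s in breakpoints.candidate_sizes
                    ],
                },
                fh,
                indent=1,
            )
        record("pivotal", "panels", panels_path)
        result.breakpoints = breakpoints
        done("pivotal", permutation_p=perm_p, breakpoints=breakpoints.breakpoints)
    except Exception as exc:  # noqa: BLE001
        raise StageError("pivotal", exc) from exc

    # ---- enrich -------------------------------------------------------
    try:
        if library:
            ecfg = config.get("enrich") or {}
            enr = enrich_genes(
                genes,
                library,
                n_random=int(ecfg.get("n_random", 200)),
                seed=stage_seeds["enrich"],
            )
            enr_path = os.path.join(outdir, "enrichment.tsv")
            write_enrichment(enr, enr_path)
            record("enrich", "enrichment", enr_path)
            done("enrich", n_terms=len(enr), top_term=enr.index[0])
        else:
            done("enrich", skipped=True, reason="no gene-set library configured")
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    # ---- evaluate -----------------------------------------------------
    try:
        vcfg = config.get("evaluate") or {}
        max_size = int(vcfg.get("max_panel_size", 10))
        panel_sizes = [s for s in breakpoints.candidate_sizes if s <= max_size]
        if not panel_sizes:
            panel_sizes = [min(4, len(breakpoints.genes))]
        classifier = eval_mod.KNNClassifier(k=int(vcfg.get("knn_k", 10)))
        scheme = vcfg.get("scheme", "kfold10")
        repeats = int(vcfg.get("repeats", 50))
        rows = []
        for size in panel_sizes:
            panel = breakpoints.panel(size)
            for ds in datasets:
                try:
                    report = eval_mod.cross_validate(
                        ds,
                        panel,
                        scheme=scheme,
                        classifier=classifier,
                        repeats=repeats,
                        seed=stage_seeds["evaluate"],
                    )
                except ValueError as exc:  # e.g. a subtype class with <2 samples
                    rows.append(
                        {
                            "panel": ";".join(panel),
                            "dataset": ds.name,
                            "scheme": scheme,
                            "classifier": classifier.name,
                            "error": str(exc),
                        }
                    )
                    continue
                rows.append(report.to_row())
                result.cv_reports.append(report)
        cv_path = os.path.join(outdir, "cv_report.tsv")
        pd.DataFrame(rows).to_csv(cv_path, sep="\t", index=False)
        record("evaluate", "cv_report", cv_path)
        done("evaluate", n_reports=len(rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    _write_manifest(manifest, outdir)
    return result


def _write_manifest(manifest: dict, outdir: str) -> None:
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
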