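"""End-to-end orchestration: ingestion (or synthesis) → co-administration →
prevalence/relative risks → null model → network → intervention, with a
manifest recording seeds, config hash and content hashes of every output."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from scipy import stats

from . import __version__
from . import io as dio
from .coadmin import (
    aggregate_pair_episodes,
    pair_intervals,
    pair_population_stats,
)
from .intervention import apply_and_recompute, plan_substitutions
from .network import build_network, export_network, pair_significance
from .nullmodel import run_null_model
from .prevalence import compute_prevalence, gender_relative_risks
from .synthetic import (
    generate_ddi_reference,
    generate_dispensations,
    generate_drug_classes,
    generate_population,
)
from .types import DataError, NullModelConfig, PlantedEffect, StudyWindow, \
    SyntheticConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    effects = [PlantedEffect(
        drug_a=e["drug_a"], drug_b=e["drug_b"],
        gender=e.get("gender", "both"),
        age_bin_range=tuple(e.get("age_bin_range", (0, 18))),
        risk_multiplier=float(e.get("risk_multiplier", 1.0)),
    ) for e in d.pop("planted_effects", [])]
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    if "severity_probs" in d:
        d["severity_probs"] = tuple(d["severity_probs"])
    if "study_window" in d:
        d["study_window"] = tuple(pd.Timestamp(x).date()
                                  for x in d["study_window"])
    return SyntheticConfig(planted_effects=effects, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and write all artifacts plus ``manifest.json``.

    ``config`` keys: either ``synthetic`` (a SyntheticConfig mapping) or
    ``inputs`` (paths for dispensations/patients/ddi/classes), plus
    ``window`` {start, end, resolution}, optional ``null_model``
    {n_reps, sampling}, ``network`` {fdr, min_tau}, ``intervention``
    {target, scope}, and ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "version": __version__,
                      "pandas": pd.__version__, "stages": [], "outputs": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    def _stage(name):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    def _write(df, name, writer=None):
        path = outdir / name
        (writer or (lambda d, p: d.to_csv(p, index=False)))(df, path)
        manifest["outputs"][name] = {"sha256": _sha256(path),
                                     "n_rows": int(len(df))}

    try:
        _stage("ingest")
        if "synthetic" in config:
            sconf = synthetic_config_from_dict(
                {**config["synthetic"], "seed": seed})
            window = sconf.window
            patients = generate_population(sconf)
            records = generate_dispensations(patients, sconf)
            ddi = generate_ddi_reference(sconf)
            try:
                classes = generate_drug_classes(sconf, ddi)
            except (DataError, ValueError):
                classes = pd.DataFrame(columns=dio.CLASS_COLUMNS)
        else:
            w = config["window"]
            window = StudyWindow(pd.Timestamp(w["start"]).date(),
                                 pd.Timestamp(w["end"]).date(),
                                 w.get("resolution", "daily"))
            inputs = config["inputs"]
            patients = dio.read_patients(inputs["patients"], window.end)
            records = dio.read_dispensations(inputs["dispensations"], window)
            ddi = dio.read_ddi_reference(inputs["ddi"])
            classes = dio.read_drug_classes(inputs["classes"]) \
                if inputs.get("classes") else pd.DataFrame(
                    columns=dio.CLASS_COLUMNS)
        _write(patients, "patients.csv", dio.write_patients)
        _write(records, "dispensations.csv",
               lambda d, p: dio.write_dispensations(d, p, window.resolution))
        _write(ddi, "ddi_reference.csv", dio.write_ddi_reference)
        _write(classes, "drug_classes.csv", dio.write_drug_classes)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage name is the contract
        raise StageError("ingest", e) from e

    try:
        _stage("coadmin")
        intervals = pair_intervals(records, window)
        episodes = aggregate_pair_episodes(intervals, records, ddi, window)
        stats_ = pair_population_stats(episodes, records, window)
        _write(episodes, "pair_episodes.csv")
        _write(stats_, "pair_stats.csv")
    except Exception as e:
        raise StageError("coadmin", e) from e

    try:
        _stage("prevalence")
        prev = compute_prevalence(intervals, records, patients, ddi)
        rr = gender_relative_risks(prev, config.get("correction", "fdr"))
        _write(prev, "prevalence.csv")
        _write(rr, "relative_risks.csv")
    except Exception as e:
        raise StageError("prevalence", e) from e

    try:
        _stage("nullmodel")
        nm_conf = config.get("null_model", {})
        nconf = NullModelConfig(
            n_reps=int(nm_conf.get("n_reps", 100)),
            sampling=nm_conf.get("sampling", "frequency_weighted"),
            seed=seed,
        )
        nm_summary, nm_reps = run_null_model(intervals, records, patients,
                                             ddi, nconf, window)
        _write(nm_summary, "nullmodel_summary.csv")
        _write(nm_reps, "nullmodel_reps.csv")
    except Exception as e:
        raise StageError("nullmodel", e) from e

    try:
        _stage("network")
        net_conf = config.get("network", {})
        fdr = float(net_conf.get("fdr", 0.05))
        n_patients = records["patient_id"].nunique()
        sig = pair_significance(stats_, n_patients)
        G = build_network(sig, episodes, records, patients, fdr=fdr,
                          classes=classes)
        export_network(G, outdir / "network.graphml", "graphml",
                       min_tau=net_conf.get("min_tau"))
        manifest["outputs"]["network.graphml"] = {
            "sha256": _sha256(outdir / "network.graphml"),
            "n_rows": G.number_of_edges(),
        }
        export_network(G, outdir / "network_edges.csv", "edgelist",
                       min_tau=net_conf.get("min_tau"))
        manifest["outputs"]["network_edges.csv"] = {
            "sha256": _sha256(outdir / "network_edges.csv"),
            "n_rows": G.number_of_edges(),
        }
    except Exception as e:
        raise StageError("network", e) from e

    iv_conf = config.get("intervention")
    if iv_conf and len(classes):
        try:
            _stage("intervention")
            target = iv_conf["target"]
            plan = plan_substitutions(records, target, classes, ddi, window,
                                      scope=iv_conf.get("scope", "ddi"))
            report, new_records = apply_and_recompute(
                records, patients, ddi, plan, target, window)
            _write(plan, "substitution_plan.csv")
            _write(report, "intervention_report.csv")
            _write(new_records, "dispensations_substituted.csv",
                   lambda d, p: dio.write_dispensations(d, p,
                                                        window.resolution))
        except Exception as e:
            raise StageError("intervention", e) from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def compare_populations(run_dirs) -> dict:
    """Cross-population comparison of two or more completed runs.

    Aligns the drug pairs shared by every run and reports the Spearman
    correlation of per-pair co-administering patient counts for each run
    pair, plus drug/pair overlap counts.
    """
    if len(run_dirs) < 2:
        raise ValueError("compare_populations needs at least two run dirs")
    tables = [pd.read_csv(Path(d) / "pair_stats.csv") for d in run_dirs]
    names = [str(d) for d in run_dirs]
    result: dict = {"runs": names, "pairs": []}
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            a, b = tables[i], tables[k]
            merged = a.merge(b, on=["drug_i", "drug_j"], suffixes=("_a", "_b"))
            shared_drugs = (set(a["drug_i"]) | set(a["drug_j"])) \
                & (set(b["drug_i"]) | set(b["drug_j"]))
            entry = {
                "run_a": names[i], "run_b": names[k],
                "n_shared_drugs": len(shared_drugs),
                "n_shared_pairs": int(len(merged)),
            }
            if len(merged) >= 2:
                rho, p = stats.spearmanr(merged["n_coadmin_users_a"],
                                         merged["n_coadmin_users_b"])
                entry["spearman_rho"] = float(rho)
                entry["spearman_p"] = float(p)
            else:
                entry["spearman_rho"] = None
                entry["spearman_p"] = None
                logger.warning("compare_populations: %s vs %s share %d pairs; "
                               "correlation undefined", names[i], names[k],
                               len(merged))
            result["pairs"].append(entry)
    return result
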