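"""End-to-end orchestration: QC -> diversity -> differentiation ->
clustering -> hybrid calls -> parentage/Ne -> power, from one config.

Each stage writes its outputs and the exact parameters used into a run
directory with a JSON manifest per stage; a stage whose config and inputs
are unchanged (content hash) is skipped on re-run, and a failing stage
marks its dependants as skipped rather than aborting the whole run.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture, diversity, fst, hybrids, ne, nullalleles, parentage, power
from .dataset import (GenotypeDataset, allele_frequencies, missing_summary,
                      read_genepop, read_population_metadata, attach_metadata,
                      write_genepop)
from .simulate import default_survey_scenario, generate_scenario

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the survey-standard settings."""
    genepop_path: str | None = None
    metadata_path: str | None = None
    simulate_default: bool = False      # generate the frozen synthetic survey
    seed: int = 0
    # QC
    null_drop_threshold: float = 0.1
    hwe_chain: tuple = (10000, 100, 5000)
    # differentiation
    fst_permutations: int = 1000
    ena_bootstrap: int = 50000
    amova_permutations: int = 20000
    # clustering
    structure_kmax: int = 6
    structure_replicates: int = 10
    run_structure: bool = True
    # hybrids
    hybrid_thresholds: tuple = (0.60, 0.95, 0.05)
    pure_q_min: float = 0.95
    # parentage / Ne
    parentage_error_rate: float = 0.01
    prop_sampled: float = 0.1
    ne_cutoff: float = 0.02
    # power
    run_power: bool = False
    power_target_fst: float = 0.005
    power_replicates: int = 200
    alpha: float = 0.05

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_done(run_dir: Path, name: str, key: str) -> bool:
    mf = run_dir / f"{name}.manifest.json"
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _write_manifest(run_dir: Path, name: str, key: str, params: dict,
                    outputs: list, status: str = "ok", error: str | None = None):
    (run_dir / f"{name}.manifest.json").write_text(json.dumps({
        "stage": name, "key": key, "params": params, "outputs": outputs,
        "status": status, "error": error,
    }, indent=2, default=str))


def run_pipeline(config: PipelineConfig, run_dir) -> dict:
    """Execute all configured stages in dependency order.

    Returns a report dict mapping stage name to status ('ok', 'skipped',
    'cached' or 'failed').  Outputs live under ``run_dir``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    key = config.content_hash()
    (run_dir / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))
    report: dict = {}
    rng = np.random.default_rng(config.seed)

    # ---- load ----
    if config.simulate_default:
        spec = default_survey_scenario(seed=config.seed)
        ds, truth = generate_scenario(spec)
        truth["individuals"].to_csv(run_dir / "truth_individuals.csv", index=False)
        write_genepop(ds, run_dir / "simulated.gen")
    elif config.genepop_path:
        ds = read_genepop(config.genepop_path)
        if config.metadata_path:
            ds = attach_metadata(ds, read_population_metadata(config.metadata_path))
    else:
        raise FileNotFoundError("no input: set genepop_path or simulate_default")
    report["load"] = "ok"

    def stage(name, deps, fn):
        if any(report.get(d) in ("failed", "skipped", None) and d not in ("load",)
               for d in deps):
            report[name] = "skipped"
            _write_manifest(run_dir, name, key, {}, [], "skipped",
                            f"dependency not satisfied: {deps}")
            return
        if _stage_done(run_dir, name, key):
            report[name] = "cached"
            return
        try:
            outputs = fn()
            _write_manifest(run_dir, name, key, {}, outputs or [])
            report[name] = "ok"
        except Exception:
            report[name] = "failed"
            _write_manifest(run_dir, name, key, {}, [], "failed",
                            traceback.format_exc())

    # ---- QC ----
    state: dict = {}

    def qc():
        missing_summary(ds).to_csv(run_dir / "missing_summary.csv")
        nulls = nullalleles.null_allele_table(ds)
        nulls.to_csv(run_dir / "null_alleles.csv", index=False)
        qc_table = nullalleles.locus_qc(nulls, config.null_drop_threshold)
        qc_table.to_csv(run_dir / "locus_qc.csv")
        nullalleles.apply_locus_qc(ds, qc_table)
        state["nulls"] = nulls
        return ["missing_summary.csv", "null_alleles.csv", "locus_qc.csv"]

    stage("qc", ["load"], qc)

    def diversity_stage():
        table = diversity.diversity_summary(ds.active_view())
        table.to_csv(run_dir / "diversity_summary.csv")
        return ["diversity_summary.csv"]

    stage("diversity", ["qc"], diversity_stage)

    def fst_stage():
        res = fst.weir_cockerham_fst(ds, permutations=config.fst_permutations,
                                     seed=int(rng.integers(2 ** 31)))
        pw = fst.pairwise_fst(ds)
        pw.to_csv(run_dir / "pairwise_fst.csv")
        ena = fst.fst_ena(ds, bootstrap_reps=config.ena_bootstrap,
                          seed=int(rng.integers(2 ** 31)))
        summary = {
            "global_theta": res.theta, "p_value": res.p_value,
            "global_theta_ena": ena.theta, "ena_ci95": ena.ci95,
            "n_pairs": pw.attrs["n_pairs"],
        }
        (run_dir / "fst_summary.json").write_text(json.dumps(summary, default=str))
        state["pairwise"] = pw
        return ["pairwise_fst.csv", "fst_summary.json"]

    stage("fst", ["qc"], fst_stage)

    def structure_stage():
        work = ds.active_view()
        kmax = min(config.structure_kmax, work.n_populations)
        fits = admixture.fit_replicates(work, range(1, kmax + 1),
                                        replicates=config.structure_replicates,
                                        seed=int(rng.integers(2 ** 31)))
        table = admixture.delta_k(fits)
        table.to_csv(run_dir / "delta_k.csv")
        k_sel = admixture.select_k(fits, work, seed=int(rng.integers(2 ** 31)))
        best = admixture.best_fit(fits, k_sel)
        q = pd.DataFrame(best.q, columns=[f"cluster_{i+1}" for i in range(k_sel)])
        q.insert(0, "individual", ds.ids)
        q.insert(1, "population", [ds.pop_names[p] for p in ds.pop_index])
        q.to_csv(run_dir / "admixture_q.csv", index=False)
        state["fit"] = best
        state["selected_K"] = k_sel
        return ["delta_k.csv", "admixture_q.csv"]

    if config.run_structure:
        stage("structure", ["qc"], structure_stage)
    else:
        report["structure"] = "skipped"

    def hybrid_stage():
        if "fit" not in state:
            raise RuntimeError("hybrid calling requires the structure stage")
        fit = state["fit"]
        groups = np.array([ds.group_labels.get(ds.pop_names[p], "")
                           for p in ds.pop_index])
        if fit.K < 2:
            # no unsupervised split: anchor a wild/farmed K = 2 fit on the
            # group labels (supervised mode), as an analyst would
            farmed_pops = [p for p in ds.pop_names
                           if ds.group_labels.get(p) == "farmed"]
            wild_pops = [p for p in ds.pop_names
                         if ds.group_labels.get(p) == "wild"]
            if not farmed_pops or not wild_pops:
                raise RuntimeError("no farmed/wild split found (K = 1) and no "
                                   "group labels to anchor one")
            sup = {p: 0 for p in wild_pops} | {p: 1 for p in farmed_pops}
            fit = admixture.fit_admixture(ds.active_view(), 2,
                                          seed=int(rng.integers(2 ** 31)),
                                          supervised_sources=sup)
        farm_score = [np.nanmean(fit.q[groups == "farmed", cl]) if
                      (groups == "farmed").any() else fit.q[:, cl].mean()
                      for cl in range(fit.K)]
        farmed_cl = int(np.argmax(farm_score))
        wild_cl = int(np.argmax([fit.q[groups == "wild", cl].mean() if
                                 (groups == "wild").any() else 0.0
                                 for cl in range(fit.K)]))
        if wild_cl == farmed_cl:
            wild_cl = int(np.argsort(farm_score)[0])
        panels = hybrids.select_pure_reference(ds.active_view(), fit, wild_cl,
                                               farmed_cl, config.pure_q_min)
        lo, hi, step = config.hybrid_thresholds
        if fit.K == 2:
            q_farm = admixture.posterior_mean_q2(ds.active_view(), fit,
                                                 cluster=farmed_cl)
        else:
            q_farm = fit.q[:, farmed_cl] / np.maximum(
                fit.q[:, farmed_cl] + fit.q[:, wild_cl], 1e-12)
        sets = {}
        adm_q = {}
        for frac in (0.15, 0.33, 0.66):
            n_hyb = int(round(200 * frac))
            per = {"Pure1": (200 - n_hyb) // 2, "Pure2": (200 - n_hyb + 1) // 2,
                   "F1": n_hyb // 4, "F2": n_hyb // 4,
                   "BC1": n_hyb // 4, "BC2": n_hyb - 3 * (n_hyb // 4)}
            sim_ds, labels = hybrids.simulate_hybrids(panels, per,
                                                      seed=int(rng.integers(2 ** 31)))
            sets[frac] = (sim_ds, labels)
            sfit = admixture.fit_admixture(sim_ds, 2, seed=int(rng.integers(2 ** 31)))
            f_cl = int(np.argmax([sfit.q[np.asarray(labels) == "Pure2", c].mean()
                                  for c in range(2)]))
            adm_q[frac] = admixture.posterior_mean_q2(sim_ds, sfit, cluster=f_cl)
        calib = hybrids.calibrate_thresholds(
            sets, panels, adm_q, np.round(np.arange(lo, hi + step / 2, step), 2))
        calib.to_csv(run_dir / "hybrid_calibration.csv", index=False)
        threshold = calib.attrs["selected_threshold"] or 0.9
        calls = hybrids.apply_hybrid_calls(ds, q_farm, threshold)
        calls.to_csv(run_dir / "hybrid_calls.csv", index=False)
        calls.attrs["population_summary"].to_csv(run_dir / "hybrid_population_summary.csv")
        return ["hybrid_calibration.csv", "hybrid_calls.csv",
                "hybrid_population_summary.csv"]

    stage("hybrids", ["structure"], hybrid_stage)

    def parentage_stage():
        groups = {p: ds.group_labels.get(p, "") for p in ds.pop_names}
        adult_pops = [p for p, g in groups.items() if g in ("wild", "farm-associated")]
        juv_pops = [p for p, g in groups.items() if g == "YoY"]
        if not adult_pops or not juv_pops:
            raise RuntimeError("no adult/juvenile group labels available")
        work = ds.active_view()
        adults = work.subset_populations(adult_pops)
        juvs = work.subset_populations(juv_pops)
        freqs = allele_frequencies(work.subset_populations(adult_pops + juv_pops))
        settings = parentage.ParentageSettings(
            error_rate=config.parentage_error_rate,
            prop_sampled=config.prop_sampled)
        pairs = parentage.find_parent_offspring(adults, juvs, freqs, settings,
                                                seed=int(rng.integers(2 ** 31)))
        pairs.to_csv(run_dir / "parent_offspring_pairs.csv", index=False)
        rows = []
        for pop in work.pop_names:
            n = int((work.pop_index == work.pop_position(pop)).sum())
            if n <= 30:
                rows.append({"population": pop, "n": n, "ne": None,
                             "note": "sample size <= 30; not analysed"})
                continue
            est = ne.ne_ld(work, pop, freq_cutoff=config.ne_cutoff)
            rows.append({"population": pop, "n": n, "ne": est.ne,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                         "note": ""})
        pd.DataFrame(rows).to_csv(run_dir / "ne_estimates.csv", index=False)
        return ["parent_offspring_pairs.csv", "ne_estimates.csv"]

    stage("parentage_ne", ["qc"], parentage_stage)

    def power_stage():
        sizes = [int((ds.pop_index == pi).sum()) for pi in range(ds.n_populations)]
        base = power.default_panel_frequencies(seed=config.seed)
        t = power.drift_for_target_fst(config.power_target_fst, ne=1000)
        scen = power.PowerScenario(base, sizes, ne=1000, t=t,
                                   replicates=config.power_replicates,
                                   alpha=config.alpha)
        res = power.simulate_power(scen, seed=int(rng.integers(2 ** 31)))
        (run_dir / "power.json").write_text(json.dumps(res, default=str))
        return ["power.json"]

    if config.run_power:
        stage("power", ["load"], power_stage)

    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
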