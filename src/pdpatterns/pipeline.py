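"""End-to-end study replica: cohort -> preprocess -> severity -> diffexpr -> patterns.

One YAML config drives every stage; all randomness flows from a single
master seed through named substreams, so repeated runs with the same
config produce byte-identical outputs.  A reproducibility manifest
(config hash, per-stage seeds, output checksums, timings) is written last.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort as cohort_mod, diffexpr, patterns as patterns_mod
from . import preprocess as prep, severity as severity_mod
from .cohort import SEVERITY_SCORE

__all__ = ["RunManifest", "ConfigError", "default_pipeline_config", "run_all"]

log = logging.getLogger("pdpatterns")

STAGES = ("cohort", "preprocess", "severity", "diffexpr", "patterns")

_KNOWN_KEYS = {
    "seed", "stages", "inputs", "cohort", "preprocess", "severity",
    "diffexpr", "patterns",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict
    version: str
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def default_pipeline_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": list(STAGES),
        "cohort": {},
        "preprocess": {"threshold": 0.5},
        "severity": {"folds": 10},
        "diffexpr": {"pooled_visits": ["week4", "week16"]},
        "patterns": {
            "comparisons": ["meta:arm", "PSOR:response"],
            "runs": 100,
            "iterations": 5000,
            "k": None,          # default: number of subgroups + 1
            "n_top": 4,
        },
    }


def _validate(config: dict) -> dict:
    merged = default_pipeline_config(int(config.get("seed", 0)))
    unknown = sorted(set(config) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    for key, val in config.items():
        if isinstance(val, dict) and key in merged and isinstance(merged[key], dict):
            merged[key].update(val)
        else:
            merged[key] = val
    bad = sorted(set(merged["stages"]) - set(STAGES))
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    merged["stages"] = [s for s in STAGES if s in merged["stages"]]
    if "cohort" not in merged["stages"]:
        inputs = merged.get("inputs") or {}
        missing = [k for k in ("dir",) if k not in inputs]
        if missing:
            raise ConfigError(
                "without the cohort stage the config must point at existing "
                f"inputs; missing inputs key(s): {missing}"
            )
    return merged


def _jsonable(obj):
    """Config hashing helper: stringify mapping keys, listify tuples."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(ss_children: dict, stage: str) -> int:
    return int(ss_children[stage].generate_state(1)[0] % 2**31)


def run_all(config, out_dir) -> RunManifest:
    """Execute the configured stages in dependency order.

    ``config`` is a dict or a YAML file path.  Any stage failure halts the
    run with the stage name; the manifest is written last.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    config = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"])
    master = np.random.SeedSequence(seed)
    children = dict(zip(STAGES, master.spawn(len(STAGES))))
    stage_seeds = {s: _stage_seed(children, s) for s in STAGES}
    canon = json.dumps(_jsonable(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest(),
        seed=seed,
        stage_seeds=stage_seeds,
        version=__version__,
    )

    state = {}
    for stage in config["stages"]:
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            _RUNNERS[stage](config, out, stage_seeds[stage], state)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.1fs", stage, manifest.timings[stage])

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[str(path.relative_to(out))] = _sha256(path)
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _run_cohort(config, out, seed, state) -> None:
    cfg = cohort_mod.default_config(seed=seed)
    for key, val in config["cohort"].items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown cohort config key {key!r}")
        setattr(cfg, key, val)
    cfg.seed = seed
    cohort = cohort_mod.generate_cohort(cfg)
    cohort_mod.write_cohort(cohort, out / "cohort", overwrite=True)
    state["cohort_dir"] = out / "cohort"
    state["truth"] = cohort.truth


def _run_preprocess(config, out, seed, state) -> None:
    src = state.get("cohort_dir") or Path(config["inputs"]["dir"])
    meta = prep.read_meta(src / "meta.tsv")
    state["meta"] = meta
    state["panels"] = {}
    threshold = float(config["preprocess"].get("threshold", 0.5))
    for ddir in sorted(p for p in src.iterdir() if p.is_dir()):
        disease = ddir.name
        raw = prep.read_panel(ddir / "analytes.tsv", ddir / "lloq.tsv")
        kept, report = prep.qc_filter(raw, threshold=threshold)
        normalized = prep.log2_quantile_normalize(prep.impute(kept))
        dest = out / "preprocess" / disease
        dest.mkdir(parents=True, exist_ok=True)
        normalized.values.rename_axis("sample_id").to_csv(
            dest / "normalized.tsv", sep="\t", float_format="%.10g")
        report.to_json(dest / "qc_report.json")
        state["panels"][disease] = normalized


def _run_severity(config, out, seed, state) -> None:
    meta = state["meta"]
    folds = int(config["severity"].get("folds", 10))
    for disease, panel in state["panels"].items():
        score_col = SEVERITY_SCORE.get(disease)
        if score_col is None or meta.loc[meta["disease"] == disease, score_col].isna().all():
            continue
        dm = meta[meta["disease"] == disease]
        dest = out / "severity" / disease
        dest.mkdir(parents=True, exist_ok=True)
        visits = list(dict.fromkeys(dm["visit"]))
        results = {}
        for visit in visits:
            sev = dm.loc[dm["visit"] == visit, score_col]
            results[visit] = severity_mod.lasso_select(
                panel, sev, folds=folds, seed=seed, visit=visit)
        coef = pd.DataFrame({v: results[v].coefficients for v in visits})
        coef.rename_axis("analyte").to_csv(dest / "lasso_coefficients.tsv",
                                           sep="\t", float_format="%.6g")
        sel = severity_mod.robust_biomarkers(results)
        (dest / "robust_biomarkers.txt").write_text(
            "\n".join(sel.robust) + ("\n" if sel.robust else ""))

        rows = []
        for a in sel.robust:
            for visit in visits:
                sev = dm.loc[dm["visit"] == visit, score_col]
                fit = severity_mod.fit_adjusted(panel, sev, meta, [a], visit=visit,
                                                response_name=score_col)
                beta, p = fit.terms[a]
                rows.append({"analyte": a, "visit": visit, "beta": beta, "p": p,
                             "r2": fit.r2, "f_pvalue": fit.f_pvalue, "model": "univariate"})
        if len(sel.robust) >= 2:
            pair = sel.robust[:2]
            for visit in visits:
                sev = dm.loc[dm["visit"] == visit, score_col]
                fit = severity_mod.fit_adjusted(panel, sev, meta, pair, visit=visit,
                                                response_name=score_col)
                for a in pair:
                    beta, p = fit.terms[a]
                    rows.append({"analyte": a, "visit": visit, "beta": beta, "p": p,
                                 "r2": fit.r2, "f_pvalue": fit.f_pvalue, "model": "additive"})
        pd.DataFrame(rows).to_csv(dest / "regression_fits.tsv", sep="\t",
                                  index=False, float_format="%.6g")

        if sel.robust:
            baseline = visits[0]
            weights = {}
            for a in sel.robust[:2]:
                sev = dm.loc[dm["visit"] == baseline, score_col]
                fit = severity_mod.fit_adjusted(panel, sev, meta, sel.robust[:2]
                                                if len(sel.robust) >= 2 else [a],
                                                visit=baseline, response_name=score_col)
                weights = {k: v[0] for k, v in fit.terms.items()
                           if k in sel.robust[:2]}
                break
            change = _visit_change(panel, dm, weights.keys(), (visits[0], visits[1]))
            score = severity_mod.aggregate_score(weights, change)
            score.rename("score").rename_axis("subject").to_csv(
                dest / "aggregated_scores.tsv", sep="\t", float_format="%.6g")
            groups = {}
            for label, sub in (("PBO", dm["arm"] == "placebo"),
                               ("AR", dm["response"] == "AR"),
                               ("ANR", dm["response"] == "ANR")):
                subjects = dm.loc[sub, "subject"].unique()
                vals = score.reindex(subjects).dropna()
                if len(vals) >= 2:
                    groups[label] = vals.to_numpy()
            if len(groups) >= 2:
                severity_mod.compare_groups(groups).to_csv(
                    dest / "group_tests.tsv", sep="\t", index=False,
                    float_format="%.6g")


def _visit_change(panel, dmeta, analytes, visit_pair) -> pd.DataFrame:
    v0, v1 = visit_pair
    analytes = list(analytes)
    rows = {}
    m = dmeta.loc[dmeta.index.intersection(panel.samples)]
    for subject, grp in m.groupby("subject"):
        s0 = grp.index[grp["visit"] == v0]
        s1 = grp.index[grp["visit"] == v1]
        if len(s0) == 1 and len(s1) == 1:
            rows[subject] = (panel.values.loc[s1[0], analytes].to_numpy()
                             - panel.values.loc[s0[0], analytes].to_numpy())
    return pd.DataFrame.from_dict(rows, orient="index", columns=analytes)


def _run_diffexpr(config, out, seed, state) -> None:
    meta = state["meta"]
    panels = state["panels"]
    pooled_visits = tuple(config["diffexpr"].get("pooled_visits", ("week4", "week16")))
    dest = out / "diffexpr"
    dest.mkdir(parents=True, exist_ok=True)
    grid_rows = []

    def _save(res):
        name = res.contrast.replace(":", "_").replace("@", "_").replace("+", "-")
        res.table.rename_axis("analyte").to_csv(dest / f"de_{name}.tsv", sep="\t",
                                                float_format="%.6g")
        grid_rows.append({"contrast": res.contrast,
                          "n_significant": int((res.table["fdr"] < 0.05).sum()),
                          "significant": ",".join(res.significant)})

    for disease, panel in panels.items():
        dm = meta[meta["disease"] == disease]
        for visit in pooled_visits:
            _save(diffexpr.moderated_de(panel, dm, visit,
                                        contrast=f"{disease}:{visit}"))
        res, _ = diffexpr.mixed_de(panel, dm, visits=pooled_visits,
                                   contrast=f"{disease}:{'+'.join(pooled_visits)}")
        _save(res)
    for visit in pooled_visits:
        _save(diffexpr.meta_de(panels, meta, visit, contrast=f"meta:{visit}"))
    pd.DataFrame(grid_rows).to_csv(dest / "significance_grid.tsv", sep="\t",
                                   index=False)


def _run_patterns(config, out, seed, state) -> None:
    meta = state["meta"]
    panels = state["panels"]
    pcfg = config["patterns"]
    n_runs = int(pcfg.get("runs", 100))
    iterations = pcfg.get("iterations", 5000)
    n_top = int(pcfg.get("n_top", 4))
    ss = np.random.SeedSequence(seed)

    for comparison, child in zip(pcfg["comparisons"], ss.spawn(len(pcfg["comparisons"]))):
        scope, kind = comparison.split(":")
        if scope == "meta":
            panel = _stack_panels(panels)
            m = meta
        else:
            panel = panels[scope]
            m = meta[meta["disease"] == scope]
        if kind == "arm":
            groups = patterns_mod.subgroups_by(m, ("arm",))
        elif kind == "response":
            m = m[m["arm"] == "apremilast"]
            groups = patterns_mod.subgroups_by(m, ("response",), include=("ANR", "AR"))
        else:
            raise ConfigError(f"unknown comparison kind {kind!r}")

        gm = patterns_mod.build_grouped_matrix(panel, m, groups)
        K = int(pcfg["k"]) if pcfg.get("k") else len(groups) + 1
        if iterations == "auto":
            n_iter, _ = patterns_mod.select_iterations(
                gm, K, n_runs=max(3, n_runs // 20),
                seed=int(child.generate_state(1)[0] % 2**31))
        else:
            n_iter = int(iterations)
        run_seeds = [int(s.generate_state(1)[0] % 2**31)
                     for s in child.spawn(n_runs)]
        runs = [patterns_mod.fit_weighted_nmf(gm, K, n_iter, s) for s in run_seeds]
        merged = patterns_mod.merge_patterns(runs)
        merged = patterns_mod.consensus_assignment(runs, merged)

        dest = out / "patterns" / comparison.replace(":", "_")
        dest.mkdir(parents=True, exist_ok=True)
        (dest / "patterns.json").write_text(json.dumps({
            "comparison": comparison,
            "columns": [list(c) for c in gm.D.columns],
            "K": K, "n_runs": n_runs, "n_iterations": n_iter,
            "rmsd_tol": merged.rmsd_tol,
            "rel_strength_range": merged.rel_strength_range,
            "centroids": merged.centroids.to_numpy().tolist(),
            "runs_per_pattern": {str(k): len(v) for k, v in merged.members.items()},
            "mean_chi2": float(np.mean([r.chi2 for r in runs])),
        }, indent=2))
        assign = pd.DataFrame({
            "pattern": merged.assignment,
            "frequency": [merged.frequencies.loc[a, p]
                          for a, p in merged.assignment.items()],
        })
        assign.rename_axis("analyte").to_csv(dest / "assignments.tsv", sep="\t",
                                             float_format="%.6g")

        if kind == "response":
            decline_rows = []
            for pid in merged.centroids.index:
                members = [a for a, p in merged.assignment.items() if p == pid]
                if len(members) < n_top:
                    continue
                top = patterns_mod.top_decliners(members, panel, m, n_top=n_top)
                if len(top) < 2:
                    continue
                try:
                    test = patterns_mod.responder_decline_test(
                        list(top.index), panel, m)
                except ValueError:
                    continue
                decline_rows.append({
                    "pattern": pid,
                    "top_analytes": ",".join(top.index),
                    "U": test.U, "p": test.p,
                    **{f"geomfold_{g}": v
                       for g, v in test.geometric_mean_fold.items()},
                })
            pd.DataFrame(decline_rows).to_csv(dest / "decline_test.tsv", sep="\t",
                                              index=False, float_format="%.6g")


def _stack_panels(panels: dict):
    common = None
    for p in panels.values():
        cols = set(p.analytes)
        common = cols if common is None else common & cols
    common = sorted(common)
    values = pd.concat([p.values[common] for _, p in sorted(panels.items())])
    lloq = next(iter(panels.values())).lloq.reindex(common)
    return prep.AnalytePanel(values=values, lloq=lloq, state="normalized")


_RUNNERS = {
    "cohort": _run_cohort,
    "preprocess": _run_preprocess,
    "severity": _run_severity,
    "diffexpr": _run_diffexpr,
    "patterns": _run_patterns,
}
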