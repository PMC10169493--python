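"""Pipeline orchestration: simulate/load -> enterotype -> community stats ->
network -> module detection per layer -> metabolome stats -> SEM chain search,
driven by one YAML config, with on-disk stage artifacts and a manifest.

Stage artifacts are written before the next stage starts so any stage can be
re-run or inspected independently; a manifest records seeds, parameters and
artifact checksums, and an unchanged config resumes from completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, enterotype, metabolome, network, sem, wgcna
from .datatypes import dump_json, to_jsonable
from .io import read_table, write_run_artifact
from .simulate import METAB_LAYERS, SimConfig, simulate_cohort

log = logging.getLogger("enterolink")

__all__ = ["PipelineConfig", "run_all", "render_report"]

STAGES = ("data", "enterotype", "community", "network", "wgcna", "metabolome", "sem", "report")


class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (a SimConfig block) or ``inputs`` (paths to
    genus/metabolome/phenotype TSVs) must be present. Per-stage parameter
    blocks are optional; the global ``seed`` is expanded into per-stage seeds
    as seed + 1000 * stage_index.
    """

    def __init__(self, raw: dict, base_dir: Path | None = None):
        self.raw = dict(raw)
        self.base_dir = Path(base_dir or ".")
        has_sim = "simulate" in raw
        has_inputs = "inputs" in raw
        if has_sim == has_inputs:
            raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
        self.seed = int(raw.get("seed", 20230509))
        self.outdir = Path(raw.get("outdir", "enterolink_out"))
        if not self.outdir.is_absolute():
            self.outdir = self.base_dir / self.outdir
        if has_sim:
            sim_block = dict(raw.get("simulate") or {})
            sim_block["seed"] = self.seed
            self.sim_config = SimConfig(**sim_block)
        else:
            self.sim_config = None
        self.inputs = raw.get("inputs")
        if self.inputs:
            for key, p in self.inputs.items():
                path = Path(p)
                if not path.is_absolute():
                    path = self.base_dir / path
                if not path.exists():
                    raise ValueError(f"input file for {key!r} not found: {path}")
                self.inputs[key] = str(path)
        self.stage_params = {s: raw.get(s, {}) or {} for s in STAGES}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, base_dir=path.parent)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + 1000 * STAGES.index(stage)) % (2**31 - 1)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True, default=str).encode()).hexdigest()


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path, config_digest: str):
        self.path = path
        self.data = {"config_digest": config_digest, "stages": {}}
        if path.exists():
            try:
                old = json.loads(path.read_text())
            except json.JSONDecodeError:
                old = None
            if old and old.get("config_digest") == config_digest:
                self.data = old
            elif old is not None:
                log.warning("stale manifest (config changed): full rerun")

    def done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all(Path(f).exists() and _sha(Path(f)) == h for f, h in entry["artifacts"].items())

    def record(self, stage: str, files: list[Path], params: dict) -> None:
        self.data["stages"][stage] = {
            "artifacts": {str(f): _sha(Path(f)) for f in files},
            "params": to_jsonable(params),
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the in-memory bundle."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config.digest())
    bundle: dict = {"outdir": out}

    try:
        _stage_data(config, bundle, manifest)
        _stage_enterotype(config, bundle, manifest)
        _stage_community(config, bundle, manifest)
        _stage_network(config, bundle, manifest)
        _stage_wgcna(config, bundle, manifest)
        _stage_metabolome(config, bundle, manifest)
        _stage_sem(config, bundle, manifest)
    except Exception as exc:  # noqa: BLE001 - halt with the failing stage named
        raise RuntimeError(f"pipeline halted at stage {bundle.get('_stage', '?')}: {exc}") from exc
    report = render_report(bundle)
    (out / "report.md").write_text(report)
    bundle["report"] = report
    manifest.record("report", [out / "report.md"], {})
    return bundle


def _stage_data(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "data"
    out = cfg.outdir
    if cfg.sim_config is not None:
        cohort = simulate_cohort(cfg.sim_config, seed=cfg.stage_seed("data"))
        files = []
        files.append(write_run_artifact(cohort["genus"], out / "genus.tsv"))
        for layer in METAB_LAYERS:
            files.append(write_run_artifact(cohort["layers"][layer], out / f"{layer}.tsv"))
        pheno = cohort["phenotype"].data.join(cohort["vfa"].data)
        files.append(write_run_artifact(pheno, out / "phenotypes.tsv"))
        dump_json(cohort["truth"].to_dict(), out / "truth.json")
        files.append(out / "truth.json")
        bundle.update(
            genus=cohort["genus"],
            layers=cohort["layers"],
            phenotype=pheno,
            truth=cohort["truth"],
        )
        manifest.record("data", files, dataclasses.asdict(cfg.sim_config))
    else:
        ins = cfg.inputs
        bundle["genus"] = read_table(ins["genus"], "abundance")
        bundle["layers"] = {
            layer: read_table(ins[key], "omics", layer_tag=layer)
            for layer, key in (("rumen_metab", "rumen"), ("serum_metab", "serum"), ("milk_metab", "milk"))
            if key in ins
        }
        bundle["phenotype"] = read_table(ins["phenotypes"], "phenotype").data
        bundle["truth"] = None
        manifest.record("data", [Path(p) for p in ins.values()], {})


def _stage_enterotype(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "enterotype"
    params = cfg.stage_params["enterotype"]
    res = enterotype.select_enterotypes(
        bundle["genus"],
        metric=params.get("metric", "jsd"),
        k_max=params.get("k_max", 6),
        seed=cfg.stage_seed("enterotype"),
    )
    bundle["enterotype"] = res
    out = cfg.outdir
    dump_json(
        {
            "labels": res.labels.to_dict(),
            "medoids": res.medoids,
            "k_best": res.k_best,
            "ch_curve": res.ch_curve,
            "strong_stratification": res.strong_stratification,
            "notes": res.notes,
        },
        out / "enterotype.json",
    )
    write_run_artifact(res.coordinates, out / "pcoa_coordinates.tsv")
    manifest.record("enterotype", [out / "enterotype.json", out / "pcoa_coordinates.tsv"], params)


def _stage_community(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "community"
    labels = bundle["enterotype"].labels.to_numpy()
    genus = bundle["genus"]
    seed = cfg.stage_seed("community")
    D = enterotype.bray_curtis(genus)
    ares = community.anosim(D, labels, n_perm=999, seed=seed)
    diff = community.mann_whitney_bh(genus.data, labels)
    out = cfg.outdir
    files = [write_run_artifact(diff, out / "genus_differential.tsv")]
    payload = {"anosim": dataclasses.asdict(ares), "n_differential_genera": diff.n_pass}
    acids = [a for a in community.VFA_ACIDS if a in bundle["phenotype"].columns]
    if len(acids) == len(community.VFA_ACIDS):
        summary = community.vfa_summary(bundle["phenotype"], labels)
        files.append(write_run_artifact(summary.to_frame(), out / "vfa_summary.tsv"))
        bundle["vfa_summary"] = summary
    dump_json(payload, out / "community.json")
    files.append(out / "community.json")
    bundle["anosim"] = ares
    bundle["genus_differential"] = diff
    manifest.record("community", files, {"n_perm": 999, "seed": seed})


def _stage_network(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "network"
    params = cfg.stage_params["network"]
    net = network.build_network(
        bundle["genus"],
        rho_min=params.get("rho_min", 0.5),
        alpha=params.get("alpha", 0.05),
    )
    hubs = network.identify_hubs(net)
    out = cfg.outdir
    files = [
        write_run_artifact(net.edges, out / "network_edges.tsv"),
        write_run_artifact(hubs, out / "network_nodes.tsv"),
    ]
    if net.n_edges:
        comp = network.random_network_comparison(net, n_rand=params.get("n_rand", 100), seed=cfg.stage_seed("network"))
        files.append(write_run_artifact(comp, out / "network_random_comparison.tsv"))
        bundle["network_comparison"] = comp
    bundle["network"] = net
    bundle["hubs"] = hubs
    manifest.record("network", files, net.params)


def _stage_wgcna(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "wgcna"
    params = cfg.stage_params["wgcna"]
    out = cfg.outdir
    modules: dict[str, wgcna.ModuleSet] = {}
    files = []
    # microbiome layer: log relative abundances
    micro = np.log(bundle["genus"].data + 1e-6)
    layer_inputs = {"rumen_micro": micro}
    for layer, om in bundle["layers"].items():
        layer_inputs[layer] = om.data
    for layer, data in layer_inputs.items():
        layer_par = params.get(layer, {})
        wp = wgcna.WgcnaParams(
            beta=layer_par.get("beta", wgcna.DEFAULT_POWERS.get(layer, 7)),
            min_module_size=layer_par.get("min_module_size", 5),
            merge_cor=layer_par.get("merge_cor", 0.75),
        )
        ms = wgcna.fit_modules(data, wp)
        modules[layer] = ms
        files.append(write_run_artifact(ms.assignment.rename("module").to_frame(), out / f"modules_{layer}.tsv"))
        files.append(write_run_artifact(ms.eigengenes, out / f"eigengenes_{layer}.tsv"))
    traits = bundle["phenotype"][["MPY"]] if "MPY" in bundle["phenotype"].columns else bundle["phenotype"]
    mt = []
    for layer, ms in modules.items():
        if ms.eigengenes.shape[1]:
            t = wgcna.module_trait_correlation(ms.eigengenes, traits)
            t.insert(0, "layer", layer)
            mt.append(t)
    if mt:
        mt_table = pd.concat(mt, ignore_index=True)
        files.append(write_run_artifact(mt_table, out / "module_trait.tsv"))
        bundle["module_trait"] = mt_table
    bundle["modules"] = modules
    manifest.record("wgcna", files, params)


def _stage_metabolome(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "metabolome"
    params = cfg.stage_params["metabolome"]
    labels = bundle["enterotype"].labels.to_numpy()
    criteria = metabolome.DifferentialCriteria.preset(params.get("criteria", "methods"))
    out = cfg.outdir
    files, results = [], {}
    for layer, om in bundle["layers"].items():
        X = om.data
        if params.get("preprocess", False):
            prep = metabolome.preprocess(X, params=metabolome.PreprocessParams())
            X_log, X_pre = prep.log_data, prep.data
        else:
            X_log, X_pre = X, None  # simulated layers are already on a log-like scale
        fit = metabolome.opls_da(X_log, labels, n_ortho=params.get("n_ortho", 1), seed=cfg.stage_seed("metabolome"))
        diff = metabolome.differential_metabolites(X_log, labels, fit.vip, criteria, X_prelog=X_pre)
        results[layer] = {"opls": fit, "differential": diff}
        files.append(write_run_artifact(diff, out / f"differential_{layer}.tsv"))
    dump_json(
        {
            layer: {"r2x": r["opls"].r2x, "q2y": r["opls"].q2y, "n_differential": r["differential"].n_pass}
            for layer, r in results.items()
        },
        out / "metabolome.json",
    )
    files.append(out / "metabolome.json")
    bundle["metabolome"] = results
    manifest.record("metabolome", files, params)


def _stage_sem(cfg: PipelineConfig, bundle: dict, manifest: _Manifest) -> None:
    bundle["_stage"] = "sem"
    params = cfg.stage_params["sem"]
    pheno_var = params.get("phenotype", "MPY")
    scores = {layer: ms.eigengenes for layer, ms in bundle["modules"].items()}
    res = sem.chain_search(scores, bundle["phenotype"][pheno_var], alpha=params.get("alpha", 0.05))
    out = cfg.outdir
    ranking = res.ranking.drop(columns=["fit", "modules"], errors="ignore")
    files = [write_run_artifact(ranking, out / "sem_ranking.tsv")]
    winner_payload = None
    if res.winner is not None:
        fit = res.winner["fit"]
        winner_payload = {
            "chain": res.winner["chain"],
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
            "chi2": fit.chi2,
            "df": fit.df,
            "estimates": fit.estimates.drop(columns=[]).to_dict("records"),
            "r_squared": fit.r_squared.to_dict(),
        }
    dump_json({"winner": winner_payload, "n_candidates": res.n_candidates}, out / "sem.json")
    files.append(out / "sem.json")
    bundle["sem"] = res
    manifest.record("sem", files, params)


def render_report(bundle: dict) -> str:
    """Consolidated markdown report over the stage artifacts in the bundle."""
    lines = ["# enterolink pipeline report", ""]
    et = bundle.get("enterotype")
    if et is not None:
        lines += ["## Enterotypes", f"- chosen k: {et.k_best}", f"- group sizes: {et.group_sizes()}",
                  f"- CH curve: {{{', '.join(f'{k}: {v:.2f}' for k, v in et.ch_curve.items())}}}",
                  f"- strong stratification: {et.strong_stratification}", ""]
    else:
        lines += ["## Enterotypes", "- absent", ""]
    if "anosim" in bundle:
        a = bundle["anosim"]
        lines += ["## Community statistics", f"- ANOSIM R = {a.R:.3f}, p = {a.p:.4f} ({a.n_permutations} permutations)",
                  f"- differential genera (BH q < 0.05): {bundle['genus_differential'].n_pass}", ""]
    if "vfa_summary" in bundle:
        v = bundle["vfa_summary"]
        tvfa = ", ".join(f"{c}: {v.group_means.loc['TVFA', c]:.2f}" for c in v.group_means.columns)
        lines += [f"- TVFA by group: {tvfa}", ""]
    if "network" in bundle:
        net = bundle["network"]
        hubs = bundle["hubs"]
        hub_names = list(hubs.loc[hubs["is_hub"], "taxon"])
        lines += ["## Co-occurrence network", f"- edges: {net.n_edges}", f"- hub genera: {hub_names or 'none'}", ""]
    else:
        lines += ["## Co-occurrence network", "- absent", ""]
    if "modules" in bundle:
        lines += ["## Co-expression modules"]
        for layer, ms in bundle["modules"].items():
            lines.append(f"- {layer}: {ms.n_modules} module(s), sizes {ms.module_sizes.to_dict()}")
        lines.append("")
    if "metabolome" in bundle:
        lines += ["## Metabolome differential analysis"]
        for layer, r in bundle["metabolome"].items():
            o = r["opls"]
            lines.append(
                f"- {layer}: R2X = {o.r2x:.3f}, Q2Y = {o.q2y:.3f}, differential metabolites = {r['differential'].n_pass}"
            )
        lines.append("")
    if "sem" in bundle:
        res = bundle["sem"]
        lines += ["## SEM chain search", f"- candidates: {res.n_candidates}"]
        if res.winner is not None:
            fit = res.winner["fit"]
            lines.append(f"- winning chain: {res.winner['chain']}")
            lines.append(f"- fit: chi2 = {fit.chi2:.3f} (df {fit.df}), RMSEA = {fit.rmsea:.3f}, CFI = {fit.cfi:.3f}")
            est = fit.estimates
            arrows = est.iloc[0]["rhs"] + "".join(
                f" -({r['std_estimate']:+.2f})-> {r['lhs']}" for _, r in est.iterrows()
            )
            lines.append(f"- path (std coefficients): {arrows}")
        else:
            lines.append("- no chain with all paths significant")
        lines.append("")
    return "\n".join(lines)
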