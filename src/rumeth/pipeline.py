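"""Pipeline orchestration: configuration, stage running, report writing.

A single YAML config drives the chain simulate -> rank -> gaskin -> predict
-> vfa -> community -> anova. Each stochastic stage has its own seed so
stages can be re-run independently; every threshold and seed is echoed to
the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as community_mod
from . import gaskin, io, ranking, rumenpred, synthio, trialstats
from . import vfa as vfa_mod
from .errors import PipelineError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "rank", "gaskin", "predict", "vfa", "community", "anova")


@dataclass
class PipelineConfig:
    out_dir: Path
    stages: tuple = ALL_STAGES
    sep: str = "\t"
    herd: dict = field(default_factory=dict)
    invitro: dict = field(default_factory=dict)
    community: dict = field(default_factory=dict)
    rumen: dict = field(default_factory=dict)
    ranking: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    reference_profiles: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        raw["out_dir"] = Path(raw.get("out_dir", "rumeth_out"))
        if "stages" in raw:
            bad = [s for s in raw["stages"] if s not in ALL_STAGES]
            if bad:
                raise PipelineError(f"unknown stages: {bad}")
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _input_path(cfg: PipelineConfig, key: str, default_name: str) -> Path:
    if key in cfg.inputs:
        return Path(cfg.inputs[key])
    return cfg.out_dir / default_name


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise PipelineError(f"stage '{stage}': required input {path} is missing")
    return path


def _stage_simulate(cfg: PipelineConfig, log: dict) -> None:
    out = cfg.out_dir
    herd_cfg = dict(cfg.herd)
    n_pairs = herd_cfg.pop("n_pairs", None)
    truth = synthio.HerdTruth(**herd_cfg)
    sim = synthio.gen_herd(truth)
    io.write_cow_table(sim.cows, out / "cows.tsv", cfg.sep)
    io.write_table(sim.offsets.rename_axis("cow_id").reset_index(),
                   out / "true_offsets.tsv", cfg.sep)
    log["herd_truth"] = {**herd_cfg, "n_pairs": n_pairs}

    inv_cfg = dict(cfg.invitro)
    runs = inv_cfg.pop("runs", 1)
    design = synthio.TreatmentDesign(runs=tuple(range(1, int(runs) + 1)))
    inv_truth = synthio.default_invitro_truth(**inv_cfg)
    run = synthio.gen_invitro_run(inv_truth, design)
    io.write_gas_curves(run.gas_curves, out / "gas.tsv", out / "bottles.tsv", cfg.sep)
    io.write_headspace(run.headspace_series, out / "headspace.tsv", cfg.sep)
    io.write_vfa_table(run.vfa_profiles, out / "vfa.tsv", cfg.sep)
    log["invitro_truth"] = {**inv_cfg, "runs": runs}

    comm_cfg = dict(cfg.community)
    truth_keys = {"overdispersion", "library_mean", "library_sd", "n_per_group",
                  "seed", "group_effect"}
    comm_truth = synthio.default_community_truth(
        **{k: v for k, v in comm_cfg.items() if k in truth_keys})
    table = synthio.gen_otu_table(comm_truth)
    io.write_otu_table(table, out / "otu.tsv", out / "otu_meta.tsv", cfg.sep)
    log["community_truth"] = {k: v for k, v in comm_cfg.items() if k in truth_keys}


def _stage_rank(cfg: PipelineConfig, log: dict) -> None:
    path = _require(_input_path(cfg, "cow_table", "cows.tsv"), "rank")
    cows = io.read_cow_table(path, cfg.sep)
    fit = ranking.fit_ch4_model(cows)
    n_pairs = int(cfg.ranking.get("n_pairs", cfg.herd.get("n_pairs", 7)))
    n_pairs = min(n_pairs, cows["cow_id"].nunique() // 2)
    rk = ranking.rank_emitters(fit, n_pairs)
    io.write_table(rk.table, cfg.out_dir / "ranking.tsv", cfg.sep)
    io.write_table(rk.pairs, cfg.out_dir / "pairs.tsv", cfg.sep)
    log["ranking"] = {"n_pairs": n_pairs,
                      "coefficients": {k: float(v) for k, v in fit.params.items()}}


def _fit_row(fit: gaskin.GompertzFit, prefix: str) -> dict:
    return {f"{prefix}_{k}": v for k, v in
            zip(("a1", "b1", "k1", "a2", "b2", "k2", "rss"),
                (*fit.params, fit.rss))}


def _stage_gaskin(cfg: PipelineConfig, log: dict) -> pd.DataFrame:
    gas_path = _require(_input_path(cfg, "gas", "gas.tsv"), "gaskin")
    bottles_path = _require(_input_path(cfg, "bottles", "bottles.tsv"), "gaskin")
    hs_path = _require(_input_path(cfg, "headspace", "headspace.tsv"), "gaskin")
    curves = io.read_gas_curves(gas_path, bottles_path, cfg.sep)
    headspace = {s.bottle_id: s for s in io.read_headspace(hs_path, cfg.sep)}
    v_hs = float(cfg.invitro.get("headspace_volume", gaskin.DEFAULT_HEADSPACE_ML))

    blanks = {}
    for c in curves:
        if c.meta.get("is_blank"):
            blanks.setdefault((c.meta["run"], c.meta["emitter"]), []).append(c)

    cells = {}
    for c in curves:
        if c.meta.get("is_blank"):
            continue
        key = (c.meta["run"], c.meta["emitter"], c.meta["diet"], c.meta["cnsl"])
        cells.setdefault(key, []).append(c)

    rows = []
    for (run, emitter, diet, cnsl), cell_curves in sorted(cells.items()):
        cell_blanks = blanks.get((run, emitter), [])
        nets, ch4s = [], []
        for c in cell_curves:
            net = gaskin.blank_correct_gas(c, cell_blanks) if cell_blanks else c
            nets.append(net.volume / net.sample_mass)
            series = headspace.get(c.bottle_id)
            if series is None:
                raise PipelineError(f"stage 'gaskin': no headspace series for {c.bottle_id}")
            conc = gaskin.fit_log_conc(series)
            ch4s.append(gaskin.estimate_ch4_curve(net, conc, v_hs).cumulative)
        t = cell_curves[0].time
        gas_fit = gaskin.fit_two_pool_gompertz(t, np.mean(nets, axis=0))
        ch4_fit = gaskin.fit_two_pool_gompertz(t, np.mean(ch4s, axis=0))
        gsum = gaskin.curve_summaries(gas_fit)
        csum = gaskin.curve_summaries(ch4_fit)
        row = {"run": run, "emitter": emitter, "diet": diet, "cnsl": cnsl,
               "gas_asymptote": gsum["asymptote"], "gas_at_48": gsum["value_at"],
               "gas_rate": gsum["rate"], "ch4_asymptote": csum["asymptote"],
               "ch4_at_48": csum["value_at"], "ch4_rate": csum["rate"],
               "ch4_to_gas_48": gaskin.ch4_to_gas_ratio(csum, gsum)}
        row.update(_fit_row(gas_fit, "gasfit"))
        row.update(_fit_row(ch4_fit, "ch4fit"))
        rows.append(row)
    table = pd.DataFrame(rows)
    io.write_table(table, cfg.out_dir / "kinetics.tsv", cfg.sep)
    log["gaskin"] = {"headspace_volume": v_hs, "n_cells": len(rows)}
    return table


def _stage_predict(cfg: PipelineConfig, log: dict) -> None:
    path = _require(_input_path(cfg, "kinetics", "kinetics.tsv"), "predict")
    table = io.read_table(path, cfg.sep)
    rcfg = rumenpred.RumenConfig(**cfg.rumen)
    preds = []
    for _, row in table.iterrows():
        fit = gaskin.GompertzFit(a1=row["ch4fit_a1"], b1=row["ch4fit_b1"],
                                 k1=row["ch4fit_k1"], a2=row["ch4fit_a2"],
                                 b2=row["ch4fit_b2"], k2=row["ch4fit_k2"])
        preds.append(rumenpred.predict_in_vivo_ch4(fit, rcfg))
    out = table[["run", "emitter", "diet", "cnsl"]].copy()
    out["ch4_in_vivo"] = preds
    io.write_table(out, cfg.out_dir / "predictions.tsv", cfg.sep)
    log["rumen"] = {"residence_ne": rcfg.residence_ne, "residence_e": rcfg.residence_e,
                    "horizon": rcfg.horizon, "step": rcfg.step}


def _stage_vfa(cfg: PipelineConfig, log: dict) -> None:
    path = _require(_input_path(cfg, "vfa", "vfa.tsv"), "vfa")
    profiles = io.read_vfa_table(path, cfg.sep)
    blank_totals = {}
    for p in profiles:
        if p.meta.get("is_blank"):
            blank_totals.setdefault((p.meta.get("run"), p.meta.get("emitter")), []).append(p.total)
    rows = []
    for p in profiles:
        if p.meta.get("is_blank"):
            continue
        props = p.proportions()
        st = vfa_mod.stoichiometry(props)
        key = (p.meta.get("run"), p.meta.get("emitter"))
        net = (vfa_mod.blank_correct_vfa(p.total, blank_totals[key])
               if key in blank_totals else np.nan)
        rows.append({"run": p.meta.get("run"), "emitter": p.meta.get("emitter"),
                     "diet": p.meta.get("diet"), "cnsl": p.meta.get("cnsl"),
                     "total_vfa": p.total, "net_vfa": net,
                     "acetate": props.acetate, "propionate": props.propionate,
                     "butyrate": props.butyrate, "ch4_vfa": st.ch4_vfa,
                     "co2_vfa": st.co2_vfa,
                     "acetate_propionate": st.acetate_propionate,
                     "propionate_butyrate": st.propionate_butyrate,
                     "lipogenic_glucogenic": st.lipogenic_glucogenic})
    io.write_table(pd.DataFrame(rows), cfg.out_dir / "vfa_results.tsv", cfg.sep)
    log["vfa"] = {"n_samples": len(rows)}


def _stage_community(cfg: PipelineConfig, log: dict) -> None:
    otu_path = _require(_input_path(cfg, "otu", "otu.tsv"), "community")
    meta_path = _require(_input_path(cfg, "otu_meta", "otu_meta.tsv"), "community")
    table = io.read_otu_table(otu_path, meta_path, cfg.sep)
    ccfg = cfg.community
    filtered = community_mod.filter_otus(table,
                                         min_reads=int(ccfg.get("min_reads", 30)),
                                         min_samples=int(ccfg.get("min_samples", 3)))
    alpha = pd.DataFrame({sid: community_mod.alpha_diversity(filtered.counts.loc[sid])
                          for sid in filtered.counts.index}).T
    io.write_table(alpha, cfg.out_dir / "alpha.tsv", cfg.sep, index=True)
    phyla = community_mod.relative_abundance(filtered, "phylum")
    io.write_table(phyla, cfg.out_dir / "phylum_abundance.tsv", cfg.sep, index=True)
    arch = community_mod.archaeal_profile(filtered)
    io.write_table(arch, cfg.out_dir / "archaeal_clades.tsv", cfg.sep, index=True)

    metric = ccfg.get("metric", "bray_curtis")
    dmat = community_mod.beta_distance(filtered, metric)
    io.write_table(pd.DataFrame(dmat.data, index=dmat.ids, columns=dmat.ids),
                   cfg.out_dir / "beta_distance.tsv", cfg.sep, index=True)
    res = community_mod.pcoa(dmat)
    io.write_table(res.coordinates, cfg.out_dir / "pcoa.tsv", cfg.sep, index=True)

    groups = filtered.metadata.loc[list(filtered.counts.index), "emitter"]
    perm = community_mod.permanova(dmat, groups,
                                   n_permutations=int(ccfg.get("permutations", 9999)),
                                   seed=ccfg.get("seed"))
    rel = filtered.counts.div(filtered.counts.sum(axis=1), axis=0)
    runs = filtered.metadata.loc[list(filtered.counts.index), "run"]
    per_otu = community_mod.blocked_feature_test(rel, groups, runs)
    io.write_table(per_otu, cfg.out_dir / "per_otu_tests.tsv", cfg.sep, index=True)
    log["community"] = {
        "metric": metric, "permutations": perm.n_permutations,
        "seed": ccfg.get("seed"), "permanova_F": perm.pseudo_f,
        "permanova_p": perm.p_value,
        "n_otus_after_filter": filtered.n_otus,
    }


_ENDPOINTS = ("gas_asymptote", "gas_at_48", "gas_rate", "ch4_asymptote",
              "ch4_at_48", "ch4_rate", "ch4_to_gas_48", "ch4_in_vivo",
              "acetate", "propionate", "butyrate", "ch4_vfa")


def _stage_anova(cfg: PipelineConfig, log: dict) -> None:
    kin = io.read_table(_require(_input_path(cfg, "kinetics", "kinetics.tsv"), "anova"), cfg.sep)
    keys = ["run", "emitter", "diet", "cnsl"]
    merged = kin
    pred_path = _input_path(cfg, "predictions", "predictions.tsv")
    if Path(pred_path).exists():
        merged = merged.merge(io.read_table(pred_path, cfg.sep), on=keys)
    vfa_path = _input_path(cfg, "vfa_results", "vfa_results.tsv")
    if Path(vfa_path).exists():
        merged = merged.merge(io.read_table(vfa_path, cfg.sep), on=keys)
    if merged["run"].nunique() < 2:
        logger.warning("anova stage skipped: need >=2 runs for residual df")
        log["anova"] = {"skipped": "fewer than 2 runs"}
        return
    all_rows, mean_rows = [], []
    for endpoint in _ENDPOINTS:
        if endpoint not in merged.columns:
            continue
        design = merged[keys + [endpoint]].rename(columns={endpoint: "value"})
        res = trialstats.factorial_block_anova(design)
        for term, row in res.terms.iterrows():
            all_rows.append({"endpoint": endpoint, "term": term,
                             "df": row.get("df"), "sum_sq": row.get("sum_sq"),
                             "F": row.get("F"), "p": row.get("p")})
        for factor, means in res.lsmeans.items():
            lsd = trialstats.lsd_value(res.residual_ms, res.residual_df,
                                       res.n_per_mean[factor])
            for level, mean in means.items():
                mean_rows.append({"endpoint": endpoint, "factor": factor,
                                  "level": level, "lsmean": mean, "lsd": lsd})
    io.write_table(pd.DataFrame(all_rows), cfg.out_dir / "anova.tsv", cfg.sep)
    io.write_table(pd.DataFrame(mean_rows), cfg.out_dir / "lsmeans.tsv", cfg.sep)
    log["anova"] = {"endpoints": [e for e in _ENDPOINTS if e in merged.columns]}


def _write_report(cfg: PipelineConfig, log: dict) -> None:
    lines = ["rumeth pipeline report", "=" * 40, ""]
    if cfg.reference_profiles:
        lines.append("Stoichiometric CH4 worked examples (mmol/mol VFA):")
        for ref in cfg.reference_profiles:
            value = vfa_mod.ch4_vfa(float(ref["acetate"]), float(ref["propionate"]),
                                    float(ref["butyrate"]))
            lines.append(f"  {ref.get('label', 'profile')}: "
                         f"CH4_VFA = {value:.1f} (rounded {round(value)})")
        lines.append("")
    for stage in ALL_STAGES:
        if stage in log.get("stages_run", []):
            lines.append(f"stage {stage}: done")
    lines.append("")
    lines.append("config and seeds:")
    lines.append(json.dumps({k: v for k, v in log.items() if k != "stages_run"},
                            indent=2, default=str, sort_keys=True))
    (cfg.out_dir / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rank": _stage_rank,
    "gaskin": _stage_gaskin,
    "predict": _stage_predict,
    "vfa": _stage_vfa,
    "community": _stage_community,
    "anova": _stage_anova,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run enabled stages in order; partial outputs are kept on failure."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    log = {"stages_run": []}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, log)
        log["stages_run"].append(stage)
    _write_report(cfg, log)
    (cfg.out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2, default=str, sort_keys=True) + "\n")
    return log
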