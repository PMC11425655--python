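"""End-to-end pipeline: simulate -> adsorption -> community -> network -> SEM.

``run_all`` executes the stages in dependency order from one configuration
mapping (YAML-friendly), writes each stage's tables under the output
directory and aggregates a machine-readable ``summary.json``.  All
randomness flows from the single ``seed`` through per-stage
``SeedSequence`` spawns, so reruns with the same seed are byte-identical
(no timestamps are recorded).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import adsorb, community, envstats, netfun, plspm, synthgen, wgcna


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthgen": {"enabled": True},
    "inputs": {},                    # otu/taxonomy/labels/env paths when not simulating
    "adsorb": {"kinetic_noise_sd": 0.02, "isotherm_noise_sd": 0.02},
    "wgcna": {"power": 6},
    "netfun": {"threshold": 0.9},
    "envstats": {"n_perm": 999},
    "permanova": {"n_perm": 999},
    "plspm": {"n_boot": 200},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_all(config: dict | None = None, outdir: str | Path = "run") -> dict:
    """Run the full pipeline; returns the summary dict (also written as JSON)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = _stage_seeds(seed, 8)
    summary: dict = {"seed": seed}

    # -- stage 1: inputs ----------------------------------------------------
    stage = "synthgen"
    try:
        if cfg["synthgen"].get("enabled", True):
            comm_kwargs = {
                k: v for k, v in cfg["synthgen"].items() if k != "enabled"
            }
            comm = synthgen.gen_community(
                synthgen.CommunityConfig(seed=seeds[0], **comm_kwargs)
            )
            table = comm.table
            trait = comm.trait
            env = synthgen.gen_env(
                synthgen.EnvConfig(seed=seeds[1]), table.treatments
            )
            env["p_CA"] = trait  # community-coupled trait is the p-CA record
            inp = outdir / "inputs"
            inp.mkdir(exist_ok=True)
            synthgen.write_otu_table(
                table, inp / "otu.tsv", inp / "taxonomy.tsv", inp / "labels.csv"
            )
            synthgen.write_env(env, inp / "env.csv")
        else:
            paths = cfg["inputs"]
            for key in ("otu", "taxonomy", "labels", "env"):
                if key not in paths:
                    raise ValueError(
                        f"synthgen disabled but inputs.{key} not configured"
                    )
            table = community.load_otu_table(
                paths["otu"], paths["taxonomy"], paths["labels"]
            )
            env = pd.read_csv(paths["env"], index_col=0)
            trait = env["p_CA"]
    except Exception as exc:  # noqa: BLE001 - single failure surface per stage
        raise PipelineError(stage, exc) from exc

    # -- stage 2: adsorption ------------------------------------------------
    stage = "adsorb"
    try:
        kin = synthgen.gen_adsorption(
            synthgen.AdsorptionSimConfig(
                model="pke",
                noise_sd=cfg["adsorb"]["kinetic_noise_sd"],
                seed=seeds[2],
            )
        )
        kin_fits = [adsorb.fit_kinetics(kin, m) for m in adsorb.KINETIC_MODELS]
        kin_ranked, _ = adsorb.model_compare(kin_fits)
        iso = synthgen.gen_adsorption(
            synthgen.AdsorptionSimConfig(
                model="langmuir",
                noise_sd=cfg["adsorb"]["isotherm_noise_sd"],
                seed=seeds[3],
            )
        )
        iso_fits = [adsorb.fit_isotherm(iso, m) for m in adsorb.ISOTHERM_MODELS]
        iso_ranked, _ = adsorb.model_compare(iso_fits)
        synthgen.write_adsorption(kin, outdir / "adsorption_kinetics.csv")
        synthgen.write_adsorption(iso, outdir / "adsorption_isotherm.csv")
        summary["adsorption"] = {
            "kinetic_ranking": [
                {"model": f.model, "r_squared": round(f.r_squared, 6),
                 "params": {k: round(v, 6) for k, v in f.params.items()}}
                for f in kin_ranked
            ],
            "isotherm_ranking": [
                {"model": f.model, "r_squared": round(f.r_squared, 6),
                 "params": {k: round(v, 6) for k, v in f.params.items()}}
                for f in iso_ranked
            ],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 3: community -------------------------------------------------
    stage = "community"
    try:
        alpha = community.alpha_diversity(table)
        alpha.to_csv(outdir / "alpha_diversity.csv")
        groups = table.treatments
        deltas = {
            idx: round(
                float(
                    (alpha.loc[groups == "AB", idx].mean()
                     - alpha.loc[groups == "NB", idx].mean())
                    / alpha.loc[groups == "NB", idx].mean() * 100.0
                ), 4,
            )
            for idx in ("Sobs", "Shannon", "Simpson")
        }
        bc = community.bray_curtis(table)
        ord_res = community.pcoa(bc)
        ord_res.coordinates.iloc[:, :2].to_csv(outdir / "pcoa.csv")
        perm = community.permanova(
            bc, groups, n_perm=cfg["permanova"]["n_perm"], seed=seeds[4]
        )
        top = community.top_genera_summary(table, k=10)
        summary["community"] = {
            "alpha_percent_change_AB_vs_NB": deltas,
            "permanova": {
                "pseudo_F": round(perm.statistic, 4),
                "r_squared": round(perm.r_squared, 4),
                "r": round(float(np.sqrt(perm.r_squared)), 4),
                "p": round(perm.p_value, 6),
            },
            "top10_cumulative_share": {
                g: round(v["cumulative_share"], 4) for g, v in top.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 4: co-expression network --------------------------------------
    stage = "wgcna"
    try:
        wcfg = wgcna.WGCNAConfig(seed=seeds[5])
        res = wgcna.run_wgcna(
            table, trait, wcfg, power=cfg["wgcna"].get("power", 6)
        )
        res.assignment.labels.to_csv(outdir / "modules.tsv", sep="\t")
        res.assignment.eigentaxa.to_csv(outdir / "eigentaxa.csv")
        res.ms_tm.to_csv(outdir / "ms_tm.tsv", sep="\t")
        res.module_trait.table.to_csv(outdir / "module_trait.csv")
        summary["wgcna"] = {
            "power": res.power,
            "n_modules": len(res.assignment.modules),
            "keystone_module": res.module_trait.keystone,
            "keystone_r": round(
                float(res.module_trait.table.loc[res.module_trait.keystone, "r"]), 4
            ),
            "keystone_p": round(
                float(res.module_trait.table.loc[res.module_trait.keystone, "p"]), 6
            ),
            "keystone_significant": res.module_trait.significant,
            "hub_genera": list(res.hub_genera.index),
            "role_counts": {
                role: int((res.ms_tm["role"] == role).sum())
                for role in wgcna.ROLES
            },
        }
        keystone_otus = res.assignment.members(res.module_trait.keystone)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 5: co-occurrence + functions ----------------------------------
    stage = "netfun"
    try:
        gm = netfun.genus_abundance(table, otus=keystone_otus)
        nets = {}
        for grp in ("NB", "AB"):
            cols = list(table.treatments.index[table.treatments == grp])
            cols = [c for c in cols if c in gm.columns]
            g = netfun.spearman_network(
                gm, threshold=cfg["netfun"]["threshold"], samples=cols
            )
            nets[grp] = netfun.network_stats(g)
        rules = netfun.load_rules()
        annot = netfun.annotate_functions(table.taxonomy, rules)
        fab = netfun.function_abundance(table, annot, restrict_to=keystone_otus)
        fab.to_csv(outdir / "function_abundance.csv")
        acd = "aromatic_compound_degradation"
        func_deltas = {}
        for f in fab.index:
            nb = fab.loc[f, table.treatments == "NB"].mean()
            ab = fab.loc[f, table.treatments == "AB"].mean()
            func_deltas[f] = {"NB_mean": round(float(nb), 6),
                              "AB_mean": round(float(ab), 6)}
        summary["netfun"] = {
            "network_stats": nets,
            "function_abundance": func_deltas,
            "acd_enriched_in_AB": bool(
                acd in fab.index
                and func_deltas[acd]["AB_mean"] > func_deltas[acd]["NB_mean"]
            ),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 6: environment statistics -------------------------------------
    stage = "envstats"
    try:
        comp = envstats.compare_groups(env, table.treatments)
        comp.to_csv(outdir / "group_comparisons.csv")
        rho, pval = envstats.pairwise_env_corr(env)
        rho.to_csv(outdir / "env_spearman.csv")
        grid = envstats.mantel_grid(
            community.bray_curtis(table), env,
            n_perm=cfg["envstats"]["n_perm"], seed=seeds[6],
        )
        grid.to_csv(outdir / "mantel.csv")
        summary["envstats"] = {
            "percent_change": {
                v: round(float(comp.loc[v, "percent_change"]), 4)
                for v in comp.index
            },
            "mantel_top_driver": str(grid["mantel_r"].idxmax()),
            "mantel": {
                v: {"r": round(float(grid.loc[v, "mantel_r"]), 4),
                    "p": round(float(grid.loc[v, "p"]), 6)}
                for v in grid.index
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 7: PLS path model ---------------------------------------------
    stage = "plspm"
    try:
        hub_otus = [
            o for o in keystone_otus
            if res.ms_tm.loc[o, "role"] == "hub"
        ] or keystone_otus
        rel = table.relative_abundance()
        data = pd.DataFrame(
            {
                "biochar": (table.treatments == "AB").astype(float),
                "pH": env["pH"],
                "SOM": env["SOM"],
                "Shannon": alpha["Shannon"],
                "hub_abundance": rel.loc[hub_otus].sum(axis=0),
                "acd_abundance": fab.loc[acd] if acd in fab.index else 0.0,
                "p_CA": env["p_CA"],
            }
        )
        model = plspm.biochar_path_model()
        fit = plspm.fit_plspm(data, model)
        boot = plspm.bootstrap_paths(
            data, model, n_boot=cfg["plspm"]["n_boot"], seed=seeds[7]
        )
        boot.to_csv(outdir / "plspm_bootstrap.csv")
        summary["plspm"] = {
            "gof": round(fit.gof, 4),
            "paths": {
                k: round(float(v), 4)
                for k, v in fit.paths["coefficient"].items()
            },
            "r_squared": {k: round(v, 4) for k, v in fit.r_squared.items()},
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
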