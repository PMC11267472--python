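"""Stage orchestration: chain the simulator and the three screens.

``run_pipeline(config, screen)`` executes one of:

* ``simulate`` — founder panel, AIP, phenotypes, covariates, pools;
* ``dgrp-gwa`` — line means, covariate adjustment, GRM, LMM scan;
* ``xqtl`` — replicated high vs control pool Z scan;
* ``divergence`` — unpaired all-pairs minimal-difference scan.

Each stage writes deterministic TSVs carrying the tool version and config
hash, plus a plain-text ``run.log`` of key=value provenance lines.
"""

from __future__ import annotations

import hashlib
import os
import time

import numpy as np
import pandas as pd

from . import __version__, gwa, io, quantgen, synthetic_data, xqtl
from .config import RunConfig
from .datatypes import InversionBlock, TraitModel


def _log(cfg: RunConfig, lines: list[str]) -> None:
    path = os.path.join(cfg.out_dir, "run.log")
    with open(path, "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def _checksum(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:12]


def run_pipeline(config: RunConfig, screen: str) -> dict:
    """Run one screen; returns a dict of output paths and key results."""
    io.ensure_dir(config.out_dir)
    h = config.config_hash()
    _log(config, [f"stage={screen} version={__version__} config_hash={h} "
                  f"seed={config.seed} time={time.strftime('%Y-%m-%dT%H:%M:%S')}"])
    try:
        if screen == "simulate":
            return _run_simulate(config, h)
        if screen == "dgrp-gwa":
            return _run_gwa(config, h)
        if screen == "xqtl":
            return _run_xqtl(config, h)
        if screen == "divergence":
            return _run_divergence(config, h)
    except Exception as exc:
        _log(config, [f"stage={screen} status=error error={exc!r}"])
        raise RuntimeError(f"stage {screen!r} failed: {exc}") from exc
    raise ValueError(f"unknown screen {screen!r}")


def _paths(cfg: RunConfig) -> dict:
    d = cfg.out_dir
    return {
        "genotypes": os.path.join(d, "genotypes.tsv"),
        "phenotypes": os.path.join(d, "phenotypes.tsv"),
        "covariates": os.path.join(d, "covariates.tsv"),
        "pools": os.path.join(d, "pool_counts.tsv"),
        "assoc": os.path.join(d, "association.tsv"),
        "xqtl": os.path.join(d, "xqtl_scan.tsv"),
        "divergence": os.path.join(d, "divergence.tsv"),
    }


def _run_simulate(cfg: RunConfig, h: str) -> dict:
    paths = _paths(cfg)
    panel = synthetic_data.simulate_founders(
        cfg.n_lines,
        cfg.n_variants,
        inversion_spec={
            "In(3R)K": InversionBlock("3R", 7_576_289, 21_966_092, 0.1),
        },
        seed=cfg.seed_for("founders"),
    )
    io.write_genotypes(panel.genotypes, paths["genotypes"], h)
    cov = panel.karyotypes.copy()
    cov["wolbachia"] = np.where(panel.wolbachia, "y", "n")
    io.write_covariates(cov, paths["covariates"], h)
    pheno = synthetic_data.simulate_line_phenotypes(
        n_lines=cfg.n_lines,
        replicates=10,
        seed=cfg.seed_for("phenotypes"),
        line_ids=panel.line_ids,
    )
    io.write_phenotypes(pheno, paths["phenotypes"], h)

    aip = synthetic_data.build_aip(
        panel, generations=cfg.aip_generations, seed=cfg.seed_for("aip")
    )
    rng = np.random.default_rng(cfg.seed_for("trait"))
    model = TraitModel.from_h2(aip, n_causal=5, h2=0.3, rng=rng)
    pools = []
    for rep in range(1, 5):
        for grp, rule in (("high", "k-fastest"), ("control", "k-random")):
            males = np.flatnonzero(aip.is_male)
            chosen = rng.choice(males, size=min(500, len(males)), replace=False)
            model.assign_liabilities(aip, rng)
            assay = synthetic_data.simulate_mating_assay(
                aip, model, male_idx=chosen, window=cfg.assay_window,
                seed=cfg.seed_for(f"assay_{grp}_{rep}"),
            )
            try:
                ids = synthetic_data.truncation_select(
                    assay, rule, 50, seed=cfg.seed_for(f"select_{grp}_{rep}")
                )
            except ValueError:
                ids = rng.choice(chosen, size=50, replace=False)
            pools.append(
                synthetic_data.simulate_pool_seq(
                    aip, coverage_law=60, member_idx=ids,
                    seed=cfg.seed_for(f"poolseq_{grp}_{rep}"),
                    pool_id=f"{grp}{rep}", group=grp, replicate=rep,
                )
            )
    io.write_pool_counts(pools, paths["pools"], h)
    _log(cfg, [f"stage=simulate status=ok outputs={sorted(paths)} "
               + " ".join(f"sha_{k}={_checksum(v)}" for k, v in paths.items()
                          if os.path.exists(v))])
    return {"paths": paths}


def _run_gwa(cfg: RunConfig, h: str) -> dict:
    paths = {**_paths(cfg), **cfg.paths}
    g = io.read_genotypes(paths["genotypes"])
    pheno = io.read_phenotypes(paths["phenotypes"])
    cov = io.read_covariates(paths["covariates"])
    means = quantgen.line_means(pheno)
    adjusted = gwa.adjust_phenotype(means, cov, include_inversions=cfg.adjust_inversions)
    g = gwa.maf_filter(g, cfg.maf_threshold)
    K = gwa.compute_grm(g)
    assoc = gwa.lmm_association(adjusted, g, K)
    io.write_table(assoc, paths["assoc"], h)
    thr = gwa.bonferroni_threshold(0.05, len(assoc))
    _log(cfg, [f"stage=dgrp-gwa status=ok n_variants={len(assoc)} "
               f"bonferroni={thr:.3g} sha_assoc={_checksum(paths['assoc'])}"])
    return {"paths": paths, "n_variants": len(assoc), "bonferroni": thr,
            "association": assoc}


def _run_xqtl(cfg: RunConfig, h: str) -> dict:
    paths = {**_paths(cfg), **cfg.paths}
    pools = io.read_pool_counts(paths["pools"])
    high = [p for p in pools if p.group == "high"]
    control = [p for p in pools if p.group == "control"]
    scan = xqtl.xqtl_scan(high, control, cfg.report_threshold, mode=cfg.z_mode)
    io.write_table(scan, paths["xqtl"], h)
    _log(cfg, [f"stage=xqtl status=ok n_variants={len(scan)} "
               f"n_significant={int(scan['significant'].sum())} "
               f"sha_xqtl={_checksum(paths['xqtl'])}"])
    return {"paths": paths, "scan": scan}


def _run_divergence(cfg: RunConfig, h: str) -> dict:
    paths = {**_paths(cfg), **cfg.paths}
    pools = io.read_pool_counts(paths["pools"])
    selected = [p for p in pools if p.group in ("high", "selected")]
    control = [p for p in pools if p.group == "control"]
    summary, pair_stats = xqtl.allpairs_divergence(
        selected, control, cfg.report_threshold, mode=cfg.z_mode
    )
    io.write_table(summary, paths["divergence"], h)
    _log(cfg, [f"stage=divergence status=ok n_pass={int(summary['pass'].sum())} "
               f"sha_divergence={_checksum(paths['divergence'])}"])
    return {"paths": paths, "summary": summary, "pairs": pair_stats}
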