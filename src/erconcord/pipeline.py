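"""End-to-end orchestration: data in, candidate/window/block tables out.

A :class:`RunConfig` (loadable from YAML) names either a sync file with a
column map or a synthetic-experiment configuration, plus the analysis
parameters (FDR target, window size, iteration counts, seed).  ``run_all``
executes: polarization -> segregation mask -> temporal Ne per time point ->
candidate scan per time point -> window enrichment -> concordance
(SNP and window level) -> block analysis (when assignments are supplied or
simulated), writing every stage's TSV, a provenance sidecar, and a JSON
run report with per-stage record counts.  Each stage is an importable
function, so intermediate tables can be regenerated individually.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blocks as blk
from . import concordance as conc
from . import windows as win
from .candidates import CandidateSet, scan_timepoint
from .ne import average_ne, estimate_ne_tensor
from .simulate import SimConfig, make_blocks, simulate_experiment
from .sync_io import (
    CountTensor,
    block_members,
    polarize_rising,
    read_block_table,
    read_sync,
    segregating_mask,
    write_provenance,
    write_sync,
)

log = logging.getLogger("erconcord")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (single source of truth)."""

    out_dir: str = "erconcord_out"
    seed: int = 0
    # input: either a sync file + column map, or a simulation config
    sync_path: str | None = None
    column_map: list | None = None  # [(replicate, generation), ...]
    sim: SimConfig | None = None
    block_path: str | None = None
    recmap_path: str | None = None
    synthetic_block_window_bp: int = 100_000
    # analysis parameters; pool_size None = whole census pooled
    pool_size: int | None = None
    fdr_q: float = 0.05
    window_snps: int = 5000
    enrichment_iterations: int = 1000
    n_boot: int = 10_000
    min_block_recovery: float = 0.9
    early_generation: int = 20
    afc_threshold: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            if "generations" in sim_raw:
                sim_raw["generations"] = tuple(sim_raw["generations"])
            cfg.sim = SimConfig(**sim_raw)
        if cfg.column_map is not None:
            cfg.column_map = [tuple(x) for x in cfg.column_map]
        return cfg

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        if self.sim is not None:
            d["sim"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.sim.__dict__.items()
                if not isinstance(v, np.ndarray)
            }
        return d


def _load_input(cfg: RunConfig):
    """Returns (CountTensor polarized, truth-or-None, block members dict|None)."""
    if cfg.sim is not None:
        sim = cfg.sim
        if sim.seed == 0 and cfg.seed:
            sim.seed = cfg.seed
        truth, ct = simulate_experiment(sim)
        ct = polarize_rising(ct)
        members_df = make_blocks(truth, cfg.synthetic_block_window_bp)
        members = (
            block_members(members_df, ct) if len(members_df) else None
        )
        return ct, truth, members
    if cfg.sync_path is None or cfg.column_map is None:
        raise ValueError("config needs either `sim` or sync_path + column_map")
    ct = polarize_rising(read_sync(cfg.sync_path, cfg.column_map))
    members = None
    if cfg.block_path:
        members = block_members(read_block_table(cfg.block_path), ct)
    return ct, None, members


def candidate_scan_all(
    ct: CountTensor,
    mask: np.ndarray,
    pool_size: int,
    q: float,
    seed: int,
) -> tuple[dict[int, CandidateSet], pd.DataFrame]:
    """Ne estimation + CMH candidate scan at every post-zero generation."""
    gens = [int(g) for g in ct.timepoints if g > 0]
    ne_rows = []
    cands: dict[int, CandidateSet] = {}
    for i, g in enumerate(gens):
        ests = estimate_ne_tensor(ct, t=g, pool_size=pool_size)
        for e in ests:
            ne_rows.append(
                {
                    "replicate": e.scope,
                    "chromosome_class": e.chromosome_class,
                    "t": e.t,
                    "ne": e.ne,
                    "unbounded": e.unbounded,
                }
            )
        avg = average_ne(ests)
        ne_auto = avg.get("autosome") or avg.get("X")
        ne_val = (
            ne_auto.ne if ne_auto is not None and not ne_auto.unbounded
            else float(pool_size)
        )
        cands[g] = scan_timepoint(
            ct, t=g, ne=ne_val, q=q, seed=seed + 17 * (i + 1), snp_mask=mask
        )
        log.info(
            "gen %d: Ne=%.0f, %d/%d candidates (FDR %.3f)",
            g, ne_val, len(cands[g]), cands[g].extra["n_tested"],
            cands[g].fdr if np.isfinite(cands[g].fdr) else float("nan"),
        )
    return cands, pd.DataFrame(ne_rows)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the result tables and report."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_jsonable(), "stages": {}}
    results: dict = {}

    ct, truth, members = _load_input(cfg)
    report["stages"]["input"] = {
        "n_snps": ct.n_snps,
        "n_replicates": ct.n_replicates,
        "timepoints": [int(t) for t in ct.timepoints],
    }
    if cfg.sim is not None:
        write_sync(ct, out / "experiment.sync")

    mask = segregating_mask(ct)
    report["stages"]["segregation_mask"] = {
        "n_segregating": int(mask.sum()),
        "n_dropped": int((~mask).sum()),
    }
    log.info("segregating in all generations/replicates: %d", mask.sum())

    cands, ne_df = candidate_scan_all(
        ct, mask, cfg.pool_size, cfg.fdr_q, cfg.seed
    )
    ne_df.to_csv(out / "ne_estimates.tsv", sep="\t", index=False)
    cand_rows = []
    for g, cs in cands.items():
        cand_rows.append(
            {
                "generation": g,
                "n_candidates": len(cs),
                "threshold": cs.threshold,
                "achieved_fdr": cs.fdr,
                "n_tested": cs.extra["n_tested"],
            }
        )
        df = pd.DataFrame(
            {"snp": cs.all_snp_ids, "cmh_p": cs.all_pvalues}
        )
        df["candidate"] = df["snp"].isin(cs.as_set()).astype(int)
        df.to_csv(out / f"candidates_gen{g}.tsv", sep="\t", index=False)
    pd.DataFrame(cand_rows).to_csv(
        out / "candidate_summary.tsv", sep="\t", index=False
    )
    report["stages"]["candidates"] = {
        str(g): len(cs) for g, cs in cands.items()
    }
    results["candidates"] = cands
    results["ne"] = ne_df

    wt = win.build_windows(ct, mask, window_snps=cfg.window_snps)
    enr_tables = {}
    window_sets: dict[int, set] = {}
    for i, (g, cs) in enumerate(sorted(cands.items())):
        enr = win.enrichment_null(
            wt, cs, iterations=cfg.enrichment_iterations,
            seed=cfg.seed + 31 * (i + 1),
        )
        enr_tables[g] = enr
        window_sets[g] = win.candidate_windows(enr)
    if enr_tables:
        pd.concat(enr_tables.values()).to_csv(
            out / "window_enrichment.tsv", sep="\t", index=False
        )
    report["stages"]["windows"] = {
        "n_windows": wt.n_windows,
        "enriched": {str(g): len(s) for g, s in window_sets.items()},
    }
    results["windows"] = wt
    results["window_sets"] = window_sets

    snp_sets = {g: cs.as_set() for g, cs in cands.items()}
    sim_snp = conc.similarity_matrix(
        snp_sets, universe_size=int(mask.sum()), level="snp",
        n_boot=cfg.n_boot, seed=cfg.seed + 101,
    )
    sim_win = conc.similarity_matrix(
        window_sets, universe_size=max(wt.n_windows, 1), level="window",
        n_boot=cfg.n_boot, seed=cfg.seed + 102,
    )
    sim_all = pd.concat([sim_snp, sim_win], ignore_index=True)
    sim_all.to_csv(out / "jaccard.tsv", sep="\t", index=False)
    cons_snp = conc.consistency_profile(snp_sets)
    cons_snp["level"] = "snp"
    cons_win = conc.consistency_profile(window_sets)
    cons_win["level"] = "window"
    pd.concat([cons_snp, cons_win], ignore_index=True).to_csv(
        out / "consistency.tsv", sep="\t", index=False
    )
    fix = conc.fixation_ratio(ct, snp_sets)
    fix.to_csv(out / "fixation.tsv", sep="\t", index=False)
    results["jaccard"] = sim_all
    results["consistency"] = {"snp": cons_snp, "window": cons_win}
    results["fixation"] = fix
    report["stages"]["concordance"] = {
        "n_pairs": int(len(sim_all)),
        "max_fixation_ratio": float(fix["ratio"].max()) if len(fix) else 0.0,
    }

    if members:
        final_g = max(cands)
        kept = blk.filter_blocks(
            members, ct, cands[final_g], cfg.min_block_recovery
        )
        report["stages"]["blocks"] = {
            "n_blocks_in": len(members),
            "n_blocks_kept": len(kept),
        }
        log.info("blocks kept after recovery filter: %d/%d",
                 len(kept), len(members))
        if kept:
            hm = blk.hadr_matrix(kept, ct, cands)
            hm.to_csv(out / "hadr_matrix.tsv", sep="\t")
            edha = blk.find_edha(
                hm, early_generation=cfg.early_generation,
                seed=cfg.seed + 201,
            )
            recmap = (
                pd.read_csv(cfg.recmap_path, sep="\t")
                if cfg.recmap_path
                else None
            )
            bt = blk.block_table(
                kept, ct, cands, recmap=recmap,
                early_generation=cfg.early_generation,
                final_generation=final_g,
                afc_threshold=cfg.afc_threshold,
                edha_flags=edha["edha"],
            )
            bt.to_csv(out / "block_table.tsv", sep="\t")
            if edha["edha"].any() and (~edha["edha"]).any():
                ft = blk.compare_features(bt)
                ft.to_csv(out / "feature_tests.tsv", sep="\t", index=False)
                results["feature_tests"] = ft
            results["hadr"] = hm
            results["edha"] = edha
            results["block_table"] = bt
            report["stages"]["blocks"]["n_edha"] = int(edha["edha"].sum())

    report["runtime_s"] = round(time.time() - t_start, 2)
    report["seed"] = cfg.seed
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    write_provenance(out / "run", report["config"] | {"seed": cfg.seed})
    results["report"] = report
    return results
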