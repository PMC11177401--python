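"""End-to-end orchestration: simulate -> call -> copy number -> selection ->
inheritance, with a consolidated, fully seed-determined run report.

Defaults reproduce the analysis settings used throughout the package: 2%
(and 5% strict) heteroplasmy filters, Q30/Q90 site quality, per-sample depth
10-500, 25 bp depth windows, Pi windows of 500 sites stepping 100, and 1 kb
repeat flanks.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, copynum, inheritance, selection, simulate
from .genome import read_fasta, read_features

log = logging.getLogger("mitohet")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mitohet_run"
    # stage toggles
    do_simulate: bool = True
    do_call: bool = True
    do_copynum: bool = True
    do_selection: bool = True
    do_inheritance: bool = True
    # analysis parameters (defaults mirror the published settings)
    min_freq: float = 0.02
    strict_freq: float = 0.05
    min_depth: int = 10
    max_depth: int = 500
    min_qual: float = 30.0
    max_missing_frac: float = 0.10
    depth_window: int = 25
    pi_window: int = 500
    pi_step: int = 100
    repeat_flank: int = 1000
    alpha_sig: float = 0.05
    majority_threshold: float = 0.50
    # pooled codon analysis uses sites recurring in >= this many individuals,
    # suppressing singleton error calls before tabulation
    selection_min_recurrence: int = 2
    # external inputs when simulation is off
    genome_path: str | None = None
    gff_path: str | None = None
    counts_dir: str | None = None
    pedigree_path: str | None = None
    totals_path: str | None = None
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)


class StageError(RuntimeError):
    """Missing upstream output for an enabled stage."""


def validate_inputs(
    counts: dict | None,
    pedigree: pd.DataFrame | None,
    l_mt: int | None,
) -> dict:
    """Cross-file consistency checks; errors vs warnings distinguished."""
    errors, warnings_ = [], []
    if pedigree is not None:
        ped_errors, ped_warnings = inheritance.validate_pedigree(pedigree)
        errors += ped_errors
        warnings_ += ped_warnings
        if counts is not None:
            missing = set(pedigree["id"]) - set(counts)
            if missing:
                warnings_.append(
                    f"pedigree individuals without counts tables: {sorted(missing)}"
                )
    if counts is not None and l_mt:
        for ind, df in counts.items():
            if (df["pos"] > l_mt).any():
                errors.append(f"{ind}: counts positions exceed L_mt={l_mt}")
    return {"errors": errors, "warnings": warnings_}


def run_all(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order and write a report.

    Identical (config, seed) yields identical outputs: all randomness flows
    through the run seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    from . import __version__

    report["version"] = __version__

    config.sim.seed = config.seed
    if config.do_simulate:
        log.info("simulating matriline (seed=%d)", config.seed)
        artifacts = simulate.write_all(config.sim, outdir / "sim")
        genome = artifacts["genome_obj"]
        annotation = artifacts["annotation"]
        state = artifacts["state"]
        tables = artifacts["tables"]
        totals = artifacts["totals_df"]
        pedigree = state.pedigree
        report["stages"]["simulate"] = {
            "n_individuals": len(state.individuals),
            "n_true_variable_sites": int((state.freqs > 0).any(axis=0).sum()),
        }
    else:
        if not (config.genome_path and config.counts_dir):
            raise StageError("analysis stages need a genome and counts dir")
        genome = read_fasta(config.genome_path)
        annotation = read_features(config.gff_path) if config.gff_path else []
        tables = {
            p.name.removesuffix(".counts.tsv"): calling.read_counts_tsv(p)
            for p in sorted(Path(config.counts_dir).glob("*.counts.tsv"))
        }
        state = None
        pedigree = (
            simulate.read_pedigree(config.pedigree_path)
            if config.pedigree_path
            else None
        )
        totals = (
            copynum.read_totals(config.totals_path) if config.totals_path else None
        )

    validation = validate_inputs(tables, pedigree, len(genome))
    report["validation"] = validation
    if validation["errors"]:
        raise StageError(f"input validation failed: {validation['errors']}")

    sites = summaries = None
    if config.do_call:
        sites = calling.call_many(tables, config.min_freq, config.min_depth)
        summaries = calling.summarize_all(sites, len(genome), list(tables))
        sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
        report["stages"]["call"] = {
            "n_individuals": len(tables),
            "n_called_sites": len(sites),
            "mean_n_variable": float(summaries["n_variable"].mean()),
        }

    ratios = None
    if config.do_copynum:
        if totals is None:
            raise StageError("copy-number stage needs read totals")
        ratios = copynum.copy_ratio_table(totals)
        ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
        stage = {
            "ratio_min": float(ratios["ratio"].min()),
            "ratio_max": float(ratios["ratio"].max()),
        }
        if summaries is not None:
            assoc = copynum.ratio_vs_het_association(ratios, summaries)
            stage["association"] = {
                "slope": assoc.slope,
                "r2": assoc.r2,
                "p": assoc.p,
                "n": assoc.n,
            }
        report["stages"]["copynum"] = stage

    if config.do_selection:
        if sites is None:
            raise StageError("selection stage needs called sites")
        sel_sites = sites
        if config.selection_min_recurrence > 1:
            rec = sites.groupby("pos")["individual"].nunique()
            keep = rec[rec >= config.selection_min_recurrence].index
            sel_sites = sites[sites["pos"].isin(keep)]
        counts = selection.tabulate_positions(sel_sites, genome, annotation)
        total = counts.get("total", selection.PositionCounts("total"))
        chi13 = (
            selection.chisq_positions(total.n1, total.n3)
            if total.n1 + total.n3
            else None
        )
        chi23 = (
            selection.chisq_positions(total.n2, total.n3)
            if total.n2 + total.n3
            else None
        )
        selection.per_gene_report(counts).to_csv(
            outdir / "selection.tsv", sep="\t", index=False
        )
        report["stages"]["selection"] = {
            "n1": total.n1,
            "n2": total.n2,
            "n3": total.n3,
            "n_syn": total.n_syn,
            "n_nonsyn": total.n_nonsyn,
            "chi2_13": chi13.statistic if chi13 else None,
            "p_13": chi13.p if chi13 else None,
            "chi2_23": chi23.statistic if chi23 else None,
            "p_23": chi23.p if chi23 else None,
        }

    if config.do_inheritance:
        if sites is None or pedigree is None:
            raise StageError("inheritance stage needs called sites and a pedigree")
        focal = pedigree[pedigree["mother"].isin(["C451", "C452"])]["id"].tolist()
        stage: dict = {}
        if focal:
            assignments = inheritance.assign_all(
                sites, "C451", "C452", focal, config.alpha_sig
            )
            assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
            truth = dict(zip(pedigree["id"], pedigree["mother"]))
            loose = assignments["loose_mother"]
            assigned = loose.notna()
            correct = sum(
                truth[o] == m for o, m in zip(assignments["offspring"], loose) if m
            )
            stage["assignment"] = {
                "n_offspring": len(focal),
                "n_loose_assigned": int(assigned.sum()),
                "n_loose_correct": int(correct),
                "n_strict_assigned": int(assignments["strict_mother"].notna().sum()),
            }
            if summaries is not None:
                merged = assignments.merge(
                    summaries, left_on="offspring", right_on="individual"
                )
                g1 = merged[merged["strict_mother"] == "C451"][
                    "mean_freq_excl_zero"
                ].dropna()
                g2 = merged[merged["strict_mother"] == "C452"][
                    "mean_freq_excl_zero"
                ].dropna()
                if len(g1) >= 2 and len(g2) >= 2:
                    t = inheritance.group_comparison(g1, g2)
                    stage["group_comparison"] = {
                        "mean_C451": t.mean1,
                        "mean_C452": t.mean2,
                        "t": t.t,
                        "df": t.df,
                        "p": t.p,
                    }
        majority = inheritance.count_majority_variants(
            sites, config.majority_threshold
        )
        rate = (
            inheritance.pedigree_mutation_rate(len(majority), len(tables), len(genome))
            if len(tables)
            else None
        )
        stage["n_majority_variants"] = len(majority)
        if rate is not None:
            stage["mutation_rate"] = rate.rate
            stage["mutation_rate_2sf"] = rate.rate_2sf
        sibs = sites[sites["individual"].isin(focal)] if focal else sites
        if focal and len(sibs):
            shared = inheritance.shared_site_stats(
                inheritance.het_matrix_from_sites(sibs, focal)
            )
            stage["shared_sites"] = {
                "mean_fraction_pct": shared.mean_fraction,
                "sd_fraction_pct": shared.sd_fraction,
                "n_positions": shared.n_variable_positions,
            }
        report["stages"]["inheritance"] = stage

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
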