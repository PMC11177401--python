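"""Shared fixtures: a small simulated genome for fast tests and
session-scoped benchmark runs reused by module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitohet import calling, copynum, inheritance
from mitohet import simulate as sim

SMALL_LAYOUT = [
    ("G1", "PCG", 900),
    ("trnX", "tRNA", 66),
    ("G2", "PCG", 600),
    ("rrnS", "rRNA", 300),
]


def small_config(**overrides) -> sim.SimConfig:
    base = dict(
        seed=1,
        L_mt=3000,
        gene_layout=SMALL_LAYOUT,
        founder_het_sites=120,
        offspring_per_cross=10,
        n_extra_sibs=2,
        n_grandoffspring=2,
        mean_depth=80.0,
        repeat_region=(2600, 2900),
    )
    base.update(overrides)
    return sim.SimConfig(**base)


@pytest.fixture(scope="session")
def small_genome():
    cfg = small_config()
    genome, annotation = sim.simulate_genome(cfg)
    return genome, annotation


@pytest.fixture(scope="session")
def small_nonsyn_table(small_genome):
    genome, annotation = small_genome
    return sim.nonsynonymous_table(genome, annotation)


@pytest.fixture(scope="session")
def small_run(small_genome, small_nonsyn_table):
    """One simulated matriline with readcounts and called sites."""
    genome, annotation = small_genome
    cfg = small_config()
    state = sim.simulate_matriline(cfg, genome, annotation, small_nonsyn_table)
    tables, totals = sim.simulate_readcounts(state, genome, cfg)
    sites = calling.call_many(tables)
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "state": state,
        "tables": tables,
        "totals": totals,
        "sites": sites,
    }


# ---------------------------------------------------------------------------
# Session-scoped property benchmarks (shared with the acceptance suite)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fp_calibration():
    """Error-only sequencing at fixed depth 100, error 0.005: observed
    per-site call rate at the 2% filter vs the exact analytic probability
    that any alternative base collects >= 2 of 100 reads."""
    from math import comb

    n_sites = 200_000
    depth = 100
    eps = 0.005
    p = eps / 3
    rng = np.random.default_rng(20240613)
    counts = rng.multinomial(depth, [1 - eps, p, p, p], size=n_sites)
    table = pd.DataFrame(
        {
            "chrom": "mt",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "depth": depth,
            "count_A": counts[:, 0],
            "count_C": counts[:, 1],
            "count_G": counts[:, 2],
            "count_T": counts[:, 3],
        }
    )
    called = len(calling.call_het_sites(table, 0.02, 10, "x")) / n_sites

    # exact P(all three error bases <= 1) under the multinomial
    analytic = 0.0
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                rest = depth - a - b - c
                coef = (
                    comb(depth, a) * comb(depth - a, b) * comb(depth - a - b, c)
                )
                analytic += coef * p ** (a + b + c) * (1 - eps) ** rest
    p_call = 1.0 - analytic
    se = np.sqrt(p_call * (1 - p_call) / n_sites)
    return {"observed": float(called), "analytic": float(p_call), "se": float(se)}


@pytest.fixture(scope="session")
def assignment_benchmark(small_genome, small_nonsyn_table):
    """Maternal assignment on focal crosses with independently drawn parent
    founder profiles (>=100 called sites per parent), bottleneck 100,
    depth 100, 12 seeds x 10 offspring."""
    genome, annotation = small_genome
    loose_correct = strict_wrong = strict_assigned = total = 0
    for seed in range(1, 13):
        cfg = small_config(
            seed=seed, founder_het_sites=350, mean_depth=100.0
        )
        state = sim.simulate_focal_cross(
            cfg, genome, annotation, n_offspring=10, nonsyn_table=small_nonsyn_table
        )
        tables, _ = sim.simulate_readcounts(state, genome, cfg)
        sites = calling.call_many(tables)
        offspring = [i for i in state.individuals if i.startswith("O")]
        res = inheritance.assign_all(sites, "P1", "P2", offspring)
        truth = dict(zip(state.pedigree["id"], state.pedigree["mother"]))
        total += len(offspring)
        for _, r in res.iterrows():
            if r.loose_mother and truth[r.offspring] == r.loose_mother:
                loose_correct += 1
            if r.strict_mother:
                strict_assigned += 1
                if truth[r.offspring] != r.strict_mother:
                    strict_wrong += 1
    return {
        "total": total,
        "loose_correct": loose_correct,
        "strict_assigned": strict_assigned,
        "strict_wrong": strict_wrong,
    }


@pytest.fixture(scope="session")
def association_power():
    """Copy-ratio coupling detection at full matriline size: with kappa=1
    the regression of true de novo counts on copy ratio, over 10 seeds."""
    cfg0 = sim.SimConfig(seed=1)
    genome, annotation = sim.simulate_genome(cfg0)
    table = sim.nonsynonymous_table(genome, annotation)
    results = []
    for seed in range(1, 11):
        state = sim.simulate_matriline(
            sim.SimConfig(seed=seed), genome, annotation, table
        )
        summ = pd.DataFrame(
            {"individual": state.individuals, "n_variable": state.de_novo_counts}
        )
        ratios = pd.DataFrame(
            {"individual": state.individuals, "ratio": state.copy_ratio}
        )
        results.append(copynum.ratio_vs_het_association(ratios, summ))
    return results


@pytest.fixture(scope="session")
def association_null(small_genome, small_nonsyn_table):
    """Type-I calibration: kappa=0 decouples copy ratio from de novo
    intensity; slope-test rejections at alpha=0.05 over 120 seeds."""
    genome, annotation = small_genome
    rejections = 0
    for seed in range(1, 121):
        cfg = small_config(
            seed=seed, kappa=0.0, offspring_per_cross=30, n_grandoffspring=0
        )
        state = sim.simulate_matriline(
            cfg, genome, annotation, small_nonsyn_table
        )
        summ = pd.DataFrame(
            {"individual": state.individuals, "n_variable": state.de_novo_counts}
        )
        ratios = pd.DataFrame(
            {"individual": state.individuals, "ratio": state.copy_ratio}
        )
        rep = copynum.ratio_vs_het_association(ratios, summ)
        if rep.p < 0.05:
            rejections += 1
    return {"rejections": rejections, "n_seeds": 120}
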