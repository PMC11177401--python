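"""Maternal-inheritance inference from parent-offspring heteroplasmy.

In a hermaphrodite pair cross the egg parent is unknown, but germline
transmission of heteroplasmy predicts that each offspring's per-site
alternative-allele frequencies correlate with its true mother's. The
procedure correlates every offspring against both candidate parents over
the union of sites variable in either member (absent sites as zero) and
assigns the mother under two criteria: strict — exactly one parent shows a
positive, significant correlation; loose — among qualifying parents, the one
with the lower p-value, ties broken by higher R-squared. When both parents
qualify the strict criterion abstains (the two candidates shared a mother,
so an offspring may correlate weakly with its father too — this confound is
reported, not modelled).

Also here: sibling shared-site statistics, the pooled-variance two-sample
t-test comparing offspring heteroplasmy by assigned mother, the count of
majority (>50%) alternative alleles, and the pedigree mutation-rate
estimate n_fixed / (n_individuals * L_mt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CorrelationReport


@dataclass(frozen=True)
class SharedSiteStats:
    n_individuals: int
    n_variable_positions: int
    mean_fraction: float  # percent of individuals sharing a variable position
    sd_fraction: float  # population SD over positions, percent


@dataclass(frozen=True)
class AssignmentResult:
    offspring: str
    parent1: str
    parent2: str
    stats1: CorrelationReport
    stats2: CorrelationReport
    strict_mother: str | None
    loose_mother: str | None


@dataclass(frozen=True)
class TTestReport:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class RateEstimate:
    n_fixed: int
    n_individuals: int
    l_mt: int
    rate: float

    @property
    def rate_2sf(self) -> float:
        if self.rate == 0:
            return 0.0
        from math import floor, log10

        exp = floor(log10(abs(self.rate)))
        return round(self.rate, -exp + 1)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def validate_pedigree(ped: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Consistency checks: mothers exist (or '.') in an earlier generation.

    Returns (errors, warnings). An absent mother is an error — she carries
    the mtDNA line; an absent father is only a warning, since fathers are
    routinely outside the matriline (different mtDNA lineage).
    """
    errors, warnings_ = [], []
    ids = set(ped["id"])
    gen = dict(zip(ped["id"], ped["generation"]))
    for _, rec in ped.iterrows():
        mother, father = rec.mother, rec.father
        if mother != "." and not pd.isna(mother):
            if mother not in ids:
                errors.append(f"{rec.id}: unknown mother {mother}")
            elif gen[mother] >= rec.generation:
                errors.append(f"{rec.id}: mother {mother} not in an earlier generation")
        if father != "." and not pd.isna(father) and father not in ids:
            warnings_.append(f"{rec.id}: father {father} not in the matriline")
    return errors, warnings_


# ---------------------------------------------------------------------------
# Shared sites among siblings
# ---------------------------------------------------------------------------

def shared_site_stats(het_matrix: pd.DataFrame) -> SharedSiteStats:
    """For each position variable in at least one individual, the fraction
    of individuals variable there; returns mean and population SD of these
    fractions (percent). Rows are individuals, columns positions, values
    boolean variability flags."""
    if len(het_matrix) < 2:
        raise ValueError("need >= 2 individuals")
    flags = het_matrix.to_numpy(dtype=bool)
    variable = flags.any(axis=0)
    if not variable.any():
        return SharedSiteStats(len(het_matrix), 0, float("nan"), float("nan"))
    fracs = flags[:, variable].mean(axis=0)
    return SharedSiteStats(
        n_individuals=len(het_matrix),
        n_variable_positions=int(variable.sum()),
        mean_fraction=float(fracs.mean() * 100),
        sd_fraction=float(fracs.std(ddof=0) * 100),
    )


def het_matrix_from_sites(sites: pd.DataFrame, individuals) -> pd.DataFrame:
    """Individuals x positions boolean variability matrix from called sites."""
    positions = sorted(sites["pos"].unique())
    mat = pd.DataFrame(False, index=list(individuals), columns=positions)
    for ind, pos in zip(sites["individual"], sites["pos"]):
        if ind in mat.index:
            mat.at[ind, pos] = True
    return mat


# ---------------------------------------------------------------------------
# Parent-offspring correlation and maternal assignment
# ---------------------------------------------------------------------------

def parent_offspring_correlation(
    parent_freqs: dict,
    offspring_freqs: dict,
    site_policy: str = "union",
) -> CorrelationReport:
    """Pearson correlation between parent and offspring per-site frequency.

    Policy ``union`` (default): sites variable in either member, absentees
    as frequency 0 — conservative against spurious perfect correlations on
    tiny intersections. Policy ``intersection``: shared sites only.
    """
    if site_policy == "union":
        keys = sorted(set(parent_freqs) | set(offspring_freqs))
    elif site_policy == "intersection":
        keys = sorted(set(parent_freqs) & set(offspring_freqs))
    else:
        raise ValueError(f"unknown site policy {site_policy!r}")
    if len(keys) < 3:
        raise ValueError(f"need >= 3 sites under {site_policy} policy")
    x = np.array([parent_freqs.get(k, 0.0) for k in keys])
    y = np.array([offspring_freqs.get(k, 0.0) for k in keys])
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(float("nan"), float("nan"), float("nan"), len(keys))
    res = stats.pearsonr(x, y)
    return CorrelationReport(
        float(res.statistic), float(res.statistic**2), float(res.pvalue), len(keys)
    )


def assign_mother(
    offspring: str,
    parent1: str,
    parent2: str,
    stats1: CorrelationReport,
    stats2: CorrelationReport,
    alpha_sig: float = 0.05,
) -> AssignmentResult:
    """Assign the putative mother from the two parents' correlation reports.

    A parent qualifies with r > 0 and two-sided p < alpha_sig (undefined
    correlations never qualify). Strict: assigned only when exactly one
    parent qualifies. Loose: among qualifiers, lower p wins, ties broken by
    higher R-squared.
    """
    def qualifies(s: CorrelationReport) -> bool:
        return s.defined and s.r > 0 and s.p < alpha_sig

    q1, q2 = qualifies(stats1), qualifies(stats2)
    strict = parent1 if q1 and not q2 else parent2 if q2 and not q1 else None
    if q1 and q2:
        key1, key2 = (stats1.p, -stats1.r2), (stats2.p, -stats2.r2)
        # a full p/R2 tie is genuinely ambiguous -> abstain (keeps assignment
        # antisymmetric under swapping the parent labels)
        loose = parent1 if key1 < key2 else parent2 if key2 < key1 else None
    else:
        loose = strict
    return AssignmentResult(offspring, parent1, parent2, stats1, stats2, strict, loose)


def assign_all(
    sites: pd.DataFrame,
    parent1: str,
    parent2: str,
    offspring: list[str],
    alpha_sig: float = 0.05,
    site_policy: str = "union",
) -> pd.DataFrame:
    """Maternal assignment for every offspring from a called-sites frame.

    Frequencies are keyed by position per individual. Emits per-offspring
    statistics for both parents, the strict and loose assignments, and a
    Benjamini-Hochberg adjusted p column (assignments themselves use the
    per-offspring uncorrected procedure).
    """
    def freq_map(ind):
        sub = sites[sites["individual"] == ind]
        return dict(zip(sub["pos"], sub["alt_freq"]))

    p1_freqs, p2_freqs = freq_map(parent1), freq_map(parent2)
    rows = []
    for off in offspring:
        of = freq_map(off)
        try:
            s1 = parent_offspring_correlation(p1_freqs, of, site_policy)
        except ValueError:
            s1 = CorrelationReport(float("nan"), float("nan"), float("nan"), 0)
        try:
            s2 = parent_offspring_correlation(p2_freqs, of, site_policy)
        except ValueError:
            s2 = CorrelationReport(float("nan"), float("nan"), float("nan"), 0)
        res = assign_mother(off, parent1, parent2, s1, s2, alpha_sig)
        rows.append(
            {
                "offspring": off,
                "r1": s1.r,
                "R2_1": s1.r2,
                "p1": s1.p,
                "n1": s1.n,
                "r2": s2.r,
                "R2_2": s2.r2,
                "p2": s2.p,
                "n2": s2.n,
                "strict_mother": res.strict_mother,
                "loose_mother": res.loose_mother,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("p1", "p2"):
        df[f"{col}_bh"] = _benjamini_hochberg(df[col].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        res = stats.false_discovery_control(p[ok], method="bh")
        out[ok] = res
    return out


# ---------------------------------------------------------------------------
# Group comparison and mutation rate
# ---------------------------------------------------------------------------

def pooled_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TTestReport:
    """Two-sided pooled-variance Student t-test from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = 0.0 if se == 0 else (mean2 - mean1) / se
    p = 1.0 if se == 0 else float(2 * stats.t.sf(abs(t), df))
    return TTestReport(mean1, mean2, sd1, sd2, n1, n2, float(t), df, p)


def group_comparison(group1, group2) -> TTestReport:
    """Pooled-variance two-sample t-test on per-offspring mean heteroplasmy
    grouped by assigned mother."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return pooled_t_from_summary(
        a.size, float(a.mean()), float(a.std(ddof=1)),
        b.size, float(b.mean()), float(b.std(ddof=1)),
    )


def count_majority_variants(
    sites: pd.DataFrame, threshold: float = 0.50
) -> pd.DataFrame:
    """Distinct (individual, position) called sites with alternative-allele
    frequency strictly above the threshold — candidate de novo mutations on
    the way to fixation; feeds n_fixed of the rate estimate."""
    hits = sites[sites["alt_freq"] > threshold]
    return hits.drop_duplicates(subset=["individual", "pos"])[
        ["individual", "pos", "alt", "alt_freq"]
    ].reset_index(drop=True)


def pedigree_mutation_rate(n_fixed: int, n_individuals: int, l_mt: int) -> RateEstimate:
    """Short-term (pedigree) mutation rate: n_fixed / (n_individuals * L_mt),
    mutations per base per generation."""
    if n_individuals <= 0 or l_mt <= 0:
        raise ValueError("denominator factors must be positive")
    if n_fixed < 0:
        raise ValueError("n_fixed must be >= 0")
    return RateEstimate(
        n_fixed, n_individuals, l_mt, n_fixed / (n_individuals * l_mt)
    )
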