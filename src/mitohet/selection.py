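"""Selection analyses on heteroplasmic sites.

Pooled heteroplasmic sites (unique position/alternative-base pairs across
individuals) are tabulated by gene, codon position and synonymy. Because
protein-coding genes contain equal numbers of each codon position, a Pearson
chi-squared test against a 50:50 expectation compares mutation counts at
codon position 1 vs 3 and 2 vs 3; an excess of third-position (largely
synonymous) changes indicates purifying selection and cannot arise from
sequencing error. The McDonald-Kreitman test contrasts the
nonsynonymous:synonymous ratio of within-matriline polymorphism against
fixed differences to an outgroup (Fisher exact, two-sided), reporting the
neutrality index NI = (Pn/Ps)/(Dn/Ds) and alpha = 1 - NI. Sliding-window
nucleotide diversity (Pi, window 500 sites, step 100) profiles variation
along the genome.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoGenome,
    classify_substitution,
    translate,
)


@dataclass
class PositionCounts:
    gene: str
    n1: int = 0
    n2: int = 0
    n3: int = 0
    n_syn: int = 0
    n_nonsyn: int = 0
    n_sites: int = 0  # records accumulated (intergenic bucket counts here only)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    small_counts: bool  # asymptotic-validity warning when nA+nB < 5


@dataclass(frozen=True)
class MKResult:
    gene: str
    pn: int
    ps: int
    dn: int
    ds: int
    fisher_p: float
    ni: float  # NaN when undefined
    alpha: float  # 1 - NI; NaN when undefined


@dataclass(frozen=True)
class PiProfile:
    window: int
    step: int
    starts: np.ndarray  # 1-based window starts
    midpoints: np.ndarray
    pi: np.ndarray


def tabulate_positions(
    sites: pd.DataFrame,
    genome: MitoGenome,
    annotation,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> dict[str, PositionCounts]:
    """Pool sites as unique (position, alt) pairs across individuals and
    count them by gene, codon position and effect.

    A site seen in forty individuals contributes once. Sites outside any
    protein-coding gene accumulate in an ``intergenic`` bucket (includes
    tRNA/rRNA positions); a site inside overlapping PCGs counts once per
    gene. A ``total`` entry pools all PCG-classified sites.
    """
    unique = sites.drop_duplicates(subset=["pos", "alt"])
    counts: dict[str, PositionCounts] = {}

    def bucket(name):
        return counts.setdefault(name, PositionCounts(gene=name))

    for pos, alt in zip(unique["pos"], unique["alt"]):
        records = classify_substitution(genome, annotation, int(pos), alt, code)
        for rec in records:
            if rec.codon_position is None:
                bucket("intergenic").n_sites += 1
                continue
            for name in (rec.gene, "total"):
                b = bucket(name)
                b.n_sites += 1
                if rec.codon_position == 1:
                    b.n1 += 1
                elif rec.codon_position == 2:
                    b.n2 += 1
                else:
                    b.n3 += 1
                if rec.effect == "synonymous":
                    b.n_syn += 1
                else:
                    b.n_nonsyn += 1
    return counts


def chisq_positions(n_a: int, n_b: int) -> ChiSquareResult:
    """Pearson chi-squared (df=1, no continuity correction) of observed
    counts at two codon positions against an equal split: PCGs contain the
    same number of positions of each class, so the neutral expectation is
    (nA+nB)/2 each. Statistic reduces to (nA-nB)^2/(nA+nB)."""
    total = n_a + n_b
    if total <= 0:
        raise ValueError("need at least one observation")
    stat = (n_a - n_b) ** 2 / total
    p = float(stats.chi2.sf(stat, df=1))
    return ChiSquareResult(statistic=float(stat), p=p, small_counts=total < 5)


def mk_test(gene: str, pn: int, ps: int, dn: int, ds: int) -> MKResult:
    """McDonald-Kreitman test on the 2x2 table [[Pn, Ps], [Dn, Ds]].

    Two-sided Fisher exact probability; NI = (Pn/Ps)/(Dn/Ds) and
    alpha = 1 - NI, carried as NaN (never silent zeros) when Ps or Dn is 0.
    """
    if min(pn, ps, dn, ds) < 0:
        raise ValueError("MK counts must be non-negative")
    _, fisher_p = stats.fisher_exact([[pn, ps], [dn, ds]], alternative="two-sided")
    if ps == 0 or dn == 0 or ds == 0:
        ni = alpha = float("nan")
    else:
        ni = (pn / ps) / (dn / ds)
        alpha = 1.0 - ni
    return MKResult(gene, pn, ps, dn, ds, float(fisher_p), ni, alpha)


def sliding_pi(
    sequences: list[str], window: int = 500, step: int = 100
) -> PiProfile:
    """Sliding-window nucleotide diversity over an alignment.

    Pi per window is the mean over all sequence pairs of differences per
    compared site; alignment columns where either member of a pair carries a
    gap (``-``) or N are excluded for that pair. Windows advance by ``step``;
    the final partial window is included.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    L = lengths.pop()
    if window > L:
        warnings.warn("window longer than alignment; using one whole-alignment window")
        window = L
    arr = np.array([list(s.upper()) for s in sequences])
    valid = (arr != "-") & (arr != "N")

    starts = np.arange(0, max(1, L - 1), step)
    starts = starts[starts < L]
    pis, mids, s1 = [], [], []
    pairs = list(itertools.combinations(range(len(sequences)), 2))
    for s in starts:
        e = min(s + window, L)
        vals = []
        for i, j in pairs:
            ok = valid[i, s:e] & valid[j, s:e]
            ncomp = int(ok.sum())
            if ncomp == 0:
                continue
            ndiff = int(((arr[i, s:e] != arr[j, s:e]) & ok).sum())
            vals.append(ndiff / ncomp)
        pis.append(float(np.mean(vals)) if vals else float("nan"))
        mids.append((s + 1 + e) / 2)
        s1.append(s + 1)
    return PiProfile(window, step, np.array(s1), np.array(mids), np.array(pis))


# ---------------------------------------------------------------------------
# Fixed differences vs an outgroup
# ---------------------------------------------------------------------------

def _codon_path_counts(ref: str, out: str, code: GeneticCode) -> tuple[float, float]:
    """Minimum-change pathway counts of (syn, nonsyn) between two codons,
    averaged over substitution orderings; orderings passing through a stop
    codon are excluded unless all do."""
    diff = [k for k in range(3) if ref[k] != out[k]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = ref
        syn = nonsyn = 0
        through_stop = False
        for k in order:
            nxt = cur[:k] + out[k] + cur[k + 1 :]
            if translate(cur, code) == translate(nxt, code):
                syn += 1
            else:
                nonsyn += 1
            if translate(nxt, code) == "*" and nxt != out:
                through_stop = True
            cur = nxt
        results.append((syn, nonsyn, through_stop))
    usable = [r for r in results if not r[2]] or results
    syn = float(np.mean([r[0] for r in usable]))
    nonsyn = float(np.mean([r[1] for r in usable]))
    return syn, nonsyn


def fixed_differences(
    consensus: str,
    outgroup: str,
    annotation,
    code: GeneticCode = INVERTEBRATE_MITO,
    genome_id: str = "consensus",
) -> dict[str, tuple[float, float]]:
    """Per-gene (Dn, Ds) between an ingroup consensus and an aligned
    outgroup sequence (alignment supplied, not computed).

    Codons differing at one position classify directly; multi-position
    differences use the minimum-change pathway averaged over orderings.
    """
    if len(consensus) != len(outgroup):
        raise ValueError("consensus and outgroup must be aligned to equal length")
    from .genome import reverse_complement

    out: dict[str, tuple[float, float]] = {}
    for feat in annotation:
        if feat.kind != "PCG":
            continue
        a = consensus[feat.start - 1 : feat.end]
        b = outgroup[feat.start - 1 : feat.end]
        if feat.strand == "-":
            a, b = reverse_complement(a), reverse_complement(b)
        if len(a) % 3:
            a, b = a[: len(a) - len(a) % 3], b[: len(b) - len(b) % 3]
        dn = ds = 0.0
        for k in range(0, len(a), 3):
            ca, cb = a[k : k + 3], b[k : k + 3]
            if "-" in ca or "-" in cb:
                continue
            syn, nonsyn = _codon_path_counts(ca, cb, code)
            ds += syn
            dn += nonsyn
        out[feat.name] = (dn, ds)
    return out


def per_gene_report(
    counts: dict[str, PositionCounts],
    mk_results: dict[str, MKResult] | None = None,
) -> pd.DataFrame:
    """Combined per-gene TSV-ready report: codon-position counts, both
    chi-squared tests, MK counts/probability/NI/alpha, and a Bonferroni
    column for transparency (per-gene tests are reported uncorrected)."""
    rows = []
    genes = [g for g in counts if g not in ("total", "intergenic")]
    for g in genes:
        c = counts[g]
        chi13 = chisq_positions(c.n1, c.n3) if (c.n1 + c.n3) else None
        chi23 = chisq_positions(c.n2, c.n3) if (c.n2 + c.n3) else None
        mk = (mk_results or {}).get(g)
        rows.append(
            {
                "gene": g,
                "n1": c.n1,
                "n2": c.n2,
                "n3": c.n3,
                "n_syn": c.n_syn,
                "n_nonsyn": c.n_nonsyn,
                "chi2_13": chi13.statistic if chi13 else np.nan,
                "p_13": chi13.p if chi13 else np.nan,
                "chi2_23": chi23.statistic if chi23 else np.nan,
                "p_23": chi23.p if chi23 else np.nan,
                "Pn": mk.pn if mk else np.nan,
                "Ps": mk.ps if mk else np.nan,
                "Dn": mk.dn if mk else np.nan,
                "Ds": mk.ds if mk else np.nan,
                "fisher_p": mk.fisher_p if mk else np.nan,
                "NI": mk.ni if mk else np.nan,
                "alpha": mk.alpha if mk else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        m = df["p_13"].notna().sum()
        df["p_13_bonferroni"] = (df["p_13"] * max(m, 1)).clip(upper=1.0)
        m = df["p_23"].notna().sum()
        df["p_23_bonferroni"] = (df["p_23"] * max(m, 1)).clip(upper=1.0)
    return df
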