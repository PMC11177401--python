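"""mtDNA copy-number estimation from read fractions and depth profiles.

The relative copy number R — mtDNA copies per haploid nuclear genome
equivalent — is inferred from the fraction of sequencing reads that are
mitochondrial: R = f_mt * G_nuc / L_mt, assuming reads sample the cell's DNA
content uniformly. Because f_mt <= 1e-3 throughout, no (1 - f) denominator
correction is applied, and no diploidy factor: the haploid-equivalent form
reproduces the observed 5-80 range. Windowed depth (25 bp windows) and a
repeat-vs-flank depth ratio quantify tandem-repeat copy number (length
heteroplasmy); an OLS regression tests the association between copy ratio
and per-individual heteroplasmy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CopyRatioRecord:
    individual: str
    mt_fraction: float
    g_nuc: float
    l_mt: int
    ratio: float


@dataclass(frozen=True)
class DepthProfile:
    window_size: int
    window_means: np.ndarray
    genome_length: int


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)


def mt_read_fraction(mt_reads: int, total_reads: int) -> float:
    """Fraction of all reads that are mitochondrial."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mt_reads < 0 or mt_reads > total_reads:
        raise ValueError(f"mt_reads {mt_reads} outside [0, {total_reads}]")
    return mt_reads / total_reads


def copy_ratio(f_mt: float, g_nuc: float, l_mt: int) -> float:
    """mtDNA copies per nuclear genome copy: f_mt * G_nuc / L_mt."""
    if g_nuc <= 0 or l_mt <= 0:
        raise ValueError("genome sizes must be positive")
    if not 0.0 <= f_mt < 1.0:
        raise ValueError(f"f_mt must be in [0,1), got {f_mt}")
    return f_mt * g_nuc / l_mt


def copy_ratio_table(totals: pd.DataFrame) -> pd.DataFrame:
    """Per-individual ratios from a read-totals table
    (individual, mt_reads, total_reads, G_nuc, L_mt)."""
    f = totals["mt_reads"] / totals["total_reads"]
    return pd.DataFrame(
        {
            "individual": totals["individual"],
            "mt_fraction": f,
            "ratio": f * totals["G_nuc"] / totals["L_mt"],
        }
    )


def windowed_depth(per_base_depth, window_size: int = 25) -> DepthProfile:
    """Non-overlapping window means of per-base depth (last window may be
    short), mirroring a windowed coverage summary."""
    depth = np.asarray(per_base_depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    starts = np.arange(0, depth.size, window_size)
    sums = np.add.reduceat(depth, starts)
    lengths = np.diff(np.append(starts, depth.size))
    return DepthProfile(window_size, sums / lengths, int(depth.size))


def _flank_indices(lo: int, hi: int, flank: int, L: int, circular: bool) -> np.ndarray:
    """0-based indices of the two flanks of the 1-based interval [lo, hi],
    wrapping on circular genomes and truncated so they never re-enter the
    repeat on short genomes."""
    repeat_len = hi - lo + 1
    max_flank = max(0, (L - repeat_len) // 2) if circular else flank
    eff = min(flank, max_flank) if circular else flank
    up = np.arange(lo - 1 - eff, lo - 1)
    down = np.arange(hi, hi + eff)
    if circular:
        idx = np.concatenate([up, down]) % L
    else:
        idx = np.concatenate([up[up >= 0], down[down < L]])
    # drop any index inside the repeat (possible on very short genomes)
    inside = (idx >= lo - 1) & (idx <= hi - 1)
    idx = idx[~inside]
    if idx.size == 0:
        raise ValueError("flanks are empty")
    return idx


def repeat_copy_number(
    per_base_depth,
    repeat_region: tuple,
    flank: int = 1000,
    circular: bool = True,
) -> float:
    """Depth ratio of a repeat region to 1 kb of flanking sequence.

    Interpreted as the per-genome copy count of a repeat assembled at single
    copy. Returns NaN when the flank mean is zero.
    """
    depth = np.asarray(per_base_depth, dtype=float)
    L = depth.size
    lo, hi = repeat_region
    if not (1 <= lo <= hi <= L):
        raise ValueError(f"repeat region {repeat_region} outside genome of {L}")
    flank_idx = _flank_indices(lo, hi, flank, L, circular)
    flank_mean = depth[flank_idx].mean()
    if flank_mean == 0:
        return float("nan")
    return float(depth[lo - 1 : hi].mean() / flank_mean)


def ratio_vs_het_association(
    ratios: pd.DataFrame,
    summaries: pd.DataFrame,
    measure: str = "n_variable",
) -> RegressionReport:
    """OLS of a per-individual heteroplasmy measure on copy ratio.

    ``measure`` is a column of the summaries table (n_variable by default,
    or a mean-frequency column). Two-sided slope test; individuals are
    matched by id.
    """
    merged = ratios.merge(summaries, on="individual")
    if len(merged) < 3:
        raise ValueError(f"need >= 3 matched individuals, got {len(merged)}")
    x = merged["ratio"].to_numpy(dtype=float)
    y = merged[measure].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0:
        return RegressionReport(*([float("nan")] * 4), n=len(x))
    res = stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_totals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"individual", "mt_reads", "total_reads", "G_nuc", "L_mt"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"totals table missing columns: {sorted(missing)}")
    return df


def read_depth(path) -> np.ndarray:
    """Per-base depth from a 2-column TSV (pos, depth) or BED-like 4-column
    windows (chrom, start0, end, depth) expanded to per-base."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 2:
        df = df.sort_values(0)
        return df[1].to_numpy(dtype=float)
    if df.shape[1] >= 4:
        length = int(df[2].max())
        depth = np.zeros(length)
        for _, row in df.iterrows():
            depth[int(row[1]) : int(row[2])] = float(row[3])
        return depth
    raise ValueError("depth file must have 2 or 4 columns")
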