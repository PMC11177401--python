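"""Heteroplasmy calling from per-site allele-count tables.

A site is called heteroplasmic in an individual when the highest-count
non-reference base reaches a minimum fraction of the site's depth (2% by
default, with 5% as the stricter check) at sufficient depth. Multiallelic
positions collapse to the top alternative base (ties broken A<C<G<T).
Per-individual summaries report the variable-site count and the mean
alternative-allele frequency both over called sites only and over all
assayed sites (zeros included), in percent. VCF-level filtering mirrors the
vcftools-style thresholds: site quality, per-sample depth range treated as
missingness, and a strict <10% missing-fraction rule; batch concordance is a
Pearson correlation with absent keys imputed as zero frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_BASES = ["A", "C", "G", "T"]
_COUNT_COLS = [f"count_{b}" for b in _BASES]


@dataclass(frozen=True)
class IndividualHetSummary:
    individual: str
    n_variable: int
    pct_sites_variable: float  # percent of assayed/genome sites
    mean_freq_excl_zero: float  # percent; NaN when n_variable == 0
    mean_freq_incl_zero: float  # percent, zeros for uncalled sites


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    r2: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    """Primary dialect: header + columns chrom, pos, ref, depth, count_A..T."""
    df = pd.read_csv(path, sep="\t")
    missing = {"pos", "ref", "depth", *_COUNT_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def read_bam_readcount(path) -> pd.DataFrame:
    """Native colon-delimited per-base pileup summary lines.

    Fields: chrom, pos, ref, depth, then one ``base:count:...`` block per
    base; only the base and count are consumed.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, pos, ref, depth = cols[0], int(cols[1]), cols[2].upper(), int(cols[3])
            counts = dict.fromkeys(_BASES, 0)
            for block in cols[4:]:
                parts = block.split(":")
                base = parts[0].upper()
                if base in counts:
                    counts[base] = int(parts[1])
            rows.append([chrom, pos, ref, depth] + [counts[b] for b in _BASES])
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "depth"] + _COUNT_COLS)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_het_sites(
    table: pd.DataFrame,
    min_freq: float = 0.02,
    min_depth: int = 10,
    individual: str | None = None,
) -> pd.DataFrame:
    """Call heteroplasmic sites for one individual's counts table.

    Returns a frame with columns individual, pos, ref, alt, alt_freq, depth —
    one row per position where the top non-reference base has frequency
    >= min_freq of the row depth and depth >= min_depth. The alternative-base
    frequency uses the row's stated depth, not the sum of base counts.
    """
    if not 0.0 < min_freq < 1.0:
        raise ValueError(f"min_freq must be in (0,1), got {min_freq}")
    refs = table["ref"].str.upper()
    if not refs.isin(_BASES).all():
        bad = sorted(set(refs) - set(_BASES))
        raise ValueError(f"malformed reference bases: {bad}")

    zero_depth = int((table["depth"] == 0).sum())
    if zero_depth:
        log.info("skipping %d zero-depth rows", zero_depth)
    df = table[table["depth"] > 0]
    refs = df["ref"].str.upper()

    counts = df[_COUNT_COLS].to_numpy(dtype=np.int64)
    ref_idx = np.searchsorted(np.array(_BASES), refs.to_numpy())
    masked = counts.copy()
    masked[np.arange(len(df)), ref_idx] = -1
    top_idx = masked.argmax(axis=1)  # argmax ties resolve to A<C<G<T
    top = masked[np.arange(len(df)), top_idx]
    depth = df["depth"].to_numpy(dtype=np.int64)
    freq = top / depth
    keep = (top > 0) & (freq >= min_freq) & (depth >= min_depth)

    out = pd.DataFrame(
        {
            "individual": individual
            if individual is not None
            else df.get("individual", pd.Series("", index=df.index)),
            "pos": df["pos"].to_numpy(),
            "ref": refs.to_numpy(),
            "alt": np.array(_BASES)[top_idx],
            "alt_freq": freq,
            "depth": depth,
        }
    )[keep]
    return out.reset_index(drop=True)


def call_many(
    tables: dict, min_freq: float = 0.02, min_depth: int = 10
) -> pd.DataFrame:
    """Call across a dict of per-individual tables; concatenated frame."""
    frames = [
        call_het_sites(df, min_freq, min_depth, individual=ind)
        for ind, df in tables.items()
    ]
    if not frames:
        return pd.DataFrame(
            columns=["individual", "pos", "ref", "alt", "alt_freq", "depth"]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_individual(
    sites: pd.DataFrame,
    L_mt: int,
    individual: str = "",
    n_assayed: int | None = None,
) -> IndividualHetSummary:
    """Per-individual heteroplasmy summary; frequencies reported in percent.

    ``n_assayed`` is the number of positions with usable counts (defaults to
    L_mt); the zero-inclusive mean averages alt_freq over all assayed
    positions with zero for uncalled sites.
    """
    if L_mt <= 0:
        raise ValueError("L_mt must be positive")
    n_assayed = L_mt if n_assayed is None else n_assayed
    n = len(sites)
    excl = float(sites["alt_freq"].mean() * 100) if n else float("nan")
    incl = float(sites["alt_freq"].sum() / n_assayed * 100) if n_assayed else 0.0
    return IndividualHetSummary(
        individual=individual or (sites["individual"].iloc[0] if n else ""),
        n_variable=n,
        pct_sites_variable=100.0 * n / L_mt,
        mean_freq_excl_zero=excl,
        mean_freq_incl_zero=incl,
    )


def summarize_all(sites: pd.DataFrame, L_mt: int, individuals=None) -> pd.DataFrame:
    """Summaries for every individual present (or an explicit id list)."""
    ids = list(individuals) if individuals is not None else sorted(
        sites["individual"].unique()
    )
    rows = []
    for ind in ids:
        s = summarize_individual(sites[sites["individual"] == ind], L_mt, ind)
        rows.append(
            [
                s.individual,
                s.n_variable,
                s.pct_sites_variable,
                s.mean_freq_excl_zero,
                s.mean_freq_incl_zero,
            ]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual",
            "n_variable",
            "pct_sites_variable",
            "mean_freq_excl_zero",
            "mean_freq_incl_zero",
        ],
    )


# ---------------------------------------------------------------------------
# VCF filtering
# ---------------------------------------------------------------------------

@dataclass
class VcfSiteRecord:
    pos: int
    ref: str
    alts: tuple
    qual: float
    depths: np.ndarray  # per-sample depth
    missing: np.ndarray  # per-sample missing-genotype flag
    raw: str = ""


def read_vcf(path) -> tuple[list[VcfSiteRecord], list[str]]:
    """Read a VCF via cyvcf2; returns records and the sample list."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        depths = np.asarray(v.format("DP")).reshape(-1).astype(int) if v.format(
            "DP"
        ) is not None else np.full(len(samples), -1)
        gts = v.gt_types  # 3 == unknown
        missing = np.asarray(gts) == 3
        records.append(
            VcfSiteRecord(
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depths=depths,
                missing=missing,
                raw=str(v).rstrip("\n"),
            )
        )
    return records, samples


def filter_vcf(
    records: list[VcfSiteRecord],
    n_samples: int,
    max_missing_frac: float = 0.10,
    min_depth: int = 10,
    max_depth: int = 500,
    min_qual: float = 30.0,
) -> tuple[list[VcfSiteRecord], dict]:
    """Apply the site filters; returns survivors and an attrition log.

    Biallelic sites only; a sample whose depth falls outside
    [min_depth, max_depth] counts as missing; sites are removed when the
    missing fraction reaches max_missing_frac (strictly fewer than 10% of
    individuals may be missing) or quality < min_qual. No minor-allele
    frequency floor: singleton de novo candidates are kept.
    """
    kept = []
    dropped = {"multiallelic": 0, "quality": 0, "missingness": 0}
    for rec in records:
        if len(rec.alts) != 1:
            dropped["multiallelic"] += 1
            continue
        if rec.qual < min_qual:
            dropped["quality"] += 1
            continue
        bad_depth = (rec.depths < min_depth) | (rec.depths > max_depth)
        n_missing = int((rec.missing | bad_depth).sum())
        if n_missing / n_samples >= max_missing_frac:
            dropped["missingness"] += 1
            continue
        kept.append(rec)
    dropped["input"] = len(records)
    dropped["kept"] = len(kept)
    return kept, dropped


def write_filtered_vcf(path_in, records: list[VcfSiteRecord], path_out) -> None:
    """Write survivors, reusing the input header verbatim."""
    keep_pos = {r.pos for r in records}
    with open(path_in) as fin, open(path_out, "w") as fout:
        for line in fin:
            if line.startswith("#"):
                fout.write(line)
                continue
            pos = int(line.split("\t", 2)[1])
            if pos in keep_pos:
                fout.write(line)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance(freqs_a: dict, freqs_b: dict) -> CorrelationReport:
    """Pearson correlation between two per-key frequency tables.

    Keys (sites, or individuals for per-individual means) form the union of
    both tables; a key absent from one table contributes frequency 0 there —
    dropping it instead would inflate the correlation.
    """
    keys = sorted(set(freqs_a) | set(freqs_b))
    if len(keys) < 3:
        raise ValueError(f"need >= 3 shared keys, got {len(keys)}")
    a = np.array([freqs_a.get(k, 0.0) for k in keys], dtype=float)
    b = np.array([freqs_b.get(k, 0.0) for k in keys], dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationReport(float("nan"), float("nan"), float("nan"), len(keys))
    res = stats.pearsonr(a, b)
    return CorrelationReport(
        r=float(res.statistic),
        r2=float(res.statistic**2),
        p=float(res.pvalue),
        n=len(keys),
    )
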