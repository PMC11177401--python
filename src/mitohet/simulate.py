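"""Forward simulator of a multigenerational snail matriline.

Emulates the data-generating process behind a whole-genome-sequenced mtDNA
pedigree: a founder carrying standing SNP heteroplasmy transmits per-site
alternative-allele frequencies through a germline bottleneck (binomial
resampling of N_b genome copies), de novo mutations arise at a per-individual
intensity negatively coupled to mtDNA copy number (intensity proportional to
copy_ratio**-kappa), selection removes nonsynonymous alternative alleles as a
multiplicative per-generation frequency penalty, and sequencing is emulated as
Poisson depth with binomial allele counts and a per-base error rate.

The default pedigree mirrors the study design: a founder mother, one
daughter, a sibship containing the two focal-cross parents, 76 focal
offspring, and four grandoffspring (90 individuals, 5 generations).

All randomness flows from a single seed; per-individual substreams are
derived by stable hashing of the individual id, so adding individuals never
perturbs the draws of others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import (
    GeneFeature,
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoGenome,
    classify_substitution,
    write_fasta,
    write_features,
)

_BASES = np.array(list("ACGT"))


def default_gene_layout() -> list[tuple[str, str, int]]:
    """Gene layout approximating a stylommatophoran mitogenome: 13 PCGs,
    2 rRNAs and tRNAs, COX1 first and a tandem tRNA-Val pair after it."""
    trna = lambda n: (f"trn{n}", "tRNA", 66)
    return [
        ("COX1", "PCG", 1530),
        trna("V"),
        trna("V2"),
        ("rrnL", "rRNA", 1000),
        ("ND1", "PCG", 900),
        trna("P"),
        ("ND6", "PCG", 480),
        ("CYTB", "PCG", 1140),
        trna("D"),
        trna("C"),
        trna("F"),
        ("COX2", "PCG", 660),
        trna("Y"),
        trna("W"),
        trna("G"),
        trna("H"),
        trna("Q"),
        trna("L1"),
        ("ATP8", "PCG", 156),
        trna("N"),
        ("ATP6", "PCG", 660),
        trna("R"),
        trna("E"),
        ("rrnS", "rRNA", 720),
        trna("M"),
        ("ND3", "PCG", 354),
        trna("S1"),
        trna("S2"),
        trna("T"),
        ("COX3", "PCG", 780),
        trna("A"),
        trna("I"),
        ("ND4L", "PCG", 294),
        trna("K"),
        ("ND5", "PCG", 1650),
        trna("L2"),
        ("ND4", "PCG", 1320),
        ("ND2", "PCG", 960),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic matriline.

    Defaults emulate the real matriline: a 14,202 base circular mitogenome,
    5 generations and ~90 individuals with a 76-offspring focal cross, a
    germline bottleneck of 100 genome copies, ~500 founder heteroplasmic
    sites with mean frequency 2.6%, copy ratios log-uniform on [5, 80] with
    de novo intensity proportional to ratio**-kappa, 0.1% sequencing error
    and 100x mean mtDNA depth on a 3.5 Gb nuclear background.
    """

    seed: int = 0
    L_mt: int = 14202
    gene_layout: list = field(default_factory=default_gene_layout)
    n_generations: int = 5
    offspring_per_cross: int = 76
    n_extra_sibs: int = 6
    n_grandoffspring: int = 4
    bottleneck: int = 100
    mu: float = 1e-2
    founder_het_sites: int = 500
    founder_freq_mean: float = 0.026
    selection_s: float = 0.8
    copy_ratio_bounds: tuple = (5.0, 80.0)
    kappa: float = 1.0
    error_rate: float = 0.001
    mean_depth: float = 100.0
    g_nuc: float = 3.5e9
    total_reads: int = 200_000_000
    repeat_region: tuple = (1533, 1666)
    repeat_copy_bounds: tuple = (2.0, 4.0)

    def __post_init__(self):
        for name in ("mu", "selection_s", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")

    def save(self, path) -> None:
        data = asdict(self)
        data["gene_layout"] = [list(t) for t in self.gene_layout]
        data["copy_ratio_bounds"] = list(self.copy_ratio_bounds)
        data["repeat_region"] = list(self.repeat_region)
        data["repeat_copy_bounds"] = list(self.repeat_copy_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("copy_ratio_bounds", "repeat_region", "repeat_copy_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        if "gene_layout" in data:
            data["gene_layout"] = [tuple(t) for t in data["gene_layout"]]
        return cls(**data)


def _substream(seed: int, individual: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(individual.encode())])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG"}


def simulate_genome(config: SimConfig) -> tuple[MitoGenome, list[GeneFeature]]:
    """Random mitogenome with a valid gene layout.

    PCGs begin with ATG, contain no in-frame internal stop codons and end
    with TAA; features are laid end-to-end with 2-base spacers.
    """
    for name, kind, length in config.gene_layout:
        if kind == "PCG" and length % 3:
            raise ValueError(f"PCG {name} length {length} not divisible by 3")
    spacer = 2
    needed = sum(l for _, _, l in config.gene_layout) + spacer * len(config.gene_layout)
    if needed > config.L_mt:
        raise ValueError(f"gene layout needs {needed} bases > L_mt={config.L_mt}")

    rng = np.random.default_rng([config.seed, zlib.crc32(b"genome")])
    seq = rng.choice(_BASES, size=config.L_mt).tolist()
    sense = [c for c in INVERTEBRATE_MITO.codon_table if c not in _STOPS]

    features = []
    cursor = 1
    for name, kind, length in config.gene_layout:
        start, end = cursor, cursor + length - 1
        if kind == "PCG":
            codons = ["ATG"]
            codons += [sense[i] for i in rng.integers(0, len(sense), length // 3 - 2)]
            codons.append("TAA")
            seq[start - 1 : end] = list("".join(codons))
        features.append(GeneFeature(name=name, kind=kind, start=start, end=end))
        cursor = end + 1 + spacer
    genome = MitoGenome(id=f"sim_mt_seed{config.seed}", sequence="".join(seq))
    return genome, features


# ---------------------------------------------------------------------------
# Matriline
# ---------------------------------------------------------------------------

@dataclass
class MatrilineState:
    """Ground truth for a simulated matriline."""

    individuals: list  # ids in pedigree order
    pedigree: pd.DataFrame  # id, mother, father, generation
    freqs: np.ndarray  # individuals x L_mt true alternative-allele frequency
    alt_alleles: np.ndarray  # per-site alternative base
    nonsyn_mask: np.ndarray  # per-site: registered alt is nonsynonymous
    copy_ratio: np.ndarray  # R_true per individual
    mt_reads: np.ndarray
    total_reads: np.ndarray
    repeat_copies: np.ndarray
    de_novo_counts: np.ndarray

    def index(self, individual: str) -> int:
        return self.individuals.index(individual)


def build_pedigree(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Default matriline shape: founder -> daughter -> focal sibship (two
    focal parents + extra sibs) -> focal offspring -> grandoffspring. The true
    mother of each focal offspring is drawn between the two focal parents
    (hermaphrodite pair mating)."""
    rows = [("C109", ".", ".", 1), ("C116", "C109", "C108", 2)]
    sibs = ["C451", "C452"] + [f"C6{60 + i}" for i in range(config.n_extra_sibs)]
    for s in sibs:
        rows.append((s, "C116", "C120", 3))
    offspring = [f"C{700 + i}" for i in range(config.offspring_per_cross)]
    mothers = rng.choice(["C451", "C452"], size=len(offspring))
    for o, m in zip(offspring, mothers):
        father = "C452" if m == "C451" else "C451"
        rows.append((o, m, father, 4))
    if config.n_generations >= 5 and offspring:
        gmoms = rng.choice(offspring, size=config.n_grandoffspring)
        for i, gm in enumerate(gmoms):
            rows.append((f"C9{i:02d}", gm, ".", 5))
    ped = pd.DataFrame(rows, columns=["id", "mother", "father", "generation"])
    if config.n_generations < 4:
        ped = ped[ped.generation <= config.n_generations].reset_index(drop=True)
    return ped


def nonsynonymous_table(genome: MitoGenome, annotation) -> np.ndarray:
    """L x 4 boolean table: substitution to each base is nonsynonymous.

    Reference-base cells are False. Computed once per genome and reusable
    across simulation replicates.
    """
    L = len(genome)
    table = np.zeros((L, 4), dtype=bool)
    for pos in range(1, L + 1):
        ref = genome.base(pos)
        for j, b in enumerate("ACGT"):
            if b == ref:
                continue
            recs = classify_substitution(genome, annotation, pos, b)
            table[pos - 1, j] = any(r.effect == "nonsynonymous" for r in recs)
    return table


def _register_sites(
    genome: MitoGenome, annotation, rng, nonsyn_table: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each position a fixed alternative base and classify its effect."""
    L = len(genome)
    if nonsyn_table is None:
        nonsyn_table = nonsynonymous_table(genome, annotation)
    ref_idx = np.searchsorted(_BASES, list(genome.sequence))
    shift = rng.integers(1, 4, size=L)
    alt_idx = (ref_idx + shift) % 4
    alts = _BASES[alt_idx]
    nonsyn = nonsyn_table[np.arange(L), alt_idx]
    return alts, nonsyn


def _quantized_ratio(r_raw: float, config: SimConfig) -> tuple[int, float]:
    """Realize a copy ratio as an exact integer mt-read count so that
    copy_ratio(mt/total, G, L) inverts to R_true exactly."""
    mt = max(1, round(r_raw * config.L_mt * config.total_reads / config.g_nuc))
    r_true = mt * config.g_nuc / (config.total_reads * config.L_mt)
    return mt, r_true


def simulate_matriline(
    config: SimConfig,
    genome: MitoGenome,
    annotation: list[GeneFeature],
    nonsyn_table: np.ndarray | None = None,
) -> MatrilineState:
    """Transmit heteroplasmy through the pedigree.

    Founder site frequencies are exponential with the configured mean
    (truncated to (0, 0.999]); each offspring's per-site frequency is
    B/N_b with B ~ Binomial(N_b, f_mother); de novo mutations arrive with
    per-site probability mu * (R/R_mid)**-kappa (R_mid the geometric middle
    of the copy-ratio bounds) seeding frequency 1/N_b; after transmission the
    frequency of each nonsynonymous alternative allele is multiplied by
    (1 - selection_s).
    """
    rng_global = np.random.default_rng([config.seed, zlib.crc32(b"pedigree")])
    ped = build_pedigree(config, rng_global)
    return _transmit_over(config, genome, annotation, ped, nonsyn_table)


def simulate_focal_cross(
    config: SimConfig,
    genome: MitoGenome,
    annotation: list[GeneFeature],
    n_offspring: int | None = None,
    nonsyn_table: np.ndarray | None = None,
) -> MatrilineState:
    """A two-parent cross where each parent draws founder heteroplasmy
    independently (disjoint-enough profiles), used to benchmark maternal
    assignment against known truth."""
    n_off = n_offspring if n_offspring is not None else config.offspring_per_cross
    rng_global = np.random.default_rng([config.seed, zlib.crc32(b"cross")])
    rows = [("P1", ".", ".", 1), ("P2", ".", ".", 1)]
    mothers = rng_global.choice(["P1", "P2"], size=n_off)
    for i, m in enumerate(mothers):
        rows.append((f"O{i:03d}", m, "P2" if m == "P1" else "P1", 2))
    ped = pd.DataFrame(rows, columns=["id", "mother", "father", "generation"])
    return _transmit_over(config, genome, annotation, ped, nonsyn_table)


def _transmit_over(config, genome, annotation, ped, nonsyn_table=None) -> MatrilineState:
    """Transmission core over an externally supplied pedigree."""
    ids = ped["id"].tolist()
    L, nb = config.L_mt, config.bottleneck
    rng_sites = np.random.default_rng([config.seed, zlib.crc32(b"sites")])
    alts, nonsyn = _register_sites(genome, annotation, rng_sites, nonsyn_table)
    lo, hi = config.copy_ratio_bounds
    r_mid = float(np.sqrt(lo * hi))

    n = len(ids)
    freqs = np.zeros((n, L))
    copy_ratio = np.zeros(n)
    mt_reads = np.zeros(n, dtype=np.int64)
    repeat_copies = np.zeros(n)
    de_novo_counts = np.zeros(n, dtype=np.int64)
    row = {ind: i for i, ind in enumerate(ids)}
    for _, rec in ped.iterrows():
        i = row[rec.id]
        rng = _substream(config.seed, rec.id)
        r_raw = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mt_reads[i], copy_ratio[i] = _quantized_ratio(r_raw, config)
        repeat_copies[i] = rng.uniform(*config.repeat_copy_bounds)
        if rec.mother == ".":
            k = min(config.founder_het_sites, L)
            sites = rng.choice(L, size=k, replace=False)
            f = np.zeros(L)
            f[sites] = np.clip(
                rng.exponential(config.founder_freq_mean, size=k), 1e-6, 0.999
            )
            freqs[i] = f
            continue
        f_mother = freqs[row[rec.mother]]
        f = rng.binomial(nb, f_mother) / nb
        intensity = min(1.0, config.mu * (copy_ratio[i] / r_mid) ** (-config.kappa))
        hits = (rng.random(L) < intensity) & (f == 0.0)
        f[hits] = 1.0 / nb
        de_novo_counts[i] = int(hits.sum())
        f[nonsyn] *= 1.0 - config.selection_s
        freqs[i] = f
    return MatrilineState(
        individuals=ids,
        pedigree=ped,
        freqs=freqs,
        alt_alleles=alts,
        nonsyn_mask=nonsyn,
        copy_ratio=copy_ratio,
        mt_reads=mt_reads,
        total_reads=np.full(n, config.total_reads, dtype=np.int64),
        repeat_copies=repeat_copies,
        de_novo_counts=de_novo_counts,
    )


# ---------------------------------------------------------------------------
# Sequencing emulation
# ---------------------------------------------------------------------------

def simulate_readcounts(
    state: MatrilineState, genome: MitoGenome, config: SimConfig
) -> tuple[dict, pd.DataFrame]:
    """Per-individual per-site allele-count tables plus read totals.

    Depth is Poisson(mean_depth); the registered alternative base receives
    Binomial(depth, f(1-e) + (1-f)e/3) reads and each other non-reference
    base an e/3 error share; remaining reads are reference. Read totals are
    the exact integer pair realizing each individual's true copy ratio.
    """
    L = config.L_mt
    eps = config.error_rate
    ref = np.array(list(genome.sequence))
    ref_idx = np.searchsorted(_BASES, ref)
    alt_idx = np.searchsorted(_BASES, state.alt_alleles)
    tables = {}
    for i, ind in enumerate(state.individuals):
        rng = _substream(config.seed, f"reads:{ind}")
        depth = rng.poisson(config.mean_depth, size=L)
        f = state.freqs[i]
        p_alt = f * (1 - eps) + (1 - f) * eps / 3
        n_alt = rng.binomial(depth, p_alt)
        rest = depth - n_alt
        p_o = (eps / 3) / np.maximum(1e-12, 1 - p_alt)
        n_o1 = rng.binomial(rest, np.minimum(1.0, p_o))
        rest2 = rest - n_o1
        p_o2 = (eps / 3) / np.maximum(1e-12, 1 - p_alt - eps / 3)
        n_o2 = rng.binomial(rest2, np.minimum(1.0, p_o2))
        n_ref = rest2 - n_o2

        counts = np.zeros((L, 4), dtype=np.int64)
        pos = np.arange(L)
        counts[pos, ref_idx] = n_ref
        counts[pos, alt_idx] += n_alt
        others = np.zeros((L, 2), dtype=np.int64)
        others[:, 0], others[:, 1] = n_o1, n_o2
        other_cols = np.array(
            [sorted(set(range(4)) - {r, a}) for r, a in zip(ref_idx, alt_idx)]
        )
        counts[pos, other_cols[:, 0]] += others[:, 0]
        counts[pos, other_cols[:, 1]] += others[:, 1]

        tables[ind] = pd.DataFrame(
            {
                "chrom": genome.id,
                "pos": pos + 1,
                "ref": ref,
                "depth": depth,
                "count_A": counts[:, 0],
                "count_C": counts[:, 1],
                "count_G": counts[:, 2],
                "count_T": counts[:, 3],
            }
        )
    totals = pd.DataFrame(
        {
            "individual": state.individuals,
            "mt_reads": state.mt_reads,
            "total_reads": state.total_reads,
            "G_nuc": config.g_nuc,
            "L_mt": config.L_mt,
        }
    )
    return tables, totals


def simulate_depth_profile(
    rng: np.random.Generator,
    r_true: float,
    flank_depth: float,
    repeat_region: tuple,
    L_mt: int,
) -> np.ndarray:
    """Per-base Poisson depth, elevated r_true-fold inside the repeat."""
    lo, hi = repeat_region
    if not (1 <= lo <= hi <= L_mt):
        raise ValueError(f"bad repeat interval {repeat_region} for L_mt={L_mt}")
    mean = np.full(L_mt, float(flank_depth))
    mean[lo - 1 : hi] = r_true * flank_depth
    return rng.poisson(mean)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_readcounts(tables: dict, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ind, df in tables.items():
        df.to_csv(outdir / f"{ind}.counts.tsv", sep="\t", index=False)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"id": str, "mother": str, "father": str})
    return ped


def write_truth(state: MatrilineState, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "individual": state.individuals,
            "copy_ratio": state.copy_ratio,
            "repeat_copies": state.repeat_copies,
            "de_novo_count": state.de_novo_counts,
            "n_true_sites": (state.freqs > 0).sum(axis=1),
        }
    ).to_csv(outdir / "truth_individuals.tsv", sep="\t", index=False)
    var = np.flatnonzero((state.freqs > 0).any(axis=0))
    freq_df = pd.DataFrame(
        state.freqs[:, var].T,
        columns=state.individuals,
    )
    freq_df.insert(0, "pos", var + 1)
    freq_df.insert(1, "alt", state.alt_alleles[var])
    freq_df.to_csv(outdir / "truth_frequencies.tsv", sep="\t", index=False)


def write_vcf(
    state: MatrilineState,
    genome: MitoGenome,
    config: SimConfig,
    path,
    tables: dict | None = None,
) -> None:
    """Minimal multi-sample VCF 4.2 of sites with true frequency > 0.

    QUAL is a stated monotone map of the maximum individual frequency:
    QUAL = min(999, 1000 * max_f). Per-sample fields are GT:DP:AD with GT 0/1
    where the individual's true frequency is positive.
    """
    var = np.flatnonzero((state.freqs > 0).any(axis=0))
    ids = state.individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        base_col = {b: f"count_{b}" for b in "ACGT"}
        for p in var:
            pos = p + 1
            ref = genome.sequence[p]
            alt = state.alt_alleles[p]
            qual = min(999.0, round(1000.0 * float(state.freqs[:, p].max()), 1))
            cells = []
            for i, ind in enumerate(ids):
                f = state.freqs[i, p]
                gt = "0/1" if f > 0 else "0/0"
                if tables is not None:
                    row = tables[ind].iloc[p]
                    dp = int(row["depth"])
                    ad = f"{int(row[base_col[ref]])},{int(row[base_col[alt]])}"
                else:
                    dp = int(round(config.mean_depth))
                    ad = f"{int(round(dp * (1 - f)))},{int(round(dp * f))}"
                cells.append(f"{gt}:{dp}:{ad}")
            fh.write(
                f"{genome.id}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\tGT:DP:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def write_all(config: SimConfig, outdir) -> dict:
    """Run the whole generator and write every artifact; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = simulate_genome(config)
    state = simulate_matriline(config, genome, annotation)
    tables, totals = simulate_readcounts(state, genome, config)

    write_fasta(genome, outdir / "genome.fa")
    write_features(annotation, outdir / "genome.gff", seqid=genome.id)
    write_readcounts(tables, outdir / "counts")
    write_pedigree(state.pedigree, outdir / "pedigree.tsv")
    totals.to_csv(outdir / "read_totals.tsv", sep="\t", index=False)
    write_truth(state, outdir)
    write_vcf(state, genome, config, outdir / "variants.vcf", tables=tables)
    config.save(outdir / "config.yaml")
    return {
        "genome": outdir / "genome.fa",
        "gff": outdir / "genome.gff",
        "counts": outdir / "counts",
        "pedigree": outdir / "pedigree.tsv",
        "totals": outdir / "read_totals.tsv",
        "vcf": outdir / "variants.vcf",
        "state": state,
        "genome_obj": genome,
        "annotation": annotation,
        "tables": tables,
        "totals_df": totals,
    }
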