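"""Reference mitogenome model: sequence, gene annotation, genetic code, and
classification of substitutions by gene, codon position and synonymy.

The annotation layer implements the manual polishing rules used for molluscan
mitogenomes: tRNA predictions are trusted as-is, protein-coding genes (PCGs)
are extended upstream to the first eligible in-frame start codon nearest the
preceding gene, PCG/tRNA overlaps are resolved by truncating the PCG (leaving
an abbreviated stop codon, a terminal T or TA completed by polyadenylation),
PCG/PCG overlaps are retained only when the two genes sit in different reading
frames, and rRNA boundaries are never extended.

Translation uses the invertebrate mitochondrial code (NCBI table 5), under
which every substitution at the second codon position changes the encoded
amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

STOP = "*"
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    """Raised when a draft annotation cannot be polished."""


@dataclass(frozen=True)
class MitoGenome:
    """A mitochondrial reference sequence.

    Coordinates throughout the package are 1-based inclusive. On a circular
    genome position arithmetic wraps modulo the length.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        bad = set(self.sequence) - set(_BASES)
        if bad:
            raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position; wraps on circular genomes."""
        L = len(self.sequence)
        if self.circular:
            return self.sequence[(position - 1) % L]
        if not 1 <= position <= L:
            raise IndexError(f"position {position} outside linear genome of length {L}")
        return self.sequence[position - 1]


@dataclass
class GeneFeature:
    """A gene feature in 1-based inclusive coordinates.

    ``start > end`` is permitted only on a circular genome and denotes a
    feature wrapping the origin.
    """

    name: str
    kind: str  # PCG | tRNA | rRNA | other
    start: int
    end: int
    strand: str = "+"
    notes: str = ""

    def length(self, L_mt: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (L_mt - self.start + 1) + self.end

    def positions(self, L_mt: int) -> range:
        """Unrolled 1-based positions; values above L_mt wrap modulo L_mt."""
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        return range(self.start, self.end + L_mt + 1)

    def contains(self, position: int, L_mt: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """Codon translation table with an explicit start-codon set.

    Defaults to NCBI table 5 (invertebrate mitochondrial) with the start set
    {ATG, ATA, ATT, ATC, TTG, GTG}: ATA initiates Met, ATY Ile, TTG Leu and
    GTG Val in molluscan mitogenomes.
    """

    table_id: int = 5
    codon_table: dict = field(default_factory=dict)
    start_codons: frozenset = frozenset({"ATG", "ATA", "ATT", "ATC", "TTG", "GTG"})

    def __post_init__(self):
        if not self.codon_table:
            ncbi = unambiguous_dna_by_id[self.table_id]
            table = dict(ncbi.forward_table)
            for stop in ncbi.stop_codons:
                table[stop] = STOP
            object.__setattr__(self, "codon_table", table)
        if len(self.codon_table) != 64:
            raise ValueError("codon table must have exactly 64 entries")

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons


INVERTEBRATE_MITO = GeneticCode()


def translate(codon: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """One-letter amino acid for a codon; ``*`` for a stop codon."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    return code.codon_table[codon]


@dataclass(frozen=True)
class SiteClassification:
    position: int
    gene: str | None
    codon_position: int | None  # 1, 2 or 3 within the reading frame
    effect: str  # synonymous | nonsynonymous | noncoding
    ref_codon: str | None = None
    alt_codon: str | None = None


def _codon_at(genome: MitoGenome, feat: GeneFeature, position: int):
    """Return (ref_codon, codon_position, within_codon_offset_positions) for a
    genomic position inside a PCG, reading strand-aware in the gene's frame."""
    L = len(genome)
    if feat.start <= feat.end:
        unrolled = position
        if not feat.start <= position <= feat.end:
            raise ValueError("position outside feature")
    else:  # wrap-around: unroll positions <= end past L
        unrolled = position + L if position <= feat.end else position
    if feat.strand == "+":
        idx = unrolled - feat.start
        codon_start = feat.start + idx - idx % 3
        pos_in_codon = idx % 3
        codon_positions = [codon_start, codon_start + 1, codon_start + 2]
        codon = "".join(genome.base(p) for p in codon_positions)
    else:
        end_unrolled = feat.end if feat.start <= feat.end else feat.end + L
        idx = end_unrolled - unrolled
        codon_first = end_unrolled - (idx - idx % 3)
        pos_in_codon = idx % 3
        codon_positions = [codon_first, codon_first - 1, codon_first - 2]
        codon = "".join(genome.base(p).translate(_COMPLEMENT) for p in codon_positions)
    return codon, pos_in_codon + 1


def classify_substitution(
    genome: MitoGenome,
    annotation: list[GeneFeature],
    position: int,
    alt: str,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[SiteClassification]:
    """Classify a substitution at ``position`` to ``alt``.

    Returns one record per protein-coding gene overlapping the position
    (overlapping PCGs in different frames each get a record). A position in a
    non-coding feature or outside all features yields a single noncoding
    record (gene set to the feature name when inside tRNA/rRNA).
    """
    alt = alt.upper()
    if alt not in _BASES:
        raise ValueError(f"invalid alternative base {alt!r}")
    ref = genome.base(position)
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref} at position {position}")

    records: list[SiteClassification] = []
    noncoding_gene = None
    for feat in annotation:
        if not feat.contains(position, len(genome)):
            continue
        if feat.kind != "PCG":
            noncoding_gene = noncoding_gene or feat.name
            continue
        ref_codon, codon_pos = _codon_at(genome, feat, position)
        sub = alt if feat.strand == "+" else alt.translate(_COMPLEMENT)
        alt_codon = (
            ref_codon[: codon_pos - 1] + sub + ref_codon[codon_pos:]
        )
        effect = (
            "synonymous"
            if translate(ref_codon, code) == translate(alt_codon, code)
            else "nonsynonymous"
        )
        records.append(
            SiteClassification(position, feat.name, codon_pos, effect, ref_codon, alt_codon)
        )
    if not records:
        records.append(SiteClassification(position, noncoding_gene, None, "noncoding"))
    return records


# ---------------------------------------------------------------------------
# Annotation polishing
# ---------------------------------------------------------------------------

def _frame(feat: GeneFeature, L_mt: int) -> int:
    """Reading-frame token for overlap comparison: strand plus start phase."""
    anchor = feat.start if feat.strand == "+" else feat.end
    return anchor % 3


def _codon_str(genome: MitoGenome, p: int, strand: str) -> str:
    if strand == "+":
        return "".join(genome.base(q) for q in (p, p + 1, p + 2))
    return "".join(genome.base(q).translate(_COMPLEMENT) for q in (p, p - 1, p - 2))


def polish_annotation(
    genome: MitoGenome,
    draft: list[GeneFeature],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[GeneFeature]:
    """Apply the manual annotation rules to a draft feature list.

    tRNA features are trusted unchanged and rRNA bounds are returned as given.
    Each PCG start is moved to the first eligible in-frame start codon nearest
    the preceding gene without overlapping it; PCG ends are truncated so that
    PCGs never overlap tRNAs, and PCG-PCG overlaps are retained only when the
    reading frames differ. A truncation that leaves a PCG length of 1 or 2
    mod 3 is flagged as an abbreviated stop (terminal T or TA completed by
    polyadenylation). Idempotent: polishing a polished annotation is a no-op.
    """
    L = len(genome)
    feats = [replace(f, notes=_strip_polish_notes(f.notes)) for f in draft]
    order = sorted(range(len(feats)), key=lambda i: feats[i].start)

    # Rule 2/6: move each PCG start to the first eligible in-frame start codon
    # after the preceding gene (strand-aware mirror on the minus strand).
    for i in order:
        f = feats[i]
        if f.kind != "PCG":
            continue
        if f.strand == "+":
            prev_end = max(
                (g.end for g in feats if g is not f and g.start < f.start),
                default=0,
            )
            # extend upstream only while clear of the preceding gene; a draft
            # already overlapping it keeps its own start as the search bound
            # (PCG-PCG overlap is rule 4's business)
            lo = prev_end + 1 if prev_end < f.start else f.start
            p = f.start - ((f.start - lo) // 3) * 3  # smallest in-frame pos >= lo
            new_start = None
            while p <= f.end - 2:
                if code.is_start(_codon_str(genome, p, "+")):
                    new_start = p
                    break
                p += 3
            if new_start is None:
                raise AnnotationError(f"no eligible start codon for gene {f.name}")
            feats[i] = replace(f, start=new_start)
        else:
            nxt_start = min(
                (g.start for g in feats if g is not f and g.end > f.end),
                default=L + 1,
            )
            hi = nxt_start - 1 if nxt_start > f.end else f.end
            p = f.end + ((hi - f.end) // 3) * 3  # largest in-frame pos <= hi
            new_end = None
            while p >= f.start + 2:
                if code.is_start(_codon_str(genome, p, "-")):
                    new_end = p
                    break
                p -= 3
            if new_end is None:
                raise AnnotationError(f"no eligible start codon for gene {f.name}")
            feats[i] = replace(f, end=new_end)

    # Rule 3: PCGs never overlap tRNAs -> truncate the PCG 3' end.
    trnas = [f for f in feats if f.kind == "tRNA"]
    for i, f in enumerate(feats):
        if f.kind != "PCG":
            continue
        if f.strand == "+":
            blockers = [t.start for t in trnas if f.start < t.start <= f.end]
            if blockers:
                feats[i] = f = replace(f, end=min(blockers) - 1)
        else:
            blockers = [t.end for t in trnas if f.start <= t.end < f.end]
            if blockers:
                feats[i] = f = replace(f, start=max(blockers) + 1)

    # Rule 4: PCG-PCG overlap kept only in different frames.
    pcgs = sorted(
        (i for i, f in enumerate(feats) if f.kind == "PCG"),
        key=lambda i: feats[i].start,
    )
    for a_idx, b_idx in zip(pcgs, pcgs[1:]):
        a, b = feats[a_idx], feats[b_idx]
        if a.end >= b.start and a.strand == b.strand and _frame(a, L) == _frame(b, L):
            feats[a_idx] = replace(a, end=b.start - 1)

    # Rule 5: flag abbreviated stops left by truncation.
    for i, f in enumerate(feats):
        if f.kind != "PCG":
            continue
        rem = f.length(L) % 3
        if rem:
            tag = "abbreviated stop (T)" if rem == 1 else "abbreviated stop (TA)"
            notes = f"{f.notes}; {tag}".strip("; ") if f.notes else tag
            feats[i] = replace(f, notes=notes)
    return feats


def _strip_polish_notes(notes: str) -> str:
    parts = [p for p in notes.split("; ") if p and not p.startswith("abbreviated stop")]
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# FASTA / feature-table I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> MitoGenome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return MitoGenome(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: MitoGenome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


_GFF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "region"}
_GFF_KIND = {v: k for k, v in _GFF_TYPE.items()}


def write_features(features: list[GeneFeature], path, seqid: str = "mtDNA") -> None:
    """Write a GFF3-style 9-column feature table (Name= attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"Name={f.name}"
            if f.notes:
                attrs += f";Note={f.notes}"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "mitohet",
                        _GFF_TYPE.get(f.kind, "region"),
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_features(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed feature line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                GeneFeature(
                    name=attrs.get("Name", cols[2]),
                    kind=_GFF_KIND.get(cols[2], "other"),
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    notes=attrs.get("Note", ""),
                )
            )
    return feats
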