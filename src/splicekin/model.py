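"""Gene models, coordinate arithmetic, splicing and translation.

Everything downstream works in *gene-strand* orientation: a gene annotated on
the minus strand is reverse-complemented at load time so that exon intervals,
the CDS start and all splice-site coordinates read 5'→3' along the transcript.
Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneModel",
    "TranscriptSeq",
    "ProteinResult",
    "read_gene_models",
    "read_gene_model",
    "write_gene_models",
    "splice_out",
    "translate_and_scan",
    "codon_to_exon_local",
]

DOMAIN_LABELS = frozenset({"IgV", "IgC", "TM", "heptad", "B30.2", "UTR", "other"})

_STOPS = frozenset(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ValidationError(ValueError):
    """An object violates a structural invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A single gene: genomic sequence plus its constitutive exon chain.

    ``genomic_seq`` is in gene-strand orientation. ``exons`` are 0-based
    half-open intervals into ``genomic_seq``, strictly increasing and
    non-overlapping. ``cds_start`` is the genomic offset of the first base of
    the start codon; ``cds_codons``, when known, is the codon count of the
    constitutive CDS including the terminal stop. ``domain_labels`` maps exon
    index to a protein-domain label (IgV, IgC, TM, heptad, B30.2, UTR, other).
    """

    gene_id: str
    genomic_seq: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    domain_labels: dict[int, str] = field(default_factory=dict)
    cds_codons: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.gene_id}: empty/inverted exon ({s},{e})")
            if s < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping or unordered exons")
            prev_end = e
        if self.exons[-1][1] > len(self.genomic_seq) or self.exons[0][0] < 0:
            raise ValidationError(f"{self.gene_id}: exon outside sequence")
        if not any(s <= self.cds_start < e for s, e in self.exons):
            raise ValidationError(f"{self.gene_id}: cds_start not inside an exon")
        for idx, lab in self.domain_labels.items():
            if lab not in DOMAIN_LABELS:
                raise ValidationError(f"{self.gene_id}: unknown domain label {lab!r}")
            if not 0 <= idx < len(self.exons):
                raise ValidationError(f"{self.gene_id}: domain label for missing exon {idx}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons, gene-strand coordinates."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def exon_seq(self, i: int) -> str:
        s, e = self.exons[i]
        return self.genomic_seq[s:e]

    def mrna(self) -> str:
        return splice_out(self, range(self.n_exons))

    def mrna_cds_offset(self) -> int:
        """Offset of the start codon within the constitutive mRNA."""
        off = 0
        for s, e in self.exons:
            if s <= self.cds_start < e:
                return off + (self.cds_start - s)
            off += e - s
        raise ValidationError(f"{self.gene_id}: cds_start not exonic")

    def exon_mrna_spans(self) -> list[tuple[int, int]]:
        """Per-exon (start, end) spans in constitutive-mRNA coordinates."""
        spans, off = [], 0
        for s, e in self.exons:
            spans.append((off, off + (e - s)))
            off += e - s
        return spans


@dataclass(frozen=True)
class TranscriptSeq:
    """One sequenced cDNA clone (an insert from a cloned PCR amplicon)."""

    clone_id: str
    seq: str
    source_animal: str
    pcr_batch: str
    gene_hint: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValidationError(f"{self.clone_id}: empty sequence")
        if set(self.seq) - set("ACGTN"):
            raise ValidationError(f"{self.clone_id}: non-ACGTN characters")


@dataclass(frozen=True)
class ProteinResult:
    """Translation outcome of an (iso)form CDS."""

    peptide: str
    first_stop_codon_index: int | None  # 1-based codon position, None if no stop
    premature: bool

    def __post_init__(self):
        if self.premature and self.first_stop_codon_index is None:
            raise ValidationError("premature stop without a stop index")


def translate_and_scan(
    mrna: str, cds_offset: int, constitutive_codons: int | None = None
) -> ProteinResult:
    """Translate from ``cds_offset`` and locate the first in-frame stop.

    Codons containing N translate to X and never count as stops. A trailing
    partial codon is ignored. ``premature`` is True when a stop appears before
    codon ``constitutive_codons`` (the annotated terminal codon); with no
    reference codon count a stop is premature if any complete codon follows it.
    """
    if not 0 <= cds_offset < len(mrna):
        raise ValueError(f"cds_offset {cds_offset} outside sequence of length {len(mrna)}")
    peptide = []
    first_stop = None
    n_codons = (len(mrna) - cds_offset) // 3
    for i in range(n_codons):
        codon = mrna[cds_offset + 3 * i : cds_offset + 3 * i + 3]
        if "N" in codon:
            peptide.append("X")
            continue
        if codon in _STOPS:
            first_stop = i + 1
            break
        peptide.append(_CODON_TABLE[codon])
    if constitutive_codons is not None:
        premature = first_stop is not None and first_stop < constitutive_codons
    else:
        premature = first_stop is not None and first_stop < n_codons
    return ProteinResult("".join(peptide), first_stop, premature)


def codon_to_exon_local(model: GeneModel, codon_index: int) -> tuple[int, int]:
    """Map a 1-based CDS codon index to (exon_index, exon-local codon index).

    Exon-local numbering restarts at 1 for the first *complete* codon whose
    first base lies in that exon — the convention under which a stop at
    protein position 94 of a gene whose first exon holds 29 codons reads as
    "triplet 65 of exon 2".
    """
    cds = model.mrna_cds_offset()
    pos = cds + 3 * (codon_index - 1)  # mRNA offset of codon's first base
    for idx, (s, e) in enumerate(model.exon_mrna_spans()):
        if s <= pos < e:
            eff = max(s, cds)  # numbering cannot start before the CDS
            first_in_exon = -((eff - cds) // -3) + 1  # ceil division, 1-based
            local = codon_index - (first_in_exon - 1)
            return idx, local
    raise ValueError(f"codon {codon_index} beyond mRNA")


def splice_out(model: GeneModel, exon_subset) -> str:
    """Concatenate the chosen exons in order (the spliced transcript)."""
    subset = list(exon_subset)
    if any(subset[i] >= subset[i + 1] for i in range(len(subset) - 1)):
        raise ValueError("exon subset must be strictly increasing")
    parts = []
    for i in subset:
        if not 0 <= i < model.n_exons:
            raise ValueError(f"exon index {i} out of range")
        parts.append(model.exon_seq(i))
    return "".join(parts)


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O
# ---------------------------------------------------------------------------

def read_gene_models(gff3_path, fasta_path) -> dict[str, GeneModel]:
    """Load gene models from a GFF3/FASTA pair, normalizing to gene strand.

    Expects gene features with child exon features and a CDS; domain labels
    are read from an optional ``domain`` attribute on exons. Minus-strand
    genes are reverse-complemented and their coordinates remapped so that all
    downstream analysis runs in transcript orientation.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise FormatError(f"{fasta_path}: no FASTA records")
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        if gene.seqid not in seqs:
            raise FormatError(f"{gff3_path}: sequence {gene.seqid!r} absent from FASTA")
        contig = seqs[gene.seqid]
        exons = []
        labels: dict[int, str] = {}
        raw = []
        for ex in db.children(gene, featuretype="exon", order_by="start"):
            raw.append((ex.start - 1, ex.end, ex.attributes.get("domain", [None])[0]))
        if not raw:
            raise FormatError(f"{gff3_path}: gene {gene.id} has no exons")
        cds_feats = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds_feats:
            raise FormatError(f"{gff3_path}: gene {gene.id} has no CDS")
        cds_lo = min(c.start - 1 for c in cds_feats)
        cds_hi = max(c.end for c in cds_feats)
        gs, ge = gene.start - 1, gene.end
        if gene.strand == "-":
            L = ge - gs
            sub = str(Seq(contig[gs:ge]).reverse_complement())
            remapped = sorted((L - e, L - s, lab) for s, e, lab in raw)
            for i, (s, e, lab) in enumerate(remapped):
                exons.append((s, e))
                if lab:
                    labels[i] = lab
            cds_start = L - cds_hi
            seq = sub
        else:
            sub = contig[gs:ge]
            for i, (s, e, lab) in enumerate(sorted(raw)):
                exons.append((s - gs, e - gs))
                if lab:
                    labels[i] = lab
            cds_start = cds_lo - gs
            seq = sub
        n_codons = gene.attributes.get("cds_codons", [None])[0]
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            genomic_seq=seq,
            exons=tuple(exons),
            cds_start=cds_start,
            domain_labels=labels,
            cds_codons=int(n_codons) if n_codons else None,
        )
    if not models:
        raise FormatError(f"{gff3_path}: no gene features")
    return models


def read_gene_model(gff3_path, fasta_path) -> GeneModel:
    """Load a single-gene GFF3/FASTA pair."""
    models = read_gene_models(gff3_path, fasta_path)
    if len(models) != 1:
        raise FormatError(f"expected exactly one gene, found {sorted(models)}")
    return next(iter(models.values()))


def write_gene_models(models, gff3_path, fasta_path) -> None:
    """Write models as one contig per gene, plus-strand GFF3 features."""
    if isinstance(models, GeneModel):
        models = [models]
    elif isinstance(models, dict):
        models = list(models.values())
    with open(fasta_path, "w") as fa:
        for m in models:
            fa.write(f">{m.gene_id}\n")
            for i in range(0, len(m.genomic_seq), 70):
                fa.write(m.genomic_seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            if m.cds_codons:
                attrs += f";cds_codons={m.cds_codons}"
            gff.write(
                f"{m.gene_id}\tsplicekin\tgene\t1\t{len(m.genomic_seq)}\t.\t+\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                attrs = f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"
                if i in m.domain_labels:
                    attrs += f";domain={m.domain_labels[i]}"
                gff.write(
                    f"{m.gene_id}\tsplicekin\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                )
            # one CDS feature carrying the start; frame bookkeeping is derived
            cds_end = m.exons[-1][1]
            gff.write(
                f"{m.gene_id}\tsplicekin\tCDS\t{m.cds_start + 1}\t{cds_end}\t.\t+\t0\t"
                f"ID={m.gene_id}.cds;Parent={m.gene_id}\n"
            )
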