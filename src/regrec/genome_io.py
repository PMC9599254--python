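"""Genome and annotation I/O plus upstream-region extraction.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open on the forward strand of its
replicon.  Gene-relative ("promoter") coordinates follow the biologist
convention used for bacterial promoter scans: position +1 is the first base of
the start codon, position -1 abuts it on the 5' side, and there is no
position 0.  The default scan window is -500..+50 (550 bp).

For a minus-strand gene the "upstream" region lies at higher replicon
coordinates and is returned reverse-complemented so that the string always
reads 5'->3' toward the gene.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse in the declared format."""


class UnknownLocusError(KeyError):
    """Raised when a locus tag is not present in a genome."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene.

    ``cds_start``/``cds_end`` are 0-based half-open coordinates on the forward
    strand of ``replicon`` regardless of gene orientation, so
    ``cds_start < cds_end`` always holds.
    """

    locus_tag: str
    replicon: str
    strand: str  # '+' or '-'
    cds_start: int
    cds_end: int
    protein: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise ValueError(
                f"{self.locus_tag}: cds_start must be < cds_end "
                f"({self.cds_start}, {self.cds_end})"
            )

    @property
    def start_codon_pos(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1


@dataclass
class AnnotatedGenome:
    """Replicon sequences plus gene models for one genome."""

    genome_id: str
    replicons: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        self._by_tag = {}
        for g in self.genes:
            if g.locus_tag in self._by_tag:
                raise ValueError(f"duplicate locus tag {g.locus_tag}")
            if g.replicon not in self.replicons:
                raise ValueError(f"{g.locus_tag}: unknown replicon {g.replicon}")
            if g.cds_end > len(self.replicons[g.replicon]):
                raise ValueError(f"{g.locus_tag}: interval exceeds replicon")
            self._by_tag[g.locus_tag] = g

    def gene(self, locus_tag: str) -> GeneModel:
        try:
            return self._by_tag[locus_tag]
        except KeyError:
            raise UnknownLocusError(
                f"locus tag {locus_tag!r} not in genome {self.genome_id}"
            ) from None

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_tag

    def cds_sequence(self, locus_tag: str) -> str:
        g = self.gene(locus_tag)
        s = self.replicons[g.replicon][g.cds_start:g.cds_end]
        return s if g.strand == "+" else revcomp(s)


@dataclass
class UpstreamRegion:
    """A strand-normalized window around a gene's start codon.

    ``sequence`` reads 5'->3' on the gene's coding strand.  ``rel_start`` and
    ``rel_end`` are the biologist-convention relative positions actually
    covered (after any contig-edge clipping); ``abs_start``/``abs_end`` is the
    corresponding forward-strand replicon interval.
    """

    locus_tag: str
    genome_id: str
    replicon: str
    strand: str
    rel_start: int  # e.g. -500
    rel_end: int    # e.g. +50 (inclusive, biologist convention); -1 if window all-upstream
    sequence: str
    abs_start: int
    abs_end: int
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    def index_of_rel(self, rel: int) -> int:
        """0-based index into ``sequence`` of relative position ``rel``."""
        if rel == 0:
            raise ValueError("no position 0 in gene-relative coordinates")
        off = rel - self.rel_start if rel < 0 or self.rel_start > 0 else rel - self.rel_start - 1
        if not 0 <= off < len(self.sequence):
            raise ValueError(f"relative position {rel} outside region")
        return off

    def rel_of_index(self, idx: int) -> int:
        """Relative position of sequence index ``idx`` (inverse of index_of_rel)."""
        if not 0 <= idx < len(self.sequence):
            raise ValueError(f"index {idx} outside region")
        rel = self.rel_start + idx
        if self.rel_start < 0 and rel >= 0:
            rel += 1  # skip the nonexistent position 0
        return rel

    def abs_interval_of(self, idx: int, length: int) -> tuple[int, int]:
        """Forward-strand replicon interval of sequence slice [idx, idx+length)."""
        if self.strand == "+":
            return self.abs_start + idx, self.abs_start + idx + length
        return self.abs_end - idx - length, self.abs_end - idx


def extract_upstream(
    genome: AnnotatedGenome,
    locus_tag: str,
    window: tuple[int, int] = (-500, 50),
) -> UpstreamRegion:
    """Extract the window ``(rel_start, rel_end)`` around a gene's start codon.

    The window is given in gene-relative biologist coordinates (no 0); the
    default -500..+50 reproduces the standard promoter-scan window.  The
    window is truncated only at replicon edges (``clipped=True``); overlap
    with neighboring CDS does not truncate it.
    """
    rel_start, rel_end = window
    if rel_start == 0 or rel_end == 0:
        raise ValueError("gene-relative coordinates have no position 0")
    if rel_start >= rel_end:
        raise ValueError("window start must precede window end")
    gene = genome.gene(locus_tag)
    seq = genome.replicons[gene.replicon]
    rep_len = len(seq)

    # Convert relative bounds to offsets from the start-codon base, in
    # gene-reading direction; offset of rel r: r if r<0 else r-1.
    off_lo = rel_start if rel_start < 0 else rel_start - 1
    off_hi = (rel_end if rel_end < 0 else rel_end - 1) + 1  # half-open

    if gene.strand == "+":
        a = gene.cds_start + off_lo
        b = gene.cds_start + off_hi
        ca, cb = max(a, 0), min(b, rep_len)
        clipped = (ca != a) or (cb != b)
        region_seq = seq[ca:cb]
        # relative position of first retained base
        n_lost_front = ca - a
    else:
        anchor = gene.cds_end - 1  # start codon base
        a = anchor - (off_hi - 1)
        b = anchor - off_lo + 1
        ca, cb = max(a, 0), min(b, rep_len)
        clipped = (ca != a) or (cb != b)
        region_seq = revcomp(seq[ca:cb])
        n_lost_front = b - cb

    def _off_to_rel(off: int) -> int:
        return off if off < 0 else off + 1

    actual_rel_start = _off_to_rel(off_lo + n_lost_front)
    n_lost_back = (off_hi - off_lo) - len(region_seq) - n_lost_front
    actual_rel_end = _off_to_rel(off_hi - 1 - n_lost_back)

    return UpstreamRegion(
        locus_tag=locus_tag,
        genome_id=genome.genome_id,
        replicon=gene.replicon,
        strand=gene.strand,
        rel_start=actual_rel_start,
        rel_end=actual_rel_end,
        sequence=region_seq,
        abs_start=ca,
        abs_end=cb,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _gene_from_seqfeature(feat, replicon: str, seqstr: str) -> GeneModel | None:
    tags = feat.qualifiers.get("locus_tag")
    if not tags:
        log.warning("CDS without locus_tag at %s skipped", feat.location)
        return None
    start, end = int(feat.location.start), int(feat.location.end)
    strand = "+" if (feat.location.strand or 1) >= 0 else "-"
    protein = feat.qualifiers.get("translation", [""])[0]
    if not protein:
        cds = seqstr[start:end]
        if strand == "-":
            cds = revcomp(cds)
        protein = str(Seq(cds).translate(table=11)).rstrip("*")
    return GeneModel(tags[0], replicon, strand, start, end, protein)


def _read_genbank(path: str, genome_id: str | None) -> AnnotatedGenome:
    replicons, genes = {}, []
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise GenomeFormatError(f"{path}: not a valid GenBank file ({exc})") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    for rec in records:
        seqstr = str(rec.seq).upper()
        _check_alphabet(seqstr, f"{path}:{rec.id}")
        replicons[rec.id] = seqstr
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            g = _gene_from_seqfeature(feat, rec.id, seqstr)
            if g is not None:
                genes.append(g)
    gid = genome_id or records[0].id
    return AnnotatedGenome(gid, replicons, genes)


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for kv in attr.strip().split(";"):
        if not kv:
            continue
        if "=" not in kv:
            raise ValueError(f"malformed attribute {kv!r}")
        k, v = kv.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _read_fasta_gff3(fasta_path: str, gff3_path: str, genome_id: str | None) -> AnnotatedGenome:
    import gffutils

    replicons = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seqstr = str(rec.seq).upper()
        _check_alphabet(seqstr, f"{fasta_path}:{rec.id}")
        replicons[rec.id] = seqstr
    if not replicons:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records found")

    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise GenomeFormatError(f"{gff3_path}: not a valid GFF3 file ({exc})") from exc

    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        tags = feat.attributes.get("locus_tag")
        if not tags:
            log.warning("%s: CDS at %s:%d without locus_tag skipped",
                        gff3_path, feat.seqid, feat.start)
            continue
        if feat.seqid not in replicons:
            raise GenomeFormatError(
                f"{gff3_path}: CDS references unknown replicon {feat.seqid}"
            )
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        strand = "-" if feat.strand == "-" else "+"
        seqstr = replicons[feat.seqid]
        cds = seqstr[start:end]
        if strand == "-":
            cds = revcomp(cds)
        protein = str(Seq(cds).translate(table=11)).rstrip("*")
        genes.append(GeneModel(tags[0], feat.seqid, strand, start, end, protein))
    gid = genome_id or os.path.splitext(os.path.basename(fasta_path))[0]
    return AnnotatedGenome(gid, replicons, genes)


def _check_alphabet(seq: str, where: str) -> None:
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise GenomeFormatError(f"{where}: non-ACGTN characters {bad}")


def read_genome(
    path: str,
    format: str = "genbank",
    gff3: str | None = None,
    genome_id: str | None = None,
) -> AnnotatedGenome:
    """Read a genome as GenBank or FASTA+GFF3.

    Parameters
    ----------
    path : str
        GenBank flat file, or genome FASTA when ``format='fasta+gff3'``.
    format : {'genbank', 'fasta+gff3'}
    gff3 : str, optional
        GFF3 annotation path (required for ``fasta+gff3``).
    genome_id : str, optional
        Override the genome identifier (defaults to first record id or the
        FASTA basename).
    """
    if format == "genbank":
        return _read_genbank(path, genome_id)
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3 path")
        return _read_fasta_gff3(path, gff3, genome_id)
    raise ValueError(f"unknown format {format!r}")


def write_fasta_gff3(genome: AnnotatedGenome, fasta_path: str, gff3_path: str) -> None:
    """Write a genome to FASTA + GFF3 (CDS rows carrying locus_tag)."""
    with open(fasta_path, "w") as fh:
        for name, seq in genome.replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.replicons.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(genome.genes, key=lambda g: (g.replicon, g.cds_start)):
            fh.write(
                "\t".join([
                    g.replicon, "regrec", "CDS",
                    str(g.cds_start + 1), str(g.cds_end),  # back to 1-based inclusive
                    ".", g.strand, "0",
                    f"ID={g.locus_tag};locus_tag={g.locus_tag}",
                ]) + "\n"
            )


def reverse_complement_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Mirror a genome: reverse-complement every replicon and flip gene strands.

    Useful as a symmetry check: upstream regions extracted from the mirrored
    genome are the reverse complements of the originals.
    """
    replicons = {name: revcomp(seq) for name, seq in genome.replicons.items()}
    genes = []
    for g in genome.genes:
        n = len(genome.replicons[g.replicon])
        genes.append(GeneModel(
            g.locus_tag, g.replicon,
            "-" if g.strand == "+" else "+",
            n - g.cds_end, n - g.cds_start,
            g.protein,
        ))
    return AnnotatedGenome(genome.genome_id, replicons, genes)
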