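"""Sliding-window operator scanning over upstream regions.

Every length-L window of each gene's upstream region is scored on the coding
strand and, by default, on its reverse complement.  Hits at or above the
threshold are reported with both gene-relative and absolute coordinates.  For
palindromic matrices a genuine site typically produces a near-identical hit
on both strands at (almost) the same position; these strand mirrors are
collapsed to the single higher-scoring representative (dedup radius 2 bp).
Same-strand tandem hits are never collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import AnnotatedGenome, extract_upstream, revcomp
from .pwm import WeightMatrix

log = logging.getLogger(__name__)

SITE_TABLE_COLUMNS = [
    "genome_id", "locus_tag", "replicon", "abs_start", "abs_end",
    "rel_start", "strand", "score", "sequence",
]


@dataclass
class ScanConfig:
    """Parameters of an upstream operator scan."""

    window: tuple[int, int] = (-500, 50)
    threshold: float = 4.3
    both_strands: bool = True
    dedup_radius: int = 2

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")


@dataclass(frozen=True)
class CandidateSite:
    """One scored motif occurrence in a gene's upstream window.

    ``strand`` is the replicon strand whose 5'->3' reading gives
    ``sequence``; ``rel_start`` is the gene-relative position (biologist
    convention, no 0) of the site's 5'-most base on the gene's coding strand.
    """

    genome_id: str
    locus_tag: str
    replicon: str
    abs_start: int
    abs_end: int
    rel_start: int
    strand: str
    score: float
    sequence: str


def scan_gene(
    genome: AnnotatedGenome,
    locus_tag: str,
    pwm: WeightMatrix,
    config: ScanConfig | None = None,
) -> list[CandidateSite]:
    """Scan one gene's upstream window; hits sorted by gene-relative position."""
    config = config or ScanConfig()
    region = extract_upstream(genome, locus_tag, config.window)
    L = pwm.length
    if len(region) < L:
        log.info("%s/%s: region shorter than motif (%d < %d), no scan",
                 genome.genome_id, locus_tag, len(region), L)
        return []

    gene = genome.gene(locus_tag)
    hits: list[CandidateSite] = []

    def _collect(scores: np.ndarray, on_coding: bool):
        for i in np.flatnonzero(scores >= config.threshold):
            i = int(i)
            a, b = region.abs_interval_of(i, L)
            # replicon strand of the match
            if on_coding:
                strand = gene.strand
            else:
                strand = "-" if gene.strand == "+" else "+"
            window_seq = region.sequence[i:i + L]
            seq = window_seq if on_coding else revcomp(window_seq)
            hits.append(CandidateSite(
                genome_id=genome.genome_id,
                locus_tag=locus_tag,
                replicon=region.replicon,
                abs_start=a,
                abs_end=b,
                rel_start=region.rel_of_index(i),
                strand=strand,
                score=float(scores[i]),
                sequence=seq,
            ))

    _collect(pwm.scan(region.sequence), on_coding=True)
    if config.both_strands:
        # scoring the reverse complement of each window == scanning with the
        # reverse-complemented matrix at the same offsets
        _collect(pwm.reverse_complement().scan(region.sequence), on_coding=False)

    hits = _dedup_strand_mirrors(hits, config.dedup_radius)
    hits.sort(key=lambda h: (h.rel_start, h.strand))
    return hits


def _dedup_strand_mirrors(hits: list[CandidateSite], radius: int) -> list[CandidateSite]:
    """Collapse opposite-strand hit pairs whose starts differ by <= radius.

    Keeps the higher-scoring member; scores are compared at 1e-6 resolution
    so that exact palindrome mirrors tie, broken deterministically toward
    the '+' strand then the lower start.  Same-strand hits are never
    collapsed.
    """
    removed = set()
    ordered = sorted(
        range(len(hits)),
        key=lambda i: (-round(hits[i].score, 6), hits[i].strand, hits[i].abs_start))
    for oi, i in enumerate(ordered):
        if i in removed:
            continue
        hi = hits[i]
        for j in ordered[oi + 1:]:
            if j in removed:
                continue
            hj = hits[j]
            if hj.strand != hi.strand and abs(hj.abs_start - hi.abs_start) <= radius:
                removed.add(j)
    return [h for k, h in enumerate(hits) if k not in removed]


def scan_genome(
    genome: AnnotatedGenome,
    pwm: WeightMatrix,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Scan every gene's upstream window; returns a site table.

    A physical site lying in the windows of two genes (a divergently
    transcribed pair) appears once per gene, sharing absolute coordinates.
    """
    config = config or ScanConfig()
    rows = []
    for gene in sorted(genome.genes, key=lambda g: (g.replicon, g.cds_start)):
        for h in scan_gene(genome, gene.locus_tag, pwm, config):
            rows.append({c: getattr(h, c) for c in SITE_TABLE_COLUMNS})
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def sites_from_table(table: pd.DataFrame) -> list[CandidateSite]:
    return [CandidateSite(**{c: row[c] for c in SITE_TABLE_COLUMNS})
            for _, row in table.iterrows()]


def write_site_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_site_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(table: pd.DataFrame, path: str) -> None:
    """BED6 export: 0-based half-open, score x100 rounded, name = locus_tag."""
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            fh.write("\t".join([
                str(r["replicon"]), str(int(r["abs_start"])), str(int(r["abs_end"])),
                str(r["locus_tag"]), str(int(round(r["score"] * 100))), str(r["strand"]),
            ]) + "\n")


def make_emsa_probe(genome: AnnotatedGenome, site: CandidateSite, flank: int = 14) -> str:
    """Build an EMSA probe: the operator plus ``flank`` bp of genomic context
    on each side, oriented on the site's match strand (49 bp at defaults for
    a 21-bp operator)."""
    seq = genome.replicons[site.replicon]
    a, b = site.abs_start - flank, site.abs_end + flank
    if a < 0 or b > len(seq):
        raise ValueError(
            f"flank {flank} exceeds replicon bounds for site at "
            f"{site.replicon}:{site.abs_start}-{site.abs_end}"
        )
    probe = seq[a:b]
    return probe if site.strand == "+" else revcomp(probe)
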