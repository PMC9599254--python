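"""Cross-genome machinery: orthology, operons, consistency filtering,
regulon assembly, footprint alignment, and per-clade PWM refinement.

The consistency check ("phylogenetic footprinting") is the step that turns a
noisy single-genome scan into a regulon: a candidate operator upstream of a
transcription unit is kept only if orthologs of that unit in enough other
genomes also carry an above-threshold site in their own upstream windows.
Genuine operators are under purifying selection and recur across a clade;
chance hits are genome-specific and get discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, Phylo

from .genome_io import AnnotatedGenome, UpstreamRegion
from .pwm import SiteAlignment, WeightMatrix, build_pwm
from .scan import CandidateSite

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Orthology (bidirectional best hits over global protein alignment)
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Bidirectional-best-hit pairs between two genomes.

    ``pairs`` maps locus tags of ``genome_a`` to locus tags of ``genome_b``;
    each locus appears in at most one pair.  ``stats`` holds (identity,
    coverage) per pair, keyed by the genome_a locus.
    """

    genome_a: str
    genome_b: str
    pairs: dict[str, str] = field(default_factory=dict)
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._rev = {v: k for k, v in self.pairs.items()}

    def mate(self, genome_id: str, locus_tag: str) -> str | None:
        """Ortholog of ``locus_tag`` (which lives in ``genome_id``) in the
        other genome of the pair, or None."""
        if genome_id == self.genome_a:
            return self.pairs.get(locus_tag)
        if genome_id == self.genome_b:
            return self._rev.get(locus_tag)
        raise KeyError(f"{genome_id} is not part of this ortholog map")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("locus_a\tlocus_b\tidentity\tcoverage\n")
            for a, b in sorted(self.pairs.items()):
                ident, cov = self.stats.get(a, (float("nan"), float("nan")))
                fh.write(f"{a}\t{b}\t{ident:.4f}\t{cov:.4f}\n")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _identity_coverage(aligner, pa: str, pb: str) -> tuple[float, float]:
    aln = aligner.align(pa, pb)[0]
    blocks_a, blocks_b = aln.aligned
    n_aligned = 0
    n_ident = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        n_aligned += a1 - a0
        n_ident += sum(x == y for x, y in zip(pa[a0:a1], pb[b0:b1]))
    # alignment length = columns incl. gaps
    aln_len = aln.shape[1]
    identity = n_ident / aln_len if aln_len else 0.0
    coverage = n_aligned / max(len(pa), len(pb)) if pa and pb else 0.0
    return identity, coverage


def bbh_orthologs(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    min_identity: float = 0.4,
    min_coverage: float = 0.7,
) -> OrthologMap:
    """Bidirectional best hits by global protein alignment.

    Scoring: match +1, mismatch -1, gap open -5, extend -1.  A pair is kept
    iff each protein is the other's best hit, with alignment identity >=
    ``min_identity`` and aligned-residue coverage (of the longer protein) >=
    ``min_coverage``.
    """
    prots_a = [(g.locus_tag, g.protein) for g in genome_a.genes if g.protein]
    prots_b = [(g.locus_tag, g.protein) for g in genome_b.genes if g.protein]
    if not prots_a or not prots_b:
        raise ValueError("empty proteome: cannot compute orthologs")

    aligner = _make_aligner()
    scores = np.empty((len(prots_a), len(prots_b)))
    for i, (_, pa) in enumerate(prots_a):
        for j, (_, pb) in enumerate(prots_b):
            scores[i, j] = aligner.score(pa, pb)

    best_b_for_a = scores.argmax(axis=1)
    best_a_for_b = scores.argmax(axis=0)

    pairs, stats = {}, {}
    for i, j in enumerate(best_b_for_a):
        if best_a_for_b[j] != i:
            continue
        tag_a, pa = prots_a[i]
        tag_b, pb = prots_b[int(j)]
        ident, cov = _identity_coverage(aligner, pa, pb)
        if ident >= min_identity and cov >= min_coverage:
            pairs[tag_a] = tag_b
            stats[tag_a] = (ident, cov)
    return OrthologMap(genome_a.genome_id, genome_b.genome_id, pairs, stats)


def all_pairs_orthologs(
    genomes: dict[str, AnnotatedGenome], **kwargs
) -> dict[tuple[str, str], OrthologMap]:
    """BBH maps for every unordered genome pair, keyed by sorted id tuple."""
    ids = sorted(genomes)
    maps = {}
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            maps[(ga, gb)] = bbh_orthologs(genomes[ga], genomes[gb], **kwargs)
    return maps


def _lookup_map(
    maps: dict[tuple[str, str], OrthologMap], ga: str, gb: str
) -> OrthologMap:
    key = (ga, gb) if (ga, gb) in maps else (gb, ga)
    if key not in maps:
        raise KeyError(f"no ortholog map for genome pair ({ga}, {gb})")
    return maps[key]


# ---------------------------------------------------------------------------
# Operons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Operon:
    """A maximal run of same-strand, closely spaced colinear genes.

    ``genes`` is in genomic coordinate order; the lead (promoter-proximal)
    gene is the first for '+' operons and the last for '-' operons.
    """

    replicon: str
    strand: str
    genes: tuple[str, ...]

    @property
    def lead(self) -> str:
        return self.genes[0] if self.strand == "+" else self.genes[-1]


def predict_operons(genome: AnnotatedGenome, max_gap: int = 150) -> list[Operon]:
    """Partition genes into operons: same replicon, same strand, intergenic
    gap <= ``max_gap`` bp between consecutive genes."""
    operons: list[Operon] = []
    ordered = sorted(genome.genes, key=lambda g: (g.replicon, g.cds_start))
    run: list = []
    for g in ordered:
        if run and (
            g.replicon == run[-1].replicon
            and g.strand == run[-1].strand
            and g.cds_start - run[-1].cds_end <= max_gap
        ):
            run.append(g)
        else:
            if run:
                operons.append(Operon(run[0].replicon, run[0].strand,
                                      tuple(x.locus_tag for x in run)))
            run = [g]
    if run:
        operons.append(Operon(run[0].replicon, run[0].strand,
                              tuple(x.locus_tag for x in run)))
    return operons


def operon_index(operons: list[Operon]) -> dict[str, Operon]:
    """locus_tag -> containing operon."""
    idx = {}
    for op in operons:
        for tag in op.genes:
            idx[tag] = op
    return idx


# ---------------------------------------------------------------------------
# Consistency filtering
# ---------------------------------------------------------------------------

def consistency_filter(
    site_tables: dict[str, pd.DataFrame],
    orthologs: dict[tuple[str, str], OrthologMap],
    operons: dict[str, list[Operon]],
    min_support: int = 2,
) -> dict[str, pd.DataFrame]:
    """Cross-genome consistency check on candidate sites.

    A site upstream of a transcription unit (TU) in genome ``g`` is retained
    iff in at least ``min_support`` other genomes an ortholog of any gene of
    that TU belongs to a TU that itself carries an above-threshold hit.  All
    sites upstream of the same TU share one fate.  Support is counted at the
    TU level so that operon fission/fusion across genomes does not break it.
    """
    genome_ids = sorted(site_tables)
    op_idx = {g: operon_index(operons[g]) for g in genome_ids}

    # TUs (by lead gene) with at least one raw hit, per genome
    hit_tus: dict[str, set[str]] = {}
    for g in genome_ids:
        tus = set()
        for tag in site_tables[g]["locus_tag"]:
            tus.add(op_idx[g][tag].lead)
        hit_tus[g] = tus

    filtered = {}
    for g in genome_ids:
        table = site_tables[g]
        keep_tu: dict[str, bool] = {}
        for tag in table["locus_tag"].unique():
            tu = op_idx[g][tag]
            if tu.lead in keep_tu:
                continue
            support = 0
            for h in genome_ids:
                if h == g:
                    continue
                omap = _lookup_map(orthologs, g, h)
                supported = False
                for member in tu.genes:
                    mate = omap.mate(g, member)
                    if mate is not None and mate in op_idx[h]:
                        if op_idx[h][mate].lead in hit_tus[h]:
                            supported = True
                            break
                if supported:
                    support += 1
            keep_tu[tu.lead] = support >= min_support
        mask = [keep_tu[op_idx[g][tag].lead] for tag in table["locus_tag"]]
        filtered[g] = table[pd.Series(mask, index=table.index)].reset_index(drop=True)
    return filtered


# ---------------------------------------------------------------------------
# Regulon assembly
# ---------------------------------------------------------------------------

@dataclass
class Regulon:
    """The inference product: per genome, operators, member operons, genes."""

    tf_name: str
    per_genome: dict[str, dict] = field(default_factory=dict)

    def genes(self, genome_id: str) -> set[str]:
        return set(self.per_genome[genome_id]["genes"])

    def operator_count(self, genome_id: str) -> int:
        return len(self.per_genome[genome_id]["operators"])

    def gene_count(self, genome_id: str, include_tf: bool = True) -> int:
        genes = self.genes(genome_id)
        if not include_tf:
            genes = genes - set(self.per_genome[genome_id].get("tf_genes", []))
        return len(genes)

    def to_json(self, path: str) -> None:
        payload = {"tf_name": self.tf_name, "genomes": {}}
        for g, entry in sorted(self.per_genome.items()):
            payload["genomes"][g] = {
                "operators": entry["operators"],
                "operons": [list(op) for op in entry["operons"]],
                "genes": sorted(entry["genes"]),
                "flags": entry.get("flags", []),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        """Flat member-gene table (locus_tag per genome, lead operator info)."""
        with open(path, "w") as fh:
            fh.write("genome_id\tlocus_tag\toperon_lead\toperator_start\t"
                     "operator_end\toperator_score\n")
            for g, entry in sorted(self.per_genome.items()):
                op_by_lead = {}
                for op in entry["operators"]:
                    op_by_lead.setdefault(op["lead"], op)
                for operon in entry["operons"]:
                    lead = operon[0] if isinstance(operon, (list, tuple)) else operon
                    for tag in operon:
                        op = op_by_lead.get(lead)
                        if op:
                            fh.write(f"{g}\t{tag}\t{lead}\t{op['abs_start']}\t"
                                     f"{op['abs_end']}\t{op['score']:.3f}\n")
                        else:
                            fh.write(f"{g}\t{tag}\t{lead}\t.\t.\t.\n")


def assemble_regulon(
    filtered_sites: pd.DataFrame,
    operons: list[Operon],
    genome: AnnotatedGenome,
    tf_name: str = "TF",
) -> dict:
    """Assemble one genome's regulon entry from retained sites.

    Member genes are the union of genes of every operon whose lead gene
    carries at least one retained operator (interior hits are reassigned to
    the operon lead).  The operator tally counts distinct absolute intervals
    once, so a site shared by a divergent gene pair is not double-counted.
    """
    idx = operon_index(operons)
    member_operons: list[Operon] = []
    seen_ops: set[tuple] = set()
    operators: list[dict] = []
    member_leads = set()

    for _, row in filtered_sites.iterrows():
        tu = idx[row["locus_tag"]]
        if tu.lead not in member_leads:
            member_leads.add(tu.lead)
            member_operons.append(tu)
        key = (row["replicon"], int(row["abs_start"]), int(row["abs_end"]))
        if key not in seen_ops:
            seen_ops.add(key)
            operators.append({
                "replicon": row["replicon"],
                "abs_start": int(row["abs_start"]),
                "abs_end": int(row["abs_end"]),
                "rel_start": int(row["rel_start"]),
                "strand": row["strand"],
                "score": float(row["score"]),
                "sequence": row["sequence"],
                "lead": tu.lead,
            })

    member_operons.sort(key=lambda op: (op.replicon, op.genes))
    genes = sorted({tag for op in member_operons for tag in op.genes})
    return {
        "tf_name": tf_name,
        "operators": sorted(operators, key=lambda o: (o["replicon"], o["abs_start"])),
        "operons": [op.genes for op in member_operons],
        "genes": genes,
    }


# ---------------------------------------------------------------------------
# Footprint alignment
# ---------------------------------------------------------------------------

@dataclass
class FootprintReport:
    """Operator-anchored, ungapped stack of orthologous upstream regions."""

    genome_ids: list[str]
    rows: list[str]              # padded with '.' outside each region
    operator_span: tuple[int, int]  # column interval of the operator
    conservation: np.ndarray     # per-column max base frequency
    unanchored: list[str]        # genomes whose region lacked a site

    def to_text(self) -> str:
        lines = []
        width = max((len(g) for g in self.genome_ids), default=8) + 2
        a, b = self.operator_span
        marker = "".join("*" if a <= i < b else " "
                         for i in range(len(self.conservation)))
        lines.append(" " * width + marker.rstrip())
        for g, row in zip(self.genome_ids, self.rows):
            lines.append(g.ljust(width) + row)
        cons = "".join(
            "|" if c == 1.0 else str(int(c * 10)) if c > 0 else "."
            for c in np.nan_to_num(self.conservation)
        )
        lines.append("cons".ljust(width) + cons)
        if self.unanchored:
            lines.append("# unanchored: " + ", ".join(self.unanchored))
        return "\n".join(lines) + "\n"


def footprint_alignment(
    regions: list[UpstreamRegion],
    sites: dict[str, CandidateSite | None],
    site_length: int | None = None,
) -> FootprintReport:
    """Anchor orthologous upstream regions at their operator start.

    ``sites`` maps genome_id -> the region's retained site (or None).
    Regions lacking a site are reported unanchored and excluded from the
    stack.  Conservation per column is the modal base frequency among the
    regions covering that column.
    """
    anchored, unanchored = [], []
    for region in regions:
        site = sites.get(region.genome_id)
        if site is None:
            unanchored.append(region.genome_id)
            continue
        anchor = region.index_of_rel(site.rel_start)
        anchored.append((region, anchor))
        if site_length is None:
            site_length = site.abs_end - site.abs_start
    if not anchored:
        raise ValueError("no region carries a site; nothing to anchor")

    left = max(anchor for _, anchor in anchored)
    right = max(len(r) - anchor for r, anchor in anchored)
    width = left + right

    genome_ids, rows = [], []
    mat = np.full((len(anchored), width), ".", dtype="U1")
    for i, (region, anchor) in enumerate(anchored):
        start = left - anchor
        mat[i, start:start + len(region)] = list(region.sequence)
        genome_ids.append(region.genome_id)
        rows.append("".join(mat[i]))

    conservation = np.zeros(width)
    for c in range(width):
        col = [x for x in mat[:, c] if x != "."]
        if col:
            _, counts = np.unique(col, return_counts=True)
            conservation[c] = counts.max() / len(col)
    return FootprintReport(
        genome_ids=genome_ids,
        rows=rows,
        operator_span=(left, left + (site_length or 0)),
        conservation=conservation,
        unanchored=unanchored,
    )


# ---------------------------------------------------------------------------
# Per-clade PWM refinement
# ---------------------------------------------------------------------------

def clades_from_newick(path: str) -> dict[str, list[str]]:
    """Partition tree leaves into clades: one group per child of the root."""
    tree = Phylo.read(path, "newick")
    groups = {}
    for i, child in enumerate(tree.root.clades, start=1):
        leaves = [t.name for t in child.get_terminals()]
        groups[f"clade{i}"] = leaves
    if not groups:
        groups["clade1"] = [t.name for t in tree.get_terminals()]
    return groups


def refine_pwm_per_clade(
    groups: dict[str, list[str]],
    initial_pwm: WeightMatrix,
    filtered_sites: dict[str, pd.DataFrame],
) -> dict[str, WeightMatrix]:
    """Rebuild the PWM separately from each clade's retained sites.

    Clades with fewer than 2 retained sites fall back to the global matrix
    (logged).  The returned dict includes the pooled 'global' matrix.
    """
    def _rebuild(seqs: list[str], label: str) -> WeightMatrix | None:
        if len(seqs) < 2:
            log.warning("%s: %d retained site(s); falling back to global PWM",
                        label, len(seqs))
            return None
        return build_pwm(
            SiteAlignment(seqs),
            palindromic=initial_pwm.palindromic,
            pseudocount=initial_pwm.pseudocount,
            threshold=initial_pwm.threshold,
        )

    all_seqs = [s for g in sorted(filtered_sites)
                for s in filtered_sites[g]["sequence"].tolist()]
    global_pwm = _rebuild(all_seqs, "global") or initial_pwm

    out = {"global": global_pwm}
    for clade, members in sorted(groups.items()):
        seqs = [s for g in members if g in filtered_sites
                for s in filtered_sites[g]["sequence"].tolist()]
        out[clade] = _rebuild(seqs, clade) or global_pwm
    return out
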