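"""Ground-truthed synthetic inputs for the reconstruction pipeline.

:func:`simulate_clade` builds an ancestral high-GC genome with annotated
genes, plants palindromic operator instances (sampled from a generating
frequency matrix) upstream of a designated regulon, derives leaf genomes by
i.i.d. substitutions — with a lower in-site rate modeling purifying
selection on functional operators — and plants single-genome decoy sites
drawn from the same matrix.  Decoys are score-indistinguishable from real
operators; only cross-genome support separates them, which is exactly what
the consistency filter exploits.

:func:`simulate_titration` and :func:`simulate_growth` emit 4PL-shaped
dose-response curves and logistic-with-lag growth curves with additive
Gaussian noise, for exercising the quantification math.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genome_io import AnnotatedGenome, GeneModel, revcomp, write_fasta_gff3
from .pwm import BASES, SiteAlignment
from .quant import GrowthCurve, TitrationCurve, four_pl

_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Generating motif
# ---------------------------------------------------------------------------

@dataclass
class GeneratingPWM:
    """A frequency matrix sites are sampled from, plus its consensus."""

    freqs: np.ndarray          # (4, L), columns sum to 1
    consensus: str
    informative: np.ndarray    # bool mask over columns

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def sample_site(self, rng: np.random.Generator, max_mismatches: int = 1) -> str:
        """Draw a site; functional operators are under selection, so draws
        with more than ``max_mismatches`` informative-position mismatches
        from the consensus are rejected and resampled."""
        info_idx = np.flatnonzero(self.informative)
        cons = np.array([BASES.index(c) for c in self.consensus])
        for _ in range(10000):
            cols = np.array([
                rng.choice(4, p=self.freqs[:, k]) for k in range(self.length)
            ])
            if (cols[info_idx] != cons[info_idx]).sum() <= max_mismatches:
                return "".join(BASES[i] for i in cols)
        raise RuntimeError("site sampling failed to satisfy mismatch bound")


def default_generating_pwm(
    consensus_half: str = "ACGTACAAT",
    spacer: int = 3,
    concentration: float = 0.98,
) -> GeneratingPWM:
    """The default 21-bp palindromic operator model.

    The two 9-bp half-sites are reverse complements of each other at
    ``concentration`` per-position consensus frequency; the central
    ``spacer`` columns are uniform (a homodimer grips the half-sites and is
    indifferent to the spacer).
    """
    right = revcomp(consensus_half)
    consensus = consensus_half + "A" * spacer + right
    L = len(consensus)
    half = len(consensus_half)
    informative = np.ones(L, dtype=bool)
    informative[half:half + spacer] = False
    freqs = np.empty((4, L))
    for k, base in enumerate(consensus):
        if informative[k]:
            freqs[:, k] = (1 - concentration) / 3
            freqs[BASES.index(base), k] = concentration
        else:
            freqs[:, k] = 0.25
    return GeneratingPWM(freqs=freqs, consensus=consensus, informative=informative)


def alternative_generating_pwm() -> GeneratingPWM:
    """A second operator variant (different half-site) for two-clade setups."""
    return default_generating_pwm(consensus_half="TTCGATAGA")


# ---------------------------------------------------------------------------
# Clade simulation
# ---------------------------------------------------------------------------

@dataclass
class CladeSimConfig:
    """Study conditions for the synthetic clade."""

    n_genomes: int = 5
    n_genes: int = 50
    gene_codons: tuple[int, int] = (100, 500)        # 300-1500 bp CDS
    intergenic: tuple[int, int] = (50, 400)          # bp
    gc: float = 0.60
    regulon_size: int = 20
    site_window: tuple[int, int] = (-120, -30)       # planted rel position
    divergence: float = 0.05                         # per-site substitution prob
    in_site_divergence: float = 0.02                 # within planted operators
    n_decoys: int = 10
    n_training_sites: int = 20
    seed: int = 42
    generating_pwms: dict[str, GeneratingPWM] | None = None  # clade -> PWM
    clades: dict[str, list[int]] | None = None       # clade -> genome indices

    def __post_init__(self):
        if not 0 < self.regulon_size <= self.n_genes:
            raise ValueError("regulon size must be in 1..n_genes")
        for p in (self.divergence, self.in_site_divergence, self.gc):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class PlantedSite:
    locus_tag: str
    family: int            # gene family index (ortholog group)
    abs_start: int
    abs_end: int
    rel_start: int
    strand: str            # replicon strand carrying the site 5'->3'
    source: str            # 'regulon' | 'decoy'
    sequence: str


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic genomes."""

    regulon_families: list[int]
    decoy_placements: list[tuple[str, int]]          # (genome_id, family)
    operators: dict[str, list[PlantedSite]] = field(default_factory=dict)
    clade_of_genome: dict[str, str] = field(default_factory=dict)
    consensus_by_clade: dict[str, str] = field(default_factory=dict)

    def regulon_genes(self, genome_id: str) -> set[str]:
        return {f"{genome_id}_g{f:03d}" for f in self.regulon_families}

    def ortholog_pairs(self, genome_ids: list[str], n_genes: int) -> set[frozenset]:
        pairs = set()
        ids = sorted(genome_ids)
        for i, ga in enumerate(ids):
            for gb in ids[i + 1:]:
                for f in range(n_genes):
                    pairs.add(frozenset((f"{ga}_g{f:03d}", f"{gb}_g{f:03d}")))
        return pairs

    def to_json(self, path: str) -> None:
        payload = {
            "regulon_families": sorted(self.regulon_families),
            "decoy_placements": [list(dp) for dp in self.decoy_placements],
            "clade_of_genome": self.clade_of_genome,
            "consensus_by_clade": self.consensus_by_clade,
            "operators": {
                g: [vars(s) for s in sites]
                for g, sites in sorted(self.operators.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons - 2) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        tri = "".join(BASES[i] for i in _random_bases(rng, 3, gc))
        if tri not in _STOPS:
            codons.append(tri)
    codons.append("TAA")
    return "".join(codons)


def _idx_to_seq(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


class _Layout:
    """Ancestral genome layout: genes on alternating strands with sampled
    intergenic gaps; records per-gene coordinates."""

    def __init__(self, cfg: CladeSimConfig, rng: np.random.Generator,
                 regulon: set[int], decoy_hosts: set[int]):
        self.genes: list[tuple[int, int, int, str]] = []  # family, start, end, strand
        parts: list[str] = []
        pos = 0
        lo, hi = cfg.intergenic
        needs_room = regulon | decoy_hosts
        for fam in range(cfg.n_genes):
            strand = "+" if fam % 2 == 0 else "-"
            gap_lo = lo
            # a gap shared by a divergent pair of planted genes must hold
            # two non-overlapping sites; give it room
            if fam > 0 and strand == "+" and (fam in needs_room) and (fam - 1 in needs_room):
                gap_lo = max(lo, 200)
            gap = int(rng.integers(gap_lo, hi + 1))
            parts.append(_idx_to_seq(_random_bases(rng, gap, cfg.gc)))
            pos += gap
            n_codons = int(rng.integers(cfg.gene_codons[0], cfg.gene_codons[1] + 1))
            cds = _random_cds(rng, n_codons, cfg.gc)
            placed = cds if strand == "+" else revcomp(cds)
            parts.append(placed)
            self.genes.append((fam, pos, pos + len(cds), strand))
            pos += len(cds)
        tail = int(rng.integers(lo, hi + 1))
        parts.append(_idx_to_seq(_random_bases(rng, tail, cfg.gc)))
        self.sequence = "".join(parts)

    def gene_interval(self, fam: int) -> tuple[int, int, str]:
        f, s, e, st = self.genes[fam]
        return s, e, st


def _site_abs_interval(start: int, end: int, strand: str, rel: int, L: int
                       ) -> tuple[int, int]:
    """Forward-strand interval of a site at gene-relative position ``rel``
    (biologist convention, upstream so rel < 0) on the coding strand."""
    off = rel  # rel < 0 maps directly to the offset from the start codon
    if strand == "+":
        a = start + off
    else:
        a = (end - 1) - off - (L - 1)
    return a, a + L


def _place_site(seq_idx: np.ndarray, site: str, a: int, strand: str) -> None:
    placed = site if strand == "+" else revcomp(site)
    seq_idx[a:a + len(site)] = [BASES.index(c) for c in placed]


def simulate_clade(config: CladeSimConfig | None = None
                   ) -> tuple[dict[str, AnnotatedGenome], SimTruth, SiteAlignment]:
    """Simulate a clade of annotated genomes with planted operators.

    Returns the genomes (keyed by id G1..Gn), the ground truth, and a
    training alignment of sites drawn from the generating matrix (the
    synthetic stand-in for a curated known-site collection).
    """
    cfg = config or CladeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    L_site = 21

    genome_ids = [f"G{i + 1}" for i in range(cfg.n_genomes)]
    clades = cfg.clades or {"clade1": list(range(cfg.n_genomes))}
    pwms = cfg.generating_pwms or {"clade1": default_generating_pwm()}
    clade_of = {}
    for clade, members in clades.items():
        for m in members:
            clade_of[genome_ids[m]] = clade

    # The regulon is chosen as whole divergent pairs: with alternating
    # strands, genes (2k-1, 2k) share their upstream intergenic region, so a
    # site planted for either lies in both windows — exactly the shared
    # operator of a divergently transcribed pair.  Pair closure keeps the
    # set of genes geometrically downstream of planted sites equal to the
    # designated regulon.
    pairs = [(f, f + 1) for f in range(1, cfg.n_genes - 1, 2)]
    n_pairs = min(cfg.regulon_size // 2, len(pairs))
    chosen = rng.choice(len(pairs), size=n_pairs, replace=False)
    regulon = {f for i in chosen for f in pairs[int(i)]}
    if len(regulon) < cfg.regulon_size:  # odd size: gene 0 has a private gap
        regulon.add(0)
    non_regulon = sorted(set(range(cfg.n_genes)) - regulon)
    decoy_hosts = list(map(int, rng.choice(non_regulon,
                                           size=min(cfg.n_decoys, len(non_regulon)),
                                           replace=False)))
    decoy_leaves = [genome_ids[int(i)]
                    for i in rng.integers(0, cfg.n_genomes, size=len(decoy_hosts))]

    layout = _Layout(cfg, rng, regulon, set(decoy_hosts))
    anc = np.array([BASES.index(c) for c in layout.sequence], dtype=np.int8)
    L_anc = len(anc)

    # --- plant ancestral regulon sites, one per clade variant -------------
    # site sequences per (clade, family); positions shared across clades
    occupied: list[tuple[int, int]] = [(s, e) for _, s, e, _ in layout.genes]

    def _fits(a: int, b: int) -> bool:
        return a >= 0 and b <= L_anc and all(
            b <= s or a >= e for s, e in occupied)

    site_plan: dict[int, tuple[int, int, dict[str, str]]] = {}  # fam -> (a, rel, seq by clade)
    rel_lo, rel_hi = cfg.site_window
    for fam in sorted(regulon):
        s, e, st = layout.gene_interval(fam)
        for attempt in range(200):
            rel = int(rng.integers(rel_lo, rel_hi + 1))
            a, b = _site_abs_interval(s, e, st, rel, L_site)
            if _fits(a, b):
                break
        else:
            raise RuntimeError(f"could not place site upstream of family {fam}")
        occupied.append((a, b))
        variants = {clade: pwms[clade].sample_site(rng)
                    if clade in pwms else pwms["clade1"].sample_site(rng)
                    for clade in clades}
        site_plan[fam] = (a, rel, variants)

    # --- derive leaves ----------------------------------------------------
    in_site_mask = np.zeros(L_anc, dtype=bool)
    for fam, (a, rel, _) in site_plan.items():
        in_site_mask[a:a + L_site] = True

    genomes: dict[str, AnnotatedGenome] = {}
    truth = SimTruth(
        regulon_families=sorted(regulon),
        decoy_placements=list(zip(decoy_leaves, decoy_hosts)),
        clade_of_genome=clade_of,
        consensus_by_clade={c: p.consensus for c, p in pwms.items()},
    )

    for gid in genome_ids:
        leaf = anc.copy()
        clade = clade_of[gid]
        # clade-specific operator variant goes in before divergence
        for fam, (a, rel, variants) in site_plan.items():
            s, e, st = layout.gene_interval(fam)
            _place_site(leaf, variants[clade], a, st)

        rates = np.where(in_site_mask, cfg.in_site_divergence, cfg.divergence)
        mutate = rng.random(L_anc) < rates
        shifts = rng.integers(1, 4, size=int(mutate.sum()))
        leaf[mutate] = (leaf[mutate] + shifts) % 4

        truth.operators[gid] = []
        for fam in sorted(regulon):
            a, rel, _ = site_plan[fam]
            s, e, st = layout.gene_interval(fam)
            fwd = _idx_to_seq(leaf[a:a + L_site])
            truth.operators[gid].append(PlantedSite(
                locus_tag=f"{gid}_g{fam:03d}", family=fam,
                abs_start=a, abs_end=a + L_site, rel_start=rel, strand=st,
                source="regulon",
                sequence=fwd if st == "+" else revcomp(fwd),
            ))

        # decoys: planted post-divergence, one genome each
        for (leaf_id, fam) in zip(decoy_leaves, decoy_hosts):
            if leaf_id != gid:
                continue
            s, e, st = layout.gene_interval(fam)
            for attempt in range(200):
                rel = int(rng.integers(rel_lo, rel_hi + 1))
                a, b = _site_abs_interval(s, e, st, rel, L_site)
                if _fits(a, b):
                    break
            else:
                raise RuntimeError(f"could not place decoy for family {fam}")
            occupied.append((a, b))
            site = pwms[clade].sample_site(rng) if clade in pwms \
                else pwms["clade1"].sample_site(rng)
            _place_site(leaf, site, a, st)
            truth.operators[gid].append(PlantedSite(
                locus_tag=f"{gid}_g{fam:03d}", family=fam,
                abs_start=a, abs_end=b, rel_start=rel, strand=st,
                source="decoy", sequence=site,
            ))

        seq = _idx_to_seq(leaf)
        genes = []
        for fam, s, e, st in layout.genes:
            cds = seq[s:e] if st == "+" else revcomp(seq[s:e])
            protein = str(Seq(cds).translate(table=11)).rstrip("*")
            genes.append(GeneModel(f"{gid}_g{fam:03d}", "chr", st, s, e, protein))
        genomes[gid] = AnnotatedGenome(gid, {"chr": seq}, genes)

    # training alignment: the synthetic analogue of a curated site collection
    first_pwm = next(iter(pwms.values()))
    training = SiteAlignment(
        [first_pwm.sample_site(rng) for _ in range(cfg.n_training_sites)]
    )
    return genomes, truth, training


def star_newick(genome_ids: list[str], branch: float = 0.05) -> str:
    return "(" + ",".join(f"{g}:{branch}" for g in genome_ids) + ");\n"


def write_clade(
    genomes: dict[str, AnnotatedGenome],
    truth: SimTruth,
    training: SiteAlignment,
    outdir: str,
) -> None:
    """Write FASTA+GFF3 per leaf, truth JSON, training sites, and a newick."""
    os.makedirs(outdir, exist_ok=True)
    for gid, genome in sorted(genomes.items()):
        write_fasta_gff3(genome, os.path.join(outdir, f"{gid}.fasta"),
                         os.path.join(outdir, f"{gid}.gff3"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    training.to_file(os.path.join(outdir, "training_sites.txt"))
    with open(os.path.join(outdir, "clade.nwk"), "w") as fh:
        fh.write(star_newick(sorted(genomes)))


# ---------------------------------------------------------------------------
# Curve simulators
# ---------------------------------------------------------------------------

def simulate_titration(
    e: float,
    b: float,
    n_points: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """A 4PL-shaped titration: x log-spaced over [e/30, 30e], Gaussian noise
    on the response, clipped to [0, 1]."""
    if e <= 0:
        raise ValueError("EC50 must be positive")
    if n_points < 4:
        raise ValueError("need >= 4 points")
    rng = np.random.default_rng(seed)
    x = np.geomspace(e / 30, 30 * e, n_points)
    y = four_pl(x, b, e)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0, noise_sd, size=n_points), 0.0, 1.0)
    orientation = "increasing" if b < 0 else "decreasing"
    return TitrationCurve(x=x, y=y, orientation=orientation)


def logistic_od(t: np.ndarray, K: float, r: float, lag: float,
                od0_frac: float = 0.01) -> np.ndarray:
    """Logistic growth with a lag: flat at K*od0_frac until ``lag``, then
    logistic approach to carrying capacity K at rate r (per hour)."""
    od0 = K * od0_frac
    tt = np.maximum(np.asarray(t, dtype=float) - lag, 0.0)
    return K / (1 + (K - od0) / od0 * np.exp(-r * tt))


def simulate_growth(
    K: float = 1.0,
    r: float = 0.8,
    lag: float = 2.0,
    t_max: float = 24.0,
    n_points: int = 25,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """A logistic-with-lag OD trajectory with Gaussian noise, floored at 0."""
    if K <= 0:
        raise ValueError("carrying capacity must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0, t_max, n_points)
    od = logistic_od(t, K, r, lag)
    if noise_sd > 0:
        od = np.maximum(od + rng.normal(0, noise_sd, size=n_points), 0.0)
    return GrowthCurve(t=t, od=od)
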