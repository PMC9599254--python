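"""Orthology, operon prediction, consistency filtering, regulon assembly,
footprints, and per-clade PWM refinement."""

import numpy as np
import pandas as pd
import pytest

from regrec.comparative import (
    Operon, bbh_orthologs, assemble_regulon, consistency_filter,
    footprint_alignment, operon_index, predict_operons, refine_pwm_per_clade,
    clades_from_newick,
)
from regrec.genome_io import AnnotatedGenome, GeneModel, extract_upstream
from regrec.pwm import SiteAlignment, build_pwm, calibrate_threshold
from regrec.scan import ScanConfig, scan_genome, sites_from_table
from regrec.synthetic_data import (
    CladeSimConfig, alternative_generating_pwm, default_generating_pwm,
    simulate_clade,
)

from conftest import RELATIVE_THRESHOLD, toy_genome


# ---------------------------------------------------------------------------
# BBH orthology
# ---------------------------------------------------------------------------

def _proteome_genome(genome_id, proteins):
    """Genome scaffold whose genes carry the given proteins (coordinates and
    sequence are placeholders; orthology only reads proteins)."""
    n = len(proteins)
    seq = "ACGT" * (100 * (n + 1))
    genes = [GeneModel(f"{genome_id}_p{i}", "chr", "+", i * 350, i * 350 + 300,
                       protein=p)
             for i, p in enumerate(proteins)]
    return AnnotatedGenome(genome_id, {"chr": seq}, genes)


AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_proteins(rng, n=8, length=80):
    return ["".join(AA[i] for i in rng.integers(0, 20, length)) for _ in range(n)]


class TestBBH:
    def test_identical_proteomes_give_identity_map(self):
        rng = np.random.default_rng(0)
        prots = _random_proteins(rng)
        a = _proteome_genome("A", prots)
        b = _proteome_genome("B", prots)
        omap = bbh_orthologs(a, b)
        assert omap.pairs == {f"A_p{i}": f"B_p{i}" for i in range(len(prots))}
        assert all(ident == pytest.approx(1.0) and cov == pytest.approx(1.0)
                   for ident, cov in omap.stats.values())

    def test_deleted_protein_drops_exactly_that_pair(self):
        rng = np.random.default_rng(1)
        prots = _random_proteins(rng)
        a = _proteome_genome("A", prots)
        b = _proteome_genome("B", prots[:3] + prots[4:])
        omap = bbh_orthologs(a, b)
        assert "A_p3" not in omap.pairs
        assert len(omap.pairs) == len(prots) - 1

    def test_empty_proteome_rejected(self):
        a = _proteome_genome("A", [""])
        b = _proteome_genome("B", ["MKL"])
        with pytest.raises(ValueError, match="empty proteome"):
            bbh_orthologs(a, b)

    def test_simulated_clade_recovers_true_pairs(self, clade42):
        """BBH on proteomes diverged ~10% (5% per leaf) recovers >= 95% of
        the true positional ortholog pairs."""
        omap = clade42["orthologs"][("G1", "G2")]
        n_genes = len(clade42["genomes"]["G1"].genes)
        truth_pairs = {(f"G1_g{f:03d}", f"G2_g{f:03d}") for f in range(n_genes)}
        got = set(omap.pairs.items())
        assert len(got & truth_pairs) / len(truth_pairs) >= 0.95


# ---------------------------------------------------------------------------
# Operons
# ---------------------------------------------------------------------------

def _linear_genome(spec):
    """spec: list of (strand, gap_before, length) tuples."""
    genes, pos = [], 0
    seq_len = 0
    for i, (strand, gap, length) in enumerate(spec):
        pos += gap
        genes.append(GeneModel(f"g{i}", "chr", strand, pos, pos + length))
        pos += length
        seq_len = pos + 10
    return AnnotatedGenome("t", {"chr": "A" * seq_len}, genes)


class TestOperons:
    def test_single_gene_is_singleton(self):
        g = _linear_genome([("+", 100, 300)])
        ops = predict_operons(g)
        assert [op.genes for op in ops] == [("g0",)]

    def test_three_contiguous_same_strand_genes_one_operon(self):
        """A gltFGH-like cluster: three same-strand genes with short gaps."""
        g = _linear_genome([("+", 100, 300), ("+", 20, 300), ("+", 50, 300)])
        ops = predict_operons(g, max_gap=150)
        assert [op.genes for op in ops] == [("g0", "g1", "g2")]
        assert ops[0].lead == "g0"

    def test_large_gap_splits(self):
        g = _linear_genome([("+", 100, 300), ("+", 100, 300), ("+", 300, 300)])
        ops = predict_operons(g, max_gap=150)
        assert [op.genes for op in ops] == [("g0", "g1"), ("g2",)]

    def test_minus_strand_lead_is_highest_coordinate(self):
        g = _linear_genome([("-", 100, 300), ("-", 20, 300)])
        ops = predict_operons(g, max_gap=150)
        assert ops[0].lead == "g1"

    def test_strand_change_splits(self):
        g = _linear_genome([("+", 100, 300), ("-", 20, 300)])
        assert len(predict_operons(g)) == 2

    def test_operons_partition_gene_set(self, clade42):
        for gid, genome in clade42["genomes"].items():
            ops = clade42["operons"][gid]
            tags = [t for op in ops for t in op.genes]
            assert sorted(tags) == sorted(g.locus_tag for g in genome.genes)
            assert len(tags) == len(set(tags))


# ---------------------------------------------------------------------------
# Consistency filter
# ---------------------------------------------------------------------------

class TestConsistencyFilter:
    def test_fully_supported_site_retained(self, clade42):
        """Planted regulon sites occur in all 5 genomes and survive."""
        truth, filtered = clade42["truth"], clade42["filtered"]
        for gid in filtered:
            kept = set(zip(filtered[gid]["abs_start"], filtered[gid]["abs_end"]))
            for s in truth.operators[gid]:
                if s.source == "regulon":
                    assert (s.abs_start, s.abs_end) in kept

    def test_single_genome_decoys_removed(self, clade42):
        truth, filtered = clade42["truth"], clade42["filtered"]
        removed = 0
        for gid, fam in truth.decoy_placements:
            decoy = next(s for s in truth.operators[gid]
                         if s.family == fam and s.source == "decoy")
            table = filtered[gid]
            present = ((table["abs_start"] == decoy.abs_start)
                       & (table["abs_end"] == decoy.abs_end)).any()
            removed += not present
        assert removed / len(truth.decoy_placements) >= 0.9

    def test_conserved_sites_retained_rate(self, clade42):
        truth, filtered, tables = (clade42["truth"], clade42["filtered"],
                                   clade42["tables"])
        total = kept_n = 0
        for gid in filtered:
            kept = set(zip(filtered[gid]["abs_start"], filtered[gid]["abs_end"]))
            for s in truth.operators[gid]:
                if s.source == "regulon":
                    total += 1
                    kept_n += (s.abs_start, s.abs_end) in kept
        assert kept_n / total >= 0.95

    def test_idempotence(self, clade42):
        once = clade42["filtered"]
        twice = consistency_filter(once, clade42["orthologs"],
                                   clade42["operons"], min_support=2)
        for gid in once:
            pd.testing.assert_frame_equal(once[gid], twice[gid])

    def test_min_support_monotonicity(self, clade42):
        sizes = []
        for ms in (1, 2, 3, 4, 10):
            filt = consistency_filter(clade42["tables"], clade42["orthologs"],
                                      clade42["operons"], min_support=ms)
            sizes.append(sum(len(t) for t in filt.values()))
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_genome_in_ortholog_maps_errors(self, clade42):
        partial = {k: v for k, v in clade42["orthologs"].items()
                   if "G5" not in k}
        with pytest.raises(KeyError, match="G5"):
            consistency_filter(clade42["tables"], partial,
                               clade42["operons"], min_support=2)


# ---------------------------------------------------------------------------
# Regulon assembly
# ---------------------------------------------------------------------------

class TestAssembleRegulon:
    def test_no_sites_gives_empty_regulon(self, clade42):
        gid = "G1"
        empty = clade42["tables"][gid].iloc[0:0]
        entry = assemble_regulon(empty, clade42["operons"][gid],
                                 clade42["genomes"][gid])
        assert entry["genes"] == [] and entry["operators"] == []

    def test_operator_on_lead_pulls_in_whole_operon(self):
        g = _linear_genome([("+", 300, 300), ("+", 20, 300), ("+", 50, 300)])
        ops = predict_operons(g, max_gap=150)
        sites = pd.DataFrame([{
            "genome_id": "t", "locus_tag": "g0", "replicon": "chr",
            "abs_start": 200, "abs_end": 221, "rel_start": -100,
            "strand": "+", "score": 10.0, "sequence": "A" * 21,
        }])
        entry = assemble_regulon(sites, ops, g)
        assert entry["genes"] == ["g0", "g1", "g2"]
        assert len(entry["operators"]) == 1

    def test_end_to_end_recovery_matches_truth_exactly(self, clade42):
        """On the default clade the assembled gene set equals the planted
        regulon in every genome (sensitivity and precision 1.0)."""
        truth = clade42["truth"]
        for gid in sorted(clade42["genomes"]):
            entry = assemble_regulon(clade42["filtered"][gid],
                                     clade42["operons"][gid],
                                     clade42["genomes"][gid])
            assert set(entry["genes"]) == truth.regulon_genes(gid)
            assert len(entry["operators"]) == len(truth.regulon_families)

    def test_shared_divergent_operator_counted_once(self, clade42):
        """Each planted operator appears in two genes' windows but is a
        single distinct interval in the operator tally."""
        gid = "G1"
        entry = assemble_regulon(clade42["filtered"][gid],
                                 clade42["operons"][gid],
                                 clade42["genomes"][gid])
        n_rows = len(clade42["filtered"][gid])
        assert n_rows == 2 * len(entry["operators"])


# ---------------------------------------------------------------------------
# Footprint alignment
# ---------------------------------------------------------------------------

class TestFootprint:
    def _regions_sites(self, clade42, family):
        genomes, filtered = clade42["genomes"], clade42["filtered"]
        regions, sites = [], {}
        for gid in sorted(genomes):
            tag = f"{gid}_g{family:03d}"
            regions.append(extract_upstream(genomes[gid], tag))
            rows = [s for s in sites_from_table(filtered[gid])
                    if s.locus_tag == tag]
            sites[gid] = min(rows, key=lambda s: abs(s.rel_start)) if rows else None
        return regions, sites

    def test_identical_regions_fully_conserved(self):
        genome = toy_genome(n_genes=2, seed=5)
        r = extract_upstream(genome, "g0", (-60, 10))
        regions = []
        for gid in ("A", "B"):
            clone = AnnotatedGenome(gid, genome.replicons, genome.genes)
            regions.append(extract_upstream(clone, "g0", (-60, 10)))
        from regrec.scan import CandidateSite
        site = CandidateSite("A", "g0", "chr", 0, 21, -50, "+", 5.0, "A" * 21)
        report = footprint_alignment(
            regions, {"A": site, "B": site}, site_length=21)
        assert np.allclose(report.conservation, 1.0)

    def test_single_substitution_halves_column_conservation(self):
        from regrec.genome_io import UpstreamRegion
        from regrec.scan import CandidateSite
        seq = "ACGTACGTACGTACGTACGTA" + "TTTT"
        mutated = seq[:5] + ("A" if seq[5] != "A" else "C") + seq[6:]
        mk = lambda gid, s: UpstreamRegion(gid + "_g", gid, "chr", "+",
                                           -25, -1, s, 0, len(s))
        site = CandidateSite("A", "A_g", "chr", 0, 21, -25, "+", 5.0, seq[:21])
        report = footprint_alignment(
            [mk("A", seq), mk("B", mutated)],
            {"A": site, "B": CandidateSite("B", "B_g", "chr", 0, 21, -25,
                                           "+", 5.0, mutated[:21])})
        assert report.conservation[5] == pytest.approx(0.5)
        assert report.conservation[4] == pytest.approx(1.0)

    def test_operator_columns_more_conserved_than_flanks(self, clade42):
        """Purifying selection in the simulator (lower in-site rate) shows
        up as higher mean conservation over operator columns."""
        ratios = []
        for family in clade42["truth"].regulon_families[:8]:
            regions, sites = self._regions_sites(clade42, family)
            if sum(s is not None for s in sites.values()) < 3:
                continue
            rep = footprint_alignment(regions, sites)
            a, b = rep.operator_span
            cov = rep.conservation
            op_mean = cov[a:b].mean()
            flank = np.r_[cov[max(0, a - 60):a], cov[b:b + 60]]
            ratios.append(op_mean - flank.mean())
        assert np.mean(ratios) > 0

    def test_region_without_site_listed_unanchored(self, clade42):
        regions, sites = self._regions_sites(clade42,
                                             clade42["truth"].regulon_families[0])
        sites["G3"] = None
        rep = footprint_alignment(regions, sites)
        assert rep.unanchored == ["G3"]
        assert "G3" not in rep.genome_ids


# ---------------------------------------------------------------------------
# Per-clade refinement
# ---------------------------------------------------------------------------

class TestRefinePerClade:
    def test_single_clade_equals_global(self, clade42):
        groups = {"clade1": sorted(clade42["genomes"])}
        refined = refine_pwm_per_clade(groups, clade42["pwm"],
                                       clade42["filtered"])
        assert np.allclose(refined["clade1"].weights,
                           refined["global"].weights)

    def test_tiny_clade_falls_back_to_global(self, clade42):
        filtered = dict(clade42["filtered"])
        filtered["G5"] = filtered["G5"].iloc[0:1]
        groups = {"small": ["G5"], "rest": ["G1", "G2", "G3", "G4"]}
        refined = refine_pwm_per_clade(groups, clade42["pwm"], filtered)
        assert np.allclose(refined["small"].weights,
                           refined["global"].weights)

    def test_two_clades_recover_their_motif_variants(self):
        """Two genome groups planted with different generating motifs: each
        refined matrix's consensus matches its own generator."""
        pwm_a = default_generating_pwm()
        pwm_b = alternative_generating_pwm()
        cfg = CladeSimConfig(
            seed=7, n_genomes=4, n_genes=30, regulon_size=10, n_decoys=4,
            clades={"cladeA": [0, 1], "cladeB": [2, 3]},
            generating_pwms={"cladeA": pwm_a, "cladeB": pwm_b},
        )
        genomes, truth, training = simulate_clade(cfg)
        scan_pwm = build_pwm(training, palindromic=True)
        threshold = calibrate_threshold(scan_pwm, "relative_max",
                                        RELATIVE_THRESHOLD)
        # scan each clade with a matrix built from its own truth sites
        # (training alignment covers clade A's motif only)
        filtered = {}
        for gid, genome in genomes.items():
            seqs = [s.sequence for s in truth.operators[gid]
                    if s.source == "regulon"]
            filtered[gid] = pd.DataFrame({"sequence": seqs})
        groups = {"cladeA": ["G1", "G2"], "cladeB": ["G3", "G4"]}
        refined = refine_pwm_per_clade(groups, scan_pwm, filtered)
        # compare at informative positions (spacer columns are uniform noise)
        for clade, gen in (("cladeA", pwm_a), ("cladeB", pwm_b)):
            cons = refined[clade].consensus()
            for k in np.flatnonzero(gen.informative):
                assert cons[k] == gen.consensus[k], (clade, k)


def test_clades_from_newick(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((G1:0.1,G2:0.1):0.05,(G3:0.1,(G4:0.1,G5:0.1):0.02):0.05);\n")
    groups = clades_from_newick(str(p))
    assert sorted(map(sorted, groups.values())) == \
        [["G1", "G2"], ["G3", "G4", "G5"]]
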