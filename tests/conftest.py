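import numpy as np
import pytest

from regrec.comparative import all_pairs_orthologs, consistency_filter, predict_operons
from regrec.genome_io import AnnotatedGenome, GeneModel
from regrec.pwm import build_pwm, calibrate_threshold
from regrec.scan import ScanConfig, scan_genome
from regrec.synthetic_data import CladeSimConfig, simulate_clade

# analysis defaults for the synthetic workflow: palindromic matrix built
# from the emitted training sites, threshold at 65% of the maximum
# attainable score (calibrated between training-site floor and genomic
# background; see docs/methods.md)
RELATIVE_THRESHOLD = 0.65


def toy_genome(n_genes=2, gene_len=30, gap=600, seed=0, genome_id="toy"):
    """Small single-replicon genome with evenly spaced alternating genes."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    total = n_genes * (gene_len + gap) + gap
    seq = "".join(bases[i] for i in rng.integers(0, 4, total))
    genes = []
    pos = gap
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"g{i}", "chr", strand, pos, pos + gene_len))
        pos += gene_len + gap
    return AnnotatedGenome(genome_id, {"chr": seq}, genes)


@pytest.fixture(scope="session")
def clade42():
    """The default synthetic clade (seed 42) run through the full chain."""
    genomes, truth, training = simulate_clade(CladeSimConfig(seed=42))
    pwm = build_pwm(training, palindromic=True)
    threshold = calibrate_threshold(pwm, "relative_max", RELATIVE_THRESHOLD)
    cfg = ScanConfig(threshold=threshold)
    tables = {g: scan_genome(genomes[g], pwm, cfg) for g in sorted(genomes)}
    orthologs = all_pairs_orthologs(genomes)
    operons = {g: predict_operons(genomes[g]) for g in sorted(genomes)}
    filtered = consistency_filter(tables, orthologs, operons, min_support=2)
    return {
        "genomes": genomes,
        "truth": truth,
        "training": training,
        "pwm": pwm,
        "threshold": threshold,
        "scan_config": cfg,
        "tables": tables,
        "orthologs": orthologs,
        "operons": operons,
        "filtered": filtered,
    }
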