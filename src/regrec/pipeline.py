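"""End-to-end orchestration: build/calibrate -> scan -> orthologs ->
consistency filter -> operons -> regulon -> promoter overlaps -> footprints.

Every stage writes its table under the run directory and is echoed to the
log with its parameters, so a run directory is a self-describing record of
the reconstruction.  Reports contain no timestamps: identical inputs and
parameters produce byte-identical outputs.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import comparative, promoter as promoter_mod
from .comparative import (
    Regulon, all_pairs_orthologs, assemble_regulon, clades_from_newick,
    consistency_filter, footprint_alignment, operon_index, predict_operons,
    refine_pwm_per_clade,
)
from .genome_io import AnnotatedGenome, extract_upstream, read_genome
from .pwm import (
    SiteAlignment, WeightMatrix, build_pwm, calibrate_threshold, logo_table,
)
from .scan import ScanConfig, scan_genome, sites_from_table, write_site_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one reconstruction run."""

    genome_paths: list[str] = field(default_factory=list)
    genome_format: str = "fasta+gff3"      # or 'genbank'
    pwm_path: str | None = None            # serialized matrix, or...
    training_sites_path: str | None = None  # ...sites to build one from
    palindromic: bool = True
    pseudocount: float = 0.5
    window: tuple[int, int] = (-500, 50)
    threshold_rule: str = "fixed"
    threshold_value: float | None = 4.3
    both_strands: bool = True
    dedup_radius: int = 2
    min_support: int = 2
    operon_max_gap: int = 150
    min_identity: float = 0.4
    min_coverage: float = 0.7
    tree_path: str | None = None
    tf_name: str = "TF"
    out_dir: str = "regrec_run"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "window" and value is not None:
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def load_genomes(cfg: PipelineConfig) -> dict[str, AnnotatedGenome]:
    genomes = {}
    for path in cfg.genome_paths:
        if cfg.genome_format == "genbank":
            g = read_genome(path, "genbank")
        else:
            gff = os.path.splitext(path)[0] + ".gff3"
            g = read_genome(path, "fasta+gff3", gff3=gff)
        genomes[g.genome_id] = g
    if not genomes:
        raise ValueError("no genomes supplied")
    return genomes


def discover_genome_paths(directory: str, fmt: str) -> list[str]:
    if fmt == "genbank":
        pats = ("*.gbk", "*.gb", "*.gbff")
    else:
        pats = ("*.fasta", "*.fa", "*.fna")
    paths: list[str] = []
    for pat in pats:
        paths.extend(glob.glob(os.path.join(directory, pat)))
    return sorted(paths)


def obtain_pwm(cfg: PipelineConfig) -> tuple[WeightMatrix, SiteAlignment | None]:
    if cfg.pwm_path:
        return WeightMatrix.from_files(cfg.pwm_path), None
    if cfg.training_sites_path:
        aln = SiteAlignment.from_file(cfg.training_sites_path)
        return build_pwm(aln, palindromic=cfg.palindromic,
                         pseudocount=cfg.pseudocount), aln
    raise ValueError("either pwm_path or training_sites_path is required")


def run_pipeline(cfg: PipelineConfig) -> Regulon:
    os.makedirs(cfg.out_dir, exist_ok=True)
    genomes = load_genomes(cfg)
    ids = sorted(genomes)
    log.info("loaded %d genome(s): %s", len(ids), ", ".join(ids))

    pwm, training = obtain_pwm(cfg)
    pwm.threshold = calibrate_threshold(
        pwm, rule=cfg.threshold_rule, value=cfg.threshold_value,
        alignment=training,
    )
    log.info("threshold rule=%s -> %.3f (matrix length %d, palindromic=%s)",
             cfg.threshold_rule, pwm.threshold, pwm.length, pwm.palindromic)
    pwm.to_files(os.path.join(cfg.out_dir, "pwm_input.tsv"))

    scan_cfg = ScanConfig(window=cfg.window, threshold=pwm.threshold,
                          both_strands=cfg.both_strands,
                          dedup_radius=cfg.dedup_radius)
    site_tables = {}
    for gid in ids:
        table = scan_genome(genomes[gid], pwm, scan_cfg)
        site_tables[gid] = table
        write_site_table(table, os.path.join(cfg.out_dir, f"sites.{gid}.tsv"))
        log.info("%s: %d candidate site rows", gid, len(table))

    operons = {gid: predict_operons(genomes[gid], cfg.operon_max_gap)
               for gid in ids}

    flags: list[str] = []
    if len(ids) >= 2:
        orthologs = all_pairs_orthologs(
            genomes, min_identity=cfg.min_identity, min_coverage=cfg.min_coverage)
        for (ga, gb), omap in sorted(orthologs.items()):
            omap.to_tsv(os.path.join(cfg.out_dir, f"orthologs.{ga}__{gb}.tsv"))
        filtered = consistency_filter(site_tables, orthologs, operons,
                                      cfg.min_support)
    else:
        log.warning("single genome: consistency filter skipped; "
                    "regulon flagged 'unsupported'")
        orthologs = {}
        filtered = site_tables
        flags.append("unsupported")

    regulon = Regulon(tf_name=cfg.tf_name)
    for gid in ids:
        write_site_table(filtered[gid],
                         os.path.join(cfg.out_dir, f"sites_filtered.{gid}.tsv"))
        entry = assemble_regulon(filtered[gid], operons[gid], genomes[gid],
                                 cfg.tf_name)
        entry["flags"] = list(flags)
        regulon.per_genome[gid] = entry
        log.info("%s: %d operators, %d member genes", gid,
                 len(entry["operators"]), len(entry["genes"]))
    regulon.to_json(os.path.join(cfg.out_dir, "regulon.json"))
    regulon.to_tsv(os.path.join(cfg.out_dir, "regulon.tsv"))

    _promoter_report(cfg, genomes, filtered)
    _footprint_report(cfg, genomes, filtered, orthologs, operons)

    # refined matrices + logo data
    if cfg.tree_path:
        groups = clades_from_newick(cfg.tree_path)
    else:
        groups = {"clade1": ids}
    refined = refine_pwm_per_clade(groups, pwm, filtered)
    for name, mat in sorted(refined.items()):
        mat.to_files(os.path.join(cfg.out_dir, f"pwm_{name}.tsv"))
    _write_logo(refined["global"], os.path.join(cfg.out_dir, "logo.tsv"))

    manifest = {
        "genomes": ids,
        "parameters": {
            "window": list(cfg.window),
            "threshold_rule": cfg.threshold_rule,
            "threshold": pwm.threshold,
            "min_support": cfg.min_support,
            "operon_max_gap": cfg.operon_max_gap,
            "min_identity": cfg.min_identity,
            "min_coverage": cfg.min_coverage,
            "palindromic": pwm.palindromic,
            "tf_name": cfg.tf_name,
        },
        "outputs": sorted(os.listdir(cfg.out_dir)),
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return regulon


def _promoter_report(cfg, genomes, filtered) -> None:
    pwm35, pwm10 = promoter_mod.train_promoter_pwms()
    cutoff = promoter_mod.training_cutoff(pwm35, pwm10)
    rows = []
    for gid in sorted(filtered):
        for site in sites_from_table(filtered[gid]):
            region = extract_upstream(genomes[gid], site.locus_tag, cfg.window)
            calls = promoter_mod.call_promoters(region, pwm35, pwm10,
                                                min_score=cutoff)
            if not calls:
                continue
            call = calls[0]  # single best promoter per region
            overlap = promoter_mod.classify_overlap(site, call)
            rows.append({
                "genome_id": gid,
                "locus_tag": site.locus_tag,
                "operator_rel_start": site.rel_start,
                "minus35_rel": call.rel_minus35,
                "minus10_rel": call.rel_minus10,
                "spacer": call.spacer,
                "element": overlap.element,
                "overlap_bp": overlap.overlap_bp,
                "architecture": overlap.architecture,
            })
    cols = ["genome_id", "locus_tag", "operator_rel_start", "minus35_rel",
            "minus10_rel", "spacer", "element", "overlap_bp", "architecture"]
    pd.DataFrame(rows, columns=cols).to_csv(
        os.path.join(cfg.out_dir, "promoter_overlaps.tsv"), sep="\t", index=False)


def _footprint_report(cfg, genomes, filtered, orthologs, operons) -> None:
    ids = sorted(genomes)
    if len(ids) < 2 or not orthologs:
        with open(os.path.join(cfg.out_dir, "footprints.txt"), "w") as fh:
            fh.write("# footprinting requires >= 2 genomes\n")
        return
    anchor_genome = ids[0]
    blocks = []
    seen_leads = set()
    idx0 = operon_index(operons[anchor_genome])

    def _proximal(sites):
        # a window can hold several operators (e.g. its own plus a divergent
        # partner's); anchor every genome at the promoter-proximal one
        return min(sites, key=lambda s: (abs(s.rel_start), s.rel_start))

    by_tag: dict[str, list] = {}
    for s in sites_from_table(filtered[anchor_genome]):
        by_tag.setdefault(s.locus_tag, []).append(s)
    sites0 = {tag: _proximal(ss) for tag, ss in by_tag.items()}
    for tag, site in sorted(sites0.items()):
        lead = idx0[tag].lead
        if lead in seen_leads:
            continue
        seen_leads.add(lead)
        regions = [extract_upstream(genomes[anchor_genome], tag, cfg.window)]
        sites = {anchor_genome: site}
        for gid in ids[1:]:
            omap = comparative._lookup_map(orthologs, anchor_genome, gid)
            mate = omap.mate(anchor_genome, tag)
            if mate is None:
                continue
            regions.append(extract_upstream(genomes[gid], mate, cfg.window))
            mate_sites = [s for s in sites_from_table(filtered[gid])
                          if s.locus_tag == mate]
            sites[gid] = _proximal(mate_sites) if mate_sites else None
        try:
            report = footprint_alignment(regions, sites)
        except ValueError:
            continue
        blocks.append(f"## {anchor_genome}:{tag}\n" + report.to_text())
    with open(os.path.join(cfg.out_dir, "footprints.txt"), "w") as fh:
        fh.write("\n".join(blocks) if blocks else "# no anchored families\n")


def _write_logo(pwm: WeightMatrix, path: str) -> None:
    rows = logo_table(pwm)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6f")
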