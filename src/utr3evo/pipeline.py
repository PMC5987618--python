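"""End-to-end orchestration: simulate -> extract -> orthologs -> repeats
-> mirna -> rates -> enrich, with a consolidated report and manifest.

The pipeline runs from one configuration (a ``SimulationConfig`` or a
YAML-style dict of its fields).  Stages execute in dependency order on
the files the previous stage wrote, every filter logs how many records
it kept and dropped, and a JSON manifest records the config snapshot,
seed, per-stage status and a checksum for every output file so that
reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    clade_divergence as cd,
    enrichment,
    genome_features as gf,
    mirna_targets as mt,
    repeat_content as rc,
    orthology,
    synthetic_data as sd,
)

log = logging.getLogger(__name__)


def validate_config(config: dict) -> list[str]:
    """Field-by-field validation; returns a list of error strings."""
    errors = []
    if "seed" not in config:
        errors.append("seed: required")
    fields = {f.name for f in dataclasses.fields(sd.SimulationConfig)}
    extra = set(config) - fields - {"energy_cutoff", "top_fraction", "window"}
    for k in sorted(extra):
        errors.append(f"{k}: unknown field")
    for key in ("n_genes", "utr5_length", "cds_length", "intergenic_length"):
        if key in config and int(config[key]) <= 0:
            errors.append(f"{key}: must be positive")
    for key in ("sigma2_focal", "sigma2_background"):
        if key in config and float(config[key]) < 0:
            errors.append(f"{key}: must be >= 0")
    for k, v in dict(config.get("repeat_densities", {})).items():
        if not 0.0 <= float(v) <= 1.0:
            errors.append(f"repeat_densities.{k}: {v} outside [0, 1]")
    frac = config.get("top_fraction", 0.05)
    if not 0.0 < float(frac) < 1.0:
        errors.append(f"top_fraction: {frac} outside (0, 1)")
    focal = list(config.get("focal_species", sd.FOCAL_SPECIES))
    backg = list(config.get("background_species", sd.BACKGROUND_SPECIES))
    if not focal or not backg:
        errors.append("focal_species/background_species: must be nonempty")
    if set(focal) & set(backg):
        errors.append("focal_species/background_species: overlap")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: sd.SimulationConfig | dict, out_dir) -> dict:
    """Run the full synthetic-data analysis; returns the manifest dict.

    Writes, under ``out_dir``: the simulated inputs (genomes, GFF3,
    repeat BED, miRNA FASTA, similarity table, term map, tree), each
    stage's TSV outputs, a plain-text ``report.txt`` with the headline
    statistics, and ``manifest.json``.
    """
    if isinstance(config, dict):
        errors = validate_config(config)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        analysis = {
            k: config.pop(k)
            for k in ("energy_cutoff", "top_fraction", "window")
            if k in config
        }
        config = sd.SimulationConfig(**config)
    else:
        analysis = {}
    energy_cutoff = float(analysis.get("energy_cutoff", mt.DEFAULT_ENERGY_CUTOFF))
    top_frac = float(analysis.get("top_fraction", 0.05))
    window = int(analysis.get("window", 50))

    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    report: list[str] = []

    def _write(relpath: str, text: str) -> Path:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        manifest["outputs"][relpath] = _sha256(path)
        return path

    # ---------------- simulate ----------------
    tree, painting = sd.make_default_tree(config)
    traits = sd.simulate_traits(
        tree,
        painting,
        config.sigma2_focal,
        config.sigma2_background,
        config.root_length,
        config.n_genes,
        config.seed,
        focal_length_factor=config.focal_length_factor,
    )
    lengths = sd.floor_lengths(traits, config.min_utr3)
    genomes = sd.build_genomes(lengths, config)
    beds = {}
    for spp, genome in genomes.items():
        genome, bed = sd.plant_repeats(genome, config.repeat_densities, config.seed)
        genomes[spp] = genome
        beds[spp] = bed
    mirnas = sd.make_mirnas(config.n_mirnas, config.mirna_length, config.seed)
    sim_table, fam_truth = sd.make_similarity_table(
        config.n_genes,
        list(traits.columns),
        config.seed,
        family_names=list(traits.index),
    )
    _write("inputs/tree.nwk", sd.default_newick(config.node_ages) + "\n")
    for spp, genome in genomes.items():
        _write(f"inputs/{spp}.fa", sd.genome_fasta(genome))
        _write(f"inputs/{spp}.gff3", genome.gff3)
        _write(
            f"inputs/{spp}.repeats.bed",
            beds[spp].to_csv(sep="\t", header=False, index=False),
        )
    _write(
        "inputs/mirnas.fa",
        "".join(f">{name}\n{seq}\n" for name, seq in mirnas),
    )
    _write(
        "inputs/similarity.tsv", sim_table.to_csv(sep="\t", header=False, index=False)
    )
    manifest["stages"]["simulate"] = "ok"

    # ---------------- extract ----------------
    utr3_by_species: dict[str, dict[str, str]] = {}
    features_by_species: dict[str, dict] = {}
    length_rows = []
    summaries = {}
    for spp, genome in genomes.items():
        genome_seqs = {genome.chrom: genome.sequence}
        by_gene, rejected = gf.parse_annotation(genome.gff3, genome_seqs)
        log.info("%s: %d genes parsed, %d records rejected", spp, len(by_gene), len(rejected))
        utr3 = {}
        feats: dict[str, list] = {"utr5": [], "cds": [], "utr3": []}
        fasta_lines = []
        for gene_id in sorted(by_gene):
            canon = gf.select_canonical(by_gene[gene_id])
            if canon is None:
                continue
            fs = gf.extract_features(canon, genome_seqs)
            utr3[f"{spp}|{gene_id}"] = fs.utr3_seq
            for cls, ivs in gf.feature_intervals(canon).items():
                feats[cls].extend(ivs)
            length_rows.append(
                {
                    "species": spp,
                    "gene_id": gene_id,
                    "transcript_id": canon.transcript_id,
                    "L5": fs.L5,
                    "Lc": fs.Lc,
                    "L3": fs.L3,
                }
            )
            fasta_lines.append(f">{gene_id}\n{fs.utr3_seq}\n")
        utr3_by_species[spp] = utr3
        features_by_species[spp] = feats
        _write(f"extract/{spp}.utr3.fa", "".join(fasta_lines))
        l3 = [r["L3"] for r in length_rows if r["species"] == spp]
        summaries[spp] = gf.summarize_lengths(l3, len(genome.sequence))
        hist = gf.length_histogram(l3, window)
        _write(
            f"extract/{spp}.utr3_hist.tsv",
            "".join(
                f"{i * window}\t{(i + 1) * window}\t{c}\n" for i, c in enumerate(hist)
            ),
        )
    lengths_df = pd.DataFrame(length_rows)
    _write("extract/lengths.tsv", lengths_df.to_csv(sep="\t", index=False))
    _write(
        "extract/length_summary.tsv",
        pd.DataFrame(
            {spp: dataclasses.asdict(s) for spp, s in summaries.items()}
        ).T.to_csv(sep="\t"),
    )
    manifest["stages"]["extract"] = "ok"

    # ---------------- orthologs ----------------
    pairs = orthology.read_similarity(sim_table)
    edges = orthology.build_edges(pairs)
    genes = sorted({g for k in edges for g in k} | {m for f in fam_truth.values() for m in f})
    families = orthology.cluster_families(genes, edges)
    table = orthology.one_to_one(families, list(traits.columns))
    _write(
        "orthologs/families.tsv",
        "".join(
            f"fam{idx:05d}\t{orthology.default_species_of(g)}\t{g}\n"
            for idx, fam in enumerate(families)
            for g in sorted(fam)
        ),
    )
    _write("orthologs/orthologs_1to1.tsv", table.to_csv(sep="\t", index=False))
    log.info("orthologs: %d families, %d 1:1", len(families), len(table))
    manifest["stages"]["orthologs"] = "ok"

    # ---------------- repeats ----------------
    repeat_rows = []
    pairs_gr = []
    for spp, genome in genomes.items():
        rep = rc.repeat_fraction(
            features_by_species[spp],
            [(genome.chrom, a, b) for _, a, b in beds[spp][["chrom", "start", "end"]].itertuples(index=False)]
            if not beds[spp].empty
            else [],
            {genome.chrom: len(genome.sequence)},
            species=spp,
        )
        repeat_rows.append({"species": spp, **rep.fractions})
        pairs_gr.append((rep.fractions["genome"], rep.fractions["utr3"]))
    repeat_df = pd.DataFrame(repeat_rows)
    signed_p = rc.paired_signed_rank(pairs_gr)
    _write("repeats/repeat_fractions.tsv", repeat_df.to_csv(sep="\t", index=False))
    _write(
        "repeats/signed_rank.txt",
        f"wilcoxon_signed_rank_two_sided_p\t{signed_p:.8g}\n",
    )
    report.append(f"repeat fractions: genome vs 3'UTR signed-rank p = {signed_p:.4g}")
    manifest["stages"]["repeats"] = "ok"

    # ---------------- mirna ----------------
    mirna_objs = [mt.MatureMiRNA(n, s) for n, s in mirnas]
    target_rows = []
    for spp in genomes:
        planted, truth = sd.plant_mirna_sites(
            utr3_by_species[spp],
            mirnas,
            config.planted_sites_per_utr,
            config.seed,
        )
        sites, counts = mt.scan_utrs(planted, mirna_objs, energy_cutoff)
        summary = mt.summarize_targets(counts)
        target_rows.append({"species": spp, **summary})
        _write(
            f"mirna/{spp}.target_sites.tsv", sites.to_csv(sep="\t", index=False)
        )
    targets_df = pd.DataFrame(target_rows)
    _write("mirna/target_summary.tsv", targets_df.to_csv(sep="\t", index=False))
    manifest["stages"]["mirna"] = "ok"

    # ---------------- rates ----------------
    model = cd.TwoRegimeBM(tree, painting)
    focal = sorted(config.focal_species)
    backg = sorted(config.background_species)
    l3_wide = lengths_df.pivot(index="gene_id", columns="species", values="L3")
    l3_wide = l3_wide[model.tip_labels]
    n_incomplete = int(l3_wide.isna().any(axis=1).sum())
    if n_incomplete:
        log.info("rates: dropping %d genes without lengths in all species", n_incomplete)
        l3_wide = l3_wide.dropna()
    fit_rows = []
    for gene_id, row in l3_wide.iterrows():
        fit = model.fit(row.to_numpy(dtype=float))
        ratio = cd.length_log_ratio(row.to_dict(), focal, backg)
        fit_rows.append(
            {
                "gene_id": gene_id,
                "sigma2_focal": fit.sigma2_focal,
                "sigma2_background": fit.sigma2_background,
                "log10_rate_ratio": fit.log10_ratio,
                "log10_length_ratio": ratio,
                "flags": ",".join(fit.flags),
            }
        )
    fits_df = pd.DataFrame(fit_rows).set_index("gene_id")
    usable = fits_df[fits_df["flags"] == ""]
    n_excluded = len(fits_df) - len(usable)
    log.info("rates: %d genes fit, %d excluded by flags", len(fits_df), n_excluded)
    t_rate, p_rate = cd.one_sample_t(usable["log10_rate_ratio"])
    t_len, p_len = cd.one_sample_t(fits_df["log10_length_ratio"])
    _write("rates/bm_fits.tsv", fits_df.to_csv(sep="\t"))
    _write(
        "rates/tests.txt",
        (
            f"n_genes\t{len(fits_df)}\n"
            f"n_excluded_flagged\t{n_excluded}\n"
            f"rate_log10_ratio_mean\t{usable['log10_rate_ratio'].mean():.6g}\n"
            f"rate_t\t{t_rate:.6g}\nrate_p\t{p_rate:.6g}\n"
            f"length_log10_ratio_mean\t{fits_df['log10_length_ratio'].mean():.6g}\n"
            f"length_t\t{t_len:.6g}\nlength_p\t{p_len:.6g}\n"
        ),
    )
    report.append(
        f"rate ratios: mean log10 = {usable['log10_rate_ratio'].mean():.4f}, "
        f"t = {t_rate:.2f}, p = {p_rate:.3g} ({len(usable)} genes)"
    )
    report.append(
        f"length ratios: mean log10 = {fits_df['log10_length_ratio'].mean():.4f}, "
        f"t = {t_len:.2f}, p = {p_len:.3g}"
    )
    manifest["stages"]["rates"] = "ok"

    # ---------------- enrich ----------------
    baseline = set(l3_wide.index)
    terms = sd.assign_terms(
        sorted(baseline),
        config.seed,
        planted_term="TERM:0000",
        top_set=set(
            enrichment.top_fraction(fits_df["log10_length_ratio"], top_frac)
        ),
    )
    _write("inputs/terms.tsv", terms.to_csv(sep="\t", header=False, index=False))
    for score_col, label in (
        ("log10_length_ratio", "length"),
        ("log10_rate_ratio", "rate"),
    ):
        scores = fits_df[score_col].dropna()
        top = set(enrichment.top_fraction(scores, top_frac))
        if not top:
            log.warning("enrich: top %s set empty at fraction %s", label, top_frac)
            manifest["stages"]["enrich"] = "skipped_empty_top_set"
            continue
        enr = enrichment.fisher_enrichment(top, baseline, terms)
        _write(f"enrich/enrichment_{label}.tsv", enr.to_csv(sep="\t", index=False))
        hits = enr[enr["significant"]]
        report.append(
            f"enrichment ({label} top {top_frac:.0%}): {len(hits)} significant terms"
            + (f", best = {hits.iloc[0]['term_id']}" if len(hits) else "")
        )
    manifest["stages"].setdefault("enrich", "ok")

    _write("report.txt", "\n".join(report) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
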