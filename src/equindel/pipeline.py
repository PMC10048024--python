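"""End-to-end pipeline: simulate/ingest -> filter -> summarize -> applications.

Produces a deterministic report bundle: a machine-readable JSON summary
(category counts, novelty report, size spectrum, density table, suspect
census, panel size) plus TSV/BED artifacts for each stage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import artifacts as art_mod
from . import popstats
from .applications import PanelCriteria, build_population_db, select_panel, panel_tsv, write_population_db
from .filters import FilterThresholds, apply_filters, filter_report_tsv
from .loci import GenotypeMatrix, chromosome_compartment, percent
from .novelty import KnownVariantSet, classify_novelty
from .simulate import SimulationConfig, simulate_population
from .vcf_io import integrate, read_chrom_table, read_known_set, read_vcf


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    outdir: str = "equindel_out"
    # either a merged VCF or per-sample VCFs
    merged_vcf: Optional[str] = None
    sample_vcfs: Sequence[str] = ()
    known_set: Optional[str] = None
    known_format: str = "gvf"
    known_total: Optional[int] = None
    chrom_table: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    panel: PanelCriteria = field(default_factory=PanelCriteria)
    assume_hom_ref: bool = False
    retain_lowqual: bool = False
    exclude_suspects_from_db: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(str(exc)) from exc
        try:
            if "simulate" in raw and raw["simulate"] is not None:
                sim = dict(raw["simulate"])
                if "chromosomes" in sim:
                    sim["chromosomes"] = tuple((str(c), int(l)) for c, l in sim["chromosomes"])
                raw["simulate"] = SimulationConfig(**sim)
            if "thresholds" in raw:
                raw["thresholds"] = FilterThresholds(**raw["thresholds"])
            if "panel" in raw:
                p = dict(raw["panel"])
                if "size_deltas" in p:
                    p["size_deltas"] = frozenset(int(d) for d in p["size_deltas"])
                raw["panel"] = PanelCriteria(**p)
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        sources = [self.merged_vcf is not None, bool(self.sample_vcfs), self.simulate is not None]
        if sum(sources) != 1:
            raise ConfigError("exactly one of merged_vcf, sample_vcfs, simulate must be given")
        for p in [self.merged_vcf, self.known_set, self.chrom_table, *self.sample_vcfs]:
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"input path does not exist: {p}")


def emit_ideogram_track(
    reports: Sequence[art_mod.SuspectLocusReport],
    regions: Sequence[art_mod.SuspectRegion],
    path: str,
) -> None:
    """Suspect loci and merged regions as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for r in reports:
            l = r.locus
            fh.write(f"{l.chrom}\t{l.pos - 1}\t{l.pos - 1 + len(l.ref)}\t{r.signature}\n")
        for reg in regions:
            fh.write(
                f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\tREGION_{reg.n_suspect_loci}_loci\n"
            )


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            out.append((cols[0], int(cols[1]), int(cols[2]), cols[3] if len(cols) > 3 else ""))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)

    # --- inputs -----------------------------------------------------------
    known: Optional[KnownVariantSet] = None
    truth = None
    if config.simulate is not None:
        sim = simulate_population(config.simulate, outdir=out("simulated"))
        matrix = sim.matrix
        chrom_table = sim.chrom_table
        truth = sim.truth
        known = read_known_set(sim.paths["known_gvf"], "gvf")
    else:
        try:
            if config.merged_vcf:
                matrix = read_vcf(config.merged_vcf)
            else:
                matrix = integrate(config.sample_vcfs, assume_hom_ref=config.assume_hom_ref)
        except ValueError as exc:
            raise DataError(str(exc)) from exc
        chrom_table = read_chrom_table(config.chrom_table) if config.chrom_table else {}
        if config.known_set:
            known = read_known_set(config.known_set, config.known_format)
    if known is not None and config.known_total:
        known.total_registered = config.known_total

    # --- hard filtering ---------------------------------------------------
    retained, fail_counts, _ = apply_filters(
        matrix, config.thresholds, retain_lowqual=config.retain_lowqual
    )
    with open(out("filter_report.tsv"), "w") as fh:
        fh.write(filter_report_tsv(fail_counts))

    # --- population statistics -------------------------------------------
    freqs = popstats.site_frequencies(retained)
    dial = [f for f in freqs if f.locus.is_diallelic]
    dial_auto = [f for f in dial if chromosome_compartment(f.locus.chrom) == "autosomes"]
    summary_df = popstats.summary_counts(retained.loci)
    spectrum, n_del, n_ins = popstats.size_spectrum([f.locus for f in dial])
    dens = popstats.density(popstats.count_by_chromosome(retained.loci), chrom_table) if chrom_table else pd.DataFrame()
    # spacing over nuclear chromosomes (the mitochondrion distorts averages)
    nuc_len = sum(l for c, l in chrom_table.items() if chromosome_compartment(c) != "MT")
    nuc_count = sum(1 for l in retained.loci if chromosome_compartment(l.chrom) != "MT")
    spacing = popstats.mean_spacing(nuc_count, nuc_len) if nuc_count and nuc_len else None
    afs_hist = popstats.afs(dial_auto, retained.n_samples)

    freq_rows = []
    for f in dial:
        freq_rows.append(
            {
                "chrom": f.locus.chrom,
                "pos": f.locus.pos,
                "ref": f.locus.ref,
                "alt": f.locus.alts[0],
                "n_called": f.n_called,
                "ref_count": f.ref_count,
                "alt_count": f.alt_counts[0],
                "ref_frequency": round(f.ref_frequency, 5) if f.n_called else None,
                "maf": round(f.maf, 5) if f.n_called else None,
                "n_het": f.n_het,
            }
        )
    pd.DataFrame(freq_rows).to_csv(out("frequencies.tsv"), sep="\t", index=False)
    pd.DataFrame({"ref_allele_count": np.arange(afs_hist.size), "n_loci": afs_hist}).to_csv(
        out("afs.tsv"), sep="\t", index=False
    )
    popstats.spectrum_table(spectrum).to_csv(out("size_spectrum.tsv"), sep="\t", index=False)
    if not dens.empty:
        dens.to_csv(out("density.tsv"), sep="\t", index=False, float_format="%.4f")

    # --- suspect signatures ----------------------------------------------
    all_het = art_mod.flag_all_het(dial, retained.n_samples)
    all_alt = art_mod.flag_all_alt_hom(dial, retained.n_samples)
    suspects = all_het + all_alt
    regions = art_mod.cluster_suspects(suspects)
    with open(out("suspects.tsv"), "w") as fh:
        fh.write(art_mod.suspect_report_tsv(suspects))
    emit_ideogram_track(suspects, regions, out("suspects.bed"))
    all_het_keys = {r.locus.key for r in all_het}

    # --- novelty ----------------------------------------------------------
    novelty_block = None
    registered = None
    if known is not None:
        flags = np.array([l.key in all_het_keys for l in retained.loci])
        registered, report = classify_novelty(retained.loci, known, all_het_flags=flags)
        novelty_block = report.as_dict()
        pd.DataFrame(
            {
                "chrom": [l.chrom for l in retained.loci],
                "pos": [l.pos for l in retained.loci],
                "registered": registered.astype(int),
            }
        ).to_csv(out("novelty.tsv"), sep="\t", index=False)

    # --- annotation -------------------------------------------------------
    ann_records, n_ann_warnings = ann_mod.annotate_matrix(retained.loci, retained.info)
    tally = ann_mod.region_tally(ann_records)
    tally.to_csv(out("region_tally.tsv"), sep="\t")
    collapsed = ann_mod.region_tally(ann_records, collapsed=True)
    collapsed.to_csv(out("region_tally_collapsed.tsv"), sep="\t")
    gene_scan = ann_mod.all_alt_frameshift_genes(ann_records, freqs)
    gene_scan.to_csv(out("all_alt_frameshift_genes.tsv"), sep="\t", index=False)

    # --- applications -----------------------------------------------------
    panel = select_panel(dial, config.panel)
    with open(out("panel.tsv"), "w") as fh:
        fh.write(panel_tsv(panel))
    suspect_keys = {r.locus.key for r in suspects}
    db = build_population_db(
        freqs,
        suspect_keys=suspect_keys,
        exclude_suspects=config.exclude_suspects_from_db,
        meta={"n_samples": retained.n_samples, "n_loci": retained.n_loci, "seed": config.seed},
    )
    write_population_db(db, out("popdb.tsv"))

    # --- summary ----------------------------------------------------------
    summary = {
        "n_samples": retained.n_samples,
        "n_input_loci": matrix.n_loci,
        "n_retained_loci": retained.n_loci,
        "filter_failures": fail_counts,
        "counts": {c: summary_df[c].to_dict() for c in summary_df.columns},
        "size_spectrum": {
            "n_deletions": n_del,
            "n_insertions": n_ins,
            "percent_deletions": percent(n_del, n_del + n_ins) if (n_del + n_ins) else None,
        },
        "mean_spacing_bp": spacing,
        "density_per_kb": {r["chrom"]: round(r["per_kb"], 4) for _, r in dens.iterrows()}
        if not dens.empty
        else {},
        "suspects": {
            "all_het_maf05": len(all_het),
            "all_alt_hom": len(all_alt),
            "regions": len(regions),
        },
        "novelty": novelty_block,
        "annotation_warnings": n_ann_warnings,
        "all_alt_frameshift": {
            "n_loci": int(len(gene_scan)),
            "n_genes": int(gene_scan["gene_id"].nunique()) if len(gene_scan) else 0,
        },
        "panel_size": len(panel),
        "popdb_entries": len(db),
    }
    if truth is not None:
        summary["simulated_truth_loci"] = int(len(truth))
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
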