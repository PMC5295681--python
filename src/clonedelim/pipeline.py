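"""End-to-end analysis pipeline and report writing.

Orchestrates: alignment/metadata input -> haplotype collapsing ->
p-distance summaries -> corrected distances -> UPGMA chronogram (on COI
haplotypes) -> GMYC delimitation -> 4x-rule species test -> AMOVA ->
strict-clock dating, and writes the TSV report bundle plus a reproducibility
manifest (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment_io import (
    Alignment, LineagePartition, check_metadata_covers, collapse_haplotypes,
    haplotype_alignment, lineage_specific_substitutions,
    partition_from_metadata, read_alignment, read_metadata, translate,
)
from .amova import amova_two_level
from .clock import DEFAULT_RATE_PER_LINEAGE, date_nodes, upgma_chronogram
from .distances import (
    DistanceMatrix, corrected_distance, difference_count_matrix, fit_model,
    group_mean_distances, p_distance_matrix,
)
from .fourx import (
    clade_diversity_table, diversity_report, four_x_all_pairs, fourx_report,
)
from .gmyc import fit_gmyc, chronogram_from_file

log = logging.getLogger("clonedelim")

__all__ = ["LocusInput", "PipelineConfig", "run_pipeline", "concatenate_loci"]


@dataclass
class LocusInput:
    name: str
    path: str
    coding: bool = False
    genetic_code_id: str = "none"
    frame_offset: int = 0


@dataclass
class PipelineConfig:
    loci: list                       # list[LocusInput]; first is the clock locus
    metadata: str
    outdir: str
    partition_source: str = "gmyc_entities"   # or "metadata_lineage"
    correction: str = "GTRG"                  # or "JC69" (no model fitting)
    amova_permutations: int = 20000
    seed: int = 0
    clock_rate: float = DEFAULT_RATE_PER_LINEAGE
    gmyc_df: int = 3
    user_tree: str | None = None              # optional newick chronogram
    pad_missing: bool = False

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def concatenate_loci(alns: list[Alignment], pad_missing: bool = False) -> Alignment:
    """Column-wise concatenation of loci over a shared sample set.

    Without ``pad_missing``, every locus must contain exactly the same
    samples; with it, absent samples are padded with gaps.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    if len(alns) == 1:
        return alns[0]
    all_ids = list(alns[0].sample_ids)
    seen = set(all_ids)
    for aln in alns[1:]:
        for s in aln.sample_ids:
            if s not in seen:
                all_ids.append(s)
                seen.add(s)
    if not pad_missing:
        mismatches = []
        for aln in alns:
            missing = seen - set(aln.sample_ids)
            if missing:
                mismatches.append((aln.locus_name, sorted(missing)))
        if mismatches:
            raise ValueError(
                f"sample sets differ across loci (no --pad-missing): "
                f"{mismatches}")
    parts = []
    offsets = {}
    pos = 0
    for aln in alns:
        lookup = dict(zip(aln.sample_ids, aln.sequences))
        gap = "-" * aln.length
        parts.append([lookup.get(s, gap) for s in all_ids])
        offsets[aln.locus_name] = (pos, pos + aln.length)
        pos += aln.length
    combined = Alignment(
        locus_name="combined",
        sample_ids=all_ids,
        sequences=["".join(chunks) for chunks in zip(*parts)],
    )
    combined.locus_offsets = offsets  # per-locus coordinate map
    return combined


@dataclass
class PipelineResult:
    alignments: dict
    metadata: pd.DataFrame
    haplotypes: dict
    p_distances: dict
    gmyc_fit: object
    entity_partition: LineagePartition
    fourx_results: list
    species_groups: list
    amova: dict
    chronogram: object
    model: object
    tables: dict = field(default_factory=dict)


def _expand_to_samples(D_hap: DistanceMatrix, hap_of: dict[str, str],
                       sample_ids: list[str]) -> DistanceMatrix:
    pos = {h: i for i, h in enumerate(D_hap.ids)}
    idx = [pos[hap_of[s]] for s in sample_ids]
    V = D_hap.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(V, 0.0)
    return DistanceMatrix(list(sample_ids), V, D_hap.kind)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        result = _run_stages(cfg, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "note": ("chronogram from UPGMA strict-clock dating on corrected "
                 "distances (distance-based approximation, not MCMC)"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return result


def _run_stages(cfg: PipelineConfig, out: Path) -> PipelineResult:
    # ---- stage: input -----------------------------------------------------
    loci = [li if isinstance(li, LocusInput) else LocusInput(**li)
            for li in cfg.loci]
    alns = {
        li.name: read_alignment(li.path, locus_name=li.name, coding=li.coding,
                                genetic_code_id=li.genetic_code_id,
                                frame_offset=li.frame_offset)
        for li in loci
    }
    meta = read_metadata(cfg.metadata)
    for aln in alns.values():
        check_metadata_covers(aln, meta)
    clock_locus = loci[0].name
    log.info("loaded %d loci, %d samples", len(alns),
             alns[clock_locus].n)

    # ---- stage: haplotypes -----------------------------------------------
    haplotypes = {}
    hap_rows = []
    for name, aln in alns.items():
        ht = collapse_haplotypes(aln)
        haplotypes[name] = ht
        hap_rows.append({"locus": name, "level": "nucleotide",
                         "n_haplotypes": ht.n_haplotypes})
        if aln.coding:
            aa = translate(aln)
            ht_aa = collapse_haplotypes(aa)
            haplotypes[f"{name}_aa"] = ht_aa
            hap_rows.append({"locus": name, "level": "amino_acid",
                             "n_haplotypes": ht_aa.n_haplotypes})
        ht.to_frame().to_csv(out / f"haplotypes_{name}.tsv", sep="\t",
                             index=False)
    hap_table = pd.DataFrame(hap_rows)
    hap_table.to_csv(out / "haplotype_counts.tsv", sep="\t", index=False)

    # ---- stage: p-distances ----------------------------------------------
    combined = concatenate_loci(list(alns.values()), cfg.pad_missing)
    p_dists = {name: p_distance_matrix(aln) for name, aln in alns.items()}
    p_dists["combined"] = p_distance_matrix(combined)
    loc_part = LineagePartition(
        dict(zip(meta["sample_id"], meta["location"])), "location")
    for name, D in p_dists.items():
        D.to_square_tsv(out / f"pdist_{name}.tsv")
        tab = group_mean_distances(D, loc_part)
        tab["mean_pct"] = (100 * tab["mean"]).round(2)
        tab["sd_pct"] = (100 * tab["sd"]).round(2)
        tab.to_csv(out / f"pdist_by_location_{name}.tsv", sep="\t",
                   index=False)

    # ---- stage: model + corrected distances (clock locus haplotypes) -----
    focal = alns[clock_locus]
    ht = haplotypes[clock_locus]
    hap_aln = haplotype_alignment(focal, ht)
    model = None
    if cfg.correction == "GTRG":
        model = fit_model(hap_aln)
        D_hap = corrected_distance(hap_aln, "GTRG", model)
    else:
        D_hap = corrected_distance(hap_aln, "JC69")
    hap_of = ht.haplotype_of()
    D_corr = _expand_to_samples(D_hap, hap_of, focal.sample_ids)
    D_corr.to_square_tsv(out / f"corrected_{clock_locus}.tsv")

    # ---- stage: chronogram + GMYC ----------------------------------------
    if cfg.user_tree:
        hap_tree = chronogram_from_file(cfg.user_tree)
        min_sep = None
    else:
        hap_tree = upgma_chronogram(D_hap)
        # distance-derived node heights are quantised at half a substitution
        # (0.5/L); separating ties at that scale keeps GMYC from reading
        # tie clusters as instantaneous branching bursts
        min_sep = 0.5 / focal.length
    fit = fit_gmyc(hap_tree, df=cfg.gmyc_df, min_separation=min_sep)
    (out / "gmyc_report.txt").write_text(fit.summary())
    ent_of_hap = fit.entity_of()
    entity_of_sample = {s: f"E{ent_of_hap[hap_of[s]] + 1}"
                        for s in focal.sample_ids}
    pd.DataFrame(
        {"sample_id": list(entity_of_sample),
         "entity": list(entity_of_sample.values())}
    ).to_csv(out / "gmyc_entities.tsv", sep="\t", index=False)
    log.info("GMYC: %d ML entities (%d clusters), LR=%.2f",
             fit.n_ml_entities, fit.n_clusters, fit.LR)

    # ---- stage: partition selection ---------------------------------------
    if cfg.partition_source == "gmyc_entities":
        part = LineagePartition(entity_of_sample, "lineage")
    elif cfg.partition_source == "metadata_lineage":
        part = partition_from_metadata(meta, "lineage")
    else:
        raise ValueError(f"unknown partition source '{cfg.partition_source}'")

    # per-lineage distance table (Table 2 style)
    for name, D in p_dists.items():
        tab = group_mean_distances(D, part.restrict(D.ids))
        tab["mean_pct"] = (100 * tab["mean"]).round(2)
        tab.to_csv(out / f"pdist_by_lineage_{name}.tsv", sep="\t",
                   index=False)

    # ---- stage: 4x rule ----------------------------------------------------
    fourx_results, species_groups, conflicts = four_x_all_pairs(
        focal, D_corr, part)
    diversity_report(clade_diversity_table(focal, part)).to_csv(
        out / "clade_diversity.tsv", sep="\t", index=False)
    rep = fourx_report(fourx_results)
    rep.to_csv(out / "fourx_pairs.tsv", sep="\t", index=False)
    (out / "fourx_species.txt").write_text(
        "\n".join("+".join(g) for g in species_groups)
        + ("\nCONFLICTS: " + str(conflicts) if conflicts else "") + "\n")

    # ---- stage: AMOVA ------------------------------------------------------
    amova_res = {}
    rows = []
    for name, aln in alns.items():
        counts = difference_count_matrix(aln)
        res = amova_two_level(counts, loc_part, n_perm=cfg.amova_permutations,
                              seed=cfg.seed)
        amova_res[name] = res
        t = res.to_frame()
        t.insert(0, "locus", name)
        rows.append(t)
    pd.concat(rows).to_csv(out / "amova.tsv", sep="\t", index=False)

    # ---- stage: clock dating ----------------------------------------------
    chrono = date_nodes(hap_tree, rate=cfg.clock_rate)
    chrono.node_ages_mya.to_csv(out / "node_ages_mya.tsv", sep="\t",
                                index=False)
    (out / "chronogram_mya.nwk").write_text(chrono.to_newick() + "\n")

    # ---- stage: diagnostic substitutions -----------------------------------
    for name, aln in alns.items():
        screens = [lineage_specific_substitutions(aln, part.restrict(
            aln.sample_ids))]
        if aln.coding:
            screens.append(lineage_specific_substitutions(
                translate(aln), part.restrict(aln.sample_ids)))
        pd.concat(screens).to_csv(
            out / f"lineage_substitutions_{name}.tsv", sep="\t", index=False)

    return PipelineResult(
        alignments=alns, metadata=meta, haplotypes=haplotypes,
        p_distances=p_dists, gmyc_fit=fit,
        entity_partition=part, fourx_results=fourx_results,
        species_groups=species_groups, amova=amova_res,
        chronogram=chrono, model=model,
        tables={"haplotype_counts": hap_table},
    )
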