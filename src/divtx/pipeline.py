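"""End-to-end orchestration of the regulatory-element analysis stages.

Stages run in dependency order: tag clustering -> noise estimation ->
DHS window quantification -> classification -> motif scans -> STARR
integration -> TAD architecture.  :func:`run_pipeline` drives a full
run from an in-memory dataset (typically the synthetic generator's
output or a file bundle loaded with :func:`load_workspace`) and returns
all stage artifacts plus a summary report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import (
    chromatin_architecture as arch,
    dhs_classification as cls_mod,
    dhs_transcription as dhstx,
    enhancer_potential as enh,
    noise_model,
    sequence_elements as seqel,
    tag_clustering as tcmod,
)
from .genomic_io import (
    CONTROL,
    EXOSOME_KD,
    GenomicInterval,
    Library,
    pool_ctss,
)


@dataclass
class PipelineParams:
    merge_dist: int = 20
    trim_fraction: float = 0.1
    valley_fraction: float = 0.1
    tc_annot_max_dist: int = 250
    prompt_dist: int = 500
    noise_n_windows: int = 10000
    noise_window_width: int = 200
    noise_quantile: float = 0.999
    noise_exclusion_flank: int = 500
    min_replicates: int = 2
    window_width: int = 200
    search_radius: int = 100
    k_classes: int = 6
    removal_min_agreement: int = 2
    motif_flank: int = 50
    motif_p_threshold: float = 0.001
    cp_clusters: int = 10
    starr_window: int = 401
    starr_threshold: float = 1.5
    tad_min_overlap: int = 200
    tad_boundary_cutoff: int = 1000
    pair_max_dist: int = 1_000_000
    tad_min_elements: int = 3
    tad_k: int = 7
    divergent_threshold: int = 500
    seed: int = 1


@dataclass
class PipelineResult:
    params: PipelineParams
    tcs: pd.DataFrame | None = None
    tc_keep: pd.DataFrame | None = None
    divergence: pd.DataFrame | None = None
    divergence_fractions: pd.Series | None = None
    noise_thresholds: dict = field(default_factory=dict)
    window_pairs: list = field(default_factory=list)
    quants: pd.DataFrame | None = None
    transcribed: pd.Series | None = None
    convergent: pd.Series | None = None
    assignments: pd.DataFrame | None = None
    label_map: dict = field(default_factory=dict)
    cluster_medians: pd.DataFrame | None = None
    annotation_crosstab: pd.DataFrame | None = None
    motif_hits: pd.DataFrame | None = None
    cp_clusters: pd.Series | None = None
    cp_enrichment: pd.DataFrame | None = None
    starr_calls: pd.DataFrame | None = None
    starr_crosstab: pd.DataFrame | None = None
    starr_rho: dict = field(default_factory=dict)
    tad_assignments: pd.DataFrame | None = None
    tad_fractions: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None
    cooccurrence: dict = field(default_factory=dict)
    tad_clusters: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)

    def classes_by_dhs(self) -> pd.Series:
        a = self.assignments
        return pd.Series(a["class"].to_numpy(), index=a["dhs_id"].to_numpy())


def noise_exclusion_regions(dhss: Sequence[GenomicInterval],
                            genes: Sequence[GenomicInterval],
                            flank: int = 500) -> list[GenomicInterval]:
    """TSS-unlikely exclusion set: DHSs and annotated gene TSSs +/- flank."""
    out = []
    for d in dhss:
        out.append(GenomicInterval(d.chrom, max(0, d.start - flank),
                                   d.end + flank))
    for g in genes:
        if g.tss is not None:
            out.append(GenomicInterval(g.chrom, max(0, g.tss - flank),
                                       g.tss + flank + 1))
    return out


def minor_above_noise_flags(quants: pd.DataFrame,
                            strand_tables: dict[str, pd.DataFrame],
                            thresholds: dict,
                            libraries: Sequence[Library],
                            min_replicates: int = 2) -> pd.Series:
    """Per-DHS flag: minor strand expressed above noise in >= min_replicates
    libraries of either condition."""
    flags_by_strand = {
        s: noise_model.filter_by_noise(df, thresholds, libraries,
                                       min_replicates)["keep_any"].to_numpy()
        for s, df in strand_tables.items()
    }
    minor_strand = np.where(quants["major_strand"] == "+", "-", "+")
    vals = [flags_by_strand[s][i] for i, s in enumerate(minor_strand)]
    return pd.Series(vals, index=quants["dhs_id"].to_numpy())


def run_pipeline(
    ctss: pd.DataFrame,
    libraries: Sequence[Library],
    dhss: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    chrom_lengths: dict[str, int],
    genome=None,
    starr: dict | None = None,
    tads: Sequence[GenomicInterval] = (),
    interactions: Sequence = (),
    params: PipelineParams | None = None,
    stages: Sequence[str] = ("tags", "noise", "dhs", "classify", "motifs",
                             "starr", "tads"),
) -> PipelineResult:
    """Run the analysis stages over one dataset.

    Stages that lack their inputs (no genome -> no motif scans, no STARR
    tracks -> no enhancer stage, no TADs -> no architecture stage) are
    skipped with a notice in ``timings``.
    """
    params = params or PipelineParams()
    res = PipelineResult(params=params)
    lib_ids = [lib.id for lib in libraries]
    kd_ids = [lib.id for lib in libraries if lib.condition == EXOSOME_KD]

    def timed(name):
        res.timings[name] = time.time()

    # --- tag clustering ---------------------------------------------------
    if "tags" in stages:
        t0 = time.time()
        pooled = pool_ctss(ctss, lib_ids)
        tcs = tcmod.call_tag_clusters(pooled, params.merge_dist,
                                      params.trim_fraction,
                                      params.valley_fraction)
        tcs = tcmod.quantify_and_normalize(tcs, ctss, libraries)
        tcs = tcmod.annotate_tcs(tcs, genes, params.tc_annot_max_dist,
                                 params.prompt_dist)
        res.tcs = tcs
        res.divergence = tcmod.divergence_profile(
            tcs, max_dist=5000, divergent_threshold=params.divergent_threshold)
        res.divergence_fractions = tcmod.cumulative_divergent_fraction(
            res.divergence, [250, 500])
        res.timings["tags"] = time.time() - t0

    # --- noise ------------------------------------------------------------
    if "noise" in stages:
        t0 = time.time()
        exclusion = noise_exclusion_regions(dhss, genes,
                                            params.noise_exclusion_flank)
        res.noise_thresholds = noise_model.estimate_noise_threshold(
            ctss, libraries, exclusion, chrom_lengths,
            n_windows=params.noise_n_windows,
            window_width=params.noise_window_width,
            quantile=params.noise_quantile, seed=params.seed)
        if res.tcs is not None:
            tpm_cols = {f"tpm_{l}": res.tcs[f"tpm_{l}"] for l in lib_ids}
            res.tc_keep = noise_model.filter_by_noise(
                pd.DataFrame(tpm_cols), res.noise_thresholds, libraries,
                params.min_replicates)
        res.timings["noise"] = time.time() - t0

    # --- DHS quantification ----------------------------------------------
    if "dhs" in stages:
        t0 = time.time()
        pooled_kd = pool_ctss(ctss, kd_ids)
        res.window_pairs = dhstx.place_windows_batch(
            dhss, pooled_kd, params.window_width, params.search_radius)
        res.quants = dhstx.quantify_dhs(res.window_pairs, ctss, libraries)
        strand_tables = dhstx.strand_expression_tables(
            res.window_pairs, ctss, libraries)
        if res.noise_thresholds:
            res.transcribed = noise_model.dhs_transcribed_flags(
                strand_tables, res.noise_thresholds, libraries,
                params.min_replicates)
            res.transcribed.index = res.quants["dhs_id"].to_numpy()
            res._minor_above_noise = minor_above_noise_flags(
                res.quants, strand_tables, res.noise_thresholds, libraries,
                params.min_replicates)
        res.convergent = pd.Series(
            [dhstx.detect_convergent(d, pooled_kd, params.window_width,
                                     params.search_radius) for d in dhss],
            index=[d.id for d in dhss])
        res.timings["dhs"] = time.time() - t0

    # --- classification ---------------------------------------------------
    if "classify" in stages and res.quants is not None:
        t0 = time.time()
        transcribed_ids = (res.transcribed[res.transcribed].index
                           if res.transcribed is not None
                           else res.quants["dhs_id"])
        tq = res.quants[res.quants["dhs_id"].isin(transcribed_ids)]
        feats = cls_mod.build_features(tq)
        assignments = cls_mod.two_step_cluster(
            feats, params.k_classes, params.seed,
            params.removal_min_agreement)
        man = getattr(res, "_minor_above_noise", None)
        labelled = cls_mod.label_classes(assignments, tq, man)
        res.assignments = labelled.assignments
        res.label_map = labelled.label_map
        res.cluster_medians = labelled.cluster_medians
        res.annotation_crosstab = cls_mod.class_annotation_table(
            res.assignments, dhss, genes)
        res.timings["classify"] = time.time() - t0

    # --- motifs -----------------------------------------------------------
    if "motifs" in stages and genome is not None and res.quants is not None:
        t0 = time.time()
        sub = res.quants
        if res.assignments is not None:
            sub = sub[sub["dhs_id"].isin(res.assignments["dhs_id"])]
        summits = _summit_table(sub)
        motifs = seqel.default_core_promoter_motifs()
        res.motif_hits = seqel.scan_windows(
            genome, summits, motifs, params.motif_flank,
            params.motif_p_threshold)
        score_mat = seqel.core_promoter_score_matrix(res.motif_hits, motifs)
        res.cp_clusters = seqel.cluster_core_promoters(
            score_mat, params.cp_clusters)
        if res.assignments is not None:
            classes = res.classes_by_dhs()
            window_classes = pd.Series(
                [classes.get(d) for d, _ in score_mat.index],
                index=score_mat.index)
            res.cp_enrichment = seqel.core_promoter_enrichment(
                res.cp_clusters, window_classes)
        res.timings["motifs"] = time.time() - t0

    # --- STARR ------------------------------------------------------------
    if "starr" in stages and starr:
        t0 = time.time()
        res.starr_calls = enh.starr_calls_table(
            dhss, starr["hkCP"], starr["dCP"], starr["input"],
            params.starr_window, params.starr_threshold)
        if res.assignments is not None:
            res.starr_crosstab = enh.class_starr_enrichment(
                res.assignments, res.starr_calls)
            merged = res.starr_calls.merge(res.quants, on="dhs_id")
            merged = merged[merged["dhs_id"].isin(
                res.assignments["dhs_id"])]
            x_expr = merged["tpm_major_kd_mean"].to_numpy()
            for kind in ("hkCP", "dCP"):
                _, rho, p = enh.binned_association(
                    merged[f"{kind}_lfc"].to_numpy(), np.log10(x_expr + 0.1))
                res.starr_rho[kind] = (rho, p)
        res.timings["starr"] = time.time() - t0
    elif "starr" in stages:
        res.timings["starr"] = "skipped: no STARR tracks supplied"

    # --- TAD architecture --------------------------------------------------
    if "tads" in stages and tads and res.quants is not None:
        t0 = time.time()
        windows = [
            GenomicInterval(r.chrom, int(r.summit_major) - 200,
                            int(r.summit_major) + 200, id=r.dhs_id)
            for r in res.quants.itertuples()
            if r.summit_major is not None and not pd.isna(r.summit_major)
        ]
        res.tad_assignments = arch.assign_tads(
            windows, tads, params.tad_min_overlap,
            params.tad_boundary_cutoff)
        if res.assignments is not None:
            classes = res.classes_by_dhs()
            res.tad_fractions = arch.inside_between_fractions(
                res.tad_assignments, classes)
            dhs_by_id = {d.id: d for d in dhss}
            eligible = arch.eligible_tad_ids(
                res.tad_assignments[res.tad_assignments["dhs_id"].isin(
                    classes.dropna().index)],
                params.tad_min_elements)
            res.pairs = arch.enumerate_pairs(
                [dhs_by_id[i] for i in classes.dropna().index
                 if i in dhs_by_id],
                res.tad_assignments, classes, params.pair_max_dist,
                interactions)
            for focal in sorted(classes.dropna().unique()):
                res.cooccurrence[focal] = arch.cooccurrence_glm(
                    res.pairs, focal, eligible)
            try:
                res.tad_clusters, _ = arch.tad_composition_clusters(
                    res.tad_assignments, classes, params.tad_min_elements,
                    params.tad_k, params.seed)
            except ValueError:
                res.tad_clusters = None
        res.timings["tads"] = time.time() - t0
    elif "tads" in stages:
        res.timings["tads"] = "skipped: no TADs supplied"
    return res


def _summit_table(quants: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in quants.itertuples(index=False):
        minor_strand = "-" if r.major_strand == "+" else "+"
        for role, strand, summit in (("major", r.major_strand,
                                      r.summit_major),
                                     ("minor", minor_strand, r.summit_minor)):
            if summit is None or pd.isna(summit):
                continue
            rows.append({"dhs_id": r.dhs_id, "strand_role": role,
                         "chrom": r.chrom, "summit": int(summit),
                         "strand": strand})
    return pd.DataFrame(rows)


def summarize_divergence(tcs: pd.DataFrame,
                         thresholds: Sequence[int] = (250, 500),
                         by_annotation: bool = True) -> pd.DataFrame:
    """Fractions of plus-strand TCs with an upstream divergent partner
    within each distance, overall and per annotation category."""
    groups = {"all": tcs}
    if by_annotation and "annotation" in tcs.columns:
        for annot, grp in tcs.groupby("annotation"):
            groups[annot] = grp

    rows = []
    for name, sub in groups.items():
        # partner TCs can come from any annotation category
        prof = tcmod.divergence_profile(
            pd.concat([sub[sub["strand"] == "+"],
                       tcs[tcs["strand"] == "-"]]),
            max_dist=max(thresholds))
        fracs = tcmod.cumulative_divergent_fraction(prof, thresholds)
        row = {"group": name, "n": int((sub["strand"] == "+").sum())}
        for t in thresholds:
            row[f"frac_within_{t}"] = fracs[t]
        rows.append(row)
    return pd.DataFrame(rows)


def report(res: PipelineResult) -> str:
    """Human-readable run summary."""
    lines = ["divtx pipeline report", "=" * 40]
    if res.assignments is not None:
        counts = res.assignments["class"].value_counts(dropna=True)
        lines.append("\nDHS class counts:")
        for cls, n in counts.items():
            lines.append(f"  {cls:40s} {n:6d}")
        lines.append(f"  removed: {int(res.assignments['removed'].sum())}")
    if res.divergence_fractions is not None:
        lines.append("\nDivergent fractions (plus-strand TCs):")
        for d, f in res.divergence_fractions.items():
            lines.append(f"  within {d:4d} bp: {f:.1%}")
    if res.convergent is not None:
        lines.append(f"\nConvergent DHSs: {int(res.convergent.sum())} "
                     f"({res.convergent.mean():.1%})")
    if res.starr_rho:
        lines.append("\nSTARR enhancer potential vs expression (Spearman):")
        for kind, (rho, p) in res.starr_rho.items():
            lines.append(f"  {kind}: rho={rho:+.2f} (p={p:.2g})")
    if res.annotation_crosstab is not None:
        lines.append("\nClass x gene annotation crosstab:")
        lines.append(res.annotation_crosstab.to_string())
    if res.starr_crosstab is not None:
        lines.append("\nClass x STARR category crosstab:")
        lines.append(res.starr_crosstab.to_string())
    if res.cooccurrence:
        lines.append("\nSame-TAD co-occurrence (focal-class coefficient):")
        for focal, model in res.cooccurrence.items():
            coef = model.coefficients
            own = coef[coef["term"] == focal]
            if len(own):
                c = own.iloc[0]
                star = c["stars"] if isinstance(c["stars"], str) else ""
                lines.append(f"  {focal:40s} {c['coef']:+.3f} {star}")
    return "\n".join(lines)
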