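"""Two-step consensus clustering of DHS transcriptional features into six
replicate-consistent regulatory-element classes.

Step 1 clusters all DHS x replicate feature rows (k-means, k=6).  Step 2
summarizes each DHS by the composition of its four replicate rows over
the step-1 groups and clusters those composition vectors again, yielding
a replicate-consensus assignment.  DHSs whose replicates disagree too
much are removed.  Clusters are then mapped to semantic labels (stable /
unstable, uni- / bidirectional, PROMPT-associated) from their median
transcriptional properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from .genomic_io import GenomicInterval

UNI_STABLE = "unidirectional_stable"
UNI_STABLE_PROMPT = "unidirectional_stable_PROMPT"
BI_STABLE = "bidirectional_stable"
WEAK_BI_UNSTABLE = "weak_bidirectional_unstable"
INTER_BI_UNSTABLE = "intermediate_bidirectional_unstable"
WEAK_UNI_UNSTABLE = "weak_unidirectional_unstable"

STABLE_CLASSES = (UNI_STABLE, UNI_STABLE_PROMPT, BI_STABLE)
UNSTABLE_CLASSES = (WEAK_BI_UNSTABLE, INTER_BI_UNSTABLE, WEAK_UNI_UNSTABLE)
ALL_CLASSES = STABLE_CLASSES + UNSTABLE_CLASSES

# label printed in the source literature for the middle unstable class
PRINTED_LABEL_ALIASES = {INTER_BI_UNSTABLE: "Intermediate bidirectional stable"}

FEATURE_COLUMNS = ["log_expr_major", "log_expr_minor", "sens_major",
                   "sens_minor", "directionality"]


class LabelCollisionError(RuntimeError):
    """Two clusters mapped to the same semantic label."""


@dataclass
class ClassificationResult:
    assignments: pd.DataFrame  # dhs_id, cluster, class, agreement, removed
    cluster_medians: pd.DataFrame
    label_map: dict[int, str] = field(default_factory=dict)


def build_features(quants: pd.DataFrame, replicates: Sequence[int] = (1, 2, 3, 4),
                   pseudo: float = 1.0, sens_pseudo_tpm: float = 1.0
                   ) -> pd.DataFrame:
    """Per-replicate standardized feature rows for transcribed DHSs.

    Features per (DHS, replicate): log2(major KD TPM + pseudo),
    log2(minor KD TPM + pseudo), major/minor per-replicate exosome
    sensitivity (control and KD replicates paired by number) and
    directionality.  Feature sensitivities are regularized ratios,
    1 - (control + a)/(KD + a) with a = *sens_pseudo_tpm*, clipped to
    [0, 1]: the raw ratio is noise-dominated on near-silent strands
    (a 0-count control window reads as sensitivity 1), and the
    pseudocount shrinks those toward 0 without moving well-expressed
    strands.  Missing values are imputed with the column mean before
    column standardization; constant columns are dropped.
    """

    def reg_sens(ctrl: float, kd: float) -> float:
        return float(np.clip(
            1.0 - (ctrl + sens_pseudo_tpm) / (kd + sens_pseudo_tpm), 0.0, 1.0))

    rows = []
    for q in quants.itertuples(index=False):
        for r in replicates:
            rows.append({
                "dhs_id": q.dhs_id,
                "replicate": r,
                "log_expr_major": np.log2(
                    getattr(q, f"tpm_major_exosomeKD_{r}") + pseudo),
                "log_expr_minor": np.log2(
                    getattr(q, f"tpm_minor_exosomeKD_{r}") + pseudo),
                "sens_major": reg_sens(
                    getattr(q, f"tpm_major_control_{r}"),
                    getattr(q, f"tpm_major_exosomeKD_{r}")),
                "sens_minor": reg_sens(
                    getattr(q, f"tpm_minor_control_{r}"),
                    getattr(q, f"tpm_minor_exosomeKD_{r}")),
                "directionality": getattr(q, f"dir_{r}"),
            })
    feats = pd.DataFrame(rows)
    dropped = []
    for col in FEATURE_COLUMNS:
        vals = feats[col].to_numpy(dtype=float)
        mean = np.nanmean(vals)
        vals = np.where(np.isnan(vals), mean, vals)
        sd = vals.std()
        if sd == 0 or np.isnan(sd):
            dropped.append(col)
            feats = feats.drop(columns=col)
            continue
        feats[col] = (vals - vals.mean()) / sd
    feats.attrs["dropped_columns"] = dropped
    return feats


def two_step_cluster(features: pd.DataFrame, k: int = 6, seed: int = 1,
                     removal_min_agreement: int = 2) -> pd.DataFrame:
    """Two-step k-means consensus clustering of DHS x replicate rows.

    Returns one row per DHS: cluster (final step-1 group id), agreement
    (modal replicate count), consensus (step-2 cluster id), removed flag.
    """
    feat_cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    X = features[feat_cols].to_numpy(dtype=float)
    dhs_ids = features["dhs_id"].to_numpy()
    n_dhs = len(pd.unique(dhs_ids))
    if k > n_dhs:
        raise ValueError(f"k={k} exceeds number of DHSs ({n_dhs})")
    km1 = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    groups = km1.fit_predict(X)

    comp = pd.crosstab(dhs_ids, groups)
    comp = comp.reindex(columns=range(k), fill_value=0)
    comp_frac = comp.div(comp.sum(axis=1), axis=0)
    km2 = KMeans(n_clusters=min(k, len(comp_frac)), init="k-means++",
                 n_init=10, random_state=seed)
    consensus = km2.fit_predict(comp_frac.to_numpy())

    counts = comp.to_numpy()
    modal_count = counts.max(axis=1)
    rows = []
    for i, dhs_id in enumerate(comp.index):
        row_counts = counts[i]
        best = row_counts.max()
        modal = np.flatnonzero(row_counts == best)
        if len(modal) == 1:
            cluster = int(modal[0])
        else:
            # tie: use the consensus centroid's largest component among tied
            centroid = km2.cluster_centers_[consensus[i]]
            cluster = int(modal[np.argmax(centroid[modal])])
        rows.append({
            "dhs_id": dhs_id,
            "cluster": cluster,
            "consensus": int(consensus[i]),
            "agreement": int(best),
            "removed": bool(best < removal_min_agreement),
        })
    return pd.DataFrame(rows)


def _cluster_medians(assignments: pd.DataFrame, quants: pd.DataFrame,
                     minor_above_noise: pd.Series | None) -> pd.DataFrame:
    merged = assignments.merge(quants, on="dhs_id")
    if minor_above_noise is not None:
        flag = minor_above_noise.rename("minor_expressed").reset_index()
        flag.columns = ["dhs_id", "minor_expressed"]
        merged = merged.merge(flag, on="dhs_id", how="left")
    else:
        merged["minor_expressed"] = merged["tpm_minor_kd_mean"] > 0
    rows = []
    for cluster, grp in merged[~merged["removed"]].groupby("cluster"):
        rows.append({
            "cluster": int(cluster),
            "n": len(grp),
            "sens_major_med": float(np.nanmedian(grp["sens_major"])),
            "sens_minor_med": float(np.nanmedian(grp["sens_minor"])),
            "dir_med": float(np.nanmedian(grp["directionality"])),
            "expr_major_med": float(np.nanmedian(grp["tpm_major_kd_mean"])),
            "minor_expr_frac": float(np.mean(grp["minor_expressed"].astype(bool))),
        })
    return pd.DataFrame(rows)


def label_classes(assignments: pd.DataFrame, quants: pd.DataFrame,
                  minor_above_noise: pd.Series | None = None,
                  sens_cutoff: float = 0.5, bidir_cutoff: float = 0.4,
                  unidir_cutoff: float = 0.7, minor_frac_cutoff: float = 0.5,
                  ) -> ClassificationResult:
    """Map the six clusters to semantic labels from their medians.

    Rules: stable superclass iff median major sensitivity < sens_cutoff.
    Among stable clusters: bidirectional_stable iff median directionality
    < bidir_cutoff; else PROMPT-associated iff the minor strand is
    expressed above noise in >= minor_frac_cutoff of members and its
    median sensitivity exceeds sens_cutoff; else unidirectional_stable.
    Among unstable clusters: weak_unidirectional_unstable iff median
    directionality > unidir_cutoff; the remaining two split by median
    major expression (lower -> weak_, higher -> intermediate_).  Each
    label must be used exactly once.
    """
    med = _cluster_medians(assignments, quants, minor_above_noise)
    if len(med) != 6:
        raise LabelCollisionError(
            f"expected 6 populated clusters, found {len(med)}:\n{med}"
        )
    label_map: dict[int, str] = {}
    stable = med[med["sens_major_med"] < sens_cutoff]
    unstable = med[med["sens_major_med"] >= sens_cutoff]
    if len(stable) != 3 or len(unstable) != 3:
        raise LabelCollisionError(
            "stable/unstable split is not 3+3; cluster medians:\n"
            f"{med.to_string(index=False)}"
        )
    # stable branch
    bi = stable[stable["dir_med"] < bidir_cutoff]
    if len(bi) != 1:
        raise LabelCollisionError(
            f"expected one bidirectional stable cluster, found {len(bi)}:\n"
            f"{med.to_string(index=False)}"
        )
    label_map[int(bi["cluster"].iloc[0])] = BI_STABLE
    rest = stable[stable["dir_med"] >= bidir_cutoff]
    prompt = rest[(rest["minor_expr_frac"] >= minor_frac_cutoff)
                  & (rest["sens_minor_med"] > sens_cutoff)]
    if len(prompt) != 1:
        raise LabelCollisionError(
            "expected one PROMPT-associated stable cluster, found "
            f"{len(prompt)}:\n{med.to_string(index=False)}"
        )
    label_map[int(prompt["cluster"].iloc[0])] = UNI_STABLE_PROMPT
    uni = rest[rest["cluster"] != prompt["cluster"].iloc[0]]
    label_map[int(uni["cluster"].iloc[0])] = UNI_STABLE
    # unstable branch
    weak_uni = unstable[unstable["dir_med"] > unidir_cutoff]
    if len(weak_uni) != 1:
        raise LabelCollisionError(
            "expected one weak unidirectional unstable cluster, found "
            f"{len(weak_uni)}:\n{med.to_string(index=False)}"
        )
    label_map[int(weak_uni["cluster"].iloc[0])] = WEAK_UNI_UNSTABLE
    remaining = unstable[unstable["cluster"] != weak_uni["cluster"].iloc[0]]
    remaining = remaining.sort_values("expr_major_med")
    label_map[int(remaining["cluster"].iloc[0])] = WEAK_BI_UNSTABLE
    label_map[int(remaining["cluster"].iloc[1])] = INTER_BI_UNSTABLE
    if len(set(label_map.values())) != 6:
        raise LabelCollisionError(f"label collision: {label_map}")
    out = assignments.copy()
    out["class"] = out["cluster"].map(label_map)
    out.loc[out["removed"], "class"] = None
    out["superclass"] = out["class"].map(
        lambda c: None if c is None
        else ("stable" if c in STABLE_CLASSES else "unstable")
    )
    return ClassificationResult(out, med, label_map)


# annotation categories for class_annotation_table
DIVERGENT_PAIR = "divergent_gene_pair"
UNIDIRECTIONAL_GENE = "unidirectional_gene"
GENE_DISTAL = "distal"


def class_annotation_table(result: pd.DataFrame,
                           dhss: Sequence[GenomicInterval],
                           gene_tss: Sequence[GenomicInterval],
                           up: int = 200, down: int = 100) -> pd.DataFrame:
    """Cross-tabulate DHS class against gene-TSS annotation.

    Gene TSSs are extended *up* bp upstream and *down* bp downstream with
    respect to the gene strand; a DHS overlapping extended TSSs on both
    strands is a divergent gene pair, on one strand a unidirectional
    gene, on none gene-distal.  Adds a chi-squared test of each class
    against the rest.
    """
    ext: dict[str, list[tuple[int, int, str]]] = {}
    for g in gene_tss:
        if g.tss is None:
            continue
        if g.strand == "+":
            iv = (g.tss - up, g.tss + down + 1)
        else:
            iv = (g.tss - down, g.tss + up + 1)
        ext.setdefault(g.chrom, []).append((iv[0], iv[1], g.strand))
    by_id = {d.id: d for d in dhss}
    cats = []
    for dhs_id in result["dhs_id"]:
        d = by_id[dhs_id]
        strands = {s for (a, b, s) in ext.get(d.chrom, [])
                   if a < d.end and d.start < b}
        if {"+", "-"} <= strands:
            cats.append(DIVERGENT_PAIR)
        elif strands:
            cats.append(UNIDIRECTIONAL_GENE)
        else:
            cats.append(GENE_DISTAL)
    tab = result.copy()
    tab["gene_annotation"] = cats
    tab = tab[~tab["removed"]]
    crosstab = pd.crosstab(tab["class"], tab["gene_annotation"])
    crosstab = crosstab.reindex(
        columns=[DIVERGENT_PAIR, UNIDIRECTIONAL_GENE, GENE_DISTAL],
        fill_value=0,
    )
    pvals = {}
    total = crosstab.sum()
    for cls in crosstab.index:
        observed = np.array([crosstab.loc[cls].to_numpy(),
                             (total - crosstab.loc[cls]).to_numpy()])
        observed = observed[:, observed.sum(axis=0) > 0]
        if observed.shape[1] < 2:
            pvals[cls] = np.nan
            continue
        pvals[cls] = float(chi2_contingency(observed)[1])
    crosstab["chi2_p_vs_rest"] = pd.Series(pvals)
    return crosstab
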