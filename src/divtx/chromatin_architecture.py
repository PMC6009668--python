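"""DHS classes in their three-dimensional chromatin context.

DHSs (as +/-200 bp windows around their major CAGE summits) are
allocated to TADs, scored for boundary proximity, and all DHS pairs
within 1 Mb are enumerated.  Binomial GLMs then model the odds that a
partner of each class shares a TAD with a focal-class DHS, corrected
for pair distance and against a random-partner background
(sum-to-zero/deviation coding).  TADs themselves are clustered by their
class composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, spearmanr
from sklearn.cluster import KMeans

from .genomic_io import GenomicInterval

BETWEEN = "BETWEEN"


@dataclass(frozen=True)
class TadAssignment:
    dhs_id: str
    tad_id: str  # TAD id or BETWEEN
    distance_to_nearest_boundary: float
    near_boundary: bool


def _check_non_overlapping(tads: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        for a, b in zip(ts[:-1], ts[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: {a.id} and {b.id}"
                )


def assign_tads(dhs_windows: Sequence[GenomicInterval],
                tads: Sequence[GenomicInterval],
                min_overlap: int = 200,
                boundary_cutoff: int = 1000) -> pd.DataFrame:
    """Allocate each DHS window (summit +/- 200 bp) to a TAD.

    A DHS gets a TAD id when the overlap is >= *min_overlap* bp; when
    two TADs qualify the larger overlap wins (ties to the upstream TAD,
    flagged).  DHSs without any TAD overlap are BETWEEN.  Boundary
    distance is measured from the window center to the nearest TAD edge.
    """
    _check_non_overlapping(tads)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for ts in by_chrom.values():
        ts.sort(key=lambda t: t.start)
    boundaries: dict[str, np.ndarray] = {
        chrom: np.sort(np.concatenate([[t.start, t.end] for t in ts]))
        for chrom, ts in by_chrom.items()
    }
    rows = []
    for d in dhs_windows:
        cands = []
        for t in by_chrom.get(d.chrom, []):
            ov = min(d.end, t.end) - max(d.start, t.start)
            if ov >= min_overlap:
                cands.append((ov, -t.start, t.id))
        ambiguous = len(cands) > 1
        tad_id = max(cands)[2] if cands else BETWEEN
        bnds = boundaries.get(d.chrom, np.array([]))
        center = d.center
        dist = float(np.abs(bnds - center).min()) if bnds.size else np.inf
        rows.append({
            "dhs_id": d.id, "tad_id": tad_id,
            "distance_to_nearest_boundary": dist,
            "near_boundary": dist <= boundary_cutoff,
            "ambiguous": ambiguous,
        })
    return pd.DataFrame(rows)


def inside_between_fractions(assignments: pd.DataFrame, classes: pd.Series
                             ) -> pd.DataFrame:
    """Per-class fractions of DHSs inside vs between TADs, with a Fisher
    test of each class against the rest, and boundary-proximity Fisher
    enrichment."""
    df = assignments.merge(
        classes.rename("class").reset_index().rename(
            columns={"index": "dhs_id"}),
        on="dhs_id",
    ).dropna(subset=["class"])
    rows = []
    inside_all = (df["tad_id"] != BETWEEN).sum()
    between_all = (df["tad_id"] == BETWEEN).sum()
    near_all = df["near_boundary"].sum()
    far_all = (~df["near_boundary"]).sum()
    for cls, grp in df.groupby("class"):
        inside = int((grp["tad_id"] != BETWEEN).sum())
        between = int((grp["tad_id"] == BETWEEN).sum())
        near = int(grp["near_boundary"].sum())
        far = int((~grp["near_boundary"]).sum())
        _, p_between = fisher_exact(
            [[between, inside],
             [between_all - between, inside_all - inside]])
        _, p_boundary = fisher_exact(
            [[near, far], [near_all - near, far_all - far]])
        rows.append({
            "class": cls, "n": len(grp),
            "frac_inside": inside / len(grp),
            "frac_between": between / len(grp),
            "fisher_p_between": float(p_between),
            "frac_near_boundary": near / len(grp),
            "fisher_p_boundary": float(p_boundary),
        })
    return pd.DataFrame(rows)


def enumerate_pairs(dhss: Sequence[GenomicInterval],
                    assignments: pd.DataFrame,
                    classes: pd.Series,
                    max_dist: int = 1_000_000,
                    interactions: Sequence[tuple[GenomicInterval,
                                                 GenomicInterval]] = (),
                    ) -> pd.DataFrame:
    """All unordered DHS pairs within *max_dist* bp between center points.

    Pairs carry same_tad (both members share a TAD id), the class labels
    and whether both members fall in the two anchors of a significant
    interaction (either orientation).
    """
    tad_of = dict(zip(assignments["dhs_id"], assignments["tad_id"]))
    cls_of = classes.to_dict()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in dhss:
        by_chrom.setdefault(d.chrom, []).append(d)
    inter_by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for a, b in interactions:
        if a.chrom == b.chrom:
            inter_by_chrom.setdefault(a.chrom, []).append(
                (a.start, a.end, b.start, b.end))
    rows = []
    for chrom, ds in by_chrom.items():
        ds.sort(key=lambda d: d.center)
        centers = [d.center for d in ds]
        inters = inter_by_chrom.get(chrom, [])
        for i, di in enumerate(ds):
            for j in range(i + 1, len(ds)):
                dist = centers[j] - centers[i]
                if dist > max_dist:
                    break
                dj = ds[j]
                ti, tj = tad_of.get(di.id, BETWEEN), tad_of.get(dj.id, BETWEEN)
                overlaps = False
                for (a1, a2, b1, b2) in inters:
                    in_a_i = a1 <= centers[i] < a2
                    in_b_i = b1 <= centers[i] < b2
                    in_a_j = a1 <= centers[j] < a2
                    in_b_j = b1 <= centers[j] < b2
                    if (in_a_i and in_b_j) or (in_b_i and in_a_j):
                        overlaps = True
                        break
                rows.append({
                    "id_i": di.id, "id_j": dj.id, "chrom": chrom,
                    "distance": dist,
                    "same_tad": ti != BETWEEN and ti == tj,
                    "tad_i": ti, "tad_j": tj,
                    "class_i": cls_of.get(di.id),
                    "class_j": cls_of.get(dj.id),
                    "overlaps_interaction": overlaps,
                })
    return pd.DataFrame(rows)


def eligible_tad_ids(assignments: pd.DataFrame, min_elements: int = 3
                     ) -> set[str]:
    """TAD ids containing at least *min_elements* transcribed DHSs."""
    counts = assignments[assignments["tad_id"] != BETWEEN].groupby(
        "tad_id").size()
    return set(counts[counts >= min_elements].index)


@dataclass
class CooccurrenceModel:
    focal_class: str
    coefficients: pd.DataFrame  # term, coef, se, p, stars
    distance_coef: float
    converged: bool
    separation: bool = False


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _deviation_design(partner: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding over partner classes; the last class
    (alphabetically) is the implicit reference whose coefficient is minus
    the sum of the others."""
    levels = sorted(partner.unique())
    k = len(levels)
    X = np.zeros((len(partner), max(k - 1, 0)))
    for i, value in enumerate(partner):
        j = levels.index(value)
        if j < k - 1:
            X[i, j] = 1.0
        else:
            X[i, :] = -1.0
    return X, levels


def cooccurrence_glm(pairs: pd.DataFrame, focal_class: str,
                     eligible_tads: set[str] | None = None) -> CooccurrenceModel:
    """Binomial GLM of same-TAD co-occurrence for one focal class.

    Uses pairs where at least one member is the focal class; the
    response is same_tad, the predictors are the partner class under
    deviation (sum-to-zero) coding — so each coefficient is the change
    in log-odds relative to encountering an average/random partner —
    plus log10 of the pair distance.
    """
    sub = pairs[(pairs["class_i"] == focal_class)
                | (pairs["class_j"] == focal_class)].copy()
    sub = sub.dropna(subset=["class_i", "class_j"])
    if eligible_tads is not None and {"tad_i", "tad_j"} <= set(sub.columns):
        ok_i = (sub["tad_i"] == BETWEEN) | sub["tad_i"].isin(eligible_tads)
        ok_j = (sub["tad_j"] == BETWEEN) | sub["tad_j"].isin(eligible_tads)
        sub = sub[ok_i & ok_j]
    partner = np.where(sub["class_i"] == focal_class,
                       sub["class_j"], sub["class_i"])
    sub["partner"] = partner
    y = sub["same_tad"].to_numpy(dtype=float)
    if len(sub) == 0 or y.min() == y.max():
        return CooccurrenceModel(
            focal_class, pd.DataFrame(
                columns=["term", "coef", "se", "p", "stars"]),
            float("nan"), converged=False, separation=True,
        )
    Xdev, levels = _deviation_design(sub["partner"])
    logd = np.log10(np.maximum(sub["distance"].to_numpy(dtype=float), 1.0))
    X = np.column_stack([np.ones(len(sub)), Xdev, logd])
    names = (["intercept"] + [f"partner_{c}" for c in levels[:-1]]
             + ["log10_distance"])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100)
        converged = bool(fit.converged)
    except Exception:
        return CooccurrenceModel(
            focal_class, pd.DataFrame(
                columns=["term", "coef", "se", "p", "stars"]),
            float("nan"), converged=False, separation=True,
        )
    rows = []
    coefs = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    ps = dict(zip(names, fit.pvalues))
    for c in levels[:-1]:
        term = f"partner_{c}"
        rows.append({"term": c, "coef": coefs[term], "se": ses[term],
                     "p": ps[term], "stars": _stars(ps[term])})
    # the omitted level's deviation coefficient (variance via the sum)
    last_coef = -sum(coefs[f"partner_{c}"] for c in levels[:-1]) \
        if len(levels) > 1 else 0.0
    rows.append({"term": levels[-1], "coef": last_coef, "se": np.nan,
                 "p": np.nan, "stars": ""})
    return CooccurrenceModel(
        focal_class, pd.DataFrame(rows), float(coefs["log10_distance"]),
        converged=converged,
    )


def tad_composition_clusters(assignments: pd.DataFrame, classes: pd.Series,
                             min_elements: int = 3, k: int = 7,
                             seed: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster TADs by their per-class DHS counts.

    Counts per TAD per class are log2(count+1) transformed and clustered
    with k-means (k-means++ init, fixed seed); only TADs with at least
    *min_elements* DHSs are eligible.  Returns (per-TAD cluster table,
    per-cluster mean composition profile).
    """
    df = assignments.merge(
        classes.rename("class").reset_index().rename(
            columns={"index": "dhs_id"}),
        on="dhs_id",
    ).dropna(subset=["class"])
    df = df[df["tad_id"] != BETWEEN]
    counts = pd.crosstab(df["tad_id"], df["class"])
    eligible = counts[counts.sum(axis=1) >= min_elements]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} TADs with >= {min_elements} elements; "
            f"cannot form {k} clusters"
        )
    X = np.log2(eligible.to_numpy(dtype=float) + 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    table = eligible.copy()
    table["tad_cluster"] = labels
    profile = table.groupby("tad_cluster").mean()
    return table.reset_index(), profile


def tad_size_enrichment(assignments: pd.DataFrame, classes: pd.Series,
                        max_group: int = 6) -> pd.DataFrame:
    """Class proportions by TAD size (number of member DHSs), grouping all
    TADs with more than *max_group* elements."""
    df = assignments.merge(
        classes.rename("class").reset_index().rename(
            columns={"index": "dhs_id"}),
        on="dhs_id",
    ).dropna(subset=["class"])
    df = df[df["tad_id"] != BETWEEN]
    sizes = df.groupby("tad_id").size()
    size_of = sizes.to_dict()
    df["tad_size"] = [min(size_of[t], max_group + 1) for t in df["tad_id"]]
    tab = pd.crosstab(df["tad_size"], df["class"], normalize="index")
    tab.index = [str(s) if s <= max_group else f">{max_group}"
                 for s in tab.index]
    return tab


def dhs_count_vs_tad_length(assignments: pd.DataFrame,
                            tads: Sequence[GenomicInterval]
                            ) -> tuple[float, float]:
    """Spearman correlation between DHS count per TAD and TAD length
    (reported, not asserted)."""
    counts = assignments[assignments["tad_id"] != BETWEEN].groupby(
        "tad_id").size()
    lengths = {t.id: len(t) for t in tads}
    common = [t for t in counts.index if t in lengths]
    if len(common) < 3:
        return float("nan"), float("nan")
    rho, p = spearmanr(counts[common].to_numpy(),
                       [lengths[t] for t in common])
    return float(rho), float(p)


def interaction_target_model(pairs: pd.DataFrame, calls: pd.DataFrame,
                             focal_class: str, potential: str = "hkCP"
                             ) -> CooccurrenceModel:
    """Binomial GLM of interaction-target enhancer potential.

    Among interacting pairs with a focal-class member, models whether
    the target has hkCP (or dCP) potential versus no STARR potential at
    all, as a function of the focal DHS class (deviation coding not
    needed here: the focal class is fixed, so the model reduces to an
    intercept + log10 distance within the focal class) — instead the
    model is fit across *all* classes with deviation coding and the
    focal row reported; callers typically loop over classes.
    """
    if potential not in ("hkCP", "dCP"):
        raise ValueError("potential must be hkCP or dCP")
    inter = pairs[pairs["overlaps_interaction"]].copy()
    if inter.empty:
        return CooccurrenceModel(
            focal_class, pd.DataFrame(
                columns=["term", "coef", "se", "p", "stars"]),
            float("nan"), converged=False, separation=True,
        )
    active = dict(zip(calls["dhs_id"], calls[f"active_{potential}"]))
    other = "dCP" if potential == "hkCP" else "hkCP"
    other_active = dict(zip(calls["dhs_id"], calls[f"active_{other}"]))
    rows = []
    for r in inter.itertuples(index=False):
        for focal_id, target_id, focal_cls in (
                (r.id_i, r.id_j, r.class_i), (r.id_j, r.id_i, r.class_j)):
            if focal_cls is None or target_id not in active:
                continue
            has = bool(active[target_id])
            background = not has and not bool(other_active.get(target_id, False))
            if not (has or background):
                continue  # targets with only the other potential excluded
            rows.append({"focal_class": focal_cls, "distance": r.distance,
                         "response": float(has)})
    df = pd.DataFrame(rows)
    if df.empty or df["response"].nunique() < 2:
        return CooccurrenceModel(
            focal_class, pd.DataFrame(
                columns=["term", "coef", "se", "p", "stars"]),
            float("nan"), converged=False, separation=True,
        )
    Xdev, levels = _deviation_design(df["focal_class"])
    logd = np.log10(np.maximum(df["distance"].to_numpy(dtype=float), 1.0))
    X = np.column_stack([np.ones(len(df)), Xdev, logd])
    fit = sm.GLM(df["response"].to_numpy(), X,
                 family=sm.families.Binomial()).fit(maxiter=100)
    names = (["intercept"] + [f"focal_{c}" for c in levels[:-1]]
             + ["log10_distance"])
    coefs = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    ps = dict(zip(names, fit.pvalues))
    out_rows = []
    for c in levels[:-1]:
        term = f"focal_{c}"
        out_rows.append({"term": c, "coef": coefs[term], "se": ses[term],
                         "p": ps[term], "stars": _stars(ps[term])})
    last = -sum(coefs[f"focal_{c}"] for c in levels[:-1]) \
        if len(levels) > 1 else 0.0
    out_rows.append({"term": levels[-1], "coef": last, "se": np.nan,
                     "p": np.nan, "stars": ""})
    return CooccurrenceModel(
        focal_class, pd.DataFrame(out_rows),
        float(coefs["log10_distance"]), converged=bool(fit.converged),
    )
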