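"""Core promoter element and RNA-processing motif analysis.

Motifs are position probability matrices scored by log-odds against a
background base composition.  Match significance uses the exact null
score distribution computed by dynamic-programming convolution over
positions.  Scans run on strand-oriented windows around major/minor
CAGE summits; downstream profiles count 5' splice-site and
polyadenylation (AWTAAA) motifs in growing windows, background
subtracted.

The bundled default motif models are consensus-derived toy matrices
(synthetic stand-ins, not the published matrices); real scans should
load matrices in MEME minimal format via :func:`read_meme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import AgglomerativeClustering

from .genomic_io import GenomeSequence

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

UNIFORM_BG = np.full(4, 0.25)


@dataclass
class MotifModel:
    """Position probability matrix scored by log2 odds vs background."""

    name: str
    matrix: np.ndarray  # L x 4 probabilities
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, word: str) -> float:
        """Log-odds score of an exact-length word; ambiguous bases score 0."""
        lo = self.log_odds
        total = 0.0
        for i, base in enumerate(word.upper()):
            j = BASE_INDEX.get(base)
            if j is not None:
                total += lo[i, j]
        return total

    def scores_along(self, seq: str) -> np.ndarray:
        """Score at every start of *seq* (length len(seq)-L+1)."""
        L = len(self)
        n = len(seq) - L + 1
        if n <= 0:
            return np.array([])
        lo = self.log_odds
        idx = np.array([BASE_INDEX.get(b, -1) for b in seq.upper()])
        out = np.zeros(n)
        for i in range(L):
            col = idx[i:i + n]
            vals = np.where(col >= 0, lo[i][np.clip(col, 0, 3)], 0.0)
            out += vals
        return out

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       background: np.ndarray | None = None,
                       pseudo: float = 0.04) -> "MotifModel":
        """Expand an IUPAC consensus into degenerate probability columns.

        Allowed bases at a position share (1 - pseudo) equally; the rest
        share *pseudo*.
        """
        bg = UNIFORM_BG if background is None else background
        rows = []
        for ch in consensus.upper():
            allowed = IUPAC[ch]
            row = np.full(4, pseudo / (4 - len(allowed))
                          if len(allowed) < 4 else 0.0)
            for b in allowed:
                row[BASE_INDEX[b]] = (1.0 - pseudo) / len(allowed) \
                    if len(allowed) < 4 else 0.25
            rows.append(row)
        return cls(name, np.array(rows), bg)


# --------------------------------------------------------------------------
# Default motif set (consensus-derived toy stand-ins for the published
# core promoter matrices) plus a canonical splice-donor PWM.
# --------------------------------------------------------------------------

CORE_PROMOTER_CONSENSUS = {
    "TATA": "TATAWAWR",
    "Inr": "TCAGTY",
    "DPE": "RGWYVT",
    "MTE": "CSARCSSA",
    "Ebox_Ohler5": "CACGTG",
    "Ohler1": "YGGTCACACTR",
    "DRE": "WATCGATW",
    "Ohler6": "YGGCACACCC",
    "Trl": "GAGAGAG",
}

POLYA_HEXAMER = "AWTAAA"  # degenerate polyadenylation signal, W = A/T


def default_core_promoter_motifs(background: np.ndarray | None = None
                                 ) -> list[MotifModel]:
    return [MotifModel.from_consensus(name, cons, background)
            for name, cons in CORE_PROMOTER_CONSENSUS.items()]


def splice_donor_motif(background: np.ndarray | None = None) -> MotifModel:
    """Canonical 5' splice-site donor PWM (positions -3..+6, MAG|GTAAGT),
    with an invariant GT dinucleotide at +1/+2."""
    bg = UNIFORM_BG if background is None else background
    # A     C     G     T
    matrix = np.array([
        [0.35, 0.35, 0.15, 0.15],  # -3 M
        [0.60, 0.10, 0.15, 0.15],  # -2 A
        [0.10, 0.05, 0.80, 0.05],  # -1 G
        [0.01, 0.01, 0.97, 0.01],  # +1 G
        [0.01, 0.01, 0.01, 0.97],  # +2 T
        [0.60, 0.05, 0.30, 0.05],  # +3 A
        [0.70, 0.07, 0.10, 0.13],  # +4 A
        [0.10, 0.05, 0.80, 0.05],  # +5 G
        [0.15, 0.15, 0.15, 0.55],  # +6 T
    ])
    return MotifModel("five_prime_SS", matrix, bg)


# --------------------------------------------------------------------------
# MEME minimal motif format
# --------------------------------------------------------------------------

def write_meme(motifs: Sequence[MotifModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else UNIFORM_BG
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)}\n"
            )
            for row in m.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str) -> list[MotifModel]:
    motifs = []
    background = UNIFORM_BG.copy()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            width = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            motifs.append(MotifModel(name, np.array(rows), background))
            i += 1 + width
            continue
        i += 1
    return motifs


# --------------------------------------------------------------------------
# Exact motif score p-values by dynamic programming
# --------------------------------------------------------------------------

def motif_pvalue_table(motif: MotifModel, resolution: float = 0.01
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the motif log-odds score.

    The per-position log-odds are discretized to *resolution* bits and
    convolved over positions under the background composition.  Returns
    (score_grid, pvalues) where pvalues[i] = P(score >= score_grid[i]).
    """
    if not np.isclose(motif.background.sum(), 1.0, atol=1e-9):
        raise ValueError("background must be normalized")
    lo = motif.log_odds
    int_scores = np.round(lo / resolution).astype(np.int64)
    lo_min = int_scores.min(axis=1)
    lo_max = int_scores.max(axis=1)
    total_min, total_max = int(lo_min.sum()), int(lo_max.sum())
    dist = np.zeros(total_max - total_min + 1)
    dist[0] = 1.0  # offset representation: index = score - running_min
    running_min = 0
    width = 1
    for i in range(len(motif)):
        new_width = width + int(lo_max[i] - lo_min[i])
        new = np.zeros(new_width)
        for j in range(4):
            shift = int(int_scores[i, j] - lo_min[i])
            new[shift:shift + width] += motif.background[j] * dist[:width]
        dist[:new_width] = new
        width = new_width
        running_min += int(lo_min[i])
    pmf = dist[:width]
    grid = (np.arange(width) + total_min) * resolution
    pvals = np.cumsum(pmf[::-1])[::-1]
    return grid, np.minimum(pvals, 1.0)


def score_pvalue(score: float, grid: np.ndarray, pvals: np.ndarray,
                 resolution: float = 0.01) -> float:
    """P(null score >= observed score), from a motif_pvalue_table result."""
    i = int(np.searchsorted(grid, score - resolution / 2, side="left"))
    if i >= len(pvals):
        return float(pvals[-1]) if len(pvals) else 1.0
    return float(pvals[i])


# --------------------------------------------------------------------------
# Window scans
# --------------------------------------------------------------------------

def scan_windows(
    genome: GenomeSequence,
    summits: pd.DataFrame,
    motifs: Sequence[MotifModel],
    flank: int = 50,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Scan +/- *flank* bp around strand-oriented CAGE summits.

    *summits* needs columns dhs_id, strand_role, chrom, summit, strand.
    Per (dhs, strand_role, motif) the maximum-score position is kept;
    ``significant`` flags p < p_threshold.  Offsets are TSS-relative on
    the oriented sequence (negative = upstream of the summit).
    """
    tables = {m.name: motif_pvalue_table(m) for m in motifs}
    rows = []
    for s in summits.itertuples(index=False):
        seq, truncated = genome.fetch(
            s.chrom, int(s.summit) - flank, int(s.summit) + flank + 1, s.strand
        )
        for m in motifs:
            scores = m.scores_along(seq)
            if scores.size == 0:
                continue
            i = int(np.argmax(scores))
            grid, pvals = tables[m.name]
            p = score_pvalue(float(scores[i]), grid, pvals)
            rows.append({
                "dhs_id": s.dhs_id,
                "strand_role": s.strand_role,
                "motif": m.name,
                "offset": i - flank,
                "score": float(scores[i]),
                "p_value": p,
                "significant": p < p_threshold,
                "truncated": truncated,
            })
    return pd.DataFrame(rows)


def positional_profile(hits: pd.DataFrame, n_dhs: int, flank: int = 50
                       ) -> pd.DataFrame:
    """Per-motif fraction of DHSs with a significant element per offset."""
    offsets = np.arange(-flank, flank + 1)
    out = []
    sig = hits[hits["significant"]] if len(hits) else hits
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["motif", "strand_role", "offset", "fraction"])
    for (motif, role), grp in sig.groupby(["motif", "strand_role"]):
        counts = grp.groupby("offset").size()
        for off in offsets:
            out.append({
                "motif": motif, "strand_role": role, "offset": int(off),
                "fraction": counts.get(off, 0) / n_dhs if n_dhs else 0.0,
            })
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Core promoter composition clustering
# --------------------------------------------------------------------------

def core_promoter_score_matrix(hits: pd.DataFrame,
                               motifs: Sequence[MotifModel]) -> pd.DataFrame:
    """Max match score per (dhs, strand_role) x motif; windows without a
    significant hit contribute the motif's minimum attainable score."""
    min_scores = {m.name: m.min_score for m in motifs}
    mat = hits.copy()
    mat.loc[~mat["significant"], "score"] = mat.loc[
        ~mat["significant"], "motif"].map(min_scores)
    pivot = mat.pivot_table(index=["dhs_id", "strand_role"], columns="motif",
                            values="score", aggfunc="max")
    for m in motifs:
        if m.name not in pivot.columns:
            pivot[m.name] = min_scores[m.name]
        pivot[m.name] = pivot[m.name].fillna(min_scores[m.name])
    return pivot[[m.name for m in motifs]]


def cluster_core_promoters(score_matrix: pd.DataFrame, k: int = 10
                           ) -> pd.Series:
    """Ward hierarchical clustering of z-scaled motif match scores, cut at
    *k* clusters; returns cluster ids (1..k) indexed like the matrix."""
    if k > len(score_matrix):
        raise ValueError(f"k={k} exceeds {len(score_matrix)} rows")
    X = score_matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError(
            "all score columns constant, cannot scale; column means: "
            f"{dict(zip(score_matrix.columns, X.mean(axis=0)))}"
        )
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(X) + 1
    return pd.Series(labels, index=score_matrix.index, name="cp_cluster")


def core_promoter_enrichment(clusters: pd.Series, classes: pd.Series
                             ) -> pd.DataFrame:
    """log2 enrichment of each DHS class in each core promoter cluster,
    with one-sided Fisher tests per cell.

    *clusters* and *classes* must share their index (dhs, strand_role
    windows).  Enrichment = log2(class fraction in cluster / overall
    fraction in cluster).
    """
    df = pd.DataFrame({"cluster": clusters, "cls": classes}).dropna()
    n_total = len(df)
    rows = []
    for cluster, grp in df.groupby("cluster"):
        in_cluster = len(grp)
        for cls in df["cls"].unique():
            n_cls = int((df["cls"] == cls).sum())
            a = int((grp["cls"] == cls).sum())
            frac_cls = a / n_cls if n_cls else 0.0
            frac_all = in_cluster / n_total
            with np.errstate(divide="ignore"):
                enr = np.log2(frac_cls / frac_all) if frac_all > 0 else np.nan
            table = [[a, n_cls - a],
                     [in_cluster - a, n_total - n_cls - (in_cluster - a)]]
            p = fisher_exact(table, alternative="greater")[1]
            rows.append({"cluster": cluster, "class": cls, "n": a,
                         "log2_enrichment": enr, "fisher_p": float(p)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Downstream RNA-processing motif profiles
# --------------------------------------------------------------------------

def count_polya_hexamers(seq: str) -> int:
    """Exact degenerate AWTAAA matches (W = A or T) in *seq*."""
    seq = seq.upper()
    n = 0
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if (w[0] == "A" and w[1] in "AT" and w[2] == "T"
                and w[3] == "A" and w[4] == "A" and w[5] == "A"):
            n += 1
    return n


def _significant_hit_positions(motif: MotifModel, seq: str,
                               grid: np.ndarray, pvals: np.ndarray,
                               p_threshold: float) -> np.ndarray:
    scores = motif.scores_along(seq)
    if scores.size == 0:
        return np.array([], dtype=int)
    keep = np.array([score_pvalue(float(s), grid, pvals) < p_threshold
                     for s in scores])
    return np.flatnonzero(keep)


def downstream_processing_profile(
    genome: GenomeSequence,
    summits: pd.DataFrame,
    motif: str | MotifModel,
    background_positions: pd.DataFrame,
    max_window: int = 1000,
    step: int = 100,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Average predicted sites per bp downstream of summits, by growing
    window size, background subtracted.

    *motif* is either the string "polyA_AWTAAA" (exact degenerate
    hexamer match) or a MotifModel scanned at p < p_threshold.
    *summits* and *background_positions* need columns chrom, summit,
    strand.  Zero means the random-genomic-background hit frequency.
    """
    windows = np.arange(step, max_window + 1, step)

    def site_positions(seq: str) -> np.ndarray:
        if isinstance(motif, str):
            if motif != "polyA_AWTAAA":
                raise ValueError(f"unknown string motif {motif!r}")
            seq = seq.upper()
            return np.array([i for i in range(len(seq) - 5)
                             if count_polya_hexamers(seq[i:i + 6]) > 0],
                            dtype=int)
        return _significant_hit_positions(motif, seq, grid, pvals, p_threshold)

    if not isinstance(motif, str):
        grid, pvals = motif_pvalue_table(motif)

    def per_bp_rates(points: pd.DataFrame) -> np.ndarray:
        rates = np.zeros((len(points), len(windows)))
        for i, s in enumerate(points.itertuples(index=False)):
            if s.strand == "+":
                seq, _ = genome.fetch(s.chrom, int(s.summit),
                                      int(s.summit) + max_window, "+")
            else:
                # downstream on '-' runs toward smaller coordinates; the
                # reverse complement starts at the summit
                seq, _ = genome.fetch(s.chrom, int(s.summit) - max_window + 1,
                                      int(s.summit) + 1, "-")
            pos = site_positions(seq)
            for j, w in enumerate(windows):
                rates[i, j] = np.sum(pos < w) / w
        return rates.mean(axis=0) if len(points) else np.zeros(len(windows))

    fg = per_bp_rates(summits)
    bg = per_bp_rates(background_positions)
    return pd.DataFrame({
        "window": windows,
        "sites_per_bp": fg,
        "background_per_bp": bg,
        "above_background": fg - bg,
    })
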