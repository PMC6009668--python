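"""CAGE tag clustering: build tag clusters (TCs) from pooled CTSS data.

A TC is a contiguous strand-specific run of CAGE 5' end positions
treated as one TSS region, with a summit at its maximum-count position.
Clustering follows a summit-fraction strategy: same-strand positions
within a merge distance are single-linkage merged, wide clusters are
trimmed of low-count tails relative to the summit, and multimodal
clusters are split at deep valleys between local summits so that each
final TC carries a single dominant peak.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CTSS_KEY, GenomicInterval, Library, library_sizes

TC_COLUMNS = ["chrom", "start", "end", "strand", "summit", "count"]

# TC annotation categories
MRNA_TSS = "mRNA_TSS"
NCRNA_TSS = "ncRNA_TSS"
PROMPT = "PROMPT"
DISTAL = "distal"


def merge_positions(pos: np.ndarray, merge_dist: int) -> list[np.ndarray]:
    """Single-linkage merge of sorted positions: split where the gap to the
    next position exceeds *merge_dist*.  Returns index arrays per group."""
    breaks = np.flatnonzero(np.diff(pos) > merge_dist) + 1
    return np.split(np.arange(len(pos)), breaks)


def _local_maxima(counts: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus contribute their leftmost index."""
    n = len(counts)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok and counts[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def _trim_profile(counts: np.ndarray, trim_fraction: float
                  ) -> tuple[int, int]:
    """Offsets (lo, hi) of the profile kept after summit-fraction trimming.

    Edges are removed while the edge count is strictly below
    trim_fraction x summit count; ties with the threshold are retained.
    """
    summit_count = counts.max()
    threshold = trim_fraction * summit_count
    lo, hi = 0, len(counts)
    while lo < hi - 1 and counts[lo] < threshold:
        lo += 1
    while hi - 1 > lo and counts[hi - 1] < threshold:
        hi -= 1
    return lo, hi


def _split_points(counts: np.ndarray, valley_fraction: float) -> list[int]:
    """Split offsets: the leftmost minimum of every qualifying valley.

    A valley between adjacent local summits qualifies when its minimum
    count is strictly below valley_fraction x min(flanking summit counts).
    """
    maxima = _local_maxima(counts)
    splits = []
    for a, b in zip(maxima[:-1], maxima[1:]):
        valley = counts[a + 1:b]
        if valley.size == 0:
            continue
        vmin = valley.min()
        if vmin < valley_fraction * min(counts[a], counts[b]):
            splits.append(a + 1 + int(np.argmin(valley)))
    return splits


def _strip_zero_edges(counts: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    while lo < hi and counts[lo] == 0:
        lo += 1
    while hi > lo and counts[hi - 1] == 0:
        hi -= 1
    return lo, hi


def call_tag_clusters(ctss_pooled: pd.DataFrame, merge_dist: int = 20,
                      trim_fraction: float = 0.1,
                      valley_fraction: float = 0.1) -> pd.DataFrame:
    """Call tag clusters from a pooled CTSS table.

    Parameters
    ----------
    ctss_pooled
        DataFrame with columns chrom, pos, strand, count (pooled over all
        libraries).  A library-keyed table (multiple count columns) is
        rejected.
    merge_dist
        Same-strand positions with gaps <= merge_dist bp are
        single-linkage merged into one pre-cluster.
    trim_fraction
        Edge positions with pooled count strictly below
        trim_fraction x summit count are trimmed.
    valley_fraction
        Internal valleys strictly below valley_fraction x the smaller of
        the two flanking local summit counts trigger a split.

    Returns
    -------
    DataFrame with columns chrom, start, end, strand, summit, count,
    sorted and non-overlapping per strand.
    """
    extra = [c for c in ctss_pooled.columns if c not in CTSS_KEY + ["count"]]
    if extra or "count" not in ctss_pooled.columns:
        raise ValueError(
            "expected a pooled CTSS table with a single 'count' column; "
            "pool library columns with genomic_io.pool_ctss first"
        )
    if merge_dist < 1:
        raise ValueError("merge_dist must be >= 1")
    for name, frac in (("trim_fraction", trim_fraction),
                       ("valley_fraction", valley_fraction)):
        if not 0 < frac < 1:
            raise ValueError(f"{name} must be in (0,1)")
    rows = []
    data = ctss_pooled[ctss_pooled["count"] > 0]
    for (chrom, strand), grp in data.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        cnt = grp["count"].to_numpy()
        order = np.argsort(pos)
        pos, cnt = pos[order], cnt[order]
        for idx in merge_positions(pos, merge_dist):
            seg_pos, seg_cnt = pos[idx], cnt[idx]
            # dense profile over the pre-cluster span (zeros at gaps)
            span = np.zeros(seg_pos[-1] - seg_pos[0] + 1, dtype=np.int64)
            span[seg_pos - seg_pos[0]] = seg_cnt
            lo, hi = _trim_profile(span, trim_fraction)
            lo, hi = _strip_zero_edges(span, lo, hi)
            trimmed = span[lo:hi]
            bounds = [0] + _split_points(trimmed, valley_fraction) + [len(trimmed)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                a2, b2 = _strip_zero_edges(trimmed, a, b)
                child = trimmed[a2:b2]
                if child.size == 0 or child.sum() == 0:
                    continue
                start = int(seg_pos[0] + lo + a2)
                summit = start + int(np.argmax(child))
                rows.append((chrom, start, start + len(child), strand,
                             summit, int(child.sum())))
    tcs = pd.DataFrame(rows, columns=TC_COLUMNS)
    return tcs.sort_values(["chrom", "start", "strand"], ignore_index=True)


def quantify_and_normalize(tcs: pd.DataFrame, ctss: pd.DataFrame,
                           libraries: Sequence[Library]) -> pd.DataFrame:
    """Count CAGE 5' ends per TC per library and convert to TPM.

    Counts are per-library sums of CTSS counts in [start, end) on the TC
    strand; TPM normalizes by genome-wide library size scaled by 1e6.
    Adds columns count_<lib> and tpm_<lib>.
    """
    sizes = library_sizes(ctss, libraries)
    for lib in libraries:
        total = lib.total_mapped_tags or sizes[lib.id]
        if total <= 0:
            raise ValueError(f"library {lib.id!r} has zero total tags")
        sizes[lib.id] = total
    out = tcs.copy()
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    lib_ids = [lib.id for lib in libraries]
    for (chrom, strand), grp in ctss.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(grp["pos"].to_numpy())
        index[(chrom, strand)] = (
            grp["pos"].to_numpy()[order],
            grp[lib_ids].to_numpy()[order],
        )
    counts = np.zeros((len(tcs), len(lib_ids)), dtype=np.int64)
    for i, (chrom, start, end, strand) in enumerate(
            tcs[["chrom", "start", "end", "strand"]].itertuples(index=False)):
        if (chrom, strand) not in index:
            continue
        pos, mat = index[(chrom, strand)]
        a, b = np.searchsorted(pos, [start, end])
        counts[i] = mat[a:b].sum(axis=0)
    for j, lib_id in enumerate(lib_ids):
        out[f"count_{lib_id}"] = counts[:, j]
        out[f"tpm_{lib_id}"] = counts[:, j] / sizes[lib_id] * 1e6
    return out


def annotate_tcs(tcs: pd.DataFrame, gene_tss: Sequence[GenomicInterval],
                 max_dist: int = 250, prompt_dist: int = 500) -> pd.DataFrame:
    """Annotate TCs against gene TSSs.

    A TC is labelled mRNA_TSS / ncRNA_TSS when its summit is within
    *max_dist* bp of a same-strand gene TSS (nearest wins, ties to the
    smaller coordinate); otherwise PROMPT when an opposite-strand gene
    TSS lies within *prompt_dist* bp downstream of the summit in the
    TC's antisense orientation (the TC is upstream of and antisense to
    the gene); otherwise distal.
    """
    sense: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for g in gene_tss:
        if g.tss is None or g.strand not in "+-":
            continue
        bt = (g.biotype or "mRNA")
        sense.setdefault((g.chrom, g.strand), []).append((g.tss, bt))
    for key in sense:
        sense[key].sort()
    labels = []
    for chrom, strand, summit in tcs[["chrom", "strand", "summit"]].itertuples(
            index=False):
        label = DISTAL
        cands = sense.get((chrom, strand), [])
        if cands:
            tss_pos = [t for t, _ in cands]
            j = bisect_left(tss_pos, summit)
            best = None  # (distance, coordinate, biotype)
            for k in (j - 1, j):
                if 0 <= k < len(cands):
                    d = abs(cands[k][0] - summit)
                    cand = (d, cands[k][0], cands[k][1])
                    if d <= max_dist and (best is None or cand < best):
                        best = cand
            if best is not None:
                label = MRNA_TSS if best[2].lower().startswith("m") else NCRNA_TSS
        if label == DISTAL:
            # PROMPT: opposite-strand gene TSS downstream in the TC's
            # antisense orientation, i.e. the gene points away from the TC.
            anti = sense.get((chrom, "-" if strand == "+" else "+"), [])
            for tss, _ in anti:
                if strand == "+":
                    # gene on '-' strand, TC upstream of it => TC at larger
                    # coordinates: gene TSS within prompt_dist upstream of summit
                    ok = 0 < summit - tss <= prompt_dist
                else:
                    ok = 0 < tss - summit <= prompt_dist
                if ok:
                    label = PROMPT
                    break
        labels.append(label)
    out = tcs.copy()
    out["annotation"] = labels
    return out


def divergence_profile(tcs: pd.DataFrame, max_dist: int = 2000,
                       divergent_threshold: int = 500) -> pd.DataFrame:
    """Distance from each plus-strand TC summit to the nearest upstream,
    non-overlapping minus-strand TC summit.

    Returns one row per plus-strand TC with its distance (NaN when no
    upstream minus TC exists within *max_dist*) and a divergent flag at
    *divergent_threshold* bp.
    """
    plus = tcs[tcs["strand"] == "+"]
    minus = tcs[tcs["strand"] == "-"]
    rows = []
    for chrom, grp in plus.groupby("chrom", sort=True):
        m = minus[minus["chrom"] == chrom]
        m_summits = np.sort(m["summit"].to_numpy())
        m_ends = m["end"].to_numpy()[np.argsort(m["summit"].to_numpy())]
        for start, summit in grp[["start", "summit"]].itertuples(index=False):
            dist = np.nan
            # upstream of a plus TC = smaller coordinates; require the minus
            # TC to end at or before the plus TC start (non-overlapping)
            j = np.searchsorted(m_summits, summit)
            for k in range(j - 1, -1, -1):
                if m_ends[k] <= start:
                    d = summit - m_summits[k]
                    if d <= max_dist:
                        dist = float(d)
                    break
            rows.append((chrom, summit, dist))
    prof = pd.DataFrame(rows, columns=["chrom", "summit", "distance"])
    prof["divergent"] = prof["distance"] <= divergent_threshold
    return prof


def cumulative_divergent_fraction(profile: pd.DataFrame,
                                  distances: Sequence[int]) -> pd.Series:
    """Fraction of plus-strand TCs with an upstream minus TC within each
    distance; non-decreasing in distance."""
    n = len(profile)
    vals = {}
    d_arr = profile["distance"].to_numpy()
    for d in distances:
        vals[d] = float(np.sum(d_arr <= d)) / n if n else 0.0
    return pd.Series(vals)


def head_to_head_distance(summits: pd.DataFrame,
                          gene_tss: Sequence[GenomicInterval]) -> np.ndarray:
    """Per-element distance from a strand-aware summit to the closest
    upstream antisense gene TSS; inf when none exists on the chromosome."""
    from .genomic_io import nearest_upstream_antisense

    return nearest_upstream_antisense(summits, gene_tss)
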