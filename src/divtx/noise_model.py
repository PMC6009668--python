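"""CAGE genomic background noise estimation and replicate-support filtering.

Background noise is estimated empirically from "TSS-unlikely" loci:
random strand-specific windows placed outside open-chromatin sites and
annotated TSS neighbourhoods.  Per library, the noise threshold is a
high quantile of the summed tag counts over those windows; expression
must exceed it in a minimum number of replicates per condition to count
as real signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CONTROL, EXOSOME_KD, GenomicInterval, Library


@dataclass(frozen=True)
class NoiseThreshold:
    library_id: str
    window_width: int
    quantile: float
    count_threshold: int
    tpm_threshold: float


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _allowed_spans(chrom_lengths: dict[str, int],
                   exclusion: Sequence[GenomicInterval],
                   window_width: int) -> list[tuple[str, int, int]]:
    """Spans where a window of window_width fits entirely outside exclusions."""
    excl: dict[str, list[tuple[int, int]]] = {}
    for iv in exclusion:
        excl.setdefault(iv.chrom, []).append((iv.start, iv.end))
    spans = []
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for s, e in _merge_intervals(excl.get(chrom, [])) + [(length, length)]:
            if s - cursor >= window_width:
                spans.append((chrom, cursor, s))
            cursor = max(cursor, e)
    return spans


def estimate_noise_threshold(
    ctss: pd.DataFrame,
    libraries: Sequence[Library],
    exclusion: Sequence[GenomicInterval],
    chrom_lengths: dict[str, int],
    n_windows: int = 10000,
    window_width: int = 200,
    quantile: float = 0.999,
    seed: int = 1,
) -> dict[str, NoiseThreshold]:
    """Estimate a per-library background-count threshold.

    *n_windows* strand-specific windows of *window_width* bp are placed
    uniformly at random outside the exclusion regions; the threshold is
    the requested empirical quantile (upper/'higher' convention) of the
    per-window summed counts, per library.
    """
    if n_windows < 1000:
        raise ValueError("n_windows must be >= 1000")
    if not exclusion:
        raise ValueError("exclusion set must be non-empty")
    spans = _allowed_spans(chrom_lengths, exclusion, window_width)
    if not spans:
        raise ValueError("genome too small to place background windows")
    rng = np.random.default_rng(seed)
    weights = np.array([e - s - window_width + 1 for _, s, e in spans], float)
    weights /= weights.sum()
    span_idx = rng.choice(len(spans), size=n_windows, p=weights)
    strands = rng.choice(np.array(["+", "-"]), size=n_windows)
    lib_ids = [lib.id for lib in libraries]
    # per (chrom, strand) sorted position index with per-library cumsums
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), grp in ctss.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(grp["pos"].to_numpy())
        pos = grp["pos"].to_numpy()[order]
        mat = grp[lib_ids].to_numpy()[order]
        index[(chrom, strand)] = (pos, np.vstack([np.zeros(len(lib_ids)),
                                                  np.cumsum(mat, axis=0)]))
    sums = np.zeros((n_windows, len(lib_ids)))
    for w in range(n_windows):
        chrom, s, e = spans[span_idx[w]]
        start = int(rng.integers(s, e - window_width + 1))
        key = (chrom, strands[w])
        if key not in index:
            continue
        pos, csum = index[key]
        a, b = np.searchsorted(pos, [start, start + window_width])
        sums[w] = csum[b] - csum[a]
    totals = {lib.id: lib.total_mapped_tags or int(ctss[lib.id].sum())
              for lib in libraries}
    out = {}
    for j, lib in enumerate(libraries):
        thr = int(np.quantile(sums[:, j], quantile, method="higher"))
        out[lib.id] = NoiseThreshold(
            lib.id, window_width, quantile, thr,
            thr / totals[lib.id] * 1e6 if totals[lib.id] else 0.0,
        )
    return out


def thresholds_table(thresholds: dict[str, NoiseThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.library_id, t.window_width, t.quantile, t.count_threshold,
          t.tpm_threshold) for t in thresholds.values()],
        columns=["library_id", "window_width", "quantile",
                 "count_threshold", "tpm_threshold"],
    )


def _min_support(min_replicates: int, n: int) -> int:
    if n == 4:
        return min_replicates
    # proportional rule for non-standard replicate counts
    return math.ceil(min_replicates / 4 * n)


def filter_by_noise(
    expression: pd.DataFrame,
    thresholds: dict[str, NoiseThreshold],
    libraries: Sequence[Library],
    min_replicates: int = 2,
    use_tpm: bool = True,
) -> pd.DataFrame:
    """Condition-wise replicate-support filter.

    *expression* holds per-library TPM columns tpm_<lib> (or count_<lib>
    when use_tpm=False).  A row is kept in a condition iff its value is
    strictly above the library's threshold in at least *min_replicates*
    replicates of that condition.  ``keep_any`` flags rows passing in
    either condition.
    """
    by_cond: dict[str, list[Library]] = {CONTROL: [], EXOSOME_KD: []}
    for lib in libraries:
        by_cond[lib.condition].append(lib)
    out = pd.DataFrame(index=expression.index)
    for cond, libs in by_cond.items():
        need = _min_support(min_replicates, len(libs))
        passing = np.zeros(len(expression), dtype=int)
        for lib in libs:
            col = f"tpm_{lib.id}" if use_tpm else f"count_{lib.id}"
            thr = (thresholds[lib.id].tpm_threshold if use_tpm
                   else thresholds[lib.id].count_threshold)
            passing += (expression[col].to_numpy() > thr).astype(int)
        out[f"keep_{cond}"] = passing >= need
    out["keep_any"] = out[f"keep_{CONTROL}"] | out[f"keep_{EXOSOME_KD}"]
    out["keep_both"] = out[f"keep_{CONTROL}"] & out[f"keep_{EXOSOME_KD}"]
    return out


def dhs_transcribed_flags(
    strand_expression: dict[str, pd.DataFrame],
    thresholds: dict[str, NoiseThreshold],
    libraries: Sequence[Library],
    min_replicates: int = 2,
) -> pd.Series:
    """A DHS is called transcribed iff any strand is above threshold in at
    least *min_replicates* libraries of either condition.

    *strand_expression* maps strand -> per-library TPM table (tpm_<lib>).
    """
    any_keep = None
    for strand_df in strand_expression.values():
        flags = filter_by_noise(strand_df, thresholds, libraries,
                                min_replicates)["keep_any"]
        any_keep = flags if any_keep is None else (any_keep | flags)
    return any_keep
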