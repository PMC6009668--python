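"""STARR-seq enhancer potential and chromatin-mark integration at DHSs.

Enhancer potential is the log2 fold change of STARR-seq signal over
input at the signal summit inside a 401-bp window centered on the DHS
midpoint; a site is called active at a fold-change threshold (default
1.5, log2 scale).  Binary ChIP marks are summarized as per-class
presence proportions near CAGE summits and as distance-binned footprint
profiles with a randomized background band; quantitative signals are
related to per-DHS values through percentile-truncated binning plus
Spearman rank correlation on untruncated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, spearmanr

from .genomic_io import GenomicInterval, SignalTrack


@dataclass(frozen=True)
class EnhancerCall:
    dhs_id: str
    hkCP_lfc: float
    dCP_lfc: float
    active_hkCP: bool
    active_dCP: bool


def _summit_lfc(dhs: GenomicInterval, signal: SignalTrack, inp: SignalTrack,
                window: int, pseudo: float) -> float:
    half = window // 2
    mid = dhs.center
    pos, sig = signal.argmax_over(dhs.chrom, mid - half, mid + half + 1)
    inp_val = inp.value_at(dhs.chrom, pos)
    return float(np.log2((sig + pseudo) / (inp_val + pseudo)))


def starr_call(dhs: GenomicInterval, hk_signal: SignalTrack,
               dcp_signal: SignalTrack, input_track: SignalTrack,
               window: int = 401, threshold: float = 1.5,
               pseudo: float = 1.0) -> EnhancerCall:
    """Call housekeeping / developmental enhancer potential for one DHS.

    The summit is the leftmost argmax of the STARR signal within the
    *window*-bp region centered on the DHS midpoint; the call uses
    log2((signal+pseudo)/(input+pseudo)) at the summit.
    """
    hk = _summit_lfc(dhs, hk_signal, input_track, window, pseudo)
    dc = _summit_lfc(dhs, dcp_signal, input_track, window, pseudo)
    return EnhancerCall(dhs.id, hk, dc, hk >= threshold, dc >= threshold)


def starr_calls_table(dhss: Sequence[GenomicInterval],
                      hk_signal: SignalTrack, dcp_signal: SignalTrack,
                      input_track: SignalTrack, window: int = 401,
                      threshold: float = 1.5, pseudo: float = 1.0
                      ) -> pd.DataFrame:
    calls = [starr_call(d, hk_signal, dcp_signal, input_track, window,
                        threshold, pseudo) for d in dhss]
    return pd.DataFrame([c.__dict__ for c in calls])


STARR_CATEGORIES = ["hkCP_only", "dCP_only", "both", "inactive"]


def class_starr_enrichment(assignments: pd.DataFrame, calls: pd.DataFrame
                           ) -> pd.DataFrame:
    """Crosstab DHS class x STARR category with chi-squared tests.

    Categories: overlapping hkCP enhancers only, dCP only, both, or
    neither (inactive/distal).  Each class is tested against the rest.
    """
    merged = assignments.merge(calls, on="dhs_id")
    merged = merged[~merged["removed"]] if "removed" in merged else merged

    def category(row) -> str:
        if row.active_hkCP and row.active_dCP:
            return "both"
        if row.active_hkCP:
            return "hkCP_only"
        if row.active_dCP:
            return "dCP_only"
        return "inactive"

    merged["starr_category"] = [category(r) for r in merged.itertuples()]
    crosstab = pd.crosstab(merged["class"], merged["starr_category"])
    crosstab = crosstab.reindex(columns=STARR_CATEGORIES, fill_value=0)
    total = crosstab.sum()
    pvals = {}
    for cls in crosstab.index:
        observed = np.array([crosstab.loc[cls].to_numpy(),
                             (total - crosstab.loc[cls]).to_numpy()])
        observed = observed[:, observed.sum(axis=0) > 0]
        if observed.shape[1] < 2 or observed.sum(axis=1).min() == 0:
            pvals[cls] = np.nan
        else:
            pvals[cls] = float(chi2_contingency(observed)[1])
    crosstab["chi2_p_vs_rest"] = pd.Series(pvals)
    return crosstab


def fisher_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided"
               ) -> tuple[float, float]:
    """Odds ratio and p-value of a 2x2 table (scipy hypergeometric)."""
    odds, p = fisher_exact(np.asarray(table), alternative=alternative)
    return float(odds), float(p)


def binned_association(x: np.ndarray, y: np.ndarray, n_bins: int = 10,
                       pct_lo: float = 1.0, pct_hi: float = 99.0
                       ) -> tuple[pd.DataFrame, float, float]:
    """Percentile-truncated equal-width binning of y by x, plus Spearman
    rank correlation on the untruncated pairs.

    Returns (bin summary table, rho, p).  Rho is NaN when x is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.all(x == x[0]):
        rho, p = float("nan"), float("nan")
    else:
        rho, p = spearmanr(x, y)
    lo, hi = np.percentile(x, [pct_lo, pct_hi])
    keep = (x >= lo) & (x <= hi)
    xt, yt = x[keep], y[keep]
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(xt, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        yb = yt[idx == b]
        rows.append({
            "bin": b, "x_lo": edges[b], "x_hi": edges[b + 1], "n": len(yb),
            "y_median": float(np.median(yb)) if len(yb) else np.nan,
            "y_q1": float(np.percentile(yb, 25)) if len(yb) else np.nan,
            "y_q3": float(np.percentile(yb, 75)) if len(yb) else np.nan,
        })
    return pd.DataFrame(rows), float(rho), float(p)


# --------------------------------------------------------------------------
# Binary ChIP marks
# --------------------------------------------------------------------------

def _interval_index(marks: Sequence[GenomicInterval]
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in marks:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out[chrom] = (np.array([a for a, _ in ivs]),
                      np.array([b for _, b in ivs]))
    return out


def _any_overlap(index, chrom: str, start: int, end: int) -> bool:
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    i = np.searchsorted(starts, end, side="left")
    return bool((ends[:i] > start).any())


def mark_proportions(assignments: pd.DataFrame,
                     marks_by_name: dict[str, Sequence[GenomicInterval]],
                     summits: pd.DataFrame, flank: int = 100) -> pd.DataFrame:
    """Per-class proportion of DHSs with at least one mark interval
    overlapping [summit-flank, summit+flank] of the major CAGE summit.

    *summits* needs columns dhs_id, chrom, summit.
    """
    merged = assignments.merge(summits, on="dhs_id")
    merged = merged[~merged["removed"]] if "removed" in merged else merged
    out = {}
    for name, marks in marks_by_name.items():
        index = _interval_index(marks)
        present = [
            _any_overlap(index, r.chrom, int(r.summit) - flank,
                         int(r.summit) + flank + 1)
            for r in merged.itertuples()
        ]
        merged[f"present_{name}"] = present
        out[name] = merged.groupby("class")[f"present_{name}"].mean()
    return pd.DataFrame(out)


def footprint_profile(marks: Sequence[GenomicInterval],
                      summits: pd.DataFrame,
                      other_dhs: Sequence[GenomicInterval],
                      chrom_lengths: dict[str, int],
                      bin_size: int = 50, max_dist: int = 5000,
                      n_randomizations: int = 10, seed: int = 1
                      ) -> pd.DataFrame:
    """Distance-binned mean binary mark presence around summits with a
    randomized background band.

    Bins cover [-max_dist, max_dist) in *bin_size* steps; a bin is
    excluded for a site when it overlaps another DHS.  The background is
    the same statistic over *n_randomizations* uniform relocations of
    the mark intervals.
    """
    edges = np.arange(-max_dist, max_dist + bin_size, bin_size)
    n_bins = len(edges) - 1
    mark_lengths = np.array([len(m) for m in marks], dtype=int)
    rng = np.random.default_rng(seed)

    # per-site bin mask: a bin is valid unless it overlaps a *different* DHS
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in other_dhs:
        by_chrom.setdefault(d.chrom, []).append(d)
    masks = []
    for r in summits.itertuples(index=False):
        s = int(r.summit)
        own = getattr(r, "dhs_id", None)
        valid = np.ones(n_bins, dtype=bool)
        for d in by_chrom.get(r.chrom, []):
            if d.id == own:
                continue
            lo = np.searchsorted(edges, d.start - s, side="right") - 1
            hi = np.searchsorted(edges, d.end - s, side="left")
            valid[max(lo, 0):min(hi, n_bins)] = False
        masks.append(valid)
    mask_arr = np.array(masks) if masks else np.zeros((0, n_bins), bool)

    def profile_for(index) -> np.ndarray:
        hits = np.zeros(n_bins)
        valid = mask_arr.sum(axis=0).astype(float)
        for i, r in enumerate(summits.itertuples(index=False)):
            s = int(r.summit)
            for b in np.flatnonzero(mask_arr[i]):
                if _any_overlap(index, r.chrom, s + edges[b], s + edges[b + 1]):
                    hits[b] += 1
        with np.errstate(invalid="ignore"):
            return np.where(valid > 0, hits / np.maximum(valid, 1), np.nan)

    fg = profile_for(_interval_index(marks))
    backgrounds = []
    chroms = list(chrom_lengths)
    for _ in range(n_randomizations):
        rand_marks = []
        for length in mark_lengths:
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
            rand_marks.append(
                GenomicInterval(chrom, start, start + int(length))
            )
        backgrounds.append(profile_for(_interval_index(rand_marks)))
    bg = np.vstack(backgrounds)
    centers = (edges[:-1] + edges[1:]) // 2
    import warnings

    with warnings.catch_warnings():
        # masked bins are all-NaN across randomizations by construction
        warnings.simplefilter("ignore", RuntimeWarning)
        bg_mean = np.nanmean(bg, axis=0)
        bg_lo = np.nanmin(bg, axis=0)
        bg_hi = np.nanmax(bg, axis=0)
    return pd.DataFrame({
        "distance": centers,
        "presence": fg,
        "background_mean": bg_mean,
        "background_lo": bg_lo,
        "background_hi": bg_hi,
    })
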