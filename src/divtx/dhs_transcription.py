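"""Divergent transcription quantification anchored on DHSs.

Each DHS gets a pair of abutting 200-bp windows in divergent
orientation: the upstream window counts minus-strand tags, the
downstream window plus-strand tags.  The anchor between them is the
position (near the DHS center) that maximizes total divergent CAGE
coverage in exosome-knockdown data.  From the windows we derive
per-replicate strand expression (TPM), exosome sensitivity (how much
expression depends on exosome depletion), and transcriptional
directionality (strand imbalance), all on the knockdown-ascertained
major/minor strand assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CONTROL, EXOSOME_KD, GenomicInterval, Library


@dataclass(frozen=True)
class WindowPair:
    """Divergent quantification window pair anchored at a DHS."""

    dhs_id: str
    chrom: str
    anchor: int
    width: int  # L

    @property
    def upstream(self) -> tuple[int, int]:
        """Minus-strand window [anchor-L, anchor)."""
        return self.anchor - self.width, self.anchor

    @property
    def downstream(self) -> tuple[int, int]:
        """Plus-strand window [anchor, anchor+L)."""
        return self.anchor, self.anchor + self.width

    def window(self, strand: str) -> tuple[int, int]:
        return self.upstream if strand == "-" else self.downstream


class _StrandIndex:
    """Sorted position index with cumulative counts per (chrom, strand)."""

    def __init__(self, ctss: pd.DataFrame, count_cols: Sequence[str]):
        self.count_cols = list(count_cols)
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), grp in ctss.groupby(["chrom", "strand"],
                                                 sort=False):
            order = np.argsort(grp["pos"].to_numpy())
            pos = grp["pos"].to_numpy()[order]
            mat = grp[self.count_cols].to_numpy(dtype=float)[order]
            csum = np.vstack([np.zeros(mat.shape[1]), np.cumsum(mat, axis=0)])
            self._idx[(chrom, strand)] = (pos, csum)

    def window_sum(self, chrom: str, strand: str, start: int, end: int
                   ) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._idx:
            return np.zeros(len(self.count_cols))
        pos, csum = self._idx[key]
        a, b = np.searchsorted(pos, [start, end])
        return csum[b] - csum[a]

    def positions_counts(self, chrom: str, strand: str, start: int, end: int
                         ) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, strand)
        if key not in self._idx:
            return np.array([], dtype=int), np.zeros((0, len(self.count_cols)))
        pos, csum = self._idx[key]
        a, b = np.searchsorted(pos, [start, end])
        return pos[a:b], np.diff(csum[a:b + 1], axis=0)


def _best_anchor(idx: _StrandIndex, chrom: str, center: int, L: int,
                 radius: int, up_strand: str, down_strand: str
                 ) -> tuple[int, float]:
    """Anchor maximizing coverage of (up_strand upstream + down_strand
    downstream); ties to nearest center, then smaller coordinate."""
    best = None
    for anchor in range(center - radius, center + radius + 1):
        cov = float(idx.window_sum(chrom, up_strand, anchor - L, anchor).sum()
                    + idx.window_sum(chrom, down_strand, anchor,
                                     anchor + L).sum())
        key = (-cov, abs(anchor - center), anchor)
        if best is None or key < best[0]:
            best = (key, anchor, cov)
    return best[1], best[2]


def place_windows(dhs: GenomicInterval, ctss_pooled_kd: pd.DataFrame,
                  L: int = 200, search_radius: int = 100) -> WindowPair:
    """Place the divergent window pair for one DHS.

    The anchor is scanned over +/- search_radius around the DHS center;
    the chosen anchor maximizes minus-strand tags in the upstream window
    plus plus-strand tags in the downstream window (pooled knockdown
    counts).  Zero-coverage DHSs anchor at the center.
    """
    idx = _StrandIndex(ctss_pooled_kd, ["count"])
    anchor, cov = _best_anchor(idx, dhs.chrom, dhs.center, L, search_radius,
                               "-", "+")
    if cov == 0:
        anchor = dhs.center
    return WindowPair(dhs.id, dhs.chrom, anchor, L)


def place_windows_batch(dhss: Sequence[GenomicInterval],
                        ctss_pooled_kd: pd.DataFrame, L: int = 200,
                        search_radius: int = 100) -> list[WindowPair]:
    idx = _StrandIndex(ctss_pooled_kd, ["count"])
    pairs = []
    for dhs in dhss:
        anchor, cov = _best_anchor(idx, dhs.chrom, dhs.center, L,
                                   search_radius, "-", "+")
        if cov == 0:
            anchor = dhs.center
        pairs.append(WindowPair(dhs.id, dhs.chrom, anchor, L))
    return pairs


def detect_convergent(dhs: GenomicInterval, ctss_pooled_kd: pd.DataFrame,
                      L: int = 200, search_radius: int = 100) -> bool:
    """True iff the best convergent configuration (plus-strand upstream,
    minus-strand downstream) has strictly greater pooled-KD coverage than
    the best divergent configuration."""
    idx = _StrandIndex(ctss_pooled_kd, ["count"])
    _, div_cov = _best_anchor(idx, dhs.chrom, dhs.center, L, search_radius,
                              "-", "+")
    _, conv_cov = _best_anchor(idx, dhs.chrom, dhs.center, L, search_radius,
                               "+", "-")
    return conv_cov > div_cov


def exosome_sensitivity(control_tpm: float, kd_tpm: float) -> float:
    """Exosome sensitivity in [0, 1]: max(0, 1 - control/KD).

    0 means expression fully captured without knockdown (stable RNA);
    1 means expression only observed upon exosome depletion.  NaN when
    KD expression is zero (undefined).
    """
    if kd_tpm < 0 or control_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    if kd_tpm == 0:
        return float("nan")
    return max(0.0, 1.0 - control_tpm / kd_tpm)


def directionality_score(major_tpm_kd: float, minor_tpm_kd: float) -> float:
    """Transcriptional directionality in [0, 1]: (major-minor)/(major+minor)
    on knockdown expression; NaN when both strands are silent."""
    if major_tpm_kd < 0 or minor_tpm_kd < 0:
        raise ValueError("TPM values must be non-negative")
    total = major_tpm_kd + minor_tpm_kd
    if total == 0:
        return float("nan")
    return (major_tpm_kd - minor_tpm_kd) / total


def _strand_summit(idx: _StrandIndex, chrom: str, strand: str,
                   start: int, end: int) -> int | None:
    """Argmax pooled-count position in [start,end); ties break to the most
    upstream position relative to the strand."""
    pos, mat = idx.positions_counts(chrom, strand, start, end)
    if pos.size == 0:
        return None
    totals = mat.sum(axis=1)
    best = totals.max()
    if best <= 0:
        return None
    cands = pos[totals == best]
    return int(cands.min() if strand == "+" else cands.max())


def quantify_dhs(
    pairs: Sequence[WindowPair],
    ctss: pd.DataFrame,
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Quantify strand expression, major/minor assignment, per-replicate
    sensitivity and directionality for each DHS window pair.

    Returns one row per DHS with columns:
    dhs_id, chrom, anchor, major_strand, summit_major, summit_minor,
    tpm_{strand-role}_{cond}_{rep}, sens_major_{rep}, sens_minor_{rep},
    dir_{rep}, plus mean-based DHS-level scores sens_major, sens_minor,
    directionality.
    """
    lib_ids = [lib.id for lib in libraries]
    totals = {lib.id: lib.total_mapped_tags or int(ctss[lib.id].sum())
              for lib in libraries}
    for lib_id, t in totals.items():
        if t <= 0:
            raise ValueError(f"library {lib_id!r} has zero total tags")
    idx = _StrandIndex(ctss, lib_ids)
    kd_libs = [lib for lib in libraries if lib.condition == EXOSOME_KD]
    ctrl_libs = [lib for lib in libraries if lib.condition == CONTROL]
    kd_cols = [lib_ids.index(lib.id) for lib in kd_libs]

    rows = []
    for pair in pairs:
        strand_tpm: dict[str, np.ndarray] = {}
        for strand in "+-":
            start, end = pair.window(strand)
            counts = idx.window_sum(pair.chrom, strand, start, end)
            strand_tpm[strand] = np.array(
                [counts[j] / totals[lib_ids[j]] * 1e6
                 for j in range(len(lib_ids))]
            )
        kd_pooled = {s: strand_tpm[s][kd_cols].sum() for s in "+-"}
        major = "+" if kd_pooled["+"] >= kd_pooled["-"] else "-"
        minor = "-" if major == "+" else "+"
        row: dict[str, object] = {
            "dhs_id": pair.dhs_id, "chrom": pair.chrom, "anchor": pair.anchor,
            "major_strand": major,
        }
        for role, strand in (("major", major), ("minor", minor)):
            summit = _strand_summit(idx, pair.chrom, strand,
                                    *pair.window(strand))
            row[f"summit_{role}"] = summit
        tpm = {}
        for role, strand in (("major", major), ("minor", minor)):
            for lib in libraries:
                j = lib_ids.index(lib.id)
                tpm[(role, lib.condition, lib.replicate)] = strand_tpm[strand][j]
                row[f"tpm_{role}_{lib.condition}_{lib.replicate}"] = (
                    strand_tpm[strand][j]
                )
        # per-replicate scores pair replicate r of each condition
        reps = sorted({lib.replicate for lib in kd_libs})
        for r in reps:
            for role in ("major", "minor"):
                row[f"sens_{role}_{r}"] = exosome_sensitivity(
                    tpm.get((role, CONTROL, r), 0.0),
                    tpm.get((role, EXOSOME_KD, r), 0.0),
                )
            row[f"dir_{r}"] = directionality_score(
                tpm.get(("major", EXOSOME_KD, r), 0.0),
                tpm.get(("minor", EXOSOME_KD, r), 0.0),
            )
        # DHS-level scores from replicate means
        for role in ("major", "minor"):
            ctrl_mean = float(np.mean([tpm[(role, CONTROL, lib.replicate)]
                                       for lib in ctrl_libs]))
            kd_mean = float(np.mean([tpm[(role, EXOSOME_KD, lib.replicate)]
                                     for lib in kd_libs]))
            row[f"tpm_{role}_control_mean"] = ctrl_mean
            row[f"tpm_{role}_kd_mean"] = kd_mean
            row[f"sens_{role}"] = exosome_sensitivity(ctrl_mean, kd_mean)
        row["directionality"] = directionality_score(
            row["tpm_major_kd_mean"], row["tpm_minor_kd_mean"]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def strand_expression_tables(
    pairs: Sequence[WindowPair], ctss: pd.DataFrame,
    libraries: Sequence[Library],
) -> dict[str, pd.DataFrame]:
    """Per-strand per-library TPM tables (tpm_<lib> columns), one row per
    DHS, for the transcribed-DHS noise filter."""
    lib_ids = [lib.id for lib in libraries]
    totals = {lib.id: lib.total_mapped_tags or int(ctss[lib.id].sum())
              for lib in libraries}
    idx = _StrandIndex(ctss, lib_ids)
    out = {}
    for strand in "+-":
        rows = []
        for pair in pairs:
            counts = idx.window_sum(pair.chrom, strand, *pair.window(strand))
            rows.append({f"tpm_{lib_ids[j]}": counts[j] / totals[lib_ids[j]] * 1e6
                         for j in range(len(lib_ids))})
        df = pd.DataFrame(rows)
        df.insert(0, "dhs_id", [p.dhs_id for p in pairs])
        out[strand] = df
    return out
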