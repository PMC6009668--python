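"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are 0-based half-open internally (BED convention); GTF
records are converted on read.  CTSS (CAGE transcription start site)
tables are pandas DataFrames keyed by (chrom, pos, strand) with one
integer count column per library.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CTSS_KEY = ["chrom", "pos", "strand"]

CONTROL = "control"
EXOSOME_KD = "exosomeKD"


class ParseError(ValueError):
    """Malformed input line; carries the file and line number."""


@dataclass(frozen=True)
class Library:
    """One CAGE sequencing library (condition x replicate)."""

    id: str
    condition: str  # {control, exosomeKD}
    replicate: int  # 1..4
    total_mapped_tags: int = 0

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, EXOSOME_KD):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.total_mapped_tags < 0:
            raise ValueError("total_mapped_tags must be non-negative")


@dataclass
class GenomicInterval:
    """0-based half-open interval with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = "."
    score: float | None = None
    tss: int | None = None  # strand-aware TSS point for gene records
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.tss is None and self.strand in "+-":
            self.tss = self.start if self.strand == "+" else self.end - 1

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# CTSS tables
# ---------------------------------------------------------------------------

def empty_ctss(library_ids: Sequence[str]) -> pd.DataFrame:
    cols = {c: pd.Series(dtype=t) for c, t in
            [("chrom", str), ("pos", np.int64), ("strand", str)]}
    df = pd.DataFrame(cols)
    for lib in library_ids:
        df[lib] = pd.Series(dtype=np.int64)
    return df


def _read_ctss_bed6(path: str, library_id: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
                count = int(parts[4])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count {count}")
            if end != start + 1:
                raise ParseError(
                    f"{path}:{lineno}: CTSS record must be single-base"
                )
            if parts[5] not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            rows.append((parts[0], start, parts[5], count))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", library_id])
    if df.empty:
        return empty_ctss([library_id])
    return df


def read_ctss(paths, libraries: Sequence[Library]) -> pd.DataFrame:
    """Read and merge per-library CTSS BED6 files into one count table.

    Parameters
    ----------
    paths
        Either a mapping {library_id: path} or a sequence of paths in the
        same order as *libraries*.
    libraries
        The library definitions; every library gets a column, zero-filled
        where a position is absent from its file.
    """
    if not isinstance(paths, dict):
        paths = {lib.id: p for lib, p in zip(libraries, paths)}
    lib_ids = [lib.id for lib in libraries]
    frames = []
    for lib_id in lib_ids:
        if lib_id not in paths:
            raise ValueError(f"no CTSS path for library {lib_id!r}")
        frames.append(
            _read_ctss_bed6(paths[lib_id], lib_id).set_index(CTSS_KEY)
        )
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    merged = merged.reset_index().sort_values(CTSS_KEY, ignore_index=True)
    if merged.duplicated(CTSS_KEY).any():
        raise ValueError("duplicate (chrom,pos,strand) after merge")
    return merged[CTSS_KEY + lib_ids]


def pool_ctss(ctss: pd.DataFrame, library_ids: Sequence[str] | None = None
              ) -> pd.DataFrame:
    """Sum counts over libraries into a single 'count' column."""
    if library_ids is None:
        library_ids = [c for c in ctss.columns if c not in CTSS_KEY]
    out = ctss[CTSS_KEY].copy()
    out["count"] = ctss[list(library_ids)].sum(axis=1).astype(np.int64)
    return out


def write_ctss(ctss: pd.DataFrame, directory: str,
               libraries: Sequence[Library]) -> dict[str, str]:
    """Write one BED6 per library (score = count); returns id -> path."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for lib in libraries:
        path = os.path.join(directory, f"ctss_{lib.id}.bed")
        sub = ctss.loc[ctss[lib.id] > 0, CTSS_KEY + [lib.id]]
        with open(path, "w") as fh:
            for chrom, pos, strand, count in sub.itertuples(index=False):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t{count}\t{strand}\n")
        paths[lib.id] = path
    return paths


def library_sizes(ctss: pd.DataFrame, libraries: Sequence[Library]
                  ) -> dict[str, int]:
    """Genome-wide tag total per library (the TPM denominator)."""
    return {lib.id: int(ctss[lib.id].sum()) for lib in libraries}


# ---------------------------------------------------------------------------
# Library manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> tuple[list[Library], dict[str, str]]:
    """Read a TSV manifest: columns file, id, condition, replicate.

    Paths are resolved relative to the manifest's directory.
    Returns (libraries, {library_id: ctss_path}).
    """
    base = os.path.dirname(os.path.abspath(path))
    df = pd.read_csv(path, sep="\t")
    required = {"file", "id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"manifest missing columns {required - set(df.columns)}")
    libs, paths = [], {}
    for row in df.itertuples(index=False):
        libs.append(Library(str(row.id), str(row.condition), int(row.replicate)))
        p = str(row.file)
        paths[str(row.id)] = p if os.path.isabs(p) else os.path.join(base, p)
    return libs, paths


def write_manifest(path: str, libraries: Sequence[Library],
                   files: dict[str, str]) -> None:
    base = os.path.dirname(os.path.abspath(path))
    with open(path, "w") as fh:
        fh.write("file\tid\tcondition\treplicate\n")
        for lib in libraries:
            rel = os.path.relpath(files[lib.id], base)
            fh.write(f"{rel}\t{lib.id}\t{lib.condition}\t{lib.replicate}\n")


# ---------------------------------------------------------------------------
# Interval formats
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field_ in attr.rstrip(";").split(";"):
        field_ = field_.strip()
        if not field_:
            continue
        key, _, value = field_.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_intervals(path: str, kind: str) -> list[GenomicInterval]:
    """Read intervals from BED3/BED6/BED12 or GTF (gene records).

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Gene records (BED6/BED12/GTF) carry a strand-aware TSS point:
    start for '+', end-1 for '-'.  A biotype may be encoded in the BED
    name field as "name|biotype".
    """
    if kind not in ("bed3", "bed6", "bed12", "gtf"):
        raise ValueError(f"unknown kind {kind!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if kind == "gtf":
                    if len(parts) < 9:
                        raise ParseError(f"{path}:{lineno}: short GTF line")
                    if parts[2] != "gene":
                        continue
                    start, end = int(parts[3]) - 1, int(parts[4])
                    strand = parts[6]
                    attrs = _parse_gtf_attributes(parts[8])
                    iv = GenomicInterval(
                        parts[0], start, end, strand,
                        id=attrs.get("gene_id", "."),
                        biotype=attrs.get("gene_biotype", attrs.get("biotype")),
                    )
                else:
                    n = {"bed3": 3, "bed6": 6, "bed12": 12}[kind]
                    if len(parts) < n:
                        raise ParseError(
                            f"{path}:{lineno}: expected >={n} fields"
                        )
                    start, end = int(parts[1]), int(parts[2])
                    strand = parts[5] if n >= 6 else "."
                    name = parts[3] if n >= 6 else "."
                    base_name, _, biotype = name.partition("|")
                    score = float(parts[4]) if n >= 6 and parts[4] != "." else None
                    iv = GenomicInterval(
                        parts[0], start, end, strand,
                        id=base_name, score=score, biotype=biotype or None,
                    )
            except ParseError:
                raise
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            if iv.strand in "+-":
                iv.tss = iv.start if iv.strand == "+" else iv.end - 1
            intervals.append(iv)
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED6 ('name|biotype' when a biotype is set)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.id if iv.biotype is None else f"{iv.id}|{iv.biotype}"
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Quantitative signal tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Per-base signal accessor over sorted, non-overlapping spans.

    Queries return 0 outside covered spans.
    """

    # per chromosome: (starts, ends, values) as numpy arrays, start-sorted
    spans: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_spans(cls, records: Iterable[tuple[str, int, int, float]]
                   ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        spans = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                if values[i] != values[i + 1]:
                    raise ValueError(
                        f"overlapping spans with conflicting values on {chrom} "
                        f"near {starts[i + 1]}"
                    )
            spans[chrom] = (starts, ends, values)
        return cls(spans)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.spans:
            return 0.0
        starts, ends, values = self.spans[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self.spans or end <= start:
            return out
        starts, ends, values = self.spans[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a, b = max(starts[i], start), min(ends[i], end)
            if a < b:
                out[a - start:b - start] = values[i]
        return out

    def max_over(self, chrom: str, start: int, end: int) -> float:
        vals = self.values(chrom, start, end)
        return float(vals.max()) if vals.size else 0.0

    def argmax_over(self, chrom: str, start: int, end: int) -> tuple[int, float]:
        """Leftmost position of the maximum value over [start, end)."""
        vals = self.values(chrom, start, end)
        i = int(np.argmax(vals))
        return start + i, float(vals[i])


def read_signal_track(path: str) -> SignalTrack:
    """Read a bedGraph or fixed/variable-step wiggle file."""
    records: list[tuple[str, int, int, float]] = []
    mode = "bedgraph"
    chrom, step, span, pos = "", 1, 1, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "fixed", opts["chrom"]
                pos = int(opts["start"]) - 1  # wiggle is 1-based
                step = int(opts.get("step", 1))
                span = int(opts.get("span", 1))
                continue
            if line.startswith("variableStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "variable", opts["chrom"]
                span = int(opts.get("span", 1))
                continue
            parts = line.split()
            try:
                if mode == "bedgraph":
                    records.append(
                        (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                    )
                elif mode == "fixed":
                    records.append((chrom, pos, pos + span, float(parts[0])))
                    pos += step
                else:  # variable
                    p = int(parts[0]) - 1
                    records.append((chrom, p, p + span, float(parts[1])))
            except (ValueError, IndexError) as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
    return SignalTrack.from_spans(records)


def write_bedgraph(track_values: Iterable[tuple[str, int, int, float]],
                   path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track_values:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Genome sequence access
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InMemoryGenome:
    """Mutable in-memory genome with the same access interface as
    :class:`GenomeSequence`; used by the synthetic-data generator."""

    def __init__(self, sequences: dict[str, str]):
        self._seq = {c: bytearray(s.encode()) for c, s in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seq)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def plant(self, chrom: str, pos: int, seq: str) -> None:
        """Overwrite genome sequence at [pos, pos+len(seq))."""
        if pos < 0 or pos + len(seq) > len(self._seq[chrom]):
            raise ValueError(f"plant outside {chrom}: {pos}+{len(seq)}")
        self._seq[chrom][pos:pos + len(seq)] = seq.upper().encode()

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+"
              ) -> tuple[str, bool]:
        length = len(self._seq[chrom])
        a, b = max(0, start), min(end, length)
        truncated = a != start or b != end
        seq = self._seq[chrom][a:b].decode() if b > a else ""
        if strand == "-":
            seq = revcomp(seq)
        return seq, truncated

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seq.items():
                fh.write(f">{chrom}\n")
                s = seq.decode()
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")


class GenomeSequence:
    """Strand-aware window extraction over a FASTA genome (pyfaidx)."""

    def __init__(self, path: str):
        from pyfaidx import Fasta

        self._fasta = Fasta(path, as_raw=True, sequence_always_upper=True)

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+"
              ) -> tuple[str, bool]:
        """Sequence of [start, end) on *strand*; truncates at contig edges.

        Returns (sequence, truncated_flag).  Minus-strand sequences are
        reverse-complemented (5'->3' on the requested strand).
        """
        length = self.chrom_length(chrom)
        a, b = max(0, start), min(end, length)
        truncated = a != start or b != end
        seq = str(self._fasta[chrom][a:b]) if b > a else ""
        if strand == "-":
            seq = revcomp(seq)
        return seq, truncated


# ---------------------------------------------------------------------------
# Generic table output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a DataFrame as TSV (header always present)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def nearest_upstream_antisense(summits: pd.DataFrame,
                               gene_tss: Sequence[GenomicInterval]
                               ) -> np.ndarray:
    """Distance from each strand-aware summit to the closest upstream
    antisense gene TSS (head-to-head composition); inf when none exists.

    *summits* needs columns chrom, summit, strand.
    """
    by_chrom_strand: dict[tuple[str, str], list[int]] = {}
    for g in gene_tss:
        if g.tss is None or g.strand not in "+-":
            continue
        by_chrom_strand.setdefault((g.chrom, g.strand), []).append(g.tss)
    for key in by_chrom_strand:
        by_chrom_strand[key].sort()
    out = np.full(len(summits), np.inf)
    for i, (chrom, summit, strand) in enumerate(
            summits[["chrom", "summit", "strand"]].itertuples(index=False)):
        anti = "-" if strand == "+" else "+"
        tss_list = by_chrom_strand.get((chrom, anti), [])
        if not tss_list:
            continue
        if strand == "+":  # upstream = smaller coordinates
            j = bisect_right(tss_list, summit - 1)
            if j > 0:
                out[i] = summit - tss_list[j - 1]
        else:  # upstream = larger coordinates
            j = bisect_right(tss_list, summit)
            if j < len(tss_list):
                out[i] = tss_list[j] - summit
    return out
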