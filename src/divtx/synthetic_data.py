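"""Fully synthetic datasets with planted regulatory-element classes.

The generator emulates the study design end to end: a random genome, a
set of DHSs laid out inside TADs, 4 control + 4 exosome-knockdown CAGE
replicates with negative-binomial counts piled around planted divergent
summits, Poisson background tags at TSS-unlikely positions, gene
annotation, core-promoter and RNA-processing motifs written into the
genome sequence, STARR-seq signal/input tracks coupled to expression
and class, TADs with planted class co-localization, and a
machine-readable truth table.

Default class parameters (mean knockdown TPM on the major/minor strand
and major/minor exosome sensitivity) mirror the archetypes the six
classes represent: strongly expressed stable promoters (with or without
a PROMPT on the minor strand), balanced stable divergent promoters, and
three flavors of lowly expressed exosome-sensitive (eRNA-like)
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dhs_classification import (
    ALL_CLASSES,
    BI_STABLE,
    INTER_BI_UNSTABLE,
    STABLE_CLASSES,
    UNI_STABLE,
    UNI_STABLE_PROMPT,
    WEAK_BI_UNSTABLE,
    WEAK_UNI_UNSTABLE,
)
from .genomic_io import (
    CONTROL,
    EXOSOME_KD,
    GenomicInterval,
    InMemoryGenome,
    Library,
    SignalTrack,
    revcomp,
    write_bedgraph,
    write_ctss,
    write_intervals,
    write_manifest,
)
from .sequence_elements import CORE_PROMOTER_CONSENSUS, IUPAC

# planted motif placements: (motif name, offset rel. to summit, plant rate)
_STABLE_MAJOR_MOTIFS = (("Ohler1", -1, 0.6), ("DRE", -35, 0.5), ("Inr", 0, 0.4))
_UNSTABLE_MAJOR_MOTIFS = (("Trl", -25, 0.6), ("Inr", 0, 0.3))

DONOR_CONSENSUS = "CAGGTAAGT"
POLYA_SITES = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class ClassParams:
    """Per-class planted expression, stability and coupling parameters."""

    name: str
    tpm_major: float
    tpm_minor: float
    sens_major: float
    sens_minor: float
    motifs_major: tuple = ()
    motifs_minor: tuple = ()
    five_ss_rate_major: float = 0.0
    five_ss_rate_minor: float = 0.0
    polya_rate_major: float = 0.0
    polya_rate_minor: float = 0.0
    dcp_lfc_mean: float = 0.3
    gene_major: bool = False
    gene_minor: bool = False
    head_to_head_frac: float = 0.0


DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    UNI_STABLE: ClassParams(
        UNI_STABLE, 50.0, 0.2, 0.1, 0.8,
        motifs_major=_STABLE_MAJOR_MOTIFS,
        five_ss_rate_major=0.8, polya_rate_major=0.1, polya_rate_minor=0.6,
        dcp_lfc_mean=0.3, gene_major=True, head_to_head_frac=0.5,
    ),
    UNI_STABLE_PROMPT: ClassParams(
        UNI_STABLE_PROMPT, 50.0, 2.0, 0.1, 0.8,
        motifs_major=(("Ohler1", -1, 0.6), ("Inr", 0, 0.4)),
        motifs_minor=(("Trl", -25, 0.5),),
        five_ss_rate_major=0.8, polya_rate_major=0.1, polya_rate_minor=0.7,
        dcp_lfc_mean=0.3, gene_major=True,
    ),
    BI_STABLE: ClassParams(
        BI_STABLE, 40.0, 25.0, 0.1, 0.15,
        motifs_major=_STABLE_MAJOR_MOTIFS,
        motifs_minor=(("Ohler1", -1, 0.5), ("DRE", -35, 0.4)),
        five_ss_rate_major=0.7, five_ss_rate_minor=0.7,
        polya_rate_major=0.1, polya_rate_minor=0.1,
        dcp_lfc_mean=0.3, gene_major=True, gene_minor=True,
    ),
    WEAK_BI_UNSTABLE: ClassParams(
        WEAK_BI_UNSTABLE, 2.0, 1.5, 0.8, 0.85,
        motifs_major=_UNSTABLE_MAJOR_MOTIFS,
        motifs_minor=(("Trl", -25, 0.3),),
        polya_rate_major=0.7, polya_rate_minor=0.7,
        dcp_lfc_mean=2.2,
    ),
    INTER_BI_UNSTABLE: ClassParams(
        INTER_BI_UNSTABLE, 6.0, 2.0, 0.7, 0.8,
        motifs_major=_UNSTABLE_MAJOR_MOTIFS,
        motifs_minor=(("Trl", -25, 0.3),),
        polya_rate_major=0.7, polya_rate_minor=0.7,
        dcp_lfc_mean=2.2,
    ),
    WEAK_UNI_UNSTABLE: ClassParams(
        WEAK_UNI_UNSTABLE, 3.0, 0.1, 0.8, 0.8,
        motifs_major=(("Trl", -25, 0.4), ("Inr", 0, 0.3)),
        polya_rate_major=0.7,
        dcp_lfc_mean=0.8,
    ),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    Library depth is tags_per_tpm x 1e6 mapped tags (default 1e7, a
    desk-scale stand-in for deeply sequenced CAGE libraries); filler
    gene promoters absorb the library mass not carried by the planted
    DHSs so that planted counts convert to the configured TPM values.
    """

    n_per_class: int = 100
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    chroms: tuple[str, ...] = ("chr2L", "chr3R")
    dhs_width: int = 300
    spacing: int = 4000
    margin: int = 20000
    tags_per_tpm: float = 10.0     # library depth / 1e6
    nb_size: float = 100.0         # NB dispersion (replicates concordant)
    noise_rate_per_bp: float = 0.005   # background tags per bp per library
    profile_halfwidth: int = 10
    profile_decay: float = 0.6     # geometric tag pile decay around summits
    summit_offset: int = 25        # planted summit distance from the anchor
    n_filler: int = 60
    filler_sens: float = 0.05
    gene_length: int = 1000
    tad_slots: tuple[int, int] = (3, 6)     # DHSs per TAD (inclusive range)
    tad_coupling: float = 0.8      # P(slot superclass == TAD archetype)
    between_tad_rate: float = 0.15
    interaction_rate: float = 0.7
    hk_lfc_intercept: float = 0.25
    hk_lfc_slope: float = 0.55
    hk_lfc_sd: float = 0.5
    dcp_lfc_sd: float = 0.6
    starr_base: float = 31.0
    n_replicates: int = 4


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    libraries: list[Library]
    ctss: pd.DataFrame
    dhss: list[GenomicInterval]
    genes: list[GenomicInterval]
    tads: list[GenomicInterval]
    interactions: list[tuple[GenomicInterval, GenomicInterval]]
    starr: dict[str, SignalTrack]
    genome: InMemoryGenome
    chrom_lengths: dict[str, int]
    truth: pd.DataFrame
    truth_motifs: pd.DataFrame

    def write(self, out_dir: str) -> dict[str, str]:
        """Emit the full file bundle; returns name -> path."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        ctss_paths = write_ctss(self.ctss, out_dir, self.libraries)
        manifest = os.path.join(out_dir, "manifest.tsv")
        write_manifest(manifest, self.libraries, ctss_paths)
        paths["manifest"] = manifest
        for name, ivs in (("dhs", self.dhss), ("genes", self.genes),
                          ("tads", self.tads)):
            p = os.path.join(out_dir, f"{name}.bed")
            write_intervals(ivs, p)
            paths[name] = p
        p = os.path.join(out_dir, "interactions.bedpe")
        with open(p, "w") as fh:
            for a, b in self.interactions:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}"
                         f"\t{b.chrom}\t{b.start}\t{b.end}\n")
        paths["interactions"] = p
        for name in ("hkCP", "dCP", "input"):
            p = os.path.join(out_dir, f"starr_{name}.bedGraph")
            spans = self.starr[name].spans
            write_bedgraph(
                ((chrom, int(s), int(e), float(v))
                 for chrom in sorted(spans)
                 for s, e, v in zip(*spans[chrom])),
                p,
            )
            paths[f"starr_{name}"] = p
        p = os.path.join(out_dir, "genome.fa")
        self.genome.to_fasta(p)
        paths["genome"] = p
        p = os.path.join(out_dir, "truth.tsv")
        self.truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p
        p = os.path.join(out_dir, "truth_motifs.tsv")
        self.truth_motifs.to_csv(p, sep="\t", index=False)
        paths["truth_motifs"] = p
        return paths


def _nb_draw(rng: np.random.Generator, mean: float, size: float) -> int:
    if mean <= 0:
        return 0
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _realize_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in consensus)


def _plant_oriented(genome: InMemoryGenome, chrom: str, summit: int,
                    strand: str, offset: int, seq: str) -> None:
    """Plant *seq* so that it reads 5'->3' on *strand* starting at
    TSS-relative *offset* from the summit."""
    L = len(seq)
    if strand == "+":
        genome.plant(chrom, summit + offset, seq)
    else:
        genome.plant(chrom, summit - offset - L + 1, revcomp(seq))


def default_libraries(n_replicates: int = 4) -> list[Library]:
    libs = []
    for cond, tag in ((CONTROL, "ctrl"), (EXOSOME_KD, "kd")):
        for r in range(1, n_replicates + 1):
            libs.append(Library(f"{tag}{r}", cond, r))
    return libs


@dataclass
class _PlannedDhs:
    dhs_id: str
    chrom: str
    center: int
    cls: str
    major_strand: str
    tad_id: str  # or BETWEEN


def _plan_layout(config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[list[_PlannedDhs], list[GenomicInterval],
                            dict[str, int], dict[str, int]]:
    """Assign classes to TAD slots with planted co-localization and lay
    DHSs out along the chromosomes.  Returns (planned DHSs, TADs,
    chromosome lengths, filler zone start per chromosome)."""
    remaining = {c: config.n_per_class for c in ALL_CLASSES}
    total = sum(remaining.values())
    planned: list[_PlannedDhs] = []
    tads: list[GenomicInterval] = []
    cursors = {c: config.margin for c in config.chroms}
    per_chrom_budget = {c: total // len(config.chroms) for c in config.chroms}
    per_chrom_budget[config.chroms[-1]] += total % len(config.chroms)

    def draw_class(superclass: str | None) -> str | None:
        if superclass == "stable":
            pool = [c for c in STABLE_CLASSES if remaining[c] > 0]
        elif superclass == "unstable":
            pool = [c for c in ALL_CLASSES if c not in STABLE_CLASSES
                    and remaining[c] > 0]
        else:
            pool = [c for c in ALL_CLASSES if remaining[c] > 0]
        if not pool:
            pool = [c for c in ALL_CLASSES if remaining[c] > 0]
        if not pool:
            return None
        weights = np.array([remaining[c] for c in pool], dtype=float)
        cls = pool[rng.choice(len(pool), p=weights / weights.sum())]
        remaining[cls] -= 1
        return cls

    dhs_counter = 0
    tad_counter = 0
    for chrom in config.chroms:
        placed = 0
        while placed < per_chrom_budget[chrom] and sum(remaining.values()) > 0:
            n_slots = int(rng.integers(config.tad_slots[0],
                                       config.tad_slots[1] + 1))
            n_slots = min(n_slots, per_chrom_budget[chrom] - placed,
                          sum(remaining.values()))
            if n_slots == 0:
                break
            stable_left = sum(remaining[c] for c in STABLE_CLASSES)
            p_stable = stable_left / max(sum(remaining.values()), 1)
            archetype = "stable" if rng.random() < p_stable else "unstable"
            slot_classes = []
            for _ in range(n_slots):
                # with prob. coupling the slot follows the TAD archetype;
                # otherwise it draws from the full pool, so coupling=0
                # makes classes independent of TADs (the null layout)
                want = archetype if rng.random() < config.tad_coupling \
                    else None
                cls = draw_class(want)
                if cls is None:
                    break
                slot_classes.append(cls)
            if not slot_classes:
                break
            # stable classes prefer boundary-proximal (edge) slots
            order = sorted(range(len(slot_classes)),
                           key=lambda i: slot_classes[i] in STABLE_CLASSES,
                           reverse=True)
            arranged = [None] * len(slot_classes)
            edges = ([0, len(slot_classes) - 1]
                     + list(range(1, len(slot_classes) - 1)))
            seen = []
            for pos in edges:
                if pos not in seen:
                    seen.append(pos)
            for slot, i in zip(seen, order):
                arranged[slot] = slot_classes[i]
            first_center = cursors[chrom] + 1500
            centers = [first_center + i * config.spacing
                       for i in range(len(arranged))]
            tad_id = f"tad_{tad_counter:04d}"
            tad_counter += 1
            tads.append(GenomicInterval(
                chrom, centers[0] - 800, centers[-1] + 800, id=tad_id))
            for c_pos, cls in zip(centers, arranged):
                planned.append(_PlannedDhs(
                    f"dhs_{dhs_counter:04d}", chrom, c_pos, cls,
                    "+" if rng.random() < 0.5 else "-", tad_id))
                dhs_counter += 1
                placed += 1
            cursors[chrom] = centers[-1] + 800 + 3000
            # occasionally a (preferentially stable) DHS between TADs
            if (rng.random() < config.between_tad_rate
                    and placed < per_chrom_budget[chrom]):
                want = "stable" if rng.random() < 0.8 else "unstable"
                cls = draw_class(want)
                if cls is not None:
                    center = cursors[chrom] + 1500
                    planned.append(_PlannedDhs(
                        f"dhs_{dhs_counter:04d}", chrom, center, cls,
                        "+" if rng.random() < 0.5 else "-", "BETWEEN"))
                    dhs_counter += 1
                    placed += 1
                    cursors[chrom] = center + 1500 + 1500
    filler_zone = {c: cursors[c] + 5000 for c in config.chroms}
    chrom_lengths = {
        c: filler_zone[c]
        + (config.n_filler // len(config.chroms) + 1) * config.spacing
        + config.margin
        for c in config.chroms
    }
    return planned, tads, chrom_lengths, filler_zone


def generate_dataset(config: SimulationConfig | None = None, seed: int = 1
                     ) -> SyntheticDataset:
    """Generate the full synthetic bundle (in memory; .write() emits files).

    Deterministic under *seed*: the same seed yields a byte-identical
    file bundle.
    """
    config = config or SimulationConfig()
    for cp in config.class_params.values():
        if not 0 <= cp.sens_major <= 1 or not 0 <= cp.sens_minor <= 1:
            raise ValueError(f"{cp.name}: sensitivities must be in [0,1]")
        if cp.tpm_major <= 0:
            raise ValueError(f"{cp.name}: mean TPM must be positive")
        for m, off, _ in cp.motifs_major + cp.motifs_minor:
            if abs(off) + len(CORE_PROMOTER_CONSENSUS[m]) > 50:
                raise ValueError(f"{cp.name}: motif {m} exceeds the scan flank")
    rng = np.random.default_rng(seed)
    libraries = default_libraries(config.n_replicates)
    lib_ids = [lib.id for lib in libraries]
    planned, tads, chrom_lengths, filler_zone = _plan_layout(config, rng)
    S = config.tags_per_tpm

    counts: dict[tuple[str, int, str], np.ndarray] = {}
    half = config.profile_halfwidth
    profile_offsets = np.arange(-half, half + 1)
    weights = config.profile_decay ** np.abs(profile_offsets)
    weights = weights / weights.sum()

    def deposit(chrom: str, summit: int, strand: str, lib_idx: int,
                n_tags: int) -> None:
        if n_tags <= 0:
            return
        spread = rng.multinomial(n_tags, weights)
        for off, n in zip(profile_offsets, spread):
            if n == 0:
                continue
            key = (chrom, summit + int(off), strand)
            if key not in counts:
                counts[key] = np.zeros(len(lib_ids), dtype=np.int64)
            counts[key][lib_idx] += n

    dhss: list[GenomicInterval] = []
    genes: list[GenomicInterval] = []
    truth_rows = []
    gene_counter = 0
    for p in planned:
        cp = config.class_params[p.cls]
        anchor = p.center
        if p.major_strand == "+":
            summit_major = anchor + config.summit_offset
            summit_minor = anchor - config.summit_offset - 1
        else:
            summit_major = anchor - config.summit_offset - 1
            summit_minor = anchor + config.summit_offset
        minor_strand = "-" if p.major_strand == "+" else "+"
        dhss.append(GenomicInterval(
            p.chrom, p.center - config.dhs_width // 2,
            p.center + config.dhs_width - config.dhs_width // 2, id=p.dhs_id))
        for role, strand, summit, tpm, sens in (
                ("major", p.major_strand, summit_major, cp.tpm_major,
                 cp.sens_major),
                ("minor", minor_strand, summit_minor, cp.tpm_minor,
                 cp.sens_minor)):
            for j, lib in enumerate(libraries):
                mean = tpm * S if lib.condition == EXOSOME_KD \
                    else tpm * (1.0 - sens) * S
                deposit(p.chrom, summit, strand, j,
                        _nb_draw(rng, mean, config.nb_size))
        # gene annotation
        if cp.gene_major:
            gid = f"gene_{gene_counter:04d}"
            gene_counter += 1
            if p.major_strand == "+":
                genes.append(GenomicInterval(
                    p.chrom, summit_major, summit_major + config.gene_length,
                    "+", id=gid, biotype="mRNA"))
            else:
                genes.append(GenomicInterval(
                    p.chrom, summit_major - config.gene_length + 1,
                    summit_major + 1, "-", id=gid, biotype="mRNA"))
        if cp.gene_minor:
            gid = f"gene_{gene_counter:04d}"
            gene_counter += 1
            if minor_strand == "+":
                genes.append(GenomicInterval(
                    p.chrom, summit_minor, summit_minor + config.gene_length,
                    "+", id=gid, biotype="mRNA"))
            else:
                genes.append(GenomicInterval(
                    p.chrom, summit_minor - config.gene_length + 1,
                    summit_minor + 1, "-", id=gid, biotype="mRNA"))
        head_to_head = False
        if cp.head_to_head_frac and rng.random() < cp.head_to_head_frac:
            # upstream antisense gene TSS 400-900 bp away, pointing away
            head_to_head = True
            gid = f"gene_{gene_counter:04d}"
            gene_counter += 1
            d = int(rng.integers(400, 901))
            if p.major_strand == "+":
                tss = summit_major - d
                genes.append(GenomicInterval(
                    p.chrom, tss - config.gene_length + 1, tss + 1, "-",
                    id=gid, biotype="mRNA"))
            else:
                tss = summit_major + d
                genes.append(GenomicInterval(
                    p.chrom, tss, tss + config.gene_length, "+",
                    id=gid, biotype="mRNA"))
        hk_lfc = (config.hk_lfc_intercept
                  + config.hk_lfc_slope * np.log2(1.0 + cp.tpm_major)
                  + rng.normal(0.0, config.hk_lfc_sd))
        dcp_lfc = rng.normal(cp.dcp_lfc_mean, config.dcp_lfc_sd)
        truth_rows.append({
            "dhs_id": p.dhs_id, "chrom": p.chrom, "center": p.center,
            "class": p.cls, "major_strand": p.major_strand,
            "summit_major": summit_major, "summit_minor": summit_minor,
            "tpm_major": cp.tpm_major, "tpm_minor": cp.tpm_minor,
            "sens_major": cp.sens_major, "sens_minor": cp.sens_minor,
            "directionality": (cp.tpm_major - cp.tpm_minor)
            / (cp.tpm_major + cp.tpm_minor),
            "hk_lfc": hk_lfc, "dcp_lfc": dcp_lfc,
            "tad_id": p.tad_id, "head_to_head": head_to_head,
        })
    truth = pd.DataFrame(truth_rows)

    # filler gene promoters absorb the remaining library mass so planted
    # counts convert to the configured TPM values
    expected_planted = sum(
        (cp.tpm_major + cp.tpm_minor) * S
        for p in planned for cp in [config.class_params[p.cls]]
    )
    expected_noise = config.noise_rate_per_bp * sum(chrom_lengths.values())
    filler_total = max(S * 1e6 - expected_planted - expected_noise, 0.0)
    filler_w = rng.lognormal(0.0, 1.0, config.n_filler)
    filler_w /= filler_w.sum()
    per_chrom_filler = np.array_split(np.arange(config.n_filler),
                                      len(config.chroms))
    for ci, chrom in enumerate(config.chroms):
        for k, fi in enumerate(per_chrom_filler[ci]):
            summit = filler_zone[chrom] + k * config.spacing
            mean_kd = filler_total * filler_w[fi]
            for j, lib in enumerate(libraries):
                mean = mean_kd if lib.condition == EXOSOME_KD \
                    else mean_kd * (1.0 - config.filler_sens)
                deposit(chrom, summit, "+", j,
                        _nb_draw(rng, mean, config.nb_size))
            gid = f"gene_filler_{fi:03d}"
            genes.append(GenomicInterval(
                chrom, summit, summit + config.gene_length, "+",
                id=gid, biotype="mRNA"))

    # Poisson background tags at uniform positions
    for j in range(len(lib_ids)):
        for chrom, length in chrom_lengths.items():
            n_tags = rng.poisson(config.noise_rate_per_bp * length)
            positions = rng.integers(0, length, n_tags)
            strands = rng.integers(0, 2, n_tags)
            codes = positions * 2 + strands
            uniq, tag_counts = np.unique(codes, return_counts=True)
            for code, n in zip(uniq, tag_counts):
                key = (chrom, int(code // 2),
                       "+" if code % 2 == 0 else "-")
                if key not in counts:
                    counts[key] = np.zeros(len(lib_ids), dtype=np.int64)
                counts[key][j] += int(n)

    keys = sorted(counts)
    ctss = pd.DataFrame(
        {"chrom": [k[0] for k in keys],
         "pos": np.array([k[1] for k in keys], dtype=np.int64),
         "strand": [k[2] for k in keys]}
    )
    mat = np.vstack([counts[k] for k in keys]) if keys else \
        np.zeros((0, len(lib_ids)), dtype=np.int64)
    for j, lib_id in enumerate(lib_ids):
        ctss[lib_id] = mat[:, j]

    # genome with planted motifs
    base_map = np.frombuffer(b"ACGT", dtype="S1")
    sequences = {}
    for chrom, length in chrom_lengths.items():
        arr = base_map[rng.integers(0, 4, length)]
        sequences[chrom] = arr.tobytes().decode()
    genome = InMemoryGenome(sequences)
    motif_rows = []
    for p, row in zip(planned, truth_rows):
        cp = config.class_params[p.cls]
        minor_strand = "-" if p.major_strand == "+" else "+"
        for role, strand, summit, motifs, five_rate, polya_rate in (
                ("major", p.major_strand, row["summit_major"],
                 cp.motifs_major, cp.five_ss_rate_major, cp.polya_rate_major),
                ("minor", minor_strand, row["summit_minor"],
                 cp.motifs_minor, cp.five_ss_rate_minor, cp.polya_rate_minor)):
            for name, offset, rate in motifs:
                if rng.random() < rate:
                    seq = _realize_consensus(
                        rng, CORE_PROMOTER_CONSENSUS[name])
                    _plant_oriented(genome, p.chrom, summit, strand,
                                    offset, seq)
                    motif_rows.append({
                        "dhs_id": p.dhs_id, "strand_role": role,
                        "motif": name, "offset": offset})
            if rng.random() < five_rate:
                off = int(rng.integers(20, 151))
                _plant_oriented(genome, p.chrom, summit, strand, off,
                                DONOR_CONSENSUS)
                motif_rows.append({"dhs_id": p.dhs_id, "strand_role": role,
                                   "motif": "five_prime_SS", "offset": off})
            if rng.random() < polya_rate:
                off = int(rng.integers(20, 151))
                site = POLYA_SITES[rng.integers(len(POLYA_SITES))]
                _plant_oriented(genome, p.chrom, summit, strand, off, site)
                motif_rows.append({"dhs_id": p.dhs_id, "strand_role": role,
                                   "motif": "polyA", "offset": off})
    truth_motifs = pd.DataFrame(
        motif_rows, columns=["dhs_id", "strand_role", "motif", "offset"])

    # STARR signal / input tracks
    base = config.starr_base
    hk_spans, dcp_spans, input_spans = [], [], []
    for chrom, length in chrom_lengths.items():
        input_spans.append((chrom, 0, length, base))
    for row, d in zip(truth_rows, dhss):
        hk_spans.append((d.chrom, d.center - 50, d.center + 50,
                         base * 2.0 ** row["hk_lfc"]))
        dcp_spans.append((d.chrom, d.center - 50, d.center + 50,
                          base * 2.0 ** row["dcp_lfc"]))
    starr = {
        "hkCP": SignalTrack.from_spans(hk_spans),
        "dCP": SignalTrack.from_spans(dcp_spans),
        "input": SignalTrack.from_spans(input_spans),
    }

    # significant interactions: within-TAD pairs; stable focal DHSs are
    # wired preferentially to strong-hkCP targets
    interactions = []
    truth_by_id = truth.set_index("dhs_id")
    by_tad: dict[str, list[GenomicInterval]] = {}
    for p, d in zip(planned, dhss):
        if p.tad_id != "BETWEEN":
            by_tad.setdefault(p.tad_id, []).append(d)
    for tad_id in sorted(by_tad):
        members = by_tad[tad_id]
        if len(members) < 2 or rng.random() >= config.interaction_rate:
            continue
        stables = [d for d in members
                   if truth_by_id.loc[d.id, "class"] in STABLE_CLASSES]
        if stables:
            focal = stables[rng.integers(len(stables))]
            others = [d for d in members if d.id != focal.id]
            target = max(others, key=lambda d: truth_by_id.loc[d.id, "hk_lfc"])
        else:
            i, j = rng.choice(len(members), size=2, replace=False)
            focal, target = members[int(i)], members[int(j)]
        interactions.append((
            GenomicInterval(focal.chrom, focal.center - 500,
                            focal.center + 500),
            GenomicInterval(target.chrom, target.center - 500,
                            target.center + 500),
        ))

    return SyntheticDataset(
        config=config, libraries=libraries, ctss=ctss, dhss=dhss,
        genes=genes, tads=tads, interactions=interactions, starr=starr,
        genome=genome, chrom_lengths=chrom_lengths, truth=truth,
        truth_motifs=truth_motifs,
    )


def generate_tad_architecture(n_dhs: int = 120, coupling: float = 0.8,
                              seed: int = 1
                              ) -> tuple[list[GenomicInterval],
                                         list[GenomicInterval], pd.Series]:
    """Lightweight DHS/TAD layout for co-occurrence model experiments.

    With *coupling* > 0, TADs carry a superclass archetype and member
    classes follow it; with coupling = 0 classes are assigned
    independently of TADs (the null architecture).  Returns (DHS
    windows, TADs, class labels by DHS id).
    """
    cfg = replace(SimulationConfig(), n_per_class=max(n_dhs // 6, 2),
                  tad_coupling=coupling, between_tad_rate=0.1)
    rng = np.random.default_rng(seed)
    planned, tads, _, _ = _plan_layout(cfg, rng)
    dhss = [GenomicInterval(p.chrom, p.center - 200, p.center + 200,
                            id=p.dhs_id) for p in planned]
    classes = pd.Series({p.dhs_id: p.cls for p in planned})
    return dhss, tads, classes


def truth_report(truth: pd.DataFrame, assignments: pd.DataFrame,
                 quants: pd.DataFrame | None = None,
                 min_tpm: float = 5.0) -> dict[str, float]:
    """Recovery metrics joining truth and pipeline outputs by DHS id."""
    from sklearn.metrics import adjusted_rand_score

    merged = truth.merge(assignments, on="dhs_id", suffixes=("_true", ""))
    if len(merged) != len(assignments):
        raise ValueError("dhs_id mismatch between truth and assignments")
    kept = merged[~merged["removed"]]
    metrics = {
        "n_dhs": float(len(merged)),
        "removed_fraction": float(merged["removed"].mean()),
        "class_accuracy": float(
            (kept["class"] == kept["class_true"]).mean()) if len(kept) else
        float("nan"),
        "adjusted_rand": float(adjusted_rand_score(
            kept["class_true"], kept["cluster"])) if len(kept) else
        float("nan"),
    }
    if quants is not None:
        q = truth.merge(quants, on="dhs_id", suffixes=("_true", "_est"))
        strong = q[q["tpm_major_kd_mean"] >= min_tpm]
        metrics["sensitivity_mae"] = float(np.nanmean(
            np.abs(strong["sens_major_est"] - strong["sens_major_true"])))
        metrics["directionality_mae"] = float(np.nanmean(
            np.abs(strong["directionality_est"]
                   - strong["directionality_true"])))
    return metrics
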