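"""Synthetic shRNA screens and treatment/rescue expression time courses.

Everything downstream of raw data — barcode QC, clone-size ratios, serial
regulation calls, enrichment — is tested against libraries, reads and
matrices generated here with known planted truth, so no external download is
ever required.

The stated world: a pooled library of ~27,500 shRNAs over ~5,500 genes
(5 shRNAs per gene), negative-binomial sequencing counts at ~10^6-10^7 reads
per sample, and a log2-scale expression matrix over nine treatment time
points (5 min ... 24 h) with matched rescue and DMSO-control columns.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DesignError, SizingError, ValidationError
from .io_formats import (
    ExpressionMatrix,
    ShrnaLibraryRecord,
    write_fastq,
    write_json,
    write_shrna_library,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Treatment grid from the study design: 5, 10, 15, 30 min, 1, 3, 6, 10, 24 h.
DEFAULT_TIME_GRID = (5.0, 10.0, 15.0, 30.0, 60.0, 180.0, 360.0, 600.0, 1440.0)

#: Constant vector-backbone flank appended 3' of the barcode in simulated reads.
READ_FLANK = "TGGAAGACGCCA"

#: Default negative-binomial dispersion for simulated screen counts. Chosen so
#: a planted 4-fold clone at high coverage is recovered within +-25% of its
#: ratio with >= 99% probability (ratio CV ~ sqrt(2*dispersion)); 0 is Poisson.
DEFAULT_DISPERSION = 0.002


# ---------------------------------------------------------------------------
# Planted truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedScreenTruth:
    """Ground truth planted into a simulated screen.

    Enriched shRNAs are planted with a treated/control abundance ratio > 2,
    depleted ones with < 0.5; hit genes carry at least two concordant planted
    shRNAs, mirroring the two-shRNA reproducibility rule used for gene calls.
    """

    enriched_shrna_ids: frozenset[str]
    depleted_shrna_ids: frozenset[str]
    hit_genes_up: frozenset[str]
    hit_genes_down: frozenset[str]
    library_size: int
    reads_per_sample: int
    enrichment_ratio: float = 4.0
    depletion_ratio: float = 0.25

    def __post_init__(self):
        if self.enriched_shrna_ids & self.depleted_shrna_ids:
            raise ValidationError("enriched and depleted shRNA sets must be disjoint")
        if not self.enrichment_ratio > 2:
            raise ValidationError("enrichment_ratio must exceed 2")
        if not 0 < self.depletion_ratio < 0.5:
            raise ValidationError("depletion_ratio must be below 0.5")

    def validate_against(self, library: Sequence[ShrnaLibraryRecord]) -> None:
        ids = {r.shrna_id for r in library}
        missing = (self.enriched_shrna_ids | self.depleted_shrna_ids) - ids
        if missing:
            raise ConsistencyError(
                f"planted shRNA IDs absent from library: {sorted(missing)[:10]}"
            )
        by_gene: dict[str, set[str]] = defaultdict(set)
        for rec in library:
            by_gene[rec.gene].add(rec.shrna_id)
        for genes, planted in ((self.hit_genes_up, self.enriched_shrna_ids),
                               (self.hit_genes_down, self.depleted_shrna_ids)):
            for gene in genes:
                if len(by_gene.get(gene, set()) & planted) < 2:
                    raise ConsistencyError(
                        f"hit gene {gene!r} has fewer than 2 planted shRNAs"
                    )


@dataclass
class PlantedTimecourseTruth:
    """Ground truth planted into a simulated expression time course.

    ``serial_up_genes`` / ``serial_down_genes`` exceed the 1.2 / 0.8 fold
    bounds at >= 4 consecutive treatment points and revert during rescue;
    ``non_rescued_genes`` hold a constant fold change (SD = 0) from the last
    treatment point through all rescue points; ``correlated_up`` /
    ``correlated_down`` carry monotone log2 fold-change ramps giving
    |Pearson R| >= 0.6 against the time-point index.
    """

    serial_up_genes: frozenset[str] = frozenset()
    serial_down_genes: frozenset[str] = frozenset()
    non_rescued_genes: frozenset[str] = frozenset()
    correlated_up: frozenset[str] = frozenset()
    correlated_down: frozenset[str] = frozenset()
    time_grid_minutes: tuple[float, ...] = DEFAULT_TIME_GRID
    rescue_grid_minutes: tuple[float, ...] = DEFAULT_TIME_GRID
    batch_labels: tuple[str, ...] = ("B1", "B2")
    batch_offsets: tuple[float, ...] = (0.0, 0.25)
    noise_sd: float = 0.05
    effect_log2fc: float = 0.585  # ~1.5-fold, comfortably past the 1.2 bound
    serial_run_length: int = 5
    allow_overlap: bool = False

    def __post_init__(self):
        grid = np.asarray(self.time_grid_minutes, dtype=float)
        if len(grid) < 2 or not np.all(np.diff(grid) > 0):
            raise ValidationError("time_grid_minutes must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if len(self.batch_offsets) != len(self.batch_labels):
            raise ValidationError("batch_offsets must parallel batch_labels")
        if not self.allow_overlap:
            sets = [self.serial_up_genes, self.serial_down_genes,
                    self.non_rescued_genes, self.correlated_up, self.correlated_down]
            seen: set[str] = set()
            for s in sets:
                if s & seen:
                    raise ValidationError(
                        f"planted gene sets overlap: {sorted(s & seen)[:5]} "
                        "(set allow_overlap=True to permit)"
                    )
                seen |= s

    @property
    def planted_genes(self) -> frozenset[str]:
        return (self.serial_up_genes | self.serial_down_genes
                | self.non_rescued_genes | self.correlated_up | self.correlated_down)


# ---------------------------------------------------------------------------
# shRNA library generation
# ---------------------------------------------------------------------------

def _required_length(n_barcodes: int, min_distance: int) -> int:
    """Smallest barcode length that can hold ``n_barcodes`` codewords at the
    requested minimum pairwise Hamming distance (Singleton bound)."""
    return max(1, math.ceil(math.log(max(n_barcodes, 1), 4))) + min_distance - 1


def _distance_violations(codes: np.ndarray, min_distance: int) -> list[tuple[int, int]]:
    """All index pairs at Hamming distance < min_distance.

    Pigeonhole: two codewords closer than d must agree exactly on at least one
    of d equal segments, so only same-segment bucket collisions are candidates.
    """
    n, length = codes.shape
    bounds = np.linspace(0, length, min_distance + 1).astype(int)
    candidates: set[tuple[int, int]] = set()
    for s in range(min_distance):
        seg = np.ascontiguousarray(codes[:, bounds[s]:bounds[s + 1]])
        buckets: dict[bytes, list[int]] = defaultdict(list)
        for i in range(n):
            buckets[seg[i].tobytes()].append(i)
        for members in buckets.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    candidates.add((members[a], members[b]))
    if not candidates:
        return []
    pairs = np.array(sorted(candidates))
    dist = (codes[pairs[:, 0]] != codes[pairs[:, 1]]).sum(axis=1)
    return [tuple(p) for p in pairs[dist < min_distance]]


def generate_shrna_library(n_genes: int, shrnas_per_gene: int, barcode_length: int = 18,
                           seed: int = 0, *, min_distance: int = 3,
                           gene_prefix: str = "GENE") -> list[ShrnaLibraryRecord]:
    """Generate a pooled shRNA library with unique, well-separated barcodes.

    Barcodes are uniform random DNA, resampled until every pair is at Hamming
    distance >= ``min_distance`` (default 3, so one-mismatch-tolerant
    demultiplexing can never be ambiguous). Deterministic per seed.

    Raises :class:`SizingError` when the barcode space cannot hold the
    requested library, naming the required length.
    """
    if n_genes < 1 or shrnas_per_gene < 1:
        raise ValidationError("n_genes and shrnas_per_gene must be positive")
    if barcode_length < 8:
        raise ValidationError("barcode_length must be >= 8")
    if min_distance < 1:
        raise ValidationError("min_distance must be >= 1")
    n = n_genes * shrnas_per_gene
    if min_distance > barcode_length or n > 4 ** (barcode_length - min_distance + 1):
        raise SizingError(
            f"{n} barcodes at pairwise Hamming distance >= {min_distance} do not fit "
            f"in length {barcode_length}; need barcode_length >= "
            f"{_required_length(n, min_distance)}"
        )

    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, barcode_length), dtype=np.uint8)
    for _ in range(100):
        # resample duplicate rows first, then near-collisions
        view = np.ascontiguousarray(codes).view([("", codes.dtype)] * barcode_length)
        _, first = np.unique(view, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        bad = set(dup.tolist())
        if not bad and min_distance > 1:
            bad = {j for _, j in _distance_violations(codes, min_distance)}
        if not bad:
            break
        idx = sorted(bad)
        codes[idx] = rng.integers(0, 4, size=(len(idx), barcode_length), dtype=np.uint8)
    else:
        raise SizingError(
            f"could not place {n} barcodes at distance >= {min_distance} in length "
            f"{barcode_length}; increase barcode_length"
        )

    seqs = _BASES[codes].view(f"S{barcode_length}").ravel()
    width = len(str(n_genes))
    records = []
    k = 0
    for g in range(n_genes):
        gene = f"{gene_prefix}{g + 1:0{width}d}"
        for s in range(shrnas_per_gene):
            records.append(ShrnaLibraryRecord(
                shrna_id=f"{gene}_sh{s + 1}",
                barcode=seqs[k].decode("ascii"),
                gene=gene,
            ))
            k += 1
    return records


def make_planted_screen_truth(library: Sequence[ShrnaLibraryRecord],
                              n_genes_up: int, n_genes_down: int,
                              reads_per_sample: int = 7_000_000, *,
                              enrichment_ratio: float = 4.0,
                              depletion_ratio: float = 0.25,
                              seed: int = 0) -> PlantedScreenTruth:
    """Pick disjoint hit genes and plant all of their shRNAs concordantly."""
    by_gene: dict[str, list[str]] = defaultdict(list)
    for rec in library:
        by_gene[rec.gene].append(rec.shrna_id)
    eligible = sorted(g for g, ids in by_gene.items() if len(ids) >= 2)
    if n_genes_up + n_genes_down > len(eligible):
        raise SizingError(
            f"cannot plant {n_genes_up + n_genes_down} hit genes: only "
            f"{len(eligible)} genes have >= 2 shRNAs"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_genes_up + n_genes_down, replace=False)
    up = frozenset(eligible[i] for i in chosen[:n_genes_up])
    down = frozenset(eligible[i] for i in chosen[n_genes_up:])
    truth = PlantedScreenTruth(
        enriched_shrna_ids=frozenset(i for g in up for i in by_gene[g]),
        depleted_shrna_ids=frozenset(i for g in down for i in by_gene[g]),
        hit_genes_up=up,
        hit_genes_down=down,
        library_size=len(library),
        reads_per_sample=reads_per_sample,
        enrichment_ratio=enrichment_ratio,
        depletion_ratio=depletion_ratio,
    )
    truth.validate_against(library)
    return truth


# ---------------------------------------------------------------------------
# Screen read simulation
# ---------------------------------------------------------------------------

def simulate_screen_counts(library: Sequence[ShrnaLibraryRecord],
                           truth: PlantedScreenTruth, depth: int, *,
                           dispersion: float = DEFAULT_DISPERSION,
                           rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw per-shRNA molecule counts for the control and treated samples.

    Counts are negative binomial via the gamma-Poisson mixture: a gamma
    multiplier with shape 1/dispersion around a common per-shRNA mean, then
    Poisson sampling. ``dispersion=0`` reduces to pure Poisson. The treated
    mean is multiplied by the planted ratio (>2 enriched, <0.5 depleted,
    1 otherwise) before resampling.
    """
    truth.validate_against(library)
    if dispersion < 0:
        raise ValidationError("dispersion must be non-negative")
    n = len(library)
    mean = depth / n
    ratios = np.ones(n)
    for i, rec in enumerate(library):
        if rec.shrna_id in truth.enriched_shrna_ids:
            ratios[i] = truth.enrichment_ratio
        elif rec.shrna_id in truth.depleted_shrna_ids:
            ratios[i] = truth.depletion_ratio

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        return rng.poisson(lam)

    return {
        "control": draw(np.full(n, mean)),
        "treated": draw(mean * ratios),
    }


def counts_to_reads(library: Sequence[ShrnaLibraryRecord], counts: np.ndarray, *,
                    error_rate: float = 0.0, corrupt_fraction: float = 0.0,
                    short_length: int = 8, rng: np.random.Generator,
                    sample: str = "S") -> Iterator[tuple[str, str, str]]:
    """Expand per-shRNA counts into shuffled (id, sequence, quality) reads.

    Each read is its shRNA's barcode plus a constant 3' vector flank.
    ``error_rate`` applies uniform substitutions per base. A
    ``corrupt_fraction`` of reads is independently corrupted to exercise QC:
    half become random no-match sequences, half are truncated below any
    sensible length cutoff.
    """
    if not 0 <= error_rate <= 0.05:
        raise ValidationError("error_rate must be in [0, 0.05]")
    if not 0 <= corrupt_fraction < 1:
        raise ValidationError("corrupt_fraction must be in [0, 1)")
    bc_len = len(library[0].barcode)
    bcodes = np.frombuffer(
        "".join(r.barcode for r in library).encode(), dtype=np.uint8
    ).reshape(len(library), bc_len)
    flank = np.frombuffer(READ_FLANK.encode(), dtype=np.uint8)
    read_len = bc_len + len(flank)

    idx = np.repeat(np.arange(len(library)), counts)
    rng.shuffle(idx)
    total = len(idx)
    seqs = np.empty((total, read_len), dtype=np.uint8)
    seqs[:, :bc_len] = bcodes[idx]
    seqs[:, bc_len:] = flank

    if error_rate > 0:
        mask = rng.random(seqs.shape) < error_rate
        # substitute with a strictly different base: shift by 1..3 in base index
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        base_idx = np.searchsorted(_BASES, seqs[mask])
        seqs[mask] = _BASES[(base_idx + shift) % 4]

    corrupt = rng.random(total) < corrupt_fraction
    corrupt_idx = np.flatnonzero(corrupt)
    half = len(corrupt_idx) // 2
    nomatch_idx = corrupt_idx[:half + len(corrupt_idx) % 2]
    short_idx = set(corrupt_idx[len(nomatch_idx):].tolist())
    if len(nomatch_idx):
        seqs[nomatch_idx] = _BASES[rng.integers(0, 4, size=(len(nomatch_idx), read_len))]

    qual_full = "I" * read_len
    qual_short = "I" * short_length
    strings = seqs.view(f"S{read_len}").ravel()
    for i in range(total):
        seq = strings[i].decode("ascii")
        if i in short_idx:
            yield f"{sample}_{i}", seq[:short_length], qual_short
        else:
            yield f"{sample}_{i}", seq, qual_full


def simulate_screen_reads(library: Sequence[ShrnaLibraryRecord],
                          truth: PlantedScreenTruth, depth: int,
                          error_rate: float = 0.0, seed: int = 0, *,
                          out_dir, corrupt_fraction: float = 0.1,
                          dispersion: float = DEFAULT_DISPERSION) -> dict:
    """Simulate a full screen to disk: control/treated FASTQ + library TSV + truth JSON.

    Returns a dict of the written paths plus the per-sample molecule counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = simulate_screen_counts(library, truth, depth,
                                    dispersion=dispersion, rng=rng)
    paths = {"library": out_dir / "library.tsv", "truth": out_dir / "screen_truth.json"}
    write_shrna_library(paths["library"], library)
    for sample in ("control", "treated"):
        path = out_dir / f"{sample}.fastq"
        write_fastq(path, counts_to_reads(
            library, counts[sample], error_rate=error_rate,
            corrupt_fraction=corrupt_fraction, rng=rng, sample=sample,
        ))
        paths[sample] = path
    write_json(paths["truth"], {
        "enriched_shrna_ids": truth.enriched_shrna_ids,
        "depleted_shrna_ids": truth.depleted_shrna_ids,
        "hit_genes_up": truth.hit_genes_up,
        "hit_genes_down": truth.hit_genes_down,
        "library_size": truth.library_size,
        "reads_per_sample": truth.reads_per_sample,
        "enrichment_ratio": truth.enrichment_ratio,
        "depletion_ratio": truth.depletion_ratio,
    })
    return {**paths, "counts": counts}


# ---------------------------------------------------------------------------
# Time-course expression simulation
# ---------------------------------------------------------------------------

def make_planted_timecourse_truth(n_serial_up: int = 25, n_serial_down: int = 25,
                                  n_non_rescued: int = 10, n_correlated_up: int = 8,
                                  n_correlated_down: int = 20,
                                  **kwargs) -> PlantedTimecourseTruth:
    """Name disjoint planted gene sets (SERUP/SERDN/NRES/CORUP/CORDN prefixes)."""
    def names(prefix: str, n: int) -> frozenset[str]:
        return frozenset(f"{prefix}{i + 1:04d}" for i in range(n))

    return PlantedTimecourseTruth(
        serial_up_genes=names("SERUP", n_serial_up),
        serial_down_genes=names("SERDN", n_serial_down),
        non_rescued_genes=names("NRES", n_non_rescued),
        correlated_up=names("CORUP", n_correlated_up),
        correlated_down=names("CORDN", n_correlated_down),
        **kwargs,
    )


def simulate_timecourse_matrix(truth: PlantedTimecourseTruth,
                               n_background_genes: int = 5000,
                               seed: int = 0) -> ExpressionMatrix:
    """Simulate a log2-scale expression matrix for the treat/rescue/control design.

    One column per (condition, time point) for conditions treated, rescue and
    control (DMSO). Per-gene baselines ~ N(8, 1); planted effects are added to
    the treated/rescue columns; batches are assigned per time point (all three
    conditions of a time point share a chip) and shifted by the configured
    batch offsets; i.i.d. Gaussian noise of ``truth.noise_sd`` on the log2
    scale everywhere — except the cells of non-rescued genes from the last
    treatment point onward, which are pinned to an exactly constant fold
    change so their planted SD is literally zero.
    """
    t_grid = truth.time_grid_minutes
    r_grid = truth.rescue_grid_minutes
    if len(t_grid) < 4:
        raise DesignError("need at least 4 treatment time points for serial-run analysis")

    planted = sorted(truth.planted_genes)
    genes = planted + [f"BG{i + 1:05d}" for i in range(n_background_genes)]
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for cond, grid in (("treated", t_grid), ("control", t_grid), ("rescue", r_grid)):
        for ti, t in enumerate(grid):
            batch = truth.batch_labels[ti % len(truth.batch_labels)]
            rows.append((f"{cond}_t{int(t)}", cond, float(t), batch, "200ug/ml"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "condition", "time_min",
                                        "batch", "dose"])

    rng = np.random.default_rng(seed)
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    n_t, n_r = len(t_grid), len(r_grid)

    # planted log2 fold-change deltas per (gene, treatment index) and rescue index
    delta_t = np.zeros((n_genes, n_t))
    delta_r = np.zeros((n_genes, n_r))
    eff = truth.effect_log2fc
    run = min(truth.serial_run_length, n_t)
    for g in sorted(truth.serial_up_genes):
        start = rng.integers(0, n_t - run + 1)
        delta_t[gene_pos[g], start:start + run] = eff
    for g in sorted(truth.serial_down_genes):
        start = rng.integers(0, n_t - run + 1)
        delta_t[gene_pos[g], start:start + run] = -eff
    ramp = np.linspace(0.0, 1.0, n_t)
    for g in sorted(truth.correlated_up):
        delta_t[gene_pos[g]] = eff * ramp
    for g in sorted(truth.correlated_down):
        delta_t[gene_pos[g]] = -eff * ramp
    for g in sorted(truth.non_rescued_genes):
        i = gene_pos[g]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta_t[i, n_t - run:] = sign * eff
        delta_r[i, :] = sign * eff  # persists through every rescue point

    def noise(shape):
        return rng.normal(0.0, truth.noise_sd, size=shape)

    offsets = dict(zip(truth.batch_labels, truth.batch_offsets))
    control = baseline[:, None] + noise((n_genes, n_t))  # one DMSO column per treatment time
    treated = baseline[:, None] + delta_t + noise((n_genes, n_t))
    rescue = baseline[:, None] + delta_r + noise((n_genes, n_r))

    # The control reference a fold-change step will use per rescue time:
    # the matched-time control column when the time exists, pooled mean otherwise.
    t_index = {t: i for i, t in enumerate(t_grid)}
    ctrl_ref_r = np.column_stack([
        control[:, t_index[t]] if t in t_index else control.mean(axis=1)
        for t in r_grid
    ])

    # Pin non-rescued genes: exactly constant fold change from the last
    # treatment point through every rescue point (planted SD = 0).
    for g in sorted(truth.non_rescued_genes):
        i = gene_pos[g]
        treated[i, -1] = control[i, -1] + delta_t[i, -1]
        rescue[i, :] = ctrl_ref_r[i, :] + delta_r[i, :]

    blocks = {"treated": treated, "control": control, "rescue": rescue}
    data = {}
    for row in sheet.itertuples(index=False):
        grid = r_grid if row.condition == "rescue" else t_grid
        ti = list(grid).index(row.time_min)
        data[row.sample_id] = blocks[row.condition][:, ti] + offsets[row.batch]
    values = pd.DataFrame(data, index=genes)
    return ExpressionMatrix(values=values, samples=sheet, scale="log2")


def write_timecourse_truth(path, truth: PlantedTimecourseTruth) -> None:
    write_json(path, {
        "serial_up_genes": truth.serial_up_genes,
        "serial_down_genes": truth.serial_down_genes,
        "non_rescued_genes": truth.non_rescued_genes,
        "correlated_up": truth.correlated_up,
        "correlated_down": truth.correlated_down,
        "time_grid_minutes": list(truth.time_grid_minutes),
        "rescue_grid_minutes": list(truth.rescue_grid_minutes),
        "batch_labels": list(truth.batch_labels),
        "batch_offsets": list(truth.batch_offsets),
        "noise_sd": truth.noise_sd,
        "effect_log2fc": truth.effect_log2fc,
        "serial_run_length": truth.serial_run_length,
    })
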