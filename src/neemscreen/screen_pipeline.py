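"""Pooled shRNA screen arm: barcode QC, counting, clone-size ratios, gene hits.

Reads are assigned to shRNAs by alignment-free barcode matching. Clone size
is the relative abundance of cells carrying an shRNA, proxied by its
depth-normalized read count; the treated/control ratio classifies each shRNA
as enriched (> 2, knockdown favors growth under drug), depleted (< 0.5,
synthetic lethality) or neutral, and a gene becomes a hit when at least two
of its shRNAs agree in direction.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io_formats import ShrnaLibraryRecord, read_fastq, read_shrna_library, write_json

ENRICHED_RATIO = 2.0    #: strict lower bound for the enriched class
DEPLETED_RATIO = 0.5    #: strict upper bound for the depleted class
DEFAULT_PSEUDOCOUNT = 0.5
NORM_SCALE = 1_000_000  # reads-per-million


@dataclass
class ScreenQCReport:
    """Read-level accounting for one sample's barcode demultiplexing."""

    total_reads: int
    qc_pass_reads: int
    too_short: int
    no_match: int
    ambiguous: int
    unique_shrnas_detected: int
    library_size: int

    @property
    def qc_pass_fraction(self) -> float:
        return self.qc_pass_reads / self.total_reads if self.total_reads else 0.0

    @property
    def detection_fraction(self) -> float:
        return self.unique_shrnas_detected / self.library_size if self.library_size else 0.0

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "qc_pass_reads": self.qc_pass_reads,
            "qc_pass_fraction": self.qc_pass_fraction,
            "too_short": self.too_short,
            "no_match": self.no_match,
            "ambiguous": self.ambiguous,
            "unique_shrnas_detected": self.unique_shrnas_detected,
            "library_size": self.library_size,
            "detection_fraction": self.detection_fraction,
        }


@dataclass
class BarcodeCountTable:
    """Per-shRNA read counts per sample, raw and depth-normalized.

    ``norm`` is reads-per-million: each column of ``raw`` scaled so that it
    sums to 10^6, making samples of unequal sequencing depth comparable.
    Zero-count shRNAs are retained as zeros.
    """

    raw: pd.DataFrame
    norm: pd.DataFrame
    gene_map: pd.Series  # shrna_id -> gene


@dataclass(frozen=True)
class CloneSizeRecord:
    shrna_id: str
    gene: str
    norm_treated: float
    norm_control: float
    ratio: float
    klass: str  # {enriched, depleted, neutral}


@dataclass(frozen=True)
class GeneHit:
    gene: str
    direction: str  # up = favors growth under treatment; down = synergistic lethality
    supporting_shrnas: tuple[str, ...]

    @property
    def n_support(self) -> int:
        return len(self.supporting_shrnas)


# ---------------------------------------------------------------------------
# Barcode demultiplexing QC
# ---------------------------------------------------------------------------

def _neighborhood1(barcode: str) -> Iterable[str]:
    for i, base in enumerate(barcode):
        for sub in "ACGT":
            if sub != base:
                yield barcode[:i] + sub + barcode[i + 1:]


def qc_filter_reads(reads: Iterable[tuple[str, str, str]],
                    library: Sequence[ShrnaLibraryRecord],
                    min_length: int | None = None,
                    max_mismatches: int = 0,
                    barcode_start: int = 0) -> tuple[dict[str, str], ScreenQCReport]:
    """Assign reads to shRNAs, discarding too-short and non-matching reads.

    A read is kept iff it is at least ``min_length`` long (default: long
    enough to cover the barcode region) and its barcode region matches exactly
    one library barcode within ``max_mismatches``. Reads matching two or more
    barcodes at equal best distance are discarded as ambiguous and tallied
    separately. Returns the read_id -> shrna_id assignments plus a QC report.
    """
    if not library:
        raise ConfigurationError("empty shRNA library")
    bc_len = len(library[0].barcode)
    if any(len(r.barcode) != bc_len for r in library):
        raise ConfigurationError("library barcodes must share one length")
    bc_end = barcode_start + bc_len
    if min_length is None:
        min_length = bc_end
    length_cut = max(min_length, bc_end)

    exact = {r.barcode: r.shrna_id for r in library}
    if max_mismatches >= 2:
        lib_arr = np.frombuffer("".join(r.barcode for r in library).encode(),
                                dtype=np.uint8).reshape(len(library), bc_len)

    assignments: dict[str, str] = {}
    total = too_short = no_match = ambiguous = 0
    for read_id, seq, _qual in reads:
        total += 1
        if len(seq) < length_cut:
            too_short += 1
            continue
        region = seq[barcode_start:bc_end]
        hit = exact.get(region)
        if hit is not None:
            assignments[read_id] = hit
            continue
        if max_mismatches == 0:
            no_match += 1
            continue
        if max_mismatches == 1:
            hits = {exact[v] for v in _neighborhood1(region) if v in exact}
            if not hits:
                no_match += 1
            elif len(hits) > 1:
                ambiguous += 1
            else:
                assignments[read_id] = hits.pop()
            continue
        # general (slow) path: full Hamming scan of the library
        arr = np.frombuffer(region.encode(), dtype=np.uint8)
        dists = (lib_arr != arr).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            no_match += 1
        elif int((dists == best).sum()) > 1:
            ambiguous += 1
        else:
            assignments[read_id] = library[int(dists.argmin())].shrna_id

    report = ScreenQCReport(
        total_reads=total,
        qc_pass_reads=len(assignments),
        too_short=too_short,
        no_match=no_match,
        ambiguous=ambiguous,
        unique_shrnas_detected=len(set(assignments.values())),
        library_size=len(library),
    )
    return assignments, report


# ---------------------------------------------------------------------------
# Counting, normalization, ratios, gene aggregation
# ---------------------------------------------------------------------------

def count_and_normalize(assignments_by_sample: Mapping[str, Mapping[str, str] | Counter],
                        library: Sequence[ShrnaLibraryRecord]) -> BarcodeCountTable:
    """Tabulate raw counts per shRNA per sample and scale to reads-per-million."""
    if not assignments_by_sample:
        raise ConfigurationError("no samples provided")
    ids = [r.shrna_id for r in library]
    raw = pd.DataFrame(0, index=ids, columns=list(assignments_by_sample), dtype=np.int64)
    for sample, assignments in assignments_by_sample.items():
        counts = (assignments if isinstance(assignments, Counter)
                  else Counter(assignments.values()))
        if not counts:
            raise DataError(f"sample {sample!r} has zero QC-pass reads")
        col = pd.Series(counts)
        raw.loc[col.index, sample] = col.astype(np.int64)
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise DataError(f"samples with zero QC-pass reads: {empty}")
    norm = raw * (NORM_SCALE / totals)
    gene_map = pd.Series({r.shrna_id: r.gene for r in library}, name="gene")
    return BarcodeCountTable(raw=raw, norm=norm, gene_map=gene_map)


def classify_ratio(ratio: float) -> str:
    """Strict thresholds: >2 enriched, <0.5 depleted; the boundaries are neutral."""
    if ratio > ENRICHED_RATIO:
        return "enriched"
    if ratio < DEPLETED_RATIO:
        return "depleted"
    return "neutral"


def compute_clone_size_ratio(counts: BarcodeCountTable, treated_sample: str,
                             control_sample: str,
                             pseudocount: float = DEFAULT_PSEUDOCOUNT,
                             ) -> list[CloneSizeRecord]:
    """Clone-size ratio per shRNA: (norm_treated + pc) / (norm_control + pc).

    The symmetric pseudocount keeps ratios finite for zero counts and makes
    swapping treated and control map every ratio r to exactly 1/r.
    """
    for sample in (treated_sample, control_sample):
        if sample not in counts.norm.columns:
            raise ConfigurationError(f"sample {sample!r} not in count table")
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    t = counts.norm[treated_sample].to_numpy()
    c = counts.norm[control_sample].to_numpy()
    ratios = (t + pseudocount) / (c + pseudocount)
    return [
        CloneSizeRecord(
            shrna_id=sid, gene=counts.gene_map[sid],
            norm_treated=float(tv), norm_control=float(cv),
            ratio=float(rv), klass=classify_ratio(float(rv)),
        )
        for sid, tv, cv, rv in zip(counts.norm.index, t, c, ratios)
    ]


def aggregate_genes(records: Iterable[CloneSizeRecord],
                    min_support: int = 2) -> list[GeneHit]:
    """Call gene hits: >= min_support shRNAs of one gene sharing a non-neutral class.

    A gene may be called in both directions when each direction independently
    meets the support threshold; neutral shRNAs never contribute.
    """
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    support: dict[tuple[str, str], list[str]] = defaultdict(list)
    for rec in records:
        if rec.klass == "enriched":
            support[(rec.gene, "up")].append(rec.shrna_id)
        elif rec.klass == "depleted":
            support[(rec.gene, "down")].append(rec.shrna_id)
    hits = [
        GeneHit(gene=gene, direction=direction,
                supporting_shrnas=tuple(sorted(ids)))
        for (gene, direction), ids in support.items()
        if len(ids) >= min_support
    ]
    return sorted(hits, key=lambda h: (h.gene, h.direction))


def consensus_gene_hits(hits_by_dose: Mapping[str, Iterable[GeneHit]]) -> list[GeneHit]:
    """Optional cross-dose consensus: keep (gene, direction) pairs called at
    every dose; supporting shRNAs are the union across doses."""
    per_dose = [
        {(h.gene, h.direction): h for h in hits} for hits in hits_by_dose.values()
    ]
    if not per_dose:
        return []
    shared = set(per_dose[0])
    for d in per_dose[1:]:
        shared &= set(d)
    out = []
    for key in sorted(shared):
        shrnas: set[str] = set()
        for d in per_dose:
            shrnas |= set(d[key].supporting_shrnas)
        out.append(GeneHit(gene=key[0], direction=key[1],
                           supporting_shrnas=tuple(sorted(shrnas))))
    return out


# ---------------------------------------------------------------------------
# Orchestration + plotting
# ---------------------------------------------------------------------------

def plot_clone_size_scatter(records: Sequence[CloneSizeRecord], path) -> None:
    """Log-log treated-vs-control scatter with the 2x / 0.5x threshold lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.array([r.norm_treated + DEFAULT_PSEUDOCOUNT for r in records])
    c = np.array([r.norm_control + DEFAULT_PSEUDOCOUNT for r in records])
    colors = {"enriched": "tab:red", "depleted": "tab:blue", "neutral": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for klass in ("neutral", "enriched", "depleted"):
        mask = np.array([r.klass == klass for r in records])
        if mask.any():
            ax.scatter(c[mask], t[mask], s=3, alpha=0.4, c=colors[klass], label=klass)
    lims = [min(c.min(), t.min()), max(c.max(), t.max())]
    grid = np.geomspace(*lims, 50)
    ax.plot(grid, grid * ENRICHED_RATIO, "k--", lw=0.8)
    ax.plot(grid, grid * DEPLETED_RATIO, "k--", lw=0.8)
    ax.set_xscale("log"); ax.set_yscale("log")
    ax.set_xlabel("control (reads per million)")
    ax.set_ylabel("treated (reads per million)")
    ax.legend(frameon=False, markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_screen(library_path, control_fastq, treated_fastq, out_dir, *,
               min_length: int | None = None, max_mismatches: int = 0,
               pseudocount: float = DEFAULT_PSEUDOCOUNT, min_support: int = 2,
               make_plot: bool = True) -> dict:
    """Full screen arm from files on disk; writes counts, ratios, hits, QC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = read_shrna_library(library_path)
    assignments = {}
    reports = {}
    for sample, path in (("control", control_fastq), ("treated", treated_fastq)):
        assignments[sample], reports[sample] = qc_filter_reads(
            read_fastq(path), library, min_length=min_length,
            max_mismatches=max_mismatches,
        )
    counts = count_and_normalize(assignments, library)
    records = compute_clone_size_ratio(counts, "treated", "control",
                                       pseudocount=pseudocount)
    hits = aggregate_genes(records, min_support=min_support)

    counts.raw.to_csv(out_dir / "counts_raw.tsv", sep="\t", index_label="shrna_id")
    counts.norm.to_csv(out_dir / "counts_rpm.tsv", sep="\t", index_label="shrna_id")
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        out_dir / "clone_sizes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(h.gene, h.direction, h.n_support, ",".join(h.supporting_shrnas)) for h in hits],
        columns=["gene", "direction", "n_support", "supporting_shrnas"],
    ).to_csv(out_dir / "gene_hits.tsv", sep="\t", index=False)
    write_json(out_dir / "qc_report.json",
               {s: r.as_dict() for s, r in reports.items()})
    if make_plot:
        plot_clone_size_scatter(records, out_dir / "clone_size_scatter.png")
    return {"counts": counts, "records": records, "hits": hits, "qc": reports}
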