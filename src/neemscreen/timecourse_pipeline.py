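"""Expression arm: normalization and the temporal selection rules.

The pipeline normalizes a raw probe/gene intensity matrix (variance-
stabilizing log transform, MA-style loess correction against a pseudo-array,
per-batch location/scale correction), converts it to per-time-point fold
changes against the DMSO control, and then applies the study's selection
rules: serial regulation (every ratio beyond the 1.2 / 0.8 bounds over at
least four consecutive time points), rescue reversal, non-rescue flatness
(SD <= 0.01 across the last treatment point and all rescue points), and
temporal Pearson correlation (|R| >= 0.6 against the time-point index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    ConfigurationError,
    DataError,
    DesignError,
    InsufficientDataError,
    ValidationError,
)
from .io_formats import ExpressionMatrix, PathwayGeneSet

logger = logging.getLogger("neemscreen")

UP_BOUND = 1.2        #: fold-change ratio above which a point counts as up-regulated
DOWN_BOUND = 0.8      #: ratio below which a point counts as down-regulated
MIN_RUN = 4           #: minimum consecutive qualifying time points
SD_THRESHOLD = 0.01   #: non-rescue flatness bound on log2 fold changes
R_UP, R_DOWN = 0.6, -0.6


@dataclass
class TimecourseProfile:
    """Per-gene fold-change trajectories (ratios > 0) for treatment and rescue."""

    gene: str
    fc_treatment: np.ndarray
    fc_rescue: np.ndarray
    time_grid: tuple[float, ...] = ()
    rescue_grid: tuple[float, ...] = ()

    def __post_init__(self):
        self.fc_treatment = np.asarray(self.fc_treatment, dtype=float)
        self.fc_rescue = np.asarray(self.fc_rescue, dtype=float)
        if (self.fc_treatment <= 0).any() or (self.fc_rescue <= 0).any():
            raise ValidationError(f"fold-change ratios for {self.gene!r} must be > 0")

    @property
    def log2fc_treatment(self) -> np.ndarray:
        return np.log2(self.fc_treatment)

    @property
    def log2fc_rescue(self) -> np.ndarray:
        return np.log2(self.fc_rescue)


@dataclass
class SerialRegulationCall:
    """Verdict of the run / rescue / flatness / correlation filters for one gene."""

    gene: str
    selected: bool
    direction: str  # {up, down, none}
    run_start_index: int
    run_length: int
    rescue_reversed: bool
    non_rescued: bool = False
    temporal_R: float = float("nan")
    temporal_class: str = "none"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def vst_transform(matrix: ExpressionMatrix, c: float = 1.0) -> ExpressionMatrix:
    """Variance-stabilizing started-log transform: log2(x + c), per array.

    The exact bead-level variance-stabilizing fit needs within-array replicate
    variances a plain matrix does not carry; the started log preserves the
    monotone, variance-flattening contract the downstream filters rely on.
    """
    if matrix.scale != "raw":
        raise DataError("vst_transform expects a raw-scale matrix")
    values = matrix.values
    bad = values.values <= 0
    if bad.any():
        r, col = np.argwhere(bad)[0]
        raise DataError(
            f"non-positive intensity {values.iat[r, col]} at probe "
            f"{values.index[r]!r}, sample {values.columns[col]!r}"
        )
    return matrix.copy_with(np.log2(values + c), scale="log2")


def loess_normalize(matrix: ExpressionMatrix, span: float = 0.3) -> ExpressionMatrix:
    """Remove intensity-dependent bias per array against the mean pseudo-array.

    MA-style: for each array, the loess fit of (array - pseudo-array) on the
    pseudo-array is subtracted, so after normalization the residual trend
    versus mean intensity is flat.
    """
    if matrix.scale != "log2":
        raise DataError("loess_normalize expects a log2-scale matrix")
    if not 0 < span <= 1:
        raise ConfigurationError("span must be in (0, 1]")
    values = matrix.values
    if len(values) < 10:
        raise InsufficientDataError(
            f"loess normalization needs >= 10 genes, got {len(values)}"
        )
    pseudo = values.mean(axis=1).to_numpy()
    corrected = {}
    for col in values.columns:
        m = values[col].to_numpy() - pseudo
        fit = lowess(m, pseudo, frac=span, return_sorted=False)
        corrected[col] = values[col].to_numpy() - fit
    return matrix.copy_with(pd.DataFrame(corrected, index=values.index))


def batch_correct(matrix: ExpressionMatrix, *, mean_only: bool = False,
                  allow_singleton: bool = False) -> ExpressionMatrix:
    """Per-gene, per-batch location/scale standardization toward the pooled moments.

    Every batch's per-gene mean (and, unless ``mean_only``, standard
    deviation) is mapped onto the pooled per-gene mean (and SD), so the
    pooled per-gene mean is preserved exactly. No empirical-Bayes shrinkage:
    with few samples per batch the shrinkage prior is under-determined.
    A single batch is returned unchanged; singleton batches are an error
    unless ``allow_singleton`` (then passed through with a warning).
    """
    if matrix.scale != "log2":
        raise DataError("batch_correct expects a log2-scale matrix")
    sheet = matrix.samples
    batches = sheet.groupby("batch")["sample_id"].apply(list)
    if len(batches) < 2:
        return matrix.copy_with(matrix.values.copy())
    singletons = [b for b, cols in batches.items() if len(cols) < 2]
    if singletons and not allow_singleton:
        raise DesignError(
            f"singleton batches {singletons}: need >= 2 samples per batch "
            "(or allow_singleton=True to pass them through)"
        )
    values = matrix.values
    pooled_mean = values.mean(axis=1)
    pooled_sd = values.std(axis=1, ddof=1)
    out = values.copy()
    for batch, cols in batches.items():
        if len(cols) < 2:
            logger.warning("singleton batch %r passed through uncorrected", batch)
            continue
        block = values[cols]
        b_mean = block.mean(axis=1)
        if mean_only:
            adj = block.sub(b_mean, axis=0).add(pooled_mean, axis=0)
        else:
            b_sd = block.std(axis=1, ddof=1)
            scale = (pooled_sd / b_sd).replace([np.inf, -np.inf], 1.0).fillna(1.0)
            adj = (block.sub(b_mean, axis=0)
                   .mul(scale, axis=0)
                   .add(pooled_mean, axis=0))
        out[cols] = adj
    # restore the exact pooled per-gene mean (scale steps can shift it slightly)
    out = out.sub(out.mean(axis=1) - pooled_mean, axis=0)
    return matrix.copy_with(out)


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def compute_fold_changes(matrix: ExpressionMatrix,
                         dose: str | None = None) -> list[TimecourseProfile]:
    """Per-gene fold-change ratios versus the DMSO control, per time point.

    Replicate columns are averaged on the log2 scale first; the control is
    matched by time point when a control column for that time exists, else
    the pooled control mean is used (logged once). Ratios are 2^(log2
    treated_t - log2 control_t).
    """
    if matrix.scale != "log2":
        raise DataError("compute_fold_changes expects a log2-scale matrix")
    sheet = matrix.samples
    control_cols = matrix.columns_for("control")
    if not control_cols:
        raise DesignError("no control samples in the sample sheet")

    control_by_time: dict[float, list[str]] = {}
    for _, row in sheet[sheet["condition"] == "control"].iterrows():
        control_by_time.setdefault(float(row.time_min), []).append(row.sample_id)
    pooled_control = matrix.values[control_cols].mean(axis=1)
    pooled_used = False

    def phase_log2fc(condition: str) -> tuple[np.ndarray, tuple[float, ...]]:
        nonlocal pooled_used
        mask = sheet["condition"] == condition
        if dose is not None:
            mask &= sheet["dose"] == dose
        times = sorted(set(sheet.loc[mask, "time_min"].astype(float)))
        cols_fc = []
        for t in times:
            cols = list(sheet.loc[mask & (sheet["time_min"] == t), "sample_id"])
            level = matrix.values[cols].mean(axis=1)
            if t in control_by_time:
                ref = matrix.values[control_by_time[t]].mean(axis=1)
            else:
                ref = pooled_control
                pooled_used = True
            cols_fc.append(level - ref)
        if not cols_fc:
            return np.empty((len(matrix.values), 0)), ()
        return np.column_stack(cols_fc), tuple(times)

    lfc_t, t_grid = phase_log2fc("treated")
    lfc_r, r_grid = phase_log2fc("rescue")
    if lfc_t.shape[1] == 0:
        raise DesignError("no treated samples in the sample sheet")
    if pooled_used:
        logger.info("some time points lack a matched control; pooled control mean used")

    return [
        TimecourseProfile(
            gene=g,
            fc_treatment=np.exp2(lfc_t[i]),
            fc_rescue=np.exp2(lfc_r[i]) if lfc_r.shape[1] else np.empty(0),
            time_grid=t_grid, rescue_grid=r_grid,
        )
        for i, g in enumerate(matrix.values.index)
    ]


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------

def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest True run; earliest start wins ties."""
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def detect_serial_regulation(profile: TimecourseProfile,
                             up_bound: float = UP_BOUND,
                             down_bound: float = DOWN_BOUND,
                             min_run: int = MIN_RUN) -> SerialRegulationCall:
    """Serial-regulation rule: a window of >= min_run consecutive treatment
    points with every ratio strictly above ``up_bound`` (up) or strictly
    below ``down_bound`` (down).

    The longest qualifying run is reported; ties between directions go to
    the earlier-starting run (then up). Boundary ratios exactly at a bound
    never qualify. ``rescue_reversed`` is true iff no qualifying run of the
    same direction exists in the rescue trajectory.
    """
    fc = profile.fc_treatment
    if len(fc) < min_run:
        raise ValidationError(
            f"profile for {profile.gene!r} has {len(fc)} treatment points, "
            f"need >= {min_run}"
        )
    up_start, up_len = _longest_run(fc > up_bound)
    dn_start, dn_len = _longest_run(fc < down_bound)

    selected = max(up_len, dn_len) >= min_run
    if not selected:
        call = SerialRegulationCall(profile.gene, False, "none", 0, 0,
                                    rescue_reversed=True)
        return call
    if up_len > dn_len or (up_len == dn_len and up_start <= dn_start):
        direction, start, length = "up", up_start, up_len
    else:
        direction, start, length = "down", dn_start, dn_len

    rescue_fc = profile.fc_rescue
    if len(rescue_fc) >= min_run:
        mask = rescue_fc > up_bound if direction == "up" else rescue_fc < down_bound
        _, rescue_run = _longest_run(mask)
        rescue_reversed = rescue_run < min_run
    else:
        rescue_reversed = True
    return SerialRegulationCall(profile.gene, True, direction, start, length,
                                rescue_reversed=rescue_reversed)


def detect_non_rescued(values: Sequence[float],
                       sd_threshold: float = SD_THRESHOLD) -> bool:
    """Flatness rule: sample SD of the log2 fold changes at the last treatment
    point plus all rescue points is at most ``sd_threshold``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("non-rescue SD needs >= 2 values")
    return float(np.std(values, ddof=1)) <= sd_threshold


def temporal_correlation(profile: TimecourseProfile, r_up: float = R_UP,
                         r_down: float = R_DOWN) -> tuple[str, float]:
    """Pearson R of log2 treatment fold changes against the time-point index.

    Classifies up when R >= r_up, down when R <= r_down, else none. A
    zero-variance profile has undefined R and is classified none with a
    warning.
    """
    y = profile.log2fc_treatment
    if len(y) < 3:
        raise ValidationError("temporal correlation needs >= 3 treatment points")
    x = np.arange(len(y), dtype=float)
    if np.std(y) == 0:
        logger.warning("gene %r: zero-variance profile, R undefined", profile.gene)
        return "none", float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if r >= r_up:
        return "up", r
    if r <= r_down:
        return "down", r
    return "none", r


def call_genes(profiles: Iterable[TimecourseProfile], *,
               up_bound: float = UP_BOUND, down_bound: float = DOWN_BOUND,
               min_run: int = MIN_RUN, sd_threshold: float = SD_THRESHOLD,
               r_up: float = R_UP, r_down: float = R_DOWN,
               ) -> list[SerialRegulationCall]:
    """Apply all four temporal filters to every profile."""
    calls = []
    for profile in profiles:
        call = detect_serial_regulation(profile, up_bound, down_bound, min_run)
        if len(profile.fc_rescue):
            tail = np.concatenate([[profile.log2fc_treatment[-1]],
                                   profile.log2fc_rescue])
            call.non_rescued = detect_non_rescued(tail, sd_threshold)
        call.temporal_class, call.temporal_R = temporal_correlation(
            profile, r_up, r_down)
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Pathway trajectories
# ---------------------------------------------------------------------------

@dataclass
class PathwayTrajectorySummary:
    """Mean member-gene log2 ratios per pathway and time point, per phase,
    plus each pathway's maximum absolute mean log2 ratio under treatment."""

    trajectories: pd.DataFrame  # index (pathway, phase), columns time points
    max_abs_log2fc: pd.Series   # pathway -> max |mean log2 ratio| (treatment)


def pathway_trajectory_summary(profiles: Sequence[TimecourseProfile],
                               gene_sets: Sequence[PathwayGeneSet],
                               ) -> PathwayTrajectorySummary:
    """Average member genes' log2 fold changes per pathway at each time point.

    Pathways with no member among the profiles are skipped with a warning.
    """
    by_gene = {p.gene: p for p in profiles}
    rows = {}
    max_abs = {}
    for gs in gene_sets:
        members = [by_gene[g] for g in sorted(gs.genes) if g in by_gene]
        if not members:
            logger.warning("pathway %r: no member gene in profiles, skipped", gs.name)
            continue
        treat = np.mean([m.log2fc_treatment for m in members], axis=0)
        rows[(gs.name, "treatment")] = treat
        if len(members[0].fc_rescue):
            rows[(gs.name, "rescue")] = np.mean(
                [m.log2fc_rescue for m in members], axis=0)
        max_abs[gs.name] = float(np.max(np.abs(treat)))
    if not rows:
        return PathwayTrajectorySummary(pd.DataFrame(), pd.Series(dtype=float))
    trajectories = pd.DataFrame.from_dict(rows, orient="index")
    trajectories.index = pd.MultiIndex.from_tuples(trajectories.index,
                                                   names=["pathway", "phase"])
    return PathwayTrajectorySummary(trajectories=trajectories,
                                    max_abs_log2fc=pd.Series(max_abs).sort_index())


def plot_pathway_trajectories(summary: PathwayTrajectorySummary, path,
                              time_grid: Sequence[float] | None = None) -> None:
    """Line chart of pathway mean log2 ratios over treatment and rescue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.trajectories.empty:
        return
    pathways = summary.trajectories.index.get_level_values("pathway").unique()
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for phase, ax in zip(("treatment", "rescue"), axes):
        for pw in pathways:
            key = (pw, phase)
            if key in summary.trajectories.index:
                y = summary.trajectories.loc[key]
                x = time_grid if time_grid is not None else range(len(y))
                ax.plot(x, y.values, marker="o", ms=3, label=pw)
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_title(phase)
        ax.set_xlabel("time (min)")
    axes[0].set_ylabel("mean log2 ratio")
    axes[0].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_timecourse(matrix: ExpressionMatrix,
                   gene_sets: Sequence[PathwayGeneSet] = (), *,
                   out_dir=None, span: float = 0.3,
                   up_bound: float = UP_BOUND, down_bound: float = DOWN_BOUND,
                   min_run: int = MIN_RUN, sd_threshold: float = SD_THRESHOLD,
                   r_up: float = R_UP, r_down: float = R_DOWN,
                   normalize: bool = True, make_plot: bool = True) -> dict:
    """Full expression arm: normalize, fold changes, temporal calls, pathways.

    When the input matrix is raw, the VST / loess / batch-correction chain is
    applied first; a matrix already on the log2 scale is normalized with
    loess + batch correction only (or taken as-is with ``normalize=False``).
    """
    if matrix.scale == "raw":
        matrix = vst_transform(matrix)
        if normalize:
            matrix = loess_normalize(matrix, span=span)
            matrix = batch_correct(matrix, allow_singleton=True)
    elif normalize:
        matrix = batch_correct(matrix, allow_singleton=True)

    profiles = compute_fold_changes(matrix)
    calls = call_genes(profiles, up_bound=up_bound, down_bound=down_bound,
                       min_run=min_run, sd_threshold=sd_threshold,
                       r_up=r_up, r_down=r_down)
    summary = pathway_trajectory_summary(profiles, gene_sets) if gene_sets else None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prof_df = pd.DataFrame(
            {p.gene: np.concatenate([p.fc_treatment, p.fc_rescue]) for p in profiles}
        ).T
        prof_df.columns = ([f"fc_treat_t{int(t)}" for t in profiles[0].time_grid]
                           + [f"fc_rescue_t{int(t)}" for t in profiles[0].rescue_grid])
        prof_df.to_csv(out_dir / "fold_changes.tsv", sep="\t", index_label="gene")
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            out_dir / "serial_calls.tsv", sep="\t", index=False)
        if summary is not None and not summary.trajectories.empty:
            summary.trajectories.to_csv(out_dir / "pathway_trajectories.tsv", sep="\t")
            summary.max_abs_log2fc.to_csv(
                out_dir / "pathway_max_abs_log2fc.tsv", sep="\t",
                header=["max_abs_log2fc"], index_label="pathway")
            if make_plot:
                plot_pathway_trajectories(summary,
                                          out_dir / "pathway_trajectories.png",
                                          profiles[0].time_grid)
    return {"matrix": matrix, "profiles": profiles, "calls": calls,
            "pathways": summary}
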