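"""Decile aggregation, regression, and cross-timescale statistics.

Within each effective network, triads are pooled into deciles of sender
mutual information and per-decile medians of the information terms are
taken; correlations and regressions relating the terms are then computed
on those ten medians. Across networks, medians are reported with
percentile-bootstrap confidence intervals, and timescale groups (synaptic,
ids 1-3, versus extrasynaptic, ids 7-9) are compared with Wilcoxon
rank-based tests in their normal-approximation form (reported as Z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .discretize import get_timescale
from .effective_network import build_effective_network, evaluate_triads, triads_to_frame
from .errors import ConfigurationError, ValidationError
from .spike_io import Recording, read_spike_table

__all__ = [
    "DecileSummary",
    "FitResult",
    "GroupComparison",
    "decile_summarize",
    "term_correlation",
    "loglog_fit",
    "bootstrap_median_ci",
    "signed_rank_test",
    "rank_sum_test",
    "holm_correct",
    "saturation_point",
    "network_stats",
    "compare_groups",
    "PipelineConfig",
    "run_pipeline",
]

TERMS = ["mi_norm", "synergy", "redundancy", "mvte", "transmission_minus_redundancy"]


@dataclass
class DecileSummary:
    """Per-decile medians of the information terms for one network.

    ``frame`` has ten rows (decile 1 = lowest sender MI) with columns
    ``decile, n`` plus the median of each term in :data:`TERMS`.
    """

    frame: pd.DataFrame = field(repr=False)
    usable: bool = True
    n_triads: int = 0


def _as_triad_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:  # list of TriadRecord
        df = triads_to_frame(data)
    df = df[np.isfinite(df["mi_norm"])]
    if "transmission_minus_redundancy" not in df.columns:
        df["transmission_minus_redundancy"] = df["mvte"] - df["redundancy"]
    return df


def decile_summarize(triads) -> DecileSummary:
    """Split triads into ten equal-count bins of sender MI and take
    per-bin medians.

    Triads are sorted by ``mi_norm``; when the count is not divisible by
    ten, the remainder is spread one-per-decile over the lowest-MI deciles
    (a fixed, deterministic rule). Fewer than ten usable triads yields a
    summary flagged unusable.
    """
    df = _as_triad_frame(triads)
    n = len(df)
    if n < 10:
        return DecileSummary(frame=pd.DataFrame(), usable=False, n_triads=n)
    df = df.sort_values("mi_norm", kind="mergesort").reset_index(drop=True)
    base, rem = divmod(n, 10)
    sizes = [base + 1 if d < rem else base for d in range(10)]
    rows = []
    start = 0
    for d, size in enumerate(sizes, start=1):
        chunk = df.iloc[start : start + size]
        start += size
        row = {"decile": d, "n": size}
        for term in TERMS:
            row[term] = float(chunk[term].median())
        rows.append(row)
    return DecileSummary(frame=pd.DataFrame(rows), usable=True, n_triads=n)


def term_correlation(summary: DecileSummary, x_term: str, y_term: str) -> float:
    """Spearman rank correlation of two terms over the ten decile medians."""
    if not summary.usable:
        raise ValidationError("summary is flagged unusable")
    x = summary.frame[x_term].to_numpy()
    y = summary.frame[y_term].to_numpy()
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing decile medians")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    n_points: int
    n_excluded: int
    log_scale: bool


def loglog_fit(summary: DecileSummary, x_term: str, y_term: str, log_scale: bool = True) -> FitResult:
    """Ordinary least squares of y on x over the decile medians, in log10
    space by default.

    Nonpositive medians cannot be log-transformed; they are excluded and
    counted rather than floored. Fewer than three usable points raises.
    """
    if not summary.usable:
        raise ValidationError("summary is flagged unusable")
    x = summary.frame[x_term].to_numpy(dtype=float)
    y = summary.frame[y_term].to_numpy(dtype=float)
    if log_scale:
        keep = (x > 0) & (y > 0)
        x, y = np.log10(x[keep]), np.log10(y[keep])
        excluded = int((~keep).sum())
    else:
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        excluded = int((~keep).sum())
    if x.size < 3:
        raise ValidationError(f"only {x.size} usable decile points for the fit")
    slope, intercept = np.polyfit(x, y, 1)
    return FitResult(float(slope), float(intercept), int(x.size), excluded, log_scale)


def bootstrap_median_ci(values, n_boot: int = 10000, seed: int | np.random.Generator = 0) -> tuple[float, float, float]:
    """Median with percentile-bootstrap 95% CI (2.5th/97.5th percentile of
    the median over resamples with replacement). Deterministic given seed."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no values to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    meds = np.median(v[idx], axis=1)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(np.median(v)), float(lo), float(hi)


def signed_rank_test(values, null_center: float = 0.0) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test in normal-approximation form.

    Returns (Z, p). Zero differences are dropped; Z is signed so that
    values above the null center give positive Z. Tie-corrected variance.
    """
    d = np.asarray(values, dtype=float).ravel() - null_center
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences are zero")
    if n < 6:
        raise ValidationError("need >= 6 nonzero differences for the normal approximation")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, normal
    approximation with tie correction. Positive Z means group A ranks
    higher."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (w - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def holm_correct(p_values) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


@dataclass
class SaturationResult:
    median_mi: float
    ci: tuple[float, float]
    per_network_mi: np.ndarray
    boundary_flags: np.ndarray  # True where the synergy peak sat on a boundary decile


def saturation_point(summaries: list[DecileSummary], n_boot: int = 10000, seed: int = 0) -> SaturationResult:
    """Sender-MI level at which decile-median synergy peaks.

    Per network: the decile-median ``mi_norm`` of the decile whose median
    synergy is maximal (boundary peaks are flagged — a monotone synergy
    curve has no interior saturation point). Across networks: median and
    bootstrap CI of those values.
    """
    per_net, flags = [], []
    for s in summaries:
        if not s.usable:
            continue
        syn = s.frame["synergy"].to_numpy()
        k = int(np.nanargmax(syn))
        per_net.append(float(s.frame["mi_norm"].iloc[k]))
        flags.append(k in (0, len(syn) - 1))
    if not per_net:
        raise ValidationError("no usable summaries")
    med, lo, hi = bootstrap_median_ci(per_net, n_boot=n_boot, seed=seed)
    return SaturationResult(med, (lo, hi), np.asarray(per_net), np.asarray(flags))


DEFAULT_PAIRS = [
    ("mi_norm", "synergy"),
    ("mi_norm", "mvte"),
    ("mi_norm", "redundancy"),
    ("mi_norm", "transmission_minus_redundancy"),
    ("synergy", "mvte"),
    ("synergy", "redundancy"),
]


def network_stats(summary: DecileSummary, pairs=None) -> pd.DataFrame:
    """Spearman r plus log-log and linear OLS fits for each term pair,
    computed on the decile medians."""
    pairs = pairs if pairs is not None else DEFAULT_PAIRS
    rows = []
    for x, y in pairs:
        row = {"x": x, "y": y, "spearman_r": term_correlation(summary, x, y)}
        try:
            fit = loglog_fit(summary, x, y, log_scale=True)
            row.update(slope_loglog=fit.slope, intercept_loglog=fit.intercept, n_log_points=fit.n_points)
        except ValidationError:
            row.update(slope_loglog=np.nan, intercept_loglog=np.nan, n_log_points=0)
        lin = loglog_fit(summary, x, y, log_scale=False)
        row.update(slope_linear=lin.slope, intercept_linear=lin.intercept)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    grouping: str
    statistic_type: str  # "rank_sum" or "signed_rank"
    z: float
    p: float
    median_a: tuple[float, float, float]  # median, lo95, hi95
    median_b: tuple[float, float, float]
    n_a: int
    n_b: int


def compare_groups(
    values_a,
    values_b,
    grouping: str = "synaptic_vs_extrasynaptic",
    paired: bool = False,
    n_boot: int = 10000,
    seed: int = 0,
) -> GroupComparison:
    """Compare a per-network statistic between two timescale groups.

    Unpaired comparisons use the rank-sum test; paired (same networks at
    two timescales) use the signed-rank test on differences. Medians carry
    bootstrap CIs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison needs equal-size groups")
        z, p = signed_rank_test(a - b, 0.0)
        kind = "signed_rank"
    else:
        z, p = rank_sum_test(a, b)
        kind = "rank_sum"
    rng = np.random.default_rng(seed)
    med_a = bootstrap_median_ci(a, n_boot=n_boot, seed=rng)
    med_b = bootstrap_median_ci(b, n_boot=n_boot, seed=rng)
    return GroupComparison(grouping, kind, z, p, med_a, med_b, a.size, b.size)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineConfig:
    """Settings for a full analysis run.

    ``recordings`` may hold :class:`Recording` objects or spike-table
    paths. Defaults match the full-scale analysis (5000 jitters at
    alpha 0.001, 10000 bootstrap iterations); scale them down together —
    alpha can only be resolved when ``n_jitter >= 1/alpha - 1``.
    """

    recordings: list
    timescale_ids: list[int]
    out_dir: str | Path | None = None
    n_jitter: int = 5000
    alpha: float = 0.001
    n_boot: int = 10000
    seed: int = 0
    pid_mode: str = "imin"
    normalized: bool = True
    triad_level: bool = False  # also emit per-triad (non-decile) statistics


@dataclass
class NetworkResult:
    recording_label: str
    timescale_id: int
    network: object
    triad_frame: pd.DataFrame = field(repr=False)
    summary: DecileSummary = None
    stats: pd.DataFrame = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    networks: list[NetworkResult]
    comparisons: list[GroupComparison]


def _load_recording(item, index: int) -> Recording:
    if isinstance(item, Recording):
        return item
    path = Path(item)
    if not path.exists():
        raise ConfigurationError(f"input path does not exist: {path}")
    rec = read_spike_table(path)
    if not rec.label:
        rec.label = path.stem
    return rec


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis: effective network, triad evaluation, decile
    summary and per-network statistics for every recording x timescale,
    then synaptic-vs-extrasynaptic group comparison of the MI-synergy
    Spearman correlation when both groups are represented.

    Fully deterministic given ``config.seed``: every stage draws from a
    child generator spawned from one seed sequence in a fixed order.
    """
    if not config.recordings:
        raise ConfigurationError("no recordings configured")
    if not config.timescale_ids:
        raise ConfigurationError("no timescales configured")
    recordings = [_load_recording(r, i) for i, r in enumerate(config.recordings)]
    specs = [get_timescale(t) for t in config.timescale_ids]
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(recordings) * len(specs) + 1)
    results: list[NetworkResult] = []
    spearman_by_group: dict[str, list[float]] = {}
    job = 0
    for ri, rec in enumerate(recordings):
        label = rec.label or f"rec{ri}"
        for spec in specs:
            rng = np.random.default_rng(children[job])
            job += 1
            network = build_effective_network(
                rec, spec, n_jitter=config.n_jitter, alpha=config.alpha, rng=rng
            )
            records = evaluate_triads(
                rec, network, mode=config.pid_mode, normalize=config.normalized
            )
            frame = triads_to_frame(records)
            summary = decile_summarize(frame)
            stats_frame = network_stats(summary) if summary.usable else None
            if summary.usable:
                r = term_correlation(summary, "mi_norm", "synergy")
                spearman_by_group.setdefault(spec.group, []).append(r)
            results.append(
                NetworkResult(label, spec.id, network, frame, summary, stats_frame)
            )
            if out_dir is not None:
                stem = f"{label}_ts{spec.id}"
                network.write_edge_list(out_dir / f"{stem}_edges.tsv")
                frame.to_csv(out_dir / f"{stem}_triads.tsv", sep="\t", index=False)
                if summary.usable:
                    summary.frame.to_csv(out_dir / f"{stem}_deciles.tsv", sep="\t", index=False)
                    stats_frame.to_csv(out_dir / f"{stem}_stats.tsv", sep="\t", index=False)

    comparisons: list[GroupComparison] = []
    syn = spearman_by_group.get("synaptic", [])
    extra = spearman_by_group.get("extrasynaptic", [])
    if syn and extra:
        comparisons.append(
            compare_groups(
                syn, extra,
                grouping="mi_synergy_spearman:synaptic_vs_extrasynaptic",
                n_boot=config.n_boot,
                seed=np.random.default_rng(children[-1]),
            )
        )

    if out_dir is not None:
        manifest = {
            "n_recordings": len(recordings),
            "timescale_ids": list(config.timescale_ids),
            "n_jitter": config.n_jitter,
            "alpha": config.alpha,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "pid_mode": config.pid_mode,
            "normalized": config.normalized,
            "comparisons": [
                {
                    "grouping": c.grouping,
                    "statistic_type": c.statistic_type,
                    "z": c.z,
                    "p": c.p,
                    "median_a": c.median_a,
                    "median_b": c.median_b,
                }
                for c in comparisons
            ],
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineResult(config=config, networks=results, comparisons=comparisons)
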