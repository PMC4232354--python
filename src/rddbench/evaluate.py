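"""Detection-theory scoring of RDD call sets against the simulated truth.

A truth site (after the configurable truth-side restrictions on coverage
and level) is a true positive when matched by a call with the same alt
base, otherwise a false negative. Calls at positions that are not truth
sites — or with the wrong alt — are false positives; calls matching truth
sites that fall outside the restrictions are excluded from both counts.
Sensitivity = TP/(TP+FN), FDR = FP/(TP+FP), and FPR uses as denominator
the number of non-truth sites whose coverage meets the call threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import PileupCounts, Thresholds, call_rdds
from .genome import GenomeModel
from .rdds import CoverageStrata, ClusterConfig


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    fdr: float | None
    fpr: float | None
    n_truth_restricted: int
    n_calls: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def fnr(self) -> float | None:
        return None if self.sensitivity is None else 1.0 - self.sensitivity

    def summary(self) -> str:
        fmt = lambda v: "NA" if v is None else f"{100 * v:.3f}%"
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn}  "
            f"sensitivity={fmt(self.sensitivity)} FDR={fmt(self.fdr)} "
            f"FPR={fmt(self.fpr)}"
        )


def match_calls(calls: pd.DataFrame, truth: pd.DataFrame,
                require_alt: bool = True) -> tuple[pd.Series, pd.Series]:
    """(per-call: matches any truth site; per-truth-site: matched by a call)."""
    cols = ["chrom", "pos", "alt"] if require_alt else ["chrom", "pos"]
    tkey = pd.MultiIndex.from_frame(truth[cols])
    ckey = pd.MultiIndex.from_frame(calls[cols])
    return pd.Series(ckey.isin(tkey), index=calls.index), pd.Series(
        tkey.isin(ckey), index=truth.index
    )


def score_calls(calls: pd.DataFrame, truth: pd.DataFrame,
                truth_min_coverage: int = 0, truth_min_level: float = 0.0,
                level_basis: str = "realized",
                coverage: dict[str, np.ndarray] | None = None,
                fpr_min_coverage: int | None = None,
                require_alt: bool = True,
                strata_columns: tuple[str, ...] = ()) -> EvalReport:
    """Confusion counts and rates for a call set against the truth table.

    level_basis selects which truth-side level ("simulated" f or the
    "realized" k/c) the restriction applies to. If a coverage track is
    given, FPR is computed over non-truth sites with coverage >=
    fpr_min_coverage (default: truth_min_coverage).
    """
    basis = {"simulated": "level", "realized": "realized_level"}[level_basis]
    restricted = truth[
        (truth["coverage"] >= truth_min_coverage) & (truth[basis] >= truth_min_level)
    ]
    call_in_any_truth, _ = match_calls(calls, truth, require_alt)
    _, truth_detected = match_calls(calls, restricted, require_alt)

    tp = int(truth_detected.sum())
    fn = len(restricted) - tp
    fp = int((~call_in_any_truth).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    if len(restricted) == 0:
        warnings.warn("no truth sites pass the restrictions; sensitivity undefined")
    fdr = fp / (tp + fp) if (tp + fp) > 0 else None

    fpr = None
    if coverage is not None:
        cmin = truth_min_coverage if fpr_min_coverage is None else fpr_min_coverage
        eligible = sum(int((cov >= cmin).sum()) for cov in coverage.values())
        n_truth = len(truth)
        denom = eligible - n_truth
        fpr = fp / denom if denom > 0 else None

    tables: dict[str, pd.DataFrame] = {}
    if strata_columns:
        t = restricted.assign(detected=truth_detected[restricted.index].to_numpy())
        for col in strata_columns:
            if col not in t.columns:
                continue
            tables[f"sensitivity_by_{col}"] = (
                t.groupby(col)["detected"].agg(["size", "sum", "mean"])
                .rename(columns={"size": "n", "sum": "tp", "mean": "sensitivity"})
                .reset_index()
            )
    return EvalReport(tp=tp, fp=fp, fn=fn, sensitivity=sensitivity, fdr=fdr,
                      fpr=fpr, n_truth_restricted=len(restricted),
                      n_calls=len(calls), tables=tables)


def roc_grid(pc: PileupCounts, model: GenomeModel, truth: pd.DataFrame,
             grid: list[Thresholds],
             coverage: dict[str, np.ndarray] | None = None,
             **score_kw) -> pd.DataFrame:
    """One scored row per threshold triple."""
    if not grid:
        raise ValueError("empty threshold grid")
    rows = []
    for th in grid:
        calls = call_rdds(pc, model, th)
        rep = score_calls(calls, truth, coverage=coverage, **score_kw)
        rows.append({
            "min_coverage": th.min_coverage, "min_level": th.min_level,
            "min_alt_reads": th.min_alt_reads, "n_calls": rep.n_calls,
            "tp": rep.tp, "fp": rep.fp, "fn": rep.fn,
            "sensitivity": rep.sensitivity, "fdr": rep.fdr, "fpr": rep.fpr,
        })
    return pd.DataFrame(rows)


@dataclass
class LevelAgreement:
    correlation: float | None
    frac_deviating_gt5: float
    frac_deviating_ge10: float
    frac_deviating_gt30: float
    underestimate_share_ge10: float | None
    n_pairs: int


def level_agreement(calls: pd.DataFrame, truth: pd.DataFrame,
                    truth_level_column: str = "level") -> LevelAgreement:
    """Observed-vs-simulated level agreement over matched true positives.

    Deviations are absolute differences in percentage points; among sites
    deviating by >= 10 points, the underestimating share is reported.
    """
    tside = truth[["chrom", "pos", "alt", truth_level_column]].rename(
        columns={truth_level_column: "truth_level"})
    merged = calls.merge(tside, on=["chrom", "pos", "alt"], how="inner")
    n = len(merged)
    if n == 0:
        return LevelAgreement(None, 0.0, 0.0, 0.0, None, 0)
    obs = merged["level"].to_numpy()
    sim = merged["truth_level"].to_numpy()
    corr = float(np.corrcoef(obs, sim)[0, 1]) if n >= 2 else None
    dev = (obs - sim) * 100.0
    adev = np.abs(dev)
    eps = 1e-9  # guard the percentage-point cutoffs against float noise
    ge10 = adev >= 10.0 - eps
    under = float((dev[ge10] < 0).mean()) if ge10.any() else None
    return LevelAgreement(
        correlation=corr,
        frac_deviating_gt5=float((adev > 5.0 + eps).mean()),
        frac_deviating_ge10=float(ge10.mean()),
        frac_deviating_gt30=float((adev > 30.0 + eps).mean()),
        underestimate_share_ge10=under,
        n_pairs=n,
    )


def filter_efficacy(verdicts: pd.DataFrame, is_tp: pd.Series) -> pd.DataFrame:
    """Per-filter and combined removal percentages among TP and FP calls,
    with FDR before/after. `verdicts` is apply_filters output; is_tp labels
    each call."""
    is_tp = is_tp.to_numpy().astype(bool)
    n_tp, n_fp = int(is_tp.sum()), int((~is_tp).sum())
    fdr_before = n_fp / (n_tp + n_fp) if (n_tp + n_fp) else None
    filt_cols = [c for c in verdicts.columns if c.startswith("removed_")]
    rows = []
    for col in filt_cols + ["removed"]:
        rem = verdicts[col].to_numpy().astype(bool)
        tp_rem = int((rem & is_tp).sum())
        fp_rem = int((rem & ~is_tp).sum())
        tp_after = n_tp - tp_rem
        fp_after = n_fp - fp_rem
        rows.append({
            "filter": "combined" if col == "removed" else col[len("removed_"):],
            "pct_tp_removed": 100.0 * tp_rem / n_tp if n_tp else 0.0,
            "pct_fp_removed": 100.0 * fp_rem / n_fp if n_fp else 0.0,
            "fdr_before": fdr_before,
            "fdr_after": (fp_after / (tp_after + fp_after)
                          if (tp_after + fp_after) else None),
        })
    return pd.DataFrame(rows)


def cluster_recruitment_stats(truth: pd.DataFrame, strata: CoverageStrata,
                              model: GenomeModel,
                              cluster_config: ClusterConfig | None = None) -> dict:
    """Replay hyperediting-cluster eligibility from the truth table and
    measure the realised same-type recruitment fraction.

    For each cluster (in seeding order), the eligible positions are those
    within the window of the seed, sharing its reference base and coverage
    bin, and not already occupied by an RDD at that point of the replay;
    the recruited positions are the cluster's non-seed truth rows.
    """
    cc = cluster_config or ClusterConfig()
    seeds = truth[truth["is_seed"]].sort_values("cluster_id")
    recruits = truth[(truth["cluster_id"] >= 0) & ~truth["is_seed"]]
    independent = truth[(truth["cluster_id"] < 0) | truth["is_seed"]]
    occupied = set(zip(independent["chrom"], independent["pos"]))
    rec_by_cluster = {
        cid: set(zip(g["chrom"], g["pos"]))
        for cid, g in recruits.groupby("cluster_id")
    }
    n_eligible = n_recruited = 0
    for seed_row in seeds.itertuples():
        chrom = seed_row.chrom
        codes = model.chromosomes[chrom]
        bins = strata.bins[chrom]
        ref_code = codes[seed_row.pos]
        lo = max(seed_row.pos - cc.window, 0)
        hi = min(seed_row.pos + cc.window + 1, codes.size)
        window = np.arange(lo, hi)
        elig = window[(codes[window] == ref_code) & (bins[window] == seed_row.bin)]
        got = rec_by_cluster.get(seed_row.cluster_id, set())
        for p in elig:
            p = int(p)
            if (chrom, p) in occupied and (chrom, p) not in got:
                continue
            n_eligible += 1
            if (chrom, p) in got:
                n_recruited += 1
        occupied |= got
    return {
        "n_clusters": len(seeds),
        "n_eligible": n_eligible,
        "n_recruited": n_recruited,
        "same_type_fraction": n_recruited / n_eligible if n_eligible else None,
    }


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_sensitivity_by_coverage(table: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(table.iloc[:, 0].astype(str), 100 * table["sensitivity"])
    ax.set_xlabel("coverage bin")
    ax.set_ylabel("sensitivity (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_grid(grid: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = [
        f"{r.min_coverage}x/{int(100 * r.min_level)}%/{r.min_alt_reads}"
        for r in grid.itertuples()
    ]
    ax.bar(labels, [100 * (r or 0) for r in grid["fdr"]])
    ax.set_ylabel("FDR (%)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
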