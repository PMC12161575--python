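"""Species-level refinement of the PWM score floor and hit deduplication.

A p-value floor alone admits a fixed rate of background matches. Because true
operator sites concentrate in non-coding (promoter) DNA while background
matches fall anywhere, the share of hits landing in non-coding sequence rises
with the score threshold; sweeping a threshold grid over that ratio yields a
calibration curve from which a refined, genome-specific threshold is chosen.
Surviving hits are then collapsed to unique binding-site locations (palindromic
motifs are matched on both strands at one interval; divergent promoters report
one site from two genes' windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CalibrationCurve:
    """Hit counts and non-coding share over an ascending threshold grid.

    ratio(s) = 100 * n_noncoding(s) / (n_noncoding(s) + n_coding(s)), NaN where
    no hits remain.
    """

    thresholds: np.ndarray
    n_noncoding: np.ndarray
    n_coding: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        total = self.n_noncoding + self.n_coding
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 100.0 * self.n_noncoding / total
        return np.where(total > 0, r, np.nan)

    @property
    def raw_quotient(self) -> np.ndarray:
        """Unbounded noncoding:coding quotient (inf where coding count is 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.n_noncoding / self.n_coding

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_noncoding": self.n_noncoding,
                "n_coding": self.n_coding,
                "ratio_pct": self.ratio,
            }
        )


def ratio_curve(hits: pd.DataFrame, grid_step: float = 0.125) -> CalibrationCurve:
    """Sweep a score grid and count surviving coding/non-coding hits."""
    if hits.empty:
        raise ValueError("cannot build a calibration curve from an empty hit list")
    scores = hits["score"].to_numpy(float)
    is_nc = (hits["region_class"] == "noncoding").to_numpy()
    lo = np.floor(scores.min() / grid_step) * grid_step
    hi = np.ceil(scores.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    n_nc = np.array([(is_nc & (scores >= s)).sum() for s in grid])
    n_c = np.array([(~is_nc & (scores >= s)).sum() for s in grid])
    return CalibrationCurve(thresholds=grid, n_noncoding=n_nc, n_coding=n_c)


def refined_threshold(
    hits: pd.DataFrame,
    method: str = "ratio_median_crossing",
    grid_step: float = 0.125,
) -> float:
    """Refine the p-value floor into a species-calibrated score threshold.

    ``ratio_median_crossing`` (default): smallest grid score at which the
    non-coding hit share reaches the median of its defined values over the
    grid — the reading under which a permissive p-value floor is tightened to
    the regime where promoter hits dominate. ``median_hit_score``: plain
    median of all floor-passing hit scores (even count = midpoint of the
    central pair). Both readings are in circulation for this calibration; see
    the methods note.
    """
    if hits.empty:
        raise ValueError("cannot refine a threshold from an empty hit list")
    if method == "median_hit_score":
        return float(np.median(hits["score"].to_numpy(float)))
    if method == "ratio_median_crossing":
        curve = ratio_curve(hits, grid_step=grid_step)
        ratio = curve.ratio
        defined = ratio[~np.isnan(ratio)]
        med = float(np.median(defined))
        crossing = np.nonzero(~np.isnan(ratio) & (ratio >= med))[0]
        return float(curve.thresholds[crossing[0]])
    raise ValueError(f"unknown refinement method: {method}")


def filter_and_dedupe(
    hits: pd.DataFrame, threshold: float, merge_overlapping: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the refined threshold and collapse hits to unique site locations.

    A location is a distinct (contig, start, end) interval regardless of
    strand; it keeps the best score, the set of strands it matched on, and the
    union of regulatory windows that contain it. With ``merge_overlapping``,
    locations whose intervals overlap are additionally merged into one site
    (coordinates of the best-scoring interval): shifted self-overlapping
    matches of a near-palindromic motif describe one operator, not several.
    """
    surviving = hits[hits["score"] >= threshold].reset_index(drop=True)
    if surviving.empty:
        locations = pd.DataFrame(
            columns=["contig", "start", "end", "best_score", "strands", "windows", "n_hits"]
        )
        return surviving, locations
    records = []
    for (contig, start, end), group in surviving.groupby(
        ["contig", "start", "end"], sort=True
    ):
        windows: set[str] = set()
        for w in group["windows"]:
            windows.update(w)
        records.append(
            {
                "contig": contig,
                "start": int(start),
                "end": int(end),
                "best_score": float(group["score"].max()),
                "strands": "".join(sorted(set(group["strand"]))),
                "windows": tuple(sorted(windows)),
                "n_hits": len(group),
            }
        )
    locations = pd.DataFrame.from_records(records).sort_values(
        ["contig", "start"]
    ).reset_index(drop=True)
    if merge_overlapping:
        locations = _merge_overlapping_locations(locations)
    return surviving, locations


def _merge_overlapping_locations(locations: pd.DataFrame) -> pd.DataFrame:
    """Chain-merge overlapping location intervals, keeping the best interval."""
    merged_records = []
    for contig, group in locations.groupby("contig", sort=True):
        group = group.sort_values("start")
        cluster: list = []
        cluster_end = -1
        for row in group.itertuples():
            if cluster and row.start < cluster_end:
                cluster.append(row)
                cluster_end = max(cluster_end, row.end)
            else:
                if cluster:
                    merged_records.append(_collapse_cluster(cluster))
                cluster = [row]
                cluster_end = row.end
        if cluster:
            merged_records.append(_collapse_cluster(cluster))
    return pd.DataFrame.from_records(merged_records).sort_values(
        ["contig", "start"]
    ).reset_index(drop=True)


def _collapse_cluster(cluster: list) -> dict:
    best = max(cluster, key=lambda r: r.best_score)
    windows: set[str] = set()
    strands: set[str] = set()
    for r in cluster:
        windows.update(r.windows)
        strands.update(r.strands)
    return {
        "contig": best.contig,
        "start": int(best.start),
        "end": int(best.end),
        "best_score": float(best.best_score),
        "strands": "".join(sorted(strands)),
        "windows": tuple(sorted(windows)),
        "n_hits": sum(r.n_hits for r in cluster),
    }


def write_locations(locations: pd.DataFrame, tsv_path, bed_path=None) -> None:
    flat = locations.copy()
    flat["windows"] = [";".join(w) for w in flat["windows"]]
    flat.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for row in locations.itertuples():
                name = row.windows[0] if row.windows else "."
                score = min(1000, int(round(row.best_score * 100)))
                strand = row.strands if len(row.strands) == 1 else "."
                fh.write(
                    f"{row.contig}\t{row.start}\t{row.end}\t{name}\t{score}\t{strand}\n"
                )


def read_locations(tsv_path) -> pd.DataFrame:
    locations = pd.read_csv(tsv_path, sep="\t")
    locations["windows"] = [
        tuple(w.split(";")) if isinstance(w, str) and w else ()
        for w in locations["windows"].fillna("")
    ]
    return locations


def plot_calibration(
    hits: pd.DataFrame,
    curve: CalibrationCurve,
    threshold: float,
    path,
) -> None:
    """Violin of hit scores with the non-coding ratio curve and threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.violinplot(hits["score"].to_numpy(float), positions=[0], widths=0.8)
    ax1.set_ylabel("PWM score (bits)")
    ax1.set_xticks([])
    ax2 = ax1.twiny()
    ax2.plot(curve.ratio, curve.thresholds, color="tab:blue")
    ax2.set_xlabel("non-coding hit share (%)")
    ax1.axhline(threshold, color="tab:orange", linestyle=":", label=f"threshold {threshold:g}")
    ax1.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
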