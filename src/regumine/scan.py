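"""Region extraction and exact-p-value PWM scanning of annotated genomes.

The scanner scores every motif-length window on both strands of each contig,
reports placements above a score floor derived from the exact distribution of
PWM scores under the background composition, labels hits coding/non-coding by
their midpoint, and records which genes' regulatory windows (by default
-350/+50 bp around the start codon) contain each hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    AnnotatedGenome,
    complement_intervals,
    interval_mask,
    merge_intervals,
)
from .motif import PWM, Background, encode_sequence

HIT_COLUMNS = [
    "contig", "start", "end", "strand", "score", "region_class", "windows", "confidence",
]


@dataclass
class RegionSet:
    """Coding/non-coding partition of each contig plus per-gene regulatory windows.

    ``coding``/``noncoding`` map contig -> merged disjoint half-open intervals
    that together tile the contig; ``regulatory`` maps gene id ->
    (contig, start, end). Windows are an overlay: they may overlap coding
    sequence of upstream genes.
    """

    coding: dict[str, list[tuple[int, int]]]
    noncoding: dict[str, list[tuple[int, int]]]
    regulatory: dict[str, tuple[str, int, int]]


def extract_regions(
    genome: AnnotatedGenome, upstream: int = 350, downstream: int = 50
) -> RegionSet:
    """Partition contigs into coding/non-coding and build regulatory windows.

    For a + strand gene starting at s the window is [s-upstream, s+downstream);
    for a - strand gene ending at e it is [e-downstream, e+upstream), both
    clipped to contig bounds. Overlapping gene bodies are merged before
    complementing so coding/non-coding is a true partition.
    """
    coding: dict[str, list[tuple[int, int]]] = {}
    noncoding: dict[str, list[tuple[int, int]]] = {}
    for contig, seq in genome.contigs.items():
        rows = genome.genes[genome.genes["contig"] == contig]
        merged = merge_intervals([(int(r.start), int(r.end)) for r in rows.itertuples()])
        coding[contig] = merged
        noncoding[contig] = complement_intervals(merged, len(seq))

    regulatory: dict[str, tuple[str, int, int]] = {}
    for row in genome.genes.itertuples():
        clen = genome.contig_length(row.contig)
        if row.strand == "+":
            lo, hi = row.start - upstream, row.start + downstream
        else:
            lo, hi = row.end - downstream, row.end + upstream
        lo, hi = max(0, lo), min(clen, hi)
        if hi <= lo:
            warnings.warn(f"zero-length regulatory window for {row.gene_id}; dropped")
            continue
        regulatory[row.gene_id] = (row.contig, lo, hi)
    return RegionSet(coding=coding, noncoding=noncoding, regulatory=regulatory)


# ---------------------------------------------------------------------------
# Exact score distribution and p-value calibrated floor


def exact_score_distribution(
    pwm: PWM, background: Background | None = None, granularity: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of PWM scores of random background sequences.

    Scores are discretized to ``granularity`` bits rounding toward -inf and the
    per-position score distributions are convolved. Returns (grid_scores,
    probabilities) with grid_scores ascending.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = background or pwm.background
    p = bg.base_probs
    q = np.floor(pwm.scores / granularity).astype(np.int64)  # 4 x L integer grid
    lo = int(q.min(axis=0).sum())
    hi = int(q.max(axis=0).sum())
    span = hi - lo + 1
    # dist[i] = P(sum == lo + i), built position by position
    dist = np.zeros(span)
    dist[0 - 0] = 0.0
    # start with the first position
    first = np.zeros(span)
    base0 = int(q[:, 0].min())
    for b in range(4):
        first[q[b, 0] - base0] += p[b]
    dist = first
    offset = base0  # current minimum achievable integer score
    for i in range(1, pwm.length):
        col = q[:, i]
        cmin = int(col.min())
        new = np.zeros(span)
        for b in range(4):
            shift = col[b] - cmin
            if shift == 0:
                new += p[b] * dist
            else:
                new[shift:] += p[b] * dist[:-shift]
        dist = new
        offset += cmin
    grid = (np.arange(span) + offset) * granularity
    return grid, dist


def score_threshold_from_pvalue(
    pwm: PWM,
    background: Background | None = None,
    p: float = 0.01,
    granularity: float = 0.001,
) -> float:
    """Least score s with P(score >= s) <= p under the background model.

    Discretization rounds scores down, so the returned floor is conservative:
    any true sequence score is >= its discretized value.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    grid, dist = exact_score_distribution(pwm, background, granularity)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(score >= grid[i])
    ok = np.nonzero(tail <= p)[0]
    if ok.size == 0:
        warnings.warn(f"no score has tail probability <= {p}; returning max_score")
        return pwm.max_score
    return float(grid[ok[0]])


# ---------------------------------------------------------------------------
# Scanning


def _position_scores(idx: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Score of the length-L window starting at every offset of idx."""
    length = scores.shape[1]
    n_pos = idx.size - length + 1
    if n_pos <= 0:
        return np.empty(0)
    out = np.zeros(n_pos)
    for k in range(length):
        out += scores[:, k][idx[k : k + n_pos]]
    return out


def scan(
    genome: AnnotatedGenome,
    regions: RegionSet,
    pwm: PWM,
    floor: float,
    confidence_fraction: float = 0.7,
) -> pd.DataFrame:
    """Scan both strands of every contig, reporting placements scoring >= floor.

    Hits are returned as a DataFrame with forward-strand 0-based half-open
    coordinates; ``region_class`` is assigned by the hit midpoint and
    ``windows`` lists the gene ids whose regulatory window fully contains the
    hit. Palindromic double-strand hits at one interval are both emitted;
    deduplication is left to calibration.
    """
    length = pwm.length
    records: list[dict] = []
    rc_scores = pwm.reverse_complement().scores
    for contig, seq in genome.contigs.items():
        if len(seq) < length:
            continue  # contig shorter than motif: nothing to scan
        idx = encode_sequence(seq)
        fwd = _position_scores(idx, pwm.scores)
        # reverse-complement matches found by scoring the forward sequence
        # with the reverse-complemented matrix
        rev = _position_scores(idx, rc_scores)
        coding_mask = interval_mask(regions.coding.get(contig, []), len(seq))
        windows = [
            (gid, lo, hi)
            for gid, (wc, lo, hi) in regions.regulatory.items()
            if wc == contig
        ]
        windows.sort(key=lambda t: t[1])
        for strand, pos_scores in (("+", fwd), ("-", rev)):
            hit_pos = np.nonzero(pos_scores >= floor)[0]
            for start in hit_pos:
                start = int(start)
                end = start + length
                mid = start + length // 2
                contained = tuple(
                    gid for gid, lo, hi in windows if lo <= start and end <= hi
                )
                records.append(
                    {
                        "contig": contig,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "score": float(pos_scores[start]),
                        "region_class": "coding" if coding_mask[mid] else "noncoding",
                        "windows": contained,
                        "confidence": classify_confidence(
                            float(pos_scores[start]), pwm, confidence_fraction
                        ),
                    }
                )
    hits = pd.DataFrame(records, columns=HIT_COLUMNS)
    return hits.sort_values(["contig", "start", "strand"]).reset_index(drop=True)


def classify_confidence(score: float, pwm: PWM, fraction: float = 0.7) -> str:
    """Tier a floor-passing hit: medium_high iff score >= fraction * max_score.

    fraction <= 0 disables tiering (every hit medium_high), including for
    floors below zero bits where fraction * max_score would misbehave.
    """
    if fraction <= 0:
        return "medium_high"
    return "medium_high" if score >= fraction * pwm.max_score else "low"


def associate_hits_with_regions(
    hits: pd.DataFrame,
    bgc_regions: list[tuple[str, int, int]],
    periphery: int,
) -> pd.DataFrame:
    """Label each hit inside/peripheral/outside relative to candidate BGC regions.

    Peripheral = within a region but within ``periphery`` bp of either region
    edge. Returns the hits with added ``association`` and ``region`` columns.
    """
    labels = []
    region_ids = []
    for row in hits.itertuples():
        label, region_id = "outside", None
        for i, (contig, lo, hi) in enumerate(bgc_regions):
            if contig != row.contig or not (lo <= row.start and row.end <= hi):
                continue
            edge_dist = min(row.start - lo, hi - row.end)
            label = "peripheral" if edge_dist <= periphery else "inside"
            region_id = i
            break
        labels.append(label)
        region_ids.append(region_id)
    out = hits.copy()
    out["association"] = labels
    out["region"] = region_ids
    return out


# ---------------------------------------------------------------------------
# Hit table I/O


def write_hits(hits: pd.DataFrame, tsv_path, bed_path=None) -> None:
    """Write hits as TSV (full precision) and optionally BED6.

    BED name = first containing window's gene (or '.'), BED score = PWM bits
    x100 rounded, capped at 1000 per BED convention.
    """
    flat = hits.copy()
    flat["windows"] = [";".join(w) for w in flat["windows"]]
    flat.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for row in hits.itertuples():
                name = row.windows[0] if row.windows else "."
                bed_score = min(1000, int(round(row.score * 100)))
                fh.write(
                    f"{row.contig}\t{row.start}\t{row.end}\t{name}\t{bed_score}\t{row.strand}\n"
                )


def read_hits(tsv_path) -> pd.DataFrame:
    hits = pd.read_csv(tsv_path, sep="\t")
    hits["windows"] = [
        tuple(w.split(";")) if isinstance(w, str) and w else ()
        for w in hits["windows"].fillna("")
    ]
    return hits
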