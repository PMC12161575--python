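"""Position frequency/weight matrices and information content for TF binding motifs.

A motif is summarised as a position frequency matrix (PFM) of base counts per
column, converted to a position weight matrix (PWM) of log2 likelihood ratios
against a background base composition (here parameterised only by GC content,
appropriate for high-GC actinobacterial genomes), and visualised/quantified via
per-position Shannon information content.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G in row order A,C,G,T


@dataclass(frozen=True)
class Background:
    """Zero-order background base composition with strand symmetry.

    P(A)=P(T)=(1-gc)/2 and P(C)=P(G)=gc/2.
    """

    gc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must be in (0, 1), got {self.gc}")

    @property
    def base_probs(self) -> np.ndarray:
        at = (1.0 - self.gc) / 2.0
        cg = self.gc / 2.0
        return np.array([at, cg, cg, at])


@dataclass(frozen=True)
class PFM:
    """Base counts per motif column; rows in fixed order A, C, G, T."""

    counts: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PFM counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if not (counts.sum(axis=0) == self.n_sites).all():
            raise ValueError("every PFM column must sum to n_sites")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sites

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log2 likelihood-ratio scores per base and column, with its background."""

    scores: np.ndarray
    background: Background
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[0] != 4:
            raise ValueError("PWM scores must be a 4 x L matrix")

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        rc = self.scores[_COMPLEMENT_ORDER, ::-1]
        return PWM(rc, self.background, self.pseudocount)


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to row indices; rejects other characters."""
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq.upper() if c not in _BASE_INDEX})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return arr.astype(np.int64)


def build_pfm(sites: list[str]) -> PFM:
    """Count base occurrences per position over aligned, equal-length sites.

    IUPAC ambiguity codes are rejected: curated operator collections are
    expected to be fully resolved sequences.
    """
    if len(sites) == 0:
        raise ValueError("at least one site is required")
    length = len(sites[0])
    if length == 0:
        raise ValueError("sites must be non-empty strings")
    if any(len(s) != length for s in sites):
        raise ValueError("all sites must have identical length")
    counts = np.zeros((4, length), dtype=int)
    for site in sites:
        idx = encode_sequence(site)
        counts[idx, np.arange(length)] += 1
    return PFM(counts, n_sites=len(sites))


def pfm_to_pwm(
    pfm: PFM,
    background: Background,
    pseudocount: float = 0.8,
    allow_infinite: bool = False,
) -> PWM:
    """Convert counts to log2 likelihood-ratio scores against the background.

    score[b][i] = log2( (counts[b][i] + pseudocount*p_b) / (n + pseudocount) / p_b ).
    With pseudocount 0 a zero count maps to -inf, which is rejected unless
    ``allow_infinite`` is set (useful only for textbook identities).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    p = background.base_probs[:, None]
    counts = pfm.counts.astype(float)
    if pseudocount == 0 and (counts == 0).any() and not allow_infinite:
        raise ValueError(
            "pseudocount 0 with zero counts yields -inf scores; "
            "pass allow_infinite=True to permit this"
        )
    with np.errstate(divide="ignore"):
        scores = np.log2((counts + pseudocount * p) / (pfm.n_sites + pseudocount) / p)
    return PWM(scores, background, pseudocount)


def information_content(
    pfm: PFM,
    small_sample_correction: bool = False,
    relative_to_background: Background | None = None,
) -> np.ndarray:
    """Per-position information content in bits.

    Default is the uniform-background Shannon form IC_i = 2 - H_i used by
    sequence-logo renderers; ``relative_to_background`` switches to relative
    entropy against that composition. The small-sample correction subtracts
    3/(2 ln2 n) (the expected entropy underestimate for n sites).
    """
    f = pfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        if relative_to_background is None:
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
            ic = 2.0 + plogp.sum(axis=0)
        else:
            p = relative_to_background.base_probs[:, None]
            terms = np.where(f > 0, f * np.log2(f / p), 0.0)
            ic = terms.sum(axis=0)
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2) * pfm.n_sites)
    return ic


def score_sequence(pwm: PWM, seq: str) -> float:
    """PWM score of a sequence exactly as long as the motif."""
    idx = encode_sequence(seq)
    if idx.size != pwm.length:
        raise ValueError(f"sequence length {idx.size} != motif length {pwm.length}")
    return float(pwm.scores[idx, np.arange(pwm.length)].sum())


# ---------------------------------------------------------------------------
# I/O


def read_sites(path: str | Path) -> list[str]:
    """Read aligned binding sites from FASTA or one-sequence-per-line text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        return [str(rec.seq).upper() for rec in SeqIO.parse(_io.StringIO(text), "fasta")]
    return [line.strip().upper() for line in text.splitlines() if line.strip()]


def write_jaspar(pfm: PFM, path: str | Path, name: str = "motif") -> None:
    from Bio import motifs as bio_motifs

    m = _to_biopython(pfm, name)
    Path(path).write_text(bio_motifs.write([m], "jaspar"))


def read_jaspar(path: str | Path) -> PFM:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
    n = int(round(counts[:, 0].sum()))
    return PFM(counts.round().astype(int), n_sites=n)


def write_meme(pfm: PFM, path: str | Path, name: str = "motif",
               background: Background | None = None) -> None:
    """Write a minimal MEME (version 4) motif file."""
    bg = background or Background(0.5)
    p = bg.base_probs
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        f"A {p[0]:.5f} C {p[1]:.5f} G {p[2]:.5f} T {p[3]:.5f}",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pfm.length} nsites= {pfm.n_sites}",
    ]
    for col in pfm.frequencies.T:
        lines.append(" " + " ".join(f"{x:.6f}" for x in col))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> PFM:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    m = record[0]
    counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
    n = int(round(counts[:, 0].sum()))
    return PFM(counts.round().astype(int), n_sites=n)


def _to_biopython(pfm: PFM, name: str):
    from Bio import motifs as bio_motifs

    counts = {b: [int(c) for c in pfm.counts[i]] for i, b in enumerate(ALPHABET)}
    m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
    m.name = name
    m.matrix_id = name
    return m
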