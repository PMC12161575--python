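"""Synthetic genomes, annotations, planted binding sites, and count matrices.

Every downstream stage of the pipeline can be exercised without downloads by
generating a GC-rich genome with stranded, non-overlapping genes organised
into operons, planting motif instances into regulatory windows of chosen
target genes, and simulating negative-binomial RNA-seq counts in which a
regulator transcript is anti-correlated with its planted regulon, operon
members are tightly co-expressed, and an optional mean-expression-linked
confounder reproduces the correlation bias the correction stack must remove.

The generative model is an explicit stand-in for real data, not a claim about
any particular organism: it reproduces the statistical regimes the analysis
must cope with (72% GC background, ~20-sample co-expression, repressor-style
anti-correlation) at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, interval_mask, reverse_complement
from .motif import ALPHABET, PFM, build_pfm

# Synthetic operator sites: ten 19-mers derived from a palindromic, AT-rich
# iron-box-like consensus with a few degenerate positions. These are
# illustrative sequences for building a test PFM, not curated experimental
# binding sites.
EXAMPLE_BINDING_SITES = [
    "TTAGGTTAGGCTAACCTAA",
    "TTAGGTTAGGCTAACCTAA",
    "ATAGGTTAGGCTAACCTAA",
    "TTAGGTTATGCTAACCTAA",
    "TTAGGTGAGGCTAACCTAT",
    "TTAGGTTAGCCTAACCTAA",
    "TTACGTTAGGCTATCCTAA",
    "TAAGGTTAGGCTAACCGAA",
    "TTAGGTTAGGATAACCTAA",
    "CTAGGTTAGGCTAACATAA",
]


def example_pfm() -> PFM:
    """PFM of the bundled synthetic operator sites (10 sites, 19 bp)."""
    return build_pfm(EXAMPLE_BINDING_SITES)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic scenario.

    Planted site coordinates are 0-based half-open on the forward strand;
    ``regulon_genes`` excludes the regulator itself; ``operon_map`` assigns
    every gene to its transcription unit.
    """

    planted_sites: list[tuple[str, int, int, str]]
    regulator_gene: str
    regulon_genes: set[str]
    operon_map: dict[str, int]
    confounder_loading: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.regulon_genes = set(self.regulon_genes)
        if self.regulator_gene in self.regulon_genes:
            raise ValueError("regulon_genes must exclude the regulator gene")

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted_sites": [list(s) for s in self.planted_sites],
            "regulator_gene": self.regulator_gene,
            "regulon_genes": sorted(self.regulon_genes),
            "operon_map": self.operon_map,
            "confounder_loading": self.confounder_loading,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            planted_sites=[tuple(s) for s in data["planted_sites"]],
            regulator_gene=data["regulator_gene"],
            regulon_genes=set(data["regulon_genes"]),
            operon_map={k: int(v) for k, v in data["operon_map"].items()},
            confounder_loading=data["confounder_loading"],
            dispersion=data["dispersion"],
            seed=data["seed"],
        )


def generate_genome(length: int, gc: float = 0.72, seed: int = 0) -> str:
    """I.i.d. background sequence with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bp")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=length, p=probs)
    return "".join(ALPHABET[i] for i in idx)


@dataclass(frozen=True)
class OperonGeometry:
    """Gene and gap length ranges (bp) for annotation generation.

    Intra-operon gaps sit below a conventional operon gap bound (200 bp),
    inter-unit gaps above it, so operon structure is recoverable from
    distance alone.
    """

    gene_length: tuple[int, int] = (800, 1250)
    intra_operon_gap: tuple[int, int] = (40, 140)
    inter_unit_gap: tuple[int, int] = (250, 450)


def generate_annotation(
    genome_length: int,
    n_genes: int,
    geometry: OperonGeometry | None = None,
    seed: int = 0,
    unit_sizes: list[int] | None = None,
    contig: str = "chr",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place stranded, non-overlapping genes grouped into transcription units.

    Units (operons, or singletons) are laid left to right; genes within a unit
    share a strand and are separated by intra-operon gaps, units by larger
    inter-unit gaps. If ``unit_sizes`` is not given, sizes are drawn as 70%
    singletons, 20% pairs, 10% triplets. Returns the gene table (0-based
    half-open) and the gene -> unit map.
    """
    geometry = geometry or OperonGeometry()
    rng = np.random.default_rng(seed)
    if unit_sizes is None:
        unit_sizes = []
        remaining = n_genes
        while remaining > 0:
            size = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            size = min(size, remaining)
            unit_sizes.append(size)
            remaining -= size
    if sum(unit_sizes) != n_genes:
        raise ValueError("unit sizes must sum to n_genes")

    pad = len(str(n_genes))
    rows = []
    operon_map: dict[str, int] = {}
    pos = int(rng.integers(*geometry.inter_unit_gap))
    gene_counter = 0
    for unit_id, size in enumerate(unit_sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        for k in range(size):
            length = int(rng.integers(*geometry.gene_length))
            start, end = pos, pos + length
            if end > genome_length:
                raise ValueError(
                    f"genome too short: gene {gene_counter + 1} would end at {end} "
                    f"> {genome_length}"
                )
            gene_id = f"g{gene_counter + 1:0{pad}d}"
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
            )
            operon_map[gene_id] = unit_id
            gene_counter += 1
            gap = (
                int(rng.integers(*geometry.intra_operon_gap))
                if k < size - 1
                else int(rng.integers(*geometry.inter_unit_gap))
            )
            pos = end + gap
    return pd.DataFrame(rows), operon_map


def plant_motifs(
    genome_seq: str,
    annotation: pd.DataFrame,
    pfm: PFM,
    target_genes: list[str],
    seed: int = 0,
    upstream: int = 350,
    downstream: int = 50,
    prefer_noncoding: bool = True,
    contig: str = "chr",
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Write one sampled motif instance into each target gene's regulatory window.

    Instances are sampled column-wise from the PFM frequencies and written on
    the target gene's strand (reverse-complemented into the forward sequence
    for minus-strand targets). Placement prefers offsets where the site lies
    in non-coding sequence — operator sites live in promoter DNA — and avoids
    previously planted intervals. Returns the modified sequence and the exact
    planted coordinates.
    """
    rng = np.random.default_rng(seed)
    length = pfm.length
    freqs = pfm.frequencies
    coding = interval_mask(
        [(int(r.start), int(r.end)) for r in annotation.itertuples()], len(genome_seq)
    )
    gene_index = annotation.set_index("gene_id")
    seq = list(genome_seq)
    planted: list[tuple[str, int, int, str]] = []
    occupied = np.zeros(len(genome_seq), dtype=bool)
    for gid in target_genes:
        if gid not in gene_index.index:
            raise KeyError(f"target gene {gid} absent from annotation")
        g = gene_index.loc[gid]
        if g["strand"] == "+":
            lo, hi = int(g["start"]) - upstream, int(g["start"]) + downstream
        else:
            lo, hi = int(g["end"]) - downstream, int(g["end"]) + upstream
        lo, hi = max(0, lo), min(len(genome_seq), hi)
        starts = [
            s
            for s in range(lo, hi - length + 1)
            if not occupied[s : s + length].any()
        ]
        if not starts:
            raise ValueError(f"regulatory window of {gid} too narrow for the motif")
        if prefer_noncoding:
            noncoding_starts = [s for s in starts if not coding[s : s + length].any()]
            starts = noncoding_starts or starts
        start = int(rng.choice(starts))
        site = "".join(
            ALPHABET[rng.choice(4, p=freqs[:, i])] for i in range(length)
        )
        written = site if g["strand"] == "+" else reverse_complement(site)
        seq[start : start + length] = written
        occupied[start : start + length] = True
        planted.append((contig, start, start + length, g["strand"]))
    return "".join(seq), planted


DEFAULT_COUNT_PARAMS: dict = {
    "base_mean": 150.0,  # scale of the lognormal gene mean distribution
    "mean_sdlog": 1.0,
    "regulon_mean": 150.0,  # regulon genes span the expression range like others
    "regulon_sdlog": 0.8,
    "regulon_min_mean": 60.0,  # planted regulon stays above the detection floor
    "regulator_mean": 500.0,  # repressor transcript is well measured
    "effect_size": 0.9,  # fractional repression at full regulator activity
    "repression_floor": 0.05,  # means truncated at floor * base mean
    "regulator_gain": 1.6,  # regulator log-mean rises by gain (nats) over the activity range
    "dispersion": 0.02,  # NB variance = mu + phi * mu^2
    "library_size_range": (0.5, 1.5),  # relative depth multipliers
    "confounder_strength": 0.7,
    "confounder_split": 0.5,  # rank quantile separating low/high loading regimes
    "operon_noise_sd": 0.25,  # shared log-scale profile per transcription unit
    "gene_noise_sd": 0.03,
}


def simulate_counts(
    truth: SyntheticTruth,
    n_samples: int = 24,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial counts with a planted repressor-regulon structure.

    Per sample j a regulator activity a_j ~ Uniform(0,1) is drawn. The
    regulator's log mean rises linearly by ``regulator_gain`` nats over the
    activity range; every regulon gene's mean scales with
    max(1 - effect_size * a_j, floor). Genes in one transcription unit
    share a latent log-scale profile. The confounder is a shared sample
    factor whose gene loading increases (stepwise) in expected mean
    expression: genes below the ``confounder_split`` rank quantile load with
    -strength, genes above with a positive value chosen so the count-mass-
    weighted loading is zero. That balance makes the factor invisible to
    library-size normalization — the regime the downstream corrections (PC1
    removal, spqn) must handle — while biasing within-bin correlations in
    every mean-expression bin (strength 0 disables it). Counts are NB with
    variance mu + phi mu^2 and per-sample relative library depths. Returns
    (counts, info) with the sample activities and per-gene loadings; the
    loadings are also written back onto ``truth``.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    p = dict(DEFAULT_COUNT_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown count parameters: {sorted(unknown)}")
        p.update(params)
    if p["dispersion"] < 0:
        raise ValueError("dispersion must be non-negative")
    if p["effect_size"] < 0:
        raise ValueError("effect_size must be non-negative")
    if p["confounder_strength"] < 0:
        raise ValueError("confounder_strength must be non-negative")

    rng = np.random.default_rng(seed)
    genes = sorted(truth.operon_map, key=lambda g: truth.operon_map[g])
    genes = list(dict.fromkeys(genes))  # stable unit order, unique
    n_genes = len(genes)
    is_regulon = np.array([g in truth.regulon_genes for g in genes])
    is_regulator = np.array([g == truth.regulator_gene for g in genes])

    base = rng.lognormal(np.log(p["base_mean"]), p["mean_sdlog"], size=n_genes)
    base[is_regulon] = np.maximum(
        rng.lognormal(
            np.log(p["regulon_mean"]), p["regulon_sdlog"], size=int(is_regulon.sum())
        ),
        p["regulon_min_mean"],
    )
    base[is_regulator] = p["regulator_mean"]

    activity = rng.uniform(0.0, 1.0, size=n_samples)
    lib = rng.uniform(*p["library_size_range"], size=n_samples)
    # two-level batch-style factor: with a binary profile every per-gene
    # response is exactly linear in the factor, so the artifact is a true
    # rank-1 component that one principal component can carry
    confounder = rng.choice([-1.0, 1.0], size=n_samples)
    # rank genes by expected log-scale measured mean (log base mean plus the
    # average log regulation modifier) so the loading regimes align with the
    # observed log-expression bins downstream
    repression_all = np.maximum(1.0 - p["effect_size"] * activity, p["repression_floor"])
    expected_log = np.log(base)
    expected_log[is_regulon] += float(np.mean(np.log(repression_all)))
    expected_log[is_regulator] += float(np.mean(p["regulator_gain"] * activity))
    expected = np.exp(expected_log)
    rank = np.argsort(np.argsort(expected_log))
    u = rank / max(n_genes - 1, 1)
    # two-regime loading: below the split rank quantile genes load with -s,
    # above with +s. The planted biology is kept orthogonal to the technical
    # factor in gene space, mirroring the genome-wide regime where one
    # regulon is a negligible fraction of all genes and does not steer the
    # leading principal component.
    high = u >= p["confounder_split"]
    loading = np.where(high, p["confounder_strength"], -p["confounder_strength"])
    planted = is_regulon | is_regulator
    loading[planted] = 0.0

    units = np.array([truth.operon_map[g] for g in genes])
    unit_ids = np.unique(units)
    unit_noise = rng.normal(0.0, p["operon_noise_sd"], size=(unit_ids.size, n_samples))
    unit_row = {uid: i for i, uid in enumerate(unit_ids)}

    log_mu = np.log(base)[:, None] + np.zeros((n_genes, n_samples))
    repression = np.maximum(1.0 - p["effect_size"] * activity, p["repression_floor"])
    log_mu[is_regulon] += np.log(repression)[None, :]
    log_mu[is_regulator] += (p["regulator_gain"] * activity)[None, :]
    log_mu += unit_noise[[unit_row[u_] for u_ in units], :]
    log_mu += rng.normal(0.0, p["gene_noise_sd"], size=(n_genes, n_samples))
    # compositional confounder: per-sample renormalization keeps the expected
    # total mass exactly constant, so the artifact changes relative
    # composition only and survives library-size normalization intact
    if p["confounder_strength"] > 0:
        conf_term = loading[:, None] * confounder[None, :]
        mass = expected[:, None] * np.exp(conf_term)
        log_z = np.log(mass.sum(axis=0) / expected.sum())
        log_mu += conf_term - log_z[None, :]
    log_mu += np.log(lib)[None, :]

    mu = np.exp(log_mu)
    phi = p["dispersion"]
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"
    truth.confounder_loading = {g: float(l) for g, l in zip(genes, loading)}
    info = {
        "activity": pd.Series(activity, index=samples),
        "library_factor": pd.Series(lib, index=samples),
        "base_mean": pd.Series(base, index=genes),
        "confounder": pd.Series(confounder, index=samples),
    }
    return counts_df, info


# ---------------------------------------------------------------------------
# Default scenario


@dataclass
class SyntheticScenario:
    """A fully assembled synthetic study: genome, motif, truth, and counts."""

    genome: AnnotatedGenome
    pfm: PFM
    truth: SyntheticTruth
    counts: pd.DataFrame
    info: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(out / "genome.fasta")
        self.genome.write_gff3(out / "annotation.gff3")
        self.counts.to_csv(out / "counts.tsv", sep="\t")
        self.truth.to_json(out / "truth.json")
        (out / "sites.txt").write_text("\n".join(EXAMPLE_BINDING_SITES) + "\n")


def default_scenario(
    seed: int = 0,
    length: int = 200_000,
    n_genes: int = 150,
    n_samples: int = 24,
    gc: float = 0.72,
    regulon_operon_sizes: tuple[int, ...] = (3, 3, 3, 3, 2, 2, 2, 2),
    count_params: dict | None = None,
    geometry: OperonGeometry | None = None,
) -> SyntheticScenario:
    """The package's reference synthetic study.

    A 200 kb, 72% GC genome carrying 150 genes; a 20-gene planted regulon in
    8 operons whose leaders get one sampled motif instance each; a singleton
    regulator gene; and a 24-sample count matrix with the default repression,
    operon, and confounder structure. All randomness derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_annot, s_plant, s_counts, s_layout = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    )
    if sum(regulon_operon_sizes) + 1 > n_genes:
        raise ValueError("regulon plus regulator exceed the requested gene count")

    # background transcription units, with the regulon operons and the
    # regulator scattered among them
    layout_rng = np.random.default_rng(s_layout)
    n_background = n_genes - sum(regulon_operon_sizes) - 1
    units: list[tuple[str, int]] = []
    remaining = n_background
    while remaining > 0:
        size = min(int(layout_rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1])), remaining)
        units.append(("bg", size))
        remaining -= size
    for kind, size in [("operon", s) for s in regulon_operon_sizes] + [("regulator", 1)]:
        units.insert(int(layout_rng.integers(0, len(units) + 1)), (kind, size))
    unit_sizes = [size for _, size in units]

    sequence = generate_genome(length, gc, s_genome)
    annotation, operon_map = generate_annotation(
        length, n_genes, geometry, s_annot, unit_sizes=unit_sizes
    )

    regulon_units = [u for u, (kind, _) in enumerate(units) if kind == "operon"]
    regulator_unit = next(u for u, (kind, _) in enumerate(units) if kind == "regulator")
    genes_of_unit: dict[int, list[str]] = {}
    for g, u_ in operon_map.items():
        genes_of_unit.setdefault(u_, []).append(g)
    regulon_genes = {g for u_ in regulon_units for g in genes_of_unit[u_]}
    regulator_gene = genes_of_unit[regulator_unit][0]
    gene_index = annotation.set_index("gene_id")
    plant_targets = []
    for u_ in regulon_units:
        members = genes_of_unit[u_]  # placed left to right
        strand = gene_index.loc[members[0], "strand"]
        leader = members[0] if strand == "+" else members[-1]
        # operator copies scale with locus size, as in real iron-box loci
        plant_targets.extend([leader] * min(len(members), 3))

    pfm = example_pfm()
    sequence, planted = plant_motifs(
        sequence, annotation, pfm, plant_targets, seed=s_plant
    )
    truth = SyntheticTruth(
        planted_sites=planted,
        regulator_gene=regulator_gene,
        regulon_genes=regulon_genes,
        operon_map=operon_map,
        dispersion=(count_params or {}).get(
            "dispersion", DEFAULT_COUNT_PARAMS["dispersion"]
        ),
        seed=seed,
    )
    counts, info = simulate_counts(truth, n_samples, count_params, s_counts)
    genome = AnnotatedGenome(contigs={"chr": sequence}, genes=annotation)
    return SyntheticScenario(genome=genome, pfm=pfm, truth=truth, counts=counts, info=info)
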