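"""Regulon assembly: binding sites -> target genes -> operons -> loci -> statistics.

A repressor's direct targets are the genes whose regulatory windows contain a
surviving binding-site location (one gene, or two for a site shared by a
divergent promoter pair). Candidates are filtered by anti-correlation with the
regulator's own transcript, expanded through predicted operons (same strand,
short intergenic gap, co-expression with the operon seed), grouped into
genomic loci, and summarised with the within-regulon vs regulator-anti-
correlation comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .coexpression import CorrelationResult, critical_pcc
from .genome import AnnotatedGenome


@dataclass
class Regulon:
    """Direct targets plus operon co-members of one regulator."""

    regulator: str
    targets: pd.DataFrame  # accepted candidates with location, score, pcc, pvalue
    members: list[str]  # targets + operon-appended genes
    operons: dict[str, list[str]]  # target -> downstream members (incl. target)
    loci: pd.DataFrame  # locus id, contig, start, end, genes

    @property
    def direct_targets(self) -> list[str]:
        return list(self.targets["gene_id"])


def assign_targets(locations: pd.DataFrame, genome: AnnotatedGenome) -> pd.DataFrame:
    """Candidate target genes for each unique binding-site location.

    Candidates are the genes whose regulatory windows contain the location
    (recorded on the location during scanning); each is annotated with its
    strand and the distance from the site to the gene's start codon. Locations
    inside no window are reported as orphans with a null gene.
    """
    records = []
    gene_info = genome.genes.set_index("gene_id")
    for loc_idx, row in enumerate(locations.itertuples()):
        if not row.windows:
            records.append(
                {
                    "location": loc_idx,
                    "contig": row.contig,
                    "site_start": row.start,
                    "site_end": row.end,
                    "score": row.best_score,
                    "gene_id": None,
                    "strand": None,
                    "distance_to_start": np.nan,
                    "orphan": True,
                }
            )
            continue
        for gid in row.windows:
            g = gene_info.loc[gid]
            if g["strand"] == "+":
                dist = int(g["start"]) - int(row.end)
            else:
                dist = int(row.start) - int(g["end"])
            records.append(
                {
                    "location": loc_idx,
                    "contig": row.contig,
                    "site_start": row.start,
                    "site_end": row.end,
                    "score": row.best_score,
                    "gene_id": gid,
                    "strand": g["strand"],
                    "distance_to_start": dist,
                    "orphan": False,
                }
            )
    return pd.DataFrame.from_records(records)


def anticorrelation_filter(
    candidates: pd.DataFrame,
    corr: CorrelationResult,
    regulator: str,
    r_threshold: float = -0.43,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Flag candidates by anti-correlation with the regulator transcript.

    Keep (status ``accepted``) candidates with PCC < r_threshold (strict) and
    p < alpha. Rejected candidates stay in the table with a status explaining
    why (``positively_correlated``, ``not_significant``), and candidates
    missing from the expression data are ``untested`` — mirroring how such
    genes are reported rather than silently dropped. ``adjust='bh'`` applies
    Benjamini-Hochberg across the regulator's correlation row before
    thresholding p.
    """
    if regulator not in corr.genes:
        raise KeyError(f"regulator {regulator} absent from correlation matrix")
    reg_r = corr.pcc.loc[regulator]
    reg_p = corr.pvalues.loc[regulator].copy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        others = reg_p.index != regulator
        valid = others & reg_p.notna()
        adjusted = reg_p.copy()
        adjusted.loc[valid] = multipletests(reg_p[valid], method="fdr_bh")[1]
        reg_p = adjusted
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust}")

    out = candidates.copy()
    pccs, pvals, status = [], [], []
    for row in out.itertuples():
        gid = row.gene_id
        if gid is None or gid not in reg_r.index or np.isnan(reg_r[gid]):
            pccs.append(np.nan)
            pvals.append(np.nan)
            status.append("untested")
            continue
        r, p = float(reg_r[gid]), float(reg_p[gid])
        pccs.append(r)
        pvals.append(p)
        if gid == regulator:
            status.append("regulator")
        elif r < r_threshold and p < alpha:
            status.append("accepted")
        elif r > 0:
            status.append("positively_correlated")
        else:
            status.append("not_significant")
    out["pcc"] = pccs
    out["pvalue"] = pvals
    out["status"] = status
    return out


def expand_operons(
    targets: pd.DataFrame,
    genome: AnnotatedGenome,
    corr: CorrelationResult,
    max_gap: int = 200,
    min_pcc: float | None = None,
    anchor: str = "seed",
) -> tuple[list[str], dict[str, list[str]]]:
    """Walk downstream of each accepted target to collect co-operonic genes.

    From each target, the next gene in the direction of transcription is
    appended while it (a) lies on the same strand, (b) follows within
    ``max_gap`` bp, and (c) correlates with the operon ``anchor`` ('seed' =
    the target itself, 'previous' = the last appended gene) at PCC >=
    ``min_pcc`` (default: the critical PCC at the dataset's sample count).
    Returns (members, operon map); expansion never removes a target.
    """
    if min_pcc is None:
        min_pcc = critical_pcc(corr.n_samples)
    if anchor not in ("seed", "previous"):
        raise ValueError("anchor must be 'seed' or 'previous'")
    members: list[str] = []
    operons: dict[str, list[str]] = {}
    target_ids = [g for g in targets["gene_id"] if g is not None]
    for contig in genome.contigs:
        contig_genes = (
            genome.genes[genome.genes["contig"] == contig]
            .sort_values("start")
            .reset_index(drop=True)
        )
        index_of = {g: i for i, g in enumerate(contig_genes["gene_id"])}
        for gid in target_ids:
            if gid not in index_of:
                continue
            i = index_of[gid]
            row = contig_genes.iloc[i]
            strand = row["strand"]
            step = 1 if strand == "+" else -1
            operon = [gid]
            prev = row
            while True:
                j = index_of[operon[-1]] + step
                if not 0 <= j < len(contig_genes):
                    break
                nxt = contig_genes.iloc[j]
                if nxt["strand"] != strand:
                    break
                gap = (
                    int(nxt["start"]) - int(prev["end"])
                    if strand == "+"
                    else int(prev["start"]) - int(nxt["end"])
                )
                if gap > max_gap:
                    break
                ref = operon[0] if anchor == "seed" else operon[-1]
                nid = nxt["gene_id"]
                if (
                    ref not in corr.genes
                    or nid not in corr.genes
                    or np.isnan(corr.pcc.at[ref, nid])
                    or corr.pcc.at[ref, nid] < min_pcc
                ):
                    break
                operon.append(nid)
                prev = nxt
            operons[gid] = operon
            for g in operon:
                if g not in members:
                    members.append(g)
    return members, operons


def group_loci(
    members: list[str], genome: AnnotatedGenome, max_intervening: int = 5
) -> pd.DataFrame:
    """Merge members separated by <= max_intervening non-member genes into loci."""
    member_set = set(members)
    records = []
    locus_id = 0
    for contig in genome.contigs:
        contig_genes = (
            genome.genes[genome.genes["contig"] == contig]
            .sort_values("start")
            .reset_index(drop=True)
        )
        positions = [
            i for i, g in enumerate(contig_genes["gene_id"]) if g in member_set
        ]
        if not positions:
            continue
        current = [positions[0]]
        for pos in positions[1:]:
            if pos - current[-1] - 1 <= max_intervening:
                current.append(pos)
            else:
                records.append(_locus_record(locus_id, contig, contig_genes, current))
                locus_id += 1
                current = [pos]
        records.append(_locus_record(locus_id, contig, contig_genes, current))
        locus_id += 1
    return pd.DataFrame.from_records(
        records, columns=["locus", "contig", "start", "end", "genes"]
    )


def _locus_record(locus_id, contig, contig_genes, positions):
    rows = contig_genes.iloc[positions]
    return {
        "locus": locus_id,
        "contig": contig,
        "start": int(rows["start"].min()),
        "end": int(rows["end"].max()),
        "genes": tuple(rows["gene_id"]),
    }


def regulon_statistics(
    regulon: Regulon, corr: CorrelationResult, regulator: str | None = None
) -> dict:
    """Within-regulon cohesion vs anti-correlation with the regulator.

    Reports the median of pairwise member-member PCCs (upper triangle), the
    median PCC between members and the regulator, and a one-sided
    Mann-Whitney U p-value for the within-regulon PCCs being stochastically
    greater than the *negated* member-regulator PCCs. U is computed exactly by
    enumeration when both groups have <= 8 values and no ties, otherwise by
    the normal approximation with tie and continuity corrections. The two
    groups share genes, so the p-value is descriptive, not an independent-
    samples inference.
    """
    regulator = regulator or regulon.regulator
    genes = [g for g in regulon.members if g in corr.genes and g != regulator]
    if len(genes) < 2:
        raise ValueError("need at least two members with expression data")
    sub = corr.pcc.loc[genes, genes].to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    within = sub[iu]
    within = within[~np.isnan(within)]
    to_reg = corr.pcc.loc[genes, regulator].to_numpy(float)
    to_reg = to_reg[~np.isnan(to_reg)]
    neg_to_reg = -to_reg
    p = mannwhitney_one_sided_greater(within, neg_to_reg)
    return {
        "n_members": len(genes),
        "median_within_pcc": float(np.median(within)),
        "median_regulator_pcc": float(np.median(to_reg)),
        "mannwhitney_p": p,
    }


def mannwhitney_one_sided_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney U p-value for x stochastically greater than y.

    Exact enumeration when both groups have <= 8 values and no ties; normal
    approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def assemble_regulon(
    locations: pd.DataFrame,
    genome: AnnotatedGenome,
    corr: CorrelationResult,
    regulator: str,
    r_threshold: float | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
    max_gap: int = 200,
    min_pcc: float | None = None,
    max_intervening: int = 5,
) -> tuple[Regulon, pd.DataFrame]:
    """Run the full target -> filter -> operon -> locus chain for one regulator.

    Returns the regulon and the full candidate table (including rejected and
    orphan candidates). The default anti-correlation threshold is minus the
    critical PCC for the dataset's sample count.
    """
    if r_threshold is None:
        r_threshold = -critical_pcc(corr.n_samples, alpha)
    candidates = assign_targets(locations, genome)
    filtered = anticorrelation_filter(
        candidates, corr, regulator, r_threshold=r_threshold, alpha=alpha, adjust=adjust
    )
    accepted = filtered[filtered["status"] == "accepted"].drop_duplicates("gene_id")
    members, operons = expand_operons(
        accepted, genome, corr, max_gap=max_gap, min_pcc=min_pcc
    )
    loci = group_loci(members, genome, max_intervening=max_intervening)
    regulon = Regulon(
        regulator=regulator,
        targets=accepted.reset_index(drop=True),
        members=members,
        operons=operons,
        loci=loci,
    )
    return regulon, filtered


def write_regulon(regulon: Regulon, corr: CorrelationResult, tsv_path) -> None:
    """Regulon member table: gene, role, locus, site/score/PCC details."""
    target_rows = regulon.targets.set_index("gene_id")
    locus_of = {}
    for row in regulon.loci.itertuples():
        for g in row.genes:
            locus_of[g] = row.locus
    rows = []
    for gene in [regulon.regulator] + regulon.members:
        role = (
            "regulator"
            if gene == regulon.regulator
            else ("target" if gene in target_rows.index else "operon_member")
        )
        r = (
            float(corr.pcc.at[gene, regulon.regulator])
            if gene in corr.genes and regulon.regulator in corr.genes
            else np.nan
        )
        rows.append(
            {
                "gene_id": gene,
                "role": role,
                "locus": locus_of.get(gene, np.nan),
                "site_start": target_rows.at[gene, "site_start"] if role == "target" else np.nan,
                "site_score": target_rows.at[gene, "score"] if role == "target" else np.nan,
                "pcc_with_regulator": r,
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
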