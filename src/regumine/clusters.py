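"""Rule-based detection of co-localized gene sets from protein-domain content.

A cluster rule names the Pfam domains a locus must contain and the maximum
intergenic distance allowed between consecutive domain-carrying genes. The
shipped presets describe the desferrioxamine core locus (desABCD: decarboxylase
PF00282, amine monooxygenase PF13434, acyltransferase PF13523, NIS synthetase
PF04183, within 5 kbp) and the accessory capping pair (desGH: amidinotransferase
PF01804 + acyltransferase PF13523, within 1 kbp). Domain annotation is an
input table; no homology search is run here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

GENE_TABLE_COLUMNS = ["gene_id", "contig", "start", "end", "domains"]


def strip_version(accession: str) -> str:
    """PF13523.9 -> PF13523; bare accessions pass through unchanged."""
    return accession.split(".")[0]


@dataclass(frozen=True)
class ClusterRule:
    """Required domain accessions (with multiplicity) within a distance bound."""

    name: str
    required_domains: tuple[str, ...]
    max_intergenic: int

    def __post_init__(self) -> None:
        if len(self.required_domains) == 0:
            raise ValueError("a rule needs at least one required domain")
        if self.max_intergenic <= 0:
            raise ValueError("max_intergenic must be positive")
        object.__setattr__(
            self,
            "required_domains",
            tuple(strip_version(d) for d in self.required_domains),
        )


PRESET_RULES: dict[str, ClusterRule] = {
    "desABCD": ClusterRule(
        "desABCD", ("PF00282", "PF13434", "PF13523", "PF04183"), 5000
    ),
    "desGH": ClusterRule("desGH", ("PF01804", "PF13523"), 1000),
}


def _gene_domains(row) -> set[str]:
    doms = row.domains
    if isinstance(doms, str):
        doms = [d for d in doms.replace(",", ";").split(";") if d]
    return {strip_version(d) for d in doms}


def detect_clusters(
    gene_table: pd.DataFrame,
    rule: ClusterRule,
    allow_multidomain_carriers: bool = True,
) -> pd.DataFrame:
    """Find maximal chains of domain carriers satisfying a cluster rule.

    Genes carrying any required domain are chained (per contig, by position)
    while consecutive carriers are <= max_intergenic apart, measured end of
    gene to start of the next, strand-agnostic; non-carrier genes in between
    are ignored. A chain is reported when its genes can jointly cover every
    required domain slot: a duplicated accession needs distinct carrier genes,
    and a single multi-domain gene may fill several different-accession slots
    only when ``allow_multidomain_carriers`` (default on, honoring fused
    genes). Returns loci with coordinates and the slot -> gene assignment.
    """
    if gene_table.empty:
        raise ValueError("empty gene table")
    required = rule.required_domains
    required_set = set(required)
    records = []
    for contig, sub in gene_table.groupby("contig"):
        sub = sub.sort_values("start").reset_index(drop=True)
        carriers = [
            (row, _gene_domains(row) & required_set)
            for row in sub.itertuples()
            if _gene_domains(row) & required_set
        ]
        chains: list[list] = []
        for row, doms in carriers:
            if chains and int(row.start) - int(chains[-1][-1][0].end) <= rule.max_intergenic:
                chains[-1].append((row, doms))
            else:
                chains.append([(row, doms)])
        for chain in chains:
            assignment = _cover_slots(chain, required, allow_multidomain_carriers)
            if assignment is None:
                continue
            rows = [c[0] for c in chain]
            records.append(
                {
                    "rule": rule.name,
                    "contig": contig,
                    "start": min(int(r.start) for r in rows),
                    "end": max(int(r.end) for r in rows),
                    "genes": tuple(r.gene_id for r in rows),
                    "assignment": assignment,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["rule", "contig", "start", "end", "genes", "assignment"]
    )


def _cover_slots(
    chain: list, required: tuple[str, ...], allow_multidomain: bool
) -> dict[str, str] | None:
    """Match required-domain slots to carrier genes; None if uncoverable.

    Bipartite maximum matching between slots (accession, copy index) and
    carriers. Without multi-domain carriers each gene fills at most one slot;
    with them, a gene may fill one slot per distinct accession (still never
    two copies of the same accession).
    """
    slots = [(acc, k) for k, acc in enumerate(required)]
    graph = nx.Graph()
    slot_nodes = [("slot", i) for i in range(len(slots))]
    graph.add_nodes_from(slot_nodes, bipartite=0)
    edges = []
    for gi, (row, doms) in enumerate(chain):
        for i, (acc, _) in enumerate(slots):
            if acc in doms:
                node = ("gene", gi) if not allow_multidomain else ("gene", gi, acc)
                edges.append((("slot", i), node))
    graph.add_edges_from(edges)
    if not edges:
        return None
    matching = nx.bipartite.maximum_matching(graph, top_nodes=slot_nodes)
    if not all(s in matching for s in slot_nodes):
        return None
    return {
        f"{slots[s[1]][0]}#{slots[s[1]][1]}": chain[matching[s][1]][0].gene_id
        for s in slot_nodes
    }


def tabulate_presence(
    genomes: dict[str, pd.DataFrame],
    rules: list[ClusterRule],
    allow_multidomain_carriers: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome presence/absence of each rule, plus all detected loci."""
    presence_rows = []
    loci_frames = []
    for name, table in genomes.items():
        row = {"genome": name}
        for rule in rules:
            if table.empty:
                row[rule.name] = False
                continue
            loci = detect_clusters(table, rule, allow_multidomain_carriers)
            row[rule.name] = not loci.empty
            if not loci.empty:
                loci = loci.copy()
                loci.insert(0, "genome", name)
                loci_frames.append(loci)
        presence_rows.append(row)
    presence = pd.DataFrame(presence_rows).set_index("genome")
    all_loci = (
        pd.concat(loci_frames, ignore_index=True)
        if loci_frames
        else pd.DataFrame(columns=["genome", "rule", "contig", "start", "end", "genes", "assignment"])
    )
    return presence, all_loci


# ---------------------------------------------------------------------------
# I/O


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, contig, start, end, domains (';'-separated)."""
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"empty gene/domain table: {path}") from err
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene/domain table missing columns: {missing}")
    return table


def read_rules(path: str | Path) -> list[ClusterRule]:
    data = json.loads(Path(path).read_text())
    return [
        ClusterRule(r["name"], tuple(r["domains"]), int(r["max_intergenic_bp"]))
        for r in data
    ]


def write_loci_gff3(loci: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in loci.itertuples():
            fh.write(
                "\t".join(
                    [
                        row.contig,
                        "regumine",
                        "biosynthetic_gene_cluster",
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        ".",
                        ".",
                        f"ID={row.rule}_{row.Index};rule={row.rule};genes={','.join(row.genes)}",
                    ]
                )
                + "\n"
            )
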