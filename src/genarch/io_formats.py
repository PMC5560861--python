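"""Readers, writers and core containers shared by every analysis stage.

Gene structures come from GFF3 (1-based inclusive coordinates, as in the
format), orthogroup membership from OrthoFinder-style TSV, species and gene
trees from Newick, protein-domain calls from pfam_scan-style TSV, TE copies
and self-alignment hits from tabular files, and regulatory intervals from BED
(0-based half-open).  All interval arithmetic performed internally converts
to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger("genarch")

OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene model (one representative mRNA).

    ``cds_segments`` are (start, end) pairs in 1-based inclusive genomic
    coordinates, sorted 5'->3' in transcription order: ascending genomic
    order on the + strand, descending on the - strand.
    """

    gene_id: str
    species: str
    scaffold: str
    strand: str
    cds_segments: list[tuple[int, int]]
    protein_length: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        # transcription order
        self.cds_segments = segs if self.strand == "+" else segs[::-1]
        n = self.cds_length
        if n % 3 != 0:
            self.partial = True
        if self.protein_length == 0:
            self.protein_length = n // 3

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def n_introns(self) -> int:
        return len(self.cds_segments) - 1

    @property
    def start(self) -> int:
        return min(s for s, _ in self.cds_segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.cds_segments)

    def introns(self) -> list[tuple[int, int, int]]:
        """Introns as (start, end, phase), 1-based inclusive genomic coords.

        Phase is the number of coding nucleotides 5' of the intron modulo 3,
        computed on the spliced CDS in transcription order.
        """
        out = []
        coding = 0
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            coding += e1 - s1 + 1
            if self.strand == "+":
                ivl = (e1 + 1, s2 - 1)
            else:
                ivl = (e2 + 1, s1 - 1)
            out.append((ivl[0], ivl[1], coding % 3))
        return out

    def intron_coding_offsets(self) -> list[tuple[int, int]]:
        """Per intron: (coding nucleotides 5' of the intron, phase)."""
        out = []
        coding = 0
        for s, e in self.cds_segments[:-1]:
            coding += e - s + 1
            out.append((coding, coding % 3))
        return out


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path | None = None,
                     species: str | None = None) -> list[GeneModel]:
    """Read one GeneModel per gene from GFF3, keeping the longest-CDS mRNA.

    Records with overlapping CDS segments are rejected with a warning;
    CDS features without resolvable mRNA parents are skipped.
    """
    gff3_path = Path(gff3_path)
    if species is None:
        species = gff3_path.stem
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    prot_len: dict[str, int] = {}
    if fasta_path is not None:
        from Bio import SeqIO
        prot_len = {rec.id: len(str(rec.seq).rstrip("*"))
                    for rec in SeqIO.parse(str(fasta_path), "fasta")}

    candidates: dict[str, GeneModel] = {}
    for mrna in db.features_of_type("mRNA"):
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not cds:
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        try:
            gm = GeneModel(
                gene_id=gene_id, species=species, scaffold=mrna.seqid,
                strand=mrna.strand, cds_segments=cds,
                protein_length=prot_len.get(mrna.id, prot_len.get(gene_id, 0)),
            )
        except ValueError as exc:
            logger.warning("rejecting %s: %s", mrna.id, exc)
            continue
        prev = candidates.get(gene_id)
        if prev is None or gm.cds_length > prev.cds_length:
            candidates[gene_id] = gm
    return list(candidates.values())


def write_gene_models(models: Iterable[GeneModel], gff3_path: str | Path) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            attrs_gene = f"ID={gm.gene_id}"
            fh.write(f"{gm.scaffold}\tgenarch\tgene\t{gm.start}\t{gm.end}\t.\t"
                     f"{gm.strand}\t.\t{attrs_gene}\n")
            mrna_id = f"{gm.gene_id}.t1"
            fh.write(f"{gm.scaffold}\tgenarch\tmRNA\t{gm.start}\t{gm.end}\t.\t"
                     f"{gm.strand}\t.\tID={mrna_id};Parent={gm.gene_id}\n")
            coding = 0
            for s, e in gm.cds_segments:
                phase = (3 - coding % 3) % 3
                fh.write(f"{gm.scaffold}\tgenarch\tCDS\t{s}\t{e}\t.\t"
                         f"{gm.strand}\t{phase}\tID={mrna_id}.cds;Parent={mrna_id}\n")
                coding += e - s + 1


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """orthogroup id -> species -> list of gene ids (empty list = absence)."""

    groups: dict[str, dict[str, list[str]]]
    species: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, per_sp in self.groups.items():
            for sp, genes in per_sp.items():
                for g in genes:
                    key = f"{sp}:{g}"
                    if key in seen:
                        raise ValueError(
                            f"gene {g!r} ({sp}) appears in orthogroups "
                            f"{seen[key]!r} and {og!r}")
                    seen[key] = og

    def genes(self, orthogroup: str, species: str) -> list[str]:
        return self.groups.get(orthogroup, {}).get(species, [])

    def single_copy_pairs(self, sp_i: str, sp_j: str) -> dict[str, tuple[str, str]]:
        """Orthogroups with exactly one gene in each of the two species."""
        out = {}
        for og, per_sp in self.groups.items():
            gi, gj = per_sp.get(sp_i, []), per_sp.get(sp_j, [])
            if len(gi) == 1 and len(gj) == 1:
                out[og] = (gi[0], gj[0])
        return out

    def gene_to_orthogroup(self) -> dict[str, str]:
        return {g: og for og, per_sp in self.groups.items()
                for genes in per_sp.values() for g in genes}


def read_orthogroups(tsv_path: str | Path) -> OrthologTable:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    first = df.columns[0]
    species = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row[first]
        groups[og] = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()]
            for sp in species
        }
    return OrthologTable(groups=groups, species=species)


def write_orthogroups(table: OrthologTable, tsv_path: str | Path) -> None:
    rows = []
    for og in sorted(table.groups):
        row = {"orthogroup": og}
        for sp in table.species:
            row[sp] = ",".join(table.groups[og].get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["orthogroup", *table.species]).to_csv(
        tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeIndex:
    """Array view of a rooted tree for vectorised traversals.

    Nodes are numbered in postorder; the root is last.  ``parent[i]`` is -1
    for the root; ``edge_length[i]`` is the length of the branch above node i.
    """

    names: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]]
    leaf_indices: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]


class SpeciesTree:
    """Rooted, possibly polytomous tree with uniquely named leaves.

    Thin wrapper over a :class:`dendropy.Tree`; unnamed internal nodes are
    auto-labelled N1, N2, ... in postorder, missing branch lengths default
    to 1.0 with a logged warning.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        tree.is_rooted = True
        leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf names in tree")
        if len(leaf_names) == 1:
            logger.warning("single-leaf tree: degenerate but accepted")
        counter = 0
        missing_len = False
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd.label = nd.taxon.label
            elif not nd.label:
                counter += 1
                nd.label = f"N{counter}"
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 1.0
                missing_len = True
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValueError("negative branch length")
        if missing_len:
            logger.warning("missing branch lengths defaulted to 1.0")

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        return cls(tree)

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def node_names(self) -> list[str]:
        return [nd.label for nd in self.tree.postorder_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def index(self) -> TreeIndex:
        nodes = list(self.tree.postorder_node_iter())
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        names = [nd.label for nd in nodes]
        parent = np.array(
            [pos[id(nd.parent_node)] if nd.parent_node is not None else -1
             for nd in nodes], dtype=int)
        edge_length = np.array(
            [nd.edge.length if nd.parent_node is not None else 0.0
             for nd in nodes], dtype=float)
        children: list[list[int]] = [[] for _ in nodes]
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                children[parent[i]].append(i)
        leaf_indices = {nd.label: i for i, nd in enumerate(nodes) if nd.is_leaf()}
        return TreeIndex(names=names, parent=parent, edge_length=edge_length,
                         children=children, leaf_indices=leaf_indices)

    def mrca(self, leaf_names: Sequence[str]) -> str:
        taxa = [t for t in self.tree.taxon_namespace if t.label in set(leaf_names)]
        if len(taxa) == 1:
            return [lf for lf in self.tree.leaf_node_iter()
                    if lf.taxon.label == taxa[0].label][0].label
        return self.tree.mrca(taxa=taxa).label


def read_tree(newick_path: str | Path) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    return SpeciesTree(tree)


def write_tree(tree: SpeciesTree, newick_path: str | Path) -> None:
    Path(newick_path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs: domains, TE tables, BED
# ---------------------------------------------------------------------------

def read_domain_table(tsv_path: str | Path) -> pd.DataFrame:
    """pfam_scan-style table: protein_id, domain_id, ali_start, ali_end, species."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"protein_id": str,
                                                "domain_id": str,
                                                "species": str})
    required = {"protein_id", "domain_id", "ali_start", "ali_end", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return df


def read_te_copies(tsv_path: str | Path) -> pd.DataFrame:
    """TE copy table: copy_id, family_id, species."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"copy_id", "family_id", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TE copy table missing columns: {sorted(missing)}")
    return df


def read_te_hits(tsv_path: str | Path) -> pd.DataFrame:
    """Self-alignment hits in 12-column BLAST outfmt-6 dialect (no header)."""
    rows = []
    skipped = 0
    with open(tsv_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                skipped += 1
                continue
            rows.append(parts[:12])
    if skipped:
        logger.warning("skipped %d malformed hit rows", skipped)
    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    bad = df["pident"].isna() | df["length"].isna()
    if bad.any():
        logger.warning("skipped %d hit rows with non-numeric fields", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return df


def read_bed(bed_path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open): chrom, start, end[, name]."""
    df = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"ivl{i}" for i in range(len(df))]
    return df
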