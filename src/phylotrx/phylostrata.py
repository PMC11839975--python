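"""Phylostratigraphy: gene-age maps from homology hit tables.

A gene's phylostratum (ps) is the oldest internode of the root-to-focal
lineage at which the gene still has a detectable homolog: ps1 is the last
common ancestor of all taxa considered (oldest), ps P is the focal species.
Given a tabular similarity-search output (query gene, subject taxon, e-value)
and a taxon -> phylostratum lineage map, each gene is assigned

    ps(gene) = min over { taxon_to_ps[t] : hit (gene, t) with e <= cutoff }

and genes with no qualifying hit are reported as unassigned (they are dropped
from all downstream indices).  Stricter cutoffs shrink hit sets, so a gene's
assigned age can only move toward the focal species (larger ps) or become
unassigned -- ``evalue_sweep`` checks this monotonicity explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "LineageMap",
    "PhylostratumMap",
    "assign_phylostrata",
    "evalue_sweep",
    "build_lineage_from_newick",
    "read_hit_table",
    "read_lineage_map",
]

#: e-value cutoffs of the standard robustness sweep (most to least permissive).
SWEEP_CUTOFFS = [10.0, 1.0, 1e-1, 1e-2, 1e-3, 1e-5, 1e-10, 1e-15, 1e-20, 1e-30, 1e-40]


@dataclass
class LineageMap:
    """Ordered internodes 1..n_ps and the taxon -> phylostratum lookup."""

    n_ps: int
    taxon_to_ps: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_ps < 2:
            raise ValueError("a lineage map needs at least 2 phylostrata")
        bad = {t: p for t, p in self.taxon_to_ps.items() if not 1 <= p <= self.n_ps}
        if bad:
            raise ValueError(f"taxa mapped outside 1..{self.n_ps}: {bad}")


@dataclass
class PhylostratumMap:
    """gene -> ps assignment plus the set of genes with no qualifying hit."""

    ps: dict[str, int]
    unassigned: set[str] = field(default_factory=set)

    def to_series(self) -> pd.Series:
        return pd.Series(self.ps, name="ps", dtype=int)


def assign_phylostrata(
    hits: pd.DataFrame, lineage: LineageMap, e_cutoff: float
) -> PhylostratumMap:
    """Assign every query gene to the oldest phylostratum with a hit.

    ``hits`` needs columns ``query``, ``taxon`` and ``evalue``; the threshold
    is inclusive (e <= cutoff).  Hits to taxa absent from the lineage map are
    an error (silent dropping would bias ages young).
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    unknown = set(hits["taxon"]) - set(lineage.taxon_to_ps)
    if unknown:
        raise ValueError(f"hit taxa absent from lineage map: {sorted(unknown)[:10]}")
    all_genes = set(hits["query"])
    qualifying = hits[hits["evalue"] <= e_cutoff]
    ps_of_hit = qualifying["taxon"].map(lineage.taxon_to_ps)
    assigned = (
        pd.Series(ps_of_hit.values, index=qualifying["query"].values)
        .groupby(level=0)
        .min()
        .astype(int)
    )
    return PhylostratumMap(
        ps=assigned.to_dict(), unassigned=all_genes - set(assigned.index)
    )


def evalue_sweep(
    hits: pd.DataFrame,
    lineage: LineageMap,
    cutoffs: list[float] | None = None,
) -> tuple[dict[float, PhylostratumMap], pd.DataFrame]:
    """One phylostratum map per cutoff plus a monotonicity report.

    Returns the maps and a DataFrame listing every (gene, looser cutoff,
    stricter cutoff) pair where the stricter cutoff assigned an *older* (
    smaller) phylostratum -- impossible under the oldest-hit rule, so a
    non-empty report flags corrupt input.
    """
    if cutoffs is None:
        cutoffs = SWEEP_CUTOFFS
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    cutoffs = sorted(set(cutoffs), reverse=True)  # most permissive first
    maps = {c: assign_phylostrata(hits, lineage, c) for c in cutoffs}
    rows = []
    for loose, strict in zip(cutoffs, cutoffs[1:]):
        loose_ps, strict_ps = maps[loose].ps, maps[strict].ps
        for gene, p_strict in strict_ps.items():
            p_loose = loose_ps.get(gene)
            if p_loose is not None and p_strict < p_loose:
                rows.append(
                    {"gene": gene, "loose": loose, "strict": strict,
                     "ps_loose": p_loose, "ps_strict": p_strict}
                )
    report = pd.DataFrame(rows, columns=["gene", "loose", "strict", "ps_loose", "ps_strict"])
    return maps, report


def build_lineage_from_newick(
    tree_text: str,
    focal: str,
    internode_labels: list[str] | None = None,
) -> LineageMap:
    """Derive a lineage map from a Newick consensus phylogeny.

    Each leaf taxon is assigned the index (1-based, root = 1) of the node on
    the root -> focal path where its lineage diverges, i.e. its most recent
    common ancestor with the focal species.  The focal species itself maps to
    the deepest index P.
    """
    tree = dendropy.Tree.get(data=tree_text, schema="newick")
    focal_leaf = [l for l in tree.leaf_node_iter() if l.taxon and l.taxon.label == focal]
    if not focal_leaf:
        raise ValueError(f"focal taxon {focal!r} not found in tree")
    path = []  # root -> focal, inclusive
    node = focal_leaf[0]
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()
    depth = {id(n): i + 1 for i, n in enumerate(path)}
    n_ps = len(path)
    if internode_labels is not None and len(internode_labels) != n_ps:
        raise ValueError(
            f"{len(internode_labels)} internode labels for {n_ps} internodes"
        )
    taxon_to_ps: dict[str, int] = {focal: n_ps}
    for leaf in tree.leaf_node_iter():
        if leaf is focal_leaf[0] or leaf.taxon is None:
            continue
        anc = leaf.parent_node
        while anc is not None and id(anc) not in depth:
            anc = anc.parent_node
        if anc is None:
            raise ValueError(f"taxon {leaf.taxon.label!r} shares no ancestor with focal")
        taxon_to_ps[leaf.taxon.label] = depth[id(anc)]
    return LineageMap(n_ps=n_ps, taxon_to_ps=taxon_to_ps)


def read_hit_table(
    path: str | Path | io.StringIO,
    fmt: str = "tsv",
    taxon_tag_sep: str = "|",
    taxon_tag_index: int = 0,
) -> pd.DataFrame:
    """Read a homology hit table.

    ``fmt='tsv'``: headered TSV with columns query, subject_taxon, e_value and
    optionally bitscore.  ``fmt='outfmt6'``: headerless 12-column BLAST
    tabular output; the subject taxon is extracted from the sseqid by
    splitting on ``taxon_tag_sep`` and taking field ``taxon_tag_index`` (the
    taxon-tag dialect varies between databases, hence configurable).
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(
            columns={"subject_taxon": "taxon", "e_value": "evalue", "bit_score": "bitscore"}
        )
        required = {"query", "taxon", "evalue"}
        if not required <= set(df.columns):
            raise ValueError(f"hit table needs columns {sorted(required)}")
    elif fmt == "outfmt6":
        names = [
            "query", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=names)
        df["taxon"] = df["sseqid"].str.split(taxon_tag_sep).str[taxon_tag_index]
    else:
        raise ValueError(f"unknown hit-table format {fmt!r}")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    return df


def read_lineage_map(path: str | Path) -> LineageMap:
    """Read a two-column TSV (taxon, ps)."""
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    return LineageMap(n_ps=max(mapping.values()), taxon_to_ps=mapping)


def write_phylostratum_map(pmap: PhylostratumMap, path: str | Path) -> None:
    pmap.to_series().rename_axis("gene").to_csv(path, sep="\t")
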