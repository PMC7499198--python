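"""Region classification of SVs, recurrent-locus merging, carrier matrix.

The four-way scheme assigns each SV, per overlapped gene, to exonic /
splicing / intronic, or — when no gene is overlapped — to intergenic with
the nearest gene.  Breakpoints are the first and last affected base of the
variant interval; an SV whose breakpoints both land in exons of a gene is
exonic for it, one confined to a single intron is intronic, and one whose
extent crosses any exon/intron boundary is splicing.  A gene can be both
exonic and splicing for the same SV (e.g. a deletion running from one exon
into the next across an intron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genome import GeneModel, GenomeIndex
from .sv_io import CohortManifest, SVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "REGION_CLASSES",
    "SVGeneAssignment",
    "SVLocusCluster",
    "classify_sv",
    "classify_all",
    "merge_loci",
    "build_carrier_matrix",
]

REGION_CLASSES = ("exonic", "splicing", "intronic", "intergenic")


@dataclass(frozen=True)
class SVGeneAssignment:
    """One (SV, gene) region-class assignment."""

    sv: SVRecord
    region_class: str
    gene_id: str
    distance: int = 0       # bp to the gene; >0 only for intergenic

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if (self.distance > 0) != (self.region_class == "intergenic"):
            raise ValueError(
                "distance must be positive exactly for intergenic assignments")


def _classes_for_gene(sv: SVRecord, gene: GeneModel) -> set[str]:
    """Region classes an interval SV earns for one overlapped gene."""
    s, e = sv.start, sv.end
    p1, p2 = s, e - 1          # first and last affected base
    in_ex1, in_ex2 = gene.in_exon(p1), gene.in_exon(p2)
    in_g1, in_g2 = gene.contains(p1), gene.contains(p2)
    crossed = any(
        s < edge < e
        for xs, xe in gene.exons
        for edge in (xs, xe)
    )
    classes: set[str] = set()
    if in_ex1 and in_ex2:
        classes.add("exonic")
        if crossed:
            classes.add("splicing")
    elif crossed:
        classes.add("splicing")
    elif in_g1 and in_g2:
        classes.add("intronic")
    else:
        # overlap without crossing an exon edge and without both ends in the
        # gene can only arise for degenerate annotations; call it splicing
        classes.add("splicing")
    return classes


def classify_sv(sv: SVRecord, index: GenomeIndex) -> list[SVGeneAssignment]:
    """Classify one SV against the gene model.

    Interval types (DEL/DUP/INV/INS) are evaluated per overlapped gene and
    may yield several assignments; breakends are classified from the
    breakend base alone.  An SV touching no gene yields a single intergenic
    assignment to the nearest gene (anchor: interval midpoint, or the
    breakend base for BND).
    """
    if sv.sv_type == "BND":
        loc = index.locate_position(sv.chrom, sv.start)
        if loc["class"] == "exon":
            return [SVGeneAssignment(sv, "exonic", g) for g in loc["genes"]]
        if loc["class"] == "intron":
            return [SVGeneAssignment(sv, "intronic", g) for g in loc["genes"]]
        return _intergenic(sv, index, sv.start)
    genes = index.genes_overlapping(sv.chrom, sv.start, sv.end)
    if not genes:
        return _intergenic(sv, index, (sv.start + sv.end) // 2)
    out: list[SVGeneAssignment] = []
    for g in genes:
        for cls in sorted(_classes_for_gene(sv, g)):
            out.append(SVGeneAssignment(sv, cls, g.gene_id))
    return out


def _intergenic(sv: SVRecord, index: GenomeIndex, anchor: int) -> list[SVGeneAssignment]:
    try:
        gene, dist = index.nearest_gene(sv.chrom, anchor)
    except LookupError:
        logger.warning("SV %s on %s: no genes on chromosome; unassigned",
                       sv.id, sv.chrom)
        return []
    return [SVGeneAssignment(sv, "intergenic", gene.gene_id, dist)]


def classify_all(records: Iterable[SVRecord], index: GenomeIndex) -> list[SVGeneAssignment]:
    out: list[SVGeneAssignment] = []
    for sv in records:
        out.extend(classify_sv(sv, index))
    return out


@dataclass
class SVLocusCluster:
    """Recurrent locus: equivalent SVs merged across samples."""

    cluster_id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    carriers: set[str] = field(default_factory=set)
    members: list[SVGeneAssignment] = field(default_factory=list)

    @property
    def occurrence(self) -> int:
        return len(self.carriers)

    @property
    def gene_classes(self) -> list[tuple[str, str]]:
        """Sorted distinct (gene_id, region_class) pairs over members."""
        return sorted({(m.gene_id, m.region_class) for m in self.members})


def _equivalent(a: SVRecord, b: SVRecord, window: int, rec_overlap: float) -> bool:
    if abs(a.start - b.start) > window or abs(a.end - b.end) > window:
        return False
    if a.sv_type in ("INS", "BND"):
        return True
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return (ov / (a.end - a.start) >= rec_overlap
            and ov / (b.end - b.start) >= rec_overlap)


def merge_loci(assignments: Sequence[SVGeneAssignment], window: int = 50,
               reciprocal_overlap: float = 0.8) -> list[SVLocusCluster]:
    """Single-linkage merge of equivalent SVs into recurrent loci.

    Two same-type same-chromosome SVs are linked when both breakpoints
    agree within ±window bp and (for interval types) reciprocal overlap is
    at least the threshold.  Output is deterministically ordered by
    (chrom, start, end, sv_type) and independent of input order.
    """
    # one node per distinct (sample, event) SV; assignments sharing an SV
    # travel together
    sv_nodes: dict[tuple, dict] = {}
    for a in assignments:
        key = (a.sv.sample_id, a.sv.event_key, a.sv.chrom, a.sv.start,
               a.sv.end, a.sv.sv_type)
        node = sv_nodes.setdefault(key, {"sv": a.sv, "assignments": []})
        node["assignments"].append(a)
    groups: dict[tuple[str, str], list[dict]] = {}
    for node in sv_nodes.values():
        sv = node["sv"]
        groups.setdefault((sv.chrom, sv.sv_type), []).append(node)

    clusters: list[SVLocusCluster] = []
    for (chrom, sv_type), nodes in sorted(groups.items()):
        nodes.sort(key=lambda n: (n["sv"].start, n["sv"].end,
                                  n["sv"].sample_id, n["sv"].event_key))
        n = len(nodes)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if nodes[j]["sv"].start - nodes[i]["sv"].start > window:
                    break
                if _equivalent(nodes[i]["sv"], nodes[j]["sv"], window,
                               reciprocal_overlap):
                    parent[find(j)] = find(i)
        by_root: dict[int, list[dict]] = {}
        for i in range(n):
            by_root.setdefault(find(i), []).append(nodes[i])
        for root in sorted(by_root):
            members = by_root[root]
            svs = [m["sv"] for m in members]
            cl = SVLocusCluster(
                cluster_id="",
                sv_type=sv_type, chrom=chrom,
                start=min(s.start for s in svs),
                end=max(s.end for s in svs),
                carriers={s.sample_id for s in svs},
                members=[a for m in members for a in m["assignments"]],
            )
            clusters.append(cl)
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.sv_type))
    for i, c in enumerate(clusters):
        c.cluster_id = f"locus_{i + 1:05d}"
    return clusters


def build_carrier_matrix(assignments: Sequence[SVGeneAssignment],
                         manifest: CohortManifest,
                         unit: str = "sv_gene",
                         clusters: Sequence[SVLocusCluster] | None = None,
                         strict: bool = True) -> pd.DataFrame:
    """Binary carrier matrix: rows are test keys, columns samples.

    In ``sv_gene`` mode the key is (gene_id, region_class, sv_type); in
    ``locus`` mode keys are cluster ids from :func:`merge_loci` (pass
    ``clusters``, or they are computed with defaults).  A sample carrying
    several qualifying events for a key counts once.  Columns cover every
    manifest sample, carriers or not.
    """
    if unit not in ("sv_gene", "locus"):
        raise ValueError(f"unknown unit {unit!r}")
    unknown = {a.sv.sample_id for a in assignments} - set(manifest.samples)
    if unknown:
        if strict:
            raise ManifestMismatch(
                f"samples with SVs but not in manifest: {sorted(unknown)[:5]}")
        logger.warning("dropping %d samples absent from manifest", len(unknown))
        assignments = [a for a in assignments
                       if a.sv.sample_id in manifest.samples]
    samples = sorted(manifest.samples)
    carriers: dict[tuple, set[str]] = {}
    if unit == "sv_gene":
        for a in assignments:
            key = (a.gene_id, a.region_class, a.sv.sv_type)
            carriers.setdefault(key, set()).add(a.sv.sample_id)
        if carriers:
            index = pd.MultiIndex.from_tuples(
                sorted(carriers), names=["gene_id", "region_class", "sv_type"])
        else:
            index = pd.MultiIndex.from_arrays(
                [[], [], []], names=["gene_id", "region_class", "sv_type"])
    else:
        if clusters is None:
            clusters = merge_loci(assignments)
        for c in clusters:
            carriers[c.cluster_id] = set(c.carriers) & set(manifest.samples)
        index = pd.Index(sorted(carriers), name="cluster_id")
    mat = pd.DataFrame(False, index=index, columns=samples, dtype=bool)
    for key, sset in carriers.items():
        mat.loc[key, sorted(sset)] = True
    return mat


class ManifestMismatch(KeyError):
    pass
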