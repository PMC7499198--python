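"""Gene-model loading and genomic interval queries.

Internally every interval is 0-based half-open; GTF/GFF3 (1-based inclusive)
is converted at the boundary.  A gene's exon set is the union-merge of exon
rows across all of its transcripts; the introns are the complement of that
union within the gene span, so exons and introns exactly tile the span.
"""

from __future__ import annotations

import bisect
import logging
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomeIndex",
    "AnnotationError",
    "load_annotation",
    "merge_intervals",
]


class AnnotationError(ValueError):
    """Malformed annotation input or inconsistent gene structure."""


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge half-open intervals into a sorted disjoint list.

    Adjacent (touching) intervals are merged too, so the result is the
    minimal disjoint cover.
    """
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, merged exon union and derived introns.

    Coordinates are 0-based half-open.  ``exons`` is the disjoint union of
    exon intervals over all transcripts; ``introns`` is its complement
    within ``span`` so that exons and introns tile the span exactly.
    """

    gene_id: str
    name: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        s, e = self.span
        if not s < e:
            raise AnnotationError(f"gene {self.gene_id}: empty span {self.span}")
        for xs, xe in self.exons:
            if xs < s or xe > e:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{xs},{xe}) outside span [{s},{e})"
                )
        if not self.introns:
            object.__setattr__(self, "introns", tuple(self._derive_introns()))

    def _derive_introns(self) -> Iterator[tuple[int, int]]:
        prev = self.span[0]
        for xs, xe in self.exons:
            if xs > prev:
                yield (prev, xs)
            prev = xe
        if prev < self.span[1]:
            yield (prev, self.span[1])

    @classmethod
    def from_exons(
        cls, gene_id: str, name: str, chrom: str, strand: str,
        span: tuple[int, int], exons: Iterable[tuple[int, int]],
    ) -> "GeneModel":
        return cls(gene_id, name, chrom, strand, span, tuple(merge_intervals(exons)))

    def contains(self, pos: int) -> bool:
        return self.span[0] <= pos < self.span[1]

    def in_exon(self, pos: int) -> bool:
        i = bisect.bisect_right([x[0] for x in self.exons], pos) - 1
        return i >= 0 and pos < self.exons[i][1]

    def distance_to(self, pos: int) -> int:
        """bp from pos to the span (0 if inside)."""
        s, e = self.span
        if pos < s:
            return s - pos
        if pos >= e:
            return pos - e + 1
        return 0


def _parse_attributes(raw: str, dialect: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if dialect == "gtf":
        for part in raw.rstrip(";").split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, val = part.partition(" ")
            attrs[key] = val.strip().strip('"')
    else:  # gff3
        for part in raw.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, val = part.partition("=")
            attrs[key] = urllib.parse.unquote(val)
    return attrs


def _gene_id_of(attrs: dict[str, str], dialect: str) -> str | None:
    if dialect == "gtf":
        return attrs.get("gene_id")
    return attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent")


def load_annotation(stream: TextIO | Iterable[str], dialect: str = "gtf") -> list[GeneModel]:
    """Parse GTF or GFF3 text into :class:`GeneModel` objects.

    Requires ``gene`` and ``exon`` feature rows carrying a gene identifier
    (GTF ``gene_id`` attribute; GFF3 ``gene_id``, ``ID`` on genes and
    ``Parent``/``gene_id`` on exons).  File coordinates (1-based inclusive)
    are converted to 0-based half-open.  Exons of each gene are union-merged
    across transcripts.

    Raises :class:`AnnotationError` naming the line number for malformed
    rows, and naming the gene for exons outside their gene span.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    gff3_tx_parent: dict[str, str] = {}  # transcript ID -> gene ID
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw_attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from None
        if start1 < 1 or end1 < start1:
            raise AnnotationError(f"line {lineno}: bad coordinate range {start1}-{end1}")
        start, end = start1 - 1, end1  # to 0-based half-open
        attrs = _parse_attributes(raw_attrs, dialect)
        ftype = feature.lower()
        if ftype == "gene":
            gid = attrs.get("gene_id") or attrs.get("ID")
            if gid is None:
                raise AnnotationError(f"line {lineno}: gene row without gene identifier")
            genes[gid] = {
                "name": attrs.get("gene_name") or attrs.get("Name") or gid,
                "chrom": chrom,
                "strand": strand,
                "span": (start, end),
            }
        elif ftype in ("transcript", "mrna"):
            if dialect == "gff3":
                tid = attrs.get("ID")
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if tid and parent:
                    gff3_tx_parent[tid] = parent
        elif ftype == "exon":
            gid = _gene_id_of(attrs, dialect)
            if gid is None:
                raise AnnotationError(f"line {lineno}: exon row without gene identifier")
            gid = gff3_tx_parent.get(gid, gid)
            exons.setdefault(gid, []).append((start, end))
    models: list[GeneModel] = []
    for gid, info in genes.items():
        ex = merge_intervals(exons.get(gid, [info["span"]]))
        for xs, xe in ex:
            if xs < info["span"][0] or xe > info["span"][1]:
                raise AnnotationError(
                    f"gene {gid}: exon [{xs},{xe}) outside gene span "
                    f"[{info['span'][0]},{info['span'][1]})"
                )
        models.append(
            GeneModel(gid, info["name"], info["chrom"], info["strand"],
                      info["span"], tuple(ex))
        )
    orphans = set(exons) - set(genes) - set(gff3_tx_parent.values())
    if orphans:
        logger.warning("exon rows for %d unknown gene ids ignored: %s",
                       len(orphans), sorted(orphans)[:5])
    models.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return models


class GenomeIndex:
    """Interval index over genes and exon unions, per chromosome.

    Supports point-location (exon / intron / intergenic with the genes
    involved) and nearest-gene queries.  ``strict`` makes queries on unknown
    chromosomes raise instead of returning intergenic-with-warning.
    """

    def __init__(self, genes: Iterable[GeneModel], strict: bool = False):
        self.strict = strict
        self.genes: dict[str, GeneModel] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._spans_sorted: dict[str, list[tuple[int, int, str]]] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            gt = self._gene_trees.setdefault(g.chrom, IntervalTree())
            gt.addi(g.span[0], g.span[1], g.gene_id)
            et = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for xs, xe in g.exons:
                et.addi(xs, xe, g.gene_id)
            self._spans_sorted.setdefault(g.chrom, []).append(
                (g.span[0], g.span[1], g.gene_id))
        self._ends_sorted: dict[str, list[tuple[int, str]]] = {}
        for chrom, spans in self._spans_sorted.items():
            spans.sort()
            self._ends_sorted[chrom] = sorted(
                (e, gid) for _, e, gid in spans)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._gene_trees)

    def _check_chrom(self, chrom: str) -> bool:
        if chrom in self._gene_trees:
            return True
        if self.strict:
            raise KeyError(f"unknown chromosome {chrom!r}")
        logger.warning("chromosome %r not in annotation; treating as intergenic", chrom)
        return False

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """All genes whose span overlaps [start, end), sorted."""
        if chrom not in self._gene_trees:
            self._check_chrom(chrom)
            return []
        hits = self._gene_trees[chrom].overlap(start, end)
        out = [self.genes[iv.data] for iv in hits]
        out.sort(key=lambda g: (g.span[0], g.gene_id))
        return out

    def locate_position(self, chrom: str, pos: int) -> dict:
        """Classify a point as exon / intron / intergenic.

        Returns ``{"class", "genes", "intron_genes"}``: ``genes`` carries
        the genes matching the reported class; when the point is exonic in
        one gene but intronic in an overlapping other, the latter appears
        in ``intron_genes``.
        """
        if not self._check_chrom(chrom):
            return {"class": "intergenic", "genes": [], "intron_genes": []}
        exon_hits = sorted(
            {iv.data for iv in self._exon_trees[chrom].at(pos)})
        gene_hits = sorted(
            {iv.data for iv in self._gene_trees[chrom].at(pos)})
        intron_hits = [g for g in gene_hits if g not in set(exon_hits)]
        if exon_hits:
            return {"class": "exon", "genes": exon_hits, "intron_genes": intron_hits}
        if gene_hits:
            return {"class": "intron", "genes": gene_hits, "intron_genes": []}
        return {"class": "intergenic", "genes": [], "intron_genes": []}

    def nearest_gene(self, chrom: str, pos: int) -> tuple[GeneModel, int]:
        """Gene span minimizing distance to pos (0 when inside).

        Ties broken by lower span start, then lexicographic gene_id.
        Raises ``LookupError`` when the chromosome has no genes.
        """
        spans = self._spans_sorted.get(chrom)
        if not spans:
            raise LookupError(f"no genes on chromosome {chrom!r}")
        inside = [iv.data for iv in self._gene_trees[chrom].at(pos)]
        if inside:
            gid = min(inside, key=lambda g: (self.genes[g].span[0], g))
            return self.genes[gid], 0
        # pos is outside every span: nearest is either the gene ending last
        # at/before pos or the gene starting first after pos
        ends = self._ends_sorted[chrom]
        starts = [s for s, _, _ in spans]
        candidates: list[str] = []
        j = bisect.bisect_right([e for e, _ in ends], pos)
        if j > 0:
            best_end = ends[j - 1][0]
            candidates += [g for e, g in ends[:j] if e == best_end]
        i = bisect.bisect_right(starts, pos)
        if i < len(spans):
            best_start = spans[i][0]
            candidates += [g for s, _, g in spans[i:] if s == best_start]
        best = min(
            candidates,
            key=lambda g: (self.genes[g].distance_to(pos), self.genes[g].span[0], g),
        )
        return self.genes[best], self.genes[best].distance_to(pos)
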