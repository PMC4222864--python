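"""Classify mapped probes as retroelement-reporting and attach context.

A probe reports sense transcription of a retroelement when its best genomic
placement lies entirely within a single repeat-masked interval and its strand
relationship to the element matches the platform chemistry: on antisense-cRNA
platforms the probe must be sense to the element (probe strand == repeat
strand); on sense-cDNA platforms it must be antisense (strands differ).

For retained probes the nearest protein-coding genes chromosomally 5' and 3'
are recorded; probes placed at multiple genomic loci keep their row but all
annotation requiring a specific genomic context is omitted.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import (
    Chemistry,
    GeneFeature,
    GenomeHit,
    LTRClass,
    PlatformManifest,
    REAnnotationRow,
    RepeatFeature,
)

logger = logging.getLogger(__name__)

# LTR retroviral class by RepBase family group; MaLRs belong to class III
_LTR_CLASS_BY_FAMILY = {
    "ERV1": LTRClass.I,
    "ERVK": LTRClass.II,
    "ERVL": LTRClass.III,
    "ERVL-MaLR": LTRClass.III,
    "MaLR": LTRClass.III,
}


def ltr_class_of(repclass: str) -> LTRClass:
    top, _, family = repclass.partition("/")
    if top != "LTR":
        return LTRClass.NA
    return _LTR_CLASS_BY_FAMILY.get(family, LTRClass.NA)


class RepeatIndex:
    """Per-chromosome interval index over repeat-masked features."""

    def __init__(self, repeats: Iterable[RepeatFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for r in repeats:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def containing(self, chrom: str, start: int, end: int) -> list[RepeatFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = [iv.data for iv in tree.overlap(start, end)
               if iv.begin <= start and end <= iv.end]
        # deterministic order: smallest enclosing interval first, then name
        out.sort(key=lambda r: (r.end - r.start, r.start, r.repeat_name))
        return out


class GeneIndex:
    """Sorted per-chromosome gene lists for nearest-neighbour queries."""

    def __init__(self, genes: Iterable[GeneFeature], coding_only: bool = True):
        if coding_only:
            genes = [g for g in genes if g.is_coding]
        else:
            genes = list(genes)
        self._by_end: dict[str, list[GeneFeature]] = {}
        self._by_start: dict[str, list[GeneFeature]] = {}
        self._trees: dict[str, IntervalTree] = {}
        chroms = {g.chrom for g in genes}
        for c in chroms:
            cg = [g for g in genes if g.chrom == c]
            self._by_end[c] = sorted(cg, key=lambda g: (g.end, g.gene_id))
            self._by_start[c] = sorted(cg, key=lambda g: (g.start, g.gene_id))
            tree = IntervalTree()
            for g in cg:
                tree.addi(g.start, g.end, g)
            self._trees[c] = tree

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._by_end

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda g: (g.start, g.gene_id))

    def five_prime(self, chrom: str, pos: int) -> Optional[GeneFeature]:
        """Gene with the greatest end <= pos on chrom."""
        lst = self._by_end.get(chrom)
        if not lst:
            return None
        ends = [g.end for g in lst]
        i = bisect.bisect_right(ends, pos)
        return lst[i - 1] if i > 0 else None

    def three_prime(self, chrom: str, pos: int) -> Optional[GeneFeature]:
        """Gene with the least start >= pos on chrom."""
        lst = self._by_start.get(chrom)
        if not lst:
            return None
        starts = [g.start for g in lst]
        i = bisect.bisect_left(starts, pos)
        return lst[i] if i < len(lst) else None


def classify_re_probe(
    hit: GenomeHit,
    repeats: RepeatIndex,
    chemistry: Chemistry,
) -> Optional[RepeatFeature]:
    """Return the repeat a probe reports, or None if it is not RE-reporting.

    Requires strict containment of the probe interval in a single repeat
    record and the chemistry-appropriate strand relationship.
    """
    chemistry = Chemistry(chemistry)
    for rep in repeats.containing(hit.sid, hit.sstart, hit.send):
        if chemistry is Chemistry.ANTISENSE_CRNA:
            ok = hit.strand == rep.strand
        else:
            ok = hit.strand != rep.strand
        if ok:
            return rep
    return None


@dataclass
class NearestGenes:
    five: Optional[GeneFeature]
    three: Optional[GeneFeature]
    distance: Optional[int]  # 0 if overlapping a gene; None if chrom unannotated


def nearest_genes(hit: GenomeHit, genes: GeneIndex) -> NearestGenes:
    """Nearest genes chromosomally 5' and 3' of the probe interval.

    5' gene: greatest end <= probe start; 3' gene: least start >= probe end
    (by coordinate, irrespective of gene strand).  Distance is the smaller
    flanking gap, 0 when the probe overlaps any gene, None when the
    chromosome has no annotation at all.
    """
    if not genes.has_chrom(hit.sid):
        return NearestGenes(None, None, None)
    five = genes.five_prime(hit.sid, hit.sstart)
    three = genes.three_prime(hit.sid, hit.send)
    if genes.overlapping(hit.sid, hit.sstart, hit.send):
        return NearestGenes(five, three, 0)
    gaps = []
    if five is not None:
        gaps.append(hit.sstart - five.end)
    if three is not None:
        gaps.append(three.start - hit.send)
    return NearestGenes(five, three, min(gaps) if gaps else None)


def build_annotation(
    manifest: PlatformManifest,
    hits: Sequence[GenomeHit],
    repeats: RepeatIndex | Iterable[RepeatFeature],
    genes: GeneIndex | Iterable[GeneFeature],
    coding_only: bool = True,
) -> list[REAnnotationRow]:
    """Assemble one annotation row per RE-classified probe.

    Classification always uses the reported best hit; genomic-context fields
    are omitted from the row when the probe maps to multiple loci.
    """
    if not isinstance(repeats, RepeatIndex):
        repeats = RepeatIndex(repeats)
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes, coding_only=coding_only)
    probes = {p.pid: p for p in manifest.probes}
    rows: list[REAnnotationRow] = []
    for hit in hits:
        probe = probes.get(hit.pid)
        if probe is None:
            raise ValueError(f"hit for unknown probe {hit.pid!r}")
        rep = classify_re_probe(hit, repeats, manifest.chemistry)
        if rep is None:
            continue
        repclass = rep.repeat_class
        if repclass.split("/", 1)[0] not in (
            "LTR", "LINE", "SINE", "DNA", "Simple_repeat", "Low_complexity", "Other"
        ):
            warnings.warn(f"repeat {rep.repeat_name}: unparsable class {repclass!r}; "
                          "recorded as Other")
            repclass = "Other"
        if hit.numhits > 1:
            rows.append(
                REAnnotationRow(
                    pid=hit.pid, probeset=probe.probeset, plen=probe.plen,
                    numhits=hit.numhits, ltr_class=ltr_class_of(repclass),
                )
            )
            continue
        ng = nearest_genes(hit, genes)
        rows.append(
            REAnnotationRow(
                pid=hit.pid,
                probeset=probe.probeset,
                plen=probe.plen,
                numhits=hit.numhits,
                sid=hit.sid,
                sstart=hit.sstart,
                send=hit.send,
                nident=hit.nident,
                repeat=rep.repeat_name,
                repclass=repclass,
                rstart=rep.start,
                rend=rep.end,
                five_id=ng.five.symbol if ng.five else None,
                five_start=ng.five.start if ng.five else None,
                five_stop=ng.five.end if ng.five else None,
                three_id=ng.three.symbol if ng.three else None,
                three_start=ng.three.start if ng.three else None,
                three_stop=ng.three.end if ng.three else None,
                intergenic_distance=ng.distance,
                ltr_class=ltr_class_of(repclass),
            )
        )
    rows.sort(key=lambda r: r.pid)
    logger.info("classified %d/%d mapped probes as RE-reporting", len(rows), len(hits))
    return rows


def intragenic_position_bins(
    rows: Sequence[REAnnotationRow],
    genes: GeneIndex | Iterable[GeneFeature],
    bins: int = 10,
    near_gene_bp: int = 1000,
) -> np.ndarray:
    """Histogram of RE-probe positions within (or within ``near_gene_bp`` of)
    genes, as bins of fraction of gene length measured 5'->3' of the gene.

    Positions are clamped to [0, 1], so near-genic probes upstream of the
    gene fall in the first bin and downstream ones in the last.
    """
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes)
    counts = np.zeros(bins, dtype=int)
    for r in rows:
        if not r.has_context:
            continue
        if r.intergenic_distance is None or r.intergenic_distance > near_gene_bp:
            continue
        mid = (r.sstart + r.send) / 2
        overlapping = genes.overlapping(r.sid, r.sstart, r.send)
        if overlapping:
            gene = overlapping[0]
        else:
            five = genes.five_prime(r.sid, r.sstart)
            three = genes.three_prime(r.sid, r.send)
            cands = [g for g in (five, three) if g is not None]
            gene = min(cands, key=lambda g: min(abs(r.sstart - g.end), abs(g.start - r.send)))
        rel = (mid - gene.start) / (gene.end - gene.start)
        if gene.strand == "-":
            rel = 1.0 - rel
        rel = min(max(rel, 0.0), 1.0)
        idx = min(int(rel * bins), bins - 1)
        counts[idx] += 1
    return counts
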