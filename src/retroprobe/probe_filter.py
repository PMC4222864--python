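"""Enhanced filtering of RE-reporting probes and platform coverage accounting.

The enhanced filter retains only probes that (i) are uniquely placed on the
genome, (ii) lie strictly more than a configurable distance (default 1 kb)
from the nearest protein-coding gene, and (iii) come from probesets in which
strictly more than 75% of member probes report retroelement expression.  The
probeset fraction is computed against all probes of the probeset in the
platform manifest, including probes that failed to map.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .models import FilterConfig, PlatformManifest, REAnnotationRow, RepeatFeature

logger = logging.getLogger(__name__)


def enhanced_filter(
    rows: Sequence[REAnnotationRow],
    manifest: PlatformManifest,
    cfg: FilterConfig | None = None,
) -> list[REAnnotationRow]:
    """Apply the enhanced filter; returns retained rows in pid order."""
    cfg = cfg or FilterConfig()
    probeset_sizes = {ps: len(members) for ps, members in manifest.probesets().items()}
    re_counts: dict[str, int] = {}
    for r in rows:
        if r.probeset not in probeset_sizes:
            raise ValueError(f"probeset {r.probeset!r} (probe {r.pid}) absent from manifest")
        re_counts[r.probeset] = re_counts.get(r.probeset, 0) + 1

    retained = []
    for r in rows:
        if cfg.require_unique and not r.is_unique:
            continue
        if r.intergenic_distance is None or r.intergenic_distance <= cfg.min_gene_distance:
            continue
        frac = re_counts[r.probeset] / probeset_sizes[r.probeset]
        if not frac > cfg.min_probeset_re_fraction:
            continue
        retained.append(r)
    retained.sort(key=lambda r: r.pid)
    logger.info("enhanced filter retained %d/%d RE-reporting probes", len(retained), len(rows))
    return retained


COVERAGE_CLASSES = ("LTR", "LINE", "SINE")


def coverage_table(
    retained: Sequence[REAnnotationRow],
    repeats: Iterable[RepeatFeature],
) -> pd.DataFrame:
    """Per-class retained-probe counts and repeat-instance coverage.

    Coverage is the percentage of distinct repeat instances of a top-level
    class (LTR / LINE / SINE) carrying at least one retained probe, out of
    all instances of that class in the repeat annotation.
    """
    repeats = list(repeats)
    instances_by_class: dict[str, set] = {c: set() for c in COVERAGE_CLASSES}
    for rep in repeats:
        if rep.top_class in instances_by_class:
            instances_by_class[rep.top_class].add((rep.chrom, rep.start, rep.end, rep.repeat_name))

    hit_instances: dict[str, set] = {c: set() for c in COVERAGE_CLASSES}
    probe_counts: dict[str, int] = {c: 0 for c in COVERAGE_CLASSES}
    for r in retained:
        if r.repclass is None:
            continue
        top = r.repclass.split("/", 1)[0]
        if top not in probe_counts:
            continue
        probe_counts[top] += 1
        hit_instances[top].add((r.sid, r.rstart, r.rend, r.repeat))

    recs = []
    for c in COVERAGE_CLASSES:
        total = len(instances_by_class[c])
        covered = len(hit_instances[c])
        pct = 100.0 * covered / total if total else 0.0
        recs.append({"class": c, "probes": probe_counts[c],
                     "instances_covered": covered, "instances_total": total,
                     "coverage_pct": pct})
    total_probes = sum(probe_counts.values())
    total_cov = sum(len(s) for s in hit_instances.values())
    total_inst = sum(len(s) for s in instances_by_class.values())
    recs.append({"class": "total", "probes": total_probes,
                 "instances_covered": total_cov, "instances_total": total_inst,
                 "coverage_pct": 100.0 * total_cov / total_inst if total_inst else 0.0})
    return pd.DataFrame(recs).set_index("class")
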