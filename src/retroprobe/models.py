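"""Core domain types shared across the pipeline.

All genomic intervals held in memory are 0-based half-open on the forward
strand; conversion to/from each file format's native convention happens only
in :mod:`retroprobe.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

# top-level RepeatMasker classes accepted in repeat_class strings
REPEAT_TOP_CLASSES = (
    "LTR",
    "LINE",
    "SINE",
    "DNA",
    "Simple_repeat",
    "Low_complexity",
    "Other",
)


class Chemistry(str, Enum):
    """Hybridization-target polarity of a platform.

    Arrays hybridizing antisense cRNA (classic 3' expression arrays) carry
    probes that are *sense* to the transcript; arrays hybridizing sense cDNA
    (whole-transcript arrays) carry probes *antisense* to the transcript.
    The polarity decides which strand relationship a probe must have with a
    retroelement in order to report its sense transcription.
    """

    ANTISENSE_CRNA = "antisense_crna"
    SENSE_CDNA = "sense_cdna"


class Scale(str, Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class LTRClass(str, Enum):
    """Retroviral LTR class: I (ERV1), II (ERVK), III (ERVL incl. MaLRs)."""

    I = "I"
    II = "II"
    III = "III"
    NA = "NA"


@dataclass(frozen=True)
class ProbeRecord:
    """One platform probe: identifiers, sequence, probeset membership."""

    pid: str
    probeset: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"probe {self.pid!r}: sequence contains non-ACGT character(s) "
                f"{sorted(bad)}"
            )
        if len(self.sequence) < 10:
            raise ValueError(f"probe {self.pid!r}: length {len(self.sequence)} < 10")

    @property
    def plen(self) -> int:
        return len(self.sequence)


@dataclass
class PlatformManifest:
    platform_name: str
    chemistry: Chemistry
    probes: list[ProbeRecord]

    def __post_init__(self) -> None:
        self.chemistry = Chemistry(self.chemistry)
        seen: set[str] = set()
        for p in self.probes:
            if p.pid in seen:
                raise ValueError(f"duplicate pid {p.pid!r} in platform manifest")
            seen.add(p.pid)

    def probesets(self) -> dict[str, list[ProbeRecord]]:
        out: dict[str, list[ProbeRecord]] = {}
        for p in self.probes:
            out.setdefault(p.probeset, []).append(p)
        return out

    def __len__(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-masked genomic interval with its RepBase identity."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"repeat {self.repeat_name}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"repeat {self.repeat_name}: bad strand {self.strand!r}")

    @property
    def top_class(self) -> str:
        return self.repeat_class.split("/", 1)[0]


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    symbol: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass(frozen=True)
class GenomeHit:
    """A probe placement on the genome.

    ``numhits`` counts all qualifying placements genome-wide; the stored
    interval/strand/nident describe the single highest-scoring placement.
    """

    pid: str
    sid: str
    sstart: int
    send: int
    strand: str
    nident: int
    numhits: int
    score: int

    def __post_init__(self) -> None:
        if self.numhits < 1:
            raise ValueError(f"hit for {self.pid}: numhits must be >= 1")


# serialized columns of the probe annotation CSV, in file order
ANNOTATION_COLUMNS = (
    "pid", "probeset", "plen", "sid", "sstart", "send", "nident", "numhits",
    "repeat", "repclass", "rstart", "rend",
    "5id", "5start", "5stop", "3id", "3start", "3stop",
)


@dataclass
class REAnnotationRow:
    """One annotated retroelement-reporting probe (18 serialized fields).

    Genomic-context fields (everything except pid/probeset/plen/numhits) are
    ``None`` for probes mapping to multiple loci, where annotation requiring
    a specific genomic context is omitted.  Derived flags are held in memory
    but never serialized.
    """

    pid: str
    probeset: str
    plen: int
    numhits: int
    sid: Optional[str] = None
    sstart: Optional[int] = None
    send: Optional[int] = None
    nident: Optional[int] = None
    repeat: Optional[str] = None
    repclass: Optional[str] = None
    rstart: Optional[int] = None
    rend: Optional[int] = None
    five_id: Optional[str] = None
    five_start: Optional[int] = None
    five_stop: Optional[int] = None
    three_id: Optional[str] = None
    three_start: Optional[int] = None
    three_stop: Optional[int] = None
    # derived, not serialized
    intergenic_distance: Optional[int] = field(default=None, compare=False)
    ltr_class: LTRClass = field(default=LTRClass.NA, compare=False)

    @property
    def is_unique(self) -> bool:
        return self.numhits == 1

    @property
    def has_context(self) -> bool:
        return self.sid is not None

    def validate(self) -> None:
        ctx = (self.sid, self.sstart, self.send, self.nident, self.repeat,
               self.repclass, self.rstart, self.rend)
        present = [v is not None for v in ctx]
        if any(present) and not all(present):
            raise ValueError(f"row {self.pid}: partial genomic context")
        if self.has_context:
            if not (self.rstart <= self.sstart and self.send <= self.rend):
                raise ValueError(
                    f"row {self.pid}: probe interval not contained in repeat interval"
                )


@dataclass
class FilterConfig:
    """Thresholds of the enhanced filter; fraction and distance tests are strict."""

    min_identity: float = 0.95
    min_probeset_re_fraction: float = 0.75
    min_gene_distance: int = 1000
    require_unique: bool = True

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_probeset_re_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_gene_distance < 0:
            raise ValueError("min_gene_distance must be >= 0")


@dataclass
class BiweightParams:
    """Tuning constants of the one-step Tukey biweight (c=5, eps=1e-4)."""

    c: float = 5.0
    epsilon: float = 0.0001

    def __post_init__(self) -> None:
        if self.c <= 0 or self.epsilon <= 0:
            raise ValueError("c and epsilon must be positive")


@dataclass
class ExpressionMatrix:
    """Probe-level intensities (probes x samples) with sample factor metadata."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids
    scale: Scale
    sample_factors: pd.DataFrame  # index = sample ids, columns = factor names

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.columns.equals(self.sample_factors.index):
            if set(self.values.columns) != set(self.sample_factors.index):
                raise ValueError("sample ids of matrix and factor table differ")
            self.sample_factors = self.sample_factors.loc[self.values.columns]
        if self.scale is Scale.LINEAR and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale matrix must be strictly positive")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> "ExpressionMatrix":
        if self.scale is Scale.LOG2:
            return self
        return ExpressionMatrix(np.log2(self.values), Scale.LOG2, self.sample_factors)
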