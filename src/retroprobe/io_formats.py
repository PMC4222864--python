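"""Readers and writers for the external file formats the pipeline touches.

Coordinate conventions are converted exactly once, here, at the boundary:

===================  =======================  =========================
format               native convention        conversion on read
===================  =======================  =========================
RepeatMasker .out    1-based inclusive        start -= 1
GTF                  1-based inclusive        start -= 1
BED                  0-based half-open        none
annotation CSV       1-based inclusive        start -= 1 (both probe
                                              and gene/repeat fields)
===================  =======================  =========================

The annotation CSV mirrors the 18-column probe-annotation schema
(pid, probeset, plen, sid, sstart, send, nident, numhits, repeat, repclass,
rstart, rend, 5id, 5start, 5stop, 3id, 3start, 3stop); context fields are
written empty for probes mapping to multiple genomic loci.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import (
    ANNOTATION_COLUMNS,
    Chemistry,
    ExpressionMatrix,
    GeneFeature,
    PlatformManifest,
    ProbeRecord,
    REAnnotationRow,
    RepeatFeature,
    Scale,
)

RM_HEADER_LINES = 3


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


# ---------------------------------------------------------------- genome FASTA

def read_genome_fasta(path) -> dict[str, str]:
    """Load a genome as {sequence name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------ RepeatMasker .out

def read_repeatmasker_out(path) -> list[RepeatFeature]:
    """Parse RepeatMasker .out: 3 header lines, whitespace-delimited columns,
    1-based inclusive coordinates, 'C' for the minus strand."""
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= RM_HEADER_LINES or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ParseError(f"{path}: line {lineno}: expected >=11 columns, got {len(parts)}")
            try:
                chrom = parts[4]
                begin = int(parts[5])
                end = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinate field ({exc})") from None
            strand_sym = parts[8]
            if strand_sym == "+":
                strand = "+"
            elif strand_sym in ("C", "c"):
                strand = "-"
            else:
                raise ParseError(f"{path}: line {lineno}: unknown strand symbol {strand_sym!r}")
            feats.append(
                RepeatFeature(
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    repeat_name=parts[9],
                    repeat_class=parts[10],
                )
            )
    return feats


def write_repeatmasker_out(repeats: Iterable[RepeatFeature], path) -> None:
    """Emit a minimal .out file (the standard column layout, dummy scores)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query     matching"
            "       repeat              position in repeat\n"
            "score   div. del. ins.  sequence    begin    end (left)   repeat"
            "       class/family         begin  end (left)   ID\n\n"
        )
        for i, r in enumerate(repeats, start=1):
            left = 0
            strand = "+" if r.strand == "+" else "C"
            fh.write(
                f" 1000    0.0  0.0  0.0  {r.chrom} {r.start + 1} {r.end} ({left}) "
                f"{strand} {r.repeat_name} {r.repeat_class} 1 {r.end - r.start} (0) {i}\n"
            )


# ----------------------------------------------------------------- GTF and BED

def read_gene_annotation(path, fmt: str = "GTF") -> list[GeneFeature]:
    """Read gene features from GTF (gene lines) or BED (chrom start end name
    score strand biotype).  Lines of other feature types are ignored in GTF."""
    fmt = fmt.upper()
    if fmt == "GTF":
        genes = _read_gtf(path)
    elif fmt == "BED":
        genes = _read_bed(path)
    else:
        raise ValueError(f"unknown gene annotation format {fmt!r}")
    seen: dict[str, GeneFeature] = {}
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen[g.gene_id] = g
    return genes


def _read_gtf(path) -> list[GeneFeature]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if feat.featuretype != "gene":
                continue
            gene_id = feat.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: gene line without gene_id")
            symbol = feat.attributes.get("gene_name", [gene_id])[0]
            biotypes = feat.attributes.get("gene_biotype", [])
            if not biotypes:
                warnings.warn(f"{path}: line {lineno}: gene {gene_id} lacks gene_biotype; "
                              "recorded as 'unknown'")
                biotype = "unknown"
            else:
                biotype = biotypes[0]
            genes.append(
                GeneFeature(
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    gene_id=gene_id,
                    symbol=symbol,
                    biotype=biotype,
                )
            )
    return genes


def _read_bed(path) -> list[GeneFeature]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: BED needs >=6 columns")
            biotype = parts[6] if len(parts) > 6 and parts[6] else "unknown"
            if biotype == "unknown":
                warnings.warn(f"{path}: line {lineno}: missing biotype; recorded as 'unknown'")
            genes.append(
                GeneFeature(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    gene_id=parts[3],
                    symbol=parts[3],
                    biotype=biotype,
                )
            )
    return genes


def write_gtf(genes: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tretroprobe\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ------------------------------------------------------------ platform manifest

CHEMISTRY_PRAGMA = "#chemistry="
PLATFORM_PRAGMA = "#platform="


def read_platform_manifest(path, chemistry: Optional[str] = None) -> PlatformManifest:
    """Read a probe manifest TSV (columns pid, probeset, sequence).

    Chemistry comes from a ``#chemistry=`` header pragma or, failing that,
    from the ``chemistry`` argument (an explicit input, never inferred from
    the platform name).
    """
    platform_name = Path(str(path)).stem
    pragma_chem = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(CHEMISTRY_PRAGMA):
                pragma_chem = line[len(CHEMISTRY_PRAGMA):].strip()
                continue
            if line.startswith(PLATFORM_PRAGMA):
                platform_name = line[len(PLATFORM_PRAGMA):].strip()
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "pid":  # column header
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns (pid, probeset, sequence)")
            rows.append(parts[:3])
    chem = pragma_chem or chemistry
    if chem is None:
        raise ValueError(f"{path}: chemistry not declared (no pragma and no argument)")
    probes = [ProbeRecord(pid=p, probeset=ps, sequence=seq.upper()) for p, ps, seq in rows]
    return PlatformManifest(platform_name=platform_name, chemistry=Chemistry(chem), probes=probes)


def write_platform_manifest(manifest: PlatformManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{PLATFORM_PRAGMA}{manifest.platform_name}\n")
        fh.write(f"{CHEMISTRY_PRAGMA}{manifest.chemistry.value}\n")
        fh.write("pid\tprobeset\tsequence\n")
        for p in manifest.probes:
            fh.write(f"{p.pid}\t{p.probeset}\t{p.sequence}\n")


# ------------------------------------------------------------- annotation CSV

def write_annotation_csv(rows: Iterable[REAnnotationRow], path) -> None:
    """Write the 18-column annotation CSV, genomic coordinates 1-based
    inclusive; context fields empty where omitted."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        for r in rows:
            r.validate()
            if r.has_context:
                ctx = [
                    r.sid, r.sstart + 1, r.send, r.nident,
                ]
                rep = [r.repeat, r.repclass, r.rstart + 1, r.rend]
                five = [r.five_id or "",
                        r.five_start + 1 if r.five_start is not None else "",
                        r.five_stop if r.five_stop is not None else ""]
                three = [r.three_id or "",
                         r.three_start + 1 if r.three_start is not None else "",
                         r.three_stop if r.three_stop is not None else ""]
            else:
                ctx = ["", "", "", ""]
                rep = ["", "", "", ""]
                five = ["", "", ""]
                three = ["", "", ""]
            w.writerow([r.pid, r.probeset, r.plen, *ctx, r.numhits, *rep, *five, *three])


def _opt_int(v: str) -> Optional[int]:
    v = v.strip()
    return int(v) if v else None


def read_annotation_csv(path) -> list[REAnnotationRow]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != ANNOTATION_COLUMNS:
            raise ParseError(f"{path}: unexpected annotation header {header}")
        for rec in reader:
            if not rec:
                continue
            d = dict(zip(ANNOTATION_COLUMNS, rec))
            sstart = _opt_int(d["sstart"])
            rstart = _opt_int(d["rstart"])
            fstart = _opt_int(d["5start"])
            tstart = _opt_int(d["3start"])
            rows.append(
                REAnnotationRow(
                    pid=d["pid"],
                    probeset=d["probeset"],
                    plen=int(d["plen"]),
                    numhits=int(d["numhits"]),
                    sid=d["sid"].strip() or None,
                    sstart=sstart - 1 if sstart is not None else None,
                    send=_opt_int(d["send"]),
                    nident=_opt_int(d["nident"]),
                    repeat=d["repeat"].strip() or None,
                    repclass=d["repclass"].strip() or None,
                    rstart=rstart - 1 if rstart is not None else None,
                    rend=_opt_int(d["rend"]),
                    five_id=d["5id"].strip() or None,
                    five_start=fstart - 1 if fstart is not None else None,
                    five_stop=_opt_int(d["5stop"]),
                    three_id=d["3id"].strip() or None,
                    three_start=tstart - 1 if tstart is not None else None,
                    three_stop=_opt_int(d["3stop"]),
                )
            )
    return rows


# --------------------------------------------------------- expression matrices

def read_expression_matrix(matrix_path, factors_path, scale: str = "log2") -> ExpressionMatrix:
    """Read a probes x samples TSV plus a sample-factor TSV (index = sample)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    factors = pd.read_csv(factors_path, sep="\t", index_col=0, comment="#", dtype=str)
    return ExpressionMatrix(values=values, scale=Scale(scale), sample_factors=factors)


def write_expression_matrix(m: ExpressionMatrix, matrix_path, factors_path=None) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    if factors_path is not None:
        m.sample_factors.to_csv(factors_path, sep="\t")
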