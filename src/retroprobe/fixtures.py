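"""Deterministic synthetic fixtures: genomes with planted repeats and genes,
platform manifests with truth-labelled probes, and expression matrices with
known effects.

The generator emulates, at toy scale, the inputs the pipeline consumes on
real data (a reference genome + RepeatMasker annotation + gene annotation +
array platform + probe-level intensity matrices).  Every planted probe
carries a truth label stating whether it should be classified as
RE-reporting and whether it should survive the enhanced filter, so that
end-to-end precision and recall against ground truth are exactly 1.0 by
construction when the pipeline is correct.

A single integer seed drives three independent sub-streams (genome,
platform, expression), so extending one plan does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats
from .models import (
    Chemistry,
    ExpressionMatrix,
    GeneFeature,
    PlatformManifest,
    ProbeRecord,
    REAnnotationRow,
    RepeatFeature,
    Scale,
)
from .probe_mapper import GenomeIndex, map_probe, reverse_complement

BASES = np.array(list("ACGT"))

# (family, class, length) cycled over unique-RE host repeats
_FAMILY_CYCLE = (
    ("RLTR1A", "LTR/ERV1", 400),
    ("RLTR44-int", "LTR/ERVK", 400),
    ("MT2B", "LTR/ERVL-MaLR", 400),
    ("L1Md_F", "LINE/L1", 500),
    ("B2_Mm2", "SINE/B2", 150),
)


@dataclass
class ExpressionPlan:
    """Statistical structure of the synthetic intensity matrix (log2 scale)."""

    tissues: tuple[str, ...] = ("heart", "liver", "spleen")
    experiments: tuple[str, ...] = ("exp1", "exp2")
    replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    tissue_effect: float = 2.0     # shift of regulated probesets in heart
    batch_sd: float = 0.3          # experiment (batch) offset SD
    gene_component_sd: float = 1.0
    shared_fraction: float = 0.3   # variance of an RE probe shared with its nearest gene
    noise_sd: float = 0.25
    outlier_shift: float = 4.0


@dataclass
class FixtureSpec:
    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 70_000
    probe_length: int = 25
    chemistry: Chemistry = Chemistry.ANTISENSE_CRNA
    n_unprobed_repeats: int = 6
    gene_length: int = 2000
    intergenic_gap: tuple[int, int] = (1100, 1500)   # strictly > 1 kb filter margin
    near_gene_gap: tuple[int, int] = (150, 450)      # < 1 kb -> fails filter
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)


@dataclass
class PlantedRepeat:
    feature: RepeatFeature
    role: str            # unique | wrong | overhang | multicopy | near_gene | unprobed
    sequence: str        # element-sense sequence (forward strand if strand +)
    nearest_gene: Optional[str] = None
    nearest_gene_distance: Optional[int] = None


@dataclass
class GenomeFixture:
    genome: dict[str, str]
    repeats: list[RepeatFeature]
    genes: list[GeneFeature]
    planted: list[PlantedRepeat]


@dataclass
class PlatformFixture:
    manifest: PlatformManifest
    truth: pd.DataFrame          # index pid: probeset, category, expected_re,
                                 # expected_retained, numhits, nearest_gene
    gene_probesets: dict[str, str]  # gene symbol -> probeset id


@dataclass
class ExpressionFixture:
    matrix: ExpressionMatrix     # log2 scale
    regulated_probesets: list[str]
    outlier_probes: list[str]


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: GenomeFixture
    platform: PlatformFixture
    expression: ExpressionFixture


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


# ------------------------------------------------------------------- genome

def generate_genome(spec: FixtureSpec, rng: np.random.Generator) -> GenomeFixture:
    """Lay out planted repeats and genes along background sequence.

    Features are placed left to right with inter-feature gaps drawn from
    ``spec.intergenic_gap`` (so intergenic repeats are strictly farther than
    1 kb from every gene) except near-gene repeats, which are attached a
    sub-kilobase gap downstream of their host gene.
    """
    # build the unit list: repeats by role, genes with optional attached repeat
    n_unique = 26
    units: list[tuple] = []
    fam_i = 0
    for i in range(n_unique):
        fam, cls, length = _FAMILY_CYCLE[fam_i % len(_FAMILY_CYCLE)]
        fam_i += 1
        units.append(("repeat", f"unique", fam, cls, length))
    for i in range(4):
        fam, cls, length = _FAMILY_CYCLE[fam_i % len(_FAMILY_CYCLE)]
        fam_i += 1
        units.append(("repeat", "wrong", fam, cls, length))
    for i in range(3):
        fam, cls, length = _FAMILY_CYCLE[fam_i % len(_FAMILY_CYCLE)]
        fam_i += 1
        units.append(("repeat", "overhang", fam, cls, length))
    multicopy_seq = _random_seq(rng, 400)
    for i in range(3):
        units.append(("repeat", "multicopy", "IAPEz-int", "LTR/ERVK", 400))
    for i in range(spec.n_unprobed_repeats):
        fam, cls, length = _FAMILY_CYCLE[fam_i % len(_FAMILY_CYCLE)]
        fam_i += 1
        units.append(("repeat", "unprobed", fam, cls, length))

    genes = []
    for i in range(10):
        genes.append((f"G{i + 1:02d}", "protein_coding"))
    for i in range(2):
        genes.append((f"NC{i + 1}", "lincRNA"))
    # near-gene repeats attach to the first four protein-coding genes
    gene_units = []
    for j, (sym, biotype) in enumerate(genes):
        attach = j < 4
        gene_units.append(("gene", sym, biotype, attach))
    units.extend(gene_units)
    rng.shuffle(units)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    for i, u in enumerate(units):
        per_chrom[chrom_names[i % spec.n_chroms]].append(u)

    genome: dict[str, str] = {}
    repeats: list[RepeatFeature] = []
    gene_feats: list[GeneFeature] = []
    planted: list[PlantedRepeat] = []
    near_done = 0

    for chrom in chrom_names:
        parts: list[str] = []
        pos = 0
        # (planted repeat index, position) pairs for nearest-gene back-fill
        chrom_features: list[tuple] = []  # ("gene", sym, start, end) / ("rep", idx)

        def append_seq(s: str):
            nonlocal pos
            parts.append(s)
            pos += len(s)

        for unit in per_chrom[chrom]:
            gap = int(rng.integers(*spec.intergenic_gap))
            append_seq(_random_seq(rng, gap))
            if unit[0] == "repeat":
                _, role, fam, cls, length = unit
                strand = "+" if rng.random() < 0.5 else "-"
                if role == "multicopy":
                    elem = multicopy_seq
                    strand = "+"  # identical copies on the forward strand
                else:
                    elem = _random_seq(rng, length)
                fwd = elem if strand == "+" else reverse_complement(elem)
                start = pos
                append_seq(fwd)
                feat = RepeatFeature(chrom, start, pos, strand, fam, cls)
                repeats.append(feat)
                planted.append(PlantedRepeat(feat, role, elem))
                chrom_features.append(("rep", len(planted) - 1))
            else:
                _, sym, biotype, attach = unit
                strand = "+" if rng.random() < 0.5 else "-"
                start = pos
                append_seq(_random_seq(rng, spec.gene_length))
                gf = GeneFeature(chrom, start, pos, strand, f"ENSF{sym}", sym, biotype)
                gene_feats.append(gf)
                chrom_features.append(("gene", sym, start, pos, biotype))
                if attach and near_done < 4:
                    near_done += 1
                    ngap = int(rng.integers(*spec.near_gene_gap))
                    append_seq(_random_seq(rng, ngap))
                    nstrand = "+" if rng.random() < 0.5 else "-"
                    elem = _random_seq(rng, 150)
                    nstart = pos
                    append_seq(elem if nstrand == "+" else reverse_complement(elem))
                    feat = RepeatFeature(chrom, nstart, pos, nstrand, "B2_Mm1a", "SINE/B2")
                    repeats.append(feat)
                    planted.append(
                        PlantedRepeat(feat, "near_gene", elem, nearest_gene=sym,
                                      nearest_gene_distance=ngap)
                    )
                    chrom_features.append(("rep", len(planted) - 1))
        append_seq(_random_seq(rng, int(rng.integers(*spec.intergenic_gap))))
        if pos > spec.chrom_length:
            raise ValueError(
                f"fixture plan exceeds chromosome capacity: {chrom} needs {pos} bases "
                f"but chrom_length is {spec.chrom_length}"
            )
        append_seq(_random_seq(rng, spec.chrom_length - pos))
        genome[chrom] = "".join(parts)

        # back-fill nearest protein-coding gene for intergenic repeats
        coding = [(f[2], f[3], f[1]) for f in chrom_features
                  if f[0] == "gene" and f[4] == "protein_coding"]
        for kind, *rest in chrom_features:
            if kind != "rep":
                continue
            pr = planted[rest[0]]
            if pr.nearest_gene is not None:
                continue
            best = None
            for gstart, gend, sym in coding:
                if gend <= pr.feature.start:
                    d = pr.feature.start - gend
                elif gstart >= pr.feature.end:
                    d = gstart - pr.feature.end
                else:
                    d = 0
                if best is None or d < best[0]:
                    best = (d, sym)
            if best is not None:
                pr.nearest_gene_distance, pr.nearest_gene = best[0], best[1]

    return GenomeFixture(genome=genome, repeats=repeats, genes=gene_feats, planted=planted)


# ----------------------------------------------------------------- platform

def _probe_from(pr: PlantedRepeat, offset: int, plen: int, map_strand: str) -> str:
    """Probe sequence that will map at the given forward-strand offset within
    the repeat, on the requested strand."""
    fwd = pr.sequence if pr.feature.strand == "+" else reverse_complement(pr.sequence)
    sub = fwd[offset:offset + plen]
    return sub if map_strand == "+" else reverse_complement(sub)


def _mutate(seq: str, n_mismatch: int, rng: np.random.Generator) -> str:
    """Introduce n_mismatch substitutions at distinct interior positions."""
    s = list(seq)
    positions = rng.choice(np.arange(2, len(s) - 2), size=n_mismatch, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


def generate_platform(
    spec: FixtureSpec,
    genome_fx: GenomeFixture,
    rng: np.random.Generator,
) -> PlatformFixture:
    """Sample probes from planted features into engineered probesets.

    Probeset compositions deliberately straddle the >75% RE-fraction
    boundary (9/11 passes, 8/11 and 3/4 exactly 75% fail); other probesets
    isolate the unique-placement, gene-distance, orientation and containment
    requirements.  Per-gene probesets provide the nearest-gene summaries used
    by the co-regulation analysis.
    """
    plen = spec.probe_length
    chem = spec.chemistry
    by_role: dict[str, list[PlantedRepeat]] = {}
    for pr in genome_fx.planted:
        by_role.setdefault(pr.role, []).append(pr)
    uniques = iter(by_role["unique"])
    genes = {g.symbol: g for g in genome_fx.genes}
    gindex = GenomeIndex(genome_fx.genome)

    probes: list[ProbeRecord] = []
    truth_rows: list[dict] = []

    def correct_strand(pr: PlantedRepeat) -> str:
        # orientation that reports sense transcription under the chemistry
        if chem is Chemistry.ANTISENSE_CRNA:
            return pr.feature.strand
        return "-" if pr.feature.strand == "+" else "+"

    def wrong_strand(pr: PlantedRepeat) -> str:
        return "-" if correct_strand(pr) == "+" else "+"

    def add(pid, probeset, seq, category, expected_re, expected_retained,
            numhits=1, nearest_gene=None, nearest_gene_distance=None):
        probes.append(ProbeRecord(pid=pid, probeset=probeset, sequence=seq))
        truth_rows.append({
            "pid": pid, "probeset": probeset, "category": category,
            "expected_re": expected_re, "expected_retained": expected_retained,
            "numhits": numhits, "nearest_gene": nearest_gene,
            "nearest_gene_distance": nearest_gene_distance,
        })

    def add_unique_re(pid, probeset, retained, n_mismatch=0):
        pr = next(uniques)
        off = int(rng.integers(0, pr.feature.end - pr.feature.start - plen + 1))
        seq = _probe_from(pr, off, plen, correct_strand(pr))
        if n_mismatch:
            seq = _mutate(seq, n_mismatch, rng)
        add(pid, probeset, seq, "re_unique_intergenic", True, retained,
            nearest_gene=pr.nearest_gene, nearest_gene_distance=pr.nearest_gene_distance)

    def add_genic(pid, probeset, symbol):
        g = genes[symbol]
        off = int(rng.integers(0, g.end - g.start - plen + 1))
        seq = genome_fx.genome[g.chrom][g.start + off:g.start + off + plen]
        add(pid, probeset, seq, "genic", False, False)

    coding_syms = [g.symbol for g in genome_fx.genes if g.is_coding]
    gsym = iter(coding_syms * 10)

    n = 0
    def pid():
        nonlocal n
        n += 1
        return f"P{n:04d}"

    # PS_RET1: 9/11 RE -> the nine RE probes pass the enhanced filter
    for _ in range(9):
        add_unique_re(pid(), "PS_RET1", retained=True)
    for _ in range(2):
        add_genic(pid(), "PS_RET1", next(gsym))
    # PS_RET2: 4/4 RE, one with a single (still-qualifying) mismatch
    add_unique_re(pid(), "PS_RET2", retained=True, n_mismatch=1)
    for _ in range(3):
        add_unique_re(pid(), "PS_RET2", retained=True)
    # PS_FRAC_FAIL: 8/11 = 72.7% -> fraction test fails
    for _ in range(8):
        add_unique_re(pid(), "PS_FRAC_FAIL", retained=False)
    for _ in range(3):
        add_genic(pid(), "PS_FRAC_FAIL", next(gsym))
    # PS_EXACT75: 3/4 = 75.0% exactly -> strict > fails
    for _ in range(3):
        add_unique_re(pid(), "PS_EXACT75", retained=False)
    add_genic(pid(), "PS_EXACT75", next(gsym))
    # PS_SINGLE / PS_SINGLE_DISC: lone RE probe among gene probes
    add_unique_re(pid(), "PS_SINGLE", retained=False)
    for _ in range(4):
        add_genic(pid(), "PS_SINGLE", "G01")
    add_unique_re(pid(), "PS_SINGLE_DISC", retained=False)
    for _ in range(4):
        add_genic(pid(), "PS_SINGLE_DISC", "G02")
    # PS_MULTI: probes present at 3 genomic loci -> numhits = 3
    multis = by_role["multicopy"]
    for k in range(4):
        pr = multis[0]
        off = int(rng.integers(0, 400 - plen + 1))
        seq = _probe_from(pr, off, plen, correct_strand(pr))
        add(pid(), "PS_MULTI", seq, "re_multi", True, False, numhits=3)
    # PS_NEAR: RE probes within 1 kb of a gene -> distance test fails
    for pr in by_role["near_gene"]:
        off = int(rng.integers(0, pr.feature.end - pr.feature.start - plen + 1))
        seq = _probe_from(pr, off, plen, correct_strand(pr))
        add(pid(), "PS_NEAR", seq, "re_near_gene", True, False,
            nearest_gene=pr.nearest_gene, nearest_gene_distance=pr.nearest_gene_distance)
    # PS_WRONG: reverse-orientation twins -> not RE-reporting
    for pr in by_role["wrong"]:
        off = int(rng.integers(0, pr.feature.end - pr.feature.start - plen + 1))
        seq = _probe_from(pr, off, plen, wrong_strand(pr))
        add(pid(), "PS_WRONG", seq, "wrong_orientation", False, False)
    # PS_OVER: probes overhanging the repeat boundary -> containment fails
    for pr in by_role["overhang"]:
        overhang = int(rng.integers(1, 6))
        chromseq = genome_fx.genome[pr.feature.chrom]
        start = pr.feature.end - plen + overhang
        sub = chromseq[start:start + plen]
        seq = sub if correct_strand(pr) == "+" else reverse_complement(sub)
        add(pid(), "PS_OVER", seq, "boundary_overhang", False, False)
    # PS_GENIC: plain gene probes
    for _ in range(4):
        add_genic(pid(), "PS_GENIC", next(gsym))
    # PS_UNMAP: absent from the genome / 2-mismatch probes below 95% identity
    for _ in range(2):
        while True:
            seq = _random_seq(rng, plen)
            probe = ProbeRecord(pid="tmp", probeset="tmp", sequence=seq)
            if map_probe(probe, gindex, 0.95) is None:
                break
        add(pid(), "PS_UNMAP", seq, "unmappable", False, False, numhits=0)
    for _ in range(2):
        pr = by_role["unprobed"][0]
        while True:
            off = int(rng.integers(0, pr.feature.end - pr.feature.start - plen + 1))
            seq = _mutate(_probe_from(pr, off, plen, correct_strand(pr)), 2, rng)
            probe = ProbeRecord(pid="tmp", probeset="tmp", sequence=seq)
            if map_probe(probe, gindex, 0.95) is None:
                break
        add(pid(), "PS_UNMAP", seq, "mismatch_2", False, False, numhits=0)
    # per-gene probesets (nearest-gene summaries for the co-regulation stage)
    gene_probesets: dict[str, str] = {}
    for g in genome_fx.genes:
        if not g.is_coding:
            continue
        ps = f"PSG_{g.symbol}"
        gene_probesets[g.symbol] = ps
        for _ in range(4):
            add_genic(pid(), ps, g.symbol)

    manifest = PlatformManifest(
        platform_name="SynthArray1", chemistry=chem, probes=probes
    )
    truth = pd.DataFrame(truth_rows).set_index("pid")
    return PlatformFixture(manifest=manifest, truth=truth, gene_probesets=gene_probesets)


# --------------------------------------------------------------- expression

def generate_expression(
    spec: FixtureSpec,
    platform: PlatformFixture,
    rng: np.random.Generator,
) -> ExpressionFixture:
    """Synthesize a log2-scale probe-level matrix with planted structure:
    probeset baselines, a heart-specific shift for the retained RE probesets,
    experiment (batch) offsets, a gene component shared between each gene's
    probeset and the RE probes nearest to it, and one outlier probe."""
    plan = spec.expression
    samples = []
    factors = []
    for t in plan.tissues:
        for e in plan.experiments:
            for r in range(1, plan.replicates + 1):
                samples.append(f"{t}_{e}_r{r}")
                factors.append({"tissue": t, "experiment": e})
    factors_df = pd.DataFrame(factors, index=samples)
    n_s = len(samples)

    truth = platform.truth
    manifest = platform.manifest
    probesets = sorted({p.probeset for p in manifest.probes})
    baselines = {ps: plan.baseline_mean + plan.baseline_sd * rng.normal()
                 for ps in probesets}
    batch = {e: plan.batch_sd * rng.normal() for e in plan.experiments}
    regulated = ["PS_RET1", "PS_RET2", "PS_SINGLE", "PS_SINGLE_DISC"]
    gene_z = {sym: rng.normal(size=n_s) for sym in platform.gene_probesets}

    values = {}
    outlier_probes: list[str] = []
    outlier_assigned = False
    f = plan.shared_fraction
    for p in manifest.probes:
        base = baselines[p.probeset]
        row = np.full(n_s, base)
        row += np.array([batch[factors_df.loc[s, "experiment"]] for s in samples])
        if p.probeset in regulated:
            is_re = bool(truth.loc[p.pid, "expected_re"]) if p.pid in truth.index else False
            eff = np.array([
                plan.tissue_effect if factors_df.loc[s, "tissue"] == plan.tissues[0] else 0.0
                for s in samples
            ])
            if p.probeset == "PS_SINGLE_DISC" and is_re:
                row -= eff  # discordant: the RE probe moves the other way
            else:
                row += eff
        # shared gene component
        if p.probeset in platform.gene_probesets.values():
            sym = next(s for s, ps in platform.gene_probesets.items() if ps == p.probeset)
            row += plan.gene_component_sd * gene_z[sym]
        elif p.pid in truth.index:
            ng = truth.loc[p.pid, "nearest_gene"]
            if isinstance(ng, str) and ng in gene_z:
                row += plan.gene_component_sd * (
                    math.sqrt(f) * gene_z[ng] + math.sqrt(1 - f) * rng.normal(size=n_s)
                )
        if p.probeset == "PS_GENIC" and not outlier_assigned:
            row += plan.outlier_shift
            outlier_probes.append(p.pid)
            outlier_assigned = True
        row += plan.noise_sd * rng.normal(size=n_s)
        values[p.pid] = row

    df = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    df = df.loc[sorted(df.index)]
    m = ExpressionMatrix(df, Scale.LOG2, factors_df)
    return ExpressionFixture(matrix=m, regulated_probesets=regulated,
                             outlier_probes=outlier_probes)


# ----------------------------------------------------------- top-level driver

def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    spec = spec or FixtureSpec()
    ss = np.random.SeedSequence(spec.seed)
    g_rng, p_rng, e_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    genome_fx = generate_genome(spec, g_rng)
    platform_fx = generate_platform(spec, genome_fx, p_rng)
    expr_fx = generate_expression(spec, platform_fx, e_rng)
    return Fixture(spec=spec, genome=genome_fx, platform=platform_fx, expression=expr_fx)


def write_fixture(fx: Fixture, outdir) -> dict[str, Path]:
    """Write every fixture artifact in its external format; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "repeats": outdir / "repeats.out",
        "genes": outdir / "genes.gtf",
        "manifest": outdir / "platform.tsv",
        "expression": outdir / "expression.tsv",
        "factors": outdir / "sample_factors.tsv",
        "truth": outdir / "probe_truth.tsv",
    }
    io_formats.write_genome_fasta(fx.genome.genome, paths["genome"])
    io_formats.write_repeatmasker_out(fx.genome.repeats, paths["repeats"])
    io_formats.write_gtf(fx.genome.genes, paths["genes"])
    io_formats.write_platform_manifest(fx.platform.manifest, paths["manifest"])
    io_formats.write_expression_matrix(fx.expression.matrix, paths["expression"],
                                       paths["factors"])
    fx.platform.truth.to_csv(paths["truth"], sep="\t")
    return paths


# --------------------------------------------- standalone statistical helpers

def generate_anova_matrix(
    n_probes: int,
    n_tissues: int = 3,
    replicates: int = 3,
    effect: float = 0.0,
    noise_sd: float = 1.0,
    batch_offsets: Optional[dict[str, float]] = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Matrix of independent probes with an optional planted tissue effect
    (tissue means graded 0, effect, 2*effect, ... so adjacent tissues differ
    by ``effect``) and optional experiment offsets."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tissues = [f"t{i + 1}" for i in range(n_tissues)]
    experiments = sorted(batch_offsets) if batch_offsets else ["e1"]
    samples, factors = [], []
    for t in tissues:
        for j, e in enumerate(experiments):
            for r in range(replicates):
                samples.append(f"{t}_{e}_r{r + 1}")
                factors.append({"tissue": t, "experiment": e})
    fdf = pd.DataFrame(factors, index=samples)
    n_s = len(samples)
    shift = np.array([
        effect * tissues.index(fdf.loc[s, "tissue"])
        + (batch_offsets[fdf.loc[s, "experiment"]] if batch_offsets else 0.0)
        for s in samples
    ])
    X = rng.normal(scale=noise_sd, size=(n_probes, n_s)) + shift
    df = pd.DataFrame(X, index=[f"probe{i}" for i in range(n_probes)], columns=samples)
    return ExpressionMatrix(df, Scale.LOG2, fdf)


def generate_regression_fixture(
    shared_fraction: float,
    n_pairs: int,
    n_samples: int,
    rng: np.random.Generator | None = None,
    repclass: str = "LTR/ERV1",
):
    """Matched RE-probe / nearest-gene values with a planted shared-variance
    fraction; returns (re_matrix, gene_summaries, annotation rows,
    sample_factors) ready for the nearest-gene regression.

    The noise component is orthogonalized against the gene component and both
    are standardized per pair, so the planted fraction is the empirical
    shared variance, not just its expectation."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_samples < 3:
        raise ValueError("need >= 3 samples per pair to orthogonalize the noise")
    samples = [f"heart_r{i + 1}" for i in range(n_samples)]
    factors = pd.DataFrame({"tissue": ["heart"] * n_samples}, index=samples)
    z_g = rng.normal(size=(n_pairs, n_samples))
    z_g = (z_g - z_g.mean(axis=1, keepdims=True))
    z_g /= z_g.std(axis=1, keepdims=True)
    e = rng.normal(size=(n_pairs, n_samples))
    e = e - e.mean(axis=1, keepdims=True)
    proj = (e * z_g).sum(axis=1, keepdims=True) / (z_g * z_g).sum(axis=1, keepdims=True)
    e = e - proj * z_g
    e /= e.std(axis=1, keepdims=True)
    re_vals = math.sqrt(shared_fraction) * z_g + math.sqrt(1 - shared_fraction) * e
    gene_ids = [f"G{i + 1}" for i in range(n_pairs)]
    re_ids = [f"RE{i + 1}" for i in range(n_pairs)]
    gene_summaries = pd.DataFrame(z_g, index=gene_ids, columns=samples)
    re_matrix = pd.DataFrame(re_vals, index=re_ids, columns=samples)
    rows = [
        REAnnotationRow(
            pid=re_ids[i], probeset=f"PS_{re_ids[i]}", plen=25, numhits=1,
            sid="chr1", sstart=10_000, send=10_025, nident=25,
            repeat="RLTR1A", repclass=repclass, rstart=9_800, rend=10_200,
            five_id=gene_ids[i], five_start=5_000, five_stop=7_000,
            intergenic_distance=3_000,
        )
        for i in range(n_pairs)
    ]
    return re_matrix, gene_summaries, rows, factors


def generate_convolution_array(
    n: int,
    alpha: float = 0.02,
    mu: float = 100.0,
    sigma: float = 15.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed = Exponential(alpha) signal + Normal(mu, sigma) noise;
    returns (observed, true signal) for background-correction checks."""
    rng = rng if rng is not None else np.random.default_rng(0)
    signal = rng.exponential(scale=1.0 / alpha, size=n)
    noise = rng.normal(loc=mu, scale=sigma, size=n)
    return signal + noise, signal
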