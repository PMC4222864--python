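"""Independent straight-line oracles used to cross-check the implementation.

These deliberately share no code with the package: the genome scanner walks
every offset with plain string comparison, and the biweight follows the
written formula step by step with the statistics module.
"""

import math
import statistics

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_map(seq: str, genome: dict, min_identity: float = 0.95):
    """All-offset scan of both strands; returns (numhits, best) where best is
    (nident, sid, offset, strand) of the top placement under the lowest
    (sid, offset, strand) tie-break, or None."""
    plen = len(seq)
    min_matches = math.ceil(min_identity * plen)
    rc = revcomp(seq)
    numhits = 0
    best = None
    for sid in sorted(genome):
        chrom = genome[sid].upper()
        for off in range(len(chrom) - plen + 1):
            window = chrom[off:off + plen]
            for strand, probe in (("+", seq), ("-", rc)):
                n = sum(1 for a, b in zip(probe, window) if a == b and a in "ACGT")
                if n >= min_matches:
                    numhits += 1
                    key = (-n, sid, off, strand)
                    if best is None or key < best:
                        best = key
    if best is None:
        return 0, None
    return numhits, (-best[0], best[1], best[2], best[3])


def biweight_oracle(values, c: float = 5.0, eps: float = 0.0001) -> float:
    """One-step Tukey biweight written directly from the formula."""
    xs = list(map(float, values))
    if len(xs) == 1:
        return xs[0]
    M = statistics.median(xs)
    S = statistics.median(sorted(abs(x - M) for x in xs))
    num = 0.0
    den = 0.0
    for x in xs:
        u = (x - M) / (c * S + eps)
        w = (1.0 - u * u) ** 2 if abs(u) < 1.0 else 0.0
        num += w * x
        den += w
    return num / den


def quantile_normalize_oracle(columns):
    """Mean-of-order-statistics normalization of equal-length lists (no ties)."""
    k = len(columns)
    n = len(columns[0])
    sorted_cols = [sorted(c) for c in columns]
    mean_sorted = [sum(sc[i] for sc in sorted_cols) / k for i in range(n)]
    out = []
    for col in columns:
        ranks = sorted(range(n), key=lambda i: col[i])
        new = [0.0] * n
        for r, i in enumerate(ranks):
            new[i] = mean_sorted[r]
        out.append(new)
    return out
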