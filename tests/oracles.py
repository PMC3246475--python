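"""Independent brute-force implementations used as test oracles.

These deliberately avoid the package's own code paths: the classifier
enumerates the 12 base-change types in a lookup table and scans the full
dinucleotide neighborhood; the chi-square statistic is computed from the
margin formula; effects come from whole-sequence translation.
"""

from Bio.Seq import Seq

# all 12 single-base changes, strand-normalized by explicit enumeration
CHANGE_TABLE = {
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
}


def brute_force_category(seq: str, pos: int, alt: str) -> str:
    """Category of the substitution at 1-based ``pos``, CpG split included."""
    ref = seq[pos - 1]
    category = CHANGE_TABLE[(ref, alt)]
    if category != "GC>AT":
        return category
    # scan every CG dinucleotide of the sequence (0-based start indices)
    cg_starts = {i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"}
    i = pos - 1
    in_cpg = (ref == "C" and i in cg_starts) or (ref == "G" and i - 1 in cg_starts)
    return "GC>AT_CpG" if in_cpg else "GC>AT"


def brute_force_effect(seq: str, pos: int, alt: str) -> str:
    """Effect by translating the whole CDS before and after the change."""
    mutated = seq[:pos - 1] + alt + seq[pos:]
    n = len(seq) - len(seq) % 3
    before = str(Seq(seq[:n]).translate())
    after = str(Seq(mutated[:n]).translate())
    if before == after:
        return "silent"
    idx = next(i for i, (x, y) in enumerate(zip(before, after)) if x != y)
    return "nonsense" if after[idx] == "*" else "missense"


def brute_force_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square from the O/E margin formula (independent path)."""
    import numpy as np
    from scipy.stats import chi2 as chi2_dist

    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))
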