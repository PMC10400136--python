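"""Per-gene co-occurrence of biallelic alteration with HRDsig status.

The association test is the two-tailed Fisher exact test, computed by exact
integer arithmetic: with row margins (r1, r2) and column margin c1 fixed,
the two-tailed p-value sums the hypergeometric probabilities of every table
whose probability does not exceed the observed table's.  P-values across
genes are Benjamini-Hochberg adjusted; for volcano plotting they are capped
at 1e-10 (the cap never feeds the q computation).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import BRCA_PALB2, HRR_GENES

P_CAP = 1e-10


@dataclass(frozen=True)
class CoOccurrenceResult:
    gene: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: biallelic +/-, cols: HRDsig +/-
    odds_ratio: float
    p_two_tailed: float
    q_fdr: float
    p_capped: float


def fisher_exact_two_tailed(table) -> tuple[float, float]:
    """Two-tailed Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample
    (cross-product) estimate — ``inf`` when only the off-diagonal is empty,
    ``nan`` for a degenerate 0/0 — and p sums, over all tables with the
    observed margins, the probabilities not exceeding the observed table's
    probability.  Exact integer arithmetic, so ties are handled without
    floating-point tolerance.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise ValueError(f"table entries must be nonnegative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    num = sum(w for w in weights if w <= observed)
    return odds, num / comb(n, c1)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cooccurrence_tests(
    statuses: pd.DataFrame,
    calls: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene 2x2 association of biallelic status with HRDsig call.

    ``statuses`` is the long per-sample-per-gene table from the zygosity
    caller; ``calls`` has columns (sample, call).  Genes default to all
    genes with at least one biallelic alteration in the cohort.
    """
    call_map = calls.set_index("sample")["call"]
    pos_samples = set(call_map[call_map == "positive"].index)
    all_samples = set(call_map.index)
    st = statuses[statuses["sample"].isin(all_samples)]
    bi = st[st["status"] == "biallelic"]
    if genes is None:
        genes = sorted(bi["gene"].unique())
    rows = []
    pvals = []
    for gene in genes:
        bi_samples = set(bi.loc[bi["gene"] == gene, "sample"])
        a = len(bi_samples & pos_samples)
        b = len(bi_samples - pos_samples)
        c = len(pos_samples - bi_samples)
        d = len(all_samples - bi_samples - pos_samples)
        odds, p = fisher_exact_two_tailed([[a, b], [c, d]])
        # Haldane-Anscombe continuity correction for plotting ORs
        or_plot = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append((gene, a, b, c, d, odds, or_plot, p))
        pvals.append(p)
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_biallelic_hrdsig_pos",
            "n_biallelic_hrdsig_neg",
            "n_wildtype_hrdsig_pos",
            "n_wildtype_hrdsig_neg",
            "odds_ratio",
            "odds_ratio_plot",
            "p_two_tailed",
        ],
    )
    df["q_fdr"] = fdr_adjust(pvals) if len(pvals) else []
    df["p_capped"] = np.maximum(df["p_two_tailed"], P_CAP)
    df["neglog10_p_capped"] = -np.log10(df["p_capped"])
    return df


PARTITION_STRATA = (
    "biallelic BRCA1/2/PALB2",
    "other biallelic HRR",
    "monoallelic/unknown HRR",
    "HRRwt",
)


@dataclass
class LandscapePartition:
    """Genomic landscape of HRDsig(+) samples (mutually exclusive strata)."""

    n_positive: int
    counts: dict[str, int]
    fractions: dict[str, float] | None  # None when there are no positives

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": list(PARTITION_STRATA),
                "count": [self.counts[s] for s in PARTITION_STRATA],
                "fraction": [
                    self.fractions[s] if self.fractions else float("nan")
                    for s in PARTITION_STRATA
                ],
            }
        )


def landscape_partition(
    statuses: pd.DataFrame, calls: pd.DataFrame
) -> LandscapePartition:
    """Partition HRDsig(+) samples by HRR genotype.

    Priority per sample: biallelic BRCA1/2/PALB2 > other biallelic HRR gene
    > any non-biallelic HRR alteration > HRR-wildtype.  Raises if a positive
    sample has no status rows.
    """
    call_map = calls.set_index("sample")["call"]
    pos_samples = [s for s, c in call_map.items() if c == "positive"]
    st = statuses[statuses["gene"].isin(HRR_GENES)]
    by_sample = {s: grp for s, grp in st.groupby("sample")}
    counts = {s: 0 for s in PARTITION_STRATA}
    for sample in pos_samples:
        grp = by_sample.get(sample)
        if grp is None:
            raise ValueError(f"HRDsig(+) sample {sample!r} has no allelic statuses")
        bi_genes = set(grp.loc[grp["status"] == "biallelic", "gene"])
        altered = set(grp.loc[grp["status"] != "wildtype", "gene"])
        if bi_genes & set(BRCA_PALB2):
            counts["biallelic BRCA1/2/PALB2"] += 1
        elif bi_genes:
            counts["other biallelic HRR"] += 1
        elif altered:
            counts["monoallelic/unknown HRR"] += 1
        else:
            counts["HRRwt"] += 1
    n = len(pos_samples)
    assert sum(counts.values()) == n
    fractions = {s: counts[s] / n for s in PARTITION_STRATA} if n else None
    return LandscapePartition(n, counts, fractions)


def compute_prevalence(positives: int, total: int) -> float:
    """Prevalence as a percentage, reported at one decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    return round(100.0 * positives / total, 1)
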