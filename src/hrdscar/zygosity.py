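"""Per-variant zygosity and per-gene allelic status calling.

A gene is called **biallelic** when any of three rules fires:

1. a deep deletion in the gene (a deep_deletion variant record, or the gene
   locus falls in a segment with total copy number 0);
2. two or more pathogenic alterations in the same gene;
3. a pathogenic short variant under LOH (the containing segment has
   minor_cn = 0 and total_cn >= 1).

**Monoallelic** is a single pathogenic short variant called heterozygous.
When a pathogenic alteration is present but zygosity cannot be assessed
(rearrangement-only, or a short variant whose heterozygosity call is
unavailable), the status is **unknown**.  A gene with no pathogenic
alteration is **wildtype**.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GENE_LOCI, HRR_GENES
from .segments import SegmentedCopyNumberProfile
from .variants import ShortVariant

STATUSES = ("biallelic", "monoallelic", "unknown", "wildtype")


@dataclass(frozen=True)
class GeneAllelicStatus:
    gene: str
    status: str
    triggering_rule: str  # "1" | "2" | "3" | "monoallelic" | "unknown" | "none"


@dataclass(frozen=True)
class SampleHrrClass:
    """Sample-level summary over the 14-gene HRR basket.

    ``label`` is one of ``HRRwt``, ``biallelic``, ``monoallelic-only``,
    ``unknown-only`` (mixed monoallelic/unknown genes without any biallelic
    gene report as monoallelic-only).
    """

    sample_id: str
    label: str
    biallelic_genes: tuple[str, ...]
    monoallelic_genes: tuple[str, ...]
    unknown_genes: tuple[str, ...]

    @property
    def is_hrr_wildtype(self) -> bool:
        return self.label == "HRRwt"


def variant_under_loh(variant: ShortVariant, profile: SegmentedCopyNumberProfile) -> bool:
    """True iff the variant's containing segment is LOH (minor 0, total >= 1).

    Deep-deletion segments (total 0) are not LOH; they are handled by the
    deep-deletion rule instead.
    """
    if variant.chrom is None or variant.pos is None:
        raise ValueError(f"variant {variant} has no position")
    seg = profile.segment_at(variant.chrom, variant.pos)
    return seg.is_loh


def _gene_in_deep_deletion(gene: str, profile: SegmentedCopyNumberProfile | None) -> bool:
    if profile is None or gene not in GENE_LOCI:
        return False
    chrom, pos = GENE_LOCI[gene]
    if chrom not in profile.genome:
        return False
    try:
        seg = profile.segment_at(chrom, pos)
    except KeyError:
        return False
    return seg.is_deep_deletion


def call_allelic_status(
    gene: str,
    variants: list[ShortVariant],
    profile: SegmentedCopyNumberProfile | None = None,
) -> GeneAllelicStatus:
    """Apply the biallelic/monoallelic/unknown/wildtype rules to one gene.

    ``variants`` must already be restricted to one sample; only pathogenic
    records are considered.  The lowest-numbered firing biallelic rule is
    recorded as metadata (the status itself does not depend on precedence).
    """
    vs = [v for v in variants if v.gene == gene and v.pathogenic]
    if not vs:
        return GeneAllelicStatus(gene, "wildtype", "none")

    # rule 1: deep deletion (record-level or segment-level)
    if any(v.var_class == "deep_deletion" for v in vs) or _gene_in_deep_deletion(
        gene, profile
    ):
        return GeneAllelicStatus(gene, "biallelic", "1")
    # rule 2: two or more pathogenic alterations
    if len(vs) >= 2:
        return GeneAllelicStatus(gene, "biallelic", "2")
    # rule 3: pathogenic short variant under LOH
    if profile is not None:
        for v in vs:
            if v.is_short_variant and v.chrom is not None and v.pos is not None:
                if variant_under_loh(v, profile):
                    return GeneAllelicStatus(gene, "biallelic", "3")

    (v,) = vs
    if v.is_short_variant and v.het_flag is True:
        return GeneAllelicStatus(gene, "monoallelic", "monoallelic")
    # rearrangement-only, or heterozygosity call unavailable
    return GeneAllelicStatus(gene, "unknown", "unknown")


def call_sample_statuses(
    sample_id: str,
    variants: list[ShortVariant],
    profile: SegmentedCopyNumberProfile | None = None,
    genes: tuple[str, ...] = HRR_GENES,
) -> dict[str, GeneAllelicStatus]:
    vs = [v for v in variants if v.sample_id == sample_id]
    return {g: call_allelic_status(g, vs, profile) for g in genes}


def classify_hrr_sample(
    sample_id: str, statuses: dict[str, GeneAllelicStatus]
) -> SampleHrrClass:
    """Sample label over the full 14-gene basket."""
    missing = [g for g in HRR_GENES if g not in statuses]
    if missing:
        raise ValueError(f"missing statuses for genes: {missing}")
    bi = tuple(g for g in HRR_GENES if statuses[g].status == "biallelic")
    mono = tuple(g for g in HRR_GENES if statuses[g].status == "monoallelic")
    unk = tuple(g for g in HRR_GENES if statuses[g].status == "unknown")
    if bi:
        label = "biallelic"
    elif mono:
        label = "monoallelic-only"
    elif unk:
        label = "unknown-only"
    else:
        label = "HRRwt"
    return SampleHrrClass(sample_id, label, bi, mono, unk)


def statuses_frame(
    per_sample: dict[str, dict[str, GeneAllelicStatus]]
) -> pd.DataFrame:
    """Long-format per-sample-per-gene status table."""
    rows = [
        (sample, st.gene, st.status, st.triggering_rule)
        for sample, statuses in per_sample.items()
        for st in statuses.values()
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "status", "triggering_rule"])
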