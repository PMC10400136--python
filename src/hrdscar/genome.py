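"""Autosomal chromosome-arm genome model.

Allele-specific copy-number segments are analysed on a per-arm coordinate
system: each chromosome contributes a p arm ``[0, p_len)`` and a q arm
``[p_len, p_len + q_len)``.  Scar features (interstitial LOH, large-scale
transitions, telomeric imbalance) are all defined relative to arm and
telomere/centromere boundaries, so the genome model is the substrate every
profile references.

Sex chromosomes are excluded: copy-number scarring on X/Y is confounded by
sex-dependent ploidy, and the scar canon is defined on autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

_MB = 1_000_000

# Approximate hg19 autosome arm lengths (Mb), centromere taken at the
# cytoband midpoint.  Acrocentric p arms (13-15, 21, 22) are short.
_ARM_TABLE_MB: tuple[tuple[str, float, float], ...] = (
    ("chr1", 125.0, 124.3),
    ("chr2", 93.3, 149.9),
    ("chr3", 91.0, 107.0),
    ("chr4", 50.4, 140.8),
    ("chr5", 48.4, 132.5),
    ("chr6", 61.0, 110.1),
    ("chr7", 59.9, 99.2),
    ("chr8", 45.6, 100.8),
    ("chr9", 49.0, 92.2),
    ("chr10", 40.2, 95.3),
    ("chr11", 53.7, 81.3),
    ("chr12", 35.8, 98.1),
    ("chr13", 17.9, 97.3),
    ("chr14", 17.6, 89.8),
    ("chr15", 19.0, 83.5),
    ("chr16", 36.6, 53.8),
    ("chr17", 24.0, 57.2),
    ("chr18", 17.2, 60.9),
    ("chr19", 26.5, 32.6),
    ("chr20", 27.5, 35.5),
    ("chr21", 13.2, 34.9),
    ("chr22", 14.7, 36.6),
)


@dataclass(frozen=True)
class Arm:
    """One chromosome arm in chromosome coordinates (0-based half-open)."""

    chrom: str
    name: str  # "p" or "q"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def telomere(self) -> int:
        """Chromosome coordinate of the telomeric end of this arm."""
        return self.start if self.name == "p" else self.end


@dataclass(frozen=True)
class GenomeModel:
    """Ordered set of chromosomes, each split into a p and a q arm.

    Parameters
    ----------
    chromosomes
        Tuples ``(name, p_arm_length_bp, q_arm_length_bp)``.  Names must be
        unique and arm lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int, int], ...]
    _arms: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        arms: dict[str, tuple[Arm, Arm]] = {}
        for name, p_len, q_len in self.chromosomes:
            if p_len <= 0 or q_len <= 0:
                raise ValueError(f"{name}: arm lengths must be > 0")
            arms[name] = (
                Arm(name, "p", 0, int(p_len)),
                Arm(name, "q", int(p_len), int(p_len) + int(q_len)),
            )
        object.__setattr__(self, "_arms", arms)

    @property
    def interrogated_length(self) -> int:
        """Total callable bp: the sum of all arm lengths."""
        return sum(p + q for _, p, q in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        p, q = self._arms[chrom]
        return q.end

    def arms(self) -> Iterator[Arm]:
        for pair in self._arms.values():
            yield from pair

    def arms_of(self, chrom: str) -> tuple[Arm, Arm]:
        return self._arms[chrom]

    def arm_at(self, chrom: str, pos: int) -> Arm:
        """Arm containing chromosome position ``pos``."""
        p, q = self._arms[chrom]
        if not 0 <= pos < q.end:
            raise KeyError(f"position {chrom}:{pos} outside chromosome")
        return p if pos < p.end else q

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arms


def default_genome() -> GenomeModel:
    """22-autosome genome with hg19-scale arm lengths (~2.9 Gb)."""
    return GenomeModel(
        tuple((c, int(p * _MB), int(q * _MB)) for c, p, q in _ARM_TABLE_MB)
    )


# Approximate hg19 loci for the 14-gene homologous recombination repair
# basket; used to place simulated alterations and to test gene/segment
# overlap (deep deletions, variants under LOH).
HRR_GENES: tuple[str, ...] = (
    "BRCA1",
    "BRCA2",
    "ATM",
    "BARD1",
    "BRIP1",
    "CDK12",
    "CHEK1",
    "CHEK2",
    "FANCL",
    "PALB2",
    "RAD51B",
    "RAD51C",
    "RAD51D",
    "RAD54L",
)

GENE_LOCI: dict[str, tuple[str, int]] = {
    "RAD54L": ("chr1", 46_714_000),
    "FANCL": ("chr2", 58_386_000),
    "BARD1": ("chr2", 215_590_000),
    "ATM": ("chr11", 108_093_000),
    "CHEK1": ("chr11", 125_495_000),
    "BRCA2": ("chr13", 32_889_000),
    "RAD51B": ("chr14", 68_286_000),
    "PALB2": ("chr16", 23_614_000),
    "RAD51D": ("chr17", 33_426_000),
    "CDK12": ("chr17", 37_618_000),
    "BRCA1": ("chr17", 41_197_000),
    "RAD51C": ("chr17", 56_769_000),
    "BRIP1": ("chr17", 59_760_000),
    "CHEK2": ("chr22", 29_083_000),
}

#: Genes whose alteration status defines the guideline biomarker arm.
BRCA_PALB2: tuple[str, ...] = ("BRCA1", "BRCA2", "PALB2")
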