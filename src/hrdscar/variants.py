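"""Gene-level short-variant calls with indel geometry and zygosity flags."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VARIANT_CLASSES = ("SNV", "indel", "rearrangement", "deep_deletion")

#: Classes that count as "short variants" for zygosity purposes.
SHORT_VARIANT_CLASSES = ("SNV", "indel")

VARIANT_COLUMNS = [
    "sample",
    "gene",
    "var_class",
    "pathogenic",
    "del_length",
    "microhomology_len",
    "het_flag",
    "chrom",
    "pos",
]


@dataclass(frozen=True)
class ShortVariant:
    """One variant call.

    ``het_flag`` is the computational heterozygosity call for short variants:
    True = called heterozygous, False = called non-heterozygous, None = the
    zygosity call could not be determined.  ``del_length`` and
    ``microhomology_len`` are present only for deletion indels.
    """

    sample_id: str
    gene: str
    var_class: str
    pathogenic: bool
    del_length: int | None = None
    microhomology_len: int | None = None
    het_flag: bool | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.del_length is not None and self.var_class != "indel":
            raise ValueError("del_length only meaningful for indels")

    @property
    def is_short_variant(self) -> bool:
        return self.var_class in SHORT_VARIANT_CLASSES

    @property
    def is_deletion(self) -> bool:
        return self.var_class == "indel" and self.del_length is not None and self.del_length > 0

    @property
    def is_mh_deletion(self) -> bool:
        """Deletion of >=5 bp flanked by >=1 bp of microhomology."""
        return (
            self.is_deletion
            and self.del_length >= 5
            and (self.microhomology_len or 0) >= 1
        )


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def _opt_bool(v):
    return None if pd.isna(v) else bool(int(v))


def variants_to_frame(variants: list[ShortVariant]) -> pd.DataFrame:
    rows = [
        (
            v.sample_id,
            v.gene,
            v.var_class,
            int(v.pathogenic),
            v.del_length,
            v.microhomology_len,
            None if v.het_flag is None else int(v.het_flag),
            v.chrom,
            v.pos,
        )
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants(variants: list[ShortVariant], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[ShortVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    out = []
    for r in df.itertuples():
        out.append(
            ShortVariant(
                sample_id=str(r.sample),
                gene=str(r.gene),
                var_class=str(r.var_class),
                pathogenic=bool(int(r.pathogenic)),
                del_length=_opt_int(r.del_length),
                microhomology_len=_opt_int(r.microhomology_len),
                het_flag=_opt_bool(r.het_flag),
                chrom=None if pd.isna(r.chrom) else str(r.chrom),
                pos=_opt_int(r.pos),
            )
        )
    return out
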