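"""Single-base substitution spectra and the FFPE deamination signature.

Formalin fixation deaminates cytosine, which surfaces in variant calls as
excess C>T (and, read on the other strand, G>A) substitutions.  The
combined C.G>T.A rate — (C>T + G>A) counts over all counted SNV alt
alleles — is the standard scalar summary of that artifact load, and the
FFPE-minus-FF difference of that rate estimates the artifact excess.

Substitutions are counted as written on the VCF reference strand;
multi-allelic SNVs contribute one count per alt allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .variant_io import SNV, VariantSet

log = logging.getLogger(__name__)

BASES = "ACGT"
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

#: strand-collapsed 6-class representation (pyrimidine reference)
COLLAPSED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans(BASES, "TGCA")


def collapse_substitution(sub: str) -> str:
    """Map one of the 12 types onto the 6 pyrimidine-reference classes."""
    ref, alt = sub.split(">")
    if ref in "AG":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SubstitutionSpectrum:
    sample_id: str
    counts: dict[str, int]  # all 12 ordered ref>alt types
    n_snv: int              # counted alt alleles

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_snv:
            raise ValueError("spectrum counts must sum to n_snv")

    @property
    def cgta_rate(self) -> float:
        """Pooled C>T + G>A fraction of all counted SNV alt alleles."""
        if self.n_snv == 0:
            raise ValueError("C.G>T.A rate undefined on an empty spectrum")
        return (self.counts["C>T"] + self.counts["G>A"]) / self.n_snv

    def collapsed(self) -> dict[str, int]:
        out = dict.fromkeys(COLLAPSED_CLASSES, 0)
        for sub, n in self.counts.items():
            out[collapse_substitution(sub)] += n
        return out


def substitution_spectrum(vs: VariantSet) -> SubstitutionSpectrum:
    """Count the 12 ref>alt substitution types over a call set's SNVs.

    INDEL records are ignored (their count is logged); each alt allele of a
    multi-allelic SNV contributes one count.
    """
    counts = dict.fromkeys(SUBSTITUTION_TYPES, 0)
    n_indel = 0
    for rec in vs:
        if rec.vclass != SNV:
            n_indel += 1
            continue
        for alt in rec.alts:
            counts[f"{rec.ref}>{alt}"] += 1
    if n_indel:
        log.info("spectrum for %s: ignored %d INDEL records", vs.meta.sample_id, n_indel)
    return SubstitutionSpectrum(
        sample_id=vs.meta.sample_id, counts=counts, n_snv=sum(counts.values())
    )


def spectrum_delta(ff: SubstitutionSpectrum, ffpe: SubstitutionSpectrum) -> float:
    """Signed FFPE-minus-FF difference of the C.G>T.A rate."""
    return ffpe.cgta_rate - ff.cgta_rate


def spectrum_table(spectra: list[SubstitutionSpectrum]) -> pd.DataFrame:
    rows = []
    for sp in spectra:
        row: dict = {"sample_id": sp.sample_id}
        row.update(sp.counts)
        row["n_snv"] = sp.n_snv
        row["cgta_rate"] = sp.cgta_rate if sp.n_snv else float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *SUBSTITUTION_TYPES, "n_snv", "cgta_rate"])
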