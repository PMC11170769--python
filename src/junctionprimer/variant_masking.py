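"""Common-variant masking: keep primers off polymorphic positions.

Positions where a short variant reaches the allele-frequency threshold
(default 1%) in the supplied VCF are projected into each transcript's cDNA
and replaced by ``N``.  Primer enumeration rejects any window containing
``N``, which makes masking a hard exclusion: a common variant under a primer
can destabilise annealing in a sample carrying the alternate allele and skew
quantification.  Indels mask their full REF footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from cyvcf2 import VCF

from .transcript_model import TranscriptModel

__all__ = ["VariantMask", "load_common_variants", "apply_mask"]


@dataclass
class VariantMask:
    """Genomic positions (0-based, per chromosome) with max AF >= threshold."""

    masked: dict[str, set[int]] = field(default_factory=dict)
    threshold: float = 0.01
    skipped_no_frequency: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")

    def positions(self, chrom: str) -> set[int]:
        return self.masked.get(chrom, set())

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.masked.values())


def _max_frequency(variant, af_key: str) -> float | None:
    value = variant.INFO.get(af_key)
    if value is None:
        return None
    if not isinstance(value, (tuple, list)):
        value = (value,)
    # INFO floats come back as float32; recover the printed decimal (6
    # significant digits) so threshold-equal records are not lost to rounding
    return max(float(f"{float(v):.6g}") for v in value)


def load_common_variants(
    vcf_path: str | Path, threshold: float = 0.01, af_key: str = "AF"
) -> VariantMask:
    """Collect the REF footprints of all variants at or above the threshold.

    Multi-allelic records use their maximum alternate frequency.  Records
    lacking the frequency INFO field are skipped and counted in
    ``skipped_no_frequency``.
    """
    mask = VariantMask(threshold=threshold)
    for variant in VCF(str(vcf_path)):
        freq = _max_frequency(variant, af_key)
        if freq is None:
            mask.skipped_no_frequency += 1
            continue
        if freq < threshold:
            continue
        start = variant.start  # 0-based
        footprint = range(start, start + max(len(variant.REF), 1))
        mask.masked.setdefault(variant.CHROM, set()).update(footprint)
    return mask


def apply_mask(transcript: TranscriptModel, mask: VariantMask | None) -> str:
    """Return the transcript cDNA with masked genomic positions as ``N``.

    Only exonic masked positions project into the cDNA; intronic variants
    leave it untouched.  Length is preserved.  ``mask=None`` (masking
    disabled) returns the cDNA unchanged.
    """
    if mask is None or not transcript.exons:
        return transcript.cdna
    chrom = transcript.exons[0].chrom
    positions = mask.positions(chrom)
    if not positions:
        return transcript.cdna
    cdna = list(transcript.cdna)
    for cdna_index, genome_pos in enumerate(transcript.genomic_positions()):
        if genome_pos in positions:
            cdna[cdna_index] = "N"
    return "".join(cdna)
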