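"""Genome-size estimation from insert-size modes and coverage arithmetic.

The estimator rests on a simple observation: when a clone library of one
species is mapped onto the genome of a smaller-genomed relative, the
apparent (reference-projected) insert sizes shrink by the ratio of
orthologous locus sizes. If indels accumulate roughly uniformly in the
intergenic space, the ratio of the modes of the two insert-size
distributions — the library's own versus the mapped one — estimates the
genome-size ratio, and multiplying by the reference genome size yields the
target genome size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Mode-ratio genome-size estimate (all sizes in bp)."""

    mapped_mode: float
    library_mode: float
    reference_size: float

    @property
    def ratio(self) -> float:
        """Genome-size ratio target/reference = library mode / mapped mode."""
        return self.library_mode / self.mapped_mode

    @property
    def estimated_size(self) -> float:
        return self.ratio * self.reference_size


def estimate_genome_size(mapped_mode: float, library_mode: float,
                         reference_size: float) -> GenomeSizeEstimate:
    """Estimate the target genome size from the two insert-size modes.

    No rounding is applied here; the reporting layer rounds.
    """
    if mapped_mode <= 0 or library_mode <= 0:
        raise InputError("insert-size modes must be positive")
    if reference_size <= 0:
        raise InputError("reference size must be positive")
    return GenomeSizeEstimate(float(mapped_mode), float(library_mode),
                              float(reference_size))


def physical_coverage(clone_count: int, mean_insert: float,
                      genome_size_assumed: float) -> float:
    """Expected clone coverage of a random position:
    clone_count x mean_insert / genome size."""
    if genome_size_assumed <= 0:
        raise InputError("genome size must be positive")
    if clone_count < 0 or mean_insert < 0:
        raise InputError("clone count and insert size must be non-negative")
    return clone_count * mean_insert / genome_size_assumed


def round_fold(x: float) -> float:
    """Fold coverage at the conventional one-decimal reporting precision."""
    return round(x, 1)


def round_genome_size(bp: float) -> int:
    """Genome size reported to the nearest 10 Mbp."""
    return int(round(bp / 1e7) * 1e7)
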