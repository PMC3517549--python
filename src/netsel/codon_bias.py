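"""Codon-usage bias descriptors: Wright's effective number of codons (ENC)
and the fraction of sense codons a gene uses.

ENC measures how far codon usage departs from uniform use of synonymous
codons: 61 means every synonymous codon is used equally, 20 means one
codon per amino acid.  Per synonymous family with total count n and
codon proportions p_i, the homozygosity estimate is
F = (n * sum(p_i^2) - 1) / (n - 1), and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where Fk is the mean F over families of synonymous size k (9 two-fold,
1 three-fold, 5 four-fold and 3 six-fold families in the standard code;
Met and Trp contribute the leading 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._genetic_code import AA_FAMILIES, CODON_INDEX, SENSE_CODONS, STOP_CODONS

ENC_UNDEFINED = float("nan")

#: family sizes and their weights in Wright's formula
_FAMILY_WEIGHTS = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


@dataclass
class CodonUsageProfile:
    """Counts of the 61 sense codons plus a tally of excluded codons."""

    counts: dict[str, int]
    excluded: int = 0

    def __post_init__(self) -> None:
        unknown = sorted(set(self.counts) - set(SENSE_CODONS))
        if unknown:
            raise ValueError(f"not sense codons: {unknown}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("codon counts must be nonnegative")
        full = dict.fromkeys(SENSE_CODONS, 0)
        full.update(self.counts)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def codon_counts(sequence: str) -> CodonUsageProfile:
    """Tally sense codons of an in-frame coding sequence.

    Stop codons and codons containing gaps or ambiguity are excluded
    and counted in :attr:`CodonUsageProfile.excluded`.
    """
    sequence = sequence.upper()
    if len(sequence) % 3 != 0:
        raise ValueError(f"sequence length {len(sequence)} is not divisible by 3")
    counts: dict[str, int] = {}
    excluded = 0
    for i in range(0, len(sequence), 3):
        codon = sequence[i : i + 3]
        if codon in CODON_INDEX:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            excluded += 1
    return CodonUsageProfile(counts=counts, excluded=excluded)


def _family_homozygosity(counts: np.ndarray) -> float | None:
    """F-hat for one synonymous family; None when undefined (n < 2 or F <= 0)."""
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    f = (n * (p**2).sum() - 1.0) / (n - 1.0)
    return float(f) if f > 0 else None


def effective_number_of_codons(profile: CodonUsageProfile) -> float:
    """Wright's ENC, clipped to [20, 61].

    Families with no observations (or with a single codon count, where
    F is undefined) borrow the mean F of observed families of the same
    synonymous size; an entirely unobserved three-fold class borrows
    the mean of the two- and four-fold classes; any other empty size
    class falls back to the neutral value 1/k.  Returns NaN when no
    family is observed at all.
    """
    by_size: dict[int, list[float]] = {k: [] for k in _FAMILY_WEIGHTS}
    for aa, codon_ids in AA_FAMILIES.items():
        size = len(codon_ids)
        if size not in _FAMILY_WEIGHTS:
            continue  # Met, Trp: the constant 2 in the formula
        counts = np.array([profile.counts[SENSE_CODONS[i]] for i in codon_ids], float)
        f = _family_homozygosity(counts)
        if f is not None:
            by_size[size].append(f)
    if not any(by_size.values()):
        return ENC_UNDEFINED

    mean_f: dict[int, float | None] = {
        k: (float(np.mean(v)) if v else None) for k, v in by_size.items()
    }
    if mean_f[3] is None and mean_f[2] is not None and mean_f[4] is not None:
        mean_f[3] = 0.5 * (mean_f[2] + mean_f[4])
    for k in _FAMILY_WEIGHTS:
        if mean_f[k] is None:
            mean_f[k] = 1.0 / k

    enc = 2.0 + sum(w / mean_f[k] for k, w in _FAMILY_WEIGHTS.items())
    return float(np.clip(enc, 20.0, 61.0))


def percent_codons_used(profile: CodonUsageProfile, min_count: int = 1) -> float:
    """Percentage of the 61 sense codons observed at least ``min_count`` times.

    The default counts any observed codon; raising ``min_count`` gives
    stricter variants of the statistic.
    """
    used = sum(1 for v in profile.counts.values() if v >= min_count)
    return 100.0 * used / len(SENSE_CODONS)


def median_enc(per_species_enc: list[float]) -> float:
    """Median ENC across species (the per-gene codon-bias summary)."""
    if len(per_species_enc) == 0:
        raise ValueError("median_enc needs at least one value")
    return float(np.median(per_species_enc))
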