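"""In-frame codon alignments.

A :class:`CodonAlignment` holds aligned coding sequences, one per taxon,
whose length is a multiple of three.  Codons containing gaps or IUPAC
ambiguity codes are treated as missing data; in-frame stop codons are
rejected by default (they usually indicate a frame error) but can be
masked column-wise instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._genetic_code import CODON_INDEX, STOP_CODONS


class AlignmentError(ValueError):
    """Raised for malformed codon alignments."""


MISSING = -1  #: sentinel state for gap/ambiguous codons


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over the 61 sense codons.

    Parameters
    ----------
    taxa
        Unique sequence labels.
    sequences
        Nucleotide strings (A/C/G/T plus gaps ``-`` and IUPAC ambiguity),
        one per taxon, all of equal length divisible by three.
    genetic_code
        Code table identifier; only ``"standard"`` is supported.
    """

    taxa: list[str]
    sequences: list[str]
    genetic_code: str = "standard"
    masked_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genetic_code != "standard":
            raise AlignmentError(f"unsupported genetic code: {self.genetic_code!r}")
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                "sequences have unequal lengths: "
                + ", ".join(f"{t}={len(s)}" for t, s in zip(self.taxa, self.sequences))
            )
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} is not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_matrix(self, mask_stops: bool = False) -> np.ndarray:
        """Encode as an integer matrix of shape (n_taxa, n_codons).

        Entries are indices into the 61 sense codons, or :data:`MISSING`
        for codons containing gaps or ambiguity.  In-frame stop codons
        raise :class:`AlignmentError` naming the offender unless
        ``mask_stops`` is set, in which case the whole column is flagged
        (recorded in :attr:`masked_columns`) and set to missing.
        """
        n = self.n_codons
        mat = np.full((self.n_taxa, n), MISSING, dtype=np.int64)
        stop_columns: set[int] = set()
        for row, (taxon, seq) in enumerate(zip(self.taxa, self.sequences)):
            for col in range(n):
                codon = seq[3 * col : 3 * col + 3]
                idx = CODON_INDEX.get(codon)
                if idx is not None:
                    mat[row, col] = idx
                elif codon in STOP_CODONS:
                    if not mask_stops:
                        raise AlignmentError(
                            f"in-frame stop codon {codon} in {taxon!r} at codon {col + 1}"
                        )
                    stop_columns.add(col)
                # anything else (gap or ambiguity) stays MISSING
        for col in stop_columns:
            mat[:, col] = MISSING
        self.masked_columns = sorted(stop_columns)
        return mat

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        """Alignment restricted to ``taxa`` (order preserved)."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        index = {t: i for i, t in enumerate(self.taxa)}
        return CodonAlignment(
            taxa=list(taxa),
            sequences=[self.sequences[index[t]] for t in taxa],
            genetic_code=self.genetic_code,
        )
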