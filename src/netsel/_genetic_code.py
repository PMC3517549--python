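"""Standard genetic code tables and precomputed codon-pair metadata.

The 61 sense codons of the standard code are indexed lexicographically
(A < C < G < T).  All arrays here are module-level constants computed once
at import; the GY94 rate-matrix construction and the ENC statistic both
draw on them.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"

#: codon -> amino acid (one letter), '*' for stop, standard code
CODON_TABLE: dict[str, str] = {}
_BASES = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
CODON_TABLE.update(_BASES)

STOP_CODONS: frozenset[str] = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

#: the 61 sense codons in lexicographic order — the state space of the model
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid of each sense codon, aligned with SENSE_CODONS
CODON_AA: tuple[str, ...] = tuple(CODON_TABLE[c] for c in SENSE_CODONS)

#: amino acid -> list of codon indices (synonymous family)
AA_FAMILIES: dict[str, list[int]] = {}
for _i, _aa in enumerate(CODON_AA):
    AA_FAMILIES.setdefault(_aa, []).append(_i)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_metadata() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nucleotide change, transition, nonsynonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single, transition, nonsyn


SINGLE_CHANGE, IS_TRANSITION, IS_NONSYNONYMOUS = _pair_metadata()
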