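"""Readers and writers for the formats the package touches.

FASTA codon alignments (via Biopython), newick trees (via dendropy),
tab-separated feature tables and similarity-hit tables, YAML causal
models, and the packaged reference gene table.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentError, CodonAlignment
from .fitting import ModelFit
from .network_stats import CausalPathModel
from .orthology import HitRecord, OrthologyCall
from .tree import PhylogeneticTree

FEATURE_COLUMNS = [
    "position",
    "protein_length",
    "connectivity",
    "enc",
    "percent_used_codons",
    "dn",
    "ds",
    "omega",
]


def read_codon_fasta(path: str | Path) -> CodonAlignment:
    """Read an aligned in-frame codon FASTA.

    Validates record ids for uniqueness, equal sequence lengths and a
    length divisible by three, naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    first_len = len(seqs[0])
    for taxon, seq in zip(taxa, seqs):
        if len(seq) != first_len:
            raise AlignmentError(
                f"record {taxon!r} has length {len(seq)}, expected {first_len}"
            )
        if len(seq) % 3 != 0:
            raise AlignmentError(
                f"record {taxon!r} has length {len(seq)}, not divisible by 3"
            )
    return CodonAlignment(taxa=taxa, sequences=seqs)


def write_codon_fasta(alignment: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path, default_length: float | None = None) -> PhylogeneticTree:
    """Read a newick tree file (first tree if several)."""
    return PhylogeneticTree.from_newick(
        Path(path).read_text(), default_length=default_length
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a gene feature table (TSV, gene symbols in the first column)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "gene"
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def validate_feature_table(table: pd.DataFrame) -> list[str]:
    """Consistency problems of a feature table (empty list when clean).

    Checks for duplicate genes, positions outside 1..8, and omega
    departing from dn/ds by more than printed-rounding tolerance.
    """
    problems = []
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        problems.append(f"duplicate genes: {dupes}")
    if "position" in table and not table["position"].between(1, 8).all():
        problems.append("positions outside 1..8")
    if {"dn", "ds", "omega"} <= set(table.columns):
        ok = table["ds"] > 0
        ratio = table.loc[ok, "dn"] / table.loc[ok, "ds"]
        off = (ratio - table.loc[ok, "omega"]).abs() > 0.02
        if off.any():
            problems.append(
                f"omega != dn/ds beyond 0.02 for: {sorted(table.index[ok][off])}"
            )
    return problems


def load_fixture_table() -> pd.DataFrame:
    """The packaged reference table of the 50 TLR signaling pathway genes.

    One row per orthologous group (eight vertebrates), transcribed at
    printed precision: pathway position (1-8), protein length,
    PPI connectivity, median ENC, percent of used codons, and the
    tree-total M0 estimates dn, ds and omega.  Note one internal
    inconsistency of the published source: the table prints
    omega = 0.29 for TLR4 while the accompanying text gives the range
    maximum as 0.25817; the table value is stored here.
    """
    ref = importlib.resources.files("netsel.data") / "tlr_pathway_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_feature_table(path)


# -- hit tables ----------------------------------------------------------

_BLAST12 = [
    "query", "subject", "percent_identity", "alignment_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "score",
]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tabular similarity-hit file.

    The first 12 columns follow the standard tabular search-output
    convention (query, subject, %identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, e-value, bit score);
    optional columns 13 and 14 add percent similarity and query
    coverage.  Without a similarity column, similarity is set equal to
    identity; without a coverage column, coverage defaults to 0.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 tab-separated columns")
    names = _BLAST12 + ["percent_similarity", "coverage"][: raw.shape[1] - 12]
    raw.columns = names[: raw.shape[1]]
    hits = []
    for _, row in raw.iterrows():
        identity = float(row["percent_identity"])
        similarity = float(row.get("percent_similarity", identity))
        hits.append(
            HitRecord(
                query=str(row["query"]),
                subject=str(row["subject"]),
                score=float(row["score"]),
                alignment_length=int(row["alignment_length"]),
                percent_identity=identity,
                percent_similarity=max(similarity, identity),
                coverage=float(row.get("coverage", 0.0)),
            )
        )
    return hits


def write_calls(calls: list[OrthologyCall], path: str | Path) -> None:
    rows = [
        {
            "gene": c.gene,
            "target_genome": c.target_genome,
            "verdict": c.verdict,
            "rationale": c.rationale,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- analysis configuration ---------------------------------------------


@dataclass
class AnalysisConfig:
    """Validated settings for a full analysis run.

    Unknown keys and out-of-range values are rejected at load time,
    before any stage runs.
    """

    model: str = "M0"
    n_classes: int = 10
    frequency_mode: str = "f3x4"
    statistics_method: str = "pearson"
    orthology_score: float = 150.0
    orthology_length: int = 50
    orthology_identity: float = 30.0
    orthology_similarity: float = 40.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        from .codon_model import MODEL_IDS

        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.frequency_mode not in ("f3x4", "f61", "uniform"):
            raise ValueError(f"unknown frequency mode {self.frequency_mode!r}")
        if self.statistics_method not in ("pearson", "rank"):
            raise ValueError(f"unknown statistics method {self.statistics_method!r}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        for name in ("orthology_score", "orthology_identity", "orthology_similarity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return AnalysisConfig(**doc)


# -- causal models and fit reports --------------------------------------


def read_causal_model(path: str | Path) -> CausalPathModel:
    """Load a causal model from YAML.

    Expected shape::

        exogenous: [position, protein_length, connectivity]
        equations:
          enc: [position, protein_length]
          dn: [position, protein_length, enc]
          omega: [dn, position, enc, protein_length]
    """
    doc = yaml.safe_load(Path(path).read_text())
    unknown = set(doc) - {"exogenous", "equations"}
    if unknown:
        raise ValueError(f"unknown keys in causal model file: {sorted(unknown)}")
    edges = [
        (parent, dep)
        for dep, parents in doc.get("equations", {}).items()
        for parent in parents
    ]
    return CausalPathModel(exogenous=list(doc.get("exogenous", [])), edges=edges)


def fit_report(fit: ModelFit) -> dict:
    """JSON-serializable summary of a model fit."""
    out = {
        "model": fit.spec.model_id,
        "log_likelihood": fit.log_likelihood,
        "kappa": fit.spec.kappa,
        "omega_params": {k: float(v) for k, v in fit.spec.omega_params.items()},
        "tree_length": fit.tree_length,
        "branch_lengths": {k: float(v) for k, v in fit.branch_lengths.items()},
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "notes": fit.notes,
    }
    for name in ("dn", "ds", "omega"):
        value = getattr(fit, name)
        if value is not None:
            out[name] = None if isinstance(value, float) and np.isnan(value) else float(value)
    if fit.branch_omegas is not None:
        out["branch_omegas"] = {k: float(v) for k, v in fit.branch_omegas.items()}
    return out


def write_fit_report(fit: ModelFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_report(fit), indent=2) + "\n")
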