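"""Core data containers shared by every pipeline stage.

Matrices are thin wrappers around :class:`pandas.DataFrame` (features x
samples) plus the patient manifest that records which tumor and normal
sample belong to each patient.  Target relations are kept as a set of
(miRNA, gene, provenance, score) tuples so merge rules stay explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientPair",
    "PairedCountMatrix",
    "ExpressionMatrix",
    "TargetRelation",
    "TargetMap",
    "read_counts_tsv",
    "read_manifest_tsv",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class PatientPair:
    """One patient's matched tumor/normal sample ids."""

    patient_id: str
    tumor_sample: str
    normal_sample: str

    def __post_init__(self) -> None:
        if self.tumor_sample == self.normal_sample:
            raise ValueError(
                f"patient {self.patient_id}: tumor and normal sample ids coincide"
            )


class PairedCountMatrix:
    """Raw count matrix (features x samples) with a tumor/normal pair manifest.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame; index = feature ids, columns = sample
        ids, both unique.
    manifest
        One :class:`PatientPair` per patient.  Every referenced sample must be
        a column of ``counts`` and no sample may appear twice.
    """

    def __init__(self, counts: pd.DataFrame, manifest: Iterable[PatientPair]):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        self.manifest = list(manifest)
        seen: set[str] = set()
        for pair in self.manifest:
            for sample in (pair.tumor_sample, pair.normal_sample):
                if sample not in counts.columns:
                    raise ValueError(
                        f"manifest sample {sample!r} (patient {pair.patient_id}) "
                        "not found in count matrix"
                    )
                if sample in seen:
                    raise ValueError(f"sample {sample!r} appears twice in manifest")
                seen.add(sample)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.manifest)

    def subset_features(self, feature_ids: Iterable[str]) -> "PairedCountMatrix":
        return PairedCountMatrix(self.counts.loc[list(feature_ids)], self.manifest)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    def manifest_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(p.patient_id, p.tumor_sample, p.normal_sample) for p in self.manifest],
            columns=["patient_id", "tumor_sample", "normal_sample"],
        ).to_csv(path, sep="\t", index=False)


class ExpressionMatrix:
    """Real-valued expression matrix (logCPM or normalized), features x samples."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate feature or sample ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.values = values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TargetRelation:
    mirna_id: str
    gene_id: str
    provenance: str  # "validated", "predicted:<source>", or "mlr"
    score: Optional[float] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


@dataclass
class TargetMap:
    """A set of miRNA->gene relations with provenance kept for audit."""

    relations: set[TargetRelation] = field(default_factory=set)

    def add(self, relation: TargetRelation) -> None:
        self.relations.add(relation)

    def keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self.relations}

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.keys()

    def __len__(self) -> int:
        return len(self.relations)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (r.mirna_id, r.gene_id, r.provenance, r.score) for r in self.relations
        )
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "provenance", "score"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetMap":
        df = pd.read_csv(path, sep="\t")
        tm = cls()
        for row in df.itertuples(index=False):
            score = getattr(row, "score", None)
            if score is not None and pd.isna(score):
                score = None
            tm.add(
                TargetRelation(
                    str(row.mirna_id), str(row.gene_id), str(row.provenance), score
                )
            )
        return tm


def read_counts_tsv(counts_path: str | Path, manifest_path: str | Path) -> PairedCountMatrix:
    """Read a counts TSV (first column feature_id) plus its pair manifest."""
    df = pd.read_csv(counts_path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    manifest = read_manifest_tsv(manifest_path)
    return PairedCountMatrix(df, manifest)


def read_manifest_tsv(path: str | Path) -> list[PatientPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        PatientPair(str(r.patient_id), str(r.tumor_sample), str(r.normal_sample))
        for r in df.itertuples(index=False)
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict; T is normalized to U."""
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("T", "U")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
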