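"""Shared domain types for the seed-compartment omics pipeline.

The experimental design has two genotypes (wild type ``WT`` and the
notched-belly mutant ``NB``), three dissected compartments (embryo ``E``,
upper endosperm ``EnU``, bottom endosperm ``EnB``) and three developmental
stages (10, 20 and 30 days after fertilization).  A *design cell* is one
(genotype, tissue, stage) combination; replicates populate each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES: tuple[str, ...] = ("WT", "NB")
TISSUES: tuple[str, ...] = ("E", "EnU", "EnB")
ENDOSPERM_TISSUES: tuple[str, ...] = ("EnU", "EnB")
DEFAULT_STAGES: tuple[int, ...] = (10, 20, 30)

#: The nine compound classes used to summarise the metabolite catalog.
COMPOUND_CLASSES: tuple[str, ...] = (
    "amino acids",
    "carbohydrates",
    "lipids",
    "CPGEC",
    "nucleotides",
    "peptides",
    "secondary metabolites",
    "phytohormones",
    "xenobiotics",
)

MATRIX_KINDS: tuple[str, ...] = ("metabolome", "transcriptome")


@dataclass(frozen=True)
class SampleRecord:
    """One sample's coordinates in the factorial design."""

    sample_id: str
    genotype: str
    tissue: str
    stage: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown genotype {self.genotype!r}"
            )
        if self.tissue not in TISSUES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r}"
            )
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )

    @property
    def cell(self) -> tuple[str, str, int]:
        """The (genotype, tissue, stage) design cell this sample fills."""
        return (self.genotype, self.tissue, self.stage)


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabulate sample records with one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "genotype": [r.genotype for r in records],
            "tissue": [r.tissue for r in records],
            "stage": [r.stage for r in records],
            "replicate": [r.replicate for r in records],
        }
    )


@dataclass
class FeatureMatrix:
    """A features x samples intensity (or FPKM) table with a detection mask.

    ``values`` holds non-negative numbers with ``NaN`` marking *not
    detected*; a missing value is missing, never an implicit zero.  The
    optional ``samples`` list pairs each column with its design coordinates
    (attached by :func:`embryoeffect.io.validate_design`).
    """

    values: pd.DataFrame
    kind: str
    samples: list[SampleRecord] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.samples is not None:
            ids = [r.sample_id for r in self.samples]
            if ids != list(self.values.columns):
                raise ValueError("sample records do not match matrix columns")
        finite = self.values.to_numpy(dtype=float)
        if np.any(np.isinf(finite)):
            raise ValueError("matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask, True where a value was observed."""
        return self.values.notna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_table(self) -> pd.DataFrame:
        if self.samples is None:
            raise ValueError("no sample metadata attached; run validate_design")
        return records_to_frame(self.samples)

    def cell_columns(self, genotype: str, tissue: str, stage: int) -> list[str]:
        """Sample ids belonging to one design cell."""
        if self.samples is None:
            raise ValueError("no sample metadata attached; run validate_design")
        return [
            r.sample_id
            for r in self.samples
            if r.cell == (genotype, tissue, stage)
        ]

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(feature_ids)
        return FeatureMatrix(self.values.loc[ids].copy(), self.kind, self.samples)

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(sample_ids)
        sub = self.values[ids].copy()
        recs = None
        if self.samples is not None:
            by_id = {r.sample_id: r for r in self.samples}
            recs = [by_id[i] for i in ids]
        return FeatureMatrix(sub, self.kind, recs)


@dataclass(frozen=True)
class CatalogEntry:
    """Catalog row: compound class and the compartments a feature occurs in."""

    feature_id: str
    compound_class: str
    tissue_presence: frozenset[str]

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"{self.feature_id}: unknown compound class "
                f"{self.compound_class!r}"
            )
        if not self.tissue_presence:
            raise ValueError(f"{self.feature_id}: empty tissue presence")
        if not self.tissue_presence <= {"embryo", "endosperm"}:
            raise ValueError(
                f"{self.feature_id}: tissue presence must be a subset of "
                "{'embryo', 'endosperm'}"
            )


def catalog_to_frame(catalog: Sequence[CatalogEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in catalog],
            "compound_class": [c.compound_class for c in catalog],
            "in_embryo": ["embryo" in c.tissue_presence for c in catalog],
            "in_endosperm": ["endosperm" in c.tissue_presence for c in catalog],
        }
    )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id}: no members")


@dataclass
class PathwaySets:
    """Named feature sets (GMT semantics); member lists are deduplicated."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, Sequence[str]]]):
        paths = {}
        for pid, (name, members) in mapping.items():
            uniq = tuple(dict.fromkeys(members))
            paths[pid] = Pathway(pid, name, uniq)
        return cls(paths)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def __iter__(self):
        return iter(self.pathways.values())
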