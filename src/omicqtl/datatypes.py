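"""Core in-memory containers shared across the pipeline.

Tabular data lives in pandas DataFrames with documented column contracts;
single records (QTL signals, colocalizations, prioritized variants) are
dataclasses so the stage interfaces stay explicit.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: phenotype vocabulary used throughout (expression = RNA, accessibility =
#: ATAC, acetylation = H3K27ac ChIP)
PHENOTYPE_TYPES = ("expression", "accessibility", "acetylation")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with variant and sample metadata.

    ``dosages`` holds hard genotype calls in {0, 1, 2} (row = sample,
    column = variant); -1 marks a missing call. ``variants`` has columns
    ``id, chrom, pos, ref, alt, af`` with 1-based, strictly increasing
    positions per chromosome. ``samples`` has ``id, family, role`` where
    role is ``founder`` or ``offspring``. A panel doubles as the mapping
    cohort and as an LD reference panel.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant (missing calls excluded)."""
        d = np.ma.masked_equal(self.dosages, -1)
        return np.asarray(d.mean(axis=0) / 2.0)

    def variant_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.variants["id"])
        return np.asarray(idx.get_indexer(list(variant_ids)))

    def genotypes(self, variant_id: str) -> np.ndarray:
        (i,) = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        return self.dosages[:, i].astype(float)

    def validate(self) -> None:
        """Check the panel invariants; raise ValueError on violation."""
        d = self.dosages
        if not np.isin(d[d >= 0], (0, 1, 2)).all():
            raise ValueError("dosages must be in {0,1,2} (or -1 for missing)")
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing per chromosome")
        af = self.allele_frequencies()
        if not ((af > 0) & (af < 1)).all():
            raise ValueError("allele frequencies must be in (0, 1)")
        if not np.allclose(af, self.variants["af"].to_numpy(), atol=1e-12):
            raise ValueError("variants.af must equal column mean / 2")

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        samples = self.samples.loc[np.asarray(mask)].reset_index(drop=True)
        dos = self.dosages[np.asarray(mask)]
        variants = self.variants.copy()
        d = np.ma.masked_equal(dos, -1)
        variants["af"] = np.asarray(d.mean(axis=0) / 2.0)
        return GenotypePanel(dos, variants, samples)


@dataclass
class PhenotypeSet:
    """Raw molecular phenotype counts plus element coordinates.

    ``counts`` is elements x samples (non-negative ints). ``elements`` has
    columns ``id, phenotype_type, tissue, chrom, start, end, strand, tss``;
    ``tss`` is defined only for expression elements (NaN otherwise).
    ``library_sizes`` is one positive number per sample.
    """

    counts: np.ndarray
    elements: pd.DataFrame
    sample_ids: list[str]
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.elements), len(self.sample_ids)):
            raise ValueError("counts must be elements x samples")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    def validate(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        is_expr = (self.elements["phenotype_type"] == "expression").to_numpy()
        tss = self.elements["tss"].to_numpy(dtype=float)
        if np.isnan(tss[is_expr]).any():
            raise ValueError("expression elements must carry a TSS")
        if is_expr.size and not np.isnan(tss[~is_expr]).all():
            raise ValueError("TSS defined iff phenotype type is expression")


@dataclass
class GwasSummary:
    """Per-variant GWAS summary statistics for one trait.

    ``table`` columns: ``variant, beta, se, p, n``.
    """

    table: pd.DataFrame
    trait: str

    def validate(self, tol: float = 1e-6) -> None:
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        from scipy import stats

        z = t["beta"] / t["se"]
        p = 2 * stats.norm.sf(np.abs(z))
        if not np.allclose(p, t["p"], atol=tol, rtol=1e-4):
            raise ValueError("p-values inconsistent with Wald statistic")


@dataclass
class GroundTruth:
    """Registry of planted structure for recovery tests.

    JSON-serializable; schema_version guards downstream readers.
    """

    causal_effects: list[dict] = field(default_factory=list)
    shared_groups: dict[str, list[str]] = field(default_factory=dict)
    temporal_classes: dict[str, str] = field(default_factory=dict)
    gwas_causal: list[dict] = field(default_factory=list)
    mopcv_fixtures: list[dict] = field(default_factory=list)
    schema_version: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


RANKS = ("primary", "conditional1", "conditional2", "conditional3")


@dataclass
class QtlRecord:
    """One association signal for one element."""

    element: str
    tissue: str
    phenotype_type: str
    rank: str
    lead_variant: str
    chrom: str
    pos: int
    beta: float
    se: float
    p: float
    corrected_p: float
    q: float = np.nan
    regressed: bool = False
    status: str = "kept"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


def records_to_frame(records: Sequence[QtlRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclass
class ComplexQtlModule:
    """A community of same-tissue QTLs sharing one genetic signal."""

    module_id: str
    tissue: str
    members: list[QtlRecord]
    category: str = ""
    representative: QtlRecord | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ColocalizationResult:
    """Five-hypothesis posterior for one QTL x GWAS trait pair."""

    qtl_id: str
    gwas_trait: str
    n_variants: int
    pp: np.ndarray  # PP.H0..PP.H4
    variant_ids: list[str]
    per_variant_h4: np.ndarray
    lead_variant: str
    lead_gwas_p: float
    lead_qtl_p: float
    lead_pp: float

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


@dataclass
class CredibleSet:
    """99% credible set: descending-probability variants to >= mass."""

    variant_ids: list[str]
    probabilities: np.ndarray
    mass: float
    high_confidence: bool

    @property
    def size(self) -> int:
        return len(self.variant_ids)


@dataclass
class MopcvRecord:
    """A credible-set variant overlapping >= 1 TF motif, with priority."""

    variant: str
    locus: str
    colocalizations: list[str]
    motif_hits: list[dict]
    priority: str = ""
    is_top: bool = False
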