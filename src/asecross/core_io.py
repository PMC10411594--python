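"""Data model and I/O for allele-specific count analysis of reciprocal crosses.

The experimental unit is a reciprocal pair of hybrid crosses between two
inbred parental lines A and B (direction ``AxB`` means an A mother crossed to
a B father).  Each hybrid sample contributes two observations per gene, one
per parental allele, so a fully observed sex x tissue x cross scope has
2 directions x 2 replicates x 2 alleles = 8 observations.

Tables are tab-separated UTF-8 text with a header row and no quoting; counts
may be fractional (they are estimates from an upstream allele-specific
quantifier) and are only rounded where an exact test requires integers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

DIRECTIONS = ("AxB", "BxA")
SEXES = ("F", "M")
TISSUES = ("head", "gonad")
ALLELES = ("A", "B")

META_COLUMNS = ["cross_id", "direction", "sex", "tissue", "replicate", "library_size"]


class DesignError(ValueError):
    """Raised when a model scope cannot support the requested design."""


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one hybrid RNA-seq sample."""

    sample_id: str
    cross_id: str
    direction: str  # AxB | BxA, mother listed first
    sex: str  # F | M
    tissue: str  # head | gonad
    replicate: int
    library_size: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class Scope:
    """Subset selector over the experimental design.

    ``None`` fields are unconstrained; the base cis/PO/MG model uses one
    sex x tissue x cross (both reciprocal directions, all replicates).
    """

    sex: str | None = None
    tissue: str | None = None
    cross_id: str | None = None
    direction: str | None = None

    def label(self) -> str:
        parts = [p for p in (self.cross_id, self.sex, self.tissue, self.direction) if p]
        return "_".join(parts) if parts else "all"

    def mask(self, meta: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=meta.index)
        for col, val in (
            ("sex", self.sex),
            ("tissue", self.tissue),
            ("cross_id", self.cross_id),
            ("direction", self.direction),
        ):
            if val is not None:
                m &= meta[col] == val
        return m


def parent_of_origin(direction: str, allele: str) -> str:
    """Parental origin of an allele given the cross direction.

    The mother is listed first in the direction label, so allele A is
    maternal exactly when the direction is AxB.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if allele not in ALLELES:
        raise ValueError(f"unknown allele {allele!r}")
    maternal_allele = "A" if direction == "AxB" else "B"
    return "maternal" if allele == maternal_allele else "paternal"


def obs_column(sample_id: str, allele: str) -> str:
    return f"{sample_id}.{allele}"


def split_obs_column(col: str) -> tuple[str, str]:
    sample_id, _, allele = col.rpartition(".")
    if allele not in ALLELES or not sample_id:
        raise ValueError(f"count column {col!r} is not of the form <sample_id>.<A|B>")
    return sample_id, allele


@dataclass
class AseCountTable:
    """Allele-resolved count matrix with per-sample design metadata.

    ``counts`` is genes x observation columns named ``<sample_id>.<allele>``;
    ``meta`` is indexed by sample_id with columns cross_id, direction, sex,
    tissue, replicate, library_size; ``gene_flags`` carries the upstream
    eligibility flags (autosomal location, >=3 exonic SNVs between the
    parental lines) as booleans.  Analyses use autosomal genes only.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.gene_flags is None:
            self.gene_flags = pd.DataFrame(
                {"is_autosomal": True, "has_min_snvs": True}, index=self.counts.index
            )
        self.counts.index.name = "gene_id"
        self.gene_flags.index.name = "gene_id"
        self.meta.index.name = "sample_id"
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.columns[(self.counts < 0).any(axis=0)].tolist()
            raise ValueError(f"negative counts in columns {bad}")
        missing = sorted(
            {split_obs_column(c)[0] for c in self.counts.columns} - set(self.meta.index)
        )
        if missing:
            raise ValueError(f"count columns without sample metadata: {missing}")
        if self.meta.index.duplicated().any():
            dups = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample_id in metadata: {dups}")
        if not self.counts.index.is_unique:
            raise ValueError("duplicated gene_id in counts")
        self._recompute_library_sizes()

    def _recompute_library_sizes(self) -> None:
        """library_size = per-sample count sum over retained (autosomal) genes."""
        auto = self.autosomal_genes()
        sizes = {}
        for sid in self.meta.index:
            cols = [
                obs_column(sid, a) for a in ALLELES if obs_column(sid, a) in self.counts.columns
            ]
            sizes[sid] = float(self.counts.loc[auto, cols].to_numpy().sum()) if cols else 0.0
        self.meta["library_size"] = pd.Series(sizes)

    # -- accessors --------------------------------------------------------

    def autosomal_genes(self) -> pd.Index:
        return self.counts.index[self.gene_flags["is_autosomal"].reindex(self.counts.index, fill_value=True)]

    def samples_in(self, scope: Scope) -> list[str]:
        return self.meta.index[scope.mask(self.meta)].tolist()

    def obs_columns(self, samples: Iterable[str] | None = None) -> list[str]:
        ids = list(samples) if samples is not None else list(self.meta.index)
        return [
            obs_column(s, a)
            for s in ids
            for a in ALLELES
            if obs_column(s, a) in self.counts.columns
        ]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        row = self.meta.loc[sample_id]
        return SampleMeta(
            sample_id=sample_id,
            cross_id=row["cross_id"],
            direction=row["direction"],
            sex=row["sex"],
            tissue=row["tissue"],
            replicate=int(row["replicate"]),
            library_size=float(row["library_size"]),
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, counts_path: str | Path, meta_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")
        flags = self.gene_flags.copy()
        flags.index.name = "gene_id"
        flags.to_csv(str(counts_path) + ".flags", sep="\t")


def read_ase_counts(
    counts_path: str | Path, meta_path: str | Path, flags_path: str | Path | None = None
) -> AseCountTable:
    """Read an allele-specific count TSV plus its sample-metadata TSV.

    The counts file has a ``gene_id`` index column and one column per
    (sample, allele) observation named ``<sample_id>.<A|B>``.  Library sizes
    are recomputed from the retained genes; parent-of-origin is implied by
    direction and allele and never stored.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    missing_meta = [c for c in META_COLUMNS if c not in meta.columns and c != "library_size"]
    if missing_meta:
        raise ValueError(f"metadata file lacks required columns: {missing_meta}")
    if "library_size" not in meta.columns:
        meta["library_size"] = 0.0
    flags = None
    if flags_path is None:
        candidate = Path(str(counts_path) + ".flags")
        flags_path = candidate if candidate.exists() else None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col="gene_id").astype(bool)
    return AseCountTable(counts=counts, meta=meta[META_COLUMNS].copy(), gene_flags=flags)


@dataclass
class ExpressionTable:
    """Genes x samples matrix of nonnegative TPM-like abundances."""

    values: pd.DataFrame
    role: str = "hybrid_overall"  # parental_overall | hybrid_overall | sexwise_expression | allele_tpm

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, role: str = "hybrid_overall") -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), role=role)


@dataclass
class AnalysisConfig:
    """Thresholds and conventions shared across the analysis stages.

    Defaults follow the study design: BH FDR 0.05 for every test family,
    expression filter TPM > 1 in at least 4 of the 8 scope observations,
    parental read-sum filter >= 20, parental eligibility fold >= 1.5 and
    hybrid deviation fold 1.25 for inheritance calls, and sex-bias bin
    bounds at -1, -0.3, 0.3, 1 on log2((exp_F+1)/(exp_M+1)).
    """

    alpha_fdr: float = 0.05
    tpm_filter_threshold: float = 1.0
    tpm_filter_min_samples: int = 4
    parental_min_reads: float = 20.0
    parental_fold_min: float = 1.5
    hybrid_fold_cutoff: float = 1.25
    sb_bounds: tuple[float, float, float, float] = (-1.0, -0.3, 0.3, 1.0)
    inclusive_fold_bounds: bool = True
    tpm_floor: float = 0.01
    pseudocount: float = 0.5
    dispersion_prior_df: float = 20.0
    common_dispersion: bool = False
    min_observations: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ValueError("alpha_fdr must lie in (0, 1)")
        bounds = tuple(self.sb_bounds)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("sb_bounds must be strictly increasing")
        for name in ("tpm_filter_threshold", "parental_min_reads", "parental_fold_min",
                     "hybrid_fold_cutoff", "tpm_floor", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sb_bounds" in raw:
            raw["sb_bounds"] = tuple(raw["sb_bounds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sb_bounds"] = list(d["sb_bounds"])
        return d


# -- design matrices -------------------------------------------------------

SEX_CODE = {"F": 0, "M": 1}
TISSUE_CODE = {"head": 0, "gonad": 1}


def build_design(table: AseCountTable, scope: Scope) -> pd.DataFrame:
    """Per-observation covariate rows for the reciprocal-cross GLM.

    Coding: CR is 0 for allele A and 1 for allele B; PO is 0 when the allele
    was inherited from the mother and 1 from the father; MG is 0 for samples
    from cross AxB and 1 from BxA.  The two allele rows of a sample share its
    log library-size offset.  Returns a DataFrame indexed by observation
    column name with columns CR, PO, MG, sex_code, tissue_code, offset,
    sample_id.
    """
    samples = table.samples_in(scope)
    rows = []
    for sid in samples:
        m = table.meta.loc[sid]
        lib = float(m["library_size"])
        if lib <= 0:
            raise DesignError(f"sample {sid} has nonpositive library size")
        for allele in ALLELES:
            col = obs_column(sid, allele)
            if col not in table.counts.columns:
                continue
            po = parent_of_origin(m["direction"], allele)
            rows.append(
                {
                    "obs": col,
                    "sample_id": sid,
                    "CR": 0 if allele == "A" else 1,
                    "PO": 0 if po == "maternal" else 1,
                    "MG": 0 if m["direction"] == "AxB" else 1,
                    "sex_code": SEX_CODE[m["sex"]],
                    "tissue_code": TISSUE_CODE[m["tissue"]],
                    "offset": math.log(lib),
                }
            )
    if len(rows) < 4:
        raise DesignError("insufficient design: fewer than 4 observations in scope")
    return pd.DataFrame(rows).set_index("obs")


# -- eligibility filters ---------------------------------------------------


def filter_expressed(
    table: AseCountTable,
    tpm: ExpressionTable,
    cfg: AnalysisConfig,
    scope: Scope | None = None,
) -> pd.Index:
    """Genes with TPM above threshold in enough scope observations.

    The unit is the allele-level observation (8 per fully observed scope);
    the inequality is strict, so TPM exactly at the threshold does not count.
    Idempotent by construction.
    """
    scope = scope or Scope()
    cols = [c for c in table.obs_columns(table.samples_in(scope)) if c in tpm.values.columns]
    if not cols:
        raise ValueError("no scope observations present in the TPM table")
    genes = table.autosomal_genes().intersection(tpm.values.index)
    sub = tpm.values.loc[genes, cols]
    keep = (sub > cfg.tpm_filter_threshold).sum(axis=1) >= cfg.tpm_filter_min_samples
    return genes[keep]


def filter_parental_reads(
    parental_sums: pd.DataFrame, cfg: AnalysisConfig
) -> pd.Index:
    """Genes whose summed parental read count reaches the minimum.

    ``parental_sums`` has one row per gene and one column per parental line
    (counts already summed over replicates); the rule is on the total across
    both lines, boundary inclusive.
    """
    if parental_sums.shape[1] != 2:
        raise ValueError("parental_sums must have exactly two line columns")
    total = parental_sums.sum(axis=1)
    return parental_sums.index[total >= cfg.parental_min_reads]
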