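"""Core in-memory containers shared by every analysis stage.

Expression data live in an :class:`ExpressionMatrix` (features x samples,
the proteomics convention), gene sets in a :class:`GeneSetCollection`, and
per-sample signature activations in a :class:`ScoreMatrix`.  Downstream
modules accept only these containers, never raw file paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Histomorphologic compartments used throughout: leading edge, infiltrating
#: tumour, cellular tumour, pseudopalisading cells around necrosis,
#: microvascular proliferation, bulk resection, leukocyte surrogate.
NICHES = ("LE", "IT", "CT", "PAN", "MVP", "WHOLE", "LEUKO")

#: The five laser-capture niches profiled per patient.
TISSUE_NICHES = ("LE", "IT", "CT", "PAN", "MVP")

MODALITIES = ("protein", "rna_tpm", "rna_counts", "sc_counts")
COUNT_MODALITIES = ("rna_counts", "sc_counts")


class TriaxisError(ValueError):
    """Base error for contract violations in this package."""


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with per-sample annotations.

    Parameters
    ----------
    values
        Non-negative abundances (protein intensity, TPM, counts or UMIs),
        features as rows, samples as columns.  May be negative only when
        ``log_scale`` is set (e.g. after log2 transform / imputation).
    sample_meta
        One row per sample (indexed by sample id) with columns
        ``patient_id``, ``niche`` and ``modality``.
    modality
        One of ``protein``, ``rna_tpm``, ``rna_counts``, ``sc_counts``.
    missing_mask
        Boolean frame marking label-free zeros that are detection failures
        rather than observations; protein modality only.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    modality: str
    missing_mask: pd.DataFrame | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise TriaxisError(f"unknown modality {self.modality!r}")
        if not self.values.index.is_unique:
            raise TriaxisError("feature ids are not unique")
        if not self.values.columns.is_unique:
            raise TriaxisError("sample ids are not unique")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise TriaxisError("expression values must be finite")
        if not self.log_scale and (vals < 0).any():
            raise TriaxisError("raw abundances must be non-negative")
        if self.modality in COUNT_MODALITIES and not np.allclose(vals, np.round(vals)):
            raise TriaxisError(f"{self.modality} values must be integer counts")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise TriaxisError(f"samples lacking metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        if self.missing_mask is not None:
            if self.missing_mask.shape != self.values.shape:
                raise TriaxisError("missing_mask shape must match values")
            self.missing_mask = self.missing_mask.astype(bool)

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def niches(self) -> pd.Series:
        return self.sample_meta["niche"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        mask = self.missing_mask[ids] if self.missing_mask is not None else None
        return ExpressionMatrix(
            self.values[ids].copy(),
            self.sample_meta.loc[ids].copy(),
            self.modality,
            missing_mask=None if mask is None else mask.copy(),
            log_scale=self.log_scale,
        )

    def subset_niches(self, niches: Iterable[str]) -> "ExpressionMatrix":
        wanted = set(niches)
        keep = [s for s in self.sample_ids if self.sample_meta.loc[s, "niche"] in wanted]
        if not keep:
            raise TriaxisError(f"no samples in niches {sorted(wanted)}")
        return self.subset_samples(keep)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        mask = self.missing_mask.loc[ids] if self.missing_mask is not None else None
        return ExpressionMatrix(
            self.values.loc[ids].copy(),
            self.sample_meta.copy(),
            self.modality,
            missing_mask=None if mask is None else mask.copy(),
            log_scale=self.log_scale,
        )

    def with_values(self, values: pd.DataFrame, **kwargs) -> "ExpressionMatrix":
        """Return a copy with new values (and optionally a new mask/scale)."""
        return ExpressionMatrix(
            values,
            self.sample_meta.loc[list(values.columns)].copy(),
            kwargs.pop("modality", self.modality),
            missing_mask=kwargs.pop("missing_mask", None),
            log_scale=kwargs.pop("log_scale", self.log_scale),
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str  # curated | hallmark | oncogenic | synthetic
    genes: tuple[str, ...]  # unique, insertion order preserved

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise TriaxisError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise TriaxisError(f"gene set {self.name!r} has duplicate genes")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered, name-indexed collection of gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise TriaxisError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._sets[n] for n in names)


@dataclass
class ScoreMatrix:
    """Signature x sample activation scores (ssGSEA or model-inferred)."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise TriaxisError("scores must be finite")

    @property
    def signatures(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns

    def row(self, signature: str) -> pd.Series:
        if signature not in self.scores.index:
            raise TriaxisError(f"unknown signature {signature!r}")
        return self.scores.loc[signature]
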