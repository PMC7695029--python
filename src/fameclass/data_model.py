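"""Domain types and CSV I/O for labeled fatty-acid profile tables.

A GC-FID fatty-acid analysis of a fish muscle sample yields, per
chromatogram, the relative percentage of each identified fatty acid methyl
ester (FAME).  Seventeen fatty acids are quantified; because the values are
relative peak areas they are compositional and sum to 100% per chromatogram.
Each fish (a *sample block*) is measured repeatedly — up to 6 chromatograms
(3 independent extractions x 2 injections) — and the block, not the
chromatogram, is the unit of resampling everywhere in this package.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical fatty-acid identifiers, in standard reporting order.  Co-eluting
#: peaks keep their joint identity ("22:1n11+22:1n9", "20:3n3+20:4n6", no
#: internal whitespace).  This order is total and shared by every module.
CANONICAL_FEATURES: tuple[str, ...] = (
    "14:0",
    "16:0",
    "16:1",
    "18:0",
    "18:1n9c",
    "18:1n7",
    "18:2n6c",
    "18:3n3",
    "20:1n9",
    "18:4n3",
    "20:2n6",
    "22:1n11+22:1n9",
    "20:3n3+20:4n6",
    "20:5n3",
    "24:1n9",
    "22:5n3",
    "22:6n3",
)

#: Default tolerance (percentage points) for the compositional closure
#: constraint sum(features) == 100.  Rounded published tables deviate from
#: exact closure by a few hundredths, so a hard equality is impractical.
CLOSURE_TOLERANCE: float = 0.5

N_FEATURES = len(CANONICAL_FEATURES)

_META_COLUMNS = ("sample_id", "class_name", "replicate")


class ClassLabel(enum.IntEnum):
    """Salmon origin classes, with the fixed code<->name bijection."""

    NORWAY_FARMED = 0
    CHILE_FARMED = 1
    CANADA_FARMED = 2
    CANADA_WILD = 3

    @property
    def display_name(self) -> str:
        return _CODE_TO_NAME[int(self)]

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls(_NAME_TO_CODE[name.strip()])
        except KeyError:
            raise ValueError(f"unknown class name: {name!r}") from None


_CODE_TO_NAME = {
    0: "Norway farmed",
    1: "Chile farmed",
    2: "Canada farmed",
    3: "Canada wild",
}
_NAME_TO_CODE = {v: k for k, v in _CODE_TO_NAME.items()}


class DatasetValidationError(ValueError):
    """Raised when rows of a feature table violate dataset invariants.

    Carries per-row diagnostics in :attr:`rejects` (list of dicts with keys
    ``row``, ``error``); serializable with :meth:`to_json`.
    """

    def __init__(self, rejects: list[dict]):
        self.rejects = rejects
        preview = "; ".join(f"row {r['row']}: {r['error']}" for r in rejects[:5])
        more = "" if len(rejects) <= 5 else f" (+{len(rejects) - 5} more)"
        super().__init__(f"{len(rejects)} invalid row(s): {preview}{more}")

    def to_json(self) -> str:
        return json.dumps(self.rejects, indent=2)


def validate_profile(values: Mapping[str, float] | Sequence[float],
                     closure_tol: float = CLOSURE_TOLERANCE) -> np.ndarray:
    """Validate one fatty-acid profile and return it as a canonical vector.

    Accepts a mapping keyed by canonical feature name or a sequence in
    canonical order.  Checks: 17 entries, all finite, each in [0, 100], and
    compositional closure |sum - 100| <= ``closure_tol``.
    """
    if isinstance(values, Mapping):
        missing = [f for f in CANONICAL_FEATURES if f not in values]
        if missing:
            raise ValueError(f"missing features: {missing}")
        vec = np.array([float(values[f]) for f in CANONICAL_FEATURES])
    else:
        vec = np.asarray(values, dtype=float)
        if vec.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    if vec.min() < 0 or vec.max() > 100:
        raise ValueError("feature value outside [0, 100]")
    total = vec.sum()
    if abs(total - 100.0) > closure_tol:
        raise ValueError(f"closure violation: features sum to {total:.4g}, "
                         f"not 100 +/- {closure_tol}")
    return vec


@dataclass(frozen=True)
class LabeledDataset:
    """Labeled chromatogram instances with block (per-fish) structure.

    Thin immutable wrapper around a DataFrame with columns ``sample_id``,
    ``class_name``, ``replicate`` followed by the feature columns.  Rows are
    kept sorted by (sample_id, replicate).  ``feature_names`` is the
    canonical 17-tuple for measured data but may be any tuple for derived
    datasets (e.g. 2-D t-SNE coordinates).
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...] = CANONICAL_FEATURES

    def __post_init__(self):
        df = self.frame
        expected = list(_META_COLUMNS) + list(self.feature_names)
        if list(df.columns) != expected:
            raise ValueError(f"columns must be {expected}, got {list(df.columns)}")
        # one label per sample block
        nlab = df.groupby("sample_id", sort=False)["class_name"].nunique()
        bad = nlab[nlab > 1]
        if len(bad):
            raise ValueError(f"inconsistent labels within sample block(s): "
                             f"{list(bad.index)}")
        reps = df.groupby("sample_id", sort=False)["replicate"].count()
        if len(reps) and (reps.min() < 1 or reps.max() > 6):
            raise ValueError("sample blocks must contain 1..6 chromatograms")
        ordered = df.sort_values(["sample_id", "replicate"],
                                 kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "frame", ordered)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(cls, X: np.ndarray, sample_ids: Sequence[str],
                    labels: Sequence[int | ClassLabel],
                    replicates: Sequence[int],
                    feature_names: Sequence[str] = CANONICAL_FEATURES,
                    ) -> "LabeledDataset":
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame({
            "sample_id": list(sample_ids),
            "class_name": [ClassLabel(int(c)).display_name for c in labels],
            "replicate": np.asarray(replicates, dtype=int),
        })
        for j, name in enumerate(feature_names):
            df[name] = X[:, j]
        return cls(df, tuple(feature_names))

    # -- accessors --------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.frame)

    @property
    def n_samples(self) -> int:
        return self.frame["sample_id"].nunique()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        """Class codes (0..3) per chromatogram instance."""
        return self.frame["class_name"].map(_NAME_TO_CODE).to_numpy()

    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        """Feature matrix, optionally restricted to a feature subset."""
        feats = list(self.feature_names if features is None else features)
        unknown = set(feats) - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        return self.frame[feats].to_numpy(dtype=float)

    def sample_table(self) -> pd.DataFrame:
        """One row per sample block: label code and replicate-averaged features.

        Averaging replicates first makes the fish, not the injection, the
        unit of statistical analysis (avoids pseudo-replication).
        """
        df = self.frame
        agg = df.groupby("sample_id", sort=True).agg(
            {"class_name": "first", **{f: "mean" for f in self.feature_names}})
        agg.insert(0, "class_code", agg["class_name"].map(_NAME_TO_CODE))
        return agg

    def class_sample_counts(self) -> dict[int, int]:
        tab = self.sample_table()
        return tab.groupby("class_code").size().to_dict()

    def subset_samples(self, sample_ids: Iterable[str]) -> "LabeledDataset":
        keep = set(sample_ids)
        return LabeledDataset(
            self.frame[self.frame["sample_id"].isin(keep)].reset_index(drop=True),
            self.feature_names)

    def with_features(self, X: np.ndarray,
                      feature_names: Sequence[str]) -> "LabeledDataset":
        """Derived dataset with the same instances but new feature columns."""
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_instances:
            raise ValueError("row count mismatch")
        return LabeledDataset.from_arrays(
            X, self.sample_ids, self.y,
            self.frame["replicate"].to_numpy(), feature_names)

    def __eq__(self, other) -> bool:  # value semantics for tests
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        return (self.feature_names == other.feature_names
                and self.frame.shape == other.frame.shape
                and self.frame.equals(other.frame))


@dataclass
class ColumnSchema:
    """Maps CSV columns onto the dataset contract.

    ``features`` maps canonical feature name -> CSV column name (defaults to
    identity); ``class_column`` may contain class names or integer codes.
    """

    sample_column: str = "sample_id"
    class_column: str = "class_name"
    replicate_column: str = "replicate"
    features: Mapping[str, str] = field(default_factory=dict)

    def feature_column(self, canonical: str) -> str:
        return self.features.get(canonical, canonical)


def read_dataset(path: str | Path, schema: ColumnSchema | None = None,
                 closure_tol: float = CLOSURE_TOLERANCE,
                 on_invalid: str = "raise") -> LabeledDataset:
    """Read a labeled feature table from CSV.

    Columns may appear in any order; ``schema`` maps nonstandard headers.
    Features are reordered canonically.  Rows violating the profile
    invariants are rejected: ``on_invalid="raise"`` (default) raises
    :class:`DatasetValidationError` with row-level diagnostics,
    ``on_invalid="drop"`` silently drops them.
    """
    schema = schema or ColumnSchema()
    raw = pd.read_csv(path, float_precision="round_trip")
    for col in (schema.sample_column, schema.class_column, schema.replicate_column):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    missing = [f for f in CANONICAL_FEATURES
               if schema.feature_column(f) not in raw.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")

    rejects: list[dict] = []
    rows = []
    for i, rec in raw.iterrows():
        try:
            cls_cell = rec[schema.class_column]
            if isinstance(cls_cell, str) and not cls_cell.strip().isdigit():
                label = ClassLabel.from_name(cls_cell)
            else:
                label = ClassLabel(int(cls_cell))
            vals = {}
            for f in CANONICAL_FEATURES:
                cell = rec[schema.feature_column(f)]
                v = float(cell)
                if np.isnan(v):
                    raise ValueError(f"non-numeric cell for {f!r}")
                vals[f] = v
            vec = validate_profile(vals, closure_tol)
            rows.append((str(rec[schema.sample_column]), label.display_name,
                         int(rec[schema.replicate_column]), vec))
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(i), "error": str(exc)})
    if rejects and on_invalid == "raise":
        raise DatasetValidationError(rejects)

    df = pd.DataFrame({
        "sample_id": [r[0] for r in rows],
        "class_name": [r[1] for r in rows],
        "replicate": [r[2] for r in rows],
    })
    mat = (np.vstack([r[3] for r in rows]) if rows
           else np.empty((0, N_FEATURES)))
    for j, f in enumerate(CANONICAL_FEATURES):
        df[f] = mat[:, j]
    return LabeledDataset(df)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write a dataset as CSV with canonical column order.

    Row order is deterministic (sample_id, replicate); floats are written at
    full precision so read->write round-trips are exact.
    """
    path = Path(path)
    dataset.frame.to_csv(path, index=False, float_format="%.17g")
    return path
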