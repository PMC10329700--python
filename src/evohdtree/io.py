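"""Reading, validation and preprocessing of targeted-metabolomics matrices.

The two preprocessing rules applied to p180-style concentration tables are:

1. a presence filter that keeps only metabolites quantified in at least a
   given fraction of all samples (default 80%), and
2. half-LOD imputation, replacing each remaining missing value with half of
   the limit of detection for that metabolite in the sample's batch.

Filtering precedes imputation, and presence is computed over all samples
jointly (not per group or per batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical diagnostic groups: glioma grades I-IV, meningioma, healthy control
GROUPS = ("GI", "GII", "GIII", "GIV", "MT", "Con")

_META_COLS = ("sample_id", "group", "batch")


class PreprocessingError(ValueError):
    """Raised when a matrix violates a structural invariant."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentration table (µM) with batch-wise LODs.

    Parameters
    ----------
    values : pandas.DataFrame
        Concentrations, rows indexed by sample id, columns by metabolite
        name. ``NaN`` marks a value below the limit of detection.
    group : pandas.Series
        Diagnostic group per sample (one of :data:`GROUPS`).
    batch : pandas.Series
        Acquisition batch per sample.
    lod : pandas.DataFrame
        Limit of detection (µM), rows indexed by metabolite, columns by
        batch.
    metabolite_class : pandas.Series, optional
        Compound class per metabolite.
    """

    values: pd.DataFrame
    group: pd.Series
    batch: pd.Series
    lod: pd.DataFrame
    metabolite_class: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise PreprocessingError(f"duplicate sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessingError(f"duplicate metabolite names: {dupes}")
        for name, s in (("group", self.group), ("batch", self.batch)):
            if not s.index.equals(self.values.index):
                raise PreprocessingError(f"{name} index does not match sample ids")
        unknown = set(self.group.unique()) - set(GROUPS)
        if unknown:
            raise PreprocessingError(f"unknown group labels: {sorted(unknown)}")
        lod_ref = self.lod.reindex(
            index=self.values.columns, columns=pd.unique(self.batch)
        )
        bad = lod_ref.to_numpy(dtype=float)
        if np.any(bad[~np.isnan(bad)] <= 0):
            raise PreprocessingError("LOD values must be positive")
        # every missing cell must have a usable LOD entry
        mask = self.values.isna()
        if mask.to_numpy().any():
            missing_lod = lod_ref.isna()
            for b in pd.unique(self.batch):
                rows = self.batch == b
                absent = mask.loc[rows].any(axis=0)
                mets = absent.index[absent]
                no_lod = missing_lod.loc[mets, b]
                if no_lod.any():
                    met = no_lod.index[no_lod][0]
                    raise PreprocessingError(
                        f"no LOD for metabolite {met!r} in batch {b!r} "
                        "although it has missing values there"
                    )

    # -- convenience ------------------------------------------------------

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, ``True`` where the concentration is unmeasured."""
        return self.values.isna()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledDataset:
    """A fully imputed two-group comparison dataset.

    ``y == 1`` marks the positive class: the patient group(s), listed first
    in the comparison name (e.g. the gliomas in "GI-II vs Con").
    """

    values: np.ndarray
    y: np.ndarray
    metabolite_names: list[str]
    positive_group: str = "pos"
    negative_group: str = "neg"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.values.ndim != 2:
            raise PreprocessingError("values must be a 2-D array")
        if self.values.shape[0] != self.y.shape[0]:
            raise PreprocessingError("values and y length mismatch")
        if np.isnan(self.values).any():
            raise PreprocessingError("dataset contains missing values; impute first")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise PreprocessingError("y must be binary 0/1")
        if self.y.sum() == 0 or self.y.sum() == len(self.y):
            raise PreprocessingError("both classes must be non-empty")
        if len(self.metabolite_names) != self.values.shape[1]:
            raise PreprocessingError("metabolite_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def name(self) -> str:
        return f"{self.positive_group} vs {self.negative_group}"

    def fingerprint(self) -> str:
        """Short content hash identifying the training data (cached)."""
        fp = getattr(self, "_fingerprint", None)
        if fp is None:
            import hashlib

            h = hashlib.md5()
            h.update(np.ascontiguousarray(self.values).tobytes())
            h.update(np.ascontiguousarray(self.y).tobytes())
            fp = h.hexdigest()[:12]
            object.__setattr__(self, "_fingerprint", fp)
        return fp


# ---------------------------------------------------------------------------
# I/O


def read_matrix(path, lod_path) -> MetaboliteMatrix:
    """Read a concentration matrix CSV plus a long-format LOD CSV.

    The matrix CSV carries one row per sample with columns
    ``sample_id,group,batch,<metabolite>,...``; empty cells or ``NA`` denote
    concentrations below the LOD. The LOD CSV has columns
    ``metabolite,batch,lod``.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "batch": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise PreprocessingError(f"matrix CSV lacks required column {col!r}")
    df = df.set_index("sample_id")
    met_cols = [c for c in df.columns if c not in ("group", "batch")]
    values = df[met_cols].apply(pd.to_numeric, errors="coerce")

    lod_long = pd.read_csv(lod_path, dtype={"metabolite": str, "batch": str})
    for col in ("metabolite", "batch", "lod"):
        if col not in lod_long.columns:
            raise PreprocessingError(f"LOD CSV lacks required column {col!r}")
    lod = lod_long.pivot(index="metabolite", columns="batch", values="lod")

    return MetaboliteMatrix(values=values, group=df["group"], batch=df["batch"], lod=lod)


def write_matrix(m: MetaboliteMatrix, path, lod_path=None) -> None:
    """Write a matrix (and optionally its LOD table) back to CSV."""
    out = pd.concat([m.group.rename("group"), m.batch.rename("batch"), m.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)
    if lod_path is not None:
        long = (
            m.lod.reset_index(names="metabolite")
            .melt(id_vars="metabolite", var_name="batch", value_name="lod")
            .dropna(subset=["lod"])
        )
        long.to_csv(lod_path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing rules


def filter_by_presence(m: MetaboliteMatrix, min_presence: float = 0.80) -> MetaboliteMatrix:
    """Keep metabolites quantified in at least ``min_presence`` of all samples.

    The boundary is inclusive: a metabolite observed in exactly 80% of the
    samples survives the default filter. Column order is preserved.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    presence = 1.0 - m.missing_mask.mean(axis=0)
    keep = presence[presence >= min_presence].index
    if len(keep) == 0:
        logger.warning("presence filter at %.2f removed every metabolite", min_presence)
    cls = m.metabolite_class.loc[keep] if m.metabolite_class is not None else None
    return MetaboliteMatrix(
        values=m.values[keep],
        group=m.group,
        batch=m.batch,
        lod=m.lod.loc[m.lod.index.intersection(keep)],
        metabolite_class=cls,
    )


def impute_half_lod(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace every missing value with half the LOD of its metabolite/batch.

    Observed cells are untouched; the operation is idempotent because the
    output has no missing values left.
    """
    values = m.values.copy()
    mask = m.missing_mask
    for b in pd.unique(m.batch):
        rows = (m.batch == b).to_numpy()
        sub_mask = mask.iloc[rows]
        cols = sub_mask.columns[sub_mask.any(axis=0)]
        for met in cols:
            lod_val = m.lod.at[met, b] if met in m.lod.index and b in m.lod.columns else np.nan
            if pd.isna(lod_val):
                raise PreprocessingError(
                    f"no LOD for metabolite {met!r} in batch {b!r}"
                )
            col = values[met].to_numpy(copy=True)
            fill = rows & values[met].isna().to_numpy()
            col[fill] = lod_val / 2.0
            values[met] = col
    return MetaboliteMatrix(
        values=values,
        group=m.group,
        batch=m.batch,
        lod=m.lod,
        metabolite_class=m.metabolite_class,
    )


def make_comparison(
    m: MetaboliteMatrix,
    positive_groups,
    negative_groups,
) -> LabeledDataset:
    """Slice a binary comparison dataset out of a fully imputed matrix.

    All metabolites are carried over unchanged — no feature pre-selection.
    ``y = 1`` for samples in ``positive_groups``.
    """
    positive_groups, negative_groups = set(positive_groups), set(negative_groups)
    if positive_groups & negative_groups:
        raise PreprocessingError(
            f"groups overlap: {sorted(positive_groups & negative_groups)}"
        )
    if m.missing_mask.to_numpy().any():
        raise PreprocessingError("matrix has missing values; run impute_half_lod first")
    in_pos = m.group.isin(positive_groups)
    in_neg = m.group.isin(negative_groups)
    if not in_pos.any() or not in_neg.any():
        raise PreprocessingError("one of the comparison classes is empty")
    sel = in_pos | in_neg
    return LabeledDataset(
        values=m.values.loc[sel].to_numpy(dtype=float),
        y=in_pos[sel].to_numpy(dtype=np.int64),
        metabolite_names=m.metabolite_names,
        positive_group="-".join(sorted(positive_groups, key=GROUPS.index)),
        negative_group="-".join(sorted(negative_groups, key=GROUPS.index)),
        sample_ids=list(m.values.index[sel]),
    )
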