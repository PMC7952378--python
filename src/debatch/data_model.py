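"""Core data containers, table I/O and validation.

The central object is :class:`FeatureMatrix`: a samples x features intensity
table with aligned per-sample metadata (batch label, injection order, QC
flag, optional biological covariates).  All correction, scoring and
downstream stages consume and produce this container.

Intensities are stored as floats with ``NaN`` marking missing (typically
below-detection-limit) entries.  A ``scale_flag`` records whether the table
holds raw or log2 intensities so that corrections can pick the right
arithmetic (ratio on raw scale, difference on log2 scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("debatch")

RAW = "raw"
LOG2 = "log2"

#: issue codes emitted by :func:`validate`
MISALIGNED = "MISALIGNED"
DUP_SAMPLE = "DUP_SAMPLE"
DUP_FEATURE = "DUP_FEATURE"
ORDER_DUP = "ORDER_DUP"
SMALL_BATCH = "SMALL_BATCH"
BAD_ORDER = "BAD_ORDER"
NEGATIVE_RAW = "NEGATIVE_RAW"


class FeatureTableError(ValueError):
    """Raised for malformed feature tables or metadata."""


@dataclass
class Issue:
    """One machine-readable validation finding."""

    severity: str  # "error" | "warning"
    code: str
    message: str
    affected: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}:{self.code}] {self.message}"


@dataclass
class FeatureMatrix:
    """Samples x features intensity matrix with aligned sample metadata.

    Parameters
    ----------
    intensities
        ``DataFrame`` indexed by sample id with one column per feature.
        ``NaN`` encodes missing values.
    batch
        Per-sample batch label, aligned to ``intensities.index``.
    injection_order
        Per-sample positive integer acquisition order, unique within batch.
    is_qc
        Per-sample boolean; ``True`` marks pooled/surrogate QC injections.
    covariates
        Optional per-sample table of biological covariates (group, age, ...).
    scale_flag
        ``"raw"`` for native intensity scale, ``"log2"`` after log transform.
    """

    intensities: pd.DataFrame
    batch: pd.Series
    injection_order: pd.Series
    is_qc: pd.Series
    covariates: pd.DataFrame | None = None
    scale_flag: str = RAW

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        self.batch = pd.Series(self.batch, index=self.intensities.index).astype(str)
        self.injection_order = pd.Series(
            self.injection_order, index=self.intensities.index
        ).astype(int)
        self.is_qc = pd.Series(self.is_qc, index=self.intensities.index).astype(bool)
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.intensities.index]
        if self.scale_flag not in (RAW, LOG2):
            raise FeatureTableError(f"unknown scale_flag {self.scale_flag!r}")

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def batches(self) -> list[str]:
        """Batch labels in order of first appearance."""
        return list(dict.fromkeys(self.batch))

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            intensities=self.intensities.copy(),
            batch=self.batch.copy(),
            injection_order=self.injection_order.copy(),
            is_qc=self.is_qc.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
            scale_flag=self.scale_flag,
        )

    def with_intensities(self, values: pd.DataFrame) -> "FeatureMatrix":
        """Return a copy holding ``values`` (sample set must be unchanged)."""
        out = self.copy()
        out.intensities = values.loc[self.sample_ids].astype(float)
        return out

    def subset_features(self, keep: Sequence[str]) -> "FeatureMatrix":
        out = self.copy()
        out.intensities = out.intensities.loc[:, list(keep)]
        return out


@dataclass
class CorrectionResult:
    """Output of one correction model.

    ``corrected`` keeps the input sample set; ``dropped_features`` lists
    features the model had to discard (e.g. features absent from every QC
    sample under the QC-lowess comparator) with the reason.
    """

    corrected: FeatureMatrix
    model_name: str
    internals: Any = None
    dropped_features: list[tuple[str, str]] = field(default_factory=list)
    runtime_log: list[dict] = field(default_factory=list)

    def log(self, level: str, code: str, message: str) -> None:
        self.runtime_log.append({"level": level, "code": code, "message": message})
        getattr(logger, level if level != "warning" else "warning", logger.info)(
            "%s: %s", code, message
        )


@dataclass
class TableLayout:
    """Column naming and orientation of on-disk tables.

    ``orientation`` is ``"samples_rows"`` when the intensity table has one
    row per sample, ``"features_rows"`` when transposed (common in
    untargeted exports).  ``zero_is_missing`` opts in to treating 0 as
    not-detected, which many untargeted pipelines emit.
    """

    sample_id_col: str = "sample_id"
    batch_col: str = "batch"
    order_col: str = "injection_order"
    qc_col: str = "is_qc"
    covariate_cols: tuple[str, ...] = ()
    orientation: str = "samples_rows"
    zero_is_missing: bool = False
    delimiter: str | None = None  # None -> sniffed from the file
    scale_flag: str = RAW

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariate_cols" in raw:
            raw["covariate_cols"] = tuple(raw["covariate_cols"])
        return cls(**raw)


_MISSING_SENTINELS = {"", "na", "nan", "n/a", "null", "none"}


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def _to_float(df: pd.DataFrame, zero_is_missing: bool) -> pd.DataFrame:
    def conv(cell: str) -> float:
        s = cell.strip()
        if s.lower() in _MISSING_SENTINELS:
            return np.nan
        try:
            v = float(s)
        except ValueError:
            return np.nan
        if zero_is_missing and v == 0:
            return np.nan
        return v

    return df.map(conv).astype(float)


def read_feature_table(
    intensity_path: str | Path,
    metadata_path: str | Path,
    layout: TableLayout | Mapping[str, Any] | None = None,
) -> FeatureMatrix:
    """Read an intensity table and its sample metadata into a FeatureMatrix.

    ``sample_id`` is the join key between the two tables; row order in the
    files carries no meaning.  Non-numeric and sentinel cells (empty, NA,
    NaN, and optionally 0) become missing.

    Raises
    ------
    FeatureTableError
        If the two tables disagree on the sample set (the message lists the
        asymmetric difference) or an id is duplicated.
    """
    if layout is None:
        layout = TableLayout()
    elif isinstance(layout, Mapping):
        layout = TableLayout(**layout)

    inten = _read_table(intensity_path, layout.delimiter)
    if layout.orientation == "features_rows":
        inten = inten.T
    elif layout.orientation != "samples_rows":
        raise FeatureTableError(f"unknown orientation {layout.orientation!r}")
    meta = _read_table(metadata_path, layout.delimiter)
    meta.index.name = layout.sample_id_col

    for name, idx in (("sample_id", inten.index), ("feature_id", inten.columns)):
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise FeatureTableError(f"duplicated {name}(s) in intensity table: {dupes}")
    if meta.index.duplicated().any():
        dupes = sorted(set(meta.index[meta.index.duplicated()]))
        raise FeatureTableError(f"duplicated sample_id(s) in metadata: {dupes}")

    only_inten = sorted(set(inten.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(inten.index))
    if only_inten or only_meta:
        raise FeatureTableError(
            "sample_ids differ between intensity and metadata tables: "
            f"only in intensities={only_inten}, only in metadata={only_meta}"
        )
    meta = meta.loc[inten.index]

    for col in (layout.batch_col, layout.order_col):
        if col not in meta.columns:
            raise FeatureTableError(f"metadata lacks required column {col!r}")
    qc = (
        meta[layout.qc_col].str.strip().str.lower().isin({"1", "true", "yes", "qc"})
        if layout.qc_col in meta.columns
        else pd.Series(False, index=meta.index)
    )
    covs = None
    if layout.covariate_cols:
        missing_cols = [c for c in layout.covariate_cols if c not in meta.columns]
        if missing_cols:
            raise FeatureTableError(f"metadata lacks covariate column(s) {missing_cols}")
        covs = meta[list(layout.covariate_cols)].copy()
        for c in covs.columns:
            try:
                covs[c] = pd.to_numeric(covs[c])
            except (ValueError, TypeError):
                pass  # categorical covariate stays as strings

    fm = FeatureMatrix(
        intensities=_to_float(inten, layout.zero_is_missing),
        batch=meta[layout.batch_col],
        injection_order=pd.to_numeric(meta[layout.order_col]).astype(int),
        is_qc=qc,
        covariates=covs,
        scale_flag=layout.scale_flag,
    )
    for issue in validate(fm):
        if issue.severity == "warning":
            logger.warning("%s", issue)
    return fm


def write_feature_table(
    fm: FeatureMatrix, out_prefix: str | Path, delimiter: str = ","
) -> tuple[Path, Path]:
    """Write ``<prefix>_intensities.csv`` and ``<prefix>_metadata.csv``.

    Missing entries are written as empty cells.  The round trip
    ``read_feature_table(*write_feature_table(fm))`` reproduces finite
    intensities bit-equal (floats are serialized with ``repr``) and
    preserves the missingness pattern and metadata.
    """
    if fm.n_features == 0:
        raise FeatureTableError("refusing to write a 0-feature table")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ipath = out_prefix.parent / (out_prefix.name + "_intensities.csv")
    mpath = out_prefix.parent / (out_prefix.name + "_metadata.csv")

    text = fm.intensities.map(lambda v: "" if np.isnan(v) else repr(float(v)))
    text.index.name = "sample_id"
    text.to_csv(ipath, sep=delimiter)

    meta = pd.DataFrame(
        {
            "batch": fm.batch,
            "injection_order": fm.injection_order,
            "is_qc": fm.is_qc.map({True: "1", False: "0"}),
        }
    )
    if fm.covariates is not None:
        meta = pd.concat([meta, fm.covariates], axis=1)
    meta.index.name = "sample_id"
    meta.to_csv(mpath, sep=delimiter)
    return ipath, mpath


def layout_for(fm: FeatureMatrix) -> TableLayout:
    """Layout matching :func:`write_feature_table` output, for re-reading."""
    covs = () if fm.covariates is None else tuple(fm.covariates.columns)
    return TableLayout(covariate_cols=covs, scale_flag=fm.scale_flag, delimiter=",")


def validate(fm: FeatureMatrix) -> list[Issue]:
    """Check FeatureMatrix invariants; returns issues, never raises.

    Codes: ``MISALIGNED`` (metadata/intensity index mismatch),
    ``DUP_SAMPLE``/``DUP_FEATURE``, ``ORDER_DUP`` (duplicate injection order
    within a batch), ``BAD_ORDER`` (non-positive order), ``SMALL_BATCH``
    (< 2 non-QC samples — a warning here, an error at correction time),
    ``NEGATIVE_RAW`` (negative intensity on the raw scale).
    """
    issues: list[Issue] = []
    idx = fm.intensities.index
    for series, name in (
        (fm.batch, "batch"),
        (fm.injection_order, "injection_order"),
        (fm.is_qc, "is_qc"),
    ):
        if not series.index.equals(idx):
            issues.append(
                Issue("error", MISALIGNED, f"{name} index differs from intensities")
            )
    if idx.duplicated().any():
        issues.append(
            Issue(
                "error",
                DUP_SAMPLE,
                "duplicated sample ids",
                tuple(sorted(set(idx[idx.duplicated()]))),
            )
        )
    if fm.feature_ids.duplicated().any():
        cols = fm.feature_ids
        issues.append(
            Issue(
                "error",
                DUP_FEATURE,
                "duplicated feature ids",
                tuple(sorted(set(cols[cols.duplicated()]))),
            )
        )
    if (fm.injection_order <= 0).any():
        bad = tuple(fm.injection_order.index[fm.injection_order <= 0])
        issues.append(Issue("error", BAD_ORDER, "non-positive injection order", bad))
    for b in fm.batches:
        in_b = fm.batch == b
        orders = fm.injection_order[in_b]
        if orders.duplicated().any():
            issues.append(
                Issue(
                    "error",
                    ORDER_DUP,
                    f"duplicate injection order within batch {b!r}",
                    (b,),
                )
            )
        n_study = int((in_b & ~fm.is_qc).sum())
        if n_study < 2:
            issues.append(
                Issue(
                    "warning",
                    SMALL_BATCH,
                    f"batch {b!r} has {n_study} non-QC sample(s); "
                    "corrections need at least 2",
                    (b,),
                )
            )
    if fm.scale_flag == RAW and (fm.intensities < 0).any().any():
        issues.append(Issue("warning", NEGATIVE_RAW, "negative raw intensities"))
    return issues


def require_valid(fm: FeatureMatrix) -> None:
    """Raise on any error-severity validation issue."""
    errors = [i for i in validate(fm) if i.severity == "error"]
    if errors:
        raise FeatureTableError("; ".join(str(i) for i in errors))
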