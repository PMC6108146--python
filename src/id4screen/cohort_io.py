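"""Read, validate, harmonize and write the tabular inputs of the pipeline.

The canonical on-disk dialect follows UCSC Xena text matrices: tab-separated,
UTF-8, one header row of sample IDs, identifier in the first column, genes (or
450K probes) on rows.  Expression values are log2(norm_count+1); methylation
values are Infinium beta values in [0, 1].  Missing cells are written as the
literal ``NA`` and accepted on read as ``NA``, the empty string or ``NaN``.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "", "NaN", "nan")

ER_LEVELS = ("ER+", "ER-", "unknown")
PAM50_LEVELS = ("LumA", "LumB", "Basal", "Normal", "Her2", "unknown")

#: Value spellings commonly found in TCGA clinical exports, mapped onto the
#: canonical vocabularies.  A column_map may extend or override these.
DEFAULT_ER_VALUES: Mapping[str, str] = {
    "ER+": "ER+", "ER-": "ER-", "Positive": "ER+", "Negative": "ER-",
    "positive": "ER+", "negative": "ER-",
}
DEFAULT_PAM50_VALUES: Mapping[str, str] = {
    "LumA": "LumA", "LumB": "LumB", "Basal": "Basal", "Normal": "Normal",
    "Her2": "Her2", "Luminal A": "LumA", "Luminal B": "LumB",
    "Basal-like": "Basal", "Normal-like": "Normal", "HER2-enriched": "Her2",
}
DEFAULT_EVENT_VALUES: Mapping[str, bool] = {
    "1": True, "0": False, "1.0": True, "0.0": False,
    "dead": True, "alive": False, "DECEASED": True, "LIVING": False,
    "True": True, "False": False,
}


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(norm_count+1) expression values."""

    values: pd.DataFrame  # index = gene IDs, columns = sample IDs

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)])


@dataclass
class MethylationMatrix:
    """Probes x samples beta-value matrix plus per-probe annotation.

    ``annotation`` is indexed by probe ID with columns ``position`` (a genomic
    position label) and ``promoter`` (bool: probe lies in the promoter region).
    """

    betas: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.betas.index), "probe")
        _check_unique(list(self.betas.columns), "sample")
        arr = self.betas.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)  # NaN compares False: missing is legal
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.betas.index[i]!r}, sample {self.betas.columns[j]!r}"
            )
        missing = [p for p in self.betas.index if p not in self.annotation.index]
        if missing:
            logger.warning(
                "%d probe(s) missing annotation; promoter_flag set to False: %s",
                len(missing), missing[:5],
            )
            pad = pd.DataFrame(
                {"position": "unannotated", "promoter": False}, index=missing
            )
            self.annotation = pd.concat([self.annotation, pad])
        self.annotation = self.annotation.loc[self.betas.index]
        self.annotation["promoter"] = self.annotation["promoter"].astype(bool)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    def promoter_probes(self) -> list[str]:
        return list(self.annotation.index[self.annotation["promoter"]])

    def subset_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(
            self.betas.loc[:, list(samples)], self.annotation.copy()
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical record: ER status, PAM50 subtype, overall survival.

    ``data`` is indexed by sample ID with columns ``er_status``, ``pam50``,
    ``os_months`` (float, NaN when unknown) and ``os_event`` (boolean, NaN
    when unknown).  ``n_unmapped`` counts categorical values that had to fall
    back to "unknown" on read.
    """

    data: pd.DataFrame
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        required = {"er_status", "pam50", "os_months", "os_event"}
        absent = required - set(self.data.columns)
        if absent:
            raise ValidationError(f"clinical table missing columns: {sorted(absent)}")
        months = self.data["os_months"].to_numpy(dtype=float)
        if (months[~np.isnan(months)] < 0).any():
            bad = self.data.index[np.nan_to_num(months, nan=0.0) < 0][0]
            raise ValidationError(f"negative os_months for sample {bad!r}")
        for col, levels in (("er_status", ER_LEVELS), ("pam50", PAM50_LEVELS)):
            vals = set(self.data[col].dropna().unique())
            if not vals <= set(levels):
                raise ValidationError(
                    f"non-canonical {col} values: {sorted(vals - set(levels))}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy(), self.n_unmapped)


@dataclass
class Cohort:
    """Expression + methylation + clinical triple on one ordered sample axis."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    clinical: ClinicalTable
    #: samples dropped from each component during harmonization
    dropped: Mapping[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


# ---------------------------------------------------------------------------
# readers


def _read_numeric_matrix(path: str | pathlib.Path) -> pd.DataFrame:
    """Read an identifier-first TSV matrix, coercing cells to float.

    Non-numeric, non-missing cells raise ParseError with coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cleaned = raw[col].where(~raw[col].isin(MISSING_TOKENS), other=np.nan)
        try:
            # python float() is correctly rounded, so text round-trips exactly
            numeric = cleaned.astype(float)
        except (ValueError, TypeError):
            for row, value in cleaned.items():
                if isinstance(value, str):
                    try:
                        float(value)
                    except ValueError:
                        raise ParseError(
                            f"non-numeric cell {value!r} at row {row!r}, "
                            f"column {col!r} in {path}"
                        ) from None
            raise
        out[col] = numeric
    return out


def read_expression_matrix(
    path: str | pathlib.Path, orientation: str = "genes_x_samples"
) -> ExpressionMatrix:
    """Read an expression TSV in either orientation into the canonical layout."""
    if orientation not in ("genes_x_samples", "samples_x_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    values = _read_numeric_matrix(path)
    if orientation == "samples_x_genes":
        values = values.T
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values)


def read_methylation_matrix(
    path: str | pathlib.Path, annotation_path: str | pathlib.Path
) -> MethylationMatrix:
    """Read a beta-value TSV and a probe-annotation TSV.

    The annotation file is keyed by probe ID and must carry a ``promoter``
    column (true/false or 1/0); a ``position`` column is optional.
    """
    betas = _read_numeric_matrix(path)
    betas.index.name = None
    betas.columns.name = None
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    ann.index = ann.index.astype(str)
    if "promoter" not in ann.columns:
        raise ValidationError("annotation file lacks a 'promoter' column")
    promoter = ann["promoter"].str.lower().isin(("true", "1", "yes"))
    annotation = pd.DataFrame(
        {
            "position": ann["position"] if "position" in ann.columns else "unknown",
            "promoter": promoter,
        },
        index=ann.index,
    )
    return MethylationMatrix(betas, annotation)


def read_clinical_table(
    path: str | pathlib.Path, column_map: Mapping[str, Any] | None = None
) -> ClinicalTable:
    """Read a clinical TSV, normalizing categories to canonical vocabularies.

    ``column_map`` names the source columns and (optionally) the value
    encodings::

        {"sample_id": "sampleID", "er_status": "ER_Status_nature2012",
         "pam50": "PAM50", "os_months": "OS.time", "os_event": "OS",
         "er_values": {...}, "pam50_values": {...}, "event_values": {...}}

    Unmappable categorical values become "unknown" and increment the
    ``n_unmapped`` warning counter; a missing sample-ID column is an error.
    """
    cmap = dict(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = cmap.get("sample_id", "sample_id")
    if id_col not in raw.columns:
        raise ValidationError(f"missing mandatory sample-ID column {id_col!r}")

    er_values = {**DEFAULT_ER_VALUES, **cmap.get("er_values", {})}
    pam50_values = {**DEFAULT_PAM50_VALUES, **cmap.get("pam50_values", {})}
    event_values = {**DEFAULT_EVENT_VALUES, **cmap.get("event_values", {})}

    n_unmapped = 0

    def _map_cat(raw_value: str, mapping: Mapping[str, Any]) -> Any:
        nonlocal n_unmapped
        if raw_value in MISSING_TOKENS:
            return "unknown"
        if raw_value in mapping:
            return mapping[raw_value]
        n_unmapped += 1
        return "unknown"

    def _col(key: str, default: str) -> pd.Series:
        name = cmap.get(key, default)
        if name not in raw.columns:
            return pd.Series([""] * len(raw), index=raw.index, dtype=str)
        return raw[name]

    er = _col("er_status", "er_status").map(lambda v: _map_cat(v, er_values))
    pam50 = _col("pam50", "pam50").map(lambda v: _map_cat(v, pam50_values))

    months_raw = _col("os_months", "os_months")
    months = pd.to_numeric(
        months_raw.where(~months_raw.isin(MISSING_TOKENS), other=np.nan),
        errors="coerce",
    )
    bad_months = months.isna() & ~months_raw.isin(MISSING_TOKENS)
    if bad_months.any():
        raise ParseError(
            f"non-numeric os_months value {months_raw[bad_months].iloc[0]!r}"
        )

    event_raw = _col("os_event", "os_event")
    event = event_raw.map(
        lambda v: np.nan if v in MISSING_TOKENS else _map_cat_event(v, event_values)
    )

    data = pd.DataFrame(
        {
            "er_status": er.to_numpy(),
            "pam50": pam50.to_numpy(),
            "os_months": months.to_numpy(dtype=float),
            "os_event": event.to_numpy(dtype=object),
        },
        index=pd.Index(raw[id_col].astype(str), name="sample_id"),
    )
    if n_unmapped:
        logger.warning("clinical read: %d value(s) fell back to 'unknown'", n_unmapped)
    return ClinicalTable(data, n_unmapped=n_unmapped)


def _map_cat_event(value: str, mapping: Mapping[str, bool]) -> Any:
    if value in mapping:
        return bool(mapping[value])
    raise ParseError(f"unmappable survival-event value {value!r}")


# ---------------------------------------------------------------------------
# harmonization and writing


def harmonize_cohort(
    expr: ExpressionMatrix, meth: MethylationMatrix, clin: ClinicalTable
) -> Cohort:
    """Restrict all three components to their shared samples, sorted.

    The shared axis is the lexicographically sorted intersection of the three
    sample-ID sets; per-component drop counts are recorded on the Cohort.
    """
    shared = sorted(
        set(expr.sample_ids) & set(meth.sample_ids) & set(clin.sample_ids)
    )
    if not shared:
        raise ValidationError("no samples shared by expression, methylation and clinical")
    dropped = {
        "expression": len(expr.sample_ids) - len(shared),
        "methylation": len(meth.sample_ids) - len(shared),
        "clinical": len(clin.sample_ids) - len(shared),
    }
    if any(dropped.values()):
        logger.info("harmonize_cohort dropped samples: %s", dropped)
    return Cohort(
        expression=expr.subset_samples(shared),
        methylation=meth.subset_samples(shared),
        clinical=clin.subset_samples(shared),
        dropped=dropped,
    )


def write_matrix(values: pd.DataFrame, path: str | pathlib.Path,
                 index_label: str = "id") -> None:
    """Write a matrix TSV at full float precision; missing cells become NA."""
    values.to_csv(path, sep="\t", na_rep="NA", index_label=index_label,
                  float_format="%.17g")


def write_results_table(
    records: Iterable[Any],
    path: str | pathlib.Path,
    sort_by: Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write a list of result dataclasses (or dicts) as a deterministic TSV.

    Column order follows the record schema; rows are stably sorted by
    ``sort_by`` when given.  Re-reading the file reproduces the values to full
    float precision.  An empty record list yields a header-only file
    (``columns`` supplies the schema in that case).
    """
    rows = list(records)
    if rows and dataclasses.is_dataclass(rows[0]):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    else:
        frame = pd.DataFrame(rows, columns=list(columns) if columns else None)
    if sort_by and len(frame):
        frame = frame.sort_values(list(sort_by), kind="stable")
    frame.to_csv(path, sep="\t", na_rep="NA", index=False, float_format="%.17g")
    return frame
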