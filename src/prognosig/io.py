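"""Expression-matrix and annotation I/O, normalization, and paired log-ratios.

The on-disk dialect is fixed so that fixtures round-trip bit-exactly: UTF-8,
tab-delimited, first column the probe identifier, header row of sample
identifiers, ``NA`` for missing values.

Probes carry one of three roles:

``candidate``
    genes screened for differential expression and prognosis association;
``panel``
    auxiliary pathway panels (e.g. collagen or hormone-receptor genes) carried
    on the array but treated like candidates downstream;
``normalization``
    probes assumed non-differential, used to median-center each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

ROLE_CANDIDATE = "candidate"
ROLE_PANEL = "panel"
ROLE_NORMALIZATION = "normalization"
ROLES = (ROLE_CANDIDATE, ROLE_PANEL, ROLE_NORMALIZATION)

SCALE_RAW = "raw_intensity"
SCALE_LOG2 = "log2"
SCALE_LOG2_RATIO = "log2_ratio"
SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_LOG2_RATIO)

LESION_MALIGNANT = "malignant"
LESION_PREMALIGNANT = "premalignant"

#: required columns of a sample annotation table, in canonical order
ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "lesion",
    "stage",
    "pathology",
    "metastasis_5yr",
    "survival_months",
    "event",
    "cohort",
]

NA_TOKEN = "NA"


@dataclass
class ExpressionMatrix:
    """A probes × samples expression matrix with probe roles attached.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with sample IDs as columns.
    probe_roles
        Series mapping probe ID to one of :data:`ROLES`; aligned to
        ``values.index`` on construction (missing probes default to
        ``candidate``).
    scale_tag
        One of :data:`SCALES`, recording what the numbers mean.
    """

    values: pd.DataFrame
    probe_roles: pd.Series
    scale_tag: str = SCALE_LOG2

    def __post_init__(self):
        if self.scale_tag not in SCALES:
            raise DataError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe IDs: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dupes[:5]}")
        roles = self.probe_roles.reindex(idx)
        missing = roles.isna()
        if missing.any():
            logger.warning(
                "%d probes missing from annotation; defaulting their role to 'candidate'",
                int(missing.sum()),
            )
            roles = roles.fillna(ROLE_CANDIDATE)
        bad = ~roles.isin(ROLES)
        if bad.any():
            raise DataError(
                f"invalid probe roles {sorted(roles[bad].unique())}; expected one of {ROLES}"
            )
        self.probe_roles = roles

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probes_with_role(self, *roles: str) -> pd.Index:
        return self.probe_ids[self.probe_roles.isin(roles)]

    def restrict(self, probes=None, samples=None) -> "ExpressionMatrix":
        """Return a sub-matrix restricted to the given probes and/or samples."""
        values = self.values
        if probes is not None:
            missing = pd.Index(probes).difference(values.index)
            if len(missing):
                raise DataError(f"unknown probes requested: {missing[:5].tolist()}")
            values = values.loc[probes]
        if samples is not None:
            missing = pd.Index(samples).difference(values.columns)
            if len(missing):
                raise DataError(f"unknown samples requested: {missing[:5].tolist()}")
            values = values[list(samples)]
        return ExpressionMatrix(values, self.probe_roles, self.scale_tag)


def read_expression(path, probe_annotation_path=None, scale_tag: str = SCALE_LOG2) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix, attaching probe roles.

    The first column is the probe ID, the header row the sample IDs. Cells are
    numeric or ``NA``. Probes absent from the annotation default to role
    ``candidate`` with a logged warning.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if raw.index.has_duplicates:
        for pos, dup in enumerate(raw.index.duplicated()):
            if dup:
                # header is line 1, first data row line 2
                raise ParseError(
                    f"{path}: duplicate probe ID {raw.index[pos]!r} at line {pos + 2}"
                )
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        masked = cell.where(cell != NA_TOKEN)
        try:
            # astype(float) is correctly rounded (unlike pd.to_numeric's fast
            # parser), which keeps the write->read round trip value-identical
            values[col] = masked.astype(float)
        except (ValueError, TypeError):
            for pos, token in enumerate(masked):
                if isinstance(token, str):
                    try:
                        float(token)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric value {token!r} for probe "
                            f"{raw.index[pos]!r}, sample {col!r} (line {pos + 2})"
                        ) from None
            raise
    if probe_annotation_path is not None:
        ann = read_probe_annotation(probe_annotation_path)
        roles = ann["role"]
    else:
        roles = pd.Series(ROLE_CANDIDATE, index=values.index)
    return ExpressionMatrix(values, roles, scale_tag)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the canonical TSV dialect (``NA`` for missing)."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    # %.17g round-trips every float64 exactly: write->read is value-identical
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.17g")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns probe_id, role[, gene_symbol]."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "role"):
        if col not in ann.columns:
            raise ParseError(f"{path}: probe annotation missing column {col!r}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicate probe ID {dup!r} in annotation")
    bad = ~ann["role"].isin(ROLES)
    if bad.any():
        raise ParseError(
            f"{path}: invalid roles {sorted(ann.loc[bad, 'role'].unique())}"
        )
    return ann.set_index("probe_id")


def write_probe_annotation(matrix: ExpressionMatrix, path, gene_symbols=None) -> None:
    ann = pd.DataFrame({"role": matrix.probe_roles})
    ann["gene_symbol"] = "" if gene_symbols is None else pd.Series(gene_symbols)
    ann.index.name = "probe_id"
    ann.to_csv(path, sep="\t")


def read_sample_annotation(path) -> pd.DataFrame:
    """Read and validate a sample annotation TSV (columns as ANNOTATION_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample annotation missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["survival_months"] = pd.to_numeric(df["survival_months"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce").astype("Int64")
    validate_sample_annotation(df)
    return df


def write_sample_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, float_format="%.10g")


def validate_sample_annotation(annotation: pd.DataFrame) -> None:
    """Raise :class:`DataError` if the annotation violates its invariants."""
    if annotation["sample_id"].duplicated().any():
        dup = annotation.loc[annotation["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample ID {dup!r} in sample annotation")
    bad_lesion = ~annotation["lesion"].isin([LESION_MALIGNANT, LESION_PREMALIGNANT])
    if bad_lesion.any():
        raise DataError(
            f"invalid lesion values: {sorted(annotation.loc[bad_lesion, 'lesion'].unique())}"
        )
    if (annotation["survival_months"].dropna() < 0).any():
        raise DataError("survival_months must be nonnegative")
    counts = annotation.groupby(["patient_id", "cohort", "lesion"]).size()
    if (counts > 1).any():
        patient = counts[counts > 1].index[0]
        raise DataError(
            f"patient {patient[0]!r} has more than one {patient[2]} sample in "
            f"cohort {patient[1]!r}"
        )


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize a matrix by median-centering each sample on normalization probes.

    Raw intensities are first log2-transformed (they must be strictly
    positive); matrices already on the log2 scale are only centered, which
    makes the operation idempotent. After normalization each sample's median
    over normalization probes is exactly 0.
    """
    norm_probes = matrix.probes_with_role(ROLE_NORMALIZATION)
    if len(norm_probes) == 0:
        raise DataError("cannot normalize: no probes with role 'normalization'")
    values = matrix.values
    if matrix.scale_tag == SCALE_RAW:
        nonpos = values <= 0
        if nonpos.any().any():
            cells = [
                (probe, sample)
                for probe, row in nonpos.iterrows()
                for sample, flag in row.items()
                if flag
            ]
            raise DataError(
                f"nonpositive raw intensities at {len(cells)} cells, e.g. {cells[:5]}"
            )
        values = np.log2(values)
    elif matrix.scale_tag != SCALE_LOG2:
        raise DataError(f"cannot normalize a matrix with scale_tag {matrix.scale_tag!r}")
    medians = values.loc[norm_probes].median(axis=0, skipna=True)
    centered = values.sub(medians, axis=1)
    return ExpressionMatrix(centered, matrix.probe_roles, SCALE_LOG2)


def paired_log_ratios(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-patient malignant − premalignant log2 differences.

    Returns a patients × probes DataFrame with one row per patient that has
    both lesion samples in ``matrix``; incomplete patients are excluded with a
    logged warning. Raises :class:`DataError` when no complete pair exists.
    """
    if matrix.scale_tag == SCALE_RAW:
        raise DataError("paired_log_ratios requires log2-scale values; normalize first")
    ann = annotation[annotation["sample_id"].isin(matrix.sample_ids)]
    rows = {}
    skipped = []
    for patient, grp in ann.groupby("patient_id", sort=False):
        mal = grp.loc[grp["lesion"] == LESION_MALIGNANT, "sample_id"]
        pre = grp.loc[grp["lesion"] == LESION_PREMALIGNANT, "sample_id"]
        if len(mal) == 1 and len(pre) == 1:
            rows[patient] = matrix.values[mal.iloc[0]] - matrix.values[pre.iloc[0]]
        else:
            skipped.append(patient)
    if skipped:
        logger.warning("excluding %d patients without a complete pair: %s",
                       len(skipped), skipped[:5])
    if not rows:
        raise DataError("no patient has a complete malignant/premalignant pair")
    return pd.DataFrame(rows).T


__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_annotation",
    "write_sample_annotation",
    "validate_sample_annotation",
    "normalize",
    "paired_log_ratios",
    "ROLE_CANDIDATE",
    "ROLE_PANEL",
    "ROLE_NORMALIZATION",
    "SCALE_RAW",
    "SCALE_LOG2",
    "SCALE_LOG2_RATIO",
    "ANNOTATION_COLUMNS",
    "LESION_MALIGNANT",
    "LESION_PREMALIGNANT",
]
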