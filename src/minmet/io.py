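"""Domain types and tabular readers/writers shared by all pipeline stages.

The pipeline works on four kinds of input: a metabolite x sample intensity
matrix (TSV, missing cells marked with a token), a sample sheet giving the
2x2 factorial design with repeated tissue measures, per-mouse polyp counts,
and GMT-format compound sets for enrichment.  All files are UTF-8,
tab-delimited, with mandatory header rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "MU")
DIETS = ("LF", "HF")
TISSUES = ("PLA", "LIV")

#: Annotation columns recognised in intensity TSVs and carried through to
#: results tables.  Unannotated metabolites carry empty strings.
ANNOTATION_COLUMNS = ("name", "HMDB", "CAS", "KEGG")


class MinmetError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MinmetError):
    """A file could not be parsed (malformed/ragged rows, bad GMT lines)."""


class ValidationError(MinmetError):
    """Input violated a domain invariant (bad factor level, duplicate ID...)."""


@dataclass
class IntensityMatrix:
    """Metabolite x sample intensity matrix with an explicit missingness mask.

    Parameters
    ----------
    values
        Real matrix of shape (p metabolites, n samples).  Cells where
        ``missing_mask`` is True are ignored by every statistic.
    missing_mask
        Boolean matrix, same shape; True marks an unobserved cell.
    metabolite_ids, sample_ids
        Unique row / column labels.
    annotations
        Optional per-metabolite frame with columns ``name, HMDB, CAS, KEGG``
        indexed like ``metabolite_ids``; missing entries are empty strings.
    scale_tag
        One of ``raw`` (strictly positive observed intensities), ``log2``,
        or ``regularized`` (variance-stabilised; may be negative).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    metabolite_ids: list[str]
    sample_ids: list[str]
    annotations: pd.DataFrame | None = None
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and missing_mask shapes differ")
        p, n = self.values.shape
        if len(self.metabolite_ids) != p or len(self.sample_ids) != n:
            raise ValidationError("row/column labels do not match matrix shape")
        if len(set(self.metabolite_ids)) != p:
            dupes = sorted(
                m for m in set(self.metabolite_ids)
                if self.metabolite_ids.count(m) > 1
            )
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if self.scale_tag not in ("raw", "log2", "regularized"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "raw":
            observed = self.values[~self.missing_mask]
            if observed.size and not np.all(observed > 0):
                raise ValidationError("raw-scale observed values must be positive")

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ma.MaskedArray:
        """Masked-array view with missing cells masked out."""
        return np.ma.masked_array(self.values, mask=self.missing_mask)

    def subset_metabolites(self, ids: list[str]) -> "IntensityMatrix":
        index = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows = [index[m] for m in ids]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[ids]
        return IntensityMatrix(
            self.values[rows], self.missing_mask[rows], list(ids),
            list(self.sample_ids), ann, self.scale_tag,
        )

    def subset_samples(self, ids: list[str]) -> "IntensityMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in ids]
        return IntensityMatrix(
            self.values[:, cols], self.missing_mask[:, cols],
            list(self.metabolite_ids), list(ids), self.annotations,
            self.scale_tag,
        )

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations aligned to metabolite order (empty strings if absent)."""
        if self.annotations is None:
            return pd.DataFrame(
                "", index=pd.Index(self.metabolite_ids),
                columns=list(ANNOTATION_COLUMNS),
            )
        out = self.annotations.reindex(self.metabolite_ids)
        for col in ANNOTATION_COLUMNS:
            if col not in out.columns:
                out[col] = ""
        return out[list(ANNOTATION_COLUMNS)].fillna("")


@dataclass
class StudyDesign:
    """Per-sample factor labels for the 2x2 factorial with repeated tissues."""

    sample_ids: list[str]
    mouse_id: list[str]
    genotype: list[str]
    diet: list[str]
    tissue: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("mouse_id", "genotype", "diet", "tissue"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name} has wrong length")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in design")
        for value in self.genotype:
            if value not in GENOTYPES:
                raise ValidationError(f"unknown genotype level {value!r}")
        for value in self.diet:
            if value not in DIETS:
                raise ValidationError(f"unknown diet level {value!r}")
        for value in self.tissue:
            if value not in TISSUES:
                raise ValidationError(f"unknown tissue level {value!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mouse_id": self.mouse_id,
                "genotype": self.genotype,
                "diet": self.diet,
                "tissue": self.tissue,
            }
        )

    def subset_tissue(self, tissue: str) -> "StudyDesign":
        if tissue not in TISSUES:
            raise ValidationError(f"unknown tissue level {tissue!r}")
        keep = [i for i, t in enumerate(self.tissue) if t == tissue]
        return StudyDesign(
            [self.sample_ids[i] for i in keep],
            [self.mouse_id[i] for i in keep],
            [self.genotype[i] for i in keep],
            [self.diet[i] for i in keep],
            [self.tissue[i] for i in keep],
        )

    def group_labels(self) -> list[str]:
        """Genotype-diet cell label per sample, e.g. ``WT-LF``."""
        return [f"{g}-{d}" for g, d in zip(self.genotype, self.diet)]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.group_labels():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes


@dataclass
class PolypCounts:
    """Non-negative integer polyp count per mouse (one record per mouse)."""

    mouse_id: list[str]
    count: np.ndarray

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count)
        if len(self.mouse_id) != self.count.shape[0]:
            raise ValidationError("mouse_id and count lengths differ")
        if len(set(self.mouse_id)) != len(self.mouse_id):
            raise ValidationError("duplicate mouse ids in polyp counts")
        if not np.issubdtype(self.count.dtype, np.integer):
            as_float = np.asarray(self.count, dtype=float)
            if not np.all(as_float == np.round(as_float)):
                raise ValidationError("polyp counts must be integers")
            self.count = as_float.astype(int)
        if np.any(self.count < 0):
            raise ValidationError("polyp counts must be >= 0")

    def aligned_to(self, mouse_ids: list[str]) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.mouse_id)}
        missing = [m for m in mouse_ids if m not in index]
        if missing:
            raise ValidationError(f"no polyp count for mice: {missing}")
        return self.count[[index[m] for m in mouse_ids]]


class EffectTable:
    """Per-metabolite effect statistics for one named contrast.

    Wraps a DataFrame with columns ``metabolite_id, logFC, t, B, p_raw,
    p_adj`` plus annotation passthrough, kept sorted by (p_adj ascending,
    B descending) — the ranking convention used for reporting.
    """

    COLUMNS = ("metabolite_id", "logFC", "t", "B", "p_raw", "p_adj")

    def __init__(self, frame: pd.DataFrame, contrast: str = ""):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"EffectTable missing columns {missing}")
        for col in ("p_raw", "p_adj"):
            p = frame[col].to_numpy(dtype=float)
            if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
                raise ValidationError(f"{col} outside [0, 1]")
        self.contrast = contrast
        self.frame = (
            frame.sort_values(["p_adj", "B"], ascending=[True, False])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["p_adj"] <= threshold]


@dataclass(frozen=True)
class CompoundSet:
    """Named set of compound identifiers over a declared universe."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"compound set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def read_intensity_matrix(path, missing_token: str = "NA",
                          scale_tag: str = "raw") -> IntensityMatrix:
    """Read a metabolite x sample TSV into an :class:`IntensityMatrix`.

    The first column holds metabolite ids; remaining columns are samples
    except for any annotation columns named ``name``/``HMDB``/``CAS``/``KEGG``.
    Cells equal to ``missing_token`` become masked.  Ragged rows raise
    :class:`ParseError` naming the offending line; duplicate metabolite ids
    raise :class:`ValidationError`.  ``scale_tag`` declares the scale of the
    stored values ("raw" enforces positivity; use "log2"/"regularized" for
    transformed matrices, which may hold negative values).
    """
    with open(path, encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_fields = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
            )
        rows.append(fields)
    frame = pd.DataFrame(rows, columns=header)
    id_col = header[0]
    metabolite_ids = frame[id_col].tolist()
    if len(set(metabolite_ids)) != len(metabolite_ids):
        dupes = sorted({m for m in metabolite_ids if metabolite_ids.count(m) > 1})
        raise ValidationError(f"{path}: duplicate metabolite ids {dupes}")
    ann_cols = [c for c in header[1:] if c in ANNOTATION_COLUMNS]
    sample_cols = [c for c in header[1:] if c not in ANNOTATION_COLUMNS]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns found")
    raw = frame[sample_cols]
    mask = raw.eq(missing_token).to_numpy()
    values = np.full(mask.shape, np.nan)
    try:
        numeric = raw.where(~pd.DataFrame(mask, columns=sample_cols)).astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric intensity cell ({exc})") from exc
    values = numeric.to_numpy()
    values[mask] = np.nan
    annotations = None
    if ann_cols:
        annotations = frame[ann_cols].copy()
        annotations.index = pd.Index(metabolite_ids)
    return IntensityMatrix(
        values=np.where(mask, 1.0, values),  # placeholder under the mask
        missing_mask=mask,
        metabolite_ids=metabolite_ids,
        sample_ids=sample_cols,
        annotations=annotations,
        scale_tag=scale_tag,
    )


def write_intensity_matrix(matrix: IntensityMatrix, path,
                           missing_token: str = "NA") -> None:
    """Write an intensity matrix back to TSV (inverse of the reader)."""
    frame = pd.DataFrame(
        matrix.values, index=matrix.metabolite_ids, columns=matrix.sample_ids
    )
    out = frame.astype(object)
    out[pd.DataFrame(matrix.missing_mask, index=frame.index,
                     columns=frame.columns)] = missing_token
    if matrix.annotations is not None:
        for col in reversed(matrix.annotations.columns):
            out.insert(0, col, matrix.annotations[col])
    out.index.name = "metabolite_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> StudyDesign:
    """Read the sample sheet (sample_id, mouse_id, genotype, diet, tissue)."""
    frame = _read_tsv(path)
    if frame.empty:
        raise ValidationError(f"{path}: empty sample sheet")
    required = ["sample_id", "mouse_id", "genotype", "diet", "tissue"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return StudyDesign(
        frame["sample_id"].tolist(),
        frame["mouse_id"].tolist(),
        frame["genotype"].tolist(),
        frame["diet"].tolist(),
        frame["tissue"].tolist(),
    )


def write_sample_sheet(design: StudyDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_polyp_counts(path) -> PolypCounts:
    """Read per-mouse polyp counts (columns mouse_id, count)."""
    frame = _read_tsv(path)
    if frame.empty:
        raise ValidationError(f"{path}: empty polyp count table")
    for col in ("mouse_id", "count"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    counts = []
    for value in frame["count"]:
        try:
            as_float = float(value)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric count {value!r}") from exc
        if as_float != round(as_float):
            raise ValidationError(f"{path}: non-integer count {value!r}")
        if as_float < 0:
            raise ValidationError(f"{path}: negative count {value!r}")
        counts.append(int(as_float))
    return PolypCounts(frame["mouse_id"].tolist(), np.array(counts))


def write_polyp_counts(counts: PolypCounts, path) -> None:
    pd.DataFrame({"mouse_id": counts.mouse_id, "count": counts.count}).to_csv(
        path, sep="\t", index=False
    )


def read_compound_sets(path) -> list[CompoundSet]:
    """Read GMT-format compound sets (name, description, members...)."""
    sets = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    "expected name, description and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m.strip() != ""]
            if not members:
                raise ParseError(f"{path}: line {lineno} has no members")
            sets.append(CompoundSet(name, description, frozenset(members)))
    return sets


def write_compound_sets(sets: list[CompoundSet], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for cs in sets:
            handle.write(
                "\t".join([cs.name, cs.description, *sorted(cs.members)]) + "\n"
            )


def write_results_table(table: EffectTable, path) -> None:
    """Write an effect table as TSV in the standard report shape.

    Columns: Metabolite, HMDB, CAS, KEGG, logFC, t, B, p.val, Adj.p.val,
    with numbers in scientific notation at 4 significant digits.
    """
    frame = table.frame
    out = pd.DataFrame({"Metabolite": frame["metabolite_id"]})
    for col in ("HMDB", "CAS", "KEGG"):
        out[col] = frame[col] if col in frame.columns else ""
    for src, dst in (("logFC", "logFC"), ("t", "t"), ("B", "B"),
                     ("p_raw", "p.val"), ("p_adj", "Adj.p.val")):
        out[dst] = [
            "" if pd.isna(v) else f"{v:.3E}" for v in frame[src]
        ]
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in ("logFC", "t", "B", "p.val", "Adj.p.val"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame
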