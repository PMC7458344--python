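"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are plain text (TSV/CSV, GMT).  The canonical in-memory
orientation is genes-in-rows for expression and cell-types-in-rows for
deconvolution output, matching how deconvolution tools print their results.
Identifiers are case-sensitive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: transform tags an ExpressionMatrix may carry
TRANSFORMS = ("tpm", "log2p1", "normalized_log")

#: diagnostic rows/columns commonly appended by deconvolution tools; dropped
#: (with a log entry) when reading their output.
DECONV_DIAGNOSTIC_FIELDS = frozenset(
    {
        "P-value",
        "P.value",
        "Pvalue",
        "Correlation",
        "RMSE",
        "Absolute score (sig.score)",
        "ImmuneScore",
        "StromaScore",
        "MicroenvironmentScore",
    }
)


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a transform tag.

    ``values`` has unique gene identifiers as the index and unique sample
    identifiers as columns.  ``transform`` records the scale: raw ``tpm``
    (non-negative), ``log2p1`` (log2(TPM+1)) or ``normalized_log`` for
    externally normalized log-scale data.
    """

    values: pd.DataFrame
    transform: str = "tpm"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform tag {self.transform!r}; expected one of {TRANSFORMS}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.transform == "tpm" and (self.values.to_numpy() < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ValueError(f"negative TPM value in gene {bad!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class IHCRecord:
    """One patient's quantitative immunohistology and outcome.

    Densities are marker-positive cells per mm^2 tissue; ``None`` means the
    stain was missing for that patient.  ``time`` is overall survival in
    months and ``event`` is True when death was observed.
    """

    patient: str
    cd3: Optional[float]
    cd8: Optional[float]
    cd68: Optional[float]
    time: float
    event: bool
    pathology: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("cd3", "cd8", "cd68"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"patient {self.patient}: negative {name} density {v}")
        if self.time < 0:
            raise ValueError(f"patient {self.patient}: negative survival time {self.time}")


@dataclass
class DeconvolutionResult:
    """Cell type x sample score matrix from a deconvolution method.

    ``semantics`` distinguishes proportion-type output (``fraction``, scores
    in [0, 1]), enrichment-type output, and anything else (``arbitrary``).
    """

    scores: pd.DataFrame
    method: str
    semantics: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.semantics not in ("fraction", "enrichment", "arbitrary"):
            raise ValueError(f"unknown score semantics {self.semantics!r}")
        _check_unique(self.scores.index, "cell type")
        _check_unique(self.scores.columns, "sample")
        self.scores.index.name = "cell_type"
        self.scores.columns.name = None
        if self.semantics == "fraction":
            arr = self.scores.to_numpy()
            if ((arr < 0) | (arr > 1)).any():
                r, c = np.argwhere((arr < 0) | (arr > 1))[0]
                raise ValueError(
                    f"fraction semantics but score {arr[r, c]} outside [0,1] at "
                    f"({self.scores.index[r]!r}, {self.scores.columns[c]!r})"
                )

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.index


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene identifiers (GMT content)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()]))
        raise FormatError(f"duplicate {what} identifiers: {dups}")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix into canonical genes-in-rows form.

    Parameters
    ----------
    path:
        Tab- or comma-separated file with one header row and one leading
        identifier column.
    orientation:
        ``genes_in_rows`` (default) or ``samples_in_rows``; the latter is
        transposed on read.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    _check_unique(df.index, "row")
    _check_unique(pd.Index(df.columns), "column")
    non_numeric = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if non_numeric.to_numpy().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        # +2: header line plus 1-based counting
        raise FormatError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r} "
            f"column {df.columns[c]!r} (line {r + 2})"
        )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(f"missing value at row {df.index[r]!r} column {df.columns[c]!r} (line {r + 2})")
    if orientation == "samples_in_rows":
        df = df.T
    return ExpressionMatrix(df.astype(float), transform="tpm")


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write genes-in-rows TSV/CSV at full float precision (round-trip safe)."""
    path = Path(path)
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene", float_format=None, lineterminator="\n")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(TPM + 1) copy of a raw-TPM matrix.

    Refuses already-transformed input so values are never double-logged.
    """
    if expr.transform != "tpm":
        raise ValueError(f"log_transform expects raw TPM input, got transform={expr.transform!r}")
    return ExpressionMatrix(np.log2(expr.values + 1.0), transform="log2p1")


_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no"}


def _parse_density(raw, patient: str, col: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() in ("", "NA"):
        return None
    v = float(raw)
    if v < 0:
        raise FormatError(f"patient {patient}: negative {col} density {v}")
    return v


def read_ihc(path) -> list[IHCRecord]:
    """Read the per-patient IHC table (CSV or TSV).

    Required columns: patient, cd3, cd8, cd68, time, event; ``pathology`` is
    optional.  Empty or ``NA`` density cells become missing values, never
    zero.  The event column must be boolean-codable (0/1/true/false).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"patient", "cd3", "cd8", "cd68", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"IHC table missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        patient = str(row["patient"])
        ev_raw = str(row["event"]).strip()
        if ev_raw in _TRUE:
            event = True
        elif ev_raw in _FALSE:
            event = False
        else:
            raise FormatError(f"patient {patient}: event value {ev_raw!r} is not boolean-codable")
        time = float(row["time"])
        if time < 0:
            raise FormatError(f"patient {patient}: negative survival time {time}")
        records.append(
            IHCRecord(
                patient=patient,
                cd3=_parse_density(row["cd3"], patient, "cd3"),
                cd8=_parse_density(row["cd8"], patient, "cd8"),
                cd68=_parse_density(row["cd68"], patient, "cd68"),
                time=time,
                event=event,
                pathology=(str(row["pathology"]) if "pathology" in df.columns and pd.notna(row["pathology"]) else None),
            )
        )
    return records


def write_ihc(records: Sequence[IHCRecord], path) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "patient": r.patient,
                "cd3": "" if r.cd3 is None else repr(r.cd3),
                "cd8": "" if r.cd8 is None else repr(r.cd8),
                "cd68": "" if r.cd68 is None else repr(r.cd68),
                "time": repr(r.time),
                "event": int(r.event),
                "pathology": r.pathology or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def ihc_frame(records: Sequence[IHCRecord]) -> pd.DataFrame:
    """Tabular view of IHC records, indexed by patient (missing -> NaN)."""
    return pd.DataFrame(
        {
            "cd3": [np.nan if r.cd3 is None else r.cd3 for r in records],
            "cd8": [np.nan if r.cd8 is None else r.cd8 for r in records],
            "cd68": [np.nan if r.cd68 is None else r.cd68 for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "pathology": [r.pathology for r in records],
        },
        index=pd.Index([r.patient for r in records], name="patient"),
    )


def read_deconvolution(path, method: str, semantics: str = "arbitrary", samples: Optional[Sequence[str]] = None) -> DeconvolutionResult:
    """Read a deconvolution score matrix into cell-types-in-rows form.

    Orientation is auto-detected when ``samples`` is supplied: whichever axis
    matches the known sample identifiers becomes the columns.  Diagnostic
    fields that tools append (p-value, correlation, RMSE, composite scores)
    are dropped by name allowlist, with a log entry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if samples is not None:
        sset = set(map(str, samples))
        col_hits = len(sset.intersection(map(str, df.columns)))
        row_hits = len(sset.intersection(df.index))
        if row_hits > col_hits:
            df = df.T
    dropped = [n for n in df.index if n in DECONV_DIAGNOSTIC_FIELDS]
    if dropped:
        logger.info("dropping diagnostic rows from %s: %s", path.name, dropped)
        df = df.drop(index=dropped)
    return DeconvolutionResult(df.astype(float), method=method, semantics=semantics)


def write_deconvolution(decon: DeconvolutionResult, path) -> None:
    path = Path(path)
    decon.scores.to_csv(path, sep=_sep_for(path), index_label="cell_type", lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then tab-separated genes.

    Descriptions are discarded; genes are de-duplicated within a set.  Empty
    sets and duplicated set names are hard errors.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = frozenset(g for g in parts[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.sets.items():
            fh.write(name + "\t\t" + "\t".join(sorted(genes)) + "\n")


def load_tcell_signature_fixture() -> tuple[ExpressionMatrix, pd.Series]:
    """Load the packaged 38-gene x 28-patient T-cell-infiltration table.

    Returns the normalized log-scale expression matrix of the genes found to
    separate highly from poorly T-cell-infiltrated pancreatic tumors,
    together with the per-sample HI/LOW class labels (15 HI, 13 LOW).  Values
    are stored verbatim as printed (two decimals); statistical tests operate
    on them directly.
    """
    pkg = resources.files("immunoconcord.data")
    with resources.as_file(pkg / "tcell_signature_expression.tsv") as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    with resources.as_file(pkg / "tcell_signature_classes.tsv") as p:
        classes = pd.read_csv(p, sep="\t", index_col=0)["class"]
    expr = ExpressionMatrix(df.astype(float), transform="normalized_log")
    return expr, classes.reindex(expr.samples)
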