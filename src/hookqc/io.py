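"""Flat-text formats for probe-level chip data, sample metadata, expression
matrices and QC reports.

All tables are UTF-8, tab-separated, with a mandatory header row; lines
starting with ``#`` are ignored.  Intensities are written with 17 significant
digits so that a write/read roundtrip is the identity on all fields.

The central in-memory container is :class:`ChipData`: one hybridized sample's
probe-level perfect-match (PM) and optional mismatch (MM) intensities together
with the 25-mer probe sequences and the probe-set structure of a 3'-expression
array.  Probe sets group the (typically 11) probes interrogating one
transcript; ``probe_index`` counts probes from the 3' end of the transcript
(1 = closest to the 3' end), which is the direction in which in-vitro
transcription labelling starts and hence the reference frame for degradation
analysis.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from functools import cached_property
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError, InsufficientDataError

BASES = "ACGT"
PROBE_LENGTH = 25
PROBE_COLUMNS = ("probe_id", "probeset_id", "probe_index", "sequence", "pm")
QC_REPORT_COLUMNS = (
    "sample_id", "d_index", "lambda", "beta", "log_kdiff", "d_ggg",
    "n_expressed", "flags",
)

_BASE_TO_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_CODE[ord(_b)] = _i

_FLOAT_FMT = "%.17g"


def encode_sequences(sequences: Sequence[str] | np.ndarray) -> np.ndarray:
    """Map an array of equal-length ACGT strings to a (n, L) uint8 code array
    (A=0, C=1, G=2, T=3).  Raises ValidationError on bad length/alphabet."""
    arr = np.asarray(sequences, dtype="U")
    if arr.size == 0:
        return np.empty((0, PROBE_LENGTH), dtype=np.uint8)
    length = arr.dtype.itemsize // 4
    bytes_view = arr.view(np.uint32).reshape(arr.size, length)
    lengths = (bytes_view != 0).sum(axis=1)
    bad = np.nonzero(lengths != PROBE_LENGTH)[0]
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"row {row + 1}: sequence {arr[row]!r} has length "
            f"{int(lengths[row])}, expected {PROBE_LENGTH}"
        )
    trimmed = bytes_view[:, :PROBE_LENGTH]
    if trimmed.max(initial=0) > 127:
        row = int(np.nonzero((trimmed > 127).any(axis=1))[0][0])
        raise ValidationError(f"row {row + 1}: sequence contains a non-ACGT character")
    codes = _BASE_TO_CODE[trimmed]
    bad = np.nonzero((codes == 255).any(axis=1))[0]
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"row {row + 1}: sequence {arr[row]!r} contains a character "
            f"outside {{A,C,G,T}}"
        )
    return codes


def decode_sequences(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_sequences`."""
    chars = np.array(list(BASES), dtype="U1")[codes]
    return np.ascontiguousarray(chars).view(f"U{codes.shape[1]}").ravel()


@dataclasses.dataclass(frozen=True)
class ProbeRecord:
    """A single probe of one hybridized sample."""

    probe_id: str
    probeset_id: str
    probe_index: int
    sequence: str
    pm: float
    mm: float | None = None


@dataclasses.dataclass
class ChipData:
    """Probe-level data of one hybridized sample (column-oriented).

    Fields are parallel arrays over probes, in file/creation order.
    """

    sample_id: str
    probe_id: np.ndarray
    probeset_id: np.ndarray
    probe_index: np.ndarray
    sequence: np.ndarray
    pm: np.ndarray
    mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.probeset_id = np.asarray(self.probeset_id, dtype=object)
        self.probe_index = np.asarray(self.probe_index, dtype=np.int64)
        self.sequence = np.asarray(self.sequence, dtype="U")
        self.pm = np.asarray(self.pm, dtype=float)
        if self.mm is not None:
            self.mm = np.asarray(self.mm, dtype=float)
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.pm.shape[0]

    @property
    def has_mm(self) -> bool:
        return self.mm is not None

    @cached_property
    def codes(self) -> np.ndarray:
        """(n_probes, 25) uint8 base codes of the PM sequences."""
        return encode_sequences(self.sequence)

    @cached_property
    def set_codes(self) -> np.ndarray:
        """Integer probe-set labels in order of first appearance."""
        codes, _ = pd.factorize(self.probeset_id)
        return codes

    @cached_property
    def set_ids(self) -> np.ndarray:
        _, uniques = pd.factorize(self.probeset_id)
        return np.asarray(uniques, dtype=object)

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    @cached_property
    def set_sizes(self) -> np.ndarray:
        return np.bincount(self.set_codes, minlength=self.n_sets)

    def validate(self) -> None:
        n = self.pm.shape[0]
        for name in ("probe_id", "probeset_id", "probe_index", "sequence"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"column {name!r} length differs from pm")
        if self.mm is not None and self.mm.shape[0] != n:
            raise ValidationError("column 'mm' length differs from pm")
        encode_sequences(self.sequence)
        bad = np.nonzero(~(self.pm > 0))[0]
        if bad.size:
            raise ValidationError(
                f"row {int(bad[0]) + 1}: pm intensity must be > 0, "
                f"got {self.pm[bad[0]]!r}"
            )
        if self.mm is not None:
            bad = np.nonzero(~(self.mm > 0))[0]
            if bad.size:
                raise ValidationError(
                    f"row {int(bad[0]) + 1}: mm intensity must be > 0, "
                    f"got {self.mm[bad[0]]!r}"
                )
        # distinct probe_index within each probe set
        df = pd.DataFrame({"set": self.probeset_id, "idx": self.probe_index})
        dup = df.duplicated()
        if dup.any():
            row = int(np.nonzero(dup.to_numpy())[0][0])
            raise ValidationError(
                f"row {row + 1}: duplicate probe_index "
                f"{int(self.probe_index[row])} within probe set "
                f"{self.probeset_id[row]!r}"
            )
        if (self.probe_index < 1).any():
            row = int(np.nonzero(self.probe_index < 1)[0][0])
            raise ValidationError(f"row {row + 1}: probe_index must be >= 1")

    def probes(self) -> Iterator[ProbeRecord]:
        mm = self.mm
        for i in range(self.n_probes):
            yield ProbeRecord(
                probe_id=str(self.probe_id[i]),
                probeset_id=str(self.probeset_id[i]),
                probe_index=int(self.probe_index[i]),
                sequence=str(self.sequence[i]),
                pm=float(self.pm[i]),
                mm=float(mm[i]) if mm is not None else None,
            )

    @cached_property
    def normalized_position(self) -> np.ndarray:
        """Per-probe position x in [0, 1]: 0 at the 3'-proximal probe of its
        set, 1 at the 5'-most.  Sets with a single probe get x = 0."""
        sizes = self.set_sizes[self.set_codes].astype(float)
        denom = np.maximum(sizes - 1.0, 1.0)
        return (self.probe_index - 1.0) / denom


def require_minimum_sets(chip: ChipData, min_sets: int = 200,
                         min_probes_per_set: int = 3) -> None:
    """Refuse chips too small for chip-level parameter estimation."""
    if chip.n_sets < min_sets:
        raise InsufficientDataError(
            f"chip {chip.sample_id!r} has {chip.n_sets} probe sets; "
            f"at least {min_sets} required"
        )
    small = np.nonzero(chip.set_sizes < min_probes_per_set)[0]
    if small.size:
        raise InsufficientDataError(
            f"chip {chip.sample_id!r}: probe set {chip.set_ids[small[0]]!r} "
            f"has {int(chip.set_sizes[small[0]])} probes; at least "
            f"{min_probes_per_set} required"
        )


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    experiment_id: str
    scan_date: _dt.date
    qc_label: str | None = None
    biological_group: str | None = None


@dataclasses.dataclass
class ExpressionMatrix:
    """Dense features x samples matrix of log10-scale expression values."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} inconsistent "
                f"with {len(self.feature_ids)} features x "
                f"{len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def _to_float(column: pd.Series, name: str, require_positive: bool = True) -> np.ndarray:
    try:
        # numpy's parser is correctly rounded (pandas' fast path is not),
        # which the 1e-12 roundtrip guarantee relies on
        values = column.to_numpy(dtype="U").astype(float)
    except ValueError:
        coerced = pd.to_numeric(column, errors="coerce").to_numpy(dtype=float)
        bad = int(np.nonzero(~np.isfinite(coerced))[0][0])
        raise ValidationError(
            f"row {bad + 1}: column {name!r} value "
            f"{column.iloc[bad]!r} is not numeric"
        ) from None
    bad = np.nonzero(~np.isfinite(values))[0]
    if bad.size:
        raise ValidationError(
            f"row {int(bad[0]) + 1}: column {name!r} value "
            f"{column.iloc[bad[0]]!r} is not numeric"
        )
    if require_positive:
        bad = np.nonzero(~(values > 0))[0]
        if bad.size:
            raise ValidationError(
                f"row {int(bad[0]) + 1}: column {name!r} must be > 0, "
                f"got {values[bad[0]]!r}"
            )
    return values


def read_probe_table(path: str | Path, sample_id: str | None = None) -> ChipData:
    """Read one sample's probe table.

    Columns: probe_id, probeset_id, probe_index, sequence, pm and optionally
    mm.  ``sample_id`` defaults to the file stem (with a trailing ``.probes``
    stripped).
    """
    path = Path(path)
    df = _read_tsv(path)
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    if sample_id is None:
        sample_id = path.stem
        if sample_id.endswith(".probes"):
            sample_id = sample_id[: -len(".probes")]
    idx = pd.to_numeric(df["probe_index"], errors="coerce")
    bad = np.nonzero(~np.isfinite(idx.to_numpy(dtype=float)))[0]
    if bad.size:
        raise ValidationError(
            f"row {int(bad[0]) + 1}: probe_index "
            f"{df['probe_index'].iloc[bad[0]]!r} is not an integer"
        )
    mm = _to_float(df["mm"], "mm") if "mm" in df.columns else None
    return ChipData(
        sample_id=sample_id,
        probe_id=df["probe_id"].to_numpy(dtype=object),
        probeset_id=df["probeset_id"].to_numpy(dtype=object),
        probe_index=idx.to_numpy(dtype=np.int64),
        sequence=df["sequence"].to_numpy(dtype="U"),
        pm=_to_float(df["pm"], "pm"),
        mm=mm,
    )


def write_probe_table(chip: ChipData, path: str | Path) -> None:
    """Write a probe table readable by :func:`read_probe_table` (lossless)."""
    if chip.n_probes == 0:
        raise ValidationError("refusing to write a chip with no probes")
    data = {
        "probe_id": chip.probe_id,
        "probeset_id": chip.probeset_id,
        "probe_index": chip.probe_index,
        "sequence": chip.sequence,
        "pm": chip.pm,
    }
    if chip.has_mm:
        data["mm"] = chip.mm
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    df = _read_tsv(path)
    for col in ("sample_id", "experiment_id", "scan_date"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        sid = str(getattr(row, "sample_id"))
        if sid in seen:
            raise ValidationError(f"row {i + 1}: duplicate sample_id {sid!r}")
        seen.add(sid)
        raw_date = str(getattr(row, "scan_date"))
        try:
            date = _dt.date.fromisoformat(raw_date)
        except ValueError as exc:
            raise ValidationError(
                f"row {i + 1}: scan_date {raw_date!r} is not an ISO 8601 date"
            ) from exc
        qc = getattr(row, "qc_label", "") if "qc_label" in df.columns else ""
        grp = (getattr(row, "biological_group", "")
               if "biological_group" in df.columns else "")
        records.append(SampleMetadata(
            sample_id=sid,
            experiment_id=str(getattr(row, "experiment_id")),
            scan_date=date,
            qc_label=str(qc) or None,
            biological_group=str(grp) or None,
        ))
    return records


def write_sample_metadata(records: Sequence[SampleMetadata],
                          path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "experiment_id": r.experiment_id,
            "scan_date": r.scan_date.isoformat(),
            "qc_label": r.qc_label or "",
            "biological_group": r.biological_group or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(
            f"{Path(path).name}: expected a feature-id column plus at least "
            f"one sample column"
        )
    feature_col = df.columns[0]
    sample_ids = [str(c) for c in df.columns[1:]]
    values = np.empty((df.shape[0], len(sample_ids)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        numeric = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(numeric))[0]
        if bad.size:
            raise ValidationError(
                f"row {int(bad[0]) + 1}, column {col!r}: value "
                f"{df[col].iloc[bad[0]]!r} is missing or non-numeric"
            )
        values[:, j] = numeric
    return ExpressionMatrix(
        feature_ids=[str(f) for f in df[feature_col]],
        sample_ids=sample_ids,
        values=values,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# QC reports
# ---------------------------------------------------------------------------

def _fmt_opt(value: float | None) -> str:
    return "NA" if value is None else _FLOAT_FMT % value


def write_qc_report(metrics: Sequence, path: str | Path) -> None:
    """Write per-sample quality metrics (see ``hookqc.metrics.QualityMetrics``)
    as a TSV.  Undefined metrics are written as ``NA``; flags are
    semicolon-joined."""
    if not metrics:
        raise ValidationError("refusing to write an empty QC report")
    rows = []
    for m in metrics:
        rows.append({
            "sample_id": m.sample_id,
            "d_index": _fmt_opt(m.d_index),
            "lambda": _fmt_opt(m.lambda_),
            "beta": _fmt_opt(m.beta),
            "log_kdiff": _fmt_opt(m.log_kdiff),
            "d_ggg": _fmt_opt(m.d_ggg),
            "n_expressed": "NA" if m.n_expressed is None else int(m.n_expressed),
            "flags": ";".join(m.flags),
        })
    pd.DataFrame(rows, columns=list(QC_REPORT_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_qc_report(path: str | Path) -> pd.DataFrame:
    """Read a QC report into a DataFrame; ``NA`` becomes NaN in the numeric
    columns and flags stay a semicolon-joined string."""
    df = _read_tsv(path)
    for col in QC_REPORT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    for col in ("d_index", "lambda", "beta", "log_kdiff", "d_ggg",
                "n_expressed"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "NA"), errors="raise")
    return df
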