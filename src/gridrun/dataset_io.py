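"""Tabular dataset I/O: ARFF (dense and sparse), CSV, synthetic fixtures.

Datasets are stored column-wise: numeric attributes as float64 arrays with
NaN marking missing cells, nominal attributes as integer level codes with
-1 marking missing.  The class attribute must be nominal (these are
classification experiments).  Column storage keeps very wide matrices
(tens of thousands of attributes, few samples) cheap to slice for
cross-validation.

ARFF conventions honoured here:

* ``?`` is the missing marker in both dialects;
* sparse rows ``{index value, ...}`` use 0-based attribute indices, and an
  omitted position means the attribute's zero element — 0 for numerics and
  the *first declared level* for nominals.  Reordering nominal levels in a
  schema therefore silently changes what sparse data means; keep level
  order stable.
* ``string``, ``date`` and relational attributes are rejected with a clear
  error rather than coerced.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttributeSchema",
    "Dataset",
    "DatasetError",
    "FormatError",
    "DataError",
    "read_arff",
    "write_arff",
    "read_csv",
    "write_csv",
    "load_dataset",
    "make_synthetic",
]

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class DatasetError(Exception):
    """Base class for dataset errors."""


class FormatError(DatasetError):
    """Structural problem with an input file (header, ragged rows, ...)."""


class DataError(DatasetError):
    """Bad value in the data section (undeclared label, index range, ...)."""


@dataclass(frozen=True)
class AttributeSchema:
    name: str
    kind: str  # "numeric" | "nominal"
    levels: tuple[str, ...] = ()


class Dataset:
    """In-memory tabular dataset with typed attributes and a class column.

    Parameters
    ----------
    name : str
        Relation name (round-tripped through ARFF ``@relation``).
    attributes : sequence of AttributeSchema
        Ordered attribute declarations; names must be unique.
    columns : sequence of arrays
        One array per attribute: float64 (NaN = missing) for numeric,
        integer level codes (-1 = missing) for nominal.
    class_index : int
        Position of the class attribute; may be negative (Python style).
    """

    def __init__(self, name, attributes, columns, class_index=-1):
        attributes = tuple(attributes)
        names = [a.name for a in attributes]
        if len(set(names)) != len(names):
            raise DatasetError("attribute names must be unique")
        for a in attributes:
            if a.kind not in ("numeric", "nominal"):
                raise DatasetError(f"unsupported attribute kind {a.kind!r}")
            if a.kind == "nominal":
                if not a.levels:
                    raise DatasetError(f"nominal attribute {a.name!r} has no levels")
                if len(set(a.levels)) != len(a.levels):
                    raise DatasetError(f"nominal attribute {a.name!r} has duplicate levels")
        if len(columns) != len(attributes):
            raise DatasetError("column count does not match attribute count")
        cols = []
        n_rows = None
        for a, c in zip(attributes, columns):
            arr = np.asarray(c, dtype=np.float64 if a.kind == "numeric" else np.int64)
            if arr.ndim != 1:
                raise DatasetError("columns must be one-dimensional")
            if n_rows is None:
                n_rows = len(arr)
            elif len(arr) != n_rows:
                raise DatasetError("columns have unequal lengths")
            if a.kind == "nominal" and len(arr) and (
                arr.max(initial=-1) >= len(a.levels) or arr.min(initial=0) < -1
            ):
                raise DatasetError(
                    f"nominal column {a.name!r} contains out-of-range codes"
                )
            cols.append(arr)
        class_index = range(len(attributes))[class_index]
        if attributes[class_index].kind != "nominal":
            raise DatasetError("class attribute must be nominal")
        self.name = name
        self.attributes = attributes
        self.columns = cols
        self.class_index = class_index
        self._features = None

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return 0 if not self.columns else len(self.columns[0])

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def class_attribute(self) -> AttributeSchema:
        return self.attributes[self.class_index]

    @property
    def class_levels(self) -> tuple[str, ...]:
        return self.class_attribute.levels

    @property
    def y(self) -> np.ndarray:
        """Class codes per row (-1 = missing)."""
        return self.columns[self.class_index]

    def features(self):
        """Cached (numeric matrix, nominal code matrix, numeric idx, nominal idx).

        The class column is excluded.  Matrices are n_rows x p; missing is
        NaN (numeric) or -1 (nominal).
        """
        if self._features is None:
            num_idx = [
                i
                for i, a in enumerate(self.attributes)
                if a.kind == "numeric" and i != self.class_index
            ]
            nom_idx = [
                i
                for i, a in enumerate(self.attributes)
                if a.kind == "nominal" and i != self.class_index
            ]
            x_num = (
                np.column_stack([self.columns[i] for i in num_idx])
                if num_idx
                else np.empty((self.n_rows, 0))
            )
            x_nom = (
                np.column_stack([self.columns[i] for i in nom_idx])
                if nom_idx
                else np.empty((self.n_rows, 0), dtype=np.int64)
            )
            self._features = (x_num, x_nom, num_idx, nom_idx)
        return self._features

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        if (
            self.name != other.name
            or self.attributes != other.attributes
            or self.class_index != other.class_index
        ):
            return False
        return all(
            np.array_equal(a, b, equal_nan=(a.dtype.kind == "f"))
            for a, b in zip(self.columns, other.columns)
        )

    def __repr__(self):
        return (
            f"<Dataset {self.name!r}: {self.n_rows} rows x "
            f"{self.n_attributes} attributes, class={self.class_attribute.name!r}>"
        )


# --------------------------------------------------------------------------
# ARFF


def _unquote(token: str) -> str:
    t = token.strip()
    if len(t) >= 2 and t[0] == t[-1] and t[0] in "'\"":
        return t[1:-1]
    return t


def _quote_if_needed(text: str) -> str:
    if text == "" or re.search(r"[\s,{}%?']", text):
        return "'" + text.replace("'", r"\'") + "'"
    return text


def _split_csv_like(line: str) -> list[str]:
    if "'" not in line and '"' not in line:
        return line.split(",")
    return next(csv.reader([line], skipinitialspace=True, quotechar="'"))


_ATTR_RE = re.compile(
    r"^@attribute\s+(?P<name>'[^']*'|\"[^\"]*\"|\S+)\s+(?P<type>.+)$",
    re.IGNORECASE,
)


def _resolve_class_index(attributes, class_attribute):
    if class_attribute == "last":
        return len(attributes) - 1
    for i, a in enumerate(attributes):
        if a.name == class_attribute:
            return i
    raise DatasetError(f"class attribute {class_attribute!r} not found")


def read_arff(stream, class_attribute: str = "last") -> Dataset:
    """Read an ARFF document (dense or sparse rows) into a Dataset.

    ``stream`` may be a file-like object or the document text itself.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    name = None
    attributes: list[AttributeSchema] = []
    level_maps: list[dict[str, int] | None] = []
    in_data = False

    # accumulated per-column cell lists
    cols: list[list] = []
    lineno = 0
    for raw in stream:
        lineno += 1
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if not in_data:
            low = line.lower()
            if low.startswith("@relation"):
                name = _unquote(line[len("@relation"):].strip())
            elif low.startswith("@attribute"):
                m = _ATTR_RE.match(line)
                if not m:
                    raise FormatError(f"line {lineno}: malformed @attribute")
                attr_name = _unquote(m.group("name"))
                type_text = m.group("type").strip()
                low_type = type_text.lower()
                if low_type in ("numeric", "real", "integer"):
                    attributes.append(AttributeSchema(attr_name, "numeric"))
                    level_maps.append(None)
                elif type_text.startswith("{") and type_text.endswith("}"):
                    levels = tuple(
                        _unquote(t) for t in _split_csv_like(type_text[1:-1])
                    )
                    attributes.append(
                        AttributeSchema(attr_name, "nominal", levels)
                    )
                    level_maps.append({lv: i for i, lv in enumerate(levels)})
                elif low_type.startswith(("string", "date", "relational")):
                    raise FormatError(
                        f"line {lineno}: attribute type "
                        f"{low_type.split()[0]!r} is not supported "
                        "(only numeric and nominal)"
                    )
                else:
                    raise FormatError(
                        f"line {lineno}: unrecognised attribute type {type_text!r}"
                    )
            elif low.startswith("@data"):
                if not attributes:
                    raise FormatError(
                        f"line {lineno}: @data before any @attribute"
                    )
                in_data = True
                cols = [[] for _ in attributes]
            else:
                raise FormatError(f"line {lineno}: unexpected header line")
            continue

        # data section
        if line.startswith("{"):
            if not line.endswith("}"):
                raise DataError(f"line {lineno}: unterminated sparse row")
            row = [
                0.0 if a.kind == "numeric" else 0 for a in attributes
            ]
            body = line[1:-1].strip()
            entries = _split_csv_like(body) if body else []
            for entry in entries:
                entry = entry.strip()
                if not entry:
                    continue
                try:
                    idx_text, value_text = entry.split(None, 1)
                    idx = int(idx_text)
                except ValueError:
                    raise DataError(
                        f"line {lineno}: malformed sparse entry {entry!r}"
                    ) from None
                if not 0 <= idx < len(attributes):
                    raise DataError(
                        f"line {lineno}: sparse index {idx} out of range "
                        f"(dataset has {len(attributes)} attributes)"
                    )
                row[idx] = _parse_cell(
                    value_text, attributes[idx], level_maps[idx], lineno
                )
            for c, v in zip(cols, row):
                c.append(v)
        else:
            tokens = _split_csv_like(line)
            if len(tokens) != len(attributes):
                raise DataError(
                    f"line {lineno}: expected {len(attributes)} values, "
                    f"got {len(tokens)}"
                )
            for c, tok, a, lm in zip(cols, tokens, attributes, level_maps):
                c.append(_parse_cell(tok, a, lm, lineno))

    if not in_data:
        raise FormatError("no @data section found")

    columns = [
        np.asarray(c, dtype=np.float64 if a.kind == "numeric" else np.int64)
        if c
        else np.empty(0, dtype=np.float64 if a.kind == "numeric" else np.int64)
        for a, c in zip(attributes, cols)
    ]
    return Dataset(
        name or "unnamed",
        attributes,
        columns,
        _resolve_class_index(attributes, class_attribute),
    )


def _parse_cell(token, attr, level_map, lineno):
    t = token.strip()
    if t == "?":
        return np.nan if attr.kind == "numeric" else -1
    t = _unquote(t)
    if attr.kind == "numeric":
        try:
            return float(t)
        except ValueError:
            raise DataError(
                f"line {lineno}: non-numeric value {t!r} for numeric "
                f"attribute {attr.name!r}"
            ) from None
    code = level_map.get(t)
    if code is None:
        raise DataError(
            f"line {lineno}: undeclared label {t!r} for nominal "
            f"attribute {attr.name!r}"
        )
    return code


def _format_numeric(v: float) -> str:
    if np.isnan(v):
        return "?"
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def write_arff(dataset: Dataset, sparse: bool = False) -> str:
    """Serialise a Dataset to ARFF text; ``sparse=True`` emits sparse rows."""
    out: list[str] = []
    out.append(f"@relation {_quote_if_needed(dataset.name)}")
    for a in dataset.attributes:
        if a.kind == "numeric":
            out.append(f"@attribute {_quote_if_needed(a.name)} numeric")
        else:
            levels = ",".join(_quote_if_needed(lv) for lv in a.levels)
            out.append(f"@attribute {_quote_if_needed(a.name)} {{{levels}}}")
    out.append("@data")

    attrs = dataset.attributes
    cols = dataset.columns
    n = dataset.n_rows
    if sparse:
        for i in range(n):
            entries = []
            for j, (a, c) in enumerate(zip(attrs, cols)):
                v = c[i]
                if a.kind == "numeric":
                    if np.isnan(v):
                        entries.append(f"{j} ?")
                    elif v != 0.0:
                        entries.append(f"{j} {_format_numeric(v)}")
                else:
                    if v == -1:
                        entries.append(f"{j} ?")
                    elif v != 0:
                        entries.append(f"{j} {_quote_if_needed(a.levels[v])}")
            out.append("{" + ",".join(entries) + "}")
    else:
        # pre-render columns token-wise, then join row-wise (fast for wide data)
        rendered = []
        for a, c in zip(attrs, cols):
            if a.kind == "numeric":
                rendered.append([_format_numeric(v) for v in c])
            else:
                labels = ["?"] + [_quote_if_needed(lv) for lv in a.levels]
                rendered.append([labels[v + 1] for v in c])
        for i in range(n):
            out.append(",".join(col[i] for col in rendered))
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# CSV


def read_csv(stream, class_attribute: str = "last") -> Dataset:
    """Read a headered CSV into a Dataset.

    A column is numeric iff every non-missing cell parses as a number;
    otherwise it is nominal, with levels in order of first appearance.
    Empty cells and ``?`` are missing.  The class column is always
    treated as nominal (class labels are labels even when they look like
    numbers).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty CSV: no header row") from None
    n_cols = len(header)
    raw_cols: list[list[str]] = [[] for _ in header]
    for rownum, row in enumerate(reader, start=2):
        if len(row) != n_cols:
            raise FormatError(
                f"row {rownum}: expected {n_cols} fields, got {len(row)}"
            )
        for c, tok in zip(raw_cols, row):
            c.append(tok)

    class_index = (
        n_cols - 1
        if class_attribute == "last"
        else next(
            (i for i, h in enumerate(header) if h == class_attribute), None
        )
    )
    if class_index is None:
        raise DatasetError(f"class attribute {class_attribute!r} not found")

    attributes: list[AttributeSchema] = []
    columns: list[np.ndarray] = []
    for i, (attr_name, raw) in enumerate(zip(header, raw_cols)):
        missing = [t == "" or t.strip() == "?" for t in raw]
        non_missing = [t for t, m in zip(raw, missing) if not m]
        numeric = i != class_index and all(
            _NUMERIC_RE.match(t.strip()) for t in non_missing
        )
        if numeric:
            attributes.append(AttributeSchema(attr_name, "numeric"))
            columns.append(
                np.array(
                    [np.nan if m else float(t) for t, m in zip(raw, missing)]
                )
            )
        else:
            levels: list[str] = []
            seen: dict[str, int] = {}
            codes = np.empty(len(raw), dtype=np.int64)
            for r, (t, m) in enumerate(zip(raw, missing)):
                if m:
                    codes[r] = -1
                    continue
                t = t.strip()
                if t not in seen:
                    seen[t] = len(levels)
                    levels.append(t)
                codes[r] = seen[t]
            if not levels:
                # degenerate (0 rows or all-missing): placeholder level so the
                # schema stays well-formed
                levels = ["none"]
            attributes.append(AttributeSchema(attr_name, "nominal", tuple(levels)))
            columns.append(codes)
    return Dataset("csv", attributes, columns, class_index)


def write_csv(dataset: Dataset) -> str:
    """Serialise to headered CSV (missing cells written as empty)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([a.name for a in dataset.attributes])
    rendered = []
    for a, c in zip(dataset.attributes, dataset.columns):
        if a.kind == "numeric":
            rendered.append(["" if np.isnan(v) else _format_numeric(v) for v in c])
        else:
            labels = [""] + list(a.levels)
            rendered.append([labels[v + 1] for v in c])
    for i in range(dataset.n_rows):
        writer.writerow([col[i] for col in rendered])
    return buf.getvalue()


def load_dataset(path, class_attribute: str = "last") -> Dataset:
    """Load ARFF or CSV by file extension."""
    p = str(path)
    with open(p, "r", encoding="utf-8") as fh:
        if p.lower().endswith(".csv"):
            return read_csv(fh, class_attribute)
        return read_arff(fh, class_attribute)


# --------------------------------------------------------------------------
# synthetic fixtures


def make_synthetic(
    n_samples: int,
    n_numeric: int = 10,
    n_nominal: int = 0,
    n_classes: int = 2,
    class_sep: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    name: str = "synthetic",
) -> Dataset:
    """Generate a classification dataset with controllable structure.

    Numeric attributes are class-conditional unit-variance Gaussians.
    Class 0 sits at the origin; class ``c`` (c >= 1) is displaced by
    ``class_sep`` along axis ``c-1``, using the first
    ``min(n_numeric, n_classes - 1)`` axes, so every pair of class means
    is at least ``class_sep`` apart.  Nominal attributes are uniform over
    three levels and independent of the class (pure noise).  Each feature
    cell is masked missing independently with probability
    ``missing_rate``.  Fully determined by ``seed``.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_samples < n_classes:
        raise ValueError("n_samples must be >= n_classes")
    if n_numeric < 0 or n_nominal < 0:
        raise ValueError("attribute counts must be non-negative")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if class_sep < 0:
        raise ValueError("class_sep must be non-negative")

    rng = np.random.default_rng(seed)

    # near-balanced labels, shuffled
    base = n_samples // n_classes
    counts = [base + (1 if c < n_samples % n_classes else 0) for c in range(n_classes)]
    y = np.repeat(np.arange(n_classes), counts)
    rng.shuffle(y)

    d = min(n_numeric, n_classes - 1)
    x = rng.standard_normal((n_samples, n_numeric)) if n_numeric else np.empty((n_samples, 0))
    for axis in range(d):
        x[y == axis + 1, axis] += class_sep

    nom = (
        rng.integers(0, 3, size=(n_samples, n_nominal))
        if n_nominal
        else np.empty((n_samples, 0), dtype=np.int64)
    )

    if missing_rate > 0:
        if n_numeric:
            x[rng.random((n_samples, n_numeric)) < missing_rate] = np.nan
        if n_nominal:
            nom[rng.random((n_samples, n_nominal)) < missing_rate] = -1

    attributes = [AttributeSchema(f"x{j}", "numeric") for j in range(n_numeric)]
    attributes += [
        AttributeSchema(f"g{j}", "nominal", ("a", "b", "c"))
        for j in range(n_nominal)
    ]
    attributes.append(
        AttributeSchema("class", "nominal", tuple(f"c{c}" for c in range(n_classes)))
    )
    columns = [x[:, j] for j in range(n_numeric)]
    columns += [nom[:, j] for j in range(n_nominal)]
    columns.append(y.astype(np.int64))
    return Dataset(name, attributes, columns, len(attributes) - 1)
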