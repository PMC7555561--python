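"""Reading, writing and recoding of item-response data.

Response matrices travel as CSV/TSV with a header row of item labels and
integer category codes in the cells.  For multiple-choice data with original
option codes, :func:`recode_by_distractor_frequency` produces the polytomous
coding in which category 0 is the correct option and categories 1..K_i are
the distractors ordered from most to least attractive (frequent), and
:func:`dichotomize` the binary correct/incorrect coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lcm import ResponseMatrix

__all__ = [
    "RawChoiceData",
    "read_responses",
    "write_responses",
    "read_key",
    "recode_by_distractor_frequency",
    "dichotomize",
]


@dataclass
class RawChoiceData:
    """Multiple-choice responses in their original option coding.

    ``responses[n, i]`` is the option code person ``n`` chose on item
    ``i``; ``key[i]`` the correct option.  ``option_codes`` optionally
    declares the full option set per item, so distractors nobody chose
    still get a category in the recoding.
    """

    responses: np.ndarray
    key: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    option_codes: Optional[list[Sequence[int]]] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.key = np.asarray(self.key, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if self.key.shape[0] != self.responses.shape[1]:
            raise ValueError("key length must equal number of items")
        if np.any(self.responses < 1) or np.any(self.key < 1):
            raise ValueError("option codes must be positive integers")
        if not self.item_labels:
            self.item_labels = [f"I{i + 1}" for i in range(self.responses.shape[1])]
        if self.option_codes is not None:
            for i, opts in enumerate(self.option_codes):
                if self.key[i] not in opts:
                    raise ValueError(f"item {i}: key {self.key[i]} not among options")

    @property
    def I(self) -> int:
        return self.responses.shape[1]


def _read_table(path, fmt: Optional[str]) -> pd.DataFrame:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError("format must be 'csv' or 'tsv'")
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_responses(path, fmt: Optional[str] = None) -> ResponseMatrix:
    """Read a wide-format response matrix (header = item labels).

    Cells must be integer categories; missing or non-integer cells raise
    a descriptive error naming the offending row and column.
    """
    df = _read_table(path, fmt)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty response table")
    for col in df.columns:
        s = df[col]
        if s.isna().any():
            row = int(s.isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        vals = pd.to_numeric(s, errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell {s[row]!r} at row {row}, column {col!r}"
            )
        if not np.all(vals == vals.astype(np.int64)):
            row = int(np.argmax(vals != vals.astype(np.int64)))
            raise ValueError(
                f"{path}: non-integer cell {s[row]!r} at row {row}, column {col!r}"
            )
    data = df.to_numpy(dtype=np.int64)
    if data.min() < 0:
        n, i = np.unravel_index(int(np.argmin(data)), data.shape)
        raise ValueError(
            f"{path}: negative category at row {n}, column {df.columns[i]!r}"
        )
    return ResponseMatrix.from_array(data, item_labels=list(df.columns))


def write_responses(data: ResponseMatrix, path, fmt: Optional[str] = None) -> None:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = "," if fmt == "csv" else "\t"
    pd.DataFrame(data.data, columns=data.item_labels).to_csv(path, sep=sep, index=False)


def read_key(path, fmt: Optional[str] = None) -> np.ndarray:
    """Read an answer key: one row (or column) of correct option codes."""
    df = _read_table(path, fmt)
    arr = df.to_numpy()
    return np.asarray(arr, dtype=np.int64).ravel()


def recode_by_distractor_frequency(raw: RawChoiceData):
    """Recode options by attractiveness: correct -> 0, distractors by frequency.

    Per item, the correct option becomes category 0 and the distractors
    categories 1..K_i in non-increasing order of their observed frequency
    (category 1 = most attractive distractor).  Frequency ties are broken
    by ascending original option code; declared-but-unobserved options
    receive the highest categories with frequency 0.

    Returns
    -------
    (ResponseMatrix, pandas.DataFrame)
        The recoded matrix and the per-item mapping table with columns
        ``item, category, original_code, count, percent``.
    """
    N, I = raw.responses.shape
    out = np.zeros((N, I), dtype=np.int64)
    rows = []
    ncats = []
    for i in range(I):
        col = raw.responses[:, i]
        key = int(raw.key[i])
        observed = set(int(v) for v in np.unique(col))
        declared = set(int(v) for v in (raw.option_codes[i] if raw.option_codes else []))
        options = sorted(observed | declared | {key})
        counts = {o: int((col == o).sum()) for o in options}
        distractors = [o for o in options if o != key]
        # stable sort: frequency descending, ties by ascending original code
        distractors.sort(key=lambda o: (-counts[o], o))
        mapping = {key: 0}
        for k, o in enumerate(distractors, start=1):
            mapping[o] = k
        lut = np.zeros(max(options) + 1, dtype=np.int64)
        for o, k in mapping.items():
            lut[o] = k
        out[:, i] = lut[col]
        for o, k in sorted(mapping.items(), key=lambda kv: kv[1]):
            rows.append([raw.item_labels[i], k, o, counts[o], 100.0 * counts[o] / N])
        ncats.append(len(options))
    mapping_df = pd.DataFrame(
        rows, columns=["item", "category", "original_code", "count", "percent"]
    )
    rm = ResponseMatrix(out, ncats, list(raw.item_labels))
    return rm, mapping_df


def dichotomize(raw: RawChoiceData) -> ResponseMatrix:
    """Score responses binary: 1 = correct option chosen, 0 = any distractor."""
    data = (raw.responses == raw.key[None, :]).astype(np.int64)
    return ResponseMatrix(data, [2] * raw.I, list(raw.item_labels))
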