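"""Balanced agreement datasets: containers, validation, I/O and summaries.

A LOAM analysis works on a *balanced* crossed design: ``a`` subjects each
measured by the same ``b`` observers, ``c`` times per (subject, observer)
cell.  Everything downstream (sums of squares, variance components,
confidence intervals) assumes this balance, so it is enforced hard at
construction time rather than warned about.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgreementData",
    "BalanceError",
    "ColumnMapError",
    "ValueParseError",
    "read_agreement_table",
    "summarize_by_observer",
    "summarize_by_subject",
]


class BalanceError(ValueError):
    """The table is not a balanced subject x observer (x replicate) design."""


class ColumnMapError(KeyError):
    """A mapped column is missing from the input table."""


class ValueParseError(ValueError):
    """A measurement value could not be parsed as a finite number."""


@dataclass(frozen=True)
class AgreementData:
    """Measurements on a balanced crossed design.

    Parameters
    ----------
    values
        Array of shape ``(a, b, c)``: axis 0 indexes subjects, axis 1
        observers, axis 2 replicates within a (subject, observer) cell.
        Replicates are exchangeable; their order carries no meaning.
    subject_ids, observer_ids
        Distinct labels for the first two axes.
    unit
        Free-text measurement unit used for axis labels and reports.
    """

    values: np.ndarray
    subject_ids: tuple = ()
    observer_ids: tuple = ()
    unit: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError(f"values must be (a, b) or (a, b, c); got shape {v.shape}")
        a, b, c = v.shape
        if a < 2 or b < 2 or c < 1:
            raise BalanceError(
                f"need at least 2 subjects, 2 observers and 1 replicate; got a={a}, b={b}, c={c}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueParseError("all measurement values must be finite")
        object.__setattr__(self, "values", v)
        subj = tuple(self.subject_ids) or tuple(range(1, a + 1))
        obs = tuple(self.observer_ids) or tuple(range(1, b + 1))
        if len(subj) != a or len(set(subj)) != a:
            raise ValueError(f"need {a} unique subject labels, got {subj!r}")
        if len(obs) != b or len(set(obs)) != b:
            raise ValueError(f"need {b} unique observer labels, got {obs!r}")
        object.__setattr__(self, "subject_ids", subj)
        object.__setattr__(self, "observer_ids", obs)

    @property
    def a(self) -> int:
        return self.values.shape[0]

    @property
    def b(self) -> int:
        return self.values.shape[1]

    @property
    def c(self) -> int:
        return self.values.shape[2]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_measurements(self) -> int:
        return self.values.size

    def grand_mean(self) -> float:
        return float(self.values.mean())

    def subject_means(self) -> np.ndarray:
        """Mean over all b*c measurements of each subject."""
        return self.values.mean(axis=(1, 2))

    def observer_means(self) -> np.ndarray:
        """Mean over all a*c measurements of each observer."""
        return self.values.mean(axis=(0, 2))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per measurement."""
        a, b, c = self.dims
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subject_ids, b * c),
                "observer": np.tile(np.repeat(self.observer_ids, c), a),
                "replicate": np.tile(np.arange(1, c + 1), a * b),
                "value": self.values.ravel(),
            }
        )

    def write_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def read_agreement_table(
    source,
    column_map: Mapping[str, str] | Sequence[str] | None = None,
    unit: str = "",
) -> AgreementData:
    """Read a long-format delimited table into :class:`AgreementData`.

    Parameters
    ----------
    source
        Path or text stream of a delimited file with a header row.
        Delimiter is auto-detected among comma, tab and semicolon.
    column_map
        Mapping with keys ``subject``, ``observer``, ``value`` and
        optionally ``replicate``, naming the corresponding columns; or a
        sequence ``(subject, observer, value[, replicate])``.  Defaults to
        those literal column names.  When no replicate column is mapped,
        replicate indices are synthesized from order of appearance within
        each (subject, observer) cell.
    unit
        Measurement unit recorded on the result.

    Raises
    ------
    ColumnMapError
        If a mapped column is absent.
    ValueParseError
        If a value is non-numeric or non-finite (the row is named).
    BalanceError
        If any (subject, observer) cell has a deviant number of values,
        or a (subject, observer, replicate) triple is duplicated.
    """
    if column_map is None:
        column_map = {"subject": "subject", "observer": "observer", "value": "value"}
    elif not isinstance(column_map, Mapping):
        names = list(column_map)
        keys = ["subject", "observer", "value", "replicate"][: len(names)]
        column_map = dict(zip(keys, names))

    df = pd.read_csv(source, sep=None, engine="python")
    for role in ("subject", "observer", "value"):
        col = column_map.get(role)
        if col is None:
            raise ColumnMapError(f"column_map must name a '{role}' column")
        if col not in df.columns:
            raise ColumnMapError(
                f"'{role}' column {col!r} not found; available: {list(df.columns)}"
            )

    raw = df[column_map["value"]]
    vals = pd.to_numeric(raw, errors="coerce").astype(float)
    bad = ~np.isfinite(vals.to_numpy())
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueParseError(
            f"non-numeric or non-finite value {raw.iloc[row]!r} in row {row + 2} "
            f"(column {column_map['value']!r})"
        )

    work = pd.DataFrame(
        {
            "subject": df[column_map["subject"]],
            "observer": df[column_map["observer"]],
            "value": vals,
        }
    )
    rep_col = column_map.get("replicate")
    if rep_col is not None:
        if rep_col not in df.columns:
            raise ColumnMapError(f"'replicate' column {rep_col!r} not found")
        work["replicate"] = df[rep_col]
        dup = work.duplicated(["subject", "observer", "replicate"])
        if dup.any():
            s, o, r = work.loc[dup.idxmax(), ["subject", "observer", "replicate"]]
            raise BalanceError(
                f"duplicate (subject, observer, replicate) triple ({s!r}, {o!r}, {r!r})"
            )
    else:
        work["replicate"] = work.groupby(["subject", "observer"], sort=False).cumcount() + 1

    subjects = list(dict.fromkeys(work["subject"]))
    observers = list(dict.fromkeys(work["observer"]))
    counts = work.groupby(["subject", "observer"], sort=False).size()
    c = int(counts.iloc[0])
    if len(counts) != len(subjects) * len(observers) or (counts != c).any():
        expected = pd.MultiIndex.from_product([subjects, observers])
        full = counts.reindex(expected, fill_value=0)
        s, o = full.index[int(np.argmin(full == c))]
        raise BalanceError(
            f"unbalanced design: cell (subject {s!r}, observer {o!r}) has "
            f"{int(full.loc[(s, o)])} values, expected {c}"
        )

    a, b = len(subjects), len(observers)
    si = {s: i for i, s in enumerate(subjects)}
    oi = {o: j for j, o in enumerate(observers)}
    values = np.empty((a, b, c))
    # replicate labels are provenance only; within-cell order is whatever the file gave
    work["_k"] = work.groupby(["subject", "observer"], sort=False).cumcount()
    values[
        work["subject"].map(si).to_numpy(),
        work["observer"].map(oi).to_numpy(),
        work["_k"].to_numpy(),
    ] = work["value"].to_numpy()
    return AgreementData(values, tuple(subjects), tuple(observers), unit=unit)


def summarize_by_observer(data: AgreementData) -> pd.DataFrame:
    """Empirical mean and sample SD of each observer's a*c measurements."""
    flat = data.values.transpose(1, 0, 2).reshape(data.b, -1)
    return pd.DataFrame(
        {
            "observer": data.observer_ids,
            "mean": flat.mean(axis=1),
            "sd": flat.std(axis=1, ddof=1),
        }
    )


def summarize_by_subject(data: AgreementData) -> pd.DataFrame:
    """Empirical mean and sample SD of each subject's b*c measurements."""
    flat = data.values.reshape(data.a, -1)
    return pd.DataFrame(
        {
            "subject": data.subject_ids,
            "mean": flat.mean(axis=1),
            "sd": flat.std(axis=1, ddof=1),
        }
    )
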