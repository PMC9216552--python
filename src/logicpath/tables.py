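"""Tabular I/O for test cases and rating matrices (plain TSV, UTF-8)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .logic_network import Direction, OutcomeClass, TestCase, ValidationError
from .evaluation import RatingMatrix

__all__ = ["cases_to_frame", "frame_to_cases", "read_cases", "write_cases",
           "read_ratings"]

_CASE_COLUMNS = ["root_input", "direction", "key_output",
                 "predicted_class", "observed_class", "pathway"]


def _cls(value) -> OutcomeClass | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"na", "nan", "none", ""}:
        return None
    return OutcomeClass(text.lower())


def cases_to_frame(cases: list[TestCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        rows.append({
            "root_input": c.root_input,
            "direction": c.direction.value,
            "key_output": c.key_output,
            "predicted_class": c.predicted_class.value if c.predicted_class else "",
            "observed_class": c.observed_class.value if c.observed_class else "",
            "pathway": c.pathway or "",
        })
    return pd.DataFrame(rows, columns=_CASE_COLUMNS)


def frame_to_cases(df: pd.DataFrame) -> list[TestCase]:
    for col in ("root_input", "direction", "key_output"):
        if col not in df.columns:
            raise ValidationError(f"case table missing column {col!r}")
    cases = []
    for _, row in df.iterrows():
        cases.append(TestCase(
            root_input=str(row["root_input"]),
            direction=Direction(str(row["direction"]).strip().lower()),
            key_output=str(row["key_output"]),
            predicted_class=_cls(row.get("predicted_class")),
            observed_class=_cls(row.get("observed_class")),
            pathway=(str(row["pathway"]) if "pathway" in df.columns
                     and str(row.get("pathway", "")).strip() else None),
        ))
    return cases


def read_cases(path: str | Path) -> list[TestCase]:
    return frame_to_cases(pd.read_csv(path, sep="\t", dtype=str,
                                      comment="#", keep_default_na=False))


def write_cases(cases: list[TestCase], path: str | Path) -> None:
    cases_to_frame(cases).to_csv(path, sep="\t", index=False)


def read_ratings(path: str | Path) -> RatingMatrix:
    """Read a ratings TSV: one row per case, one column per rater (an
    optional leading ``case_id`` column is ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c for c in df.columns if c.lower() not in {"case_id", "case"}]
    if len(cols) < 2:
        raise ValidationError("ratings table needs at least 2 rater columns")
    labels = [[OutcomeClass(str(v).strip().lower()) for v in row]
              for row in df[cols].itertuples(index=False)]
    return RatingMatrix(labels=labels)
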